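# ssrexp

Mining simple sequence repeats (SSRs, microsatellites) from a
transcriptome and detecting **expression-modulating motifs**: motif ×
transcribed-region combinations whose repeat content is statistically
associated with a gene's expression capacity or tissue specificity.

SSRs — tandem repeats of 1–6 bp units — are thought to act as "tuning
knobs" of gene expression, with effects that depend on the repeat unit,
the transcribed region it sits in (5'-UTR, CDS, 3'-UTR), and its
abundance, density and tract length. `ssrexp` implements the full
statistical pipeline to probe this from a transcript FASTA, a CDS
coordinate table and a TPM expression matrix — no genome or read-level
data required — plus a synthetic-data generator with planted ground
truth so every stage can be validated end to end.

## The method

1. **Mining** (`ssrexp.miner`). Perfect (uninterrupted) repeats of
   primitive 1–6 bp units, at MISA-convention minimum repeat counts
   (15, 8, 5, 4, 3, 3 for mono- through hexanucleotides). Maximal runs,
   truncated trailing units, runs broken at `N`. Adjacent records form
   compound SSRs. Each actual motif *m* (as read on the transcript
   strand) is folded into its standardized class: the lexicographically
   smallest string over all rotations of *m* and of its reverse
   complement (so GA, CT and TC all belong to class AG).
2. **Region mapping** (`ssrexp.regions`). Full containment in 5'-UTR /
   CDS / 3'-UTR from the CDS interval; junction-straddling SSRs go to
   boundary categories and are excluded from region statistics; lncRNAs
   are their own category. The relative position of an SSR inside its
   region is `(start − region_start + 1) / region_length` ∈ (0, 1].
3. **Expression profiling** (`ssrexp.expression`). Per transcript,
   TPM_max = max over organs (expression capacity) and TPM_CV = sample
   coefficient of variation (tissue specificity; √n for a transcript
   expressed in one of n organs, hence the 3.4641 cut for 12 organs).
   Both are binned into 5 levels (cuts 1/10/100/1000 and
   0.5/1/1.5/3.4641; level 1 = highest).
4. **Association statistics** (`ssrexp.stats`). Densities (SSRs/Mb),
   frequencies, motif-type tallies; Pearson chi-squared with per-cell
   adjusted standardized residuals to localize motif–region enrichment;
   Kruskal–Wallis + Dunn post hoc (BH-adjusted) contrasts of expression
   between single-region SSR carriers and SSR-free genes; Kendall
   tau-b.
5. **expMotif detection** (`ssrexp.detector`). A two-stage cascade per
   motif × region × response (lnTPM_max, lnTPM_CV): (i) Mann–Whitney
   carrier-vs-noncarrier screen (raw p < 0.05), with Kruskal–Wallis
   across regions for widespread motifs; (ii) a regression suite —
   polynomial fits of degree 1–3 on each SSR characteristic (abundance,
   density, tract length) plus additive bivariate fits screened by VIF —
   with BIC model selection and an overfit guard. A motif is *called*
   only when both stages are significant. Standardized classes are
   tested first, then actual strand-specific motifs (> 10 carriers) of
   candidate classes. Relative positions of called motifs are profiled
   with a boundary-reflected Gaussian KDE per expression level.

## Worked example

Mining one sequence:

```python
>>> from ssrexp.miner import find_perfect_ssrs
>>> for r in find_perfect_ssrs("CCTG" + "AG" * 9 + "TTACG" + "A" * 16 + "GC"):
...     print(r.motif, r.canonical_motif, r.start, r.end, r.repeat_count)
GA AG 4 21 9
A A 28 43 16
```

Note the first record: the run is read as **GA** ×9 starting at the G of
"CCTG" (maximality), and standardizes to class **AG**. Actual and
canonical motifs are kept separate throughout because strand-specific
effects differ.

Survey arithmetic works on plain counts — e.g. 48 295 SSRs found in
63 940 sequences totalling 194 653 584 bp:

```python
>>> from ssrexp.stats import density, frequency_pct
>>> round(density(48_295, 194_653_584), 2), round(frequency_pct(48_295, 63_940), 2)
(248.11, 75.53)
```

A full synthetic run from the shell:

```bash
$ cat sim.yaml
seed: 11
simulate:
  n_transcripts: 120
  coding_fraction: 0.85
  lncrna_fraction: 0.05
  ssr_plants:
    - {motif: AG, region: 5UTR, probability: 0.5, min_repeats: 8, max_repeats: 12}
    - {motif: A, region: 3UTR, probability: 0.4, min_repeats: 15, max_repeats: 18}
  effects:
    - {motif: AG, region: 5UTR, characteristic: density, beta: 0.004}
$ ssrexp run --config sim.yaml --out run1
run complete: 15 outputs in run1
```

`run1/` then contains every stage table. The planted effect — ln(TPM_max)
rising by 0.004 per SSR/Mb of AG density in the 5'-UTR — is recovered in
`calls_standardized.tsv`:

```
motif region   response    primary_p best_form best_predictors  best_r_squared
   AG   5UTR ln_tpm_max 2.227920e-09    linear         density        0.090071
```

i.e. the Mann–Whitney screen flags AG/5'-UTR carriers (p ≈ 2 × 10⁻⁹), and
the BIC-optimal regression is linear in density, explaining ~9% of the
variance in ln(TPM_max) among carriers — a subtle but significant effect,
which is the regime the cascade is built for. `summary_regions.tsv`
reports the per-region density bookkeeping for the same run (e.g. 51
SSRs in 27 948 bp of 5'-UTR → 1824.82 /Mb).

Subcommands `simulate`, `mine`, `map`, `profile`, `stats` and `detect`
run the stages separately; `ssrexp <cmd> --help` lists their options.

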