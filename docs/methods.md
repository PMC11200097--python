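# Methods

This note records the models, conventions and design choices behind
`ssrexp`, in the order of the pipeline.

## SSR mining

A perfect SSR is a maximal uninterrupted run of a primitive 1–6 bp unit
meeting a per-size minimum repeat count (defaults 15, 8, 5, 4, 3, 3 —
the MISA-style criteria common in transcriptome surveys; configurable
via `MinerCriteria`). Conventions:

- Coordinates are 1-based inclusive on the transcript. This matches the
  "+ 1" in the relative-position formula below.
- A trailing partial unit is truncated: `tract_length =
  motif_size × repeat_count` exactly, with `repeat_count` the floor of
  run length / unit size.
- A run is reported once, at the smallest primitive unit that meets its
  minimum. Primitivity (the unit is not a whole-number repetition of a
  shorter string) prevents an AG-run from also being reported as AGAG.
- Runs are split at any `N` (perfect repeats only).
- Records of the *same* motif never overlap; records of different
  motifs may share a base (an A-run legitimately absorbs the leading A
  of a following AT-run). For compound detection the strict contract
  rejects overlapping input; the pipeline calls it with
  `on_overlap="chain"`, where a shared-base pair counts as adjacent —
  the same convention MISA uses when it marks overlapping repeats as
  compound.
- Compound SSRs are maximal chains of ≥ 2 records with inter-record gap
  ≤ `max_interruption_bp` (default 0: "no interrupting bases";
  MISA-interoperable value 100). Members stay in the flat SSR list.

The standardized class of a motif is the lexicographic minimum over all
rotations of the motif and all rotations of its reverse complement.
Exhaustive enumeration gives 2, 4, 10, 33, 102 and 350 classes for unit
sizes 1–6; both actual-motif and class tallies are reported, since the
two "motif type" counts differ.

The scanner is validated against an independently written brute-force
oracle (every start × unit size, explicit unit-copy comparison) on
seeded repeat-enriched 2 kb sequences and on arbitrary short strings via
property-based fuzzing.

## Region assignment

A CDS interval partitions a coding transcript into 5'-UTR / CDS /
3'-UTR. Assignment is by full containment; an SSR overlapping a
junction goes to a boundary category (5'UTR–CDS or CDS–3'UTR, the
5'-most junction winning if a record spans the whole CDS) and is
excluded from region-level statistics. lncRNAs are a category of their
own, with the whole transcript as the positional region; transcripts
with neither CDS nor lncRNA flag are "other" (no position defined).

Relative position of an SSR inside its region is
`(ssr_start − region_start + 1) / region_length`, read at the SSR's
*start* base — the only reading that keeps the value in (0, 1] for every
tract length (a midpoint variant would need separate clamping).

GC content is 100·(G+C)/(A+C+G+T), with `N` excluded from the
denominator. The background GC of an SSR is the GC of its host region
with *all* SSR tracts of that region excised, so repeat composition does
not contaminate the context estimate; a region fully covered by tracts
yields NaN rather than a fabricated value.

## Expression profiles

TPM_max is the maximum TPM over organs; TPM_CV is the sample
(n−1 denominator) coefficient of variation. The sample convention is
load-bearing: a transcript expressed in exactly one of n organs then has
CV = √n, which is what makes 3.4641 = √12 the natural "one-organ" cut
for a 12-organ panel. Both statistics are binned into five levels
(level 1 = highest) with default cuts 1/10/100/1000 (TPM_max) and
0.5/1/1.5/3.4641 (TPM_CV). Each level interval is closed at its lower
cut, so a value exactly at the top cut is level 1 — required for
one-organ transcripts to land in CV level 1; closure for interior levels
follows the same rule and is configurable in principle by supplying
different cuts. Transcripts never expressed (zero-mean TPM vector) are
dropped: their CV and ln(TPM_max) are undefined. The "expressed
everywhere" filter used by the region-differential contrast keeps
transcripts with every TPM strictly greater than 0.01.

## Association statistics

- Density is SSR count per Mb of *summed* sequence (not a per-sequence
  average), frequency is 100 × SSR count / sequence count, abundance is
  count per sequence. Summed-bp denominators make per-region densities
  additive: any aggregate density is recoverable from component counts
  and bp.
- Motif–region enrichment: Pearson chi-squared (no continuity
  correction) with per-cell adjusted standardized residuals
  `(obs − exp) / sqrt(exp (1 − row/N)(1 − col/N))`, approximately
  standard normal under independence (checked by simulation on Poisson
  tables).
- Group contrasts: Kruskal–Wallis with mid-rank tie correction, then
  Dunn's post hoc z tests with the usual tie term and
  Benjamini–Hochberg adjustment across pairs. Dunn's test is
  implemented in-package (z on rank means; verified against a
  hand-computed rank example) because no installed library provides it.
  One-sided Dunn tests (direction from the rank-mean ordering) are
  available where a directional letter display is wanted; two-sided is
  the default.
- An all-identical-values contrast returns p = 1 rather than erroring.
- Kendall tau-b (tie-corrected) for ordinal trends, checked against an
  O(n²) pair-counting oracle.
- The region-differential contrast compares TPM_max and TPM_CV across
  four groups — SSRs only in the 5'-UTR, only in the CDS, only in the
  3'-UTR, and SSR-free — among transcripts expressed in all organs.
  Transcripts with SSRs in more than one region are excluded entirely.
  Stratified variants (by motif size or class) skip any contrast with an
  empty group, with a warning.

## expMotif detection

Groups are built per motif × region over the three core regions:
carriers are transcripts holding ≥ 1 SSR of that motif there, with
per-carrier characteristics abundance (SSR count), density (count per
Mb of the *transcript*, so raw values are in the hundreds), and summed
tract length. Responses are ln(TPM_max) and ln(TPM_CV); carriers with
non-positive values are dropped from the group.

**Stage 1 — primary filter.** Mann–Whitney compares carriers against all
other profiled transcripts, per response. The asymptotic z *without*
continuity correction is used (matching the Kruskal–Wallis convention);
this variant's null rejection rate sits at the nominal α, which the
calibration test asserts, where the continuity-corrected variant is
conservative. Motifs occupying ≥ 3 regions additionally get a
Kruskal–Wallis across regions with Dunn post hoc. Groups with < 3
carriers are skipped with a warning. Candidates have raw p < 0.05; an
optional BH mode across all combinations exists but is off by default,
mirroring the raw-p screening convention of this analysis style.

**Stage 2 — regression suite.** For each candidate group with > 10
carriers: OLS fits of the response on each characteristic at polynomial
degrees 1–3, plus the three additive bivariate linear fits. Guards:

- *Overfit guard (polynomials):* a degree-k fit (k ≥ 2) is ineligible if
  its top-order coefficient has p ≥ 0.05 or its BIC does not improve on
  the degree-(k−1) fit by ≥ 2 — a reproducible stand-in for manual
  exclusion of overfitted curves.
- *Overfit guard (bivariate):* both slope coefficients must be
  individually significant. Without this, on (near-)noiseless data a
  bivariate model carrying one useless predictor can win by numerically
  degenerate BIC.
- *VIF screen:* bivariate fits with max variance inflation factor > 10
  (the common convention; configurable) or a singular design are
  discarded.
- *Exact-fit tie-break:* if any eligible fit has R² = 1 to numerical
  tolerance, BIC differences are float noise; the most parsimonious
  exact fit wins.

The optimal model is the minimum-BIC eligible fit whose overall F test
is significant. A group is **called** an expMotif only when primary
p < 0.05 *and* such an optimal fit exists (conjunction rule) — under the
null this compounds two ≈ α screens, and the measured false-call rate on
pure-null synthetic data stays far below α. Detection runs on
standardized classes first; actual (strand-read) motifs are then tested
only within candidate classes and only with > 10 carrier sequences.

**Stage 3 — positional profiles.** Relative positions of a called
motif's SSRs, split by TPM level, are smoothed with a Gaussian KDE using
Silverman's rule-of-thumb bandwidth, *reflected* at both ends of the
(0, 1] support so mass is conserved (each curve integrates to 1 ± 0.02
on its grid) and edge peaks are not attenuated. All-identical positions
get a floor bandwidth of 0.01 instead of a degenerate kernel. Levels
with < 5 positions are skipped with a warning. Peaks are local maxima
with ≥ 5% relative prominence, falling back to the global maximum.

## Synthetic data

The generator emulates the statistical structure the analysis assumes,
as study conditions rather than tunable dials:

- Transcripts are coding (default 75%), lncRNA (10%) or unclassified,
  with uniform length ranges (5'-UTR 100–400, CDS 300–1200, 3'-UTR
  150–600, lncRNA 400–1500, other 300–1500 bp) and region-specific GC
  (0.48 / 0.52 / 0.38 / 0.42 / 0.45) — UTRs AT-richer than CDS, as in
  real plant transcriptomes.
- Backgrounds are rejection-sampled against the miner until SSR-free, so
  the planted truth table is exhaustive and recall assertions can be
  exact. After planting, the flanking base on each side is mutated if it
  would extend the run's period, keeping truth coordinates identical to
  what the miner reports. Planted tracts keep ≥ 2 bp separation so no
  unintended compounds arise.
- Expression: per transcript, ln(total expression) = N(2.5, 1.5) + Σ
  β · characteristic (planted effects) + N(0, 0.5); organ shares are
  Dirichlet with concentration 5 (broad expression) or a low value
  (default 0.3) for tissue-specific transcripts — carriers of configured
  tissue effects plus a random 10% — which concentrates expression on
  few organs and raises TPM_CV. Each of the 12 organ columns is scaled
  to a total of 10⁶, mimicking TPM's compositional constraint.
- Betas are in raw characteristic units (per SSR, per SSR/Mb, per bp).
  Simulation studies that plant density effects therefore use betas like
  0.004/(SSR/Mb), which at typical transcript densities of 500–3000
  SSR/Mb produces ln-scale effects of order 1–10.
- A group-level generator (`simulate_association_groups`,
  `simulate_regression_group`) builds detector-ready carrier groups and
  profiles directly, without sequences. It backs the repeated
  power/calibration/coverage studies, where sequence-level simulation
  would add cost but no additional coverage of the logic under test;
  one full FASTA → mine → map → profile → detect recovery run is kept
  alongside them.

What the generator does **not** emulate: read-level noise and mapping
ambiguity, isoform structure, correlated expression between paralogs,
sequence composition beyond per-region GC, and imperfect/interrupted
repeats. Passing tests therefore demonstrate the correctness and
calibration of the statistical machinery under the stated model, not
robustness to those real-data complications.

## Pipeline, determinism, problem sizes

Every stage writes a TSV; a manifest records the package version, a
SHA-256 hash of the canonical JSON of the config, the seed and row
counts, and warnings are collected into a sidecar log. All randomness
flows from one seed through separate `numpy` seed-sequence streams for
sequence and expression generation, so a rerun with the same config is
byte-identical (asserted in tests).

Validation studies run at deliberately modest sizes chosen to make their
statistical assertions sharp but cheap: 100 × 2 kb sequences for oracle
equivalence; 100 seeded runs of 1 planted + 50 null groups (40 carriers,
500 background) for recovery/false-call bounds; 201 replicates at
n = 500 for slope CI coverage; 1000 independent null groups for filter
calibration. The false-call bound (rate ≤ 0.02) was fixed a priori from
the conjunction argument: two ≈ 0.05 screens with stage-2 selection
inflation bounded by ~3 effective model families.

## Known limitations

- Imperfect/approximate repeats and units > 6 bp are out of scope.
- The miner is a per-transcript scanner; it is not tuned for
  chromosome-scale inputs.
- Boundary SSRs are categorized but never given positions; an SSR
  spanning the entire CDS still counts as a single 5'UTR–CDS boundary
  record.
- With heavily tied characteristics (e.g. every carrier holding exactly
  one SSR), abundance is constant and silently contributes no fits —
  the evidence table records the exclusion reason.
- BH adjustment in the primary filter is available but off by default;
  at transcriptome scale the raw-p screen is anticonservative across
  many motif-region combinations, which the conjunction with stage 2
  only partially offsets.
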