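"""Synthetic transcriptomes and expression matrices with planted effects.

The generator emulates the statistical structure the analysis assumes: a
transcriptome of protein-coding transcripts (5'-UTR / CDS / 3'-UTR
partition), lncRNAs and unclassified transcripts, with region-specific
GC content; SSRs planted at recorded coordinates into backgrounds that
are rejection-sampled to be SSR-free (so the planted truth table is
exact); and a 12-organ TPM matrix in which ln(TPM_max) receives additive
planted effects of SSR characteristics (abundance, density or summed
tract length per transcript) and tissue specificity (TPM_CV) is raised
for selected transcripts by concentrating their expression on few organs
via a low Dirichlet concentration.

Everything is deterministic under the configured seed.  A group-level
generator (`simulate_association_groups`) builds detector-ready
motif-region groups directly, for power and calibration studies that do
not need sequence-level simulation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .detector import MotifRegionGroup
from .miner import (
    MinerCriteria,
    canonicalize_motif,
    find_perfect_ssrs,
    is_primitive,
)
from .regions import TranscriptAnnotation

TRUTH_COLUMNS = [
    "transcript_id",
    "motif",
    "canonical_motif",
    "region",
    "repeat_count",
    "start",
    "end",
    "tract_length",
]


@dataclass(frozen=True)
class SSRPlant:
    """One planting rule: a motif planted into a region with given probability."""

    motif: str
    region: str  # "5UTR" | "CDS" | "3UTR" | "lncRNA"
    probability: float
    min_repeats: int
    max_repeats: int

    def __post_init__(self) -> None:
        if not is_primitive(self.motif.upper()):
            raise ValueError(f"planted motif must be primitive: {self.motif!r}")
        if not 0.0 <= self.probability <= 1.0:
            raise ValueError("probability must be in [0, 1]")
        if not 2 <= self.min_repeats <= self.max_repeats:
            raise ValueError("need 2 <= min_repeats <= max_repeats")


@dataclass(frozen=True)
class ExpressionEffect:
    """Additive effect of one SSR characteristic on ln(TPM_max).

    ``beta`` is per raw characteristic unit: per SSR for abundance, per
    SSR/Mb for density, per bp for length.
    """

    motif: str  # standardized class
    region: str
    characteristic: str  # "abundance" | "density" | "length"
    beta: float


@dataclass(frozen=True)
class TissueEffect:
    """Carriers of this motif-region get a low Dirichlet concentration,
    concentrating expression on few organs and raising TPM_CV."""

    motif: str
    region: str
    concentration: float = 0.3


@dataclass(frozen=True)
class SyntheticConfig:
    seed: int
    n_transcripts: int = 500
    coding_fraction: float = 0.75
    lncrna_fraction: float = 0.10
    utr5_length: tuple[int, int] = (100, 400)
    cds_length: tuple[int, int] = (300, 1200)
    utr3_length: tuple[int, int] = (150, 600)
    lncrna_length: tuple[int, int] = (400, 1500)
    other_length: tuple[int, int] = (300, 1500)
    gc_by_region: Mapping[str, float] = field(
        default_factory=lambda: {
            "5UTR": 0.48,
            "CDS": 0.52,
            "3UTR": 0.38,
            "lncRNA": 0.42,
            "other": 0.45,
        }
    )
    ssr_plants: tuple[SSRPlant, ...] = ()
    n_organs: int = 12
    baseline_ln_tpm_mean: float = 2.5
    baseline_ln_tpm_sd: float = 1.5
    effects: tuple[ExpressionEffect, ...] = ()
    tissue_effects: tuple[TissueEffect, ...] = ()
    tissue_specific_fraction: float = 0.10
    base_concentration: float = 5.0
    noise_sd: float = 0.5

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("a seed is mandatory")
        if not 0 <= self.coding_fraction + self.lncrna_fraction <= 1:
            raise ValueError("category fractions must sum to <= 1")
        if self.n_organs < 2:
            raise ValueError("need >= 2 organs")


def load_config(path) -> SyntheticConfig:
    """Read a SyntheticConfig from a YAML file (nested key-value structure)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return config_from_dict(raw)


def config_from_dict(raw: dict) -> SyntheticConfig:
    raw = dict(raw)
    raw["ssr_plants"] = tuple(SSRPlant(**p) for p in raw.get("ssr_plants", []))
    raw["effects"] = tuple(ExpressionEffect(**e) for e in raw.get("effects", []))
    raw["tissue_effects"] = tuple(
        TissueEffect(**t) for t in raw.get("tissue_effects", [])
    )
    for key in ("utr5_length", "cds_length", "utr3_length", "lncrna_length", "other_length"):
        if key in raw:
            raw[key] = tuple(raw[key])
    return SyntheticConfig(**raw)


def _random_seq(rng: np.random.Generator, length: int, gc: float) -> list[str]:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return list(rng.choice(list("ACGT"), size=length, p=probs))


def _break_flanks(seq: list[str], start0: int, end0: int, size: int,
                  rng: np.random.Generator) -> None:
    """Mutate flanking bases so the planted run cannot extend in either
    direction, keeping truth coordinates exact."""
    left = start0 - 1
    if left >= 0 and seq[left] == seq[left + size]:
        choices = [b for b in "ACGT" if b != seq[left + size]]
        seq[left] = choices[int(rng.integers(len(choices)))]
    right = end0 + 1
    if right < len(seq) and seq[right] == seq[right - size]:
        choices = [b for b in "ACGT" if b != seq[right - size]]
        seq[right] = choices[int(rng.integers(len(choices)))]


def generate_transcriptome(
    config: SyntheticConfig,
    criteria: MinerCriteria | None = None,
) -> tuple[dict[str, str], dict[str, TranscriptAnnotation], pd.DataFrame]:
    """Generate sequences, annotations and the planted-SSR truth table.

    Backgrounds are resampled until the miner finds nothing in them, so
    every SSR in the final sequences is a planted one with exactly the
    recorded coordinates.
    """
    if criteria is None:
        criteria = MinerCriteria()
    rng = np.random.default_rng([config.seed, 0])
    seqs: dict[str, str] = {}
    anns: dict[str, TranscriptAnnotation] = {}
    truth_rows: list[tuple] = []

    for i in range(config.n_transcripts):
        tid = f"TX{i + 1:06d}"
        u = rng.random()
        if u < config.coding_fraction:
            category = "coding"
        elif u < config.coding_fraction + config.lncrna_fraction:
            category = "lncRNA"
        else:
            category = "other"

        for _attempt in range(50):
            if category == "coding":
                l5 = int(rng.integers(*config.utr5_length))
                lc = int(rng.integers(*config.cds_length))
                l3 = int(rng.integers(*config.utr3_length))
                chars = (
                    _random_seq(rng, l5, config.gc_by_region["5UTR"])
                    + _random_seq(rng, lc, config.gc_by_region["CDS"])
                    + _random_seq(rng, l3, config.gc_by_region["3UTR"])
                )
                bounds = {"5UTR": (1, l5), "CDS": (l5 + 1, lc), "3UTR": (l5 + lc + 1, l3)}
                ann = TranscriptAnnotation(tid, l5 + lc + l3, l5 + 1, l5 + lc, False)
            elif category == "lncRNA":
                ln = int(rng.integers(*config.lncrna_length))
                chars = _random_seq(rng, ln, config.gc_by_region["lncRNA"])
                bounds = {"lncRNA": (1, ln)}
                ann = TranscriptAnnotation(tid, ln, None, None, True)
            else:
                lo = int(rng.integers(*config.other_length))
                chars = _random_seq(rng, lo, config.gc_by_region["other"])
                bounds = {}
                ann = TranscriptAnnotation(tid, lo, None, None, False)
            if not find_perfect_ssrs("".join(chars), criteria):
                break
        else:
            raise RuntimeError(f"could not draw an SSR-free background for {tid}")

        occupied: list[tuple[int, int]] = []  # planted spans, transcript coords
        for plant in config.ssr_plants:
            if plant.region not in bounds:
                continue
            if rng.random() >= plant.probability:
                continue
            count = int(rng.integers(plant.min_repeats, plant.max_repeats + 1))
            motif = plant.motif.upper()
            size = len(motif)
            tract = count * size
            rstart, rlen = bounds[plant.region]
            # keep a 1 bp margin inside the region for the flank guard
            if rlen < tract + 2:
                raise ValueError(
                    f"planted SSR {motif}x{count} ({tract} bp) does not fit in "
                    f"{plant.region} of {tid} ({rlen} bp)"
                )
            placed = False
            for _try in range(30):
                local = int(rng.integers(2, rlen - tract + 1))  # 1-based in region
                start = rstart + local - 1
                end = start + tract - 1
                if all(end < s - 2 or start > e + 2 for s, e in occupied):
                    placed = True
                    break
            if not placed:
                warnings.warn(f"no room to plant {motif}x{count} in {tid}; skipped")
                continue
            chars[start - 1 : end] = list(motif * count)
            _break_flanks(chars, start - 1, end - 1, size, rng)
            occupied.append((start, end))
            truth_rows.append(
                (tid, motif, canonicalize_motif(motif), plant.region, count,
                 start, end, tract)
            )

        seqs[tid] = "".join(chars)
        anns[tid] = ann

    truth = pd.DataFrame(truth_rows, columns=TRUTH_COLUMNS)
    return seqs, anns, truth


def _characteristic_matrix(
    truth: pd.DataFrame,
    anns: Mapping[str, TranscriptAnnotation],
    effect: ExpressionEffect,
    tids: Sequence[str],
) -> np.ndarray:
    sub = truth[
        (truth["canonical_motif"] == canonicalize_motif(effect.motif))
        & (truth["region"] == effect.region)
    ]
    counts = sub.groupby("transcript_id").size()
    lengths = sub.groupby("transcript_id")["tract_length"].sum()
    x = np.zeros(len(tids))
    for k, tid in enumerate(tids):
        c = counts.get(tid, 0)
        if c == 0:
            continue
        if effect.characteristic == "abundance":
            x[k] = c
        elif effect.characteristic == "density":
            x[k] = c / (anns[tid].length / 1e6)
        elif effect.characteristic == "length":
            x[k] = lengths.get(tid, 0)
        else:
            raise ValueError(f"unknown characteristic {effect.characteristic!r}")
    return x


def generate_expression(
    config: SyntheticConfig,
    truth: pd.DataFrame,
    anns: Mapping[str, TranscriptAnnotation],
) -> pd.DataFrame:
    """Generate the transcripts x organs TPM matrix.

    Per transcript: ln(total expression) = N(mu0, sigma0) + sum of planted
    characteristic effects + N(0, noise_sd); organ shares are Dirichlet
    with a low concentration for tissue-specific transcripts; every organ
    column is scaled to a fixed total of 1e6 (TPM's compositional
    constraint).
    """
    rng = np.random.default_rng([config.seed, 1])
    tids = list(anns)
    n = len(tids)
    ln_e = rng.normal(config.baseline_ln_tpm_mean, config.baseline_ln_tpm_sd, n)
    for effect in config.effects:
        ln_e = ln_e + effect.beta * _characteristic_matrix(truth, anns, effect, tids)
    ln_e = ln_e + rng.normal(0.0, config.noise_sd, n)

    conc = np.full(n, config.base_concentration)
    carriers_ts = set()
    for te in config.tissue_effects:
        sub = truth[
            (truth["canonical_motif"] == canonicalize_motif(te.motif))
            & (truth["region"] == te.region)
        ]
        carriers_ts |= set(sub["transcript_id"])
        conc[[k for k, t in enumerate(tids) if t in set(sub["transcript_id"])]] = (
            te.concentration
        )
    random_specific = (rng.random(n) < config.tissue_specific_fraction) & np.array(
        [t not in carriers_ts for t in tids]
    )
    conc[random_specific] = min(0.3, config.base_concentration)

    gamma = rng.gamma(np.repeat(conc[:, None], config.n_organs, axis=1), 1.0)
    shares = gamma / gamma.sum(axis=1, keepdims=True)
    x = np.exp(ln_e)[:, None] * shares * config.n_organs
    tpm = x / x.sum(axis=0, keepdims=True) * 1e6
    cols = [f"organ_{k + 1:02d}" for k in range(config.n_organs)]
    return pd.DataFrame(tpm, index=pd.Index(tids, name="transcript_id"), columns=cols)


def write_fasta(seqs: Mapping[str, str], path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for tid, seq in seqs.items():
            fh.write(f">{tid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# group-level simulation (no sequences): detector power / calibration studies


def _carrier_characteristics(rng: np.random.Generator, n: int) -> pd.DataFrame:
    abundance = 1 + rng.poisson(0.7, n).astype(float)
    tr_len = rng.uniform(500, 3000, n)
    unit_tract = rng.integers(15, 41, n).astype(float)
    return pd.DataFrame(
        {
            "abundance": abundance,
            "density": abundance / (tr_len / 1e6),
            "length": abundance * unit_tract,
        }
    )


def simulate_regression_group(
    seed: int,
    n: int = 500,
    beta: float = 1.0,
    characteristic: str = "density",
    noise_sd: float = 1.0,
    intercept: float = 2.0,
    motif: str = "SIM",
    region: str = "3UTR",
) -> MotifRegionGroup:
    """One carrier group whose ln(TPM_max) is linear in one characteristic.

    Used for parameter-recovery studies: y = intercept + beta * x + noise.
    """
    rng = np.random.default_rng(seed)
    chars = _carrier_characteristics(rng, n)
    y = intercept + beta * chars[characteristic].to_numpy() + rng.normal(0, noise_sd, n)
    members = chars.copy()
    members.insert(0, "transcript_id", [f"C{i:05d}" for i in range(n)])
    members["ln_tpm_max"] = y
    members["ln_tpm_cv"] = rng.normal(0.0, 0.3, n)
    return MotifRegionGroup(motif=motif, motif_mode="standardized", region=region,
                            members=members)


def simulate_association_groups(
    seed: int,
    n_null_groups: int = 50,
    n_carriers: int = 40,
    n_background: int = 500,
    planted_beta: float = 0.004,
    characteristic: str = "density",
    baseline_mean: float = 2.5,
    baseline_sd: float = 1.0,
) -> tuple[list[MotifRegionGroup], pd.DataFrame, str]:
    """Detector-ready groups: one planted expMotif among null motifs.

    Null groups draw carrier responses from the same distribution as the
    background; the planted group adds ``planted_beta`` times the chosen
    characteristic (per raw unit, e.g. per SSR/Mb) to ln(TPM_max).
    Returns (groups, profiles, planted_motif_label); profiles cover all
    carriers and background transcripts.
    """
    rng = np.random.default_rng(seed)
    regions = ("5UTR", "CDS", "3UTR")
    groups: list[MotifRegionGroup] = []
    prof_rows: list[tuple[str, float, float]] = []

    for b in range(n_background):
        y = rng.normal(baseline_mean, baseline_sd)
        prof_rows.append((f"BG{b:05d}", float(np.exp(y)), float(np.exp(rng.normal(0, 0.3)))))

    planted_label = "PLANTED"
    for gi in range(n_null_groups + 1):
        planted = gi == n_null_groups
        label = planted_label if planted else f"NULL{gi:03d}"
        chars = _carrier_characteristics(rng, n_carriers)
        y = rng.normal(baseline_mean, baseline_sd, n_carriers)
        if planted:
            y = y + planted_beta * chars[characteristic].to_numpy()
        ids = [f"{label}_T{k:04d}" for k in range(n_carriers)]
        ln_cv = rng.normal(0.0, 0.3, n_carriers)
        members = chars.copy()
        members.insert(0, "transcript_id", ids)
        members["ln_tpm_max"] = y
        members["ln_tpm_cv"] = ln_cv
        groups.append(
            MotifRegionGroup(
                motif=label,
                motif_mode="standardized",
                region=regions[gi % 3],
                members=members,
            )
        )
        for tid, yy, cc in zip(ids, y, ln_cv):
            prof_rows.append((tid, float(np.exp(yy)), float(np.exp(cc))))

    profiles = pd.DataFrame(prof_rows, columns=["transcript_id", "tpm_max", "tpm_cv"])
    return groups, profiles, planted_label
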