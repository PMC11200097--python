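"""Expression profiles: TPM_max, TPM_CV and their five-level binning.

For each transcript, TPM_max (the maximum TPM across organs) measures
expression capacity and TPM_CV (sample coefficient of variation of the
TPM vector) measures tissue specificity.  TPM_CV uses the n-1 denominator:
for a transcript expressed in exactly one of n organs the CV equals
sqrt(n), hence the level-1 cut of 3.4641 = sqrt(12) for 12 organs.

Both statistics are binned into 5 levels, level 1 = highest values.  Each
level interval is closed at its lower cut, so a value exactly equal to
the top cut lands in level 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

DEFAULT_MAX_CUTS = (1.0, 10.0, 100.0, 1000.0)
DEFAULT_CV_CUTS = (0.5, 1.0, 1.5, 3.4641)

PROFILE_COLUMNS = [
    "transcript_id",
    "tpm_max",
    "tpm_cv",
    "level_max",
    "level_cv",
    "expressed_everywhere",
]


@dataclass(frozen=True)
class LevelThresholds:
    max_cuts: tuple[float, ...] = DEFAULT_MAX_CUTS
    cv_cuts: tuple[float, ...] = DEFAULT_CV_CUTS

    def __post_init__(self) -> None:
        for cuts in (self.max_cuts, self.cv_cuts):
            if len(cuts) != 4:
                raise ValueError("exactly 4 cut points are required")
            if any(b <= a for a, b in zip(cuts, cuts[1:])):
                raise ValueError("cut points must be strictly increasing")


def tpm_cv(tpm) -> float:
    """Sample coefficient of variation (SD with n-1 denominator over mean)."""
    v = np.asarray(tpm, dtype=float)
    if v.ndim != 1 or v.size < 2:
        raise ValueError("tpm must be a vector of length >= 2")
    if np.any(v < 0) or not np.all(np.isfinite(v)):
        raise ValueError("tpm values must be finite and non-negative")
    mean = v.mean()
    if mean <= 0:
        raise ValueError("tpm_cv undefined for a zero-mean vector")
    return float(v.std(ddof=1) / mean)


def assign_level(value: float, cuts) -> int:
    """Bin a value into levels 1-5 (level 1 = highest, closed lower bounds)."""
    if not np.isfinite(value):
        raise ValueError(f"value must be finite, got {value!r}")
    cuts = tuple(cuts)
    if len(cuts) != 4 or any(b <= a for a, b in zip(cuts, cuts[1:])):
        raise ValueError("cuts must be 4 strictly increasing values")
    return int(5 - np.searchsorted(cuts, value, side="right"))


def _assign_levels(values: np.ndarray, cuts) -> np.ndarray:
    return 5 - np.searchsorted(np.asarray(cuts, dtype=float), values, side="right")


def expressed_filter(tpm_df: pd.DataFrame, floor: float = 0.01) -> pd.Series:
    """Boolean mask of transcripts with every TPM strictly above ``floor``."""
    return (tpm_df > floor).all(axis=1)


def build_profiles(
    tpm_df: pd.DataFrame,
    thresholds: LevelThresholds | None = None,
    floor: float = 0.01,
) -> pd.DataFrame:
    """Derive per-transcript profiles from a transcripts x organs TPM matrix.

    Transcripts whose TPM vector has zero mean (never expressed) are
    dropped: their CV is undefined and ln(TPM_max) would be -inf.
    """
    if thresholds is None:
        thresholds = LevelThresholds()
    if tpm_df.shape[1] < 2:
        raise ValueError("TPM matrix needs >= 2 organ columns")
    mat = tpm_df.to_numpy(dtype=float)
    if np.any(mat < 0) or not np.all(np.isfinite(mat)):
        raise ValueError("TPM matrix must be finite and non-negative")
    mean = mat.mean(axis=1)
    keep = mean > 0
    mat = mat[keep]
    tmax = mat.max(axis=1)
    tcv = mat.std(axis=1, ddof=1) / mat.mean(axis=1)
    out = pd.DataFrame(
        {
            "transcript_id": tpm_df.index[keep].astype(str),
            "tpm_max": tmax,
            "tpm_cv": tcv,
            "level_max": _assign_levels(tmax, thresholds.max_cuts),
            "level_cv": _assign_levels(tcv, thresholds.cv_cuts),
            "expressed_everywhere": (mat > floor).all(axis=1),
        }
    )
    return out


def read_tpm_matrix(path) -> pd.DataFrame:
    """Read a TPM TSV with transcript ids in the first column, organs as columns."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_profiles(profiles: pd.DataFrame, path) -> None:
    profiles.to_csv(path, sep="\t", index=False)


def read_profiles(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"transcript_id": str})
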