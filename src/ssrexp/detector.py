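"""Detection of expression-modulating motifs (expMotifs).

An expMotif is a motif x transcribed-region combination whose SSRs show
statistically supported association with expression.  The cascade has
two mandatory stages plus a descriptive stage:

1. Primary nonparametric filter: for each motif-region group, a
   Mann-Whitney test compares the response (lnTPM_max or lnTPM_CV) of
   carrier transcripts against non-carriers; when a motif occupies >= 3
   regions a Kruskal-Wallis test across regions is added, with Dunn post
   hoc for candidates.  Candidates have raw p < 0.05.
2. Regression suite: per candidate group, polynomial (degree 1-3) fits of
   the response on each SSR characteristic (abundance = SSRs per
   transcript, density = SSRs per Mb of transcript, length = summed
   tract bp) plus additive bivariate linear fits over characteristic
   pairs.  Bivariate fits are screened by variance inflation factor
   (VIF <= 10).  Higher-degree fits are excluded by a reproducible
   overfit guard (top coefficient not significant, or BIC improvement
   over the next-lower degree < 2).  The optimal model is the minimum-BIC
   surviving fit that is significant by its overall F test.

A group is called an expMotif only when both stages are significant.
Detection is run on standardized motif classes first, then on actual
(strand-specific) motifs restricted to classes that were candidates,
keeping only actual motifs with more than 10 carrier sequences.

Stage 3 profiles the relative positions of a called motif's SSRs with a
boundary-reflected Gaussian KDE per expression level.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.signal import find_peaks
import statsmodels.api as sm

from .stats import bh_adjust, kw_dunn

CHARACTERISTICS = ("abundance", "density", "length")
CORE_REGION_LABELS = ("5UTR", "CDS", "3UTR")


@dataclass
class MotifRegionGroup:
    """Carrier transcripts of one motif in one region, with characteristics."""

    motif: str
    motif_mode: str  # "standardized" | "actual"
    region: str
    members: pd.DataFrame  # transcript_id, abundance, density, length, ln_tpm_max, ln_tpm_cv

    @property
    def n_carriers(self) -> int:
        return len(self.members)


@dataclass
class RegressionFit:
    form: str  # "linear" | "quadratic" | "cubic" | "bivariate"
    predictors: tuple[str, ...]
    coefficients: np.ndarray  # intercept first
    coef_pvalues: np.ndarray
    conf_int: np.ndarray  # 95% CI per coefficient, shape (k, 2)
    r_squared: float
    bic: float
    f_pvalue: float
    vif: Optional[float] = None  # max VIF, bivariate fits only
    significant: bool = False
    eligible: bool = False
    excluded_reason: str = ""


@dataclass
class FitSuite:
    fits: list[RegressionFit]
    optimal: Optional[RegressionFit]


@dataclass
class ExpMotifCall:
    motif: str
    motif_mode: str
    region: str
    response: str
    primary_p: float
    best_fit: Optional[RegressionFit]
    called: bool


# ---------------------------------------------------------------------------
# group construction


def build_groups(
    assign_df: pd.DataFrame,
    profiles: pd.DataFrame,
    transcript_lengths: Mapping[str, int],
    mode: str = "standardized",
    regions: Sequence[str] = CORE_REGION_LABELS,
    min_carriers: int = 0,
    motifs: Sequence[str] | None = None,
) -> list[MotifRegionGroup]:
    """Build motif x region carrier groups with per-transcript characteristics.

    ``density`` is the carrier's SSR count for that motif-region per Mb of
    its transcript.  Responses are natural logs of TPM_max and TPM_CV;
    carriers with non-positive TPM_max or TPM_CV are dropped from the
    group (the log is undefined for them).
    """
    if mode not in ("standardized", "actual"):
        raise ValueError("mode must be 'standardized' or 'actual'")
    motif_col = "canonical_motif" if mode == "standardized" else "motif"
    df = assign_df[assign_df["region"].isin(regions)].copy()
    if motifs is not None:
        df = df[df[motif_col].isin(set(motifs))]
    if df.empty:
        return []
    prof = profiles.set_index(profiles["transcript_id"].astype(str))
    prof = prof[(prof["tpm_max"] > 0) & (prof["tpm_cv"] > 0)]

    groups: list[MotifRegionGroup] = []
    for (motif, region), grp in df.groupby([motif_col, "region"]):
        agg = grp.groupby("transcript_id").agg(
            abundance=("motif", "size"), length=("tract_length", "sum")
        )
        agg.index = agg.index.astype(str)
        agg = agg[agg.index.isin(prof.index)]
        if len(agg) < max(min_carriers, 1):
            continue
        lens = np.array([transcript_lengths[t] for t in agg.index], dtype=float)
        members = pd.DataFrame(
            {
                "transcript_id": agg.index,
                "abundance": agg["abundance"].to_numpy(dtype=float),
                "density": agg["abundance"].to_numpy(dtype=float) / (lens / 1e6),
                "length": agg["length"].to_numpy(dtype=float),
                "ln_tpm_max": np.log(prof.loc[agg.index, "tpm_max"].to_numpy(dtype=float)),
                "ln_tpm_cv": np.log(prof.loc[agg.index, "tpm_cv"].to_numpy(dtype=float)),
            }
        ).reset_index(drop=True)
        groups.append(
            MotifRegionGroup(motif=motif, motif_mode=mode, region=region, members=members)
        )
    return groups


# ---------------------------------------------------------------------------
# stage 1: primary nonparametric filter


def primary_filter(
    groups: Sequence[MotifRegionGroup],
    profiles: pd.DataFrame,
    responses: Sequence[str] = ("ln_tpm_max", "ln_tpm_cv"),
    alpha: float = 0.05,
    min_carriers: int = 3,
) -> pd.DataFrame:
    """Mann-Whitney carrier-vs-noncarrier screen per motif x region x response.

    Adds a Kruskal-Wallis p across regions (``kw_p`` column) for motifs
    occupying >= 3 regions.  A group with fewer than ``min_carriers``
    carriers is skipped with a warning.  Candidates have raw
    Mann-Whitney p < alpha.
    """
    prof = profiles.set_index(profiles["transcript_id"].astype(str))
    prof = prof[(prof["tpm_max"] > 0) & (prof["tpm_cv"] > 0)]
    ln_resp = {
        "ln_tpm_max": np.log(prof["tpm_max"].to_numpy(dtype=float)),
        "ln_tpm_cv": np.log(prof["tpm_cv"].to_numpy(dtype=float)),
    }
    universe = prof.index

    by_motif: dict[tuple[str, str], list[MotifRegionGroup]] = {}
    for g in groups:
        by_motif.setdefault((g.motif, g.motif_mode), []).append(g)

    kw_p_by_motif: dict[tuple[str, str, str], float] = {}
    for key, glist in by_motif.items():
        if len(glist) >= 3:
            for response in responses:
                vecs = [g.members[response].to_numpy() for g in glist]
                if any(len(v) < 1 for v in vecs):
                    continue
                try:
                    res = kw_dunn(vecs, labels=[g.region for g in glist])
                    kw_p_by_motif[(key[0], key[1], response)] = res.kw.p_value
                except ValueError:
                    continue

    rows = []
    for g in groups:
        if g.n_carriers < min_carriers:
            warnings.warn(
                f"group {g.motif}/{g.region} skipped: "
                f"{g.n_carriers} carriers < {min_carriers}"
            )
            continue
        carrier_ids = set(g.members["transcript_id"])
        mask_nc = ~universe.isin(carrier_ids)
        for response in responses:
            carriers = g.members[response].to_numpy()
            noncarriers = ln_resp[response][mask_nc]
            if len(noncarriers) < 1:
                continue
            # asymptotic z without continuity correction, matching the KW
            # convention, so the filter's rejection rate sits at alpha
            mw = sps.mannwhitneyu(
                carriers, noncarriers, alternative="two-sided",
                method="asymptotic", use_continuity=False,
            )
            kw_p = kw_p_by_motif.get((g.motif, g.motif_mode, response), np.nan)
            rows.append(
                (
                    g.motif,
                    g.motif_mode,
                    g.region,
                    response,
                    g.n_carriers,
                    float(mw.statistic),
                    float(mw.pvalue),
                    kw_p,
                    float(mw.pvalue) < alpha,
                )
            )
    return pd.DataFrame(
        rows,
        columns=[
            "motif",
            "motif_mode",
            "region",
            "response",
            "n_carriers",
            "mw_statistic",
            "mw_p",
            "kw_p",
            "candidate",
        ],
    )


# ---------------------------------------------------------------------------
# stage 2: regression suite with BIC selection and VIF screening

_POLY_FORMS = {1: "linear", 2: "quadratic", 3: "cubic"}


def _ols(y: np.ndarray, cols: list[np.ndarray]):
    X = sm.add_constant(np.column_stack(cols))
    return sm.OLS(y, X).fit()


def fit_regressions(
    group: MotifRegionGroup,
    response: str,
    alpha: float = 0.05,
    vif_threshold: float = 10.0,
    bic_margin: float = 2.0,
) -> FitSuite:
    """Fit the regression suite for one group and select the optimal model.

    Polynomial fits of degree 1-3 per characteristic, plus the three
    additive bivariate linear fits.  A degree-k fit (k >= 2) is excluded
    from optimal-model selection when its top-order coefficient is not
    significant or its BIC does not beat the degree-(k-1) fit by at least
    ``bic_margin`` (a reproducible guard against overfitting).  Bivariate
    fits with max VIF above ``vif_threshold`` (or a singular design) are
    discarded.  The optimal model is the minimum-BIC eligible fit that is
    significant by its overall F test; ``optimal`` is None when no fit
    survives.
    """
    if group.n_carriers <= 10:
        raise ValueError(
            f"group {group.motif}/{group.region} has {group.n_carriers} "
            "carriers; regression requires > 10"
        )
    y = group.members[response].to_numpy(dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("response must be finite for all members")

    fits: list[RegressionFit] = []
    for char in CHARACTERISTICS:
        x = group.members[char].to_numpy(dtype=float)
        if np.ptp(x) == 0:
            fits.append(
                RegressionFit(
                    form="linear",
                    predictors=(char,),
                    coefficients=np.array([]),
                    coef_pvalues=np.array([]),
                        conf_int=np.empty((0, 2)),
                    r_squared=float("nan"),
                    bic=float("inf"),
                    f_pvalue=float("nan"),
                    excluded_reason="constant predictor",
                )
            )
            continue
        prev_bic = None
        for degree in (1, 2, 3):
            cols = [x**d for d in range(1, degree + 1)]
            try:
                res = _ols(y, cols)
            except Exception as exc:  # singular design at high degree
                fits.append(
                    RegressionFit(
                        form=_POLY_FORMS[degree],
                        predictors=(char,),
                        coefficients=np.array([]),
                        coef_pvalues=np.array([]),
                        conf_int=np.empty((0, 2)),
                        r_squared=float("nan"),
                        bic=float("inf"),
                        f_pvalue=float("nan"),
                        excluded_reason=f"fit failed: {exc}",
                    )
                )
                continue
            top_p = float(res.pvalues[-1])
            significant = bool(np.isfinite(res.f_pvalue) and res.f_pvalue < alpha)
            eligible = significant
            reason = "" if significant else "overall F not significant"
            if degree > 1:
                if not (np.isfinite(top_p) and top_p < alpha):
                    eligible, reason = False, "top-order coefficient not significant"
                elif prev_bic is not None and res.bic > prev_bic - bic_margin:
                    eligible, reason = False, "insufficient BIC improvement"
            fits.append(
                RegressionFit(
                    form=_POLY_FORMS[degree],
                    predictors=(char,),
                    coefficients=np.asarray(res.params),
                    coef_pvalues=np.asarray(res.pvalues),
                    conf_int=np.asarray(res.conf_int()),
                    r_squared=float(res.rsquared),
                    bic=float(res.bic),
                    f_pvalue=float(res.f_pvalue),
                    significant=significant,
                    eligible=eligible,
                    excluded_reason=reason,
                )
            )
            prev_bic = float(res.bic)

    for a, b in combinations(CHARACTERISTICS, 2):
        xa = group.members[a].to_numpy(dtype=float)
        xb = group.members[b].to_numpy(dtype=float)
        if np.ptp(xa) == 0 or np.ptp(xb) == 0:
            continue
        r = np.corrcoef(xa, xb)[0, 1]
        max_vif = float("inf") if abs(r) >= 1.0 - 1e-12 else 1.0 / (1.0 - r**2)
        if not np.isfinite(max_vif) or max_vif > vif_threshold:
            fits.append(
                RegressionFit(
                    form="bivariate",
                    predictors=(a, b),
                    coefficients=np.array([]),
                    coef_pvalues=np.array([]),
                        conf_int=np.empty((0, 2)),
                    r_squared=float("nan"),
                    bic=float("inf"),
                    f_pvalue=float("nan"),
                    vif=max_vif,
                    excluded_reason="VIF above threshold",
                )
            )
            continue
        res = _ols(y, [xa, xb])
        significant = bool(np.isfinite(res.f_pvalue) and res.f_pvalue < alpha)
        # both slopes must carry weight, else the extra predictor overfits
        slopes_ok = bool(
            np.all(np.isfinite(res.pvalues[1:])) and np.all(res.pvalues[1:] < alpha)
        )
        eligible = significant and slopes_ok
        if not significant:
            reason = "overall F not significant"
        elif not slopes_ok:
            reason = "predictor coefficient not significant"
        else:
            reason = ""
        fits.append(
            RegressionFit(
                form="bivariate",
                predictors=(a, b),
                coefficients=np.asarray(res.params),
                coef_pvalues=np.asarray(res.pvalues),
                conf_int=np.asarray(res.conf_int()),
                r_squared=float(res.rsquared),
                bic=float(res.bic),
                f_pvalue=float(res.f_pvalue),
                vif=max_vif,
                significant=significant,
                eligible=eligible,
                excluded_reason=reason,
            )
        )

    eligible = [f for f in fits if f.eligible and f.significant and np.isfinite(f.bic)]
    # an exact fit makes BIC differences pure float noise: prefer parsimony
    exact = [f for f in eligible if f.r_squared >= 1.0 - 1e-9]
    if exact:
        optimal = min(exact, key=lambda f: (len(f.coefficients), f.bic))
    elif eligible:
        optimal = min(eligible, key=lambda f: f.bic)
    else:
        optimal = None
    return FitSuite(fits=fits, optimal=optimal)


def fits_to_frame(
    suites: Mapping[tuple[str, str, str], FitSuite]
) -> pd.DataFrame:
    """One row per fitted model; key is (motif, region, response)."""
    rows = []
    for (motif, region, response), suite in suites.items():
        for f in suite.fits:
            rows.append(
                (
                    motif,
                    region,
                    response,
                    f.form,
                    "+".join(f.predictors),
                    ";".join(f"{c:.6g}" for c in f.coefficients),
                    f.r_squared,
                    f.bic,
                    f.f_pvalue,
                    f.vif if f.vif is not None else np.nan,
                    f.significant,
                    f is suite.optimal,
                    f.excluded_reason,
                )
            )
    return pd.DataFrame(
        rows,
        columns=[
            "motif",
            "region",
            "response",
            "form",
            "predictors",
            "coefficients",
            "r_squared",
            "bic",
            "f_p",
            "max_vif",
            "significant",
            "optimal",
            "excluded_reason",
        ],
    )


# ---------------------------------------------------------------------------
# stage 3: conjunction call


def call_expmotifs(
    candidates: pd.DataFrame,
    groups: Sequence[MotifRegionGroup],
    alpha: float = 0.05,
    vif_threshold: float = 10.0,
    min_fit_carriers: int = 10,
) -> tuple[pd.DataFrame, dict[tuple[str, str, str], FitSuite]]:
    """Run regressions for primary-filter candidates and call expMotifs.

    A group is called for a response only when its primary Mann-Whitney p
    is < alpha AND an eligible regression fit is significant (conjunction
    rule).  Groups with <= ``min_fit_carriers`` carriers cannot enter the
    regression stage and are never called.  Returns the evidence table
    (called and uncalled rows) and the fitted suites.
    """
    by_key = {(g.motif, g.motif_mode, g.region): g for g in groups}
    suites: dict[tuple[str, str, str], FitSuite] = {}
    rows = []
    for row in candidates.itertuples(index=False):
        key = (row.motif, row.motif_mode, row.region)
        group = by_key.get(key)
        best: Optional[RegressionFit] = None
        if row.candidate and group is not None and group.n_carriers > min_fit_carriers:
            skey = (row.motif, row.region, row.response)
            if skey not in suites:
                suites[skey] = fit_regressions(
                    group, row.response, alpha=alpha, vif_threshold=vif_threshold
                )
            best = suites[skey].optimal
        called = bool(row.candidate and best is not None and best.significant)
        rows.append(
            (
                row.motif,
                row.motif_mode,
                row.region,
                row.response,
                row.n_carriers,
                row.mw_p,
                best.form if best else "",
                "+".join(best.predictors) if best else "",
                best.r_squared if best else np.nan,
                best.bic if best else np.nan,
                called,
            )
        )
    calls = pd.DataFrame(
        rows,
        columns=[
            "motif",
            "motif_mode",
            "region",
            "response",
            "n_carriers",
            "primary_p",
            "best_form",
            "best_predictors",
            "best_r_squared",
            "best_bic",
            "called",
        ],
    )
    return calls, suites


def detect_expmotifs(
    assign_df: pd.DataFrame,
    profiles: pd.DataFrame,
    transcript_lengths: Mapping[str, int],
    alpha: float = 0.05,
    min_carriers: int = 10,
    vif_threshold: float = 10.0,
    responses: Sequence[str] = ("ln_tpm_max", "ln_tpm_cv"),
) -> dict[str, pd.DataFrame]:
    """Full two-mode detection: standardized classes first, then actual motifs.

    Actual-motif detection is restricted to motifs whose standardized
    class was a candidate in the first pass, and to actual motifs with
    more than ``min_carriers`` carrier sequences.
    """
    out: dict[str, pd.DataFrame] = {}
    groups_std = build_groups(
        assign_df, profiles, transcript_lengths, mode="standardized", min_carriers=3
    )
    cand_std = primary_filter(groups_std, profiles, responses=responses, alpha=alpha)
    calls_std, suites_std = call_expmotifs(
        cand_std, groups_std, alpha=alpha, vif_threshold=vif_threshold,
        min_fit_carriers=min_carriers,
    )
    out["candidates_standardized"] = cand_std
    out["calls_standardized"] = calls_std
    out["fits_standardized"] = fits_to_frame(suites_std)

    cand_classes = set(cand_std.loc[cand_std["candidate"], "motif"])
    if cand_classes:
        actual_motifs = sorted(
            set(
                assign_df.loc[
                    assign_df["canonical_motif"].isin(cand_classes), "motif"
                ]
            )
        )
        groups_act = build_groups(
            assign_df,
            profiles,
            transcript_lengths,
            mode="actual",
            min_carriers=min_carriers + 1,  # strict "> 10 sequences" rule
            motifs=actual_motifs,
        )
        cand_act = primary_filter(groups_act, profiles, responses=responses, alpha=alpha)
        calls_act, suites_act = call_expmotifs(
            cand_act, groups_act, alpha=alpha, vif_threshold=vif_threshold,
            min_fit_carriers=min_carriers,
        )
    else:
        cand_act = cand_std.iloc[0:0]
        calls_act = calls_std.iloc[0:0]
        suites_act = {}
    out["candidates_actual"] = cand_act
    out["calls_actual"] = calls_act
    out["fits_actual"] = fits_to_frame(suites_act)
    return out


# ---------------------------------------------------------------------------
# stage 4: relative-position probability density


def _silverman_bandwidth(x: np.ndarray) -> float:
    n = x.size
    sd = x.std(ddof=1) if n > 1 else 0.0
    iqr = np.subtract(*np.percentile(x, [75, 25]))
    spread = min(sd, iqr / 1.34) if iqr > 0 else sd
    h = 0.9 * spread * n ** (-0.2)
    return h if h > 0 else 0.01


def _reflected_kde(points: np.ndarray, grid: np.ndarray, bandwidth: float) -> np.ndarray:
    """Gaussian KDE on (0, 1] with reflection at both boundaries."""
    dens = np.zeros_like(grid)
    for reflected in (points, -points, 2.0 - points):
        z = (grid[:, None] - reflected[None, :]) / bandwidth
        dens += np.exp(-0.5 * z**2).sum(axis=1)
    dens /= points.size * bandwidth * np.sqrt(2.0 * np.pi)
    return dens


def position_density(
    positions,
    levels,
    grid_size: int = 512,
    min_points: int = 5,
    bandwidth: float | None = None,
    peak_prominence: float = 0.05,
) -> tuple[pd.DataFrame, dict[int, list[float]]]:
    """Per-expression-level KDE of relative positions on (0, 1].

    Bandwidth defaults to Silverman's rule per level, with reflection at
    both support boundaries so each curve still integrates to ~1.  Levels
    with fewer than ``min_points`` positions are skipped with a warning.
    Returns the tidy curve table (level, x, density) and per-level peak
    locations (local maxima by prominence, falling back to the global
    maximum).
    """
    positions = np.asarray(positions, dtype=float)
    levels = np.asarray(levels)
    if positions.size == 0:
        raise ValueError("no positions given")
    if positions.shape != levels.shape:
        raise ValueError("positions and levels must align")
    if np.any((positions <= 0) | (positions > 1)):
        raise ValueError("relative positions must lie in (0, 1]")
    grid = np.linspace(1.0 / grid_size, 1.0, grid_size)
    frames = []
    peaks: dict[int, list[float]] = {}
    for level in sorted(pd.unique(levels)):
        pts = positions[levels == level]
        if pts.size < min_points:
            warnings.warn(
                f"level {level} skipped: {pts.size} positions < {min_points}"
            )
            continue
        h = bandwidth if bandwidth is not None else _silverman_bandwidth(pts)
        dens = _reflected_kde(pts, grid, h)
        frames.append(pd.DataFrame({"level": level, "x": grid, "density": dens}))
        idx, _ = find_peaks(dens, prominence=peak_prominence * dens.max())
        if idx.size == 0:
            idx = np.array([int(np.argmax(dens))])
        peaks[level] = [float(grid[i]) for i in idx]
    if not frames:
        raise ValueError("no level had enough positions for a density curve")
    return pd.concat(frames, ignore_index=True), peaks
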