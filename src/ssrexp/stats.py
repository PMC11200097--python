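"""Descriptive SSR statistics and nonparametric association tests.

Conventions: density is SSR counts per Mb of summed sequence, frequency
is 100 * SSR count / sequence count, abundance is SSR count per
sequence.  Enrichment of motif classes across regions is localized with
per-cell adjusted standardized residuals of the Pearson chi-squared
test.  Group comparisons use Kruskal-Wallis with mid-rank tie
correction followed by Dunn's post hoc z tests with Benjamini-Hochberg
adjustment; Dunn's test is implemented here directly (z statistic on
rank means with the usual tie term).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests


@dataclass
class TestResult:
    statistic: float
    p_value: float
    df: Optional[int] = None
    adjusted_p: Optional[float] = None
    extra: dict = field(default_factory=dict)


@dataclass
class GroupStats:
    """SSR characteristics for one grouping (motif class / region / level)."""

    group: tuple
    n_sequences: int
    n_ssr_sequences: int
    n_ssrs: int
    total_bp: int
    mean_gc: float = float("nan")
    mean_tract_length: float = float("nan")

    @property
    def abundance(self) -> float:
        return self.n_ssrs / self.n_sequences

    @property
    def proportion_ssr_sequences(self) -> float:
        return self.n_ssr_sequences / self.n_sequences

    @property
    def density(self) -> float:
        return density(self.n_ssrs, self.total_bp)

    @property
    def frequency_pct(self) -> float:
        return frequency_pct(self.n_ssrs, self.n_sequences)


def density(n_ssrs: int, total_bp: int) -> float:
    """SSRs per Mb of sequence."""
    if total_bp <= 0:
        raise ValueError("total_bp must be positive")
    if n_ssrs < 0:
        raise ValueError("n_ssrs must be non-negative")
    return n_ssrs / (total_bp / 1e6)


def frequency_pct(n_ssrs: int, n_sequences: int) -> float:
    """SSR frequency: 100 * SSR count / number of sequences examined."""
    if n_sequences <= 0:
        raise ValueError("n_sequences must be positive")
    if n_ssrs < 0:
        raise ValueError("n_ssrs must be non-negative")
    return 100.0 * n_ssrs / n_sequences


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def chi_square_with_residuals(table) -> tuple[TestResult, np.ndarray]:
    """Pearson chi-squared independence test with adjusted standardized residuals.

    The per-cell residual is
    ``(obs - exp) / sqrt(exp * (1 - row_total/N) * (1 - col_total/N))``,
    approximately standard normal under independence, and is used to
    localize which cells drive a significant table.
    """
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or obs.shape[0] < 2 or obs.shape[1] < 2:
        raise ValueError("table must be at least 2x2")
    if np.any(obs < 0):
        raise ValueError("counts must be non-negative")
    row = obs.sum(axis=1)
    col = obs.sum(axis=0)
    if np.any(row == 0) or np.any(col == 0):
        raise ValueError("all row and column totals must be positive")
    n = obs.sum()
    stat, p, dof, exp = sps.chi2_contingency(obs, correction=False)
    denom = np.sqrt(
        exp * (1.0 - row[:, None] / n) * (1.0 - col[None, :] / n)
    )
    resid = (obs - exp) / denom
    return TestResult(statistic=float(stat), p_value=float(p), df=int(dof)), resid


def kendall_tau(x, y) -> TestResult:
    """Kendall tau-b (tie-corrected) rank correlation with p-value.

    A constant input vector leaves tau undefined; the result is flagged
    (NaN statistic) rather than raising.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("x and y must be equal-length vectors of size >= 2")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return TestResult(statistic=float("nan"), p_value=float("nan"),
                          extra={"undefined": True})
    res = sps.kendalltau(x, y, variant="b")
    return TestResult(statistic=float(res.statistic), p_value=float(res.pvalue),
                      extra={"tau": float(res.statistic)})


def dunn_posthoc(
    groups: Sequence[np.ndarray],
    labels: Sequence | None = None,
    one_sided: bool = False,
) -> pd.DataFrame:
    """Dunn's post hoc z tests on rank means, BH-adjusted across pairs.

    For groups i, j with rank means Ri, Rj over the pooled mid-ranks,
    ``z = (Ri - Rj) / sqrt((N(N+1)/12 - T) (1/ni + 1/nj))`` where
    ``T = sum(t^3 - t) / (12 (N - 1))`` over tie blocks.  One-sided tests
    take the direction from the rank-mean ordering.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if labels is None:
        labels = list(range(len(groups)))
    if len(groups) < 2 or any(len(g) < 1 for g in groups):
        raise ValueError("need >= 2 non-empty groups")
    pooled = np.concatenate(groups)
    n_total = pooled.size
    ranks = sps.rankdata(pooled)
    sizes = [len(g) for g in groups]
    offsets = np.cumsum([0] + sizes)
    rank_means = [
        ranks[offsets[i] : offsets[i + 1]].mean() for i in range(len(groups))
    ]
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (12.0 * (n_total - 1))
    var_base = n_total * (n_total + 1) / 12.0 - tie_term

    rows = []
    for i, j in combinations(range(len(groups)), 2):
        se = np.sqrt(var_base * (1.0 / sizes[i] + 1.0 / sizes[j]))
        if se == 0:
            z, p = 0.0, 1.0
        else:
            z = (rank_means[i] - rank_means[j]) / se
            p = sps.norm.sf(abs(z)) if one_sided else 2.0 * sps.norm.sf(abs(z))
        rows.append((labels[i], labels[j], z, min(p, 1.0)))
    out = pd.DataFrame(rows, columns=["group_i", "group_j", "z", "p"])
    out["p_adj"] = bh_adjust(out["p"].to_numpy())
    return out


@dataclass
class KWDunnResult:
    kw: TestResult
    dunn: pd.DataFrame


def kw_dunn(
    groups: Sequence,
    labels: Sequence | None = None,
    one_sided: bool = False,
) -> KWDunnResult:
    """Kruskal-Wallis H (tie-corrected) plus pairwise Dunn post hoc tests."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if labels is None:
        labels = list(range(len(groups)))
    if len(groups) < 2 or any(len(g) < 1 for g in groups):
        raise ValueError("need >= 2 non-empty groups")
    if sum(len(g) for g in groups) < 3:
        raise ValueError("need a total of >= 3 observations")
    pooled = np.concatenate(groups)
    dfree = len(groups) - 1
    if np.ptp(pooled) == 0:
        # all values identical: no evidence of difference
        kw = TestResult(statistic=0.0, p_value=1.0, df=dfree)
    else:
        stat, p = sps.kruskal(*groups)
        kw = TestResult(statistic=float(stat), p_value=float(p), df=dfree)
    dunn = dunn_posthoc(groups, labels=labels, one_sided=one_sided)
    return KWDunnResult(kw=kw, dunn=dunn)


# ---------------------------------------------------------------------------
# dataset-level summaries


def summarize_dataset(
    ssr_df: pd.DataFrame, n_sequences: int, total_bp: int
) -> pd.DataFrame:
    """Whole-dataset summary in the style of a transcriptome SSR survey table.

    Rows: totals (sequences examined, bp examined, SSR count, SSR-containing
    sequences, multi-SSR sequences, compound members), per-size counts,
    frequency and density, plus actual/standardized motif-type tallies.
    """
    n_ssrs = len(ssr_df)
    per_tid = ssr_df.groupby("transcript_id").size() if n_ssrs else pd.Series(dtype=int)
    n_ssr_seqs = int((per_tid >= 1).sum())
    n_multi = int((per_tid > 1).sum())
    compound_members = (
        int((ssr_df["compound_id"].astype(str).str.len() > 0).sum()) if n_ssrs else 0
    )
    n_compounds = (
        ssr_df.loc[ssr_df["compound_id"].astype(str).str.len() > 0, "compound_id"]
        .nunique()
        if n_ssrs
        else 0
    )
    rows = [
        ("total_sequences", n_sequences),
        ("total_bp", total_bp),
        ("total_ssrs", n_ssrs),
        ("ssr_containing_sequences", n_ssr_seqs),
        ("sequences_with_multiple_ssrs", n_multi),
        ("compound_ssrs", n_compounds),
        ("ssrs_in_compound_formation", compound_members),
    ]
    for size in range(1, 7):
        rows.append((f"size_{size}_ssrs", int((ssr_df["motif_size"] == size).sum()) if n_ssrs else 0))
    rows.append(("frequency_pct", round(frequency_pct(n_ssrs, n_sequences), 2)))
    rows.append(("density_per_mb", round(density(n_ssrs, total_bp), 2)))
    rows.append(("actual_motif_types", int(ssr_df["motif"].nunique()) if n_ssrs else 0))
    rows.append(
        ("standardized_motif_types", int(ssr_df["canonical_motif"].nunique()) if n_ssrs else 0)
    )
    return pd.DataFrame(rows, columns=["item", "value"])


def summarize_regions(
    assign_df: pd.DataFrame,
    region_sizes: Mapping[str, tuple[int, int]],
) -> pd.DataFrame:
    """Per-region counts and densities.

    ``region_sizes`` maps region label -> (n_sequences, total_bp) for the
    regions with a defined extent; boundary categories get counts only.
    """
    rows = []
    for region, grp in assign_df.groupby("region"):
        n_ssr = len(grp)
        if region in region_sizes:
            n_seq, bp = region_sizes[region]
            rows.append((region, n_seq, bp, n_ssr, round(density(n_ssr, bp), 2)))
        else:
            rows.append((region, np.nan, np.nan, n_ssr, np.nan))
    return pd.DataFrame(
        rows,
        columns=["region", "n_sequences", "total_bp", "n_ssrs", "density_per_mb"],
    )


# ---------------------------------------------------------------------------
# region-differential analysis


def _single_region_groups(
    profiles: pd.DataFrame, assign_df: pd.DataFrame, core_regions=("5UTR", "CDS", "3UTR")
) -> dict[str, pd.Index]:
    """Partition transcripts into single-region SSR carriers and SSR-free.

    Transcripts with SSRs in more than one core region are excluded
    entirely; transcripts with no SSR at all form the SSR-free group.
    """
    pid = pd.Index(profiles["transcript_id"].astype(str))
    in_core = assign_df[assign_df["region"].isin(core_regions)]
    regions_per_tid = in_core.groupby("transcript_id")["region"].agg(set)
    any_ssr = set(assign_df["transcript_id"].astype(str))
    groups: dict[str, pd.Index] = {}
    for region in core_regions:
        only = regions_per_tid[regions_per_tid.apply(lambda s: s == {region})].index
        groups[region] = pid.intersection(only.astype(str))
    groups["SSR-free"] = pid[~pid.isin(any_ssr)]
    return groups


def region_differential(
    profiles: pd.DataFrame,
    assign_df: pd.DataFrame,
    responses: Sequence[str] = ("tpm_max", "tpm_cv"),
    one_sided: bool = False,
) -> dict[str, KWDunnResult]:
    """Compare expression between single-region SSR carriers and SSR-free genes.

    ``profiles`` should already be restricted to transcripts expressed in
    all organs (TPM > 0.01 everywhere).  Returns one KW + Dunn result per
    response; a contrast with any empty group is skipped with a warning.
    """
    groups = _single_region_groups(profiles, assign_df)
    labels = list(groups)
    prof = profiles.set_index(profiles["transcript_id"].astype(str))
    results: dict[str, KWDunnResult] = {}
    for response in responses:
        vecs = [prof.loc[idx, response].to_numpy(dtype=float) for idx in groups.values()]
        if any(len(v) == 0 for v in vecs):
            empty = [l for l, v in zip(labels, vecs) if len(v) == 0]
            warnings.warn(
                f"region differential for {response} skipped: empty group(s) {empty}"
            )
            continue
        results[response] = kw_dunn(vecs, labels=labels, one_sided=one_sided)
    return results


def region_differential_stratified(
    profiles: pd.DataFrame,
    assign_df: pd.DataFrame,
    by: str,
    responses: Sequence[str] = ("tpm_max", "tpm_cv"),
    one_sided: bool = False,
) -> dict[tuple, dict[str, KWDunnResult]]:
    """Repeat the region-differential contrast within strata of ``by``
    (e.g. ``motif_size`` or ``canonical_motif``)."""
    out: dict[tuple, dict[str, KWDunnResult]] = {}
    for value, grp in assign_df.groupby(by):
        res = region_differential(profiles, grp, responses=responses, one_sided=one_sided)
        if res:
            out[(by, value)] = res
    return out


def tidy_test_results(results: Mapping[str, KWDunnResult]) -> pd.DataFrame:
    """Flatten KW + Dunn results into a tidy table."""
    rows = []
    for name, res in results.items():
        rows.append((name, "kruskal-wallis", "", "", res.kw.statistic, res.kw.df, res.kw.p_value, np.nan))
        for r in res.dunn.itertuples(index=False):
            rows.append((name, "dunn", str(r.group_i), str(r.group_j), r.z, np.nan, r.p, r.p_adj))
    return pd.DataFrame(
        rows,
        columns=["contrast", "test", "group_i", "group_j", "statistic", "df", "p", "p_adj"],
    )
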