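"""Nonparametric statistical battery for repeated-measures contrast data.

The pipeline mirrors the analysis conventions of small imaging cohorts:
Shapiro-Wilk normality screening; paired two-sided t-test or Wilcoxon
signed-rank for condition-vs-comparator contrasts; a Friedman omnibus
test across all repeated conditions with Dunn post hoc z-tests under
Bonferroni correction; and Kruskal-Wallis for independent group
comparisons.  Signed-rank p-values are exact for n <= 25 (no ties) and
use the continuity-corrected normal approximation otherwise;
Kruskal-Wallis p-values are exact by enumeration for small samples.
The Friedman statistic is computed from mid-ranks with the standard tie
correction.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "StatsReport",
    "normality_screen",
    "paired_compare",
    "friedman_omnibus",
    "dunn_bonferroni",
    "group_compare_independent",
    "run_paper_battery",
]

ALPHA_DEFAULT = 0.05


@dataclass(frozen=True)
class StatsReport:
    """Machine-readable result of one hypothesis test."""

    test: str
    comparison: str
    statistic: float
    p_raw: float
    p_adjusted: float
    n: int
    note: str = ""

    def __post_init__(self) -> None:
        for p in (self.p_raw, self.p_adjusted):
            if not (math.isnan(p) or 0.0 <= p <= 1.0):
                raise ValueError(f"p-value outside [0, 1]: {p}")

    def to_dict(self) -> dict:
        return {
            "test": self.test,
            "comparison": self.comparison,
            "statistic": self.statistic,
            "p_raw": self.p_raw,
            "p_adjusted": self.p_adjusted,
            "n": self.n,
            "note": self.note,
        }


def normality_screen(sample) -> tuple[float, bool]:
    """Shapiro-Wilk screen; returns (p, is_normal) with flag = p > 0.05."""
    x = np.asarray(sample, dtype=float)
    x = x[~np.isnan(x)]
    if x.size < 3:
        raise ValueError(f"normality screen needs n >= 3, got {x.size}")
    if np.ptp(x) == 0:
        raise ValueError("constant sample: normality is undefined")
    p = float(sps.shapiro(x).pvalue)
    return p, p > ALPHA_DEFAULT


def _signed_rank(x: np.ndarray, y: np.ndarray, n: int) -> StatsReport:
    d = x - y
    nz = d[d != 0]
    if nz.size == 0:
        return StatsReport(
            "wilcoxon_signed_rank", "", 0.0, 1.0, 1.0, n,
            note="all paired differences zero",
        )
    ranks = sps.rankdata(np.abs(nz))
    has_ties = np.unique(np.abs(nz)).size < nz.size
    if nz.size <= 25 and not has_ties:
        res = sps.wilcoxon(nz, method="exact")
    else:
        res = sps.wilcoxon(nz, method="approx", correction=True)
    return StatsReport(
        "wilcoxon_signed_rank", "", float(res.statistic), float(res.pvalue),
        float(res.pvalue), n,
        note="exact" if (nz.size <= 25 and not has_ties) else "normal approx, cc",
    )


def paired_compare(x, y, route: str = "auto") -> StatsReport:
    """Two-sided paired comparison of two repeated measurements.

    ``route``: ``"parametric"`` (paired t), ``"nonparametric"`` (Wilcoxon
    signed-rank), or ``"auto"`` (signed-rank unless the Shapiro-Wilk
    screen of the differences passes).  Pairs with a missing value are
    deleted; n >= 5 complete pairs are required.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    n = int(x.size)
    if n < 5:
        raise ValueError(f"need >= 5 complete pairs, got {n}")
    d = x - y
    if route == "auto":
        try:
            _, is_normal = normality_screen(d)
        except ValueError:
            is_normal = False
        route = "parametric" if is_normal else "nonparametric"
    if route == "parametric":
        if np.all(d == 0):
            return StatsReport(
                "paired_t", "", 0.0, 1.0, 1.0, n, note="all paired differences zero"
            )
        if np.ptp(d) == 0:
            return StatsReport(
                "paired_t", "", math.nan, math.nan, math.nan, n,
                note="degenerate: zero-variance nonzero differences, statistic undefined",
            )
        res = sps.ttest_rel(x, y)
        return StatsReport(
            "paired_t", "", float(res.statistic), float(res.pvalue),
            float(res.pvalue), n,
        )
    if route == "nonparametric":
        return _signed_rank(x, y, n)
    raise ValueError(f"unknown route {route!r}")


def _friedman_from_ranks(ranks: np.ndarray) -> tuple[float, float, int, int]:
    """Tie-corrected Friedman chi-square from within-row mid-ranks."""
    n, k = ranks.shape
    rbar = ranks.mean(axis=0)
    ss = float(np.sum((rbar - (k + 1) / 2.0) ** 2))
    raw = 12.0 * n / (k * (k + 1)) * ss
    ties = 0.0
    for row in ranks:
        _, counts = np.unique(row, return_counts=True)
        ties += float(np.sum(counts**3 - counts))
    correction = 1.0 - ties / (n * k * (k**2 - 1))
    if correction <= 0:
        return 0.0, 1.0, n, k  # every row fully tied: no evidence at all
    stat = raw / correction
    p = float(sps.chi2.sf(stat, k - 1))
    return stat, p, n, k


def friedman_omnibus(table) -> StatsReport:
    """Friedman test over an ``n x k`` repeated-measures block (k >= 3).

    ``table`` is a 2D array or DataFrame, rows = subjects, columns =
    conditions.  Rows containing missing values are deleted listwise and
    counted in the report note.
    """
    arr = np.asarray(table, dtype=float)
    if arr.ndim != 2 or arr.shape[1] < 3:
        raise ValueError("need an n x k block with k >= 3")
    complete = ~np.isnan(arr).any(axis=1)
    dropped = int((~complete).sum())
    arr = arr[complete]
    if arr.shape[0] < 2:
        raise ValueError("fewer than 2 complete rows after listwise deletion")
    ranks = sps.rankdata(arr, axis=1)
    stat, p, n, k = _friedman_from_ranks(ranks)
    return StatsReport(
        "friedman", f"{k} conditions", stat, p, p, n,
        note=f"df={k - 1}; {dropped} incomplete rows dropped" if dropped else f"df={k - 1}",
    )


def dunn_bonferroni(table, comparisons, columns=None) -> list[StatsReport]:
    """Dunn post hoc z-tests on Friedman mean ranks, Bonferroni-adjusted.

    ``comparisons`` is a list of (name_i, name_j) column-name pairs; the
    adjustment multiplier is the number of requested comparisons.  Pass a
    DataFrame, or an array plus ``columns``.
    """
    if isinstance(table, pd.DataFrame):
        columns = list(table.columns)
        arr = table.to_numpy(dtype=float)
    else:
        arr = np.asarray(table, dtype=float)
        if columns is None:
            raise ValueError("column names required for an array table")
        columns = list(columns)
    for a, b in comparisons:
        if a not in columns or b not in columns:
            raise ValueError(f"comparison ({a!r}, {b!r}) not in table columns")
    complete = ~np.isnan(arr).any(axis=1)
    arr = arr[complete]
    n, k = arr.shape
    ranks = sps.rankdata(arr, axis=1)
    rbar = ranks.mean(axis=0)
    se = math.sqrt(k * (k + 1) / (6.0 * n))
    m = len(comparisons)
    out = []
    for a, b in comparisons:
        z = (rbar[columns.index(a)] - rbar[columns.index(b)]) / se
        p_raw = float(2.0 * sps.norm.sf(abs(z)))
        out.append(
            StatsReport(
                "dunn_bonferroni", f"{a} vs {b}", float(z), p_raw,
                min(1.0, m * p_raw), n, note=f"m={m}",
            )
        )
    return out


def _kruskal_h(groups: list[np.ndarray]) -> float:
    all_vals = np.concatenate(groups)
    ranks = sps.rankdata(all_vals)
    n = all_vals.size
    h = 0.0
    start = 0
    for g in groups:
        r = ranks[start : start + g.size]
        h += r.sum() ** 2 / g.size
        start += g.size
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    _, counts = np.unique(all_vals, return_counts=True)
    ties = float(np.sum(counts**3 - counts))
    correction = 1.0 - ties / (n**3 - n)
    if correction <= 0:
        return 0.0
    return h / correction


def group_compare_independent(
    groups, exact_max_n: int = 12, labels: list[str] | None = None
) -> StatsReport:
    """Kruskal-Wallis H with tie correction for >= 2 independent groups.

    For total n <= ``exact_max_n`` the p-value is exact: every distinct
    assignment of the pooled observations to the group sizes is
    enumerated and ``P(H >= H_obs)`` reported.  Larger samples use the
    chi-square approximation.  Each group needs n >= 3.
    """
    gs = [np.asarray(g, dtype=float) for g in groups]
    gs = [g[~np.isnan(g)] for g in gs]
    if len(gs) < 2:
        raise ValueError("need >= 2 groups")
    for i, g in enumerate(gs):
        if g.size < 3:
            raise ValueError(f"group {i} has n = {g.size} < 3")
    total = int(sum(g.size for g in gs))
    h_obs = _kruskal_h(gs)
    label = " vs ".join(labels) if labels else f"{len(gs)} groups"
    if total <= exact_max_n:
        pooled = np.concatenate(gs)
        sizes = [g.size for g in gs]
        count = 0
        n_assign = 0
        idx = np.arange(total)
        for assign in _group_assignments(idx, sizes):
            n_assign += 1
            perm_groups = [pooled[list(a)] for a in assign]
            if _kruskal_h(perm_groups) >= h_obs - 1e-12:
                count += 1
        p = count / n_assign
        note = f"exact permutation p over {n_assign} assignments"
    else:
        p = float(sps.chi2.sf(h_obs, len(gs) - 1))
        note = f"chi-square approximation, df={len(gs) - 1}"
    return StatsReport("kruskal_wallis", label, h_obs, p, p, total, note=note)


def _group_assignments(idx: np.ndarray, sizes: list[int]):
    """All distinct partitions of ``idx`` into ordered groups of the given sizes."""
    if len(sizes) == 1:
        yield (tuple(idx),)
        return
    for first in itertools.combinations(idx, sizes[0]):
        rest = np.array([i for i in idx if i not in set(first)])
        for tail in _group_assignments(rest, sizes[1:]):
            yield (first,) + tail


@dataclass
class BatteryResult:
    """Full output of the cohort statistical battery."""

    llc_summary: pd.DataFrame
    reports: list[StatsReport] = field(default_factory=list)
    subgroups: dict = field(default_factory=dict)

    def reports_frame(self) -> pd.DataFrame:
        return pd.DataFrame([r.to_dict() for r in self.reports])

    def to_dict(self) -> dict:
        return {
            "llc_summary": self.llc_summary.reset_index().to_dict(orient="records"),
            "reports": [r.to_dict() for r in self.reports],
            "subgroups": {
                e: {
                    "llc_summary": sub["llc_summary"].reset_index().to_dict(orient="records"),
                    "reports": [r.to_dict() for r in sub["reports"]],
                }
                for e, sub in self.subgroups.items()
            },
        }


def _battery_core(table: pd.DataFrame, comparator: str, scope: str) -> tuple[pd.DataFrame, list[StatsReport]]:
    wide = table.pivot(index="lesion_id", columns="condition", values="llc")
    conditions = [c for c in wide.columns if c != comparator]

    summary = table.groupby("condition")["llc"].agg(["mean", "std", "count"])
    summary.columns = ["mean_llc", "sd_llc", "n"]

    reports: list[StatsReport] = []
    if comparator in wide.columns:
        for cond in conditions:
            pair = wide[[cond, comparator]].dropna()
            if len(pair) < 5:
                reports.append(
                    StatsReport(
                        "paired_compare", f"{scope}: {cond} vs {comparator}",
                        math.nan, math.nan, math.nan, len(pair),
                        note="skipped: fewer than 5 complete pairs",
                    )
                )
                continue
            rep = paired_compare(pair[cond], pair[comparator], route="auto")
            reports.append(
                StatsReport(
                    rep.test, f"{scope}: {cond} vs {comparator}", rep.statistic,
                    rep.p_raw, rep.p_adjusted, rep.n, rep.note,
                )
            )
    if wide.shape[1] >= 3:
        om = friedman_omnibus(wide)
        reports.append(
            StatsReport(om.test, f"{scope}: omnibus {wide.shape[1]} conditions",
                        om.statistic, om.p_raw, om.p_adjusted, om.n, om.note)
        )
        if comparator in wide.columns:
            posthoc = dunn_bonferroni(
                wide, [(c, comparator) for c in conditions]
            )
            for rep in posthoc:
                reports.append(
                    StatsReport(rep.test, f"{scope}: {rep.comparison}", rep.statistic,
                                rep.p_raw, rep.p_adjusted, rep.n, rep.note)
                )
    return summary, reports


def run_paper_battery(
    cohort_table: pd.DataFrame,
    comparator: str = "VIBE",
    subgroup_entities: tuple[str, ...] = ("HCC", "CRC"),
    all_pairs: bool = False,
) -> BatteryResult:
    """Run the full battery on a long-format contrast table.

    Emits mean +/- SD LLC per condition, paired comparisons of every IR
    condition against the comparator, the Friedman omnibus across all
    conditions with Dunn-Bonferroni post hocs, a paired lesion-vs-liver
    T1 comparison when T1 covariates are present, and the same analyses
    within each requested entity subgroup that is present in the data.
    With ``all_pairs`` the post hoc family is every condition pair
    instead of the condition-vs-comparator set.
    """
    summary, reports = _battery_core(cohort_table, comparator, "all")
    if all_pairs:
        wide = cohort_table.pivot(index="lesion_id", columns="condition", values="llc")
        pairs = list(itertools.combinations(wide.columns, 2))
        for rep in dunn_bonferroni(wide, pairs):
            reports.append(
                StatsReport(rep.test, f"all-pairs: {rep.comparison}", rep.statistic,
                            rep.p_raw, rep.p_adjusted, rep.n, rep.note)
            )

    if {"t1_lesion_ms", "t1_liver_ms"}.issubset(cohort_table.columns):
        per_lesion = cohort_table.drop_duplicates("lesion_id")
        if len(per_lesion) >= 5:
            rep = paired_compare(
                per_lesion["t1_lesion_ms"], per_lesion["t1_liver_ms"], route="auto"
            )
            reports.append(
                StatsReport(rep.test, "all: T1 lesion vs liver", rep.statistic,
                            rep.p_raw, rep.p_adjusted, rep.n, rep.note)
            )

    subgroups: dict = {}
    if "entity" in cohort_table.columns:
        for entity in subgroup_entities:
            sub = cohort_table[cohort_table["entity"] == entity]
            if sub["lesion_id"].nunique() < 5:
                continue
            s_summary, s_reports = _battery_core(sub, comparator, entity)
            if {"t1_lesion_ms", "t1_liver_ms"}.issubset(sub.columns):
                per_lesion = sub.drop_duplicates("lesion_id")
                rep = paired_compare(
                    per_lesion["t1_lesion_ms"], per_lesion["t1_liver_ms"], route="auto"
                )
                s_reports.append(
                    StatsReport(rep.test, f"{entity}: T1 lesion vs liver",
                                rep.statistic, rep.p_raw, rep.p_adjusted, rep.n, rep.note)
                )
            subgroups[entity] = {"llc_summary": s_summary, "reports": s_reports}
    return BatteryResult(llc_summary=summary, reports=reports, subgroups=subgroups)
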