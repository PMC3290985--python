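"""Cohort-level statistics on HI / MCR screening results.

Covers the distributional questions a screening-level cumulative risk
assessment asks of a cohort of mixtures:

* how large are MCR values for mixtures with typical, high-end and
  upper-bound hazard (HI-centile subgroups);
* how do the two non-detect conventions (case 1 / case 2) shift HI and MCR;
* does MCR fall as HI rises (Kendall rank trend, per mixture and on
  medians of mixtures grouped by component count n);
* do subgroups differ (two-sample Wilcoxon rank-sum comparisons).

Conventions fixed here (they matter for reproducibility): the centile of
the r-th ranked of N values is 100·r/N and a centile band (low, high] is
half-open; a mixture with HI exactly at the split threshold counts as
"above"; Kendall's tau is the tie-corrected tau-b; rank-sum p-values are
computed by exhaustive enumeration when the arrangement count is small and
by the tie-corrected normal approximation otherwise. No multiple-testing
correction is applied — p-values are reported raw.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exposure import ExposureAssumptions, NDCase
from .mcr_core import (
    ExclusionLog,
    MixtureResult,
    SampleMixture,
    apply_exclusion_criteria,
    cumulative_contribution,
    rank_chemicals_by_mean_hq,
    results_to_frame,
    screen_cohort,
)
from .pd_registry import PDRegistry

__all__ = [
    "AnalysisConfig",
    "CentileRange",
    "CohortSummary",
    "GroupSummary",
    "HISplit",
    "TrendResult",
    "centile_subgroup",
    "grouped_median_trend",
    "kendall_trend",
    "run_full_analysis",
    "split_by_hi",
    "summarize_group",
    "wilcoxon_compare",
]

#: Exact rank-sum enumeration is used while C(m+n, m) stays below this.
MAX_EXACT_ARRANGEMENTS = 200_000


@dataclass(frozen=True)
class CentileRange:
    """Half-open centile band (low, high] on a 0–100 scale."""

    low: float
    high: float

    def __post_init__(self) -> None:
        if not (0 <= self.low < self.high <= 100):
            raise ValueError(f"need 0 <= low < high <= 100, got {self.low}–{self.high}")

    def __str__(self) -> str:
        return f"{self.low:g}-{self.high:g}"


@dataclass(frozen=True)
class GroupSummary:
    n_members: int
    min_mcr: float
    max_mcr: float
    mean_mcr: float


@dataclass(frozen=True)
class TrendResult:
    """Kendall tau-b and its two-sided p-value over n observation pairs."""

    tau: float
    p_value: float
    n: int


@dataclass(frozen=True)
class HISplit:
    """Partition of results at an HI threshold (HI >= threshold → above)."""

    below: tuple[MixtureResult, ...]
    above: tuple[MixtureResult, ...]
    threshold: float

    @property
    def frac_above(self) -> float:
        total = len(self.below) + len(self.above)
        return len(self.above) / total if total else float("nan")

    @property
    def frac_below(self) -> float:
        total = len(self.below) + len(self.above)
        return len(self.below) / total if total else float("nan")


def centile_subgroup(
    results: Sequence[MixtureResult], crange: CentileRange
) -> list[MixtureResult]:
    """Members whose HI centile rank falls in the band.

    Results are ranked by HI ascending (ties broken by sample id, so the
    selection is deterministic); the r-th of N has centile 100·r/N and is a
    member iff low < 100·r/N <= high.
    """
    if len(results) == 0:
        raise ValueError("empty results")
    ordered = sorted(results, key=lambda r: (r.hi, r.sample_id))
    n = len(ordered)
    return [
        r
        for rank, r in enumerate(ordered, start=1)
        if crange.low < 100.0 * rank / n <= crange.high
    ]


def summarize_group(members: Sequence[MixtureResult]) -> GroupSummary:
    """Min/max/mean MCR of a subgroup; members with undefined MCR are dropped."""
    if len(members) == 0:
        raise ValueError("empty group")
    mcrs = [m.mcr for m in members if m.mcr_defined]
    if not mcrs:
        return GroupSummary(0, float("nan"), float("nan"), float("nan"))
    return GroupSummary(
        n_members=len(mcrs),
        min_mcr=min(mcrs),
        max_mcr=max(mcrs),
        mean_mcr=float(np.mean(mcrs)),
    )


def split_by_hi(
    results: Sequence[MixtureResult], threshold: float = 1.0
) -> HISplit:
    """Partition results into HI < threshold and HI >= threshold."""
    if len(results) == 0:
        raise ValueError("empty results")
    below = tuple(r for r in results if r.hi < threshold)
    above = tuple(r for r in results if r.hi >= threshold)
    return HISplit(below=below, above=above, threshold=threshold)


def kendall_trend(x: Sequence[float], y: Sequence[float]) -> TrendResult:
    """Kendall tau-b rank correlation with a two-sided p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.size < 2:
        raise ValueError("need at least 2 observations")
    res = stats.kendalltau(x, y)
    return TrendResult(tau=float(res.statistic), p_value=float(res.pvalue), n=x.size)


def _exact_rank_sum_p(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided exact rank-sum p by enumerating group assignments.

    Works with ties (midranks): every way of choosing which pooled ranks
    belong to the first group is equally likely under the null, and the
    p-value counts arrangements whose rank-sum deviates from its null mean
    at least as much as the observed one.
    """
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    m, n_total = len(a), len(pooled)
    w_obs = ranks[:m].sum()
    mu = m * (n_total + 1) / 2.0
    dev = abs(w_obs - mu) - 1e-12
    hits = 0
    total = 0
    for idx in combinations(range(n_total), m):
        w = ranks[list(idx)].sum()
        if abs(w - mu) >= dev:
            hits += 1
        total += 1
    return hits / total


def wilcoxon_compare(
    a: Sequence[float], b: Sequence[float], paired: bool = False
) -> float:
    """Two-sided Wilcoxon comparison of two samples; returns the p-value.

    Default is the unpaired two-sample rank-sum test: exact by enumeration
    while the number of group assignments is manageable
    (:data:`MAX_EXACT_ARRANGEMENTS`), otherwise the tie-corrected normal
    approximation. ``paired=True`` runs the signed-rank test instead (for
    per-sample case-1 vs case-2 comparisons).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    if paired:
        if a.size != b.size:
            raise ValueError("paired comparison needs equal lengths")
        d = a - b
        if np.all(d == 0):
            return 1.0
        return float(stats.wilcoxon(a, b).pvalue)
    if math.comb(a.size + b.size, a.size) <= MAX_EXACT_ARRANGEMENTS:
        return _exact_rank_sum_p(a, b)
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):  # degenerate: no information, p = 1
        return 1.0
    return float(
        stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic").pvalue
    )


def grouped_median_trend(
    results: Sequence[MixtureResult],
    group_key: Optional[str] = None,
    min_group: int = 5,
    value: str = "hi",
) -> Optional[TrendResult]:
    """Kendall trend on (n, median value) pairs of results grouped by n.

    ``group_key`` is ``"n_detects"``, ``"n_analytes"`` or ``None`` for the
    result's own case-dependent n. Groups with fewer than ``min_group``
    members are dropped (medians of tiny groups are unstable). Returns
    ``None`` when fewer than two groups survive.
    """
    if len(results) == 0:
        raise ValueError("empty results")
    if value not in ("hi", "mcr"):
        raise ValueError(f"value must be 'hi' or 'mcr', got {value!r}")
    groups: dict[int, list[float]] = {}
    for r in results:
        v = getattr(r, value)
        if value == "mcr" and not r.mcr_defined:
            continue
        key = getattr(r, group_key) if group_key else r.n
        groups.setdefault(int(key), []).append(v)
    pairs = [
        (k, float(np.median(vs)))
        for k, vs in sorted(groups.items())
        if len(vs) >= min_group
    ]
    if len(pairs) < 2:
        return None
    ns, medians = zip(*pairs)
    return kendall_trend(ns, medians)


# --------------------------------------------------------------------------
# Full-cohort orchestration


@dataclass(frozen=True)
class AnalysisConfig:
    """Knobs of the cohort screen; defaults follow the ground-water study design.

    ``top_k``/``min_detects`` drive the data reduction (samples must have
    assayed the top-k mean-HQ chemicals and carry >= min_detects detects);
    ``compare_top_k`` lists the panel-completeness options whose effect on
    subgroup MCR is tabulated side by side.
    """

    top_k: int = 3
    min_detects: int = 5
    compare_top_k: tuple[int, ...] = (3, 6)
    centile_ranges: tuple[tuple[float, float], ...] = ((49, 51), (94, 96), (98, 100))
    hi_threshold: float = 1.0
    nd_cases: tuple[str, ...] = ("case1", "case2")
    min_group: int = 5
    ranking_nd_case: str = "case2"
    mean_denominator: str = "measured"
    n_top_contributors: int = 6
    paired_case_comparison: bool = False

    def ranges(self) -> tuple[CentileRange, ...]:
        return tuple(CentileRange(lo, hi) for lo, hi in self.centile_ranges)

    def cases(self) -> tuple[NDCase, ...]:
        return tuple(NDCase.coerce(c) for c in self.nd_cases)


@dataclass
class CohortSummary:
    """Everything the cohort screen reports, in tabular form."""

    config: AnalysisConfig
    n_input: int
    exclusion_log: ExclusionLog
    n_retained: int
    ranking: pd.Series
    topk_comparison: pd.DataFrame
    counts_table: pd.DataFrame
    top_contributors: pd.DataFrame
    results: dict[NDCase, list[MixtureResult]]
    hi_mcr_summary: pd.DataFrame
    hi_split: pd.DataFrame
    centile_summary: pd.DataFrame
    trends: pd.DataFrame
    case_comparison: pd.DataFrame
    undefined_mcr_counts: dict[str, int] = field(default_factory=dict)

    def results_frame(self, nd_case: NDCase | str) -> pd.DataFrame:
        return results_to_frame(self.results[NDCase.coerce(nd_case)])

    def to_text(self) -> str:
        lines: list[str] = []
        w = lines.append
        w("Cumulative-risk screen: HI / MCR cohort summary")
        w("=" * 48)
        w(f"samples in: {self.n_input}")
        for rule, count in sorted(self.exclusion_log.counts().items()):
            w(f"  excluded ({rule}): {count}")
        w(f"samples retained: {self.n_retained}")
        for case, n_undef in sorted(self.undefined_mcr_counts.items()):
            if n_undef:
                w(f"  {case}: {n_undef} mixture(s) with HI = 0 (MCR undefined)")
        w("")
        w("Top mean-HQ chemicals and cumulative share of mean HI:")
        w(self.top_contributors.to_string(index=False))
        w("")
        w("Panel-completeness options (mean MCR by HI-centile band):")
        w(self.topk_comparison.to_string(index=False))
        w("")
        w("Detect / non-detect / panel counts over retained samples:")
        w(self.counts_table.to_string(index=False))
        w("")
        w("HI and MCR distribution by ND convention:")
        w(self.hi_mcr_summary.to_string(index=False))
        w("")
        w(f"Split at HI = {self.config.hi_threshold:g}:")
        w(self.hi_split.to_string(index=False))
        w("")
        w("HI-centile subgroups (MCR):")
        w(self.centile_summary.to_string(index=False))
        w("")
        w("Kendall trends:")
        w(self.trends.to_string(index=False))
        w("")
        w("Case 1 vs case 2:")
        w(self.case_comparison.to_string(index=False))
        w("")
        return "\n".join(lines)

    def write(self, outdir: str | Path) -> None:
        """Write all tables as CSV plus a plain-text summary."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for case, res in self.results.items():
            results_to_frame(res).to_csv(
                outdir / f"results_{case.value}.csv", index=False
            )
        self.exclusion_log.entries.to_csv(outdir / "exclusion_log.csv", index=False)
        self.ranking.rename_axis("chemical").reset_index().to_csv(
            outdir / "ranking.csv", index=False
        )
        tables = {
            "topk_comparison": self.topk_comparison,
            "counts_table": self.counts_table,
            "top_contributors": self.top_contributors,
            "hi_mcr_summary": self.hi_mcr_summary,
            "hi_split": self.hi_split,
            "centile_summary": self.centile_summary,
            "trends": self.trends,
            "case_comparison": self.case_comparison,
        }
        for name, table in tables.items():
            table.to_csv(outdir / f"{name}.csv", index=False)
        (outdir / "summary.txt").write_text(self.to_text())


def _centile_means(
    results: Sequence[MixtureResult], ranges: Sequence[CentileRange]
) -> dict[str, float]:
    out = {}
    for cr in ranges:
        members = centile_subgroup(results, cr)
        out[str(cr)] = summarize_group(members).mean_mcr if members else float("nan")
    return out


def run_full_analysis(
    cohort: Sequence[SampleMixture],
    registry: PDRegistry,
    assumptions: ExposureAssumptions = ExposureAssumptions(),
    config: AnalysisConfig = AnalysisConfig(),
) -> CohortSummary:
    """Data reduction, per-sample screening and all cohort statistics.

    Deterministic given the cohort and configuration. The steps are:
    rank chemicals by mean HQ (for the panel-completeness rule) → exclude
    samples → screen the retained samples under each ND convention →
    tabulate distributional summaries, centile subgroups, HI splits,
    Kendall trends and case comparisons.
    """
    if len(cohort) == 0:
        raise ValueError("empty cohort")
    ranking_case = NDCase.coerce(config.ranking_nd_case)
    ranges = config.ranges()

    ranking = rank_chemicals_by_mean_hq(
        cohort, registry, assumptions, ranking_case, config.mean_denominator
    )
    retained, exclusion_log = apply_exclusion_criteria(
        cohort, list(ranking.index), config.top_k, config.min_detects
    )
    if len(retained) == 0:
        raise ValueError("exclusion criteria removed every sample")

    # effect of alternative panel-completeness requirements (top-3 vs top-6)
    topk_rows = []
    for k in config.compare_top_k:
        retained_k, _ = apply_exclusion_criteria(
            cohort, list(ranking.index), k, config.min_detects
        )
        res_k = screen_cohort(retained_k, registry, assumptions, ranking_case)
        row: dict[str, object] = {"top_k": k, "n_retained": len(retained_k)}
        row.update(
            {f"mean_mcr_{name}": v for name, v in _centile_means(res_k, ranges).items()}
        )
        topk_rows.append(row)
    topk_comparison = pd.DataFrame(topk_rows)

    results = {
        case: screen_cohort(retained, registry, assumptions, case)
        for case in config.cases()
    }
    undefined_mcr_counts = {
        case.value: sum(not r.mcr_defined for r in res)
        for case, res in results.items()
    }

    counts = pd.DataFrame(
        {
            "n_detects": [s.n_detects for s in retained],
            "n_nondetects": [s.n_analytes - s.n_detects for s in retained],
            "n_analytes": [s.n_analytes for s in retained],
        }
    )
    counts_table = pd.DataFrame(
        {
            "statistic": ["minimum", "maximum", "mean"],
            **{
                col: [counts[col].min(), counts[col].max(), counts[col].mean()]
                for col in counts.columns
            },
        }
    )

    # top contributors to the mean HI of the retained cohort (case-2 view);
    # all-sample denominators so that shares of the mean HI sum to 100%
    retained_ranking = rank_chemicals_by_mean_hq(
        retained, registry, assumptions, ranking_case, denominator="all"
    )
    mean_hi = float(np.mean([r.hi for r in results.get(ranking_case, [])])) if (
        ranking_case in results
    ) else float(
        np.mean(
            [r.hi for r in screen_cohort(retained, registry, assumptions, ranking_case)]
        )
    )
    top = retained_ranking.head(config.n_top_contributors)
    top_contributors = pd.DataFrame(
        {
            "chemical": top.index,
            "mean_hq": top.values,
            "cumulative_pct_of_mean_hi": cumulative_contribution(
                top.values, mean_hi
            ),
        }
    )

    summary_rows = []
    split_rows = []
    trend_rows = []
    for case, res in results.items():
        defined = [r for r in res if r.mcr_defined]
        his = [r.hi for r in res]
        mcrs = [r.mcr for r in defined]
        summary_rows.append(
            {
                "nd_case": case.value,
                "hi_min": min(his),
                "hi_max": max(his),
                "hi_mean": float(np.mean(his)),
                "mcr_min": min(mcrs) if mcrs else float("nan"),
                "mcr_max": max(mcrs) if mcrs else float("nan"),
                "mcr_mean": float(np.mean(mcrs)) if mcrs else float("nan"),
            }
        )

        split = split_by_hi(res, config.hi_threshold)
        below_s = summarize_group(split.below) if split.below else None
        above_s = summarize_group(split.above) if split.above else None
        below_mcr = [r.mcr for r in split.below if r.mcr_defined]
        above_mcr = [r.mcr for r in split.above if r.mcr_defined]
        p_split = (
            wilcoxon_compare(below_mcr, above_mcr)
            if below_mcr and above_mcr
            else float("nan")
        )
        for side, frac, summ in (
            ("below", split.frac_below, below_s),
            ("above", split.frac_above, above_s),
        ):
            split_rows.append(
                {
                    "nd_case": case.value,
                    "side": side,
                    "pct_of_mixtures": 100.0 * frac,
                    "n": len(split.below if side == "below" else split.above),
                    "min_mcr": summ.min_mcr if summ else float("nan"),
                    "max_mcr": summ.max_mcr if summ else float("nan"),
                    "mean_mcr": summ.mean_mcr if summ else float("nan"),
                    "wilcoxon_p_below_vs_above": p_split,
                }
            )

        # trends: MCR vs HI on individual mixtures; HI and MCR vs n on
        # individual mixtures and on medians of n-groups
        tr = kendall_trend([r.hi for r in defined], [r.mcr for r in defined])
        trend_rows.append(
            {"nd_case": case.value, "relation": "mcr_vs_hi", "scope": "individual",
             "tau": tr.tau, "p_value": tr.p_value, "n": tr.n}
        )
        for value, label in (("hi", "hi_vs_n"), ("mcr", "mcr_vs_n")):
            vals = [(r.n, getattr(r, value)) for r in res
                    if value == "hi" or r.mcr_defined]
            tr = kendall_trend([v[0] for v in vals], [v[1] for v in vals])
            trend_rows.append(
                {"nd_case": case.value, "relation": label, "scope": "individual",
                 "tau": tr.tau, "p_value": tr.p_value, "n": tr.n}
            )
            gtr = grouped_median_trend(res, min_group=config.min_group, value=value)
            trend_rows.append(
                {"nd_case": case.value, "relation": label, "scope": "grouped_median",
                 "tau": gtr.tau if gtr else float("nan"),
                 "p_value": gtr.p_value if gtr else float("nan"),
                 "n": gtr.n if gtr else 0}
            )

    hi_mcr_summary = pd.DataFrame(summary_rows)
    hi_split = pd.DataFrame(split_rows)
    trends = pd.DataFrame(trend_rows)

    # HI-centile subgroup tables per case + case1-vs-case2 comparison per band
    centile_rows = []
    cases = config.cases()
    for cr in ranges:
        members_by_case = {
            case: centile_subgroup(results[case], cr) for case in cases
        }
        p_between = float("nan")
        if len(cases) == 2:
            m0 = [r.mcr for r in members_by_case[cases[0]] if r.mcr_defined]
            m1 = [r.mcr for r in members_by_case[cases[1]] if r.mcr_defined]
            if m0 and m1:
                if config.paired_case_comparison and len(m0) == len(m1):
                    p_between = wilcoxon_compare(m0, m1, paired=True)
                else:
                    p_between = wilcoxon_compare(m0, m1)
        for case in cases:
            members = members_by_case[case]
            summ = summarize_group(members) if members else None
            centile_rows.append(
                {
                    "centile_range": str(cr),
                    "nd_case": case.value,
                    "n_members": summ.n_members if summ else 0,
                    "min_mcr": summ.min_mcr if summ else float("nan"),
                    "max_mcr": summ.max_mcr if summ else float("nan"),
                    "mean_mcr": summ.mean_mcr if summ else float("nan"),
                    "wilcoxon_p_between_cases": p_between,
                }
            )
    centile_summary = pd.DataFrame(centile_rows)

    # case-1 vs case-2 shift (per-sample HI difference; MCR comparison)
    case_rows = []
    if len(cases) == 2:
        res_a = {r.sample_id: r for r in results[cases[0]]}
        res_b = {r.sample_id: r for r in results[cases[1]]}
        common = sorted(set(res_a) & set(res_b))
        hi_diff = [res_b[s].hi - res_a[s].hi for s in common]
        mcr_a = [res_a[s].mcr for s in common if res_a[s].mcr_defined]
        mcr_b = [res_b[s].mcr for s in common if res_b[s].mcr_defined]
        if config.paired_case_comparison and len(mcr_a) == len(mcr_b):
            p_mcr = wilcoxon_compare(mcr_a, mcr_b, paired=True)
        else:
            p_mcr = wilcoxon_compare(mcr_a, mcr_b)
        case_rows.append(
            {
                "comparison": f"{cases[1].value} - {cases[0].value}",
                "mean_hi_difference": float(np.mean(hi_diff)),
                "wilcoxon_p_hi": wilcoxon_compare(
                    [res_a[s].hi for s in common],
                    [res_b[s].hi for s in common],
                    paired=config.paired_case_comparison,
                ),
                "wilcoxon_p_mcr": p_mcr,
            }
        )
    case_comparison = pd.DataFrame(
        case_rows,
        columns=["comparison", "mean_hi_difference", "wilcoxon_p_hi", "wilcoxon_p_mcr"],
    )

    return CohortSummary(
        config=config,
        n_input=len(cohort),
        exclusion_log=exclusion_log,
        n_retained=len(retained),
        ranking=ranking,
        topk_comparison=topk_comparison,
        counts_table=counts_table,
        top_contributors=top_contributors,
        results=results,
        hi_mcr_summary=hi_mcr_summary,
        hi_split=hi_split,
        centile_summary=centile_summary,
        trends=trends,
        case_comparison=case_comparison,
        undefined_mcr_counts=undefined_mcr_counts,
    )
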