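"""Hazard index and maximum cumulative ratio per mixture, plus the
cohort-reduction rules applied before MCR statistics are reported.

For a mixture with component hazard quotients HQ_i:

* ``HI = sum_i HQ_i`` — the cumulative exposure metric under dose additivity;
* ``MHQ = max_i HQ_i`` — the largest single-chemical contribution;
* ``MCR = HI / MHQ`` — bounded by 1 and the number of components with
  nonzero HQ. MCR near 1 means one chemical carries the mixture's predicted
  toxicity; MCR near n means the toxicity is spread evenly and a
  chemical-by-chemical assessment would miss most of it.

Cohort reduction mirrors survey practice: samples that did not assay the
chemicals known to dominate the cohort's hazard (the top-k by mean HQ) are
excluded, as are samples with too few detected components for a stable MCR.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .exposure import ExposureAssumptions, Measurement, NDCase, sample_hqs
from .pd_registry import PDRegistry, normalize_name

__all__ = [
    "MixtureResult",
    "SampleMixture",
    "apply_exclusion_criteria",
    "cumulative_contribution",
    "evaluate_mixture",
    "missed_fraction",
    "rank_chemicals_by_mean_hq",
    "results_to_frame",
    "screen_cohort",
    "screen_sample",
]

RESULT_COLUMNS = (
    "sample_id",
    "nd_case",
    "hi",
    "mhq",
    "mcr",
    "n_detects",
    "n_analytes",
    "top_chemical",
)


@dataclass(frozen=True)
class SampleMixture:
    """All measurements taken on one water sample."""

    sample_id: str
    measurements: tuple[Measurement, ...]

    def __post_init__(self) -> None:
        if len(self.measurements) == 0:
            raise ValueError(f"sample {self.sample_id!r} has no measurements")

    @property
    def n_analytes(self) -> int:
        """Number of analytes on this sample's panel (measured)."""
        return sum(m.measured for m in self.measurements)

    @property
    def n_detects(self) -> int:
        return sum(m.detected for m in self.measurements)

    def measured_analytes(self) -> set[str]:
        """Normalized names of the analytes measured in this sample."""
        return {normalize_name(m.analyte) for m in self.measurements if m.measured}


@dataclass(frozen=True)
class MixtureResult:
    """HI / MHQ / MCR for one sample under one ND convention.

    ``mcr`` is NaN when the mixture's HI is zero (possible under case 1 when
    nothing was detected); such results are excluded from MCR summaries.
    """

    sample_id: str
    hi: float
    mhq: float
    mcr: float
    n_detects: int
    n_analytes: int
    nd_case: NDCase
    top_chemical: Optional[str]

    @property
    def mcr_defined(self) -> bool:
        return not math.isnan(self.mcr)

    @property
    def n(self) -> int:
        """The component count 'n' under this result's ND convention.

        With NDs at zero (case 1) only detects contribute, so n is the
        detect count; with NDs imputed (case 2) every measured analyte
        contributes, so n is the panel size.
        """
        return self.n_detects if self.nd_case is NDCase.CASE1 else self.n_analytes


def evaluate_mixture(
    hqs: Mapping[str, float] | Sequence[float],
    n_detects: Optional[int] = None,
    n_analytes: Optional[int] = None,
    nd_case: NDCase | str = NDCase.CASE1,
    sample_id: str = "",
) -> MixtureResult:
    """HI, MHQ and MCR of one HQ vector.

    ``hqs`` may be a chemical → HQ mapping or a plain sequence (components
    are then auto-named ``c0, c1, ...``). Ties in the maximum are broken in
    favour of the lexicographically first chemical name; the tie does not
    affect HI or MCR. An all-zero vector yields HI = 0 with MCR = NaN.
    """
    if not isinstance(hqs, Mapping):
        hqs = {f"c{i}": v for i, v in enumerate(hqs)}
    if len(hqs) == 0:
        raise ValueError("empty HQ vector")
    values = np.asarray(list(hqs.values()), dtype=float)
    if (values < 0).any():
        raise ValueError("HQ values must be >= 0")

    hi = float(values.sum())
    mhq = float(values.max())
    if mhq > 0:
        mcr = hi / mhq
        top_chemical = min(name for name, v in hqs.items() if v == mhq)
    else:
        mcr = float("nan")
        top_chemical = None
    return MixtureResult(
        sample_id=sample_id,
        hi=hi,
        mhq=mhq,
        mcr=mcr,
        n_detects=n_detects if n_detects is not None else int((values > 0).sum()),
        n_analytes=n_analytes if n_analytes is not None else len(values),
        nd_case=NDCase.coerce(nd_case),
        top_chemical=top_chemical,
    )


def missed_fraction(mcr: float) -> float:
    """Fraction of a mixture's HI missed by assessing only its top chemical.

    1 − 1/MCR: an MCR of 5 means 80% of the hazard index is invisible to a
    chemical-by-chemical assessment; an MCR of 1.25 means 20%.
    """
    if mcr < 1:
        raise ValueError(f"MCR must be >= 1, got {mcr}")
    return 1.0 - 1.0 / mcr


def screen_sample(
    sample: SampleMixture,
    registry: PDRegistry,
    assumptions: ExposureAssumptions = ExposureAssumptions(),
    nd_case: NDCase | str = NDCase.CASE1,
) -> MixtureResult:
    """Full HQ → HI/MCR evaluation of one sample."""
    hqs = sample_hqs(sample, registry, assumptions, nd_case)
    if not hqs:
        # no measured analyte had a PD: an empty, flagged result
        return MixtureResult(
            sample_id=sample.sample_id,
            hi=0.0,
            mhq=0.0,
            mcr=float("nan"),
            n_detects=sample.n_detects,
            n_analytes=sample.n_analytes,
            nd_case=NDCase.coerce(nd_case),
            top_chemical=None,
        )
    return evaluate_mixture(
        hqs,
        n_detects=sample.n_detects,
        n_analytes=sample.n_analytes,
        nd_case=nd_case,
        sample_id=sample.sample_id,
    )


def screen_cohort(
    cohort: Iterable[SampleMixture],
    registry: PDRegistry,
    assumptions: ExposureAssumptions = ExposureAssumptions(),
    nd_case: NDCase | str = NDCase.CASE1,
) -> list[MixtureResult]:
    return [screen_sample(s, registry, assumptions, nd_case) for s in cohort]


def results_to_frame(results: Iterable[MixtureResult]) -> pd.DataFrame:
    """Tabulate results in the standard column order."""
    rows = [
        {
            "sample_id": r.sample_id,
            "nd_case": r.nd_case.value,
            "hi": r.hi,
            "mhq": r.mhq,
            "mcr": r.mcr,
            "n_detects": r.n_detects,
            "n_analytes": r.n_analytes,
            "top_chemical": r.top_chemical,
        }
        for r in results
    ]
    return pd.DataFrame(rows, columns=list(RESULT_COLUMNS))


def rank_chemicals_by_mean_hq(
    cohort: Sequence[SampleMixture],
    registry: PDRegistry,
    assumptions: ExposureAssumptions = ExposureAssumptions(),
    nd_case: NDCase | str = NDCase.CASE2,
    denominator: str = "measured",
) -> pd.Series:
    """Chemicals ordered by their mean HQ across a cohort (descending).

    ``denominator`` controls the averaging population: ``"measured"`` (the
    default) divides each chemical's HQ total by the number of samples in
    which it was measured, so sparsely assayed chemicals are not diluted;
    ``"all"`` divides by the cohort size. Ranking defaults to case-2
    imputation so that non-detects of potent chemicals still register.
    Ties in the mean are broken alphabetically for determinism.
    """
    if len(cohort) == 0:
        raise ValueError("empty cohort")
    if denominator not in ("measured", "all"):
        raise ValueError(f"denominator must be 'measured' or 'all', got {denominator!r}")
    totals: dict[str, float] = {}
    counts: dict[str, int] = {}
    for sample in cohort:
        for chem, hq in sample_hqs(sample, registry, assumptions, nd_case).items():
            totals[chem] = totals.get(chem, 0.0) + hq
            counts[chem] = counts.get(chem, 0) + 1
    n_all = len(cohort)
    means = {
        chem: total / (counts[chem] if denominator == "measured" else n_all)
        for chem, total in totals.items()
    }
    ser = pd.Series(means, name="mean_hq")
    return ser.sort_index().sort_values(ascending=False, kind="stable")


@dataclass
class ExclusionLog:
    """Accounting of which reduction rule removed each excluded sample."""

    entries: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["sample_id", "rule"])
    )

    def counts(self) -> dict[str, int]:
        if self.entries.empty:
            return {}
        return self.entries["rule"].value_counts().to_dict()


def apply_exclusion_criteria(
    cohort: Sequence[SampleMixture],
    ranked_chemicals: Sequence[str],
    top_k: int = 3,
    min_detects: int = 5,
) -> tuple[list[SampleMixture], ExclusionLog]:
    """Drop samples that miss a top-k chemical or have too few detects.

    A sample is retained only if every one of the ``top_k`` highest-ranked
    chemicals was on its analytical panel AND it has at least
    ``min_detects`` detected components. The log records, per excluded
    sample, the first rule that removed it (panel rule checked first).
    """
    if top_k < 0 or min_detects < 0:
        raise ValueError("top_k and min_detects must be >= 0")
    required = {normalize_name(c) for c in list(ranked_chemicals)[:top_k]}
    retained: list[SampleMixture] = []
    log_rows: list[dict[str, str]] = []
    for sample in cohort:
        if not required <= sample.measured_analytes():
            log_rows.append({"sample_id": sample.sample_id, "rule": "missing_top_k"})
        elif sample.n_detects < min_detects:
            log_rows.append({"sample_id": sample.sample_id, "rule": "too_few_detects"})
        else:
            retained.append(sample)
    log = ExclusionLog(pd.DataFrame(log_rows, columns=["sample_id", "rule"]))
    return retained, log


def cumulative_contribution(
    mean_hqs: Sequence[float], total_mean_hi: float
) -> np.ndarray:
    """Running percentage of the cohort mean HI explained by ranked chemicals.

    ``mean_hqs`` must already be in rank order; the result is the cumulative
    sum divided by ``total_mean_hi`` as percentages (0–100).
    """
    arr = np.asarray(mean_hqs, dtype=float)
    partial = float(arr.sum())
    if total_mean_hi <= 0:
        raise ValueError("total mean HI must be > 0")
    if partial > total_mean_hi * (1 + 1e-12):
        raise ValueError(
            f"sum of mean HQs ({partial}) exceeds total mean HI ({total_mean_hi})"
        )
    return np.cumsum(arr) / total_mean_hi * 100.0
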