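"""Water concentration → chronic dose → hazard quotient.

The screening dose model is deliberately simple and conservative: a person
drinks a fixed volume of untreated well water every day for a lifetime and
absorbs the full amount of every contaminant in it. Non-detects (NDs) —
analytes that were measured but fell below the analytical detection limit
(DL) — are handled under two bracketing conventions:

* **case 1** — NDs contribute nothing (concentration 0);
* **case 2** — NDs sit at DL/sqrt(2), the standard substitution for
  lognormally distributed environmental concentrations.

All concentrations are mg/L and all doses mg/kg/day; inputs in other units
must be converted before they reach this module.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from enum import Enum
from typing import TYPE_CHECKING, Optional

if TYPE_CHECKING:  # pragma: no cover
    from .pd_registry import PDRegistry

__all__ = [
    "ExposureAssumptions",
    "Measurement",
    "NDCase",
    "concentration_to_dose",
    "hazard_quotient",
    "impute_nd",
    "sample_hqs",
]


class NDCase(str, Enum):
    """Non-detect substitution convention."""

    CASE1 = "case1"  # ND -> 0
    CASE2 = "case2"  # ND -> DL / sqrt(2)

    @classmethod
    def coerce(cls, value: "NDCase | str") -> "NDCase":
        return value if isinstance(value, cls) else cls(str(value).lower())


@dataclass(frozen=True)
class Measurement:
    """One analyte in one water sample.

    ``measured`` records whether the analyte was on this sample's analytical
    panel at all (surveys rarely assay every analyte in every sample);
    ``detected`` whether it was quantified above its detection limit.
    """

    analyte: str
    measured: bool
    detected: bool
    concentration: Optional[float] = None  # mg/L, present iff detected
    detection_limit: Optional[float] = None  # mg/L, present iff measured

    def __post_init__(self) -> None:
        if self.detected and not self.measured:
            raise ValueError(f"{self.analyte!r}: detected implies measured")
        if self.detected:
            if self.concentration is None or self.concentration < 0:
                raise ValueError(
                    f"{self.analyte!r}: a detect needs a concentration >= 0"
                )
        elif self.concentration is not None:
            raise ValueError(f"{self.analyte!r}: non-detect carries no concentration")
        if self.detection_limit is not None and not (self.detection_limit > 0):
            raise ValueError(f"{self.analyte!r}: detection limit must be > 0")
        if not self.measured and self.detection_limit is not None:
            raise ValueError(f"{self.analyte!r}: unmeasured analyte has no DL")


@dataclass(frozen=True)
class ExposureAssumptions:
    """Screening intake assumptions: 2 L/day, 60 kg, 100% oral absorption."""

    water_intake: float = 2.0  # L/day
    body_weight: float = 60.0  # kg
    absorption_fraction: float = 1.0

    def __post_init__(self) -> None:
        if self.water_intake <= 0 or self.body_weight <= 0:
            raise ValueError("water_intake and body_weight must be > 0")
        if not (0 < self.absorption_fraction <= 1):
            raise ValueError("absorption_fraction must be in (0, 1]")


def impute_nd(detection_limit: float, nd_case: NDCase | str) -> float:
    """Substituted concentration (mg/L) for a non-detect."""
    if detection_limit < 0:
        raise ValueError(f"detection limit must be >= 0, got {detection_limit}")
    nd_case = NDCase.coerce(nd_case)
    if nd_case is NDCase.CASE1:
        return 0.0
    return detection_limit / math.sqrt(2)


def concentration_to_dose(
    concentration: float, assumptions: ExposureAssumptions = ExposureAssumptions()
) -> float:
    """Chronic daily dose (mg/kg/day) from a water concentration (mg/L)."""
    if concentration < 0:
        raise ValueError(f"concentration must be >= 0, got {concentration}")
    return (
        concentration
        * assumptions.water_intake
        * assumptions.absorption_fraction
        / assumptions.body_weight
    )


def hazard_quotient(dose: float, pd: float) -> float:
    """HQ = dose / permitted dose; the toxicity-normalized exposure."""
    if pd <= 0:
        raise ValueError(f"permitted dose must be > 0, got {pd}")
    if dose < 0:
        raise ValueError(f"dose must be >= 0, got {dose}")
    return dose / pd


def sample_hqs(
    sample,
    registry: "PDRegistry",
    assumptions: ExposureAssumptions = ExposureAssumptions(),
    nd_case: NDCase | str = NDCase.CASE1,
) -> dict[str, float]:
    """Per-chemical HQ vector for one sample under one ND convention.

    Only measured analytes with a resolvable PD contribute; anything else
    (off-panel analytes, chemicals with no PD and no parent mapping) is
    omitted — its contribution to the hazard index is modelled as zero.
    A non-detect without a recorded DL cannot be imputed under case 2 and
    is dropped with a warning.

    Returns a dict keyed by the analyte names as they appear in the sample.
    """
    nd_case = NDCase.coerce(nd_case)
    hqs: dict[str, float] = {}
    for m in sample.measurements:
        if not m.measured:
            continue
        rec = registry.lookup(m.analyte)
        if rec is None:
            continue
        if m.detected:
            conc = m.concentration
        else:
            if m.detection_limit is None:
                warnings.warn(
                    f"sample {getattr(sample, 'sample_id', '?')}: non-detect "
                    f"{m.analyte!r} has no detection limit; dropped",
                    stacklevel=2,
                )
                continue
            conc = impute_nd(m.detection_limit, nd_case)
        hqs[m.analyte] = hazard_quotient(
            concentration_to_dose(conc, assumptions), rec.pd
        )
    return hqs
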