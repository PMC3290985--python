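"""Permitted-dose (PD) registry.

A PD is the chronic daily oral dose of a chemical (mg/kg/day) below which
non-carcinogenic effects are not expected — an RfD, PAD, MRL, TDI, ADI or a
value derived from an MCL. The registry loads a chemical → PD table, resolves
metabolites to their parent compound's PD, and converts an inhalation
reference concentration (RfC) to an oral-equivalent PD for compounds that
lack an oral value.

Chemical names in published PD tables are typographically inconsistent
(stray hyphens, spacing, case), so all lookups go through
:func:`normalize_name`, which is deliberately aggressive: case, whitespace
and hyphens are all erased before comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterator, Mapping, Optional

import pandas as pd

__all__ = [
    "PDRecord",
    "PDRegistry",
    "PDTableFormatError",
    "PDValidationError",
    "PlausibilityWarning",
    "load_pd_table",
    "load_default_registry",
    "normalize_name",
    "rfc_to_oral_pd",
]

#: Accepted regulatory bases for a permitted dose.
VALID_BASES = frozenset({"RfD", "PAD", "MRL", "MCL", "TDI", "ADI", "derived"})

#: PDs above this many mg/kg/day are flagged as implausibly large for a
#: drinking-water contaminant. Flagged records are kept verbatim — the
#: registry reproduces its source table and never silently "corrects" it.
DEFAULT_PLAUSIBILITY_CEILING = 10.0

REQUIRED_COLUMNS = ("chemical", "pd_mg_per_kg_day", "source_code", "basis")


class PDTableFormatError(ValueError):
    """The PD table file does not have the expected columns/layout."""


class PDValidationError(ValueError):
    """The PD table parsed but its contents violate registry invariants."""


class PlausibilityWarning(UserWarning):
    """A PD value exceeds the configured plausibility ceiling."""


def normalize_name(name: str) -> str:
    """Canonical matching key for a chemical name.

    Casefolds, unifies apostrophe variants, and strips all whitespace and
    hyphens, so e.g. ``"Dibromochloro- methane"`` and
    ``"dibromochloromethane"`` compare equal.
    """
    s = name.casefold().replace("’", "'").replace("‘", "'")
    return "".join(ch for ch in s if not ch.isspace() and ch != "-")


@dataclass(frozen=True)
class PDRecord:
    """One chemical's permitted dose with provenance."""

    chemical: str
    pd: float  # mg/kg/day
    source_code: int
    basis: str

    def __post_init__(self) -> None:
        if not self.chemical or not self.chemical.strip():
            raise PDValidationError("chemical name must be non-empty")
        if not (self.pd > 0):
            raise PDValidationError(
                f"{self.chemical!r}: permitted dose must be > 0, got {self.pd}"
            )
        if self.basis not in VALID_BASES:
            raise PDValidationError(
                f"{self.chemical!r}: basis {self.basis!r} not one of {sorted(VALID_BASES)}"
            )


class PDRegistry:
    """Queryable collection of :class:`PDRecord` plus metabolite → parent map.

    Lookup order is: direct record, then the parent compound's record (a
    metabolite is assumed to carry its parent's toxicity), then ``None`` —
    "no PD" is a modelled outcome (the chemical simply contributes nothing
    to a hazard index), not an error.
    """

    def __init__(
        self,
        records: list[PDRecord] | tuple[PDRecord, ...],
        parent_map: Optional[Mapping[str, str]] = None,
        plausibility_ceiling: float = DEFAULT_PLAUSIBILITY_CEILING,
    ) -> None:
        self._records: dict[str, PDRecord] = {}
        for rec in records:
            key = normalize_name(rec.chemical)
            if key in self._records:
                raise PDValidationError(
                    f"duplicate chemical {rec.chemical!r} "
                    f"(collides with {self._records[key].chemical!r})"
                )
            self._records[key] = rec

        self._parent_map: dict[str, str] = {}
        for metabolite, parent in (parent_map or {}).items():
            pkey = normalize_name(parent)
            if pkey not in self._records:
                raise PDValidationError(
                    f"parent map target {parent!r} (for {metabolite!r}) has no PD record"
                )
            self._parent_map[normalize_name(metabolite)] = pkey

        self.flagged: tuple[str, ...] = tuple(
            r.chemical for r in self._records.values() if r.pd > plausibility_ceiling
        )
        if self.flagged:
            warnings.warn(
                "PD values above the plausibility ceiling "
                f"({plausibility_ceiling} mg/kg/day) kept verbatim: "
                + ", ".join(self.flagged),
                PlausibilityWarning,
                stacklevel=2,
            )

    def lookup(self, chemical: str) -> Optional[PDRecord]:
        """Resolve a chemical to its PD record, via the parent map if needed.

        Returns ``None`` when neither a direct record nor a parent mapping
        exists — the caller treats the chemical as contributing no hazard.
        """
        key = normalize_name(chemical)
        rec = self._records.get(key)
        if rec is not None:
            return rec
        parent_key = self._parent_map.get(key)
        if parent_key is not None:
            return self._records[parent_key]
        return None

    def __len__(self) -> int:
        return len(self._records)

    def __iter__(self) -> Iterator[PDRecord]:
        return iter(self._records.values())

    def __contains__(self, chemical: str) -> bool:
        return self.lookup(chemical) is not None

    @property
    def parent_map(self) -> dict[str, str]:
        """Normalized metabolite-key → normalized parent-key associations."""
        return dict(self._parent_map)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "chemical": r.chemical,
                    "pd_mg_per_kg_day": r.pd,
                    "source_code": r.source_code,
                    "basis": r.basis,
                }
                for r in self
            ]
        )

    def save(self, path: str | Path) -> None:
        """Write the records back out in the load format (round-trippable)."""
        self.to_frame().to_csv(path, index=False)


def _read_parent_map(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, dtype=str)
    missing = {"metabolite", "parent"} - set(df.columns)
    if missing:
        raise PDTableFormatError(f"parent map missing column(s): {sorted(missing)}")
    return dict(zip(df["metabolite"], df["parent"]))


def load_pd_table(
    path: str | Path,
    sep: str = ",",
    parent_map_path: Optional[str | Path] = None,
    plausibility_ceiling: float = DEFAULT_PLAUSIBILITY_CEILING,
) -> PDRegistry:
    """Load a permitted-dose table (and optional metabolite map) from CSV.

    The table must carry the header
    ``chemical,pd_mg_per_kg_day,source_code,basis``. Non-numeric or
    non-positive PDs are rejected; duplicate chemicals (after name
    normalization) are reported together in one error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    missing = set(REQUIRED_COLUMNS) - set(df.columns)
    if missing:
        raise PDTableFormatError(
            f"{path}: missing required column(s): {sorted(missing)}"
        )

    records: list[PDRecord] = []
    for i, row in df.iterrows():
        try:
            pd_value = float(row["pd_mg_per_kg_day"])
        except ValueError as exc:
            raise PDValidationError(
                f"{path} row {i}: non-numeric PD {row['pd_mg_per_kg_day']!r}"
            ) from exc
        records.append(
            PDRecord(
                chemical=str(row["chemical"]).strip(),
                pd=pd_value,
                source_code=int(row["source_code"]),
                basis=str(row["basis"]).strip(),
            )
        )

    seen: dict[str, str] = {}
    duplicates: list[str] = []
    for rec in records:
        key = normalize_name(rec.chemical)
        if key in seen:
            duplicates.append(f"{seen[key]!r}/{rec.chemical!r}")
        else:
            seen[key] = rec.chemical
    if duplicates:
        raise PDValidationError(f"{path}: duplicate chemicals: {', '.join(duplicates)}")

    parent_map = _read_parent_map(parent_map_path) if parent_map_path else None
    return PDRegistry(records, parent_map, plausibility_ceiling=plausibility_ceiling)


def load_default_registry(
    plausibility_ceiling: float = DEFAULT_PLAUSIBILITY_CEILING,
) -> PDRegistry:
    """Registry from the packaged PD table and metabolite → parent map."""
    data = resources.files("mcrscreen").joinpath("data")
    with resources.as_file(data.joinpath("pd_table.csv")) as pd_path, resources.as_file(
        data.joinpath("parent_map.csv")
    ) as map_path:
        return load_pd_table(
            pd_path,
            parent_map_path=map_path,
            plausibility_ceiling=plausibility_ceiling,
        )


def rfc_to_oral_pd(
    rfc: float,
    breathing_rate: float = 20.0,
    clearance_fraction: float = 0.4,
    body_weight: float = 60.0,
) -> float:
    """Oral-equivalent permitted dose from an inhalation RfC.

    Parameters
    ----------
    rfc : float
        Inhalation reference concentration, mg/m^3.
    breathing_rate : float
        Daily air intake, m^3/day (screening default 20).
    clearance_fraction : float
        Fraction of the inhaled amount absorbed via the lung (default 0.4).
    body_weight : float
        kg (screening default 60).

    Returns
    -------
    float
        mg/kg/day. The value is returned unrounded; rounding to match a
        published table entry is a presentation choice left to the caller.
    """
    if rfc < 0 or breathing_rate < 0 or not (0 <= clearance_fraction <= 1):
        raise ValueError("rfc, breathing_rate must be >= 0; clearance_fraction in [0, 1]")
    if body_weight <= 0:
        raise ValueError("body_weight must be > 0")
    return rfc * breathing_rate * clearance_fraction / body_weight
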