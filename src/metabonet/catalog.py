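"""Catalog of the 15 physiological variables.

The analysis operates on 15 non-derivative, continuous physiological
variables covering anthropometry (waist, weight, height), fasting blood
chemistry (glucose, HbA1c, insulin, HDL, LDL, triglycerides, uric acid,
urea, creatinine) and vital signs (axillary temperature, systolic and
diastolic blood pressure).  Each catalog entry carries the measurement
unit and a permissive plausibility range used for cell-level cleaning:
values outside the range are treated as recording errors incompatible
with life, not as extreme phenotypes.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class VariableEntry:
    """One physiological variable: name, unit, plausibility range, kind."""

    name: str
    unit: str
    plausible_min: float
    plausible_max: float
    kind: str  # anthropometric | blood | vital

    def __post_init__(self) -> None:
        if not self.plausible_min < self.plausible_max:
            raise ValueError(
                f"{self.name}: plausible_min must be < plausible_max "
                f"({self.plausible_min} >= {self.plausible_max})"
            )
        if self.kind not in ("anthropometric", "blood", "vital"):
            raise ValueError(f"{self.name}: unknown kind {self.kind!r}")


#: Canonical variable order, shared by every downstream matrix and network.
VARIABLE_NAMES: tuple[str, ...] = (
    "glucose",
    "hba1c",
    "insulin",
    "hdl",
    "ldl",
    "triglycerides",
    "uric_acid",
    "urea",
    "creatinine",
    "waist",
    "weight",
    "height",
    "temperature",
    "systolic",
    "diastolic",
)

_DEFAULT_ENTRIES: tuple[VariableEntry, ...] = (
    VariableEntry("glucose", "mmol/L", 1.0, 40.0, "blood"),
    VariableEntry("hba1c", "%", 2.0, 20.0, "blood"),
    VariableEntry("insulin", "pmol/L", 1.0, 3000.0, "blood"),
    VariableEntry("hdl", "mmol/L", 0.1, 5.0, "blood"),
    VariableEntry("ldl", "mmol/L", 0.1, 15.0, "blood"),
    VariableEntry("triglycerides", "mmol/L", 0.1, 30.0, "blood"),
    VariableEntry("uric_acid", "umol/L", 50.0, 1200.0, "blood"),
    VariableEntry("urea", "mmol/L", 0.5, 60.0, "blood"),
    VariableEntry("creatinine", "umol/L", 10.0, 2000.0, "blood"),
    VariableEntry("waist", "cm", 40.0, 200.0, "anthropometric"),
    VariableEntry("weight", "kg", 25.0, 300.0, "anthropometric"),
    VariableEntry("height", "cm", 100.0, 230.0, "anthropometric"),
    VariableEntry("temperature", "degC", 30.0, 43.0, "vital"),
    VariableEntry("systolic", "mmHg", 60.0, 260.0, "vital"),
    VariableEntry("diastolic", "mmHg", 30.0, 200.0, "vital"),
)


@dataclass(frozen=True)
class VariableCatalog:
    """The set of physiological variables the pipeline recognises.

    Exactly 15 entries in the canonical order; used for schema
    validation on read and for plausibility masking on clean.
    """

    entries: tuple[VariableEntry, ...] = field(default=_DEFAULT_ENTRIES)

    def __post_init__(self) -> None:
        names = tuple(e.name for e in self.entries)
        if len(names) != len(set(names)):
            raise ValueError("duplicate variable names in catalog")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(e.name for e in self.entries)

    def __getitem__(self, name: str) -> VariableEntry:
        for e in self.entries:
            if e.name == name:
                return e
        raise KeyError(name)

    def __contains__(self, name: str) -> bool:
        return any(e.name == name for e in self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    def with_ranges(self, ranges: dict[str, tuple[float, float]]) -> "VariableCatalog":
        """Return a copy with some plausibility ranges overridden."""
        new = []
        for e in self.entries:
            if e.name in ranges:
                lo, hi = ranges[e.name]
                new.append(VariableEntry(e.name, e.unit, lo, hi, e.kind))
            else:
                new.append(e)
        return VariableCatalog(tuple(new))


def default_catalog() -> VariableCatalog:
    """The shipped catalog of 15 variables with permissive ranges."""
    return VariableCatalog()
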