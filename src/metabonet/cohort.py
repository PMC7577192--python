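"""Reading, validating, cleaning, and age-stratifying cohort tables.

A cohort is represented as a :class:`pandas.DataFrame` with columns
``participant_id`` (str), ``age`` (int, years), ``sex`` ('M'/'F') and
the 15 physiological variables of the :class:`~metabonet.catalog.VariableCatalog`
(float; ``NaN`` marks a missing measurement).  Cleaning masks individual
implausible cells — it never drops participants — and reports every
masked cell.  Stratification partitions the cohort into half-open
``[lower, upper)`` age bins; the default six strata are <25, 25-34,
35-44, 45-54, 55-64 and 65+.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from metabonet.catalog import VariableCatalog, default_catalog

logger = logging.getLogger(__name__)

#: Default age-stratum lower boundaries (years); top bin is open-ended.
DEFAULT_BOUNDARIES: tuple[int, ...] = (18, 25, 35, 45, 55, 65)

DEMOGRAPHIC_COLUMNS = ("participant_id", "age", "sex")


@dataclass
class ExclusionReport:
    """Cells masked during cleaning, with per-variable counts."""

    masked_cells: list[dict] = field(default_factory=list)

    @property
    def counts_by_variable(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for cell in self.masked_cells:
            counts[cell["variable"]] = counts.get(cell["variable"], 0) + 1
        return counts

    @property
    def n_masked(self) -> int:
        return len(self.masked_cells)


@dataclass
class AgeStratum:
    """A half-open [lower, upper) age bin and its cohort members."""

    label: str
    lower: int
    upper: float  # np.inf for the open top bin
    members: pd.DataFrame

    @property
    def n(self) -> int:
        return len(self.members)


class SchemaError(ValueError):
    """The input table does not match the variable catalog schema."""


def read_cohort(path, catalog: VariableCatalog | None = None) -> pd.DataFrame:
    """Read a delimited cohort table and validate it against the catalog.

    Parameters
    ----------
    path : str or file-like
        CSV file (UTF-8, header row) with columns ``age``, ``sex``,
        the 15 catalog variables, and optionally ``participant_id``
        (generated as ``P000001`` ... when absent).
    catalog : VariableCatalog, optional
        Schema to validate against; the default catalog when omitted.

    Returns
    -------
    pandas.DataFrame
        One row per input row; unparseable numeric cells become NaN.

    Raises
    ------
    SchemaError
        On an empty file, a missing required column, a column not in
        the catalog, an unparseable/out-of-range age, or a sex value
        other than M/F.
    """
    catalog = catalog or default_catalog()
    df = pd.read_csv(path, dtype=str, skipinitialspace=True)
    if df.empty:
        raise SchemaError("empty cohort file")
    df.columns = [c.strip() for c in df.columns]

    required = ["age", "sex", *catalog.names]
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"missing required column: {col!r}")
    known = set(DEMOGRAPHIC_COLUMNS) | set(catalog.names)
    unknown = [c for c in df.columns if c not in known]
    if unknown:
        raise SchemaError(f"columns not in variable catalog: {unknown}")

    out = pd.DataFrame(index=df.index)
    if "participant_id" in df.columns:
        out["participant_id"] = df["participant_id"].astype(str)
    else:
        out["participant_id"] = [f"P{i + 1:06d}" for i in range(len(df))]

    age = pd.to_numeric(df["age"], errors="coerce")
    if age.isna().any():
        bad = df.loc[age.isna(), "age"].iloc[0]
        raise SchemaError(f"unparseable age value: {bad!r}")
    if (age < 18).any() or (age > 120).any():
        raise SchemaError("ages must lie within [18, 120]")
    out["age"] = age.astype(int)

    sex = df["sex"].str.strip().str.upper()
    if not sex.isin(["M", "F"]).all():
        bad = sex[~sex.isin(["M", "F"])].iloc[0]
        raise SchemaError(f"sex must be M or F, got {bad!r}")
    out["sex"] = sex

    for name in catalog.names:
        out[name] = pd.to_numeric(df[name], errors="coerce")
    return out


def write_cohort(table: pd.DataFrame, path) -> None:
    """Write a cohort table as CSV, round-tripping values through repr
    precision (missing cells become empty fields)."""
    table.to_csv(path, index=False, float_format="%.12g")


def clean_cohort(
    table: pd.DataFrame,
    catalog: VariableCatalog | None = None,
    waist_height_ratio: tuple[float, float] = (0.25, 1.0),
) -> tuple[pd.DataFrame, ExclusionReport]:
    """Mask physiologically implausible cells; never drop participants.

    Two rules apply, mirroring the exclusion criteria of community
    biomarker surveys: (1) any cell outside its catalog plausibility
    range is masked with reason ``implausible``; (2) waist/height pairs
    whose ratio falls outside ``waist_height_ratio`` are mutually
    inconsistent and the waist cell is masked with reason
    ``inconsistent`` (waist is by far the more error-prone of the two
    measurements).  Cleaning is total (never raises) and idempotent.

    Returns the cleaned copy and an :class:`ExclusionReport` listing
    every masked cell.
    """
    catalog = catalog or default_catalog()
    out = table.copy()
    report = ExclusionReport()

    for entry in catalog.entries:
        col = out[entry.name]
        bad = col.notna() & ((col < entry.plausible_min) | (col > entry.plausible_max))
        for idx in out.index[bad]:
            cell = {
                "participant_id": out.at[idx, "participant_id"],
                "variable": entry.name,
                "value": float(col.at[idx]),
                "reason": "implausible",
            }
            report.masked_cells.append(cell)
            logger.info(
                "masked %s/%s=%.6g (%s)",
                cell["participant_id"], entry.name, cell["value"], cell["reason"],
            )
        out.loc[bad, entry.name] = np.nan

    lo, hi = waist_height_ratio
    ratio = out["waist"] / out["height"]
    bad = ratio.notna() & ((ratio < lo) | (ratio > hi))
    for idx in out.index[bad]:
        cell = {
            "participant_id": out.at[idx, "participant_id"],
            "variable": "waist",
            "value": float(out.at[idx, "waist"]),
            "reason": "inconsistent",
        }
        report.masked_cells.append(cell)
        logger.info(
            "masked %s/waist=%.6g (inconsistent with height %.6g)",
            cell["participant_id"], cell["value"], float(out.at[idx, "height"]),
        )
    out.loc[bad, "waist"] = np.nan

    return out, report


def _stratum_label(lower: int, upper: float) -> str:
    if np.isinf(upper):
        return f"{lower}+"
    return f"<{upper:.0f}" if lower <= 18 else f"{lower}-{upper - 1:.0f}"


def stratify_by_age(
    table: pd.DataFrame, boundaries: tuple[int, ...] = DEFAULT_BOUNDARIES
) -> list[AgeStratum]:
    """Partition the cohort into half-open age bins.

    ``boundaries`` are the strictly increasing lower bin edges; the last
    bin is open-ended.  Every participant lands in exactly one stratum;
    an age below the first boundary is a hard error.
    """
    bounds = list(boundaries)
    if any(b2 <= b1 for b1, b2 in zip(bounds, bounds[1:])):
        raise ValueError("stratum boundaries must be strictly increasing")
    if (table["age"] < bounds[0]).any():
        raise ValueError(f"ages below the first stratum boundary ({bounds[0]})")

    edges = bounds + [np.inf]
    strata = []
    for lower, upper in zip(edges[:-1], edges[1:]):
        mask = (table["age"] >= lower) & (table["age"] < upper)
        strata.append(
            AgeStratum(
                label=_stratum_label(lower, upper),
                lower=int(lower),
                upper=upper,
                members=table.loc[mask].copy(),
            )
        )
    assert sum(s.n for s in strata) == len(table)
    return strata
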