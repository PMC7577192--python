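"""Pathological-state assessment and age-trend statistics.

Twelve binary pathological states are derived from the 15 physiological
variables by literature cut-offs (risk thresholds, deliberately lower
than diagnostic ones): hyperglycemia, high HbA1c, insulin resistance
(HOMA-IR), low HDL, high LDL, hypertriglyceridemia, hyperuricemia,
azotemia, low eGFR (CKD-EPI), overweight (waist), high temperature and
high blood pressure.  Comparisons with a cut-off are strict; a state is
missing whenever any of its inputs is missing.  The harmonized
metabolic-syndrome (MetS) flag — at least 3 of 5 criteria — and the
per-variable OLS age slopes / per-state Cochran–Armitage trend tests
are computed here as well.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from metabonet.cohort import AgeStratum

__all__ = [
    "STATE_NAMES",
    "ThresholdRule",
    "default_rules",
    "homa_ir",
    "egfr",
    "assess_states",
    "mets_harmonized",
    "TrendResult",
    "trend_statistics",
]

#: Conversion factor insulin pmol/L -> uU/mL (literature range 6.0-6.945).
INSULIN_PMOL_PER_UU = 6.945


def homa_ir(
    glucose: float | np.ndarray,
    insulin: float | np.ndarray,
    insulin_factor: float = INSULIN_PMOL_PER_UU,
) -> float | np.ndarray:
    """Homeostasis Model Assessment of insulin resistance.

    ``(glucose [mmol/L] * insulin [uU/mL]) / 22.5`` with insulin given
    in pmol/L and converted by ``insulin_factor``.  Non-positive or
    missing inputs yield NaN.
    """
    glucose = np.asarray(glucose, dtype=float)
    insulin = np.asarray(insulin, dtype=float)
    with np.errstate(invalid="ignore"):
        out = glucose * (insulin / insulin_factor) / 22.5
        out = np.where((glucose > 0) & (insulin > 0), out, np.nan)
    return float(out) if out.ndim == 0 else out


def egfr(
    creatinine: float | np.ndarray,
    age: float | np.ndarray,
    sex: str | np.ndarray,
    race_coefficient: float = 1.0,
) -> float | np.ndarray:
    """Estimated glomerular filtration rate, CKD-EPI 2009 creatinine.

    Creatinine in umol/L (converted to mg/dL by /88.4); returns
    mL/min/1.73 m^2.  The race coefficient defaults to 1 (omitted);
    pass 1.159 to include it.  Non-positive creatinine yields NaN.
    """
    scr = np.asarray(creatinine, dtype=float) / 88.4
    age = np.asarray(age, dtype=float)
    female = np.char.upper(np.asarray(sex, dtype=str)) == "F"
    kappa = np.where(female, 0.7, 0.9)
    alpha = np.where(female, -0.329, -0.411)
    with np.errstate(invalid="ignore"):
        ratio = scr / kappa
        out = (
            141.0
            * np.minimum(ratio, 1.0) ** alpha
            * np.maximum(ratio, 1.0) ** -1.209
            * 0.993 ** age
            * np.where(female, 1.018, 1.0)
            * race_coefficient
        )
        out = np.where(scr > 0, out, np.nan)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class ThresholdRule:
    """One pathological-state rule.

    ``cutoff`` is a single number, a ``{"M": .., "F": ..}`` mapping for
    sex-specific thresholds, or — for multi-input rules — a list of
    such entries aligned with ``inputs`` and combined by OR (used by
    the blood-pressure rule: systolic > 120 OR diastolic > 80).
    ``inputs`` may name raw variables or the derived indices
    ``homa_ir`` and ``egfr``.
    """

    state: str
    inputs: tuple[str, ...]
    direction: str  # above | below
    cutoff: object
    age_dependent: bool = False

    def __post_init__(self) -> None:
        if self.direction not in ("above", "below"):
            raise ValueError(f"{self.state}: direction must be above/below")

    def _resolve(self, cut, sex: pd.Series) -> pd.Series:
        if isinstance(cut, dict):
            return sex.map({"M": float(cut["M"]), "F": float(cut["F"])})
        return pd.Series(float(cut), index=sex.index)

    def evaluate(self, values: pd.DataFrame, sex: pd.Series) -> pd.Series:
        """Apply the rule; returns a nullable-boolean series.

        Multi-input rules combine by OR; a state is <NA> whenever any
        of its inputs is missing.
        """
        cuts = self.cutoff if isinstance(self.cutoff, (list, tuple)) else [self.cutoff] * len(self.inputs)
        result = pd.Series(False, index=values.index, dtype="boolean")
        any_missing = pd.Series(False, index=values.index)
        for name, cut in zip(self.inputs, cuts):
            col = values[name]
            thr = self._resolve(cut, sex)
            hit = col > thr if self.direction == "above" else col < thr
            result = result | hit.astype("boolean")
            any_missing |= col.isna()
        return result.mask(any_missing)


#: Fixed state order of every StateMatrix.
STATE_NAMES: tuple[str, ...] = (
    "hyperglycemia",
    "high_hba1c",
    "insulin_resistance",
    "low_hdl",
    "high_ldl",
    "hypertriglyceridemia",
    "hyperuricemia",
    "azotemia",
    "low_egfr",
    "overweight",
    "high_temperature",
    "high_blood_pressure",
)

_DEFAULT_RULES: tuple[ThresholdRule, ...] = (
    ThresholdRule("hyperglycemia", ("glucose",), "above", 5.55),
    ThresholdRule("high_hba1c", ("hba1c",), "above", 6.5),
    ThresholdRule("insulin_resistance", ("homa_ir",), "above", {"M": 1.7, "F": 1.8}),
    ThresholdRule("low_hdl", ("hdl",), "below", {"M": 1.03, "F": 1.3}),
    ThresholdRule("high_ldl", ("ldl",), "above", 3.0),
    ThresholdRule("hypertriglyceridemia", ("triglycerides",), "above", 1.7),
    ThresholdRule("hyperuricemia", ("uric_acid",), "above", 405.0),
    ThresholdRule("azotemia", ("urea",), "above", 7.5),
    ThresholdRule("low_egfr", ("egfr",), "below", 90.0, age_dependent=True),
    ThresholdRule("overweight", ("waist",), "above", {"M": 90.0, "F": 80.0}),
    ThresholdRule("high_temperature", ("temperature",), "above", 37.0),
    ThresholdRule(
        "high_blood_pressure", ("systolic", "diastolic"), "above", [120.0, 80.0]
    ),
)


def default_rules() -> tuple[ThresholdRule, ...]:
    """The 12 shipped threshold rules, in fixed column order."""
    return _DEFAULT_RULES


def rules_to_yaml(rules, path) -> None:
    doc = [
        {
            "state": r.state,
            "inputs": list(r.inputs),
            "direction": r.direction,
            "cutoff": r.cutoff,
            "age_dependent": r.age_dependent,
        }
        for r in rules
    ]
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def rules_from_yaml(path) -> tuple[ThresholdRule, ...]:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return tuple(
        ThresholdRule(
            d["state"], tuple(d["inputs"]), d["direction"], d["cutoff"],
            bool(d.get("age_dependent", False)),
        )
        for d in doc
    )


def assess_states(
    cohort: pd.DataFrame,
    rules: tuple[ThresholdRule, ...] | None = None,
    insulin_factor: float = INSULIN_PMOL_PER_UU,
) -> pd.DataFrame:
    """Apply the 12 threshold rules; returns a nullable-boolean matrix.

    Derived indices (HOMA-IR, eGFR) are computed on the fly.  A state
    is <NA> whenever any of its inputs is missing; the blood-pressure
    rule is True when either reading exceeds its cut-off (120/80).
    """
    rules = rules or default_rules()
    values = cohort.copy()
    values["homa_ir"] = homa_ir(
        cohort["glucose"].to_numpy(), cohort["insulin"].to_numpy(), insulin_factor
    )
    values["egfr"] = egfr(
        cohort["creatinine"].to_numpy(),
        cohort["age"].to_numpy(),
        cohort["sex"].to_numpy(),
    )
    out = pd.DataFrame(index=cohort.index)
    for rule in rules:
        for name in rule.inputs:
            if name not in values.columns:
                raise KeyError(f"rule {rule.state!r} refers to unknown input {name!r}")
        out[rule.state] = rule.evaluate(values, cohort["sex"])
    return out


def mets_harmonized(cohort: pd.DataFrame) -> pd.Series:
    """Harmonized metabolic-syndrome flag: >= 3 of 5 criteria.

    Criteria (biomarker-only, no medication information): elevated
    waist (M > 90 / F > 80 cm), triglycerides >= 1.7 mmol/L, low HDL
    (< 1.03 M / < 1.3 F mmol/L), blood pressure >= 130/85 mmHg (either
    reading), fasting glucose >= 5.55 mmol/L.  Missing whenever any
    criterion input is missing.
    """
    sex = cohort["sex"]
    waist_cut = sex.map({"M": 90.0, "F": 80.0})
    hdl_cut = sex.map({"M": 1.03, "F": 1.3})
    criteria = pd.DataFrame(
        {
            "waist": cohort["waist"] > waist_cut,
            "tg": cohort["triglycerides"] >= 1.7,
            "hdl": cohort["hdl"] < hdl_cut,
            "bp": (cohort["systolic"] >= 130.0) | (cohort["diastolic"] >= 85.0),
            "glu": cohort["glucose"] >= 5.55,
        }
    )
    any_missing = (
        cohort[["waist", "triglycerides", "hdl", "systolic", "diastolic", "glucose"]]
        .isna()
        .any(axis=1)
    )
    flag = (criteria.sum(axis=1) >= 3).astype("boolean")
    return flag.mask(any_missing)


@dataclass
class TrendResult:
    """Age-trend statistics.

    ``variables``: per-variable OLS slope of value on continuous age
    (units/year) with its two-sided p-value.  ``states``: per-state
    Cochran–Armitage chi-square for trend across the ordered strata
    (midpoint-age scores, 1 df) plus prevalence by stratum.
    """

    variables: pd.DataFrame
    states: pd.DataFrame
    prevalence: pd.DataFrame


def _midpoint_age(stratum: AgeStratum) -> float:
    if np.isinf(stratum.upper):
        return stratum.lower + 5.0  # open top bin: nominal 10-year width
    return (stratum.lower + stratum.upper) / 2.0


def cochran_armitage(
    positives: np.ndarray, totals: np.ndarray, scores: np.ndarray
) -> tuple[float, float]:
    """Chi-square test for trend in proportions across ordered groups.

    Returns (chi2, p) with 1 degree of freedom.  With two groups this
    reduces to the (uncorrected) Pearson chi-square of the 2x2 table.
    """
    r = np.asarray(positives, dtype=float)
    n = np.asarray(totals, dtype=float)
    s = np.asarray(scores, dtype=float)
    keep = n > 0
    r, n, s = r[keep], n[keep], s[keep]
    N = n.sum()
    if N == 0 or len(n) < 2:
        return 0.0, 1.0
    pbar = r.sum() / N
    if pbar in (0.0, 1.0):
        return 0.0, 1.0
    num = (s * (r - n * pbar)).sum() ** 2
    den = pbar * (1 - pbar) * ((n * s**2).sum() - (n * s).sum() ** 2 / N)
    if den <= 0:
        return 0.0, 1.0
    chi2 = num / den
    return float(chi2), float(stats.chi2.sf(chi2, df=1))


def trend_statistics(
    cohort: pd.DataFrame,
    states: pd.DataFrame,
    strata: list[AgeStratum],
    variables: tuple[str, ...] | None = None,
) -> TrendResult:
    """Per-variable OLS age slopes and per-state trend chi-squares."""
    from metabonet.catalog import VARIABLE_NAMES

    variables = variables or VARIABLE_NAMES
    age = cohort["age"].to_numpy(dtype=float)

    var_rows = {}
    for name in variables:
        y = cohort[name].to_numpy(dtype=float)
        ok = ~np.isnan(y)
        if ok.sum() < 3 or np.nanstd(y[ok]) == 0 or np.std(age[ok]) == 0:
            var_rows[name] = {"slope": 0.0, "slope_p": 1.0}
            continue
        fit = stats.linregress(age[ok], y[ok])
        var_rows[name] = {"slope": float(fit.slope), "slope_p": float(fit.pvalue)}
    var_df = pd.DataFrame.from_dict(var_rows, orient="index")

    scores = np.array([_midpoint_age(s) for s in strata])
    labels = [s.label for s in strata]
    state_rows = {}
    prev_rows = {}
    for state in states.columns:
        col = states[state]
        pos = np.array(
            [float((col.loc[s.members.index] == True).sum()) for s in strata]  # noqa: E712
        )
        tot = np.array([float(col.loc[s.members.index].notna().sum()) for s in strata])
        with np.errstate(invalid="ignore", divide="ignore"):
            prev = np.where(tot > 0, pos / tot, np.nan)
        chi2, p = cochran_armitage(pos, tot, scores)
        state_rows[state] = {"chi2_trend": chi2, "trend_p": p}
        prev_rows[state] = dict(zip(labels, prev))
    return TrendResult(
        variables=var_df,
        states=pd.DataFrame.from_dict(state_rows, orient="index"),
        prevalence=pd.DataFrame.from_dict(prev_rows, orient="index"),
    )
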