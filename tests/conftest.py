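import io

import numpy as np
import pandas as pd
import pytest

from metabonet.catalog import VARIABLE_NAMES, default_catalog
from metabonet.synthetic import Marginal, StratumSpec, SyntheticCohortSpec


@pytest.fixture
def catalog():
    return default_catalog()


def make_cohort(rows: list[dict]) -> pd.DataFrame:
    """Build an in-memory cohort table from partial row dicts.

    Unspecified variables get mid-range plausible values; sex defaults
    to M and age to 40.
    """
    defaults = {
        "glucose": 4.8, "hba1c": 5.2, "insulin": 50.0, "hdl": 1.4, "ldl": 2.5,
        "triglycerides": 1.2, "uric_acid": 300.0, "urea": 5.0, "creatinine": 70.0,
        "waist": 85.0, "weight": 70.0, "height": 165.0, "temperature": 36.6,
        "systolic": 110.0, "diastolic": 70.0,
    }
    out = []
    for i, row in enumerate(rows):
        rec = {"participant_id": f"P{i:04d}", "age": 40, "sex": "M", **defaults}
        rec.update(row)
        out.append(rec)
    return pd.DataFrame(out)


def cohort_csv(df: pd.DataFrame) -> io.StringIO:
    buf = io.StringIO()
    df.to_csv(buf, index=False)
    buf.seek(0)
    return buf


def inrange_marginals(families: dict | None = None) -> dict:
    """Marginals centred in each variable's plausibility range.

    Mean = range midpoint, SD = range/20, so cleaned cohorts keep
    essentially every cell.
    """
    families = families or {}
    cat = default_catalog()
    return {
        v: Marginal(
            (cat[v].plausible_min + cat[v].plausible_max) / 2,
            (cat[v].plausible_max - cat[v].plausible_min) / 20,
            families.get(v, "normal"),
        )
        for v in VARIABLE_NAMES
    }


def flat_spec(
    n: int = 1000,
    target: np.ndarray | None = None,
    seed: int = 0,
    families: dict | None = None,
) -> SyntheticCohortSpec:
    """Single-stratum spec with in-range normal marginals."""
    marginals = {"all": inrange_marginals(families)}
    return SyntheticCohortSpec(
        strata=[StratumSpec("all", n, (18, 80))],
        marginals=marginals,
        target_spearman=np.eye(len(VARIABLE_NAMES)) if target is None else target,
        seed=seed,
    )
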