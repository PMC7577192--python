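"""Synthetic cohort generation via a Gaussian copula.

The downstream analysis consumes only two features of the data: rank
correlations between the 15 physiological variables and threshold
exceedances of their marginals.  A Gaussian copula controls both
directly: a latent multivariate normal with correlation
``2*sin(pi*rho_s/6)`` (the exact Pearson correlation that yields a
target Spearman ``rho_s`` on the latent scale) is pushed through each
variable's marginal quantile function.  Marginals are normal or
lognormal (moment-matched), per age stratum, with defaults taken from
the study population: six strata of sizes 680/528/445/468/352/99
(n = 2572), 65% female, and the published per-stratum biomarker
means and standard deviations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from metabonet.catalog import VARIABLE_NAMES

__all__ = [
    "Marginal",
    "StratumSpec",
    "SyntheticCohortSpec",
    "spearman_to_pearson",
    "nearest_psd_correlation",
    "generate_cohort",
    "default_study_spec",
    "default_dependence_matrix",
]


@dataclass(frozen=True)
class Marginal:
    """A univariate marginal: mean and SD in variable units."""

    mean: float
    sd: float
    family: str = "normal"  # normal | lognormal

    def __post_init__(self) -> None:
        if self.sd <= 0:
            raise ValueError("sd must be positive")
        if self.family not in ("normal", "lognormal"):
            raise ValueError(f"unknown family {self.family!r}")
        if self.family == "lognormal" and self.mean <= 0:
            raise ValueError("lognormal marginal requires positive mean")

    def ppf(self, u: np.ndarray) -> np.ndarray:
        """Quantile function evaluated at probabilities ``u``."""
        if self.family == "normal":
            return stats.norm.ppf(u, loc=self.mean, scale=self.sd)
        # moment-matched lognormal: E=mean, SD=sd
        sigma2 = np.log1p((self.sd / self.mean) ** 2)
        mu = np.log(self.mean) - sigma2 / 2.0
        return stats.lognorm.ppf(u, np.sqrt(sigma2), scale=np.exp(mu))


@dataclass(frozen=True)
class StratumSpec:
    """One age stratum: label, size, and inclusive age range."""

    label: str
    n: int
    age_range: tuple[int, int]

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("stratum size must be >= 1")
        if self.age_range[0] > self.age_range[1]:
            raise ValueError("age_range must be (low, high) with low <= high")


@dataclass
class SyntheticCohortSpec:
    """Full recipe for a synthetic cohort.

    ``marginals`` maps stratum label -> {variable -> Marginal};
    ``target_spearman`` is the 15x15 symmetric Spearman matrix the
    copula should reproduce (unit diagonal, entries in [-1, 1]).
    """

    strata: list[StratumSpec]
    marginals: dict[str, dict[str, Marginal]]
    target_spearman: np.ndarray
    female_fraction: float = 0.65
    seed: int = 0

    def __post_init__(self) -> None:
        self.target_spearman = np.asarray(self.target_spearman, dtype=float)
        k = len(VARIABLE_NAMES)
        if self.target_spearman.shape != (k, k):
            raise ValueError(f"target_spearman must be {k}x{k}")
        if not np.allclose(self.target_spearman, self.target_spearman.T):
            raise ValueError("target_spearman must be symmetric")
        if not np.allclose(np.diag(self.target_spearman), 1.0):
            raise ValueError("target_spearman must have unit diagonal")
        if np.abs(self.target_spearman).max() > 1.0 + 1e-12:
            raise ValueError("Spearman entries must lie in [-1, 1]")
        if not 0.0 <= self.female_fraction <= 1.0:
            raise ValueError("female_fraction must lie in [0, 1]")
        for s in self.strata:
            missing = set(VARIABLE_NAMES) - set(self.marginals.get(s.label, {}))
            if missing:
                raise ValueError(f"stratum {s.label!r} lacks marginals for {sorted(missing)}")

    @property
    def total_n(self) -> int:
        return sum(s.n for s in self.strata)

    # -- YAML round-trip -------------------------------------------------

    def to_yaml(self, path) -> None:
        doc = {
            "female_fraction": self.female_fraction,
            "seed": self.seed,
            "strata": [
                {"label": s.label, "n": s.n, "age_range": list(s.age_range)}
                for s in self.strata
            ],
            "marginals": {
                label: {
                    v: {"mean": m.mean, "sd": m.sd, "family": m.family}
                    for v, m in margs.items()
                }
                for label, margs in self.marginals.items()
            },
            "target_spearman": self.target_spearman.tolist(),
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SyntheticCohortSpec":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        return cls(
            strata=[
                StratumSpec(d["label"], int(d["n"]), tuple(d["age_range"]))
                for d in doc["strata"]
            ],
            marginals={
                label: {v: Marginal(**m) for v, m in margs.items()}
                for label, margs in doc["marginals"].items()
            },
            target_spearman=np.asarray(doc["target_spearman"], dtype=float),
            female_fraction=float(doc.get("female_fraction", 0.65)),
            seed=int(doc.get("seed", 0)),
        )


def spearman_to_pearson(rho_s: np.ndarray) -> np.ndarray:
    """Latent-normal Pearson correlation reproducing a Spearman target.

    For a bivariate normal with Pearson correlation r, the Spearman
    correlation is (6/pi)*asin(r/2); the inverse map is
    r = 2*sin(pi*rho_s/6).
    """
    return 2.0 * np.sin(np.pi * np.asarray(rho_s, dtype=float) / 6.0)


def nearest_psd_correlation(
    corr: np.ndarray, clip: float = 1e-8, tol: float = 0.05
) -> np.ndarray:
    """Repair a near-PSD correlation matrix by eigenvalue clipping.

    Eigenvalues below ``clip`` are raised to ``clip`` and the matrix is
    rescaled back to unit diagonal.  A smallest eigenvalue below
    ``-tol`` indicates a genuinely infeasible dependence target and is
    a hard error.
    """
    corr = np.asarray(corr, dtype=float)
    w, v = np.linalg.eigh(corr)
    if w.min() < -tol:
        raise ValueError(
            f"dependence target is not positive semi-definite beyond repair: "
            f"smallest eigenvalue {w.min():.6g}"
        )
    if w.min() >= clip:
        return corr
    w = np.clip(w, clip, None)
    fixed = (v * w) @ v.T
    d = np.sqrt(np.diag(fixed))
    fixed = fixed / np.outer(d, d)
    np.fill_diagonal(fixed, 1.0)
    return fixed


def generate_cohort(
    spec: SyntheticCohortSpec, seed: int | None = None
) -> pd.DataFrame:
    """Draw a cohort table from a :class:`SyntheticCohortSpec`.

    Ages are uniform integers within each stratum's range, sex is
    Bernoulli(female_fraction), and the 15 variables follow the
    stratum marginals coupled by the Gaussian copula.  Fully
    reproducible from ``seed`` (defaults to ``spec.seed``).
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    latent = nearest_psd_correlation(spearman_to_pearson(spec.target_spearman))
    chol = np.linalg.cholesky(latent + 1e-12 * np.eye(latent.shape[0]))

    frames = []
    offset = 0
    for stratum in spec.strata:
        z = rng.standard_normal((stratum.n, len(VARIABLE_NAMES))) @ chol.T
        u = stats.norm.cdf(z)
        margs = spec.marginals[stratum.label]
        data = {
            "participant_id": [f"S{offset + i + 1:06d}" for i in range(stratum.n)],
            "age": rng.integers(
                stratum.age_range[0], stratum.age_range[1] + 1, size=stratum.n
            ),
            "sex": np.where(rng.random(stratum.n) < spec.female_fraction, "F", "M"),
        }
        for j, name in enumerate(VARIABLE_NAMES):
            data[name] = margs[name].ppf(u[:, j])
        frames.append(pd.DataFrame(data))
        offset += stratum.n
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# Default study-like specification
# ---------------------------------------------------------------------------

#: Per-stratum (mean, sd) for each variable, six strata in age order.
_STRATUM_LABELS = ("<25", "25-34", "35-44", "45-54", "55-64", "65+")
_STRATUM_N = (680, 528, 445, 468, 352, 99)
_STRATUM_AGES = ((18, 24), (25, 34), (35, 44), (45, 54), (55, 64), (65, 81))

_MARGINALS: dict[str, tuple[tuple[float, float], ...]] = {
    "glucose": ((4.6, 0.5), (4.7, 0.7), (5, 1), (5, 2), (5, 2), (6, 2)),
    "hba1c": ((5.1, 0.5), (5.1, 0.6), (5, 2), (6, 2), (6, 2), (6, 2)),
    "insulin": ((55, 36), (54, 52), (57, 42), (60, 62), (59, 40), (59, 44)),
    "hdl": ((1.3, 0.3), (1.2, 0.3), (1.2, 0.3), (1.2, 0.3), (1.2, 0.3), (1.3, 0.3)),
    "ldl": ((2.5, 0.6), (3, 1), (3, 2), (3.2, 0.8), (3.3, 0.9), (3.2, 0.8)),
    "triglycerides": ((1.1, 0.6), (1, 1), (2, 2), (2, 1), (2, 1), (2, 1)),
    "uric_acid": ((323, 92), (326, 90), (319, 87), (315, 82), (331, 88), (335, 85)),
    "urea": ((4, 1), (5, 2), (4, 1), (5, 1), (5, 1), (6, 2)),
    "creatinine": ((70, 14), (74, 45), (70, 16), (70, 17), (74, 18), (88, 78)),
    "waist": ((82, 11), (87, 12), (91, 12), (93, 12), (93, 11), (94, 12)),
    "weight": ((63, 13), (68, 15), (72, 15), (71, 14), (70, 14), (68, 13)),
    "height": ((162, 9), (164, 9), (162, 9), (159, 9), (160, 10), (159, 10)),
    "temperature": (
        (37.2, 0.5), (37.0, 0.5), (37.0, 0.5), (37.0, 0.5), (36.8, 0.5), (36.7, 0.6)
    ),
    "systolic": ((109, 11), (109, 12), (113, 14), (115, 14), (121, 16), (124, 19)),
    "diastolic": ((71, 9), (73, 9), (76, 11), (77, 10), (79, 11), (78, 11)),
}

# Right-skewed labs (SD comparable to mean) default to lognormal
# marginals; everything else is normal.
_LOGNORMAL_VARS = frozenset({"insulin", "triglycerides", "creatinine"})


def default_dependence_matrix() -> np.ndarray:
    """Documented default Spearman dependence target.

    Moderate positive blocks among adiposity, glycaemic, lipid, renal
    and blood-pressure variables, with the physiologic cross-block
    links (adiposity-insulin, adiposity-triglycerides, urate with
    adiposity/lipids, pressure with adiposity) and negative HDL
    couplings.  Axillary temperature is left uncoupled.  This is a
    package fixture describing a plausible metabolic dependence
    structure, chosen so that threshold-derived pathological states
    co-occur above chance at study-like sample sizes.
    """
    k = len(VARIABLE_NAMES)
    idx = {v: i for i, v in enumerate(VARIABLE_NAMES)}
    rho = np.eye(k)

    pairs = {
        # adiposity block
        ("waist", "weight"): 0.75,
        ("weight", "height"): 0.45,
        ("waist", "height"): 0.20,
        # glycaemic block
        ("glucose", "hba1c"): 0.60,
        ("glucose", "insulin"): 0.45,
        ("hba1c", "insulin"): 0.35,
        # lipid block
        ("ldl", "triglycerides"): 0.35,
        ("hdl", "triglycerides"): -0.45,
        ("hdl", "ldl"): -0.10,
        # renal block
        ("uric_acid", "urea"): 0.30,
        ("uric_acid", "creatinine"): 0.40,
        ("urea", "creatinine"): 0.50,
        # pressure block
        ("systolic", "diastolic"): 0.70,
        # cross-block couplings
        ("waist", "insulin"): 0.45,
        ("weight", "insulin"): 0.40,
        ("waist", "glucose"): 0.30,
        ("weight", "glucose"): 0.25,
        ("waist", "triglycerides"): 0.40,
        ("weight", "triglycerides"): 0.30,
        ("waist", "hdl"): -0.35,
        ("weight", "hdl"): -0.30,
        ("waist", "uric_acid"): 0.35,
        ("weight", "uric_acid"): 0.35,
        ("height", "uric_acid"): 0.20,
        ("glucose", "triglycerides"): 0.30,
        ("insulin", "triglycerides"): 0.35,
        ("insulin", "hdl"): -0.30,
        ("insulin", "uric_acid"): 0.25,
        ("uric_acid", "triglycerides"): 0.30,
        ("waist", "systolic"): 0.30,
        ("weight", "systolic"): 0.30,
        ("waist", "diastolic"): 0.25,
        ("weight", "diastolic"): 0.25,
        ("glucose", "systolic"): 0.20,
        ("uric_acid", "systolic"): 0.20,
        ("uric_acid", "diastolic"): 0.20,
        ("creatinine", "urea"): 0.50,
    }
    for (a, b), r in pairs.items():
        rho[idx[a], idx[b]] = rho[idx[b], idx[a]] = r
    return rho


def default_study_spec(seed: int = 0) -> SyntheticCohortSpec:
    """Spec pre-loaded with the study's six strata and marginals.

    Stratum sizes 680/528/445/468/352/99 (total 2572), 65% female,
    the published per-stratum means and SDs, and the documented default
    dependence matrix.
    """
    marginals = {
        label: {
            v: Marginal(
                *[float(x) for x in _MARGINALS[v][i]],
                family="lognormal" if v in _LOGNORMAL_VARS else "normal",
            )
            for v in VARIABLE_NAMES
        }
        for i, label in enumerate(_STRATUM_LABELS)
    }
    return SyntheticCohortSpec(
        strata=[
            StratumSpec(label, n, ages)
            for label, n, ages in zip(_STRATUM_LABELS, _STRATUM_N, _STRATUM_AGES)
        ],
        marginals=marginals,
        target_spearman=default_dependence_matrix(),
        female_fraction=0.65,
        seed=seed,
    )
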