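"""Synthetic KNHANES-like cohort generator with known ground truth.

The generator emulates the structure of the restricted source survey for
adults aged 65+: fifteen correlated binary chronic-disease flags, an
EQ-5D-3L index with a large point mass at 1.00 and a left-skewed continuous
remainder, HRQoL groups (good / normal / poor), survey weights, and
independent socio-demographic covariates.

Mechanism, per sex:

1. Disease flags are drawn by thresholding a latent multivariate Gaussian
   (Gaussian copula): flag j is 1 iff Z_j < Φ⁻¹(p_j), so each marginal is
   exactly Bernoulli(p_j) and dependence is controlled by the latent
   correlation matrix. The per-sex marginals are the share-weighted mixture
   of the configured good/normal/poor stratum prevalence rows.
2. Poor HRQoL is assigned by a logistic link on the multimorbidity category
   m ∈ {0, 1, 2, ≥3}: P(poor | m) = expit(α + β_m), with α calibrated so the
   realized poor share matches the target. The β vector is therefore the
   generator's known truth for odds-ratio recovery.
3. Non-poor individuals are *good* (index exactly 1.00) with the probability
   implied by the configured good mass, else *normal*. Continuous indices
   are drawn from a scaled Beta on [floor, 1), truncated to the poor or
   normal side of the cutpoint.
4. Survey weights are log-normal with configurable coefficient of variation,
   normalized to mean 1; covariates are sampled independently from
   realistic marginal frequencies (so they are non-confounding by design).
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import optimize, stats
from scipy.special import expit, ndtri

from . import reference
from .cohort import Cohort, MULTIMORBIDITY_CATEGORIES
from .eq5d import classify_hrqol
from .panel import AGE_GROUPS, DISEASES, POOR_CUTOFF, SEXES

__all__ = [
    "SimulationConfig",
    "sample_correlated_binary",
    "generate_cohort",
    "default_latent_corr",
    "default_marginal_prev",
    "expected_pair_lift",
    "repair_correlation",
]

#: Covariate marginal frequencies (with explicit small missing shares) the
#: generator samples from; magnitudes follow the published older-adult
#: cohort description.
COVARIATE_LEVELS: dict[str, dict[str, float]] = {
    "marital": {"married": 0.661, "other": 0.333, "missing": 0.006},
    "income": {"low": 0.247, "middle": 0.498, "high": 0.247, "missing": 0.008},
    "working": {"employed": 0.330, "unemployed": 0.670},
    "education": {"elementary": 0.621, "secondary": 0.289, "college": 0.083, "missing": 0.007},
    "bmi_category": {"underweight": 0.033, "normal": 0.353, "overweight": 0.256, "obesity": 0.354, "missing": 0.004},
    "smoking": {"no": 0.881, "yes": 0.106, "missing": 0.013},
    "drinking": {"no": 0.952, "yes": 0.036, "missing": 0.012},
    "walking": {"no": 0.622, "yes": 0.366, "missing": 0.012},
    "sleeping": {"short": 0.442, "optimal": 0.485, "long": 0.056, "missing": 0.017},
    "stress": {"no": 0.790, "yes": 0.196, "missing": 0.014},
}

AGE_SHARES = (0.334, 0.302, 0.225, 0.139)

#: Latent-correlation boosts for disease pairs with known strong
#: co-occurrence (metabolic cluster, renal–thyroid, cardiac, respiratory);
#: everything else sits at a mild common background correlation.
_CORR_BOOSTS: dict[tuple[str, str], float] = {
    ("angina_pectoris", "myocardial_infarction"): 0.45,
    ("angina_pectoris", "hyperlipidemia"): 0.25,
    ("arthritis", "depression"): 0.20,
    ("asthma", "tuberculosis"): 0.35,
    ("cancer", "liver_disease"): 0.30,
    ("ckd", "renal_failure"): 0.50,
    ("ckd", "myocardial_infarction"): 0.30,
    ("ckd", "stroke"): 0.25,
    ("ckd", "thyroid"): 0.25,
    ("diabetes", "hypertension"): 0.20,
    ("diabetes", "hyperlipidemia"): 0.25,
    ("hyperlipidemia", "hypertension"): 0.25,
    ("hypertension", "stroke"): 0.25,
    ("renal_failure", "thyroid"): 0.45,
    ("diabetes", "stroke"): 0.20,
}


def default_latent_corr(background: float = 0.08) -> np.ndarray:
    """Default 15×15 latent correlation: mild background plus pair boosts."""
    k = len(DISEASES)
    corr = np.full((k, k), background)
    np.fill_diagonal(corr, 1.0)
    idx = {d: i for i, d in enumerate(DISEASES)}
    for (a, b), r in _CORR_BOOSTS.items():
        corr[idx[a], idx[b]] = corr[idx[b], idx[a]] = r
    return repair_correlation(corr)


def default_marginal_prev() -> dict[tuple[str, str], np.ndarray]:
    """Per-(sex × HRQoL) disease prevalence targets from the published tables."""
    return {
        (sex, grp): reference.stratum_prevalence(sex, grp)
        for sex in SEXES
        for grp in ("good", "normal", "poor")
    }


def repair_correlation(corr: np.ndarray, tol: float = 0.05) -> np.ndarray:
    """Validate a latent correlation matrix, clipping eigenvalues if needed.

    Mildly indefinite matrices (smallest eigenvalue > -``tol``) are repaired
    by eigenvalue clipping and re-normalization to unit diagonal, with a
    warning; anything worse is a hard error.
    """
    corr = np.asarray(corr, dtype=float)
    if corr.ndim != 2 or corr.shape[0] != corr.shape[1]:
        raise ValueError("latent correlation must be a square matrix")
    if not np.allclose(corr, corr.T, atol=1e-10):
        raise ValueError("latent correlation must be symmetric")
    if not np.allclose(np.diag(corr), 1.0, atol=1e-10):
        raise ValueError("latent correlation must have a unit diagonal")
    eigval = np.linalg.eigvalsh(corr)
    if eigval[0] >= -1e-12:
        return corr
    if eigval[0] < -tol:
        raise ValueError(
            f"latent correlation is not positive semi-definite "
            f"(smallest eigenvalue {eigval[0]:.4f} below repair tolerance -{tol})"
        )
    warnings.warn(
        f"latent correlation repaired by eigenvalue clipping "
        f"(smallest eigenvalue was {eigval[0]:.2e})",
        stacklevel=2,
    )
    w, v = np.linalg.eigh(corr)
    w = np.clip(w, 1e-10, None)
    fixed = (v * w) @ v.T
    d = np.sqrt(np.diag(fixed))
    fixed = fixed / np.outer(d, d)
    np.fill_diagonal(fixed, 1.0)
    return fixed


def sample_correlated_binary(
    marginals: Sequence[float],
    latent_corr: np.ndarray,
    n: int,
    seed: int | np.random.Generator,
) -> np.ndarray:
    """Draw an n × k binary matrix with given marginals and copula dependence.

    Column j is exactly Bernoulli(marginals[j]); dependence comes from
    thresholding a latent multivariate normal at the per-column quantile
    Φ⁻¹(p_j). Marginals of 0 or 1 are rejected as degenerate.
    """
    p = np.asarray(marginals, dtype=float)
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError("marginal prevalences must lie strictly in (0, 1)")
    corr = repair_correlation(np.asarray(latent_corr, dtype=float))
    if corr.shape[0] != p.size:
        raise ValueError(
            f"latent correlation is {corr.shape[0]}×{corr.shape[0]} "
            f"but {p.size} marginals were given"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    # Cholesky with a tiny jitter floor: repair guarantees PSD up to rounding.
    try:
        chol = np.linalg.cholesky(corr)
    except np.linalg.LinAlgError:
        chol = np.linalg.cholesky(corr + 1e-10 * np.eye(corr.shape[0]))
    z = rng.standard_normal((int(n), p.size)) @ chol.T
    return (z < ndtri(p)).astype(np.uint8)


def expected_pair_lift(p1: float, p2: float, rho: float) -> float:
    """Population lift of a disease pair under the latent-Gaussian model.

    The joint probability is the bivariate-normal orthant probability
    Φ₂(Φ⁻¹(p1), Φ⁻¹(p2); ρ) (evaluated by numerical integration), so the
    lift is Φ₂ / (p1·p2). This is the documented mapping from latent
    correlation to achieved lift.
    """
    mvn = stats.multivariate_normal(mean=[0.0, 0.0], cov=[[1.0, rho], [rho, 1.0]])
    joint = float(mvn.cdf([ndtri(p1), ndtri(p2)]))
    return joint / (p1 * p2)


@dataclass
class SimulationConfig:
    """Everything the generator needs; identical config + seed ⇒ identical cohort.

    Parameters
    ----------
    n_per_stratum:
        Nominal count per (sex × HRQoL) cell; each sex pool has size
        ``3 * n_per_stratum`` and realized cell sizes follow the group
        shares.
    marginal_prev:
        Target disease prevalences, one row per (sex, group), panel order.
    latent_corr:
        15×15 latent-Gaussian correlation (symmetric, unit diagonal, PSD up
        to the repair tolerance).
    good_mass:
        Fraction of the cohort at index exactly 1.00.
    hrqol_link_beta:
        Log-odds increments of poor HRQoL for multimorbidity categories
        (0, 1, 2, ≥3); the first entry is the reference and the vector is
        the generator's recoverable truth.
    index_beta_shapes:
        Beta(a, b) shapes of the continuous index part on [floor, 1); the
        default is left-skewed with ≈26% of the continuous mass below the
        0.721 cutpoint, giving overall good/normal/poor shares ≈ 45/41/14%.
    weight_cv:
        Coefficient of variation of the log-normal survey weights.
    """

    n_per_stratum: int = 2000
    disease_names: tuple[str, ...] = DISEASES
    marginal_prev: Mapping[tuple[str, str], np.ndarray] = field(default_factory=default_marginal_prev)
    latent_corr: np.ndarray = field(default_factory=default_latent_corr)
    good_mass: float = 0.449
    poor_cutoff: float = POOR_CUTOFF
    hrqol_link_beta: tuple[float, float, float, float] = (0.0, 0.39, 0.63, 0.99)
    index_floor: float = -0.17
    index_beta_shapes: tuple[float, float] = (7.17, 1.5)
    weight_cv: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_stratum < 1:
            raise ValueError("n_per_stratum must be a positive integer")
        if self.n_per_stratum < 30:
            warnings.warn(
                "n_per_stratum below 30: empirical checks will be unstable",
                stacklevel=2,
            )
        if tuple(self.disease_names) != DISEASES and len(self.disease_names) != len(DISEASES):
            raise ValueError(f"disease panel must have {len(DISEASES)} entries")
        if len(self.hrqol_link_beta) != len(MULTIMORBIDITY_CATEGORIES):
            raise ValueError("hrqol_link_beta needs one entry per multimorbidity category")
        if not 0 < self.good_mass < 1:
            raise ValueError("good_mass must be in (0, 1)")
        self.latent_corr = repair_correlation(np.asarray(self.latent_corr, dtype=float))
        for key, row in self.marginal_prev.items():
            row = np.asarray(row, dtype=float)
            if row.size != len(self.disease_names):
                raise ValueError(f"marginal_prev[{key}] length mismatch with disease panel")
            if np.any((row <= 0) | (row >= 1)):
                raise ValueError(f"marginal_prev[{key}] must lie strictly in (0, 1)")
        if self.good_mass + self.poor_share() > 1 + 1e-12:
            raise ValueError("good mass plus implied poor fraction exceeds 1")

    # -- derived quantities -------------------------------------------------
    def beta_cut(self) -> float:
        """Cutpoint on the Beta's (0,1) scale."""
        return (self.poor_cutoff - self.index_floor) / (1.0 - self.index_floor)

    def poor_share(self) -> float:
        """Implied overall poor fraction: continuous mass below the cutpoint."""
        a, b = self.index_beta_shapes
        return (1.0 - self.good_mass) * float(stats.beta.cdf(self.beta_cut(), a, b))

    def sex_mixture_prev(self, sex: str) -> np.ndarray:
        """Share-weighted mixture of the three stratum prevalence rows."""
        poor = self.poor_share()
        shares = {"good": self.good_mass, "poor": poor, "normal": 1.0 - self.good_mass - poor}
        return sum(
            shares[g] * np.asarray(self.marginal_prev[(sex, g)], dtype=float)
            for g in ("good", "normal", "poor")
        )

    def config_hash(self) -> str:
        payload = {
            "n_per_stratum": self.n_per_stratum,
            "diseases": list(self.disease_names),
            "marginal_prev": {f"{s}:{g}": np.round(np.asarray(v, float), 10).tolist()
                              for (s, g), v in sorted(self.marginal_prev.items())},
            "latent_corr": np.round(self.latent_corr, 10).tolist(),
            "good_mass": self.good_mass,
            "poor_cutoff": self.poor_cutoff,
            "hrqol_link_beta": list(self.hrqol_link_beta),
            "index_floor": self.index_floor,
            "index_beta_shapes": list(self.index_beta_shapes),
            "weight_cv": self.weight_cv,
            "seed": self.seed,
        }
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimulationConfig":
        d = dict(d)
        if "marginal_prev" in d:
            d["marginal_prev"] = {
                tuple(k.split(":")): np.asarray(v, float)
                for k, v in d["marginal_prev"].items()
            }
        if "latent_corr" in d:
            d["latent_corr"] = np.asarray(d["latent_corr"], float)
        for key in ("hrqol_link_beta", "index_beta_shapes", "disease_names"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


def _calibrate_alpha(categories: np.ndarray, beta: np.ndarray, target: float) -> float:
    """Intercept such that the mean logistic poor-probability hits ``target``."""
    def gap(alpha: float) -> float:
        return float(expit(alpha + beta[categories]).mean() - target)
    return float(optimize.brentq(gap, -30.0, 10.0, xtol=1e-12))


def generate_cohort(config: SimulationConfig) -> Cohort:
    """Generate one synthetic cohort; deterministic given the config seed."""
    import pandas as pd

    ss = np.random.SeedSequence(config.seed)
    rng_by_sex = {sex: np.random.default_rng(child)
                  for sex, child in zip(SEXES, ss.spawn(len(SEXES)))}
    a, b = config.index_beta_shapes
    f_cut = float(stats.beta.cdf(config.beta_cut(), a, b))
    poor_target = config.poor_share()
    good_given_not_poor = config.good_mass / (1.0 - poor_target)
    beta = np.asarray(config.hrqol_link_beta, dtype=float)

    frames = []
    for sex in SEXES:
        rng = rng_by_sex[sex]
        n = 3 * config.n_per_stratum
        flags = sample_correlated_binary(
            config.sex_mixture_prev(sex), config.latent_corr, n, rng
        )
        counts = flags.sum(axis=1)
        cats = np.minimum(counts, 3)
        alpha = _calibrate_alpha(cats, beta, poor_target)
        p_poor = expit(alpha + beta[cats])
        poor = rng.random(n) < p_poor
        good = ~poor & (rng.random(n) < good_given_not_poor)

        # Index: point mass at 1.0 for good; truncated scaled Beta otherwise.
        u = np.empty(n)
        u[poor] = rng.uniform(0.0, f_cut, size=int(poor.sum()))
        normal_mask = ~poor & ~good
        u[normal_mask] = rng.uniform(f_cut, 1.0, size=int(normal_mask.sum()))
        index = np.ones(n)
        cont = ~good
        index[cont] = config.index_floor + (1.0 - config.index_floor) * stats.beta.ppf(
            u[cont], a, b
        )
        # Guard the truncation boundaries against ppf rounding.
        index[poor] = np.minimum(index[poor], config.poor_cutoff)
        index[normal_mask] = np.clip(
            index[normal_mask], np.nextafter(config.poor_cutoff, 1.0), np.nextafter(1.0, 0.0)
        )
        hrqol = np.where(poor, "poor", np.where(good, "good", "normal"))

        if config.weight_cv > 0:
            sigma = np.sqrt(np.log1p(config.weight_cv**2))
            weights = rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=n)
            weights /= weights.mean()
        else:
            weights = np.ones(n)

        age = rng.choice(AGE_GROUPS, size=n, p=np.asarray(AGE_SHARES) / np.sum(AGE_SHARES))
        cov_cols = {}
        for cov, levels in COVARIATE_LEVELS.items():
            labels = list(levels)
            probs = np.asarray(list(levels.values()), dtype=float)
            cov_cols[cov] = rng.choice(labels, size=n, p=probs / probs.sum())

        n_clusters = max(20, n // 200)
        df = pd.DataFrame(
            {
                "id": [f"{sex[0]}{i:06d}" for i in range(n)],
                "sex": sex,
                "age_group": age,
                "weight": weights,
                "stratum_id": [f"st{v:02d}" for v in rng.integers(1, 17, size=n)],
                "cluster_id": [f"{sex[0]}c{v:03d}" for v in rng.integers(0, n_clusters, size=n)],
                **cov_cols,
                **{d: flags[:, j].astype(np.int64) for j, d in enumerate(config.disease_names)},
                "eq5d_index": index,
            }
        )
        df["hrqol"] = hrqol
        frames.append(df)

    data = pd.concat(frames, ignore_index=True)
    # Internal consistency: assigned groups must agree with the classifier.
    assert (data["hrqol"] == [classify_hrqol(v, config.poor_cutoff) for v in data["eq5d_index"]]).all()
    return Cohort(
        data,
        provenance={
            "generator": "mmnet.synthetic",
            "seed": str(config.seed),
            "config_hash": config.config_hash(),
            "truth_hrqol_link_beta": ",".join(f"{v:g}" for v in config.hrqol_link_beta),
        },
    )
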