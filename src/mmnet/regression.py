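"""Survey-weighted logistic regression with robust (sandwich) variance.

The coefficient vector maximizes the weight-multiplied Bernoulli
log-likelihood Σ w_i [y_i log μ_i + (1−y_i) log(1−μ_i)] by iteratively
reweighted least squares. Standard errors come from the sandwich estimator
B⁻¹ M B⁻¹ with bread B = Σ w_i μ_i(1−μ_i) x_i x_iᵀ and meat M built from
score contributions w_i (y_i − μ_i) x_i, aggregated within clusters when
cluster ids are supplied (with the usual G/(G−1) correction). This is a
first-order linearization stand-in for full multistage survey variance:
point estimates match the design-weighted fit; stratification and finite
population corrections are not modelled.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .cohort import Cohort, morbidity_categories

__all__ = [
    "RegressionResult",
    "SeparationError",
    "fit_weighted_logistic",
    "univariable_screen",
    "fit_poor_hrqol_model",
    "build_design",
    "REFERENCE_LEVELS",
]

#: Reference level per categorical analysis term.
REFERENCE_LEVELS: dict[str, str] = {
    "age_group": "65-69",
    "sex": "male",
    "marital": "married",
    "income": "high",
    "working": "employed",
    "education": "college",
    "bmi_category": "normal",
    "smoking": "no",
    "drinking": "no",
    "walking": "yes",
    "sleeping": "optimal",
    "stress": "no",
    "multimorbidity": "0",
}

DEFAULT_TERMS = (
    "age_group", "sex", "marital", "income", "working", "education",
    "bmi_category", "smoking", "drinking", "walking", "sleeping", "stress",
    "multimorbidity",
)


class SeparationError(RuntimeError):
    """Raised when a coefficient diverges (quasi-complete separation)."""


@dataclass
class RegressionResult:
    """Per-term estimates on the log-odds and odds-ratio scales.

    ``table`` has one row per estimated column: beta, se, or, ci_low,
    ci_high (95%, normal approximation). Reference levels are not estimated
    (their OR is identically 1).
    """

    table: pd.DataFrame
    cov: pd.DataFrame
    se_source: str
    n_obs: int
    n_iter: int
    outcome: str = "poor_hrqol"
    reference_levels: dict[str, str] = field(default_factory=dict)

    def odds_ratio(self, term: str) -> tuple[float, float, float]:
        row = self.table.loc[term]
        return float(row["or"]), float(row["ci_low"]), float(row["ci_high"])


def fit_weighted_logistic(
    X: pd.DataFrame | np.ndarray,
    y: Sequence[float],
    weights: Optional[Sequence[float]] = None,
    cluster_ids: Optional[Sequence] = None,
    add_intercept: bool = False,
    tol: float = 1e-8,
    max_iter: int = 50,
) -> RegressionResult:
    """IRLS fit of a weighted logistic model with sandwich standard errors.

    The design must be full rank after reference-column dropping; weights
    strictly positive. Without ``cluster_ids`` the variance is
    heteroscedasticity-robust (HC0); with them, cluster-aggregated with a
    G/(G−1) factor.
    """
    if isinstance(X, pd.DataFrame):
        names = list(X.columns)
        Xm = X.to_numpy(dtype=float)
    else:
        Xm = np.asarray(X, dtype=float)
        names = [f"x{j}" for j in range(Xm.shape[1])]
    if add_intercept:
        Xm = np.column_stack([np.ones(len(Xm)), Xm])
        names = ["intercept"] + names
    yv = np.asarray(y, dtype=float)
    if set(np.unique(yv)) - {0.0, 1.0}:
        raise ValueError("outcome must be binary 0/1")
    w = np.ones(len(yv)) if weights is None else np.asarray(weights, dtype=float)
    if (w <= 0).any():
        raise ValueError("weights must be strictly positive")
    if np.linalg.matrix_rank(Xm) < Xm.shape[1]:
        raise ValueError("design matrix is rank deficient (constant or collinear term)")

    beta = np.zeros(Xm.shape[1])
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        eta = Xm @ beta
        mu = expit(eta)
        irls_w = w * mu * (1.0 - mu)
        # Working response; clip the weight to keep the solve well posed.
        irls_w = np.maximum(irls_w, 1e-12)
        z = eta + (yv - mu) / np.maximum(mu * (1.0 - mu), 1e-12)
        WX = Xm * irls_w[:, None]
        hess = Xm.T @ WX
        try:
            beta_new = np.linalg.solve(hess, WX.T @ z)
        except np.linalg.LinAlgError as err:
            raise SeparationError(f"IRLS normal equations singular at iteration {n_iter}") from err
        if np.max(np.abs(beta_new)) > 30.0:
            worst = names[int(np.argmax(np.abs(beta_new)))]
            raise SeparationError(
                f"coefficient for {worst!r} diverging (|beta| > 30): separation suspected"
            )
        step = np.max(np.abs(beta_new - beta)) / max(1.0, np.max(np.abs(beta_new)))
        beta = beta_new
        if step < tol:
            break
    else:
        raise RuntimeError(
            f"IRLS did not converge in {max_iter} iterations "
            f"(last relative step {step:.2e}; beta={np.round(beta, 4)})"
        )

    mu = expit(Xm @ beta)
    bread = np.linalg.inv(Xm.T @ (Xm * (w * mu * (1.0 - mu))[:, None]))
    scores = Xm * (w * (yv - mu))[:, None]
    if cluster_ids is not None:
        ids = pd.Series(np.asarray(cluster_ids))
        grouped = pd.DataFrame(scores).groupby(ids.values).sum().to_numpy()
        g = grouped.shape[0]
        if g < 2:
            raise ValueError("need at least two clusters for cluster-robust variance")
        meat = (grouped.T @ grouped) * g / (g - 1)
        se_source = "cluster-robust"
    else:
        meat = scores.T @ scores
        se_source = "heteroscedasticity-robust"
    cov = bread @ meat @ bread
    se = np.sqrt(np.diag(cov))
    table = pd.DataFrame(
        {
            "beta": beta,
            "se": se,
            "or": np.exp(beta),
            "ci_low": np.exp(beta - 1.959963984540054 * se),
            "ci_high": np.exp(beta + 1.959963984540054 * se),
        },
        index=pd.Index(names, name="term"),
    )
    return RegressionResult(
        table=table,
        cov=pd.DataFrame(cov, index=names, columns=names),
        se_source=se_source,
        n_obs=len(yv),
        n_iter=n_iter,
    )


# ---------------------------------------------------------------------------
# cohort-level model building

def build_design(
    df: pd.DataFrame,
    terms: Sequence[str],
    reference_levels: Optional[dict[str, str]] = None,
) -> pd.DataFrame:
    """Dummy-coded design matrix (no intercept column) for categorical terms.

    Each term's reference level is dropped; dummy columns are named
    ``term[level]``. Rows with a missing level (or an explicit 'missing'
    code) in any requested term are excluded by the caller.
    """
    refs = {**REFERENCE_LEVELS, **(reference_levels or {})}
    pieces = []
    for term in terms:
        col = df[term].astype(str)
        if col.nunique() < 2:
            raise ValueError(f"term {term!r} is constant (rank deficient)")
        levels = [lv for lv in pd.unique(col) if lv != refs.get(term)]
        levels.sort()
        if refs.get(term) not in set(pd.unique(col)):
            raise ValueError(
                f"reference level {refs.get(term)!r} absent from term {term!r}"
            )
        for lv in levels:
            pieces.append(pd.Series((col == lv).astype(float), name=f"{term}[{lv}]"))
    return pd.concat(pieces, axis=1)


def _analysis_frame(cohort: Cohort, terms: Sequence[str]) -> pd.DataFrame:
    df = cohort.data.copy()
    df["multimorbidity"] = morbidity_categories(cohort).astype(str)
    df["_poor"] = (df["hrqol"] == "poor").astype(float)
    use = [t for t in terms]
    before = len(df)
    for t in use:
        df = df[df[t].astype(str) != "missing"]
        df = df[df[t].notna()]
    dropped = before - len(df)
    if dropped:
        warnings.warn(
            f"listwise deletion removed {dropped} records with missing covariates",
            stacklevel=2,
        )
    return df


def fit_poor_hrqol_model(
    cohort: Cohort,
    terms: Sequence[str] = DEFAULT_TERMS,
    weighted: bool = True,
    cluster_robust: bool = True,
) -> RegressionResult:
    """Multivariable weighted logistic model of poor HRQoL on all terms."""
    df = _analysis_frame(cohort, terms)
    X = build_design(df, terms)
    res = fit_weighted_logistic(
        X,
        df["_poor"],
        weights=df["weight"] if weighted else None,
        cluster_ids=df["cluster_id"] if (cluster_robust and "cluster_id" in df) else None,
        add_intercept=True,
    )
    res.reference_levels = {t: REFERENCE_LEVELS.get(t, "") for t in terms}
    return res


def univariable_screen(
    cohort: Cohort,
    terms: Sequence[str] = DEFAULT_TERMS,
    weighted: bool = True,
    cluster_robust: bool = True,
) -> dict[str, RegressionResult]:
    """One single-term weighted fit per covariate (crude odds ratios)."""
    out = {}
    for term in terms:
        out[term] = fit_poor_hrqol_model(
            cohort, [term], weighted=weighted, cluster_robust=cluster_robust
        )
    return out


def results_table(results: "RegressionResult | dict[str, RegressionResult]") -> pd.DataFrame:
    """Flat report table (term, OR, 95% CI) for one or several fits."""
    if isinstance(results, RegressionResult):
        results = {"model": results}
    rows = []
    for model, res in results.items():
        for term, row in res.table.iterrows():
            if term == "intercept":
                continue
            rows.append(
                {
                    "model": model,
                    "term": term,
                    "beta": row["beta"],
                    "se": row["se"],
                    "or": row["or"],
                    "ci_low": row["ci_low"],
                    "ci_high": row["ci_high"],
                    "se_source": res.se_source,
                    "n": res.n_obs,
                }
            )
    return pd.DataFrame(rows)
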