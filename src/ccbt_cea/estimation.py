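"""Regression models on completed datasets and Rubin's-rules pooling.

Three models are fitted on each imputed dataset:

* a joint bivariate gaussian identity-link system for (cost, QALY) with
  correlated residuals, adjusting for treatment, age, sex and baseline
  utility.  Because both equations share the same regressors, the joint
  maximum-likelihood coefficient estimates coincide with per-equation least
  squares (the seemingly-unrelated-regressions collapse); the joint fit
  additionally delivers the residual correlation and the cross-equation
  covariance of the two treatment coefficients, which drives the joint
  uncertainty of (incremental cost, incremental QALY);
* binomial-logit models for treatment response (>= 50% PHQ-9 reduction) at
  the 12-week and 6-month timepoints, adjusting for treatment, age, sex and
  baseline PHQ-9.

Estimates from the m imputed datasets are pooled with Rubin's rules
(within-imputation variance + (1 + 1/m) x between-imputation variance) with
the Barnard-Rubin small-sample degrees of freedom.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

from .config import DEFAULT_TIMES_YEARS, CostParameters
from .costing import build_cost_ledger
from .outcomes import add_derived_outcomes

COST_QALY_COVARIATES: tuple[str, ...] = ("treatment", "age", "female", "baseline_utility")
RESPONSE_COVARIATES: tuple[str, ...] = ("treatment", "age", "female", "baseline_phq9")


@dataclass(frozen=True)
class ModelSpec:
    """Outcome + family-link + covariate set for one regression."""

    outcome: str  # {"cost", "qaly", "response_post", "response_fu3", "response_fu6"}
    family: str  # {"gaussian-identity", "binomial-logit"}
    covariates: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.outcome == "qaly" and "baseline_utility" not in self.covariates:
            raise ValueError("the QALY model must adjust for baseline utility")
        if self.outcome.startswith("response") and "baseline_phq9" not in self.covariates:
            raise ValueError("response models must adjust for baseline PHQ-9")


def default_cost_qaly_specs() -> tuple[ModelSpec, ModelSpec]:
    return (
        ModelSpec("cost", "gaussian-identity", COST_QALY_COVARIATES),
        ModelSpec("qaly", "gaussian-identity", COST_QALY_COVARIATES),
    )


@dataclass
class FitResult:
    """Named coefficients with their covariance from a single fit."""

    params: pd.Series
    cov: pd.DataFrame
    n_used: int
    residual_correlation: Optional[float] = None
    separation: bool = False
    extras: dict = field(default_factory=dict)


class SeparationWarning(UserWarning):
    """Perfect separation in a logistic fit; a penalized fit is used."""


def build_analysis_frame(
    completed: pd.DataFrame,
    costs: Optional[CostParameters] = None,
    times_years: Sequence[float] = DEFAULT_TIMES_YEARS,
) -> pd.DataFrame:
    """Per-participant analysis variables from one completed dataset.

    Derives QALY (trapezoid area under the utility trajectory), total
    intervention cost, and response indicators; codes treatment (CCBT = 1)
    and sex (female = 1).
    """
    df = add_derived_outcomes(completed, times_years)
    ledger = build_cost_ledger(completed, costs)
    return pd.DataFrame(
        {
            "treatment": (df["arm"] == "intervention").astype(float),
            "age": df["age"].astype(float),
            "female": (df["sex"] == "female").astype(float),
            "baseline_utility": df["utility_baseline"].astype(float),
            "baseline_phq9": df["phq9_baseline"].astype(float),
            "qaly": df["qaly"].astype(float),
            "cost": ledger["total"].to_numpy(float),
            "response_post": df["response_post"].astype(float),
            "response_fu3": df["response_fu3"].astype(float),
            "response_fu6": df["response_fu6"].astype(float),
        }
    )


def _design_matrix(frame: pd.DataFrame, covariates: Sequence[str]):
    names = ["intercept", *covariates]
    X = np.column_stack(
        [np.ones(len(frame))] + [frame[c].to_numpy(float) for c in covariates]
    )
    _check_full_rank(X, names)
    return X, names


def _check_full_rank(X: np.ndarray, names: Sequence[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank == X.shape[1]:
        return
    # Identify offending columns via pivoted QR: the columns not among the
    # first `rank` pivots are (numerically) linear combinations of the rest.
    from scipy.linalg import qr

    _, _, piv = qr(X, mode="economic", pivoting=True)
    bad = sorted(names[j] for j in piv[rank:])
    raise ValueError(
        f"design matrix is rank deficient; collinear/degenerate columns: {bad}"
    )


def fit_joint_cost_qaly(
    frame: pd.DataFrame,
    specs: Optional[tuple[ModelSpec, ModelSpec]] = None,
    residual_corr_fixed: Optional[float] = None,
) -> FitResult:
    """Jointly fit the cost and QALY gaussian regressions.

    Coefficients are the (joint-ML = per-equation OLS) estimates; the
    residual 2x2 covariance is estimated from the residuals (or its
    correlation fixed via ``residual_corr_fixed``, 0 giving two independent
    regressions); the returned covariance is the full cross-equation
    coefficient covariance ``Sigma (x) (X'X)^-1``, coefficient names prefixed
    ``cost:`` / ``qaly:``.
    """
    specs = specs or default_cost_qaly_specs()
    if specs[0].covariates != specs[1].covariates:
        raise ValueError("joint fit requires a common covariate set")
    X, names = _design_matrix(frame, specs[0].covariates)
    Y = frame[[specs[0].outcome, specs[1].outcome]].to_numpy(float)
    n, p = X.shape

    XtX = X.T @ X
    XtX_inv = np.linalg.inv(XtX)
    B = XtX_inv @ (X.T @ Y)  # (p, 2) coefficients
    E = Y - X @ B
    sigma = (E.T @ E) / (n - p)
    if residual_corr_fixed is not None:
        if not -1.0 <= residual_corr_fixed <= 1.0:
            raise ValueError("residual correlation must lie in [-1, 1]")
        off = residual_corr_fixed * np.sqrt(sigma[0, 0] * sigma[1, 1])
        sigma = np.array([[sigma[0, 0], off], [off, sigma[1, 1]]])
    denom = np.sqrt(sigma[0, 0] * sigma[1, 1])
    corr = float(sigma[0, 1] / denom) if denom > 0 else 0.0

    full_names = [f"{o}:{nm}" for o in (specs[0].outcome, specs[1].outcome) for nm in names]
    params = pd.Series(np.concatenate([B[:, 0], B[:, 1]]), index=full_names)
    cov = pd.DataFrame(np.kron(sigma, XtX_inv), index=full_names, columns=full_names)
    return FitResult(params=params, cov=cov, n_used=n, residual_correlation=corr)


def fit_response_logit(
    frame: pd.DataFrame,
    timepoint: str = "post",
    covariates: Sequence[str] = RESPONSE_COVARIATES,
    penalty: float = 1.0,
) -> FitResult:
    """Binomial-logit fit of treatment response at a follow-up timepoint.

    On perfect separation (or a degenerate all-0/all-1 outcome) the maximum
    likelihood diverges; the fit falls back to a ridge-penalized logistic
    regression and warns.  ``extras`` carries the treatment odds ratio with
    CI and the average marginal effect (risk difference) of treatment with a
    delta-method variance, used for the response-based cost-effectiveness
    analysis.
    """
    import statsmodels.api as sm
    from statsmodels.tools.sm_exceptions import PerfectSeparationWarning

    covariates = tuple(covariates)
    if "baseline_phq9" in covariates:
        # The default analysis model; enforce its covariate invariant.
        ModelSpec(f"response_{timepoint}", "binomial-logit", covariates)
    y = frame[f"response_{timepoint}"].to_numpy(float)
    X, names = _design_matrix(frame, covariates)

    separation = False
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", PerfectSeparationWarning)
            res = sm.GLM(y, X, family=sm.families.Binomial()).fit()
        beta = np.asarray(res.params)
        cov = np.asarray(res.cov_params())
        if not np.all(np.isfinite(beta)) or np.abs(beta).max() > 15:
            raise ValueError("diverged")
    except Exception:
        separation = True
        warnings.warn(
            f"perfect separation in response_{timepoint} logit; "
            "using ridge-penalized fit",
            SeparationWarning,
        )
        beta, cov = _ridge_logit(y, X, penalty)

    params = pd.Series(beta, index=names)
    covdf = pd.DataFrame(cov, index=names, columns=names)

    # Average marginal effect of treatment (g-computation risk difference).
    j = names.index("treatment")
    X1, X0 = X.copy(), X.copy()
    X1[:, j], X0[:, j] = 1.0, 0.0
    p1, p0 = expit(X1 @ beta), expit(X0 @ beta)
    ame = float(np.mean(p1 - p0))
    grad = (p1 * (1 - p1))[:, None] * X1 - (p0 * (1 - p0))[:, None] * X0
    g = grad.mean(axis=0)
    ame_var = float(g @ cov @ g)

    se_t = float(np.sqrt(covdf.iloc[j, j]))
    extras = {
        "odds_ratio": float(np.exp(beta[j])),
        "or_ci": (
            float(np.exp(beta[j] - 1.96 * se_t)),
            float(np.exp(beta[j] + 1.96 * se_t)),
        ),
        "risk_difference": ame,
        "risk_difference_var": ame_var,
        "timepoint": timepoint,
    }
    return FitResult(
        params=params, cov=covdf, n_used=len(y), separation=separation, extras=extras
    )


def _ridge_logit(y: np.ndarray, X: np.ndarray, penalty: float):
    """Newton-Raphson logistic regression with an L2 penalty on every
    coefficient (the penalty is what keeps a separated or degenerate fit
    finite); covariance from the inverse penalized Hessian."""
    n, p = X.shape
    lam = np.full(p, penalty)
    beta = np.zeros(p)
    for _ in range(100):
        mu = expit(X @ beta)
        W = mu * (1 - mu)
        grad = X.T @ (y - mu) - lam * beta
        H = X.T @ (X * W[:, None]) + np.diag(lam)
        step = np.linalg.solve(H, grad)
        beta = beta + step
        if np.abs(step).max() < 1e-10:
            break
    mu = expit(X @ beta)
    H = X.T @ (X * (mu * (1 - mu))[:, None]) + np.diag(lam)
    return beta, np.linalg.inv(H)


@dataclass
class PooledEstimates:
    """Rubin-pooled coefficients across m imputations.

    ``table`` holds, per coefficient: pooled estimate, within-imputation
    variance, between-imputation variance, total variance
    T = W + (1 + 1/m) B, Barnard-Rubin degrees of freedom and the t-based CI.
    ``covariance`` is the pooled full covariance matrix (W-bar matrix plus
    (1 + 1/m) x between-imputation covariance), whose (cost:treatment,
    qaly:treatment) block is the joint uncertainty of (incremental cost,
    incremental QALY).
    """

    table: pd.DataFrame
    covariance: pd.DataFrame
    m: int
    nu_complete: float

    def estimate(self, name: str) -> float:
        return float(self.table.loc[name, "estimate"])

    def delta_block(
        self, names: tuple[str, str] = ("cost:treatment", "qaly:treatment")
    ) -> tuple[np.ndarray, np.ndarray]:
        """Pooled mean vector and covariance of (incremental cost, effect)."""
        mean = self.table.loc[list(names), "estimate"].to_numpy()
        cov = self.covariance.loc[list(names), list(names)].to_numpy()
        return mean, cov

    def to_dict(self) -> dict:
        return {
            "schema_version": "1.0",
            "m": self.m,
            "nu_complete": self.nu_complete,
            "coefficients": {
                name: {k: float(v) for k, v in row.items()}
                for name, row in self.table.iterrows()
            },
            "covariance": {
                "names": list(self.covariance.index),
                "matrix": self.covariance.to_numpy().tolist(),
            },
        }

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def pool_rubin(
    fits: Sequence[FitResult], ci_level: float = 0.95, n_params: Optional[int] = None
) -> PooledEstimates:
    """Pool m fits with Rubin's rules.

    Point estimate = mean of the m estimates; within variance W = mean of the
    m sampling variances; between variance B = sample variance of the m
    estimates; total T = W + (1 + 1/m) B; degrees of freedom by the
    Barnard-Rubin small-sample formula with complete-data df = n - p.
    """
    m = len(fits)
    if m < 2:
        raise ValueError("Rubin pooling needs m >= 2 fits")
    names = list(fits[0].params.index)
    for f in fits[1:]:
        if list(f.params.index) != names:
            raise ValueError("all fits must share identical coefficient names")

    Q = np.vstack([f.params.to_numpy() for f in fits])  # (m, k)
    U = np.stack([f.cov.to_numpy() for f in fits])  # (m, k, k)
    qbar = Q.mean(axis=0)
    ubar = U.mean(axis=0)
    dev = Q - qbar
    Bmat = dev.T @ dev / (m - 1)
    Tmat = ubar + (1 + 1 / m) * Bmat

    k = len(names) if n_params is None else n_params
    nu_com = max(fits[0].n_used - k, 1)
    w = np.diag(ubar)
    b = np.diag(Bmat)
    t = np.diag(Tmat)

    with np.errstate(divide="ignore", invalid="ignore"):
        gamma = np.where(t > 0, (1 + 1 / m) * b / t, 0.0)
    nu_obs = (nu_com + 1) / (nu_com + 3) * nu_com * (1 - gamma)
    with np.errstate(divide="ignore"):
        nu_old = np.where(gamma > 0, (m - 1) / gamma**2, np.inf)
    df = 1.0 / (1.0 / nu_old + 1.0 / nu_obs)

    alpha = 1 - ci_level
    tcrit = stats.t.ppf(1 - alpha / 2, df)
    se = np.sqrt(t)
    table = pd.DataFrame(
        {
            "estimate": qbar,
            "within_var": w,
            "between_var": b,
            "total_var": t,
            "se": se,
            "df": df,
            "ci_lo": qbar - tcrit * se,
            "ci_hi": qbar + tcrit * se,
        },
        index=names,
    )
    covariance = pd.DataFrame(Tmat, index=names, columns=names)
    return PooledEstimates(
        table=table, covariance=covariance, m=m, nu_complete=float(nu_com)
    )


def pool_scalar(
    estimates: Sequence[float], variances: Sequence[float], n_used: int, n_params: int
) -> dict[str, float]:
    """Rubin-pool a scalar quantity (e.g. a risk difference)."""
    fits = [
        FitResult(
            params=pd.Series([q], index=["value"]),
            cov=pd.DataFrame([[u]], index=["value"], columns=["value"]),
            n_used=n_used,
        )
        for q, u in zip(estimates, variances)
    ]
    pooled = pool_rubin(fits, n_params=n_params)
    row = pooled.table.loc["value"]
    return {k: float(row[k]) for k in row.index}
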