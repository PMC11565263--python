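"""Multiple imputation by chained equations with predictive mean matching.

Each incomplete follow-up column is imputed from a linear model on baseline
covariates and the other (currently completed) outcome columns, cycling
through columns in a fixed timepoint order for a configured number of
burn-in cycles, independently for each of the m imputations.

Predictive mean matching (type 2): coefficients are redrawn from their
approximate posterior for every imputation step, predictions are formed for
observed and missing rows with the *drawn* coefficients, and each missing
cell receives the observed outcome of a donor sampled uniformly from the k
nearest observed rows in predicted value (ties at the k-th distance are all
included).  Imputed values therefore always lie in the observed support of
their column — PHQ-9 imputations stay integers in 0..27, utilities stay in
[0, 1] — and skewed or bounded distributions are preserved.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import FOLLOWUPS, ImputationConfig
from . import synthetic_trial as st

#: Baseline (always-complete) predictors entering every imputation model.
BASELINE_PREDICTORS: tuple[str, ...] = (
    "arm",
    "age",
    "sex",
    "utility_baseline",
    "phq9_baseline",
)

#: Fixed column visit order: left-to-right by timepoint, utility before PHQ-9.
VISIT_ORDER: tuple[str, ...] = tuple(
    col for t in FOLLOWUPS for col in (st.UTILITY_COLS[t], st.PHQ9_COLS[t])
)


class SingularDesignWarning(UserWarning):
    """Raised (as a warning) when the PMM design is singular; a ridge term
    is added so the step can proceed."""


def pmm_impute_variable(
    observed_outcomes: np.ndarray,
    predictors_observed: np.ndarray,
    predictors_missing: np.ndarray,
    k_donors: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Impute one variable's missing rows by predictive mean matching.

    Parameters are raw arrays: ``observed_outcomes`` (n_obs,), design
    matrices *without* an intercept column (one is added internally).
    Returns one imputed value per row of ``predictors_missing``; each equals
    some entry of ``observed_outcomes``.
    """
    y = np.asarray(observed_outcomes, float)
    X_obs = np.column_stack([np.ones(len(y)), np.asarray(predictors_observed, float)])
    n_obs, p = X_obs.shape
    n_mis = len(predictors_missing)
    if n_mis == 0:
        return np.empty(0)
    X_mis = np.column_stack(
        [np.ones(n_mis), np.asarray(predictors_missing, float)]
    )
    if n_obs < k_donors:
        raise ValueError(
            f"only {n_obs} observed rows but k_donors={k_donors}; cannot match"
        )
    if n_obs <= p:
        raise ValueError(f"need more than {p} observed rows to fit the PMM model")

    XtX = X_obs.T @ X_obs
    Xty = X_obs.T @ y
    # Ridge fallback on singular designs: small diagonal inflation, warned.
    try:
        beta_hat = np.linalg.solve(XtX, Xty)
        XtX_inv = np.linalg.inv(XtX)
        if np.linalg.cond(XtX) > 1e12:
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        warnings.warn(
            "singular design in PMM step; adding ridge term", SingularDesignWarning
        )
        lam = 1e-6 * np.trace(XtX) / p
        XtX = XtX + lam * np.eye(p)
        beta_hat = np.linalg.solve(XtX, Xty)
        XtX_inv = np.linalg.inv(XtX)

    resid = y - X_obs @ beta_hat
    df = max(n_obs - p, 1)
    rss = float(resid @ resid)

    # Type-2 parameter draw: sigma^2 from the scaled inverse-chi^2, beta from
    # its normal approximation around the least-squares fit.
    sigma2_dot = rss / rng.chisquare(df) if rss > 0 else 0.0
    cov = sigma2_dot * XtX_inv
    # Symmetrize before factoring; guard semi-definite corner cases.
    cov = (cov + cov.T) / 2
    try:
        L = np.linalg.cholesky(cov + 1e-12 * np.eye(p))
    except np.linalg.LinAlgError:
        w, V = np.linalg.eigh(cov)
        L = V @ np.diag(np.sqrt(np.clip(w, 0, None)))
    beta_dot = beta_hat + L @ rng.standard_normal(p)

    yhat_obs = X_obs @ beta_dot
    yhat_mis = X_mis @ beta_dot

    imputed = np.empty(n_mis)
    k = min(k_donors, n_obs)
    for i in range(n_mis):
        d = np.abs(yhat_obs - yhat_mis[i])
        kth = np.partition(d, k - 1)[k - 1]
        donors = np.flatnonzero(d <= kth + 1e-12 * max(kth, 1.0))
        imputed[i] = y[donors[rng.integers(len(donors))]]
    return imputed


@dataclass
class ImputedStack:
    """m completed copies of a trial table plus imputation provenance."""

    datasets: list[pd.DataFrame]
    mask: pd.DataFrame  # True where the source cell was missing
    config: ImputationConfig
    column_order: tuple[str, ...]
    source_columns: tuple[str, ...] = field(default_factory=tuple)

    @property
    def m(self) -> int:
        return len(self.datasets)

    def complete(self, j: int) -> pd.DataFrame:
        return self.datasets[j]

    def manifest(self) -> dict:
        return {
            "m": self.m,
            "k_donors": self.config.k_donors,
            "n_cycles": self.config.n_cycles,
            "seed": self.config.seed,
            "column_order": list(self.column_order),
        }

    def to_csvs(self, out_dir: str | Path) -> Path:
        """Write m completed CSVs plus a JSON manifest; returns manifest path."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for j, df in enumerate(self.datasets):
            df.to_csv(out_dir / f"imputed_{j:04d}.csv", index=False)
        man = self.manifest()
        man["files"] = [f"imputed_{j:04d}.csv" for j in range(self.m)]
        path = out_dir / "imputation_manifest.json"
        with open(path, "w") as fh:
            json.dump(man, fh, indent=2)
        return path


def _imputable_columns(data: pd.DataFrame) -> list[str]:
    cols = [c for c in VISIT_ORDER if c in data.columns and data[c].isna().any()]
    for c in cols:
        if data[c].isna().all():
            raise ValueError(f"column {c!r} is entirely missing: no donors for PMM")
    return cols


def _design(data: pd.DataFrame, predictors: list[str]) -> np.ndarray:
    out = []
    for c in predictors:
        if c == "arm":
            out.append((data["arm"] == "intervention").to_numpy(float))
        elif c == "sex":
            out.append((data["sex"] == "female").to_numpy(float))
        else:
            out.append(data[c].to_numpy(float))
    return np.column_stack(out)


def run_mice(data: pd.DataFrame, config: ImputationConfig) -> ImputedStack:
    """Run chained-equation PMM imputation, returning m completed datasets.

    Baseline columns must be complete.  Missing cells are initialized with a
    random draw from the column's observed values, then each incomplete
    column is re-imputed for ``n_cycles`` cycles in the fixed
    :data:`VISIT_ORDER`, conditioning on baseline covariates and the current
    completed values of the other outcome columns.  Observed cells pass
    through bit-identical.  A complete input yields m identical copies.
    """
    for c in BASELINE_PREDICTORS:
        if data[c].isna().any():
            raise ValueError(f"baseline column {c!r} must be complete")

    targets = _imputable_columns(data)
    mask = data[list(VISIT_ORDER)].isna() if targets else pd.DataFrame(
        False, index=data.index, columns=list(VISIT_ORDER)
    )

    streams = [
        np.random.default_rng(s)
        for s in np.random.SeedSequence(config.seed).spawn(config.m)
    ]
    datasets: list[pd.DataFrame] = []
    for rng in streams:
        work = data.copy()
        if targets:
            for c in targets:
                obs_vals = work[c].dropna().to_numpy(float)
                n_mis = int(work[c].isna().sum())
                work.loc[work[c].isna(), c] = rng.choice(obs_vals, n_mis)
            for _ in range(config.n_cycles):
                for c in targets:
                    miss = mask[c].to_numpy()
                    predictors = _predictors_for(c, targets, config)
                    X = _design(work, predictors)
                    y_obs = data.loc[~miss, c].to_numpy(float)
                    imp = pmm_impute_variable(
                        y_obs, X[~miss], X[miss], config.k_donors, rng
                    )
                    work.loc[miss, c] = imp
        datasets.append(work)

    return ImputedStack(
        datasets=datasets,
        mask=mask,
        config=config,
        column_order=tuple(targets),
        source_columns=tuple(data.columns),
    )


def _predictors_for(
    target: str, targets: list[str], config: ImputationConfig
) -> list[str]:
    if config.variables_in_model is not None:
        pool = [c for c in config.variables_in_model if c != target]
    else:
        pool = list(BASELINE_PREDICTORS) + [c for c in VISIT_ORDER if c != target]
    return pool
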