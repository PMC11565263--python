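"""End-to-end orchestration: simulate/load -> impute -> estimate -> decide.

``run_pipeline`` composes the stages and writes a reproducible result bundle
(CSV/JSON only); ``report_tables`` renders the bundle as human-readable
tables.  A run is fully determined by its :class:`~ccbt_cea.config.RunConfig`
— rerunning with the same config reproduces identical outputs.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .config import RunConfig, FOLLOWUPS
from . import cea as cea_mod
from . import synthetic_trial as st
from .estimation import (
    FitResult,
    PooledEstimates,
    build_analysis_frame,
    fit_joint_cost_qaly,
    fit_response_logit,
    pool_rubin,
    pool_scalar,
)
from .mice_pmm import run_mice

#: Named WTP thresholds reported in the decision summary (USD per QALY, and
#: USD per additional responder for the response analysis).
QALY_THRESHOLDS = (50_000.0, 100_000.0)
RESPONSE_THRESHOLD = 5_000.0

BUNDLE_FILES = (
    "trial.csv",
    "imputation_manifest.json",
    "pooled_estimates.json",
    "ce_draws.csv",
    "ceac.csv",
    "decision_summary.json",
    "extrapolation.csv",
    "table1.csv",
    "table2.csv",
    "run_manifest.json",
)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and a remediation hint."""

    def __init__(self, stage: str, hint: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause} (hint: {hint})")
        self.stage = stage


@dataclass
class ResultBundle:
    """In-memory results of a full pipeline run."""

    config: RunConfig
    trial_observed: pd.DataFrame
    pooled_joint: PooledEstimates
    pooled_logit: dict[str, PooledEstimates]
    response_rd: dict[str, dict[str, float]]
    end_utility_gap: dict[str, float]
    ce_dist: cea_mod.CEDistribution
    ceac_curve: Optional[cea_mod.CEACurve]
    decision: dict
    extrapolation: pd.DataFrame
    table1: pd.DataFrame
    residual_correlation: float
    joint_fits: list[FitResult] = field(default_factory=list)


def _fit_utility_gap(frame: pd.DataFrame, completed: pd.DataFrame) -> FitResult:
    """OLS of 6-month utility on treatment, age, sex, baseline utility —
    the adjusted end-of-trial utility gap used by the extrapolation."""
    aug = frame.copy()
    aug["utility_fu6"] = completed[st.UTILITY_COLS["fu6"]].to_numpy(float)
    X = np.column_stack(
        [
            np.ones(len(aug)),
            aug["treatment"],
            aug["age"],
            aug["female"],
            aug["baseline_utility"],
        ]
    )
    names = ["intercept", "treatment", "age", "female", "baseline_utility"]
    y = aug["utility_fu6"].to_numpy(float)
    XtX_inv = np.linalg.inv(X.T @ X)
    beta = XtX_inv @ (X.T @ y)
    resid = y - X @ beta
    s2 = resid @ resid / (len(y) - X.shape[1])
    return FitResult(
        params=pd.Series(beta, index=names),
        cov=pd.DataFrame(s2 * XtX_inv, index=names, columns=names),
        n_used=len(y),
    )


def run_pipeline(config: RunConfig, out_dir: Optional[str | Path] = None) -> ResultBundle:
    """Run the full within-trial cost-effectiveness analysis.

    Writes the result bundle under ``out_dir`` (default: the config's
    ``out_dir``) and returns the in-memory results.
    """
    out = Path(out_dir if out_dir is not None else config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    # --- data -------------------------------------------------------------
    try:
        if config.input_csv == "simulate":
            complete = st.generate_trial(config.generator)
            trial = st.induce_missingness(complete, config.generator)
            st.write_trial_csv(
                trial,
                out / "trial.csv",
                meta={
                    "seed": config.generator.seed,
                    "generator": config.generator.model_dump(mode="json"),
                },
            )
        else:
            trial = st.read_trial_csv(config.input_csv)
            st.write_trial_csv(trial, out / "trial.csv", meta={"source": config.input_csv})
        st.validate_trial(trial)
    except Exception as e:  # noqa: BLE001
        raise StageError("data", "check the input CSV schema / generator config", e)

    # --- imputation --------------------------------------------------------
    try:
        stack = run_mice(trial, config.imputation)
        with open(out / "imputation_manifest.json", "w") as fh:
            json.dump(stack.manifest(), fh, indent=2)
    except Exception as e:  # noqa: BLE001
        raise StageError("imputation", "ensure no column is entirely missing", e)

    # --- estimation ---------------------------------------------------------
    try:
        joint_fits, gap_fits = [], []
        logit_fits: dict[str, list[FitResult]] = {"post": [], "fu6": []}
        for j in range(stack.m):
            completed = stack.complete(j)
            frame = build_analysis_frame(completed, config.costs, config.times_years)
            joint_fits.append(fit_joint_cost_qaly(frame))
            for tp in ("post", "fu6"):
                logit_fits[tp].append(fit_response_logit(frame, timepoint=tp))
            gap_fits.append(_fit_utility_gap(frame, completed))

        pooled_joint = pool_rubin(joint_fits, n_params=5)
        pooled_logit = {tp: pool_rubin(fits) for tp, fits in logit_fits.items()}
        response_rd = {
            tp: pool_scalar(
                [f.extras["risk_difference"] for f in fits],
                [f.extras["risk_difference_var"] for f in fits],
                n_used=fits[0].n_used,
                n_params=5,
            )
            for tp, fits in logit_fits.items()
        }
        pooled_gap = pool_rubin(gap_fits)
        end_gap = {
            "estimate": pooled_gap.estimate("treatment"),
            "se": float(pooled_gap.table.loc["treatment", "se"]),
        }
        resid_corr = float(
            np.mean([f.residual_correlation for f in joint_fits])
        )
        pooled_joint.to_json(out / "pooled_estimates.json")
    except Exception as e:  # noqa: BLE001
        raise StageError("estimation", "inspect the completed datasets for degeneracy", e)

    # --- decision analysis ---------------------------------------------------
    try:
        mean, cov = pooled_joint.delta_block()
        dist = cea_mod.simulate_ce_distribution(
            mean, cov, n_draws=config.n_draws, seed=config.cea_seed
        )
        dist.to_frame().to_csv(out / "ce_draws.csv", index=False)

        icer_point = cea_mod.compute_icer(mean[0], mean[1])
        try:
            ci = cea_mod.icer_ci(dist)
        except ValueError as err:
            # Too many draws with non-positive effect: the ratio CI is not
            # meaningful; record the refusal rather than aborting the run.
            ci = {"refused": str(err)}
        grid = np.arange(0.0, config.wtp_max + config.wtp_step / 2, config.wtp_step)
        grid = grid[grid <= config.wtp_max]
        curve: Optional[cea_mod.CEACurve] = None
        if grid.size == 0:
            warnings.warn("empty WTP grid: CEAC section omitted from the summary")
            pd.DataFrame(columns=["wtp", "prob_cost_effective"]).to_csv(
                out / "ceac.csv", index=False
            )
        else:
            curve = cea_mod.ceac(dist, grid)
            curve.to_frame().to_csv(out / "ceac.csv", index=False)

        rd_post = response_rd["post"]["estimate"]
        resp = cea_mod.response_icer(mean[0], rd_post) if rd_post > 0 else None
        # Response-based plane: cost and response models are fitted
        # separately, so the joint draws use a zero cross-covariance.
        resp_cov = np.diag([cov[0, 0], response_rd["post"]["total_var"]])
        resp_dist = cea_mod.simulate_ce_distribution(
            [mean[0], rd_post],
            resp_cov,
            n_draws=config.n_draws,
            seed=config.cea_seed + 1,
            effect_units="responder",
        )
        resp_dist.to_frame().to_csv(out / "response_ce_draws.csv", index=False)

        mean_ratio_pos = dist.delta_effect > 0
        decision = {
            "schema_version": "1.0",
            "icer_per_qaly": icer_point["icer"],
            "icer_quadrant": icer_point["quadrant"],
            "icer_ci": ci,
            "icer_mean_of_ratios": float(
                np.mean(dist.delta_cost[mean_ratio_pos] / dist.delta_effect[mean_ratio_pos])
            ),
            "delta_cost": float(mean[0]),
            "delta_qaly": float(mean[1]),
            "residual_correlation": resid_corr,
            "odds_ratio_12wk": float(
                np.exp(pooled_logit["post"].estimate("treatment"))
            ),
            "odds_ratio_6mo": float(np.exp(pooled_logit["fu6"].estimate("treatment"))),
            "incremental_response_prob_12wk": rd_post,
            "response_icer": resp,
            "prob_cost_effective_response_threshold": (
                float(
                    cea_mod.ceac(resp_dist, [RESPONSE_THRESHOLD]).probability[0]
                )
            ),
            "end_utility_gap": end_gap,
            "m": pooled_joint.m,
            "n_draws": config.n_draws,
        }
        if curve is not None:
            decision["prob_cost_effective"] = {
                f"{int(thr)}": curve.at(thr)
                for thr in QALY_THRESHOLDS
                if thr <= grid[-1]
            }
        ext = cea_mod.extrapolation_table(
            mean[1], end_gap["estimate"], mean[0], config.extrapolation_horizons_months
        )
        ext.to_csv(out / "extrapolation.csv", index=False)
        with open(out / "decision_summary.json", "w") as fh:
            json.dump(decision, fh, indent=2)
    except Exception as e:  # noqa: BLE001
        raise StageError("cea", "check the pooled covariance is PSD", e)

    # --- reporting -----------------------------------------------------------
    table1 = st.summarize_trial(trial)
    table1.to_csv(out / "table1.csv", index=False)
    table2 = _coefficient_table(pooled_joint, pooled_logit)
    table2.to_csv(out / "table2.csv", index=False)

    manifest = {
        "schema_version": "1.0",
        "package_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "config": config.model_dump(mode="json"),
        "files": list(BUNDLE_FILES),
    }
    with open(out / "run_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)

    return ResultBundle(
        config=config,
        trial_observed=trial,
        pooled_joint=pooled_joint,
        pooled_logit=pooled_logit,
        response_rd=response_rd,
        end_utility_gap=end_gap,
        ce_dist=dist,
        ceac_curve=curve,
        decision=decision,
        extrapolation=ext,
        table1=table1,
        residual_correlation=resid_corr,
        joint_fits=joint_fits,
    )


def _coefficient_table(
    pooled_joint: PooledEstimates, pooled_logit: dict[str, PooledEstimates]
) -> pd.DataFrame:
    rows = []
    for name, row in pooled_joint.table.iterrows():
        outcome, coef = str(name).split(":", 1)
        rows.append(
            {
                "model": outcome,
                "coefficient": coef,
                "estimate": row["estimate"],
                "se": row["se"],
                "ci_lo": row["ci_lo"],
                "ci_hi": row["ci_hi"],
                "scale": "identity",
            }
        )
    label = {"post": "response_12wk", "fu6": "response_6mo"}
    for tp, pooled in pooled_logit.items():
        for name, row in pooled.table.iterrows():
            rows.append(
                {
                    "model": label[tp],
                    "coefficient": str(name),
                    "estimate": float(np.exp(row["estimate"])),
                    "se": row["se"],
                    "ci_lo": float(np.exp(row["ci_lo"])),
                    "ci_hi": float(np.exp(row["ci_hi"])),
                    "scale": "odds_ratio",
                }
            )
    return pd.DataFrame(rows)


def report_tables(out_dir: str | Path) -> dict[str, pd.DataFrame]:
    """Load and return the human-readable tables of a completed run.

    Raises with the list of missing files if the bundle is incomplete.
    """
    out = Path(out_dir)
    missing = [f for f in BUNDLE_FILES if not (out / f).exists()]
    if missing:
        raise FileNotFoundError(f"incomplete result bundle; missing: {missing}")
    tables = {
        "table1": pd.read_csv(out / "table1.csv"),
        "table2": pd.read_csv(out / "table2.csv"),
        "ceac": pd.read_csv(out / "ceac.csv"),
        "extrapolation": pd.read_csv(out / "extrapolation.csv"),
    }
    with open(out / "decision_summary.json") as fh:
        decision = json.load(fh)
    tables["decision"] = pd.json_normalize(decision)
    return tables
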