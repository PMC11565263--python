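"""Synthetic two-arm depression-trial data generator.

The participant-level data of the underlying randomized trial are not
publicly deposited, so the pipeline is exercised on synthetic data with the
same statistical structure: a two-arm trial of computer-assisted CBT added to
treatment as usual (intervention) versus treatment as usual alone (control),
with SF-12-derived utilities at baseline / post-treatment (12 weeks) / 3- and
6-month follow-up, PHQ-9 depression scores at the same occasions, session
attendance and device-lending records in the intervention arm, and
missing-at-random follow-up assessments.

Generative model (per participant i):

* a shared latent severity factor ``z_i ~ N(0, 1)`` links utilities, PHQ-9
  and treatment response;
* baseline utility ``u0 ~ N(mu0[arm], sd0)``;
* follow-up utility ``u_t = mu[arm][t] + slope (u0 - mu0[arm]) + w_u z + eps``;
* baseline PHQ-9 is an integer draw truncated to [10, 27] (trial inclusion
  required a score of at least 10);
* response (>= 50% PHQ-9 reduction) at each follow-up is a Gaussian-copula
  Bernoulli with the configured arm-by-timepoint marginal probability,
  loading on z (severity) and on a persistent response propensity;
* follow-up PHQ-9 scores are drawn consistent with the response indicator;
* sessions attended ~ beta-binomial on 0..12 (intervention arm only).

All draws come from a single :class:`numpy.random.Generator`, so the same
(config, seed) yields a byte-identical table.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .config import ARMS, DEFAULT_TIMES_YEARS, FOLLOWUPS, CostParameters, GeneratorConfig

#: Wide-format column order of the trial CSV (one row per participant;
#: empty cell = missing).
TRIAL_COLUMNS: tuple[str, ...] = (
    "id",
    "arm",
    "age",
    "sex",
    "utility_baseline",
    "utility_post",
    "utility_fu3",
    "utility_fu6",
    "phq9_baseline",
    "phq9_post",
    "phq9_fu3",
    "phq9_fu6",
    "sessions",
    "borrowed_device",
    "returned_device",
)

UTILITY_COLS = {t: f"utility_{t}" for t in ("baseline",) + FOLLOWUPS}
PHQ9_COLS = {t: f"phq9_{t}" for t in ("baseline",) + FOLLOWUPS}

# SF-12 component-summary trajectories used only when generate_sf12=True:
# means by arm and timepoint for the mental component score (MCS); the
# physical component score (PCS) is stable over follow-up.
_MCS_MEANS = {
    "intervention": (27.96, 40.91, 39.50, 38.12),
    "control": (29.76, 33.73, 33.00, 31.49),
}
_MCS_SD = 8.0
_PCS_MEAN, _PCS_SD = 44.0, 10.0


def generate_trial(config: GeneratorConfig) -> pd.DataFrame:
    """Generate a complete (pre-missingness) participant-level trial table.

    Arm counts are exact (``n_intervention`` / ``n_total - n_intervention``);
    arm labels are randomly permuted across participant ids.
    """
    rng = np.random.default_rng([config.seed, 0])
    n = config.n_total

    arm = np.array(
        ["intervention"] * config.n_intervention
        + ["control"] * (n - config.n_intervention)
    )
    rng.shuffle(arm)
    is_int = arm == "intervention"

    sex = np.where(rng.random(n) < config.prop_female, "female", "male")
    age = np.clip(rng.normal(config.age_mean, config.age_sd, n), 18.0, 90.0)

    z = rng.standard_normal(n)  # shared latent severity

    mu0 = np.where(
        is_int,
        config.baseline_utility_mean["intervention"],
        config.baseline_utility_mean["control"],
    )
    u0 = np.clip(rng.normal(mu0, config.baseline_utility_sd), 0.0, 1.0)

    w_p = config.latent_phq9_weight
    phq9_raw = config.baseline_phq9_mean + config.baseline_phq9_sd * (
        w_p * z + np.sqrt(1.0 - w_p**2) * rng.standard_normal(n)
    )
    phq9_0 = np.clip(np.rint(phq9_raw), config.baseline_phq9_min, 27).astype(int)

    data: dict[str, np.ndarray] = {
        "id": np.arange(1, n + 1),
        "arm": arm,
        "age": age,
        "sex": sex,
        UTILITY_COLS["baseline"]: u0,
        PHQ9_COLS["baseline"]: phq9_0,
    }

    if config.generate_sf12:
        from .outcomes import DEFAULT_TARIFF, map_sf12_to_utility

        for j, t in enumerate(("baseline",) + FOLLOWUPS):
            mcs_mu = np.where(
                is_int, _MCS_MEANS["intervention"][j], _MCS_MEANS["control"][j]
            )
            mcs = np.clip(rng.normal(mcs_mu, _MCS_SD), 0.0, 100.0)
            pcs = np.clip(rng.normal(_PCS_MEAN, _PCS_SD, n), 0.0, 100.0)
            data[f"mcs_{t}"] = mcs
            data[f"pcs_{t}"] = pcs
            data[UTILITY_COLS[t]] = map_sf12_to_utility(mcs, pcs, DEFAULT_TARIFF)
    else:
        for t in FOLLOWUPS:
            mu_t = np.where(
                is_int,
                config.utility_trajectory_mean["intervention"][t],
                config.utility_trajectory_mean["control"][t],
            )
            u_t = (
                mu_t
                + config.baseline_utility_slope * (u0 - mu0)
                + config.latent_utility_weight * z
                + config.utility_noise_sd * rng.standard_normal(n)
            )
            data[UTILITY_COLS[t]] = np.clip(u_t, 0.0, 1.0)

    # Treatment response via a Gaussian copula: marginal rate is exactly the
    # configured arm-by-timepoint probability; loadings on z (severity) and a
    # persistent propensity g induce realistic correlation without changing
    # the marginals.
    w_r = config.latent_response_weight
    c_r = config.response_persistence
    resid = np.sqrt(max(0.0, 1.0 - w_r**2 - c_r**2))
    g = rng.standard_normal(n)
    for t in FOLLOWUPS:
        p_t = np.where(
            is_int,
            config.response_prob["intervention"][t],
            config.response_prob["control"][t],
        )
        s_t = w_r * z + c_r * g + resid * rng.standard_normal(n)
        responder = stats.norm.cdf(s_t) < p_t

        # Follow-up PHQ-9 consistent with the response flag: responders end
        # at <= baseline/2 (floor keeps odd baselines on the response side of
        # the 50% boundary), non-responders strictly above it.
        u_resp = rng.uniform(0.1, 1.0, n)
        u_non = rng.uniform(0.55, 1.15, n)
        f_resp = np.floor(u_resp * phq9_0 / 2.0)
        f_non = np.minimum(np.ceil(u_non * phq9_0), 27.0)
        data[PHQ9_COLS[t]] = np.where(responder, f_resp, f_non).astype(int)

    # Intervention-arm process data: sessions, device borrowing.
    p_sess = rng.beta(config.session_alpha, config.session_beta, n)
    sessions = rng.binomial(config.session_n, p_sess).astype(float)
    sessions[~is_int] = np.nan
    borrowed = is_int & (rng.random(n) < config.borrow_prob)
    returned = borrowed & (rng.random(n) < config.return_prob_given_borrow)
    data["sessions"] = sessions
    data["borrowed_device"] = borrowed
    data["returned_device"] = returned

    df = pd.DataFrame(data)
    ordered = [c for c in TRIAL_COLUMNS if c in df.columns]
    extra = [c for c in df.columns if c not in ordered]
    return df[ordered + extra]


def induce_missingness(
    data: pd.DataFrame, config: GeneratorConfig
) -> pd.DataFrame:
    """Mask follow-up assessments missing-at-random.

    Missingness is visit-level (utility and PHQ-9 at a timepoint vanish
    together, as when a participant skips an assessment) with probability
    logistic in *observed* covariates only — arm, age, baseline PHQ-9 — never
    in the masked values themselves.  The intercept of each timepoint's logit
    is solved numerically so the realized marginal rate equals the configured
    rate for the covariates at hand.  Baseline columns are never touched.
    """
    rng = np.random.default_rng([config.seed, 1])
    out = data.copy()

    w = config.mar_covariate_weights
    covs = {
        "arm": (data["arm"] == "intervention").to_numpy(float),
        "age": data["age"].to_numpy(float),
        "baseline_phq9": data[PHQ9_COLS["baseline"]].to_numpy(float),
    }
    lp = np.zeros(len(data))
    for name, x in covs.items():
        sd = x.std()
        if w.get(name, 0.0) and sd > 0:
            lp += w[name] * (x - x.mean()) / sd

    for t in FOLLOWUPS:
        rate = config.missing_rate.get(t, 0.0)
        if rate <= 0.0:
            continue
        if rate >= 1.0:
            miss = np.ones(len(data), bool)
        else:
            intercept = optimize.brentq(
                lambda c: stats.logistic.cdf(c + lp).mean() - rate, -30.0, 30.0
            )
            miss = rng.random(len(data)) < stats.logistic.cdf(intercept + lp)
        out.loc[miss, UTILITY_COLS[t]] = np.nan
        out.loc[miss, PHQ9_COLS[t]] = np.nan

    return out


def validate_trial(data: pd.DataFrame) -> None:
    """Raise ``ValueError`` on any violated participant-table invariant."""
    missing_cols = [c for c in TRIAL_COLUMNS if c not in data.columns]
    if missing_cols:
        raise ValueError(f"missing trial columns: {missing_cols}")
    if data[["id", "arm", "age", "sex"]].isna().any().any():
        raise ValueError("baseline identification columns must be complete")
    for t in ("baseline",) + FOLLOWUPS:
        u = data[UTILITY_COLS[t]].dropna()
        if ((u < 0) | (u > 1)).any():
            raise ValueError(f"utilities at {t} outside [0, 1]")
        q = data[PHQ9_COLS[t]].dropna()
        if ((q < 0) | (q > 27)).any():
            raise ValueError(f"PHQ-9 at {t} outside [0, 27]")
    if data[[UTILITY_COLS["baseline"], PHQ9_COLS["baseline"]]].isna().any().any():
        raise ValueError("baseline utility/PHQ-9 must be complete")
    s = data.loc[data["arm"] == "intervention", "sessions"].dropna()
    if ((s < 0) | (s > 12)).any():
        raise ValueError("sessions outside [0, 12]")
    bad = data["returned_device"] & ~data["borrowed_device"]
    if bad.any():
        raise ValueError("returned_device requires borrowed_device")


def summarize_trial(data: pd.DataFrame, ci_level: float = 0.95) -> pd.DataFrame:
    """Arm-by-timepoint summary of observed utilities and response rates.

    Returns one row per (arm, timepoint) with the observed-case utility mean
    and t-based CI, and — at follow-ups — the treatment-response fraction
    (>= 50% PHQ-9 reduction among observed cases) with a Wilson CI.  A
    timepoint with no observed cases in an arm is flagged ``available=False``
    rather than raising.
    """
    from statsmodels.stats.proportion import proportion_confint

    rows = []
    alpha = 1.0 - ci_level
    for arm in ARMS:
        sub = data[data["arm"] == arm]
        if len(sub) == 0:
            raise ValueError(f"no participants in arm {arm!r}")
        base = sub[PHQ9_COLS["baseline"]].to_numpy(float)
        for t in ("baseline",) + FOLLOWUPS:
            u = sub[UTILITY_COLS[t]].dropna()
            row: dict[str, object] = {"arm": arm, "timepoint": t, "n_obs": len(u)}
            row["available"] = len(u) > 0
            if len(u) > 0:
                row["utility_mean"] = u.mean()
                if len(u) > 1:
                    half = stats.t.ppf(1 - alpha / 2, len(u) - 1) * stats.sem(u)
                    row["utility_lo"], row["utility_hi"] = u.mean() - half, u.mean() + half
                else:
                    row["utility_lo"] = row["utility_hi"] = u.mean()
            if t != "baseline":
                fup = sub[PHQ9_COLS[t]].to_numpy(float)
                obs = ~np.isnan(fup)
                if obs.any():
                    resp = (base[obs] - fup[obs]) / base[obs] >= 0.5
                    k, n_obs = int(resp.sum()), int(obs.sum())
                    lo, hi = proportion_confint(k, n_obs, alpha=alpha, method="wilson")
                    row.update(
                        response_rate=k / n_obs, response_lo=lo, response_hi=hi
                    )
            rows.append(row)
    return pd.DataFrame(rows)


def relative_success_gain(p_intervention: float, p_control: float) -> float:
    """Relative increase in treatment-success probability, as a percentage.

    E.g. rates of 0.582 vs 0.340 give ~71% higher success under intervention.
    """
    if p_control <= 0:
        raise ValueError("control response rate must be positive")
    return 100.0 * (p_intervention - p_control) / p_control


def implied_effects(
    config: GeneratorConfig,
    costs: Optional[CostParameters] = None,
    times_years: tuple[float, ...] = DEFAULT_TIMES_YEARS,
) -> dict[str, float]:
    """Closed-form generating values of the quantities the pipeline estimates.

    Returns the covariate-adjusted incremental QALY (the trapezoid-weighted
    contrast of arm trajectories at fixed baseline utility), the expected
    incremental intervention cost, and the marginal response odds ratios.
    The adjusted response odds ratio additionally conditions on baseline
    PHQ-9 and is slightly larger than the marginal one (non-collapsibility);
    see :func:`oracle_adjusted_response_or` for a simulation-based value.
    """
    costs = costs or CostParameters()
    t = np.asarray(times_years)
    # Trapezoid weight of each timepoint in the QALY integral.
    w = np.zeros(len(t))
    w[0] = (t[1] - t[0]) / 2
    w[-1] = (t[-1] - t[-2]) / 2
    w[1:-1] = (t[2:] - t[:-2]) / 2

    mu_i = config.utility_trajectory_mean["intervention"]
    mu_c = config.utility_trajectory_mean["control"]
    d_base = (
        config.baseline_utility_mean["intervention"]
        - config.baseline_utility_mean["control"]
    )
    delta_qaly = sum(
        w[j + 1] * ((mu_i[t_] - mu_c[t_]) - config.baseline_utility_slope * d_base)
        for j, t_ in enumerate(FOLLOWUPS)
    )

    mean_sessions = config.session_n * config.session_alpha / (
        config.session_alpha + config.session_beta
    )
    p_b, p_r = config.borrow_prob, config.return_prob_given_borrow
    exp_device = p_b * (
        costs.mifi_monthly * costs.mifi_months
        + p_r * costs.depreciation_fraction * costs.laptop_unit_cost
        + (1 - p_r) * costs.laptop_unit_cost
    )
    delta_cost = costs.session_rate * mean_sessions + costs.software_cost + exp_device

    out = {"delta_qaly": float(delta_qaly), "delta_cost": float(delta_cost)}
    for t_ in FOLLOWUPS:
        p1 = config.response_prob["intervention"][t_]
        p0 = config.response_prob["control"][t_]
        out[f"response_or_{t_}"] = (p1 / (1 - p1)) / (p0 / (1 - p0))
    return out


def oracle_adjusted_response_or(
    config: GeneratorConfig,
    timepoint: str = "post",
    n_oracle: int = 200_000,
    seed: int = 12345,
) -> float:
    """Covariate-adjusted response odds ratio implied by the generator.

    Estimated by generating one very large complete trial and fitting the
    response logit (treatment + age + sex + baseline PHQ-9); serves as the
    generating truth for parameter-recovery experiments, since conditioning
    on baseline PHQ-9 (correlated with the latent severity factor) makes the
    adjusted odds ratio differ from the marginal one.
    """
    import statsmodels.api as sm

    big = config.model_copy(
        update={
            "n_total": n_oracle,
            "n_intervention": n_oracle // 2,
            "seed": seed,
        }
    )
    df = generate_trial(big)
    base = df[PHQ9_COLS["baseline"]].to_numpy(float)
    fup = df[PHQ9_COLS[timepoint]].to_numpy(float)
    y = ((base - fup) / base >= 0.5).astype(float)
    X = sm.add_constant(
        np.column_stack(
            [
                (df["arm"] == "intervention").to_numpy(float),
                df["age"].to_numpy(float),
                (df["sex"] == "female").to_numpy(float),
                base,
            ]
        )
    )
    fit = sm.GLM(y, X, family=sm.families.Binomial()).fit()
    return float(np.exp(fit.params[1]))


def write_trial_csv(
    data: pd.DataFrame, path: str | Path, meta: Optional[dict] = None
) -> None:
    """Write the trial table as CSV (empty cell = missing).

    Generation metadata (seed, config) goes to a ``<path>.meta.json``
    sidecar so the CSV stays a plain rectangular table.
    """
    path = Path(path)
    data.to_csv(path, index=False)
    if meta is not None:
        with open(path.with_suffix(path.suffix + ".meta.json"), "w") as fh:
            json.dump(meta, fh, indent=2, default=str)


def read_trial_csv(path: str | Path) -> pd.DataFrame:
    """Read a trial table written by :func:`write_trial_csv`."""
    df = pd.read_csv(path)
    for col in ("borrowed_device", "returned_device"):
        if col in df.columns:
            df[col] = df[col].astype(bool)
    validate_trial(df)
    return df
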