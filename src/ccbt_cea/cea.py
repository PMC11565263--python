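"""Decision quantities: ICERs, CE planes, acceptability curves, extrapolation.

The incremental cost-effectiveness ratio (ICER) is the ratio of the pooled
treatment coefficients of the cost and effect regressions.  Uncertainty is
propagated by simulating joint draws of (incremental cost, incremental
effect) from the pooled mean vector and covariance; the cost-effectiveness
acceptability curve (CEAC) reports, at each willingness-to-pay (WTP) value
lambda, the fraction of draws with positive net monetary benefit
``lambda x dE - dC``.  Horizon extrapolation projects the end-of-trial
utility gap forward under two durability scenarios: linear waning to zero at
the horizon end, or a stable benefit, with no intervention cost beyond the
trial.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

MONTHS_PER_YEAR = 12.0


@dataclass
class CEDistribution:
    """Simulated joint draws of (incremental cost, incremental effect)."""

    delta_cost: np.ndarray
    delta_effect: np.ndarray
    seed: Optional[int]
    source_mean: np.ndarray
    source_cov: np.ndarray
    effect_units: str = "QALY"

    def __post_init__(self) -> None:
        if len(self.delta_cost) != len(self.delta_effect):
            raise ValueError("cost and effect draws must be aligned")

    @property
    def n_draws(self) -> int:
        return len(self.delta_cost)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"delta_cost": self.delta_cost, "delta_effect": self.delta_effect}
        )


@dataclass
class CEACurve:
    """Probability cost-effective over an ordered willingness-to-pay grid."""

    wtp: np.ndarray
    probability: np.ndarray
    effect_units: str = "QALY"

    def __post_init__(self) -> None:
        if (np.diff(self.wtp) <= 0).any():
            raise ValueError("WTP grid must be strictly increasing")
        if ((self.probability < 0) | (self.probability > 1)).any():
            raise ValueError("probabilities must lie in [0, 1]")

    def at(self, wtp_value: float) -> float:
        """Probability cost-effective at a WTP value (must be on the grid)."""
        idx = np.flatnonzero(np.isclose(self.wtp, wtp_value))
        if len(idx) == 0:
            raise KeyError(f"{wtp_value} not on the WTP grid")
        return float(self.probability[idx[0]])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"wtp": self.wtp, "prob_cost_effective": self.probability})


def simulate_ce_distribution(
    mean: Sequence[float],
    cov: np.ndarray,
    n_draws: int = 1000,
    seed: Optional[int] = 0,
    effect_units: str = "QALY",
) -> CEDistribution:
    """Multivariate-normal draws of (incremental cost, incremental effect).

    ``mean``/``cov`` are typically the Rubin-pooled treatment coefficients
    and their pooled joint covariance.  The covariance must be (numerically)
    positive semidefinite; otherwise an error suggests projecting to the
    nearest PSD matrix.
    """
    mean = np.asarray(mean, float)
    cov = np.asarray(cov, float)
    if mean.shape != (2,) or cov.shape != (2, 2):
        raise ValueError("need a 2-vector mean and 2x2 covariance")
    eig = np.linalg.eigvalsh((cov + cov.T) / 2)
    if eig.min() < -1e-10 * max(eig.max(), 1.0):
        raise ValueError(
            "covariance is not positive semidefinite; project it to the "
            "nearest PSD matrix (clip negative eigenvalues) before simulating"
        )
    rng = np.random.default_rng(seed)
    draws = rng.multivariate_normal(mean, cov, size=n_draws, method="svd")
    return CEDistribution(
        delta_cost=draws[:, 0],
        delta_effect=draws[:, 1],
        seed=seed,
        source_mean=mean,
        source_cov=cov,
        effect_units=effect_units,
    )


def simulate_ce_mixture(
    means: Sequence[Sequence[float]],
    covs: Sequence[np.ndarray],
    n_draws: int = 1000,
    seed: Optional[int] = 0,
    effect_units: str = "QALY",
) -> CEDistribution:
    """Alternative sampler: a uniform mixture over per-imputation fits.

    Each draw picks one imputation's (mean, covariance) and samples a
    bivariate normal from it, reflecting between-imputation uncertainty
    without the single-normal approximation.
    """
    rng = np.random.default_rng(seed)
    m = len(means)
    idx = rng.integers(m, size=n_draws)
    out = np.empty((n_draws, 2))
    for j in range(m):
        sel = idx == j
        if sel.any():
            out[sel] = rng.multivariate_normal(
                np.asarray(means[j], float), np.asarray(covs[j], float),
                size=int(sel.sum()), method="svd",
            )
    mix_mean = np.mean(np.asarray(means, float), axis=0)
    return CEDistribution(
        delta_cost=out[:, 0],
        delta_effect=out[:, 1],
        seed=seed,
        source_mean=mix_mean,
        source_cov=np.cov(out.T),
        effect_units=effect_units,
    )


def compute_icer(delta_cost: float, delta_effect: float) -> dict[str, object]:
    """ICER = incremental cost / incremental effect, with quadrant labeling.

    North-east quadrant (more costly, more effective) gives the usual
    positive ratio; a negative ratio from the south-east quadrant (cheaper,
    more effective) is flagged ``dominant``, from the north-west (costlier,
    less effective) ``dominated``.
    """
    if delta_effect == 0:
        raise ZeroDivisionError("ICER undefined: incremental effect is zero")
    icer = delta_cost / delta_effect
    if delta_effect > 0:
        quadrant = "dominant (SE)" if delta_cost < 0 else "NE"
    else:
        quadrant = "dominated (NW)" if delta_cost > 0 else "SW"
    return {"icer": float(icer), "quadrant": quadrant}


def icer_ci(
    dist: CEDistribution, level: float = 0.95
) -> dict[str, float]:
    """Percentile interval of the draw-wise ICER.

    Restricted to draws with positive incremental effect (ratios are not
    orderable across quadrants); the excluded fraction is reported, and more
    than 50% exclusions refuse with an error since a ratio CI is then
    meaningless.
    """
    pos = dist.delta_effect > 0
    frac_excluded = 1.0 - pos.mean()
    if frac_excluded > 0.5:
        raise ValueError(
            f"{frac_excluded:.0%} of draws have non-positive incremental "
            "effect; a percentile ICER interval is not meaningful"
        )
    ratios = dist.delta_cost[pos] / dist.delta_effect[pos]
    alpha = 1 - level
    lo, hi = np.quantile(ratios, [alpha / 2, 1 - alpha / 2])
    return {
        "lo": float(lo),
        "hi": float(hi),
        "level": level,
        "fraction_excluded": float(frac_excluded),
    }


def ceac(dist: CEDistribution, wtp_grid: Sequence[float]) -> CEACurve:
    """CEAC: P(net monetary benefit > 0) at each WTP value.

    NMB(lambda) = lambda x dE - dC; ties (NMB exactly 0) count as not
    cost-effective.
    """
    grid = np.asarray(wtp_grid, float)
    if grid.size == 0:
        raise ValueError("WTP grid must be nonempty")
    nmb = grid[:, None] * dist.delta_effect[None, :] - dist.delta_cost[None, :]
    prob = (nmb > 0).mean(axis=1)
    return CEACurve(wtp=grid, probability=prob, effect_units=dist.effect_units)


def response_icer(delta_cost: float, delta_response_prob: float) -> dict[str, float]:
    """Cost per additional treatment responder.

    ``delta_response_prob`` is the incremental probability of response
    (risk difference); the same quantity per 100 patients is also reported.
    """
    if not 0 < delta_response_prob <= 1:
        raise ValueError("incremental response probability must lie in (0, 1]")
    return {
        "icer_per_responder": delta_cost / delta_response_prob,
        "extra_responders_per_100": 100.0 * delta_response_prob,
    }


def extrapolate_icer(
    trial_delta_qaly: float,
    end_utility_gap: float,
    delta_cost: float,
    horizon_months: float,
    durability: str = "stable",
) -> dict[str, float]:
    """ICER over an extended horizon beyond the trial window.

    Post-trial QALY gain = end-of-trial utility gap x horizon (stable
    benefit) or half that (benefit waning linearly to zero at the horizon
    end).  No intervention cost accrues beyond the trial, so the ICER is
    ``delta_cost / (trial dQALY + post-trial dQALY)``.
    """
    if horizon_months <= 0:
        raise ValueError("horizon must be positive")
    if durability not in ("stable", "linear_waning"):
        raise ValueError("durability must be 'stable' or 'linear_waning'")
    h_years = horizon_months / MONTHS_PER_YEAR
    added = end_utility_gap * h_years
    if durability == "linear_waning":
        added /= 2.0
    total_dqaly = trial_delta_qaly + added
    if total_dqaly == 0:
        raise ZeroDivisionError("total incremental QALY is zero")
    return {
        "horizon_months": float(horizon_months),
        "durability": durability,  # type: ignore[dict-item]
        "added_qaly": float(added),
        "total_delta_qaly": float(total_dqaly),
        "icer": float(delta_cost / total_dqaly),
    }


def extrapolation_table(
    trial_delta_qaly: float,
    end_utility_gap: float,
    delta_cost: float,
    horizons_months: Sequence[float] = (12, 24, 36, 48, 60),
) -> pd.DataFrame:
    """Both durability scenarios across a set of horizons, as one table."""
    rows = [
        extrapolate_icer(trial_delta_qaly, end_utility_gap, delta_cost, h, d)
        for h in horizons_months
        for d in ("linear_waning", "stable")
    ]
    return pd.DataFrame(rows)
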