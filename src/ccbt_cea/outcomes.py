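"""Health outcomes: SF-12 utility mapping, QALYs, treatment response.

Utilities are preference-based health-state valuations on a 0 (death) to 1
(perfect health) scale.  QALYs over the trial window are the area under the
participant's utility trajectory (trapezoid rule, exact for piecewise-linear
trajectories).  Treatment response is a reduction of at least 50% in the
PHQ-9 depression score relative to baseline.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .config import DEFAULT_TIMES_YEARS, FOLLOWUPS
from . import synthetic_trial as st


@dataclass(frozen=True)
class TariffSpec:
    """Affine (MCS, PCS) -> utility mapping, clamped to [0, 1].

    The licensed SF-6D valuation coefficients are proprietary, so the package
    ships a synthetic affine stand-in calibrated to reproduce the trial's
    arm-level mean utilities from its published component-score trajectories;
    any tariff can be loaded from file in its place.
    """

    intercept: float
    coefficient_mcs: float
    coefficient_pcs: float
    floor: float = 0.0
    ceiling: float = 1.0

    def __post_init__(self) -> None:
        vals = (self.intercept, self.coefficient_mcs, self.coefficient_pcs)
        if not all(np.isfinite(vals)):
            raise ValueError("tariff coefficients must be finite")
        if self.floor >= self.ceiling:
            raise ValueError("floor must be below ceiling")

    @classmethod
    def from_file(cls, path: str | Path) -> "TariffSpec":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))

    def to_file(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.__dict__, fh, sort_keys=False)


#: Synthetic default tariff (see :class:`TariffSpec`).
DEFAULT_TARIFF = TariffSpec(
    intercept=-0.066, coefficient_mcs=0.0101, coefficient_pcs=0.0062
)


def map_sf12_to_utility(mcs, pcs, tariff: TariffSpec = DEFAULT_TARIFF):
    """Map SF-12 mental/physical component summary scores to utility.

    Accepts scalars or arrays; scores must lie in the norm-based 0-100 range.
    Output is clamped to the tariff's [floor, ceiling] (default [0, 1]).
    """
    mcs = np.asarray(mcs, float)
    pcs = np.asarray(pcs, float)
    if ((mcs < 0) | (mcs > 100)).any() or ((pcs < 0) | (pcs > 100)).any():
        raise ValueError("MCS/PCS scores must lie in [0, 100]")
    u = tariff.intercept + tariff.coefficient_mcs * mcs + tariff.coefficient_pcs * pcs
    u = np.clip(u, tariff.floor, tariff.ceiling)
    return float(u) if u.ndim == 0 else u


def compute_qaly_auc(times_years, utilities) -> float:
    """QALYs as the trapezoid-rule area under a utility trajectory.

    ``times_years`` must be strictly increasing and start at 0; missing
    utilities are an error (integration happens on completed data only).
    """
    t = np.asarray(times_years, float)
    u = np.asarray(utilities, float)
    if t.shape != u.shape or t.ndim != 1 or len(t) < 2:
        raise ValueError("need >= 2 aligned (time, utility) points")
    if t[0] != 0.0 or (np.diff(t) <= 0).any():
        raise ValueError("times must start at 0 and strictly increase")
    if np.isnan(u).any():
        raise ValueError("utility trajectory contains missing values")
    return float(np.trapezoid(u, t))


def classify_response(baseline_phq9: float, followup_phq9: float) -> bool:
    """True when PHQ-9 fell by at least 50% from baseline (inclusive).

    Baseline must be positive (trial inclusion required >= 10); worsening
    simply classifies as non-response.
    """
    for s, name in ((baseline_phq9, "baseline"), (followup_phq9, "follow-up")):
        if not 0 <= s <= 27:
            raise ValueError(f"{name} PHQ-9 score {s} outside [0, 27]")
    if baseline_phq9 <= 0:
        raise ValueError("baseline PHQ-9 must be positive to define response")
    return (baseline_phq9 - followup_phq9) / baseline_phq9 >= 0.5


def add_derived_outcomes(
    data: pd.DataFrame, times_years=DEFAULT_TIMES_YEARS
) -> pd.DataFrame:
    """Append per-participant QALY and response columns to a completed table.

    QALY and response indicators are always derived *after* imputation from
    the completed utility/PHQ-9 columns, never imputed directly.
    """
    out = data.copy()
    ucols = [st.UTILITY_COLS[t] for t in ("baseline",) + FOLLOWUPS]
    U = out[ucols].to_numpy(float)
    if np.isnan(U).any():
        raise ValueError("utilities contain missing values; impute first")
    t = np.asarray(times_years, float)
    out["qaly"] = np.trapezoid(U, t, axis=1)

    base = out[st.PHQ9_COLS["baseline"]].to_numpy(float)
    for tp in FOLLOWUPS:
        fup = out[st.PHQ9_COLS[tp]].to_numpy(float)
        if np.isnan(fup).any():
            raise ValueError(f"PHQ-9 at {tp} contains missing values; impute first")
        out[f"response_{tp}"] = ((base - fup) / base >= 0.5).astype(int)
    return out
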