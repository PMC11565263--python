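"""Intervention costing from unit prices, attendance and device lending.

Costs are from the health-care payer perspective and cover the intervention
only: clinician-supported sessions at the Medicare psychotherapy
reimbursement rate, the per-participant software license, and loaner
laptop + MiFi data plans for participants without their own device.  Lost
laptops are charged at full unit cost; returned laptops incur a depreciation
charge; the MiFi plan is charged to every borrower for the full loan period.
The control arm (treatment as usual) carries zero intervention cost — the
analysis is incremental and the trial collected no non-intervention
health-service use.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import CostParameters
from . import synthetic_trial as st


def participant_cost(
    sessions: float,
    borrowed: bool,
    returned: bool,
    params: CostParameters | None = None,
) -> float:
    """Total intervention cost (USD) for one intervention-arm participant."""
    params = params or CostParameters()
    if not 0 <= sessions <= 12:
        raise ValueError("sessions must lie in [0, 12]")
    if returned and not borrowed:
        raise ValueError("a device cannot be returned if it was never borrowed")
    device = 0.0
    if borrowed:
        laptop_frac = params.depreciation_fraction if returned else 1.0
        device = (
            laptop_frac * params.laptop_unit_cost
            + params.mifi_monthly * params.mifi_months
        )
    return sessions * params.session_rate + params.software_cost + device


def device_pool_mean_cost(
    n_borrowed: int,
    n_returned: int,
    group_n: int,
    params: CostParameters | None = None,
) -> float:
    """Mean device cost per participant, averaged over the whole arm.

    Lost laptops (borrowed, never returned) at full cost, returned laptops at
    the depreciation fraction, plus the MiFi plan for every borrower.  With
    the default unit costs and the trial's 17 borrowed / 9 returned out of
    95, this is $39.3 per participant.
    """
    params = params or CostParameters()
    if group_n <= 0:
        raise ValueError("group_n must be positive")
    if not 0 <= n_returned <= n_borrowed <= group_n:
        raise ValueError("need 0 <= n_returned <= n_borrowed <= group_n")
    n_lost = n_borrowed - n_returned
    total = (
        n_lost * params.laptop_unit_cost
        + n_returned * params.depreciation_fraction * params.laptop_unit_cost
        + n_borrowed * params.mifi_monthly * params.mifi_months
    )
    return total / group_n


def build_cost_ledger(
    data: pd.DataFrame, params: CostParameters | None = None
) -> pd.DataFrame:
    """Per-participant cost ledger: session, software, device components.

    Control-arm rows are zero throughout.  ``total`` is exactly the sum of
    the components.
    """
    params = params or CostParameters()
    is_int = (data["arm"] == "intervention").to_numpy()
    sessions = data["sessions"].to_numpy(float)
    sessions = np.where(is_int, sessions, 0.0)
    if np.isnan(sessions).any():
        raise ValueError("intervention-arm session counts must be observed")
    if ((sessions < 0) | (sessions > 12)).any():
        raise ValueError("sessions must lie in [0, 12]")
    borrowed = data["borrowed_device"].to_numpy(bool) & is_int
    returned = data["returned_device"].to_numpy(bool) & is_int
    if (returned & ~borrowed).any():
        raise ValueError("a device cannot be returned if it was never borrowed")

    session_cost = np.where(is_int, sessions * params.session_rate, 0.0)
    software = np.where(is_int, params.software_cost, 0.0)
    laptop_frac = np.where(returned, params.depreciation_fraction, 1.0)
    device = np.where(
        borrowed,
        laptop_frac * params.laptop_unit_cost
        + params.mifi_monthly * params.mifi_months,
        0.0,
    )
    ledger = pd.DataFrame(
        {
            "id": data["id"].to_numpy(),
            "session_cost": session_cost,
            "software_cost": software,
            "device_cost": device,
        }
    )
    ledger["total"] = (
        ledger["session_cost"] + ledger["software_cost"] + ledger["device_cost"]
    )
    return ledger


def arm_cost_summary(
    data: pd.DataFrame, ledger: pd.DataFrame, ci_level: float = 0.95
) -> dict[str, float]:
    """Intervention-arm mean total cost with a t-based confidence interval."""
    from scipy import stats

    totals = ledger.loc[
        (data["arm"] == "intervention").to_numpy(), "total"
    ].to_numpy()
    if len(totals) == 0:
        raise ValueError("no intervention-arm participants")
    mean = float(totals.mean())
    half = 0.0
    if len(totals) > 1 and totals.std(ddof=1) > 0:
        half = float(
            stats.t.ppf(1 - (1 - ci_level) / 2, len(totals) - 1)
            * stats.sem(totals)
        )
    return {"mean": mean, "lo": mean - half, "hi": mean + half, "n": len(totals)}
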