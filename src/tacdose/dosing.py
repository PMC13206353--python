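"""Dose recommendation: invert the trough forecast onto the 0.5 mg grid.

For each candidate maintenance dose the patient's realized dose history
is extended with q12h administrations of the candidate over the forecast
horizon, the trough at the next TDM time is forecast, and the candidate
is admissible when that forecast lies in the target window (default
8-12 ng/mL, closed on both ends; forecasts within a small relative
tolerance of a boundary — default 0.1%, far below assay precision —
count as attaining it).  The point recommendation is the admissible dose
whose forecast is nearest the window midpoint, ties resolved toward the
lower dose.  Candidates exceeding 1.5x the prior dose are flagged as an
excessive adjustment.

With mechanism-informed parameters the forecast is strictly increasing
in the candidate dose (alpha > 0), so the admissible set is always a
contiguous run of the grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .pk_core import DoseEvent, PKParams, concentration_simplified

__all__ = [
    "DoseRecommendation",
    "default_grid",
    "recommend_from_params",
    "recommend_with_forecaster",
    "recommend_range_check",
]

EXCESSIVE_CHANGE_FACTOR = 1.5
WINDOW_TOL_REL = 1e-3


def default_grid(max_dose: float = 15.0, step: float = 0.5) -> np.ndarray:
    """Candidate per-administration doses: 0.5 mg .. max, 0.5 mg steps."""
    return np.round(np.arange(step, max_dose + step / 2, step), 3)


@dataclass
class DoseRecommendation:
    """Admissible dose set for a target trough window with safety flags."""

    admissible_mg: list[float]
    point_mg: float | None
    forecasts: dict[float, float]
    flags: dict[float, list[str]]
    target_window: tuple[float, float]
    prior_dose_mg: float | None = None
    nearest_miss_mg: float | None = None  # set when the admissible set is empty

    def is_excessive(self, dose: float) -> bool:
        return "excessive_change" in self.flags.get(dose, [])


def recommend_with_forecaster(
    forecast: Callable[[list[DoseEvent], float], float],
    realized_doses: Sequence[DoseEvent],
    decision_time: float,
    *,
    target_window: tuple[float, float] = (8.0, 12.0),
    horizon_hours: float = 24.0,
    interval_hours: float = 12.0,
    grid: np.ndarray | None = None,
    prior_dose_mg: float | None = None,
    window_tol_rel: float = WINDOW_TOL_REL,
) -> DoseRecommendation:
    """Grid search over candidate q12h doses under any forecaster.

    ``forecast(doses, t)`` returns the predicted trough (ng/mL) at ``t``
    given a full dose history.  Candidate administrations are appended at
    ``decision_time, decision_time + interval, ...`` strictly before the
    forecast time ``decision_time + horizon_hours``.  Deterministic.
    """
    lo, hi = target_window
    if not (0 < lo < hi):
        raise ValueError(f"invalid target window {target_window}")
    if grid is None:
        grid = default_grid()
    realized = [d for d in realized_doses if d.time < decision_time]
    t_forecast = decision_time + horizon_hours
    new_times = np.arange(decision_time, t_forecast - 1e-9, interval_hours)

    forecasts: dict[float, float] = {}
    flags: dict[float, list[str]] = {}
    admissible: list[float] = []
    for d in grid:
        d = float(d)
        doses = realized + [DoseEvent(float(t), d) for t in new_times]
        c = forecast(doses, t_forecast)
        forecasts[d] = c
        f: list[str] = []
        if prior_dose_mg is not None and d > EXCESSIVE_CHANGE_FACTOR * prior_dose_mg:
            f.append("excessive_change")
        flags[d] = f
        if lo * (1 - window_tol_rel) <= c <= hi * (1 + window_tol_rel):
            admissible.append(d)

    mid = 0.5 * (lo + hi)
    point = None
    nearest_miss = None
    if admissible:
        # ties toward the lower dose: stable min over (|gap|, dose)
        point = min(admissible, key=lambda d: (abs(forecasts[d] - mid), d))
    else:
        nearest_miss = min(grid, key=lambda d: (abs(forecasts[float(d)] - mid), d))
        nearest_miss = float(nearest_miss)
    return DoseRecommendation(
        admissible_mg=admissible,
        point_mg=point,
        forecasts=forecasts,
        flags=flags,
        target_window=(lo, hi),
        prior_dose_mg=prior_dose_mg,
        nearest_miss_mg=nearest_miss,
    )


def recommend_from_params(
    params: PKParams,
    realized_doses: Sequence[DoseEvent],
    decision_time: float,
    **kwargs,
) -> DoseRecommendation:
    """Recommendation under the simplified trough equation with frozen
    individual parameters (alpha, ke) — the mechanism-informed pathway.
    The forecast is strictly increasing in the candidate dose, so the
    admissible set is a contiguous grid run (asserted)."""
    rec = recommend_with_forecaster(
        lambda doses, t: concentration_simplified(doses, t, params),
        realized_doses,
        decision_time,
        **kwargs,
    )
    if rec.admissible_mg:
        run = np.asarray(rec.admissible_mg)
        step = np.diff(run)
        assert step.size == 0 or np.allclose(step, step[0]), (
            "admissible set must be a contiguous grid run for a monotone forecast"
        )
    return rec


def recommend_range_check(actual_dose_mg: float, rec: DoseRecommendation) -> str:
    """Classify an administered dose against the recommended range
    (the hull of the admissible set, closed at both bounds)."""
    if not rec.admissible_mg:
        return "no_recommendation"
    lo, hi = min(rec.admissible_mg), max(rec.admissible_mg)
    if actual_dose_mg < lo:
        return "below"
    if actual_dose_mg > hi:
        return "above"
    return "within"
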