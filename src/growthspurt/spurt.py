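"""Pubertal growth-spurt parameters from a height-velocity curve.

Five parameters per individual:

* AOGS — age of onset of the growth spurt: the age before the velocity
  peak at which the velocity curve rises most steeply, i.e. the maximum
  of the acceleration v'(t).
* OGSV — the velocity at AOGS (cm/year).
* APHV / PHV — age and magnitude of peak height velocity.
* end age — the first age after APHV at which velocity falls back to
  OGSV; the span end − AOGS is the growth spurt interval (GSI).

Extrema and roots are located on a dense age grid (0.01 y) and refined
to 1e-4 y (bounded minimisation for extrema, bisection for the root).
Estimates landing on a search-window boundary, and end ages not reached
before the search limit, are flagged; flagged subjects are excluded from
cohort summaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from scipy.optimize import brentq, minimize_scalar

__all__ = [
    "SpurtParameters",
    "extract_cohort",
    "extract_spurt_parameters",
    "find_peak",
    "find_spurt_end",
    "find_takeoff",
]

GRID_STEP = 0.01   # years, scan resolution before refinement
REFINE_TOL = 1e-4  # years

FLAG_PEAK_BOUNDARY = "peak_on_boundary"
FLAG_TAKEOFF_BOUNDARY = "takeoff_on_boundary"
FLAG_END_CENSORED = "end_censored"


@dataclass(frozen=True)
class SpurtParameters:
    """Per-subject growth-spurt parameters; NaN where flagged unavailable."""

    subject_id: str
    aogs: float      # years
    ogsv: float      # cm/year
    aphv: float      # years
    phv: float       # cm/year
    end_age: float   # years
    gsi: float       # years, == end_age - aogs
    flags: tuple[str, ...] = field(default_factory=tuple)

    @property
    def ok(self) -> bool:
        return not self.flags


def _grid_argmax(f: Callable, lo: float, hi: float, step: float = GRID_STEP):
    n = max(int(np.ceil((hi - lo) / step)) + 1, 5)
    grid = np.linspace(lo, hi, n)
    vals = np.asarray(f(grid), dtype=float)
    i = int(np.nanargmax(vals))
    return grid, i, vals


def _refine_max(f: Callable, lo: float, hi: float):
    """Dense grid scan then bounded scalar refinement of the maximum."""
    grid, i, _ = _grid_argmax(f, lo, hi)
    if i == 0 or i == len(grid) - 1:
        # Maximum on the window boundary: no interior bracket.
        t = float(grid[i])
        return t, float(np.asarray(f(t))), True
    a, b = grid[i - 1], grid[i + 1]
    res = minimize_scalar(
        lambda t: -float(np.asarray(f(t))),
        bounds=(a, b),
        method="bounded",
        options={"xatol": REFINE_TOL},
    )
    return float(res.x), float(-res.fun), False


def find_peak(velocity_curve: Callable, search_window: tuple[float, float]):
    """Age and magnitude of peak height velocity on the window.

    Returns ``(aphv, phv, on_boundary)``.
    """
    lo, hi = search_window
    if hi <= lo:
        raise ValueError("empty search window")
    aphv, phv, boundary = _refine_max(velocity_curve, lo, hi)
    return aphv, phv, boundary


def find_takeoff(
    velocity_curve: Callable,
    aphv: float,
    search_window: tuple[float, float],
    acceleration: Callable | None = None,
):
    """Onset of the growth spurt: maximum of v'(t) before the velocity peak.

    ``acceleration`` is the analytic v'(t) when available; otherwise a
    central finite difference of the velocity curve is used.  Returns
    ``(aogs, ogsv, on_boundary)``.
    """
    lo = search_window[0]
    hi = min(search_window[1], aphv)
    if hi <= lo:
        raise ValueError("takeoff window is empty")
    if acceleration is None:
        h = 1e-5
        acceleration = lambda t: (
            np.asarray(velocity_curve(np.asarray(t) + h)) - np.asarray(velocity_curve(np.asarray(t) - h))
        ) / (2 * h)
    aogs, _, boundary = _refine_max(acceleration, lo, hi)
    ogsv = float(np.asarray(velocity_curve(aogs)))
    return aogs, ogsv, boundary


def find_spurt_end(
    velocity_curve: Callable,
    aphv: float,
    ogsv: float,
    search_limit: float,
):
    """Smallest root of v(t) = OGSV after the peak.

    Returns ``(end_age, censored)``; when no crossing occurs before
    ``search_limit`` the end is censored at the limit.
    """
    if search_limit <= aphv:
        raise ValueError("search limit must exceed aphv")
    f = lambda t: float(np.asarray(velocity_curve(t))) - ogsv
    n = max(int(np.ceil((search_limit - aphv) / GRID_STEP)) + 1, 5)
    grid = np.linspace(aphv, search_limit, n)
    vals = np.asarray(velocity_curve(grid), dtype=float) - ogsv
    below = np.nonzero(vals <= 0)[0]
    interior = below[below > 0]
    if interior.size == 0:
        return float(search_limit), True
    j = int(interior[0])
    if vals[j] == 0.0:
        return float(grid[j]), False
    root = brentq(f, grid[j - 1], grid[j], xtol=REFINE_TOL)
    return float(root), False


def extract_from_velocity(
    velocity_curve: Callable,
    search_window: tuple[float, float],
    subject_id: str = "",
    acceleration: Callable | None = None,
    end_search_limit: float | None = None,
) -> SpurtParameters:
    """Compose peak, takeoff and spurt-end searches on one velocity curve."""
    lo, hi = search_window
    limit = end_search_limit if end_search_limit is not None else hi
    flags: list[str] = []

    aphv, phv, peak_boundary = find_peak(velocity_curve, (lo, hi))
    if peak_boundary:
        return SpurtParameters(
            subject_id, np.nan, np.nan, aphv, phv, np.nan, np.nan, (FLAG_PEAK_BOUNDARY,)
        )

    aogs, ogsv, takeoff_boundary = find_takeoff(
        velocity_curve, aphv, (lo, aphv), acceleration=acceleration
    )
    if takeoff_boundary:
        flags.append(FLAG_TAKEOFF_BOUNDARY)
        return SpurtParameters(
            subject_id, np.nan, np.nan, aphv, phv, np.nan, np.nan, tuple(flags)
        )

    end_age, censored = find_spurt_end(velocity_curve, aphv, ogsv, limit)
    if censored:
        flags.append(FLAG_END_CENSORED)
        return SpurtParameters(
            subject_id, aogs, ogsv, aphv, phv, np.nan, np.nan, tuple(flags)
        )

    return SpurtParameters(
        subject_id, aogs, ogsv, aphv, phv, end_age, end_age - aogs, ()
    )


def extract_spurt_parameters(
    fit,
    subject_id: str,
    age_window: tuple[float, float] | None = None,
    end_search_limit: float | None = None,
) -> SpurtParameters:
    """Growth-spurt parameters for one subject of a fitted SITAR model.

    ``age_window`` defaults to the fitted curve's boundary-knot span.
    """
    sid = str(subject_id)
    effects = fit.random_effects_of(sid)
    if age_window is None:
        age_window = fit.curve.basis.boundary_knots
    v = lambda t: fit.predict_velocity(effects, t, allow_extrapolation=True)
    a = lambda t: fit.predict_acceleration(effects, t, allow_extrapolation=True)
    return extract_from_velocity(
        v, age_window, subject_id=sid, acceleration=a, end_search_limit=end_search_limit
    )


def extract_cohort(
    fit,
    age_window: tuple[float, float] | None = None,
    end_search_limit: float | None = None,
) -> pd.DataFrame:
    """One row of spurt parameters per fitted subject.

    Columns: subject_id, aogs, ogsv, aphv, phv, end_age, gsi, flags
    (semicolon-joined, empty when clean).
    """
    rows = []
    for sid in fit.subject_ids:
        p = extract_spurt_parameters(fit, sid, age_window, end_search_limit)
        rows.append(
            {
                "subject_id": p.subject_id,
                "aogs": p.aogs,
                "ogsv": p.ogsv,
                "aphv": p.aphv,
                "phv": p.phv,
                "end_age": p.end_age,
                "gsi": p.gsi,
                "flags": ";".join(p.flags),
            }
        )
    return pd.DataFrame(rows)
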