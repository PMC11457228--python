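"""Population mean-curve templates for the synthetic cohort generator.

Two template families live here:

* :class:`TemplateCurve` — the classic closed-form Preece–Baines model 1
  (PB1) height curve.  PB1 is smooth, monotone and has a single spurt,
  but its takeoff geometry is rigid: with takeoff defined as the maximum
  of the acceleration, PB1's takeoff velocity is always at least ~0.69
  of peak velocity, and its spurt interval is locked near 1.8 times the
  takeoff-to-peak spacing.  Published reference cohorts (takeoff
  velocity near 0.56–0.61 of peak, spurt intervals of ~3.6 years) fall
  well outside that envelope, so PB1 can only be calibrated to a subset
  of spurt-parameter targets (see :func:`calibrate_pb1_template`).

* :class:`DesignedTemplate` — a piecewise-polynomial velocity curve
  (scipy ``PPoly``) constructed so that *all* spurt-parameter targets —
  takeoff age and velocity, peak age and velocity, spurt interval and
  adult height — hold exactly by construction: the acceleration maximum
  is pinned at the target takeoff (zero jerk there), the velocity peak
  at the target APHV/PHV, and velocity returns to the takeoff value
  exactly one spurt interval after takeoff.  This is the family the
  packaged per-sex presets use; :func:`calibrate_template` builds and
  verifies one.

Both families expose analytic ``height``, ``velocity`` and
``acceleration`` plus a natural-spline re-expression (``as_spline``)
used by the cohort generator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import PPoly
from scipy.optimize import least_squares

from .splines import NaturalSplineBasis, NaturalSplineCurve
from .spurt import SpurtParameters, extract_from_velocity

__all__ = [
    "CalibrationTargets",
    "DesignedTemplate",
    "TemplateCurve",
    "calibrate_pb1_template",
    "calibrate_template",
    "extract_template_spurt",
    "preece_baines_height",
]

#: Default age window (years) for template spurt extraction.
TEMPLATE_WINDOW = (6.0, 18.0)


def _sample_as_spline(height_fn, df: int, bounds: tuple[float, float]) -> NaturalSplineCurve:
    """Least-squares natural-spline re-expression of a height function."""
    lo, hi = bounds
    grid = np.linspace(lo, hi, max(12 * df, 200))
    interior = np.linspace(lo, hi, df + 1)[1:-1]
    basis = NaturalSplineBasis(interior_knots=interior, boundary_knots=(lo, hi))
    design = np.column_stack([np.ones(grid.size), basis.design(grid)])
    coef, *_ = np.linalg.lstsq(design, height_fn(grid), rcond=None)
    return basis.curve(coef[1:], intercept=coef[0])


# ---------------------------------------------------------------------
# Preece–Baines model 1
# ---------------------------------------------------------------------

@dataclass(frozen=True)
class TemplateCurve:
    """PB1 parameters: heights in cm, rates in 1/years, theta in years.

    h(t) = h1 - 2 (h1 - h_theta) / (exp(s0 (t - theta)) + exp(s1 (t - theta)))
    """

    h1: float
    h_theta: float
    s0: float
    s1: float
    theta: float

    def __post_init__(self):
        if not (self.s1 > self.s0 > 0):
            raise ValueError("requires s1 > s0 > 0")
        if not self.h1 > self.h_theta:
            raise ValueError("requires h1 > h_theta")
        if not (8.0 < self.theta < 16.0):
            raise ValueError("theta must lie in (8, 16) years")

    def height(self, t):
        t = np.asarray(t, dtype=float)
        tau = t - self.theta
        d = np.exp(self.s0 * tau) + np.exp(self.s1 * tau)
        return self.h1 - 2.0 * (self.h1 - self.h_theta) / d

    def velocity(self, t):
        t = np.asarray(t, dtype=float)
        tau = t - self.theta
        e0, e1 = np.exp(self.s0 * tau), np.exp(self.s1 * tau)
        d = e0 + e1
        d1 = self.s0 * e0 + self.s1 * e1
        return 2.0 * (self.h1 - self.h_theta) * d1 / d**2

    def acceleration(self, t):
        t = np.asarray(t, dtype=float)
        tau = t - self.theta
        e0, e1 = np.exp(self.s0 * tau), np.exp(self.s1 * tau)
        d = e0 + e1
        d1 = self.s0 * e0 + self.s1 * e1
        d2 = self.s0**2 * e0 + self.s1**2 * e1
        return 2.0 * (self.h1 - self.h_theta) * (d2 * d - 2.0 * d1**2) / d**3

    __call__ = height

    def as_spline(self, df: int = 30, bounds: tuple[float, float] = (4.0, 22.0)) -> NaturalSplineCurve:
        return _sample_as_spline(self.height, df, bounds)


def preece_baines_height(template: TemplateCurve, t):
    """PB1 height (cm) at decimal age(s) ``t``."""
    return template.height(t)


# ---------------------------------------------------------------------
# Designed piecewise-polynomial template
# ---------------------------------------------------------------------

@dataclass(frozen=True)
class CalibrationTargets:
    """Spurt-parameter targets a template must reproduce.

    Units: years (aogs, aphv, gsi), cm/year (ogsv, phv), cm (adult_height).
    ``ogsv``/``gsi`` may be None for PB1 calibration (left free); the
    designed template requires both.
    """

    aogs: float
    aphv: float
    phv: float
    adult_height: float
    ogsv: float | None = None
    gsi: float | None = None

    def __post_init__(self):
        if not self.aogs < self.aphv:
            raise ValueError("targets must satisfy aogs < aphv")
        if self.gsi is not None and self.aogs + self.gsi <= self.aphv:
            raise ValueError("spurt must end after the peak (aogs + gsi > aphv)")
        if self.ogsv is not None and self.ogsv >= self.phv:
            raise ValueError("requires ogsv < phv")


@dataclass(frozen=True)
class DesignedTemplate:
    """Mean height curve with exactly prescribed spurt parameters.

    The velocity curve is assembled from five polynomial segments over
    [t_start, t_flat] (childhood decline, spurt onset, rise to peak,
    post-peak descent, tail to zero), C1 everywhere and C2 at the
    takeoff and the peak.  Height is its antiderivative anchored so the
    plateau equals ``targets.adult_height``.

    Free shape constants (package choices, not target-derived): the age
    and depth of the pre-spurt velocity nadir, the childhood velocity at
    ``t_start`` and the takeoff acceleration margin.
    """

    targets: CalibrationTargets
    t_start: float = 4.0
    nadir_lead: float = 1.1      # years before takeoff
    nadir_drop: float = 0.25     # cm/y below takeoff velocity
    child_excess: float = 1.6    # cm/y above takeoff velocity at t_start
    accel_margin: float = 1.25   # takeoff acceleration over the flat-top minimum
    _v: PPoly = field(repr=False, default=None, compare=False)
    _h: PPoly = field(repr=False, default=None, compare=False)

    def __post_init__(self):
        tg = self.targets
        if tg.ogsv is None or tg.gsi is None:
            raise ValueError("designed template requires ogsv and gsi targets")
        v = self._build_velocity()
        object.__setattr__(self, "_v", v)
        h = v.antiderivative()
        t_flat = v.x[-1]
        h.c[-1, :] += tg.adult_height - h(t_flat)
        object.__setattr__(self, "_h", h)

    def _build_velocity(self) -> PPoly:
        tg = self.targets
        aogs, ogsv, aphv, phv, gsi = tg.aogs, tg.ogsv, tg.aphv, tg.phv, tg.gsi
        t_n = aogs - self.nadir_lead
        v_n = ogsv - self.nadir_drop
        v0 = ogsv + self.child_excess
        if t_n <= self.t_start + 0.5:
            raise ValueError("takeoff too close to template start")

        breaks = [self.t_start, t_n, aogs, aphv, aogs + gsi]
        segs: list[np.ndarray] = []  # highest-degree-first coefficients per piece

        # 1) childhood decline: cubic Hermite (v0, 0) -> (v_n, 0)
        L = t_n - self.t_start
        segs.append(np.array([
            2 * (v0 - v_n) / L**3, -3 * (v0 - v_n) / L**2, 0.0, v0,
        ]))

        # 3) rise to peak first (its takeoff slope feeds segment 2):
        # quartic p(tau) = ogsv + a tau + c3 tau^3 + c4 tau^4 with
        # p(L3)=phv, p'(L3)=0; acceleration max at tau=0 requires
        # a >= 4*(phv-ogsv)/(3*L3) (then c3 <= 0).
        L3 = aphv - aogs
        delta = phv - ogsv
        a_max = self.accel_margin * 4.0 * delta / (3.0 * L3)
        c3 = (4 * delta - 3 * a_max * L3) / L3**3
        c4 = (2 * a_max * L3 - 3 * delta) / L3**4
        seg3 = np.array([c4, c3, 0.0, a_max, ogsv])

        # 2) onset: quartic (v_n, slope 0) -> (ogsv, slope a_max, curvature 0)
        L2 = aogs - t_n
        A = np.array([
            [L2**2, L2**3, L2**4],
            [2 * L2, 3 * L2**2, 4 * L2**3],
            [2.0, 6 * L2, 12 * L2**2],
        ])
        b2, b3, b4 = np.linalg.solve(A, [ogsv - v_n, a_max, 0.0])
        segs.append(np.array([b4, b3, b2, 0.0, v_n]))
        segs.append(seg3)

        # 4) post-peak descent: cubic (phv, 0, curvature matched) -> v = ogsv
        # exactly at aogs + gsi.
        kappa = 6 * c3 * L3 + 12 * c4 * L3**2  # p''(L3) < 0
        L4 = aogs + gsi - aphv
        d3 = (ogsv - phv - 0.5 * kappa * L4**2) / L4**3
        seg4 = np.array([d3, 0.5 * kappa, 0.0, phv])
        segs.append(seg4)

        # 5) tail: cubic Hermite from (ogsv, s_e) to (0, 0)
        s_e = kappa * L4 + 3 * d3 * L4**2
        if s_e >= 0:
            raise ValueError("post-peak descent must reach the takeoff velocity "
                             "with negative slope; adjust targets")
        tail = float(np.clip(2.0 * ogsv / -s_e, 1.5, 4.0))
        L5 = tail
        M = np.array([
            [L5**2, L5**3],
            [2 * L5, 3 * L5**2],
        ])
        e2, e3 = np.linalg.solve(M, [-ogsv - s_e * L5, -s_e])
        segs.append(np.array([e3, e2, s_e, ogsv]))
        breaks.append(breaks[-1] + tail)

        # 6) flat adult plateau out to the domain end
        segs.append(np.array([0.0]))
        breaks.append(22.0 if breaks[-1] < 21.0 else breaks[-1] + 1.0)

        deg = max(len(c) for c in segs)
        C = np.zeros((deg, len(segs)))
        for j, c in enumerate(segs):
            C[deg - len(c):, j] = c
        v = PPoly(C, np.asarray(breaks), extrapolate=True)

        grid = np.linspace(self.t_start, breaks[-1], 2000)
        if np.any(v(grid) < -1e-9):
            raise ValueError("designed velocity went negative; adjust shape constants")
        acc = v.derivative()(np.linspace(self.t_start + 0.3, aphv, 1500))
        if np.nanmax(acc) > v.derivative()(aogs) + 1e-6:
            raise ValueError("acceleration maximum not at the takeoff; adjust shape constants")
        return v

    # -- evaluation ---------------------------------------------------
    @property
    def domain(self) -> tuple[float, float]:
        return float(self._v.x[0]), float(self._v.x[-1])

    def height(self, t):
        return self._h(np.asarray(t, dtype=float))

    def velocity(self, t):
        return self._v(np.asarray(t, dtype=float))

    def acceleration(self, t):
        return self._v.derivative()(np.asarray(t, dtype=float))

    __call__ = height

    def as_spline(self, df: int = 30, bounds: tuple[float, float] = (4.0, 22.0)) -> NaturalSplineCurve:
        return _sample_as_spline(self.height, df, bounds)


# ---------------------------------------------------------------------
# Spurt extraction and calibration
# ---------------------------------------------------------------------

def extract_template_spurt(template, window: tuple[float, float] = TEMPLATE_WINDOW) -> SpurtParameters:
    """Spurt parameters of a noiseless template velocity curve."""
    return extract_from_velocity(
        template.velocity,
        window,
        subject_id="template",
        acceleration=template.acceleration,
    )


def calibrate_template(targets: CalibrationTargets, tol_age: float = 0.02,
                       tol_velocity: float = 0.05, **shape) -> DesignedTemplate:
    """Build a designed template for ``targets`` and verify it by extraction.

    The construction satisfies the targets exactly; the verification
    step re-extracts them through the same peak/takeoff/root searches
    applied to fitted subjects and checks agreement within ``tol_age``
    (AOGS, APHV) and ``tol_velocity`` (OGSV, PHV), guarding against
    shape-constant combinations that displace the acceleration maximum.
    """
    tpl = DesignedTemplate(targets=targets, **shape)
    sp = extract_template_spurt(tpl)
    errs = {
        "aogs": abs(sp.aogs - targets.aogs),
        "aphv": abs(sp.aphv - targets.aphv),
        "ogsv": abs(sp.ogsv - targets.ogsv),
        "phv": abs(sp.phv - targets.phv),
        "gsi": abs(sp.gsi - targets.gsi),
    }
    bad = {k: v for k, v in errs.items()
           if v > (tol_age if k in ("aogs", "aphv", "gsi") else tol_velocity)}
    if not sp.ok or bad:
        raise RuntimeError(f"template verification failed: flags={sp.flags} residuals={bad}")
    return tpl


def calibrate_pb1_template(
    targets: CalibrationTargets,
    x0: TemplateCurve | None = None,
    tol_age: float = 0.02,
    tol_velocity: float = 0.05,
) -> TemplateCurve:
    """Least-squares PB1 calibration to (aogs, aphv, phv, adult height).

    OGSV and GSI targets, when given, enter the objective but are *not*
    enforced: PB1's takeoff geometry cannot reach the low takeoff-to-peak
    velocity ratios of spline-derived reference curves.  Raises when the
    feasible subset (AOGS, APHV within ``tol_age``; PHV within
    ``tol_velocity``) is missed.
    """
    if x0 is None:
        x0 = TemplateCurve(
            h1=targets.adult_height,
            h_theta=targets.adult_height - 12.0,
            s0=0.11,
            s1=1.1,
            theta=min(targets.aphv + 0.9, 15.8),
        )

    def unpack(p) -> TemplateCurve:
        return TemplateCurve(h1=p[0], h_theta=p[0] - np.exp(p[1]), s0=np.exp(p[2]),
                             s1=np.exp(p[2]) + np.exp(p[3]), theta=p[4])

    p0 = np.array([x0.h1, np.log(x0.h1 - x0.h_theta), np.log(x0.s0),
                   np.log(x0.s1 - x0.s0), x0.theta])

    def residuals(p):
        try:
            sp = extract_template_spurt(unpack(p))
        except (ValueError, FloatingPointError):
            return np.full(6, 1e3)
        if not sp.ok:
            return np.full(6, 1e3)
        return np.array([
            (sp.aogs - targets.aogs) / 0.01,
            (sp.aphv - targets.aphv) / 0.01,
            (sp.phv - targets.phv) / 0.02,
            (unpack(p).height(22.0) - targets.adult_height) / 1.0,
            0.0 if targets.ogsv is None else (sp.ogsv - targets.ogsv) / 1.0,
            0.0 if targets.gsi is None else (sp.gsi - targets.gsi) / 1.0,
        ])

    sol = least_squares(
        residuals, p0,
        bounds=([140.0, np.log(4.0), np.log(0.02), np.log(0.05), 8.5],
                [200.0, np.log(40.0), np.log(0.6), np.log(4.0), 15.9]),
        xtol=1e-12, ftol=1e-12, gtol=1e-12,
    )
    tpl = unpack(sol.x)
    sp = extract_template_spurt(tpl)
    errs = {"aogs": abs(sp.aogs - targets.aogs), "aphv": abs(sp.aphv - targets.aphv),
            "phv": abs(sp.phv - targets.phv)}
    bad = {k: v for k, v in errs.items()
           if v > (tol_age if k in ("aogs", "aphv") else tol_velocity)}
    if bad:
        raise RuntimeError(f"PB1 calibration failed, residuals beyond tolerance: {bad}")
    return tpl
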