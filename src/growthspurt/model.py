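"""SITAR shape-invariant growth model: fitting and prediction.

Model.  Height of subject *i* at age *t*:

    h_it = g(x_it) + alpha_i + e_it,
    x_it = x0 + (t - x0 - b0 - beta_i) * exp(c0 + gamma_i),

where g is a natural cubic spline (intercept included), ``x0`` a fixed
age offset (the mean observation age) about which the age scale is
stretched, (b0, c0) fixed tempo/velocity offsets that absorb random-
effect means, and (alpha_i, beta_i, gamma_i) zero-mean trivariate normal
random effects: size (cm, vertical shift), tempo (years, later beta =
later spurt) and velocity (log age-scale factor; positive gamma =
compressed age scale = steeper, earlier-resolving spurt).

Estimation.  Approximate maximum likelihood by alternating optimisation:

1. given random effects, the spline coefficients solve a linear least
   squares problem on transformed ages;
2. given the mean curve, each subject's effects maximise its penalised
   (shrunken) Gaussian log-likelihood by damped Gauss–Newton steps,
   accepted only when the objective improves;
3. exact re-centering: random-effect means move into (intercept, b0, c0)
   leaving every prediction unchanged;
4. variance components update by a Laplace EM step (posterior modes plus
   posterior covariances), which keeps the random-effect covariance from
   collapsing toward the shrunken sample covariance.

The recorded log-likelihood is the Laplace approximation to the marginal
likelihood; convergence is declared when its relative change drops below
``tol``.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import LongitudinalDataset
from .splines import NaturalSplineBasis, NaturalSplineCurve, build_natural_spline_basis

__all__ = [
    "FitOptions",
    "SitarFit",
    "fit_sitar",
    "load_fit",
    "mean_absolute_error",
    "save_fit",
    "select_df",
]

_LOG2PI = float(np.log(2.0 * np.pi))


@dataclass(frozen=True)
class FitOptions:
    """Tunable fitting controls.

    tol — relative Laplace log-likelihood change declaring convergence.
    max_iter — outer alternating iterations.
    guard_band — years beyond the boundary knots within which prediction
    is allowed without explicitly enabling extrapolation.
    min_measurements — subjects with fewer rows are dropped with a warning.
    """

    tol: float = 1e-6
    max_iter: int = 200
    guard_band: float = 0.25
    min_measurements: int = 3
    min_sigma: float = 1e-4  # cm, residual-SD floor for noiseless data


@dataclass
class SitarFit:
    """A fitted SITAR model."""

    curve: NaturalSplineCurve          # population mean curve (intercept included)
    xoffset: float                     # x0, years
    b0: float                          # fixed tempo offset, years
    c0: float                          # fixed velocity offset, log scale
    random_effects: pd.DataFrame       # index subject_id; columns alpha, beta, gamma
    random_effect_covariance: np.ndarray  # 3x3
    residual_sd: float                 # cm
    loglik_trace: list[float]
    converged: bool
    n_iter: int
    df: int
    dropped_subjects: list[str] = field(default_factory=list)
    warnings_: list[str] = field(default_factory=list)

    # -- accessors ----------------------------------------------------
    @property
    def subject_ids(self) -> list[str]:
        return list(self.random_effects.index)

    @property
    def loglik(self) -> float:
        return self.loglik_trace[-1]

    def random_effects_of(self, subject_id: str) -> tuple[float, float, float]:
        try:
            row = self.random_effects.loc[str(subject_id)]
        except KeyError:
            raise KeyError(f"subject {subject_id!r} not present in fit") from None
        return float(row["alpha"]), float(row["beta"]), float(row["gamma"])

    # -- prediction ---------------------------------------------------
    def _transform(self, effects, ages) -> np.ndarray:
        _, beta, gamma = effects
        t = np.asarray(ages, dtype=float)
        return self.xoffset + (t - self.xoffset - self.b0 - beta) * np.exp(self.c0 + gamma)

    def _check_support(self, ages, allow_extrapolation: bool, guard: float):
        lo, hi = self.curve.basis.boundary_knots
        t = np.asarray(ages, dtype=float)
        if not allow_extrapolation and (np.any(t < lo - guard) or np.any(t > hi + guard)):
            raise ValueError(
                f"ages outside [{lo - guard:.2f}, {hi + guard:.2f}]; "
                "pass allow_extrapolation=True to evaluate the linear tails"
            )

    def predict_height(self, effects, ages, allow_extrapolation: bool = False,
                       guard_band: float = 0.25):
        """h(t) = alpha + g(x(t)) for a (alpha, beta, gamma) triple."""
        self._check_support(ages, allow_extrapolation, guard_band)
        alpha = effects[0]
        return alpha + self.curve.value(self._transform(effects, ages))

    def predict_velocity(self, effects, ages, allow_extrapolation: bool = False,
                         guard_band: float = 0.25):
        """Analytic dh/dt = exp(c0 + gamma) * g'(x(t)), cm/year."""
        self._check_support(ages, allow_extrapolation, guard_band)
        _, _, gamma = effects
        x = self._transform(effects, ages)
        return np.exp(self.c0 + gamma) * self.curve.slope(x)

    def predict_acceleration(self, effects, ages, allow_extrapolation: bool = False,
                             guard_band: float = 0.25):
        """Analytic d2h/dt2 = exp(2 (c0 + gamma)) * g''(x(t)), cm/year^2."""
        self._check_support(ages, allow_extrapolation, guard_band)
        _, _, gamma = effects
        x = self._transform(effects, ages)
        return np.exp(2.0 * (self.c0 + gamma)) * self.curve.curvature(x)

    def predict_subject(self, subject_id: str, ages, **kw):
        return self.predict_height(self.random_effects_of(subject_id), ages, **kw)

    def mean_height(self, ages, **kw):
        return self.predict_height((0.0, 0.0, 0.0), ages, **kw)

    def mean_velocity(self, ages, **kw):
        return self.predict_velocity((0.0, 0.0, 0.0), ages, **kw)


def predict_height(fit: SitarFit, effects, ages, **kw):
    """Module-level alias of :meth:`SitarFit.predict_height`."""
    return fit.predict_height(effects, ages, **kw)


def predict_velocity(fit: SitarFit, effects, ages, **kw):
    """Module-level alias of :meth:`SitarFit.predict_velocity`."""
    return fit.predict_velocity(effects, ages, **kw)


# ---------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------

class _Subject:
    __slots__ = ("sid", "t", "y", "u")

    def __init__(self, sid, t, y):
        self.sid = sid
        self.t = t
        self.y = y
        self.u = np.zeros(3)


def _subject_objective(curve, xoff, b0, c0, s, u, sig2, omega_inv):
    x = xoff + (s.t - xoff - b0 - u[1]) * np.exp(c0 + u[2])
    r = s.y - u[0] - curve.value(x)
    return 0.5 * (r @ r) / sig2 + 0.5 * (u @ omega_inv @ u), r, x


def _subject_update(curve, xoff, b0, c0, s, sig2, omega_inv, n_steps=8):
    """Damped Gauss-Newton maximisation of one subject's penalised likelihood."""
    u = s.u.copy()
    f, r, x = _subject_objective(curve, xoff, b0, c0, s, u, sig2, omega_inv)
    lam = 1e-3
    ec = np.exp(c0 + u[2])
    step = np.zeros(3)
    for _ in range(n_steps):
        g1 = curve.slope(x)
        # residual Jacobian d r / d u
        G = np.column_stack([-np.ones_like(x), g1 * ec, -g1 * (x - xoff)])
        grad = (G.T @ r) / sig2 + omega_inv @ u
        H = (G.T @ G) / sig2 + omega_inv
        accepted = False
        for _ in range(6):
            try:
                step = np.linalg.solve(H + lam * np.diag(np.diag(H)), -grad)
            except np.linalg.LinAlgError:
                lam *= 10.0
                continue
            u_new = u + step
            f_new, r_new, x_new = _subject_objective(curve, xoff, b0, c0, s, u_new, sig2, omega_inv)
            if f_new < f:
                u, f, r, x = u_new, f_new, r_new, x_new
                ec = np.exp(c0 + u[2])
                lam = max(lam / 3.0, 1e-6)
                accepted = True
                break
            lam *= 10.0
        if not accepted or np.abs(step).max() < 1e-10:
            break
    return u, f


def fit_sitar(data: LongitudinalDataset, df: int = 5,
              options: FitOptions | None = None) -> SitarFit:
    """Fit the SITAR model to a (single-stratum) longitudinal dataset.

    Subjects with fewer than ``options.min_measurements`` rows are
    dropped with a warning; fewer than 20 subjects triggers a warning.
    Non-convergence within ``options.max_iter`` returns the fit with
    ``converged=False`` — never a silent success.
    """
    opt = options or FitOptions()
    notes: list[str] = []
    dframe = data.df
    if dframe.empty:
        raise ValueError("empty dataset")

    counts = dframe.groupby("subject_id").size()
    dropped = sorted(counts[counts < opt.min_measurements].index)
    if dropped:
        notes.append(f"dropped {len(dropped)} subject(s) with fewer than "
                     f"{opt.min_measurements} measurements")
        warnings.warn(notes[-1])
        dframe = dframe[~dframe["subject_id"].isin(dropped)]
    if dframe.empty:
        raise ValueError("no subject has enough measurements to fit")

    subjects = [
        _Subject(sid, grp["age"].to_numpy(), grp["height"].to_numpy())
        for sid, grp in dframe.groupby("subject_id", sort=True)
    ]
    n = len(subjects)
    if n < 20:
        notes.append(f"only {n} subjects; estimates of the random-effect "
                     "covariance will be unstable")
        warnings.warn(notes[-1])

    ages = dframe["age"].to_numpy()
    heights = dframe["height"].to_numpy()
    N = len(ages)
    xoff = float(ages.mean())
    basis = build_natural_spline_basis(ages, df)
    b0 = 0.0
    c0 = 0.0

    # init: size offsets from subject means, tempo/velocity at zero
    grand = heights.mean()
    for s in subjects:
        s.u[0] = s.y.mean() - grand

    # priors for the first shrinkage pass; overwritten by the EM update
    omega = np.diag([
        max(np.var([s.u[0] for s in subjects]), 1.0),
        0.5**2,
        0.1**2,
    ])
    sig2 = 1.0
    curve = None
    trace: list[float] = []
    converged = False

    for it in range(opt.max_iter):
        # (1) spline refit on transformed ages
        x_all = np.concatenate([
            xoff + (s.t - xoff - b0 - s.u[1]) * np.exp(c0 + s.u[2]) for s in subjects
        ])
        y_all = np.concatenate([s.y - s.u[0] for s in subjects])
        design = np.column_stack([np.ones(N), basis.design(x_all)])
        coef, *_ = np.linalg.lstsq(design, y_all, rcond=None)
        curve = basis.curve(coef[1:], intercept=coef[0])

        # (2) subject updates
        omega_inv = np.linalg.inv(omega)
        for s in subjects:
            s.u, _ = _subject_update(curve, xoff, b0, c0, s, sig2, omega_inv)

        # (3) exact re-centering: means move into fixed effects
        U = np.array([s.u for s in subjects])
        mean_u = U.mean(axis=0)
        curve = basis.curve(curve.coef, intercept=curve.intercept + mean_u[0])
        b0 += mean_u[1]
        c0 += mean_u[2]
        for s in subjects:
            s.u = s.u - mean_u
        U -= mean_u

        # (4) Laplace EM variance update + marginal log-likelihood
        rss = 0.0
        trace_corr = 0.0
        sum_outer = np.zeros((3, 3))
        loglik = 0.0
        omega_inv = np.linalg.inv(omega)
        sign, logdet_omega = np.linalg.slogdet(omega)
        for s in subjects:
            x = xoff + (s.t - xoff - b0 - s.u[1]) * np.exp(c0 + s.u[2])
            r = s.y - s.u[0] - curve.value(x)
            g1 = curve.slope(x)
            G = np.column_stack([-np.ones_like(x), g1 * np.exp(c0 + s.u[2]),
                                 -g1 * (x - xoff)])
            P = (G.T @ G) / sig2 + omega_inv  # posterior precision (Laplace)
            V = np.linalg.inv(P)
            rss += r @ r
            trace_corr += np.trace(G.T @ G @ V)
            sum_outer += np.outer(s.u, s.u) + V
            _, logdet_P = np.linalg.slogdet(P)
            loglik += (
                -0.5 * len(r) * (_LOG2PI + np.log(sig2))
                - 0.5 * (r @ r) / sig2
                - 0.5 * (3 * _LOG2PI + logdet_omega)
                - 0.5 * (s.u @ omega_inv @ s.u)
                + 0.5 * (3 * _LOG2PI - logdet_P)
            )
        sig2 = max((rss + trace_corr) / N, opt.min_sigma**2)
        omega_new = sum_outer / n
        if np.linalg.eigvalsh(omega_new).min() < 1e-10:
            omega_new += 1e-8 * np.eye(3)
            notes.append("random-effect covariance near singular; ridge added")
            warnings.warn(notes[-1])
        omega = omega_new

        trace.append(float(loglik))
        if it > 0 and abs(trace[-1] - trace[-2]) < opt.tol * abs(trace[-2]):
            converged = True
            break

    if not converged:
        notes.append(f"not converged after {len(trace)} iterations "
                     f"(last relative change {abs(trace[-1] - trace[-2]) / abs(trace[-2]):.2e})")
        warnings.warn(notes[-1])

    U = np.array([s.u for s in subjects])
    ranef = pd.DataFrame(U, columns=["alpha", "beta", "gamma"],
                         index=pd.Index([s.sid for s in subjects], name="subject_id"))
    return SitarFit(
        curve=curve,
        xoffset=xoff,
        b0=b0,
        c0=c0,
        random_effects=ranef,
        random_effect_covariance=omega,
        residual_sd=float(np.sqrt(sig2)),
        loglik_trace=trace,
        converged=converged,
        n_iter=len(trace),
        df=df,
        dropped_subjects=list(dropped),
        warnings_=notes,
    )


def select_df(data: LongitudinalDataset, candidates=(4, 5, 6, 7),
              options: FitOptions | None = None) -> tuple[int, dict[int, float]]:
    """BIC-based spline-df selection.

    Fits each candidate and scores it by BIC = -2 loglik + k log N with
    k = (df + 1) spline parameters + 2 transform offsets + 6 covariance
    entries + 1 residual variance.  Returns (best df, per-df BIC).
    """
    n_rows = data.n_measurements
    bics: dict[int, float] = {}
    for df in candidates:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = fit_sitar(data, df=df, options=options)
        k = (df + 1) + 2 + 6 + 1
        bics[df] = -2.0 * fit.loglik + k * np.log(n_rows)
    best = min(bics, key=bics.get)
    return best, bics


def mean_absolute_error(fit: SitarFit, data: LongitudinalDataset) -> float:
    """Mean |observed - predicted| (cm) using each subject's random effects."""
    total = 0.0
    count = 0
    for sid, grp in data.df.groupby("subject_id"):
        effects = fit.random_effects_of(sid)  # KeyError if absent from fit
        pred = fit.predict_height(effects, grp["age"].to_numpy(),
                                  allow_extrapolation=True)
        total += np.abs(grp["height"].to_numpy() - pred).sum()
        count += len(grp)
    return total / count


# ---------------------------------------------------------------------
# Serialization (versioned JSON; floats round-trip exactly via repr)
# ---------------------------------------------------------------------

_FORMAT_VERSION = 1


def save_fit(fit: SitarFit, path) -> None:
    doc = {
        "format": "growthspurt-sitar-fit",
        "version": _FORMAT_VERSION,
        "basis": {
            "interior_knots": fit.curve.basis.interior_knots.tolist(),
            "boundary_knots": list(fit.curve.basis.boundary_knots),
        },
        "curve": {"intercept": fit.curve.intercept, "coef": fit.curve.coef.tolist()},
        "xoffset": fit.xoffset,
        "b0": fit.b0,
        "c0": fit.c0,
        "random_effects": {
            sid: fit.random_effects.loc[sid].tolist() for sid in fit.subject_ids
        },
        "random_effect_covariance": fit.random_effect_covariance.tolist(),
        "residual_sd": fit.residual_sd,
        "loglik_trace": fit.loglik_trace,
        "converged": fit.converged,
        "n_iter": fit.n_iter,
        "df": fit.df,
        "dropped_subjects": fit.dropped_subjects,
        "warnings": fit.warnings_,
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh, indent=1)


def load_fit(path) -> SitarFit:
    with open(path, encoding="utf-8") as fh:
        doc = json.load(fh)
    if doc.get("format") != "growthspurt-sitar-fit":
        raise ValueError(f"{path} is not a SITAR fit document")
    if doc["version"] > _FORMAT_VERSION:
        raise ValueError(f"fit format version {doc['version']} is newer than supported")
    basis = NaturalSplineBasis(
        interior_knots=np.asarray(doc["basis"]["interior_knots"]),
        boundary_knots=tuple(doc["basis"]["boundary_knots"]),
    )
    curve = basis.curve(np.asarray(doc["curve"]["coef"]), intercept=doc["curve"]["intercept"])
    ranef = pd.DataFrame.from_dict(
        doc["random_effects"], orient="index", columns=["alpha", "beta", "gamma"]
    )
    ranef.index.name = "subject_id"
    return SitarFit(
        curve=curve,
        xoffset=doc["xoffset"],
        b0=doc["b0"],
        c0=doc["c0"],
        random_effects=ranef,
        random_effect_covariance=np.asarray(doc["random_effect_covariance"]),
        residual_sd=doc["residual_sd"],
        loglik_trace=list(doc["loglik_trace"]),
        converged=doc["converged"],
        n_iter=doc["n_iter"],
        df=doc["df"],
        dropped_subjects=list(doc.get("dropped_subjects", [])),
        warnings_=list(doc.get("warnings", [])),
    )
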