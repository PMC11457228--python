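"""Synthetic mixed-longitudinal cohort generation.

Each subject's height trajectory follows the SITAR generative model
around a calibrated template mean curve g_T:

    h = alpha + g_T(x0 + (t - x0 - beta) exp(gamma)) + e,
    (alpha, beta, gamma) ~ N(0, Omega),   e ~ N(0, noise_sd^2),

observed at a nominal biannual visit schedule with per-visit jitter and
independent missingness.  The packaged per-sex presets ("boys_gp2024",
"girls_gp2024") are calibrated so the template's extracted spurt
parameters equal published Korean reference means, the tempo SD matches
the reference APHV SD, the velocity (log-scale) SD matches the reference
PHV coefficient of variation, correlations follow the reference
random-effect correlation matrix, and the noise SD reproduces the
reference model fit MAE through the half-normal mean identity
E|e| = noise_sd * sqrt(2/pi).

Randomness: one generator per subject, seeded as (cohort seed, subject
index), so subject k's data are invariant to the cohort size.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

from .data import LongitudinalDataset
from .splines import NaturalSplineCurve
from .template import CalibrationTargets, DesignedTemplate, calibrate_template

__all__ = [
    "CohortPreset",
    "available_presets",
    "load_preset",
    "simulate_cohort",
    "true_spurt_parameters",
]


@dataclass(frozen=True)
class CohortPreset:
    """Generative population parameters for one sex stratum."""

    name: str
    sex: str                                  # 'male' | 'female'
    template: DesignedTemplate
    random_effect_sds: tuple[float, float, float]   # (cm, years, log-scale)
    random_effect_correlations: np.ndarray          # 3x3, unit diagonal
    noise_sd: float                           # cm
    schedule: np.ndarray                      # nominal visit ages, years
    visit_jitter: float = 0.1                 # years, uniform +/-
    missingness_prob: float = 0.30            # per visit
    seed: int | None = None                   # default stream; overridable per call
    template_spline_df: int = 30

    def __post_init__(self):
        if self.sex not in ("male", "female"):
            raise ValueError("sex must be 'male' or 'female'")
        corr = np.asarray(self.random_effect_correlations, dtype=float)
        if corr.shape != (3, 3) or not np.allclose(corr, corr.T):
            raise ValueError("correlation matrix must be symmetric 3x3")
        if not np.allclose(np.diag(corr), 1.0):
            raise ValueError("correlation matrix must have unit diagonal")
        if np.linalg.eigvalsh(corr).min() < -1e-10:
            raise ValueError("correlation matrix must be positive semidefinite")
        if not (0.0 <= self.missingness_prob < 1.0):
            raise ValueError("missingness_prob must lie in [0, 1)")
        if any(sd < 0 for sd in self.random_effect_sds) or self.noise_sd < 0:
            raise ValueError("standard deviations must be nonnegative")
        object.__setattr__(self, "random_effect_correlations", corr)
        object.__setattr__(self, "schedule", np.asarray(self.schedule, dtype=float))

    @property
    def covariance(self) -> np.ndarray:
        s = np.asarray(self.random_effect_sds)
        return self.random_effect_correlations * np.outer(s, s)

    @property
    def xoffset(self) -> float:
        return float(self.schedule.mean())

    def with_overrides(self, **kw) -> "CohortPreset":
        return replace(self, **kw)


_PRESET_CACHE: dict[str, CohortPreset] = {}
_SPLINE_CACHE: dict[int, NaturalSplineCurve] = {}


def available_presets() -> list[str]:
    root = importlib.resources.files("growthspurt") / "presets"
    return sorted(p.name[:-5] for p in root.iterdir() if p.name.endswith(".yaml"))


def load_preset(name: str) -> CohortPreset:
    """Load a packaged preset (or a path to a preset YAML file)."""
    key = str(name)
    if key in _PRESET_CACHE:
        return _PRESET_CACHE[key]
    root = importlib.resources.files("growthspurt") / "presets"
    candidate = root / f"{name}.yaml"
    if candidate.is_file():
        text = candidate.read_text(encoding="utf-8")
    else:
        with open(name, encoding="utf-8") as fh:
            text = fh.read()
    doc = yaml.safe_load(text)
    tpl = calibrate_template(CalibrationTargets(**doc["template_targets"]))
    sched = doc["schedule"]
    schedule = np.arange(sched["start"], sched["stop"] + 1e-9, sched["step"])
    preset = CohortPreset(
        name=doc["name"],
        sex=doc["sex"],
        template=tpl,
        random_effect_sds=tuple(doc["random_effect_sds"]),
        random_effect_correlations=np.asarray(doc["random_effect_correlations"]),
        noise_sd=doc["noise_sd"],
        schedule=schedule,
        visit_jitter=sched.get("jitter", 0.1),
        missingness_prob=doc["missingness_prob"],
    )
    _PRESET_CACHE[key] = preset
    return preset


def _template_spline(preset: CohortPreset) -> NaturalSplineCurve:
    key = id(preset.template), preset.template_spline_df
    if key not in _SPLINE_CACHE:
        _SPLINE_CACHE[key] = preset.template.as_spline(df=preset.template_spline_df)
    return _SPLINE_CACHE[key]


def _draw_effects(preset: CohortPreset, rng: np.random.Generator) -> np.ndarray:
    cov = preset.covariance
    sds = np.asarray(preset.random_effect_sds)
    active = sds > 0
    z = rng.standard_normal(3)
    if not active.any():
        return np.zeros(3)
    # Cholesky on the active block only, so zero-SD components stay exactly zero
    u = np.zeros(3)
    sub = cov[np.ix_(active, active)]
    L = np.linalg.cholesky(sub + 1e-12 * np.eye(active.sum()))
    u[active] = L @ z[active]
    return u


def simulate_cohort(preset: CohortPreset, n_subjects: int,
                    seed: int | None = None) -> tuple[LongitudinalDataset, pd.DataFrame]:
    """Generate a cohort; returns (dataset, true random effects per subject).

    The effects frame (index subject_id; columns alpha, beta, gamma) is
    the generating truth, useful for recovery experiments.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    seed = preset.seed if seed is None else seed
    if seed is None:
        raise ValueError("a seed is required (preset.seed or argument)")
    g_t = _template_spline(preset)
    xoff = preset.xoffset
    prefix = "B" if preset.sex == "male" else "G"

    rows = []
    effects = []
    sids = []
    for k in range(n_subjects):
        rng = np.random.default_rng([int(seed), k])
        u = _draw_effects(preset, rng)
        jitter = rng.uniform(-preset.visit_jitter, preset.visit_jitter,
                             size=preset.schedule.size)
        missing = rng.random(preset.schedule.size) < preset.missingness_prob
        noise = rng.normal(0.0, preset.noise_sd, size=preset.schedule.size)
        ages = preset.schedule + jitter
        keep = ~missing
        if not keep.any():
            keep[rng.integers(preset.schedule.size)] = True  # never an empty subject
        sid = f"{prefix}{k:04d}"
        x = xoff + (ages[keep] - xoff - u[1]) * np.exp(u[2])
        h = u[0] + g_t.value(x) + noise[keep]
        for age, height in zip(ages[keep], h):
            rows.append((sid, preset.sex, float(age), float(height)))
        effects.append(u)
        sids.append(sid)

    df = pd.DataFrame(rows, columns=["subject_id", "sex", "age", "height"])
    data = LongitudinalDataset(
        df, provenance=f"simulated preset={preset.name} n={n_subjects} seed={seed}"
    )
    eff = pd.DataFrame(np.array(effects), columns=["alpha", "beta", "gamma"],
                       index=pd.Index(sids, name="subject_id"))
    return data, eff


def true_spurt_parameters(preset: CohortPreset, effects: pd.DataFrame) -> pd.DataFrame:
    """Analytic per-subject spurt parameters implied by template + effects.

    No model fitting: ages transform as t = x0 + (x - x0) e^(-gamma) + beta
    of the template's values, velocities scale by e^(gamma).  Used to
    check the generator against its calibration targets.
    """
    from .template import extract_template_spurt

    sp = extract_template_spurt(preset.template)
    xoff = preset.xoffset
    out = pd.DataFrame(index=effects.index)
    e_neg = np.exp(-effects["gamma"])
    e_pos = np.exp(effects["gamma"])
    out["aogs"] = xoff + (sp.aogs - xoff) * e_neg + effects["beta"]
    out["aphv"] = xoff + (sp.aphv - xoff) * e_neg + effects["beta"]
    out["end_age"] = xoff + (sp.end_age - xoff) * e_neg + effects["beta"]
    out["ogsv"] = sp.ogsv * e_pos
    out["phv"] = sp.phv * e_pos
    out["gsi"] = out["end_age"] - out["aogs"]
    return out
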