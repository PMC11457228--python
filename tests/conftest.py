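import warnings

import numpy as np
import pytest

from growthspurt.data import filter_age_segments
from growthspurt.model import FitOptions, fit_sitar
from growthspurt.simulate import load_preset, simulate_cohort
from growthspurt.spurt import extract_cohort

# Study-scale configuration shared by recovery and acceptance experiments:
# n=150 subjects per sex, five-segment filter, SITAR df=5, seeds 1-3.
STUDY_N = 150
STUDY_DF = 5
STUDY_SEEDS = (1, 2, 3)
SIGN_SEEDS = (1, 2, 3, 4, 5)

_FIT_OPTIONS = FitOptions(max_iter=600)


@pytest.fixture(scope="session")
def boys_preset():
    return load_preset("boys_gp2024")


@pytest.fixture(scope="session")
def girls_preset():
    return load_preset("girls_gp2024")


def _run_study(preset, seed):
    data, true_effects = simulate_cohort(preset, STUDY_N, seed=seed)
    filtered = filter_age_segments(data)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = fit_sitar(filtered, df=STUDY_DF, options=_FIT_OPTIONS)
    params = extract_cohort(fit)
    return {"data": filtered, "true_effects": true_effects, "fit": fit,
            "params": params}


@pytest.fixture(scope="session")
def boys_runs(boys_preset):
    """Study-scale boys pipeline runs keyed by seed (seeds 1..5)."""
    return {seed: _run_study(boys_preset, seed) for seed in SIGN_SEEDS}


@pytest.fixture(scope="session")
def girls_runs(girls_preset):
    """Study-scale girls pipeline runs keyed by seed (seeds 1..3)."""
    return {seed: _run_study(girls_preset, seed) for seed in STUDY_SEEDS}


@pytest.fixture(scope="session")
def small_cohort(boys_preset):
    """A quick 45-subject filtered cohort for unit-scale fitting tests."""
    data, effects = simulate_cohort(boys_preset, 45, seed=11)
    return filter_age_segments(data), effects


@pytest.fixture(scope="session")
def small_fit(small_cohort):
    data, _ = small_cohort
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return fit_sitar(data, df=STUDY_DF, options=_FIT_OPTIONS)


@pytest.fixture(scope="session")
def synthetic_fit(boys_preset):
    """A SITAR fit assembled by hand (no optimisation) around the boys
    template, with three synthetic subjects; used for prediction and
    extraction identities."""
    import pandas as pd

    from growthspurt.model import SitarFit

    curve = boys_preset.template.as_spline(df=12, bounds=(5.0, 20.0))
    ranef = pd.DataFrame(
        [[0.0, 0.0, 0.0], [4.0, -0.5, 0.0], [-2.0, 0.4, 0.12]],
        columns=["alpha", "beta", "gamma"],
        index=pd.Index(["S0", "S1", "S2"], name="subject_id"),
    )
    return SitarFit(
        curve=curve,
        xoffset=11.5,
        b0=0.0,
        c0=0.0,
        random_effects=ranef,
        random_effect_covariance=np.diag([25.0, 0.5, 0.02]),
        residual_sd=0.6,
        loglik_trace=[0.0],
        converged=True,
        n_iter=1,
        df=12,
    )
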