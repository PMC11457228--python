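"""SITAR model: prediction identities, fitting, invariances, serialization."""

import warnings

import numpy as np
import pandas as pd
import pytest

from growthspurt.data import LongitudinalDataset
from growthspurt.model import (
    FitOptions,
    fit_sitar,
    load_fit,
    mean_absolute_error,
    save_fit,
)
from growthspurt.simulate import simulate_cohort

AGES = np.linspace(7.0, 16.0, 40)


class TestPredictionIdentities:
    def test_zero_effects_reproduce_mean_curve(self, synthetic_fit):
        np.testing.assert_allclose(
            synthetic_fit.predict_height((0.0, 0.0, 0.0), AGES),
            synthetic_fit.mean_height(AGES),
            rtol=0, atol=0,
        )

    def test_pure_size_shift(self, synthetic_fit):
        np.testing.assert_allclose(
            synthetic_fit.predict_height((5.0, 0.0, 0.0), AGES),
            synthetic_fit.mean_height(AGES) + 5.0,
            atol=1e-12,
        )

    def test_pure_tempo_shift_moves_curve_one_year_later(self, synthetic_fit):
        np.testing.assert_allclose(
            synthetic_fit.predict_height((0.0, 1.0, 0.0), AGES),
            synthetic_fit.mean_height(AGES - 1.0, allow_extrapolation=True),
            atol=1e-12,
        )

    def test_velocity_matches_finite_differences(self, synthetic_fit):
        t = np.linspace(7.5, 15.5, 100)
        h = 1e-4
        for effects in [(0.0, 0.0, 0.0), (3.0, -0.4, 0.1)]:
            fd = (synthetic_fit.predict_height(effects, t + h)
                  - synthetic_fit.predict_height(effects, t - h)) / (2 * h)
            v = synthetic_fit.predict_velocity(effects, t)
            assert np.abs(fd - v).max() < 1e-5

    def test_velocity_scale_doubles_peak(self, synthetic_fit):
        t = np.linspace(8.0, 16.0, 2000)
        base_peak = synthetic_fit.predict_velocity((0.0, 0.0, 0.0), t).max()
        # gamma = ln 2 compresses the age axis about xoffset and doubles
        # the peak velocity (chain rule)
        t_wide = np.linspace(6.0, 18.0, 4000)
        scaled_peak = synthetic_fit.predict_velocity(
            (0.0, 0.0, np.log(2.0)), t_wide, allow_extrapolation=True
        ).max()
        assert scaled_peak == pytest.approx(2.0 * base_peak, rel=1e-3)

    def test_extrapolation_guard(self, synthetic_fit):
        lo, hi = synthetic_fit.curve.basis.boundary_knots
        with pytest.raises(ValueError, match="extrapolation"):
            synthetic_fit.predict_height((0.0, 0.0, 0.0), np.array([hi + 1.0]))
        # inside the guard band is fine
        synthetic_fit.predict_height((0.0, 0.0, 0.0), np.array([hi + 0.2]))

    def test_unknown_subject_raises(self, synthetic_fit):
        with pytest.raises(KeyError, match="not present"):
            synthetic_fit.random_effects_of("nope")


class TestMeanAbsoluteError:
    def test_exact_recomputation_on_fixture(self, small_fit, small_cohort):
        data, _ = small_cohort
        got = mean_absolute_error(small_fit, data)
        # brute-force per-row recomputation
        total, count = 0.0, 0
        for _, row in data.df.iterrows():
            eff = small_fit.random_effects_of(row["subject_id"])
            pred = small_fit.predict_height(eff, np.array([row["age"]]),
                                            allow_extrapolation=True)[0]
            total += abs(row["height"] - pred)
            count += 1
        assert got == pytest.approx(total / count, abs=1e-12)

    def test_residual_pair_identity(self, synthetic_fit):
        # residuals of +1 and -1 cm -> MAE exactly 1.0
        ages = np.array([9.0, 12.0])
        h = synthetic_fit.predict_subject("S0", ages) + np.array([1.0, -1.0])
        data = LongitudinalDataset(pd.DataFrame({
            "subject_id": ["S0", "S0"], "sex": ["male", "male"],
            "age": ages, "height": h,
        }))
        assert mean_absolute_error(synthetic_fit, data) == pytest.approx(1.0, abs=1e-12)

    def test_subject_absent_from_fit_errors(self, synthetic_fit):
        data = LongitudinalDataset(pd.DataFrame({
            "subject_id": ["zz"], "sex": ["male"], "age": [10.0], "height": [140.0],
        }))
        with pytest.raises(KeyError):
            mean_absolute_error(synthetic_fit, data)


def _noiseless_model_cohort(preset, n, seed, df=5):
    """Cohort generated exactly from the fitter's model class: a natural
    spline on the knots fit_sitar would choose for this visit schedule,
    plus SITAR random effects, no noise and no missingness."""
    from growthspurt.splines import build_natural_spline_basis

    sched = preset.schedule
    ages = np.tile(sched, n)
    basis = build_natural_spline_basis(ages, df=df)
    design = np.column_stack([np.ones(sched.size), basis.design(sched)])
    coef, *_ = np.linalg.lstsq(design, np.asarray(preset.template.height(sched)),
                               rcond=None)
    curve = basis.curve(coef[1:], intercept=coef[0])
    xoff = float(ages.mean())
    rng = np.random.default_rng(seed)
    effects = rng.multivariate_normal(np.zeros(3), preset.covariance, size=n)
    rows = []
    for k, (a, b, c) in enumerate(effects):
        x = xoff + (sched - xoff - b) * np.exp(c)
        h = a + curve.value(x)
        rows += [(f"m{k:03d}", preset.sex, float(t), float(y))
                 for t, y in zip(sched, h)]
    return LongitudinalDataset(pd.DataFrame(
        rows, columns=["subject_id", "sex", "age", "height"]))


class TestFitting:
    def test_noiseless_self_consistency(self, boys_preset):
        """Data generated exactly from the model class (spline mean curve +
        SITAR effects, no noise) must be reproduced to < 0.05 cm MAE."""
        data = _noiseless_model_cohort(boys_preset, 60, seed=3)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = fit_sitar(data, df=5, options=FitOptions(max_iter=300))
        assert mean_absolute_error(fit, data) < 0.05

    def test_random_effect_sd_recovery(self, boys_runs, boys_preset):
        """Across seeds 1-3 the fitted random-effect SDs stay within 15%
        of the generating (size, tempo, velocity) SDs."""
        true_sds = np.asarray(boys_preset.random_effect_sds)
        for seed in (1, 2, 3):
            fitted = boys_runs[seed]["fit"].random_effects.std().to_numpy()
            assert np.all(np.abs(fitted - true_sds) / true_sds < 0.15), (seed, fitted)

    def test_in_sample_mae_near_half_normal_mean(self, boys_runs, boys_preset):
        """Noise SD 0.78 cm implies E|e| ~ 0.62 cm; the in-sample fit MAE
        sits near it (slightly below, since fitting absorbs noise)."""
        expected = boys_preset.noise_sd * np.sqrt(2.0 / np.pi)
        for seed in (1, 2, 3):
            mae = mean_absolute_error(boys_runs[seed]["fit"], boys_runs[seed]["data"])
            assert 0.7 * expected < mae < 1.1 * expected

    def test_loglik_nondecreasing(self, small_fit):
        ll = np.asarray(small_fit.loglik_trace)
        drops = np.diff(ll) / np.abs(ll[:-1])
        assert drops.min() > -1e-6

    def test_random_effects_centered(self, small_fit):
        means = small_fit.random_effects.mean()
        sds = small_fit.random_effects.std()
        assert np.all(np.abs(means) <= 1e-6 * sds + 1e-12)

    def test_covariance_symmetric_psd_and_residual_positive(self, small_fit):
        om = small_fit.random_effect_covariance
        assert np.allclose(om, om.T)
        assert np.linalg.eigvalsh(om).min() > 0
        assert small_fit.residual_sd > 0

    def test_short_subjects_dropped_with_warning(self, boys_preset):
        data, _ = simulate_cohort(boys_preset, 25, seed=5)
        df = data.df
        # truncate one subject to 2 rows
        sid = data.subject_ids[0]
        df = pd.concat([df[df.subject_id != sid], df[df.subject_id == sid].head(2)])
        short = LongitudinalDataset(df)
        with pytest.warns(UserWarning, match="dropped"):
            fit = fit_sitar(short, df=5, options=FitOptions(max_iter=30))
        assert sid in fit.dropped_subjects
        assert sid not in fit.subject_ids

    def test_bic_df_selection_returns_candidate(self, boys_preset):
        from growthspurt.model import select_df
        data, _ = simulate_cohort(boys_preset, 25, seed=19)
        best, bics = select_df(data, candidates=(4, 5),
                               options=FitOptions(max_iter=40))
        assert best in (4, 5)
        assert set(bics) == {4, 5}
        assert all(np.isfinite(v) for v in bics.values())

    def test_nonconvergence_is_flagged_not_silent(self, small_cohort):
        data, _ = small_cohort
        with pytest.warns(UserWarning, match="not converged"):
            fit = fit_sitar(data, df=5, options=FitOptions(max_iter=3))
        assert not fit.converged


EQUIV_OPTS = FitOptions(max_iter=120)


@pytest.fixture(scope="module")
def equivariance_base(small_cohort):
    data, _ = small_cohort
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return data, fit_sitar(data, df=5, options=EQUIV_OPTS)


class TestEquivariance:
    OPTS = EQUIV_OPTS

    def test_height_shift_moves_only_the_intercept(self, equivariance_base):
        """h -> h + c shifts the fitted mean curve by c and leaves the
        random effects unchanged (the optimisation path is identical)."""
        data, fit0 = equivariance_base
        df = data.df
        df["height"] += 5.0
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit1 = fit_sitar(LongitudinalDataset(df), df=5, options=self.OPTS)
        assert fit1.curve.intercept - fit0.curve.intercept == pytest.approx(5.0, abs=1e-6)
        for col in ("alpha", "beta", "gamma"):
            assert np.abs(fit1.random_effects[col] - fit0.random_effects[col]).max() < 1e-6

    def test_time_shift_moves_the_curve_not_the_effects(self, equivariance_base):
        """t -> t + c shifts knots, offset and every subject's timing by c,
        leaving random effects and velocities unchanged."""
        data, fit0 = equivariance_base
        df = data.df
        df["age"] += 1.5
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit1 = fit_sitar(LongitudinalDataset(df), df=5, options=self.OPTS)
        assert fit1.xoffset - fit0.xoffset == pytest.approx(1.5, abs=1e-9)
        for col in ("beta", "gamma"):
            assert np.abs(fit1.random_effects[col] - fit0.random_effects[col]).max() < 1e-6
        t = np.linspace(8.0, 15.0, 60)
        sid = fit0.subject_ids[3]
        np.testing.assert_allclose(
            fit1.predict_height(fit1.random_effects_of(sid), t + 1.5),
            fit0.predict_height(fit0.random_effects_of(sid), t),
            atol=1e-6,
        )


class TestSerialization:
    def test_round_trip_bit_exact(self, small_fit, tmp_path):
        path = tmp_path / "fit.json"
        save_fit(small_fit, path)
        again = load_fit(path)
        assert again.curve.intercept == small_fit.curve.intercept
        np.testing.assert_array_equal(again.curve.coef, small_fit.curve.coef)
        np.testing.assert_array_equal(
            again.curve.basis.interior_knots, small_fit.curve.basis.interior_knots
        )
        pd.testing.assert_frame_equal(again.random_effects, small_fit.random_effects)
        np.testing.assert_array_equal(
            again.random_effect_covariance, small_fit.random_effect_covariance
        )
        assert again.residual_sd == small_fit.residual_sd
        t = np.linspace(7.5, 16.0, 30)
        np.testing.assert_array_equal(
            again.predict_height((1.0, 0.2, 0.05), t),
            small_fit.predict_height((1.0, 0.2, 0.05), t),
        )

    def test_rejects_foreign_documents(self, tmp_path):
        p = tmp_path / "x.json"
        p.write_text('{"format": "something-else"}')
        with pytest.raises(ValueError, match="not a SITAR fit"):
            load_fit(p)
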