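"""Descriptives, correlations and quintile contrasts, with independent
direct-formula oracles for the Pearson and Welch statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from growthspurt.analysis import (
    CENTILE_LEVELS,
    build_report,
    contrast_table,
    descriptive_summary,
    descriptive_table,
    quintile_contrast,
    random_effect_correlations,
)


def pearson_oracle(x, y):
    """Direct-formula Pearson r and two-sided p via the t transform."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    n = len(x)
    xd, yd = x - x.mean(), y - y.mean()
    r = (xd @ yd) / np.sqrt((xd @ xd) * (yd @ yd))
    t = r * np.sqrt((n - 2) / (1 - r**2))
    p = 2 * stats.t.sf(abs(t), n - 2)
    return r, p


def welch_oracle(a, b):
    """Direct-formula Welch t statistic and two-sided p."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
    t = (a.mean() - b.mean()) / np.sqrt(va + vb)
    df = (va + vb) ** 2 / (va**2 / (len(a) - 1) + vb**2 / (len(b) - 1))
    p = 2 * stats.t.sf(abs(t), df)
    return t, p


class TestDescriptives:
    def test_two_value_row(self):
        r = descriptive_table([2.0, 4.0], "x")
        assert r.mean == 3.0
        assert r.sd == pytest.approx(np.sqrt(2.0))

    def test_centile_interpolation_rule(self):
        # linear interpolation between order statistics ("type 7")
        r = descriptive_table(np.arange(1.0, 101.0), "x")
        assert r.centiles[50] == pytest.approx(50.5)
        assert r.centiles[25] == pytest.approx(25.75)

    def test_constant_values_degenerate(self):
        r = descriptive_table([7.7] * 10, "x")
        assert r.sd == 0.0
        assert all(v == 7.7 for v in r.centiles.values())

    def test_too_few_values(self):
        with pytest.raises(ValueError, match="at least 2"):
            descriptive_table([1.0], "x")
        with pytest.raises(ValueError):
            descriptive_table([1.0, np.nan], "x")

    @given(st.lists(st.floats(-1e3, 1e3), min_size=2, max_size=200))
    def test_centiles_monotone(self, values):
        r = descriptive_table(values, "x")
        ordered = [r.centiles[c] for c in CENTILE_LEVELS]
        assert all(b >= a for a, b in zip(ordered, ordered[1:]))

    def test_summary_has_one_row_per_parameter(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame({p: rng.normal(size=40)
                           for p in ("aogs", "aphv", "ogsv", "phv", "gsi")})
        out = descriptive_summary(df)
        assert list(out.index) == ["aogs", "aphv", "ogsv", "phv", "gsi"]
        assert (out["n"] == 40).all()


class TestCorrelations:
    def _frame(self, a, b, g):
        return pd.DataFrame({"alpha": a, "beta": b, "gamma": g})

    def test_perfect_correlation(self):
        x = np.arange(10.0)
        corr, pv = random_effect_correlations(self._frame(x, x, x[::-1]))
        assert corr.loc["alpha", "beta"] == pytest.approx(1.0)
        assert pv.loc["alpha", "beta"] < 1e-12
        assert corr.loc["alpha", "gamma"] == pytest.approx(-1.0)

    def test_hand_computed_three_points(self):
        corr, _ = random_effect_correlations(
            self._frame([1.0, 2.0, 3.0], [1.0, 2.0, 4.0], [0.0, 1.0, 2.0]))
        assert corr.loc["alpha", "beta"] == pytest.approx(0.981980506, abs=1e-8)

    def test_matches_direct_formula_oracle(self):
        rng = np.random.default_rng(5)
        re = self._frame(*rng.normal(size=(3, 60)))
        corr, pv = random_effect_correlations(re)
        for a, b in (("alpha", "beta"), ("alpha", "gamma"), ("beta", "gamma")):
            r_o, p_o = pearson_oracle(re[a], re[b])
            assert corr.loc[a, b] == pytest.approx(r_o, abs=1e-10)
            assert pv.loc[a, b] == pytest.approx(p_o, abs=1e-10)

    def test_zero_variance_gives_nan_with_note(self):
        corr, _ = random_effect_correlations(
            self._frame([1.0] * 5, np.arange(5.0), np.arange(5.0)))
        assert np.isnan(corr.loc["alpha", "beta"])
        assert corr.attrs["warnings"]

    def test_symmetric_unit_diagonal(self, small_fit):
        corr, pv = random_effect_correlations(small_fit.random_effects)
        assert np.allclose(corr, corr.T)
        assert np.allclose(np.diag(corr), 1.0)
        assert ((pv.to_numpy() >= 0) & (pv.to_numpy() <= 1)).all()


class TestQuintileContrast:
    def _params(self, values, outcome=None):
        return pd.DataFrame({"x": values, "y": outcome if outcome is not None else values})

    def test_counting_example(self):
        c = quintile_contrast(self._params(np.arange(1.0, 11.0)), "x", "y")
        # top {9, 10}, bottom {1, 2} -> difference 8.0
        assert c.group_size == 2
        assert c.mean_difference == pytest.approx(8.0)

    def test_self_contrast_always_positive(self, small_fit):
        from growthspurt.spurt import extract_cohort
        tab = extract_cohort(small_fit)
        clean = tab[tab["flags"] == ""]
        for p in ("aphv", "phv", "gsi"):
            c = quintile_contrast(clean, p, p)
            assert c.mean_difference > 0

    def test_antisymmetry_under_rank_reversal(self):
        rng = np.random.default_rng(8)
        df = pd.DataFrame({"x": rng.normal(size=50), "y": rng.normal(size=50)})
        fwd = quintile_contrast(df, "x", "y")
        rev = quintile_contrast(df.assign(x=-df["x"]), "x", "y")
        assert fwd.mean_difference == pytest.approx(-rev.mean_difference, abs=1e-12)

    def test_welch_statistics_match_oracle(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame({"x": rng.normal(size=80), "y": rng.normal(size=80)})
        c = quintile_contrast(df, "x", "y")
        k = 16
        ranked = df.sort_values("x")
        t_o, p_o = welch_oracle(ranked["y"].iloc[-k:], ranked["y"].iloc[:k])
        assert c.t_statistic == pytest.approx(t_o, abs=1e-10)
        assert c.p_value == pytest.approx(p_o, abs=1e-10)

    def test_null_simulation_type_I_error(self):
        """Outcome independent of ranking: differences centre on zero and
        p < 0.05 occurs at the nominal rate (binomial 99% envelope over
        400 replicates)."""
        rng = np.random.default_rng(12)
        rejections = 0
        diffs = []
        for _ in range(400):
            df = pd.DataFrame({"x": rng.normal(size=200), "y": rng.normal(size=200)})
            c = quintile_contrast(df, "x", "y")
            rejections += c.p_value < 0.05
            diffs.append(c.mean_difference)
        assert 8 <= rejections <= 32  # 400 * 0.05 = 20 +- 2.58 * sqrt(n p q)
        assert abs(np.mean(diffs)) < 0.05

    def test_needs_enough_subjects(self):
        with pytest.raises(ValueError, match="at least 10"):
            quintile_contrast(self._params(np.arange(5.0)), "x", "y")


class TestBuildReport:
    def test_mixed_sex_rejected(self, small_fit):
        params = pd.DataFrame({
            "subject_id": ["a", "b"], "sex": ["male", "female"],
            "aogs": [10.0, 9.0], "aphv": [12.0, 11.0], "ogsv": [5.0, 5.0],
            "phv": [9.0, 8.0], "gsi": [3.5, 3.6], "flags": ["", ""],
        })
        with pytest.raises(ValueError, match="mixed-sex"):
            build_report(small_fit, params)

    def test_report_tables_and_determinism(self, small_fit, tmp_path):
        from growthspurt.spurt import extract_cohort
        params = extract_cohort(small_fit)
        params.insert(1, "sex", "male")
        clean = params[params["flags"] == ""]
        contrasts = contrast_table(clean)
        out1, out2 = tmp_path / "r1", tmp_path / "r2"
        t1 = build_report(small_fit, params, contrasts=contrasts, outdir=out1)
        build_report(small_fit, params, contrasts=contrasts, outdir=out2)
        # descriptive table rows = number of summarised parameters
        assert len(t1.descriptives) == 5
        assert t1.contrasts is not None and len(t1.contrasts) == 9
        for name in ("descriptives.csv", "correlations.csv", "contrasts.csv"):
            assert (out1 / name).read_bytes() == (out2 / name).read_bytes()
        assert (out1 / "velocity_curves.png").exists()
        assert (out1 / "boxplots.png").exists()

    def test_empty_contrasts_skips_contrast_table(self, small_fit, tmp_path):
        from growthspurt.spurt import extract_cohort
        params = extract_cohort(small_fit)
        t = build_report(small_fit, params, contrasts=None, outdir=tmp_path / "r")
        assert t.contrasts is None
        assert not (tmp_path / "r" / "contrasts.csv").exists()
        assert (tmp_path / "r" / "descriptives.csv").exists()
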