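import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vmrnorm import (
    BaselineNormalizer,
    BatchEffectNormalizer,
    DegeneratePredictorError,
    IntegratedNormalizer,
    LightIntensityNormalizer,
    NormalizationError,
    OffsetPolicy,
    apply_normalization,
    compute_baseline_target,
    fit_baseline_factors,
    fit_batch_model,
    fit_light_model,
    fits_from_frame,
    fits_to_frame,
    integrated_normalize,
    join_light,
    subset_window,
)

from conftest import make_table


def ols_oracle(x, y):
    """Closed-form simple-regression normal equations from summed
    cross-products, independent of any fitting library."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    sxx = (x * x).sum() - x.sum() ** 2 / n
    sxy = (x * y).sum() - x.sum() * y.sum() / n
    slope = sxy / sxx
    intercept = y.mean() - slope * x.mean()
    resid = y - intercept - slope * x
    s2 = (resid ** 2).sum() / (n - 2)
    se_slope = np.sqrt(s2 / sxx)
    se_intercept = np.sqrt(s2 * (1 / n + x.mean() ** 2 / sxx))
    return intercept, slope, se_intercept, se_slope


class TestLightModel:
    def test_constant_response_gives_zero_slope(self, light_map):
        df = make_table(n_larvae=6, activity=0.05)
        (fit,) = fit_light_model(df, light_map)
        assert fit.coefficients["beta0"] == pytest.approx(0.05, abs=1e-12)
        assert fit.coefficients["beta_light"] == pytest.approx(0.0, abs=1e-12)

    def test_matches_normal_equation_oracle(self, light_map, rng):
        df = make_table(n_larvae=24, t_values=range(-5, 5))
        df = join_light(df, light_map)
        x = df["light_intensity"].to_numpy()
        df["activity"] = 0.02 - 2e-4 * x + rng.normal(0, 1e-3, len(df))
        (fit,) = fit_light_model(df, light_map)
        b0, b1, se0, se1 = ols_oracle(x, df["activity"])
        assert fit.coefficients["beta0"] == pytest.approx(b0, rel=1e-10)
        assert fit.coefficients["beta_light"] == pytest.approx(b1, rel=1e-10)
        assert fit.standard_errors["beta0"] == pytest.approx(se0, rel=1e-8)
        assert fit.standard_errors["beta_light"] == pytest.approx(se1, rel=1e-8)
        # generating slope recovered within sampling error
        assert abs(fit.coefficients["beta_light"] + 2e-4) < 3 * se1

    def test_constant_intensity_is_degenerate(self):
        df = make_table(n_larvae=6, wells=["A1"] * 6)
        uniform = pd.Series(25.0, index=[f"{r}{c}" for r in "ABCDEFGH"
                                         for c in range(1, 13)])
        with pytest.raises(DegeneratePredictorError):
            fit_light_model(df, uniform)

    def test_small_group_skipped_with_warning(self, light_map):
        big = make_table(n_larvae=8, stage_dpf=6)
        tiny = make_table(n_larvae=1, t_values=[0], stage_dpf=9)
        df = pd.concat([big, tiny], ignore_index=True)
        with pytest.warns(UserWarning, match="below minimum size"):
            fits = fit_light_model(df, light_map, min_group_size=5)
        assert [f.group for f in fits] == [("TL", 6, "LightOn")]


class TestBatchModel:
    def test_identical_batches_give_zero_effects(self):
        a = make_table(n_larvae=4, batch="R1")
        b = make_table(n_larvae=4, batch="R2")
        b["larva_id"] = "b-" + b["larva_id"]
        (fit,) = fit_batch_model(pd.concat([a, b], ignore_index=True))
        for v in fit.batch_effects.values():
            assert v == pytest.approx(0.0, abs=1e-12)

    def test_effects_equal_shift_minus_mean_shift(self):
        # flat baseline 0.01 with injected shifts, equal n
        shifts = {"R1": -0.002, "R2": 0.001, "R3": 0.001}
        parts = []
        for i, (b, s) in enumerate(shifts.items()):
            part = make_table(n_larvae=4, batch=b, activity=0.01 + s)
            part["larva_id"] = f"{b}-" + part["larva_id"]
            parts.append(part)
        (fit,) = fit_batch_model(pd.concat(parts, ignore_index=True))
        mean_shift = np.mean(list(shifts.values()))
        for b, s in shifts.items():
            assert fit.batch_effects[b] == pytest.approx(s - mean_shift,
                                                         abs=1e-12)
        assert fit.coefficients["beta0"] == pytest.approx(0.01 + mean_shift,
                                                          abs=1e-12)

    def test_unbalanced_batches_use_unweighted_mean_of_batch_means(self, rng):
        a = make_table(n_larvae=10, batch="R1",
                       activity=lambda i, t: 0.01 + 0.001 * (i % 3))
        b = make_table(n_larvae=3, batch="R2",
                       activity=lambda i, t: 0.02 + 0.001 * (i % 2))
        b["larva_id"] = "b-" + b["larva_id"]
        df = pd.concat([a, b], ignore_index=True)
        (fit,) = fit_batch_model(df)
        means = df.groupby("batch")["activity"].mean()  # arithmetic oracle
        grand = means.mean()  # unweighted
        assert fit.coefficients["beta0"] == pytest.approx(grand, abs=1e-12)
        for b_, m in means.items():
            assert fit.batch_effects[b_] == pytest.approx(m - grand,
                                                          abs=1e-12)

    def test_effects_sum_to_zero(self, sim_default):
        table, _, _ = sim_default
        for fit in fit_batch_model(table):
            assert abs(sum(fit.batch_effects.values())) < 1e-10

    def test_single_batch_gives_zero_effect_and_group_mean(self):
        df = make_table(n_larvae=4, activity=lambda i, t: 0.01 * (i + 1))
        (fit,) = fit_batch_model(df)
        assert fit.coefficients["beta0"] == pytest.approx(
            df["activity"].mean(), abs=1e-12)
        assert list(fit.batch_effects.values()) == [0.0]


class TestBaseline:
    def test_grand_mean_is_weighted_by_group_size(self):
        a = make_table(n_larvae=100, t_values=[-1], activity=0.01,
                       stage_dpf=3)
        b = make_table(n_larvae=300, t_values=[-1], activity=0.02,
                       stage_dpf=9)
        b["larva_id"] = "b-" + b["larva_id"]
        df = pd.concat([a, b], ignore_index=True)
        assert compute_baseline_target(df) == pytest.approx(0.0175, abs=1e-12)

    def test_constant_activity_returns_it(self):
        df = make_table(t_values=range(-29, 1), activity=0.042)
        assert compute_baseline_target(df) == pytest.approx(0.042, abs=1e-15)

    def test_factor_is_group_mean_minus_target(self):
        df = make_table(t_values=range(-10, 1), activity=0.015)
        (fit,) = fit_baseline_factors(df, target=0.01024,
                                      baseline_window=(-10, 0))
        assert fit.coefficients["baseline_factor"] == pytest.approx(
            0.00476, abs=1e-12)

    def test_group_at_target_gives_zero_factor(self):
        df = make_table(t_values=range(-10, 1), activity=0.01024)
        (fit,) = fit_baseline_factors(df, target=0.01024,
                                      baseline_window=(-10, 0))
        assert fit.coefficients["baseline_factor"] == pytest.approx(0.0,
                                                                    abs=1e-15)

    def test_group_absent_from_window_raises(self):
        a = make_table(t_values=range(-5, 5), stage_dpf=3)
        b = make_table(t_values=range(1, 5), stage_dpf=9)  # post-change only
        b["larva_id"] = "b-" + b["larva_id"]
        df = pd.concat([a, b], ignore_index=True)
        with pytest.raises(NormalizationError, match="absent"):
            fit_baseline_factors(df, target=0.01, baseline_window=(-5, 0))


class TestApplyNormalization:
    def test_exactly_linear_data_collapses_to_offset(self, light_map):
        df = make_table(n_larvae=12)
        df = join_light(df, light_map)
        df["activity"] = 0.02 - 2e-4 * df["light_intensity"]
        fits = fit_light_model(df, light_map)
        out, rep = apply_normalization(df, fits, offset=0.06,
                                       light_map=light_map)
        np.testing.assert_allclose(out["activity"], 0.06, atol=1e-12)
        assert rep.offset_used == 0.06

    def test_light_residual_means_are_zero_per_group(self, sim_default):
        table, lm, _ = sim_default
        fits = fit_light_model(table, lm)
        out, rep = apply_normalization(table, fits, offset=0.0,
                                       light_map=lm)
        grouped = out.groupby(["strain", "stage_dpf"])["activity"].mean()
        np.testing.assert_allclose(grouped, 0.0, atol=1e-10)
        np.testing.assert_allclose(rep.residual_summary["mean"], 0.0,
                                   atol=1e-10)

    def test_baseline_shift_moves_group_means_to_target_plus_offset(
            self, sim_default):
        table, _, _ = sim_default
        target = compute_baseline_target(table)
        fits = fit_baseline_factors(table, target)
        out, _ = apply_normalization(table, fits, offset=0.06)
        base = subset_window(out, -29, 0)
        means = base.groupby(["strain", "stage_dpf"])["activity"].mean()
        np.testing.assert_allclose(means, target + 0.06, atol=1e-12)

    def test_baseline_shift_preserves_within_group_variance(self,
                                                            sim_default):
        table, _, _ = sim_default
        fits = fit_baseline_factors(table, 0.01)
        out, _ = apply_normalization(table, fits, offset=0.06)
        v_in = table.groupby(["strain", "stage_dpf"])["activity"].var()
        v_out = out.groupby(["strain", "stage_dpf"])["activity"].var()
        np.testing.assert_allclose(v_in, v_out, atol=1e-12)

    def test_auto_offset_guarantees_non_negative_output(self, sim_default):
        table, lm, _ = sim_default
        fits = fit_light_model(table, lm)
        out, rep = apply_normalization(table, fits, offset="auto",
                                       light_map=lm)
        assert out["activity"].min() >= 0
        assert rep.offset_used >= 0

    def test_auto_offset_is_zero_when_nothing_is_negative(self):
        df = make_table(activity=0.5)
        fits = fit_baseline_factors(df, target=0.6, baseline_window=(-2, 0))
        out, rep = apply_normalization(df, fits, offset="auto")
        assert rep.offset_used == 0.0

    def test_missing_group_fit_raises(self, sim_default):
        table, lm, _ = sim_default
        fits = fit_light_model(table[table.stage_dpf == 6], lm)
        with pytest.raises(NormalizationError, match="no light fit"):
            apply_normalization(table, fits, light_map=lm)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(pre_min=st.floats(-0.5, 0.5, allow_nan=False))
    def test_offset_policy_auto_bound(self, pre_min):
        mu = OffsetPolicy(mode="auto").resolve(pre_min)
        assert mu >= 0
        assert pre_min + mu >= 0
        if pre_min >= 0:
            assert mu == 0.0


class TestIntegrated:
    def test_fully_degenerate_chain_is_identity_plus_offset(self):
        uniform = pd.Series(25.0, index=[f"{r}{c}" for r in "ABCDEFGH"
                                         for c in range(1, 13)])
        df = make_table(n_larvae=6, t_values=range(-5, 6),
                        activity=lambda i, t: 0.01 + 0.002 * (t > 0))
        # baseline already at target: single group, target defaults to its
        # own baseline mean
        out, rep = integrated_normalize(df, uniform, baseline_window=(-5, 0),
                                        offset=0.06)
        np.testing.assert_allclose(out["activity"],
                                   df["activity"] + 0.06, atol=1e-12)
        assert rep.steps == ["light", "batch", "baseline"]

    def test_removes_all_three_systematic_effects(self, sim_default):
        table, lm, truth = sim_default
        out, rep = integrated_normalize(table, lm, offset=0.06)
        out = join_light(out, lm)
        target = compute_baseline_target(table)
        for _, g in out.groupby(["strain", "stage_dpf"]):
            r = np.corrcoef(g["activity"], g["light_intensity"])[0, 1]
            assert abs(r) < 0.02
            bm = g.groupby("batch")["activity"].mean()
            assert bm.max() - bm.min() < 1e-10
        base = subset_window(out, -29, 0)
        means = base.groupby(["strain", "stage_dpf"])["activity"].mean()
        np.testing.assert_allclose(means, target + 0.06, atol=1e-12)

    def test_equivariant_under_relabeling_and_reordering(self, sim_default):
        table, lm, _ = sim_default
        out1, _ = integrated_normalize(table, lm)
        shuffled = table.sample(frac=1, random_state=0).reset_index(drop=True)
        shuffled["larva_id"] = "x" + shuffled["larva_id"]
        out2, _ = integrated_normalize(shuffled, lm)
        key = ["larva_id", "trial", "t"]
        a = out1.assign(larva_id="x" + out1.larva_id).sort_values(key)
        b = out2.sort_values(key)
        np.testing.assert_allclose(a["activity"].to_numpy(),
                                   b["activity"].to_numpy(), atol=1e-12)


class TestEstimatorInterface:
    def test_get_params_round_trip(self, light_map):
        est = LightIntensityNormalizer(light_map=light_map, offset=0.06)
        params = est.get_params()
        assert params["offset"] == 0.06
        est.set_params(offset="auto")
        assert est.offset == "auto"

    def test_fit_transform_equals_fit_then_transform(self, sim_default):
        table, lm, _ = sim_default
        est = BatchEffectNormalizer(offset=0.0)
        a = est.fit_transform(table)
        b = est.fit(table).transform(table)
        np.testing.assert_allclose(a["activity"], b["activity"], atol=1e-15)

    def test_transform_does_not_mutate_input(self, sim_default):
        table, lm, _ = sim_default
        before = table.copy()
        IntegratedNormalizer(light_map=lm).fit(table).transform(table)
        pd.testing.assert_frame_equal(table, before)

    def test_fits_serialization_round_trip(self, sim_default):
        table, lm, _ = sim_default
        fits = fit_batch_model(table)
        back = fits_from_frame(fits_to_frame(fits))
        assert len(back) == len(fits)
        orig = {f.group: f for f in fits}
        for f in back:
            o = orig[f.group]
            for k, v in f.coefficients.items():
                assert v == pytest.approx(o.coefficients[k], abs=1e-15)
        # round-tripped fits still apply
        out, _ = apply_normalization(table, back, offset=0.0)
        assert np.isfinite(out["activity"]).all()
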