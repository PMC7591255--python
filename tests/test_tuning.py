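import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from v1contrast import synth, tuning


def _tuned_cell(stim, boost_direction=0.0, boost_contrast=0.8, factor=10.0, seed=0):
    """Baseline-1 cell with one boosted condition."""
    rng = np.random.default_rng(seed)
    responses = rng.gamma(4.0, 0.25, size=len(stim))
    sel = (stim["direction"] == boost_direction) & (stim["contrast"] == boost_contrast)
    responses[sel.to_numpy()] *= factor
    return responses


class TestChisqResponsiveness:
    def test_constant_responses_give_zero_statistic(self, stim_single):
        chi2, p = tuning.chisq_responsiveness(
            np.ones(len(stim_single)), stim_single, n_shuffles=200, seed=0
        )
        assert chi2 == 0.0
        assert p > 0.99

    def test_all_zero_cell_is_not_significant(self, stim_single):
        chi2, p = tuning.chisq_responsiveness(
            np.zeros(len(stim_single)), stim_single, n_shuffles=200, seed=0
        )
        assert chi2 == 0.0
        assert p > 0.99

    def test_strongly_tuned_cell_is_significant(self, stim_single):
        responses = _tuned_cell(stim_single)
        _, p = tuning.chisq_responsiveness(
            responses, stim_single, n_shuffles=2000, seed=1
        )
        assert p < 0.01

    def test_permutation_variant_agrees_on_tuned_cell(self, stim_single):
        responses = _tuned_cell(stim_single)
        _, p = tuning.chisq_responsiveness(
            responses, stim_single, n_shuffles=2000, seed=1, method="permutation"
        )
        assert p < 0.01

    def test_null_calibration_small(self, stim_single):
        """Type-I error on exchangeable null cells is near the nominal level."""
        truth = synth.sample_population_tuning({"flat": 1.0}, 150, seed=40)
        responses = synth.generate_event_responses(stim_single, truth, seed=41)
        _, p = tuning.chisq_responsiveness_batch(
            responses, stim_single, n_shuffles=500, seed=42
        )
        # 95% binomial envelope around 5% for 150 cells: [1.5%, 8.5%]
        assert 0.015 <= (p < 0.05).mean() <= 0.085

    def test_p_values_smoothed_above_zero(self, stim_single):
        responses = _tuned_cell(stim_single, factor=100.0)
        _, p = tuning.chisq_responsiveness(
            responses, stim_single, n_shuffles=100, seed=0
        )
        assert p == pytest.approx(1.0 / 101.0)


class TestConditionResponseStats:
    def test_blank_subtraction(self, stim_single):
        responses = np.full(len(stim_single), 0.5)
        sel = (stim_single["direction"] == 90.0) & (stim_single["contrast"] == 0.4)
        responses[sel.to_numpy()] = 2.0
        crt = tuning.condition_response_stats(responses, stim_single, n_boot=500, seed=0)
        row = crt.table[(crt.table["direction"] == 90.0) & (crt.table["contrast"] == 0.4)]
        assert row["rbar"].iloc[0] == pytest.approx(1.5)

    def test_constant_cell_sits_mid_null(self, stim_single):
        crt = tuning.condition_response_stats(
            np.ones(len(stim_single)), stim_single, n_boot=500, seed=0
        )
        assert np.allclose(crt.table["percentile"], 0.5)
        assert np.allclose(crt.table["rbar"], 0.0)

    def test_requires_blanks(self):
        stim = synth.make_stimulus_table(n_reps=2, n_blanks=0, seed=0)
        with pytest.raises(tuning.ConfigurationError, match="blank"):
            tuning.condition_response_stats(np.ones(len(stim)), stim)

    def test_zeroed_high_contrast_is_low_percentile(self, stim_single):
        rng = np.random.default_rng(3)
        responses = rng.gamma(4.0, 0.25, len(stim_single))
        responses[(stim_single["contrast"] == 0.8).to_numpy()] = 0.0
        crt = tuning.condition_response_stats(responses, stim_single, n_boot=2000, seed=1)
        high = crt.table[crt.table["contrast"] == 0.8]
        assert (high["percentile"] < 0.05).all()
        assert crt.pooled[crt.pooled["contrast"] == 0.8]["percentile"].iloc[0] < 0.05

    def test_percentiles_uniform_for_null_cells(self, stim_single):
        """Bootstrap percentile of the blank-subtracted mean is ~Uniform(0,1)
        for exchangeable cells (pooling one grating condition per cell)."""
        truth = synth.sample_population_tuning({"flat": 1.0}, 150, seed=50)
        responses = synth.generate_event_responses(stim_single, truth, seed=51)
        rng = np.random.default_rng(52)
        pct = []
        for i, cell in enumerate(responses):
            crt = tuning.condition_response_stats(cell, stim_single, n_boot=400, seed=rng)
            pct.append(crt.table["percentile"].iloc[i % 48])
        assert stats.kstest(pct, "uniform").pvalue > 0.001


class TestSuppressedByContrast:
    def _suppressed_cell(self, stim, seed=4):
        rng = np.random.default_rng(seed)
        responses = rng.gamma(4.0, 0.25, len(stim))
        responses[(stim["contrast"] == 0.8).to_numpy()] *= 0.3
        responses[(stim["contrast"] == 0.6).to_numpy()] *= 0.6
        return responses

    def test_suppressed_cell_flagged_under_both_variants(self, stim_single):
        crt = tuning.condition_response_stats(
            self._suppressed_cell(stim_single), stim_single, n_boot=2000, seed=5
        )
        assert tuning.suppressed_by_contrast(crt, "peak_direction")
        assert tuning.suppressed_by_contrast(crt, "all_directions")

    def test_high_pass_cell_not_flagged(self, stim_single):
        rng = np.random.default_rng(6)
        responses = rng.gamma(4.0, 0.1, len(stim_single))
        for c, f in [(0.4, 3), (0.6, 6), (0.8, 10)]:
            responses[(stim_single["contrast"] == c).to_numpy()] *= f
        crt = tuning.condition_response_stats(responses, stim_single, n_boot=1000, seed=7)
        assert not tuning.suppressed_by_contrast(crt, "peak_direction")
        assert not tuning.suppressed_by_contrast(crt, "all_directions")

    def test_flat_cells_rarely_flagged(self, flat_dataset):
        stim, _, responses = flat_dataset
        rng = np.random.default_rng(8)
        flags = []
        for cell in responses:
            crt = tuning.condition_response_stats(cell, stim, n_boot=400, seed=rng)
            flags.append(tuning.suppressed_by_contrast(crt, "peak_direction"))
        assert np.mean(flags) <= 0.05 + 1e-9

    def test_unknown_variant_rejected(self, stim_single):
        crt = tuning.condition_response_stats(
            np.ones(len(stim_single)), stim_single, n_boot=100, seed=0
        )
        with pytest.raises(ValueError, match="variant"):
            tuning.suppressed_by_contrast(crt, "mean_of_everything")


class TestSelectivityMetrics:
    def test_gosi_single_direction_is_one(self):
        r = np.zeros(8)
        r[2] = 1.0  # only 90 degrees
        assert tuning.gosi(r) == pytest.approx(1.0)
        assert tuning.gosi(r, convention="literal") == pytest.approx(1.0)

    def test_gosi_uniform_is_zero(self):
        assert tuning.gosi(np.ones(8)) == pytest.approx(0.0, abs=1e-12)

    def test_gosi_convention_differs_for_opposite_directions(self):
        r = np.zeros(8)
        r[[0, 4]] = 1.0  # 0 and 180 degrees
        assert tuning.gosi(r, convention="doubled_angle") == pytest.approx(1.0)
        assert tuning.gosi(r, convention="literal") == pytest.approx(0.0, abs=1e-12)

    def test_gosi_all_zero_is_nan(self):
        assert np.isnan(tuning.gosi(np.zeros(8)))

    @pytest.mark.parametrize(
        "pref,null,expected", [(2.0, 1.0, 1 / 3), (1.0, 0.0, 1.0), (1.0, 1.0, 0.0)]
    )
    def test_dsi_closed_forms(self, pref, null, expected):
        assert tuning.dsi(pref, null) == pytest.approx(expected)

    def test_dsi_both_zero_is_nan(self):
        assert np.isnan(tuning.dsi(0.0, 0.0))

    def test_ccom_single_contrast(self):
        r = np.zeros(6)
        r[3] = 2.0  # only c = 0.40
        assert tuning.contrast_com(r) == pytest.approx(0.40)

    def test_ccom_geometric_mean_of_extremes(self):
        r = np.zeros(6)
        r[[0, 5]] = 1.0  # 0.05 and 0.80
        assert tuning.contrast_com(r) == pytest.approx(0.20)

    def test_ccom_uniform_is_geometric_mean(self):
        expected = float(np.exp(np.mean(np.log(synth.CONTRASTS))))
        assert tuning.contrast_com(np.ones(6)) == pytest.approx(expected)
        assert expected == pytest.approx(0.24, abs=0.005)

    @given(
        scale=st.floats(min_value=1e-3, max_value=1e3),
        seed=st.integers(min_value=0, max_value=100),
    )
    @settings(max_examples=25, deadline=None)
    def test_metrics_invariant_to_positive_scaling(self, scale, seed):
        rng = np.random.default_rng(seed)
        r8 = rng.gamma(2.0, 1.0, 8) + 1e-6
        r6 = rng.gamma(2.0, 1.0, 6) + 1e-6
        assert tuning.gosi(r8 * scale) == pytest.approx(tuning.gosi(r8), rel=1e-9)
        assert tuning.dsi_from_tuning(r8 * scale) == pytest.approx(
            tuning.dsi_from_tuning(r8), rel=1e-9
        )
        assert tuning.contrast_com(r6 * scale) == pytest.approx(
            tuning.contrast_com(r6), rel=1e-9
        )


class TestPopulationBias:
    def test_opposed_pairs_cancel(self):
        bias = tuning.population_direction_bias(
            np.array([0.0, 180.0, 0.0, 180.0]), n_null=200, seed=0
        )
        assert bias.r_bias == pytest.approx(0.0, abs=1e-12)

    def test_identical_preferences_saturate(self):
        bias = tuning.population_direction_bias(np.zeros(25), n_null=200, seed=0)
        assert bias.r_bias == pytest.approx(1.0)
        assert bias.theta_bias == pytest.approx(0.0, abs=1e-9)

    def test_empty_population_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            tuning.population_direction_bias(np.array([]))

    def test_uniform_population_below_corrected_radius(self):
        """Uniformly tiled populations stay inside the null CI nearly always."""
        rng = np.random.default_rng(9)
        radius = tuning.population_direction_bias(
            rng.choice(synth.DIRECTIONS, 100), n_null=4000, seed=10
        ).null_ci_radius
        below = 0
        n_sim = 300
        for _ in range(n_sim):
            dirs = rng.choice(synth.DIRECTIONS, 100)
            z = np.exp(1j * np.radians(dirs)).mean()
            below += np.abs(z) < radius
        assert below / n_sim >= 0.94

    def test_rbias_shrinks_with_population_size(self):
        rng = np.random.default_rng(11)

        def mean_rbias(n):
            vals = []
            for _ in range(200):
                z = np.exp(1j * np.radians(rng.choice(synth.DIRECTIONS, n))).mean()
                vals.append(np.abs(z))
            return np.mean(vals)

        assert mean_rbias(400) < mean_rbias(25)


class TestNormalizedResponse:
    @pytest.mark.parametrize(
        "r_dc,r_b,r_bar,expected",
        [(3.0, 1.0, 2.0, 2 / 3), (1.0, 1.0, 2.0, 0.0), (2.0, 0.0, 1.0, 2.0)],
    )
    def test_closed_forms(self, r_dc, r_b, r_bar, expected):
        assert tuning.normalized_response(r_dc, r_b, r_bar) == pytest.approx(expected)

    def test_zero_denominator_is_nan(self):
        assert np.isnan(tuning.normalized_response(1.0, 0.0, 0.0))


class TestLocomotionSplit:
    def test_all_stationary_excludes_everything(self, stim_single):
        stim = stim_single.copy()
        stim["run_speed"] = 0.0
        split = tuning.split_by_locomotion(stim)
        assert not split.table["included"].any()

    def test_threshold_is_inclusive(self, stim_single):
        stim = stim_single.copy()
        stim["run_speed"] = 1.0
        split = tuning.split_by_locomotion(stim)
        assert split.run_state.all()

    def test_alternating_split_included(self):
        stim = synth.make_stimulus_table(n_reps=16, n_blanks=0, seed=0)
        stim = stim.sort_values(["direction", "contrast"]).reset_index(drop=True)
        stim["run_speed"] = np.tile([0.0, 2.0], len(stim) // 2)
        split = tuning.split_by_locomotion(stim)
        gratings = split.table[~split.table["is_blank"]]
        assert (gratings["n_run"] == 8).all()
        assert (gratings["n_stationary"] == 8).all()
        assert gratings["included"].all()


class TestPopulationSummary:
    def test_flat_cells_summarize_to_zero(self, stim_single):
        truth = synth.sample_population_tuning({"flat": 1.0}, 5, seed=60)
        responses = synth.generate_event_responses(
            stim_single, truth, noise=synth.NoiseSpec(0.0, None), seed=0
        )
        out = tuning.population_tuning_summary(responses, stim_single)
        means = out["surface"]["mean"].dropna()
        assert np.allclose(means, 0.0, atol=1e-12)

    def test_too_few_responsive_cells_yield_empty_summary(self, stim_single):
        out = tuning.population_tuning_summary(
            np.ones((2, len(stim_single))), stim_single
        )
        assert out["surface"].empty

    def test_vip_population_running_enhancement(self, vip_dataset):
        stim, _, responses = vip_dataset
        out = tuning.population_tuning_summary(responses, stim)
        surf = out["surface"]
        low0 = surf[(surf["direction"] == 0.0) & (surf["contrast"] <= 0.10)]
        run = low0[low0["state"] == "run"]["mean"].mean()
        stat = low0[low0["state"] == "stationary"]["mean"].mean()
        assert run > stat

    def test_sst_population_prefers_high_contrast(self, stim_single):
        stim, truth, responses = synth.generate_dataset("sst", 25, seed=70)
        out = tuning.population_tuning_summary(responses, stim)
        surf = out["surface"]
        for state in ("run", "stationary"):
            sub = surf[surf["state"] == state]
            high = sub[sub["contrast"] >= 0.6]["mean"].mean()
            low = sub[sub["contrast"] <= 0.1]["mean"].mean()
            assert high > low
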