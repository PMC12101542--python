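"""Tests for dF/F, transient fitting, ISI statistics and modulation detection."""

import math
import warnings

import numpy as np
import pytest

from optoclamp import (
    ClampConfig,
    OpenLoopProtocol,
    default_population,
    run_closed_loop,
    run_open_loop,
)
from optoclamp.synth_neuro import NeuronParams, TraceSet, post_clamp_params
from optoclamp.transient_analysis import (
    compare_pre_post,
    compute_dff,
    detect_modulated_rois,
    extract_and_fit_transient,
    isi_statistics,
    transient_duration_from_variances,
)

FS = 30.0


class TestDff:
    def test_constant_trace_is_zero(self):
        trace = np.full(300, 1.7)
        np.testing.assert_allclose(compute_dff(trace, FS, (0.0, 5.0)), 0.0, atol=1e-12)

    def test_doubling_gives_unity(self):
        trace = np.full(300, 0.8)
        trace[150] = 1.6
        dff = compute_dff(trace, FS, (0.0, 3.0))
        assert dff[150] == pytest.approx((1.6 - 0.8) / 0.8, rel=1e-6)

    def test_nonpositive_f0_rejected(self):
        with pytest.raises(ValueError, match="F0"):
            compute_dff(np.full(300, -1.0), FS, (0.0, 5.0))

    def test_generator_spike_peak_recovers_amplitude(self):
        # a single forced spike of fluorescence quantum A on resting level F0
        # appears in dF/F with peak ~ A / F0
        from optoclamp import simulate_population

        p = NeuronParams(baseline_rate=0.0, noise_sd=0.0)
        model = default_population(n_roi=1, seed=0, params=p)
        traces, _ = simulate_population(model, None, 10.0, seed=0, forced_spikes=[(0, 5.0)])
        dff = compute_dff(traces.roi(0), FS, (0.0, 4.0))
        assert dff.max() == pytest.approx(p.ca_amp / p.f0, rel=0.05)


class TestTransientFit:
    def _synthetic_trace(self, alpha, tau_s, baseline, onsets, n=None, noise=0.0, rng=None):
        n = n or int((max(onsets) + 10) * FS)
        t = np.arange(n) / FS
        y = np.full(n, baseline)
        for t0 in onsets:
            m = t >= t0
            y[m] += alpha * np.exp(-(t[m] - t0) / tau_s)
        if noise:
            y = y + noise * rng.standard_normal(n)
        return y

    def test_exact_model_recovered(self):
        onsets = np.array([5.0, 20.0, 35.0])
        y = self._synthetic_trace(2.0, 1.5, 0.1, onsets)
        fit = extract_and_fit_transient(y, FS, onsets, window_s=8.0)
        assert fit.valid
        assert fit.alpha_e == pytest.approx(2.0, rel=1e-4)
        assert fit.tau_e_ms == pytest.approx(1500.0, rel=1e-4)
        assert fit.baseline == pytest.approx(0.1, abs=1e-4)
        assert fit.n_events == 3

    def test_fraction_remaining_at_tau_is_e_inverse(self):
        onsets = np.array([5.0, 20.0])
        y = self._synthetic_trace(1.0, 2.257, 0.0, onsets)
        fit = extract_and_fit_transient(y, FS, onsets, window_s=8.0)
        assert fit.fraction_remaining(fit.tau_e_ms / 1000.0) == pytest.approx(
            math.exp(-1.0), rel=1e-9
        )

    def test_fit_is_idempotent_on_its_own_prediction(self):
        onsets = np.array([5.0, 20.0])
        rng = np.random.default_rng(0)
        y = self._synthetic_trace(1.2, 2.0, 0.05, onsets, noise=0.05, rng=rng)
        fit1 = extract_and_fit_transient(y, FS, onsets, window_s=8.0)
        t = np.arange(int(8 * FS)) / FS
        pred = fit1.predict(t)
        refit = extract_and_fit_transient(pred, FS, np.array([0.0]), window_s=7.9)
        assert refit.alpha_e == pytest.approx(fit1.alpha_e, rel=1e-6)
        assert refit.tau_e_ms == pytest.approx(fit1.tau_e_ms, rel=1e-6)

    def test_parameter_recovery_from_simulated_probes(self):
        # 50 simulated open-loop probe events; the fitted decay constant must
        # sit within 3 empirical SE of the generator's kernel constant
        from optoclamp.transient_analysis import fit_events_grouped

        model = default_population(n_roi=1, seed=9)
        run = run_open_loop(model, 0, OpenLoopProtocol(n_reps=50), ClampConfig(), seed=9)
        dff = compute_dff(run.traces.roi(0), FS, (0.0, 12.0))
        fit, se = fit_events_grouped(dff, FS, run.pulses.onsets(), 8.0, n_groups=10)
        assert fit.valid
        assert abs(fit.tau_e_ms - 2257.0) < 3 * se

    def test_poor_fit_flagged_invalid(self):
        rng = np.random.default_rng(1)
        y = rng.standard_normal(int(40 * FS))
        with pytest.warns(UserWarning):
            fit = extract_and_fit_transient(y, FS, np.array([5.0, 20.0]), 8.0, r2_floor=0.9)
        assert not fit.valid


class TestComparePrePost:
    def _cohort_fits(self, params, seeds):
        fits = []
        for seed in seeds:
            model = default_population(n_roi=1, seed=seed, params=params)
            run = run_open_loop(model, 0, OpenLoopProtocol(), ClampConfig(), seed=seed)
            dff = compute_dff(run.traces.roi(0), FS, (0.0, 12.0))
            fits.append(extract_and_fit_transient(dff, FS, run.pulses.onsets(), 8.0))
        return fits

    def test_identical_epochs_null(self):
        fits = self._cohort_fits(NeuronParams(), range(6))
        out = compare_pre_post({"pre": fits, "post": fits})
        assert (out["diff"] == 0).all()
        assert (out["p_value"] > 0.9).all()

    def test_attenuated_cohort_detected_at_3min_not_after_recovery(self):
        # cells probed with the +3 min post-clamp kinetics (18% amplitude
        # attenuation) separate from their pre-clamp probes at alpha = 0.05;
        # fully recovered cells do not
        seeds = range(7)
        pre = self._cohort_fits(NeuronParams(), seeds)
        post3 = self._cohort_fits(post_clamp_params(NeuronParams()), seeds)
        recovered = self._cohort_fits(NeuronParams(), [s + 100 for s in seeds])
        out = compare_pre_post({"pre": pre, "post3": post3, "post8": recovered})
        row = out[(out.epoch_a == "pre") & (out.epoch_b == "post3") & (out.param == "alpha_e")]
        assert float(row["p_value"].iloc[0]) < 0.05
        row8 = out[(out.epoch_a == "pre") & (out.epoch_b == "post8") & (out.param == "alpha_e")]
        assert float(row8["p_value"].iloc[0]) > 0.05

    def test_too_few_cells_rejected(self):
        fits = self._cohort_fits(NeuronParams(), [0])
        with pytest.raises(ValueError, match="fewer than 2"):
            compare_pre_post({"pre": fits, "post": fits})


class TestISIStatistics:
    def test_periodic_pulses_have_zero_variance_and_transient(self):
        onsets = np.arange(0.0, 266.0, 2.0)
        st = isi_statistics(onsets, (0.0, 266.0))
        np.testing.assert_allclose(st.per_bin_var, 0.0, atol=1e-20)
        assert st.transient_duration == 0.0

    def test_worked_example_bins_rule(self):
        # variances [5, 2, 1.05, 1.0] s^2 with steady 1.0: the last bin above
        # 1.1 x steady ends at 120 s
        edges = np.array([0.0, 60.0, 120.0, 180.0, 240.0])
        out = transient_duration_from_variances(
            np.array([5.0, 2.0, 1.05, 1.0]), edges, steady_var=1.0
        )
        assert out == 120.0

    def test_binning_partitions_clamp_exactly(self):
        rng = np.random.default_rng(4)
        onsets = np.sort(rng.uniform(0.0, 266.0, size=200))
        st = isi_statistics(onsets, (0.0, 266.0))
        assert st.per_bin_count.sum() == len(st.isis)
        # 266 s -> 60 s bins with the remainder pooled into the tail bin
        np.testing.assert_allclose(st.bin_edges, [0.0, 60.0, 120.0, 180.0, 266.0])

    def test_sparse_bin_excluded_with_warning(self):
        onsets = np.concatenate([np.arange(0, 58, 1.0), [130.0, 230.0, 231.0, 232.0]])
        with pytest.warns(UserWarning, match="fewer than 2"):
            st = isi_statistics(onsets, (0.0, 240.0))
        assert np.isnan(st.per_bin_var[1]) or st.per_bin_count[1] < 2

    def test_needs_three_pulses(self):
        with pytest.raises(ValueError, match="3 pulses"):
            isi_statistics(np.array([1.0, 2.0]), (0.0, 266.0))

    def test_higher_target_level_lower_early_isi_variance(self):
        # the 5*SD clamp stabilises faster than the 3*SD clamp: its first
        # 60 s ISI variance is lower, averaged over 20 seeded runs
        first_bin = {}
        for k in (3.0, 5.0):
            vals = []
            for seed in range(20):
                model = default_population(n_roi=1, seed=seed)
                run = run_closed_loop(model, 0, ClampConfig(k_sd=k, t_cl=266.0), seed=seed)
                st = isi_statistics(run.pulses.onsets(), run.clamp_window)
                vals.append(st.per_bin_var[0])
            first_bin[k] = np.mean(vals)
        assert first_bin[5.0] < first_bin[3.0]


class TestDetectModulatedRois:
    def _population_run(self, n_coupled, seed, n_roi=12, strength=0.06):
        rng = np.random.default_rng(seed)
        coupling = np.zeros((n_roi, n_roi))
        if n_coupled:
            driven = rng.choice(np.arange(1, n_roi), size=n_coupled, replace=False)
            coupling[driven, 0] = strength
        else:
            driven = np.array([], dtype=int)
        model = default_population(n_roi=n_roi, coupling=coupling, seed=seed, clamped_index=0)
        run = run_closed_loop(
            model, 0, ClampConfig(k_sd=5.0, t_cl=120.0, baseline_window_s=60.0), seed=seed
        )
        return run, set(driven.tolist())

    def test_ground_truth_recovery_17_of_46(self):
        # strong coupling, low noise: exactly the 17 driven ROIs of 46
        # candidates are flagged at a strict threshold
        run, driven = self._population_run(n_coupled=17, seed=0, n_roi=47)
        res = detect_modulated_rois(
            run.traces,
            run.pulses.onsets(),
            clamped_roi=0,
            clamp_window=run.clamp_window,
            baseline_window=(0.0, 60.0),
            alpha_level=0.001,
        )
        assert res.n_total == 46
        detected = set(res.table.loc[res.table.significant, "roi"].tolist())
        assert detected == driven
        assert res.n_significant == 17

    def test_clamped_roi_excluded(self):
        run, _ = self._population_run(n_coupled=3, seed=1)
        res = detect_modulated_rois(
            run.traces, run.pulses.onsets(), 0, run.clamp_window, (0.0, 60.0)
        )
        assert 0 not in set(res.table["roi"])
        assert res.n_total == run.traces.data.shape[0] - 1

    def test_driven_rois_show_positive_peak_delta(self):
        run, driven = self._population_run(n_coupled=4, seed=2)
        res = detect_modulated_rois(
            run.traces, run.pulses.onsets(), 0, run.clamp_window, (0.0, 60.0)
        )
        sub = res.table[res.table["roi"].isin(driven)]
        assert (sub["peak_delta"] > 0).all()

    def test_missing_baseline_epoch_rejected(self):
        run, _ = self._population_run(n_coupled=0, seed=3)
        with pytest.raises(ValueError, match="baseline"):
            detect_modulated_rois(
                run.traces, run.pulses.onsets(), 0, run.clamp_window, (0.0, 1.0)
            )
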