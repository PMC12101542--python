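"""Unit and property tests for the neuron/population simulator."""

import dataclasses
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from optoclamp.synth_neuro import (
    BTSPConfig,
    IPConfig,
    NeuronParams,
    NeuronState,
    apply_ip_update,
    btsp_update,
    default_population,
    post_clamp_params,
    relax_ip,
    simulate_population,
    synaptic_scaling_step,
)


def silent_params(**kw):
    defaults = dict(baseline_rate=0.0, noise_sd=0.0)
    defaults.update(kw)
    return NeuronParams(**defaults)


class TestForwardModel:
    def test_zero_stimulus_silent_neuron_is_flat(self):
        model = default_population(n_roi=1, seed=0, params=silent_params())
        traces, spikes = simulate_population(model, None, duration=5.0, seed=0)
        assert spikes.counts()[0] == 0
        np.testing.assert_allclose(traces.roi(0), model.params[0].f0)

    def test_forced_spike_jumps_and_decays_exponentially(self):
        p = silent_params()
        model = default_population(n_roi=1, seed=0, params=p)
        traces, spikes = simulate_population(
            model, None, duration=10.0, seed=0, forced_spikes=[(0, 1.0)]
        )
        f = traces.roi(0) - p.f0
        fs = traces.fs
        k1 = int(1.0 * fs)  # frame containing the spike
        assert f[k1 - 1] == 0.0
        # peak sample reflects the within-frame decay from the spike time
        assert f[k1] == pytest.approx(p.ca_amp, rel=0.05)
        # decay over the following 2 seconds follows exp(-t/tau_ca)
        k2 = k1 + int(2.0 * fs)
        assert f[k2] / f[k1] == pytest.approx(math.exp(-2.0 / p.tau_ca), rel=1e-6)
        assert spikes.trains[0].tolist() == [1.0]

    def test_constant_rate_mean_dff_matches_shot_noise_formula(self):
        # time-averaged fluorescence above rest = r * A * tau for a Poisson
        # spike train convolved with an exponential kernel (Campbell's theorem)
        p = silent_params(baseline_rate=3.0, noise_sd=0.0)
        expected = 3.0 * p.ca_amp * p.tau_ca
        means = []
        for seed in range(20):
            model = default_population(n_roi=1, seed=seed, params=p)
            traces, _ = simulate_population(model, None, duration=60.0, seed=seed)
            burn = int(15.0 * traces.fs)
            means.append((traces.roi(0)[burn:] - p.f0).mean())
        means = np.asarray(means)
        se = means.std(ddof=1) / math.sqrt(means.size)
        assert abs(means.mean() - expected) < 3 * se

    def test_identical_seed_and_config_bit_identical(self):
        for _ in range(2):
            out = []
            for _ in range(2):
                model = default_population(n_roi=3, seed=11)
                traces, spikes = simulate_population(model, None, duration=8.0, seed=11)
                out.append((traces.data.copy(), [t.copy() for t in spikes.trains]))
            assert np.array_equal(out[0][0], out[1][0])
            for a, b in zip(out[0][1], out[1][1]):
                assert np.array_equal(a, b)

    def test_input_validation(self):
        model = default_population(n_roi=1, seed=0)
        with pytest.raises(ValueError, match="duration"):
            simulate_population(model, None, duration=-1.0, seed=0)
        bad = np.full((1, 30), np.nan)
        with pytest.raises(ValueError, match="non-finite"):
            simulate_population(model, bad, duration=1.0, seed=0)

    def test_coupled_neighbor_sees_pulse_locked_increase(self):
        coupling = np.array([[0.0, 0.0], [0.06, 0.0]])  # roi1 driven by roi0
        model = default_population(n_roi=2, coupling=coupling, seed=3)
        n = int(20 * 30)
        stim = np.zeros((2, n))
        onsets = np.arange(2.0, 18.0, 4.0)
        for t in onsets:
            k = int(t * 30)
            stim[0, k : k + 2] = 10.0
        traces, _ = simulate_population(model, stim, duration=20.0, seed=3)
        f1 = traces.roi(1)
        peaks = [f1[int(t * 30) : int(t * 30) + 15].max() for t in onsets]
        rest = f1[: int(1.5 * 30)].max()
        assert np.mean(peaks) > rest + 0.1


class TestIntrinsicPlasticity:
    def test_zero_duration_is_identity(self):
        s = NeuronState()
        out = apply_ip_update(s, NeuronParams(), clamp_level_k=5.0, clamp_duration=0.0)
        assert out.ip_atten == 1.0 and out.ip_tau_factor == 1.0

    def test_negative_level_rejected(self):
        with pytest.raises(ValueError, match="k must be"):
            apply_ip_update(NeuronState(), NeuronParams(), -1.0, 100.0)

    def test_stronger_clamp_deeper_attenuation(self):
        s = NeuronState()
        p = NeuronParams()
        a3 = apply_ip_update(s, p, 3.0, 200.0)
        a5 = apply_ip_update(s, p, 5.0, 200.0)
        assert a5.ip_atten < a3.ip_atten < 1.0
        assert a5.ip_tau_factor < a3.ip_tau_factor < 1.0
        # k=3 induction is 60% of the k=5 effect
        assert (1 - a3.ip_atten) == pytest.approx(0.6 * (1 - a5.ip_atten), rel=1e-9)

    def test_longer_clamp_deeper_attenuation(self):
        s = NeuronState()
        p = NeuronParams()
        short = apply_ip_update(s, p, 5.0, 50.0)
        long = apply_ip_update(s, p, 5.0, 200.0)
        assert long.ip_atten < short.ip_atten

    def test_relaxation_is_monotone_and_complete(self):
        s = apply_ip_update(NeuronState(), NeuronParams(), 5.0, 200.0)
        cfg = IPConfig()
        prev = s.ip_atten
        for elapsed in (60.0, 120.0, 300.0, 3000.0):
            out = relax_ip(s, elapsed, cfg)
            assert out.ip_atten > prev or elapsed == 60.0
            prev = out.ip_atten
        far = relax_ip(s, 1e6, cfg)
        assert far.ip_atten == pytest.approx(1.0, abs=1e-12)
        assert far.ip_tau_factor == pytest.approx(1.0, abs=1e-12)

    def test_calibration_anchor_at_probe_delay(self):
        # 180 s after a 200 s clamp at k=5 the evoked amplitude is down 18%
        # and the decay constant has shrunk from 2257 ms to 1850 ms
        p = post_clamp_params(NeuronParams())
        assert p.ca_amp / NeuronParams().ca_amp == pytest.approx(0.82, abs=1e-9)
        assert p.tau_ca == pytest.approx(1.850, abs=1e-9)


class TestBTSP:
    def test_zero_reward_leaves_weights(self):
        s = NeuronState(weights=np.array([1.0, 2.0]), eligibility=np.array([0.5, 0.1]))
        out = btsp_update(s, np.zeros(2), plateau=False, reward=0.0, dt=0.1)
        np.testing.assert_array_equal(out.weights, s.weights)

    def test_eligibility_decays_exponentially(self):
        cfg = BTSPConfig(tau_elig=4.0)
        s = NeuronState(weights=np.zeros(1), eligibility=np.array([2.0]))
        t = 0.0
        for _ in range(30):
            s = btsp_update(s, np.zeros(1), plateau=False, reward=0.0, dt=0.1, cfg=cfg)
            t += 0.1
        assert s.eligibility[0] == pytest.approx(2.0 * math.exp(-t / 4.0), rel=1e-9)

    def test_delayed_reward_gain_ratio(self):
        # an input tagged 2 s before the reward gains exp(-2/4) of a
        # coincident input's gain (tau_elig = 4 s)
        cfg = BTSPConfig(tau_elig=4.0, eta=0.1)
        dt = 0.01

        def gain(delay: float) -> float:
            s = NeuronState(weights=np.zeros(1), eligibility=np.zeros(1))
            s = btsp_update(s, np.ones(1), plateau=True, reward=0.0, dt=dt, cfg=cfg)
            steps = int(round(delay / dt))
            for _ in range(steps):
                s = btsp_update(s, np.zeros(1), plateau=False, reward=0.0, dt=dt, cfg=cfg)
            s = btsp_update(s, np.zeros(1), plateau=False, reward=1.0, dt=dt, cfg=cfg)
            return float(s.weights[0])

    # analytic rule: w = eta * e0 * exp(-delay/tau); simulation must agree
        ratio = gain(2.0) / gain(0.0)
        assert ratio == pytest.approx(math.exp(-2.0 / 4.0), rel=1e-6)

    def test_negative_tau_rejected(self):
        with pytest.raises(ValueError, match="tau_elig"):
            BTSPConfig(tau_elig=-1.0)


class TestSynapticScaling:
    def _model_with(self, rates, weights):
        model = default_population(n_roi=len(rates), seed=0, n_synapses=len(weights[0]))
        for s, r, w in zip(model.states, rates, weights):
            s.rate = r
            s.weights = np.asarray(w, dtype=float)
        return model

    def test_at_target_is_fixed_point(self):
        model = self._model_with([4.0], [[1.0, 2.0, 3.0]])
        out = synaptic_scaling_step(model, [4.0], epsilon=0.5)
        np.testing.assert_allclose(out.states[0].weights, [1.0, 2.0, 3.0])

    def test_double_rate_epsilon_one_halves_weights(self):
        model = self._model_with([8.0], [[1.0, 2.0]])
        out = synaptic_scaling_step(model, [4.0], epsilon=1.0)
        np.testing.assert_allclose(out.states[0].weights, [0.5, 1.0])

    def test_iteration_converges_preserving_ratios(self):
        # rate proportional to summed weights; repeated scaling drives the
        # rate to target while within-neuron ratios stay exact
        w = np.array([1.0, 3.0, 0.5])
        target = 5.0
        gain_per_weight = 2.0
        model = self._model_with([gain_per_weight * w.sum()], [w])
        ratios0 = model.states[0].weights / model.states[0].weights[0]
        for _ in range(200):
            model.states[0].rate = gain_per_weight * model.states[0].weights.sum()
            model = synaptic_scaling_step(model, [target], epsilon=0.2)
        final_rate = gain_per_weight * model.states[0].weights.sum()
        assert final_rate == pytest.approx(target, rel=1e-9)
        ratios = model.states[0].weights / model.states[0].weights[0]
        np.testing.assert_array_equal(ratios, ratios0)

    def test_zero_rate_skipped_with_warning(self):
        model = self._model_with([0.0], [[1.0, 2.0]])
        with pytest.warns(UserWarning, match="skipped"):
            out = synaptic_scaling_step(model, [4.0], epsilon=0.5)
        np.testing.assert_array_equal(out.states[0].weights, [1.0, 2.0])

    @given(
        weights=st.lists(st.floats(0.01, 100.0), min_size=2, max_size=6),
        rate=st.floats(0.1, 50.0),
        target=st.floats(0.1, 50.0),
        epsilon=st.floats(0.01, 1.0),
    )
    def test_ratio_conservation_property(self, weights, rate, target, epsilon):
        model = self._model_with([rate], [weights])
        out = synaptic_scaling_step(model, [target], epsilon=epsilon)
        w0 = np.asarray(weights)
        w1 = out.states[0].weights
        np.testing.assert_allclose(w1 / w1[0], w0 / w0[0], rtol=1e-12)


class TestValidation:
    def test_params_invariants(self):
        with pytest.raises(ValueError):
            NeuronParams(f_max=-1.0)
        with pytest.raises(ValueError):
            NeuronParams(tau_ca=0.0)
        with pytest.raises(ValueError):
            NeuronParams(alpha_adapt=-0.1)

    def test_state_invariants(self):
        with pytest.raises(ValueError):
            NeuronState(ip_atten=1.5)
        with pytest.raises(ValueError):
            NeuronState(eligibility=np.array([-1.0]), weights=np.array([1.0]))

    def test_coupling_must_have_zero_diagonal(self):
        from optoclamp.synth_neuro import PopulationModel

        p = [NeuronParams()]
        s = [NeuronState()]
        with pytest.raises(ValueError, match="diagonal"):
            PopulationModel(params=p, states=s, coupling=np.array([[1.0]]))
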