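"""Synthetic all-optical experiment generator.

Model neurons with a Boltzmann f-I curve, subtractive spike-rate adaptation,
intrinsic-plasticity (IP) state, behavioral-timescale synaptic plasticity
(BTSP) eligibility traces and homeostatic synaptic scaling (SS), plus a
linear spike-to-fluorescence forward model emulating a slow genetically
encoded calcium indicator imaged at 30 Hz.

The instantaneous firing rate of a neuron receiving input current ``I`` is

    r(t) = clip( r0 + f_max * [sigma((I - theta0 - a)/s) - sigma((-theta0 - a)/s)],
                 0, f_max )

where ``sigma`` is the logistic function, ``r0`` the spontaneous rate and
``a(t)`` the adaptation variable obeying ``da/dt = (alpha*r - a)/tau_a``
(a rightward, input-axis shift of the f-I curve under sustained firing).
Subtracting the zero-input value of the shifted curve anchors the rest
point: spontaneous firing is an input-independent Poisson source, so
adaptation attenuates evoked responses without silencing the baseline.
Spikes are drawn as an inhomogeneous Poisson process at the imaging frame
resolution, and fluorescence is the exact shot-noise convolution of spikes
with an instantaneous-rise, mono-exponential-decay kernel plus additive
Gaussian read noise.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "NeuronParams",
    "NeuronState",
    "PopulationModel",
    "TraceSet",
    "SpikeTrains",
    "IPConfig",
    "BTSPConfig",
    "PopulationSim",
    "simulate_population",
    "apply_ip_update",
    "relax_ip",
    "post_clamp_params",
    "btsp_update",
    "synaptic_scaling_step",
    "default_population",
    "PRE_CLAMP_TAU_E_MS",
    "POST_CLAMP_TAU_E_MS",
]

# Calibration anchors for the evoked-transient kinetics: the averaged evoked
# transient decays with tau_e = 2257 ms before the clamp and 1850 ms when
# probed 180 s after a 200 s clamp at the 5*SD target level, with ~18% peak
# attenuation at that probe, partially rebounding by +480 s.
PRE_CLAMP_TAU_E_MS = 2257.0
POST_CLAMP_TAU_E_MS = 1850.0
PROBE_DELAY_S = 180.0
AMP_ATTENUATION_AT_PROBE = 0.18
DEFAULT_TAU_REC_S = 300.0

_REBOUND_AT_PROBE = math.exp(PROBE_DELAY_S / DEFAULT_TAU_REC_S)
#: IP induction depths at clamp end (k = 5, 200 s) such that, after 180 s of
#: exponential recovery with tau_rec, the amplitude is attenuated by 18% and
#: the decay constant has shrunk from 2257 ms to 1850 ms.
DEPTH_AMP_REF = AMP_ATTENUATION_AT_PROBE * _REBOUND_AT_PROBE
DEPTH_TAU_REF = (1.0 - POST_CLAMP_TAU_E_MS / PRE_CLAMP_TAU_E_MS) * _REBOUND_AT_PROBE


def _sigmoid(x: np.ndarray | float) -> np.ndarray | float:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -500.0, 500.0)))


@dataclass(frozen=True)
class NeuronParams:
    """Static parameters of one model neuron.

    Parameters
    ----------
    baseline_rate : float
        Spontaneous firing rate, spikes/s.
    f_max : float
        Ceiling of the Boltzmann f-I curve, spikes/s.
    theta0 : float
        Half-activation input of the f-I curve (input units).
    slope : float
        Softness of the f-I curve (input units).
    tau_adapt : float
        Adaptation time constant tau_a, seconds.
    alpha_adapt : float
        Adaptation strength alpha, input units per (spikes/s).
    ca_amp : float
        Fluorescence increment per spike (dF/F units).
    tau_ca : float
        Indicator decay time constant, seconds.  The default reproduces the
        pre-clamp evoked decay constant of 2257 ms.
    noise_sd : float
        Additive Gaussian read noise SD (fluorescence units).
    stim_gain : float
        Input units delivered per unit of photostimulation laser power.
    f0 : float
        Resting fluorescence level (arbitrary units).
    """

    baseline_rate: float = 1.0
    f_max: float = 400.0
    theta0: float = 5.0
    slope: float = 1.5
    tau_adapt: float = 15.0
    alpha_adapt: float = 0.5
    ca_amp: float = 0.019
    tau_ca: float = PRE_CLAMP_TAU_E_MS / 1000.0
    noise_sd: float = 0.058
    stim_gain: float = 1.0
    f0: float = 1.0

    def __post_init__(self) -> None:
        if self.f_max <= 0:
            raise ValueError("f_max must be > 0")
        if self.tau_adapt <= 0:
            raise ValueError("tau_adapt must be > 0")
        if self.tau_ca <= 0:
            raise ValueError("tau_ca must be > 0")
        if self.alpha_adapt < 0:
            raise ValueError("alpha_adapt must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.baseline_rate < 0:
            raise ValueError("baseline_rate must be >= 0")
        if self.slope <= 0:
            raise ValueError("slope must be > 0")


@dataclass
class NeuronState:
    """Dynamic state: rate, adaptation, IP attenuation, synapses.

    ``ip_atten`` multiplies the per-spike fluorescence amplitude and
    ``ip_tau_factor`` the indicator decay constant; both relax toward 1
    after a clamp.  ``eligibility`` is the BTSP synaptic tag vector.
    """

    rate: float = 0.0
    adapt_var: float = 0.0
    ip_atten: float = 1.0
    ip_tau_factor: float = 1.0
    weights: np.ndarray = field(default_factory=lambda: np.ones(1))
    eligibility: np.ndarray = field(default_factory=lambda: np.zeros(1))

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.eligibility = np.asarray(self.eligibility, dtype=float)
        if self.weights.shape != self.eligibility.shape:
            raise ValueError("weights and eligibility must have equal shape")
        if not (0.0 <= self.ip_atten <= 1.0):
            raise ValueError("ip_atten must lie in [0, 1]")
        if self.ip_tau_factor <= 0:
            raise ValueError("ip_tau_factor must be > 0")
        if np.any(self.eligibility < 0):
            raise ValueError("eligibility must be >= 0 elementwise")
        if self.adapt_var < 0:
            raise ValueError("adapt_var must be >= 0")


@dataclass
class PopulationModel:
    """A set of neurons plus a directed ROI-to-ROI coupling matrix."""

    params: list[NeuronParams]
    states: list[NeuronState]
    coupling: np.ndarray | None = None
    clamped_index: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        n = len(self.params)
        if len(self.states) != n:
            raise ValueError("params and states must have equal length")
        if self.coupling is not None:
            self.coupling = np.asarray(self.coupling, dtype=float)
            if self.coupling.shape != (n, n):
                raise ValueError("coupling must be square of size n_neurons")
            if np.any(np.diag(self.coupling) != 0):
                raise ValueError("coupling diagonal must be zero")
        if self.clamped_index is not None and not (0 <= self.clamped_index < n):
            raise ValueError("clamped_index out of range")

    @property
    def n(self) -> int:
        return len(self.params)


@dataclass
class TraceSet:
    """Multi-ROI fluorescence time series; ``data`` is ROI x time."""

    data: np.ndarray
    fs: float
    roi_ids: list[str]

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.fs <= 0:
            raise ValueError("fs must be > 0")
        if self.data.shape[0] != len(self.roi_ids):
            raise ValueError("row count must equal number of roi_ids")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("traces must not contain missing samples")

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.data.shape[1]) / self.fs

    @property
    def duration(self) -> float:
        return self.data.shape[1] / self.fs

    def roi(self, index: int) -> np.ndarray:
        return self.data[index]


@dataclass
class SpikeTrains:
    """Per-ROI sorted spike times in seconds (latent behind a TraceSet)."""

    trains: list[np.ndarray]
    duration: float

    def __post_init__(self) -> None:
        self.trains = [np.asarray(t, dtype=float) for t in self.trains]
        for t in self.trains:
            if t.size and (np.any(np.diff(t) < 0) or t[0] < 0 or t[-1] > self.duration + 1e-9):
                raise ValueError("spike times must be sorted within [0, duration]")

    def counts(self) -> np.ndarray:
        return np.array([t.size for t in self.trains])


@dataclass(frozen=True)
class IPConfig:
    """Intrinsic-plasticity induction/recovery parameters.

    Induction depth scales linearly with the clamp level k relative to
    ``k_ref`` = 5 (so k = 3 produces 60% of the reference effect) and
    saturates with clamp duration with constant ``tau_induction``; the
    depth relaxes exponentially toward zero with ``tau_rec``.  Values at
    k = 1 are an uncalibrated interpolation.
    """

    tau_rec: float = DEFAULT_TAU_REC_S
    tau_induction: float = 80.0
    k_ref: float = 5.0
    depth_amp_ref: float = DEPTH_AMP_REF
    depth_tau_ref: float = DEPTH_TAU_REF
    max_depth: float = 0.95
    ref_duration: float = 200.0

    def depth(self, k: float, duration: float) -> tuple[float, float]:
        """Induction depths (amplitude, tau) at clamp end for level k."""
        if k < 0:
            raise ValueError("clamp level k must be >= 0")
        if duration < 0:
            raise ValueError("clamp duration must be >= 0")
        g = (1.0 - math.exp(-duration / self.tau_induction)) / (
            1.0 - math.exp(-self.ref_duration / self.tau_induction)
        )
        s = k / self.k_ref
        d_amp = min(self.depth_amp_ref * s * g, self.max_depth)
        d_tau = min(self.depth_tau_ref * s * g, self.max_depth)
        return d_amp, d_tau


@dataclass(frozen=True)
class BTSPConfig:
    """BTSP rule parameters: seconds-scale eligibility decay and learning rate.

    ``plateau_rate_threshold`` is the recent-rate level above which a
    dendritic plateau is considered triggered (free parameter; the
    underlying biophysical condition is not quantified).
    """

    tau_elig: float = 4.0
    eta: float = 0.05
    plateau_rate_threshold: float = 20.0

    def __post_init__(self) -> None:
        if self.tau_elig <= 0:
            raise ValueError("tau_elig must be > 0")
        if self.eta < 0:
            raise ValueError("eta must be >= 0")


def apply_ip_update(
    state: NeuronState,
    params: NeuronParams,
    clamp_level_k: float,
    clamp_duration: float,
    cfg: IPConfig | None = None,
) -> NeuronState:
    """Return a new state with IP induced by a clamp of level k and duration.

    Stronger / longer clamps produce deeper attenuation of both the evoked
    amplitude (``ip_atten``) and decay constant (``ip_tau_factor``).  If the
    neuron is already attenuated, the deeper of the existing and induced
    depths is kept (induction does not relieve prior attenuation).
    A zero-duration clamp leaves the state unchanged.
    """
    cfg = cfg or IPConfig()
    d_amp, d_tau = cfg.depth(clamp_level_k, clamp_duration)
    if clamp_duration == 0:
        return dataclasses.replace(state)
    new_amp = 1.0 - max(1.0 - state.ip_atten, d_amp)
    new_tau = 1.0 - max(1.0 - state.ip_tau_factor, d_tau)
    return dataclasses.replace(state, ip_atten=new_amp, ip_tau_factor=new_tau)


def relax_ip(state: NeuronState, elapsed: float, cfg: IPConfig | None = None) -> NeuronState:
    """Exponentially relax IP attenuation toward 1 over ``elapsed`` seconds."""
    cfg = cfg or IPConfig()
    if elapsed < 0:
        raise ValueError("elapsed must be >= 0")
    decay = math.exp(-elapsed / cfg.tau_rec)
    return dataclasses.replace(
        state,
        ip_atten=1.0 - (1.0 - state.ip_atten) * decay,
        ip_tau_factor=1.0 - (1.0 - state.ip_tau_factor) * decay,
    )


def post_clamp_params(
    params: NeuronParams,
    k: float = 5.0,
    clamp_duration: float = 200.0,
    elapsed: float = PROBE_DELAY_S,
    cfg: IPConfig | None = None,
) -> NeuronParams:
    """Effective indicator kinetics at ``elapsed`` seconds after a clamp.

    Applies the IP induction depth for (k, duration), relaxes it for
    ``elapsed`` seconds, and folds the resulting attenuation into the
    calcium kernel: with the defaults (k = 5, 200 s clamp, +180 s) the
    evoked amplitude is scaled by 0.82 and the decay constant from
    2257 ms to 1850 ms.
    """
    cfg = cfg or IPConfig()
    state = apply_ip_update(NeuronState(), params, k, clamp_duration, cfg)
    state = relax_ip(state, elapsed, cfg)
    return dataclasses.replace(
        params,
        ca_amp=params.ca_amp * state.ip_atten,
        tau_ca=params.tau_ca * state.ip_tau_factor,
    )


def btsp_update(
    state: NeuronState,
    presyn_activity: np.ndarray,
    plateau: bool,
    reward: float,
    dt: float,
    cfg: BTSPConfig | None = None,
) -> NeuronState:
    """One BTSP step: decay/refresh the eligibility trace, convert on reward.

    The eligibility trace decays with ``tau_elig`` (seconds) and is
    incremented by the presynaptic activity whenever a plateau is present;
    the instructive signal converts the trace into weight change,
    ``w += eta * reward * eligibility``.  With ``reward == 0`` weights are
    untouched.
    """
    cfg = cfg or BTSPConfig()
    if dt <= 0:
        raise ValueError("dt must be > 0")
    presyn = np.asarray(presyn_activity, dtype=float)
    if presyn.shape != state.eligibility.shape:
        raise ValueError("presyn_activity must match eligibility shape")
    elig = state.eligibility * math.exp(-dt / cfg.tau_elig)
    if plateau:
        elig = elig + presyn
    weights = state.weights
    if reward != 0.0:
        weights = weights + cfg.eta * reward * elig
    return dataclasses.replace(state, weights=weights, eligibility=elig)


def synaptic_scaling_step(
    model: PopulationModel,
    target_rates: Sequence[float],
    epsilon: float,
) -> PopulationModel:
    """Multiplicative homeostatic scaling toward per-neuron target rates.

    Each neuron's whole weight vector is multiplied by
    ``(target / recent_rate) ** epsilon`` (recent rate is ``state.rate``),
    preserving within-neuron weight ratios exactly.  Neurons whose recent
    rate is zero are skipped with a warning.
    """
    if not (0 < epsilon <= 1):
        raise ValueError("epsilon must lie in (0, 1]")
    targets = np.asarray(target_rates, dtype=float)
    if targets.shape != (model.n,):
        raise ValueError("target_rates must have one entry per neuron")
    if np.any(targets <= 0):
        raise ValueError("target_rates must be > 0")
    new_states = []
    for state, target in zip(model.states, targets):
        if state.rate <= 0:
            warnings.warn("recent mean rate is zero; synaptic scaling skipped")
            new_states.append(dataclasses.replace(state))
            continue
        factor = (target / state.rate) ** epsilon
        new_states.append(dataclasses.replace(state, weights=state.weights * factor))
    return dataclasses.replace(model, states=new_states)


class PopulationSim:
    """Frame-locked stepper for a population at imaging resolution.

    The controller modules drive this one frame at a time; ``step`` takes
    the per-ROI photostimulation input for the frame (already in input
    units) and returns the sampled fluorescence vector.
    """

    def __init__(
        self,
        model: PopulationModel,
        fs: float = 30.0,
        seed: int | None = None,
        ip_relax: bool = False,
        ip_cfg: IPConfig | None = None,
        record_spikes: bool = True,
    ) -> None:
        if fs <= 0:
            raise ValueError("fs must be > 0")
        self.model = model
        self.fs = float(fs)
        self.dt = 1.0 / self.fs
        self.rng = np.random.default_rng(model.seed if seed is None else seed)
        p = model.params
        self.n = model.n
        self._baseline = np.array([q.baseline_rate for q in p])
        self._f_max = np.array([q.f_max for q in p])
        self._theta0 = np.array([q.theta0 for q in p])
        self._slope = np.array([q.slope for q in p])
        self._tau_adapt = np.array([q.tau_adapt for q in p])
        self._alpha = np.array([q.alpha_adapt for q in p])
        self._ca_amp = np.array([q.ca_amp for q in p])
        self._tau_ca = np.array([q.tau_ca for q in p])
        self._noise_sd = np.array([q.noise_sd for q in p])
        self._f0 = np.array([q.f0 for q in p])
        self.a = np.array([s.adapt_var for s in model.states], dtype=float)
        self.ip_atten = np.array([s.ip_atten for s in model.states], dtype=float)
        self.ip_tau = np.array([s.ip_tau_factor for s in model.states], dtype=float)
        self.coupling = None if model.coupling is None else np.asarray(model.coupling)
        self.c = np.zeros(self.n)
        self.prev_rates = np.zeros(self.n)
        self._frame = 0  # integer clock; t = _frame / fs avoids drift
        self.t = 0.0
        self._ip_relax = ip_relax
        self._ip_cfg = ip_cfg or IPConfig()
        self._record_spikes = record_spikes
        self.spikes: list[list[float]] = [[] for _ in range(self.n)]
        # warm start: steady baseline calcium so traces begin near rest level
        self.c[:] = self._baseline * self._ca_amp * self._tau_ca
        self.rates = self._baseline.copy()
        self.prev_rates = self.rates.copy()
        self._rate_accum = np.zeros(self.n)
        self._rate_frames = 0

    def set_ip(self, roi: int, ip_atten: float, ip_tau_factor: float) -> None:
        self.ip_atten[roi] = ip_atten
        self.ip_tau[roi] = ip_tau_factor

    def mean_rates(self, reset: bool = True) -> np.ndarray:
        """Mean firing rate per neuron since the last reset."""
        out = self._rate_accum / max(self._rate_frames, 1)
        if reset:
            self._rate_accum[:] = 0.0
            self._rate_frames = 0
        return out

    def step(
        self,
        stim: np.ndarray | None = None,
        forced_spike_times: Iterable[tuple[int, float]] | None = None,
    ) -> np.ndarray:
        """Advance one frame; return the fluorescence sample at frame end."""
        dt = self.dt
        if stim is None:
            drive = np.zeros(self.n)
        else:
            drive = np.asarray(stim, dtype=float)
        if self.coupling is not None:
            drive = drive + self.coupling @ self.prev_rates
        x = (drive - self._theta0 - self.a) / self._slope
        rest_sig = _sigmoid((-self._theta0 - self.a) / self._slope)
        r = np.clip(self._baseline + self._f_max * (_sigmoid(x) - rest_sig), 0.0, self._f_max)
        counts = self.rng.poisson(r * dt)
        tau_eff = self._tau_ca * self.ip_tau
        amp_eff = self._ca_amp * self.ip_atten
        self.c *= np.exp(-dt / tau_eff)
        t_end = self.t + dt
        for i in np.flatnonzero(counts):
            u = np.sort(self.rng.random(counts[i]))
            self.c[i] += amp_eff[i] * np.exp(-(1.0 - u) * dt / tau_eff[i]).sum()
            if self._record_spikes:
                self.spikes[i].extend(self.t + u * dt)
        if forced_spike_times is not None:
            for roi, s in forced_spike_times:
                if not (self.t - 1e-12 <= s <= t_end + 1e-12):
                    raise ValueError("forced spike outside current frame")
                self.c[roi] += amp_eff[roi] * math.exp(-(t_end - s) / tau_eff[roi])
                if self._record_spikes:
                    self.spikes[roi].append(s)
        fluor = self._f0 + self.c + np.where(
            self._noise_sd > 0, self._noise_sd * self.rng.standard_normal(self.n), 0.0
        )
        self.a += dt * (self._alpha * r - self.a) / self._tau_adapt
        np.maximum(self.a, 0.0, out=self.a)
        if self._ip_relax:
            decay = math.exp(-dt / self._ip_cfg.tau_rec)
            self.ip_atten = 1.0 - (1.0 - self.ip_atten) * decay
            self.ip_tau = 1.0 - (1.0 - self.ip_tau) * decay
        self.prev_rates = r
        self.rates = r
        self._rate_accum += r
        self._rate_frames += 1
        self._frame += 1
        self.t = self._frame / self.fs
        return fluor

    def spike_trains(self) -> SpikeTrains:
        return SpikeTrains(
            trains=[np.sort(np.asarray(s)) for s in self.spikes], duration=self.t
        )

    def writeback(self) -> None:
        """Copy dynamic variables back into the model's NeuronStates."""
        for i, s in enumerate(self.model.states):
            s.rate = float(self.rates[i])
            s.adapt_var = float(self.a[i])
            s.ip_atten = float(self.ip_atten[i])
            s.ip_tau_factor = float(self.ip_tau[i])


def simulate_population(
    model: PopulationModel,
    stim: np.ndarray | None,
    duration: float,
    seed: int,
    fs: float = 30.0,
    forced_spikes: Sequence[tuple[int, float]] | None = None,
) -> tuple[TraceSet, SpikeTrains]:
    """Simulate the population under a fixed stimulation schedule.

    Parameters
    ----------
    stim : array of shape (n_roi, n_frames) or None
        Per-ROI input (input units) per frame; None means no stimulation.
    forced_spikes : sequence of (roi_index, time_s)
        Deterministic spikes injected on top of the Poisson process.

    Identical (model, stim, seed) produce bit-identical output.
    """
    if duration <= 0:
        raise ValueError("duration must be > 0")
    n_frames = int(round(duration * fs))
    if stim is not None:
        stim = np.asarray(stim, dtype=float)
        if not np.all(np.isfinite(stim)):
            raise ValueError("stimulus contains non-finite values")
        if stim.shape != (model.n, n_frames):
            raise ValueError(
                f"stim must have shape ({model.n}, {n_frames}), got {stim.shape}"
            )
    forced_by_frame: dict[int, list[tuple[int, float]]] = {}
    if forced_spikes:
        for roi, s in forced_spikes:
            k = min(int(s * fs), n_frames - 1)
            forced_by_frame.setdefault(k, []).append((roi, s))
    sim = PopulationSim(model, fs=fs, seed=seed)
    data = np.empty((model.n, n_frames))
    for k in range(n_frames):
        data[:, k] = sim.step(
            None if stim is None else stim[:, k], forced_by_frame.get(k)
        )
    sim.writeback()
    roi_ids = [f"roi{i:02d}" for i in range(model.n)]
    return TraceSet(data=data, fs=fs, roi_ids=roi_ids), sim.spike_trains()


def default_population(
    n_roi: int = 1,
    coupling: np.ndarray | None = None,
    seed: int = 0,
    params: NeuronParams | Sequence[NeuronParams] | None = None,
    clamped_index: int | None = None,
    n_synapses: int = 1,
) -> PopulationModel:
    """Build a population of identical default neurons (convenience)."""
    if params is None:
        plist = [NeuronParams() for _ in range(n_roi)]
    elif isinstance(params, NeuronParams):
        plist = [params] * n_roi
    else:
        plist = list(params)
    states = [
        NeuronState(
            rate=p.baseline_rate,
            adapt_var=p.alpha_adapt * p.baseline_rate,  # rest fixed point
            weights=np.ones(n_synapses),
            eligibility=np.zeros(n_synapses),
        )
        for p in plist
    ]
    return PopulationModel(
        params=plist, states=states, coupling=coupling, clamped_index=clamped_index, seed=seed
    )
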