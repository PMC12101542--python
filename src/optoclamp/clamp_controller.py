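"""Closed-loop optical clamp and open-loop probe protocol.

The optical clamp holds a neuron's somatic calcium at a target level
``A_CL = mean + k_sd * SD`` of its baseline fluorescence: at each imaging
frame (30 Hz), if the previous fluorescence sample is below the target and
the lockout has elapsed, a photostimulation pulse (default 50 ms) is
delivered, for a preset interval ``T_CL``.  The open-loop probe delivers a
fixed schedule of single pulses (default 5 repetitions, 15 s apart) used to
measure the evoked transient before and at set delays after a clamp.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synth_neuro import (
    IPConfig,
    PopulationModel,
    PopulationSim,
    TraceSet,
    apply_ip_update,
)

__all__ = [
    "ClampConfig",
    "OpenLoopProtocol",
    "PulseLog",
    "ClampRun",
    "SessionBundle",
    "compute_target_level",
    "run_closed_loop",
    "run_open_loop",
    "run_session_protocol",
    "replay_controller",
]


@dataclass(frozen=True)
class ClampConfig:
    """Closed-loop controller settings.

    ``k_sd`` sets the target level in baseline-SD units; ``t_cl`` the clamp
    duration (s); pulses are ``pulse_width_ms`` long at ``pulse_power``
    (arbitrary laser-power units); ``lockout_ms`` is the minimum inter-pulse
    onset interval and ``baseline_window_s`` the window used to estimate the
    baseline mean and SD.
    """

    k_sd: float = 3.0
    t_cl: float = 266.0
    pulse_width_ms: float = 50.0
    pulse_power: float = 10.0
    lockout_ms: float = 100.0
    baseline_window_s: float = 60.0

    def __post_init__(self) -> None:
        if self.k_sd < 0:
            raise ValueError("k_sd must be >= 0")
        if self.t_cl <= 0:
            raise ValueError("t_cl must be > 0")
        if self.pulse_width_ms <= 0:
            raise ValueError("pulse_width_ms must be > 0")
        if self.lockout_ms < self.pulse_width_ms:
            raise ValueError("lockout_ms must be >= pulse_width_ms")
        if self.baseline_window_s <= 0:
            raise ValueError("baseline_window_s must be > 0")


@dataclass(frozen=True)
class OpenLoopProtocol:
    """Open-loop probe schedule: n_reps pulses at fixed spacing, with
    post-clamp probe onsets at the given offsets after clamp end."""

    n_reps: int = 5
    spacing_s: float = 15.0
    post_offsets_s: tuple[float, ...] = (180.0, 480.0)
    lead_in_s: float = 15.0

    def __post_init__(self) -> None:
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        if self.spacing_s <= 0:
            raise ValueError("spacing_s must be > 0")

    @property
    def probe_duration(self) -> float:
        return (self.n_reps - 1) * self.spacing_s

    def onsets(self, start: float = 0.0) -> np.ndarray:
        return start + np.arange(self.n_reps) * self.spacing_s


@dataclass
class PulseLog:
    """Timestamped photostimulation events for one run."""

    events: pd.DataFrame  # columns: roi_id, onset_s, width_ms, power
    mode: str = "closed_loop"

    def __post_init__(self) -> None:
        required = {"roi_id", "onset_s", "width_ms", "power"}
        if not required.issubset(self.events.columns):
            raise ValueError(f"events must have columns {sorted(required)}")
        if self.mode not in ("closed_loop", "open_loop"):
            raise ValueError("mode must be closed_loop or open_loop")
        for _, grp in self.events.groupby("roi_id"):
            if np.any(np.diff(grp["onset_s"].to_numpy()) < 0):
                raise ValueError("onsets must be sorted per ROI")

    @classmethod
    def from_onsets(
        cls, onsets: np.ndarray, roi_id: int, width_ms: float, power: float, mode: str
    ) -> "PulseLog":
        df = pd.DataFrame(
            {
                "roi_id": np.full(len(onsets), roi_id, dtype=int),
                "onset_s": np.asarray(onsets, dtype=float),
                "width_ms": width_ms,
                "power": power,
            }
        )
        return cls(events=df, mode=mode)

    @property
    def n_pulses(self) -> int:
        return len(self.events)

    def onsets(self, roi_id: int | None = None) -> np.ndarray:
        df = self.events
        if roi_id is not None:
            df = df[df["roi_id"] == roi_id]
        return df["onset_s"].to_numpy()

    def rate_per_min(self, duration_s: float) -> float:
        """Pulse rate in pulses per minute over ``duration_s``."""
        if duration_s <= 0:
            raise ValueError("duration_s must be > 0")
        return self.n_pulses / duration_s * 60.0

    def check_lockout(self, lockout_ms: float) -> bool:
        for _, grp in self.events.groupby("roi_id"):
            isis = np.diff(grp["onset_s"].to_numpy())
            if np.any(isis < lockout_ms / 1000.0 - 1e-9):
                return False
        return True


@dataclass
class ClampRun:
    """Traces and pulses from one controller run, plus controller metadata."""

    traces: TraceSet
    pulses: PulseLog
    a_cl: float | None
    baseline_mean: float | None
    baseline_sd: float | None
    target_roi: int
    clamp_window: tuple[float, float] | None = None
    seed: int | None = None


@dataclass
class SessionBundle:
    """Full session: pre-probe, clamp, and post-probes on one session clock."""

    traces: TraceSet
    pre_pulses: PulseLog
    clamp_pulses: PulseLog
    post_pulses: dict[float, PulseLog]  # keyed by offset after clamp end
    segments: dict[str, tuple[float, float]]
    a_cl: float
    target_roi: int
    seed: int


def compute_target_level(baseline: np.ndarray, k_sd: float) -> float:
    """Target level A_CL = mean + k_sd * SD of the baseline window.

    SD is the population standard deviation of the baseline samples.
    """
    baseline = np.asarray(baseline, dtype=float)
    if baseline.size == 0:
        raise ValueError("baseline window is empty")
    if not np.all(np.isfinite(baseline)):
        raise ValueError("baseline contains non-finite values")
    if k_sd < 0:
        raise ValueError("k_sd must be >= 0")
    return float(baseline.mean() + k_sd * baseline.std(ddof=0))


def _pulse_frames(width_ms: float, fs: float) -> int:
    return max(1, int(round(width_ms / 1000.0 * fs)))


def _closed_loop_segment(
    sim: PopulationSim,
    target_roi: int,
    a_cl: float,
    cfg: ClampConfig,
    n_frames: int,
    data: np.ndarray,
    col0: int,
    last_sample: float,
) -> list[float]:
    """Drive ``sim`` for ``n_frames`` under closed-loop control.

    The decision for frame k uses the sample of frame k-1 (one-frame
    controller latency).  Returns pulse onset times on the session clock.
    """
    pw = _pulse_frames(cfg.pulse_width_ms, sim.fs)
    lockout = cfg.lockout_ms / 1000.0
    input_amp = sim.model.params[target_roi].stim_gain * cfg.pulse_power
    onsets: list[float] = []
    stim_left = 0
    last_onset = -np.inf
    stim = np.zeros(sim.n)
    for k in range(n_frames):
        if last_sample < a_cl and sim.t - last_onset >= lockout - 1e-9:
            onsets.append(sim.t)
            last_onset = sim.t
            stim_left = pw
        stim[target_roi] = input_amp if stim_left > 0 else 0.0
        if stim_left > 0:
            stim_left -= 1
        fluor = sim.step(stim)
        data[:, col0 + k] = fluor
        last_sample = fluor[target_roi]
    return onsets


def _open_loop_segment(
    sim: PopulationSim,
    target_roi: int,
    cfg: ClampConfig,
    onsets_rel: np.ndarray,
    n_frames: int,
    data: np.ndarray,
    col0: int,
) -> list[float]:
    """Deliver scheduled pulses regardless of fluorescence."""
    pw = _pulse_frames(cfg.pulse_width_ms, sim.fs)
    input_amp = sim.model.params[target_roi].stim_gain * cfg.pulse_power
    onset_frames = {int(round(t * sim.fs)) for t in onsets_rel}
    onsets: list[float] = []
    stim_left = 0
    stim = np.zeros(sim.n)
    for k in range(n_frames):
        if k in onset_frames:
            onsets.append(sim.t)
            stim_left = pw
        stim[target_roi] = input_amp if stim_left > 0 else 0.0
        if stim_left > 0:
            stim_left -= 1
        data[:, col0 + k] = sim.step(stim)
    return onsets


def _quiet_segment(sim: PopulationSim, n_frames: int, data: np.ndarray, col0: int) -> None:
    for k in range(n_frames):
        data[:, col0 + k] = sim.step(None)


def run_closed_loop(
    model: PopulationModel,
    target_roi: int,
    config: ClampConfig,
    seed: int,
    fs: float = 30.0,
) -> ClampRun:
    """Estimate the baseline, then clamp ``target_roi`` for ``t_cl`` seconds.

    Returns the full traces (baseline window followed by the clamp), the
    pulse log, and the computed target level.  A target below the resting
    fluorescence produces a degenerate always-above run with zero pulses
    (warned).
    """
    if not (0 <= target_roi < model.n):
        raise ValueError("target_roi out of range")
    sim = PopulationSim(model, fs=fs, seed=seed)
    nb = int(round(config.baseline_window_s * fs))
    nc = int(round(config.t_cl * fs))
    data = np.empty((model.n, nb + nc))
    _quiet_segment(sim, nb, data, 0)
    baseline = data[target_roi, :nb]
    a_cl = compute_target_level(baseline, config.k_sd)
    if a_cl <= baseline.min():
        warnings.warn("A_CL is below the resting fluorescence range; clamp is degenerate")
    onsets = _closed_loop_segment(
        sim, target_roi, a_cl, config, nc, data, nb, baseline[-1]
    )
    sim.writeback()
    traces = TraceSet(data=data, fs=fs, roi_ids=[f"roi{i:02d}" for i in range(model.n)])
    pulses = PulseLog.from_onsets(
        np.asarray(onsets), target_roi, config.pulse_width_ms, config.pulse_power, "closed_loop"
    )
    return ClampRun(
        traces=traces,
        pulses=pulses,
        a_cl=a_cl,
        baseline_mean=float(baseline.mean()),
        baseline_sd=float(baseline.std(ddof=0)),
        target_roi=target_roi,
        clamp_window=(nb / fs, (nb + nc) / fs),
        seed=seed,
    )


def run_open_loop(
    model: PopulationModel,
    target_roi: int,
    protocol: OpenLoopProtocol,
    config: ClampConfig,
    seed: int = 0,
    fs: float = 30.0,
    tail_s: float = 12.0,
) -> ClampRun:
    """Deliver ``n_reps`` identical pulses at fixed spacing (no feedback)."""
    if not (0 <= target_roi < model.n):
        raise ValueError("target_roi out of range")
    tau = model.params[target_roi].tau_ca
    if protocol.spacing_s < 4.0 * tau:
        warnings.warn("probe spacing is shorter than the evoked transient; events overlap")
    sim = PopulationSim(model, fs=fs, seed=seed)
    total = protocol.lead_in_s + protocol.probe_duration + tail_s
    n_frames = int(round(total * fs))
    data = np.empty((model.n, n_frames))
    onsets_rel = protocol.onsets(protocol.lead_in_s)
    onsets = _open_loop_segment(sim, target_roi, config, onsets_rel, n_frames, data, 0)
    sim.writeback()
    traces = TraceSet(data=data, fs=fs, roi_ids=[f"roi{i:02d}" for i in range(model.n)])
    pulses = PulseLog.from_onsets(
        np.asarray(onsets), target_roi, config.pulse_width_ms, config.pulse_power, "open_loop"
    )
    return ClampRun(
        traces=traces,
        pulses=pulses,
        a_cl=None,
        baseline_mean=None,
        baseline_sd=None,
        target_roi=target_roi,
        seed=seed,
    )


def run_session_protocol(
    model: PopulationModel,
    target_roi: int,
    config: ClampConfig,
    protocol: OpenLoopProtocol,
    seed: int,
    fs: float = 30.0,
    ip_cfg: IPConfig | None = None,
    ip_enabled: bool = True,
) -> SessionBundle:
    """Full session: baseline, pre-probe, clamp (IP induced), post-probes.

    All segments run on one continuous session clock and one simulator, so
    calcium, adaptation and IP recovery evolve through the gaps.  IP is
    induced at clamp end via :func:`apply_ip_update` and relaxes
    exponentially during the post-clamp period.
    """
    if not (0 <= target_roi < model.n):
        raise ValueError("target_roi out of range")
    ip_cfg = ip_cfg or IPConfig()
    probe_len = protocol.probe_duration + 12.0  # tail to capture the last transient
    post_offsets = sorted(protocol.post_offsets_s)
    if any(
        b - a < probe_len for a, b in zip(post_offsets, post_offsets[1:])
    ):
        raise ValueError("post-probe segments overlap")
    if post_offsets and post_offsets[0] < 0:
        raise ValueError("post-probe offsets must be >= 0")

    # ---- session timeline -------------------------------------------------
    t_base = (0.0, config.baseline_window_s)
    t_pre = (t_base[1], t_base[1] + probe_len)
    t_clamp = (t_pre[1], t_pre[1] + config.t_cl)
    clamp_end = t_clamp[1]
    seg_bounds: dict[str, tuple[float, float]] = {
        "baseline": t_base,
        "pre_probe": t_pre,
        "clamp": t_clamp,
    }
    for off in post_offsets:
        seg_bounds[f"post_{int(off)}"] = (clamp_end + off, clamp_end + off + probe_len)
    total = clamp_end + post_offsets[-1] + probe_len if post_offsets else clamp_end
    n_total = int(round(total * fs))

    sim = PopulationSim(model, fs=fs, seed=seed, ip_relax=True, ip_cfg=ip_cfg)
    data = np.empty((model.n, n_total))

    def frames(t0: float, t1: float) -> tuple[int, int]:
        return int(round(t0 * fs)), int(round(t1 * fs))

    # baseline
    b0, b1 = frames(*t_base)
    _quiet_segment(sim, b1 - b0, data, b0)
    baseline = data[target_roi, b0:b1]
    a_cl = compute_target_level(baseline, config.k_sd)

    # pre probe
    p0, p1 = frames(*t_pre)
    pre_onsets = _open_loop_segment(
        sim, target_roi, config, protocol.onsets(0.0), p1 - p0, data, p0
    )

    # clamp
    c0, c1 = frames(*t_clamp)
    clamp_onsets = _closed_loop_segment(
        sim, target_roi, a_cl, config, c1 - c0, data, c0, data[target_roi, c0 - 1]
    )

    # IP induction at clamp end
    if ip_enabled:
        st = apply_ip_update(
            model.states[target_roi],
            model.params[target_roi],
            config.k_sd,
            config.t_cl,
            ip_cfg,
        )
        sim.set_ip(target_roi, st.ip_atten, st.ip_tau_factor)

    # gaps and post probes
    post_logs: dict[float, list[float]] = {}
    cursor = c1
    for off in post_offsets:
        g0, g1 = frames(clamp_end, clamp_end + off)
        seg0, seg1 = frames(clamp_end + off, clamp_end + off + probe_len)
        _quiet_segment(sim, seg0 - cursor, data, cursor)
        post_logs[off] = _open_loop_segment(
            sim, target_roi, config, protocol.onsets(0.0), seg1 - seg0, data, seg0
        )
        cursor = seg1
    sim.writeback()

    traces = TraceSet(data=data, fs=fs, roi_ids=[f"roi{i:02d}" for i in range(model.n)])

    def log(onsets: list[float], mode: str) -> PulseLog:
        return PulseLog.from_onsets(
            np.asarray(onsets), target_roi, config.pulse_width_ms, config.pulse_power, mode
        )

    return SessionBundle(
        traces=traces,
        pre_pulses=log(pre_onsets, "open_loop"),
        clamp_pulses=log(clamp_onsets, "closed_loop"),
        post_pulses={off: log(v, "open_loop") for off, v in post_logs.items()},
        segments=seg_bounds,
        a_cl=a_cl,
        target_roi=target_roi,
        seed=seed,
    )


def replay_controller(
    traces: TraceSet,
    target_roi: int,
    config: ClampConfig,
    a_cl: float,
    clamp_window: tuple[float, float],
) -> PulseLog:
    """Re-run the trigger logic over a recorded trace.

    Because the controller's decision at frame k depends only on the sample
    at frame k-1 and its own pulse history, replaying it over the recorded
    fluorescence reproduces the original pulse log exactly.
    """
    fs = traces.fs
    trace = traces.roi(target_roi)
    k0 = int(round(clamp_window[0] * fs))
    k1 = int(round(clamp_window[1] * fs))
    if k0 < 1 or k1 > trace.size:
        raise ValueError("clamp window out of range (needs one frame of history)")
    lockout = config.lockout_ms / 1000.0
    onsets = []
    last_onset = -np.inf
    for k in range(k0, k1):
        t = k / fs
        if trace[k - 1] < a_cl and t - last_onset >= lockout - 1e-9:
            onsets.append(t)
            last_onset = t
    return PulseLog.from_onsets(
        np.asarray(onsets), target_roi, config.pulse_width_ms, config.pulse_power, "closed_loop"
    )
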