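"""One-dimensional BCI task: pair-difference decoder, trial engine, a
BTSP-learning agent, session metrics and across-session comparisons.

The decoder is a velocity integrator of the instantaneous difference
between the mean rates of a positive pair N+ and a negative pair N-:

    pos += gain * bin * (mean r[N+] - mean r[N-])

and the trial succeeds when the cursor position reaches the threshold T1
before the timeout.  The agent learns by reinforcement of its own rate
fluctuations: each neuron carries two nonnegative eligibility traces (one
for upward, one for downward rate deviations, each decaying over seconds)
and a scalar reward at target attainment converts them into opposing
modulation weights via the BTSP rule, so neurons whose fluctuations drove
rewarded cursor movement acquire a matching firing-rate bias with no
built-in knowledge of the decoder.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .synth_neuro import BTSPConfig, NeuronState, btsp_update

__all__ = [
    "EnsembleSpec",
    "TrialRecord",
    "SessionMetrics",
    "BCIAgent",
    "decode_step",
    "run_trial",
    "run_session",
    "across_session_comparison",
    "simulate_drift",
    "classify_learner",
]

STRONG_LEARNER_THRESHOLD = 0.60


@dataclass(frozen=True)
class EnsembleSpec:
    """Decoder definition: the N+/N- pairs, threshold T1 and trial timing."""

    n_plus: tuple[int, int] = (0, 1)
    n_minus: tuple[int, int] = (2, 3)
    t1: float = 1.0
    gain: float = 0.08
    timeout: float = 30.0
    bin_s: float = 0.1
    start_range: tuple[float, float] = (0.2, 0.8)  # fractions of t1

    def __post_init__(self) -> None:
        idx = (*self.n_plus, *self.n_minus)
        if len(set(idx)) != 4:
            raise ValueError("N+ and N- must name four distinct neurons")
        if self.t1 <= 0:
            raise ValueError("t1 must be > 0")
        if self.timeout <= 0:
            raise ValueError("timeout must be > 0")
        if self.bin_s <= 0:
            raise ValueError("bin_s must be > 0")


@dataclass
class TrialRecord:
    """Outcome of one trial; ``tt`` is defined only on success."""

    success: bool
    tt: float
    cursor_path: np.ndarray
    start_pos: float

    def __post_init__(self) -> None:
        if self.success and math.isnan(self.tt):
            raise ValueError("successful trials must report a time-to-target")


@dataclass
class SessionMetrics:
    """Session summary; ``learner_class`` uses the 60% success criterion."""

    success_rate: float
    mean_tt: float
    sd_tt: float
    learner_class: str
    n_trials: int


def classify_learner(success_rate: float) -> str:
    """'strong' iff success_rate >= 0.60 (boundary counts as strong)."""
    if not (0.0 <= success_rate <= 1.0):
        raise ValueError("success_rate must lie in [0, 1]")
    return "strong" if success_rate >= STRONG_LEARNER_THRESHOLD else "weak"


def decode_step(rates: np.ndarray, spec: EnsembleSpec, pos: float) -> float:
    """One decoder update; pure function of the four ensemble rates."""
    rates = np.asarray(rates, dtype=float)
    if not np.all(np.isfinite(rates)):
        raise ValueError("rates must be finite")
    drive = rates[list(spec.n_plus)].mean() - rates[list(spec.n_minus)].mean()
    return pos + spec.gain * spec.bin_s * drive


class BCIAgent:
    """Population of rate neurons with a reinforcement-eligibility policy.

    Each neuron fires at ``baseline + (w_up - w_down) + noise`` (clipped to
    [0, f_max]); ``w_up``/``w_down`` are the two nonnegative BTSP weight
    channels, updated by :func:`optoclamp.synth_neuro.btsp_update` with the
    positive/negative parts of the neuron's recent rate deviation as
    presynaptic activity.  ``eta = 0`` gives a non-learning (null) agent.
    """

    def __init__(
        self,
        n_neurons: int = 4,
        baseline: float = 5.0,
        noise_sd: float = 2.5,
        f_max: float = 40.0,
        forget_tau_s: float | None = 1500.0,
        btsp: BTSPConfig | None = None,
        seed: int = 0,
    ) -> None:
        self.n = n_neurons
        self.baseline = np.full(n_neurons, float(baseline))
        self.noise_sd = float(noise_sd)
        self.f_max = float(f_max)
        self.forget_tau_s = forget_tau_s
        self.btsp = btsp or BTSPConfig(eta=0.05)
        self.rng = np.random.default_rng(seed)
        # weight/eligibility channel 0 = up-modulation, 1 = down-modulation
        self.states = [
            NeuronState(rate=baseline, weights=np.zeros(2), eligibility=np.zeros(2))
            for _ in range(n_neurons)
        ]

    @property
    def modulation(self) -> np.ndarray:
        return np.array([s.weights[0] - s.weights[1] for s in self.states])

    def sample_rates(self) -> tuple[np.ndarray, np.ndarray]:
        """Rates for one bin and the raw fluctuations that produced them."""
        noise = self.noise_sd * self.rng.standard_normal(self.n)
        rates = np.clip(self.baseline + self.modulation + noise, 0.0, self.f_max)
        return rates, noise

    def accumulate(self, deviations: np.ndarray, dt: float) -> None:
        """Tag each neuron's eligibility with its signed rate deviation.

        Learned modulation also leaks slowly (``forget_tau_s``, minutes):
        without continued reinforcement the bias relaxes, which bounds the
        weights instead of letting reinforcement run away to the rate
        ceiling.
        """
        leak = math.exp(-dt / self.forget_tau_s) if self.forget_tau_s else 1.0
        for i, s in enumerate(self.states):
            presyn = np.array([max(deviations[i], 0.0), max(-deviations[i], 0.0)])
            new = btsp_update(s, presyn, plateau=True, reward=0.0, dt=dt, cfg=self.btsp)
            new.weights = new.weights * leak
            self.states[i] = new

    def reinforce(self, reward: float, dt: float) -> None:
        """Convert current eligibility into weight change (instructive signal)."""
        zero = np.zeros(2)
        for i, s in enumerate(self.states):
            self.states[i] = btsp_update(s, zero, plateau=False, reward=reward, dt=dt, cfg=self.btsp)


def run_trial(agent: BCIAgent, spec: EnsembleSpec, rng: np.random.Generator) -> tuple[TrialRecord, np.ndarray]:
    """One trial: integrate the decoder on binned agent rates until target
    or timeout; reward 1 on success is routed to the BTSP rule.

    Returns the trial record plus the per-bin rate matrix (bins x neurons).
    """
    lo, hi = spec.start_range
    pos = float(rng.uniform(lo, hi) * spec.t1)
    start = pos
    path = [pos]
    rates_log = []
    n_bins = int(round(spec.timeout / spec.bin_s))
    success = False
    tt = math.nan
    for k in range(n_bins):
        rates, noise = agent.sample_rates()
        rates_log.append(rates)
        agent.accumulate(noise, spec.bin_s)
        pos = decode_step(rates, spec, pos)
        path.append(pos)
        if pos >= spec.t1:
            success = True
            tt = (k + 1) * spec.bin_s
            agent.reinforce(1.0, spec.bin_s)
            break
    rec = TrialRecord(success=success, tt=tt, cursor_path=np.asarray(path), start_pos=start)
    return rec, np.asarray(rates_log)


def run_session(
    agent: BCIAgent,
    spec: EnsembleSpec,
    n_trials: int,
    seed: int,
    inter_trial_s: float = 2.0,
) -> tuple[SessionMetrics, list[TrialRecord], pd.DataFrame]:
    """Sequential trials with plasticity carried across trials.

    Returns session metrics, the trial records, and a tidy per-bin rate
    table (columns time_s, n0..n3) on the session clock for rate analyses.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    rng = np.random.default_rng(seed)
    records: list[TrialRecord] = []
    rate_rows = []
    clock = 0.0
    for _ in range(n_trials):
        rec, rates = run_trial(agent, spec, rng)
        records.append(rec)
        times = clock + spec.bin_s * np.arange(len(rates))
        rate_rows.append(
            pd.DataFrame(
                {"time_s": times, **{f"n{i}": rates[:, i] for i in range(agent.n)}}
            )
        )
        clock = times[-1] + spec.bin_s + inter_trial_s if len(times) else clock + inter_trial_s
    successes = [r for r in records if r.success]
    sr = len(successes) / n_trials
    tts = np.array([r.tt for r in successes])
    metrics = SessionMetrics(
        success_rate=sr,
        mean_tt=float(tts.mean()) if tts.size else math.nan,
        sd_tt=float(tts.std(ddof=1)) if tts.size > 1 else math.nan,
        learner_class=classify_learner(sr),
        n_trials=n_trials,
    )
    return metrics, records, pd.concat(rate_rows, ignore_index=True)


def _window_means(rates: pd.DataFrame, window_s: float) -> pd.DataFrame:
    """Average each neuron column over complete, non-overlapping windows."""
    t = rates["time_s"].to_numpy()
    span = t[-1] - t[0]
    n_win = int(span // window_s)
    if n_win < 2:
        raise ValueError("record shorter than two windows")
    cols = [c for c in rates.columns if c != "time_s"]
    out = {c: [] for c in cols}
    for w in range(n_win):
        sel = (t - t[0] >= w * window_s) & (t - t[0] < (w + 1) * window_s)
        for c in cols:
            out[c].append(rates.loc[sel, c].mean())
    return pd.DataFrame(out)


def across_session_comparison(
    sessions: list[pd.DataFrame],
    window_s: float = 50.0,
) -> pd.DataFrame:
    """Compare per-neuron firing between the first and last session.

    Rates are averaged in non-overlapping windows (default 50 s) within
    each session; a two-sided Welch t-test per neuron compares the first
    and last sessions and the direction of change is reported.
    """
    if len(sessions) < 2:
        raise ValueError("need at least 2 sessions")
    first = _window_means(sessions[0], window_s)
    last = _window_means(sessions[-1], window_s)
    rows = []
    for col in first.columns:
        a = first[col].to_numpy()
        b = last[col].to_numpy()
        t, p = stats.ttest_ind(a, b, equal_var=False)
        diff = b.mean() - a.mean()
        rows.append(
            {
                "neuron": col,
                "mean_first": a.mean(),
                "mean_last": b.mean(),
                "diff": diff,
                "direction": "up" if diff > 0 else ("down" if diff < 0 else "flat"),
                "t": float(t),
                "p_value": float(p),
            }
        )
    return pd.DataFrame(rows)


def simulate_drift(
    baseline_rates: np.ndarray,
    n_days: int,
    seed: int,
    fluctuation_sd: float = 0.05,
    ss_enabled: bool = True,
    epsilon: float = 0.2,
    target_rates: np.ndarray | None = None,
    n_synapses: int = 5,
) -> pd.DataFrame:
    """Day-by-day baseline-rate drift from stochastic synaptic fluctuation
    tempered by synaptic scaling.

    Each neuron's rate is proportional to its summed synaptic weight.  Every
    day the weights are jittered multiplicatively (log-normal with SD
    ``fluctuation_sd``; activity-independent synaptic turnover) and, if SS
    is enabled, the whole weight vector is rescaled by
    ``(target / rate) ** epsilon`` toward the homeostatic target.  With both
    processes disabled the rates stay constant.  Returns a day x neuron
    rate table.
    """
    if n_days < 1:
        raise ValueError("n_days must be >= 1")
    base = np.asarray(baseline_rates, dtype=float)
    targets = base.copy() if target_rates is None else np.asarray(target_rates, dtype=float)
    rng = np.random.default_rng(seed)
    n = base.size
    weights = np.ones((n, n_synapses))
    rows = []
    for day in range(n_days):
        rates = base * weights.mean(axis=1)
        rows.append({"day": day, **{f"n{i}": rates[i] for i in range(n)}})
        if fluctuation_sd > 0:
            weights *= np.exp(fluctuation_sd * rng.standard_normal(weights.shape))
        if ss_enabled:
            rates_now = base * weights.mean(axis=1)
            factor = (targets / np.maximum(rates_now, 1e-12)) ** epsilon
            weights *= factor[:, None]
    return pd.DataFrame(rows)
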