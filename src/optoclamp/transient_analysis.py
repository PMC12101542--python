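"""Trace-derived statistics: dF/F, evoked-transient fits, ISI statistics,
pre/post comparisons and neighbor-ROI modulation detection.

The averaged pulse-locked transient is summarised by a mono-exponential
model ``F(t) = b + alpha_e * exp(-t / tau_e)`` fitted to the post-peak
decay by least squares; ``tau_e`` is the time at which the decay has
fallen to e^-1 (~37%) of its peak amplitude ``alpha_e``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .synth_neuro import TraceSet

__all__ = [
    "TransientFit",
    "ISIStats",
    "ModulationResult",
    "compute_dff",
    "extract_events",
    "extract_and_fit_transient",
    "fit_events_grouped",
    "compare_pre_post",
    "isi_statistics",
    "transient_duration_from_variances",
    "detect_modulated_rois",
]


@dataclass
class TransientFit:
    """Mono-exponential summary of an averaged evoked transient."""

    alpha_e: float
    tau_e_ms: float
    baseline: float
    r2: float
    n_events: int
    tau_e_se_ms: float = math.nan
    valid: bool = True

    def predict(self, t_s: np.ndarray) -> np.ndarray:
        """Model decay evaluated at times (s) after the peak."""
        t_s = np.asarray(t_s, dtype=float)
        return self.baseline + self.alpha_e * np.exp(-t_s / (self.tau_e_ms / 1000.0))

    def fraction_remaining(self, t_s: float) -> float:
        """Fraction of alpha_e remaining t_s seconds after the peak."""
        return math.exp(-t_s / (self.tau_e_ms / 1000.0))


@dataclass
class ISIStats:
    """Inter-stimulation-interval statistics over a clamp, in 60 s bins."""

    isis: np.ndarray
    bin_edges: np.ndarray
    per_bin_mean: np.ndarray
    per_bin_var: np.ndarray
    per_bin_count: np.ndarray
    steady_var: float
    transient_duration: float


@dataclass
class ModulationResult:
    """Per-ROI pulse-locked modulation during a clamp vs its own baseline."""

    table: pd.DataFrame  # roi, peak_delta, tau_delta_ms, p_value, significant
    n_significant: int
    n_total: int
    alpha_level: float


def compute_dff(
    trace: np.ndarray, fs: float, baseline_window: tuple[float, float]
) -> np.ndarray:
    """(F - F0) / F0 with F0 the mean over ``baseline_window`` (seconds)."""
    trace = np.asarray(trace, dtype=float)
    k0 = int(round(baseline_window[0] * fs))
    k1 = int(round(baseline_window[1] * fs))
    if k1 <= k0 or k0 < 0 or k1 > trace.size:
        raise ValueError("baseline window is empty or out of range")
    f0 = trace[k0:k1].mean()
    if f0 <= 0:
        raise ValueError("baseline fluorescence F0 must be > 0")
    return (trace - f0) / f0


def extract_events(
    dff: np.ndarray, fs: float, onsets: np.ndarray, window_s: float
) -> np.ndarray:
    """Stack pulse-aligned segments (events x samples); incomplete events
    at the end of the trace are dropped."""
    dff = np.asarray(dff, dtype=float)
    nw = int(round(window_s * fs))
    segs = []
    for t in np.asarray(onsets, dtype=float):
        k = int(round(t * fs))
        if k + nw <= dff.size:
            segs.append(dff[k : k + nw])
    if not segs:
        raise ValueError("no complete events within the trace")
    return np.asarray(segs)


def _fit_decay(
    t: np.ndarray, y: np.ndarray, n_events: int, r2_floor: float
) -> TransientFit:
    """Least-squares fit of b + a*exp(-t/tau) to a post-peak decay."""
    span = y.max() - y.min()
    p0 = (float(y.min()), float(max(span, 1e-12)), max(t[-1] / 3.0, 1e-3))
    try:
        popt, pcov = optimize.curve_fit(
            lambda tt, b, a, tau: b + a * np.exp(-tt / tau),
            t,
            y,
            p0=p0,
            bounds=([-np.inf, 0.0, 1e-4], [np.inf, np.inf, np.inf]),
            maxfev=20000,
        )
    except RuntimeError:
        warnings.warn("transient fit did not converge; flagged invalid")
        return TransientFit(math.nan, math.nan, math.nan, -math.inf, n_events, valid=False)
    b, a, tau = popt
    resid = y - (b + a * np.exp(-t / tau))
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - float((resid**2).sum()) / ss_tot if ss_tot > 0 else 1.0
    tau_se = math.sqrt(pcov[2, 2]) * 1000.0 if np.isfinite(pcov[2, 2]) else math.nan
    fit = TransientFit(
        alpha_e=float(a),
        tau_e_ms=float(tau * 1000.0),
        baseline=float(b),
        r2=r2,
        n_events=n_events,
        tau_e_se_ms=tau_se,
        valid=True,
    )
    if r2 < r2_floor:
        warnings.warn(f"transient fit quality r2={r2:.3f} below floor; flagged invalid")
        fit.valid = False
    return fit


def extract_and_fit_transient(
    dff: np.ndarray,
    fs: float,
    onsets: np.ndarray,
    window_s: float = 8.0,
    r2_floor: float = 0.2,
) -> TransientFit:
    """Average pulse-aligned events and fit the post-peak mono-exponential.

    The rise phase is excluded: the fit domain runs from the sample of the
    averaged event's peak to the window end.  ``tau_e`` is reported in ms.
    """
    events = extract_events(dff, fs, onsets, window_s)
    avg = events.mean(axis=0)
    ipk = int(np.argmax(avg))
    if avg.size - ipk < 4:
        raise ValueError("too few samples after the peak to fit a decay")
    t = np.arange(avg.size - ipk) / fs
    return _fit_decay(t, avg[ipk:], events.shape[0], r2_floor)


def fit_events_grouped(
    dff: np.ndarray,
    fs: float,
    onsets: np.ndarray,
    window_s: float = 8.0,
    n_groups: int = 20,
) -> tuple[TransientFit, float]:
    """Fit the pooled average plus an empirical SE of tau_e.

    Events are split into ``n_groups`` disjoint groups; each group average
    is fitted separately and the SE of the pooled tau_e is estimated as
    sd(group tau) / sqrt(n_groups).  Robust to temporally correlated
    residual noise, which the curve-fit covariance underestimates.
    """
    onsets = np.asarray(onsets, dtype=float)
    pooled = extract_and_fit_transient(dff, fs, onsets, window_s)
    groups = np.array_split(onsets, n_groups)
    taus = []
    for grp in groups:
        if len(grp) == 0:
            continue
        fit = extract_and_fit_transient(dff, fs, grp, window_s, r2_floor=-np.inf)
        if fit.valid or np.isfinite(fit.tau_e_ms):
            taus.append(fit.tau_e_ms)
    taus = np.asarray(taus)
    se = float(taus.std(ddof=1) / math.sqrt(taus.size)) if taus.size >= 2 else math.nan
    return pooled, se


def compare_pre_post(
    fits_by_epoch: dict[str, list[TransientFit]],
) -> pd.DataFrame:
    """Welch two-sided t-tests on per-cell alpha_e and tau_e between epochs.

    Returns one row per (parameter, epoch pair) with group means, the
    difference and the p-value.
    """
    epochs = list(fits_by_epoch)
    if len(epochs) < 2:
        raise ValueError("need at least two epochs to compare")
    for name, fits in fits_by_epoch.items():
        if len(fits) < 2:
            raise ValueError(f"epoch {name!r} has fewer than 2 cells")
    rows = []
    for i, ea in enumerate(epochs):
        for eb in epochs[i + 1 :]:
            for param in ("alpha_e", "tau_e_ms"):
                a = np.array([getattr(f, param) for f in fits_by_epoch[ea]])
                b = np.array([getattr(f, param) for f in fits_by_epoch[eb]])
                t, p = stats.ttest_ind(a, b, equal_var=False)
                rows.append(
                    {
                        "param": param,
                        "epoch_a": ea,
                        "epoch_b": eb,
                        "mean_a": a.mean(),
                        "mean_b": b.mean(),
                        "diff": b.mean() - a.mean(),
                        "t": float(t),
                        "p_value": float(p),
                    }
                )
    return pd.DataFrame(rows)


def transient_duration_from_variances(
    per_bin_var: np.ndarray,
    bin_edges: np.ndarray,
    steady_var: float,
    factor: float = 1.1,
) -> float:
    """End time of the last bin whose ISI variance exceeds factor*steady.

    The transient state is the interval from clamp onset during which the
    ISI variance remains elevated above its steady-state value by more
    than 10% (v > 1.1 * v_ss by default); perfectly stationary pulse
    trains give a transient duration of zero.
    """
    per_bin_var = np.asarray(per_bin_var, dtype=float)
    bin_edges = np.asarray(bin_edges, dtype=float)
    if per_bin_var.size != bin_edges.size - 1:
        raise ValueError("need one variance per bin")
    above = np.where(per_bin_var > factor * steady_var)[0]
    if above.size == 0:
        return 0.0
    return float(bin_edges[above[-1] + 1] - bin_edges[0])


def isi_statistics(
    onsets: np.ndarray,
    clamp_window: tuple[float, float],
    bin_s: float = 60.0,
    transient_factor: float = 1.1,
    steady: str = "final_bin",
) -> ISIStats:
    """ISI mean/variance in consecutive 60 s bins across the clamp.

    The last bin absorbs any remainder shorter than a full bin (so a 266 s
    clamp yields bins 0-60, 60-120, 120-180, 180-266).  ``steady`` selects
    the steady-state variance: the final bin (default) or all ISIs from
    180 s onward ("pooled_tail").  An ISI belongs to the bin containing the
    onset of its leading pulse; bins with fewer than two ISIs are excluded
    with a warning.
    """
    onsets = np.sort(np.asarray(onsets, dtype=float))
    t0, t1 = clamp_window
    onsets = onsets[(onsets >= t0) & (onsets <= t1)]
    if onsets.size < 3:
        raise ValueError("need at least 3 pulses in the clamp window")
    isis = np.diff(onsets)
    lead = onsets[:-1]

    n_full = int((t1 - t0) // bin_s)
    if n_full < 2:
        raise ValueError("clamp window must span at least two bins")
    edges = t0 + bin_s * np.arange(n_full + 1)
    edges[-1] = t1  # merge the remainder into the final bin
    idx = np.clip(np.searchsorted(edges, lead, side="right") - 1, 0, n_full - 1)

    means = np.full(n_full, np.nan)
    varis = np.full(n_full, np.nan)
    counts = np.zeros(n_full, dtype=int)
    for b in range(n_full):
        vals = isis[idx == b]
        counts[b] = vals.size
        if vals.size >= 1:
            means[b] = vals.mean()
        if vals.size >= 2:
            varis[b] = vals.var(ddof=1)
        else:
            warnings.warn(f"bin {b} has fewer than 2 ISIs; variance undefined")

    if steady == "final_bin":
        steady_var = float(varis[-1])
    elif steady == "pooled_tail":
        tail = isis[lead >= t0 + 3 * bin_s]
        steady_var = float(tail.var(ddof=1)) if tail.size >= 2 else float(varis[-1])
    else:
        raise ValueError("steady must be 'final_bin' or 'pooled_tail'")

    ok = ~np.isnan(varis)
    transient = transient_duration_from_variances(
        np.where(ok, varis, 0.0), edges, steady_var, transient_factor
    )
    return ISIStats(
        isis=isis,
        bin_edges=edges,
        per_bin_mean=means,
        per_bin_var=varis,
        per_bin_count=counts,
        steady_var=steady_var,
        transient_duration=transient,
    )


def _event_peaks(
    dff: np.ndarray, fs: float, onsets: np.ndarray, window_s: float
) -> np.ndarray:
    return extract_events(dff, fs, onsets, window_s).max(axis=1)


def detect_modulated_rois(
    traces: TraceSet,
    onsets: np.ndarray,
    clamped_roi: int,
    clamp_window: tuple[float, float],
    baseline_window: tuple[float, float],
    alpha_level: float = 0.05,
    event_window_s: float = 1.0,
    fit_window_s: float = 4.0,
    min_separation_s: float | None = None,
    bh_correct: bool = False,
) -> ModulationResult:
    """Which non-clamped ROIs are modulated pulse-locked during the clamp.

    For every ROI except the clamped one, pulse-locked peak dF/F values
    during the clamp are compared against peaks at matched pseudo-events
    placed evenly through that ROI's pre-clamp baseline (two-sided Welch
    t-test on the peaks; significance is the intensity test at
    ``alpha_level``, optionally Benjamini-Hochberg corrected).  The change
    in event decay constant is reported from averaged-event fits in each
    epoch.  The clamped ROI never appears in the result.
    """
    if traces.data.shape[0] < 2:
        raise ValueError("need at least 2 ROIs")
    onsets = np.asarray(onsets, dtype=float)
    onsets = onsets[(onsets >= clamp_window[0]) & (onsets <= clamp_window[1])]
    if onsets.size < 5:
        raise ValueError("need at least 5 pulses")
    b0, b1 = baseline_window
    if b1 - b0 < 2 * event_window_s:
        raise ValueError("pre-clamp baseline epoch missing or too short")
    # Peaks of nearby windows are correlated over the indicator decay time;
    # subsample events to a minimum separation so the t-test sees
    # approximately independent samples in both epochs.
    if min_separation_s is None:
        tau_max = 3.0  # conservative for second-scale indicators
        min_separation_s = max(event_window_s, tau_max)
    kept = [onsets[0]]
    for t in onsets[1:]:
        if t - kept[-1] >= min_separation_s:
            kept.append(t)
    onsets = np.asarray(kept)
    if onsets.size < 5:
        raise ValueError("fewer than 5 events remain after decorrelation")
    n_pseudo = min(onsets.size, max(2, int((b1 - b0) / min_separation_s)))
    pseudo = np.linspace(b0, b1 - event_window_s, n_pseudo)

    fs = traces.fs
    rows = []
    for roi in range(traces.data.shape[0]):
        if roi == clamped_roi:
            continue
        dff = compute_dff(traces.roi(roi), fs, baseline_window)
        peaks_clamp = _event_peaks(dff, fs, onsets, event_window_s)
        peaks_base = _event_peaks(dff, fs, pseudo, event_window_s)
        t, p = stats.ttest_ind(peaks_clamp, peaks_base, equal_var=False)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                fit_clamp = extract_and_fit_transient(
                    dff, fs, onsets, fit_window_s, r2_floor=-np.inf
                )
                fit_base = extract_and_fit_transient(
                    dff, fs, pseudo, fit_window_s, r2_floor=-np.inf
                )
                tau_delta = fit_clamp.tau_e_ms - fit_base.tau_e_ms
            except ValueError:
                tau_delta = math.nan
        rows.append(
            {
                "roi": roi,
                "peak_delta": float(peaks_clamp.mean() - peaks_base.mean()),
                "tau_delta_ms": tau_delta,
                "p_value": float(p),
            }
        )
    table = pd.DataFrame(rows)
    pvals = table["p_value"].to_numpy()
    if bh_correct:
        order = np.argsort(pvals)
        m = len(pvals)
        thresh = alpha_level * (np.arange(1, m + 1)) / m
        passed = pvals[order] <= thresh
        cut = passed.nonzero()[0].max() + 1 if passed.any() else 0
        sig = np.zeros(m, dtype=bool)
        sig[order[:cut]] = True
    else:
        sig = pvals < alpha_level
    table["significant"] = sig
    return ModulationResult(
        table=table,
        n_significant=int(sig.sum()),
        n_total=len(table),
        alpha_level=alpha_level,
    )
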