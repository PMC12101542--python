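"""Two-parameter Boltzmann f-I adaptation model.

A neuron's firing rate follows a Boltzmann (logistic) function of its
input, ``B(I) = f_max / (1 + exp(-(I - theta0)/slope))``, and sustained
firing shifts the curve rightward along the input axis through a
subtractive adaptation variable:

    f = B(I - a),    da/dt = (alpha * f - a) / tau_a

``alpha`` (adaptation strength, input units per spikes/s) sets how far the
curve shifts at steady state; ``tau_a`` (s) sets how fast.  Laser power is
treated as linearly proportional to injected current, so power-frequency
measurements before/after a clamp can be fitted directly.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize

__all__ = [
    "FICurve",
    "AdaptationFit",
    "boltzmann",
    "steady_state_rate",
    "steady_state_curve",
    "simulate_adaptation",
    "fit_adaptation",
]


def boltzmann(i: np.ndarray | float, f_max: float, theta0: float, slope: float):
    """Boltzmann f-I curve."""
    return f_max / (1.0 + np.exp(-(np.asarray(i, dtype=float) - theta0) / slope))


@dataclass
class FICurve:
    """Input (laser power) vs firing rate, for one epoch (pre or post)."""

    inputs: np.ndarray
    rates: np.ndarray
    epoch: str = "pre"

    def __post_init__(self) -> None:
        self.inputs = np.asarray(self.inputs, dtype=float)
        self.rates = np.asarray(self.rates, dtype=float)
        if self.inputs.shape != self.rates.shape:
            raise ValueError("inputs and rates must have equal length")
        if np.any(np.diff(self.inputs) <= 0):
            raise ValueError("inputs must be strictly increasing")
        if np.any(self.rates < 0):
            raise ValueError("rates must be >= 0")


@dataclass
class AdaptationFit:
    """Fitted Boltzmann parameters plus adaptation strength and time constant."""

    alpha: float
    tau_a: float | None
    f_max: float
    theta0: float
    slope: float
    residual: float
    tau_identifiable: bool

    @property
    def boltzmann_params(self) -> tuple[float, float, float]:
        return (self.f_max, self.theta0, self.slope)


def steady_state_rate(
    i: float,
    f_max: float,
    theta0: float,
    slope: float,
    alpha: float,
    tol: float = 1e-9,
    max_iter: int = 10000,
    damping: float = 0.5,
) -> float:
    """Self-consistent rate solving f = B(I - alpha*f) by damped iteration."""
    f = float(boltzmann(i, f_max, theta0, slope))
    for _ in range(max_iter):
        f_new = (1.0 - damping) * f + damping * float(
            boltzmann(i - alpha * f, f_max, theta0, slope)
        )
        if abs(f_new - f) < tol:
            return f_new
        f = f_new
    raise RuntimeError(
        f"steady-state iteration did not converge at I={i} (alpha={alpha}); "
        f"last step {abs(f_new - f):.3e}"
    )


def steady_state_curve(
    inputs: np.ndarray,
    f_max: float,
    theta0: float,
    slope: float,
    alpha: float,
    epoch: str = "pre",
) -> FICurve:
    """Adapted steady-state f-I curve over the given input levels."""
    rates = np.array([steady_state_rate(i, f_max, theta0, slope, alpha) for i in np.asarray(inputs, dtype=float)])
    return FICurve(inputs=np.asarray(inputs, dtype=float), rates=rates, epoch=epoch)


def simulate_adaptation(
    input_series: np.ndarray,
    dt: float,
    f_max: float,
    theta0: float,
    slope: float,
    alpha: float,
    tau_a: float,
    a0: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Integrate the adaptation ODE over an input time series (Euler).

    Returns (rates, adaptation variable), one sample per input sample.
    A step input relaxes to the steady state with an effective time
    constant tau_a / (1 + alpha * B'), on the order of tau_a.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    if tau_a <= 0:
        raise ValueError("tau_a must be > 0")
    if dt >= tau_a / 10.0:
        warnings.warn("dt >= tau_a/10: Euler integration may be inaccurate")
    i_series = np.asarray(input_series, dtype=float)
    a = float(a0)
    rates = np.empty_like(i_series)
    avals = np.empty_like(i_series)
    for k, i in enumerate(i_series):
        f = float(boltzmann(i - a, f_max, theta0, slope))
        rates[k] = f
        avals[k] = a
        a += dt * (alpha * f - a) / tau_a
    return rates, avals


def _fit_boltzmann(curve: FICurve) -> tuple[float, float, float]:
    i, r = curve.inputs, curve.rates
    p0 = (max(r.max() * 1.05, 1e-3), float(i[np.argmin(np.abs(r - r.max() / 2))]), max((i[-1] - i[0]) / 10.0, 1e-3))
    popt, _ = optimize.curve_fit(
        boltzmann, i, r, p0=p0,
        bounds=([1e-6, -np.inf, 1e-6], [np.inf, np.inf, np.inf]),
        maxfev=20000,
    )
    return tuple(float(v) for v in popt)


def fit_adaptation(
    pre: FICurve,
    post: FICurve,
    dynamics: tuple[np.ndarray, np.ndarray, float] | None = None,
    allow_negative_alpha: bool = False,
) -> AdaptationFit:
    """Fit (f_max, theta0, slope) on the pre curve and alpha from the post shift.

    The post-clamp curve is modelled as the adapted steady state of the pre
    curve; ``alpha`` is the input-axis shift per unit rate that best
    explains the suppression.  ``tau_a`` is only identifiable from dynamics:
    pass ``dynamics = (t, rate, I_step)``, a rate-vs-time record following a
    step input, to fit it; otherwise it is reported as None with
    ``tau_identifiable = False`` (any tau_a yields the same steady state).

    A post curve above the pre curve everywhere would require negative
    alpha (sensitization) and is rejected under the default bounds.
    """
    if pre.inputs.size < 4 or post.inputs.size < 4:
        raise ValueError("need at least 4 input levels per curve")
    f_max, theta0, slope = _fit_boltzmann(pre)

    pre_pred = boltzmann(post.inputs, f_max, theta0, slope)
    if np.all(post.rates > pre_pred) and not allow_negative_alpha:
        raise ValueError(
            "post curve lies above the pre curve everywhere; alpha would be "
            "negative (sensitization) and is rejected under default bounds"
        )

    # parametrize alpha = exp(x) - floor so the default fit stays >= 0;
    # a large floor effectively frees the sign when sensitization is allowed
    alpha_floor = 1e-6 if not allow_negative_alpha else 10.0

    def resid(log_alpha: np.ndarray) -> np.ndarray:
        alpha = float(np.exp(log_alpha[0])) - alpha_floor
        model = np.array(
            [steady_state_rate(i, f_max, theta0, slope, alpha) for i in post.inputs]
        )
        return model - post.rates

    sol = optimize.least_squares(resid, x0=[math.log(0.05 + alpha_floor)], xtol=1e-12)
    alpha = float(np.exp(sol.x[0])) - alpha_floor
    residual = float((sol.fun**2).sum())

    tau_a: float | None = None
    identifiable = False
    if dynamics is not None:
        t, rate_obs, i_step = dynamics
        t = np.asarray(t, dtype=float)
        rate_obs = np.asarray(rate_obs, dtype=float)
        dt = float(t[1] - t[0])
        # linearized initial guess: rate relaxes with tau_a / (1 + alpha*B')
        r_ss = rate_obs[-1]
        x = (i_step - alpha * r_ss - theta0) / slope
        sig = 1.0 / (1.0 + math.exp(-x))
        bprime = f_max * sig * (1.0 - sig) / slope
        tau_guess = max(dt * 5, (t[-1] / 5.0))

        def resid_tau(log_tau: np.ndarray) -> np.ndarray:
            tau = float(np.exp(log_tau[0]))
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model, _ = simulate_adaptation(
                    np.full_like(t, i_step), dt, f_max, theta0, slope, alpha, tau
                )
            return model - rate_obs

        sol_t = optimize.least_squares(resid_tau, x0=[math.log(tau_guess)], xtol=1e-12)
        tau_a = float(np.exp(sol_t.x[0]))
        identifiable = True
        del bprime  # guess only; full ODE fit supersedes the linearization

    return AdaptationFit(
        alpha=alpha,
        tau_a=tau_a,
        f_max=f_max,
        theta0=theta0,
        slope=slope,
        residual=residual,
        tau_identifiable=identifiable,
    )
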