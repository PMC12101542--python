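# Methods

This note documents the models behind `optoclamp`, the choices made where
the design was genuinely open, and what the synthetic experiments do and do
not establish about real recordings.

## Neuron and forward model

Firing is an inhomogeneous Poisson process at imaging-frame resolution
(30 Hz) with instantaneous rate

    r = clip( r0 + f_max·[σ((I − θ0 − a)/s) − σ((−θ0 − a)/s)], 0, f_max ),
    da/dt = (α·r − a)/τ_a ,

where `I` is the total input (photostimulation plus coupling from other
ROIs), `σ` the logistic function and `a` the adaptation variable. This is
the standard subtractive (input-axis) form of spike-rate adaptation: a
sustained rate shifts the Boltzmann f–I curve rightward by `α·r` at steady
state, reducing the evoked response, which is the phenomenology the
adaptation analyses quantify. Two deliberate refinements:

- **Rest-point anchoring.** The zero-input value of the shifted curve is
  subtracted, so spontaneous firing (`r0`) is input-independent and
  unaffected by `a`. Without this, adaptation silences the baseline within
  a minute, making "baseline" epochs non-stationary — statistically fatal
  for any pre-vs-during comparison (the neighbor-modulation detector's
  type-I error calibration exposed this immediately). Conceptually,
  spontaneous spiking is treated as a separate drive that does not pass
  through the adapting input pathway.
- **Subtractive, not divisive.** A rightward shift, rather than a gain
  division, is what a two-parameter (α, τ_a) adaptation model of
  power–frequency curves expresses; the fitting module assumes the same
  form, and the fit records it.

Fluorescence is the exact shot-noise convolution of spike times with an
instantaneous-rise kernel `A·exp(−t/τ_ca)` plus iid Gaussian read noise,
sampled at frame ends (each spike contributes `A·exp(−(t_frame − t_spike)/τ_ca)`,
so Campbell's theorem holds exactly: a constant rate `r` yields mean
ΔF = r·A·τ_ca). Indicator saturation and rise kinetics are omitted: every
analysis downstream fits mono-exponential decays, and a slow indicator's
rise at 30 Hz is sub-frame. The simulator is deterministic per
(model, stimulus, seed), bit-for-bit.

### Default parameters

| parameter | value | units | why |
|---|---|---|---|
| `baseline_rate` | 1.0 | spikes/s | sparse spontaneous cortical activity |
| `f_max` | 400 | spikes/s | ceiling of the *burst* response to a 50 ms pulse (≈25 reliable spikes/pulse in probes); chosen with `ca_amp` so evoked transients have low trial-to-trial CV (~0.2) |
| `θ0`, `slope` | 5.0, 1.5 | input units | half-activation well above rest; pulse input (gain 1 × power 10) sits in the saturating region |
| `τ_a` (`tau_adapt`) | 15 | s | clamp ISI settles within the first 60 s bin, elevated variance confined there |
| `α` (`alpha_adapt`) | 0.5 | input/(spikes/s) | calibrated so the 3·SD, 266 s clamp delivers ≈161 pulses (measured 162 ± 6 over ten seeds) |
| `ca_amp` | 0.019 | ΔF per spike | with `f_max`, sets probe transient amplitude ≈0.43 ΔF/F |
| `τ_ca` (`tau_ca`) | 2.257 | s | the pre-clamp evoked decay constant (2257 ms) |
| `noise_sd` | 0.058 | F units | keeps the baseline SD (shot + read noise) at the level that, with `k = 3`, reproduces the clamp operating point |
| `f0`, `stim_gain` | 1.0, 1.0 | arbitrary | scale conventions |

These defaults were calibrated **once** against the published operating
points of the protocol (pulse counts, ISI variance ordering, probe
attenuation, decay constants) and then frozen; tests and the acceptance
script run against them unmodified. The calibration reproduces the 3·SD
pulse count but *not* the near-equality of 3·SD and 5·SD counts
(161 vs 168 in the source data): with a threshold controller and
exponential calcium decay, the inter-pulse interval shrinks roughly as
`τ_ca·ln(1 + ΔF/(k·SD))`, so the 5·SD clamp needs substantially more
pulses (~274) unless adaptation exactly compensates per cell. The count
ordering (more pulses at higher targets) and the variance ordering (lower
early ISI variance at 5·SD) are reproduced and tested.

## Intrinsic plasticity (IP)

A clamp of level `k` and duration `d` attenuates the evoked calcium
response: the per-spike amplitude is scaled by `ip_atten` and the decay
constant by `ip_tau_factor`, both relaxing exponentially toward 1 with
`τ_rec = 300 s`. Induction depth is `D_ref · (k/5) · g(d)` with
`g(d) = (1 − e^(−d/80 s))/(1 − e^(−200 s/80 s))`, capped at 0.95; `k = 3`
therefore induces 60% of the `k = 5` effect, and `k = 1` values are an
uncalibrated linear interpolation. The reference depths are fixed by two
anchors at the +3 min probe after a 200 s, 5·SD clamp: 18% amplitude
attenuation and decay-constant shrink from 2257 to 1850 ms. Because
recovery runs during the probe itself (and continuously in the session
engine), a cohort measurement at +3 min reads slightly below the
instantaneous anchor (≈16% mean over ten cells), and the +8 min probe is
partially rebounded — the ordering |Δ₈| < |Δ₃| is the tested claim.
Repeated inductions keep the deeper of the existing and new depths.

## Closed-loop controller

Decisions are frame-locked with one frame of latency: the sample at frame
k−1 determines stimulation during frame k. Pulses are 50 ms (2 frames at
30 Hz), lockout 100 ms, and the target is `A_CL = mean + k·SD` (population
SD) of a 60 s baseline window recorded in the same session. The trigger
compares raw fluorescence, not ΔF/F, because the target is defined from
baseline fluorescence statistics. Because decisions depend only on past
samples and the controller's own pulse history, replaying the rule over a
recorded trace reproduces the pulse log exactly; a hand-built
frame-by-frame oracle (independent of the package's engine) checks the
trigger semantics and the closed-form inter-pulse interval in the tests.

## Trace analysis

ΔF/F is `(F − F0)/F0` with `F0` the baseline-window mean. Evoked
transients are averaged across pulse-aligned windows (8 s) and fitted with
`b + α_e·exp(−t/τ_e)` from the *post-peak* sample onward — the rise is
excluded because somatic stimulation does not resolve it — by
`scipy.optimize.curve_fit` with a nonnegative-amplitude bound;
non-convergent or low-r² fits are flagged invalid, never silently
returned. `τ_e` is the e-fold time: the fit retains e⁻¹ ≈ 37% of `α_e` at
`t = τ_e`. For recovery benchmarks the SE of `τ_e` is estimated
empirically from disjoint event groups (the curve-fit covariance assumes
iid residuals and understates the error under temporally correlated shot
noise).

ISI statistics bin the intervals by the leading pulse's onset into
consecutive 60 s bins, the remainder pooled into the final ("180+") bin;
the steady-state variance is the final bin's (a pooled-tail option
exists). The transient state ends with the last bin whose variance exceeds
1.1× steady. The literal "greater than 10% of its steady-state value"
phrasing would classify the steady state itself as transient, so the
1.1× reading is adopted (configurable).

The neighbor-modulation detector compares pulse-locked peak ΔF/F during
the clamp against matched pseudo-events placed through the pre-clamp
baseline (two-sided Welch t-test per ROI; the clamped ROI is excluded;
Benjamini–Hochberg optional, off by default to report raw per-ROI
p-values). Events are first subsampled to a minimum separation
(default max(window, 3 s)): peak windows closer than the indicator
correlation time are strongly dependent, and without decorrelation the
empirical type-I rate was 0.13 at a nominal 0.05 (0.058 with it, within
binomial tolerance over 200 null runs). Decay-constant changes are
reported from averaged-event fits per epoch; significance is the intensity
test.

All epoch comparisons use two-sided Welch (unequal-variance) t-tests, the
conservative default when variance pooling is unspecified; per-cell
averaged fits are the replication unit (per-event fits are available).

## Adaptation fitting

`steady_state_rate` solves the self-consistency `f = B(I − α·f)` by damped
fixed-point iteration (tolerance 1e−9); an independent bisection oracle
verifies it in the tests. `fit_adaptation` estimates the Boltzmann triple
on the pre curve, then `α ≥ 0` from the post-curve shift
(log-parametrized least squares; a post curve above pre everywhere implies
sensitization and is rejected under default bounds, with an explicit
opt-in). `τ_a` is identifiable only from dynamics: given a step-response
rate record it is fitted by matching the full ODE simulation, seeded from
the linearized constant `τ_a/(1 + α·B′)`; without dynamics it is reported
as `None`. Note the pointwise slope of the adapted curve is *not* monotone
in α (a right-shifted sigmoid is locally steeper in the saturated region);
the monotone facts — pointwise rates and peak gain non-increasing — are
what the invariants assert. Recovery on 2%-noise synthetic datasets: α
within 10%, τ_a within 15% (means ≈2% and ≈3%).

## BCI task and agent

The decoder is a velocity integrator,
`pos += gain·bin·(mean r[N+] − mean r[N−])`, with success at `pos ≥ T1`
(≥ 0.60 session success ⇒ "strong" learner; the boundary counts as
strong). The cursor-position decoder form, T1 scale, 30 s timeout and the
uniform [0.2, 0.8]·T1 start range are configuration values echoed in
outputs. Each agent neuron fires at `baseline + (w_up − w_down) + noise`
(clipped to [0, f_max]) per 100 ms bin; the two nonnegative weight
channels are driven by the BTSP rule with the positive/negative parts of
the neuron's own rate fluctuation as presynaptic activity and the binary
trial reward as the instructive signal. Credit assignment is therefore
emergent — the agent has no knowledge of the decoder — and individual
neurons may adopt either sign of modulation (compensatory within-pair
strategies arise naturally); the learned quantity the tests assert is the
net pair-difference drive. A slow weight leak (`forget_tau_s = 1500 s`)
bounds reinforcement; with long training, modulation still saturates at
the rate bounds, a known idealization. Agent defaults
(gain 0.08, noise SD 2.5 spikes/s, η = 0.05) give first-session success
≈0.9 for the learning agent versus ≈0.18 for η = 0; only this separation
and the 0.60 boundary are treated as claims, not the absolute rates.

Baseline drift across days multiplies each synaptic weight by a log-normal
factor daily (activity-independent turnover) and, when enabled, applies
multiplicative synaptic scaling `(target/rate)^ε` toward the homeostatic
target. Log-rate variance grows linearly without scaling; with scaling the
population mean stays within ±5% of target while individual neurons
wander.

## Synthetic data: scope and limits

The generator emulates multi-ROI 30 Hz fluorescence with second-scale
transients, pulse logs, and session-structured behavior. It does **not**
emulate imaging artifacts (motion, neuropil contamination, bleaching),
indicator nonlinearity, bursting beyond Poisson statistics, spatial
off-target excitation, or real synaptic connectivity (coupling is an
additive rate-proportional input with no delay). Passing tests therefore
establish the correctness and calibration of the *procedures* —
controller logic, estimators, statistics — under a known forward model,
not the biological values a real experiment would measure; in particular
the animal-behavior success rates and per-cell counts of the in-vivo study
are outside what synthetic data can reproduce.

## Numerical and testing choices

Problem sizes were chosen to keep the full suite to a few minutes on one
CPU: 200-event probe recoveries, ten-cell session cohorts, 10–20-seed
controller batteries and 200-run null calibrations. Every stochastic test
fixes its seeds; hypothesis property tests run derandomized. Degenerate
inputs (zero-SD baselines, targets below rest, zero recent rate in
scaling, sparse ISI bins, unidentifiable τ_a) produce warnings, skips of
the affected element, or explicit errors rather than silent results.
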