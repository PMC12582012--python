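# Methods

This note documents the models, estimators and numerical choices behind
`tracekin`, and what the synthetic benchmarks do and do not demonstrate.

## The kinetic model

A surface-tethered molecule follows a continuous-time Markov chain (CTMC)
over chemical states.  The default scheme is the iminium-catalysed
Diels–Alder cycle

    S ⇌ IM1 ⇌ IM2 → P

with rate constants (the package's reference parameterisation, from
single-molecule measurements of this system):

| transition | order        | coupled species | "mac"  | "ctrl" | units    |
|------------|--------------|-----------------|--------|--------|----------|
| S → IM1    | bimolecular  | catalyst        | 23.75  | 23.75  | M⁻¹ s⁻¹  |
| IM1 → S    | unimolecular | —               | 0.21   | 0.21   | s⁻¹      |
| IM1 → IM2  | unimolecular | —               | 0.20   | 0.20   | s⁻¹      |
| IM2 → IM1  | unimolecular | —               | 0.22   | 0.22   | s⁻¹      |
| IM2 → P    | bimolecular  | diene           | 6.64   | 3.82   | M⁻¹ s⁻¹  |

Bimolecular steps are pseudo-first-order: the effective rate is the constant
times the coupled concentration (entered in mM at every interface, converted
to M internally).  P and the photobleached state are absorbing.  P emits at
IM1's intensity — product formation is optically invisible, which is exactly
why the indirect (Markov-property) estimator below exists.

## Synthetic trajectory generator

`simulate_state_path` is an exact stochastic simulation: exponential waiting
times with the total exit rate, branch choice proportional to rates.
`render_trace` models the camera: the noiseless level of a frame is the
occupancy-time-weighted mean of the emission means of the states visited
during the frame (exposure integration), and Gaussian noise with the majority
state's sd is added.  Defaults emulate the imaging conditions of the
experiment this package targets: 0.1 s frames, 600 frames (1 min), 200
trajectories per condition, emission means S = 1.00, IM1 = P = 0.60,
IM2 = 0.25, background/bleached = 0.05, sd = 0.08 (arbitrary units).  The
absolute levels are a convention — the real experiment does not pin them —
and which species is brightest is configurable downstream (`label_states`).
Photobleaching is an optional extra first-order channel into an absorbing
dark state (default rate 0; it exists to exercise the QC filter).

What the generator does **not** emulate: shot noise and intensity drift,
detector nonlinearity, blinking, spot-detection errors, and any non-Markov
dynamics.  Recovery results on synthetic data therefore demonstrate estimator
correctness under the stated observation model, not robustness to every
artifact of real microscope data.

## HMM segmentation

One Gaussian-emission discrete-time HMM is fitted per experimental condition,
pooled over all trajectories (shared initial distribution, transition matrix
and emissions).  Fitting is Baum–Welch with scaled forward–backward
recursions, vectorised across traces of equal length; the log-likelihood
trace is recorded and checked for monotonicity every iteration.  EM stops at
a relative log-likelihood change below 1e-6 (default) or 500 iterations.

Initialisation matters when one state dominates the intensity histogram (low
catalyst concentration: mostly S).  Restart 0 spreads the K emission means
evenly over the robust data range (0.5th–99.5th percentile bin midpoints);
restart 1 uses the 10/50/90-style quantiles (good for balanced occupancy);
further restarts perturb these alternately with seeded noise.  Three restarts
by default; best final likelihood wins.  Emission sds are floored at
1e-6 × pooled sd to prevent variance collapse.

Decoding is Viterbi in log space with ties broken toward the lower state
index; forward–backward posteriors are attached.  States are mapped to
species by emission-mean rank (default: brightest = S, dimmest = IM2).

Model selection uses BIC = −2 log L + p ln(N_obs) with
p = (K−1) + K(K−1) + 2K free parameters and N_obs = total frames.

**Known property: state-number selection on camera-blurred data.**  Exposure
integration makes ~5 % of frames mid-level "transition" frames.  With ~10⁵
pooled frames, BIC's penalty (p ln N) is far smaller than the likelihood gain
of dedicating a short-lived extra state to those frames, so argmin-BIC
prefers K = 4–5 on data whose *chemistry* has three states; the extra states
are recognisable by near-zero self-transition probability and means between
the chemical levels.  On point-sampled data (no integration) BIC recovers
K = 3 cleanly.  This is a real feature of penalised-likelihood state counting
on integrating detectors, not an implementation defect; when the state count
is known, fix `k = 3` in the analysis config rather than selecting it.

## Dwell times and rate constants

Decoded paths are run-length encoded into dwells; the first and last runs are
censored (their duration is truncated by the observation window).  A censored
dwell keeps its destination when a following run exists; rate estimation uses
censored dwells' *time* but never counts them as events.

**Per-transition rates.**  The CTMC maximum-likelihood estimator
k(n→m) = N(n→m)/T(n) (observed exits over total occupancy time,
SE = √N/T).  Excluding censored time as well would bias rates up by roughly
τ/T_trace (~5 % here); including it makes the estimator asymptotically
unbiased.  When the frame period is supplied, the total exit rate is further
corrected for frame quantisation with the geometric-sampling MLE
k_tot = −ln(1 − N·Δt/T)/Δt (the exact MLE for a discretely observed
two-state reduction; identical to N/T to first order in Δt) and split over
destinations by the embedded branching fractions N(n→m)/N(n).

**Residual bias (documented limitation).**  Dwells shorter than about one
frame are invisible: Viterbi merges them into the surrounding runs, deleting
two events each.  No dead-time correction is applied.  At the default
settings (rates 0.2–0.9 s⁻¹, Δt = 0.1 s) the net effect is a systematic
underestimate of 2–5 % on recovered rate constants — visible in the
benchmarks as recovered slopes ~3 % below the generating constants — and it
grows with kΔt.  Users comparing conditions are largely protected because the
bias is shared; absolute rate constants near the frame rate are not reliable.

**Dwell-time distributions.**  The gamma density k^n t^(n−1) e^(−kt)/Γ(n) is
fitted by maximum likelihood; n ≈ 1 indicates a single rate-limiting step,
n ≈ 2 a hidden two-step (Erlang) convolution.  For frame-quantised decoded
dwells, pass the frame period: transitions are timed to frame midpoints
((m−½)Δt) and the likelihood is left-truncated at Δt/2, because the one-frame
detection floor otherwise masquerades as shape > 1 (+0.15 at default
settings).  SEs come from the inverse (observed) Fisher information.

**Concentration series.**  Pseudo-first-order rates are regressed against
concentration (in M) through the origin by weighted least squares
(statsmodels), weights 1/SE².  The reported slope SE uses the estimated
residual scale — robust to overdispersion from the decoding biases above;
the fixed "known-variance" SE is kept in the diagnostics.  A slope+intercept
fit is run alongside purely as a linearity/zero-order diagnostic (its 95 %
slope CI should cover 0 for concentration-independent steps).

**Indirect product rate.**  With diene present, τ_IM2 = 1/(k_IM2→IM1 +
k_IM2→P[diene]).  The estimator subtracts the *total* IM2 exit rate of a
diene-free reference from the total IM2 exit rate at each diene
concentration — the same estimator on both sides, so decoding artifacts
largely cancel — then fits the diene series through the origin.  SEs
propagate by the delta method; a negative point estimate is returned with a
warning flag, never clipped.  Default benchmark series: 25, 50, 100 mM diene
plus the diene-free reference, at 15 mM catalyst; values chosen as a
realistic span giving IM2 dwell shortening between ~1.7× and ~4× (not stated
by the source experiments).

## Transition statistics and group comparisons

Per-frame transition probabilities are P(n→m) = (frame pairs n→m)/(frame
pairs starting in n), diagonal included, so count rows sum to occupancy.
Note this per-occupancy-frame normalisation need not match other published
normalisations (per event, per all frames), which are often unstated.

The transition density plot uses dwell-mean intensities before/after each
decoded transition (robust to frame noise), histogrammed on shared axes.

Group comparisons default to Welch's unequal-variance t-test with a
Mann–Whitney option (falling back to the rank test when variances are
degenerate); no multiple-testing correction is applied, and the star
annotation (0.05/0.01/10⁻⁴) is report formatting only.  Fold changes are
ratios of per-trace statistics with seeded trace-level percentile bootstrap
CIs (default 1000 resamples).  The slope-ratio bootstrap resamples traces
within every condition and recomputes the whole indirect-rate/series-fit
estimator from per-trace dwell statistics (the HMM is not refitted inside
the bootstrap loop; segmentation uncertainty is not propagated).

## QC / bleach filtering

A trace is flagged bleached at the earliest frame from which the mean of all
remaining intensities falls below a threshold (default 0.15, between the
background 0.05 and the dimmest state 0.25), requiring at least 10 remaining
frames so single noise excursions cannot trigger.  Bleached traces are
truncated there and dropped if fewer than 50 frames survive.  On synthetic
ensembles with bleaching enabled, sensitivity to ground-truth bleaching is
≥ 95 % (traces that bleach within the last 10 frames are undetectable in
principle).

## Reproducibility and problem sizes

All randomness flows from explicit seeds through `numpy` `SeedSequence`
spawning (one child stream per trace), so every ensemble and report is
bit-reproducible.  The benchmark problem sizes — 6 catalyst concentrations ×
200 traces × 600 frames for the concentration series; 2 × (1 reference +
3 diene conditions) × 200 traces for the product-rate recovery; 10 seeded
replicates for state-number selection — mirror the emulated study design
(~200 trajectories per condition) and complete in a few minutes on one CPU.

## Known limitations

- No missed-event (dead-time) correction: absolute rates carry a −2…−5 %
  bias at kΔt ≈ 0.02–0.09 (see above).
- BIC over-counts states on exposure-integrated data (see above).
- Gaussian, state-stationary noise only; per-trace emission heterogeneity is
  not modelled (pooled fit).
- The spec of a dwell as ≥ 1 frame means sub-frame chemistry (protonation,
  conformational flips) is invisible by construction.
- Bootstrap CIs do not propagate HMM segmentation uncertainty.
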