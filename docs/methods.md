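# Methods

This note documents the models implemented in `nirsdip`, the choices made
where the design was genuinely open, and what the synthetic data can and
cannot establish.

## Signal model and desired HRF

Each channel's chromophore series is modelled as a linear-in-parameters ARX
process driven by the *desired HRF* u(k): the canonical HRF convolved with
the binary task boxcar. The canonical HRF is a linear combination of three
gamma-density lobes

    h(t) = Σ_{j=1..3} A_j t^(α_j−1) β_j^{α_j} e^{−β_j t} / Γ(α_j)

with defaults A = (−1.5, 7, −2), α = (1.5, 6, 16), β = (1, 1, 1) s⁻¹. The
first (negative) lobe models the initial dip, the second the main response,
the third the late undershoot. Two-gamma variants omit the dip lobe and are
deliberately not provided. The time argument is interpreted in seconds at
sample instants t = n/fs; with these defaults that places the main peak
near 5 s, which is the physiological scale. Evaluation is in log-space
(`gammaln`) so large shape parameters (α₃ = 16) do not overflow.

Sample-count conventions are floor-based and per-block: a trial of
(task + rest) seconds occupies ⌊(task+rest)·fs⌋ samples, of which the first
⌊task·fs⌋ are task; a session concatenates its trials. At 9.19 Hz the
30 s trial is 275 samples and a six-trial session 1650. The convolution
u(k) = Σ_{l=0..k} h(l) s(k−l) is the standard causal form (the summation
includes the l = k term; h(0) = 0 anyway for α_j > 1). u is normalized to
unit peak by default so predictor coefficients absorb the response
amplitude.

## Online estimators

**RLS.** Standard exponentially weighted recursion with forgetting factor
λ (default 0.98), θ̂(0) = 0 and P(0) = 10⁶·I (a numerically uninformative
prior). With λ = 1 and persistent excitation it converges to the batch
least-squares solution; the test suite checks this to 1e-6.

**KRLS.** The recursion maintains the exact kernel ridge regression
solution over the retained dictionary: Q(k) = (K_k + Rλ I)⁻¹ grown by
rank-one block inversion, a(k) = Q(k) y. The regularizer R (default 1e-8)
enters only through the product Rλ; the recursion applies no exponential
down-weighting. Kernels: Gaussian (σ = 1), polynomial (c = 1, p = 1),
sigmoid (s = t = 1) — the scale-1 defaults are the operating point for
band-limited signals of roughly unit amplitude.

**ALD sparsification.** A new regressor is admitted only if its
feature-space projection residual δ = Rλ + κ(φ,φ) − zᵀK exceeds the
threshold ν (default 1e-4, with an optional dictionary cap of 500).
Dependent samples take the dictionary-fixed coefficient update of the
standard ALD formulation, which needs an auxiliary covariance P alongside
Q; growth initializes its new diagonal entry to 1. On the band-limited
synthetic signals the dictionary stabilizes at a few tens of entries over
~3,300-sample streams, which is what makes the per-sample update cheap.

Numerical notes. The growing branch requires δ > 0; δ ≤ 0 while growing
raises an explicit degeneracy error rather than silently corrupting Q. Two
situations produce it: a ridge far below the Gram matrix's rank-deficiency
floor (e.g. the p = 1 polynomial kernel, whose Gram has rank ≤ dim+1), and
the sigmoid kernel, which is *not* positive definite for general inputs —
its Gram can be indefinite, in which case the recursive solution ceases to
exist even though a batch solve may limp through. The recursive-vs-batch
equivalence tests therefore use a ridge of 1e-2 and modest-amplitude
ARX-style regressors, a regime where all three regularized Grams are
positive definite; equivalence there holds to ~1e-10.

## q-step-ahead prediction

At issue time k the newest observation is y(k), so the regressor is
φ = [y(k)…y(k−n_o+1), u(k)…u(k−m_o+1), 1] (orders default n_o = m_o = 1,
exogenous order p_o = 0; the regressor builder supports p_o > 0 for
extension). Multi-step prediction uses the **direct strategy**: one
predictor per horizon, trained online on pairs (φ at time k, target
y(k+q)). For q = 1 this is exactly the model equation's one-step predictor,
so a noiseless ARX-generated channel is recovered with %FIT > 99.9. The
direct strategy is causal — nothing in φ postdates the issue time. An
**iterated strategy** (a one-step model rolled forward q times on its own
outputs) is available behind `strategy="iterated"`; it is exact for linear
noiseless systems but compounds model error on real signals.

Streaming follows the standard adaptive-filter evaluation: at each step the
predictor first emits ŷ(k+q), then absorbs the pair (φ, y(k+q)). Training
runs through the resting baseline plus session 1; updates continue through
session 2 (the test segment), and %FIT is scored on session-2 targets only.

%FIT is implemented exactly as the variance-ratio form
100·(1 − SS_res/SS_tot); the rooted NRMSE-style variant is available via
`variant="nrmse"` since the system-identification literature uses both. A
constant measured series makes the criterion undefined; this is flagged
explicitly (`degenerate=True`, error in the scalar API) rather than
propagating NaN.

## Vector-phase analysis and dip detection

ΔCBV and ΔCOE are the 45° counterclockwise rotation of (ΔHbO, ΔHbR); the
rotation is an isometry, and the full-quadrant angle satisfies
∠p = atan(ΔCOE/ΔCBV) + 45° on the ΔCBV > 0 branch. Eight phases partition
the plane by strict inequalities on the four indices; boundary points (any
tie, measure zero) classify as *none* and never open a dip, avoiding
arbitrary assignment.

Calibration: r1 is the maximum resting-state magnitude √(ΔHbO²+ΔHbR²) —
per-channel by default, since the defining formula is channel-generic; a
global mode uses the most-active channel's r1 everywhere. The most-active
channel maximizes [max ΔHbO of training-trial 1 − max resting ΔHbO], ties
to the lowest id. r2 = r1 + 0.3(p1 + SD) with p1 and SD the peak and
standard deviation of the across-trials average ΔHbO of that channel over
the training session.

Detection per trial: a candidate opens at the first sample in Phases 3–5
with r1 < |p| ≤ r2 inside the candidate window (default (0, 4] s from task
onset; the window and the confirmation boundary are parameters because the
verbal rule "within first 2–4 s … after 2–4 s" admits both readings, and
the defaults take the permissive window with a 2 s confirmation boundary).
Any in-window excursion above r2 voids the candidate as a false dip; a
transition into Phases 7–8 at or after the boundary confirms it. Detection
time is the candidate-opening time; human-readable outputs truncate it to
two decimals, the same convention as horizon labels (q = 20 at 9.19 Hz is
2.176 s, printed 2.17). The one-sample granularity at 9.19 Hz is 0.1088 s.
When predictions replace measured trajectories, both are scanned on the
same trial-aligned time base, so their detection times are directly
comparable; the practical gain is that the predicted trajectory is
available q samples before the measured one.

## Synthetic data generator

The generator emulates the finger-tapping study conditions: fs = 9.19 Hz,
a 30 s resting baseline (the calibration segment; its duration is a config
knob since no canonical value exists) followed by two sessions of six
trials (10 s task + 20 s rest), 36 channels by default with active subset
{17, 18, 21, 29, 33}. Active channels carry HbO gain 1.0 (unit-peak dHRF),
HbR gain −0.3 (the canonical antagonistic ratio), and an initial-dip
component of gain 0.4 built from the cHRF's own negative early lobe
(clipped to the first 2.5 s, unit trough) so the injected dip has exactly
the shape the response model assumes; the HbR dip is mirrored with the
same −0.3 ratio so the dip raises ΔHbR. Noise per channel and chromophore:
cardiac 1.0 Hz (amplitude 0.05), Mayer 0.1 Hz (0.10), respiration 0.25 Hz
(0.05), i.i.d. Gaussian sd 0.1, linear drift 0.002 units/s, with
per-channel random sinusoid phases. All sub-streams draw from generators
spawned deterministically from the master seed (`SeedSequence`), making the
record a pure function of (config, seed).

What this does *not* emulate: optical-density-to-concentration conversion,
motion artifacts, instrument-specific noise, inter-subject variability,
nonstationary coupling. Consequently the packaged-dataset tests establish
that the pipeline behaves as designed under its own assumptions — %FIT
degrades with horizon, the kernel predictor dominates the linear one at
long horizons, predicted trajectories advance detection — not that those
effect sizes transfer to measured cortical data. On this synthetic material
the KRLS-over-RLS margin (~3–7 %FIT points at q = 15) is far smaller than
on real recordings, because the band-limited synthetic signals are close to
linearly predictable.

## Problem sizes and defaults

The packaged demonstration dataset uses 8 channels (5 active) under the
full paradigm — 3,575 samples per series — which keeps the two-model,
five-horizon sweep at roughly half a minute of CPU while still exercising
every stage at study timing; the full 36-channel montage is generated and
round-tripped in tests but not swept. Pipeline defaults throughout equal
the study settings: λ = 0.98, R = 1e-8, kernel scales 1, orders (1, 1, 0),
horizons {1, 5, 10, 15, 20}, Butterworth order 4 at 0.01/0.15 Hz, session
1 train / session 2 test.

Filtering is causal (forward-only) by default because the package's claim
is online operation; zero-phase filtering is provided for offline
reproduction. The band-pass is the cascade of the low-pass and high-pass
sections, not a single 8th-order design.

## Known limitations

- The sigmoid kernel's indefiniteness means KRLS with it is only
  well-posed for restricted input regimes; the implementation surfaces the
  failure as a diagnostic error instead of guarding against it silently.
- The streaming evaluation absorbs the pair (φ, y(k+q)) immediately after
  predicting; a strictly online system would delay each update by q
  samples. This is the standard simplification and affects only how fresh
  the model state is, never the causality of an individual prediction.
- Dip detection reports the first qualifying sample; it does not estimate
  sub-sample onset or integrate evidence across channels.
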