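# nirsdip

Online prediction of fNIRS hemodynamic signals and fast initial-dip
detection for brain–computer interfaces.

Functional near-infrared spectroscopy (fNIRS) measures cortical
oxy-/deoxyhemoglobin changes (ΔHbO/ΔHbR), but the hemodynamic response lags
neuronal activation by seconds, which throttles fNIRS-based BCIs. Two ideas
shorten that lag. First, an *online q-step-ahead predictor* forecasts the
hemodynamic signal q samples into the future, using either exponentially
weighted recursive least squares (RLS) or kernel RLS (KRLS) with
approximate-linear-dependency (ALD) dictionary sparsification. Second, the
*initial dip* — the brief early decrease in ΔHbO from local oxygen
extraction, spatially specific to active cortex — is detected in the
vector-phase plane of (ΔHbO, ΔHbR) with dual calibrated threshold circles.
Running the detector on predicted instead of measured trajectories moves
detection close to the sampling limit.

## Model

Per channel i, brain activity is a low-order ARX form

    y_i(k) = Σ_n a_n y_i(k−n) + Σ_m b_m u(k−m) + c_0 + ε_i(k)

whose input u is the *desired HRF*: the canonical HRF — a linear
combination of three gamma functions h(t) = Σ_j A_j t^(α_j−1) β_j^{α_j}
e^{−β_j t} / Γ(α_j), whose first lobe models the initial dip — convolved
with the task boxcar s(k). Coefficients are estimated online; in kernel
form the KRLS recursion maintains the exact kernel ridge regression
solution a(k) = (K_k + Rλ I)⁻¹ y(1:k) over an ALD-sparsified dictionary,
with Gaussian, polynomial, or sigmoid kernels. Prediction quality is scored
as percent of captured variance,

    %FIT = 100 · (1 − Σ(y − ŷ)² / Σ(y − ȳ)²).

For detection, the plane is rotated 45°: ΔCBV = (ΔHbO+ΔHbR)/√2,
ΔCOE = (ΔHbR−ΔHbO)/√2; eight phases partition the plane, Phases 3–5 open a
dip candidate when the trajectory sits between the circles r1 (maximum
resting-state magnitude) and r2 = r1 + 0.3(p1 + SD), and a later handover
to Phases 7–8 confirms it.

Because real multi-channel fNIRS recordings of this kind are not publicly
distributable, the package ships a synthetic generator that reproduces the
experiment's statistical structure: 9.19 Hz sampling, two sessions of six
30 s trials (10 s finger-tapping task + 20 s rest) after a 30 s resting
baseline, 36 channels with a configurable active subset, three-gamma
responses with an injected initial-dip lobe, sinusoidal cardiac/Mayer/
respiratory noise, slow drift, and Gaussian noise.

## Worked example

```python
from nirsdip import SignalPredictionModel, bandpass, generate_dataset
from nirsdip.pipeline import dhrf_for_record
from nirsdip.simulate import SimulationConfig

record = generate_dataset(SimulationConfig(n_channels=8,
                                           active_channels=(2, 3, 5, 6, 8)),
                          seed=1)
filtered = bandpass(record)                       # 0.01–0.15 Hz, order 4
u = dhrf_for_record(filtered)                     # three-gamma dHRF input
results = SignalPredictionModel(filtered, u, model="krls",
                                kernel="gaussian").fit()
print(results.summary())
```

prints

```
q-step-ahead prediction results
==============================================
model: krls-gaussian    strategy: direct
orders: n_o=1 m_o=1 p_o=0    lambda=0.98 R=1e-08
test session: 2    channels: 8
----------------------------------------------
   q    sec       %FIT HbO       %FIT HbR
   1   0.10    99.9 ±  0.1    99.8 ±  0.1
   5   0.54    96.7 ±  3.3    95.9 ±  2.5
  10   1.08    88.7 ± 11.5    85.8 ±  8.7
  15   1.63    79.8 ± 20.9    74.6 ± 15.9
  20   2.17    73.7 ± 27.5    67.2 ± 20.7
==============================================
```

Each row is one prediction horizon (q samples, i.e. q/9.19 s, truncated to
two decimals): models are trained online through the resting baseline and
session 1, then scored on session 2. %FIT decreases as the horizon grows —
the predicted signal carries less of the measured signal's information the
further ahead it must look — and the Gaussian-kernel predictor outperforms
linear RLS, most visibly at long horizons. Feeding the q=15 (1.63 s ahead)
trajectories into the vector-phase detector then yields dip detections down
to a single sample period (0.11 s) after task onset:

```python
from nirsdip import VectorPhaseModel
vp = VectorPhaseModel(filtered)
dips = vp.fit(trajectories={ch: (results.result(ch, "hbo", 15).y_pred,
                                 results.result(ch, "hbr", 15).y_pred)
                            for ch in record.active_channels})
print(dips.summary())
```

```
initial-dip detection
========================================
channels scanned: 5   trials/channel: 6
candidates: 30   confirmed: 30
detection time (s): min 0.10  median 0.10  max 2.50
========================================
```

The same pipeline is available from the shell:

```sh
nirsdip simulate --seed 1 --out rec.csv
nirsdip preprocess --in rec.csv --out filt.csv
nirsdip predict --in filt.csv --model krls --kernel gaussian --out fits.tsv
nirsdip detect --in filt.csv --out dips.tsv
nirsdip run --demo --out-dir demo_run     # everything at once
```

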