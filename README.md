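# pherospace

Analysis toolkit for **spatial coding of bilateral pheromone signals** in
*Drosophila*. A male fly emits the low-volatility pheromone cVA; a nearby
receiver fly senses it with Or67d receptor neurons (ORNs) on both antennae.
Because the signal falls off steeply with distance, the concentration at
the antennae encodes the male's **distance**, and the small left/right
difference between the antennae — amplified by contralateral inhibition in
the antennal lobe — encodes his **angular position**. This package
implements the quantitative analyses by which those codes are measured and
read out, together with a forward-model synthetic data generator with
known ground truth, so every estimator ships with parameter-recovery and
oracle tests.

It is aimed at systems-neuroscience practitioners working with calcium
imaging traces, animal-tracking trajectories, spherical-treadmill
recordings and connectome synapse-table exports.

## What it computes

* **Trace preprocessing** (`pherospace.traces`) — ΔF/F₀ with a
  baseline window from 1 s after sweep start to stimulus onset, zero-phase
  Butterworth smoothing, per-ROI max normalization, peak/mean responses,
  half-rise time, adaptation index, pose-track cleaning.
* **Tuning models** (`pherospace.tuning`) — four-parameter logistic
  distance tuning R(d) = base + (top − base)/(1 + e^{(d − ED₅₀)/s}) fitted
  by nonlinear least squares (reports ED₅₀ and the residual standard error
  √(RSS/(n − 4))); stimulus–response cross-correlation lags; the rectified
  first-derivative (approach-speed) model; a normality-gated statistical
  dispatch (Shapiro–Wilk + F-test → t-test / rank tests, with
  Benjamini–Hochberg post-hocs).
* **Spatial code** (`pherospace.spatial`) — the 16-position hexagonal
  stimulation lattice (rings at 1, √3 and 2 mm, no position directly
  behind), angular tuning with linear-in-distance interpolation onto the
  √3 mm ring, sin/cos regressions of the bilateral difference and sum, and
  the bivariate linear decoder (x, y) ~ (R − L) + (R + L) with angular and
  positional error reports, in-sample or leave-one-fly-out.
* **Behavior** (`pherospace.behavior`) — opposite-sex-preference score
  OSP = (t_near,opposite − t_near,same)/T × 100 with distance profiles;
  turn-initiation detection gated on angular velocity (>60°/s), sensation
  range (antennae–abdomen < 5 mm, centroids > 2 mm) and a 30 s
  post-contact cool-off; circular medians and a nonparametric
  common-circular-median test; treadmill trial classification and
  dead-reckoned lateral displacement with a permutation test.
* **Connectome** (`pherospace.connectome`) — downstream-partner selection
  (≤10 synapses excluded, >50 included, in between a boundary line from
  (10, 4%) to (50, 0.5%) relative input), input-selectivity classes
  (multimodal / DA1-selective / mixed-olfactory), per-glomerulus
  contra/ipsi ORN-input ratios, cable fraction inside a neuropil volume on
  1 µm-resampled pruned SWC skeletons, Ward clustering of a similarity
  matrix.
* **Synthetic data** (`pherospace.synthetic`) — the forward model behind
  all recovery tests: logistic-in-distance receptor drive per antenna, a
  first-order calcium kernel, a bilateral PN stage
  PN = w_ipsi·ORN_same + w_contra·ORN_other − g_inhib·ORN_other (clipped at
  0), lattice sessions, arena random walks with controllable attraction,
  scripted turn scenarios, treadmill trials and toy synapse tables.

## Worked example

```python
from pherospace.spatial import build_hex_lattice, cross_validate_decoder, \
    angular_tuning, sincos_regression
from pherospace.synthetic import ForwardModelParams, generate_lattice_session

lattice = build_hex_lattice()                      # 16 positions, 11 angles
params = ForwardModelParams(noise_sd=0.05)         # trial noise in ΔF/F units
responses = generate_lattice_session(params, lattice, n_flies=8,
                                     n_trials=3, seed=7)

tuning = angular_tuning(responses, lattice)
reg = sincos_regression(tuning.angles,
                        tuning.right_mean - tuning.left_mean,
                        tuning.right_mean + tuning.left_mean)
result = cross_validate_decoder(responses, lattice, scheme="loo-fly")
print(reg["diff_vs_sin"][2], reg["sum_vs_cos"][2])
print(result.median_angular_error)
```

prints

```
0.989 0.995
14.8
```

— the left/right response *difference* tracks sin(θ) and the *sum* tracks
cos(θ) of the male's angular position (R² of 0.989 and 0.995 at this noise
level), and the linear decoder reads back the angle of held-out single
trials with a median error of ~15°. With `noise_sd=0` both R² become
exactly 1 and the decoding error vanishes. The `examples/` directory holds
one narrative script per capability (distance tuning, angular decoding,
bilateral contrast, behavior, treadmill, connectome rules).

A thin CLI wraps the generators and the end-to-end pipeline:

```sh
pherospace simulate lattice --seed 1 --out responses.csv
pherospace run-all --seed 1 --out report.json
```

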