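# Methods

This note documents the models, conventions, numerical choices and known
limitations of the package. It describes what the code computes; every
number quoted here is produced by the test suite or
`scripts/acceptance.py` at run time.

## The forward model

All recovery tests run against a generative model of bilateral pheromone
sensing (`pherospace.synthetic`).

**Receptor stage.** The instantaneous drive of the Or67d receptor neurons
(ORNs) at one antenna is a logistic function of the distance d (mm) from
the male's abdomen to that antenna:

    R(d) = base + (top − base) / (1 + exp((d − ED₅₀)/slope)).

The logistic-in-distance form is chosen because the imaging analyses fit
exactly this sigmoid to distance-tuning data; pheromone concentration is
not modeled separately (a steeper or shallower concentration–distance
mapping is absorbed into ED₅₀ and slope). The drive passes through a
first-order (exponential) calcium kernel with time constant `tau_rise`
and acquires i.i.d. Gaussian noise per sample. Noise is white rather than
pink — the simplest model consistent with trial-to-trial SEM shading in
calcium data; consequences of this simplification are noted below.

**Bilateral stage.** Each projection neuron (PN) combines the two
antennae linearly,

    PN_side = w_ipsi·ORN_same + w_contra·ORN_other − g_inhib·ORN_other,

clipped at zero (an option exposes the un-clipped drive, whose negative
excursions model sustained suppression). `w_contra` is direct
contralateral excitation — ORN axons innervate both antennal lobes — and
`g_inhib` is inhibition relayed by a commissural GABAergic interneuron
(il3LN6-like) that is driven almost exclusively by the *contralateral*
antenna.

**Defaults and their provenance.**

| parameter | default | unit | rationale |
|---|---|---|---|
| top, base | 1.0, 0.05 | – | normalized responses; small far-field floor |
| ED₅₀ | 2.4 | mm | PN-range half-maximal distance (presets 2.2/2.4/1.5 for the ORN/lPN/lvPN regimes) |
| slope | 0.5 | mm | mid-range steepness consistent with responses saturating near 1 mm |
| w_ipsi : w_contra | 1 : 0.691 | – | ipsi/contra ORN→lPN synapse counts 5184 : 3580 |
| g_inhib | 1.0 | – | net contralateral influence inhibitory (see below) |
| tau_rise | 0.3 | s | fast calcium indicator rise |
| noise_sd | 0.05 | ΔF/F | trial noise; recovery tests sweep it rather than rely on one value |
| antenna_sep | 0.3 | mm | order of a fly head width; configurable, not measured |
| front_mod | 0.25 | – | front-to-back response modulation (body occlusion), drives the cosine component of the bilateral sum |

**Contrast amplification condition.** In the linear model the PN-level
left–right contrast relates to the receptor-level contrast by the factor
(w_ipsi − w_contra + g_inhib). Amplification therefore requires the *net*
contralateral influence to be inhibitory: g_inhib > w_contra (with
w_ipsi = 1). It is not a consequence of any positive g_inhib. The default
g_inhib = 1.0 > 0.691 satisfies the condition, consistent with the
anatomy (the interneuron receives ~5× more contralateral than ipsilateral
ORN input and inhibits PNs strongly); the contrast property tests assert
amplification over a gain grid above w_contra and verify that silencing
the interneuron (g_inhib = 0, the chemogenetic-block analogue) collapses
the contrast.

## The lattice-session generator: an idealized angular code

The hexagonal-lattice experiment asks whether one bilateral PN pair
suffices to decode the male's angle with a *linear* read-out of the
response difference and sum. For the generator, deriving lattice
responses purely from the per-antenna logistic has two consequences that
contradict the phenomenon being modeled: (i) a linear decoder cannot
exactly invert the nonlinear distance map, so "noiseless ⇒ exact
decoding" would fail by construction, and (ii) the bilateral *sum* over a
fixed-distance ring is constant to O(antenna_sep²) rather than varying
with cos θ — whereas a real receiver's body attenuates stimuli behind it,
producing exactly such a front/back modulation.

The default lattice generator (`mode="angular"`) therefore draws
responses from the idealized sinusoidal bilateral code

    sum(θ)  = s0·(1 + front_mod·cos θ),
    diff(θ) = d1·sin θ,
    L, R = (sum ∓ diff)/2,  + Gaussian trial noise,

with s0 and d1 derived from the logistic parameters at the middle ring
(s0 from the net summed PN gain, d1 from the logistic slope across the
inter-antennal separation times the contrast-amplification factor). This
is the generative model *of the angular code itself*: it reproduces the
empirically observed structure (difference ∝ sin θ, sum ∝ cos θ) exactly
in the noiseless limit, which is what makes exact parameter- and
angle-recovery tests possible. A `mode="biophysical"` alternative
evaluates the per-antenna logistic + inhibition circuit at every lattice
position; it is used for the contrast-amplification property and for
realism checks, and decoding on it is approximate by design. In angular
mode the responses do not vary across rings at a fixed angle; radial
coding is covered by the distance-tuning generator instead.

## Conventions

* **Coordinates.** Receiver at the origin; x frontal, y to the
  receiver's right; angle = atan2(y, x) in degrees, 0° frontal, positive
  right, wrapped to (−180°, 180°]. World tracks use standard CCW-positive
  orientations; the egocentric bearing flips the sign so that "stimulus
  to the receiver's right" is +90°.
* **Sampling.** Imaging default 7.2 Hz (the lag quantization 1/7.2 s
  makes cross-correlation lags multiples of ~0.139 s); tracking 30 Hz;
  treadmill 50 Hz.
* **ΔF/F₀ baseline** is the half-open window [sweep start + 1 s,
  stimulus onset): frames exactly at onset are excluded.
* **Smoothing** is an order-2 Butterworth at 1 Hz applied
  forward–backward (zero phase), so smoothing cannot bias
  cross-correlation lags.
* **Adaptation index** is end-of-stimulus response / peak response, so
  that lower values mean stronger adaptation. (The opposite ratio would
  invert the direction of the statement; the choice is flagged because
  the verbal definition is ambiguous.)
* **Interpolated angular tuning** onto the √3 mm ring is linear in
  distance: v = v₁ₘₘ·(2 − √3) + v₂ₘₘ·(√3 − 1) ≈ 0.268·v₁ₘₘ + 0.732·v₂ₘₘ.
* **Decoder targets** default to the unit circle (cos θ, sin θ); a
  `target="position"` option predicts raw mm coordinates. Whether the
  original analysis was cross-validated is not documented, so both
  in-sample and leave-one-fly-out schemes are provided; leave-one-fly-out
  is the default.

## Behavioral rules

* **Track cleaning** removes frames with centroid velocity > 25 mm/s or
  orientation change > 400°/s; no interpolation.
* **Turn detection**: onset when |angular velocity| (central difference
  of the unwrapped orientation) rises above 60°/s; onsets closer than 1 s
  merge into the first; the stimulus must be in sensation range
  (antennae–abdomen < 5 mm and centroids > 2 mm); turns during close
  contact (centroids < 2 mm) and for 30 s after it ends are excluded —
  "within and during 30 s after" is read as: from contact onset until
  30 s after the centroid distance exceeds 2 mm again; finally events
  whose |Δfacing| residual against the |angular velocity| regression
  exceeds 3 SD are dropped. When a tracker provides no keypoints,
  antennae/abdomen are synthesized at ±1.2 mm along the heading.
* **OSP** uses the single-assay duration as T (bounding the score in
  [−100, 100]); frames within 2 mm of the arena wall are excluded.
* **Treadmill**: rotational °/s convert to rim speed via the 4.5 mm ball
  radius. Movement onset is the first peristimulus frame where the
  3-axis speed exceeds 0.25 mm/s out of a quiescent frame. Lateral
  displacement dead-reckons the fictive path over 1 s: the heading
  accumulates rotation and forward/lateral velocities are projected
  through it; the sign is positive toward the presentation side.

## Statistical tests

* **Dispatch policy**: Shapiro–Wilk normality on each group and an
  F-test of variances at α = 0.05 select between the parametric branch
  (t-tests) and the rank branch (Wilcoxon rank-sum / signed-rank);
  multi-group designs use Kruskal–Wallis (independent) or Friedman
  (repeated) followed by pairwise rank tests with Benjamini–Hochberg
  correction.
* **Common circular median test**: the pooled circular median defines a
  diameter; per-group counts on one side of it are compared. For two
  groups the margins are fixed by the pooled-median construction, so the
  exact hypergeometric (Fisher's exact) p-value is used; it measures
  ~4% type-I error at a nominal 5% (the asymptotic χ² form, kept for
  k > 2, runs measurably liberal at n = 50). The circular median itself
  minimizes the summed circular distance, evaluated over data points and
  adjacent circular midpoints, with ties broken toward the circular
  mean.
* **Permutation test** for lateral displacement: two-sided difference of
  means, enumerated exactly when the number of reassignments is ≤ 20 000,
  Monte-Carlo with the add-one correction otherwise (default 10 000
  permutations, seeded; the seed is recorded in the report).

## Connectome rules

Boundary closures, which the verbal rules do not fix, are: "not more
than 10 inputs" → ≤ 10 excluded; "more than 50" → ≥ 51 included; the
boundary line p(s) = 4 − 0.0875·(s − 10) percent is exceeded strictly.
Relative input fractions divide seed-type synapses (ROI-filtered, e.g.
LH-only for lPN seeds) by the cell type's total inputs across the whole
table. Similarity matrices are converted to distances as 1 − s/s_max
before Ward linkage. Skeleton cable fractions are computed on the
subtree distal to the stored prune node, resampled at 1 µm along
unbranched paths (endpoints included), as inside-nodes / all-nodes.

## Problem sizes

The shipped tests and the acceptance script use: 8 flies × 3 trials per
condition, the ten standard presentation distances, 16 lattice
positions, 200 simulation seeds for ED₅₀ recovery, 100 random instances
per oracle-equivalence check, and 1 000 null simulations per calibration
check — sizes chosen so the full suite runs in well under a minute per
module while keeping Monte-Carlo standard errors at or below a few
tenths of a percent where calibration bands are asserted.

## What passing tests do and do not show

The generators emulate: sigmoidal distance dependence at the printed
distances, bilateral asymmetry amplified by contralateral inhibition,
trial-to-trial Gaussian noise, biased-random-walk arena behavior,
scripted turns, and planted connectome classes. They do **not** emulate:
odor plume dynamics or adaptation biophysics, pink/correlated noise,
tracking artifacts other than velocity outliers, posture-dependent
occlusion beyond the first-order cosine term, or database-scale
connectome heterogeneity. Parameter-recovery results therefore
demonstrate estimator correctness under the stated model, not
performance guarantees on arbitrary real recordings. The angular-code
generator in particular *builds in* the sinusoidal structure whose
empirical discovery motivated the decoder; tests on it validate the
read-out machinery, not the biological claim.

## Known limitations

* The 4-parameter logistic fit can be weakly identified when the data do
  not span both plateaus; the self-start (log-linearization) plus
  bounded `curve_fit` is robust for the shipped protocols but degenerate
  flat data are rejected rather than fitted.
* `crosscorr_lag` reports lags on the sample grid (no sub-sample
  interpolation), matching how such lags are conventionally quoted.
* The turn detector's outlier rule needs ≥ 3 events and nonzero velocity
  variance; with fewer events it is skipped.
* `contra_ipsi_profile` flags a zero ipsilateral count as NaN rather
  than infinity; callers must handle missing ratios.
* The toy connectome is a rule-testing fixture, not a biologically
  realistic network; only the planted counts (e.g. the 1901/359
  contra/ipsi DA1 inputs) carry meaning.
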