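# Methods

This note documents the models, parameters and numerical choices behind
`ramanbayes`, and what the synthetic fixtures do and do not establish.

## Problem setting

A fiber-coupled 785 nm Raman probe interrogates a ~50–85 µm spot of
resected breast tissue and returns one spectrum per target: intensity
(detector counts) over Raman shifts of roughly 147–3350 cm⁻¹ at ~4.5
cm⁻¹ resolution. Tumor-rich tissue differs from healthy tissue in two
robust ways visible to this probe: nucleic-acid signal rises in the
fingerprint region (a relative increase of the 796 cm⁻¹ DNA|RNA
ring-breathing/backbone band against the neighbouring 828 cm⁻¹
protein/saccharide band), and the C–H stretch signal in the
high-wavenumber region collapses as lipid-rich cytoplasm is lost. The
pipeline turns these contrasts into a per-target Bayesian tumor
probability with an explicit error estimate, supervised either by
histology or entirely autonomously.

## Preprocessing

Stages, in order, per spectrum:

1. **Crop** to [600, 3350] cm⁻¹, inclusive at both ends (all ranges in
   this package are inclusive). Below 600 cm⁻¹ the signal is dominated
   by fiber fluorescence and laser bleed-through.
2. **arPLS baseline subtraction.** The fluorescence baseline z solves
   the weighted penalized least-squares problem
   (W + λ DᵀD) z = W y, with D the second-difference operator,
   λ = 10⁵ (default) and W = diag(w). Weights are updated
   asymmetrically from the residual d = y − z using the logistic
   w = 1/(1 + exp(2(d − (2s − m))/s)) with m, s the mean and standard
   deviation of the negative residuals, so channels far above the
   baseline (Raman peaks) lose weight. Iteration stops when the
   relative change of the weight vector drops below ratio = 10⁻³, with
   a cap of 100 iterations (a `ConvergenceWarning` marks a capped run).
   Two guards handle degenerate inputs: a residual that is zero to
   rounding error (peak-free signals the penalized system fits exactly,
   threshold 10⁻¹⁰ relative — without it the reweighting would chase
   float noise chaotically) and an empty negative-residual set. The
   sparse solver is validated against a dense direct solve of the
   identical system at every iteration (tests, rtol 10⁻⁸).
3. **Savitzky–Golay smoothing**, window 7 channels, polynomial order 3.
   The order is a standard choice that preserves peak shape at this
   window; it is configurable. Edges are handled by fitting the
   polynomial on the truncated window (no mirrored samples), so
   polynomials of degree ≤ 3 pass through exactly.
4. **Mean-centering** and **unit Euclidean normalization**. After this,
   spectra are unit vectors; band fluxes are relative intensities and
   negative values are expected. Constant spectra are rejected.

Smoothing order relative to baseline subtraction matters only through
the nonlinear arPLS reweighting (all other stages are affine-equivariant,
so e.g. normalizing first provably changes nothing); the pipeline fixes
the order above and a regression test pins it.

The detector-silent 1800–2800 cm⁻¹ zone stays in every data structure;
only `plotting.plot_spectra` drops it, for display.

## Band features

The nine diagnostic centers {796, 828, 1048, 1300, 1437, 1654, 2853,
2896, 2937} cm⁻¹ are fixed; `suggest_bands` reproduces the
variance-maxima heuristic that motivates them (information-rich
channels outside ink-contamination regions) but never alters the set.
Band flux = intensity at the channel nearest the center, ties to the
lower wavenumber; a ±6 cm⁻¹ window mean (≈ the instrument resolution)
is available but off by default, since the band list specifies single
peak positions. Feature sets: FP (6 bands), HW (3), FPHW (9,
column-concatenation of FP then HW). The high-wavenumber region is
taken as 2800–3000 cm⁻¹ (all three HW bands lie inside it).

## Autonomous labeling

k-means with k = 2, squared Euclidean distance and k-means++
initialization runs on the band-flux matrix (not on PCA projections; a
PCA-input mode is deliberately not implemented). `fit_kmeans` performs
`n_restarts` independent runs seeded seed…seed+n_restarts−1 and keeps
the minimum-inertia run, making results reproducible and robust; the
default is 10 restarts. On unstructured tiny instances (≤ 8 points)
k-means with few restarts can stop in a local optimum; raising the
restart count to ~100 recovers the exhaustive-enumeration global
optimum on every instance in the test suite's 50-instance sweep, at
well under a second per instance. Structured two-cluster data of the
kind this pipeline sees needs far fewer.

Cluster → class semantics: for any feature set containing HW bands, the
centroid with the smaller mean HW flux is *tumor* (high-wavenumber
collapse); for FP-only features, the centroid with the larger
flux(796)/flux(828) ratio is *tumor* (nucleotide rise). Exact ties —
measure-zero in practice — label cluster 0 tumor with a warning. The
mapping is invariant to cluster relabeling.

## Networks and training

Each classifier is a 3-layer perceptron: n inputs (9/6/3 for
FPHW/FP/HW), 3 tanh hidden units, 2 softmax outputs, with one-hot
targets [1,0] = tumor, [0,1] = healthy. Inputs are min-max scaled to
[−1, 1] with training-set statistics (constant features map to 0).
Training minimizes full-batch cross-entropy with Møller's scaled
conjugate gradient; stops at a gradient infinity-norm below 10⁻⁶, a
loss below 10⁻¹⁰, or 1000 iterations (defaults; stopping criteria are
engineering choices). Weights initialize from a seeded uniform
distribution with Glorot-style limits; biases start at zero. A fixed
seed gives bit-identical training — stochasticity enters *only* through
the seed — which is what makes the variance machinery meaningful. There
is no validation split, regularization or class weighting: with tens of
targets and leave-one-out evaluation, all n−1 training samples train.

**Leave-one-out round robin.** Each target i is scored by a network
trained on the other n−1 targets (or on the eligible training pool
minus i when a pool is restricted, e.g. histology end-members); no fold
ever sees its test target. Fold seeds follow the documented schedule
`fold_seed = base · 10⁶ + cycle · 10³ + fold`, with the effective base
`base_seed · 10 + config_index` (FPHW = 0, FP = 1, HW = 2), reduced
mod 2³¹−1. Any fold whose training pool loses a class fails loudly with
the target named.

## Uncertainty quantification

For each configuration, 10 full LOO cycles with fresh weight seeds
yield per-target cycle probabilities; V_RA is their sample variance and
the cycle mean is that configuration's P. V_ER is the sample variance of
the three configurations' means. Both use denominator n−1 (n = 10 and
n = 3); the convention is recorded in report metadata because either
convention is defensible and downstream thresholds scale with it.

Flags: for each variance family (V_RA per configuration, V_ER) the
threshold is the family mean plus one family standard deviation; values
strictly above are flagged. This makes flagging invariant to target
order and to global rescaling of a family, and a zero-spread family
flags nothing. A degree-5 least-squares polynomial of V_RA against mean
P, intersected with the 1σ level, reports the boundary-zone edges
(where intra-network variance rises between the confidently-healthy and
confidently-tumor regimes); it is a reporting aid with no effect on
classification.

Binning uses the *maximum* of the three configuration means — the most
alarmed network drives triage — into five equal-width bins
[0,0.2), [0.2,0.4), [0.4,0.6), [0.6,0.8), [0.8,1.0], the last closed.
The histology-vs-bin cross-tabulation excludes (and counts) targets
without a histology quintile.

## Prediction statistics

Accuracy = 100·(TP+TN)/total, sensitivity = 100·TP/(TP+FN),
specificity = 100·TN/(TN+FP), tumor positive everywhere (stated in
report headers). Ratios are exact rationals internally; displayed
values round half-up to two decimals; zero-denominator ratios report as
NA, never 0.

## Synthetic data generator

The generator emulates the statistical structure the pipeline assumes,
not any measured amplitudes (no quantitative spectra are published for
this setting, so defaults cannot be validated against printed numbers):

- axis 600–3000 cm⁻¹ in 2 cm⁻¹ steps (oversampling the ~4.5 cm⁻¹
  resolution; widen to 147–3350 to exercise cropping);
- pseudo-Voigt tissue bands, FWHM 20 cm⁻¹, at the nine diagnostic
  centers plus filler bands, with healthy amplitudes satisfying
  796 < 828 and a strong HW triplet, and tumor amplitudes satisfying
  796 > 828 with the HW triplet scaled by `hw_collapse_factor` = 0.3;
- boundary targets as convex mixtures m·tumor + (1−m)·healthy,
  m ∈ {0.25, 0.5, 0.75}, with class = tumor iff m ≥ 0.5 and the derived
  histology quintile the nearest of {0, 25, 50, 75, 100} to 100·m;
- a fluorescence baseline (decaying exponential plus a mild quadratic,
  scale 5 — a few times the tallest Raman band, as in tissue);
- additive Gaussian noise, σ = 0.02 (~1 % of the strongest band); an
  optional signal-dependent mode exists but is off by default;
- per-target ±10 % per-band amplitude jitter in datasets;
- optional surgical-ink contaminants: narrow (FWHM 8 cm⁻¹) peaks
  constrained to lie ≥ 15 cm⁻¹ from every diagnostic band, so
  contamination never compromises the features by construction.

Everything is deterministic given (config, m, seed).

**What passing on synthetic data shows — and does not.** The fixtures
establish that the machinery is correct: preprocessing contracts hold,
clustering recovers a separable partition, the ensemble's probabilities
track the mixture fraction monotonically, variance flags land on
boundary targets. The generator's classes are far better separated than
real surgical tissue, where patient-to-patient biochemistry, depth
mismatch between probe and H&E section, and heterogeneity at the laser
spot scale all blur the boundary; perfect synthetic statistics therefore
say nothing about clinical accuracy, only that the algorithms do what
they claim on data with the assumed structure.

## Pipeline modes and sizes

`gold_standard="kmeans"` trains each feature set's networks on its own
autonomous cluster labels; `"histology"` trains only on end-member
targets (quintile 0 or 100) while scoring everything, and
`balance_classes=True` subsamples the larger training class to the
smaller's size (seeded). Feature matrices are identical between modes;
only the label source differs. All randomness flows from `base_seed`.

Default study sizes used by the test suite and `scripts/acceptance.py`
— 40+40 end-member targets and a 5×12 mixture grid, 3 configurations ×
10 cycles × leave-one-out ≈ 4,200 network trainings — run in well under
a minute on one CPU; the tiny architectures train in a few
milliseconds each.

## Known limitations

- Band flux is a single-channel read-out; miscalibrated wavenumber axes
  shift it (no wavelength calibration is attempted — out of scope).
- The cluster-naming rule presumes the HW-collapse/796-rise phenomenology;
  a dataset violating it would be labeled inversely, which the
  histology cross-check (when available) would expose.
- The 1σ flag thresholds are relative to the analyzed batch; a batch of
  uniformly uncertain targets flags only its worst members.
- k-means and the networks see the same features; their agreement is
  not independent evidence.
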