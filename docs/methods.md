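# Methods

## Model overview and assumptions

`wavediv` scores a micrograph patch by how far its wavelet-texture profile
sits from a *normal* reference, on a one-dimensional malignancy scale
d ∈ [0, 1] with fixed decision bands ([0, 0.4) normal, [0.4, 0.6) benign,
[0.6, 1] malignant). The model's central assumptions are:

* texture statistics of the three classes are ordered: benign lies between
  normal and malignant on most informative attributes, so a scalar distance
  from normal can separate all three;
* attributes are treated independently, both in the weighted divergence
  score and in the exponential likelihood model (a naive-Bayes-style
  factorization);
* class priors are equal (the design is balanced).

## Wavelet features

A 4-level 2-D DWT with the orthonormal Daubechies db4 wavelet decomposes
each patch into 13 stored subbands (CA4; CH/CV/CD at levels 1–4).
Boundary handling is **periodization**, chosen deliberately over the common
symmetric default: it is the only standard mode that yields exact dyadic
subband sizes (N/2^l) and Parseval energy conservation, which makes the
normalized energy NE = Σ|C|²/Σ|I|² interpretable as an exact energy
fraction (Σ NE over the 13 bands = 1; tested to 1e-6). Periodization
implicitly treats each patch as a torus; for texture statistics the induced
edge wrap-around is immaterial.

Per band, seven statistics form the 91-attribute vector. Conventions:

* `std` is the population standard deviation (divisor n);
* `skewness`/`kurtosis` are standardized 3rd/4th central moments; kurtosis
  is **not** excess (Gaussian ≈ 3);
* `entropy` is Shannon entropy in bits of a 64-bin histogram over the
  band's own [min, max];
* zero-variance bands define skewness = kurtosis = entropy = 0, and an
  all-zero patch defines NE = 0 (with a warning).

Attribute order is fixed (band-major: `energy_CA4 … NE_CD4`) because weight
vectors are indexed positionally.

## Class references and likelihoods

Each attribute's three class distributions share one set of 64 bin edges
spanning the pooled training range extended by 5% on each side; shared
support is required by the divergences. Histograms are smoothed by a
Gaussian kernel of 1 bin standard deviation (discrete convolution with
reflecting boundaries, which keeps a uniform histogram uniform), floored at
ε = 1e-9, and renormalized. The floor guarantees every divergence is finite.
64 bins balance resolution against the ~90-patch class training size; the
1-bin bandwidth interpolates between neighboring bins without washing out
class differences.

The exponential likelihood route models each attribute per class as
Exp(λ) after the shift x' = x − min_pooled + δ (δ = 1e-6 of the pooled
range), because several attributes (means, skewness) can be negative while
the exponential support cannot. λ is the closed-form MLE 1/mean(x'). Test
values falling below the pooled training minimum are clipped to x' = 0.
Posteriors are the stable softmax of the three joint log-likelihoods under
equal priors. Per-attribute 5th–95th-percentile class intervals ("stage
ranges") are stored for reporting and QC only; they do not enter the
decision.

## Divergences and attribute weighting

Three symmetric f-divergences are exposed on a common [0, 1] range so one
set of bands serves all three:

* JSD: base-2 Jensen–Shannon divergence (information radius);
* HD: squared Hellinger distance, ½ Σ (√p − √q)²;
* TD: triangular discrimination Σ (p−q)²/(p+q), halved from its native
  [0, 2].

A binary-KL variant of JSD is available as `jsd_variant="printed"` for
comparison only; it is clipped and not used by any default path.

Attribute weights: W_av(i) is the mean divergence of attribute i's class
distributions over the three unordered class pairs; H(i) is the entropy
(bits) of the pooled all-class distribution, floored at 0.1 bit so
near-deterministic attributes cannot blow up; W(i) = W_av(i)/(z·H(i)) with
z the constant making Σ W(i) = 1. If no attribute separates the classes at
all, weights fall back to uniform rather than dividing by z = 0.

## The d-test and calibration

A test patch's attribute value becomes a point-mass distribution on its
shared bins, smoothed and floored exactly like training distributions. The
raw score is the weighted divergence from the *normal* class reference, so
normal patches score low. Raw scores have no intrinsic scale, so a monotone
piecewise-linear calibration, fitted on training data, anchors the class
median raw scores at d = 0.2 / 0.5 / 0.8, extends the end segments linearly
and clips to [0, 1]. When classes are statistically identical the three
anchors nearly coincide; a 1e-9-of-range nudge keeps the map strictly
monotone, and banding then degenerates gracefully to chance-level
assignment. Band boundaries are half-open ([0.4, 0.6) is benign) so the
partition of [0, 1] is total and disjoint.

Consensus across the three divergences is by default the band of the median
d (`per_divergence` evaluation, where each divergence classifies
independently, is used for the six-group summary tables). Modality fusion
averages the two d values per divergence and multiplies-then-renormalizes
the posterior vectors; both choices are the minimal symmetric combiners and
are idempotent on identical inputs.

## Synthetic data generator

The generator emulates only the statistical structure the classifier
consumes — not SEM/AFM contrast physics:

* background: white noise blurred at a class correlation length
  (normal 6 px > benign 4.5 > malignant 3), scaled to a class contrast
  (0.05 / 0.09 / 0.13) around a 0.45 baseline;
* bright Gaussian blobs (σ = 4 px, amplitude 0.25), Poisson-placed with
  class density 1.5 / 4.0 / 7.0 per 10⁴ px — a caricature of nuclear
  enlargement and crowding in malignant texture;
* modality filter: SEM adds high-pass grain (gain 0.04); AFM low-passes at
  radius 1.2 px;
* additive Gaussian noise (sd 0.02), then clipping to [0, 1].

`separation` linearly scales each class's offset from the benign (middle)
parameters: 0 collapses all classes onto one distribution (the null used by
chance-level checks), 1 is the default. Class parameters are monotone in
blob density and contrast so the one-dimensional d band structure can hold.
Defaults were calibrated once so the default pipeline lands in a realistic
85–100% per-group accuracy range, then frozen; this calibrates the fixture,
not the method. Generation is bit-reproducible: every image draws from its
own child of `SeedSequence(seed)` in a fixed order.

What passing tests on synthetic data do **not** show: robustness to
acquisition artifacts (drift, charging, tip convolution), inter-patient
variability, stain/illumination shifts, or class imbalance — none of which
the generator emulates. Results on it validate the machinery, not clinical
performance.

## Evaluation

Per-group percent correct over the six groups (class × modality), total
correct count, and the average success rate (100 × total correct / total
used, 2 decimals). `aggregate_rates` reproduces totals from rounded
per-group percentages by rounding Σ rate·n/100 to the nearest integer
(rounded published rates imply fractional counts, e.g. 98% of 90 = 88.2).
Confidence intervals are plain percentile bootstrap (numpy
linear-interpolation percentiles at 2.5/97.5), 10,000 resamples by default,
seeded; precision/recall/F1 are macro-averaged over the three classes with
zero-denominator classes contributing 0.

## Problem sizes and defaults

Default experiment scale: 30 source images per class per modality at
256×256 (four 128×128 patches each), half the sources for training, half
held out — 360 test patches per run; properties are averaged over 10 seeds
(3 seeds for the separation-0 null). The acceptance script uses 5 seeds.
Training images within a source never split across train/test by default
(`split_by="source"`); `split_by="patch"` replicates per-patch splitting at
the cost of potential leakage.

## Known limitations

* The d-test measures distance from *normal* only; a pathological patch
  unlike both normal and malignant training texture still maps onto the
  single malignancy axis.
* The exponential likelihood is a crude shape model for symmetric or
  left-skewed attributes; posteriors are best read as relative scores.
* Attribute independence is assumed twice (weights, likelihoods); strongly
  correlated subband statistics are effectively double-counted.
* Calibration anchors depend on training medians; severe train/test shift
  moves the bands with no warning.
* With histogram sampling noise at n ≈ 10⁴, smoothed uniform histograms are
  near-uniform only to a max/min ratio ≈ 1.2 (exactly uniform inputs are
  preserved exactly).
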