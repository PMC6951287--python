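# Methods

## The screening problem and the model

A Raman spectrum of a liquid biological sample is modelled as

    y(w) = b(w) + Σ_j A_j g((w − c_j)/σ_j) + ε(w)

on a wavenumber grid w (cm⁻¹): a smooth, low-order polynomial background
b(w) (fluorescence and scattering), a set of vibrational bands with centers
c_j, widths σ_j, and amplitudes A_j, and detector noise ε. Class membership
(e.g. healthy vs. diseased) expresses itself in the *relative* band
amplitudes. The pipeline turns a matrix of such scans into a validated
two-group (or multi-group) classifier:

1. truncate to 400–1800 cm⁻¹ (closed interval);
2. remove b(w) with an asymmetric-cost polynomial fit (below);
3. scale each spectrum to unit Euclidean norm;
4. average replicate scans per specimen;
5. PCA on the processed matrix; retain k components;
6. linear discriminant classification in k-dimensional score space;
7. grouped leave-one-out (LOO) validation across a grid of k.

Steps run in exactly this order. Because normalization (3) precedes
averaging (4), an averaged spectrum has norm ≤ 1 rather than exactly 1;
`PreprocessConfig.renormalize_after_average` restores unit norm if wanted
(off by default, to keep the printed order's semantics).

## Baseline correction

The baseline is a polynomial of degree ≤ `poly_order` (default 3) that
minimizes an asymmetric truncated quadratic cost of the residual
r = y − p(w):

* r < 0 (data below the fit): cost `below_weight · r²` (default 100) — the
  baseline should stay under the data;
* r ≥ 0: cost `s² u²/(1 + u²)` with u = r/s — quadratic for r ≪ s but
  saturating at s², so band intensity cannot pull the fit upward.

The peak threshold s is the (1 − `peak_ratio`) quantile (default
`peak_ratio` 0.5) of the positive residuals of a moving-average-smoothed
working copy (window 5); smoothing keeps noise out of the threshold
estimate while the cost itself acts on the raw intensities, so a peak-free
polynomial input is fit *exactly* (any weighting of exact polynomial data
reproduces the ordinary least-squares solution). Starting from the OLS fit,
each outer round freezes s, minimizes the cost with L-BFGS (analytic
gradient, coefficients in an abscissa scaled to [−1, 1] for conditioning),
then re-estimates s; by default 6 rounds, stopping early when the fit
changes by less than `tol` (10⁻⁶ of the intensity scale). The procedure is
deterministic; a failed inner minimization raises
`BaselineConvergenceError`.

Design note: a plain iteratively-reweighted least-squares version of the
same cost was tried first and either entered limit cycles or crawled along
geometric tails (contraction ratio ≈ 0.993) on noisy inputs; minimizing the
explicit objective is both faster and unconditionally terminating. The
strong below-fit asymmetry biases the baseline toward the lower envelope of
the noise; at the per-scan noise levels the pipeline targets
(σ of order 1–3% of band height) this offset is far below the band signal
and is common-mode across scans.

Measured on synthetic ground truth: off-peak recovery error ≤ 0.9% of peak
height for noiseless cubic baselines with two sparse Gaussian bands
(tested bound: 2%); agreement with the OLS oracle to < 10⁻¹⁴ relative on
peak-free polynomials (tested bound: 10⁻⁶).

## PCA and DAPC

PCA is the SVD of the row-centered matrix; the sign of each loading is
fixed so its largest-magnitude entry is positive, making runs bit
reproducible. Explained-variance fractions are relative to the total
variance, so they sum to ≤ 1 when components are truncated.

The discriminant rule in k-dimensional score space is linear (pooled
within-class covariance, i.e. LDA rather than QDA — the conventional
choice for discriminant analysis of principal components) with uniform
class priors: δ_c = sᵀW⁺μ_c − ½μ_cᵀW⁺μ_c + ln π_c, argmax over classes,
ties broken by class order (alphabetical). Uniform priors are what make the
two-class chance level 50% regardless of class sizes; proportional priors
would change that and are deliberately not the default. W is inverted by a
tolerance-based pseudo-inverse (cutoff = dimension · machine ε · largest
eigenvalue). No shrinkage is applied: at k near the training rank W is
nearly singular and predictions degrade — that degradation is a *finding*
the validation is supposed to surface, not a numerical nuisance to
regularize away. With uniform priors this rule coincides with
Mahalanobis-nearest-centroid up to class-independent terms.

Canonical coordinates for cluster plots are the leading eigenvectors of
W⁺B (B = between-class scatter of the training class means); with two
classes there is one axis and the second coordinate is written as zero.

## Grouped leave-one-out validation

The validation unit is a specimen (default) or an individual (all of an
individual's specimens held out together). For every unit, *everything* —
centering, loadings, class means, pooled covariance — is refit on the
remaining units before the held-out spectra are predicted; no statistic of
the held-out unit leaks into the fold model. Within a fold, the PCA
loadings are nested across k, so the sweep fits one decomposition per fold
at max(k) and rebuilds only the discriminant statistics per k; this is
exactly equivalent to refitting per k (asserted in the tests).

Accuracy is the percentage of validated spectra predicted correctly;
sensitivity and specificity are one-vs-rest rates against a user-designated
positive class (for disease screening, the diseased label). Ratios with an
empty denominator are reported as NaN with a warning, never coerced to 0
or 100. The variance-explained column of the sweep report comes from a
single full-data PCA (one value per k, as sweep tables conventionally
print), not from the per-fold models.

## Chance baselines

* `uniform-guess` (default): a classifier drawing labels uniformly over the
  class set. Closed form, independent of class representation: accuracy and
  every per-class sensitivity are 100/k_classes; every specificity is
  100·(k_classes−1)/k_classes. Two classes: 50/50/50.
* `permutation`: predictions are a uniformly random permutation of the true
  labels; metrics are Monte-Carlo means ± standard error over `n_mc`
  replicates (expected accuracy Σ_i p_i² for class fractions p_i).
  Deterministic for a fixed seed.

The permutation model respects class representation and is the right null
for judging LOO results on unbalanced data; the uniform-guess model is the
conventional headline number.

## The synthetic generator

`SynthConfig` defaults describe the acquisition setting the pipeline
targets: a 400–1800 cm⁻¹ grid at 1 cm⁻¹ spacing, two classes
("healthy"/"unhealthy"), 10 replicate scans per specimen, random cubic
baselines an order of magnitude larger than the bands, five Gaussian bands
at common biofluid positions, log-normal per-specimen band-amplitude
variability (σ = 0.08), a smooth per-specimen "fingerprint" component
(per-point σ = 0.01, correlation length 30 cm⁻¹), and replicate noise
σ = 0.02.

Two generator choices matter and are deliberate:

* The class effect is a *band-ratio* pattern (`class_effect_vector`), not a
  scalar gain — vector normalization removes any scalar gain, so a scalar
  "effect" would silently produce null data.
* The fingerprint component spreads within-class variance over many
  principal components, as real compositional variability does. Without
  it the synthetic data live on a ~9-dimensional manifold, the pooled
  covariance stays well-conditioned at any feasible k, and high-k models do
  not over-fit — unlike real spectra.

What the generator does *not* emulate: Lorentzian/Voigt line-shape mixtures
(a pure-Lorentzian flag exists), cosmic-ray spikes, wavelength-calibration
drift, water bands, detector nonlinearity, or non-polynomial fluorescence.
Passing tests therefore show that the pipeline recovers the structure this
model encodes — they do not certify performance on any particular
instrument's data.

## Validation-study scale and measured behavior

The end-to-end studies in the test suite and `scripts/acceptance.py` use 20
"healthy" + 30 "unhealthy" specimens, 10 replicates, and a 5 cm⁻¹ grid
(281 points) so that a full multi-seed LOO study runs in minutes on one
CPU. At that scale, with moderate class contrast (0.10):

* mean LOO accuracy at k = 5 exceeds that at k = 45 (near the 48-component
  rank of a 49-spectrum training fold) by about 6 percentage points,
  averaged over 12 seeds — the over-fitting signature;
* with zero class contrast, mean LOO accuracy over 20 seeds is
  statistically indistinguishable (within 3 combined standard errors) from
  the permutation-chance level;
* with strong contrast (0.5) and small noise, the sweep returns
  100/100/100 at the generative k.

At exactly k = rank the pseudo-inverse cutoff discards the null directions
and partially re-regularizes the model, so the sharpest degradation sits
just *below* the rank; the sweep grid should include such values.

## Numerical conventions and degenerate inputs

* Truncation interval closed on both ends; fewer than 2 surviving points is
  an error.
* Moving-average edges shrink to the available points within the
  half-window.
* All-zero spectra cannot be vector-normalized (error naming the scan).
* A dataset whose rows are all identical has zero variance: PCA errors.
* Conflicting class labels within an averaging group or validation unit
  are an error naming the group.
* Interpolation onto a grid outside the source span is refused (no
  extrapolation).
* Percentages are carried at full precision internally and rounded to one
  decimal only in written reports.

## Known limitations

* No shrinkage/regularized LDA and no QDA — by design, see above.
* The baseline model is polynomial; backgrounds with sharp structure
  (etaloning, substrate lines) violate its assumptions.
* LOO at specimen level treats specimens as exchangeable; repeated
  specimens from one individual should use the individual-level unit, at
  the cost of fewer folds.
* The permutation chance model permutes labels globally; it does not model
  a classifier that has learned class frequencies from training folds.
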