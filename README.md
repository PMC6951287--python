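# ramclass

Chemometric classification of Raman spectra with honest validation.

Raman spectroscopy of biofluids (the motivating case is urine screening for
chronic kidney disease) produces spectra that act as molecular
"fingerprints": hundreds of overlapping bands on top of a broad fluorescence
background. `ramclass` implements the standard chemometric screening
pipeline for such data and — its main point — the validation machinery that
tells you whether a classifier built on it actually generalizes:

1. **Preprocessing** — truncation to the fingerprint region
   (400–1800 cm⁻¹), polynomial baseline removal with an iterative
   asymmetric-cost fit (order 3, estimated peak ratio 0.5, smoothing
   window 5), vector normalization, and replicate averaging per specimen.
2. **PCA → DAPC** — principal component analysis of the processed spectra
   followed by linear discriminant classification in the space of the first
   *k* PC scores (discriminant analysis of principal components). The
   discriminant score of class *c* for a score vector *s* is

       δ_c = sᵀ W⁺ μ_c − ½ μ_cᵀ W⁺ μ_c + ln π_c

   with per-class score means μ_c, the pseudo-inverse W⁺ of the pooled
   within-class covariance, and uniform priors π_c.
3. **Grouped leave-one-out validation** — each specimen (or individual) is
   held out in turn, the whole model (PCA included) is refit on the
   remainder, and the held-out spectra are predicted. Accuracy, sensitivity
   (true-positive rate), and specificity (true-negative rate) are reported
   per retained-PC count *k*, which makes over-fitting at large *k* directly
   visible.
4. **Chance baselines** — closed-form uniform-guess values (50% for two
   classes, however unbalanced) and a Monte-Carlo permutation model, so LOO
   results can be judged against what a label-agnostic classifier would
   score.
5. **Synthetic data** — a generator for liquid-sample Raman spectra with
   known ground truth (polynomial baselines, Gaussian/Lorentzian peaks,
   class-dependent band ratios, specimen-level variability, replicate
   noise), so every stage is testable without instrument data.

## Worked example

```sh
ramclass synth --out-dir demo --seed 1 --n-specimens 20 --n-specimens 30 \
    --grid-step 5 --class-effect 0.12
ramclass process --spectra demo/spectra.csv --meta demo/metadata.csv --out-dir demo
ramclass sweep --spectra demo/processed_spectra.csv \
    --meta demo/processed_metadata.csv --k 1,2,5,10,45 --out demo/sweep.csv
ramclass chance --meta demo/metadata.csv
```

`process` logs the record count after each step to stderr
(`truncate: 500 spectra … average: 50 spectra` — ten replicate scans
averaged per specimen). The sweep report `demo/sweep.csv` then reads:

```
n_pcs,variance_explained_pct,accuracy_pct,sensitivity_pct,specificity_pct
1,32.7,86.0,80.0,95.0
2,49.6,86.0,80.0,95.0
5,75.6,88.0,86.7,90.0
10,85.2,88.0,86.7,90.0
45,99.6,80.0,76.7,85.0
```

With this moderate class contrast the model plateaus at 86–88% accuracy —
well above the 50% chance level that `ramclass chance` prints for any
two-class dataset — and at k = 45, close to the 48-component rank of a
49-spectrum training fold, accuracy falls to 80% even though the retained
variance is higher: the over-fitting signature the PC sweep exists to
expose. `ramclass loo` validates a single k, and `ramclass scores` writes
per-spectrum canonical discriminant coordinates with predicted labels and
correctness flags for cluster plots.

The same pipeline is available as a library (`ramclass.generate_dataset`,
`run_preprocess`, `fit_dapc`, `loo_validate`, `pc_sweep`, `random_chance`).

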