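# Methods

This note documents the models and numerical choices behind `beanspec`:
what the synthetic-data generator emulates (and deliberately does not), how
the chemometric core is defined, and where the design was genuinely open.

## Study design emulated by the generator

The package targets the single-bean workflow used in roast-coffee aroma
screening: 25 commercial batches (a mix of Arabica and Robusta origins), 10
beans per batch, each bean scanned on both sides by a push-broom SWIR
camera (~900–2500 nm, ~6 nm bands), and characterized chemically by
SPME-GC–MS as relative peak areas (% of total) over a 50-compound roster.
`SimulationConfig` defaults mirror this design: `n_batches=25`,
`beans_per_batch=10`, 20-segment cross-validation downstream, a 10%
segregation fraction.

### Chemistry model

Each bean carries K = 4 latent roast/precursor factors `z`, standard normal
as batch random effect plus bean effect (`batch_icc = 0.30` of the variance
at batch level — an assumption, not an estimate; the underlying
bean-to-bean variance structure of real coffee is unknown). The factors map
to biochemical families:

| factor | chemical classes |
|---|---|
| 0 Maillard / N-heterocycles | Pyrazine, Heterocyclic N, Pyrrole |
| 1 Strecker / lipid volatiles | Aldehyde, Alcohol, Ester, Acetate |
| 2 caramelization products | Ketone, Furan, Sulphide |
| 3 phenolics & acids | Phenolic, Acid |

A compound's standardized score is `s_c = a_g z_k(g) + b_g h_g + c_g e_c`
with `h_g` a per-bean class-level hidden component and `e_c` compound-level
noise (`compound_noise_share = 0.30` of the hidden variance); its abundance
is `mu_c (1 + cv s_c)` clipped at zero, with `cv = 0.25` relative spread.
Sharing `z` within (and across related) classes produces the within-class
correlation that motivates grouped modelling, and sharing factor 0 between
pyrazines and heterocyclic-N compounds reproduces the co-shift of those
groups under pyrazine-targeted segregation.

Baseline abundances `mu_c` are anchored to the published per-compound
reference SDs (RPD × RMSECV from the packaged reference table), giving a
mean composition with pyrazines ≈ 30% of total area. Robusta batches shift
pyrazine-class compounds up and aldehydes down by ±0.5 compound-SD
(configurable); the shift is routed through the latent factors so that it
is expressed in the spectra, as species differences are in real scans.

### Spectral forward model

Absorbance is a fixed broad baseline plus each latent factor times its
Gaussian-band loading; band centres sit at the NIR overtone/combination
assignments reported as informative for roast coffee (1435, 1450, 1680,
1940, 1975, 2050, 2100, 2276, 2300 nm; widths 20–60 nm), with loading
amplitude 0.05 AU per unit factor score. Scatter is a per-spectrum
lognormal gain (`scatter_sd = 0.10`) plus additive offset (0.2 ×
`scatter_sd` AU) — exactly the affine distortion family that SNV removes,
so pre-treatment comparisons are meaningful by construction. Band noise is
i.i.d. Gaussian (`noise_sd = 0.002` AU). Reflectance is R = 10^(−A),
clipped to (0, 1].

Within a hypercube, beans are 8×12-pixel ellipses on a dark-tray background
(reflectance ~0.04–0.06), with 5% relative per-pixel gain jitter
(`pixel_jitter`, set to 0 for noiseless round-trip checks); raw counts are
`dark + R·(white − dark)` with dark ≈ 100 and white ≈ 10000 counts, and the
dark/white reference stacks carry frame noise proportional to `noise_sd`.

### The signal_r2 calibration

`signal_r2` is defined as the population fraction of variance of the
dominant chemical class's *normalized* abundance (% of total) that is
expressible from noise-free spectra. Because profiles are
closure-normalized, a class share couples to every other class's
fluctuations; the generator therefore calibrates the loading scale
analytically — a first-order delta-method expansion of the share through
the normalization, followed by a 1-D Brent root find — so that the
dominant class (pyrazines under the default roster) hits the configured
level. The linearization error is second order in `cv` and empirically
within ±0.01. If the species shift routed through the latent factors would
by itself explain more share variance than requested, the shift falls back
to the spectrally invisible compound level (relevant only for very small
`signal_r2`; at `signal_r2 = 0` the spectra carry no information about the
profiles at all, which is the leakage-sentinel condition).

At the design point (`signal_r2 = 0.70`, 250 beans), the pooled 20-segment
cross-validated R² of the pyrazine share averages ≈ 0.68 over seeds
(population value 0.70 minus ~0.02 fold-estimation loss), with a
seed-to-seed SD of ≈ 0.03 dominated by the 25-batch sampling. Acceptance
checks therefore pool a fixed set of five replicate datasets.

### What the generator does not emulate

No radiative-transfer or scattering physics; no roasting-kinetics
chemistry; no wavelength-dependent detector noise; no bean-shape or
orientation variability beyond the ellipse raster; species effects are
mean shifts only. Passing tests demonstrate the *pipeline's* correctness
and statistical calibration under a plausible low-rank linear world — they
do not certify prediction accuracy on real beans, where the
spectral–chemistry link is indirect (precursors and correlated roast
chemistry rather than the volatiles themselves).

## Imaging

Reflectance is `(raw − dark)/(white − dark)` per pixel and band, reference
stacks frame-averaged first, clipped to [1e-4, 1.5] — the floor protects
log10(1/R), the ceiling tolerates overshoot above a PTFE reference that is
only approximately 100% reflective. Detector edges below 950 nm and above
2450 nm are trimmed by default (configurable). Segmentation thresholds the
band nearest 1300 nm: Otsu's criterion is computed first, then re-centred
by Ridler–Calvard iteration because Otsu's between-class variance is flat
across an empty histogram valley and its first-bin argmax can sit inside
the background tail; components are 8-connected, those under `min_pixels`
(default 20) discarded, and labels ordered top-to-bottom then
left-to-right, so label k of a batch cube is the k-th placed bean. Bean
spectra are per-band arithmetic means over label pixels; the two scanned
sides are averaged *before* pre-treatment (SNV does not commute with
averaging; the order is fixed and regression-tested).

## Pre-treatment

All methods start from apparent absorbance log10(1/R). SNV standardizes
each spectrum with the sample (n−1) SD. The 2nd derivative uses
Savitzky–Golay convolution with window 11 points and polynomial order 2 —
a standard choice at ~6 nm resolution; both are configurable — with
polynomial edge interpolation, exactness on polynomials up to the window
order, and a 1% uniform-grid tolerance. All three are stateless per
spectrum, so they cannot leak information across cross-validation folds.

## Chemometrics

PLS2 uses NIPALS with Y-block deflation; X and Y are mean-centered but not
variance-scaled (a common chemometrics default; optional Y autoscaling via
`scale_y` since abundances span orders of magnitude). The inner iteration
converges on the weight vector to 1e-10; a zero-norm weight stops
extraction early with the achieved component count reported. Score vectors
are mutually orthogonal to 1e-8 and the full-rank solution coincides with
ordinary least squares (both oracle-tested).

Cross-validation uses 20 segments with fold assignment stratified by
batch: beans are shuffled within batch and dealt round-robin into a
shuffled segment order, so segment sizes differ by at most one and each
batch spans many segments — the conservative anti-leakage choice when
batches share roasting conditions. Centering is recomputed on each
training fold. R² is the coefficient of determination of pooled held-out
predictions (not a squared correlation — the two differ). The LV count is
the smallest whose response-averaged RMSECV lies within 2% of the global
minimum, a testable form of the "lowest possible LV" robustness rule; the
pipeline logs each model's decision. RPD uses the cross-validated RMSE.

PCA is a centered SVD; Pearson p-values come from the t-transform with
n−2 degrees of freedom, with constant columns flagged NaN.

## Segregation

Group size is ⌈fraction × n⌉ (ceiling — "10%" of a small batch is
ambiguous otherwise), ties broken by bean id. Groups (high / low /
remainder) are compared per attribute by one-way ANOVA and Tukey's HSD at
α = 0.05; the compact letter display uses the insert-and-absorb algorithm
(start with one all-group set; each significant pair splits the sets
containing both; absorb subsets; letters ordered by descending group
mean). Exact separation with zero within-group variance is flagged and
lettered by mean order. The synthetic validation compares per-bean true
profiles rather than a pooled re-measurement of each segregated batch; at
these sample sizes the two are statistically equivalent, and the per-bean
form is strictly more informative.

## Degenerate inputs and numeric edges

All-zero concentration vectors, constant spectra under SNV, zero-variance
reference responses, zero pyrazine or negative-valence sums, and empty
scenes raise typed errors (or, for empty scenes, return an empty mask with
no error). Perfect cross-validated predictions report RPD = +inf. An
F-statistic that cancels to a microscopically negative value (identical
groups) is reported as p = 1. ENVI I/O validates header/payload size
consistency and requires a wavelength list for hypercubes.

## Known limitations

* The descriptor (odorant-series) mapping and the positive/negative
  valence labels are literature-derived configuration, not measured data;
  all descriptor-level results are mapping-relative, and the mapping file
  is replaceable.
* The roster's chemical-class labels are transcribed verbatim from the
  source table, including two chemically surprising assignments (phenol
  under "Heterocyclic N", 2-formylpyrrole under "Phenolic"); a corrected
  variant ships alongside but is not the default.
* SNV output is not exactly linear in the latent factors (its per-spectrum
  SD depends on them), so the composed SNV-then-regression recovery is
  near-exact (R² > 0.98) rather than exact; recovery from plain absorbance
  is exact in the noiseless limit.
* PLS prediction of a closure-normalized share is linear in the spectra
  while the share is a ratio of latent quantities; in the perfect-signal
  limit the ranking is therefore near- but not exactly truth-ordered.
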