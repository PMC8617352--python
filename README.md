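# beanspec

Single-bean near-infrared hyperspectral chemometrics for roasted-coffee
aroma. `beanspec` implements the full workflow for predicting the volatile
aroma composition of individual roasted coffee beans from SWIR hyperspectral
scans (~900–2500 nm): reflectance calibration against dark/white references,
bean segmentation, spectral pre-treatment, multi-response PLS regression
with cross-validation, reduction of the 50-compound volatile roster to
chemical-class and odorant-series indicators, and model-guided segregation
of beans into high/low aroma batches.

It is aimed at chemometricians and food scientists who want a tested,
scriptable version of this workflow — and, because the original bean scans
and GC–MS profiles are not publicly deposited, it ships a synthetic-data
generator with known ground truth so every stage is verifiable end to end.

## The model

Each bean is scanned on both sides; per-bean mean reflectance spectra are
averaged across sides and converted to apparent absorbance log10(1/R).
Three representations are compared, mirroring standard NIR practice:

* **log(1/R)** — absorbance itself;
* **SNV** — standard normal variate, x ↦ (x − mean(x))/sd(x) per spectrum,
  which removes multiplicative scatter and additive baseline exactly;
* **2nd derivative** — Savitzky–Golay least-squares polynomial convolution
  (default window 11 points, order 2), sharpening overlapping bands.

The regression core is PLS2 (NIPALS): latent variables **t** = **Xw** are
extracted to maximize covariance with the response block **Y** (one column
per volatile compound or aroma group), deflating **X** and **Y** per
component; the regression matrix is **B** = **W**(**P**ᵀ**W**)⁻¹**Q**ᵀ.
Model complexity is chosen from the RMSECV-vs-LV curve of a 20-segment
k-fold cross-validation, taking the smallest LV count within 2% of the
minimum. Per response the package reports R² (coefficient of
determination), RMSE/RMSECV, and RPD = sd(reference)/RMSECV (≈1: no better
than the mean; 1.4–2: screening quality; >2: quantitative).

Volatile profiles enter as relative GC–MS peak areas (% of total peak
area) over a packaged 50-compound roster (12 pyrazines, 12 ketones, 5
aldehydes, …, with GC-olfactometry and literature odour-activity
annotations). Profiles are reduced to chemical-class sums, odorant-series
(descriptor) sums, the aldehyde/pyrazine ratio and the positive/negative
valence ratio. A segregation trial ranks beans by a model-predicted
attribute, selects the top and bottom 10%, and compares the resulting
batches by one-way ANOVA with Tukey's HSD (compact letter display).

## Worked example

```python
import beanspec as bs
from beanspec.grouping import group_by_class
from beanspec.preprocess import PretreatmentSpec, apply_pretreatment

ds = bs.simulate_bean_dataset(bs.SimulationConfig(seed=1))   # 25 batches x 10 beans
Y = group_by_class(ds.profiles, bs.load_roster())[["Pyrazine", "Aldehyde", "Ketone"]]
X = apply_pretreatment(ds.reflectance.to_numpy(), ds.wavelengths, PretreatmentSpec("snv"))
plan = bs.make_cv_plan(len(Y), batches=ds.meta["batch_id"].to_numpy(), n_segments=20, seed=1)
cv = bs.cross_validate(X, Y, lv_max=12, plan=plan)
lv = bs.select_lv(cv.rmsecv)
model = bs.fit_pls2(X, Y, n_lv=lv)
metrics = bs.compute_metrics(Y, model.predict(X), cv.y_pred[lv - 1], list(Y.columns))
print(f"chosen LV = {lv}")
print(metrics.round(3))
```

prints

```
chosen LV = 4
          r2_cal  rmse_cal  r2_cv  rmse_cv    rpd
target
Pyrazine   0.649     3.067  0.631    3.143  1.650
Aldehyde   0.775     2.072  0.761    2.136  2.051
Ketone     0.715     0.683  0.699    0.702  1.825
```

i.e. from spectra alone, the cross-validated models explain ~63–76% of the
between-bean variance in the class sums (units: % of total peak area), with
RPD 1.6–2.1 — screening-grade models, matching the configured spectral
signal level of the generator (`signal_r2 = 0.70`).

The same analysis runs from the shell on an on-disk dataset (ENVI cubes +
reference frames + profile tables):

```bash
beanspec simulate --out data --seed 1
beanspec run --data data --out results
beanspec segregate --run results --target Pyrazine
beanspec report --run results
```

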