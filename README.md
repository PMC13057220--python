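# organ-age

Organ-specific biological age from images, end to end, on synthetic
phantoms with known ground truth.

Aging is heterogeneous across the body: two people of the same calendar
age can carry organs in very different physiological states.
Imaging-based *biological age* (BA) estimation trains a regressor to
predict chronological age (CA) from organ images of healthy subjects —
for whom CA ≈ BA — and reads the *predicted age gap*
(PAG = corrected predicted age − CA) of a new subject as accelerated
(PAG > θ), typical (|PAG| ≤ θ) or decelerated (PAG < −θ) organ aging,
with θ the cohort SD of PAGs per organ.  Elevated organ PAGs are then
tested as prognostic markers for disease and mortality.

This package implements that whole chain for nine organ systems (brain,
heart, left/right kidney, liver, pancreas, spleen, left/right fundus) and
— because population imaging cohorts are access-controlled — ships a
first-class synthetic generator whose phantom images *encode* each organ's
biological age as the radius of a dark inner cavity.  Every stage is
validated by parameter recovery against the generator's ground truth.

The pieces, each usable on its own:

| stage | module | core method |
|---|---|---|
| cohort + phantoms | `organ_age.synthetic` | factor-structured organ age gaps; proportional-hazards outcomes; age-encoding phantoms |
| image preparation | `organ_age.preprocess` | min-max normalization, mask-guided crop with margin, robust-z QC, grid resampling |
| age regression | `organ_age.age_model` | residual CNN predicting `N(mu(x), sigma(x)²)`, trained by heteroscedastic Gaussian NLL on healthy subjects |
| bias correction | `organ_age.bias` | median regression of PAG on CA + preserved covariates; subtract only the CA effect, anchored at the cohort median age |
| PAG statistics | `organ_age.pagstats` | SD-threshold stratification, Bonferroni-controlled Pearson matrix (36 pairs), Welch contrasts, KDE summaries |
| survival | `organ_age.survival` | left-truncated (age time-scale, delayed entry) Kaplan–Meier and Cox PH, ordinal group coding 0/1/2, LRT |
| explainability | `organ_age.explain` | Grad-CAM on the age output with a quantitative localization score |
| orchestration | `organ_age.pipeline` / `organ-age` CLI | YAML-configured generate → preprocess → train → predict → correct → analyze |

The estimation components follow the statsmodels convention: a model
object built from data whose `fit()` returns a results object
(`AgeModel → AgeFitResults`, `PagBiasModel → BiasFit`, `cox_fit → CoxFit`)
carrying estimates, uncertainties and a `summary()`.

## Worked example

Train on 500 phantoms of one organ (healthy 80/20 split, 20 epochs on one
CPU, a few minutes), then push the predictions through bias correction,
stratification, the disease contrast and attention mapping:

```python
from organ_age import experiments

out = experiments.end_to_end_experiment(seed=1, n=500, epochs=20,
                                        organ="kidney_left", outcome="ckd")
print(f"healthy-test MAE  {out['test_mae']:.2f} y   "
      f"(CA SD {out['sd_ca']:.2f} y, mean-predictor MAE {out['baseline_mae']:.2f} y)")
print(f"pearson r         {out['test_pearson_r']:.3f}")
print(f"theta             {out['theta']:.2f} y;  typical fraction "
      f"{out['typical_fraction']:.2f}")
print(f"CKD group shift   {out['disease_mean_shift']:+.2f} y  "
      f"(Welch p = {out['welch_p']:.2e}, threshold {out['welch_threshold']:.2e})")
print(f"Grad-CAM enrichment over chance  {out['gradcam_precision_ratio']:.1f}x")
```

prints (seed 1):

```
healthy-test MAE  2.53 y   (CA SD 7.34 y, mean-predictor MAE 5.95 y)
pearson r         0.903
theta             2.71 y;  typical fraction 0.68
CKD group shift   +2.67 y  (Welch p = 2.89e-07, threshold 4.55e-03)
Grad-CAM enrichment over chance  2.7x
```

Read: the regressor recovers the image-encoded organ age to 2.5 years
(against a 7.3-year cohort SD — a mean predictor gets 6.0 y); subjects
whose kidneys the generator aged by +3 years because of chronic kidney
disease show up 2.7 years older than healthy controls, detected far below
the Bonferroni-corrected level; and the attention map concentrates on the
cavity region that actually carries the age signal at 2.7× chance level.

Hazard-ratio recovery on oracle PAGs (the survival machinery alone):

```python
out = experiments.cox_recovery_experiment(seed=1, n=5000)
# true HR exp(0.14) = 1.150 per PAG year; recovered 1.139 from 935 events
```

The same flow as a reproducible, file-driven experiment:

```bash
organ-age run --config experiment.yaml --out-dir report/
# report/: cohort.csv, predictions.csv, bias_<organ>.json, pag_table.csv,
#          pag_corr_{r,p,significant}.csv, survival_<outcome>.json,
#          km_<outcome>.{csv,svg}, pag_kde.svg, metrics.json, run.log
```

Stage subcommands (`synth`, `preprocess`, `train`, `predict`, `correct`,
`pagstats`, `survival`, `explain`) expose the same steps individually;
rerunning with the same config is bit-identical for CSV/JSON outputs.

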