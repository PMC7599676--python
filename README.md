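# meningrad

Radiomic and semantic risk stratification of atypical meningiomas (WHO
grade II). Up to 60% of these tumors recur within five years of resection,
yet no established radiological criteria identify the high-risk cases.
`meningrad` implements, as a tested and reusable pipeline, the analysis
chain used to associate preoperative MRI features with tumor recurrence
and progression-free survival (PFS):

1. **Feature extraction** — from a contrast-enhanced T1 volume and its
   manual tumor segmentation (NIfTI pairs): isotropic resampling, gray-level
   discretization, and a 13-feature radiomic panel per filter channel
   (original, Laplacian of Gaussian, eight wavelet subbands):
   - first-order: mean, median, minimum, skewness;
   - shape: spherical disproportion `A / (4πR²)`, `R = (3V/4π)^{1/3}`;
   - co-occurrence (GLCM `p(i,j)`, distance 1, 13 directions, symmetric):
     cluster prominence `Σ (i+j−μᵢ−μⱼ)⁴ p(i,j)`, difference entropy
     `−Σ p_{x−y}(k) log₂ p_{x−y}(k)`, inverse difference normalized
     `Σ p(i,j)/(1+|i−j|/N_g)`;
   - run-length (GLRLM `r(i,j)`): run length non-uniformity
     `Σ_j (Σ_i r(i,j))²/N_r`, short-run low gray-level emphasis
     `(1/N_r) Σ r(i,j)/(i²j²)`;
   - size-zone (GLSZM `s(i,j)`, 26-connected zones): high-intensity large
     area emphasis `(1/N_z) Σ s(i,j) i²j²`, low-intensity large/small area
     emphasis `(1/N_z) Σ s(i,j) j²/i²` and `(1/N_z) Σ s(i,j)/(i²j²)`.
2. **Statistical screening** — univariate logistic regression (odds ratios
   with Wald 95% CIs) of 11 binary semantic annotations (cystic component,
   edema, hyperostosis, ...) on relapse; ROC analysis of continuous radiomic
   features with Youden-index dichotomization; multivariate Cox
   proportional-hazards models (Efron ties) of time-to-recurrence on the
   features that pass screening; Kaplan–Meier curves, restricted mean
   survival times and log-rank tests.
3. **Synthetic data** — ellipsoidal tumor phantoms with a controllable
   correlated-texture field and optional hypointense cystic core, plus
   simulated cohorts with exponential event times under proportional
   hazards (defaults: HR 20.21 for cystic component, HR 5.89 for the
   high-cluster-prominence phenotype) and uniform administrative censoring
   over 3–168 months — so every stage is testable without patient data.

## Worked example

Simulate a 200-patient cohort at the default effect sizes and run the full
screening chain:

```python
from meningrad import CohortSimSpec, simulate_cohort, run_screening_procedure, render_report

cohort = simulate_cohort(CohortSimSpec(n_patients=200, seed=12))
print(render_report(run_screening_procedure(cohort)))
```

prints (abridged):

```
Screening report (n = 200)
Cohort: mean age 58.9 (SD 12.8), 59.5% women, relapse 48 (24.0%)

Univariate semantic screening (OR, 95% CI, p):
  ...
  cystic_component: OR 24.25 (9.98-58.93), p=1.94e-12
  ...
ROC of radiomic features:
  cluster_prominence: AUC 0.544 (p=0.359), Youden threshold 5.746e+04 (sens 0.58, spec 0.62)

Advanced to multivariate: ['cystic_component']
Multivariate recurrence model:
  cystic_component: HR 12.54 (6.92-22.70), p=7.03e-17
...
Kaplan-Meier by cystic_component: restricted mean PFS (months) False: 148.7, True: 50.8;
log-rank chi2=111.55, p=4.49e-26
```

The cystic component passes univariate screening (OR 24.25) and remains a
strong hazard in the multivariate Cox model; in this replicate the
cluster-prominence feature shows no significant ROC trend and does not
advance, and the PFS table contains one chance clinical association
(`age_over_65`, simulated independent of outcome) — the expected behavior
of unadjusted screening at these thresholds. Restricted mean PFS is far
shorter with a cystic component (50.8 vs 148.7 months).

The same chain runs from the shell on image data:

```sh
meningrad simulate --n 20 --seed 1 --out work/data        # NIfTI phantoms + cohort CSV
meningrad extract  --data work/data --cohort work/data/cohort.csv --out work/features
meningrad analyze  --cohort work/data/cohort.csv \
                   --features work/features/features_wide.csv --out work/analysis
# or all three at once: meningrad run-all --n 20 --seed 1 --out work
```

Feature tables use `channel__feature` columns
(e.g. `original__cluster_prominence`, `wavelet_HHH__skewness`).

Note that any absolute threshold on a texture feature (such as a Youden
cutoff for cluster prominence) is tied to the discretization used and is
**not transferable** between pipelines; thresholds are always re-derived
from the data at hand.

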