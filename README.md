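# rrespstate

Classify the mental context — **relaxation**, **basal rest** or **stress** —
in which relaxation-response episodes occur, from two wearable-grade
physiological signals: the RR tachogram (inter-beat intervals derived from the
electrocardiogram, in seconds) and electrodermal activity (skin conductance,
in µS). The package is aimed at physiological-computing and affective-science
practitioners who need a reproducible pipeline from raw signal tables to a
statistically defensible classifier comparison.

## What it computes

Both signals are low-pass filtered at 2 Hz (zero-phase) and chopped into
20 s windows with a 15 s stride. Each window yields **51 features**:

- **13 time-domain features** — RR extrema/range/mean (raw and min-max
  normalised against the whole register, `X_norm = (X − X_min)/(X_max −
  X_min)`), least-squares slopes of RR and EDA, and three "surface"
  features `∫|signal(t) − L(t)| dt` measuring excursion around a regression
  line `L` (including the mixed surface of RR around the EDA regression);
- **26 rolling statistics** — trailing four-window mean and sample standard
  deviation of each time-domain feature (a short-term physiological memory);
- **2 spectral features** — the strongest band power `P_max` over
  0.05–0.5 Hz at 0.05 Hz resolution and its frequency `f_Pmax`;
- **9 Poincaré descriptors** of the lag-1 return map (points
  `(RR_i, RR_{i+1})` with centroid `(x̄, ȳ)`):

  ```
  SD1c = √(mean d₁²),  SD2c = √(mean d₂²)        (centroid-referenced axes)
  SD1b = √(Σ(xᵢ−yᵢ)²/2n)                         (bisector-referenced)
  SD1e, SD1d : SD1b split over points above/below y = x, so that
  SD1e² + SD1d² = SD1b²,  Ce = SD1e²/SD1b²,  Cd = SD1d²/SD1b²,  Ce + Cd = 1
  ```

- **RR_Band** — a subject-adaptive code discretising the window's mean RR
  into thirds of the register's own RR span: 1 (longest intervals,
  relaxation), 2 (rest), 3 (shortest, stress).

A 12-classifier harness (1R, decision tree, 1-/5-NN, naïve Bayes, RBF- and
linear-kernel SVMs, logistic regression, AdaBoost/Bagging/random forest with
10 trees each, MLP) is evaluated under 10-run 10-fold cross-validation with
shared fold partitions, with optional correlation-based feature selection
(CFS, best-first search over the merit
`k·r̄_cf / √(k + k(k−1)·r̄_ff)`). Algorithms are compared with a Friedman
rank test and pairwise **Bayesian correlated t-tests**: the posterior of the
mean metric difference is Student-t with `dof = n−1`, location `x̄` and
`scale² = (1/n + ρ/(1−ρ))·s²`, and its mass is split below / inside / above
a ±0.01 region of practical equivalence (ROPE).

A seeded synthetic-register generator (state-dependent RR level, respiratory
sinus arrhythmia, AR(1) noise; EDA tonic drift plus Poisson-timed
bi-exponential skin-conductance responses) makes the whole pipeline testable
without any recorded data.

## Worked example

```
$ rrespstate simulate --seed 7 --out reg
$ rrespstate extract --eda reg/synth_eda.csv --rr reg/synth_rr.csv \
      --annotations reg/synth_annotations.csv --out table.csv
wrote 59 instances x 51 features to table.csv
$ rrespstate evaluate --table table.csv --algorithms 1R,DT,NB,RF \
      --runs 2 --folds 5 --seed 7 --out metrics.json
   1R  acc 94.85 +/- 4.44 %   F1 0.95   AUC 0.96
   DT  acc 94.02 +/- 5.71 %   F1 0.94   AUC 0.96
   NB  acc 96.59 +/- 4.41 %   F1 0.97   AUC 0.98
   RF  acc 99.17 +/- 2.64 %   F1 0.99   AUC 1.00
$ rrespstate compare --metrics metrics.json --out matrix.csv
Friedman chi2 = 11.49, p = 0.00936 (equivalence rejected at alpha = 0.05)
wrote 4x4 comparison matrix to matrix.csv
```

The simulated register is one subject's 15-minute three-stage protocol
(rest, stress, relaxation; 300 s each). Its 59 labeled windows are almost
perfectly separable — the synthetic states are deliberately well separated at
default settings — so even the one-rule baseline reaches ~95% accuracy; the
Friedman test still rejects exact equivalence of the four algorithms, and the
matrix cells hold the posterior probability backing each pairwise verdict.
Accuracy on this generator says nothing about accuracy on recorded human
data; see `docs/methods.md` for what the synthetic world does and does not
establish.

## Acceptance script

```
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes, from scratch at run time, the package's desk-scale acceptance
quantities (currently the Poincaré contribution identity Ce + Cd evaluated
over 100 seeded random beat sequences) and writes them as JSON.

## Layout

- `rrespstate.preprocess` — register I/O, zero-phase low-pass filter,
  tachogram resampling, min-max normalisation
- `rrespstate.windows` — sliding-window segmentation and label assignment
- `rrespstate.features_time` / `features_freq` / `poincare` / `rr_band` —
  the four feature families
- `rrespstate.pipeline` — register → 51-column feature table
- `rrespstate.ml_harness` — classifier roster, repeated stratified (optionally
  group-aware) CV, confusion matrices, CFS
- `rrespstate.compare` — Friedman test, Bayesian correlated t-test, pairwise
  comparison matrix
- `rrespstate.synth` — seeded synthetic register and cohort generator
- `rrespstate.cli` — `rrespstate simulate | extract | evaluate | compare`
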