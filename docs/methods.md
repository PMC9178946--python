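# Methods

This note documents the models, the numerical choices and the limits of what
the test suite establishes. It is the package's own account of its science;
all quantitative statements here are computed by the tests or the acceptance
script, not asserted from elsewhere.

## Signals and preprocessing

A *register* is one recording session: electrodermal activity (EDA, µS) and
the RR tachogram (inter-beat intervals, s, stamped at the closing beat).
Physiological context: RR variability reflects the autonomic balance (long
intervals = slow heart = parasympathetic dominance), while EDA is driven
purely by the sympathetic branch — its slow *tonic* level (< ~0.05 Hz)
tracks arousal and its fast *phasic* responses mark discrete sympathetic
events.

**Low-pass filter.** Both signals pass a 2 Hz cutoff filter before
windowing: the RR spectrum is bounded below 0.5 Hz and the EDA tonic band
below ~0.05 Hz, so 2 Hz removes only noise. The filter family and phase
behaviour are open choices; we use a 4th-order Butterworth run forward and
backward (`sosfiltfilt`). Zero phase matters because features are indexed by
window timestamps — a causal filter would lag every feature by the group
delay. The effective amplitude response is the squared one-pass magnitude;
tests verify a 0.1 Hz tone passes within 1% and a 10 Hz tone is attenuated
at least as strongly as the analytic |H|² = 1/(1+(f/f_c)^8) bound.

**Tachogram grid.** The tachogram is unevenly sampled by construction, so
slopes, surfaces and spectra need an even grid. We interpolate with
monotone-preserving cubics (PCHIP — no overshoot beyond the local beat
range) at 8 Hz, filter there (4 Hz would put Nyquist exactly at the cutoff),
and decimate to the conventional 4 Hz HRV analysis grid.

**Normalisation.** `X_norm = (X − X_min)/(X_max − X_min)` with extrema taken
from the whole register's filtered RR. This places each window inside the
subject's own dynamic range but **leaks future signal into early windows**;
a causal running-extrema variant is available
(`normalization.mode = causal`), falling back to whole-register parameters
until the running extrema separate.

## Windows and labels

20 s windows, 15 s stride (5 s overlap), half-open `[t_start, t_end)` on an
axis anchored at the first instant both signals cover. 20 s is the period of
the slowest RR component (0.05 Hz) and the usual span for EDA tonic
features; the overlap prevents a pattern from being split across a boundary.
Trailing partial windows are discarded, never padded. Windows with fewer
than 2 beats cannot support beat-level descriptors and are dropped with a
warning. A window is labeled when a single annotation covers ≥ 50% of it;
exact ties stay unlabeled and are excluded from training tables. Note the
coverage pattern of this geometry: only the 5 s overlap zones are covered by
two windows; the remaining 10 s of each stride belongs to one window.

## Features (51 per window)

**Time domain (13).** RR max/min/range/mean from the windowed 4 Hz grid, the
same four from the normalised signal, OLS slopes of RR and EDA versus time,
and three "surface" features. A *surface* is interpreted as the
time-integral of the absolute residual around a regression line
(trapezoidal on the window grid) — a signed residual would integrate to ≈ 0
around the signal's own regression by construction. `EDA/RR_SurfDiff`
integrates the RR residual around the *EDA's* regression line evaluated on
the RR grid; its units mix s and µS (we read the definition literally), and
`surfdiff.standardize = true` offers a z-scored variant for unit-free use.

**Rolling statistics (26).** Trailing four-window mean (`_Avg`) and sample
(n−1) standard deviation (`_Std`) of each time-domain feature, expanding at
the register start (window 0: Avg = value, Std = 0). These act as a
short-term memory of the recent physiological trajectory.

**Spectrum (2).** Power in the ten 0.05 Hz-wide bands centred at
0.05…0.50 Hz of the mean-detrended window; `P_max` is the strongest band,
`f_Pmax` its centre, ties broken toward the lowest band, and numerically
zero spectra (constant windows, power < 1e−30) resolve to the 0.05 Hz band.
The default estimator is the periodogram of the evenly resampled window
with 'spectrum' scaling, so summed band powers are bounded by the window
variance (a Parseval-style check in the tests); a Lomb–Scargle estimator on
the raw beats is available (`spectrum.estimator = lombscargle`). With a
20 s window exactly one 0.05 Hz period fits, so the lowest band is resolved
at the edge of what the window permits — widening the window would change
the instance definition, so we document the limitation instead.

**Poincaré descriptors (9).** Computed per window on the raw beat intervals
inside it (typically 15–35 beats). The partial sums behind SD1e/SD1d keep
the same 1/(2n) normalisation over *all* n plotted points, which is exactly
what makes SD1e² + SD1d² = SD1b² an algebraic identity (tested to machine
precision); points exactly on the bisector contribute zero and are counted
in neither n_e nor n_d. Ce and Cd are reported as NaN when SD1b = 0 (a
constant window) rather than an arbitrary 0/0 convention; the ML harness
imputes such values by the column median. For long stationary series SD1b
converges to SD1c (tested at 10⁵ AR(1) beats, gap < 1%).

**RR_Band (1).** The register's filtered-RR span is cut into three equal
bands; the window's mean RR selects band 1/2/3 (relaxation/rest/stress,
band 1 = longest intervals). Boundary values go to the calmer band —
arbitrary but fixed. Because boundaries derive from the subject's own
extrema the code is invariant under any increasing affine rescaling of the
signal (tested exactly). Band orientation follows physiology: slow heart =
relaxation.

## Learning harness

Twelve classifiers spanning the usual paradigms, with scikit-learn as the
engine and two in-repo components: Holte's 1R (supervised bucketing with a
minimum bucket size of 6, adjacent same-prediction buckets merged) and the
CFS machinery. Ensembles use 10 decision trees. Exact parity with any other
toolkit's defaults (notably the RBF network, approximated here as an
RBF-kernel SVM) is a non-goal — headline accuracies from other
implementations are outside the test surface. Scale-sensitive learners are
wrapped in a standardising scaler; all estimators are fronted by median
imputation.

Cross-validation is stratified (all three classes present in every fold)
and the fold partitions are generated once per evaluation and shared by all
algorithms, making per-fold metric differences paired observations. F1 and
AUC are prevalence-weighted (per-class / one-vs-rest). Confusion matrices
are summed within a run and averaged over runs, so each row sums to the
class prevalence. A majority-class baseline is reported alongside.

**Group-aware option.** `run_cv(..., groups=subject_ids)` switches to
stratified *group* folds. Overlapping windows of one register are
near-duplicates (shared 5 s of signal, shared rolling spans, autocorrelated
noise), so instance-level folds overstate accuracy whenever train and test
contain neighbouring windows. The effect is large: on a synthetic cohort
with **zero** state separation, instance-level CV plateaus near 0.45–0.49
accuracy while the permuted-label control sits at 1/3; register-grouped
folds restore chance level exactly. The recovery tests therefore use
grouped folds; the instance-level design remains the default because it
matches the classical evaluation protocol for this problem.

**CFS.** Features are discretised by Fayyad–Irani MDL entropy partitioning;
feature–class and feature–feature correlations are symmetrical
uncertainties of the discretised codes; subsets are scored by Hall's merit
`k·r̄_cf/√(k + k(k−1)·r̄_ff)` and searched best-first (forward, stopping
after 5 stale expansions). Constant-after-discretisation features are
excluded before the search. Best-first is greedy: on random 8-feature
tables it matches exhaustive search in ≥ 95/100 seeded trials (tested), and
can never exceed it.

## Statistical comparison

**Friedman test.** Rank-based with average ranks for ties and the standard
tie correction, blocks = the runs×folds paired measurements, rejection at
α = 0.05. Implemented in-package because the scipy version requires ≥ 3
algorithms while the pairwise degenerate case (k = 2, a sign-test-like
reduction) must work; for k ≥ 3 the implementation is verified against
scipy exactly, and its null rejection rate is calibrated (5% ± 2% over 500
simulations).

**Bayesian correlated t-test.** Cross-validated differences are correlated
across folds because test sets overlap; the correlated correction inflates
the posterior scale by `ρ/(1−ρ)` with ρ = the test-set fraction 1/folds
(0.1 for tenfold) — the standard heuristic, since ρ is not identifiable
from the data. The posterior of the mean difference is Student-t
(dof n−1, location x̄, scale² = (1/n + ρ/(1−ρ))·s²); region masses over
(−∞,−0.01), [−0.01,0.01], (0.01,∞) decide column-better / equivalent /
row-better, and a cell displays the winning region's mass. Runs are pooled
into one 100-length difference vector. Degenerate zero-variance vectors
collapse to a point mass; a mean exactly on a ROPE edge counts as inside
(closed-interval convention). As ρ → 0 the posterior recovers the ordinary
one-sample t (tested numerically).

## Synthetic world

The generator emulates the statistical structure the classifier relies on,
with defaults chosen once from physiology:

| parameter | Relax | Basal | Stress | rationale |
|---|---|---|---|---|
| mean RR (s) | 1.00 | 0.80 | 0.62 | 60 / 75 / 97 bpm seated range |
| RSA amplitude (s) | 0.05 | 0.03 | 0.015 | vagally mediated, shrinks under arousal |
| EDA tonic slope (µS/s) | −0.010 | 0 | +0.020 | sympathetic drift |
| SCR rate (min⁻¹) | 1 | 3 | 10 | spontaneous response frequency |

plus RSA at 0.25 Hz (15 breaths/min) with a uniformly random per-register
phase (a shared deterministic phase would let window position leak segment
identity — a generator artifact, not physiology), AR(1) beat noise
(sd 0.025 s, φ = 0.8, ~3 s correlation time), a 0.25 s interval floor,
bi-exponential SCRs (1 s rise, 4 s decay, 0.4 µS), 0.02 µS sensor noise,
EDA sampled at 8 Hz. Noise scales leave the basal class overlapping both
neighbours, so the intermediate class is the hardest — mirroring the
qualitative structure of real recordings. `scaled_separation(f)` shrinks
every state-dependent parameter toward the basal value for the
convergence-to-chance tests; cohorts can counterbalance segment order per
subject so window position carries no class information.

**What a green test establishes — and what it does not.** The synthetic
world has clean annotations, stationary states, no artefacts, no ectopic
beats, no electrode dropouts and no inter-subject physiology differences
beyond the seeded noise. Recovery of ≥ 90% accuracy here validates the
pipeline's plumbing and the features' sensitivity to the modelled effects;
it says nothing about accuracy on recorded human data, and the original
study's headline numbers are not reproducible without its unpublished
dataset. The RR_Band ablation test is directional only (adding the code to
an EDA-only feature set raises accuracy).

## Degenerate inputs and numerical conventions

- Constant signals: normalisation and band boundaries raise a
  degenerate-signal error; Poincaré Ce/Cd become NaN.
- Filter preconditions: series must exceed the edge padding (28 samples at
  order 4) and the grid Nyquist must exceed the cutoff.
- Sample (n−1) standard deviations throughout; OLS via `polyfit`/`lstsq`;
  integrals trapezoidal on the native grid.
- Every stochastic component draws from `numpy.random.default_rng` with an
  explicit seed; identical seeds reproduce registers bit for bit.

## Known limitations

- The instance-level CV default inherits the optimism of overlapping-window
  evaluation (quantified above); use `groups=` for cohort-level claims.
- The 0.05 Hz spectral band sits at the window's resolution limit.
- `EDA/RR_SurfDiff` mixes units unless standardisation is enabled.
- Whole-register normalisation and band boundaries are non-causal by
  default.
- The RResp-episode *detection* step that precedes labeling in the original
  workflow is out of scope; instances here are labeled windows.
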