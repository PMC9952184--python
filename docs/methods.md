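# Methods

## Structural models and covariate submodels

All three shipped models are linear mammillary compartment models with
zero-order (constant-rate) intravenous infusion input and first-order
elimination from the central compartment.  Concentrations are central
amounts divided by the central volume, in mg/L; times are in hours,
doses in mg, clearances in L/h, volumes in L.

The covariate submodels are evaluated per patient from sex, age (y),
total body weight (kg), serum creatinine (mg/dL) and a binary dialysis
flag:

| model   | cpts | clearance (L/h)                        | volume(s) (L)                          |
|---------|------|----------------------------------------|----------------------------------------|
| llopis  | 2    | 0.034·Clcr + 0.015·TBW                 | Vc = 0.414·TBW, Q = 7.48, Vp = 1.32·TBW |
| revilla | 1    | 0.67·Clcr·age⁻⁰·²⁴                     | V = 0.82·2.49^A L/kg × TBW, A = 1[Scr>1] |
| goti    | 2    | 4.5·(Clcr/120)⁰·⁸·0.7^DIAL             | Vc = 58.4·(TBW/70)·0.5^DIAL, Q = 6.5, Vp = 38.4 |

Creatinine clearance is Cockcroft–Gault,
`(140 − age)·TBW / (72·Scr)` × 0.85 for females, on total body weight
(the covariate records carry no ideal or adjusted weight; the weight
choice for obese patients is a known open point and is deliberately not
configurable yet).  Only the Goti model truncates its clearance input:
creatinine is floored at 1 mg/dL for patients older than 65 with a
measured value below 1, and the resulting clearance is capped at
150 mL/min.  Boundary behaviour is strict: age exactly 65 does not
trigger the floor and a clearance of exactly 150 mL/min is not capped.
Llopis and Revilla receive the raw Cockcroft–Gault value.

Two published inconsistencies are treated as configuration, not code:

* **Revilla clearance units.**  The published coefficient table leaves
  the unit in which Clcr multiplies 0.67 ambiguous (mL/min vs L/h), and
  neither choice reproduces the published cohort-mean clearance at the
  printed covariate means.  `revilla_parameters` therefore takes a
  `clcr_unit` keyword (`"ml_min"`, the literal table reading, is the
  documented default; `"l_h"` converts first).  No Revilla clearance
  value participates in checkpoint verification.
* **Revilla volume scaling.**  The table prints V = 0.82·2.49^A without
  a weight factor, but the published cohort-mean volume (≈1.02 L/kg at
  the mean weight) is only consistent with per-kg scaling, so the
  coefficient is interpreted as L/kg and multiplied by TBW.

## Variability model

Interindividual variability is multiplicative log-normal: each
structural parameter is multiplied by exp(η), η ~ N(0, ω²), drawn
independently per parameter (no correlation matrix is published).  The
CV%→ω mapping defaults to the first-order convention ω = CV/100; the
exact log-normal mapping ω = √ln(1 + CV²) is available via
`convention="lognormal"` (they differ by <6% below CV 40%).  The
published per-parameter CV%s are stored with each model, but the
prediction protocol uses a single simulation-wide override — CV 30%
for all parameters and an additive residual SD of 3 mg/L — matching the
evaluation protocol this package implements.  The published model-native
residual SDs are likewise stored but not used by default, because their
error-model interpretation (additive vs proportional) is not stated.

Residual error is additive and applied only to the simulated trough
(the observed quantity), not at every grid point; simulated
observations below zero are clamped to 0 mg/L.

## Simulation engine

The closed form uses disposition exponents and coefficients: for one
compartment a single exponent k = CL/V with unit coefficient; for two
compartments the α/β macro-constants of the mammillary model with
coefficients (α − k21)/(α − β) and (k21 − β)/(α − β), where
k10 = CL/Vc, k12 = Q/Vc, k21 = Q/Vp.  A single infusion of rate R and
duration T contributes, t hours after its start,

    C(t) = (R/Vc) Σᵢ (cᵢ/λᵢ)·(1 − e^{−λᵢ·min(t,T)})·e^{−λᵢ·max(t−T,0)}

and multi-dose profiles are superpositions of per-dose responses.
`1 − e^{−x}` is computed with `expm1` for small-argument accuracy.  The
independent oracle integrates the amount-balance ODEs with
`scipy.integrate.solve_ivp` (DOP853, rtol 1e−11, atol 1e−12), segment
by segment between infusion-rate breakpoints so the rate
discontinuities are exact.  The test suite holds the two engines to
≤ 1e−6 relative agreement over randomized parameter/regimen sweeps;
equal α/β (a measure-zero degeneracy) is not special-cased.

Trough convention: "the trough at t" is the left limit at t —
the concentration just before any dose administered at t, which for the
default q12h regimen (doses at 0, 12, 24 h) makes the 36 h value the
sample before the fourth dose.  Because infusions start at zero rate
contribution, the left limit equals the closed-form value at t with the
simultaneous dose excluded automatically.

The *prediction* runs `n_runs = 5` independent 1000-replicate
Monte-Carlo simulations (sub-seeds spawned from the user seed via
`numpy.random.SeedSequence`), summarises each run by its median and
reports the median of the run medians; the 95% band is the empirical
2.5th/97.5th percentile of the first run's replicates (no
distributional assumption).  With CV = SD = 0 the prediction equals
the deterministic estimate exactly.

Steady-state exposure is AUC24 = daily dose / CL with bands:
below (<400), in-target [400, 600], above-target (600, 700),
toxicity-risk (≥700) mg·h/L; both band edges follow the AUC-guided
dosing guidance for MIC 1 mg/L.

## Performance evaluation

For paired simulated/observed troughs: mean accuracy is the mean of
per-case ratios ×100%; mean bias is the mean Bland–Altman percentage
difference, (C_sim − C_obs)/((C_sim + C_obs)/2)·100% — the pair-mean
denominator makes it antisymmetric under swapping the two vectors, and
negative values mean underestimation; RMSE is in mg/L.  The reported
accuracy/bias SDs are across cases (not bootstrap replicates).
Bland–Altman limits of agreement use 1.96 × sample SD (n−1).
Shapiro–Wilk and paired Wilcoxon summaries are computed by
`scipy.stats` at contract level and are descriptive only; the Wilcoxon
uses `zero_method="zsplit"` with the normal approximation (recorded in
the output metadata), so a vector paired with itself yields p = 1.
Cases without a positive observed trough are excluded (the accuracy
ratio is undefined at 0) and listed in the report with n reduced.

## Synthetic cohorts

`CohortSpec` defaults encode the reference cohort's printed marginals:
n = 15, age 53.67 ± 23.53 y, weight 68.87 ± 14.63 kg, creatinine
0.76 ± 0.19 mg/dL, male fraction 9/15, no dialysis (the evaluated
patients received no renal replacement therapy; a dialysis fraction is
available for exercising the Goti DIAL terms).  Covariates are drawn by
rejection from truncated normals with physiologically plausible adult
ICU bounds — age [18, 95] y, weight [35, 160] kg, creatinine
[0.3, 6.0] mg/dL — chosen here because only means and SDs are
published.  Only marginals are matched: the real cohort's covariate
joint structure (e.g., the creatinine-clearance mean it implies) cannot
be pinned down from printed marginals, so passing recovery tests on
synthetic cohorts demonstrates pipeline correctness, not transportable
clinical performance.  The default virtual regimen is 1000 mg loading
then 1000 mg q12h infused over 1 h (no regimen numbers are published;
all of it is configurable).

Virtual observations realize individual parameters from a chosen
ground-truth model, simulate the 36 h trough and add N(0, SD²) assay
noise.  With variability off, the closed loop is exact (accuracy 100%,
bias 0, RMSE 0) for every model — the self-consistency check.  With the
protocol variability (CV 30%, SD 3) on a 200-patient Llopis-truth
cohort, the Llopis report's mean accuracy is closest to 100% among the
three models in a majority of 20 seeds; the margin is checked in
estimate mode, where the dominance is a deterministic function of the
seed and the check runs in seconds.

## Numerical and design choices

* Output files round concentrations/metrics to 4 decimal places; all
  comparisons in tests use tolerances, never string equality.
* Per-case prediction sub-seeds are derived as
  `(seed·100003 + index·7919 + 1) mod 2³¹` so cohort evaluation is
  reproducible case by case.
* Determinism contracts are tested bit-for-bit (same seed → identical
  files from the CLI).
* Steady-state comparisons run ~30 half-lives because the
  approach-to-steady-state transient decays as e^{−kt} and must sit
  below the 1e−6 comparison tolerance.
* Problem sizes in tests (10 000-draw Monte-Carlo medians, 100-draw
  engine sweeps, 20-seed dominance checks at n = 200) were chosen to
  keep Monte-Carlo error well inside the asserted tolerances while the
  suite stays fast.

## Known limitations

* No Bayesian (MAP) individual parameter estimation — predictions are
  pure forward simulation; the evaluation protocol here is a priori.
* No nonlinear elimination, protein binding, continuous-infusion
  optimisation, or renal-replacement modalities beyond the binary
  dialysis flag; no CKD-EPI/MDRD renal formulas.
* The external 15-patient validation statistics of the original
  evaluation are not reproducible: that dataset is available only on
  request, so the package verifies the analytically forced model
  checkpoints and the pipeline's internal consistency instead.
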