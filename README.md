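# vancosim

Population-pharmacokinetic simulation and trough prediction for
vancomycin model-informed precision dosing (MIPD) in critically ill
adults.

Vancomycin dosing is guided by therapeutic drug monitoring: the trough
concentration sampled immediately before the fourth dose (36 h into a
q12h regimen) and the daily exposure AUC24, which should sit between
400 and 600 mg·h/L for an MIC of 1 mg/L and stay below 700 mg·h/L to
limit nephrotoxicity.  `vancosim` implements the computational core of
an MIPD workflow for clinical pharmacologists and pharmacometricians:

* **Three published population models**, selected for ICU use:
  - *Llopis* (2 compartments): CL = 0.034·Clcr + 0.015·TBW L/h,
    Vc = 0.414·TBW, Q = 7.48 L/h, Vp = 1.32·TBW;
  - *Revilla* (1 compartment): CL = 0.67·Clcr·age⁻⁰·²⁴,
    V = 0.82·2.49^A L/kg × TBW with A = 1[Scr > 1 mg/dL];
  - *Goti* (2 compartments): CL = 4.5·(Clcr/120)⁰·⁸·0.7^DIAL,
    Vc = 58.4·(TBW/70)·0.5^DIAL, Q = 6.5 L/h, Vp = 38.4 L, where the
    Goti clearance input is Cockcroft–Gault with creatinine floored at
    1 mg/dL for patients over 65 and the result capped at 150 mL/min.
* **An intermittent-infusion simulator**: closed-form superposition of
  one/two-compartment infusion responses, validated against an
  independent ODE integration oracle to ≤ 1e−6 relative error.
* **Trough estimation and prediction**: the deterministic
  (typical-value) *estimate* and the Monte-Carlo *prediction* — 1000
  replicates per run with log-normal interindividual variability
  (CV 30% by default) and additive residual error (SD 3 mg/L), five
  runs, reported as the median of the run medians with an empirical
  95% band.
* **Predictive-performance evaluation**: mean accuracy
  (mean of C_sim/C_obs × 100%), mean bias (Bland–Altman percentage
  difference), RMSE, Bland–Altman tables with 1.96·SD limits of
  agreement, and Shapiro–Wilk/Wilcoxon distribution summaries.
* **A synthetic cohort generator** reproducing the reference cohort's
  marginal demographics (n = 15, age 53.67 ± 23.53 y, weight
  68.87 ± 14.63 kg, creatinine 0.76 ± 0.19 mg/dL, 9/15 male), so the
  whole pipeline is testable without patient data.

## Worked example

```python
import vancosim as vs

patient = vs.Patient(id="p1", sex="M", age=54, tbw=69, scr=0.76)
regimen = vs.DosingRegimen(loading_dose=1000, maintenance_dose=1000,
                           interval=12, infusion_duration=1, horizon=48)

params = vs.population_parameters("llopis", patient)
print(f"CL={params.cl:.2f} L/h  Vc={params.vc:.2f} L  Vp={params.vp:.2f} L")

estimate = vs.estimate_trough("llopis", patient, regimen)      # 36 h trough
summary = vs.predict_trough("llopis", patient, regimen, seed=42)
auc, band = vs.steady_state_auc24(params.cl, regimen.daily_dose)
print(f"estimate={estimate:.2f} mg/L  prediction={summary.prediction:.2f} "
      f"[{summary.ci_low:.2f}, {summary.ci_high:.2f}] mg/L")
print(f"AUC24={auc:.0f} mg*h/L ({band})")
```

prints

```
CL=4.72 L/h  Vc=28.57 L  Vp=91.08 L
estimate=6.81 mg/L  prediction=6.88 [0.17, 13.66] mg/L
AUC24=424 mg*h/L (in_target)
```

The estimate (6.81 mg/L) is the trough this patient's typical-value
parameters produce just before the fourth dose; the prediction is the
median of five 1000-replicate Monte-Carlo runs under the default
variability settings, with its 95% replicate band; 2000 mg/day over a
clearance of 4.72 L/h gives an AUC24 of 424 mg·h/L, inside the
400–600 efficacy window.

The same workflow is available from the shell:

```sh
vancosim cohort-gen --n 15 --seed 1 --truth-model llopis --out-dir run/
vancosim evaluate --patients run/patients.csv --observations run/observations.csv \
    --mode both --seed 1 --out-dir run/
```

which writes one JSON performance report per model × mode (six in
total), each embedding the tool version, seed and config hash.

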