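"""Synthetic ICU cohorts and virtual trough observations.

The shipped 15-patient evaluation cohort is not public, so this module
generates virtual cohorts matching its printed marginal demographics
(age 53.67 ± 23.53 y, weight 68.87 ± 14.63 kg, serum creatinine
0.76 ± 0.19 mg/dL, 9/15 male) from truncated normals, and virtual
"observed" troughs from a chosen ground-truth model with log-normal
interindividual variability and additive assay noise.  Everything is
deterministic given (spec, seed), and the emitted CSV files are the
same formats the evaluation pipeline consumes, so synthetic and real
data are interchangeable.

Only marginal distributions are matched: no covariate correlation
structure is imposed (none is published), and no dialysis patients are
generated by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .evaluation import PerformanceReport, evaluate_cohort
from .infusion import DEFAULT_TROUGH_TIME, DosingRegimen, estimate_trough
from .models import (
    ModelDefinition,
    PKParameters,
    VariabilityOverride,
    get_model,
    population_parameters,
    realize_individual,
)
from .patients import Patient
from .infusion import _conc_at, _disposition

__all__ = [
    "CohortSpec",
    "VirtualObservation",
    "generate_cohort",
    "simulate_observations",
    "cross_model_experiment",
    "DEFAULT_REGIMEN",
]

#: Default virtual dosing: 1000 mg loading then 1000 mg q12h, 1 h infusions.
DEFAULT_REGIMEN = DosingRegimen(
    loading_dose=1000.0, maintenance_dose=1000.0, interval=12.0,
    infusion_duration=1.0, horizon=48.0,
)


@dataclass(frozen=True)
class CohortSpec:
    """Marginal covariate distributions of a virtual cohort.

    Defaults reproduce the reference cohort's printed demographics;
    covariates are truncated normals (bounds chosen as physiologically
    plausible adult ICU ranges), sex is Bernoulli(male_fraction).
    """

    n: int = 15
    age_mean: float = 53.67
    age_sd: float = 23.53
    weight_mean: float = 68.87
    weight_sd: float = 14.63
    scr_mean: float = 0.76
    scr_sd: float = 0.19
    male_fraction: float = 9.0 / 15.0
    age_bounds: tuple[float, float] = (18.0, 95.0)
    weight_bounds: tuple[float, float] = (35.0, 160.0)
    scr_bounds: tuple[float, float] = (0.3, 6.0)
    dialysis_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("cohort size n must be >= 1")
        for name in ("age_sd", "weight_sd", "scr_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("age_bounds", "weight_bounds", "scr_bounds"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ValueError(f"{name} must be ordered (low < high)")
        if not 0.0 <= self.male_fraction <= 1.0:
            raise ValueError("male_fraction must lie in [0, 1]")
        if not 0.0 <= self.dialysis_fraction <= 1.0:
            raise ValueError("dialysis_fraction must lie in [0, 1]")


@dataclass(frozen=True)
class VirtualObservation:
    """A synthetic "measured" trough with its full provenance, so any
    observation is exactly regenerable from (spec, seed)."""

    patient_id: str
    true_model: str
    true_parameters: PKParameters
    trough: float  # mg/L, >= 0
    noise_sd: float  # mg/L
    seed: int


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, bounds: tuple[float, float], n: int
) -> np.ndarray:
    """Rejection sampling from Normal(mean, sd) restricted to bounds.
    sd = 0 degenerates to the mean (which must lie inside the bounds)."""
    lo, hi = bounds
    if sd == 0:
        if not lo <= mean <= hi:
            raise ValueError(f"degenerate mean {mean} outside bounds {bounds}")
        return np.full(n, mean)
    out = rng.normal(mean, sd, size=n)
    bad = (out < lo) | (out > hi)
    while bad.any():
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
        bad = (out < lo) | (out > hi)
    return out


def generate_cohort(spec: CohortSpec = CohortSpec()) -> list[Patient]:
    """Draw a virtual cohort; deterministic for a fixed ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    age = _truncated_normal(rng, spec.age_mean, spec.age_sd, spec.age_bounds, spec.n)
    tbw = _truncated_normal(rng, spec.weight_mean, spec.weight_sd, spec.weight_bounds, spec.n)
    scr = _truncated_normal(rng, spec.scr_mean, spec.scr_sd, spec.scr_bounds, spec.n)
    male = rng.random(spec.n) < spec.male_fraction
    dialysis = rng.random(spec.n) < spec.dialysis_fraction
    width = len(str(spec.n))
    return [
        Patient(
            id=f"P{i + 1:0{width}d}",
            sex="M" if male[i] else "F",
            age=float(age[i]),
            tbw=float(tbw[i]),
            scr=float(scr[i]),
            dialysis=bool(dialysis[i]),
        )
        for i in range(spec.n)
    ]


def simulate_observations(
    patients: Sequence[Patient],
    true_model: str | ModelDefinition,
    regimen: DosingRegimen = DEFAULT_REGIMEN,
    iiv_cv: float = 30.0,
    noise_sd: float = 3.0,
    seed: int = 0,
    trough_time: float = DEFAULT_TROUGH_TIME,
    convention: str = "direct",
    **model_config,
) -> list[VirtualObservation]:
    """Virtual "observed" troughs: per patient, realize individual
    parameters from the truth model at ``iiv_cv`` CV%, simulate the
    trough, add Normal(0, noise_sd²) assay noise and clamp at zero."""
    model_def = get_model(true_model)
    rng = np.random.default_rng(seed)
    override = VariabilityOverride(iiv_cv_percent=iiv_cv, residual_sd=noise_sd)
    out: list[VirtualObservation] = []
    for patient in patients:
        pop = population_parameters(model_def, patient, **model_config)
        indiv = realize_individual(pop, override=override, seed=rng, convention=convention)
        lam, coef = _disposition(indiv.cl, indiv.vc, indiv.q, indiv.vp)
        trough = float(_conc_at(lam, coef, indiv.vc, regimen, float(trough_time)))
        if noise_sd > 0:
            trough += float(rng.normal(0.0, noise_sd))
        out.append(
            VirtualObservation(
                patient_id=patient.id,
                true_model=model_def.name,
                true_parameters=indiv,
                trough=max(trough, 0.0),
                noise_sd=noise_sd,
                seed=seed,
            )
        )
    return out


def cross_model_experiment(
    cohort: Sequence[Patient],
    truth_model: str | ModelDefinition,
    candidate_models: Sequence[str | ModelDefinition],
    regimen: DosingRegimen = DEFAULT_REGIMEN,
    seed: int = 0,
    iiv_cv: float = 30.0,
    noise_sd: float = 3.0,
    modes: Sequence[str] = ("estimate", "prediction"),
    n_replicates: int = 1000,
    n_runs: int = 5,
    trough_time: float = DEFAULT_TROUGH_TIME,
) -> dict[tuple[str, str], PerformanceReport]:
    """The study design in miniature: one virtual observed dataset from
    ``truth_model``, scored by every candidate model in each requested
    mode.  Returns one report per (model name, mode).

    In expectation, the truth model's estimate-mode report is the one
    whose mean accuracy lies closest to 100%.
    """
    if not candidate_models:
        raise ValueError("at least one candidate model is required")
    observations = simulate_observations(
        cohort, truth_model, regimen, iiv_cv, noise_sd, seed, trough_time
    )
    observed = {o.patient_id: o.trough for o in observations if o.trough > 0}
    reports: dict[tuple[str, str], PerformanceReport] = {}
    for candidate in candidate_models:
        model_def = get_model(candidate)
        for mode in modes:
            reports[(model_def.name, mode)] = evaluate_cohort(
                cohort, observed, model_def, mode, regimen,
                seed=seed,
                override=VariabilityOverride(iiv_cv_percent=iiv_cv, residual_sd=noise_sd),
                trough_time=trough_time,
                n_replicates=n_replicates,
                n_runs=n_runs,
            )
    return reports
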