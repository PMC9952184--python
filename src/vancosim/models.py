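"""Population pharmacokinetic models of vancomycin.

Three published covariate models are shipped:

* **Llopis** — two compartments, clearance linear in creatinine
  clearance and total body weight, volumes linear in weight.
* **Revilla** — one compartment, clearance a power function of age
  scaled by creatinine clearance, distribution volume per kg switching
  on a serum-creatinine indicator.
* **Goti** — two compartments, clearance a power function of
  (truncated) creatinine clearance normalised to 120 mL/min, central
  volume normalised to 70 kg, with dialysis factors 0.7 (CL) and 0.5
  (Vc); Q and Vp are fixed constants.

Each model bundles its fixed-effect coefficients (thetas), the published
interindividual variability (CV% per parameter) and residual-error SDs
(mg/L).  ``realize_individual`` turns population parameters into one
individual's parameters by independent log-normal perturbation.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Mapping

import numpy as np

from .patients import Patient
from .renal import cockcroft_gault, goti_effective_clcr

__all__ = [
    "PKParameters",
    "ModelDefinition",
    "VariabilityOverride",
    "llopis_parameters",
    "revilla_parameters",
    "revilla_volume_per_kg",
    "goti_parameters",
    "population_parameters",
    "realize_individual",
    "cv_to_omega",
    "get_model",
    "register_model",
    "available_models",
    "model_to_json",
    "model_from_json",
]


@dataclass(frozen=True)
class PKParameters:
    """Structural PK parameters for one individual (or the population
    typical values).

    cl : vancomycin clearance, L/h
    vc : central (or total, one-compartment) volume, L
    vp : peripheral volume, L — ``None`` for one-compartment models
    q  : intercompartmental clearance, L/h — ``None`` for one-compartment
    """

    cl: float
    vc: float
    vp: float | None = None
    q: float | None = None

    def __post_init__(self) -> None:
        for name in ("cl", "vc", "vp", "q"):
            value = getattr(self, name)
            if value is not None and not value > 0:
                raise ValueError(f"PK parameter {name} must be strictly positive, got {value}")
        if (self.vp is None) != (self.q is None):
            raise ValueError("vp and q must both be present (2-cpt) or both absent (1-cpt)")

    @property
    def n_compartments(self) -> int:
        return 1 if self.vp is None else 2

    def as_dict(self) -> dict[str, float]:
        d = {"cl": self.cl, "vc": self.vc}
        if self.vp is not None:
            d["vp"] = self.vp
            d["q"] = self.q
        return d


@dataclass(frozen=True)
class VariabilityOverride:
    """Simulation-wide variability settings used for predictions:
    one CV% applied to every structural parameter and one additive
    residual SD (mg/L) applied to the simulated trough.

    Defaults are CV 30% and SD 3 mg/L.
    """

    iiv_cv_percent: float = 30.0
    residual_sd: float = 3.0

    def __post_init__(self) -> None:
        if self.iiv_cv_percent < 0:
            raise ValueError("interindividual CV% must be >= 0")
        if self.residual_sd < 0:
            raise ValueError("residual SD must be >= 0")


@dataclass(frozen=True)
class ModelDefinition:
    """A population model: named fixed effects, IIV CV% per parameter and
    residual SDs, plus the structural covariate equation (referenced by
    ``structure``, one of the shipped equation families).

    Definitions round-trip through JSON (see :func:`model_to_json`), so a
    re-estimated coefficient set can be shipped as data without code
    changes, as long as it reuses one of the shipped equation forms.
    """

    name: str
    n_compartments: int
    thetas: Mapping[str, float]
    omegas: Mapping[str, float]  # CV% per parameter
    sigmas: Mapping[str, float]  # residual SDs, mg/L
    structure: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "thetas", dict(self.thetas))
        object.__setattr__(self, "omegas", dict(self.omegas))
        object.__setattr__(self, "sigmas", dict(self.sigmas))
        if not self.structure:
            object.__setattr__(self, "structure", self.name)
        if self.n_compartments not in (1, 2):
            raise ValueError("n_compartments must be 1 or 2")
        if any(v < 0 for v in self.omegas.values()):
            raise ValueError("interindividual CV% values must be >= 0")
        if any(v < 0 for v in self.sigmas.values()):
            raise ValueError("residual SDs must be >= 0")
        if self.n_compartments == 1 and ("vp" in self.omegas or "q" in self.omegas):
            raise ValueError("one-compartment model cannot carry vp/q variability")

    def population_parameters(self, patient: Patient, **config) -> PKParameters:
        """Typical-value parameters for ``patient`` (no random effects)."""
        try:
            equation = _STRUCTURES[self.structure]
        except KeyError:
            raise KeyError(
                f"unknown structural equation {self.structure!r}; "
                f"available: {sorted(_STRUCTURES)}"
            ) from None
        return equation(self.thetas, patient, **config)


# ---------------------------------------------------------------------------
# Covariate equations


def llopis_parameters(clcr: float, tbw: float) -> PKParameters:
    """Llopis model: CL = 0.034·Clcr + 0.015·TBW (L/h); Vc = 0.414·TBW;
    Q = 7.48 L/h; Vp = 1.32·TBW.  Clcr in mL/min, TBW in kg."""
    return _llopis_equation(LLOPIS.thetas, clcr=clcr, tbw=tbw)


def _llopis_equation(thetas, patient: Patient | None = None, *, clcr=None, tbw=None) -> PKParameters:
    if patient is not None:
        clcr = cockcroft_gault(patient.age, patient.tbw, patient.scr, patient.sex)
        tbw = patient.tbw
    if not clcr > 0:
        raise ValueError(f"creatinine clearance must be > 0 mL/min, got {clcr}")
    if not tbw > 0:
        raise ValueError(f"body weight must be > 0 kg, got {tbw}")
    t = thetas
    return PKParameters(
        cl=t["theta1"] * clcr + t["theta2"] * tbw,
        vc=t["theta3"] * tbw,
        q=t["theta4"],
        vp=t["theta5"] * tbw,
    )


def revilla_volume_per_kg(scr: float) -> float:
    """Revilla per-kg distribution volume (L/kg): 0.82 for Scr <= 1 mg/dL,
    0.82 × 2.49 above."""
    t = REVILLA.thetas
    indicator = 0 if scr <= 1.0 else 1
    return t["theta3"] * t["theta4"] ** indicator


def revilla_parameters(
    clcr: float,
    age: float,
    scr: float,
    tbw: float,
    clcr_unit: str = "ml_min",
) -> PKParameters:
    """Revilla model: V = 0.82·2.49^A L/kg × TBW with A = 1[Scr > 1 mg/dL];
    CL = 0.67 · Clcr · age^(-0.24) in L/h.

    ``clcr_unit`` selects the unit in which Clcr enters the clearance
    equation — ``"ml_min"`` (the literal published reading, the default)
    or ``"l_h"`` (Clcr converted to L/h first).  The published source
    leaves the convention ambiguous, so it is an explicit configuration
    knob rather than a hidden constant.
    """
    return _revilla_equation(
        REVILLA.thetas, clcr=clcr, age=age, scr=scr, tbw=tbw, clcr_unit=clcr_unit
    )


def _revilla_equation(
    thetas,
    patient: Patient | None = None,
    *,
    clcr=None,
    age=None,
    scr=None,
    tbw=None,
    clcr_unit: str = "ml_min",
) -> PKParameters:
    if patient is not None:
        clcr = cockcroft_gault(patient.age, patient.tbw, patient.scr, patient.sex)
        age, scr, tbw = patient.age, patient.scr, patient.tbw
    for name, value in (("clcr", clcr), ("age", age), ("scr", scr), ("tbw", tbw)):
        if not value > 0:
            raise ValueError(f"{name} must be strictly positive, got {value}")
    if clcr_unit == "ml_min":
        clcr_in = clcr
    elif clcr_unit == "l_h":
        clcr_in = clcr * 60.0 / 1000.0
    else:
        raise ValueError(
            f"clcr_unit must be 'ml_min' or 'l_h', got {clcr_unit!r}"
        )
    t = thetas
    indicator = 0 if scr <= 1.0 else 1
    v_per_kg = t["theta3"] * t["theta4"] ** indicator
    return PKParameters(
        cl=t["theta1"] * clcr_in * age ** t["theta2"],
        vc=v_per_kg * tbw,
    )


def goti_parameters(clcr_goti: float, tbw: float, dialysis: bool) -> PKParameters:
    """Goti model: CL = 4.5·(Clcr/120)^0.8 · 0.7^DIAL (L/h);
    Vc = 58.4·(TBW/70) · 0.5^DIAL; Q = 6.5 L/h; Vp = 38.4 L.

    ``clcr_goti`` must already be truncated (<= 150 mL/min); the caller
    is responsible for the creatinine floor and clearance cap (see
    :func:`vancosim.renal.goti_effective_clcr`).
    """
    return _goti_equation(GOTI.thetas, clcr_goti=clcr_goti, tbw=tbw, dialysis=dialysis)


def _goti_equation(
    thetas,
    patient: Patient | None = None,
    *,
    clcr_goti=None,
    tbw=None,
    dialysis=None,
) -> PKParameters:
    if patient is not None:
        clcr_goti = goti_effective_clcr(patient)
        tbw, dialysis = patient.tbw, patient.dialysis
    if not clcr_goti > 0:
        raise ValueError(f"creatinine clearance must be > 0 mL/min, got {clcr_goti}")
    if clcr_goti > 150.0:
        raise ValueError(
            f"Goti model requires pre-truncated clearance <= 150 mL/min, got {clcr_goti}"
        )
    if not tbw > 0:
        raise ValueError(f"body weight must be > 0 kg, got {tbw}")
    t = thetas
    dial = 1 if dialysis else 0
    return PKParameters(
        cl=t["theta1"] * (clcr_goti / 120.0) ** t["theta2"] * t["theta3"] ** dial,
        vc=t["theta4"] * (tbw / 70.0) * t["theta5"] ** dial,
        q=t["q"],
        vp=t["vp"],
    )


_STRUCTURES: dict[str, Callable[..., PKParameters]] = {
    "llopis": _llopis_equation,
    "revilla": _revilla_equation,
    "goti": _goti_equation,
}


# ---------------------------------------------------------------------------
# Shipped model definitions (published coefficient tables)

LLOPIS = ModelDefinition(
    name="llopis",
    n_compartments=2,
    thetas={"theta1": 0.034, "theta2": 0.015, "theta3": 0.414, "theta4": 7.48, "theta5": 1.32},
    omegas={"cl": 29.2, "vc": 36.4, "vp": 39.8},
    sigmas={"sigma1": 4.88, "sigma2": 4.3},
)

REVILLA = ModelDefinition(
    name="revilla",
    n_compartments=1,
    thetas={"theta1": 0.67, "theta2": -0.24, "theta3": 0.82, "theta4": 2.49},
    omegas={"cl": 30.13, "vc": 22.83},
    sigmas={"sigma1": 4.23},
)

GOTI = ModelDefinition(
    name="goti",
    n_compartments=2,
    thetas={"theta1": 4.5, "theta2": 0.8, "theta3": 0.7, "theta4": 58.4, "theta5": 0.5,
            "q": 6.5, "vp": 38.4},
    omegas={"cl": 39.8, "vc": 81.6, "vp": 57.1},
    sigmas={"sigma1": 5.13, "sigma2": 3.4},
)

_REGISTRY: dict[str, ModelDefinition] = {m.name: m for m in (LLOPIS, REVILLA, GOTI)}


def get_model(model: str | ModelDefinition) -> ModelDefinition:
    """Look a model up by name (or pass a definition through)."""
    if isinstance(model, ModelDefinition):
        return model
    try:
        return _REGISTRY[model]
    except KeyError:
        raise KeyError(f"unknown model {model!r}; available: {sorted(_REGISTRY)}") from None


def register_model(definition: ModelDefinition) -> None:
    """Add a model to the registry; its ``structure`` must reference one
    of the shipped equation families."""
    if definition.structure not in _STRUCTURES:
        raise KeyError(
            f"structure {definition.structure!r} unknown; available: {sorted(_STRUCTURES)}"
        )
    _REGISTRY[definition.name] = definition


def available_models() -> list[str]:
    return sorted(_REGISTRY)


def population_parameters(model: str | ModelDefinition, patient: Patient, **config) -> PKParameters:
    """Typical-value parameters of ``model`` for ``patient``."""
    return get_model(model).population_parameters(patient, **config)


def model_to_json(model: str | ModelDefinition, path: str | Path | None = None) -> str:
    """Serialize a model definition (thetas/omegas/sigmas blocks) to JSON."""
    m = get_model(model)
    doc = {
        "name": m.name,
        "structure": m.structure,
        "n_compartments": m.n_compartments,
        "thetas": dict(m.thetas),
        "omegas": dict(m.omegas),
        "sigmas": dict(m.sigmas),
    }
    text = json.dumps(doc, indent=2)
    if path is not None:
        Path(path).write_text(text + "\n")
    return text


def model_from_json(source: str | Path) -> ModelDefinition:
    """Inverse of :func:`model_to_json`; accepts a JSON string or a path."""
    text = Path(source).read_text() if isinstance(source, Path) else str(source)
    if isinstance(source, str) and not text.lstrip().startswith("{"):
        text = Path(source).read_text()
    doc = json.loads(text)
    return ModelDefinition(
        name=doc["name"],
        n_compartments=int(doc["n_compartments"]),
        thetas=doc["thetas"],
        omegas=doc["omegas"],
        sigmas=doc["sigmas"],
        structure=doc.get("structure", doc["name"]),
    )


# ---------------------------------------------------------------------------
# Interindividual variability


def cv_to_omega(cv_percent: float, convention: str = "direct") -> float:
    """Map a CV% to the log-scale SD of the log-normal random effect.

    ``"direct"`` (default) uses omega = CV/100, the first-order
    convention; ``"lognormal"`` uses omega = sqrt(ln(1 + (CV/100)^2)),
    exact for a log-normal.  At CV <= 40% the two differ by < 6%.
    """
    if cv_percent < 0:
        raise ValueError("CV% must be >= 0")
    cv = cv_percent / 100.0
    if convention == "direct":
        return cv
    if convention == "lognormal":
        return math.sqrt(math.log1p(cv * cv))
    raise ValueError(f"convention must be 'direct' or 'lognormal', got {convention!r}")


def realize_individual(
    pop: PKParameters,
    model: ModelDefinition | None = None,
    override: VariabilityOverride | None = None,
    *,
    seed: int | np.random.Generator,
    convention: str = "direct",
) -> PKParameters:
    """One individual's parameters: every parameter multiplied by
    ``exp(eta)`` with eta ~ Normal(0, omega^2), drawn independently per
    parameter.

    If ``override`` is given its single CV% applies to every structural
    parameter; otherwise the model's published per-parameter CV%s are
    used (parameters without a published omega stay fixed).  CV = 0
    returns the population values unchanged; a fixed seed is fully
    reproducible.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    names = [n for n in ("cl", "vc", "vp", "q") if getattr(pop, n) is not None]
    if override is not None:
        cvs = {n: override.iiv_cv_percent for n in names}
    elif model is not None:
        cvs = {n: model.omegas.get(n, 0.0) for n in names}
    else:
        raise ValueError("either a model definition or a variability override is required")
    values = {}
    for n in names:
        omega = cv_to_omega(cvs[n], convention)
        eta = rng.normal(0.0, omega) if omega > 0 else 0.0
        values[n] = getattr(pop, n) * math.exp(eta)
    return PKParameters(**values)
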