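"""Creatinine-clearance covariates.

Cockcroft–Gault creatinine clearance from age, total body weight, serum
creatinine and sex, plus the two truncations the Goti model applies to
its clearance input:

* serum creatinine is floored at 1 mg/dL for patients older than 65
  years whose measured value is below 1 (augmented renal function in the
  elderly otherwise inflates the estimate), and
* the resulting clearance is capped at 150 mL/min.

The Llopis and Revilla models receive the raw Cockcroft–Gault value;
only the Goti model uses the truncated one.
"""

from __future__ import annotations

from dataclasses import dataclass

from .patients import Patient

__all__ = [
    "cockcroft_gault",
    "goti_effective_scr",
    "goti_effective_clcr",
    "renal_function",
    "RenalFunction",
    "GOTI_CLCR_CAP",
]

#: Upper truncation of creatinine clearance (mL/min) in the Goti model.
GOTI_CLCR_CAP = 150.0


@dataclass(frozen=True)
class RenalFunction:
    """Raw and Goti-truncated renal function for one patient.

    Attributes
    ----------
    clcr_raw:
        Cockcroft–Gault clearance from measured covariates, mL/min.
    clcr_goti:
        Clearance after the Goti creatinine floor and 150 mL/min cap.
    scr_goti:
        The creatinine value (mg/dL) that entered the Goti computation.
    """

    clcr_raw: float
    clcr_goti: float
    scr_goti: float


def cockcroft_gault(age: float, tbw: float, scr: float, sex: str) -> float:
    """Cockcroft–Gault creatinine clearance in mL/min.

    ``((140 - age) * tbw) / (72 * scr)``, multiplied by 0.85 for females.
    Total body weight is used (no ideal/adjusted-weight variant).
    """
    if scr <= 0:
        raise ValueError(f"serum creatinine must be > 0 mg/dL, got {scr}")
    if tbw <= 0:
        raise ValueError(f"body weight must be > 0 kg, got {tbw}")
    if age >= 140:
        raise ValueError(f"age must be < 140 years, got {age}")
    if sex not in ("M", "F"):
        raise ValueError(f"sex must be 'M' or 'F', got {sex!r}")
    clcr = (140.0 - age) * tbw / (72.0 * scr)
    if sex == "F":
        clcr *= 0.85
    return clcr


def goti_effective_scr(age: float, scr: float) -> float:
    """Creatinine the Goti model uses: floored at 1 mg/dL when age > 65
    and the measured value is below 1 mg/dL; otherwise unchanged."""
    if scr <= 0:
        raise ValueError(f"serum creatinine must be > 0 mg/dL, got {scr}")
    if age > 65 and scr < 1.0:
        return 1.0
    return scr


def goti_effective_clcr(patient: Patient) -> float:
    """Clearance input of the Goti model: Cockcroft–Gault on the floored
    creatinine, then capped at 150 mL/min."""
    scr_eff = goti_effective_scr(patient.age, patient.scr)
    clcr = cockcroft_gault(patient.age, patient.tbw, scr_eff, patient.sex)
    return min(clcr, GOTI_CLCR_CAP)


def renal_function(patient: Patient) -> RenalFunction:
    """Both renal-function views for a patient."""
    return RenalFunction(
        clcr_raw=cockcroft_gault(patient.age, patient.tbw, patient.scr, patient.sex),
        clcr_goti=goti_effective_clcr(patient),
        scr_goti=goti_effective_scr(patient.age, patient.scr),
    )
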