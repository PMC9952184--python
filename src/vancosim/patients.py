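"""Patient covariates and CSV round-tripping.

A :class:`Patient` carries the covariates the shipped population models
consume: sex, age (years), total body weight (kg), serum creatinine
(mg/dL) and a binary dialysis flag.  Covariate validation happens at
construction so no model ever sees an out-of-range value.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = ["Patient", "read_patients_csv", "write_patients_csv", "PATIENT_CSV_COLUMNS"]

#: Canonical patient-CSV header, one row per patient.
PATIENT_CSV_COLUMNS = ["id", "sex", "age", "weight_kg", "scr_mgdl", "dialysis"]

_SEXES = frozenset({"M", "F"})


@dataclass(frozen=True)
class Patient:
    """A single patient's model-input covariates.

    Parameters
    ----------
    id:
        Free-text case label.
    sex:
        ``"M"`` or ``"F"``.
    age:
        Age in years; must lie in the open interval (0, 130).
    tbw:
        Total body weight in kg; must lie in (20, 300).
    scr:
        Serum creatinine in mg/dL; strictly positive.
    dialysis:
        True if the patient is on dialysis (the DIAL covariate of the
        Goti model).
    """

    id: str
    sex: str
    age: float
    tbw: float
    scr: float
    dialysis: bool = False

    def __post_init__(self) -> None:
        if self.sex not in _SEXES:
            raise ValueError(f"patient {self.id!r}: sex must be 'M' or 'F', got {self.sex!r}")
        if not 0 < self.age < 130:
            raise ValueError(f"patient {self.id!r}: age {self.age} outside (0, 130) years")
        if not 20 < self.tbw < 300:
            raise ValueError(f"patient {self.id!r}: weight {self.tbw} outside (20, 300) kg")
        if not self.scr > 0:
            raise ValueError(f"patient {self.id!r}: serum creatinine must be > 0 mg/dL")

    @property
    def is_female(self) -> bool:
        return self.sex == "F"

    def to_row(self) -> dict:
        return {
            "id": self.id,
            "sex": self.sex,
            "age": self.age,
            "weight_kg": self.tbw,
            "scr_mgdl": self.scr,
            "dialysis": int(self.dialysis),
        }


def read_patients_csv(path: str | Path) -> list[Patient]:
    """Read patients from CSV with header ``id,sex,age,weight_kg,scr_mgdl,dialysis``.

    Parsing is strict: missing required columns raise, unknown columns are
    ignored.  Lines starting with ``#`` are treated as comments (output
    files embed provenance that way).
    """
    df = pd.read_csv(path, comment="#", dtype={"id": str, "sex": str})
    missing = [c for c in PATIENT_CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    patients = []
    for i, row in df.iterrows():
        try:
            patients.append(
                Patient(
                    id=str(row["id"]),
                    sex=str(row["sex"]).strip().upper(),
                    age=float(row["age"]),
                    tbw=float(row["weight_kg"]),
                    scr=float(row["scr_mgdl"]),
                    dialysis=bool(int(row["dialysis"])),
                )
            )
        except (ValueError, TypeError) as exc:
            raise ValueError(f"{path}: row {i + 2}: {exc}") from exc
    return patients


def write_patients_csv(
    patients: Iterable[Patient],
    path: str | Path,
    header_comments: Sequence[str] = (),
) -> None:
    """Write patients in the canonical CSV layout, optionally preceded by
    ``#``-prefixed provenance comment lines."""
    df = pd.DataFrame([p.to_row() for p in patients], columns=PATIENT_CSV_COLUMNS)
    with open(path, "w") as fh:
        for line in header_comments:
            fh.write(f"# {line}\n")
        df.to_csv(fh, index=False)
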