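"""Predictive-performance evaluation.

Given paired simulated and observed troughs (one pair per case j), three
summary metrics are computed:

* mean accuracy:  (1/n) * sum_j C_sim,j / C_obs,j  × 100%
* mean bias:      (1/n) * sum_j (C_sim,j − C_obs,j) / ((C_sim,j + C_obs,j)/2) × 100%
  (the Bland–Altman percentage difference; negative = underestimation)
* RMSE:           sqrt((1/n) * sum_j (C_sim,j − C_obs,j)^2), mg/L

plus a Bland–Altman agreement table (per-case pair mean and difference,
mean difference, 1.96·SD limits of agreement with sample SD) and
contract-level distribution summaries (Shapiro–Wilk normality, paired
Wilcoxon signed-rank) via scipy.stats.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .infusion import (
    DEFAULT_TROUGH_TIME,
    DosingRegimen,
    estimate_trough,
    predict_trough,
)
from .models import ModelDefinition, VariabilityOverride, get_model
from .patients import Patient

__all__ = [
    "EvaluationCase",
    "PerformanceReport",
    "BlandAltmanResult",
    "mean_accuracy",
    "mean_bias",
    "rmse",
    "bland_altman_table",
    "evaluate_cohort",
    "distribution_summary",
    "read_observations_csv",
    "write_observations_csv",
]

MODES = ("estimate", "prediction")


@dataclass(frozen=True)
class EvaluationCase:
    """One simulated/observed trough pair."""

    case_id: str
    c_sim: float  # mg/L
    c_obs: float  # mg/L
    mode: str = "estimate"

    def __post_init__(self) -> None:
        if self.c_sim < 0:
            raise ValueError(f"case {self.case_id!r}: simulated trough must be >= 0 mg/L")
        if not self.c_obs > 0:
            raise ValueError(f"case {self.case_id!r}: observed trough must be > 0 mg/L")
        if self.mode not in MODES:
            raise ValueError(f"case {self.case_id!r}: mode must be one of {MODES}")


def _as_arrays(cases: Sequence[EvaluationCase]) -> tuple[np.ndarray, np.ndarray]:
    if len(cases) < 1:
        raise ValueError("at least one evaluation case is required")
    sim = np.array([c.c_sim for c in cases], dtype=float)
    obs = np.array([c.c_obs for c in cases], dtype=float)
    return sim, obs


def mean_accuracy(cases: Sequence[EvaluationCase]) -> float:
    """Mean of per-case ratios C_sim/C_obs, as a percentage."""
    sim, obs = _as_arrays(cases)
    return float(np.mean(sim / obs) * 100.0)


def mean_bias(cases: Sequence[EvaluationCase]) -> float:
    """Mean percentage difference relative to the pair mean; negative
    means the model underestimates the observation."""
    sim, obs = _as_arrays(cases)
    pair_mean = (sim + obs) / 2.0
    if np.any(pair_mean <= 0):
        bad = [cases[i].case_id for i in np.where(pair_mean <= 0)[0]]
        raise ValueError(f"pair mean is zero for case(s) {bad}; bias undefined")
    return float(np.mean((sim - obs) / pair_mean) * 100.0)


def rmse(cases: Sequence[EvaluationCase]) -> float:
    """Root mean squared difference, mg/L."""
    sim, obs = _as_arrays(cases)
    return float(np.sqrt(np.mean((sim - obs) ** 2)))


@dataclass(frozen=True)
class BlandAltmanResult:
    """Per-case agreement table plus the bias line and 1.96·SD limits of
    agreement (sample SD, n−1).  Limits are None with a warning status
    when fewer than two cases are available."""

    table: pd.DataFrame  # columns: case_id, pair_mean, difference
    mean_difference: float
    loa_low: float | None
    loa_high: float | None
    status: str = "ok"

    def to_csv(self, path: str | Path, header_comments: Sequence[str] = ()) -> None:
        with open(path, "w") as fh:
            for line in header_comments:
                fh.write(f"# {line}\n")
            fh.write(f"# mean_difference: {self.mean_difference:.4f}\n")
            if self.loa_low is not None:
                fh.write(f"# loa_low: {self.loa_low:.4f}\n")
                fh.write(f"# loa_high: {self.loa_high:.4f}\n")
            self.table.to_csv(fh, index=False, float_format="%.4f")


def bland_altman_table(cases: Sequence[EvaluationCase]) -> BlandAltmanResult:
    """Bland–Altman agreement analysis of simulated vs observed troughs."""
    sim, obs = _as_arrays(cases)
    diff = sim - obs
    table = pd.DataFrame(
        {
            "case_id": [c.case_id for c in cases],
            "pair_mean": (sim + obs) / 2.0,
            "difference": diff,
        }
    )
    mean_diff = float(np.mean(diff))
    if len(cases) < 2:
        return BlandAltmanResult(table, mean_diff, None, None, status="too_few_cases_for_limits")
    sd = float(np.std(diff, ddof=1))
    return BlandAltmanResult(table, mean_diff, mean_diff - 1.96 * sd, mean_diff + 1.96 * sd)


@dataclass(frozen=True)
class PerformanceReport:
    """All performance results for one model × mode over a cohort."""

    model: str
    mode: str
    n: int
    mean_accuracy: float  # %
    accuracy_sd: float  # % (across cases)
    mean_bias: float  # %
    bias_sd: float  # %
    rmse: float  # mg/L
    cases: tuple[EvaluationCase, ...]
    bland_altman: BlandAltmanResult
    excluded_ids: tuple[str, ...] = ()
    seed: int | None = None
    metadata: Mapping[str, object] = field(default_factory=dict)

    def to_json(self, path: str | Path | None = None) -> str:
        doc = {
            "metadata": {
                "model": self.model,
                "mode": self.mode,
                "seed": self.seed,
                "excluded_ids": list(self.excluded_ids),
                **dict(self.metadata),
            },
            "metrics": {
                "n": self.n,
                "mean_accuracy_pct": round(self.mean_accuracy, 4),
                "accuracy_sd_pct": round(self.accuracy_sd, 4),
                "mean_bias_pct": round(self.mean_bias, 4),
                "bias_sd_pct": round(self.bias_sd, 4),
                "rmse_mg_L": round(self.rmse, 4),
            },
            "cases": [
                {"case_id": c.case_id, "c_sim_mg_L": c.c_sim, "c_obs_mg_L": c.c_obs,
                 "mode": c.mode}
                for c in self.cases
            ],
            "bland_altman": {
                "mean_difference_mg_L": self.bland_altman.mean_difference,
                "loa_low_mg_L": self.bland_altman.loa_low,
                "loa_high_mg_L": self.bland_altman.loa_high,
                "status": self.bland_altman.status,
            },
        }
        text = json.dumps(doc, indent=2)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "PerformanceReport":
        text = Path(source).read_text() if isinstance(source, Path) else source
        doc = json.loads(text)
        cases = tuple(
            EvaluationCase(c["case_id"], c["c_sim_mg_L"], c["c_obs_mg_L"], c["mode"])
            for c in doc["cases"]
        )
        meta = dict(doc["metadata"])
        return cls(
            model=meta.pop("model"),
            mode=meta.pop("mode"),
            n=doc["metrics"]["n"],
            mean_accuracy=doc["metrics"]["mean_accuracy_pct"],
            accuracy_sd=doc["metrics"]["accuracy_sd_pct"],
            mean_bias=doc["metrics"]["mean_bias_pct"],
            bias_sd=doc["metrics"]["bias_sd_pct"],
            rmse=doc["metrics"]["rmse_mg_L"],
            cases=cases,
            bland_altman=bland_altman_table(cases) if cases else None,
            excluded_ids=tuple(meta.pop("excluded_ids", ())),
            seed=meta.pop("seed", None),
            metadata=meta,
        )


def _report_from_cases(
    model_name: str,
    mode: str,
    cases: Sequence[EvaluationCase],
    excluded: Sequence[str] = (),
    seed: int | None = None,
    metadata: Mapping[str, object] | None = None,
) -> PerformanceReport:
    sim, obs = _as_arrays(cases)
    ratios = sim / obs * 100.0
    pct_diff = (sim - obs) / ((sim + obs) / 2.0) * 100.0
    n = len(cases)
    return PerformanceReport(
        model=model_name,
        mode=mode,
        n=n,
        mean_accuracy=mean_accuracy(cases),
        accuracy_sd=float(np.std(ratios, ddof=1)) if n > 1 else 0.0,
        mean_bias=mean_bias(cases),
        bias_sd=float(np.std(pct_diff, ddof=1)) if n > 1 else 0.0,
        rmse=rmse(cases),
        cases=tuple(cases),
        bland_altman=bland_altman_table(cases),
        excluded_ids=tuple(excluded),
        seed=seed,
        metadata=dict(metadata or {}),
    )


def evaluate_cohort(
    patients: Sequence[Patient],
    observed_troughs: Mapping[str, float],
    model: str | ModelDefinition,
    mode: str,
    regimen: DosingRegimen | Mapping[str, DosingRegimen],
    seed: int = 0,
    override: VariabilityOverride = VariabilityOverride(),
    trough_time: float = DEFAULT_TROUGH_TIME,
    n_replicates: int = 1000,
    n_runs: int = 5,
    **model_config,
) -> PerformanceReport:
    """Simulate every patient's trough under ``model`` and score against
    the observed troughs.

    ``mode`` is ``"estimate"`` (deterministic typical-value trough) or
    ``"prediction"`` (median of Monte-Carlo run medians with the
    variability override).  ``regimen`` may be shared or a per-patient-id
    mapping.  Patients without an observation — or with a non-positive
    one, for which the accuracy ratio is undefined — are excluded and
    listed in the report; n shrinks accordingly.
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}, got {mode!r}")
    model_def = get_model(model)
    cases: list[EvaluationCase] = []
    excluded: list[str] = []
    for i, patient in enumerate(patients):
        if patient.id not in observed_troughs or not observed_troughs[patient.id] > 0:
            excluded.append(patient.id)
            continue
        reg = regimen[patient.id] if isinstance(regimen, Mapping) else regimen
        if mode == "estimate":
            c_sim = estimate_trough(model_def, patient, reg, trough_time, **model_config)
        else:
            c_sim = predict_trough(
                model_def, patient, reg, override,
                n_replicates=n_replicates, n_runs=n_runs,
                seed=_case_seed(seed, i), trough_time=trough_time, **model_config,
            ).prediction
        cases.append(EvaluationCase(patient.id, c_sim, observed_troughs[patient.id], mode))
    if not cases:
        raise ValueError("no patient id matches an observed trough")
    meta = {"trough_time_h": trough_time}
    if mode == "prediction":
        meta.update(
            iiv_cv_percent=override.iiv_cv_percent,
            residual_sd_mg_L=override.residual_sd,
            n_replicates=n_replicates,
            n_runs=n_runs,
        )
    return _report_from_cases(model_def.name, mode, cases, excluded, seed, meta)


def _case_seed(seed: int, index: int) -> int:
    # distinct, stable per-case sub-seed below 2**31
    return int((seed * 100003 + index * 7919 + 1) % (2**31))


def distribution_summary(
    values_by_group: Mapping[str, Sequence[float]],
) -> dict:
    """Shapiro–Wilk normality per group and two-sided paired Wilcoxon
    signed-rank for every group pair.

    Results are descriptive only (carried in reports, never used for
    gating).  Groups must share a common length for pairing.  Constant
    groups and groups with n < 3 are flagged instead of tested; the
    Wilcoxon zero-handling method is recorded in the output metadata.
    """
    groups = {k: np.asarray(v, dtype=float) for k, v in values_by_group.items()}
    lengths = {k: v.size for k, v in groups.items()}
    if len(set(lengths.values())) > 1:
        raise ValueError(f"group sizes differ, cannot pair: {lengths}")
    normality = {}
    for name, values in groups.items():
        if values.size < 3:
            normality[name] = {"W": None, "p": None, "status": "too_few_values"}
        elif np.ptp(values) == 0:
            normality[name] = {"W": None, "p": None, "status": "degenerate_constant"}
        else:
            w, p = stats.shapiro(values)
            normality[name] = {"W": float(w), "p": float(p), "status": "ok"}
    pairwise = {}
    for a, b in itertools.combinations(sorted(groups), 2):
        diff = groups[a] - groups[b]
        if np.all(diff == 0):
            pairwise[f"{a}_vs_{b}"] = {"W": 0.0, "p": 1.0, "status": "identical"}
        else:
            res = stats.wilcoxon(groups[a], groups[b], zero_method="zsplit", method="approx")
            pairwise[f"{a}_vs_{b}"] = {
                "W": float(res.statistic), "p": float(res.pvalue), "status": "ok",
            }
    return {
        "normality": normality,
        "pairwise_wilcoxon": pairwise,
        "metadata": {"wilcoxon_zero_method": "zsplit", "wilcoxon_method": "approx"},
    }


# ---------------------------------------------------------------------------
# Observed-trough CSV


def read_observations_csv(path: str | Path) -> dict[str, float]:
    """Read observed troughs from CSV with header
    ``id,trough_mg_L,sample_time_h``."""
    df = pd.read_csv(path, comment="#", dtype={"id": str})
    for col in ("id", "trough_mg_L"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    return {str(r["id"]): float(r["trough_mg_L"]) for _, r in df.iterrows()}


def write_observations_csv(
    observations: Mapping[str, float],
    path: str | Path,
    sample_time_h: float = DEFAULT_TROUGH_TIME,
    header_comments: Sequence[str] = (),
) -> None:
    with open(path, "w") as fh:
        for line in header_comments:
            fh.write(f"# {line}\n")
        fh.write("id,trough_mg_L,sample_time_h\n")
        for pid, trough in observations.items():
            fh.write(f"{pid},{trough:.4f},{sample_time_h:.4f}\n")
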