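"""Dosimetric plan-quality metrics and between-method comparison.

All target metrics are reported as fractions of the prescription dose:

* coverage D99/D98/D95 — dose received by at least 99/98/95% of the PTV,
* Dmax — the single maximum voxel dose anywhere in the volume,
* homogeneity H1 = (D2 - D98) / D50 and H2 = D95 / D50 inside the PTV,
* conformity: CI = |PTV & V100| / |PTV| (target coverage fraction) and the
  van't Riet conformation number |PTV & V100|^2 / (|PTV| * |V100|), where
  V100 is the set of voxels at or above the prescription isodose,
* mean dose error per structure: mean |Dtrue - Dpred| over the structure as
  a percent of the prescription,
* Vx: percent of a structure receiving at least x Gy.

Percentile convention: Dp is the dose exceeded (or met) by p% of the
structure volume — sort masked doses descending and take rank
``ceil(p/100 * n)``; voxel volumes are treated as equal.

Method comparison uses the two-tailed equal-variance Student's t-test
(Welch's variant available via ``equal_var=False``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import DoseVolume, EmptyStructureError, PlanCase, ShapeError

__all__ = [
    "PrescriptionContext",
    "dose_percentile",
    "coverage_and_max",
    "homogeneity",
    "conformity",
    "mean_dose_error",
    "vxx",
    "compare_methods",
    "case_report",
    "cohort_report",
    "summarize_cohort",
]


@dataclass
class PrescriptionContext:
    """Prescription level and which structure is the coverage target."""

    prescription: float
    target_name: str = "PTV"

    def __post_init__(self) -> None:
        if self.prescription <= 0:
            raise ValueError("prescription must be positive")

    @property
    def iso100(self) -> float:
        return self.prescription


def _values(dose) -> np.ndarray:
    if isinstance(dose, DoseVolume):
        return dose.values
    return np.asarray(dose, dtype=np.float64)


def _masked(dose, mask) -> np.ndarray:
    vals = _values(dose)
    mask = np.asarray(mask).astype(bool)
    if mask.shape != vals.shape:
        raise ShapeError("mask and dose grids disagree")
    if not mask.any():
        raise EmptyStructureError("structure mask has no voxels")
    return vals[mask]


def dose_percentile(dose, mask, p: float) -> float:
    """Dp: the dose received by at least p% of the structure's volume."""
    if not 0 < p < 100:
        raise ValueError("percentile must lie strictly between 0 and 100")
    vals = np.sort(_masked(dose, mask))[::-1]
    rank = int(np.ceil(p / 100.0 * len(vals)))
    return float(vals[max(rank, 1) - 1])


def coverage_and_max(dose, case_or_structures, ctx: PrescriptionContext) -> dict[str, float]:
    """D99/D98/D95 on the target and global Dmax, as fractions of prescription."""
    structures = getattr(case_or_structures, "structures", case_or_structures)
    target = structures[ctx.target_name]
    out = {}
    for p in (99, 98, 95):
        out[f"D{p}"] = dose_percentile(dose, target, p) / ctx.prescription
    out["Dmax"] = float(_values(dose).max()) / ctx.prescription
    return out


def homogeneity(dose, case_or_structures, ctx: PrescriptionContext) -> tuple[float, float]:
    """H1 = (D2 - D98)/D50 and H2 = D95/D50 on the target structure."""
    structures = getattr(case_or_structures, "structures", case_or_structures)
    target = structures[ctx.target_name]
    d2 = dose_percentile(dose, target, 2)
    d50 = dose_percentile(dose, target, 50)
    d95 = dose_percentile(dose, target, 95)
    d98 = dose_percentile(dose, target, 98)
    if d50 == 0:
        raise ValueError("degenerate plan: median target dose is zero")
    return (d2 - d98) / d50, d95 / d50


def conformity(dose, case_or_structures, ctx: PrescriptionContext) -> tuple[float, float]:
    """(CI, van't Riet) of the prescription isodose against the target."""
    structures = getattr(case_or_structures, "structures", case_or_structures)
    target = np.asarray(structures[ctx.target_name]).astype(bool)
    if not target.any():
        raise EmptyStructureError("target structure is empty")
    v100 = _values(dose) >= ctx.iso100
    n_t = int(target.sum())
    n_v = int(v100.sum())
    n_i = int((target & v100).sum())
    ci = n_i / n_t
    vant = 0.0 if n_v == 0 else n_i**2 / (n_t * n_v)
    return ci, vant


def mean_dose_error(d_true, d_pred, structures, ctx: PrescriptionContext) -> dict[str, float]:
    """Per-structure mean |Dtrue - Dpred| as percent of prescription.

    Empty structures are skipped (the cohort aggregation averages over the
    cases that actually carry each structure).
    """
    vt, vp = _values(d_true), _values(d_pred)
    if vt.shape != vp.shape:
        raise ShapeError("dose volumes must share one grid")
    out = {}
    for name, mask in structures.masks.items():
        mask = mask.astype(bool)
        if not mask.any():
            continue
        out[name] = float(np.abs(vt[mask] - vp[mask]).mean()) / ctx.prescription * 100.0
    return out


def vxx(dose, mask, x: float) -> float:
    """Percent of the structure's volume receiving at least x Gy."""
    vals = _masked(dose, mask)
    return float((vals >= x).mean()) * 100.0


def compare_methods(scores_a, scores_b, equal_var: bool = True) -> float:
    """Two-tailed Student's t-test p-value between two per-case score samples."""
    a = np.asarray(scores_a, dtype=np.float64)
    b = np.asarray(scores_b, dtype=np.float64)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs at least 2 values")
    if np.var(a) == 0 and np.var(b) == 0:
        return 1.0 if np.isclose(a.mean(), b.mean()) else 0.0
    p = stats.ttest_ind(a, b, equal_var=equal_var).pvalue
    return float(p)


def case_report(
    case: PlanCase,
    d_pred: DoseVolume,
    target_name: str | None = None,
    vx_levels: tuple[float, ...] = (30.0, 35.0),
) -> pd.DataFrame:
    """All metrics for one case: one row per structure plus a 'plan' row
    carrying the target-level coverage/homogeneity/conformity of the
    prediction."""
    if target_name is None:
        targets = case.structures.targets()
        target_name = "PTV" if "PTV" in case.structures else (targets[0] if targets else None)
    if target_name is None:
        raise ValueError("no target structure available for plan-level metrics")
    ctx = PrescriptionContext(case.prescription, target_name)
    rows = []
    cov = coverage_and_max(d_pred, case, ctx)
    try:
        h1, h2 = homogeneity(d_pred, case, ctx)
    except ValueError:  # degenerate plan (zero median target dose)
        h1 = h2 = float("nan")
    ci, vant = conformity(d_pred, case, ctx)
    rows.append(
        {
            "case_id": case.case_id,
            "structure": "plan",
            "role": "plan",
            **cov,
            "H1": h1,
            "H2": h2,
            "CI": ci,
            "vantRiet": vant,
        }
    )
    errors = mean_dose_error(case.reference_dose, d_pred, case.structures, ctx)
    for name in case.structures.nonempty():
        row = {
            "case_id": case.case_id,
            "structure": name,
            "role": case.structures.roles.get(name, "oar"),
            "mean_dose_error_pct": errors[name],
        }
        for x in vx_levels:
            row[f"V{x:g}"] = vxx(d_pred, case.structures[name], x)
        rows.append(row)
    return pd.DataFrame(rows)


def cohort_report(
    cases: list[PlanCase],
    predictions: list[DoseVolume],
    target_name: str | None = None,
) -> pd.DataFrame:
    """Concatenated per-case reports for a cohort."""
    frames = [case_report(c, p, target_name) for c, p in zip(cases, predictions)]
    return pd.concat(frames, ignore_index=True)


def summarize_cohort(report: pd.DataFrame) -> pd.DataFrame:
    """Cohort mean +- SD for every numeric metric, per structure row type."""
    num = report.select_dtypes("number")
    grouped = report[["structure", "role"]].join(num).groupby(["structure", "role"])
    mean = grouped.mean()
    sd = grouped.std(ddof=1)
    out = pd.concat({"mean": mean, "sd": sd}, axis=1)
    out.columns = [f"{metric}_{stat}" for stat, metric in out.columns]
    return out.reset_index()
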