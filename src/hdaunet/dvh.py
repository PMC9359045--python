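"""Exact and differentiable dose-volume histograms and the training losses.

A DVH curve for structure *s* with binary mask ``M_s`` evaluated on dose
``D`` is the vector of volume fractions

    v_{s,t} = #{voxels in M_s with D >= d_t} / #voxels in M_s

over an ascending threshold grid ``d_t`` (default 0..80 Gy in 1 Gy steps,
81 values). The exact curve is a step function of the dose and therefore
useless as a training signal; the differentiable surrogate replaces the
hard count with a logistic ramp,

    v~_{s,t} = sum_ijk sigmoid((m / beta_t) (D_ijk - d_t)) M_s,ijk / sum M_s,

with steepness ``m`` (default 1) and bin width ``beta_t`` (default 1 Gy).
As ``m`` grows, v~ converges pointwise to v wherever no voxel sits exactly
on a threshold.

The DVH loss is the mean squared discrepancy between the surrogate curves
of the true and predicted doses, averaged over structures and thresholds;
the combined training objective is ``w1 * MSE + w2 * DVH`` with default
weights (1, 0.1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor
from .core import DoseVolume, EmptyStructureError, ShapeError, StructureSet

__all__ = [
    "DVHSpec",
    "LossWeights",
    "exact_dvh",
    "approx_dvh",
    "approx_dvh_tensor",
    "dvh_loss",
    "dvh_loss_tensor",
    "combined_loss",
    "combined_loss_tensor",
    "dvh_table",
]


def _default_thresholds() -> np.ndarray:
    return np.arange(0.0, 81.0, 1.0)


@dataclass
class DVHSpec:
    """Threshold grid and surrogate parameters for DVH computation."""

    thresholds: np.ndarray = field(default_factory=_default_thresholds)
    bin_width: float = 1.0
    steepness: float = 1.0

    def __post_init__(self) -> None:
        self.thresholds = np.asarray(self.thresholds, dtype=np.float64)
        if self.thresholds.ndim != 1 or len(self.thresholds) < 1:
            raise ValueError("thresholds must be a 1D grid")
        if np.any(np.diff(self.thresholds) <= 0):
            raise ValueError("thresholds must be strictly ascending")
        if self.bin_width <= 0 or self.steepness <= 0:
            raise ValueError("bin_width and steepness must be positive")

    @property
    def n_thresholds(self) -> int:
        return len(self.thresholds)


@dataclass
class LossWeights:
    """Weights of the combined objective: w1 for MSE, w2 for the DVH term."""

    w1: float = 1.0
    w2: float = 0.1

    def __post_init__(self) -> None:
        if self.w1 < 0 or self.w2 < 0 or (self.w1 == 0 and self.w2 == 0):
            raise ValueError("weights must be non-negative and not both zero")


def _dose_values(dose) -> np.ndarray:
    if isinstance(dose, DoseVolume):
        return dose.values
    return np.asarray(dose, dtype=np.float64)


def _masked(dose, mask: np.ndarray) -> np.ndarray:
    values = _dose_values(dose)
    mask = np.asarray(mask).astype(bool)
    if mask.shape != values.shape:
        raise ShapeError(f"mask shape {mask.shape} != dose shape {values.shape}")
    if not mask.any():
        raise EmptyStructureError("structure mask has no voxels")
    return values[mask]


def exact_dvh(dose, mask: np.ndarray, spec: DVHSpec | None = None) -> np.ndarray:
    """Exact cumulative DVH: fraction of masked voxels receiving >= d_t."""
    spec = spec or DVHSpec()
    vals = np.sort(_masked(dose, mask))
    n = len(vals)
    # voxels with value >= d_t are those past the left insertion point
    idx = np.searchsorted(vals, spec.thresholds, side="left")
    return (n - idx) / n


def approx_dvh(dose, mask: np.ndarray, spec: DVHSpec | None = None) -> np.ndarray:
    """Sigmoid-relaxed DVH (numpy evaluation of the differentiable form)."""
    spec = spec or DVHSpec()
    vals = _masked(dose, mask)
    z = (spec.steepness / spec.bin_width) * (vals[None, :] - spec.thresholds[:, None])
    return _stable_sigmoid(z).mean(axis=1)


def _stable_sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def approx_dvh_tensor(dose: Tensor, mask: np.ndarray, spec: DVHSpec | None = None) -> Tensor:
    """Differentiable DVH of an autodiff tensor dose; gradients flow to the dose."""
    spec = spec or DVHSpec()
    mask = np.asarray(mask).astype(bool)
    if mask.shape != dose.shape:
        raise ShapeError(f"mask shape {mask.shape} != dose shape {dose.shape}")
    idx = np.flatnonzero(mask.ravel())
    if idx.size == 0:
        raise EmptyStructureError("structure mask has no voxels")
    vals = dose.gather_flat(idx)  # (n_vox,)
    scale = spec.steepness / spec.bin_width
    z = (vals.reshape(1, -1) - Tensor(spec.thresholds.reshape(-1, 1))) * scale
    return z.sigmoid().mean(axis=1)


def _nonempty_masks(structures: StructureSet, shape) -> dict[str, np.ndarray]:
    masks = {}
    for name, m in structures.masks.items():
        if m.shape != tuple(shape):
            raise ShapeError(f"mask {name!r} is not on the dose grid")
        if m.any():
            masks[name] = m
    if not masks:
        raise ValueError("no nonempty structures to evaluate the DVH loss on")
    return masks


def dvh_loss_tensor(
    d_true: Tensor | np.ndarray,
    d_pred: Tensor,
    structures: StructureSet,
    spec: DVHSpec | None = None,
) -> Tensor:
    """DVH loss on autodiff tensors: mean over structures and thresholds of
    the squared difference between relaxed DVH curves. Empty structures are
    skipped; the structure count ``ns`` counts only nonempty masks."""
    spec = spec or DVHSpec()
    if not isinstance(d_true, Tensor):
        d_true = Tensor(_dose_values(d_true))
    masks = _nonempty_masks(structures, d_pred.shape)
    total = None
    for mask in masks.values():
        diff = approx_dvh_tensor(d_true, mask, spec) - approx_dvh_tensor(d_pred, mask, spec)
        term = (diff**2).sum()
        total = term if total is None else total + term
    return total * (1.0 / (len(masks) * spec.n_thresholds))


def dvh_loss(d_true, d_pred, structures: StructureSet, spec: DVHSpec | None = None) -> float:
    """DVH loss between two dose volumes (plain number)."""
    t = dvh_loss_tensor(Tensor(_dose_values(d_true)), Tensor(_dose_values(d_pred)), structures, spec)
    return t.item()


def combined_loss_tensor(
    d_true: Tensor | np.ndarray,
    d_pred: Tensor,
    structures: StructureSet,
    spec: DVHSpec | None = None,
    weights: LossWeights | None = None,
) -> tuple[Tensor, float, float]:
    """Weighted MSE + DVH objective; returns (loss, mse_value, dvh_value)."""
    weights = weights or LossWeights()
    if not isinstance(d_true, Tensor):
        d_true = Tensor(_dose_values(d_true))
    if d_true.shape != d_pred.shape:
        raise ShapeError("dose volumes must share one grid")
    mse = ((d_true - d_pred) ** 2).mean()
    loss = mse * weights.w1
    dvh_val = 0.0
    if weights.w2 > 0:
        dvh = dvh_loss_tensor(d_true, d_pred, structures, spec)
        dvh_val = dvh.item()
        loss = loss + dvh * weights.w2
    return loss, mse.item(), dvh_val


def combined_loss(d_true, d_pred, structures, spec=None, weights=None) -> float:
    loss, _, _ = combined_loss_tensor(
        Tensor(_dose_values(d_true)), Tensor(_dose_values(d_pred)), structures, spec, weights
    )
    return loss.item()


def dvh_table(dose, structures: StructureSet, spec: DVHSpec | None = None):
    """Per-structure exact DVH curves as a tidy DataFrame
    (columns: structure, threshold_gy, volume_fraction)."""
    import pandas as pd

    spec = spec or DVHSpec()
    rows = []
    for name in structures.nonempty():
        curve = exact_dvh(dose, structures[name], spec)
        for d_t, v in zip(spec.thresholds, curve):
            rows.append({"structure": name, "threshold_gy": d_t, "volume_fraction": v})
    return pd.DataFrame(rows)
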