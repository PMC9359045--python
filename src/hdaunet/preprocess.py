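"""Preprocessing: in-plane downscaling, min-max normalization, channel assembly.

The network consumes one multi-channel array per case: channel 0 is the
min-max normalized CT, followed by one binary channel per structure in a
fixed order shared across the cohort. Structures missing from a case are
encoded as all-zero channels so the channel count stays constant.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .core import DegenerateInputError, PlanCase, ShapeError

__all__ = [
    "downscale_volume",
    "downscale_mask",
    "minmax_normalize",
    "minmax_denormalize",
    "assemble_channels",
    "extract_channel",
]


def _out_len(n: int, factor: int) -> int:
    # resampling targets ceil(n / factor); no padding of the source
    return -(-n // factor)


def downscale_volume(v: np.ndarray, factor: int, order: int = 3) -> np.ndarray:
    """Downscale a scalar volume in-plane (first two axes) by ``factor``.

    Uses b-spline interpolation of the given ``order`` (cubic by default).
    The cranio-caudal axis is left untouched. Output in-plane shape is
    ``ceil(n / factor)`` per axis, e.g. 512x512 -> 128x128 at factor 4.
    """
    v = np.asarray(v)
    if v.ndim != 3:
        raise ShapeError(f"expected a 3D volume, got shape {v.shape}")
    if int(factor) != factor or factor < 1:
        raise ValueError(f"downscale factor must be a positive integer, got {factor}")
    factor = int(factor)
    if factor == 1:
        return v.astype(np.float64, copy=True)
    nx, ny = v.shape[:2]
    ox, oy = _out_len(nx, factor), _out_len(ny, factor)
    out = ndimage.zoom(
        v.astype(np.float64),
        (ox / nx, oy / ny, 1.0),
        order=order,
        mode="mirror",
        grid_mode=True,
    )
    assert out.shape[:2] == (ox, oy)
    return out


def downscale_mask(m: np.ndarray, factor: int) -> np.ndarray:
    """Downscale a binary mask in-plane, keeping it binary.

    Linear interpolation of the mask followed by thresholding at 0.5, so
    output voxels are 1 where the downscaled footprint is majority-inside.
    """
    m = np.asarray(m)
    vals = np.unique(m)
    if not np.isin(vals, (0, 1)).all():
        raise ValueError("downscale_mask expects a binary mask")
    out = downscale_volume(m.astype(np.float64), factor, order=1)
    return (out > 0.5).astype(np.uint8)


def minmax_normalize(v: np.ndarray) -> tuple[np.ndarray, float, float]:
    """Rescale ``v`` linearly to span exactly [0, 1]; return (array, min, max)."""
    v = np.asarray(v, dtype=np.float64)
    lo, hi = float(v.min()), float(v.max())
    if hi == lo:
        raise DegenerateInputError("constant volume cannot be min-max normalized")
    return (v - lo) / (hi - lo), lo, hi


def minmax_denormalize(v: np.ndarray, lo: float, hi: float) -> np.ndarray:
    return np.asarray(v, dtype=np.float64) * (hi - lo) + lo


def assemble_channels(case: PlanCase, structure_order: list[str]) -> np.ndarray:
    """Stack the network input: normalized CT first, then one mask per name.

    Names absent from the case become all-zero channels (consistent fixed
    channel count across a cohort with partial structure coverage).
    """
    if len(set(structure_order)) != len(structure_order):
        dupes = sorted({n for n in structure_order if structure_order.count(n) > 1})
        raise ValueError(f"duplicate structure names in channel order: {dupes}")
    ct_norm, _, _ = minmax_normalize(case.ct)
    shape = case.shape
    channels = [ct_norm]
    for name in structure_order:
        if name in case.structures:
            channels.append(case.structures[name].astype(np.float64))
        else:
            channels.append(np.zeros(shape, dtype=np.float64))
    return np.stack(channels, axis=0)


def extract_channel(stack: np.ndarray, structure_order: list[str], name: str) -> np.ndarray:
    """Recover a structure mask channel from an assembled stack."""
    idx = structure_order.index(name)
    return stack[1 + idx]
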