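"""Core volumetric containers for dose-prediction cases.

A *case* is one patient-like unit: a CT-like scalar volume, a set of named
binary structure masks (planning target volumes and organs at risk) on the
same voxel grid, a reference dose distribution in Gy, and the prescription
dose. All arrays use axis order ``(x, y, z)`` with ``z`` the cranio-caudal
axis and 0-based voxel indices.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DoseVolume",
    "StructureSet",
    "PlanCase",
    "DegenerateInputError",
    "EmptyStructureError",
    "FormatError",
    "GenerationError",
    "DivergenceError",
    "ShapeError",
    "TARGET",
    "OAR",
]

TARGET = "target"
OAR = "oar"


class DegenerateInputError(ValueError):
    """An input volume is degenerate (e.g. constant under min-max scaling)."""


class EmptyStructureError(ValueError):
    """A structure mask contains no voxels."""


class FormatError(ValueError):
    """A file does not follow the expected on-disk layout."""


class GenerationError(RuntimeError):
    """Synthetic geometry could not be placed within bounded retries."""


class DivergenceError(RuntimeError):
    """Training produced a non-finite loss."""


class ShapeError(ValueError):
    """Array shapes are incompatible with the requested operation."""


@dataclass
class DoseVolume:
    """A 3D scalar dose grid.

    Parameters
    ----------
    values
        Dose per voxel, shape ``(nx, ny, nz)``. In Gy unless ``normalized``.
    spacing
        Voxel spacing in mm per axis.
    normalized
        When True, ``values`` lie in [0, 1] and ``norm_bounds`` records the
        (min, max) in Gy used for the rescaling, so the volume can always be
        mapped back to Gy.
    """

    values: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    normalized: bool = False
    norm_bounds: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise ShapeError(f"dose volume must be 3D, got shape {self.values.shape}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("dose volume contains non-finite values")
        if self.normalized:
            if self.norm_bounds is None:
                raise ValueError("normalized dose volume requires norm_bounds")
            if self.values.min() < -1e-9 or self.values.max() > 1 + 1e-9:
                raise ValueError("normalized dose values must lie in [0, 1]")
        elif self.values.min() < 0:
            raise ValueError("dose in Gy must be non-negative")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    def normalize(self) -> "DoseVolume":
        """Min-max normalize to [0, 1], recording the bounds for inversion."""
        from .preprocess import minmax_normalize

        if self.normalized:
            return self
        arr, lo, hi = minmax_normalize(self.values)
        return DoseVolume(arr, self.spacing, normalized=True, norm_bounds=(lo, hi))

    def denormalize(self) -> "DoseVolume":
        """Invert :meth:`normalize`, returning a volume in Gy."""
        if not self.normalized:
            return self
        lo, hi = self.norm_bounds  # type: ignore[misc]
        return DoseVolume(self.values * (hi - lo) + lo, self.spacing)


@dataclass
class StructureSet:
    """Named binary masks sharing one voxel grid.

    ``roles`` tags every structure as either ``"target"`` (GTV/CTV/PTV) or
    ``"oar"``; metrics and losses use the tag to decide which structures are
    coverage targets.
    """

    masks: dict[str, np.ndarray]
    roles: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        shapes = set()
        clean: dict[str, np.ndarray] = {}
        for name, m in self.masks.items():
            m = np.asarray(m)
            vals = np.unique(m)
            if not np.isin(vals, (0, 1)).all():
                raise ValueError(f"mask {name!r} is not binary")
            clean[name] = m.astype(np.uint8)
            shapes.add(m.shape)
        if len(shapes) > 1:
            raise ShapeError(f"masks disagree on grid shape: {sorted(shapes)}")
        self.masks = clean
        for name in self.masks:
            self.roles.setdefault(name, OAR)
        unknown = set(self.roles) - set(self.masks)
        if unknown:
            raise ValueError(f"roles given for unknown structures: {sorted(unknown)}")

    @property
    def names(self) -> list[str]:
        return list(self.masks)

    @property
    def shape(self) -> tuple[int, int, int] | None:
        for m in self.masks.values():
            return m.shape
        return None

    def targets(self) -> list[str]:
        return [n for n in self.masks if self.roles.get(n) == TARGET]

    def oars(self) -> list[str]:
        return [n for n in self.masks if self.roles.get(n) == OAR]

    def nonempty(self) -> list[str]:
        return [n for n, m in self.masks.items() if m.any()]

    def __getitem__(self, name: str) -> np.ndarray:
        return self.masks[name]

    def __contains__(self, name: str) -> bool:
        return name in self.masks


@dataclass
class PlanCase:
    """One training/evaluation unit: CT, structures, reference dose, Rx."""

    ct: np.ndarray
    structures: StructureSet
    reference_dose: DoseVolume
    prescription: float
    case_id: str = "case"
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.ct = np.asarray(self.ct, dtype=np.float64)
        if self.prescription <= 0:
            raise ValueError("prescription must be positive")
        sshape = self.structures.shape
        shapes = {self.ct.shape, self.reference_dose.shape}
        if sshape is not None:
            shapes.add(sshape)
        if len(shapes) > 1:
            raise ShapeError(f"ct/masks/dose grids disagree: {sorted(shapes)}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.ct.shape  # type: ignore[return-value]
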