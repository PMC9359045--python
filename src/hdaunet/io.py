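"""Case input/output: NIfTI case directories and the OpenKBP sparse-CSV layout.

NIfTI layout (one directory per case)::

    case_dir/
      case.yaml            # case_id, prescription, spacing, structure roles
      ct.nii.gz
      dose.nii.gz
      mask_<NAME>.nii.gz   # one uint8 volume per structure

OpenKBP layout (one directory per case, 128x128x128 grid)::

    case_dir/
      ct.csv               # rows "linear_index,value" (C-order flat index)
      dose.csv
      <STRUCTURE>.csv      # rows "linear_index" (or "linear_index,1")

Unlisted voxels are zero. Structure names containing "PTV", "CTV" or "GTV"
are tagged as targets; the prescription of a loaded OpenKBP case is 70 Gy.
"""

from __future__ import annotations

import os

import nibabel as nib
import numpy as np
import yaml

from .core import OAR, TARGET, DoseVolume, FormatError, PlanCase, StructureSet

__all__ = [
    "read_nifti_case",
    "write_nifti_case",
    "read_openkbp_case",
    "write_openkbp_case",
    "write_cohort",
    "read_cohort",
    "OPENKBP_GRID",
    "OPENKBP_PRESCRIPTION",
]

OPENKBP_GRID = (128, 128, 128)
OPENKBP_PRESCRIPTION = 70.0


# ---------------------------------------------------------------------------
# NIfTI
# ---------------------------------------------------------------------------

def _save_nii(path: str, arr: np.ndarray, spacing, dtype) -> None:
    affine = np.diag(list(spacing) + [1.0])
    nib.save(nib.Nifti1Image(np.asarray(arr, dtype=dtype), affine), path)


def _load_nii(path: str) -> tuple[np.ndarray, tuple[float, float, float]]:
    img = nib.load(path)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return np.asarray(img.get_fdata()), spacing


def write_nifti_case(case: PlanCase, case_dir: str) -> None:
    os.makedirs(case_dir, exist_ok=True)
    _save_nii(os.path.join(case_dir, "ct.nii.gz"), case.ct, case.spacing, np.float64)
    _save_nii(
        os.path.join(case_dir, "dose.nii.gz"),
        case.reference_dose.values,
        case.spacing,
        np.float64,
    )
    for name, mask in case.structures.masks.items():
        _save_nii(os.path.join(case_dir, f"mask_{name}.nii.gz"), mask, case.spacing, np.uint8)
    meta = {
        "case_id": case.case_id,
        "prescription": float(case.prescription),
        "spacing": [float(s) for s in case.spacing],
        "structures": [
            {"name": n, "role": case.structures.roles.get(n, OAR)}
            for n in case.structures.names
        ],
    }
    with open(os.path.join(case_dir, "case.yaml"), "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=False)


def read_nifti_case(case_dir: str) -> PlanCase:
    meta_path = os.path.join(case_dir, "case.yaml")
    if not os.path.exists(meta_path):
        raise FormatError(f"missing case manifest: {meta_path}")
    with open(meta_path) as fh:
        meta = yaml.safe_load(fh)
    ct, spacing = _load_nii(os.path.join(case_dir, "ct.nii.gz"))
    dose, dspacing = _load_nii(os.path.join(case_dir, "dose.nii.gz"))
    if dose.shape != ct.shape:
        raise FormatError(
            f"{case_dir}: dose shape {dose.shape} does not match ct shape {ct.shape}"
        )
    masks, roles = {}, {}
    for entry in meta.get("structures", []):
        name = entry["name"]
        m, _ = _load_nii(os.path.join(case_dir, f"mask_{name}.nii.gz"))
        if m.shape != ct.shape:
            raise FormatError(f"{case_dir}: mask {name} shape {m.shape} != ct {ct.shape}")
        masks[name] = (m > 0.5).astype(np.uint8)
        roles[name] = entry.get("role", OAR)
    spacing = tuple(meta.get("spacing", spacing))
    return PlanCase(
        ct=ct,
        structures=StructureSet(masks, roles),
        reference_dose=DoseVolume(dose, spacing),
        prescription=float(meta["prescription"]),
        case_id=str(meta.get("case_id", os.path.basename(os.path.normpath(case_dir)))),
        spacing=spacing,
    )


# ---------------------------------------------------------------------------
# OpenKBP sparse CSV
# ---------------------------------------------------------------------------

def _read_sparse_csv(path: str, n_vox: int) -> tuple[np.ndarray, np.ndarray]:
    """Parse a sparse CSV into (indices, values); mask files get value 1."""
    idx, vals = [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh):
            line = line.strip()
            if not line:
                continue
            parts = [p.strip() for p in line.replace("\t", ",").split(",") if p.strip()]
            try:
                i = int(float(parts[0]))
            except (ValueError, IndexError):
                if lineno == 0:  # tolerated header row
                    continue
                raise FormatError(f"{path}: malformed row {lineno + 1}: {line!r}")
            if not 0 <= i < n_vox:
                raise FormatError(f"{path}: voxel index {i} out of range [0, {n_vox})")
            idx.append(i)
            if len(parts) > 1:
                try:
                    vals.append(float(parts[1]))
                except ValueError:
                    raise FormatError(f"{path}: malformed value on row {lineno + 1}")
            else:
                vals.append(1.0)
    return np.asarray(idx, dtype=np.intp), np.asarray(vals, dtype=np.float64)


def _densify(idx: np.ndarray, vals: np.ndarray, shape) -> np.ndarray:
    arr = np.zeros(int(np.prod(shape)), dtype=np.float64)
    arr[idx] = vals
    return arr.reshape(shape)


def read_openkbp_case(
    case_dir: str,
    grid_shape: tuple[int, int, int] = OPENKBP_GRID,
    spacing: tuple[float, float, float] = (3.906, 3.906, 2.5),
) -> PlanCase:
    """Load a sparse-CSV case directory into a dense :class:`PlanCase`."""
    n_vox = int(np.prod(grid_shape))
    files = sorted(f for f in os.listdir(case_dir) if f.endswith(".csv"))
    if "ct.csv" not in files or "dose.csv" not in files:
        raise FormatError(f"{case_dir}: an OpenKBP case needs ct.csv and dose.csv")
    ct = _densify(*_read_sparse_csv(os.path.join(case_dir, "ct.csv"), n_vox), grid_shape)
    dose = _densify(*_read_sparse_csv(os.path.join(case_dir, "dose.csv"), n_vox), grid_shape)
    masks, roles = {}, {}
    for fname in files:
        name = fname[:-4]
        if name in ("ct", "dose", "possible_dose_mask", "voxel_dimensions"):
            continue
        idx, _ = _read_sparse_csv(os.path.join(case_dir, fname), n_vox)
        masks[name] = _densify(idx, np.ones(len(idx)), grid_shape).astype(np.uint8)
        upper = name.upper()
        roles[name] = TARGET if any(t in upper for t in ("PTV", "CTV", "GTV")) else OAR
    return PlanCase(
        ct=ct,
        structures=StructureSet(masks, roles),
        reference_dose=DoseVolume(np.clip(dose, 0.0, None), spacing),
        prescription=OPENKBP_PRESCRIPTION,
        case_id=os.path.basename(os.path.normpath(case_dir)),
        spacing=spacing,
    )


def write_openkbp_case(case: PlanCase, case_dir: str) -> None:
    """Write a case back to the sparse-CSV layout (inverse of the reader)."""
    os.makedirs(case_dir, exist_ok=True)

    def dump(fname: str, arr: np.ndarray, with_values: bool) -> None:
        flat = np.asarray(arr).reshape(-1)
        idx = np.flatnonzero(flat)
        with open(os.path.join(case_dir, fname), "w") as fh:
            for i in idx:
                if with_values:
                    fh.write(f"{i},{float(flat[i])!r}\n")
                else:
                    fh.write(f"{i}\n")

    dump("ct.csv", case.ct, True)
    dump("dose.csv", case.reference_dose.values, True)
    for name, mask in case.structures.masks.items():
        dump(f"{name}.csv", mask, False)


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

def write_cohort(cases: list[PlanCase], out_dir: str) -> str:
    """Write each case as a NIfTI directory plus a cohort manifest; returns
    the manifest path."""
    os.makedirs(out_dir, exist_ok=True)
    entries = []
    order: list[str] = []
    roles: dict[str, str] = {}
    for case in cases:
        case_dir = os.path.join(out_dir, case.case_id)
        write_nifti_case(case, case_dir)
        entries.append(case.case_id)
        for name in case.structures.names:
            if name not in order:
                order.append(name)
                roles[name] = case.structures.roles.get(name, OAR)
    manifest = {
        "cases": entries,
        "structure_order": order,
        "roles": roles,
    }
    path = os.path.join(out_dir, "manifest.yaml")
    with open(path, "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    return path


def read_cohort(manifest_path: str) -> tuple[list[PlanCase], list[str]]:
    """Load a cohort manifest; returns (cases, structure_order)."""
    with open(manifest_path) as fh:
        manifest = yaml.safe_load(fh)
    root = os.path.dirname(os.path.abspath(manifest_path))
    cases = [read_nifti_case(os.path.join(root, cid)) for cid in manifest["cases"]]
    return cases, list(manifest["structure_order"])
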