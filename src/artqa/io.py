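"""File formats: course CSV/JSON, NIfTI mask/dose stacks, DICOM-RT reading.

Canonical interchange is plain text: a per-fraction course CSV (one row per
patient-fraction, one column per dosimetric parameter, unit suffixes in the
column names), a JSON sidecar with plan metadata and planned parameter
values, and YAML configuration. Masks and dose grids can be serialized as
NIfTI; DICOM-RT RTSTRUCT/RTDOSE ingestion is an optional reader, never
required by the pipeline.

Every writer embeds a schema tag, the seed and a config hash in a leading
comment line (CSV) or top-level fields (JSON); readers reject unknown
schemas loudly.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .core import CoursePlan, CourseRecord, FractionRecord, StructureSet, VoxelGrid

__all__ = [
    "write_course_csv",
    "read_course_csv",
    "write_course_json",
    "read_course_json",
    "save_structures_nifti",
    "load_structures_nifti",
    "save_dose_nifti",
    "load_dose_nifti",
    "read_dicom_rt",
    "config_hash",
]

COURSE_SCHEMA = "artqa.course.v1"
_FIXED_COLUMNS = ["patient_id", "fraction", "assessed", "contour_change_cm", "flagged"]


def config_hash(config: Mapping) -> str:
    """Short deterministic hash of a configuration mapping."""
    payload = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


def _header_line(schema: str, seed: Optional[int], cfg_hash: Optional[str]) -> str:
    parts = [f"# schema={schema}"]
    if seed is not None:
        parts.append(f"seed={seed}")
    if cfg_hash is not None:
        parts.append(f"config={cfg_hash}")
    return " ".join(parts)


def write_course_csv(
    courses: Sequence[CourseRecord],
    path: str | Path,
    seed: Optional[int] = None,
    cfg_hash: Optional[str] = None,
) -> None:
    """Write per-fraction records of a cohort to the course CSV format."""
    param_cols = sorted(
        {pid for c in courses for fr in c.fractions for pid in fr.parameters}
    )
    rows = []
    for c in courses:
        for fr in c.fractions:
            row = {
                "patient_id": c.patient_id,
                "fraction": fr.fraction_index,
                "assessed": fr.assessed,
                "contour_change_cm": fr.contour_change,
                "flagged": fr.flagged,
            }
            for pid in param_cols:
                row[pid] = fr.parameters.get(pid)
            rows.append(row)
    frame = pd.DataFrame(rows, columns=_FIXED_COLUMNS + param_cols)
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(_header_line(COURSE_SCHEMA, seed, cfg_hash) + "\n")
        frame.to_csv(fh, index=False)


def read_course_csv(
    path: str | Path, plans: Optional[Mapping[str, CoursePlan]] = None
) -> list[CourseRecord]:
    """Read a course CSV back into validated :class:`CourseRecord` objects.

    ``plans`` optionally supplies per-patient plans (e.g. from the JSON
    sidecar); otherwise the number of fractions is taken from the rows of
    each patient. Schema or invariant breaches raise with row context.
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.readline().strip()
        if not first.startswith(f"# schema={COURSE_SCHEMA}"):
            raise ValueError(
                f"{path}: expected '# schema={COURSE_SCHEMA}' header, got {first[:60]!r}"
            )
        frame = pd.read_csv(fh)
    if frame.empty:
        raise ValueError(f"{path}: no fraction rows")
    missing = [c for c in _FIXED_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    param_cols = [c for c in frame.columns if c not in _FIXED_COLUMNS]

    bad = frame[frame["flagged"].astype(bool) & ~frame["assessed"].astype(bool)]
    if not bad.empty:
        raise ValueError(
            f"{path}: flagged=true on unassessed fraction at rows {list(bad.index + 2)}"
        )
    assessed_rows = frame[frame["assessed"].astype(bool)]
    if param_cols:
        incomplete = assessed_rows[assessed_rows[param_cols].isna().any(axis=1)]
        if not incomplete.empty:
            raise ValueError(
                f"{path}: assessed fractions missing parameter values at rows "
                f"{list(incomplete.index + 2)}"
            )

    courses = []
    for pid, group in frame.groupby("patient_id", sort=False):
        plan = (plans or {}).get(str(pid)) or CoursePlan(n_fractions=len(group))
        fractions = []
        for _, row in group.sort_values("fraction").iterrows():
            assessed = bool(row["assessed"])
            cc = row["contour_change_cm"]
            params = (
                {c: float(row[c]) for c in param_cols if pd.notna(row[c])}
                if assessed
                else {}
            )
            fractions.append(
                FractionRecord(
                    fraction_index=int(row["fraction"]),
                    assessed=assessed,
                    contour_change=None if pd.isna(cc) else float(cc),
                    flagged=bool(row["flagged"]),
                    parameters=params,
                )
            )
        courses.append(CourseRecord(str(pid), plan=plan, fractions=fractions))
    return courses


def write_course_json(
    courses: Sequence[CourseRecord],
    path: str | Path,
    seed: Optional[int] = None,
    cfg_hash: Optional[str] = None,
) -> None:
    """Plan metadata and planned parameter values, one entry per patient."""
    doc = {
        "schema": "artqa.courses.v1",
        "seed": seed,
        "config": cfg_hash,
        "patients": {
            c.patient_id: {
                "plan": {
                    "n_fractions": c.plan.n_fractions,
                    "prescription_high_gy": c.plan.prescription_high,
                    "prescription_low_gy": c.plan.prescription_low,
                },
                "planned_parameters": c.planned_parameters,
            }
            for c in courses
        },
    }
    Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")


def read_course_json(path: str | Path) -> tuple[dict[str, CoursePlan], dict[str, dict]]:
    """Per-patient plans and planned parameter mappings from the sidecar."""
    doc = json.loads(Path(path).read_text())
    if doc.get("schema") != "artqa.courses.v1":
        raise ValueError(f"{path}: not an artqa.courses.v1 document")
    plans, planned = {}, {}
    for pid, entry in doc["patients"].items():
        p = entry["plan"]
        plans[pid] = CoursePlan(
            n_fractions=int(p["n_fractions"]),
            prescription_high=float(p["prescription_high_gy"]),
            prescription_low=float(p["prescription_low_gy"]),
        )
        planned[pid] = {k: float(v) for k, v in entry["planned_parameters"].items()}
    return plans, planned


# ---------------------------------------------------------------------------
# NIfTI


def _affine(grid: VoxelGrid) -> np.ndarray:
    # NIfTI affines are in mm; internal units are cm
    aff = np.diag([grid.spacing[0] * 10, grid.spacing[1] * 10, grid.spacing[2] * 10, 1.0])
    aff[:3, 3] = np.asarray(grid.origin) * 10
    return aff


def _grid_from_affine(affine: np.ndarray, shape) -> VoxelGrid:
    spacing = tuple(float(affine[i, i]) / 10.0 for i in range(3))
    origin = tuple(float(affine[i, 3]) / 10.0 for i in range(3))
    return VoxelGrid(tuple(shape[:3]), spacing, origin)


def save_structures_nifti(sset: StructureSet, path: str | Path) -> None:
    """Save a structure set as a labelled 4-D NIfTI stack plus JSON sidecar."""
    import nibabel as nib

    names = sset.names
    stack = np.stack([sset[n] for n in names], axis=-1).astype(np.uint8)
    nib.save(nib.Nifti1Image(stack, _affine(sset.grid)), str(path))
    sidecar = Path(path).with_suffix("").with_suffix(".json")
    sidecar.write_text(json.dumps({"structures": names}) + "\n")


def load_structures_nifti(path: str | Path) -> StructureSet:
    import nibabel as nib

    img = nib.load(str(path))
    sidecar = Path(path).with_suffix("").with_suffix(".json")
    names = json.loads(sidecar.read_text())["structures"]
    data = np.asarray(img.dataobj).astype(bool)
    grid = _grid_from_affine(img.affine, data.shape)
    return StructureSet(grid, {n: data[..., i] for i, n in enumerate(names)})


def save_dose_nifti(dose: np.ndarray, grid: VoxelGrid, path: str | Path) -> None:
    import nibabel as nib

    nib.save(nib.Nifti1Image(dose.astype(np.float32), _affine(grid)), str(path))


def load_dose_nifti(path: str | Path) -> tuple[np.ndarray, VoxelGrid]:
    import nibabel as nib

    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    return data, _grid_from_affine(img.affine, data.shape)


# ---------------------------------------------------------------------------
# DICOM-RT (optional reader)


def read_dicom_rt(
    rtstruct_path: str | Path,
    rtdose_path: str | Path,
    aliases: Optional[Mapping[str, str]] = None,
    grid: Optional[VoxelGrid] = None,
    required: Sequence[str] = ("external",),
) -> tuple[StructureSet, np.ndarray]:
    """Rasterize a DICOM-RT structure set onto its companion dose grid.

    Contours are rasterized slice-by-slice onto the RTDOSE grid (DICOM mm
    converted to cm). ``aliases`` maps DICOM ROI names to canonical structure
    names (e.g. ``{"SpinalCord": "spinal_cord"}``); unmapped names are kept
    lower-cased. When ``grid`` is given it must match the dose grid —
    resampling is not performed. Missing ``required`` structures after
    aliasing raise with the names listed.
    """
    import pydicom
    from skimage.draw import polygon2mask

    dose_ds = pydicom.dcmread(str(rtdose_path))
    scaling = float(getattr(dose_ds, "DoseGridScaling", 1.0))
    arr = dose_ds.pixel_array.astype(float) * scaling  # (frames=z, rows=y, cols=x)
    dose = np.transpose(arr, (2, 1, 0))
    ipp = [float(v) / 10.0 for v in dose_ds.ImagePositionPatient]  # cm
    row_sp, col_sp = (float(v) / 10.0 for v in dose_ds.PixelSpacing)
    offsets = [float(v) / 10.0 for v in dose_ds.GridFrameOffsetVector]
    dz = offsets[1] - offsets[0] if len(offsets) > 1 else 1.0
    # ImagePositionPatient is the first voxel *center*; internal origin is the
    # grid corner.
    dose_grid = VoxelGrid(
        dose.shape,
        (col_sp, row_sp, dz),
        (ipp[0] - col_sp / 2, ipp[1] - row_sp / 2, ipp[2] + offsets[0] - dz / 2),
    )
    if grid is not None and grid != dose_grid:
        raise ValueError(
            f"configured grid {grid} does not match RTDOSE grid {dose_grid}; "
            "resampling is not supported"
        )

    struct_ds = pydicom.dcmread(str(rtstruct_path))
    roi_names = {
        int(roi.ROINumber): str(roi.ROIName)
        for roi in struct_ds.StructureSetROISequence
    }
    aliases = dict(aliases or {})
    masks: dict[str, np.ndarray] = {}
    for contour_set in struct_ds.ROIContourSequence:
        dicom_name = roi_names[int(contour_set.ReferencedROINumber)]
        name = aliases.get(dicom_name, dicom_name.lower())
        mask = np.zeros(dose_grid.shape, dtype=bool)
        for contour in getattr(contour_set, "ContourSequence", []):
            pts = np.array(contour.ContourData, dtype=float).reshape(-1, 3) / 10.0
            k = int(round((pts[0, 2] - dose_grid.axis_centers(2)[0]) / dz))
            if not 0 <= k < dose_grid.shape[2]:
                continue
            # polygon vertices in fractional voxel indices (x, y)
            ij = np.column_stack(
                [
                    (pts[:, 0] - dose_grid.origin[0]) / dose_grid.spacing[0] - 0.5,
                    (pts[:, 1] - dose_grid.origin[1]) / dose_grid.spacing[1] - 0.5,
                ]
            )
            mask[:, :, k] |= polygon2mask(dose_grid.shape[:2], ij)
        masks[name] = mask

    missing = [n for n in required if n not in masks]
    if missing:
        raise ValueError(
            f"required structures missing after aliasing: {missing}; "
            f"found {sorted(masks)}"
        )
    return StructureSet(dose_grid, masks), dose
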