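"""Body-contour-change replan flag.

The institutional flag evaluated here measures, for each assessed fraction,
the largest pointwise distance between the current and reference external
contours on any axial slice — a maximum axial slice-based Hausdorff distance —
and flags the fraction when that distance strictly exceeds a threshold
(1.5 cm by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial.distance import directed_hausdorff

from .core import CourseRecord, StructureSet

__all__ = [
    "FlagProtocol",
    "ContourChangeResult",
    "slice_hausdorff",
    "boundary_points",
    "body_contour_change",
    "apply_flag",
    "threshold_sweep",
]

_CROSS = ndimage.generate_binary_structure(2, 1)  # 4-connectivity


@dataclass(frozen=True)
class FlagProtocol:
    """Flagging protocol: threshold (cm) with a strictly-greater comparator.

    ``z_range`` optionally restricts the slices considered, emulating the
    limited field of view of on-unit cone-beam CT; by default all slices on
    which both externals are non-empty contribute.
    """

    threshold: float = 1.5
    directed: bool = False
    z_range: Optional[tuple[int, int]] = None

    def __post_init__(self) -> None:
        if self.threshold <= 0:
            raise ValueError("threshold must be > 0")


@dataclass
class ContourChangeResult:
    """Per-slice contour distances (cm) and their maximum."""

    per_slice_distance: dict[int, float] = field(default_factory=dict)

    @property
    def max_distance(self) -> float:
        return max(self.per_slice_distance.values())

    @property
    def argmax_slice(self) -> int:
        return max(self.per_slice_distance, key=self.per_slice_distance.get)


def slice_hausdorff(
    contour_a: np.ndarray, contour_b: np.ndarray, *, directed: bool = False
) -> float:
    """Hausdorff distance (cm) between two planar point sets.

    The symmetric form (default) is ``max(h(A→B), h(B→A))`` with
    ``h(A→B) = max_{a∈A} min_{b∈B} |a−b|``; ``directed=True`` returns only
    ``h(A→B)``.
    """
    a = np.asarray(contour_a, dtype=float)
    b = np.asarray(contour_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("empty contour point set")
    d_ab = directed_hausdorff(a, b)[0]
    if directed:
        return float(d_ab)
    return float(max(d_ab, directed_hausdorff(b, a)[0]))


def boundary_points(mask2d: np.ndarray, spacing: Sequence[float]) -> np.ndarray:
    """In-plane centers (cm) of boundary voxels of a 2-D mask.

    A boundary voxel is a mask voxel with at least one non-mask 4-neighbor
    (voxels on the array edge count as boundary). Sampling the boundary at
    voxel centers bounds the discretisation error of downstream Hausdorff
    distances by one in-plane voxel diagonal.
    """
    eroded = ndimage.binary_erosion(mask2d, structure=_CROSS, border_value=0)
    idx = np.argwhere(mask2d & ~eroded)
    return (idx + 0.5) * np.asarray(spacing, dtype=float)[:2]


def body_contour_change(
    reference: StructureSet,
    current: StructureSet,
    *,
    directed: bool = False,
    z_range: Optional[tuple[int, int]] = None,
) -> ContourChangeResult:
    """Slice-wise contour distance between two external contours.

    Both structure sets must share a grid and be pre-aligned (bony-anatomy
    registration happens upstream). Only slices where both externals are
    non-empty contribute; the result depends on the external masks alone.
    """
    if reference.grid != current.grid:
        raise ValueError("reference and current structure sets are on different grids")
    ref = reference["external"]
    cur = current["external"]
    spacing = reference.grid.spacing
    nz = reference.grid.shape[2]
    lo, hi = (0, nz) if z_range is None else (max(0, z_range[0]), min(nz, z_range[1]))
    per_slice: dict[int, float] = {}
    for k in range(lo, hi):
        r, c = ref[:, :, k], cur[:, :, k]
        if not (r.any() and c.any()):
            continue
        per_slice[k] = slice_hausdorff(
            boundary_points(r, spacing), boundary_points(c, spacing), directed=directed
        )
    if not per_slice:
        raise ValueError("no axial slice has both external contours non-empty")
    return ContourChangeResult(per_slice)


def apply_flag(course: CourseRecord, protocol: FlagProtocol = FlagProtocol()) -> CourseRecord:
    """Set per-fraction flags: contour change strictly above the threshold.

    Unassessed fractions (and assessed fractions without a measured contour
    change) are never flagged. Returns a new :class:`CourseRecord`.
    """
    new = []
    for fr in course.fractions:
        flagged = (
            fr.assessed
            and fr.contour_change is not None
            and fr.contour_change > protocol.threshold
        )
        new.append(replace(fr, flagged=flagged))
    return course.replace_fractions(new)


def threshold_sweep(
    courses: Sequence[CourseRecord],
    thresholds: Sequence[float],
    violations: Sequence[bool],
) -> pd.DataFrame:
    """Diagnostic metrics of the flag at each candidate threshold.

    ``violations`` is the ground-truth violation status of every assessed
    fraction, in course order then fraction order. Sensitivity is
    non-increasing and specificity non-decreasing in the threshold, tracing
    the flag's receiver operating behaviour.
    """
    from .assessment import diagnostic_metrics, truth_table

    if len(thresholds) == 0:
        raise ValueError("thresholds must be non-empty")
    changes = [
        fr.contour_change
        for course in courses
        for fr in course.assessed_fractions
    ]
    if any(c is None for c in changes):
        raise ValueError("all assessed fractions need a contour_change value")
    if len(changes) != len(violations):
        raise ValueError(
            f"{len(violations)} violation states for {len(changes)} assessed fractions"
        )
    rows = []
    for t in thresholds:
        flags = [c > t for c in changes]
        tt = truth_table(flags, list(violations), label=f"threshold={t}")
        m = diagnostic_metrics(tt)
        rows.append(
            {
                "threshold_cm": t,
                "tp": tt.tp,
                "fn": tt.fn,
                "fp": tt.fp,
                "tn": tt.tn,
                "sensitivity": m.sensitivity,
                "specificity": m.specificity,
                "ppv": m.ppv,
                "npv": m.npv,
                "accuracy": m.accuracy,
            }
        )
    return pd.DataFrame(rows)
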