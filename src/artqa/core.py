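"""Shared domain types and voxel-grid geometry.

All masks in a treatment course live on a single :class:`VoxelGrid` as boolean
numpy arrays with axis order ``(x, y, z)``, where ``z`` indexes axial slices.
Distances are in centimetres and doses in gray throughout; fraction indices
are 1-based, matching clinical convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Optional

import numpy as np
from scipy import ndimage

__all__ = [
    "VoxelGrid",
    "StructureSet",
    "CoursePlan",
    "MarginSpec",
    "FractionRecord",
    "CourseRecord",
    "expand_margin",
    "build_plan_structures",
    "REQUIRED_STRUCTURES",
]

#: Structure names every planning StructureSet must carry.
REQUIRED_STRUCTURES = (
    "external",
    "gtv_high",
    "ctv_high",
    "ctv_low",
    "ptv_high",
    "ptv_low",
    "spinal_cord",
    "spinal_cord_prv",
    "brainstem",
    "brainstem_prv",
)

#: Structures fixed in the bony frame (not advected by soft-tissue change).
BONY_FRAME_STRUCTURES = (
    "spinal_cord",
    "spinal_cord_prv",
    "brainstem",
    "brainstem_prv",
)


@dataclass(frozen=True)
class VoxelGrid:
    """Regular voxel grid in the room (bony-alignment) frame.

    Parameters
    ----------
    shape
        Voxel counts ``(nx, ny, nz)``.
    spacing
        Voxel size ``(dx, dy, dz)`` in cm; strictly positive.
    origin
        Room-frame position (cm) of the grid corner. Voxel ``(i, j, k)`` has
        its center at ``origin + (i + 0.5, j + 0.5, k + 0.5) * spacing``.
    """

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        object.__setattr__(self, "shape", tuple(int(n) for n in self.shape))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))
        if len(self.shape) != 3 or any(n <= 0 for n in self.shape):
            raise ValueError(f"shape must be three positive counts, got {self.shape}")
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing}")

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in cm^3."""
        dx, dy, dz = self.spacing
        return dx * dy * dz

    def axis_centers(self, axis: int) -> np.ndarray:
        """Voxel-center coordinates (cm) along one axis."""
        n = self.shape[axis]
        return self.origin[axis] + (np.arange(n) + 0.5) * self.spacing[axis]

    def center_mesh(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Broadcastable voxel-center coordinate arrays ``(X, Y, Z)``."""
        x = self.axis_centers(0)[:, None, None]
        y = self.axis_centers(1)[None, :, None]
        z = self.axis_centers(2)[None, None, :]
        return x, y, z

    def new_mask(self) -> np.ndarray:
        return np.zeros(self.shape, dtype=bool)


@dataclass
class StructureSet:
    """Named boolean masks sharing one :class:`VoxelGrid`.

    Invariants (checked by :meth:`validate`): every non-external structure is
    a subset of ``external``; ``ctv ⊇ gtv`` and ``ptv ⊇ ctv`` for each dose
    level where the structures are present.
    """

    grid: VoxelGrid
    masks: dict[str, np.ndarray] = field(default_factory=dict)

    def __getitem__(self, name: str) -> np.ndarray:
        try:
            return self.masks[name]
        except KeyError:
            raise KeyError(
                f"structure {name!r} not present; available: {sorted(self.masks)}"
            ) from None

    def __contains__(self, name: str) -> bool:
        return name in self.masks

    @property
    def names(self) -> list[str]:
        return sorted(self.masks)

    def with_structure(self, name: str, mask: np.ndarray) -> "StructureSet":
        new = dict(self.masks)
        new[name] = mask
        return StructureSet(self.grid, new)

    def volume_cc(self, name: str) -> float:
        """Structure volume in cm^3 (voxel count times voxel volume)."""
        return float(np.count_nonzero(self[name])) * self.grid.voxel_volume

    def validate(self, require_all: bool = False) -> None:
        for name, mask in self.masks.items():
            if mask.shape != self.grid.shape:
                raise ValueError(
                    f"structure {name!r} shape {mask.shape} does not match grid {self.grid.shape}"
                )
            if mask.dtype != np.bool_:
                raise ValueError(f"structure {name!r} must be a boolean mask")
        if require_all:
            missing = [n for n in REQUIRED_STRUCTURES if n not in self.masks]
            if missing:
                raise ValueError(f"missing required structures: {missing}")
        if "external" in self.masks:
            ext = self.masks["external"]
            for name, mask in self.masks.items():
                if name != "external" and np.any(mask & ~ext):
                    raise ValueError(f"structure {name!r} extends outside external")
        for level in ("high", "low"):
            gtv = self.masks.get(f"gtv_{level}")
            ctv = self.masks.get(f"ctv_{level}")
            ptv = self.masks.get(f"ptv_{level}")
            if gtv is not None and ctv is not None and np.any(gtv & ~ctv):
                raise ValueError(f"gtv_{level} not contained in ctv_{level}")
            if ctv is not None and ptv is not None and np.any(ctv & ~ptv):
                raise ValueError(f"ctv_{level} not contained in ptv_{level}")


@dataclass(frozen=True)
class CoursePlan:
    """Prescription arithmetic for a fractionated course.

    Defaults reflect a radical head-and-neck regimen: 70 Gy to the high-risk
    planning volume and 59.4 Gy to the low-risk (elective nodal) volume in 33
    fractions, i.e. 2.12 and 1.8 Gy per fraction.
    """

    n_fractions: int = 33
    prescription_high: float = 70.0
    prescription_low: float = 59.4

    def __post_init__(self) -> None:
        if self.n_fractions < 1:
            raise ValueError("n_fractions must be >= 1")
        if self.prescription_high <= 0 or self.prescription_low <= 0:
            raise ValueError("prescriptions must be positive")

    @property
    def dose_per_fraction_high(self) -> float:
        return self.prescription_high / self.n_fractions

    @property
    def dose_per_fraction_low(self) -> float:
        return self.prescription_low / self.n_fractions


@dataclass(frozen=True)
class MarginSpec:
    """Planning margins in cm.

    ``ctv_from_gtv`` defaults to 0.75 cm, the midpoint of the conventional
    0.5-1.0 cm microscopic-spread margin; the setup margin CTV→PTV is 0.3 cm
    and the planning organ-at-risk (PRV) margins are 0.3 cm for brainstem and
    0.5 cm for spinal cord.
    """

    ctv_from_gtv: float = 0.75
    ptv_from_ctv: float = 0.3
    prv_brainstem: float = 0.3
    prv_cord: float = 0.5

    def __post_init__(self) -> None:
        for name in ("ctv_from_gtv", "ptv_from_ctv", "prv_brainstem", "prv_cord"):
            if getattr(self, name) < 0:
                raise ValueError(f"margin {name} must be >= 0")


@dataclass
class FractionRecord:
    """One treatment fraction of a course.

    ``contour_change`` (cm) and dose ``parameters`` are present only for
    fractions with a volumetric assessment (CBCT acquired); ``flagged`` can
    only be true on assessed fractions.
    """

    fraction_index: int
    assessed: bool = False
    contour_change: Optional[float] = None
    flagged: bool = False
    parameters: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.fraction_index < 1:
            raise ValueError("fraction_index is 1-based")
        if self.contour_change is not None and self.contour_change < 0:
            raise ValueError("contour_change must be >= 0")
        if self.flagged and not self.assessed:
            raise ValueError(
                f"fraction {self.fraction_index}: flagged requires assessed"
            )
        if self.parameters and not self.assessed:
            raise ValueError(
                f"fraction {self.fraction_index}: parameters present on unassessed fraction"
            )


@dataclass
class CourseRecord:
    """A patient's full course: plan, planned parameter values, fractions."""

    patient_id: str
    plan: CoursePlan = field(default_factory=CoursePlan)
    planned_parameters: dict[str, float] = field(default_factory=dict)
    fractions: list[FractionRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.fractions:
            idx = [f.fraction_index for f in self.fractions]
            expected = list(range(1, self.plan.n_fractions + 1))
            if sorted(idx) != expected:
                raise ValueError(
                    f"course {self.patient_id}: fraction indices must be exactly 1..{self.plan.n_fractions}"
                )

    @property
    def assessed_fractions(self) -> list[FractionRecord]:
        return [f for f in self.fractions if f.assessed]

    def replace_fractions(self, fractions: list[FractionRecord]) -> "CourseRecord":
        return replace(self, fractions=fractions)


def expand_margin(mask: np.ndarray, margin: float, grid: VoxelGrid) -> np.ndarray:
    """Isotropic Euclidean expansion of a boolean mask.

    Returns the set of voxels whose center lies within ``margin`` cm (3-D
    Euclidean distance, anisotropic spacing respected) of some voxel center of
    the input mask. Always a superset of the input; ``margin == 0`` returns a
    copy.
    """
    if margin < 0:
        raise ValueError(f"margin must be >= 0, got {margin}")
    if mask.shape != grid.shape:
        raise ValueError("mask shape does not match grid")
    if margin == 0 or not mask.any():
        return mask.copy()
    dist = ndimage.distance_transform_edt(~mask, sampling=grid.spacing)
    # tiny epsilon so centers exactly at the margin survive float round-off
    return dist <= margin + 1e-9


def build_plan_structures(
    gtv: np.ndarray,
    anatomy: Mapping[str, np.ndarray],
    margins: MarginSpec,
    grid: VoxelGrid,
    *,
    crop_to_external: bool = True,
    elective_margin: float = 1.0,
) -> StructureSet:
    """Derive the planning structure set from gross tumor and anatomy.

    ``anatomy`` must provide ``external``, ``spinal_cord`` and ``brainstem``
    masks and may provide ``ctv_low`` (the delineated elective nodal volume),
    parotids and optic structures, which are passed through. When ``ctv_low``
    is absent it is approximated as the high-risk CTV grown by
    ``elective_margin`` cm. All derived structures are cropped to the body
    surface when ``crop_to_external`` is set (default), so the containment
    invariants of :class:`StructureSet` hold by construction.
    """
    external = anatomy["external"]
    if np.any(gtv & ~external):
        raise ValueError("gtv extends outside the external contour")

    def crop(mask: np.ndarray) -> np.ndarray:
        return mask & external if crop_to_external else mask

    ctv_high = crop(expand_margin(gtv, margins.ctv_from_gtv, grid))
    if "ctv_low" in anatomy:
        ctv_low = crop(anatomy["ctv_low"] | ctv_high)
    else:
        ctv_low = crop(expand_margin(ctv_high, elective_margin, grid))
    ptv_high = crop(expand_margin(ctv_high, margins.ptv_from_ctv, grid))
    ptv_low = crop(expand_margin(ctv_low, margins.ptv_from_ctv, grid))

    cord = anatomy["spinal_cord"]
    brainstem = anatomy["brainstem"]
    masks = {
        "external": external,
        "gtv_high": gtv.copy(),
        "ctv_high": ctv_high,
        "ctv_low": ctv_low,
        "ptv_high": ptv_high,
        "ptv_low": ptv_low,
        "spinal_cord": cord.copy(),
        "spinal_cord_prv": crop(expand_margin(cord, margins.prv_cord, grid)),
        "brainstem": brainstem.copy(),
        "brainstem_prv": crop(expand_margin(brainstem, margins.prv_brainstem, grid)),
    }
    for name, mask in anatomy.items():
        if name not in masks and name != "ctv_low":
            masks[name] = mask.copy()
    sset = StructureSet(grid, masks)
    sset.validate(require_all=True)
    return sset
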