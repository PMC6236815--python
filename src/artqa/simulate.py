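"""Synthetic phantom cohorts for end-to-end pipeline exercise.

No clinical images accompany this package, so the simulator generates a
head-and-neck phantom (elliptic-cylinder "neck" with optional shoulder
blocks, embedded spherical tumor, posterior spinal-cord cylinder, lateral
parotids) together with a deliberately simple dose engine, and then evolves
the anatomy over a 33-fraction course under one of four scenarios:

* ``weight_loss`` — uniform in-plane radial erosion of the external contour,
  with soft-tissue structures advected toward the shrinking surface while
  bony-frame structures (cord, brainstem and their PRVs) stay fixed;
* ``localized_edema`` — the high-dose target follows a piecewise-linear
  volume trajectory (growth to a peak at a mid-course changepoint, then
  shrinkage below baseline), with a matching localized bulge of the external
  contour adjacent to the tumor;
* ``shoulder_shift`` — the external contour of the inferior (shoulder)
  slices is displaced in-plane, changing the body contour without touching
  the dose to neck structures;
* ``composite`` — weight loss plus the edema trajectory.

The dose engine holds the planned dose fixed in the bony frame (emulating
image-guided bony alignment) and rescales each voxel by ``exp(mu * d)`` for a
reduction ``d`` of the tissue path from the surface along the lateral beam
directions — an exponential percent-depth-dose model beyond build-up. It is
not a treatment-planning-system surrogate; it is built to reproduce the
directional phenomena that matter here (hot spots rise when tissue is lost,
coverage falls when targets shift relative to the fixed dose field).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage

from .core import (
    BONY_FRAME_STRUCTURES,
    CoursePlan,
    CourseRecord,
    FractionRecord,
    MarginSpec,
    StructureSet,
    VoxelGrid,
    build_plan_structures,
    expand_margin,
)
from .dosimetry import DoseParameterSpec, extract_fraction_parameters
from .flagging import body_contour_change

__all__ = [
    "ScenarioConfig",
    "BeamModel",
    "Phantom",
    "central_axis_dose_change",
    "build_phantom",
    "simulate_course",
    "simulate_cohort",
    "random_flag_cohort",
    "DEFAULT_SCHEDULE",
]

#: Default CBCT assessment schedule: approximately every five fractions.
DEFAULT_SCHEDULE = (1, 5, 10, 15, 20, 25, 30)


@dataclass(frozen=True)
class ScenarioConfig:
    """Anatomy-trajectory scenario for one simulated course.

    Magnitudes default to the study conditions: the edema trajectory peaks at
    fraction 8 with a 25.6% volume increase and ends at 59.8% of the planned
    volume; contour measurements carry optional zero-mean Gaussian noise
    (sigma 0.1 cm) emulating manual therapist measurement; CBCTs follow
    ``schedule`` (about every five fractions), optionally with the first
    three fractions added. The weight-loss rate and shoulder shift have no
    printed anchors and default to values that trip the 1.5 cm flag late in
    the course and immediately, respectively.
    """

    kind: str = "none"
    shrink_rate: float = 0.06  # cm per fraction, uniform in-plane erosion
    edema_peak_fraction: int = 8
    edema_peak_ratio: float = 1.256
    edema_end_ratio: float = 0.598
    bulge_gain: float = 5.0  # external displacement per cm of tumor-radius change
    bulge_sigma: float = 2.5  # cm, spatial extent of the localized bulge
    shift: tuple[float, float] = (2.0, 0.0)  # cm, in-plane shoulder displacement
    shoulder_top_cm: float = 4.0  # slices below this are "shoulder"
    target_drift: tuple[float, float] = (0.0, 0.0)  # cm per fraction, high-dose targets
    noise_sigma: float = 0.1  # cm, contour-measurement noise
    schedule: tuple[int, ...] = DEFAULT_SCHEDULE
    include_first_three: bool = False
    advect_soft_tissue: bool = True
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.kind not in ("none", "weight_loss", "localized_edema", "shoulder_shift", "composite"):
            raise ValueError(f"unknown scenario kind {self.kind!r}")
        if self.edema_peak_ratio <= 0 or self.edema_end_ratio <= 0:
            raise ValueError("edema volume ratios must be > 0")
        if self.noise_sigma < 0 or self.shrink_rate < 0:
            raise ValueError("shrink_rate and noise_sigma must be >= 0")

    def assessed_fractions(self, n_fractions: int) -> tuple[int, ...]:
        fx = set(f for f in self.schedule if 1 <= f <= n_fractions)
        if self.include_first_three:
            fx |= {1, 2, 3}
        return tuple(sorted(fx))

    def volume_ratio(self, fraction: int) -> float:
        """Piecewise-linear high-dose target volume ratio at a fraction."""
        f, fp = float(fraction), float(self.edema_peak_fraction)
        if f <= fp:
            return 1.0 + (self.edema_peak_ratio - 1.0) * (f - 1.0) / max(fp - 1.0, 1.0)
        end = 33.0
        frac = (f - fp) / max(end - fp, 1.0)
        return self.edema_peak_ratio + (self.edema_end_ratio - self.edema_peak_ratio) * frac

    # scenario presets -----------------------------------------------------
    @classmethod
    def none(cls, **kw) -> "ScenarioConfig":
        return cls(kind="none", **kw)

    @classmethod
    def weight_loss(cls, **kw) -> "ScenarioConfig":
        return cls(kind="weight_loss", **kw)

    @classmethod
    def localized_edema(cls, **kw) -> "ScenarioConfig":
        return cls(kind="localized_edema", **kw)

    @classmethod
    def shoulder_shift(cls, **kw) -> "ScenarioConfig":
        return cls(kind="shoulder_shift", **kw)

    @classmethod
    def composite(cls, **kw) -> "ScenarioConfig":
        return cls(kind="composite", **kw)


@dataclass(frozen=True)
class BeamModel:
    """Exponential-falloff lateral-beam dose model.

    ``mu`` is the fractional dose falloff per cm of tissue path beyond
    build-up (0.035/cm is representative of 6 MV); ``penumbra_sigma`` is the
    Gaussian penumbra width and ``flash_margin`` the dilation applied to the
    target before penumbra convolution so the prescription covers the PTV.
    """

    mu: float = 0.035
    penumbra_sigma: float = 0.5
    flash_margin: float = 1.0

    def __post_init__(self) -> None:
        if self.mu <= 0 or self.penumbra_sigma <= 0 or self.flash_margin < 0:
            raise ValueError("mu and penumbra_sigma must be > 0, flash_margin >= 0")


def central_axis_dose_change(depth_reduction: float, mu: float = 0.035) -> float:
    """Fractional central-axis dose change for a tissue-depth reduction.

    Under an exponential percent-depth-dose model beyond build-up, losing
    ``depth_reduction`` cm of overlying tissue multiplies the dose by
    ``exp(mu * depth_reduction)``; the fractional change is that factor minus
    one. A 1.5 cm radius loss of a 15-cm-diameter cylinder at 6 MV
    (``mu = 0.035``) gives ~5%.
    """
    if mu <= 0:
        raise ValueError("mu must be > 0")
    return math.exp(mu * depth_reduction) - 1.0


# ---------------------------------------------------------------------------
# phantom construction


@dataclass
class Phantom:
    """Planning-time phantom: structures, planned dose and cached geometry."""

    structures: StructureSet
    dose: np.ndarray  # Gy, full-course planned dose
    plan: CoursePlan
    margins: MarginSpec
    beam: BeamModel
    shoulder_top_index: int
    signed_distance: np.ndarray = field(repr=False, default=None)  # per-slice 2-D
    bulge_weight: np.ndarray = field(repr=False, default=None)
    _ref_depth: Optional[tuple[np.ndarray, np.ndarray]] = field(
        repr=False, default=None
    )

    @property
    def grid(self) -> VoxelGrid:
        return self.structures.grid

    def reference_depth(self) -> tuple[np.ndarray, np.ndarray]:
        if self._ref_depth is None:
            self._ref_depth = _tissue_depth(
                self.structures["external"], self.grid.spacing[0]
            )
        return self._ref_depth


def _ellipse_mask(grid: VoxelGrid, center, semi_axes, z_lo, z_hi) -> np.ndarray:
    x, y, z = grid.center_mesh()
    inplane = ((x - center[0]) / semi_axes[0]) ** 2 + ((y - center[1]) / semi_axes[1]) ** 2 <= 1.0
    return inplane & (z >= z_lo) & (z < z_hi)


def _ellipsoid_mask(grid: VoxelGrid, center, semi_axes) -> np.ndarray:
    x, y, z = grid.center_mesh()
    return (
        ((x - center[0]) / semi_axes[0]) ** 2
        + ((y - center[1]) / semi_axes[1]) ** 2
        + ((z - center[2]) / semi_axes[2]) ** 2
        <= 1.0
    )


def default_grid(spacing: float = 0.2) -> VoxelGrid:
    """Grid covering the default phantom: 26 x 15 x 16 cm."""
    shape = (
        int(round(26.0 / spacing)),
        int(round(15.0 / spacing)),
        int(round(16.0 / spacing)),
    )
    return VoxelGrid(shape, (spacing, spacing, spacing), origin=(-13.0, -7.5, 0.0))


def _signed_distance_2d(external: np.ndarray, spacing) -> np.ndarray:
    """Per-slice signed distance to the external boundary (<0 inside)."""
    out = np.empty(external.shape, dtype=float)
    samp = spacing[:2]
    for k in range(external.shape[2]):
        sl = external[:, :, k]
        if not sl.any():
            out[:, :, k] = np.inf
            continue
        d_out = ndimage.distance_transform_edt(~sl, sampling=samp)
        d_in = ndimage.distance_transform_edt(sl, sampling=samp)
        out[:, :, k] = d_out - d_in
    return out


def _conformity(mask: np.ndarray, beam: BeamModel, grid: VoxelGrid) -> np.ndarray:
    flashed = expand_margin(mask, beam.flash_margin, grid)
    sigma = [beam.penumbra_sigma / s for s in grid.spacing]
    return ndimage.gaussian_filter(flashed.astype(float), sigma=sigma)


def build_phantom(
    plan: CoursePlan = CoursePlan(),
    margins: MarginSpec = MarginSpec(),
    grid: Optional[VoxelGrid] = None,
    beam: BeamModel = BeamModel(),
    *,
    with_shoulders: bool = True,
    neck_semi_axes: tuple[float, float] = (7.5, 6.5),
    gtv_center: tuple[float, float, float] = (2.5, 1.0, 10.0),
    gtv_radius: float = 1.5,
    cord_center: tuple[float, float] = (0.0, -3.1),
    cord_radius: float = 0.5,
    shoulder_top_cm: float = 4.0,
) -> Phantom:
    """Construct the default neck phantom and its planned dose.

    The external is an elliptic cylinder (semi-axes 7.5 x 6.5 cm) above the
    shoulder region and a wide shoulder block below it; the spherical GTV
    sits anterolateral to the posterior spinal-cord cylinder with enough
    clearance that the planned cord Dmax stays safely below the 49.4 Gy
    major-violation dose and the cord lies entirely outside that isodose.
    Planned dose is the voxel-wise maximum of each prescription level times
    its penumbra-convolved PTV conformity.
    """
    grid = grid or default_grid()
    a, b = neck_semi_axes
    nz_cm = grid.origin[2] + grid.shape[2] * grid.spacing[2]
    shoulder_top = shoulder_top_cm if with_shoulders else grid.origin[2]

    neck = _ellipse_mask(grid, (0.0, 0.0), (a, b), shoulder_top, nz_cm)
    external = neck
    if with_shoulders:
        shoulders = _ellipse_mask(
            grid, (0.0, -0.5), (12.5, 5.5), grid.origin[2], shoulder_top
        )
        external = neck | shoulders

    gtv = _ellipsoid_mask(grid, gtv_center, (gtv_radius,) * 3)
    x, y, z = grid.center_mesh()
    cord = (
        ((x - cord_center[0]) ** 2 + (y - cord_center[1]) ** 2 <= cord_radius**2)
        & np.broadcast_to(np.ones_like(z, dtype=bool), grid.shape)
    ) & external
    brainstem = (
        ((x - 0.0) ** 2 + (y + 1.5) ** 2 <= 1.0**2) & (z >= nz_cm - 2.0)
    ) & external
    anatomy = {
        "external": external,
        "spinal_cord": cord,
        "brainstem": brainstem,
        "parotid_left": _ellipsoid_mask(grid, (-5.2, 0.8, 10.5), (0.9, 1.3, 2.2)) & external,
        "parotid_right": _ellipsoid_mask(grid, (5.2, 0.8, 10.5), (0.9, 1.3, 2.2)) & external,
    }
    structures = build_plan_structures(gtv, anatomy, margins, grid)

    dose = np.maximum(
        plan.prescription_high * _conformity(structures["ptv_high"], beam, grid),
        plan.prescription_low * _conformity(structures["ptv_low"], beam, grid),
    )

    shoulder_top_index = int(round((shoulder_top - grid.origin[2]) / grid.spacing[2]))
    phantom = Phantom(
        structures=structures,
        dose=dose,
        plan=plan,
        margins=margins,
        beam=beam,
        shoulder_top_index=shoulder_top_index,
    )
    phantom.signed_distance = _signed_distance_2d(external, grid.spacing)
    phantom.bulge_weight = _bulge_weight(phantom, gtv_center)
    return phantom


def _bulge_weight(phantom: Phantom, gtv_center) -> np.ndarray:
    """Gaussian weight around the external surface point nearest the tumor."""
    grid = phantom.grid
    ext = phantom.structures["external"]
    k0 = int(round((gtv_center[2] - grid.origin[2]) / grid.spacing[2]))
    sl = ext[:, :, k0]
    eroded = ndimage.binary_erosion(sl, border_value=0)
    boundary = np.argwhere(sl & ~eroded)
    centers = (boundary + 0.5) * np.asarray(grid.spacing[:2]) + np.asarray(grid.origin[:2])
    d = np.hypot(centers[:, 0] - gtv_center[0], centers[:, 1] - gtv_center[1])
    anchor = centers[np.argmin(d)]
    x, y, z = grid.center_mesh()
    r2 = (x - anchor[0]) ** 2 + (y - anchor[1]) ** 2 + (z - gtv_center[2]) ** 2
    sigma = 2.5
    return np.exp(-r2 / (2.0 * sigma**2))


# ---------------------------------------------------------------------------
# per-fraction anatomy and dose


def _tissue_depth(external: np.ndarray, dx: float) -> tuple[np.ndarray, np.ndarray]:
    """Tissue path length (cm) traversed to each voxel along the two lateral
    beams (entering from low-x and high-x)."""
    t = external.astype(float)
    low = (np.cumsum(t, axis=0) - 0.5 * t) * dx
    high = (np.cumsum(t[::-1], axis=0)[::-1] - 0.5 * t) * dx
    return low, high


def _shift_mask(mask: np.ndarray, shift_vox: Sequence[float]) -> np.ndarray:
    return ndimage.shift(mask.astype(np.uint8), shift_vox, order=0, prefilter=False) > 0


def _scale_mask(mask: np.ndarray, factor: float, center_vox: Sequence[float]) -> np.ndarray:
    """Isotropic rescale of a mask about a point (nearest-neighbor resample)."""
    if factor == 1.0:
        return mask.copy()
    c = np.asarray(center_vox, dtype=float)
    matrix = np.eye(3) / factor
    offset = c - c / factor
    # linear interpolation + 0.5 threshold tracks the analytically scaled
    # boundary to sub-voxel accuracy (nearest-neighbor biases the volume)
    out = ndimage.affine_transform(
        mask.astype(float), matrix, offset=offset, order=1, prefilter=False
    )
    return out >= 0.5


_HIGH_TARGETS = ("gtv_high", "ctv_high", "ptv_high")
_SOFT_TISSUE = (
    "gtv_high",
    "ctv_high",
    "ctv_low",
    "ptv_high",
    "ptv_low",
    "parotid_left",
    "parotid_right",
)


def _fraction_anatomy(
    phantom: Phantom, scenario: ScenarioConfig, fraction: int
) -> tuple[StructureSet, float]:
    """Transform the planning anatomy to one fraction.

    Returns the fraction's structure set and the effective tumor-radius
    change (cm) used for the edema bulge (zero for other scenarios).
    """
    grid = phantom.grid
    ref = phantom.structures
    masks = {name: m for name, m in ref.masks.items()}
    weight_loss = scenario.kind in ("weight_loss", "composite")
    edema = scenario.kind in ("localized_edema", "composite")

    shrink = scenario.shrink_rate * fraction if weight_loss else 0.0
    bulge = 0.0
    scale = 1.0
    if edema:
        ratio = scenario.volume_ratio(fraction)
        scale = ratio ** (1.0 / 3.0)
        r0 = (3.0 * ref.volume_cc("ctv_high") / (4.0 * math.pi)) ** (1.0 / 3.0)
        bulge = scenario.bulge_gain * r0 * (scale - 1.0)

    # external contour
    if scenario.kind == "shoulder_shift":
        ext = ref["external"].copy()
        shift_vox = (
            scenario.shift[0] / grid.spacing[0],
            scenario.shift[1] / grid.spacing[1],
        )
        k = phantom.shoulder_top_index
        shoulder = ext[:, :, :k]
        ext[:, :, :k] = _shift_mask(shoulder, (*shift_vox, 0.0))[:, :, :]
        masks["external"] = ext
    elif weight_loss or edema:
        disp = -shrink + bulge * phantom.bulge_weight
        masks["external"] = phantom.signed_distance <= disp
    external = masks["external"]
    if not external.any():
        raise ValueError(f"fraction {fraction}: external contour vanished")

    # high-dose target scaling (edema trajectory)
    if edema and scale != 1.0:
        gtv_idx = np.argwhere(ref["gtv_high"])
        center_vox = gtv_idx.mean(axis=0)
        for name in _HIGH_TARGETS:
            masks[name] = _scale_mask(ref[name], scale, center_vox)

    # soft-tissue advection under weight loss + optional target drift
    shift_cm = np.array(scenario.target_drift, dtype=float) * fraction
    if weight_loss and scenario.advect_soft_tissue and shrink > 0:
        # advection from in-plane area contraction at the tumor slice
        k_t = int(np.argwhere(ref["gtv_high"])[:, 2].mean())
        a0 = ref["external"][:, :, k_t].sum()
        a1 = external[:, :, k_t].sum()
        lam = math.sqrt(a1 / a0) if a0 else 1.0
        centroid = (np.argwhere(ref["gtv_high"])[:, :2].mean(axis=0) + 0.5) * np.asarray(
            grid.spacing[:2]
        ) + np.asarray(grid.origin[:2])
        shift_cm = shift_cm + (lam - 1.0) * centroid
    if np.any(shift_cm != 0.0):
        shift_vox = (shift_cm[0] / grid.spacing[0], shift_cm[1] / grid.spacing[1], 0.0)
        for name in _SOFT_TISSUE:
            if name in masks:
                masks[name] = _shift_mask(masks[name], shift_vox)

    # keep tissue inside the body; bony-frame structures are untouched
    for name in _SOFT_TISSUE:
        if name in masks:
            masks[name] = masks[name] & external
    for name in BONY_FRAME_STRUCTURES:
        if np.any(masks[name] & ~external):
            raise ValueError(
                f"fraction {fraction}: bony-frame structure {name!r} left the body"
            )

    out = StructureSet(grid, masks)
    out.validate()
    return out, bulge


def _fraction_dose(phantom: Phantom, anatomy: StructureSet) -> np.ndarray:
    """Planned dose held in the bony frame, path-length rescaled."""
    grid = phantom.grid
    dx = grid.spacing[0]
    ref_lo, ref_hi = phantom.reference_depth()
    cur_lo, cur_hi = _tissue_depth(anatomy["external"], dx)
    reduction = 0.5 * ((ref_lo - cur_lo) + (ref_hi - cur_hi))
    return phantom.dose * np.exp(phantom.beam.mu * reduction)


def simulate_course(
    phantom: Phantom,
    scenario: ScenarioConfig,
    specs: Sequence[DoseParameterSpec],
    patient_id: str = "sim",
) -> CourseRecord:
    """Run one course: per-fraction anatomy, dose, and CBCT measurements.

    Contour change (with measurement noise when configured) and dose
    parameters are recorded only at scheduled assessment fractions; flags are
    left unset so that the flagging protocol is applied downstream.
    """
    plan = phantom.plan
    rng = np.random.default_rng(scenario.seed)
    assessed = set(scenario.assessed_fractions(plan.n_fractions))
    planned_params = extract_fraction_parameters(phantom.structures, phantom.dose, specs)

    fractions: list[FractionRecord] = []
    for f in range(1, plan.n_fractions + 1):
        if f not in assessed:
            fractions.append(FractionRecord(f, assessed=False))
            continue
        anatomy, _ = _fraction_anatomy(phantom, scenario, f)
        dose_f = _fraction_dose(phantom, anatomy)
        change = body_contour_change(phantom.structures, anatomy).max_distance
        if scenario.noise_sigma > 0:
            change = max(0.0, change + rng.normal(0.0, scenario.noise_sigma))
        params = extract_fraction_parameters(anatomy, dose_f, specs)
        fractions.append(
            FractionRecord(
                f, assessed=True, contour_change=float(change), parameters=params
            )
        )
    return CourseRecord(
        patient_id=patient_id,
        plan=plan,
        planned_parameters=planned_params,
        fractions=fractions,
    )


DEFAULT_MIX = {
    "shoulder_shift": 0.4,
    "weight_loss": 0.25,
    "localized_edema": 0.2,
    "none": 0.15,
}


def simulate_cohort(
    n_patients: int,
    specs: Sequence[DoseParameterSpec],
    mix: Optional[dict[str, float]] = None,
    seed: int = 0,
    phantom: Optional[Phantom] = None,
) -> list[CourseRecord]:
    """Simulate a cohort with scenarios drawn from a probability mix.

    One phantom is shared across patients; per-patient scenario magnitudes
    are jittered (uniform ±30% on the weight-loss rate, shoulder shifts drawn
    from 1.2-2.5 cm) so courses differ. Fully reproducible for a given seed.
    """
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    mix = dict(DEFAULT_MIX if mix is None else mix)
    total = sum(mix.values())
    kinds = sorted(mix)
    probs = np.array([mix[k] / total for k in kinds])
    rng = np.random.default_rng(seed)
    phantom = phantom or build_phantom()

    courses = []
    for i in range(1, n_patients + 1):
        kind = kinds[int(rng.choice(len(kinds), p=probs))]
        sub = int(rng.integers(0, 2**31 - 1))
        if kind == "weight_loss":
            scenario = ScenarioConfig.weight_loss(
                shrink_rate=0.06 * rng.uniform(0.7, 1.3), seed=sub
            )
        elif kind == "shoulder_shift":
            scenario = ScenarioConfig.shoulder_shift(
                shift=(float(rng.uniform(1.2, 2.5)), 0.0), seed=sub
            )
        elif kind == "localized_edema":
            scenario = ScenarioConfig.localized_edema(seed=sub)
        elif kind == "composite":
            scenario = ScenarioConfig.composite(
                shrink_rate=0.05 * rng.uniform(0.7, 1.3), seed=sub
            )
        else:
            scenario = ScenarioConfig.none(seed=sub)
        courses.append(
            simulate_course(phantom, scenario, specs, patient_id=f"P{i:03d}")
        )
    return courses


def random_flag_cohort(
    n_patients: int,
    k: int = 6,
    p_flag: float = 0.20,
    p_viol: float = 0.15,
    seed: int = 0,
    n_fractions: int = 33,
) -> tuple[list[CourseRecord], list[bool]]:
    """Cohort with independent random flags and violations.

    Builds lightweight :class:`CourseRecord` plumbing for the random-flag
    baseline: each patient has ``k`` assessed fractions whose contour-change
    values land above the 1.5 cm threshold with probability ``p_flag``
    (2.0 cm vs 0.5 cm), and an independent per-fraction violation label drawn
    with probability ``p_viol``. Returns the courses (flags unset; apply the
    flagging protocol downstream) and the aligned violation labels.
    """
    if k > n_fractions:
        raise ValueError("k cannot exceed n_fractions")
    rng = np.random.default_rng(seed)
    plan = CoursePlan(n_fractions=n_fractions)
    assessed = set(np.linspace(1, n_fractions, k).round().astype(int).tolist())
    courses, violations = [], []
    for i in range(1, n_patients + 1):
        fractions = []
        for f in range(1, n_fractions + 1):
            if f in assessed:
                change = 2.0 if rng.random() < p_flag else 0.5
                fractions.append(
                    FractionRecord(f, assessed=True, contour_change=change)
                )
                violations.append(bool(rng.random() < p_viol))
            else:
                fractions.append(FractionRecord(f, assessed=False))
        courses.append(CourseRecord(f"R{i:05d}", plan=plan, fractions=fractions))
    return courses, violations
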