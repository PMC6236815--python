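"""Dose-volume-histogram parameter extraction and course accumulation.

Conventions (stated so that oracle tests are unambiguous):

* ``Dmax`` is the single hottest voxel, with no small-volume smoothing.
* ``Dx%`` (dose at volume) is the k-th highest voxel dose with
  ``k = ceil(x/100 * N)`` — no fractional interpolation between voxels.
* ``VxGy`` (volume at dose) uses an inclusive ``>=`` comparison, the
  cumulative-DVH convention, and is reported in percent of the structure.
* Course accumulation linearly interpolates parameter values between assessed
  fractions, holds the nearest assessed value before the first and after the
  last assessment, and averages the resulting per-fraction series.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .core import FractionRecord, StructureSet

__all__ = [
    "DoseParameterSpec",
    "ParameterSeries",
    "dvh_parameter",
    "extract_fraction_parameters",
    "interpolate_series",
    "accumulate_course",
]

_KINDS = ("max", "mean", "dose_at_volume", "volume_at_dose")


@dataclass(frozen=True)
class DoseParameterSpec:
    """One dosimetric parameter: a structure plus a DVH statistic.

    ``kind`` is one of ``max``, ``mean`` (both in Gy), ``dose_at_volume``
    (``level`` = volume percent x, result Dx% in Gy) or ``volume_at_dose``
    (``level`` = dose in Gy, result VxGy in percent of volume). ``exclude``
    names a structure subtracted from the mask before evaluation, used e.g.
    to evaluate the low-dose PTV excluding the high-dose PTV volume.
    """

    id: str
    structure: str
    kind: str
    level: Optional[float] = None
    exclude: Optional[str] = None

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown statistic kind {self.kind!r}; expected one of {_KINDS}")
        if self.kind == "dose_at_volume":
            if self.level is None or not 0 < self.level <= 100:
                raise ValueError(f"{self.id}: dose_at_volume needs level in (0, 100]")
        if self.kind == "volume_at_dose":
            if self.level is None or self.level <= 0:
                raise ValueError(f"{self.id}: volume_at_dose needs a positive dose level (Gy)")

    @property
    def unit(self) -> str:
        return "%" if self.kind == "volume_at_dose" else "Gy"


def _statistic_from_name(name: str) -> tuple[str, Optional[float]]:
    """Parse a statistic token like ``dmax``, ``dmean``, ``d95`` or ``v49.4``."""
    token = name.strip().lower()
    if token == "dmax":
        return "max", None
    if token == "dmean":
        return "mean", None
    m = re.fullmatch(r"d(\d+(?:\.\d+)?)", token)
    if m:
        return "dose_at_volume", float(m.group(1))
    m = re.fullmatch(r"v(\d+(?:\.\d+)?)", token)
    if m:
        return "volume_at_dose", float(m.group(1))
    raise ValueError(f"cannot parse DVH statistic {name!r}")


def spec_from_statistic(
    parameter_id: str, structure: str, statistic: str, exclude: Optional[str] = None
) -> DoseParameterSpec:
    """Build a :class:`DoseParameterSpec` from a clinical statistic name."""
    kind, level = _statistic_from_name(statistic)
    return DoseParameterSpec(parameter_id, structure, kind, level, exclude)


@dataclass
class ParameterSeries:
    """A parameter over a full course after interpolation.

    ``values[f-1]`` is the value at fraction ``f``; ``accumulated`` is the
    arithmetic mean of all per-fraction values, the conservative estimate of
    overall course deposition used when voxel-wise dose warping is
    unavailable.
    """

    parameter: str
    values: np.ndarray
    assessed_fractions: tuple[int, ...] = field(default_factory=tuple)

    @property
    def accumulated(self) -> float:
        return float(np.mean(self.values))


def dvh_parameter(dose: np.ndarray, mask: np.ndarray, spec: DoseParameterSpec) -> float:
    """Evaluate one DVH statistic of ``dose`` (Gy) over a boolean mask."""
    if dose.shape != mask.shape:
        raise ValueError("dose and mask must share a grid")
    values = dose[mask]
    n = values.size
    if n == 0:
        raise ValueError(f"structure {spec.structure!r} is empty for parameter {spec.id!r}")
    if spec.kind == "max":
        return float(values.max())
    if spec.kind == "mean":
        return float(values.mean())
    if spec.kind == "dose_at_volume":
        k = math.ceil(spec.level / 100.0 * n)  # k-th highest voxel dose
        return float(np.sort(values)[n - k])
    # volume_at_dose
    return float(100.0 * np.count_nonzero(values >= spec.level) / n)


def resolve_mask(structures: StructureSet, spec: DoseParameterSpec) -> np.ndarray:
    mask = structures[spec.structure]
    if spec.exclude is not None:
        mask = mask & ~structures[spec.exclude]
    return mask


def extract_fraction_parameters(
    structures: StructureSet,
    dose: np.ndarray,
    specs: Iterable[DoseParameterSpec],
) -> dict[str, float]:
    """Evaluate every spec on one fraction's anatomy and dose grid."""
    out: dict[str, float] = {}
    for spec in specs:
        try:
            mask = resolve_mask(structures, spec)
        except KeyError as exc:
            raise KeyError(f"parameter {spec.id!r}: {exc.args[0]}") from None
        out[spec.id] = dvh_parameter(dose, mask, spec)
    return out


def interpolate_series(
    assessed: Mapping[int, float] | Sequence[tuple[int, float]],
    n_fractions: int,
    parameter: str = "",
) -> ParameterSeries:
    """Fill a per-fraction series from sparsely assessed values.

    Linear interpolation between consecutive assessed fractions; the nearest
    assessed value is held constant before the first and after the last
    assessment.
    """
    pairs = sorted(dict(assessed).items())
    if not pairs:
        raise ValueError(f"parameter {parameter!r}: no assessed values to interpolate")
    fx = np.array([p[0] for p in pairs], dtype=float)
    if fx[0] < 1 or fx[-1] > n_fractions:
        raise ValueError("assessed fraction indices must lie within 1..n_fractions")
    vals = np.array([p[1] for p in pairs], dtype=float)
    series = np.interp(np.arange(1, n_fractions + 1), fx, vals)
    return ParameterSeries(parameter, series, tuple(int(f) for f in fx))


def accumulate_course(
    fractions: Sequence[FractionRecord], n_fractions: int
) -> dict[str, ParameterSeries]:
    """Interpolated series and accumulated estimate for every parameter."""
    by_param: dict[str, dict[int, float]] = {}
    for fr in fractions:
        if not fr.assessed:
            continue
        for pid, value in fr.parameters.items():
            by_param.setdefault(pid, {})[fr.fraction_index] = value
    return {
        pid: interpolate_series(pairs, n_fractions, parameter=pid)
        for pid, pairs in by_param.items()
    }
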