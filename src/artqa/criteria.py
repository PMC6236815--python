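"""Ground-truth replan criteria: survey aggregation and fraction grading.

Replan "ground truth" is defined by physician-survey responses: each
respondent states the percentage violation of a planning objective that would
warrant a replan, the per-parameter median becomes the margin ``v``, and the
criteria are stratified into *major* and *minor* severity classes by the
clinical relevance of the structure/parameter (target coverage and
brainstem/spinal-cord sparing vs target hot spot and parotid sparing).
Severity class is a property of the criterion, not of the breach magnitude.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import yaml

from .core import FractionRecord
from .dosimetry import DoseParameterSpec, spec_from_statistic

__all__ = [
    "SurveyResponseSet",
    "CriterionSpec",
    "ViolationReport",
    "aggregate_survey",
    "violation_threshold",
    "grade_fraction",
    "load_criteria",
    "default_criteria",
    "CATEGORIES",
]

#: Truth-table categories, in reporting order.
CATEGORIES = (
    "all_major",
    "all_major_excluding_ptv",
    "oar",
    "target_with_ptv",
    "target_without_ptv",
)

CATEGORY_LABELS = {
    "all_major": "All major violations",
    "all_major_excluding_ptv": "All major violations excluding PTV",
    "oar": "Organs at risk (brainstem, spinal cord, optics)",
    "target_with_ptv": "Target coverage (GTV, CTV, PTV)",
    "target_without_ptv": "Target coverage (GTV, CTV)",
}

SurveyResponseSet = Mapping[str, Sequence[float]]


@dataclass(frozen=True)
class CriterionSpec:
    """One graded parameter: reference, direction and percentage margins.

    ``reference`` in Gy (or percent for volume statistics); ``None`` means the
    planned value of the course stands in for a formal objective. ``v_major``
    and ``v_minor`` are percentage margins; either may be absent.
    """

    parameter: str
    structure: str
    statistic: str
    direction: str  # "limit" | "coverage"
    reference: Optional[float] = None
    v_major: Optional[float] = None
    v_minor: Optional[float] = None
    severity_class: str = "major"
    exclude: Optional[str] = None

    def __post_init__(self) -> None:
        if self.direction not in ("limit", "coverage"):
            raise ValueError(f"{self.parameter}: direction must be 'limit' or 'coverage'")
        if self.severity_class not in ("major", "minor"):
            raise ValueError(f"{self.parameter}: class must be 'major' or 'minor'")
        if self.v_major is None and self.v_minor is None:
            raise ValueError(f"{self.parameter}: at least one of v_major/v_minor required")
        if self.v_major is not None and self.v_minor is not None and self.v_major < self.v_minor:
            raise ValueError(f"{self.parameter}: v_major must be >= v_minor")
        if self.reference is not None and self.reference <= 0:
            raise ValueError(f"{self.parameter}: reference must be positive")

    def parameter_spec(self) -> DoseParameterSpec:
        """The DVH extraction spec this criterion grades."""
        return spec_from_statistic(self.parameter, self.structure, self.statistic, self.exclude)

    @property
    def is_ptv(self) -> bool:
        return self.structure.startswith("ptv")

    @property
    def is_target(self) -> bool:
        return self.structure.startswith(("gtv", "ctv", "ptv"))

    @property
    def is_oar(self) -> bool:
        return self.structure.startswith(("spinal_cord", "brainstem", "optic"))


@dataclass
class ViolationReport:
    """Per-parameter violation statuses of one fraction plus category rollup.

    ``statuses`` maps parameter id to ``"none" | "minor" | "major"``;
    ``categories`` holds one boolean per truth-table category, true when any
    *major* violation falls among that category's structures.
    """

    fraction_index: int
    statuses: dict[str, str] = field(default_factory=dict)
    categories: dict[str, bool] = field(default_factory=dict)

    def any_major(self) -> bool:
        return any(s == "major" for s in self.statuses.values())

    def any_minor(self) -> bool:
        return any(s in ("minor", "major") for s in self.statuses.values())


def aggregate_survey(responses: SurveyResponseSet) -> dict[str, float]:
    """Median percentage-violation margin per parameter.

    With an even respondent count the mean of the two middle values is used
    (the usual median convention).
    """
    out: dict[str, float] = {}
    for parameter, values in responses.items():
        vals = np.asarray(list(values), dtype=float)
        if vals.size == 0:
            raise ValueError(f"parameter {parameter!r}: no survey responses")
        if not np.all(np.isfinite(vals)) or np.any(vals <= 0):
            raise ValueError(f"parameter {parameter!r}: responses must be finite and > 0%")
        out[parameter] = float(np.median(vals))
    return out


def _resolve_reference(criterion: CriterionSpec, planned: Optional[Mapping[str, float]]) -> float:
    if criterion.reference is not None:
        return criterion.reference
    if planned is None or criterion.parameter not in planned:
        raise ValueError(
            f"criterion {criterion.parameter!r} has no absolute reference and no "
            "planned value was provided"
        )
    return float(planned[criterion.parameter])


def violation_threshold(
    criterion: CriterionSpec,
    severity: str,
    planned: Optional[Mapping[str, float]] = None,
) -> float:
    """Threshold value for one severity level of a criterion.

    ``limit`` direction: ``reference * (1 + v/100)``; ``coverage`` direction:
    ``reference * (1 - v/100)``.
    """
    v = {"major": criterion.v_major, "minor": criterion.v_minor}.get(severity)
    if severity not in ("major", "minor"):
        raise ValueError(f"unknown severity {severity!r}")
    if v is None:
        raise ValueError(f"criterion {criterion.parameter!r} defines no {severity} margin")
    ref = _resolve_reference(criterion, planned)
    sign = 1.0 if criterion.direction == "limit" else -1.0
    return ref * (1.0 + sign * v / 100.0)


def _breaches(value: float, threshold: float, direction: str) -> bool:
    # strict comparison: a value exactly at threshold is not a violation
    return value > threshold if direction == "limit" else value < threshold


def grade_fraction(
    record: FractionRecord,
    planned: Mapping[str, float],
    criteria: Sequence[CriterionSpec],
) -> ViolationReport:
    """Grade one assessed fraction against every criterion.

    A parameter's status is ``major`` when it breaches the major threshold,
    else ``minor`` when it breaches the minor threshold, else ``none``.
    Category booleans are true when any major violation occurs among the
    category's structures; the with/without-PTV target variants exist because
    CTV→PTV margins make modest PTV-coverage compromises expected under setup
    uncertainty, while large ones indicate dose spilling into healthy tissue.
    """
    statuses: dict[str, str] = {}
    for c in criteria:
        if c.parameter not in record.parameters:
            raise KeyError(
                f"fraction {record.fraction_index}: parameter {c.parameter!r} missing from record"
            )
        value = record.parameters[c.parameter]
        status = "none"
        if c.v_major is not None and _breaches(
            value, violation_threshold(c, "major", planned), c.direction
        ):
            status = "major"
        elif c.v_minor is not None and _breaches(
            value, violation_threshold(c, "minor", planned), c.direction
        ):
            status = "minor"
        statuses[c.parameter] = status

    by_param = {c.parameter: c for c in criteria}
    major = [by_param[p] for p, s in statuses.items() if s == "major"]
    categories = {
        "all_major": bool(major),
        "all_major_excluding_ptv": any(not c.is_ptv for c in major),
        "oar": any(c.is_oar for c in major),
        "target_with_ptv": any(c.is_target for c in major),
        "target_without_ptv": any(c.is_target and not c.is_ptv for c in major),
    }
    return ViolationReport(record.fraction_index, statuses, categories)


def _criterion_from_mapping(entry: Mapping) -> CriterionSpec:
    return CriterionSpec(
        parameter=entry["parameter"],
        structure=entry["structure"],
        statistic=entry["statistic"],
        direction=entry["direction"],
        reference=entry.get("reference"),
        v_major=entry.get("v_major"),
        v_minor=entry.get("v_minor"),
        severity_class=entry.get("class", "major"),
        exclude=entry.get("exclude"),
    )


def load_criteria(path: str | Path) -> list[CriterionSpec]:
    """Read a criteria YAML file (see the packaged default for the schema)."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or doc.get("schema") != "artqa.criteria.v1":
        raise ValueError(f"{path}: not an artqa.criteria.v1 document")
    return [_criterion_from_mapping(e) for e in doc["criteria"]]


def default_criteria() -> list[CriterionSpec]:
    """The packaged default (reconstructed) criteria set."""
    ref = resources.files("artqa.data").joinpath("default_criteria.yaml")
    with resources.as_file(ref) as path:
        return load_criteria(path)


def filter_to_available(
    criteria: Iterable[CriterionSpec], structure_names: Iterable[str]
) -> list[CriterionSpec]:
    """Drop criteria whose structures are absent from the course anatomy."""
    names = set(structure_names)
    return [
        c
        for c in criteria
        if c.structure in names and (c.exclude is None or c.exclude in names)
    ]
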