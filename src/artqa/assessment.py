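"""Truth-table flag assessment and the random-flag sensitivity baseline.

Every assessed fraction is treated as an independent data point and
cross-tabulated by flag state versus presence of a (major) violation:

* TP — flagged, violation present
* FN — unflagged, violation present
* FP — flagged, no violation
* TN — unflagged, no violation

yielding sensitivity TP/(TP+FN), specificity TN/(TN+FP), positive predictive
value TP/(TP+FP), negative predictive value TN/(TN+FN) and accuracy
(TP+TN)/total. A ratio with zero denominator is reported as absent (``None``)
rather than zero, so that averages are not silently deflated.

The *random-flag baseline* quantifies the sensitivity a completely
uninformative flag would achieve in a cohort assembled the way flagged-patient
studies are: flags and violations are drawn independently per fraction, but
only patients with at least one flagged fraction enter the cohort. That
inclusion bias inflates the pooled sensitivity from ``p_flag`` to
``p_flag / (1 - (1 - p_flag)^k)`` for ``k`` assessed fractions per patient —
the benchmark any clinically meaningful flag must beat.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import sqrt
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core import CourseRecord
from .criteria import CATEGORIES, CATEGORY_LABELS, ViolationReport

__all__ = [
    "TruthTable",
    "DiagnosticMetrics",
    "BaselineModel",
    "BaselineResult",
    "truth_table",
    "diagnostic_metrics",
    "assess_categories",
    "random_flag_sensitivity",
]


@dataclass(frozen=True)
class TruthTable:
    """TP/FN/FP/TN fraction counts for one violation category."""

    tp: int
    fn: int
    fp: int
    tn: int
    label: str = ""

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise ValueError("truth-table counts must be >= 0")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.fp + self.tn

    def percent_of_total(self, count: int) -> int:
        """A count as a whole percent of the table total (report style)."""
        if self.total == 0:
            raise ValueError("empty truth table")
        return round(100.0 * count / self.total)


@dataclass(frozen=True)
class DiagnosticMetrics:
    """The five accuracy statistics, as fractions in [0, 1] or ``None``."""

    sensitivity: Optional[float]
    specificity: Optional[float]
    ppv: Optional[float]
    npv: Optional[float]
    accuracy: Optional[float]

    def as_percent(self, ndigits: int = 1) -> dict[str, Optional[float]]:
        """Metrics scaled to percent, rounded only at reporting time."""
        return {
            name: (None if value is None else round(100.0 * value, ndigits))
            for name, value in self.__dict__.items()
        }


def truth_table(
    flags: Sequence[bool], violations: Sequence[bool], label: str = ""
) -> TruthTable:
    """Cross-tabulate aligned per-fraction flag and violation states."""
    if len(flags) != len(violations):
        raise ValueError(
            f"length mismatch: {len(flags)} flags vs {len(violations)} violations"
        )
    f = np.asarray(flags, dtype=bool)
    v = np.asarray(violations, dtype=bool)
    return TruthTable(
        tp=int(np.count_nonzero(f & v)),
        fn=int(np.count_nonzero(~f & v)),
        fp=int(np.count_nonzero(f & ~v)),
        tn=int(np.count_nonzero(~f & ~v)),
        label=label,
    )


def _ratio(num: int, den: int) -> Optional[float]:
    return None if den == 0 else num / den


def diagnostic_metrics(t: TruthTable) -> DiagnosticMetrics:
    """Sensitivity, specificity, PPV, NPV and accuracy of a truth table."""
    if t.total == 0:
        raise ValueError("cannot compute metrics of an empty truth table")
    return DiagnosticMetrics(
        sensitivity=_ratio(t.tp, t.tp + t.fn),
        specificity=_ratio(t.tn, t.tn + t.fp),
        ppv=_ratio(t.tp, t.tp + t.fp),
        npv=_ratio(t.tn, t.tn + t.fn),
        accuracy=_ratio(t.tp + t.tn, t.total),
    )


def assess_categories(
    courses: Sequence[CourseRecord],
    reports: Sequence[ViolationReport],
    weights: Optional[Sequence[float]] = None,
) -> pd.DataFrame:
    """Truth table and metrics per violation category over a cohort.

    ``reports`` must align one-to-one with the assessed fractions of
    ``courses`` (course order, then fraction order). Optional per-fraction
    ``weights`` (default uniform) let a center emphasise, e.g., the first half
    of treatment; weighted counts are reported as floats.
    """
    flags = [fr.flagged for c in courses for fr in c.assessed_fractions]
    if len(flags) != len(reports):
        raise ValueError(
            f"{len(reports)} violation reports for {len(flags)} assessed fractions"
        )
    if weights is not None and len(weights) != len(flags):
        raise ValueError("weights must align with assessed fractions")
    w = np.ones(len(flags)) if weights is None else np.asarray(weights, dtype=float)
    f = np.asarray(flags, dtype=bool)

    rows = []
    for cat in CATEGORIES:
        v = np.asarray([r.categories[cat] for r in reports], dtype=bool)
        if weights is None:
            tt = truth_table(f, v, label=cat)
            counts = {"tp": tt.tp, "fn": tt.fn, "fp": tt.fp, "tn": tt.tn}
        else:
            counts = {
                "tp": float(w[f & v].sum()),
                "fn": float(w[~f & v].sum()),
                "fp": float(w[f & ~v].sum()),
                "tn": float(w[~f & ~v].sum()),
            }
            tt = TruthTable(
                *(int(round(counts[k])) for k in ("tp", "fn", "fp", "tn")), label=cat
            )
        m = diagnostic_metrics(tt)
        total = sum(counts.values())
        row = {"category": cat, "label": CATEGORY_LABELS[cat], **counts, "total": total}
        row.update(
            {
                f"{k}_pct": round(100.0 * counts[k] / total)
                for k in ("tp", "fn", "fp", "tn")
            }
        )
        row.update(m.as_percent(ndigits=1))
        rows.append(row)
    return pd.DataFrame(rows).set_index("category")


@dataclass(frozen=True)
class BaselineModel:
    """Random-flag cohort model.

    Per assessed fraction, a flag is raised with probability ``p_flag`` and a
    clinically significant violation occurs independently with probability
    ``p_viol``; each patient contributes ``k`` assessed fractions. With
    ``condition_on_flagged`` (the default), patients without any flagged
    fraction are excluded before pooling, emulating flagged-cohort inclusion
    bias.
    """

    p_flag: float = 0.20
    p_viol: float = 0.15
    k: int = 6
    n_patients: int = 100_000
    seed: int = 0
    condition_on_flagged: bool = True

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_flag <= 1.0 and 0.0 <= self.p_viol <= 1.0):
            raise ValueError("probabilities must lie in [0, 1]")
        if self.k < 1 or self.n_patients < 1:
            raise ValueError("k and n_patients must be >= 1")

    @property
    def closed_form_sensitivity(self) -> float:
        """Expected pooled sensitivity under the model.

        Conditioned on inclusion, the expected share of flagged fractions per
        retained patient rises to ``p / (1 - (1-p)^k)``; because violations
        are independent of flags, the pooled sensitivity equals that share.
        Without conditioning it is simply ``p_flag``. Independent of
        ``p_viol`` either way.
        """
        if not self.condition_on_flagged:
            return self.p_flag
        if self.p_flag == 0.0:
            raise ValueError("p_flag = 0 with conditioning retains no patients")
        return self.p_flag / (1.0 - (1.0 - self.p_flag) ** self.k)


@dataclass(frozen=True)
class BaselineResult:
    """Monte-Carlo estimate of the baseline sensitivity plus its closed form."""

    model: BaselineModel
    closed_form: float
    mc_sensitivity: float
    mc_standard_error: float
    pooled: TruthTable
    n_retained: int


def random_flag_sensitivity(model: BaselineModel) -> BaselineResult:
    """Simulate the random-flag cohort and pool its truth table.

    Draws flags and violations independently for ``n_patients`` patients of
    ``k`` fractions each, applies the inclusion conditioning, and pools
    TP/FN/FP/TN across retained patients. The Monte-Carlo sensitivity
    converges to the closed form as the cohort grows.
    """
    closed = model.closed_form_sensitivity  # raises for p_flag=0 conditioned
    rng = np.random.default_rng(model.seed)
    flags = rng.random((model.n_patients, model.k)) < model.p_flag
    viols = rng.random((model.n_patients, model.k)) < model.p_viol
    if model.condition_on_flagged:
        keep = flags.any(axis=1)
        if not keep.any():
            raise ValueError("no patients retained after conditioning on >=1 flag")
        flags, viols = flags[keep], viols[keep]
    pooled = truth_table(flags.ravel(), viols.ravel(), label="random-flag baseline")
    positives = pooled.tp + pooled.fn
    sens = pooled.tp / positives if positives else float("nan")
    se = sqrt(sens * (1.0 - sens) / positives) if positives else float("nan")
    return BaselineResult(
        model=model,
        closed_form=closed,
        mc_sensitivity=float(sens),
        mc_standard_error=float(se),
        pooled=pooled,
        n_retained=int(flags.shape[0]),
    )
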