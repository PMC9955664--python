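"""Validation of cutoff classifiers against the logic-tree reference.

Positive class is *sexual* acquisition throughout: a true positive is a
participant the reference calls sexual that the cutoff also calls
sexual; a true negative is vertical under both.  Participants left
unclassified by either source are excluded before counting.

The ROC "curve" for a single cutoff is the two-segment polyline through
(0,0), (1−specificity, sensitivity), (1,1); its trapezoidal area equals
(sensitivity + specificity) / 2.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Optional

import numpy as np

from .cutoff_classifier import allocate_by_cutoff
from .harmonization import HarmonizedProfile, TreeConfig

__all__ = [
    "ConfusionMatrix",
    "DiagnosticResult",
    "confusion_matrix",
    "diagnostic_metrics",
    "auc_single_threshold",
    "evaluate_cutoffs",
    "optimal_cutoffs",
]

POSITIVE_LABEL = "sexual"
NEGATIVE_LABEL = "vertical"
_DEFINITE = frozenset({POSITIVE_LABEL, NEGATIVE_LABEL})


@dataclass(frozen=True)
class ConfusionMatrix:
    """2x2 counts with positive fixed to sexual acquisition."""

    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self):
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.fn + self.fp + self.tn


@dataclass(frozen=True)
class DiagnosticResult:
    """Validation metrics for one cutoff age.

    ``ppv``/``npv`` are None when their denominator is zero (no positive
    or no negative test calls).  ``auc`` is filled by
    :func:`evaluate_cutoffs`; when present it equals
    (sensitivity + specificity) / 2 by the two-point ROC identity.
    """

    cutoff_age: int
    sensitivity: float
    specificity: float
    abs_difference: float
    ppv: Optional[float]
    npv: Optional[float]
    auc: Optional[float]
    n_evaluated: int


def confusion_matrix(
    reference_labels: Mapping[str, str], test_labels: Mapping[str, str]
) -> ConfusionMatrix:
    """Count agreement over participants classified by both sources.

    ``reference_labels``/``test_labels`` map participant_id to a label in
    {sexual, vertical, unclassified/missing}; only ids carrying a
    definite label in *both* mappings are counted.
    """
    tp = fn = fp = tn = 0
    for pid, ref in reference_labels.items():
        if ref not in _DEFINITE:
            continue
        test = test_labels.get(pid)
        if test not in _DEFINITE:
            continue
        if ref == POSITIVE_LABEL:
            if test == POSITIVE_LABEL:
                tp += 1
            else:
                fn += 1
        else:
            if test == POSITIVE_LABEL:
                fp += 1
            else:
                tn += 1
    cm = ConfusionMatrix(tp=tp, fn=fn, fp=fp, tn=tn)
    if cm.n == 0:
        raise ValueError("no participants are classified by both the reference and the test")
    return cm


def diagnostic_metrics(cm: ConfusionMatrix, cutoff_age: int = -1) -> DiagnosticResult:
    """Sensitivity, specificity, PPV, NPV and |sens − spec| from counts.

    Requires at least one reference positive and one reference negative;
    PPV/NPV are reported as None when undefined (zero denominator).
    AUC is left unset.
    """
    if cm.tp + cm.fn == 0:
        raise ValueError("reference positive (sexual) class is empty")
    if cm.tn + cm.fp == 0:
        raise ValueError("reference negative (vertical) class is empty")
    sens = cm.tp / (cm.tp + cm.fn)
    spec = cm.tn / (cm.tn + cm.fp)
    ppv = cm.tp / (cm.tp + cm.fp) if (cm.tp + cm.fp) > 0 else None
    npv = cm.tn / (cm.tn + cm.fn) if (cm.tn + cm.fn) > 0 else None
    return DiagnosticResult(
        cutoff_age=cutoff_age,
        sensitivity=sens,
        specificity=spec,
        abs_difference=abs(sens - spec),
        ppv=ppv,
        npv=npv,
        auc=None,
        n_evaluated=cm.n,
    )


def auc_single_threshold(sensitivity: float, specificity: float) -> float:
    """Trapezoidal area under the two-point ROC polyline.

    Integrates (0,0) → (1−specificity, sensitivity) → (1,1) by the
    trapezoidal rule; algebraically (sensitivity + specificity) / 2, but
    computed geometrically so the identity is a checked property rather
    than an assumption.
    """
    for name, v in (("sensitivity", sensitivity), ("specificity", specificity)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must be in [0, 1], got {v}")
    x = np.array([0.0, 1.0 - specificity, 1.0])
    y = np.array([0.0, sensitivity, 1.0])
    return float(np.trapezoid(y, x))


def evaluate_cutoffs(
    profiles: Iterable[HarmonizedProfile],
    tree_allocations: Iterable,
    config: TreeConfig = TreeConfig(),
) -> tuple[list[DiagnosticResult], list[dict]]:
    """Validate every configured cutoff against the tree reference.

    Returns ``(results, roc_points)``: one :class:`DiagnosticResult` per
    cutoff (AUC filled), and the per-cutoff ROC operating points
    ``{"cutoff_age", "fpr", "tpr"}`` for plotting.
    """
    profiles = list(profiles)
    reference = {a.participant_id: a.label for a in tree_allocations}
    results: list[DiagnosticResult] = []
    roc_points: list[dict] = []
    for cutoff in config.cutoff_ages:
        test = {p.participant_id: allocate_by_cutoff(p, cutoff).label for p in profiles}
        cm = confusion_matrix(reference, test)
        res = diagnostic_metrics(cm, cutoff_age=cutoff)
        res = replace(res, auc=auc_single_threshold(res.sensitivity, res.specificity))
        results.append(res)
        roc_points.append(
            {"cutoff_age": cutoff, "fpr": 1.0 - res.specificity, "tpr": res.sensitivity}
        )
    return results, roc_points


def optimal_cutoffs(results: Iterable[DiagnosticResult]) -> dict[str, list[int]]:
    """Flag optimal cutoffs under the three selection criteria.

    Returns, for each criterion (max sensitivity, min |sens − spec|,
    max AUC), every cutoff attaining the optimum (ties kept).
    """
    results = list(results)
    if not results:
        raise ValueError("no diagnostic results to rank")
    best_sens = max(r.sensitivity for r in results)
    best_absd = min(r.abs_difference for r in results)
    best_auc = max(r.auc for r in results)
    return {
        "max_sensitivity": [r.cutoff_age for r in results if r.sensitivity == best_sens],
        "min_abs_difference": [r.cutoff_age for r in results if r.abs_difference == best_absd],
        "max_auc": [r.cutoff_age for r in results if r.auc == best_auc],
    }
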