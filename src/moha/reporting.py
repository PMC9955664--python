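"""Report assembly: rounding rules, summary tables and run manifests.

Reported proportions are rounded half-up (3 decimals for metrics, 1 for
percentages); internal arithmetic is never rounded.
"""

from __future__ import annotations

import hashlib
import json
import platform
import sys
from dataclasses import asdict, dataclass, field
from datetime import datetime, timezone
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd

from .diagnostics import DiagnosticResult

__all__ = [
    "round_half_up",
    "percent",
    "metrics_frame",
    "allocation_summary",
    "RunManifest",
    "build_manifest",
    "file_sha256",
]

METRICS_COLUMNS = (
    "cutoff",
    "sensitivity",
    "specificity",
    "abs_difference",
    "ppv",
    "npv",
    "auc",
    "n",
)


def round_half_up(value: float, decimals: int = 3) -> float:
    """Round half away from zero at the given decimal place.

    Python's ``round`` is banker's rounding; reported cells use the
    conventional half-up rule instead (0.2265 → 0.227 at 3 decimals).
    """
    quantum = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(value)).quantize(quantum, rounding=ROUND_HALF_UP))


def percent(count: int, total: int, decimals: int = 1) -> float:
    """Share of ``count`` in ``total`` as a half-up-rounded percentage."""
    if total <= 0:
        raise ValueError("total must be positive")
    return round_half_up(100.0 * count / total, decimals)


def metrics_frame(results: Iterable[DiagnosticResult]) -> pd.DataFrame:
    """Validation metrics table, one row per cutoff, 3-decimal cells.

    Columns mirror the standard layout: cutoff, sensitivity, specificity,
    abs_difference, ppv, npv, auc, n.  Undefined PPV/NPV cells are empty.
    """
    rows = []
    for r in results:
        rows.append(
            {
                "cutoff": r.cutoff_age,
                "sensitivity": round_half_up(r.sensitivity),
                "specificity": round_half_up(r.specificity),
                "abs_difference": round_half_up(r.abs_difference),
                "ppv": round_half_up(r.ppv) if r.ppv is not None else None,
                "npv": round_half_up(r.npv) if r.npv is not None else None,
                "auc": round_half_up(r.auc) if r.auc is not None else None,
                "n": r.n_evaluated,
            }
        )
    return pd.DataFrame(rows, columns=METRICS_COLUMNS)


def allocation_summary(
    tree_allocations: Iterable,
    cutoff_allocations: Iterable,
    reference_cutoff: int = 10,
) -> pd.DataFrame:
    """Original-vs-algorithm allocation counts and percentages.

    "Original" rows are the cutoff allocation at ``reference_cutoff``;
    "algorithm" rows are the logic-tree allocation, with an ``n_a`` row
    for the unclassified.  Percentages are over all participants.
    """
    tree = list(tree_allocations)
    cut = [a for a in cutoff_allocations if a.cutoff_age == reference_cutoff]
    n = len(tree)
    if n == 0 or len(cut) == 0:
        raise ValueError("empty allocation input")
    rows = []
    for label in ("sexual", "vertical", "missing"):
        count = sum(1 for a in cut if a.label == label)
        rows.append({"allocation": "original", "label": label, "n": count, "pct": percent(count, n)})
    for label in ("sexual", "vertical"):
        count = sum(1 for a in tree if a.label == label)
        rows.append({"allocation": "algorithm", "label": label, "n": count, "pct": percent(count, n)})
    n_na = sum(1 for a in tree if a.label == "unclassified")
    rows.append({"allocation": "algorithm", "label": "n_a", "n": n_na, "pct": percent(n_na, n)})
    return pd.DataFrame(rows, columns=["allocation", "label", "n", "pct"])


# ---------------------------------------------------------------------------
# manifests

def file_sha256(path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            digest.update(chunk)
    return digest.hexdigest()


@dataclass
class RunManifest:
    """Provenance for one pipeline stage, sufficient to re-run identically."""

    stage: str
    seed: Optional[int]
    config: dict
    inputs: dict[str, str] = field(default_factory=dict)    # name -> sha256
    outputs: dict[str, str] = field(default_factory=dict)   # name -> sha256
    row_counts: dict[str, int] = field(default_factory=dict)
    versions: dict[str, str] = field(default_factory=dict)
    timestamp: str = ""

    def write(self, path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(asdict(self), indent=2, sort_keys=True, default=str))
        return path


def build_manifest(
    stage: str,
    config: Mapping,
    seed: Optional[int] = None,
    inputs: Optional[Mapping[str, Path]] = None,
    outputs: Optional[Mapping[str, Path]] = None,
    row_counts: Optional[Mapping[str, int]] = None,
) -> RunManifest:
    from . import __version__

    return RunManifest(
        stage=stage,
        seed=seed,
        config=dict(config),
        inputs={k: file_sha256(v) for k, v in (inputs or {}).items()},
        outputs={k: file_sha256(v) for k, v in (outputs or {}).items()},
        row_counts=dict(row_counts or {}),
        versions={
            "moha": __version__,
            "python": sys.version.split()[0],
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "platform": platform.platform(),
        },
        timestamp=datetime.now(timezone.utc).isoformat(),
    )
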