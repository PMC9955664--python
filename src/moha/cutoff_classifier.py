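"""ART-initiation-age cutoff allocation.

The boundary convention is deliberate and load-bearing: a participant who
initiated ART *at* the cutoff age is allocated *sexual*; strictly younger
is *vertical*.  An off-by-one here changes every downstream validation
metric, so it is tested explicitly and exhaustively.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import pandas as pd

from .harmonization import HarmonizedProfile, TreeConfig

__all__ = ["CutoffAllocation", "allocate_by_cutoff", "allocate_all_cutoffs", "cutoff_count_table"]


@dataclass(frozen=True)
class CutoffAllocation:
    participant_id: str
    cutoff_age: int
    label: str  # "vertical" | "sexual" | "missing"


def allocate_by_cutoff(profile: HarmonizedProfile, cutoff_age: int) -> CutoffAllocation:
    """Allocate one participant at one cutoff.

    init age < cutoff → vertical; init age ≥ cutoff → sexual (boundary
    goes to sexual); no resolved init age → missing.
    """
    if profile.art_init_age is None:
        label = "missing"
    elif profile.art_init_age < cutoff_age:
        label = "vertical"
    else:
        label = "sexual"
    return CutoffAllocation(profile.participant_id, cutoff_age, label)


def allocate_all_cutoffs(
    profiles: Iterable[HarmonizedProfile], config: TreeConfig = TreeConfig()
) -> list[CutoffAllocation]:
    """One allocation per (participant, configured cutoff)."""
    return [
        allocate_by_cutoff(profile, cutoff)
        for profile in profiles
        for cutoff in config.cutoff_ages
    ]


def cutoff_count_table(allocations: Iterable[CutoffAllocation]) -> pd.DataFrame:
    """Per-cutoff vertical/sexual/missing counts (one row per cutoff)."""
    df = pd.DataFrame(
        [(a.cutoff_age, a.label) for a in allocations], columns=["cutoff_age", "label"]
    )
    if df.empty:
        return pd.DataFrame(columns=["cutoff_age", "vertical", "sexual", "missing", "n"])
    table = (
        df.groupby(["cutoff_age", "label"]).size().unstack(fill_value=0)
        .reindex(columns=["vertical", "sexual", "missing"], fill_value=0)
        .reset_index()
    )
    table.columns.name = None
    table["n"] = table[["vertical", "sexual", "missing"]].sum(axis=1)
    return table
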