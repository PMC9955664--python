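"""Ordered rule-based decision tree producing the reference-standard label.

A gateway question (any sexual activity or sexual abuse ever reported)
routes each participant into the sexual arm or the vertical arm.  Each
arm is an ordered list of branch predicates evaluated first-hit: the
first true predicate confirms the arm's label and records the exit
branch.  Branches are ordered strongest-evidence-first, so a lower exit
index means a determination on stronger grounds.

Participants entering the sexual arm whose branches all fall through are
re-run on the vertical side as *switchers*, where only the
switcher-eligible vertical branches (V1, V2, V3, V6, V7) are offered.
There is no vertical→sexual switching: vertical-arm fall-throughs are
unclassified.

Countering information (opposite-arm predicates that are also true) is
surfaced as ``conflict_flags`` and an audit log line, never a label
change — confirmation is monotone.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from statistics import mean, stdev
from typing import Callable, Iterable, Optional

import pandas as pd

from .harmonization import HarmonizedProfile, TreeConfig

logger = logging.getLogger(__name__)

__all__ = [
    "MohaAllocation",
    "BranchDefinition",
    "SEXUAL_BRANCHES",
    "VERTICAL_BRANCHES",
    "ALL_BRANCH_IDS",
    "SWITCHER_BRANCH_IDS",
    "MOTHERS_DISABLED_BRANCHES",
    "mothers_tree_config",
    "gateway",
    "run_sexual_arm",
    "run_vertical_arm",
    "allocate",
    "allocate_cohort",
    "count_affirmatory_factors",
    "exit_frequency_table",
    "affirmatory_summary",
]

Predicate = Callable[[HarmonizedProfile, TreeConfig], bool]


@dataclass(frozen=True)
class BranchDefinition:
    """One decision node: a pure predicate over the harmonized profile."""

    branch_id: str
    arm: str  # "sexual" | "vertical"
    order: int
    predicate: Predicate
    label: str
    description: str
    available_to_switchers: bool = False


@dataclass(frozen=True)
class MohaAllocation:
    """Tree output for one participant."""

    participant_id: str
    label: str  # "vertical" | "sexual" | "unclassified"
    arm_entered: str
    exit_branch: Optional[str] = None
    switched: bool = False
    affirmatory_count: int = 0
    conflict_flags: tuple[str, ...] = ()


# ---------------------------------------------------------------------------
# branch predicates

def _sex_before_diagnosis(p: HarmonizedProfile, cfg: TreeConfig) -> bool:
    # debut strictly before the earlier of ART initiation and first HIV test
    if p.sexual_debut_age is None:
        return False
    refs = [a for a in (p.art_init_age, p.first_hiv_test_age) if a is not None]
    return bool(refs) and p.sexual_debut_age < min(refs)


def _initiated_before_rollout(p: HarmonizedProfile, cfg: TreeConfig) -> bool:
    return p.art_init_year is not None and p.art_init_year < cfg.art_rollout_year


def _early_first_test(p: HarmonizedProfile, cfg: TreeConfig) -> bool:
    # for ART-naive profiles the slow-progressor branch takes over
    return (
        not p.art_naive
        and p.first_hiv_test_age is not None
        and p.first_hiv_test_age < cfg.first_test_age_threshold
    )


def _slow_progressor(p: HarmonizedProfile, cfg: TreeConfig) -> bool:
    return (
        p.art_naive
        and p.first_hiv_test_age is not None
        and p.first_hiv_test_age < cfg.first_test_age_threshold
    )


SEXUAL_BRANCHES: tuple[BranchDefinition, ...] = (
    BranchDefinition("S1", "sexual", 1, _sex_before_diagnosis, "sexual",
                     "sexual debut before HIV+ diagnosis / ART initiation"),
    BranchDefinition("S2", "sexual", 2, lambda p, c: p.ever_sexual_abuse, "sexual",
                     "history of penetrative sexual abuse"),
    BranchDefinition("S3", "sexual", 3, lambda p, c: p.discordant_disclosure, "sexual",
                     "discordant sexual-debut disclosure across waves"),
    BranchDefinition("S4", "sexual", 4, lambda p, c: p.consistent_unprotected_sex, "sexual",
                     "consistent unprotected sex"),
    BranchDefinition("S5", "sexual", 5, lambda p, c: p.other_risky_behaviour, "sexual",
                     "other risky sexual behaviour"),
    BranchDefinition("S6", "sexual", 6, lambda p, c: p.hiv_status_aware, "sexual",
                     "HIV+ status awareness"),
)

VERTICAL_BRANCHES: tuple[BranchDefinition, ...] = (
    BranchDefinition("V1", "vertical", 1, lambda p, c: p.maternal_hiv_orphan, "vertical",
                     "maternal HIV/AIDS orphan", available_to_switchers=True),
    BranchDefinition("V2", "vertical", 2, lambda p, c: p.mother_on_art, "vertical",
                     "mother on ART or HIV-symptomatic", available_to_switchers=True),
    BranchDefinition("V3", "vertical", 3, lambda p, c: p.maternal_orphan_le10_presumed, "vertical",
                     "maternal orphan at ≤ threshold age, presumed HIV cause",
                     available_to_switchers=True),
    BranchDefinition("V4", "vertical", 4, lambda p, c: p.cognitive_delay, "vertical",
                     "cognitive delay"),
    BranchDefinition("V5", "vertical", 5, lambda p, c: p.poor_physical_health, "vertical",
                     "chronic poor physical health"),
    BranchDefinition("V6", "vertical", 6, lambda p, c: p.paternal_hiv_orphan_or_dad_art, "vertical",
                     "paternal HIV orphan or father on ART", available_to_switchers=True),
    BranchDefinition("V7", "vertical", 7, lambda p, c: p.paternal_orphan_le10_presumed, "vertical",
                     "paternal orphan at ≤ threshold age, presumed HIV cause",
                     available_to_switchers=True),
    BranchDefinition("V8", "vertical", 8, _initiated_before_rollout, "vertical",
                     "ART initiated before public rollout year"),
    BranchDefinition("V9", "vertical", 9, _early_first_test, "vertical",
                     "first HIV test before threshold age"),
    BranchDefinition("SLOW", "vertical", 10, _slow_progressor, "vertical",
                     "ART-naive slow progressor with early first HIV test"),
)

ALL_BRANCH_IDS: frozenset[str] = frozenset(
    b.branch_id for b in SEXUAL_BRANCHES + VERTICAL_BRANCHES
)
SWITCHER_BRANCH_IDS: frozenset[str] = frozenset(
    b.branch_id for b in VERTICAL_BRANCHES if b.available_to_switchers
)
#: branches needing multi-wave or wave-1-only data the single-wave sample lacks
MOTHERS_DISABLED_BRANCHES: frozenset[str] = frozenset({"S3", "V3", "V7"})


def mothers_tree_config(base: TreeConfig = TreeConfig()) -> TreeConfig:
    """Config variant for the single-wave young-mothers sample.

    Disables the discordant-disclosure and presumed-orphan branches and
    forces every participant through the sexual gateway.
    """
    enabled = (base.enabled_branches or ALL_BRANCH_IDS) - MOTHERS_DISABLED_BRANCHES
    return TreeConfig(
        cutoff_ages=base.cutoff_ages,
        art_rollout_year=base.art_rollout_year,
        orphan_age_threshold=base.orphan_age_threshold,
        discordance_gap_years=base.discordance_gap_years,
        first_test_age_threshold=base.first_test_age_threshold,
        seroconversion_to_death_years=base.seroconversion_to_death_years,
        enabled_branches=frozenset(enabled),
        force_sexual_gateway=True,
    )


# ---------------------------------------------------------------------------

def gateway(profile: HarmonizedProfile, config: TreeConfig = TreeConfig()) -> str:
    """Route a profile to the sexual or vertical arm."""
    if config.force_sexual_gateway or profile.ever_sexual_activity or profile.ever_sexual_abuse:
        return "sexual"
    return "vertical"


def _run_arm(
    branches: tuple[BranchDefinition, ...],
    profile: HarmonizedProfile,
    config: TreeConfig,
    switcher_only: bool = False,
) -> Optional[tuple[str, str]]:
    for branch in branches:
        if not config.branch_enabled(branch.branch_id):
            continue
        if switcher_only and not branch.available_to_switchers:
            continue
        if branch.predicate(profile, config):
            return branch.label, branch.branch_id
    return None


def run_sexual_arm(
    profile: HarmonizedProfile, config: TreeConfig = TreeConfig()
) -> Optional[tuple[str, str]]:
    """First-hit evaluation of the sexual branches; None on fall-through."""
    return _run_arm(SEXUAL_BRANCHES, profile, config)


def run_vertical_arm(
    profile: HarmonizedProfile, config: TreeConfig = TreeConfig(), switcher: bool = False
) -> Optional[tuple[str, str]]:
    """First-hit evaluation of the vertical branches.

    With ``switcher=True`` only the switcher-eligible branches
    (V1, V2, V3, V6, V7) are offered.
    """
    return _run_arm(VERTICAL_BRANCHES, profile, config, switcher_only=switcher)


def count_affirmatory_factors(
    profile: HarmonizedProfile, arm: str, config: TreeConfig = TreeConfig()
) -> int:
    """Number of the arm's enabled branch predicates evaluating true.

    Counts over *all* enabled branches of the arm, ignoring the switcher
    restriction and first-hit short-circuiting — it measures the total
    concentration of corroborating evidence, not the exit point.
    """
    branches = SEXUAL_BRANCHES if arm == "sexual" else VERTICAL_BRANCHES
    return sum(
        1
        for b in branches
        if config.branch_enabled(b.branch_id) and b.predicate(profile, config)
    )


def _conflicts(profile: HarmonizedProfile, final_arm: str, config: TreeConfig) -> tuple[str, ...]:
    other = VERTICAL_BRANCHES if final_arm == "sexual" else SEXUAL_BRANCHES
    return tuple(
        b.branch_id
        for b in other
        if config.branch_enabled(b.branch_id) and b.predicate(profile, config)
    )


def allocate(profile: HarmonizedProfile, config: TreeConfig = TreeConfig()) -> MohaAllocation:
    """Run the full tree for one profile.

    Sexual-arm fall-throughs are re-run on the vertical side with the
    switcher restriction; fall-through everywhere yields ``unclassified``
    (no exit branch, zero affirmatory count).
    """
    arm = gateway(profile, config)
    switched = False
    if arm == "sexual":
        hit = run_sexual_arm(profile, config)
        if hit is None:
            hit = run_vertical_arm(profile, config, switcher=True)
            switched = hit is not None
    else:
        hit = run_vertical_arm(profile, config, switcher=False)

    if hit is None:
        return MohaAllocation(profile.participant_id, "unclassified", arm)

    label, branch_id = hit
    conflicts = _conflicts(profile, label, config)
    if conflicts:
        logger.info(
            "participant_id=%s: label=%s exit=%s with countering factors %s",
            profile.participant_id, label, branch_id, ",".join(conflicts),
        )
    return MohaAllocation(
        participant_id=profile.participant_id,
        label=label,
        arm_entered=arm,
        exit_branch=branch_id,
        switched=switched,
        affirmatory_count=count_affirmatory_factors(profile, label, config),
        conflict_flags=conflicts,
    )


def allocate_cohort(
    profiles: Iterable[HarmonizedProfile], config: TreeConfig = TreeConfig()
) -> list[MohaAllocation]:
    return [allocate(p, config) for p in profiles]


# ---------------------------------------------------------------------------
# reporting

_EXIT_ORDER = [b.branch_id for b in SEXUAL_BRANCHES] + [b.branch_id for b in VERTICAL_BRANCHES]
_BRANCH_ARM = {b.branch_id: b.arm for b in SEXUAL_BRANCHES + VERTICAL_BRANCHES}


def exit_frequency_table(allocations: Iterable[MohaAllocation]) -> pd.DataFrame:
    """Counts by exit branch and label (exit-frequency summary).

    One row per exit branch in tree order plus a total row per label;
    per-label totals equal the number classified with that label.
    """
    allocations = list(allocations)
    rows = []
    for label in ("sexual", "vertical"):
        label_allocs = [a for a in allocations if a.label == label]
        rows.append({"exit_branch": f"total_{label}", "label": label, "n": len(label_allocs)})
        for branch_id in _EXIT_ORDER:
            if _BRANCH_ARM[branch_id] != label:
                continue
            count = sum(1 for a in label_allocs if a.exit_branch == branch_id)
            rows.append({"exit_branch": branch_id, "label": label, "n": count})
    n_unclassified = sum(1 for a in allocations if a.label == "unclassified")
    rows.append({"exit_branch": "unclassified", "label": "unclassified", "n": n_unclassified})
    return pd.DataFrame(rows, columns=["exit_branch", "label", "n"])


def affirmatory_summary(
    allocations: Iterable[MohaAllocation],
    profiles: Iterable[HarmonizedProfile],
    config: TreeConfig = TreeConfig(),
) -> pd.DataFrame:
    """Per-arm mean (sample SD) of affirmatory counts + per-factor counts.

    Sample SD uses the n−1 denominator; an arm with a single allocation
    reports SD 0.0 and an empty arm is omitted with a logged notice.
    Per-factor rows give, for each enabled branch of the arm, the number
    and percentage of that arm's classified participants for whom the
    branch predicate is true (whether or not it was their exit).
    """
    allocations = list(allocations)
    by_pid = {p.participant_id: p for p in profiles}
    rows = []
    for label, branches in (("sexual", SEXUAL_BRANCHES), ("vertical", VERTICAL_BRANCHES)):
        members = [a for a in allocations if a.label == label]
        if not members:
            logger.info("affirmatory_summary: no %s allocations; row omitted", label)
            continue
        counts = [a.affirmatory_count for a in members]
        sd = stdev(counts) if len(counts) > 1 else 0.0
        rows.append(
            {
                "arm": label, "factor": "__arm_total__", "n": len(members),
                "pct": 100.0, "mean_affirmatory": mean(counts), "sd_affirmatory": sd,
            }
        )
        member_profiles = [by_pid[a.participant_id] for a in members if a.participant_id in by_pid]
        for b in branches:
            if not config.branch_enabled(b.branch_id):
                continue
            n_true = sum(1 for p in member_profiles if b.predicate(p, config))
            rows.append(
                {
                    "arm": label, "factor": b.branch_id, "n": n_true,
                    "pct": 100.0 * n_true / len(members),
                    "mean_affirmatory": None, "sd_affirmatory": None,
                }
            )
    return pd.DataFrame(
        rows, columns=["arm", "factor", "n", "pct", "mean_affirmatory", "sd_affirmatory"]
    )
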