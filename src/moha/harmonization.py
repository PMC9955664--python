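"""Collapse wave-level raw measures into per-participant derived factors.

Every boolean factor is the OR over available waves of its wave-level
indicator ("any wave" convention); ages are minimised across waves.
Factors whose inputs are missing at every wave are false with
availability marked ``unobserved`` — no imputation is performed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Optional

from .io_model import MedicalRecord, Participant, WaveRecord

logger = logging.getLogger(__name__)

__all__ = [
    "TreeConfig",
    "HarmonizedProfile",
    "ParentalHistory",
    "youngest_art_initiation_age",
    "detect_discordant_disclosure",
    "classify_parental_history",
    "harmonize",
    "harmonize_cohort",
]

#: parental-death causes presumed to be HIV/AIDS when undisclosed
PRESUMED_HIV_CAUSES = frozenset({"unknown", "illness", "poison"})

DEFAULT_CUTOFF_AGES = (10, 11, 12, 13, 14, 15)


@dataclass(frozen=True)
class TreeConfig:
    """Tunable constants for harmonization and the logic tree.

    ``seroconversion_to_death_years`` is a documentation constant: the
    ~10.2-year adult seroconversion-to-AIDS-death timeline is what
    justifies ``orphan_age_threshold`` = 10 (a parent dying of a
    presumed-HIV cause while the child was ≤10 would have been infected
    around the child's conception).

    ``enabled_branches`` of ``None`` enables every branch; the
    single-wave young-mothers variant disables S3/V3/V7 and forces the
    sexual gateway (see :func:`moha.logic_tree.mothers_tree_config`).
    """

    cutoff_ages: tuple[int, ...] = DEFAULT_CUTOFF_AGES
    art_rollout_year: int = 2005
    orphan_age_threshold: int = 10
    discordance_gap_years: int = 3
    first_test_age_threshold: int = 10
    seroconversion_to_death_years: float = 10.2
    enabled_branches: Optional[frozenset[str]] = None
    force_sexual_gateway: bool = False

    def __post_init__(self):
        if not self.cutoff_ages:
            raise ValueError("cutoff_ages must be non-empty")
        if any(b >= a for a, b in zip(self.cutoff_ages[1:], self.cutoff_ages)):
            raise ValueError("cutoff_ages must be strictly increasing")
        for name in (
            "orphan_age_threshold",
            "discordance_gap_years",
            "first_test_age_threshold",
            "seroconversion_to_death_years",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def branch_enabled(self, branch_id: str) -> bool:
        return self.enabled_branches is None or branch_id in self.enabled_branches


class ParentalHistory(NamedTuple):
    maternal_hiv_orphan: bool
    mother_on_art: bool
    maternal_orphan_le10_presumed: bool
    paternal_hiv_orphan_or_dad_art: bool
    paternal_orphan_le10_presumed: bool


#: factor names carried in the availability mask
FACTOR_NAMES = (
    "art_init_age",
    "sexual_debut_age",
    "ever_sexual_abuse",
    "discordant_disclosure",
    "consistent_unprotected_sex",
    "other_risky_behaviour",
    "hiv_status_aware",
    "first_hiv_test_age",
    "maternal_hiv_orphan",
    "mother_on_art",
    "maternal_orphan_le10_presumed",
    "paternal_hiv_orphan_or_dad_art",
    "paternal_orphan_le10_presumed",
    "cognitive_delay",
    "poor_physical_health",
)


@dataclass(frozen=True)
class HarmonizedProfile:
    """Cross-wave derived factors for one participant (classifier input)."""

    participant_id: str
    art_init_age: Optional[int] = None
    art_init_source: Optional[str] = None  # "medical" | "self_report"
    art_init_year: Optional[int] = None
    art_naive: bool = False
    sexual_debut_age: Optional[int] = None
    ever_sexual_activity: bool = False
    ever_sexual_abuse: bool = False
    discordant_disclosure: bool = False
    consistent_unprotected_sex: bool = False
    other_risky_behaviour: bool = False
    hiv_status_aware: bool = False
    first_hiv_test_age: Optional[int] = None
    maternal_hiv_orphan: bool = False
    mother_on_art: bool = False
    maternal_orphan_le10_presumed: bool = False
    paternal_hiv_orphan_or_dad_art: bool = False
    paternal_orphan_le10_presumed: bool = False
    cognitive_delay: bool = False
    poor_physical_health: bool = False
    factor_availability: dict[str, bool] = field(default_factory=dict)

    def observed(self, factor: str) -> bool:
        return self.factor_availability.get(factor, False)


def youngest_art_initiation_age(
    medical_record: Optional[MedicalRecord], wave_records: Iterable[WaveRecord]
) -> Optional[tuple[int, str]]:
    """Resolve ART initiation age with medical-record precedence.

    The clinic-file age wins when present (source ``"medical"``);
    otherwise the youngest non-missing self-reported age across waves is
    used (source ``"self_report"``).  Returns ``None`` when no source
    reports an age — absence is a valid outcome, not an error.
    """
    if medical_record is not None and medical_record.art_init_age_record is not None:
        return medical_record.art_init_age_record, "medical"
    ages = [r.art_init_age_selfreport for r in wave_records if r.art_init_age_selfreport is not None]
    if ages:
        return min(ages), "self_report"
    return None


def detect_discordant_disclosure(wave_records: Iterable[WaveRecord], gap: int = 3) -> bool:
    """True when wave-1 sexual-debut reporting is discordant with later waves.

    Rule (1): no debut age at wave 1 but a debut age reported at a later
    (ACASI) wave.  Rule (2): the wave-1 debut age exceeds a later-wave
    debut age by ``gap`` years or more.  Requires a wave-1 record and at
    least one later-wave record; otherwise returns False.
    """
    records = list(wave_records)
    wave1 = next((r for r in records if r.wave == 1), None)
    later = [r for r in records if r.wave > 1]
    if wave1 is None or not later:
        return False
    later_debuts = [r.sexual_debut_age for r in later if r.sexual_debut_age is not None]
    if wave1.sexual_debut_age is None:
        return bool(later_debuts)
    return any(wave1.sexual_debut_age - d >= gap for d in later_debuts)


def _resolve_death_age(records: list[WaveRecord], attr: str) -> Optional[int]:
    # wave-1 value preferred when duplicated (wave-1 is where it was asked)
    by_wave = sorted(records, key=lambda r: r.wave)
    for rec in by_wave:
        value = getattr(rec, attr)
        if value is not None:
            return value
    return None


def _parent_flags(
    records: list[WaveRecord],
    vital_attr: str,
    cause_attr: str,
    art_attr: str,
    death_age_attr: str,
    threshold: int,
) -> tuple[bool, bool, bool]:
    vitals = [(r.wave, getattr(r, vital_attr)) for r in records if getattr(r, vital_attr) is not None]
    statuses = {v for _, v in vitals}
    if statuses == {"alive", "dead"}:
        pid = records[0].participant_id if records else "?"
        logger.warning(
            "participant_id=%s: contradictory %s across waves; resolving to 'dead'",
            pid,
            vital_attr,
        )
    dead = "dead" in statuses
    causes = {getattr(r, cause_attr) for r in records if getattr(r, cause_attr) is not None}
    hiv_orphan = dead and "hiv_aids" in causes
    on_art = any(getattr(r, art_attr) for r in records if getattr(r, art_attr) is not None)
    death_age = _resolve_death_age(records, death_age_attr)
    presumed = (
        dead
        and not hiv_orphan
        and bool(causes & PRESUMED_HIV_CAUSES)
        and death_age is not None
        and death_age <= threshold
    )
    return hiv_orphan, on_art, presumed


def classify_parental_history(
    wave_records: Iterable[WaveRecord], orphan_age_threshold: int = 10
) -> ParentalHistory:
    """Derive the five parental-history flags from all waves.

    A parent dead of HIV/AIDS at any wave sets the HIV-orphan flag; a
    parent reported on ART or HIV-symptomatic at any wave sets the
    on-ART flag; death with an undisclosed/presumed cause (``unknown``,
    ``illness``, ``poison`` — never ``other``) while the participant was
    aged ``orphan_age_threshold`` or younger sets the presumed flag.
    Contradictory vital statuses resolve toward death with a logged
    warning (deaths are not retractable).
    """
    records = list(wave_records)
    m = _parent_flags(
        records, "mother_vital", "mother_death_cause", "mother_on_art_or_symptomatic",
        "age_at_mother_death", orphan_age_threshold,
    )
    f = _parent_flags(
        records, "father_vital", "father_death_cause", "father_on_art_or_symptomatic",
        "age_at_father_death", orphan_age_threshold,
    )
    return ParentalHistory(m[0], m[1], m[2], f[0], f[1])


def _any(records: list[WaveRecord], attr: str) -> bool:
    return any(getattr(r, attr) for r in records if getattr(r, attr) is not None)


def _observed(records: list[WaveRecord], *attrs: str) -> bool:
    return any(getattr(r, a) is not None for r in records for a in attrs)


def _min_age(records: list[WaveRecord], attr: str) -> Optional[int]:
    values = [getattr(r, attr) for r in records if getattr(r, attr) is not None]
    return min(values) if values else None


def harmonize(
    participant: Participant,
    wave_records: Iterable[WaveRecord],
    medical_record: Optional[MedicalRecord],
    config: TreeConfig = TreeConfig(),
) -> HarmonizedProfile:
    """Build the :class:`HarmonizedProfile` for one participant.

    For ``single_wave_sample`` participants the discordant-disclosure and
    both presumed-orphan-≤threshold factors are forced false with
    availability ``unobserved``: those branches need multi-wave or wave-1
    data that the single-wave sample lacks.
    """
    records = sorted(
        (r for r in wave_records if r.participant_id == participant.participant_id),
        key=lambda r: r.wave,
    )
    med = medical_record if (
        medical_record is not None and medical_record.participant_id == participant.participant_id
    ) else None

    art = youngest_art_initiation_age(med, records)
    art_init_age, art_source = art if art is not None else (None, None)
    art_init_year = (
        participant.birth_year + art_init_age if art_init_age is not None else None
    )
    explicit_on_art = any(r.art_naive is False for r in records)
    art_naive = art_init_age is None and not explicit_on_art

    debut = _min_age(records, "sexual_debut_age")
    parental = classify_parental_history(records, config.orphan_age_threshold)

    single = participant.single_wave_sample
    discordant = False if single else detect_discordant_disclosure(
        records, config.discordance_gap_years
    )

    availability = {
        "art_init_age": art_init_age is not None or _observed(records, "art_init_age_selfreport", "art_naive"),
        "sexual_debut_age": _observed(records, "sexual_debut_age"),
        "ever_sexual_abuse": _observed(records, "ever_sexual_abuse"),
        "discordant_disclosure": (not single) and _observed(records, "sexual_debut_age"),
        "consistent_unprotected_sex": _observed(records, "consistent_unprotected_sex"),
        "other_risky_behaviour": _observed(
            records, "transactional_sex", "multiple_partners", "partner_age_gap_5plus"
        ),
        "hiv_status_aware": _observed(records, "hiv_status_aware"),
        "first_hiv_test_age": _observed(records, "first_hiv_test_age"),
        "maternal_hiv_orphan": _observed(records, "mother_vital", "mother_death_cause"),
        "mother_on_art": _observed(records, "mother_on_art_or_symptomatic"),
        "maternal_orphan_le10_presumed": (not single)
        and _observed(records, "mother_death_cause", "age_at_mother_death"),
        "paternal_hiv_orphan_or_dad_art": _observed(
            records, "father_vital", "father_death_cause", "father_on_art_or_symptomatic"
        ),
        "paternal_orphan_le10_presumed": (not single)
        and _observed(records, "father_death_cause", "age_at_father_death"),
        "cognitive_delay": _observed(records, "cognitive_delay_indicator"),
        "poor_physical_health": _observed(records, "poor_physical_health"),
    }

    return HarmonizedProfile(
        participant_id=participant.participant_id,
        art_init_age=art_init_age,
        art_init_source=art_source,
        art_init_year=art_init_year,
        art_naive=art_naive,
        sexual_debut_age=debut,
        ever_sexual_activity=debut is not None,
        ever_sexual_abuse=_any(records, "ever_sexual_abuse"),
        discordant_disclosure=discordant,
        consistent_unprotected_sex=_any(records, "consistent_unprotected_sex"),
        other_risky_behaviour=(
            _any(records, "transactional_sex")
            or _any(records, "multiple_partners")
            or _any(records, "partner_age_gap_5plus")
        ),
        hiv_status_aware=_any(records, "hiv_status_aware"),
        first_hiv_test_age=_min_age(records, "first_hiv_test_age"),
        maternal_hiv_orphan=parental.maternal_hiv_orphan,
        mother_on_art=parental.mother_on_art,
        maternal_orphan_le10_presumed=False if single else parental.maternal_orphan_le10_presumed,
        paternal_hiv_orphan_or_dad_art=parental.paternal_hiv_orphan_or_dad_art,
        paternal_orphan_le10_presumed=False if single else parental.paternal_orphan_le10_presumed,
        cognitive_delay=_any(records, "cognitive_delay_indicator"),
        poor_physical_health=_any(records, "poor_physical_health"),
        factor_availability=availability,
    )


def harmonize_cohort(participants, wave_records, medical_records, config=TreeConfig()):
    """Harmonize every participant; returns a list of profiles in input order."""
    waves_by_pid: dict[str, list[WaveRecord]] = {}
    for rec in wave_records:
        waves_by_pid.setdefault(rec.participant_id, []).append(rec)
    med_by_pid = {m.participant_id: m for m in medical_records}
    return [
        harmonize(p, waves_by_pid.get(p.participant_id, []), med_by_pid.get(p.participant_id), config)
        for p in participants
    ]
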