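"""Raw data model and CSV I/O for per-participant, per-wave survey records.

Three input tables are consumed (participants, wave records, medical
records) and one allocation table is emitted.  All files are UTF-8,
comma-delimited CSV with a mandatory header row.  Missing values are
encoded as empty cells; booleans are serialized ``0``/``1``.  Missingness
is always distinguishable from ``False``/``0``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

__all__ = [
    "AGE_MIN",
    "AGE_MAX",
    "Participant",
    "WaveRecord",
    "MedicalRecord",
    "CohortValidationError",
    "read_cohort",
    "write_cohort",
    "write_allocations",
    "read_allocations",
]

AGE_MIN = 0
AGE_MAX = 25

VALID_SEX = frozenset({"female", "male"})
VALID_VITAL = frozenset({"alive", "dead"})
VALID_DEATH_CAUSE = frozenset({"hiv_aids", "unknown", "illness", "poison", "other"})
VALID_WAVES = frozenset({1, 2, 3})


class CohortValidationError(ValueError):
    """Raised when one or more rows violate the column dictionary.

    ``errors`` holds one human-readable message per offending cell/row,
    each naming the participant_id and column involved.
    """

    def __init__(self, errors: Sequence[str]):
        self.errors = list(errors)
        preview = "\n  ".join(self.errors[:20])
        more = "" if len(self.errors) <= 20 else f"\n  ... {len(self.errors) - 20} more"
        super().__init__(f"{len(self.errors)} validation error(s):\n  {preview}{more}")


@dataclass(frozen=True)
class Participant:
    """One study participant.

    ``single_wave_sample`` marks members of the young-mothers sample who
    were observed at wave 3 only; for them ``waves_present`` must equal
    ``{3}`` and ``is_mother`` must be true.
    """

    participant_id: str
    sex: str
    birth_year: int
    is_mother: bool = False
    single_wave_sample: bool = False
    waves_present: frozenset[int] = frozenset({1})
    rural_wave1: Optional[bool] = None
    rural_wave2: Optional[bool] = None
    rural_wave3: Optional[bool] = None


@dataclass(frozen=True)
class WaveRecord:
    """Raw self-reported measures for one participant at one wave."""

    participant_id: str
    wave: int
    sexual_debut_age: Optional[int] = None
    ever_sexual_abuse: Optional[bool] = None
    consistent_unprotected_sex: Optional[bool] = None
    transactional_sex: Optional[bool] = None
    multiple_partners: Optional[bool] = None
    partner_age_gap_5plus: Optional[bool] = None
    mother_vital: Optional[str] = None
    mother_death_cause: Optional[str] = None
    mother_on_art_or_symptomatic: Optional[bool] = None
    father_vital: Optional[str] = None
    father_death_cause: Optional[str] = None
    father_on_art_or_symptomatic: Optional[bool] = None
    age_at_mother_death: Optional[int] = None
    age_at_father_death: Optional[int] = None
    cognitive_delay_indicator: Optional[bool] = None
    poor_physical_health: Optional[bool] = None
    art_init_age_selfreport: Optional[int] = None
    first_hiv_test_age: Optional[int] = None
    hiv_status_aware: Optional[bool] = None
    art_naive: Optional[bool] = None


@dataclass(frozen=True)
class MedicalRecord:
    """Clinic-file ART initiation age for one participant (at most one)."""

    participant_id: str
    art_init_age_record: Optional[int] = None


# ---------------------------------------------------------------------------
# column dictionaries

_PARTICIPANT_BOOL = ("is_mother", "single_wave_sample", "rural_wave1", "rural_wave2", "rural_wave3")
_WAVE_BOOL = (
    "ever_sexual_abuse",
    "consistent_unprotected_sex",
    "transactional_sex",
    "multiple_partners",
    "partner_age_gap_5plus",
    "mother_on_art_or_symptomatic",
    "father_on_art_or_symptomatic",
    "cognitive_delay_indicator",
    "poor_physical_health",
    "hiv_status_aware",
    "art_naive",
)
_WAVE_AGE = (
    "sexual_debut_age",
    "age_at_mother_death",
    "age_at_father_death",
    "art_init_age_selfreport",
    "first_hiv_test_age",
)
_WAVE_CAT = {
    "mother_vital": VALID_VITAL,
    "father_vital": VALID_VITAL,
    "mother_death_cause": VALID_DEATH_CAUSE,
    "father_death_cause": VALID_DEATH_CAUSE,
}

PARTICIPANT_COLUMNS = tuple(f.name for f in fields(Participant))
WAVE_COLUMNS = tuple(f.name for f in fields(WaveRecord))
MEDICAL_COLUMNS = tuple(f.name for f in fields(MedicalRecord))
ALLOCATION_COLUMNS = (
    "participant_id",
    "label",
    "arm",
    "exit_branch",
    "switched",
    "affirmatory_count",
)


# ---------------------------------------------------------------------------
# cell parsers: every parser maps the empty string to None explicitly

def _parse_bool(raw: str, pid: str, col: str, errors: list[str]) -> Optional[bool]:
    if raw == "":
        return None
    low = raw.strip().lower()
    if low in ("1", "true"):
        return True
    if low in ("0", "false"):
        return False
    errors.append(f"participant_id={pid} column={col}: invalid boolean {raw!r} (use 0/1 or empty)")
    return None


def _parse_age(raw: str, pid: str, col: str, errors: list[str]) -> Optional[int]:
    if raw == "":
        return None
    try:
        value = int(raw)
    except ValueError:
        errors.append(f"participant_id={pid} column={col}: malformed age {raw!r} (not an integer)")
        return None
    if not (AGE_MIN <= value <= AGE_MAX):
        errors.append(
            f"participant_id={pid} column={col}: age {value} out of range [{AGE_MIN}, {AGE_MAX}]"
        )
        return None
    return value


def _parse_cat(raw: str, pid: str, col: str, allowed: frozenset, errors: list[str]) -> Optional[str]:
    if raw == "":
        return None
    if raw not in allowed:
        errors.append(
            f"participant_id={pid} column={col}: {raw!r} not in {sorted(allowed)}"
        )
        return None
    return raw


def _read_raw(path) -> pd.DataFrame:
    # dtype=str + keep_default_na=False gives full control of missingness:
    # an empty cell stays "" and never becomes NaN/0/False.
    return pd.read_csv(path, dtype=str, keep_default_na=False, na_filter=False)


def _warn_unknown(df: pd.DataFrame, known: Sequence[str], table: str) -> None:
    unknown = [c for c in df.columns if c not in known]
    if unknown:
        warnings.warn(f"{table}: ignoring unknown column(s) {unknown}", stacklevel=3)


# ---------------------------------------------------------------------------

def read_cohort(wave_csv_path, medical_csv_path, participants_csv_path):
    """Read and validate the three cohort tables.

    Parameters
    ----------
    wave_csv_path, medical_csv_path, participants_csv_path
        Paths to the wave-record, medical-record and participant CSVs.
        The medical CSV may be empty (header only); the pipeline then
        falls back to self-reported ART ages.

    Returns
    -------
    (participants, wave_records, medical_records)
        Lists of :class:`Participant`, :class:`WaveRecord` and
        :class:`MedicalRecord` with validated invariants.

    Raises
    ------
    CohortValidationError
        On malformed cells (row-level, naming participant and column),
        duplicate ``(participant_id, wave)`` pairs, duplicate participant
        ids, or referential/invariant violations.
    """
    errors: list[str] = []

    pdf = _read_raw(participants_csv_path)
    _warn_unknown(pdf, PARTICIPANT_COLUMNS, "participants")
    for col in ("participant_id", "sex", "birth_year"):
        if col not in pdf.columns:
            raise CohortValidationError([f"participants: required column {col!r} missing"])

    participants: list[Participant] = []
    seen_ids: set[str] = set()
    for row in pdf.itertuples(index=False):
        row = row._asdict()
        pid = row["participant_id"]
        if pid == "":
            errors.append("participants: empty participant_id")
            continue
        if pid in seen_ids:
            errors.append(f"participant_id={pid}: duplicate participant row")
            continue
        seen_ids.add(pid)
        sex = _parse_cat(row["sex"], pid, "sex", VALID_SEX, errors)
        try:
            birth_year = int(row["birth_year"])
        except ValueError:
            errors.append(f"participant_id={pid} column=birth_year: malformed year {row['birth_year']!r}")
            birth_year = 0
        bools = {
            c: _parse_bool(row.get(c, ""), pid, c, errors) for c in _PARTICIPANT_BOOL if c in row
        }
        waves_raw = row.get("waves_present", "")
        if waves_raw:
            try:
                waves = frozenset(int(w) for w in waves_raw.split(";"))
            except ValueError:
                errors.append(f"participant_id={pid} column=waves_present: malformed {waves_raw!r}")
                waves = frozenset()
            if waves and not waves <= VALID_WAVES:
                errors.append(f"participant_id={pid} column=waves_present: waves must be within {{1,2,3}}")
        else:
            waves = frozenset()
        participants.append(
            Participant(
                participant_id=pid,
                sex=sex or "female",
                birth_year=birth_year,
                is_mother=bool(bools.get("is_mother")),
                single_wave_sample=bool(bools.get("single_wave_sample")),
                waves_present=waves,
                rural_wave1=bools.get("rural_wave1"),
                rural_wave2=bools.get("rural_wave2"),
                rural_wave3=bools.get("rural_wave3"),
            )
        )

    wdf = _read_raw(wave_csv_path)
    _warn_unknown(wdf, WAVE_COLUMNS, "waves")
    for col in ("participant_id", "wave"):
        if col not in wdf.columns:
            raise CohortValidationError([f"waves: required column {col!r} missing"])

    wave_records: list[WaveRecord] = []
    seen_pw: set[tuple[str, int]] = set()
    for row in wdf.itertuples(index=False):
        row = row._asdict()
        pid = row["participant_id"]
        try:
            wave = int(row["wave"])
        except ValueError:
            errors.append(f"participant_id={pid} column=wave: malformed wave {row['wave']!r}")
            continue
        if wave not in VALID_WAVES:
            errors.append(f"participant_id={pid} column=wave: wave {wave} not in {{1,2,3}}")
            continue
        if (pid, wave) in seen_pw:
            errors.append(f"participant_id={pid} wave={wave}: duplicate (participant_id, wave)")
            continue
        seen_pw.add((pid, wave))
        kwargs: dict = {"participant_id": pid, "wave": wave}
        for col in _WAVE_AGE:
            kwargs[col] = _parse_age(row.get(col, ""), pid, col, errors)
        for col in _WAVE_BOOL:
            kwargs[col] = _parse_bool(row.get(col, ""), pid, col, errors)
        for col, allowed in _WAVE_CAT.items():
            kwargs[col] = _parse_cat(row.get(col, ""), pid, col, allowed, errors)
        wave_records.append(WaveRecord(**kwargs))

    mdf = _read_raw(medical_csv_path)
    _warn_unknown(mdf, MEDICAL_COLUMNS, "medical")
    if "participant_id" not in mdf.columns:
        raise CohortValidationError(["medical: required column 'participant_id' missing"])
    medical_records: list[MedicalRecord] = []
    seen_med: set[str] = set()
    for row in mdf.itertuples(index=False):
        row = row._asdict()
        pid = row["participant_id"]
        if pid in seen_med:
            errors.append(f"participant_id={pid}: more than one medical record")
            continue
        seen_med.add(pid)
        medical_records.append(
            MedicalRecord(
                participant_id=pid,
                art_init_age_record=_parse_age(
                    row.get("art_init_age_record", ""), pid, "art_init_age_record", errors
                ),
            )
        )

    # cross-table invariants
    by_pid: dict[str, set[int]] = {}
    for rec in wave_records:
        by_pid.setdefault(rec.participant_id, set()).add(rec.wave)
    fixed: list[Participant] = []
    for part in participants:
        observed = frozenset(by_pid.get(part.participant_id, set()))
        waves = part.waves_present or observed
        if not observed <= waves:
            errors.append(
                f"participant_id={part.participant_id}: wave rows {sorted(observed)} "
                f"outside declared waves_present {sorted(waves)}"
            )
        if not waves:
            errors.append(f"participant_id={part.participant_id}: waves_present empty and no wave rows")
        if part.single_wave_sample and (waves != frozenset({3}) or not part.is_mother):
            errors.append(
                f"participant_id={part.participant_id}: single_wave_sample requires "
                "waves_present == {3} and is_mother == 1"
            )
        fixed.append(
            part if part.waves_present else Participant(**{**_asdict(part), "waves_present": waves})
        )
    known = {p.participant_id for p in fixed}
    for rec in wave_records:
        if rec.participant_id not in known:
            errors.append(f"participant_id={rec.participant_id}: wave row without participant row")

    if errors:
        raise CohortValidationError(errors)
    return fixed, wave_records, medical_records


def _asdict(obj) -> dict:
    return {f.name: getattr(obj, f.name) for f in fields(obj)}


def _cell(value) -> str:
    if value is None:
        return ""
    if isinstance(value, bool):
        return "1" if value else "0"
    return str(value)


def write_cohort(participants, wave_records, medical_records, out_dir) -> dict[str, Path]:
    """Write the three cohort tables under ``out_dir``.

    Returns a mapping of table name to the written path.  Inverse of
    :func:`read_cohort` (round-trip safe).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "participants": out_dir / "participants.csv",
        "waves": out_dir / "waves.csv",
        "medical": out_dir / "medical.csv",
    }

    prows = []
    for p in participants:
        d = _asdict(p)
        d["waves_present"] = ";".join(str(w) for w in sorted(p.waves_present))
        prows.append({k: _cell(v) if k != "waves_present" else v for k, v in d.items()})
    pd.DataFrame(prows, columns=PARTICIPANT_COLUMNS).to_csv(paths["participants"], index=False)

    wrows = [{k: _cell(v) for k, v in _asdict(r).items()} for r in wave_records]
    pd.DataFrame(wrows, columns=WAVE_COLUMNS).to_csv(paths["waves"], index=False)

    mrows = [{k: _cell(v) for k, v in _asdict(r).items()} for r in medical_records]
    pd.DataFrame(mrows, columns=MEDICAL_COLUMNS).to_csv(paths["medical"], index=False)
    return paths


def write_allocations(allocations: Iterable, path) -> Path:
    """Write tree allocations to CSV (participant_id, label, arm, exit_branch,
    switched, affirmatory_count).

    Unclassified participants get label ``unclassified`` and an empty
    exit_branch cell.  The file re-reads losslessly via
    :func:`read_allocations`.
    """
    allocations = list(allocations)
    if not allocations:
        raise ValueError("allocations must be non-empty")
    rows = []
    for a in allocations:
        rows.append(
            {
                "participant_id": a.participant_id,
                "label": a.label,
                "arm": a.arm_entered,
                "exit_branch": a.exit_branch or "",
                "switched": "1" if a.switched else "0",
                "affirmatory_count": a.affirmatory_count,
            }
        )
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rows, columns=ALLOCATION_COLUMNS).to_csv(path, index=False)
    return path


def read_allocations(path):
    """Read an allocations CSV written by :func:`write_allocations`."""
    from .logic_tree import MohaAllocation  # deferred: avoids import cycle

    df = _read_raw(path)
    out = []
    for row in df.itertuples(index=False):
        row = row._asdict()
        out.append(
            MohaAllocation(
                participant_id=row["participant_id"],
                label=row["label"],
                arm_entered=row["arm"],
                exit_branch=row["exit_branch"] or None,
                switched=row["switched"] == "1",
                affirmatory_count=int(row["affirmatory_count"]),
            )
        )
    return out
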