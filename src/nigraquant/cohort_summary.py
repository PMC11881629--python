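"""Patient-level symptom status, symptom grouping, and the parkinsonism flag.

Excerpt-level assertions collapse to one status per (patient, symptom):
undetermined calls carry no information; a single "present" call makes the
symptom present; otherwise any "absent" call makes it absent; with no
informative call the status is "not available" and the patient drops out of
analyses of that symptom. Grouping terms aggregate member symptoms as "any
present"; the operational parkinsonism flag is bradykinesia together with
rigidity or rest tremor.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .record_abstraction import (
    ABSENT,
    PRESENT,
    Call,
    SymptomAssertion,
    SymptomDictionary,
)

__all__ = [
    "PatientProfile",
    "aggregate_symptom",
    "apply_grouping",
    "flag_parkinsonism",
    "build_profiles",
    "profiles_to_frame",
]

PRESENT_S = "present"
ABSENT_S = "absent"
NA_S = "NA"


@dataclass(frozen=True)
class PatientProfile:
    """Per-patient status for every dictionary symptom plus parkinsonism."""

    patient_id: str
    status: dict[str, str]
    parkinsonism: str = NA_S

    def __post_init__(self) -> None:
        for sid, st in self.status.items():
            if st not in (PRESENT_S, ABSENT_S, NA_S):
                raise ValueError(f"invalid status {st!r} for {sid}")


def aggregate_symptom(calls: Iterable[Call]) -> str:
    """Collapse assertion calls for one (patient, symptom) to a status.

    Order-invariant and idempotent: undetermined calls are ignored; any 1
    wins over any number of 0s; only-undetermined or empty lists give NA.
    """
    calls = list(calls)
    if any(c == PRESENT for c in calls):
        return PRESENT_S
    if any(c == ABSENT for c in calls):
        return ABSENT_S
    return NA_S


def apply_grouping(profile: PatientProfile, dictionary: SymptomDictionary) -> PatientProfile:
    """Add grouping-term statuses: present if any member is present, absent
    if every evaluated member is absent (and at least one was evaluated),
    NA otherwise."""
    status = dict(profile.status)
    for group, members in dictionary.groups().items():
        unknown = [m for m in members if m not in status]
        if unknown:
            raise KeyError(f"group {group!r} references unknown symptoms {unknown}")
        member_status = [status[m] for m in members]
        if any(s == PRESENT_S for s in member_status):
            status[group] = PRESENT_S
        elif any(s == ABSENT_S for s in member_status):
            status[group] = ABSENT_S
        else:
            status[group] = NA_S
    return PatientProfile(
        patient_id=profile.patient_id, status=status, parkinsonism=profile.parkinsonism
    )


def flag_parkinsonism(profile: PatientProfile) -> str:
    """Bradykinesia together with rigidity or rest tremor.

    Present when the conjunction holds; absent when the available statuses
    falsify it (no bradykinesia, or bradykinesia with both rigidity and
    rest tremor absent); NA when the record cannot decide either way.
    """
    brady = profile.status.get("bradykinesia", NA_S)
    rigid = profile.status.get("rigidity", NA_S)
    tremor = profile.status.get("rest_tremor", NA_S)
    if brady == PRESENT_S and (rigid == PRESENT_S or tremor == PRESENT_S):
        return PRESENT_S
    if brady == ABSENT_S:
        return ABSENT_S
    if brady == PRESENT_S and rigid == ABSENT_S and tremor == ABSENT_S:
        return ABSENT_S
    return NA_S


def build_profiles(
    assertions: Sequence[SymptomAssertion],
    dictionary: SymptomDictionary,
    patient_ids: Iterable[str] | None = None,
) -> list[PatientProfile]:
    """Aggregate excerpt-level assertions into one profile per patient.

    ``patient_ids`` optionally forces profiles (all-NA if unmentioned) for
    patients without a single excerpt, e.g. the full cohort manifest.
    """
    by_patient: dict[str, dict[str, list[Call]]] = {}
    for a in assertions:
        sid = a.excerpt.symptom_id
        pid = a.excerpt.patient_id
        by_patient.setdefault(pid, {}).setdefault(sid, []).append(a.call)
    ids = list(patient_ids) if patient_ids is not None else sorted(by_patient)
    profiles = []
    for pid in ids:
        calls = by_patient.get(pid, {})
        status = {
            sid: aggregate_symptom(calls.get(sid, [])) for sid in dictionary.symptom_ids
        }
        prof = PatientProfile(patient_id=pid, status=status)
        prof = apply_grouping(prof, dictionary)
        prof = PatientProfile(
            patient_id=pid, status=prof.status, parkinsonism=flag_parkinsonism(prof)
        )
        profiles.append(prof)
    return profiles


def profiles_to_frame(profiles: Sequence[PatientProfile]) -> pd.DataFrame:
    """One row per patient, one column per symptom, plus parkinsonism."""
    rows = []
    for p in profiles:
        row: dict[str, str] = {"patient_id": p.patient_id}
        row.update(p.status)
        row["parkinsonism"] = p.parkinsonism
        rows.append(row)
    return pd.DataFrame(rows).set_index("patient_id")
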