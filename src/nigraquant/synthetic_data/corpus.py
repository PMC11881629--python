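"""Synthetic clinical corpora with planted symptom mentions and PHI tokens.

Each patient receives a handful of plain-text documents made of neutral
filler sentences, PHI-like lines (titled names, dates, facility names), and
at most one planted mention per (patient, symptom): an affirmed, negated or
indeterminate templated sentence embedding one of the symptom's search
terms. The generator records excerpt-level truth (one row per planted
mention with its 0/1/undetermined call) and patient-level truth
(present/absent/NA per symptom plus the parkinsonism flag), so search,
classification and aggregation can each be scored exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..record_abstraction import (
    ABSENT,
    PRESENT,
    UNDETERMINED,
    SymptomDictionary,
    default_dictionary,
)

__all__ = ["ClinicalCorpusParams", "SyntheticCorpus", "generate_clinical_corpus"]

_AFFIRMED_TEMPLATES = (
    "{Term} was noted on examination.",
    "The patient exhibited {term} during the visit.",
    "Examination revealed {term} today.",
)
_NEGATED_TEMPLATES = (
    "No {term} was observed on examination.",
    "The patient denies {term}.",
    "Negative for {term} at this visit.",
)
_INDETERMINATE_TEMPLATES = (
    "{Term} could not be assessed at this visit.",
    "Possible {term} reported by the family.",
    "Family history of {term} was discussed.",
)

#: Filler sentences: deliberately free of every default dictionary term.
_FILLER = (
    "Routine follow-up visit completed.",
    "Vital signs were stable throughout the encounter.",
    "Medication list was reviewed and reconciled.",
    "Laboratory results were within normal limits.",
    "The care plan was discussed in detail.",
    "Follow-up appointment scheduled as needed.",
    "Diet and exercise counseling provided.",
    "Imaging reports were reviewed with the team.",
)

_SURNAMES = ("Smith", "Jones", "Garcia", "Chen", "Patel", "Olsen", "Murphy", "Kim")
_FACILITIES = ("Lakeside", "Riverview", "Hillcrest", "Maplewood")
_FACILITY_KINDS = ("Medical Center", "Hospital", "Clinic")


@dataclass(frozen=True)
class ClinicalCorpusParams:
    """Corpus size, mention mix and PHI density.

    ``p_affirmed``/``p_negated``/``p_indeterminate`` form a multinomial over
    mention types per (patient, symptom); the remainder is "no mention".
    ``phi_rate`` is the expected number of PHI-like lines per document.
    """

    n_patients: int = 10
    docs_per_patient: int = 3
    symptom_dictionary: SymptomDictionary | None = None
    p_affirmed: float = 0.25
    p_negated: float = 0.15
    p_indeterminate: float = 0.10
    phi_rate: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if self.docs_per_patient < 1:
            raise ValueError("docs_per_patient must be >= 1")
        probs = (self.p_affirmed, self.p_negated, self.p_indeterminate)
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValueError("mention probabilities must be in [0, 1]")
        if sum(probs) > 1.0 + 1e-12:
            raise ValueError("mention probabilities must sum to <= 1")
        if self.phi_rate < 0:
            raise ValueError("phi_rate must be >= 0")
        if self.symptom_dictionary is not None and not self.symptom_dictionary.entries:
            raise ValueError("symptom dictionary must be non-empty")

    def dictionary(self) -> SymptomDictionary:
        return self.symptom_dictionary or default_dictionary()


@dataclass(frozen=True)
class SyntheticCorpus:
    """Documents plus the two truth tables and the document manifest."""

    documents: dict[str, str]
    manifest: pd.DataFrame  # doc_id, patient_id
    excerpt_truth: pd.DataFrame  # patient_id, doc_id, symptom_id, line_index, term, call
    patient_truth: pd.DataFrame  # one row per patient, one column per symptom (+parkinsonism)
    phi_tokens: tuple[str, ...] = field(default=())

    @property
    def patient_ids(self) -> list[str]:
        return list(self.patient_truth.index)


def _mention_sentence(
    kind: str, term: str, rng: np.random.Generator
) -> str:
    pool = {
        "affirmed": _AFFIRMED_TEMPLATES,
        "negated": _NEGATED_TEMPLATES,
        "indeterminate": _INDETERMINATE_TEMPLATES,
    }[kind]
    tpl = pool[rng.integers(0, len(pool))]
    return tpl.format(term=term, Term=term[0].upper() + term[1:])


def _phi_line(rng: np.random.Generator, inventory: list[str]) -> str:
    name = _SURNAMES[rng.integers(0, len(_SURNAMES))]
    month = int(rng.integers(1, 13))
    day = int(rng.integers(1, 29))
    year = int(rng.integers(2005, 2023))
    date = f"{month:02d}/{day:02d}/{year}"
    facility = (
        f"{_FACILITIES[rng.integers(0, len(_FACILITIES))]} "
        f"{_FACILITY_KINDS[rng.integers(0, len(_FACILITY_KINDS))]}"
    )
    inventory.extend([f"Dr. {name}", date, facility])
    choice = rng.integers(0, 3)
    if choice == 0:
        return f"Seen by Dr. {name} on {date}."
    if choice == 1:
        return f"Transferred from {facility} on {date}."
    return f"Dr. {name} reviewed the chart at {facility}."


def generate_clinical_corpus(params: ClinicalCorpusParams) -> SyntheticCorpus:
    """Build the corpus; pure function of ``params`` (incl. seed).

    At most one mention is planted per (patient, symptom), in a uniformly
    chosen document of that patient. Patient truth per symptom is present
    for an affirmed mention, absent for a negated one, NA otherwise. The
    parkinsonism column applies the operational criterion (bradykinesia and
    either rigidity or rest tremor) to the planted statuses.
    """
    rng = np.random.default_rng(params.seed)
    dictionary = params.dictionary()
    symptoms = list(dictionary.symptom_ids)
    probs = np.array(
        [params.p_affirmed, params.p_negated, params.p_indeterminate], dtype=float
    )
    probs = np.append(probs, 1.0 - probs.sum())

    # doc -> list of mention sentences to weave in
    planned: dict[str, list[tuple[str, str, str]]] = {}  # doc -> (symptom, term, kind)
    manifest_rows = []
    patient_rows = {}
    mention_kind: dict[tuple[str, str], tuple[str, str, str]] = {}

    for p in range(params.n_patients):
        pid = f"P{p:04d}"
        doc_ids = [f"{pid}_D{d}" for d in range(params.docs_per_patient)]
        for did in doc_ids:
            manifest_rows.append({"doc_id": did, "patient_id": pid})
            planned[did] = []
        status = {}
        for sid in symptoms:
            kind_idx = rng.choice(4, p=probs)
            kind = ("affirmed", "negated", "indeterminate", "none")[kind_idx]
            if kind != "none":
                entry = dictionary.entries[sid]
                term = entry.search_terms[rng.integers(0, len(entry.search_terms))]
                did = doc_ids[rng.integers(0, len(doc_ids))]
                planned[did].append((sid, term, kind))
                mention_kind[(pid, sid)] = (did, term, kind)
            status[sid] = {"affirmed": "present", "negated": "absent"}.get(kind, "NA")
        patient_rows[pid] = status

    phi_inventory: list[str] = []
    documents: dict[str, str] = {}
    truth_rows = []
    for did, mentions in planned.items():
        pid = did.split("_")[0]
        lines: list[str] = []
        lines.append(_FILLER[rng.integers(0, len(_FILLER))])
        for _ in range(rng.poisson(params.phi_rate)):
            lines.append(_phi_line(rng, phi_inventory))
        for sid, term, kind in mentions:
            lines.append(_FILLER[rng.integers(0, len(_FILLER))])
            line_idx = len(lines)
            lines.append(_mention_sentence(kind, term, rng))
            call = {"affirmed": PRESENT, "negated": ABSENT, "indeterminate": UNDETERMINED}[kind]
            truth_rows.append(
                {
                    "patient_id": pid,
                    "doc_id": did,
                    "symptom_id": sid,
                    "line_index": line_idx,
                    "matched_term": term,
                    "call": call,
                }
            )
        lines.append(_FILLER[rng.integers(0, len(_FILLER))])
        documents[did] = "\n".join(lines)

    patient_truth = pd.DataFrame.from_dict(patient_rows, orient="index")
    patient_truth.index.name = "patient_id"
    patient_truth["parkinsonism"] = [
        _parkinsonism_truth(row) for _, row in patient_truth.iterrows()
    ]
    excerpt_truth = pd.DataFrame(
        truth_rows,
        columns=["patient_id", "doc_id", "symptom_id", "line_index", "matched_term", "call"],
    )
    return SyntheticCorpus(
        documents=documents,
        manifest=pd.DataFrame(manifest_rows, columns=["doc_id", "patient_id"]),
        excerpt_truth=excerpt_truth,
        patient_truth=patient_truth,
        phi_tokens=tuple(dict.fromkeys(phi_inventory)),
    )


def _parkinsonism_truth(status: pd.Series) -> str:
    """Operational criterion applied to planted statuses."""
    brady = status.get("bradykinesia", "NA")
    rig = status.get("rigidity", "NA")
    trem = status.get("rest_tremor", "NA")
    if brady == "present" and (rig == "present" or trem == "present"):
        return "present"
    if brady == "absent":
        return "absent"
    if brady == "present" and rig == "absent" and trem == "absent":
        return "absent"
    return "NA"
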