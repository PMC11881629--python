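"""Symptom mention search, de-identified excerpts, and assertion calls.

The abstraction pipeline mirrors manual chart review: search each document
for every symptom's term set, excerpt a three-line window around each hit,
redact patient-identifiable tokens, and decide for each excerpt whether the
symptom is present (1), absent (0) or undetermined. Classification is a
pluggable interface; the shipped default is an auditable rule engine with
clause-scoped negation, so the whole pipeline runs without any external
model. Classifiers are scored by accuracy and Cohen's κ over the three
categories.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence, Union

import numpy as np
import yaml

__all__ = [
    "ABSENT",
    "PRESENT",
    "UNDETERMINED",
    "SymptomDictionary",
    "SymptomEntry",
    "Excerpt",
    "SymptomAssertion",
    "ClassifierEval",
    "default_dictionary",
    "find_excerpts",
    "redact",
    "rule_classify",
    "evaluate_classifier",
]

ABSENT = 0
PRESENT = 1
UNDETERMINED = "undetermined"
Call = Union[int, str]
CATEGORIES: tuple[Call, ...] = (ABSENT, PRESENT, UNDETERMINED)


@dataclass(frozen=True)
class SymptomEntry:
    search_terms: tuple[str, ...]
    group: str | None = None

    def __post_init__(self) -> None:
        if not self.search_terms:
            raise ValueError("search term list must be non-empty")
        object.__setattr__(self, "search_terms", tuple(self.search_terms))


@dataclass(frozen=True)
class SymptomDictionary:
    """symptom_id → term set (+ optional grouping term)."""

    entries: Mapping[str, SymptomEntry]

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValueError("symptom dictionary must be non-empty")
        object.__setattr__(self, "entries", dict(self.entries))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SymptomDictionary":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls.from_mapping(raw)

    @classmethod
    def from_mapping(cls, raw: Mapping) -> "SymptomDictionary":
        entries = {
            sid: SymptomEntry(
                search_terms=tuple(spec["search_terms"]), group=spec.get("group")
            )
            for sid, spec in raw.items()
        }
        return cls(entries=entries)

    @property
    def symptom_ids(self) -> tuple[str, ...]:
        return tuple(self.entries)

    def groups(self) -> dict[str, list[str]]:
        """grouping term → member symptom ids."""
        out: dict[str, list[str]] = {}
        for sid, entry in self.entries.items():
            if entry.group:
                out.setdefault(entry.group, []).append(sid)
        return out


def default_dictionary() -> SymptomDictionary:
    """The shipped symptom dictionary (editable YAML packaged with the code)."""
    ref = resources.files("nigraquant.data").joinpath("symptoms.yaml")
    return SymptomDictionary.from_mapping(yaml.safe_load(ref.read_text()))


@dataclass(frozen=True)
class Excerpt:
    """A ≤3-line window around a matched term.

    ``line_index`` is the 0-based document line of the match;
    ``window_start`` the document line of the first window line. The matched
    term always occurs on line ``line_index - window_start`` of ``text``.
    """

    patient_id: str
    doc_id: str
    symptom_id: str
    matched_term: str
    line_index: int
    window_start: int
    text: str
    redacted: bool = False

    def matched_line(self) -> str:
        return self.text.split("\n")[self.line_index - self.window_start]


@dataclass(frozen=True)
class SymptomAssertion:
    excerpt: Excerpt
    call: Call

    def __post_init__(self) -> None:
        if self.call not in CATEGORIES:
            raise ValueError(f"call must be one of {CATEGORIES}")


Classifier = Callable[[Excerpt], SymptomAssertion]


def _term_pattern(term: str) -> re.Pattern:
    # Word-boundary match: no word character may abut either end of the term.
    return re.compile(rf"(?<!\w){re.escape(term)}(?!\w)", re.IGNORECASE)


def find_excerpts(
    document: str,
    dictionary: SymptomDictionary,
    patient_id: str = "",
    doc_id: str = "",
) -> list[Excerpt]:
    """Search a newline-delimited document for every symptom's term set.

    Matching is case-insensitive at word boundaries. For each matching line,
    the excerpt is that line plus one line above and one below (clamped at
    document edges). At most one excerpt is produced per (line, symptom)
    even when several of the symptom's terms match; the recorded term is the
    leftmost (ties: longest) match.
    """
    if not document:
        return []
    lines = document.split("\n")
    out: list[Excerpt] = []
    for i, line in enumerate(lines):
        for sid, entry in dictionary.entries.items():
            best: tuple[int, int, str] | None = None  # (start, -len, term)
            for term in entry.search_terms:
                m = _term_pattern(term).search(line)
                if m and (best is None or (m.start(), -len(term)) < best[:2]):
                    best = (m.start(), -len(term), term)
            if best is None:
                continue
            lo, hi = max(0, i - 1), min(len(lines), i + 2)
            out.append(
                Excerpt(
                    patient_id=patient_id,
                    doc_id=doc_id,
                    symptom_id=sid,
                    matched_term=best[2],
                    line_index=i,
                    window_start=lo,
                    text="\n".join(lines[lo:hi]),
                )
            )
    return out


#: Default PHI patterns: numeric and written dates, and titled person names.
DEFAULT_PHI_PATTERNS: tuple[str, ...] = (
    r"\b\d{1,2}[/-]\d{1,2}[/-]\d{2,4}\b",
    r"\b(?:January|February|March|April|May|June|July|August|September|"
    r"October|November|December)\s+\d{1,2},?\s+\d{4}\b",
    r"\b(?:Dr|Mr|Mrs|Ms|Prof)\.?\s+[A-Z][a-z]+(?:\s+[A-Z][a-z]+)?",
    r"\b[A-Z][a-z]+\s+(?:Medical Center|Hospital|Clinic|Nursing Home)\b",
)

REDACTION_TOKEN = "[REDACTED]"


def redact(excerpt: Excerpt, patterns: Sequence[str] | None = None) -> Excerpt:
    """Replace PHI-like spans with ``[REDACTED]``; the matched term survives.

    Idempotent: the replacement token matches none of the default patterns.
    """
    if patterns is None:
        patterns = DEFAULT_PHI_PATTERNS
    term_re = _term_pattern(excerpt.matched_term)
    text = excerpt.text
    for pat in patterns:
        def _sub(m: re.Match) -> str:
            # Never redact a span that contains the matched symptom term.
            if term_re.search(m.group(0)):
                return m.group(0)
            return REDACTION_TOKEN

        text = re.sub(pat, _sub, text)
    return replace(excerpt, text=text, redacted=True)


#: Cue inventories for the rule classifier.
_HEDGE_CUES = (
    "could not be assessed",
    "cannot be assessed",
    "unable to assess",
    "not assessed",
    "possible",
    "possibly",
    "family history of",
    "unclear whether",
    "question of",
)
_NEGATION_CUES = (
    "no",
    "not",
    "denies",
    "denied",
    "without",
    "negative for",
    "absence of",
    "free of",
    "never had",
)

_CLAUSE_SPLIT = re.compile(r"[;,]|\bbut\b", re.IGNORECASE)


def _contains_cue(text: str, cues: Iterable[str]) -> bool:
    low = text.lower()
    return any(re.search(rf"(?<!\w){re.escape(c)}(?!\w)", low) for c in cues)


def rule_classify(excerpt: Excerpt) -> SymptomAssertion:
    """Reference rule-based assertion call on the matched line.

    The matched line is split into clauses (on ';', ',' and 'but'); only the
    clause containing the term is inspected. Hedge / unassessable cues
    anywhere in the line yield ``undetermined``; otherwise a negation cue in
    the term's clause yields 0 (absent); otherwise 1 (present).
    """
    line = excerpt.matched_line()
    if _contains_cue(line, _HEDGE_CUES):
        return SymptomAssertion(excerpt=excerpt, call=UNDETERMINED)
    clause = line
    for part in _CLAUSE_SPLIT.split(line):
        if _term_pattern(excerpt.matched_term).search(part):
            clause = part
            break
    if _contains_cue(clause, _NEGATION_CUES):
        return SymptomAssertion(excerpt=excerpt, call=ABSENT)
    return SymptomAssertion(excerpt=excerpt, call=PRESENT)


@dataclass(frozen=True)
class ClassifierEval:
    """Agreement of classifier calls with reference labels (3 categories)."""

    n: int
    accuracy: float
    cohens_kappa: float
    confusion: np.ndarray = field(compare=False)

    @property
    def categories(self) -> tuple[Call, ...]:
        return CATEGORIES


def evaluate_classifier(
    calls: Sequence[Call], truth: Sequence[Call]
) -> ClassifierEval:
    """Accuracy and Cohen's κ of aligned call/truth sequences.

    κ = (p_o − p_e) / (1 − p_e), with expected agreement p_e from the
    row/column marginals of the 3×3 confusion matrix (truth rows,
    classifier columns). κ is 1.0 when agreement is perfect even though the
    denominator degenerates.
    """
    if len(calls) != len(truth):
        raise ValueError("calls and truth must be aligned 1:1")
    n = len(calls)
    if n == 0:
        raise ValueError("cannot evaluate zero excerpts")
    idx = {c: k for k, c in enumerate(CATEGORIES)}
    conf = np.zeros((3, 3), dtype=int)
    for c, t in zip(calls, truth):
        conf[idx[t], idx[c]] += 1
    p_o = float(np.trace(conf)) / n
    p_e = float(np.sum(conf.sum(axis=0) * conf.sum(axis=1))) / n**2
    kappa = 1.0 if p_e == 1.0 else (p_o - p_e) / (1.0 - p_e)
    return ClassifierEval(n=n, accuracy=p_o, cohens_kappa=kappa, confusion=conf)
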