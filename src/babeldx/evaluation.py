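"""Parse free-text differentials, ground names to disease ids, score.

The automatic evaluation has three stages:

1. **parse** — extract an ordered candidate list from the model's raw
   text (numbered or bulleted lists); a response with no extractable
   list, e.g. a refusal, becomes the NO_DIAGNOSIS outcome;
2. **ground** — map each candidate name to a disease id by exact match
   after normalization, first against primary labels, then against
   synonyms; ambiguous synonyms and unknown names are grounding
   failures, never guesses;
3. **score** — the case outcome is RANKED(k) at the smallest rank whose
   grounded id falls in the ground truth's subtype-equivalence class,
   NOT_RANKED when none does.

Grounding is English-only by design: the prompts instruct the model to
answer in English, so the index is built from English labels and
synonyms; candidates in other scripts simply fail to ground and are
counted as failures.
"""

from __future__ import annotations

import re
import unicodedata
from enum import Enum
from typing import Literal, Union

from pydantic import BaseModel, ConfigDict, model_validator

from .ontology import DiseaseGraph, SynonymScope, equivalence_class

GROUNDING_FAILURE = "GROUNDING_FAILURE"


class DifferentialList(BaseModel):
    model_config = ConfigDict(frozen=True)

    case_id: str
    language: str
    candidates: tuple[str, ...]  # rank 1..n, in order

    @model_validator(mode="after")
    def _nonempty_candidates(self) -> "DifferentialList":
        if not self.candidates or any(not c for c in self.candidates):
            raise ValueError("candidates must be non-empty strings")
        return self


class GroundedEntry(BaseModel):
    model_config = ConfigDict(frozen=True)

    rank: int
    grounding: str  # CURIE or GROUNDING_FAILURE
    raw: str


class GroundedDifferential(BaseModel):
    model_config = ConfigDict(frozen=True)

    case_id: str
    entries: tuple[GroundedEntry, ...]


class Outcome(str, Enum):
    RANKED = "RANKED"
    NOT_RANKED = "NOT_RANKED"
    NO_DIAGNOSIS = "NO_DIAGNOSIS"


class CaseResult(BaseModel):
    model_config = ConfigDict(frozen=True)

    case_id: str
    language: str
    outcome: Outcome
    rank: int | None = None  # set iff outcome is RANKED
    n_candidates: int = 0
    n_grounding_failures: int = 0

    @model_validator(mode="after")
    def _invariants(self) -> "CaseResult":
        if self.outcome is Outcome.RANKED:
            if self.rank is None or not 1 <= self.rank <= self.n_candidates:
                raise ValueError("RANKED requires 1 <= rank <= n_candidates")
        elif self.rank is not None:
            raise ValueError("rank only meaningful for RANKED outcomes")
        if self.outcome is Outcome.NO_DIAGNOSIS and self.n_candidates != 0:
            raise ValueError("NO_DIAGNOSIS implies zero candidates")
        return self


# --- response parsing ------------------------------------------------------

# "1. Foo", "2) Foo", "3 - Foo", "4: Foo"
_NUMBERED_RE = re.compile(r"^\s*(\d+)\s*[.):\-]\s*(.+)$")
_BULLET_RE = re.compile(r"^\s*[-*•]\s+(.+)$")
# trailing parenthetical annotation, e.g. "(FBN1)" gene symbols
_TRAILING_PAREN_RE = re.compile(r"\s*[(（][^()（）]*[)）]\s*$")


def _clean_candidate(text: str) -> str:
    text = text.strip().strip(".,;:。、").strip()
    text = _TRAILING_PAREN_RE.sub("", text)
    return text.strip().strip(".,;:。、").strip()


def parse_response(
    raw_text: str, *, case_id: str = "", language: str = ""
) -> DifferentialList | Literal["NO_DIAGNOSIS"]:
    """Extract the ranked candidate list from a raw model response.

    Numbered lines win over bullets when both appear; ranks follow line
    order and are not capped (the top-10 cap is an aggregation-time
    policy, not a parsing one). Returns the string ``"NO_DIAGNOSIS"``
    when no list can be extracted — that includes refusals and empty
    responses.
    """
    numbered: list[str] = []
    bulleted: list[str] = []
    for line in raw_text.splitlines():
        m = _NUMBERED_RE.match(line)
        if m:
            cand = _clean_candidate(m.group(2))
            if cand:
                numbered.append(cand)
            continue
        m = _BULLET_RE.match(line)
        if m:
            cand = _clean_candidate(m.group(1))
            if cand:
                bulleted.append(cand)
    candidates = numbered if numbered else bulleted
    if not candidates:
        return "NO_DIAGNOSIS"
    return DifferentialList(
        case_id=case_id, language=language, candidates=tuple(candidates)
    )


# --- name normalization and grounding --------------------------------------

_PUNCT_RE = re.compile(r"[^\w\s]", re.UNICODE)
_WS_RE = re.compile(r"\s+")


def normalize_name(s: str) -> str:
    """Canonical form for exact-match grounding.

    Compatibility-decomposed Unicode, case-folded, punctuation replaced
    by spaces, whitespace collapsed, a leading/trailing English article
    dropped. Idempotent.
    """
    s = unicodedata.normalize("NFKC", s)
    s = s.casefold()
    s = _PUNCT_RE.sub(" ", s)
    s = _WS_RE.sub(" ", s).strip()
    words = s.split(" ")
    if words and words[0] == "the":
        words = words[1:]
    if words and words[-1] == "the":
        words = words[:-1]
    return " ".join(words)


class GroundingIndex:
    """Exact-match index over normalized labels and synonyms.

    Primary labels always win; a synonym shared by several diseases is
    recorded as ambiguous and grounds nothing. ``exact_only`` restricts
    the synonym index to EXACT-scope synonyms.
    """

    def __init__(self, graph: DiseaseGraph, *, exact_only: bool = False):
        self.graph = graph
        self._labels: dict[str, str] = {}
        self._synonyms: dict[str, str] = {}
        self.ambiguous: set[str] = set()
        for term in graph.terms.values():
            self._labels[normalize_name(term.label)] = term.id
        for term in graph.terms.values():
            for syn, scope in term.synonyms:
                if exact_only and scope is not SynonymScope.EXACT:
                    continue
                key = normalize_name(syn)
                if key in self._labels:
                    continue  # label matches take precedence anyway
                if key in self._synonyms and self._synonyms[key] != term.id:
                    self.ambiguous.add(key)
                else:
                    self._synonyms[key] = term.id

    def lookup(self, candidate: str) -> str:
        key = normalize_name(candidate)
        if key in self._labels:
            return self._labels[key]
        if key in self.ambiguous:
            return GROUNDING_FAILURE
        return self._synonyms.get(key, GROUNDING_FAILURE)


def ground(
    candidate: str,
    graph: DiseaseGraph | GroundingIndex,
    *,
    exact_only: bool = False,
) -> str:
    """Ground one candidate name; returns a CURIE or GROUNDING_FAILURE.

    Accepts a prebuilt :class:`GroundingIndex` to amortize index
    construction across a whole run.
    """
    index = (
        graph
        if isinstance(graph, GroundingIndex)
        else GroundingIndex(graph, exact_only=exact_only)
    )
    return index.lookup(candidate)


def ground_differential(
    d: DifferentialList, index: GroundingIndex
) -> GroundedDifferential:
    entries = tuple(
        GroundedEntry(rank=i, grounding=index.lookup(c), raw=c)
        for i, c in enumerate(d.candidates, start=1)
    )
    return GroundedDifferential(case_id=d.case_id, entries=entries)


def score_case(
    g: Union[GroundedDifferential, Literal["NO_DIAGNOSIS"]],
    truth: str,
    graph: DiseaseGraph,
    *,
    language: str = "",
    case_id: str | None = None,
) -> CaseResult:
    """Score one grounded differential against the ground truth.

    Any member of the truth's equivalence class (the clinical disease or
    any of its genetic subtypes) counts as correct; the outcome rank is
    the smallest matching rank. Grounding failures never match.
    """
    truth_class = equivalence_class(truth, graph)  # raises UnknownDiseaseError
    if g == "NO_DIAGNOSIS":
        return CaseResult(
            case_id=case_id or "",
            language=language,
            outcome=Outcome.NO_DIAGNOSIS,
        )
    assert isinstance(g, GroundedDifferential)
    n_failures = sum(1 for e in g.entries if e.grounding == GROUNDING_FAILURE)
    for entry in g.entries:
        if entry.grounding != GROUNDING_FAILURE and entry.grounding in truth_class:
            return CaseResult(
                case_id=g.case_id,
                language=language,
                outcome=Outcome.RANKED,
                rank=entry.rank,
                n_candidates=len(g.entries),
                n_grounding_failures=n_failures,
            )
    return CaseResult(
        case_id=g.case_id,
        language=language,
        outcome=Outcome.NOT_RANKED,
        n_candidates=len(g.entries),
        n_grounding_failures=n_failures,
    )


def evaluate_response(
    raw_text: str,
    truth: str,
    graph: DiseaseGraph,
    index: GroundingIndex | None = None,
    *,
    case_id: str = "",
    language: str = "",
) -> CaseResult:
    """Convenience: parse → ground → score in one call."""
    if index is None:
        index = GroundingIndex(graph)
    parsed = parse_response(raw_text, case_id=case_id, language=language)
    if parsed == "NO_DIAGNOSIS":
        return score_case(
            "NO_DIAGNOSIS", truth, graph, language=language, case_id=case_id
        )
    return score_case(
        ground_differential(parsed, index), truth, graph, language=language
    )


def grounding_failure_rate(results: list[CaseResult]) -> float:
    """Item-level failure fraction: failed items / all candidate items.

    Duplicated candidate strings count once per occurrence. Empty input
    (or zero candidates overall) yields 0.0 rather than dividing by
    zero.
    """
    total = sum(r.n_candidates for r in results)
    if total == 0:
        return 0.0
    return sum(r.n_grounding_failures for r in results) / total
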