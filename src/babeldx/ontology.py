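"""Phenotype vocabulary with translations, and the disease graph.

Two ontology facts drive the whole benchmark:

* the multilingual lexicon — which HPO terms have human-confirmed
  translations in which languages — determines which cases are even
  eligible (a case enters the cohort only if *every* one of its terms,
  observed and excluded, is translated in all eight non-English
  languages);
* the disease graph's subtype links define diagnostic equivalence — a
  clinical disease and any of its genetic subtypes count as the same
  answer (e.g. Loeys-Dietz syndrome and its six genetic subforms).

The subtype relation is deliberately single-level: each genetic subtype
points at its clinical-disease group head. Deeper disease hierarchy is
out of scope for scoring.
"""

from __future__ import annotations

import csv
import io
import json
from enum import Enum
from pathlib import Path

from pydantic import BaseModel, ConfigDict, field_validator, model_validator

from .errors import (
    EncodingError,
    FormatError,
    MissingTranslationError,
    UnknownDiseaseError,
)
from .schema_io import CaseVignette

#: The nine study languages (ISO-639-1).
LANGUAGES: tuple[str, ...] = ("en", "zh", "cs", "nl", "de", "it", "ja", "es", "tr")

#: The eight languages whose translations gate cohort membership.
NON_ENGLISH: tuple[str, ...] = tuple(c for c in LANGUAGES if c != "en")


class SynonymScope(str, Enum):
    EXACT = "EXACT"
    RELATED = "RELATED"


class OntologyTerm(BaseModel):
    model_config = ConfigDict(frozen=True)

    id: str
    label: str
    synonyms: tuple[tuple[str, SynonymScope], ...] = ()
    parents: tuple[str, ...] = ()

    @field_validator("label")
    @classmethod
    def _nonempty(cls, v: str) -> str:
        if not v:
            raise ValueError("label must be non-empty")
        return v

    @model_validator(mode="after")
    def _no_self_parent(self) -> "OntologyTerm":
        if self.id in self.parents:
            raise ValueError(f"{self.id} lists itself as a parent")
        return self


class MultilingualLexicon(BaseModel):
    """(term id, language) → translated labels.

    English labels come from the ontology itself, so an ``en`` entry is
    required for every term the lexicon knows about.
    """

    model_config = ConfigDict(frozen=True)

    entries: dict[tuple[str, str], tuple[str, ...]]
    languages: tuple[str, ...]

    @model_validator(mode="after")
    def _english_everywhere(self) -> "MultilingualLexicon":
        term_ids = {tid for tid, _lang in self.entries}
        missing = [t for t in sorted(term_ids) if (t, "en") not in self.entries]
        if missing:
            raise ValueError(f"terms without an English label: {missing[:5]}")
        return self

    def lookup(self, term_id: str, language: str) -> tuple[str, ...]:
        return self.entries.get((term_id, language), ())


class DiseaseGraph(BaseModel):
    """Disease terms plus the genetic-subtype → group-head link map."""

    model_config = ConfigDict(frozen=True)

    terms: dict[str, OntologyTerm]
    subtype_links: dict[str, str]

    @model_validator(mode="after")
    def _links_well_formed(self) -> "DiseaseGraph":
        for sub, head in self.subtype_links.items():
            if sub not in self.terms or head not in self.terms:
                raise ValueError(f"subtype link {sub}→{head} has unknown endpoint")
            if sub == head:
                raise ValueError(f"subtype link {sub} points at itself")
            if head in self.subtype_links:
                raise ValueError(
                    f"group head {head} is itself a subtype: links must be single-level"
                )
        return self

    def __contains__(self, disease_id: str) -> bool:
        return disease_id in self.terms


def load_lexicon(tsv_text: str | bytes) -> MultilingualLexicon:
    """Ingest a three-column translation table.

    Columns (header required): ``term_id``, ``language_code``,
    ``translated_label``. Multi-valued entries accumulate in row order;
    exact duplicate rows are dropped.
    """
    if isinstance(tsv_text, bytes):
        try:
            tsv_text = tsv_text.decode("utf-8")
        except UnicodeDecodeError as exc:
            raise EncodingError(f"lexicon TSV is not valid UTF-8: {exc}") from exc
    reader = csv.reader(io.StringIO(tsv_text), delimiter="\t")
    try:
        header = next(reader)
    except StopIteration:
        raise FormatError("empty lexicon TSV") from None
    if [h.strip() for h in header] != ["term_id", "language_code", "translated_label"]:
        raise FormatError(
            "lexicon TSV header must be: term_id, language_code, translated_label"
        )
    entries: dict[tuple[str, str], list[str]] = {}
    languages: set[str] = set()
    for lineno, row in enumerate(reader, start=2):
        if not row or (len(row) == 1 and not row[0].strip()):
            continue  # blank line
        if len(row) != 3:
            raise FormatError(f"line {lineno}: expected 3 columns, got {len(row)}")
        term_id, lang, label = (c.strip() for c in row)
        languages.add(lang)
        labels = entries.setdefault((term_id, lang), [])
        if label not in labels:
            labels.append(label)
    return MultilingualLexicon(
        entries={k: tuple(v) for k, v in entries.items()},
        languages=tuple(sorted(languages)),
    )


def dump_lexicon(lexicon: MultilingualLexicon) -> str:
    """Inverse of :func:`load_lexicon` (row order: term, then language)."""
    out = io.StringIO()
    writer = csv.writer(out, delimiter="\t", lineterminator="\n")
    writer.writerow(["term_id", "language_code", "translated_label"])
    for (term_id, lang), labels in sorted(lexicon.entries.items()):
        for label in labels:
            writer.writerow([term_id, lang, label])
    return out.getvalue()


def translate_term(
    term_id: str, language: str, lexicon: MultilingualLexicon
) -> str:
    """First translated label for (term, language).

    Raises :class:`MissingTranslationError` when absent — callers use
    that signal for cohort filtering, it is not fatal.
    """
    labels = lexicon.lookup(term_id, language)
    if not labels:
        raise MissingTranslationError(term_id, language)
    return labels[0]


def has_full_translation(
    v: CaseVignette,
    lexicon: MultilingualLexicon,
    languages: tuple[str, ...] = NON_ENGLISH,
) -> bool:
    """True iff every feature term (observed AND excluded) is translated
    in every requested language.

    The default language set is the eight non-English study languages,
    which is exactly the corpus-restriction rule: a case is analyzable
    only when all of its terms exist in all eight translations.
    """
    return all(
        lexicon.lookup(f.term_id, lang)
        for f in v.features
        for lang in languages
    )


def filter_cohort(
    vignettes: list[CaseVignette],
    lexicon: MultilingualLexicon,
    languages: tuple[str, ...] = NON_ENGLISH,
) -> list[CaseVignette]:
    """Restrict a cohort to fully-translated cases (order preserved)."""
    return [v for v in vignettes if has_full_translation(v, lexicon, languages)]


def equivalence_class(disease_id: str, graph: DiseaseGraph) -> frozenset[str]:
    """All disease ids that count as the same diagnosis.

    The class is {group head} ∪ {every subtype of that head}; a disease
    with no subtype relations is its own singleton class.
    """
    if disease_id not in graph.terms:
        raise UnknownDiseaseError(disease_id)
    head = graph.subtype_links.get(disease_id, disease_id)
    members = {head}
    members.update(
        sub for sub, h in graph.subtype_links.items() if h == head
    )
    return frozenset(members)


def load_disease_graph(json_text: str) -> DiseaseGraph:
    """Load the disease-graph JSON dialect.

    Shape: ``{"terms": [{"id", "label", "synonyms": [[label, scope]...],
    "parents": [...]}, ...], "subtype_links": [[subtype, head], ...]}``.
    """
    try:
        doc = json.loads(json_text)
    except json.JSONDecodeError as exc:
        raise FormatError(f"disease graph is not valid JSON: {exc}") from exc
    if not isinstance(doc, dict) or "terms" not in doc or "subtype_links" not in doc:
        raise FormatError("disease graph JSON needs 'terms' and 'subtype_links'")
    terms: dict[str, OntologyTerm] = {}
    for tdoc in doc["terms"]:
        term = OntologyTerm(
            id=tdoc["id"],
            label=tdoc["label"],
            synonyms=tuple(
                (s[0], SynonymScope(s[1])) for s in tdoc.get("synonyms", ())
            ),
            parents=tuple(tdoc.get("parents", ())),
        )
        if term.id in terms:
            raise FormatError(f"duplicate disease id {term.id}")
        terms[term.id] = term
    links = {sub: head for sub, head in doc["subtype_links"]}
    try:
        return DiseaseGraph(terms=terms, subtype_links=links)
    except ValueError as exc:
        raise FormatError(str(exc)) from exc


def dump_disease_graph(graph: DiseaseGraph) -> str:
    doc = {
        "terms": [
            {
                "id": t.id,
                "label": t.label,
                "synonyms": [[s, scope.value] for s, scope in t.synonyms],
                "parents": list(t.parents),
            }
            for t in sorted(graph.terms.values(), key=lambda t: t.id)
        ],
        "subtype_links": sorted(graph.subtype_links.items()),
    }
    return json.dumps(doc, indent=2, ensure_ascii=False)
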