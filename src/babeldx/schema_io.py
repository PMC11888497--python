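"""Read, validate and write the phenopacket-subset JSON dialect.

One patient is a :class:`CaseVignette`: subject demographics, an ordered
list of observed/excluded HPO phenotype terms, and the curated diagnosis.
The dialect is a strict subset of the GA4GH Phenopacket Schema v2 — only
the fields the prompting and scoring stages consume (age, sex, features
with optional onset, diagnosis). Unknown fields are ignored with a logged
warning so real phenopackets still load.

The diagnosis is carried for scoring but must never reach a prompt; the
prompt factory enforces that, this layer merely preserves it.
"""

from __future__ import annotations

import json
import logging
import re
from enum import Enum
from pathlib import Path
from typing import Iterable

from pydantic import BaseModel, ConfigDict, field_validator, model_validator

from ._duration import is_valid_duration
from .errors import CurieError, EmptyCohortError, SchemaError

logger = logging.getLogger(__name__)

_HP_CURIE_RE = re.compile(r"^HP:\d{7}$")
_CURIE_RE = re.compile(r"^[A-Za-z][A-Za-z0-9.]*:\S+$")


class Sex(str, Enum):
    MALE = "MALE"
    FEMALE = "FEMALE"
    OTHER = "OTHER"
    UNKNOWN = "UNKNOWN"


class Subject(BaseModel):
    """Patient demographics: an opaque id, sex, and an ISO-8601 age."""

    model_config = ConfigDict(frozen=True)

    id: str
    sex: Sex = Sex.UNKNOWN
    age: str | None = None  # ISO-8601 duration, kept verbatim

    @field_validator("age")
    @classmethod
    def _age_is_iso_duration(cls, v: str | None) -> str | None:
        if v is not None and not is_valid_duration(v):
            raise ValueError(f"age is not a valid ISO-8601 duration: {v!r}")
        return v


class PhenotypicFeature(BaseModel):
    """One observed or excluded phenotype term, with optional onset.

    ``onset`` is either an ISO-8601 duration (age at onset) or an
    onset-class CURIE such as HP:0003577 (congenital onset).
    """

    model_config = ConfigDict(frozen=True)

    term_id: str
    excluded: bool = False
    onset: str | None = None

    @field_validator("term_id")
    @classmethod
    def _valid_hp_curie(cls, v: str) -> str:
        if not _HP_CURIE_RE.match(v):
            raise CurieError(f"malformed HPO CURIE: {v!r}")
        return v

    @field_validator("onset")
    @classmethod
    def _valid_onset(cls, v: str | None) -> str | None:
        if v is None:
            return v
        if is_valid_duration(v) or _CURIE_RE.match(v):
            return v
        raise ValueError(f"onset is neither ISO-8601 duration nor CURIE: {v!r}")


class CaseDiagnosis(BaseModel):
    """Curated ground-truth disease; resolvability against a graph is
    checked at scoring time, not here.

    ``onset`` is the disease-level age of onset (ISO-8601 duration or an
    onset-class CURIE), distinct from per-feature onsets.
    """

    model_config = ConfigDict(frozen=True)

    disease_id: str
    label: str
    onset: str | None = None

    @field_validator("disease_id")
    @classmethod
    def _valid_curie(cls, v: str) -> str:
        if not _CURIE_RE.match(v):
            raise CurieError(f"malformed disease CURIE: {v!r}")
        return v

    @field_validator("onset")
    @classmethod
    def _valid_onset(cls, v: str | None) -> str | None:
        if v is None or is_valid_duration(v) or _CURIE_RE.match(v):
            return v
        raise ValueError(f"onset is neither ISO-8601 duration nor CURIE: {v!r}")


class CaseVignette(BaseModel):
    model_config = ConfigDict(frozen=True)

    id: str
    subject: Subject
    features: tuple[PhenotypicFeature, ...]
    diagnosis: CaseDiagnosis

    @model_validator(mode="after")
    def _invariants(self) -> "CaseVignette":
        if not any(not f.excluded for f in self.features):
            raise ValueError("vignette needs at least one observed feature")
        ids = [f.term_id for f in self.features]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate feature term_ids within one case")
        return self

    @property
    def observed(self) -> tuple[PhenotypicFeature, ...]:
        return tuple(f for f in self.features if not f.excluded)

    @property
    def excluded_features(self) -> tuple[PhenotypicFeature, ...]:
        return tuple(f for f in self.features if f.excluded)

    def term_ids(self) -> tuple[str, ...]:
        """All feature term ids, observed and excluded, in order."""
        return tuple(f.term_id for f in self.features)


_KNOWN_TOP = {"id", "subject", "features", "diagnosis"}
_KNOWN_SUBJECT = {"id", "sex", "age"}
_KNOWN_FEATURE = {"term_id", "excluded", "onset"}
_KNOWN_DIAGNOSIS = {"disease_id", "label", "onset"}


def _warn_unknown(fields: Iterable[str], known: set[str], where: str) -> None:
    unknown = sorted(set(fields) - known)
    if unknown:
        logger.warning("ignoring unknown %s fields: %s", where, ", ".join(unknown))


def read_vignette(json_text: str) -> CaseVignette:
    """Parse one vignette from its JSON representation.

    Unknown schema fields are dropped with a logged warning; missing
    required sections raise :class:`SchemaError`, malformed identifiers
    :class:`CurieError`.
    """
    doc = json.loads(json_text)
    if not isinstance(doc, dict):
        raise SchemaError("vignette document must be a JSON object")
    for key in ("subject", "features", "diagnosis"):
        if key not in doc:
            raise SchemaError(f"vignette missing required field {key!r}")
    if not isinstance(doc["features"], list):
        raise SchemaError("'features' must be a JSON array")

    _warn_unknown(doc, _KNOWN_TOP, "vignette")
    subject_doc = doc["subject"]
    if not isinstance(subject_doc, dict):
        raise SchemaError("'subject' must be a JSON object")
    _warn_unknown(subject_doc, _KNOWN_SUBJECT, "subject")
    diagnosis_doc = doc["diagnosis"]
    if not isinstance(diagnosis_doc, dict):
        raise SchemaError("'diagnosis' must be a JSON object")
    _warn_unknown(diagnosis_doc, _KNOWN_DIAGNOSIS, "diagnosis")

    features = []
    for i, fdoc in enumerate(doc["features"]):
        if not isinstance(fdoc, dict):
            raise SchemaError(f"feature #{i} is not a JSON object")
        _warn_unknown(fdoc, _KNOWN_FEATURE, "feature")
        try:
            features.append(
                PhenotypicFeature(
                    **{k: v for k, v in fdoc.items() if k in _KNOWN_FEATURE}
                )
            )
        except CurieError:
            raise
        except (TypeError, ValueError) as exc:
            raise SchemaError(f"invalid feature #{i}: {exc}") from exc

    try:
        return CaseVignette(
            id=str(doc.get("id", "")),
            subject=Subject(
                **{k: v for k, v in subject_doc.items() if k in _KNOWN_SUBJECT}
            ),
            features=tuple(features),
            diagnosis=CaseDiagnosis(
                **{k: v for k, v in diagnosis_doc.items() if k in _KNOWN_DIAGNOSIS}
            ),
        )
    except CurieError:
        raise
    except (TypeError, ValueError) as exc:
        raise SchemaError(str(exc)) from exc


def write_vignette(v: CaseVignette, *, indent: int | None = 2) -> str:
    """Serialize a vignette; ``read_vignette`` of the result is identity."""
    doc = {
        "id": v.id,
        "subject": {"id": v.subject.id, "sex": v.subject.sex.value},
        "features": [],
        "diagnosis": {
            "disease_id": v.diagnosis.disease_id,
            "label": v.diagnosis.label,
        },
    }
    if v.diagnosis.onset is not None:
        doc["diagnosis"]["onset"] = v.diagnosis.onset
    if v.subject.age is not None:
        doc["subject"]["age"] = v.subject.age
    for f in v.features:
        fdoc: dict = {"term_id": f.term_id, "excluded": f.excluded}
        if f.onset is not None:
            fdoc["onset"] = f.onset
        doc["features"].append(fdoc)
    return json.dumps(doc, indent=indent, ensure_ascii=False)


class CohortLoadFailure(BaseModel):
    """Per-file parse failure collected (not raised) during cohort load."""

    path: str
    error: str


def read_cohort(
    directory: str | Path,
) -> tuple[list[CaseVignette], list[CohortLoadFailure]]:
    """Load every ``*.json`` vignette under a directory.

    Files are read in lexicographic filename order so cohort order never
    depends on filesystem enumeration. Per-file failures are collected
    and returned alongside the successes; only an entirely unreadable
    cohort raises :class:`EmptyCohortError`.
    """
    directory = Path(directory)
    vignettes: list[CaseVignette] = []
    failures: list[CohortLoadFailure] = []
    paths = sorted(directory.glob("*.json"), key=lambda p: p.name)
    for path in paths:
        try:
            vignettes.append(read_vignette(path.read_text(encoding="utf-8")))
        except (SchemaError, ValueError) as exc:
            logger.warning("skipping %s: %s", path.name, exc)
            failures.append(CohortLoadFailure(path=str(path), error=str(exc)))
    if not vignettes:
        raise EmptyCohortError(f"no parseable vignettes in {directory}")
    return vignettes, failures


def write_cohort(vignettes: Iterable[CaseVignette], directory: str | Path) -> None:
    """Write one ``<case id>.json`` per vignette."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for v in vignettes:
        (directory / f"{v.id}.json").write_text(
            write_vignette(v), encoding="utf-8"
        )
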