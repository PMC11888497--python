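"""Deterministic rendering of case vignettes into diagnostic prompts.

Each of the nine study languages ships a template file: constant header
text (the task statement, the statement that the case is a genetic
disease), an example-output block that is always in English, an explicit
directive to answer in English, and phrase templates for the sex/age
sentence, the disease-onset sentence, and the observed/excluded feature
sentences. Translated phenotype labels are substituted into the phrase
templates; list connectors are per-language data.

Two hard guarantees, both enforced here:

* determinism — ``build_prompt`` is a pure function of its inputs, so
  re-rendering yields byte-identical text;
* leakage-freedom — the ground-truth diagnosis (label and id) never
  appears in the prompt; rendering raises if it would.
"""

from __future__ import annotations

import re
from importlib import resources
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict

from ._duration import Duration, parse_duration
from .errors import BabeldxError, NoTemplateError
from .ontology import LANGUAGES, MultilingualLexicon, translate_term
from .schema_io import CaseVignette, PhenotypicFeature, Sex, Subject


class LeakageError(BabeldxError):
    """The rendered prompt would contain the ground-truth diagnosis."""


class PromptTemplate(BaseModel):
    """Per-language prompt phrasing; placeholders use ``{name}`` syntax."""

    model_config = ConfigDict(frozen=True)

    language: str
    header: str
    example_output: str
    answer_directive: str
    sex_nouns: dict[str, str]
    sentence_with_age: str
    sentence_no_age: str
    age_years: str
    age_months: str
    age_days: str
    dur_years: str
    dur_months: str
    dur_days: str
    disease_onset: str
    feature_onset: str
    observed_features: str
    excluded_features: str
    list_separator: str
    final_conjunction: str


class PromptText(BaseModel):
    model_config = ConfigDict(frozen=True)

    case_id: str
    language: str
    text: str


_PLACEHOLDER_RE = re.compile(r"\{([A-Za-z_][A-Za-z0-9_]*)\}")

#: placeholders each phrase template may use
_EXPECTED_PLACEHOLDERS: dict[str, set[str]] = {
    "sentence_with_age": {"age", "sex_noun"},
    "sentence_no_age": {"sex_noun"},
    "age_years": {"n"},
    "age_months": {"n"},
    "age_days": {"n"},
    "dur_years": {"n"},
    "dur_months": {"n"},
    "dur_days": {"n"},
    "disease_onset": {"onset"},
    "feature_onset": {"label", "onset"},
    "observed_features": {"features"},
    "excluded_features": {"features"},
    "header": set(),
    "example_output": set(),
    "answer_directive": set(),
    "list_separator": set(),
    "final_conjunction": set(),
}


def load_template(yaml_text: str) -> PromptTemplate:
    return PromptTemplate(**yaml.safe_load(yaml_text))


def load_builtin_templates(
    languages: tuple[str, ...] = LANGUAGES,
) -> dict[str, PromptTemplate]:
    """Load the template set shipped with the package."""
    templates: dict[str, PromptTemplate] = {}
    pkg = resources.files("babeldx") / "templates"
    for lang in languages:
        path = pkg / f"{lang}.yaml"
        templates[lang] = load_template(path.read_text(encoding="utf-8"))
    return templates


def load_templates_dir(directory: str | Path) -> dict[str, PromptTemplate]:
    templates = {}
    for path in sorted(Path(directory).glob("*.yaml")):
        tpl = load_template(path.read_text(encoding="utf-8"))
        templates[tpl.language] = tpl
    return templates


def _format_age(d: Duration, tpl: PromptTemplate, *, attributive: bool) -> str:
    """Render a duration at natural clinical granularity.

    Years when at least one year old, months below that, days below one
    month. ``attributive`` picks the phrasing used inside the sex/age
    sentence ("14-year-old") over the free-standing one ("14 years").
    """
    if d.years >= 1:
        key = tpl.age_years if attributive else tpl.dur_years
        n = d.years
    elif d.months >= 1:
        key = tpl.age_months if attributive else tpl.dur_months
        n = d.months
    else:
        key = tpl.age_days if attributive else tpl.dur_days
        n = d.weeks * 7 + d.days
    return key.format(n=n)


def _render_onset(
    onset: str, language: str, lexicon: MultilingualLexicon, tpl: PromptTemplate
) -> str:
    """Onset is either an ISO duration (→ age phrase) or an onset-class
    CURIE (→ translated label, falling back to the raw id)."""
    try:
        d = parse_duration(onset)
    except ValueError:
        labels = lexicon.lookup(onset, language)
        return labels[0] if labels else onset
    return _format_age(d, tpl, attributive=False)


def render_age_sex(
    subject: Subject, language: str, templates: dict[str, PromptTemplate]
) -> str:
    """The demographic sentence, e.g. "The patient was a 14-year-old female."."""
    tpl = templates.get(language)
    if tpl is None:
        raise NoTemplateError(language)
    sex_noun = tpl.sex_nouns[subject.sex.value]
    if subject.age is None:
        return tpl.sentence_no_age.format(sex_noun=sex_noun)
    age = _format_age(parse_duration(subject.age), tpl, attributive=True)
    return tpl.sentence_with_age.format(age=age, sex_noun=sex_noun)


def _join(labels: list[str], tpl: PromptTemplate) -> str:
    if len(labels) == 1:
        return labels[0]
    return tpl.list_separator.join(labels[:-1]) + tpl.final_conjunction + labels[-1]


def _feature_phrase(
    f: PhenotypicFeature,
    language: str,
    lexicon: MultilingualLexicon,
    tpl: PromptTemplate,
) -> str:
    label = translate_term(f.term_id, language, lexicon)
    if f.onset is None:
        return label
    onset = _render_onset(f.onset, language, lexicon, tpl)
    return tpl.feature_onset.format(label=label, onset=onset)


def build_prompt(
    v: CaseVignette,
    language: str,
    lexicon: MultilingualLexicon,
    templates: dict[str, PromptTemplate],
) -> PromptText:
    """Render one vignette into a diagnostic prompt.

    Sections, in order: header (task statement + genetic-disease
    statement), English example output, English-answer directive,
    demographic sentence, disease-onset sentence (when recorded),
    observed-feature sentence, excluded-feature sentence (elided when
    there are none).
    """
    tpl = templates.get(language)
    if tpl is None:
        raise NoTemplateError(language)

    sentences = [render_age_sex(v.subject, language, templates)]
    if v.diagnosis.onset is not None:
        onset = _render_onset(v.diagnosis.onset, language, lexicon, tpl)
        sentences.append(tpl.disease_onset.format(onset=onset))
    observed = [
        _feature_phrase(f, language, lexicon, tpl) for f in v.observed
    ]
    sentences.append(tpl.observed_features.format(features=_join(observed, tpl)))
    excluded = [
        _feature_phrase(f, language, lexicon, tpl) for f in v.excluded_features
    ]
    if excluded:
        sentences.append(
            tpl.excluded_features.format(features=_join(excluded, tpl))
        )

    text = "\n\n".join(
        [
            tpl.header.strip(),
            tpl.example_output.strip(),
            tpl.answer_directive.strip(),
            " ".join(sentences),
        ]
    )

    low = text.lower()
    for token in (v.diagnosis.label, v.diagnosis.disease_id):
        if token and token.lower() in low:
            raise LeakageError(
                f"diagnosis token {token!r} would leak into prompt for case {v.id}"
            )
    return PromptText(case_id=v.id, language=language, text=text)


class TemplateViolation(BaseModel):
    language: str
    message: str


def validate_templates(
    templates: dict[str, PromptTemplate],
) -> list[TemplateViolation]:
    """Structural review of a template set (report-only, never raises).

    Checks per language: header present; the English example-output
    block and the answer-language directive present; every placeholder
    in every phrase template is one the renderer will substitute; the
    four sex nouns are covered.
    """
    violations: list[TemplateViolation] = []
    for lang, tpl in sorted(templates.items()):
        def bad(msg: str) -> None:
            violations.append(TemplateViolation(language=lang, message=msg))

        if not tpl.header.strip():
            bad("missing header")
        if not tpl.example_output.strip():
            bad("missing example-output block")
        if not tpl.answer_directive.strip():
            bad("missing answer-language directive")
        for sex in Sex:
            if not tpl.sex_nouns.get(sex.value):
                bad(f"missing sex noun for {sex.value}")
        for key, allowed in _EXPECTED_PLACEHOLDERS.items():
            found = set(_PLACEHOLDER_RE.findall(getattr(tpl, key)))
            for name in sorted(found - allowed):
                bad(f"undeclared placeholder {{{name}}} in {key}")
            for name in sorted(allowed - found):
                bad(f"unused required placeholder {{{name}}} in {key}")
    return violations
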