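"""Seeded generators for every fixture the pipeline consumes.

The generators emulate the statistical shape of the real benchmark
corpus without any download: a disease graph whose clinical diseases
carry 0–6 genetic subtypes (the subtype-equivalence structure scoring
depends on), a phenotype vocabulary with per-language pseudo-translation
tables at a configurable completeness rate, and patient cohorts whose
per-case term counts are Poisson-shaped around 14 with a fraction of
excluded features. Defaults mirror the study corpus: 4967 cases, 378
clinical diseases, 2618 phenotype terms, nine languages.

Every generator is a pure function of its spec (the seed included), so
fixtures are reproducible byte-for-byte. A :class:`GroundTruthLedger`
records what was planted — each case's true disease and whether its
terms were generated translation-complete — so parameter-recovery tests
can join scored output back to ground truth case by case.

Translated labels are *pseudo*-translations (language-tagged English
labels): the benchmark machinery only needs distinct per-language
strings, not linguistic content.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .errors import SpecError
from .llm import MockSpec, OutcomeDistribution
from .ontology import (
    LANGUAGES,
    DiseaseGraph,
    MultilingualLexicon,
    OntologyTerm,
    SynonymScope,
)
from .schema_io import (
    CaseDiagnosis,
    CaseVignette,
    PhenotypicFeature,
    Sex,
    Subject,
)

_SYLLABLES = (
    "al", "ber", "cor", "dan", "el", "far", "gol", "har", "is", "jor",
    "kel", "lom", "mar", "nor", "os", "per", "quin", "ros", "sel", "tor",
    "ul", "ver", "wil", "xan", "yor", "zel",
)
_DISEASE_KINDS = ("syndrome", "disease", "dysplasia", "deficiency")
_SYNONYM_KINDS = ("disorder", "anomaly", "condition")
_PHENO_SITES = (
    "cardiac", "ocular", "renal", "hepatic", "skeletal", "neural",
    "dermal", "aortic", "cochlear", "pulmonary", "vascular", "cranial",
)
_PHENO_KINDS = (
    "hypoplasia", "hyperplasia", "stenosis", "atrophy", "dystrophy",
    "malformation", "dysfunction", "calcification", "fragility",
)


class GeneratorSpec(BaseModel):
    """Study-shaped defaults; override for desk-scale fixtures."""

    model_config = ConfigDict(frozen=True)

    seed: int = 0
    n_diseases: int = Field(default=378, ge=1)  # clinical group heads
    subtype_count_min: int = Field(default=0, ge=0)
    subtype_count_max: int = Field(default=6, ge=0)
    n_phenotype_terms: int = Field(default=2618, ge=1)
    languages: tuple[str, ...] = LANGUAGES
    n_cases: int = Field(default=4967, ge=1)
    terms_per_case_mean: float = Field(default=14.0, gt=0)
    terms_per_case_fixed: bool = False  # every case gets exactly round(mean)
    excluded_fraction: float = Field(default=0.2, ge=0.0, le=1.0)
    translation_completeness_rate: float = Field(default=1.0, ge=0.0, le=1.0)
    synonyms_per_disease_mean: float = Field(default=2.0, ge=0.0)

    @model_validator(mode="after")
    def _ranges(self) -> "GeneratorSpec":
        if self.subtype_count_max < self.subtype_count_min:
            raise SpecError("subtype_count_max < subtype_count_min")
        if "en" not in self.languages:
            raise SpecError("languages must include 'en'")
        return self


@dataclass
class CaseGroundTruth:
    case_id: str
    disease_id: str
    fully_translated: bool


@dataclass
class GroundTruthLedger:
    """Everything planted during generation, keyed for exact joins."""

    cases: dict[str, CaseGroundTruth] = field(default_factory=dict)
    #: term_id → languages its translation is missing from
    incomplete_terms: dict[str, tuple[str, ...]] = field(default_factory=dict)

    @property
    def n_fully_translated(self) -> int:
        return sum(1 for c in self.cases.values() if c.fully_translated)


def _unique_name(rng: np.random.Generator, used: set[str], kinds) -> str:
    for _ in range(1000):
        n_syl = int(rng.integers(2, 4))
        idx = rng.choice(len(_SYLLABLES), size=n_syl)
        stem = "".join(_SYLLABLES[int(i)] for i in idx).capitalize()
        name = f"{stem} {kinds[int(rng.integers(len(kinds)))]}"
        if name.casefold() not in used:
            used.add(name.casefold())
            return name
    raise SpecError("name space exhausted; reduce n_diseases")


def generate_ontology(
    spec: GeneratorSpec,
) -> tuple[DiseaseGraph, list[OntologyTerm], MultilingualLexicon, GroundTruthLedger]:
    """Build the disease graph, phenotype vocabulary and lexicon.

    Diseases: ``n_diseases`` clinical heads, each with a sampled number
    of genetic subtypes ("<head label> type <i>") linked back to it, and
    a sampled number of globally unique synonyms. Phenotype terms get an
    English label plus language-tagged pseudo-translations in each other
    language; with probability 1 − completeness a term is *incomplete* —
    missing a random non-empty subset of the non-English languages. The
    returned ledger records which terms are incomplete.
    """
    rng = np.random.default_rng([spec.seed, 11])
    used_names: set[str] = set()
    used_synonyms: set[str] = set()
    terms: dict[str, OntologyTerm] = {}
    subtype_links: dict[str, str] = {}
    next_id = 8000001

    def mondo_id() -> str:
        nonlocal next_id
        curie = f"MONDO:{next_id:07d}"
        next_id += 1
        return curie

    for _ in range(spec.n_diseases):
        head_id = mondo_id()
        label = _unique_name(rng, used_names, _DISEASE_KINDS)
        stem = label.rsplit(" ", 1)[0]
        n_syn = int(rng.poisson(spec.synonyms_per_disease_mean))
        synonyms = []
        for _s in range(n_syn):
            syn = f"{stem} {_SYNONYM_KINDS[int(rng.integers(len(_SYNONYM_KINDS)))]}"
            if syn.casefold() in used_synonyms or syn.casefold() in used_names:
                syn = f"{syn} {len(used_synonyms)}"
            used_synonyms.add(syn.casefold())
            scope = (
                SynonymScope.EXACT if rng.random() < 0.7 else SynonymScope.RELATED
            )
            synonyms.append((syn, scope))
        terms[head_id] = OntologyTerm(
            id=head_id, label=label, synonyms=tuple(synonyms)
        )
        n_sub = int(
            rng.integers(spec.subtype_count_min, spec.subtype_count_max + 1)
        )
        for i in range(1, n_sub + 1):
            sub_id = mondo_id()
            sub_label = f"{label} type {i}"
            used_names.add(sub_label.casefold())
            sub_syns = []
            if rng.random() < 0.5:
                syn = f"{stem} {i}"
                if syn.casefold() not in used_synonyms:
                    used_synonyms.add(syn.casefold())
                    sub_syns.append((syn, SynonymScope.EXACT))
            terms[sub_id] = OntologyTerm(
                id=sub_id, label=sub_label, synonyms=tuple(sub_syns),
                parents=(head_id,),
            )
            subtype_links[sub_id] = head_id
    graph = DiseaseGraph(terms=terms, subtype_links=subtype_links)

    phenotypes: list[OntologyTerm] = []
    entries: dict[tuple[str, str], tuple[str, ...]] = {}
    ledger = GroundTruthLedger()
    non_english = [l for l in spec.languages if l != "en"]
    for i in range(spec.n_phenotype_terms):
        term_id = f"HP:{9000001 + i:07d}"
        site = _PHENO_SITES[int(rng.integers(len(_PHENO_SITES)))]
        kind = _PHENO_KINDS[int(rng.integers(len(_PHENO_KINDS)))]
        label = f"{site.capitalize()} {kind} {i + 1}"
        phenotypes.append(OntologyTerm(id=term_id, label=label))
        entries[(term_id, "en")] = (label,)
        missing: tuple[str, ...] = ()
        if non_english and rng.random() >= spec.translation_completeness_rate:
            n_missing = int(rng.integers(1, len(non_english) + 1))
            picks = rng.choice(len(non_english), size=n_missing, replace=False)
            missing = tuple(sorted(non_english[j] for j in picks))
            ledger.incomplete_terms[term_id] = missing
        for lang in non_english:
            if lang in missing:
                continue
            entries[(term_id, lang)] = (f"[{lang}] {label}",)
    lexicon = MultilingualLexicon(
        entries=entries, languages=tuple(sorted(spec.languages))
    )
    return graph, phenotypes, lexicon, ledger


def generate_cohort(
    spec: GeneratorSpec,
    graph: DiseaseGraph,
    phenotypes: list[OntologyTerm],
    ledger: GroundTruthLedger | None = None,
) -> tuple[list[CaseVignette], GroundTruthLedger]:
    """Sample patient vignettes against a generated ontology.

    Per case: a shifted-Poisson feature count (mean ``terms_per_case_mean``,
    minimum one), features excluded at ``excluded_fraction`` with at
    least one observed, optional ISO-8601 ages and onsets, and one true
    disease drawn uniformly from the whole graph (heads and subtypes).
    The ledger gains each case's truth and whether all of its terms were
    generated translation-complete.
    """
    if ledger is None:
        ledger = GroundTruthLedger()
    rng = np.random.default_rng([spec.seed, 22])
    disease_ids = sorted(graph.terms)
    n_pheno = len(phenotypes)
    if n_pheno < 1:
        raise SpecError("need at least one phenotype term")
    vignettes: list[CaseVignette] = []
    sexes = list(Sex)
    for i in range(spec.n_cases):
        case_id = f"case-{i:05d}"
        if spec.terms_per_case_fixed:
            n_terms = max(1, round(spec.terms_per_case_mean))
        else:
            # shifted Poisson keeps the configured mean while enforcing >= 1
            n_terms = 1 + int(rng.poisson(spec.terms_per_case_mean - 1))
        n_terms = min(n_terms, n_pheno)
        picks = rng.choice(n_pheno, size=n_terms, replace=False)
        features: list[PhenotypicFeature] = []
        observed_slot = int(rng.integers(n_terms))  # guaranteed observed
        for j, p in enumerate(picks):
            term = phenotypes[int(p)]
            excluded = (
                j != observed_slot and rng.random() < spec.excluded_fraction
            )
            onset = None
            if not excluded and rng.random() < 0.2:
                onset = f"P{int(rng.integers(0, 15))}Y{int(rng.integers(0, 12))}M"
            features.append(
                PhenotypicFeature(
                    term_id=term.id, excluded=excluded, onset=onset
                )
            )
        age = None
        if rng.random() < 0.9:
            years = int(rng.integers(0, 70))
            if years == 0:
                age = f"P{int(rng.integers(1, 12))}M"
            else:
                age = f"P{years}Y"
        sex = sexes[int(rng.integers(len(sexes)))]
        truth = disease_ids[int(rng.integers(len(disease_ids)))]
        diag_onset = None
        if rng.random() < 0.5:
            diag_onset = f"P{int(rng.integers(0, 40))}Y"
        v = CaseVignette(
            id=case_id,
            subject=Subject(id=f"subject-{i:05d}", sex=sex, age=age),
            features=tuple(features),
            diagnosis=CaseDiagnosis(
                disease_id=truth,
                label=graph.terms[truth].label,
                onset=diag_onset,
            ),
        )
        fully = all(
            f.term_id not in ledger.incomplete_terms for f in features
        )
        ledger.cases[case_id] = CaseGroundTruth(
            case_id=case_id, disease_id=truth, fully_translated=fully
        )
        vignettes.append(v)
    return vignettes, ledger


def generate_mock_spec(
    outcome_probabilities: dict,
    per_language_overrides: dict[str, dict] | None = None,
    *,
    synonym_rate: float = 0.3,
    ungroundable_rate: float = 0.05,
    n_items: int = 10,
    mode: str = "exact",
) -> MockSpec:
    """Build a mock-backend spec from outcome probability dictionaries.

    ``outcome_probabilities`` holds ``rank_probs`` (rank → probability),
    ``not_ranked`` and ``refusal``; per-language overrides replace the
    default wholesale for that language. Probabilities must sum to one
    (tolerance 1e-9) or a :class:`SpecError` is raised.
    """
    default = OutcomeDistribution(**outcome_probabilities)
    per_language = {
        lang: OutcomeDistribution(**fields)
        for lang, fields in (per_language_overrides or {}).items()
    }
    return MockSpec(
        default=default,
        per_language=per_language,
        synonym_rate=synonym_rate,
        ungroundable_rate=ungroundable_rate,
        n_items=n_items,
        mode=mode,
    )


def distribution_from_counts(
    top1: int,
    top3: int,
    top10: int,
    not_ranked: int,
    no_diagnosis: int,
) -> OutcomeDistribution:
    """Outcome distribution matching published-style cumulative counts.

    Rank-1 probability comes straight from Top-1; the Top-3 and Top-10
    increments are spread evenly over ranks 2–3 and 4–10. Useful for
    planting a published per-language row into the mock backend.
    """
    n = top10 + not_ranked + no_diagnosis
    if n <= 0 or not 0 <= top1 <= top3 <= top10:
        raise SpecError("counts must be non-negative, cumulative, and non-empty")
    rank_probs: dict[int, float] = {1: top1 / n}
    for k in (2, 3):
        rank_probs[k] = (top3 - top1) / 2 / n
    for k in range(4, 11):
        rank_probs[k] = (top10 - top3) / 7 / n
    return OutcomeDistribution(
        rank_probs=rank_probs,
        not_ranked=not_ranked / n,
        refusal=no_diagnosis / n,
    )
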