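import json

import pytest

from babeldx.ontology import (
    DiseaseGraph,
    MultilingualLexicon,
    OntologyTerm,
    SynonymScope,
)
from babeldx.prompts import load_builtin_templates
from babeldx.schema_io import (
    CaseDiagnosis,
    CaseVignette,
    PhenotypicFeature,
    Sex,
    Subject,
)
from babeldx.synthetic import GeneratorSpec, generate_cohort, generate_ontology

LANGS = ("en", "zh", "cs", "nl", "de", "it", "ja", "es", "tr")


@pytest.fixture(scope="session")
def templates():
    return load_builtin_templates()


@pytest.fixture(scope="session")
def toy_graph() -> DiseaseGraph:
    """Hand-built graph: one clinical disease with six genetic subtypes
    (the subtype-rollup shape), one synonym-rich disease, one ambiguous
    synonym shared by two diseases, one isolated disease."""
    terms = {}
    links = {}
    terms["MONDO:0000001"] = OntologyTerm(
        id="MONDO:0000001",
        label="Loeys-Dietz syndrome",
        synonyms=(("LDS", SynonymScope.EXACT),),
    )
    for i in range(1, 7):
        sid = f"MONDO:000001{i}"
        terms[sid] = OntologyTerm(
            id=sid,
            label=f"Loeys-Dietz syndrome type {i}",
            synonyms=((f"LDS{i}", SynonymScope.EXACT),),
            parents=("MONDO:0000001",),
        )
        links[sid] = "MONDO:0000001"
    terms["MONDO:0000002"] = OntologyTerm(
        id="MONDO:0000002",
        label="Marfan syndrome",
        synonyms=(
            ("Marfan's syndrome", SynonymScope.EXACT),
            ("MFS", SynonymScope.RELATED),
        ),
    )
    terms["MONDO:0000003"] = OntologyTerm(
        id="MONDO:0000003",
        label="Homocystinuria",
        synonyms=(("shared alias", SynonymScope.EXACT),),
    )
    terms["MONDO:0000004"] = OntologyTerm(
        id="MONDO:0000004",
        label="Stickler syndrome",
        synonyms=(("shared alias", SynonymScope.EXACT),),
    )
    return DiseaseGraph(terms=terms, subtype_links=links)


@pytest.fixture(scope="session")
def tiny_lexicon() -> MultilingualLexicon:
    entries = {}
    for i, term_id in enumerate(["HP:0000001", "HP:0000002", "HP:0000003"]):
        entries[(term_id, "en")] = (f"Finding {i + 1}",)
        for lang in LANGS[1:]:
            entries[(term_id, lang)] = (f"[{lang}] Finding {i + 1}",)
    # HP:0000004 misses only the Czech translation
    entries[("HP:0000004", "en")] = ("Partial finding",)
    for lang in LANGS[1:]:
        if lang != "cs":
            entries[("HP:0000004", lang)] = (f"[{lang}] Partial finding",)
    return MultilingualLexicon(entries=entries, languages=LANGS)


@pytest.fixture
def minimal_vignette() -> CaseVignette:
    return CaseVignette(
        id="case-min",
        subject=Subject(id="s1", sex=Sex.MALE),
        features=(PhenotypicFeature(term_id="HP:0000001"),),
        diagnosis=CaseDiagnosis(disease_id="MONDO:0000002", label="Marfan syndrome"),
    )


MINIMAL_JSON = json.dumps(
    {
        "id": "case-min",
        "subject": {"id": "s1", "sex": "MALE"},
        "features": [{"term_id": "HP:0000001", "excluded": False}],
        "diagnosis": {"disease_id": "MONDO:0000002", "label": "Marfan syndrome"},
    }
)


@pytest.fixture(scope="session")
def small_world():
    """A generated ontology + 50-case cohort shared by pipeline tests."""
    spec = GeneratorSpec(
        seed=101,
        n_diseases=30,
        n_phenotype_terms=120,
        n_cases=50,
    )
    graph, phenotypes, lexicon, ledger = generate_ontology(spec)
    cohort, ledger = generate_cohort(spec, graph, phenotypes, ledger)
    return {
        "spec": spec,
        "graph": graph,
        "phenotypes": phenotypes,
        "lexicon": lexicon,
        "ledger": ledger,
        "cohort": cohort,
    }
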