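"""Query contract to a text-generation backend, plus offline backends.

The pipeline never talks to a model directly; it hands a rendered
prompt to a *backend* and gets raw text back. Three backends satisfy
the contract:

* ``MockBackend`` — emits synthetic differentials realizing a planted
  outcome distribution (correct diagnosis at a chosen rank among
  distractors, not-ranked lists, refusals, ungroundable strings). It is
  the workhorse for testing: seeded, deterministic, and its planted
  outcomes are recorded so parameter recovery can be checked exactly.
* ``RecordedBackend`` — replays responses from a directory
  (``responses/<language>/<case_id>.txt``); a missing file is a
  recorded gap, returned as an empty string and treated as a refusal
  downstream.
* ``LiveBackend`` — a thin optional adapter for a real API; never used
  by tests.

Evaluation depends only on ``raw_text``; the backend tag is provenance.
"""

from __future__ import annotations

from enum import Enum
from pathlib import Path
from typing import Protocol

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .errors import BackendUnavailableError, SpecError
from .evaluation import GROUNDING_FAILURE, GroundingIndex
from .ontology import DiseaseGraph, equivalence_class
from .prompts import PromptText

_PROB_TOL = 1e-9


class BackendTag(str, Enum):
    MOCK = "MOCK"
    RECORDED = "RECORDED"
    LIVE = "LIVE"


class LLMConfig(BaseModel):
    """Decoding parameters; defaults mirror an unconstrained API call
    (unit temperature, no token cap)."""

    model_config = ConfigDict(frozen=True, protected_namespaces=())

    model_name: str = "mock"
    temperature: float = Field(default=1.0, ge=0.0)
    max_tokens: int | None = None


class LLMResponse(BaseModel):
    model_config = ConfigDict(frozen=True)

    case_id: str
    language: str
    raw_text: str
    backend_tag: BackendTag


class Backend(Protocol):
    tag: BackendTag

    def generate(self, prompt: PromptText, config: LLMConfig) -> str: ...


def query(prompt: PromptText, config: LLMConfig, backend: Backend) -> LLMResponse:
    """Exactly one response per prompt; backend failures raise, they
    never surface as silent empty successes."""
    try:
        text = backend.generate(prompt, config)
    except BackendUnavailableError:
        raise
    except Exception as exc:  # surface with case context, retryable
        raise BackendUnavailableError(
            f"backend failed for case {prompt.case_id} [{prompt.language}]: {exc}"
        ) from exc
    return LLMResponse(
        case_id=prompt.case_id,
        language=prompt.language,
        raw_text=text,
        backend_tag=backend.tag,
    )


# --- mock backend ----------------------------------------------------------

#: Outcome labels, in the fixed enumeration order used everywhere
#: (ranks ascending, then not-ranked, then refusal).
def _outcome_order(rank_probs: dict[int, float]) -> list[str]:
    return [f"rank{k}" for k in sorted(rank_probs)] + ["not_ranked", "refusal"]


class OutcomeDistribution(BaseModel):
    """Per-case outcome probabilities for one language."""

    model_config = ConfigDict(frozen=True)

    rank_probs: dict[int, float] = Field(default_factory=dict)
    not_ranked: float = 0.0
    refusal: float = 0.0

    @model_validator(mode="after")
    def _sums_to_one(self) -> "OutcomeDistribution":
        for k, p in self.rank_probs.items():
            if k < 1:
                raise SpecError(f"rank must be >= 1, got {k}")
            if p < 0:
                raise SpecError(f"negative probability for rank {k}")
        if self.not_ranked < 0 or self.refusal < 0:
            raise SpecError("negative outcome probability")
        total = sum(self.rank_probs.values()) + self.not_ranked + self.refusal
        if abs(total - 1.0) > _PROB_TOL:
            raise SpecError(f"outcome probabilities sum to {total}, not 1")
        return self

    def as_vector(self) -> tuple[list[str], np.ndarray]:
        names = _outcome_order(self.rank_probs)
        probs = [self.rank_probs[k] for k in sorted(self.rank_probs)]
        probs += [self.not_ranked, self.refusal]
        return names, np.asarray(probs, dtype=float)


class MockSpec(BaseModel):
    """Full specification of the mock's behavior.

    ``mode="exact"`` assigns outcomes deterministically so aggregate
    counts match the distribution as closely as integer counts allow
    (largest-remainder apportionment over a seeded case shuffle);
    ``mode="sample"`` draws each case independently.
    """

    model_config = ConfigDict(frozen=True)

    default: OutcomeDistribution
    per_language: dict[str, OutcomeDistribution] = Field(default_factory=dict)
    synonym_rate: float = Field(default=0.3, ge=0.0, le=1.0)
    ungroundable_rate: float = Field(default=0.05, ge=0.0, le=1.0)
    n_items: int = Field(default=10, ge=1)
    mode: str = "exact"

    @model_validator(mode="after")
    def _valid_mode(self) -> "MockSpec":
        if self.mode not in ("exact", "sample"):
            raise SpecError(f"unknown mock mode {self.mode!r}")
        return self

    def distribution_for(self, language: str) -> OutcomeDistribution:
        return self.per_language.get(language, self.default)


#: Refusal sentences the mock draws from; the English one is the
#: canonical refusal wording the parser must recognize as NO_DIAGNOSIS.
REFUSAL_BANK: dict[str, tuple[str, ...]] = {
    "en": (
        "I'm sorry but based on the information provided, I cannot return a confident diagnosis",
        "I cannot provide a diagnosis for this case.",
    ),
    "de": ("Es tut mir leid, aber ich kann keine sichere Diagnose stellen.",),
    "es": ("Lo siento, pero no puedo ofrecer un diagnóstico con confianza.",),
    "ja": ("申し訳ありませんが、確信を持って診断をお答えすることはできません。",),
    "zh": ("抱歉,根据所提供的信息,我无法给出可靠的诊断。",),
}


def _largest_remainder(probs: np.ndarray, n: int) -> np.ndarray:
    """Integer apportionment of n cases over outcome probabilities."""
    raw = probs * n
    counts = np.floor(raw).astype(int)
    remainder = n - counts.sum()
    if remainder > 0:
        order = np.argsort(-(raw - counts), kind="stable")
        counts[order[:remainder]] += 1
    return counts


class PlantedOutcome(BaseModel):
    model_config = ConfigDict(frozen=True)

    case_id: str
    language: str
    outcome: str  # "rank<k>" | "not_ranked" | "refusal"
    rank: int | None = None
    used_synonym: bool = False
    n_ungroundable: int = 0


class MockBackend:
    """Seeded synthetic responder.

    Needs the disease graph (to name correct answers and sample
    distractors from outside the truth's equivalence class) and the map
    from case id to ground-truth disease. Every decision is drawn from
    a generator keyed by (seed, language, case index), so responses are
    independent of query order and reproducible run-to-run.
    """

    tag = BackendTag.MOCK

    def __init__(
        self,
        spec: MockSpec,
        graph: DiseaseGraph,
        truths: dict[str, str],
        seed: int,
    ):
        self.spec = spec
        self.graph = graph
        self.truths = dict(truths)
        self.seed = int(seed)
        self._case_order = {cid: i for i, cid in enumerate(sorted(truths))}
        self._index = GroundingIndex(graph)
        self._all_ids = sorted(graph.terms)
        self._assignments: dict[str, list[str]] = {}
        self.planted: dict[tuple[str, str], PlantedOutcome] = {}

    # -- outcome assignment

    def _lang_key(self, language: str) -> int:
        # stable small integer per language, independent of run order
        return sum(language.encode("utf-8")) % 100_000

    def _exact_assignment(self, language: str) -> list[str]:
        if language not in self._assignments:
            dist = self.spec.distribution_for(language)
            names, probs = dist.as_vector()
            n = len(self._case_order)
            counts = _largest_remainder(probs, n)
            outcomes: list[str] = []
            for name, c in zip(names, counts):
                outcomes.extend([name] * int(c))
            rng = np.random.default_rng([self.seed, self._lang_key(language), 1])
            perm = rng.permutation(n)
            assigned = [""] * n
            for slot, outcome in zip(perm, outcomes):
                assigned[slot] = outcome
            self._assignments[language] = assigned
        return self._assignments[language]

    def _outcome_for(self, case_id: str, language: str, rng) -> str:
        if self.spec.mode == "exact":
            return self._exact_assignment(language)[self._case_order[case_id]]
        dist = self.spec.distribution_for(language)
        names, probs = dist.as_vector()
        return names[rng.choice(len(names), p=probs)]

    # -- response realization

    def _correct_name(self, truth: str, rng) -> tuple[str, bool]:
        """A string that grounds into the truth's equivalence class:
        the truth's label, or (at the synonym rate) a label or synonym
        of any class member that grounds unambiguously."""
        members = sorted(equivalence_class(truth, self.graph))
        if rng.random() < self.spec.synonym_rate:
            pool: list[str] = []
            for mid in members:
                term = self.graph.terms[mid]
                pool.extend(s for s, _scope in term.synonyms)
                if mid != truth:
                    pool.append(term.label)
            rng.shuffle(pool)
            for name in pool:
                if self._index.lookup(name) in members:
                    return name, True
        return self.graph.terms[truth].label, False

    def _distractor_names(self, truth: str, k: int, rng) -> list[str]:
        members = equivalence_class(truth, self.graph)
        pool = [d for d in self._all_ids if d not in members]
        if not pool:
            return []
        replace = len(pool) < k
        picks = rng.choice(len(pool), size=k, replace=replace)
        return [self.graph.terms[pool[i]].label for i in picks]

    def _realize(
        self, case_id: str, language: str, outcome: str, rng
    ) -> tuple[str, PlantedOutcome]:
        if outcome == "refusal":
            bank = REFUSAL_BANK.get(language, REFUSAL_BANK["en"])
            text = bank[rng.integers(len(bank))]
            return text, PlantedOutcome(
                case_id=case_id, language=language, outcome=outcome
            )
        truth = self.truths[case_id]
        n_items = self.spec.n_items
        rank: int | None = None
        used_synonym = False
        if outcome.startswith("rank"):
            rank = int(outcome[4:])
            n_items = max(n_items, rank)
        names = self._distractor_names(truth, n_items, rng)
        if rank is not None:
            correct, used_synonym = self._correct_name(truth, rng)
            names[rank - 1] = correct
        n_ungroundable = 0
        for i in range(len(names)):
            if rank is not None and i == rank - 1:
                continue  # never clobber the planted correct answer
            if rng.random() < self.spec.ungroundable_rate:
                names[i] = f"unrecognized clinical entity XN-{rng.integers(10**6)}"
                n_ungroundable += 1
        lines = [f"{i}. {name}" for i, name in enumerate(names, start=1)]
        planted = PlantedOutcome(
            case_id=case_id,
            language=language,
            outcome=outcome,
            rank=rank,
            used_synonym=used_synonym,
            n_ungroundable=n_ungroundable,
        )
        return "\n".join(lines), planted

    def generate(self, prompt: PromptText, config: LLMConfig) -> str:
        case_id, language = prompt.case_id, prompt.language
        if case_id not in self.truths:
            raise BackendUnavailableError(f"mock knows no truth for case {case_id}")
        rng = np.random.default_rng(
            [self.seed, self._lang_key(language), self._case_order[case_id], 2]
        )
        outcome = self._outcome_for(case_id, language, rng)
        text, planted = self._realize(case_id, language, outcome, rng)
        self.planted[(case_id, language)] = planted
        return text


def make_mock_backend(
    spec: MockSpec, graph: DiseaseGraph, truths: dict[str, str], seed: int
) -> MockBackend:
    return MockBackend(spec, graph, truths, seed)


# --- recorded and live backends --------------------------------------------


class RecordedBackend:
    """Replay responses from ``<root>/<language>/<case_id>.txt``."""

    tag = BackendTag.RECORDED

    def __init__(self, root: str | Path):
        self.root = Path(root)
        if not self.root.is_dir():
            raise BackendUnavailableError(f"no response directory at {self.root}")

    def generate(self, prompt: PromptText, config: LLMConfig) -> str:
        path = self.root / prompt.language / f"{prompt.case_id}.txt"
        if not path.is_file():
            return ""  # recorded gap: downstream treats as refusal
        return path.read_text(encoding="utf-8")


class LiveBackend:
    """Placeholder adapter for a real completion API.

    Kept behind the same contract so the pipeline code is identical;
    instantiating it without a configured client raises immediately
    rather than failing mid-run.
    """

    tag = BackendTag.LIVE

    def __init__(self, client=None):
        if client is None:
            raise BackendUnavailableError(
                "live backend requires a configured API client"
            )
        self.client = client

    def generate(self, prompt: PromptText, config: LLMConfig) -> str:
        result = self.client.complete(
            model=config.model_name,
            temperature=config.temperature,
            max_tokens=config.max_tokens,
            prompt=prompt.text,
        )
        if not result:
            raise BackendUnavailableError(
                f"empty completion for case {prompt.case_id}"
            )
        return result


__all__ = [
    "Backend",
    "BackendTag",
    "GROUNDING_FAILURE",
    "LLMConfig",
    "LLMResponse",
    "LiveBackend",
    "MockBackend",
    "MockSpec",
    "OutcomeDistribution",
    "PlantedOutcome",
    "RecordedBackend",
    "REFUSAL_BANK",
    "make_mock_backend",
    "query",
]
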