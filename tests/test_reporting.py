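"""Aggregation arithmetic, the H-test, and the pipeline driver."""

import itertools

import numpy as np
import pytest

from babeldx.errors import (
    DegenerateError,
    EmptyInputError,
    InsufficientGroupsError,
)
from babeldx.evaluation import CaseResult, Outcome
from babeldx.ontology import dump_disease_graph, dump_lexicon
from babeldx.reporting import (
    BackendConfig,
    LanguageSummary,
    PipelineConfig,
    aggregate,
    build_rank_samples,
    kruskal_wallis,
    load_published_counts,
    round_half_up_1dp,
    run_pipeline,
    topn_frequency,
)
from babeldx.schema_io import write_cohort


def _results_from_row(language, top1, top3, top10, not_ranked, no_diagnosis):
    """Expand a summary row into per-case results (ranks 1, 2, 4)."""
    results = []
    counts = {
        1: top1,
        2: top3 - top1,
        4: top10 - top3,
    }
    i = 0
    for rank, n in counts.items():
        for _ in range(n):
            results.append(
                CaseResult(
                    case_id=f"{language}-{i}", language=language,
                    outcome=Outcome.RANKED, rank=rank, n_candidates=10,
                )
            )
            i += 1
    for _ in range(not_ranked):
        results.append(
            CaseResult(
                case_id=f"{language}-{i}", language=language,
                outcome=Outcome.NOT_RANKED, n_candidates=10,
            )
        )
        i += 1
    for _ in range(no_diagnosis):
        results.append(
            CaseResult(
                case_id=f"{language}-{i}", language=language,
                outcome=Outcome.NO_DIAGNOSIS,
            )
        )
        i += 1
    return results


def test_aggregate_reproduces_the_english_reference_row():
    results = _results_from_row("en", 985, 1340, 1546, 3420, 1)
    summary = aggregate(results, "en")
    assert (summary.top1, summary.top3, summary.top10) == (985, 1340, 1546)
    assert (summary.not_ranked, summary.no_diagnosis) == (3420, 1)
    assert summary.top10 + summary.not_ranked + summary.no_diagnosis == 4967


def test_aggregate_all_no_diagnosis():
    results = _results_from_row("en", 0, 0, 0, 0, 12)
    summary = aggregate(results, "en")
    assert (summary.top1, summary.top3, summary.top10, summary.not_ranked) == (
        0, 0, 0, 0,
    )
    assert summary.no_diagnosis == 12
    with pytest.raises(DegenerateError):
        topn_frequency(summary, 1)


def test_aggregate_empty_input_raises():
    with pytest.raises(EmptyInputError):
        aggregate([], "en")


def test_rank_beyond_ten_counts_as_not_ranked():
    results = [
        CaseResult(case_id="a", language="en", outcome=Outcome.RANKED,
                   rank=11, n_candidates=12),
        CaseResult(case_id="b", language="en", outcome=Outcome.RANKED,
                   rank=10, n_candidates=12),
    ]
    summary = aggregate(results, "en")
    assert summary.top10 == 1 and summary.not_ranked == 1


def test_topn_frequencies_match_published_percentages():
    rows = {s.language: s for s in load_published_counts()}
    en = rows["English"]
    assert topn_frequency(en, 1) == 19.8
    assert topn_frequency(en, 3) == 27.0
    assert topn_frequency(en, 10) == 31.1
    assert topn_frequency(rows["Spanish"], 10) == 31.8


def test_zero_top1_gives_zero_frequency():
    s = LanguageSummary(language="x", n_total=10, top1=0, top3=0, top10=0,
                        not_ranked=10, no_diagnosis=0)
    assert topn_frequency(s, 1) == 0.0


def test_denominator_excludes_no_diagnosis_only_in_second_decimal():
    """English Top-1: 985/4966 vs 985/4967 — the published denominator
    choice moves the unrounded value only past the first decimal."""
    with_exclusion = 100 * 985 / 4966
    without = 100 * 985 / 4967
    assert round_half_up_1dp(985, 4966) == 19.8
    assert round_half_up_1dp(985, 4967) == 19.8
    assert abs(with_exclusion - without) < 0.01
    assert with_exclusion != without


def test_row_sum_invariant_enforced_by_the_type():
    with pytest.raises(ValueError):
        LanguageSummary(language="x", n_total=10, top1=1, top3=1, top10=1,
                        not_ranked=1, no_diagnosis=1)


def _kruskal_oracle(groups):
    """Independent tie-corrected rank-sum computation."""
    pooled = sorted(x for g in groups for x in g)
    n = len(pooled)
    # average ranks with ties
    ranks = {}
    i = 0
    while i < n:
        j = i
        while j < n and pooled[j] == pooled[i]:
            j += 1
        avg = (i + 1 + j) / 2
        ranks[pooled[i]] = avg
        i = j
    h = 0.0
    for g in groups:
        r = sum(ranks[x] for x in g)
        h += r * r / len(g)
    h = 12 / (n * (n + 1)) * h - 3 * (n + 1)
    # tie correction
    ties = 0.0
    i = 0
    while i < n:
        j = i
        while j < n and pooled[j] == pooled[i]:
            j += 1
        t = j - i
        ties += t**3 - t
        i = j
    correction = 1 - ties / (n**3 - n)
    return h / correction if correction > 0 else 0.0


def test_identical_constant_groups_have_zero_h():
    comparison = kruskal_wallis({"a": [5, 5, 5], "b": [5, 5], "c": [5]})
    assert comparison.H == 0.0 and comparison.p_value == 1.0


def test_two_separated_groups_match_hand_oracle():
    groups = {"a": [1, 2, 3], "b": [4, 5, 6]}
    comparison = kruskal_wallis(groups)
    expected = _kruskal_oracle([[1, 2, 3], [4, 5, 6]])
    assert comparison.H == pytest.approx(expected, abs=1e-12)
    # rank sums are 6 and 15 on n=6: H = 12/42*(36/3+225/3) - 21
    assert expected == pytest.approx(12 / 42 * (12 + 75) - 21)


def test_h_matches_oracle_on_all_small_instances():
    """Exhaustive check against the rank-sum oracle for every 2-group
    size composition with total n <= 8, over seeded tied-value draws."""
    rng = np.random.default_rng(12)
    checked = 0
    for n in range(2, 9):
        for n1 in range(1, n):
            n2 = n - n1
            for _rep in range(5):
                values = rng.integers(1, 5, size=n).tolist()
                g1, g2 = values[:n1], values[n1:]
                if len(set(values)) == 1:
                    continue
                comparison = kruskal_wallis({"a": g1, "b": g2})
                assert comparison.H == pytest.approx(
                    _kruskal_oracle([g1, g2]), abs=1e-10
                )
                checked += 1
    assert checked > 100


def test_insufficient_groups_raise():
    with pytest.raises(InsufficientGroupsError):
        kruskal_wallis({"a": [1, 2]})
    with pytest.raises(InsufficientGroupsError):
        kruskal_wallis({"a": [1, 2], "b": []})


def test_type_one_error_rate_is_nominal():
    """Nine groups drawn from one distribution: the omnibus test should
    reject at 5% about 5% of the time."""
    rng = np.random.default_rng(99)
    rejections = 0
    reps = 100
    for _ in range(reps):
        samples = {
            f"g{i}": rng.integers(1, 12, size=40).tolist() for i in range(9)
        }
        if kruskal_wallis(samples).p_value < 0.05:
            rejections += 1
    assert rejections <= 12  # 3 binomial SEs above the nominal 5


def test_build_rank_samples_default_construction():
    results = {
        "en": [
            CaseResult(case_id="a", language="en", outcome=Outcome.RANKED,
                       rank=2, n_candidates=10),
            CaseResult(case_id="b", language="en", outcome=Outcome.NOT_RANKED,
                       n_candidates=10),
            CaseResult(case_id="c", language="en",
                       outcome=Outcome.NO_DIAGNOSIS),
        ]
    }
    assert build_rank_samples(results) == {"en": [2, 11]}
    scored = build_rank_samples(results, no_diagnosis="score")
    assert scored == {"en": [2, 11, 12]}


# --- pipeline driver -------------------------------------------------------


@pytest.fixture(scope="module")
def pipeline_inputs(tmp_path_factory):
    from babeldx.synthetic import GeneratorSpec, generate_cohort, generate_ontology

    root = tmp_path_factory.mktemp("pipeline")
    spec = GeneratorSpec(seed=5, n_diseases=25, n_phenotype_terms=90, n_cases=50)
    graph, phenotypes, lexicon, ledger = generate_ontology(spec)
    cohort, _ = generate_cohort(spec, graph, phenotypes, ledger)
    write_cohort(cohort, root / "cohort")
    (root / "graph.json").write_text(dump_disease_graph(graph), encoding="utf-8")
    (root / "lexicon.tsv").write_text(dump_lexicon(lexicon), encoding="utf-8")
    return root


def _config(root, out, seed=7, per_language=None):
    mock_spec = {
        "default": {"rank_probs": {1: 0.2, 2: 0.1, 3: 0.1}, "not_ranked": 0.55,
                    "refusal": 0.05},
        "mode": "exact",
    }
    if per_language:
        mock_spec["per_language"] = per_language
    return PipelineConfig(
        cohort_dir=str(root / "cohort"),
        lexicon_tsv=str(root / "lexicon.tsv"),
        graph_json=str(root / "graph.json"),
        out_dir=str(out),
        seed=seed,
        backend=BackendConfig(kind="mock", mock_spec=mock_spec),
    )


def test_pipeline_run_satisfies_row_sums(pipeline_inputs, tmp_path):
    result = run_pipeline(_config(pipeline_inputs, tmp_path / "out"))
    summaries = result["summaries"]
    assert len(summaries) == 9
    total_results = sum(
        len(v) for v in result["results_by_language"].values()
    )
    assert total_results == 450
    for s in summaries:
        assert s.top10 + s.not_ranked + s.no_diagnosis == s.n_total == 50
        assert s.top1 <= s.top3 <= s.top10 <= s.n_total - s.no_diagnosis


def test_pipeline_is_deterministic_across_runs(pipeline_inputs, tmp_path):
    run_pipeline(_config(pipeline_inputs, tmp_path / "a"))
    run_pipeline(_config(pipeline_inputs, tmp_path / "b"))
    for name in ("summary_counts.tsv", "summary_freq.tsv", "results.jsonl",
                 "comparison.json"):
        a = (tmp_path / "a" / name).read_bytes()
        b = (tmp_path / "b" / name).read_bytes()
        assert a == b, name


def test_per_language_planting_orders_recovered_frequencies(
    pipeline_inputs, tmp_path
):
    per_language = {
        "en": {"rank_probs": {1: 0.6}, "not_ranked": 0.4},
        "de": {"rank_probs": {1: 0.3}, "not_ranked": 0.7},
        "ja": {"rank_probs": {1: 0.1}, "not_ranked": 0.9},
    }
    result = run_pipeline(
        _config(pipeline_inputs, tmp_path / "out", per_language=per_language)
    )
    freq = {s.language: s.freq_top1 for s in result["summaries"]}
    assert freq["en"] > freq["de"] > freq["ja"]
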