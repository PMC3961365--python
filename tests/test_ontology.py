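"""Ontology traversal, specificity measures, and EASE enrichment."""

import math

import numpy as np
import pytest
from scipy import stats

from seednet.ontology import (
    OntologyDag,
    ease_enrichment,
    ease_pvalue,
    fisher_pvalue,
    go_proportion,
    information_content,
    offspring_score,
    read_annotations,
    read_obo,
    specificity_table,
)


def test_ancestor_counting(diamond_dag):
    assert diamond_dag.count_ancestors("root") == 0
    assert diamond_dag.count_ancestors("A") == 1
    # distinct-set semantics: C reaches root once despite two paths
    assert diamond_dag.count_ancestors("C") == 3
    chain = OntologyDag({"r": [], "a": [("r", "is_a")], "b": [("a", "is_a")]})
    assert chain.count_ancestors("b") == 2


def test_offspring_counting(diamond_dag):
    assert diamond_dag.count_offspring("C") == 0
    assert diamond_dag.count_offspring("root") == 3


def test_unknown_term_raises(diamond_dag):
    with pytest.raises(KeyError):
        diamond_dag.count_ancestors("nope")


def test_ancestor_offspring_containment(annotated_dag):
    """Each parent is among a child's ancestors; each child among the
    parent's offspring (DAGs forbid the naive count monotonicity)."""
    for term in annotated_dag.terms:
        for parent, _ in annotated_dag.parents(term):
            assert parent in annotated_dag.ancestors(term)
            assert term in annotated_dag.offspring(parent)


def test_cycle_rejected():
    with pytest.raises(ValueError, match="cycle|root"):
        OntologyDag({"a": [("b", "is_a")], "b": [("a", "is_a")], "r": []})


@pytest.mark.parametrize(
    "n_off,expected",
    [(1, 9.389), (2, 8.982)],
)
def test_offspring_score_table_anchors(n_off, expected):
    """Anchor rows of the published specificity table; the printed values
    carry <=1.5e-3 rounding slack (they are mutually inconsistent at the
    fourth decimal for any single root constant)."""
    assert offspring_score(n_off, 23877) == pytest.approx(expected, abs=1.5e-3)


def test_offspring_score_properties():
    assert offspring_score(23877, 23877) == 0.0
    # strictly decreasing in the offspring count
    scores = [offspring_score(n, 100) for n in range(0, 101)]
    assert all(a > b for a, b in zip(scores, scores[1:]))
    with pytest.raises(ValueError):
        offspring_score(101, 100)


def test_go_proportion_values_and_monotonicity():
    assert go_proportion(9, 1) == pytest.approx(0.9)
    assert go_proportion(8, 2) == pytest.approx(0.8)
    assert go_proportion(81, 1) == pytest.approx(81 / 82)
    assert go_proportion(0, 50) == 0.0
    # strictly increasing in ancestors at fixed offspring
    props = [go_proportion(a, 5) for a in range(0, 30)]
    assert all(x < y for x, y in zip(props, props[1:]))
    with pytest.raises(ValueError):
        go_proportion(0, 0)


def test_information_content_inversion():
    """Published IC values invert to integer annotation counts in base 2."""
    assert information_content(7, 14673) == pytest.approx(11.034, abs=5e-4)
    assert information_content(107, 14673) == pytest.approx(7.099, abs=5e-4)
    assert information_content(14673, 14673) == 0.0
    with pytest.raises(ValueError):
        information_content(0, 14673)


def test_annotation_conservation(annotated_dag):
    """Direct annotation counts sum to the number of annotation records."""
    direct = annotated_dag.direct_annotation_sets()
    total_records = sum(len(ts) for ts in annotated_dag.annotations.values())
    assert sum(len(ps) for ps in direct.values()) == total_records


def test_annotation_propagation(annotated_dag):
    prop = annotated_dag.propagated_annotation_sets()
    # root annotates every annotated protein
    assert prop["root"] == set(annotated_dag.annotations)
    # leaf2 is part_of mid2, so its proteins propagate there too
    assert {"p2", "p5"} <= prop["mid2"]


def test_ease_matches_hypergeometric_oracle():
    """Study 10 of population 100; a term annotating 10 with 4 study hits
    has EASE p equal to the hypergeometric tail P(X >= 3)."""
    expected = sum(
        stats.hypergeom.pmf(x, 100, 10, 10) for x in range(3, 11)
    )
    assert ease_pvalue(4, 10, 10, 100) == pytest.approx(expected)


def test_ease_single_hit_never_enriched():
    assert ease_pvalue(1, 10, 10, 100) == 1.0


def test_ease_full_population_term():
    assert ease_pvalue(10, 10, 100, 100) == pytest.approx(1.0)


def test_ease_conservative_vs_fisher(rng):
    """EASE p >= plain Fisher p on random tables; both match the
    hypergeometric tail oracle."""
    for _ in range(1000):
        N = int(rng.integers(10, 200))
        K = int(rng.integers(1, N + 1))
        n = int(rng.integers(1, N + 1))
        k_max = min(K, n)
        k = int(rng.integers(0, k_max + 1))
        ease = ease_pvalue(k, n, K, N)
        fisher = fisher_pvalue(k, n, K, N)
        assert ease >= fisher - 1e-12
        oracle = float(stats.hypergeom.sf(k - 1, N, K, n))
        assert fisher == pytest.approx(oracle)


def test_enrichment_on_planted_term(annotated_dag):
    res = ease_enrichment(annotated_dag, {"p1", "p2"}, alpha=None)
    by_term = {r.term: r for r in res}
    # both study proteins annotate leaf1 -> strongest enrichment there
    assert "leaf1" in by_term
    assert by_term["leaf1"].study_count == 2
    best = min(res, key=lambda r: r.ease_p)
    assert best.term in ("leaf1", "mid1")
    with pytest.raises(ValueError):
        ease_enrichment(annotated_dag, {"p1", "nope"})


def test_specificity_table_composition(annotated_dag):
    rows = specificity_table(annotated_dag, ["root", "mid1", "leaf1"], A=23877)
    by_term = {r.term: r for r in rows}
    assert by_term["root"].go_proportion == 0.0
    assert by_term["root"].information_content == 0.0
    m = by_term["mid1"]
    assert m.n_ancestors == 1 and m.n_offspring == 2
    assert m.offspring_score == pytest.approx(math.log(23878 / 3))
    assert m.go_proportion == pytest.approx(1 / 3)
    # leaf1 has no scored offspring -> most specific; mid1 has leaf1 scored
    assert by_term["leaf1"].most_specific
    assert not by_term["mid1"].most_specific


def test_specificity_sort_is_stable_on_ties():
    dag = OntologyDag(
        {"r": [], "x1": [("r", "is_a")], "x2": [("r", "is_a")]}
    )
    rows = specificity_table(dag, ["x1", "x2"], A=10, total_annotated=1)
    assert [r.term for r in rows] == ["x1", "x2"]  # tie -> term-ID order


def test_obo_roundtrip(tmp_path):
    from seednet.synthetic import write_obo

    parents = {
        "T:R": [],
        "T:A": [("T:R", "is_a")],
        "T:B": [("T:R", "is_a"), ("T:A", "part_of")],
    }
    obo = write_obo(parents, tmp_path / "toy.obo")
    (tmp_path / "ann.tsv").write_text("p1\tT:B\np2\tT:A\n")
    dag = read_obo(obo, read_annotations(tmp_path / "ann.tsv"))
    assert dag.root == "T:R"
    assert dag.count_ancestors("T:B") == 2
    assert set(dag.parents("T:B")) == {("T:R", "is_a"), ("T:A", "part_of")}
    assert dag.protein_terms("p1") == {"T:B"}
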