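import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from enuscreen.errors import ParameterError
from enuscreen.filtering import build_event_matrix, compute_burdens
from enuscreen.slapenrich import (
    enrichment_to_frame,
    exclusive_coverage,
    pathway_block_length,
    pathway_enrichment,
    poisson_binomial_tail,
    sample_pathway_prob,
)
from ._oracles import enumerate_poisson_binomial_tail


def test_pathway_block_length_sums_union(small_genome):
    genes = [g.gene_id for g in small_genome.genes[:2]]
    expected = sum(small_genome.genes[i].coding_length for i in range(2))
    assert pathway_block_length(genes, small_genome) == expected
    # duplicates count once (set semantics)
    assert pathway_block_length(genes + [genes[0]], small_genome) == expected
    with pytest.raises(ParameterError):
        pathway_block_length([], small_genome)
    with pytest.raises(ParameterError):
        pathway_block_length(["nope"], small_genome)


def test_sample_pathway_prob_closed_forms():
    assert sample_pathway_prob(100, 100, 10000, "poisson") == pytest.approx(
        1 - np.exp(-1), abs=1e-12
    )
    assert sample_pathway_prob(0, 100, 10000, "poisson") == 0.0
    assert sample_pathway_prob(0, 100, 10000, "bernoulli") == 0.0
    assert sample_pathway_prob(1, 100, 10000, "bernoulli") == pytest.approx(0.01)
    with pytest.raises(ParameterError):
        sample_pathway_prob(5, 200, 100)


def test_poisson_binomial_special_cases():
    assert poisson_binomial_tail([0.5] * 10, 10) == pytest.approx(0.5**10, abs=1e-15)
    assert poisson_binomial_tail([0.1, 0.2, 0.3], 2) == pytest.approx(0.098, abs=1e-12)
    assert poisson_binomial_tail([0.3, 0.9], 0) == 1.0
    with pytest.warns(UserWarning):
        assert poisson_binomial_tail([0.5, 0.5], 3) == 0.0


def test_poisson_binomial_matches_enumeration():
    rng = np.random.default_rng(12)
    for _ in range(30):
        n = int(rng.integers(1, 13))
        probs = rng.random(n)
        o = int(rng.integers(0, n + 1))
        assert poisson_binomial_tail(probs, o) == pytest.approx(
            enumerate_poisson_binomial_tail(probs, o), abs=1e-12
        )


@settings(deadline=None, derandomize=True, max_examples=40)
@given(
    st.lists(st.floats(0, 1), min_size=2, max_size=20),
    st.floats(0.001, 0.999),
    st.integers(0, 20),
)
def test_tail_is_monotone_in_success_probabilities(probs, bump, o_raw):
    """Increasing any p_i stochastically increases X, so P(X >= o) cannot
    decrease."""
    o = min(o_raw, len(probs))
    base = poisson_binomial_tail(probs, o)
    bumped = list(probs)
    bumped[0] = min(1.0, bumped[0] + bump)
    assert poisson_binomial_tail(bumped, o) >= base - 1e-12


def _matrix(cells, genes, samples):
    m = pd.DataFrame(0, index=genes, columns=samples, dtype=int)
    for g, s in cells:
        m.loc[g, s] = 1
    return m


def test_exclusive_coverage_counts():
    m = _matrix(
        [("A", "s1"), ("A", "s2"), ("B", "s2"), ("B", "s3")], ["A", "B"], ["s1", "s2", "s3"]
    )
    assert exclusive_coverage(m, {"A", "B"}) == pytest.approx(2 / 3)
    # perfect exclusivity
    m2 = _matrix([("A", "s1"), ("B", "s2")], ["A", "B"], ["s1", "s2"])
    assert exclusive_coverage(m2, {"A", "B"}) == 1.0
    # one covered sample hit in all three genes
    m3 = _matrix([("A", "s1"), ("B", "s1"), ("C", "s1")], ["A", "B", "C"], ["s1"])
    assert exclusive_coverage(m3, {"A", "B", "C"}) == 0.0
    # zero coverage -> undefined
    m4 = _matrix([], ["A"], ["s1"])
    assert exclusive_coverage(m4, {"A"}) is None
    with pytest.raises(ParameterError):
        exclusive_coverage(m, {"Z"})


@pytest.fixture()
def toy_enrichment(small_genome):
    samples = [f"s{i}" for i in range(6)]
    pathways = small_genome.pathway_collection
    target = small_genome.resistance_pathway
    target_genes = sorted(pathways[target])
    cells = [(target_genes[i % len(target_genes)], s) for i, s in enumerate(samples)]
    matrix = _matrix(cells, sorted({g for g, _ in cells}), samples)
    burdens = pd.Series(2, index=samples)
    return matrix, burdens, pathways, target


def test_enrichment_flags_exclusively_covered_pathway(small_genome, toy_enrichment):
    matrix, burdens, pathways, target = toy_enrichment
    results = pathway_enrichment(matrix, burdens, pathways, small_genome)
    frame = enrichment_to_frame(results)
    top = frame.iloc[0]
    assert top["pathway_id"] == target
    assert top["enriched"] and top["exclusive_coverage"] == 1.0
    assert top["observed"] == 6
    # expected equals the sum of per-sample probabilities exactly
    r = [x for x in results if x.pathway_id == target][0]
    assert r.expected == pytest.approx(r.sample_probs.sum())


def test_enrichment_invariant_under_sample_permutation(small_genome, toy_enrichment):
    matrix, burdens, pathways, target = toy_enrichment
    a = enrichment_to_frame(
        pathway_enrichment(matrix, burdens, pathways, small_genome)
    )
    perm = list(matrix.columns[::-1])
    b = enrichment_to_frame(
        pathway_enrichment(matrix[perm], burdens[perm], pathways, small_genome)
    )
    pd.testing.assert_frame_equal(a, b)


def test_zero_burden_screen_is_null(small_genome):
    samples = ["s1", "s2"]
    matrix = _matrix([], [small_genome.genes[0].gene_id], samples)
    burdens = pd.Series(0, index=samples)
    results = pathway_enrichment(
        matrix, burdens, small_genome.pathway_collection, small_genome
    )
    for r in results:
        assert r.expected == 0.0 and r.observed == 0 and r.pvalue == 1.0
        assert not r.enriched
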