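import numpy as np
import pytest
from scipy import stats

from enuscreen.channels import encode
from enuscreen.errors import GenerationError, ParameterError
from enuscreen.genome import GeneModel, GenomeModel
from enuscreen.catalog import channel_of_variant
from enuscreen.signature import default_enu_signature
from enuscreen.simulate import (
    ScreenConfig,
    find_missense_snv,
    simulate_clone,
    simulate_screen,
)
from ._oracles import connected_components_oracle


@pytest.fixture(scope="module")
def sig():
    return default_enu_signature()


def test_clone_has_requested_burden(small_genome, sig):
    cvs = simulate_clone(small_genome, sig, 470, 20, seed=1)
    assert len(cvs) == 490
    n_snv = sum(1 for v in cvs.variants if v.vtype == "SNV")
    assert n_snv == 470
    assert n_snv / len(cvs) == pytest.approx(0.96, abs=0.005)
    assert all(v.parental_alt == 0 for v in cvs.variants)


def test_empty_burden_with_driver_yields_only_driver(small_genome, sig):
    rng = np.random.default_rng(5)
    gene = small_genome.genes[3]
    driver = find_missense_snv(small_genome, gene, rng)
    cvs = simulate_clone(small_genome, sig, 0, 0, driver=driver, seed=2)
    assert len(cvs) == 1
    v = cvs.variants[0]
    assert v.key == driver.key and v.consequence == "missense"


def test_sampled_channels_match_signature(small_genome, sig):
    """Chi-square goodness of fit of sampled channels to the target profile
    is non-significant at alpha=0.01 in at least 9 of 10 seeds."""
    ok = 0
    active = np.flatnonzero(sig.channel_probs > 0)
    for seed in range(10):
        cvs = simulate_clone(small_genome, sig, 10000, 0, seed=100 + seed)
        counts = np.zeros(96)
        for v in cvs.variants:
            counts[channel_of_variant(v)] += 1
        expected = sig.channel_probs[active] * counts.sum()
        chi2, p = stats.chisquare(counts[active], expected)
        ok += p > 0.01
    assert ok >= 9


def test_generation_error_names_unavailable_channel():
    # a genome whose only context is A-homopolymer cannot host most channels
    cds = "A" * 300
    gene = GeneModel("G0", "chr1", 11, "+", cds)
    genome = GenomeModel(
        genes=[gene],
        pathway_collection={},
        chrom_codes={"chr1": encode("A" * 320)},
    )
    with pytest.raises(GenerationError, match=r"\["):
        simulate_clone(genome, default_enu_signature(), 10, 0, seed=0)


@pytest.fixture(scope="module")
def small_screen(small_genome):
    # a single hypermutator: two MSI-heavy clones can legitimately share
    # >3 variants by chance, which would add a chance edge to the sharing
    # graph that the constructed ground truth does not model
    cfg = ScreenConfig(
        seed=11,
        n_clones=24,
        n_substitutions=60,
        n_hypermutators=1,
        n_related_sets=3,
        related_set_size=4,
    )
    return cfg, simulate_screen(cfg, genome=small_genome)


def test_related_sets_force_fifteen_groups(small_screen):
    """3 related sets of 4 plus 12 singletons = 15 groups, confirmed by an
    independent union-find oracle on pairwise sharing."""
    cfg, (clones, parental, truth, genome) = small_screen
    keys = {c.clone_id: c.keys for c in clones}
    ids = sorted(keys)
    edges = [
        (a, b)
        for i, a in enumerate(ids)
        for b in ids[i + 1 :]
        if len(keys[a] & keys[b]) > 3
    ]
    components = connected_components_oracle(ids, edges)
    assert len(components) == 15
    truth_groups = sorted(
        (sorted(g) for g in truth.expected_groups()), key=lambda g: g[0]
    )
    assert sorted((sorted(c) for c in components), key=lambda g: g[0]) == truth_groups


def test_hypermutators_have_multiplied_burden(small_screen):
    cfg, (clones, parental, truth, genome) = small_screen
    counts = {c.clone_id: len(c) for c in clones}
    normal = np.median(
        [n for cid, n in counts.items() if cid not in truth.hypermutator_clones]
    )
    assert truth.hypermutator_clones
    for cid in truth.hypermutator_clones:
        assert counts[cid] / normal == pytest.approx(
            cfg.hypermutator_multiplier, rel=0.15
        )


def test_shared_subclonal_vafs_straddle_filter_threshold(small_screen):
    cfg, (clones, parental, truth, genome) = small_screen
    vafs = [sv["parental_vaf"] for sv in truth.shared_subclonal_variants]
    assert any(v >= 0.005 for v in vafs) and any(v < 0.005 for v in vafs)


def test_truth_consistency_one_driver_per_clone(small_screen):
    cfg, (clones, parental, truth, genome) = small_screen
    pathway = genome.pathway_collection[truth.driver_pathway]
    by_id = {c.clone_id: c for c in clones}
    for cid, (gene_id, key) in truth.driver_assignments.items():
        assert gene_id in pathway
        assert key in by_id[cid].keys
    assert set(truth.driver_assignments) == set(by_id)


def test_screen_is_deterministic(small_genome):
    cfg = ScreenConfig(seed=3, n_clones=6, n_substitutions=40, n_related_sets=1,
                       related_set_size=2, n_hypermutators=1)
    a = simulate_screen(cfg, genome=small_genome)
    b = simulate_screen(cfg, genome=small_genome)
    assert [c.keys for c in a[0]] == [c.keys for c in b[0]]
    assert a[1].equals(b[1])


def test_invalid_screen_config_lists_offending_keys():
    cfg = ScreenConfig(n_clones=4, n_related_sets=3, related_set_size=4)
    with pytest.raises(ParameterError, match="n_related_sets"):
        cfg.validate()
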