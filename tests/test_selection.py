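import numpy as np
import pytest

from enuscreen.errors import ParameterError
from enuscreen.channels import CHANNEL_NAMES
from enuscreen.genome import SENSE_CODONS
from enuscreen.selection import (
    CloneGroup,
    MutationSpectrum,
    estimate_rate_dispersion,
    estimate_spectrum,
    fisher_combine,
    gene_change_table,
    gene_dnds_test,
    gene_opportunities,
    indel_recurrence_test,
    merge_related_clones,
    rank_resistance_genes,
    stratified_fdr,
)
from enuscreen.simulate import simulate_clone
from enuscreen.signature import signature_from_class_weights
from enuscreen.variants import CloneVariantSet, Variant
from ._oracles import opportunity_oracle


def _clone(cid, positions):
    return CloneVariantSet(
        cid, [Variant(cid, "chr1", p, "C", "T", 0, 10) for p in positions]
    )


def test_sharing_exactly_three_is_not_merged():
    a = _clone("a", [1, 2, 3, 10])
    b = _clone("b", [1, 2, 3, 20])
    groups = merge_related_clones([a, b], min_shared=3)
    assert len(groups) == 2  # strictly more than three required


def test_transitive_merging_single_group():
    a = _clone("a", [1, 2, 3, 4, 10, 11])
    b = _clone("b", [1, 2, 3, 4, 20, 21, 30, 31, 32, 33])
    c = _clone("c", [30, 31, 32, 33, 20, 40])
    groups = merge_related_clones([a, b, c], min_shared=3)
    assert len(groups) == 1
    assert groups[0].member_clones == {"a", "b", "c"}
    keys = [v.key for v in groups[0].variants]
    assert len(keys) == len(set(keys))  # union deduplicated
    assert {k[1] for k in keys} == {1, 2, 3, 4, 10, 11, 20, 21, 30, 31, 32, 33, 40}


def test_no_sharing_gives_singletons_and_partition_is_order_free():
    clones = [_clone(f"c{i}", [100 * i + j for j in range(5)]) for i in range(6)]
    groups = merge_related_clones(clones)
    assert len(groups) == 6
    shuffled = merge_related_clones(clones[::-1])
    assert sorted(
        (frozenset(g.member_clones) for g in groups), key=sorted
    ) == sorted((frozenset(g.member_clones) for g in shuffled), key=sorted)
    # partition: every clone in exactly one group
    all_members = [c for g in groups for c in g.member_clones]
    assert sorted(all_members) == sorted(c.clone_id for c in clones)


def test_uniform_sampling_yields_flat_spectrum(small_genome):
    """Mutations drawn from a flat profile give channel rates near 1 after
    context-availability normalization."""
    flat = signature_from_class_weights(np.ones(6))
    cvs = simulate_clone(small_genome, flat, 20000, 0, seed=5, clone_id="u")
    spec = estimate_spectrum(
        [CloneGroup("g", {"u"}, cvs.variants)], small_genome
    )
    assert spec.rates.mean() == pytest.approx(1.0, abs=1e-9)
    counts_based = spec.rates[spec.available > 0]
    # ~208 expected per channel; 3 binomial SEs relative ~ 0.21
    assert np.all(np.abs(counts_based - 1) < 0.35)


def test_spectrum_scale_invariance(small_genome):
    # enough draws that every channel is observed; the zero-count floor
    # would otherwise not scale with the counts
    cvs = simulate_clone(
        small_genome, signature_from_class_weights(np.ones(6)), 20000, 0, seed=8, clone_id="u"
    )
    one = estimate_spectrum([CloneGroup("g", {"u"}, cvs.variants)], small_genome)
    doubled = estimate_spectrum(
        [
            CloneGroup("g1", {"u"}, cvs.variants),
            CloneGroup("g2", {"u"}, cvs.variants),
        ],
        small_genome,
    )
    assert np.allclose(one.rates, doubled.rates)


def test_gene_opportunities_match_exhaustive_oracle(single_gene_genome_factory):
    rng = np.random.default_rng(123)
    cds = "".join(rng.choice(SENSE_CODONS, size=30))  # 90 bp, 270 changes
    genome = single_gene_genome_factory(cds)
    gene = genome.genes[0]
    rates = rng.gamma(2.0, 0.5, size=96)
    rates /= rates.mean()
    spectrum = MutationSpectrum(rates=rates, available=np.ones(96, dtype=int))
    got = gene_opportunities(gene, spectrum)
    want = opportunity_oracle(cds, dict(zip(CHANNEL_NAMES, rates)))
    for key in ("R_syn", "R_mis", "R_non"):
        assert got[key] == pytest.approx(want[key], rel=1e-12)
    assert got["R_splice"] == 0.0


def test_uniform_spectrum_collapses_to_site_counts(single_gene_genome_factory):
    cds = "".join(np.random.default_rng(4).choice(SENSE_CODONS, size=50))
    genome = single_gene_genome_factory(cds)
    gene = genome.genes[0]
    uniform = MutationSpectrum(rates=np.ones(96), available=np.ones(96, dtype=int))
    got = gene_opportunities(gene, uniform)
    counts, terminal = gene_change_table(gene)
    for i, key in enumerate(("R_syn", "R_mis", "R_non")):
        assert got[key] == pytest.approx(counts[i].sum() + terminal[i])
    total = sum(got[k] for k in ("R_syn", "R_mis", "R_non", "R_splice"))
    assert total == pytest.approx(3 * gene.coding_length)


def test_tryptophan_repeat_gene_has_nonsense_opportunity(single_gene_genome_factory):
    genome = single_gene_genome_factory("TGG" * 30)
    uniform = MutationSpectrum(rates=np.ones(96), available=np.ones(96, dtype=int))
    got = gene_opportunities(genome.genes[0], uniform)
    assert got["R_non"] > 0  # TGG -> TGA / TAG


def test_dnds_exact_null_fit_has_unit_omega_and_p_one():
    R = {"R_syn": 100.0, "R_mis": 300.0, "R_non": 0.0, "R_splice": 0.0}
    omega, _, p_mis, p_sub = gene_dnds_test(
        {"n_syn": 10, "n_mis": 30}, R, background_syn_rate=10 / 100.0
    )
    assert omega == pytest.approx(1.0)
    assert p_mis == pytest.approx(1.0)
    assert p_sub == pytest.approx(1.0)


def test_dnds_zero_missense_boundary():
    R = {"R_syn": 100.0, "R_mis": 300.0, "R_non": 20.0, "R_splice": 0.0}
    omega, _, p_mis, _ = gene_dnds_test(
        {"n_syn": 10, "n_mis": 0}, R, background_syn_rate=0.1
    )
    assert omega == 0.0
    assert 0 < p_mis <= 1


def test_rate_dispersion_shrinks_with_overdispersion():
    rng = np.random.default_rng(6)
    R = np.full(3000, 500.0)
    g = 0.02
    homogeneous = rng.poisson(g * R)
    mixed = rng.poisson(g * R * rng.gamma(2.0, 0.5, size=3000))
    th_hom = estimate_rate_dispersion(homogeneous, R, homogeneous.sum() / R.sum())
    th_mix = estimate_rate_dispersion(mixed, R, mixed.sum() / R.sum())
    assert th_hom > 50
    assert th_mix < 10  # Gamma(2) rate variation detected


def test_indel_recurrence_closed_forms():
    assert indel_recurrence_test(0, 1e-5, 1000) == 1.0
    # lambda = 0.5, n = 3: 1 - e^-0.5 (1 + 0.5 + 0.125)
    assert indel_recurrence_test(3, 0.0005, 1000) == pytest.approx(
        1 - np.exp(-0.5) * (1 + 0.5 + 0.125), abs=1e-10
    )
    assert indel_recurrence_test(5, 0.0005, 1000) < indel_recurrence_test(3, 0.0005, 1000)


def test_fisher_combination_closed_forms():
    assert fisher_combine(1.0, 1.0) == pytest.approx(1.0)
    # chi2(4) upper tail at X2 = -2(ln .1 + ln .1)
    assert fisher_combine(0.1, 0.1) == pytest.approx(0.05605, abs=5e-5)
    for p in (0.3, 0.05, 0.9):
        # analytic identity for df=4: combine(p, 1) = p (1 - ln p)
        assert fisher_combine(p, 1.0) == pytest.approx(p * (1 - np.log(p)), rel=1e-10)
    with pytest.raises(ParameterError):
        fisher_combine(0.0, 0.5)


def test_stratified_fdr_bh_by_hand():
    p = np.array([0.01, 0.02, 0.03, 0.04])
    assert np.allclose(stratified_fdr(p), [0.04, 0.04, 0.04, 0.04])
    two = np.concatenate([p, p])
    labels = np.array([0, 0, 0, 0, 1, 1, 1, 1])
    assert np.allclose(stratified_fdr(two, labels), [0.04] * 8)
    assert np.allclose(stratified_fdr(np.ones(5)), 1.0)


def test_rank_rule_is_or_of_the_two_qvalues():
    import pandas as pd

    frame = pd.DataFrame(
        {
            "qmis_sfdr": [0.04, 0.06, 0.2],
            "qglobal_sfdr": [0.2, 0.06, 0.01],
            "min_q": [0.04, 0.06, 0.01],
        },
        index=["g1", "g2", "g3"],
    )
    flagged = rank_resistance_genes(frame)
    assert list(flagged.index) == ["g3", "g1"]  # sorted by min q; g2 excluded
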