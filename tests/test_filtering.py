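import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from enuscreen.errors import DataError
from enuscreen.filtering import (
    build_event_matrix,
    filter_parental_subclonal,
    read_variants,
    spectrum_summary,
)
from enuscreen.genome import SENSE_CODONS
from enuscreen.variants import Variant, classify_consequence
from ._oracles import classify_snv_oracle


def _v(palt, pdep, pos=100, clone="c1"):
    return Variant(clone, "chr1", pos, "C", "T", palt, pdep)


@pytest.mark.parametrize(
    "palt,pdep,removed",
    [
        (5, 1000, True),   # exactly 0.5%: "0.5% or more" is removed
        (6, 1000, True),
        (1, 1000, False),  # 0.1% retained
        (0, 200, False),   # zero evidence retained
    ],
)
def test_parental_vaf_threshold_boundary(palt, pdep, removed):
    kept, rem = filter_parental_subclonal([_v(palt, pdep)])
    assert (len(rem) == 1) is removed
    assert len(kept) + len(rem) == 1


def test_zero_depth_kept_and_flagged():
    kept, rem = filter_parental_subclonal([_v(0, 0)])
    assert len(kept) == 1 and not rem
    assert "no_parental_evidence" in kept[0].flags


def test_negative_counts_rejected_at_construction():
    with pytest.raises(DataError):
        Variant("c", "chr1", 1, "C", "T", -1, 10)
    with pytest.raises(DataError):
        Variant("c", "chr1", 1, "C", "T", 11, 10)


@settings(deadline=None, derandomize=True)
@given(
    st.lists(
        st.tuples(st.integers(0, 50), st.integers(0, 5000)),
        min_size=0,
        max_size=60,
    )
)
def test_filter_partitions_input_and_preserves_order(counts):
    variants = [
        _v(min(a, d), d, pos=i + 1, clone=f"c{i % 3}")
        for i, (a, d) in enumerate(counts)
    ]
    kept, removed = filter_parental_subclonal(variants)
    assert len(kept) + len(removed) == len(variants)
    assert {id(v) for v in kept} | {id(v) for v in removed} == {id(v) for v in variants}
    kept_pos = [v.pos for v in kept]
    assert kept_pos == sorted(kept_pos)
    for v in removed:
        assert v.parental_depth > 0 and v.parental_alt / v.parental_depth >= 0.005
    for v in kept:
        assert v.parental_depth == 0 or v.parental_alt / v.parental_depth < 0.005


def test_consequence_classifier_agrees_with_translation_oracle(
    single_gene_genome_factory,
):
    """Every possible single-base change of a 999-bp random CDS is classified
    identically by the codon classifier and whole-protein translation."""
    rng = np.random.default_rng(77)
    cds = "".join(rng.choice(SENSE_CODONS, size=333))
    genome = single_gene_genome_factory(cds)
    gene = genome.genes[0]
    mismatches = 0
    for i, ref in enumerate(cds):
        for alt in "ACGT":
            if alt == ref:
                continue
            v = Variant("c", gene.chrom, gene.cds_start + i, ref, alt, 0, 0)
            got = classify_consequence(v, gene)
            expected = classify_snv_oracle(cds, i, alt)
            mismatches += got != expected
    assert mismatches == 0


def test_indel_consequence_by_length_mod_three(single_gene_genome_factory):
    genome = single_gene_genome_factory("".join(np.random.default_rng(3).choice(SENSE_CODONS, 40)))
    gene = genome.genes[0]
    chrom_seq = genome.ref_slice(gene.chrom, 1, genome.chrom_length(gene.chrom))
    pos = gene.cds_start + 5
    ref2 = genome.ref_slice(gene.chrom, pos, 3)
    frameshift = Variant("c", gene.chrom, pos, ref2, ref2[0], 0, 0)
    assert classify_consequence(frameshift, gene) == "frameshift_indel"
    ref3 = genome.ref_slice(gene.chrom, pos, 4)
    inframe = Variant("c", gene.chrom, pos, ref3, ref3[0], 0, 0)
    assert classify_consequence(inframe, gene) == "inframe_indel"
    outside = Variant("c", gene.chrom, 2, genome.ref_slice(gene.chrom, 2, 2),
                      genome.ref_slice(gene.chrom, 2, 1), 0, 0)
    assert classify_consequence(outside, gene) == "noncoding"


def _annotated(clone, gene, consequence, pos=10):
    v = Variant(clone, "chr1", pos, "C", "T", 0, 100)
    v.gene_id = gene
    v.consequence = consequence
    return v


def test_event_matrix_minimal_and_binary():
    variants = [
        _annotated("clone1", "geneA", "missense"),
        _annotated("clone1", "geneA", "missense", pos=20),  # still 1, binary
        _annotated("clone2", "geneB", "synonymous"),  # non-qualifying
    ]
    m = build_event_matrix(variants, ["clone1", "clone2"])
    assert list(m.index) == ["geneA"]
    assert m.loc["geneA", "clone1"] == 1
    assert m.loc["geneA", "clone2"] == 0
    assert set(np.unique(m.to_numpy())) <= {0, 1}


def test_event_matrix_rejects_unknown_sample():
    with pytest.raises(DataError):
        build_event_matrix([_annotated("ghost", "geneA", "missense")], ["clone1"])


def test_spectrum_summary_fractions_and_intermutation():
    variants = [
        Variant("c", "chr1", 100 + i, "C", "T", 0, 10) for i in range(96)
    ] + [Variant("c", "chr1", 500 + i, "CT", "C", 0, 10) for i in range(4)]
    out = spectrum_summary(variants)
    assert out["categories"].loc["SNV", "fraction"] == pytest.approx(0.96)
    assert out["classes"].loc["C>T", "fraction"] == pytest.approx(1.0)

    three = [Variant("c", "chrZ", p, "C", "A", 0, 10) for p in (100, 250, 400)]
    dist = spectrum_summary(three)["intermutation"]
    assert sorted(dist["distance"]) == [150, 150]


def test_spectrum_summary_empty_input():
    out = spectrum_summary([])
    assert out["categories"].empty and out["intermutation"].empty


def test_read_variants_splits_multiallelic_and_flags_ref_mismatch(
    small_genome, tmp_path
):
    gene = small_genome.genes[0]
    # find a C inside the gene for a clean multi-allelic record
    off = gene.coding_sequence.index("C", 5)
    pos = gene.cds_start + off
    vcf = tmp_path / "t.vcf"
    lines = [
        "##fileformat=VCFv4.2",
        '##INFO=<ID=PALT,Number=1,Type=Integer,Description="x">',
        '##INFO=<ID=PDEP,Number=1,Type=Integer,Description="x">',
        f"##contig=<ID={gene.chrom}>",
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO",
        f"{gene.chrom}\t{pos}\t.\tC\tT,G\t.\tPASS\tPALT=0;PDEP=100",
        f"{gene.chrom}\t{pos + 3}\t.\tNNN\tN\t.\tPASS\tPALT=2;PDEP=100",
    ]
    vcf.write_text("\n".join(lines) + "\n")
    variants = read_variants(vcf, small_genome, clone_id="cX")
    assert len(variants) == 3  # multi-allelic split into two + mismatch record
    assert variants[0].alt == "T" and variants[1].alt == "G"
    assert variants[0].vtype == "SNV"
    assert "ref_mismatch" in variants[2].flags
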