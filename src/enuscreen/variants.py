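"""Somatic variant records and coding-consequence classification."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio.Seq import Seq

from .channels import pyrimidine_context_str
from .errors import DataError
from .genome import GeneModel, GenomeModel

SNV = "SNV"
INSERTION = "insertion"
DELETION = "deletion"

SYNONYMOUS = "synonymous"
MISSENSE = "missense"
NONSENSE = "nonsense"
SPLICE = "splice"
FRAMESHIFT = "frameshift_indel"
INFRAME = "inframe_indel"
NONCODING = "noncoding"

QUALIFYING_DEFAULT = frozenset({MISSENSE, NONSENSE, SPLICE, FRAMESHIFT, INFRAME})

# codon (base-4 index) -> amino acid, via the standard genetic code
CODON_AA = np.array(
    [
        str(Seq("".join(("ACGT"[i // 16], "ACGT"[(i // 4) % 4], "ACGT"[i % 4]))).translate())
        for i in range(64)
    ]
)


@dataclass
class Variant:
    """One somatic call with parental read evidence.

    Coordinates are 1-based inclusive, VCF-style; for indels ``pos`` is the
    anchor base.  ``context`` is the pyrimidine-normalized trinucleotide,
    defined only for SNVs inside a gene.
    """

    clone_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    parental_alt: int = 0
    parental_depth: int = 0
    gene_id: str | None = None
    context: str | None = None
    consequence: str | None = None
    flags: set[str] = field(default_factory=set)

    def __post_init__(self):
        if self.parental_alt < 0 or self.parental_depth < 0:
            raise DataError(
                f"{self.chrom}:{self.pos} negative parental read counts"
            )
        if self.parental_alt > self.parental_depth:
            raise DataError(
                f"{self.chrom}:{self.pos} parental_alt {self.parental_alt} exceeds "
                f"depth {self.parental_depth}"
            )

    @property
    def vtype(self) -> str:
        if len(self.ref) == 1 and len(self.alt) == 1:
            return SNV
        if len(self.alt) > len(self.ref):
            return INSERTION
        return DELETION

    @property
    def indel_length(self) -> int:
        return abs(len(self.alt) - len(self.ref))

    @property
    def parental_vaf(self) -> float | None:
        if self.parental_depth == 0:
            return None
        return self.parental_alt / self.parental_depth

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass
class CloneVariantSet:
    """All somatic variants of one clone."""

    clone_id: str
    variants: list[Variant]

    def __len__(self) -> int:
        return len(self.variants)

    @property
    def keys(self) -> set[tuple[str, int, str, str]]:
        return {v.key for v in self.variants}


def classify_consequence(variant: Variant, gene: GeneModel) -> str:
    """Coding consequence of a variant with respect to a gene's CDS.

    SNVs are classified by translating the affected codon before and after
    the change (synonymous / missense / nonsense); indels by whether the
    inserted or deleted length is a multiple of 3.  Positions outside the
    CDS are noncoding.  Synthetic genes are single-exon, so no splice-site
    calls arise here; the category exists for multi-exon gene models.
    """
    if variant.vtype == SNV:
        if not gene.contains(variant.pos):
            return NONCODING
        off = variant.pos - gene.cds_start  # 0-based within CDS
        codon_start = (off // 3) * 3
        codon = list(gene.coding_sequence[codon_start : codon_start + 3])
        if codon[off % 3] != variant.ref:
            raise DataError(
                f"{variant.chrom}:{variant.pos} REF {variant.ref} does not match "
                f"CDS base {codon[off % 3]} of {gene.gene_id}"
            )
        aa_before = CODON_AA[_codon_index(codon)]
        codon[off % 3] = variant.alt
        aa_after = CODON_AA[_codon_index(codon)]
        if aa_after == aa_before:
            return SYNONYMOUS
        if aa_after == "*":
            return NONSENSE
        return MISSENSE
    # indel: classify by overlap of the changed bases with the CDS
    if variant.vtype == DELETION:
        first_changed = variant.pos + 1
        last_changed = variant.pos + len(variant.ref) - 1
        overlaps = first_changed <= gene.cds_end and last_changed >= gene.cds_start
    else:
        overlaps = gene.contains(variant.pos)
    if not overlaps:
        return NONCODING
    return FRAMESHIFT if variant.indel_length % 3 else INFRAME


def _codon_index(codon) -> int:
    lut = {"A": 0, "C": 1, "G": 2, "T": 3}
    return lut[codon[0]] * 16 + lut[codon[1]] * 4 + lut[codon[2]]


def annotate_variant(variant: Variant, genome: GenomeModel) -> Variant:
    """Fill gene_id, trinucleotide context and consequence in place."""
    gene = genome.gene_at(variant.chrom, variant.pos)
    if gene is None:
        variant.gene_id = None
        variant.context = None
        variant.consequence = NONCODING
        return variant
    variant.gene_id = gene.gene_id
    variant.consequence = classify_consequence(variant, gene)
    if variant.vtype == SNV:
        pos0 = variant.pos - 1
        codes = genome.chrom_codes[variant.chrom]
        if 1 <= pos0 <= len(codes) - 2:
            five = genome.ref_slice(variant.chrom, variant.pos - 1)
            three = genome.ref_slice(variant.chrom, variant.pos + 1)
            variant.context = pyrimidine_context_str(five, variant.ref, three)
    return variant


def annotate_variants(variants: list[Variant], genome: GenomeModel) -> list[Variant]:
    for v in variants:
        annotate_variant(v, genome)
    return variants
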