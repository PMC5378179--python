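"""Synthetic genome models: gene coding sequences, pathway sets, site indexes.

A :class:`GenomeModel` is the shared reference for variant annotation,
mutational opportunity calculations, and screen simulation.  Synthetic
genomes are laid out as a small number of chromosomes, each a concatenation
of single-exon coding sequences separated by short random spacers, so that
variants carry ordinary chromosomal coordinates and the reference base at
any position can be checked against the FASTA.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property

import numpy as np

from .channels import N_CONTEXTS, context_classes, decode, encode
from .errors import ParameterError

# the 61 sense codons (no TAA/TAG/TGA), used to build ORFs free of
# in-frame internal stops
_STOPS = {"TAA", "TAG", "TGA"}
SENSE_CODONS = tuple(
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in _STOPS
)


@dataclass
class GeneModel:
    """A single-exon coding gene placed on a synthetic chromosome."""

    gene_id: str
    chrom: str
    cds_start: int  # 1-based inclusive
    strand: str
    coding_sequence: str

    @property
    def coding_length(self) -> int:
        return len(self.coding_sequence)

    @property
    def cds_end(self) -> int:
        """1-based inclusive end coordinate."""
        return self.cds_start + self.coding_length - 1

    @cached_property
    def codes(self) -> np.ndarray:
        return encode(self.coding_sequence)

    def contains(self, pos: int) -> bool:
        return self.cds_start <= pos <= self.cds_end


@dataclass
class GenomeModel:
    """Genes, pathway memberships and chromosome sequences.

    ``background_length`` is the total exon-block length (sum of coding
    lengths over all genes); pathway-level exon-block lengths and
    per-sample hit probabilities are derived from it.
    """

    genes: list[GeneModel]
    pathway_collection: dict[str, set[str]]
    resistance_pathway: str | None = None
    chrom_codes: dict[str, np.ndarray] = field(default_factory=dict, repr=False)

    @property
    def background_length(self) -> int:
        return sum(g.coding_length for g in self.genes)

    @cached_property
    def gene_by_id(self) -> dict[str, GeneModel]:
        return {g.gene_id: g for g in self.genes}

    @cached_property
    def _chrom_gene_lookup(self) -> dict[str, tuple[np.ndarray, np.ndarray, list[GeneModel]]]:
        out: dict[str, tuple[np.ndarray, np.ndarray, list[GeneModel]]] = {}
        for chrom in self.chrom_codes:
            genes = sorted(
                (g for g in self.genes if g.chrom == chrom), key=lambda g: g.cds_start
            )
            starts = np.array([g.cds_start for g in genes], dtype=np.int64)
            ends = np.array([g.cds_end for g in genes], dtype=np.int64)
            out[chrom] = (starts, ends, genes)
        return out

    def gene_at(self, chrom: str, pos: int) -> GeneModel | None:
        """Gene whose CDS covers 1-based ``pos``, or None."""
        if chrom not in self._chrom_gene_lookup:
            return None
        starts, ends, genes = self._chrom_gene_lookup[chrom]
        i = int(np.searchsorted(starts, pos, side="right")) - 1
        if i >= 0 and pos <= ends[i]:
            return genes[i]
        return None

    def ref_slice(self, chrom: str, pos: int, length: int = 1) -> str:
        """Reference bases at 1-based ``pos`` (length bases)."""
        codes = self.chrom_codes[chrom]
        return decode(codes[pos - 1 : pos - 1 + length])

    def chrom_length(self, chrom: str) -> int:
        return len(self.chrom_codes[chrom])

    @cached_property
    def site_index(self) -> "SiteIndex":
        return SiteIndex.build(self)

    def pathway_length(self, pathway_id: str) -> int:
        genes = self.pathway_collection[pathway_id]
        return sum(self.gene_by_id[g].coding_length for g in set(genes))

    def validate(self) -> None:
        seen = set()
        for g in self.genes:
            if g.gene_id in seen:
                raise ParameterError(f"duplicate gene id {g.gene_id}")
            seen.add(g.gene_id)
            if g.coding_length <= 0 or g.coding_length % 3:
                raise ParameterError(
                    f"{g.gene_id}: coding length {g.coding_length} not a positive multiple of 3"
                )
        for pid, members in self.pathway_collection.items():
            missing = set(members) - seen
            if missing:
                raise ParameterError(f"pathway {pid} references unknown genes {sorted(missing)}")


class SiteIndex:
    """Index of interior coding positions by pyrimidine-normalized context.

    Interior means positions with a complete trinucleotide context inside
    the gene's CDS (the first and last coding base of each gene are
    excluded).  Used to sample substitution sites conditioned on a
    signature channel and to normalize observed channel counts by context
    availability.
    """

    def __init__(
        self,
        chrom_names: list[str],
        sites: np.ndarray,
        ctx_sorted: np.ndarray,
        bounds: np.ndarray,
    ):
        self._chrom_names = chrom_names
        self._sites = sites  # int64, chrom_idx << 40 | pos (1-based), context-sorted
        self._ctx_sorted = ctx_sorted
        self._bounds = bounds  # len 33, class c occupies [bounds[c], bounds[c+1])

    @classmethod
    def build(cls, genome: GenomeModel) -> "SiteIndex":
        chrom_names = list(genome.chrom_codes)
        site_chunks: list[np.ndarray] = []
        ctx_chunks: list[np.ndarray] = []
        for ci, chrom in enumerate(chrom_names):
            codes = genome.chrom_codes[chrom]
            ctx = context_classes(codes)  # per 0-based position
            mask = np.zeros(len(codes), dtype=bool)
            for g in genome.genes:
                if g.chrom != chrom or g.coding_length < 3:
                    continue
                # interior coding positions only (0-based)
                mask[g.cds_start : g.cds_end - 1] = True
            pos0 = np.flatnonzero(mask)
            site_chunks.append((np.int64(ci) << 40) | (pos0 + 1))
            ctx_chunks.append(ctx[pos0])
        sites = np.concatenate(site_chunks) if site_chunks else np.empty(0, dtype=np.int64)
        ctx_all = np.concatenate(ctx_chunks) if ctx_chunks else np.empty(0, dtype=np.int16)
        order = np.argsort(ctx_all, kind="stable")
        sites = sites[order]
        ctx_sorted = ctx_all[order]
        bounds = np.searchsorted(ctx_sorted, np.arange(N_CONTEXTS + 1))
        return cls(chrom_names, sites, ctx_sorted, bounds)

    @property
    def n_sites(self) -> int:
        return len(self._sites)

    @cached_property
    def context_counts(self) -> np.ndarray:
        """Number of available interior coding sites per context class (32,)."""
        return np.diff(self._bounds).astype(np.int64)

    def sample(self, ctx: int, rng: np.random.Generator, size: int) -> list[tuple[str, int]]:
        """Draw ``size`` uniform sites of context class ``ctx`` (with replacement)."""
        lo, hi = int(self._bounds[ctx]), int(self._bounds[ctx + 1])
        if hi <= lo:
            raise ValueError(f"no available sites for context class {ctx}")
        idx = rng.integers(lo, hi, size=size)
        packed = self._sites[idx]
        return [
            (self._chrom_names[int(p >> 40)], int(p & ((1 << 40) - 1))) for p in packed
        ]

    def sample_uniform(self, rng: np.random.Generator, size: int) -> list[tuple[str, int]]:
        """Draw ``size`` sites uniformly over all interior coding positions."""
        idx = rng.integers(0, len(self._sites), size=size)
        packed = self._sites[idx]
        return [
            (self._chrom_names[int(p >> 40)], int(p & ((1 << 40) - 1))) for p in packed
        ]


def generate_genome_model(
    n_genes: int,
    n_pathways: int,
    mean_cds_length: int = 900,
    seed: int = 0,
    pathway_size_range: tuple[int, int] = (2, 5),
    resistance_pathway_size: int = 4,
    spacer_length: int = 100,
) -> GenomeModel:
    """Generate a deterministic synthetic genome with a pathway collection.

    Genes are single-exon ORFs built from sense codons (no in-frame
    internal stop), placed on chromosomes separated by random spacers.
    Pathways are disjoint gene sets with sizes drawn uniformly from
    ``pathway_size_range``; the first pathway is flagged as the designated
    resistance pathway and has ``resistance_pathway_size`` genes.

    Lengths are in bases; ``mean_cds_length`` must be at least 300 and the
    realized per-gene CDS lengths are positive multiples of 3.
    """
    if n_genes < 2 * n_pathways:
        raise ParameterError(
            f"n_genes={n_genes} must be at least twice n_pathways={n_pathways}"
        )
    if mean_cds_length < 300:
        raise ParameterError(f"mean_cds_length={mean_cds_length} must be >= 300")
    lo, hi = pathway_size_range
    if lo < 2 or hi < lo:
        raise ParameterError(f"invalid pathway_size_range {pathway_size_range}")
    if not (lo <= resistance_pathway_size <= max(hi, lo)):
        resistance_pathway_size = min(max(resistance_pathway_size, lo), hi)

    rng = np.random.default_rng(np.random.SeedSequence(seed))

    # per-gene codon counts: normal around the mean, floored well above 0
    mean_codons = mean_cds_length / 3
    n_codons = np.maximum(
        30, np.round(rng.normal(mean_codons, mean_codons / 4, size=n_genes))
    ).astype(np.int64)

    codon_lut = np.array([encode(c) for c in SENSE_CODONS], dtype=np.uint8)  # (61, 3)
    spacer_lut = np.arange(4, dtype=np.uint8)

    n_chrom = max(1, min(23, n_genes // 8 or 1))
    chrom_of_gene = np.arange(n_genes) % n_chrom

    genes: list[GeneModel] = []
    chrom_codes: dict[str, np.ndarray] = {}
    width = len(str(n_genes - 1))
    for ci in range(n_chrom):
        parts: list[np.ndarray] = []
        offset = 0
        for gi in np.flatnonzero(chrom_of_gene == ci):
            spacer = spacer_lut[rng.integers(0, 4, size=spacer_length)]
            parts.append(spacer)
            offset += spacer_length
            codons = codon_lut[rng.integers(0, len(SENSE_CODONS), size=n_codons[gi])]
            seq = codons.reshape(-1)
            genes.append(
                GeneModel(
                    gene_id=f"G{gi:0{width}d}",
                    chrom=f"chr{ci + 1}",
                    cds_start=offset + 1,
                    strand="+",
                    coding_sequence=decode(seq),
                )
            )
            parts.append(seq)
            offset += len(seq)
        parts.append(spacer_lut[rng.integers(0, 4, size=spacer_length)])
        chrom_codes[f"chr{ci + 1}"] = np.concatenate(parts)

    genes.sort(key=lambda g: g.gene_id)

    # disjoint pathway memberships over a shuffled gene order
    sizes = rng.integers(lo, hi + 1, size=n_pathways)
    sizes[0] = resistance_pathway_size
    if sizes.sum() > n_genes:
        raise ParameterError(
            f"pathway sizes sum to {int(sizes.sum())} but only {n_genes} genes exist"
        )
    shuffled = [g.gene_id for g in genes]
    rng.shuffle(shuffled)
    pathway_collection: dict[str, set[str]] = {}
    cursor = 0
    pw_width = len(str(n_pathways - 1))
    for pi, size in enumerate(sizes):
        pid = f"PW{pi:0{pw_width}d}"
        pathway_collection[pid] = set(shuffled[cursor : cursor + int(size)])
        cursor += int(size)

    model = GenomeModel(
        genes=genes,
        pathway_collection=pathway_collection,
        resistance_pathway=f"PW{0:0{pw_width}d}",
        chrom_codes=chrom_codes,
    )
    model.validate()
    return model
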