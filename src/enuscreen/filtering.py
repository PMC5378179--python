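"""Variant ingestion, parental-subclonal filtering, event matrix, spectra.

The central filtering rule: any variant supported by 0.5% or more of the
reads in the deep-sequenced parental cell line is treated as a
pre-existing subclonal variant and removed, so that pathway and selection
analyses see only mutagen-induced (or truly novel) mutations.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DataError
from .genome import GenomeModel
from .variants import (
    QUALIFYING_DEFAULT,
    SNV,
    CloneVariantSet,
    Variant,
    annotate_variant,
)

logger = logging.getLogger(__name__)

PARENTAL_VAF_THRESHOLD = 0.005  # "0.5% or more reads" in the parental control


def read_variants(
    path,
    genome: GenomeModel,
    clone_id: str | None = None,
    parental_table: pd.DataFrame | None = None,
) -> list[Variant]:
    """Read one clone's variants from a minimal VCF (or flat TSV).

    Multi-allelic records are split; variants outside any gene are kept as
    noncoding.  Parental allele counts come from the PALT/PDEP INFO fields
    or, failing that, from a sidecar table keyed by (chrom, pos, ref, alt).
    A REF inconsistent with the genome triggers a warning and the record is
    kept with a ``ref_mismatch`` flag.
    """
    path = Path(path)
    if path.suffix in {".tsv", ".txt"}:
        from .screen_io import read_variants_tsv

        variants = read_variants_tsv(path)
        for v in variants:
            annotate_variant(v, genome)
        return variants

    import pysam

    if clone_id is None:
        clone_id = path.stem

    lookup = None
    if parental_table is not None:
        lookup = {
            (str(r.chrom), int(r.pos), str(r.ref), str(r.alt)): (
                int(r.parental_alt),
                int(r.parental_depth),
            )
            for r in parental_table.itertuples()
        }

    variants: list[Variant] = []
    try:
        vcf = pysam.VariantFile(str(path))
    except (OSError, ValueError) as exc:
        raise DataError(f"{path}: cannot parse VCF: {exc}") from exc
    for rec in vcf:
        for alt in rec.alts or ():
            palt = rec.info.get("PALT")
            pdep = rec.info.get("PDEP")
            if palt is None or pdep is None:
                key = (rec.chrom, rec.pos, rec.ref, alt)
                if lookup is not None and key in lookup:
                    palt, pdep = lookup[key]
                else:
                    palt, pdep = 0, 0
            v = Variant(
                clone_id=clone_id,
                chrom=rec.chrom,
                pos=rec.pos,
                ref=rec.ref,
                alt=str(alt),
                parental_alt=int(palt),
                parental_depth=int(pdep),
            )
            if v.parental_depth == 0:
                v.flags.add("no_parental_evidence")
            if rec.chrom in genome.chrom_codes:
                expected = genome.ref_slice(rec.chrom, rec.pos, len(rec.ref))
                if expected != rec.ref:
                    logger.warning(
                        "%s:%d REF %s does not match genome %s; record kept",
                        rec.chrom, rec.pos, rec.ref, expected,
                    )
                    v.flags.add("ref_mismatch")
            if "ref_mismatch" not in v.flags:
                annotate_variant(v, genome)
            variants.append(v)
    return variants


def filter_parental_subclonal(
    variants: list[Variant], max_parental_vaf: float = PARENTAL_VAF_THRESHOLD
) -> tuple[list[Variant], list[Variant]]:
    """Split variants into (kept, removed) by parental allele fraction.

    A variant is removed iff its parental depth is positive and
    ``parental_alt / parental_depth >= max_parental_vaf`` (the threshold
    itself is removed: "0.5% *or more*").  Variants with no parental
    coverage are kept and flagged.  Order is preserved and the two lists
    partition the input.
    """
    kept: list[Variant] = []
    removed: list[Variant] = []
    for v in variants:
        if v.parental_alt < 0 or v.parental_depth < 0:
            raise DataError(f"{v.chrom}:{v.pos} negative parental read counts")
        if v.parental_depth == 0:
            v.flags.add("no_parental_evidence")
            kept.append(v)
        elif v.parental_alt / v.parental_depth >= max_parental_vaf:
            removed.append(v)
        else:
            kept.append(v)
    return kept, removed


def build_event_matrix(
    variants: list[Variant],
    samples: list[str],
    qualifying: frozenset[str] | set[str] = QUALIFYING_DEFAULT,
) -> pd.DataFrame:
    """Binary gene x sample matrix of qualifying-mutation presence.

    Entry (g, s) is 1 iff sample ``s`` carries at least one variant in gene
    ``g`` whose consequence is in ``qualifying``.  Genes with no qualifying
    mutation anywhere are omitted.
    """
    sample_set = set(samples)
    cells: set[tuple[str, str]] = set()
    for v in variants:
        if v.clone_id not in sample_set:
            raise DataError(f"unknown sample id {v.clone_id!r} in variant list")
        if v.gene_id and v.consequence in qualifying:
            cells.add((v.gene_id, v.clone_id))
    genes = sorted({g for g, _ in cells})
    mat = pd.DataFrame(0, index=genes, columns=list(samples), dtype=np.int8)
    for g, s in cells:
        mat.at[g, s] = 1
    return mat


def spectrum_summary(variants: list[Variant]) -> dict[str, pd.DataFrame]:
    """Counts and fractions by mutation category, substitution class, and
    per-chromosome intermutation distances.

    Returns dict with keys ``categories`` (vtype/consequence counts and
    fractions), ``classes`` (six-class fractions among substitutions), and
    ``intermutation`` (successive-position differences per chromosome).
    """
    if not variants:
        empty = pd.DataFrame()
        return {"categories": empty, "classes": empty, "intermutation": empty}

    n = len(variants)
    vtypes = pd.Series([v.vtype for v in variants]).value_counts()
    categories = pd.DataFrame(
        {"count": vtypes, "fraction": vtypes / n}
    ).rename_axis("category")

    sub_classes = []
    for v in variants:
        if v.vtype == SNV:
            ref, alt = v.ref, v.alt
            if ref in "AG":
                comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
                ref, alt = comp[ref], comp[alt]
            sub_classes.append(f"{ref}>{alt}")
    cls_counts = pd.Series(sub_classes).value_counts().sort_index()
    classes = pd.DataFrame(
        {"count": cls_counts, "fraction": cls_counts / max(len(sub_classes), 1)}
    ).rename_axis("class")

    rows = []
    df = pd.DataFrame(
        {"chrom": [v.chrom for v in variants], "pos": [v.pos for v in variants]}
    )
    for chrom, grp in df.groupby("chrom"):
        pos = np.sort(grp["pos"].to_numpy())
        for p, d in zip(pos[1:], np.diff(pos)):
            rows.append({"chrom": chrom, "pos": int(p), "distance": int(d)})
    intermutation = pd.DataFrame(rows, columns=["chrom", "pos", "distance"])
    return {"categories": categories, "classes": classes, "intermutation": intermutation}


def compute_burdens(
    variants: list[Variant],
    samples: list[str],
    background_genes: set[str] | None = None,
    qualifying: frozenset[str] | set[str] = QUALIFYING_DEFAULT,
) -> pd.Series:
    """Per-sample count of qualifying mutations in background genes.

    This is the sample mutation burden n_i used by the pathway-enrichment
    model; ``background_genes`` defaults to all genes (any gene_id).
    """
    counts = {s: 0 for s in samples}
    for v in variants:
        if v.gene_id is None or v.consequence not in qualifying:
            continue
        if background_genes is not None and v.gene_id not in background_genes:
            continue
        if v.clone_id in counts:
            counts[v.clone_id] += 1
    return pd.Series(counts, name="n_mutations")
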