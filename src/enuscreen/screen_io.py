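"""On-disk formats for simulated screens and pipeline stages.

A screen is persisted as: one minimal VCF 4.2 per clone (with parental
allele counts in INFO), a genome FASTA plus a gene table TSV, a pathway
collection GMT, a parental allele-count sidecar TSV, and a truth JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .channels import encode, decode
from .errors import DataError
from .genome import GeneModel, GenomeModel
from .simulate import ScreenTruth
from .variants import CloneVariantSet, Variant

_VCF_HEADER = """##fileformat=VCFv4.2
##source=enuscreen
##INFO=<ID=GENE,Number=1,Type=String,Description="Gene id of overlapping CDS">
##INFO=<ID=CTX,Number=1,Type=String,Description="Pyrimidine-normalized trinucleotide context">
##INFO=<ID=CSQ,Number=1,Type=String,Description="Coding consequence">
##INFO=<ID=PALT,Number=1,Type=Integer,Description="Parental alt read count">
##INFO=<ID=PDEP,Number=1,Type=Integer,Description="Parental total read depth">
"""


def write_screen(
    clones: list[CloneVariantSet],
    parental: pd.DataFrame,
    truth: ScreenTruth,
    genome: GenomeModel,
    out_dir,
) -> dict[str, Path]:
    """Write a simulated screen to ``out_dir``; returns the paths written."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["genome_fasta"] = out / "genome.fa"
    write_genome_fasta(genome, paths["genome_fasta"])
    paths["gene_table"] = out / "genes.tsv"
    write_gene_table(genome, paths["gene_table"])
    paths["pathways_gmt"] = out / "pathways.gmt"
    write_gmt(genome, paths["pathways_gmt"])

    paths["parental_counts"] = out / "parental_counts.tsv"
    parental.to_csv(paths["parental_counts"], sep="\t", index=False)

    paths["truth_json"] = out / "truth.json"
    with open(paths["truth_json"], "w") as fh:
        json.dump(truth.to_json_dict(), fh, indent=1, sort_keys=True)

    vcf_dir = out / "vcf"
    vcf_dir.mkdir(exist_ok=True)
    for cvs in clones:
        p = vcf_dir / f"{cvs.clone_id}.vcf"
        write_clone_vcf(cvs, genome, p)
        paths[f"vcf:{cvs.clone_id}"] = p
    return paths


def write_clone_vcf(cvs: CloneVariantSet, genome: GenomeModel, path) -> None:
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        for chrom in genome.chrom_codes:
            fh.write(f"##contig=<ID={chrom},length={genome.chrom_length(chrom)}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for v in sorted(cvs.variants, key=lambda v: (v.chrom, v.pos, v.ref, v.alt)):
            info = [f"PALT={v.parental_alt}", f"PDEP={v.parental_depth}"]
            if v.gene_id:
                info.insert(0, f"GENE={v.gene_id}")
            if v.context:
                info.append(f"CTX={v.context}")
            if v.consequence:
                info.append(f"CSQ={v.consequence}")
            fh.write(
                f"{v.chrom}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t.\tPASS\t{';'.join(info)}\n"
            )


def write_genome_fasta(genome: GenomeModel, path) -> None:
    records = [
        SeqRecord(Seq(decode(codes)), id=chrom, description="")
        for chrom, codes in genome.chrom_codes.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def write_gene_table(genome: GenomeModel, path) -> None:
    rows = [
        {
            "gene_id": g.gene_id,
            "chrom": g.chrom,
            "cds_start": g.cds_start,
            "strand": g.strand,
            "coding_length": g.coding_length,
        }
        for g in genome.genes
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_gmt(genome: GenomeModel, path) -> None:
    with open(path, "w") as fh:
        for pid, members in genome.pathway_collection.items():
            desc = (
                "designated_resistance_pathway"
                if pid == genome.resistance_pathway
                else "synthetic_pathway"
            )
            fh.write("\t".join([pid, desc] + sorted(members)) + "\n")


def read_gmt(path) -> tuple[dict[str, set[str]], str | None]:
    """Parse a GMT file; returns (pathway collection, resistance pathway id)."""
    collection: dict[str, set[str]] = {}
    resistance = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise DataError(f"{path}:{lineno}: GMT line needs id, description, genes")
            pid, desc = fields[0], fields[1]
            collection[pid] = set(fields[2:])
            if "resistance" in desc:
                resistance = pid
    return collection, resistance


def read_genome(fasta_path, gene_table_path, gmt_path=None) -> GenomeModel:
    """Reconstruct a GenomeModel from FASTA + gene table (+ optional GMT)."""
    chrom_codes = {
        rec.id: encode(str(rec.seq).upper()) for rec in SeqIO.parse(str(fasta_path), "fasta")
    }
    table = pd.read_csv(gene_table_path, sep="\t")
    genes = []
    for row in table.itertuples():
        codes = chrom_codes[row.chrom]
        start0 = int(row.cds_start) - 1
        seq = decode(codes[start0 : start0 + int(row.coding_length)])
        genes.append(
            GeneModel(
                gene_id=str(row.gene_id),
                chrom=str(row.chrom),
                cds_start=int(row.cds_start),
                strand=str(row.strand),
                coding_sequence=seq,
            )
        )
    pathways: dict[str, set[str]] = {}
    resistance = None
    if gmt_path is not None:
        pathways, resistance = read_gmt(gmt_path)
    model = GenomeModel(
        genes=genes,
        pathway_collection=pathways,
        resistance_pathway=resistance,
        chrom_codes=chrom_codes,
    )
    model.validate()
    return model


def read_truth(path) -> ScreenTruth:
    with open(path) as fh:
        return ScreenTruth.from_json_dict(json.load(fh))


def write_variants_tsv(variants: list[Variant], path) -> None:
    rows = [
        {
            "clone_id": v.clone_id,
            "chrom": v.chrom,
            "pos": v.pos,
            "ref": v.ref,
            "alt": v.alt,
            "vtype": v.vtype,
            "gene_id": v.gene_id or "",
            "context": v.context or "",
            "consequence": v.consequence or "",
            "parental_alt": v.parental_alt,
            "parental_depth": v.parental_depth,
            "flags": ",".join(sorted(v.flags)),
        }
        for v in variants
    ]
    pd.DataFrame(
        rows,
        columns=[
            "clone_id", "chrom", "pos", "ref", "alt", "vtype", "gene_id",
            "context", "consequence", "parental_alt", "parental_depth", "flags",
        ],
    ).to_csv(path, sep="\t", index=False)


def read_variants_tsv(path) -> list[Variant]:
    table = pd.read_csv(path, sep="\t", keep_default_na=False)
    out = []
    for row in table.itertuples():
        v = Variant(
            clone_id=str(row.clone_id),
            chrom=str(row.chrom),
            pos=int(row.pos),
            ref=str(row.ref),
            alt=str(row.alt),
            parental_alt=int(row.parental_alt),
            parental_depth=int(row.parental_depth),
            gene_id=str(row.gene_id) or None,
            context=str(row.context) or None,
            consequence=str(row.consequence) or None,
        )
        if getattr(row, "flags", ""):
            v.flags = set(str(row.flags).split(","))
        out.append(v)
    return out
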