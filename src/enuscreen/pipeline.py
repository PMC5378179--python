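"""End-to-end orchestration: simulate/ingest -> filter -> signatures ->
pathway enrichment -> selection, with a machine-readable run report."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .catalog import build_catalog, catalogs_to_frame
from .deciphering import decipher_signatures
from .errors import ParameterError
from .filtering import (
    PARENTAL_VAF_THRESHOLD,
    build_event_matrix,
    compute_burdens,
    filter_parental_subclonal,
    read_variants,
    spectrum_summary,
)
from .genome import GenomeModel
from .screen_io import (
    read_genome,
    read_truth,
    write_screen,
    write_variants_tsv,
)
from .selection import merge_related_clones, rank_resistance_genes, run_selection
from .simulate import ScreenConfig, ScreenTruth, simulate_screen
from .slapenrich import enrichment_to_frame, pathway_enrichment
from .variants import CloneVariantSet, Variant

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of a pipeline run.

    Either ``simulate`` is set (synthetic screen generated in-run) or
    ``variants_dir``/``genome_fasta``/``gene_table``/``pathways_gmt`` point
    at existing inputs.
    """

    out_dir: str = "enuscreen_run"
    simulate: ScreenConfig | None = None
    variants_dir: str | None = None
    genome_fasta: str | None = None
    gene_table: str | None = None
    pathways_gmt: str | None = None
    parental_counts: str | None = None
    truth_json: str | None = None
    vaf_threshold: float = PARENTAL_VAF_THRESHOLD
    fdr_alpha: float = 0.05
    ec_threshold: float = 0.8
    min_shared: int = 3
    prob_model: str = "poisson"
    spectrum_estimator: str = "all_substitutions"
    k_range: tuple[int, ...] = ()  # empty: skip NMF deciphering
    n_bootstrap: int = 30
    n_restarts: int = 5
    seed: int = 0

    def validate(self) -> None:
        bad = []
        if not 0 <= self.vaf_threshold <= 1:
            bad.append("vaf_threshold")
        if not 0 < self.fdr_alpha < 1:
            bad.append("fdr_alpha")
        if not 0 <= self.ec_threshold <= 1:
            bad.append("ec_threshold")
        if self.min_shared < 0:
            bad.append("min_shared")
        if self.prob_model not in ("poisson", "bernoulli"):
            bad.append("prob_model")
        if bad:
            raise ParameterError(f"invalid run config values for: {', '.join(bad)}")
        if self.simulate is None:
            for name in ("variants_dir", "genome_fasta", "gene_table", "pathways_gmt"):
                value = getattr(self, name)
                if value is None:
                    bad.append(name)
                elif not Path(value).exists():
                    raise ParameterError(f"{name} path does not exist: {value}")
            if bad:
                raise ParameterError(f"missing inputs: {', '.join(bad)}")


def evaluate_against_truth(
    truth: ScreenTruth,
    kept: list[Variant],
    removed: list[Variant],
    enrichment: pd.DataFrame,
    selection: pd.DataFrame,
    alpha: float = 0.05,
) -> dict:
    """Compare pipeline output with the generator's implanted truth.

    Reports the subclonal-filter confusion matrix (a true positive is an
    implanted parental variant at VAF >= 0.5% that was removed), driver
    gene recall/precision under the selection significance rule, and
    whether the designated pathway was flagged.
    """
    high = {
        (sv["chrom"], sv["pos"], sv["ref"], sv["alt"])
        for sv in truth.shared_subclonal_variants
        if sv["parental_vaf"] >= PARENTAL_VAF_THRESHOLD
    }
    removed_keys = {v.key for v in removed}
    kept_keys = {v.key for v in kept}
    tp = len(high & removed_keys)
    fn = len(high & kept_keys)
    fp = len(removed_keys - high)
    precision = tp / (tp + fp) if tp + fp else None
    recall = tp / (tp + fn) if tp + fn else None

    implanted_genes = {g for g, _ in truth.driver_assignments.values()}
    block: dict = {
        "subclonal_filter": {
            "true_positives": tp,
            "false_negatives": fn,
            "false_positives": fp,
            "precision": precision,
            "recall": recall,
        }
    }
    if implanted_genes:
        if len(selection):
            flagged = set(rank_resistance_genes(selection, alpha).index)
        else:
            flagged = set()
        hit = implanted_genes & flagged
        block["driver_genes"] = {
            "implanted": sorted(implanted_genes),
            "flagged": sorted(flagged),
            "recall": len(hit) / len(implanted_genes),
            "precision": len(hit) / len(flagged) if flagged else None,
        }
    else:
        block["driver_genes"] = {"implanted": [], "recall": None, "precision": None}
    if truth.driver_pathway and len(enrichment):
        row = enrichment[enrichment["pathway_id"] == truth.driver_pathway]
        block["driver_pathway"] = {
            "pathway_id": truth.driver_pathway,
            "enriched": bool(row["enriched"].iloc[0]) if len(row) else False,
            "qvalue": float(row["qvalue"].iloc[0]) if len(row) else None,
            "exclusive_coverage": (
                float(row["exclusive_coverage"].iloc[0]) if len(row) else None
            ),
        }
    return block


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages, persisting stage outputs under ``config.out_dir``.

    Returns the run report (also written as ``report.json``): per-stage
    record counts, enriched pathways, significant genes, signature
    stability, and a truth-evaluation block when the generator's truth is
    available.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"version": __version__, "seed": config.seed, "stages": {}}

    # stage 1: obtain inputs
    truth: ScreenTruth | None = None
    if config.simulate is not None:
        clones, parental, truth, genome = simulate_screen(config.simulate)
        sim_dir = out / "screen"
        write_screen(clones, parental, truth, genome, sim_dir)
        logger.info("simulated %d clones into %s", len(clones), sim_dir)
    else:
        genome = read_genome(config.genome_fasta, config.gene_table, config.pathways_gmt)
        parental = (
            pd.read_csv(config.parental_counts, sep="\t")
            if config.parental_counts
            else None
        )
        clones = []
        vcfs = sorted(Path(config.variants_dir).glob("*.vcf"))
        if not vcfs:
            raise ParameterError(f"no VCF files in {config.variants_dir}")
        for p in vcfs:
            variants = read_variants(p, genome, parental_table=parental)
            clones.append(CloneVariantSet(p.stem, variants))
        if config.truth_json:
            truth = read_truth(config.truth_json)

    samples = [c.clone_id for c in clones]
    all_variants = [v for c in clones for v in c.variants]
    report["stages"]["input"] = {"n_clones": len(clones), "n_variants": len(all_variants)}

    # stage 2: parental subclonal filter
    kept, removed = filter_parental_subclonal(all_variants, config.vaf_threshold)
    write_variants_tsv(kept, out / "variants_kept.tsv")
    write_variants_tsv(removed, out / "variants_removed.tsv")
    report["stages"]["filter"] = {
        "input_n": len(all_variants),
        "kept_n": len(kept),
        "removed_n": len(removed),
    }

    # stage 3: spectrum summary + catalogs (+ optional NMF)
    summary = spectrum_summary(kept)
    summary["categories"].to_csv(out / "spectrum_categories.tsv", sep="\t")
    summary["classes"].to_csv(out / "spectrum_classes.tsv", sep="\t")
    summary["intermutation"].to_csv(out / "intermutation_distances.tsv", sep="\t", index=False)
    catalogs = build_catalog(kept, samples)
    catalogs_to_frame(catalogs).to_csv(out / "catalogs.tsv", sep="\t")
    report["stages"]["catalog"] = {
        "input_n": len(kept),
        "n_substitutions": int(sum(c.total for c in catalogs)),
    }
    if config.k_range:
        results, selected_k = decipher_signatures(
            catalogs,
            k_range=config.k_range,
            n_bootstrap=config.n_bootstrap,
            n_restarts=config.n_restarts,
            seed=config.seed,
        )
        best = results[selected_k]
        pd.DataFrame(
            best.signatures, columns=[f"signature_{i+1}" for i in range(best.k)]
        ).to_csv(out / "signatures.tsv", sep="\t", index=False)
        pd.DataFrame(
            best.exposures,
            index=[f"signature_{i+1}" for i in range(best.k)],
            columns=best.sample_ids,
        ).to_csv(out / "exposures.tsv", sep="\t")
        report["stages"]["signatures"] = {
            "selected_k": selected_k,
            "stability": {
                k: float(r.mean_stability) for k, r in results.items()
            },
            "reconstruction_error": {
                k: r.reconstruction_error for k, r in results.items()
            },
        }

    # stage 4: event matrix + pathway enrichment
    event = build_event_matrix(kept, samples)
    event.to_csv(out / "event_matrix.tsv", sep="\t")
    network_genes = (
        set().union(*genome.pathway_collection.values())
        if genome.pathway_collection
        else set()
    )
    burdens = compute_burdens(kept, samples, background_genes=network_genes or None)
    enr = pathway_enrichment(
        event,
        burdens,
        genome.pathway_collection,
        genome,
        model=config.prob_model,
        fdr_threshold=config.fdr_alpha,
        ec_threshold=config.ec_threshold,
    )
    enr_frame = enrichment_to_frame(enr)
    enr_frame.to_csv(out / "pathway_enrichment.tsv", sep="\t", index=False)
    report["stages"]["enrichment"] = {
        "input_n": len(kept),
        "n_pathways_tested": len(enr_frame),
        "n_enriched": int(enr_frame["enriched"].sum()) if len(enr_frame) else 0,
        "enriched_pathways": (
            enr_frame.loc[enr_frame["enriched"], "pathway_id"].tolist()
            if len(enr_frame)
            else []
        ),
    }

    # stage 5: clone merging + dN/dS selection
    kept_by_clone = {cid: [] for cid in samples}
    for v in kept:
        kept_by_clone[v.clone_id].append(v)
    filtered_clones = [CloneVariantSet(cid, kept_by_clone[cid]) for cid in samples]
    groups = merge_related_clones(filtered_clones, min_shared=config.min_shared)
    pd.DataFrame(
        [
            {"group_id": g.group_id, "clones": ",".join(sorted(g.member_clones)), "n_variants": len(g.variants)}
            for g in groups
        ]
    ).to_csv(out / "clone_groups.tsv", sep="\t", index=False)
    selection = run_selection(
        groups,
        genome,
        spectrum_estimator=config.spectrum_estimator,
        alpha=config.fdr_alpha,
    )
    selection.to_csv(out / "gene_selection.tsv", sep="\t")
    significant = rank_resistance_genes(selection, config.fdr_alpha)
    significant.to_csv(out / "significant_genes.tsv", sep="\t")
    report["stages"]["selection"] = {
        "input_n": len(kept),
        "n_groups": len(groups),
        "n_genes_tested": len(selection),
        "n_significant": len(significant),
        "significant_genes": list(significant.index),
    }

    if truth is not None:
        report["truth_evaluation"] = evaluate_against_truth(
            truth, kept, removed, enr_frame, selection, config.fdr_alpha
        )

    cfg_text = json.dumps(
        {k: str(v) for k, v in vars(config).items()}, sort_keys=True
    )
    report["config_hash"] = hashlib.sha256(cfg_text.encode()).hexdigest()[:16]
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True, default=str)
    return report
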