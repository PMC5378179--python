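"""Simulation of ENU mutagenesis resistance screens.

The generator emulates the design of an ENU + targeted-drug resistance
experiment read out by exome sequencing: a few dozen drug-resistant clones,
each carrying hundreds of random point mutations drawn from an ENU-like
96-channel signature plus a small fraction of short indels; subsets of
clones that share pre-existing parental subclonal variants (detectable at
low allele fraction in the deep-sequenced parental line); occasional
hypermutator clones with a multiplied burden and a contaminating
MSI-like substitution process; and exactly one implanted driver mutation
per clone, mutually exclusive within a designated resistance pathway.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .channels import (
    COMP,
    channel_to_context_alt,
    decode,
)
from .errors import GenerationError, ParameterError
from .genome import GeneModel, GenomeModel, generate_genome_model
from .signature import (
    SignatureProfile,
    default_enu_signature,
    msi_like_signature,
)
from .variants import (
    MISSENSE,
    CloneVariantSet,
    Variant,
    annotate_variant,
)

_MASK40 = (1 << 40) - 1


@dataclass
class ScreenTruth:
    """Ground truth implanted by the simulator, for downstream evaluation."""

    driver_assignments: dict[str, tuple[str, tuple[str, int, str, str]]]
    shared_subclonal_variants: list[dict]
    hypermutator_clones: set[str]
    related_sets: list[list[str]]
    clone_burdens: dict[str, dict[str, int]]
    driver_pathway: str | None = None
    signature_class_totals: dict[str, float] = field(default_factory=dict)

    def expected_groups(self, min_shared: int = 3) -> list[set[str]]:
        """Clone groupings forced by construction: each related set shares
        more than ``min_shared`` retained subclonal variants; all other
        clones are singletons."""
        grouped: set[str] = set()
        groups: list[set[str]] = []
        for members in self.related_sets:
            retained = sum(
                1
                for sv in self.shared_subclonal_variants
                if sv["set"] == self.related_sets.index(members)
                and sv["parental_vaf"] < 0.005
            )
            if retained > min_shared:
                groups.append(set(members))
                grouped |= set(members)
        for cid in self.clone_burdens:
            if cid not in grouped:
                groups.append({cid})
        return groups

    def to_json_dict(self) -> dict:
        d = asdict(self)
        d["hypermutator_clones"] = sorted(self.hypermutator_clones)
        d["driver_assignments"] = {
            c: [g, list(k)] for c, (g, k) in self.driver_assignments.items()
        }
        return d

    @classmethod
    def from_json_dict(cls, d: dict) -> "ScreenTruth":
        return cls(
            driver_assignments={
                c: (g, (k[0], int(k[1]), k[2], k[3]))
                for c, (g, k) in d["driver_assignments"].items()
            },
            shared_subclonal_variants=d["shared_subclonal_variants"],
            hypermutator_clones=set(d["hypermutator_clones"]),
            related_sets=[list(s) for s in d["related_sets"]],
            clone_burdens=d["clone_burdens"],
            driver_pathway=d.get("driver_pathway"),
            signature_class_totals=d.get("signature_class_totals", {}),
        )


@dataclass
class ScreenConfig:
    """Study conditions for a simulated screen.

    Defaults follow the scale of the original experiment: ~470
    substitutions per clone with a ~4% indel fraction, an ENU-like
    signature with C>G depleted to 3%, two hypermutator clones at 10x
    burden carrying an additional MSI-like process, and related clone sets
    sharing 10 parental subclonal variants, half above and half below the
    0.5% parental allele-fraction filter threshold.
    """

    n_clones: int = 24
    n_substitutions: int = 470
    indel_fraction: float = 0.04
    signature: SignatureProfile = field(default_factory=default_enu_signature)
    n_hypermutators: int = 2
    hypermutator_multiplier: float = 10.0
    hypermutator_signature: SignatureProfile = field(default_factory=msi_like_signature)
    n_related_sets: int = 3
    related_set_size: int = 4
    n_shared_subclonal: int = 10
    subclonal_vaf_high: float = 0.01
    subclonal_vaf_low: float = 0.001
    subclonal_depth: int = 2000
    parental_depth: int = 150
    implant_drivers: bool = True
    driver_pathway: str | None = None
    # genome defaults when no model is supplied: a desk-scale exome with a
    # realistic gene count and a 100-pathway collection
    n_genes: int = 19000
    n_pathways: int = 100
    mean_cds_length: int = 900
    seed: int = 0

    @property
    def n_indels(self) -> int:
        if not 0 <= self.indel_fraction < 1:
            raise ParameterError("indel_fraction must be in [0, 1)")
        return int(round(self.n_substitutions * self.indel_fraction / (1 - self.indel_fraction)))

    def validate(self) -> None:
        bad = []
        if self.n_clones < 1:
            bad.append("n_clones")
        if self.n_substitutions < 0:
            bad.append("n_substitutions")
        if not 0 <= self.indel_fraction < 1:
            bad.append("indel_fraction")
        if self.n_hypermutators < 0 or self.n_hypermutators > self.n_clones:
            bad.append("n_hypermutators")
        if self.hypermutator_multiplier < 1:
            bad.append("hypermutator_multiplier")
        if self.n_related_sets * self.related_set_size > self.n_clones:
            bad.append("n_related_sets/related_set_size")
        if self.related_set_size < 2 and self.n_related_sets > 0:
            bad.append("related_set_size")
        if not 0 <= self.subclonal_vaf_low <= 1 or not 0 <= self.subclonal_vaf_high <= 1:
            bad.append("subclonal_vaf_low/subclonal_vaf_high")
        if self.subclonal_depth <= 0 or self.parental_depth <= 0:
            bad.append("subclonal_depth/parental_depth")
        if bad:
            raise ParameterError(f"invalid screen config values for: {', '.join(bad)}")


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def simulate_clone(
    genome: GenomeModel,
    signature: SignatureProfile,
    n_substitutions: int,
    n_indels: int,
    driver: Variant | None = None,
    seed=0,
    clone_id: str = "clone",
    parental_depth: int = 150,
) -> CloneVariantSet:
    """Simulate one clone's somatic variant list.

    Substitution sites are drawn by sampling a 96-channel from the
    signature, then a uniform genomic site among the coding positions whose
    pyrimidine-normalized context matches that channel.  Indels (1-10 bp)
    are placed uniformly over coding positions.  All ENU variants carry
    zero parental alt reads; the optional driver variant is appended.
    """
    if n_substitutions < 0 or n_indels < 0:
        raise ParameterError("mutation burdens must be non-negative")
    rng = _rng(seed)
    index = genome.site_index
    probs = signature.channel_probs
    ctx_counts = index.context_counts
    for ch in np.flatnonzero(probs > 0):
        ctx, _ = channel_to_context_alt(int(ch))
        if ctx_counts[ctx] == 0:
            from .channels import channel_name

            raise GenerationError(
                f"signature channel {channel_name(int(ch))} has probability "
                f"{probs[ch]:.4g} but no available context sites in the genome"
            )

    variants: dict[tuple, Variant] = {}
    pos_taken: set[tuple[str, int]] = set()

    n_snv = 0
    while n_snv < n_substitutions:
        channels = rng.choice(96, size=n_substitutions - n_snv, p=probs)
        for ch in channels:
            ctx, alt_pyr = channel_to_context_alt(int(ch))
            chrom, pos = index.sample(ctx, rng, 1)[0]
            if (chrom, pos) in pos_taken:
                continue
            ref = genome.ref_slice(chrom, pos)
            alt = decode(np.array([alt_pyr], dtype=np.uint8))
            if ref in "AG":  # site stored pyrimidine-normalized on other strand
                alt = COMP[alt]
            pos_taken.add((chrom, pos))
            variants[(chrom, pos, ref, alt)] = Variant(
                clone_id, chrom, pos, ref, alt, 0, parental_depth
            )
            n_snv += 1

    n_placed = 0
    while n_placed < n_indels:
        chrom, pos = index.sample_uniform(rng, 1)[0]
        length = int(rng.integers(1, 11))
        if pos + length >= genome.chrom_length(chrom):
            continue
        if (chrom, pos) in pos_taken:
            continue
        if rng.random() < 0.5:  # deletion
            ref = genome.ref_slice(chrom, pos, length + 1)
            alt = ref[0]
        else:  # insertion
            ref = genome.ref_slice(chrom, pos)
            ins = decode(rng.integers(0, 4, size=length).astype(np.uint8))
            alt = ref + ins
        pos_taken.add((chrom, pos))
        variants[(chrom, pos, ref, alt)] = Variant(
            clone_id, chrom, pos, ref, alt, 0, parental_depth
        )
        n_placed += 1

    out = list(variants.values())
    if driver is not None:
        out = [v for v in out if (v.chrom, v.pos) != (driver.chrom, driver.pos)]
        out.append(
            Variant(
                clone_id,
                driver.chrom,
                driver.pos,
                driver.ref,
                driver.alt,
                driver.parental_alt,
                driver.parental_depth or parental_depth,
            )
        )
    out.sort(key=lambda v: (v.chrom, v.pos, v.ref, v.alt))
    for v in out:
        annotate_variant(v, genome)
    return CloneVariantSet(clone_id, out)


def find_missense_snv(
    genome: GenomeModel, gene: GeneModel, rng: np.random.Generator
) -> Variant:
    """A random missense substitution inside a gene (used as a driver hotspot)."""
    for _ in range(10000):
        off = int(rng.integers(1, gene.coding_length - 1))
        pos = gene.cds_start + off
        ref = gene.coding_sequence[off]
        alt = rng.choice([b for b in "ACGT" if b != ref])
        v = Variant("truth", gene.chrom, pos, ref, str(alt), 0, 0)
        annotate_variant(v, genome)
        if v.consequence == MISSENSE:
            return v
    raise GenerationError(f"no missense site found in {gene.gene_id}")


def simulate_screen(
    config: ScreenConfig, genome: GenomeModel | None = None
) -> tuple[list[CloneVariantSet], "pd.DataFrame", ScreenTruth, GenomeModel]:
    """Simulate a full screen: clones, parental read-count table, truth.

    Clones are generated from per-clone random streams derived from the
    master seed (stream ``(1, i)`` for clone ``i``; stream ``(0,)`` for
    screen-level structure), so adding clones does not perturb earlier
    ones.  Returns the clone variant sets, the parental allele-count table,
    the implanted truth, and the genome model used.
    """
    import pandas as pd

    config.validate()
    if genome is None:
        genome = generate_genome_model(
            config.n_genes,
            config.n_pathways,
            config.mean_cds_length,
            seed=config.seed,
        )
    screen_rng = np.random.default_rng(
        np.random.SeedSequence(config.seed, spawn_key=(0,))
    )
    clone_ids = [f"clone_{i:02d}" for i in range(config.n_clones)]

    # related sets occupy the first clones; hypermutators the last ones
    related_sets = [
        clone_ids[i * config.related_set_size : (i + 1) * config.related_set_size]
        for i in range(config.n_related_sets)
    ]
    hypermutators = set(clone_ids[config.n_clones - config.n_hypermutators :])

    # shared parental subclonal variants per related set, half above and
    # half below the 0.5% parental VAF threshold
    shared: list[dict] = []
    shared_by_set: list[list[Variant]] = []
    for si in range(config.n_related_sets):
        members: list[Variant] = []
        taken: set[tuple[str, int]] = set()
        for vi in range(config.n_shared_subclonal):
            while True:
                chrom, pos = genome.site_index.sample_uniform(screen_rng, 1)[0]
                if (chrom, pos) not in taken:
                    taken.add((chrom, pos))
                    break
            ref = genome.ref_slice(chrom, pos)
            alt = str(screen_rng.choice([b for b in "ACGT" if b != ref]))
            vaf = (
                config.subclonal_vaf_high
                if vi < config.n_shared_subclonal // 2
                else config.subclonal_vaf_low
            )
            palt = int(round(vaf * config.subclonal_depth))
            members.append(
                Variant("truth", chrom, pos, ref, alt, palt, config.subclonal_depth)
            )
            shared.append(
                {
                    "set": si,
                    "chrom": chrom,
                    "pos": pos,
                    "ref": ref,
                    "alt": alt,
                    "parental_vaf": palt / config.subclonal_depth,
                    "clones": list(related_sets[si]),
                }
            )
        shared_by_set.append(members)

    # driver hotspots: one recurrent missense variant per resistance-pathway
    # gene; each clone is assigned exactly one driver gene
    driver_assignments: dict[str, tuple[str, tuple[str, int, str, str]]] = {}
    hotspots: dict[str, Variant] = {}
    pathway_id = config.driver_pathway or genome.resistance_pathway
    if config.implant_drivers:
        if pathway_id is None or pathway_id not in genome.pathway_collection:
            raise ParameterError(f"driver pathway {pathway_id!r} not in genome")
        pathway_genes = sorted(genome.pathway_collection[pathway_id])
        for gid in pathway_genes:
            hotspots[gid] = find_missense_snv(genome, genome.gene_by_id[gid], screen_rng)
        for cid in clone_ids:
            gid = str(screen_rng.choice(pathway_genes))
            driver_assignments[cid] = (gid, hotspots[gid].key)

    clones: list[CloneVariantSet] = []
    burdens: dict[str, dict[str, int]] = {}
    for i, cid in enumerate(clone_ids):
        clone_rng = np.random.default_rng(
            np.random.SeedSequence(config.seed, spawn_key=(1, i))
        )
        n_sub, n_ind = config.n_substitutions, config.n_indels
        driver = None
        if cid in driver_assignments:
            gid, _ = driver_assignments[cid]
            driver = hotspots[gid]
        cvs = simulate_clone(
            genome,
            config.signature,
            n_sub,
            n_ind,
            driver=driver,
            seed=clone_rng,
            clone_id=cid,
            parental_depth=config.parental_depth,
        )
        if cid in hypermutators:
            extra = int(round((config.hypermutator_multiplier - 1) * n_sub))
            extra_ind = int(round((config.hypermutator_multiplier - 1) * n_ind))
            existing = cvs.keys
            extra_set = simulate_clone(
                genome,
                config.hypermutator_signature,
                extra,
                extra_ind,
                seed=np.random.default_rng(
                    np.random.SeedSequence(config.seed, spawn_key=(2, i))
                ),
                clone_id=cid,
                parental_depth=config.parental_depth,
            )
            merged = {v.key: v for v in cvs.variants}
            existing_pos = {(k[0], k[1]) for k in existing}
            for v in extra_set.variants:
                if (v.chrom, v.pos) not in existing_pos:
                    merged.setdefault(v.key, v)
            cvs = CloneVariantSet(cid, sorted(merged.values(), key=lambda v: (v.chrom, v.pos, v.ref, v.alt)))
        # implant shared parental subclonal variants for related clones
        for si, members in enumerate(related_sets):
            if cid in members:
                existing_pos = {(v.chrom, v.pos) for v in cvs.variants}
                for sv in shared_by_set[si]:
                    if (sv.chrom, sv.pos) in existing_pos:
                        continue
                    v = Variant(
                        cid, sv.chrom, sv.pos, sv.ref, sv.alt, sv.parental_alt, sv.parental_depth
                    )
                    annotate_variant(v, genome)
                    cvs.variants.append(v)
                cvs.variants.sort(key=lambda v: (v.chrom, v.pos, v.ref, v.alt))
        burdens[cid] = {
            "n_substitutions": sum(1 for v in cvs.variants if v.vtype == "SNV"),
            "n_indels": sum(1 for v in cvs.variants if v.vtype != "SNV"),
        }
        clones.append(cvs)

    parental_rows = []
    seen_keys: set = set()
    for cvs in clones:
        for v in cvs.variants:
            if v.key not in seen_keys:
                seen_keys.add(v.key)
                parental_rows.append(
                    {
                        "chrom": v.chrom,
                        "pos": v.pos,
                        "ref": v.ref,
                        "alt": v.alt,
                        "parental_alt": v.parental_alt,
                        "parental_depth": v.parental_depth,
                    }
                )
    parental = pd.DataFrame(
        parental_rows, columns=["chrom", "pos", "ref", "alt", "parental_alt", "parental_depth"]
    ).sort_values(["chrom", "pos", "ref", "alt"], ignore_index=True)

    truth = ScreenTruth(
        driver_assignments=driver_assignments,
        shared_subclonal_variants=shared,
        hypermutator_clones=hypermutators,
        related_sets=related_sets,
        clone_burdens=burdens,
        driver_pathway=pathway_id if config.implant_drivers else None,
        signature_class_totals=config.signature.class_totals(),
    )
    return clones, parental, truth, genome
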