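"""Gene-level positive-selection analysis (spectrum-aware dN/dS).

Related clones that share pre-existing subclonal variants are first
condensed into representative groups (union of variants over clones
sharing more than a threshold number of mutations).  For each gene, the
observed synonymous / missense / nonsense counts are compared with
neutral expectations derived from the mutation spectrum (per-channel
relative rates, normalized by context availability) and the gene's own
sequence (exhaustive enumeration of all single-base changes).  Selection
is tested by Poisson likelihood-ratio tests with the gene's local
mutation rate profiled out; indel recurrence is tested against the
exome-wide coding indel rate; substitution and indel evidence are
combined with Fisher's method, and FDR control is applied (optionally
within strata).
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .catalog import channel_of_variant
from .channels import COMP_CODE, N_CHANNELS, _CTX_ALT_TO_CHANNEL, context_classes
from .errors import ParameterError
from .genome import GeneModel, GenomeModel
from .variants import (
    CODON_AA,
    FRAMESHIFT,
    INFRAME,
    MISSENSE,
    NONSENSE,
    SNV,
    SPLICE,
    SYNONYMOUS,
    CloneVariantSet,
    Variant,
)

CLASS_SYN, CLASS_MIS, CLASS_NON, CLASS_SPLICE = 0, 1, 2, 3


@dataclass
class CloneGroup:
    """A set of related clones analysed as one sample."""

    group_id: str
    member_clones: set[str]
    variants: list[Variant]  # union over members, deduplicated by site/allele


@dataclass
class MutationSpectrum:
    """Relative mutation rate per 96-channel, normalized to mean 1.

    Rates are observed channel counts divided by the number of available
    context sites, so they are per-site relative rates; channels whose
    context does not occur in the genome are excluded (rate 0, masked).
    """

    rates: np.ndarray
    available: np.ndarray  # per-channel context-site counts

    def __post_init__(self):
        self.rates = np.asarray(self.rates, dtype=float)
        self.available = np.asarray(self.available, dtype=np.int64)
        if self.rates.shape != (N_CHANNELS,):
            raise ParameterError("spectrum needs 96 channel rates")
        if (self.rates < 0).any():
            raise ParameterError("spectrum rates must be non-negative")


def merge_related_clones(
    clone_variant_sets: list[CloneVariantSet], min_shared: int = 3
) -> list[CloneGroup]:
    """Condense clones into groups sharing more than ``min_shared`` variants.

    Two clones are connected iff they share strictly more than
    ``min_shared`` variants (by chrom/pos/ref/alt); groups are the
    connected components and each group's variant list is the union of its
    members' variants, deduplicated.  The result partitions the clone set
    and does not depend on input order.
    """
    graph = nx.Graph()
    keys = {cvs.clone_id: cvs.keys for cvs in clone_variant_sets}
    by_id = {cvs.clone_id: cvs for cvs in clone_variant_sets}
    graph.add_nodes_from(keys)
    ids = sorted(keys)
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            if len(keys[a] & keys[b]) > min_shared:
                graph.add_edge(a, b)
    groups: list[CloneGroup] = []
    components = sorted(nx.connected_components(graph), key=lambda c: sorted(c)[0])
    for gi, comp in enumerate(components):
        union: dict[tuple, Variant] = {}
        for cid in sorted(comp):
            for v in by_id[cid].variants:
                union.setdefault(v.key, v)
        groups.append(
            CloneGroup(
                group_id=f"grp_{gi:02d}",
                member_clones=set(comp),
                variants=sorted(
                    union.values(), key=lambda v: (v.chrom, v.pos, v.ref, v.alt)
                ),
            )
        )
    return groups


def estimate_spectrum(
    groups: list[CloneGroup] | list[Variant],
    genome: GenomeModel,
    estimator: str = "all_substitutions",
) -> MutationSpectrum:
    """Per-channel relative mutation rates from observed substitutions.

    ``all_substitutions`` uses every coding SNV (in a mutagenesis screen,
    passengers vastly outnumber drivers so driver contamination is
    negligible); ``synonymous_only`` restricts to synonymous changes.
    Rates are counts over available context sites, normalized to mean 1;
    channels with zero observed counts are floored at 0.5 pseudo-counts to
    avoid zero neutral expectations.
    """
    variants: list[Variant] = []
    for item in groups:
        if isinstance(item, CloneGroup):
            variants.extend(item.variants)
        else:
            variants.append(item)
    if estimator == "synonymous_only":
        variants = [v for v in variants if v.consequence == SYNONYMOUS]
    elif estimator != "all_substitutions":
        raise ParameterError(f"unknown spectrum estimator {estimator!r}")

    counts = np.zeros(N_CHANNELS)
    for v in variants:
        if v.vtype != SNV:
            continue
        ch = channel_of_variant(v)
        if ch is not None:
            counts[ch] += 1
    if counts.sum() == 0:
        raise ParameterError("no substitutions available to estimate a spectrum")

    ctx_counts = genome.site_index.context_counts  # (32,)
    available = np.array(
        [ctx_counts[_channel_ctx(ch)] for ch in range(N_CHANNELS)], dtype=np.int64
    )
    rates = np.zeros(N_CHANNELS)
    mask = available > 0
    floored = np.maximum(counts[mask], 0.5)
    rates[mask] = floored / available[mask]
    rates[mask] /= rates[mask].mean()
    return MutationSpectrum(rates=rates, available=available)


def _channel_ctx(ch: int) -> int:
    from .channels import channel_to_context_alt

    return channel_to_context_alt(ch)[0]


_CODON_MULT = np.array([16, 4, 1], dtype=np.int64)
_AA_CODES = np.unique(CODON_AA, return_inverse=True)[1]
_STOP_CODE = int(np.flatnonzero(np.unique(CODON_AA) == "*")[0])


def gene_change_table(gene: GeneModel) -> tuple[np.ndarray, np.ndarray]:
    """Exhaustively enumerate all 3L single-base changes of a gene's CDS.

    Returns ``(counts, terminal)`` where ``counts[cls, channel]`` is the
    number of possible changes of consequence class cls (0 synonymous, 1
    missense, 2 nonsense) falling in each 96-channel, and ``terminal[cls]``
    counts changes at the two CDS-terminal bases, which lack a complete
    in-gene trinucleotide context and are weighted at the mean rate.
    """
    s = gene.codes.astype(np.int64)
    L = len(s)
    ctx = context_classes(gene.codes).astype(np.int64)  # -1 at the 2 ends
    pos = np.arange(L)
    r = pos % 3
    codon_of = (s[0::3] * 16 + s[1::3] * 4 + s[2::3])[pos // 3]
    aa_old = _AA_CODES[codon_of]

    counts = np.zeros((4, N_CHANNELS), dtype=np.int64)
    terminal = np.zeros(4, dtype=np.int64)
    for off in (1, 2, 3):
        alt = (s + off) % 4
        new_codon = codon_of + (alt - s) * _CODON_MULT[r]
        aa_new = _AA_CODES[new_codon]
        cls = np.where(aa_new == aa_old, CLASS_SYN, np.where(aa_new == _STOP_CODE, CLASS_NON, CLASS_MIS))
        purine = (s == 0) | (s == 2)
        alt_pyr = np.where(purine, COMP_CODE[alt], alt).astype(np.int64)
        interior = ctx >= 0
        ch = _CTX_ALT_TO_CHANNEL[ctx[interior], alt_pyr[interior]]
        np.add.at(counts, (cls[interior], ch), 1)
        np.add.at(terminal, cls[~interior], 1)
    return counts, terminal


def gene_opportunities(gene: GeneModel, spectrum: MutationSpectrum) -> dict[str, float]:
    """Spectrum-weighted relative rates of each consequence class.

    ``R_class`` sums the spectrum rate of every possible single-base change
    of the CDS producing that class.  Single-exon genes have no splice
    window, so ``R_splice`` is 0.
    """
    counts, terminal = gene_change_table(gene)
    R = counts @ spectrum.rates + terminal  # terminal changes at mean rate 1
    return {
        "R_syn": float(R[CLASS_SYN]),
        "R_mis": float(R[CLASS_MIS]),
        "R_non": float(R[CLASS_NON]),
        "R_splice": float(R[CLASS_SPLICE]),
    }


def _opportunity_matrix(genome: GenomeModel, spectrum: MutationSpectrum) -> pd.DataFrame:
    """Per-gene opportunity table; change tables are cached on the genome."""
    cache = getattr(genome, "_change_tables", None)
    if cache is None:
        cache = {}
        for g in genome.genes:
            cache[g.gene_id] = gene_change_table(g)
        genome._change_tables = cache
    rows = {}
    for gid, (counts, terminal) in cache.items():
        R = counts @ spectrum.rates + terminal
        rows[gid] = R
    return pd.DataFrame.from_dict(
        rows, orient="index", columns=["R_syn", "R_mis", "R_non", "R_splice"]
    )


def _pois_ll(n: float, mu: float) -> float:
    if mu <= 0:
        return 0.0 if n == 0 else -np.inf
    return float(n * np.log(mu) - mu) if n > 0 else float(-mu)


_MAX_DISPERSION_SHAPE = 1e6


def estimate_rate_dispersion(
    n_syn: np.ndarray, R_syn: np.ndarray, background_syn_rate: float
) -> float:
    """Gamma shape of cross-gene mutation-rate variation, from synonymous counts.

    Models per-gene synonymous counts as negative binomial with mean
    ``background_syn_rate * R_syn`` and a common shape theta (per-gene
    rates ~ Gamma with coefficient of variation 1/sqrt(theta)); returns the
    maximum-likelihood theta, capped for numerical stability.  Large theta
    means homogeneous rates and licenses strong shrinkage of each gene's
    rate toward the exome-wide value.
    """
    n_syn = np.asarray(n_syn, dtype=float)
    mu = background_syn_rate * np.asarray(R_syn, dtype=float)
    keep = mu > 0
    n_syn, mu = n_syn[keep], mu[keep]
    if len(n_syn) == 0 or background_syn_rate <= 0:
        return _MAX_DISPERSION_SHAPE

    def negll(log_theta: float) -> float:
        theta = np.exp(log_theta)
        p = theta / (theta + mu)
        return -float(stats.nbinom.logpmf(n_syn, theta, p).sum())

    from scipy.optimize import minimize_scalar

    res = minimize_scalar(
        negll, bounds=(np.log(1e-2), np.log(_MAX_DISPERSION_SHAPE)), method="bounded"
    )
    return float(np.exp(res.x))


def gene_dnds_test(
    counts: dict[str, float],
    opportunities: dict[str, float],
    background_syn_rate: float,
    prior_shape: float = _MAX_DISPERSION_SHAPE,
    one_sided: bool = False,
) -> tuple[float, float, float, float]:
    """Likelihood-ratio tests for excess nonsynonymous substitutions.

    The gene's local neutral rate lambda is estimated from its synonymous
    count with conjugate Gamma shrinkage toward the exome-wide synonymous
    rate (``background_syn_rate`` mutations per unit synonymous
    opportunity): the prior contributes ``prior_shape`` pseudo-mutations at
    the exome-wide rate, so ``prior_shape`` should be the estimated
    cross-gene rate-dispersion shape (see
    :func:`estimate_rate_dispersion`).  Tests: H0 omega_mis = 1 (1 df) for
    ``p_mis``; H0 omega_mis = omega_trunc = 1 (2 df) for ``p_sub_global``,
    where trunc pools nonsense and splice changes.  Returns
    ``(omega_mis, omega_trunc, p_mis, p_sub_global)``.
    """
    n_syn = float(counts.get("n_syn", 0))
    n_mis = float(counts.get("n_mis", 0))
    n_tr = float(counts.get("n_non", 0)) + float(counts.get("n_splice", 0))
    R_syn = float(opportunities["R_syn"])
    R_mis = float(opportunities["R_mis"])
    R_tr = float(opportunities["R_non"]) + float(opportunities["R_splice"])
    if R_syn <= 0:
        raise ParameterError("synonymous opportunity must be positive")

    # conjugate shrinkage: prior_shape pseudo-counts at the exome-wide rate
    if background_syn_rate > 0 and prior_shape > 0:
        syn_eff = n_syn + prior_shape
        R_syn_eff = R_syn + prior_shape / background_syn_rate
    else:
        syn_eff = n_syn
        R_syn_eff = R_syn
    lam = syn_eff / R_syn_eff

    omega_mis = n_mis / (lam * R_mis) if R_mis > 0 and lam > 0 else 0.0
    omega_trunc = n_tr / (lam * R_tr) if R_tr > 0 and lam > 0 else 0.0

    def lrt(parts: list[tuple[float, float]], df: int) -> float:
        # parts: (count, opportunity) for the non-synonymous classes tested
        tot_n = syn_eff + sum(n for n, _ in parts)
        tot_R = R_syn_eff + sum(R for _, R in parts)
        lam0 = tot_n / tot_R
        ll0 = _pois_ll(syn_eff, lam0 * R_syn_eff) + sum(
            _pois_ll(n, lam0 * R) for n, R in parts
        )
        ll1 = _pois_ll(syn_eff, lam * R_syn_eff) + sum(
            _pois_ll(n, n if n > 0 else 0.0) if R > 0 else _pois_ll(n, 0.0)
            for n, R in parts
        )
        lr = max(0.0, 2.0 * (ll1 - ll0))
        return float(stats.chi2.sf(lr, df))

    p_mis = lrt([(n_mis, R_mis)], 1) if R_mis > 0 else 1.0
    parts = [(n_mis, R_mis)] if R_mis > 0 else []
    if R_tr > 0:
        parts.append((n_tr, R_tr))
    p_sub_global = lrt(parts, len(parts)) if parts else 1.0
    if one_sided:
        p_mis = p_mis / 2 if omega_mis > 1 else 1 - p_mis / 2
    return omega_mis, omega_trunc, p_mis, p_sub_global


def exome_indel_rate(groups: list[CloneGroup], genome: GenomeModel) -> float:
    """Coding indels per coding base, aggregated over all groups."""
    n_ind = sum(
        1
        for g in groups
        for v in g.variants
        if v.consequence in (FRAMESHIFT, INFRAME)
    )
    return n_ind / genome.background_length


def indel_recurrence_test(n_ind: int, rate_per_base: float, coding_length: int) -> float:
    """Poisson upper tail for recurrent coding indels in one gene.

    There is no synonymous-like neutral reference for indels, so
    recurrence is tested against the exome-wide coding indel rate:
    ``p = P(K >= n_ind)`` with ``K ~ Poisson(rate_per_base * length)``.
    """
    if n_ind < 0 or rate_per_base < 0 or coding_length <= 0:
        raise ParameterError("invalid indel test inputs")
    if n_ind == 0:
        return 1.0
    lam = rate_per_base * coding_length
    return float(stats.poisson.sf(n_ind - 1, lam))


def fisher_combine(p1: float, p2: float) -> float:
    """Fisher combination of two independent p-values (chi-square, 4 df)."""
    for p in (p1, p2):
        if not 0 < p <= 1:
            raise ParameterError(f"p-values must be in (0, 1], got {p}")
    x2 = -2.0 * (np.log(p1) + np.log(p2))
    return float(stats.chi2.sf(x2, 4))


def stratified_fdr(pvalues, strata_labels=None) -> np.ndarray:
    """Benjamini-Hochberg q-values computed independently within strata.

    With a single stratum (or ``strata_labels=None``) this is plain BH.
    """
    pvalues = np.asarray(pvalues, dtype=float)
    q = np.empty_like(pvalues)
    if strata_labels is None:
        strata_labels = np.zeros(len(pvalues), dtype=int)
    strata_labels = np.asarray(strata_labels)
    if len(strata_labels) != len(pvalues):
        raise ParameterError("one stratum label per p-value required")
    for label in np.unique(strata_labels):
        idx = strata_labels == label
        if idx.any():
            q[idx] = multipletests(pvalues[idx], method="fdr_bh")[1]
    return q


def count_gene_mutations(groups: list[CloneGroup]) -> pd.DataFrame:
    """Observed per-gene mutation counts pooled over groups."""
    rows: dict[str, dict[str, int]] = {}
    for g in groups:
        for v in g.variants:
            if not v.gene_id:
                continue
            rec = rows.setdefault(
                v.gene_id,
                {"n_syn": 0, "n_mis": 0, "n_non": 0, "n_splice": 0, "n_ind": 0},
            )
            if v.consequence == SYNONYMOUS:
                rec["n_syn"] += 1
            elif v.consequence == MISSENSE:
                rec["n_mis"] += 1
            elif v.consequence == NONSENSE:
                rec["n_non"] += 1
            elif v.consequence == SPLICE:
                rec["n_splice"] += 1
            elif v.consequence in (FRAMESHIFT, INFRAME):
                rec["n_ind"] += 1
    return pd.DataFrame.from_dict(rows, orient="index").rename_axis("gene_id")


def run_selection(
    groups: list[CloneGroup],
    genome: GenomeModel,
    spectrum: MutationSpectrum | None = None,
    spectrum_estimator: str = "all_substitutions",
    prior_shape: float | None = None,
    alpha: float = 0.05,
    strata: str | None = None,
) -> pd.DataFrame:
    """Full gene-level selection analysis over clone groups.

    Genes with at least one observed coding mutation are tested; FDR is
    plain BH by default or stratified by gene-opportunity tertiles when
    ``strata='opportunity_tertiles'``.  The shrinkage prior shape defaults
    to the dispersion estimated from the per-gene synonymous counts over
    all genes.  Returns one row per tested gene with counts, omegas,
    p- and q-values and the significance flag (``qmis_sfdr < alpha`` OR
    ``qglobal_sfdr < alpha``).
    """
    if spectrum is None:
        spectrum = estimate_spectrum(groups, genome, estimator=spectrum_estimator)
    counts = count_gene_mutations(groups)
    opp = _opportunity_matrix(genome, spectrum)

    # exome-wide synonymous rate per unit synonymous opportunity
    total_syn = counts["n_syn"].sum() if len(counts) else 0
    total_R_syn = opp["R_syn"].sum()
    background_syn_rate = total_syn / total_R_syn if total_R_syn > 0 else 0.0
    if prior_shape is None:
        syn_all = counts["n_syn"].reindex(opp.index).fillna(0).to_numpy()
        prior_shape = estimate_rate_dispersion(
            syn_all, opp["R_syn"].to_numpy(), background_syn_rate
        )
    ind_rate = exome_indel_rate(groups, genome)

    rows = []
    for gid, rec in counts.iterrows():
        if gid not in opp.index:
            continue
        o = opp.loc[gid].to_dict()
        omega_mis, omega_trunc, p_mis, p_sub = gene_dnds_test(
            rec.to_dict(), o, background_syn_rate, prior_shape
        )
        gene = genome.gene_by_id[gid]
        p_ind = indel_recurrence_test(int(rec["n_ind"]), ind_rate, gene.coding_length)
        p_global = fisher_combine(p_sub, p_ind)
        if background_syn_rate > 0 and prior_shape > 0:
            lam = (rec["n_syn"] + prior_shape) / (
                o["R_syn"] + prior_shape / background_syn_rate
            )
        else:
            lam = rec["n_syn"] / o["R_syn"]
        rows.append(
            {
                "gene_id": gid,
                **{k: int(rec[k]) for k in ("n_syn", "n_mis", "n_non", "n_splice", "n_ind")},
                "e_mis": lam * o["R_mis"],
                "e_non": lam * o["R_non"],
                "e_splice": lam * o["R_splice"],
                "omega_mis": omega_mis,
                "omega_trunc": omega_trunc,
                "p_mis": p_mis,
                "p_sub_global": p_sub,
                "p_ind": p_ind,
                "p_global": p_global,
                "opportunity": o["R_syn"] + o["R_mis"] + o["R_non"] + o["R_splice"],
            }
        )
    result = pd.DataFrame(rows)
    if result.empty:
        return result
    result = result.set_index("gene_id")

    labels = None
    if strata == "opportunity_tertiles":
        labels = pd.qcut(result["opportunity"], 3, labels=False, duplicates="drop")
        labels = np.asarray(labels)
    result["qmis_sfdr"] = stratified_fdr(result["p_mis"].to_numpy(), labels)
    result["qglobal_sfdr"] = stratified_fdr(result["p_global"].to_numpy(), labels)
    result["significant"] = (result["qmis_sfdr"] < alpha) | (result["qglobal_sfdr"] < alpha)
    result["min_q"] = result[["qmis_sfdr", "qglobal_sfdr"]].min(axis=1)
    return result.sort_values(["min_q", "p_global"])


def rank_resistance_genes(results: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Significant genes under the q_mis OR q_global rule, sorted by min q."""
    if results.empty:
        return results
    flagged = results[
        (results["qmis_sfdr"] < alpha) | (results["qglobal_sfdr"] < alpha)
    ].copy()
    return flagged.sort_values("min_q")
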