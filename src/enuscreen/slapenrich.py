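"""Sample-level pathway enrichment through a Poisson binomial model.

For each pathway P and sample i, the probability p_i of observing at
least one mutated member gene is derived from the pathway's total
exon-block length L_P, the background coding length L_bg, and the
sample's mutation burden n_i.  The number of samples with >= 1 mutated
member gene is then a sum of independent, non-identical Bernoulli trials
— a Poisson binomial variable — and the enrichment p-value is the exact
upper tail P(X >= o) at the observed count o.  Enriched pathways are
additionally required to show mutual exclusivity of their mutated genes
(exclusive coverage).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .errors import ParameterError
from .genome import GenomeModel

logger = logging.getLogger(__name__)


@dataclass
class PathwayStats:
    """Per-pathway enrichment statistics."""

    pathway_id: str
    block_length: int  # L_P
    member_genes: set[str]
    sample_probs: np.ndarray  # p_i
    expected: float  # sum of p_i
    observed: int  # samples with >=1 mutated member gene
    pvalue: float
    qvalue: float = np.nan
    exclusive_coverage: float | None = None
    enriched: bool = False
    all_genes_present: bool = True


def pathway_block_length(pathway_genes, genome: GenomeModel) -> int:
    """Total exon-block length L_P of the union of member genes (bases).

    Duplicate gene ids count once; an empty pathway is an error.
    """
    members = set(pathway_genes)
    if not members:
        raise ParameterError("empty pathway")
    missing = members - set(genome.gene_by_id)
    if missing:
        raise ParameterError(f"pathway genes not in genome: {sorted(missing)}")
    return sum(genome.gene_by_id[g].coding_length for g in members)


def sample_pathway_prob(n_i: int, L_P: int, L_bg: int, model: str = "poisson") -> float:
    """Probability that a sample with burden n_i hits the pathway at least once.

    Under a uniform mutation rate over the background coding length, the
    poisson model gives ``1 - exp(-n_i * L_P / L_bg)`` and the bernoulli
    model ``1 - (1 - L_P/L_bg)**n_i``; they agree to O((L_P/L_bg)^2).
    """
    if n_i < 0:
        raise ParameterError("burden must be non-negative")
    if not 0 < L_P <= L_bg:
        raise ParameterError(f"need 0 < L_P ({L_P}) <= L_bg ({L_bg})")
    if n_i == 0:
        return 0.0
    ratio = L_P / L_bg
    if model == "poisson":
        return float(1.0 - np.exp(-n_i * ratio))
    if model == "bernoulli":
        return float(1.0 - (1.0 - ratio) ** n_i)
    raise ParameterError(f"unknown probability model {model!r}")


def poisson_binomial_pmf(probs) -> np.ndarray:
    """Exact pmf of a sum of independent Bernoulli(p_i) by DP convolution."""
    probs = np.asarray(probs, dtype=float)
    if ((probs < 0) | (probs > 1)).any():
        raise ParameterError("probabilities must be in [0, 1]")
    pmf = np.zeros(len(probs) + 1)
    pmf[0] = 1.0
    for i, p in enumerate(probs):
        pmf[1 : i + 2] = pmf[1 : i + 2] * (1 - p) + pmf[: i + 1] * p
        pmf[0] *= 1 - p
    return pmf


def poisson_binomial_tail(probs, o: int) -> float:
    """Exact upper tail P(X >= o) of the Poisson binomial distribution."""
    probs = np.asarray(probs, dtype=float)
    n = len(probs)
    if o < 0:
        return 1.0
    if o > n:
        warnings.warn(f"observed {o} exceeds number of trials {n}; tail is 0")
        return 0.0
    pmf = poisson_binomial_pmf(probs)
    return float(min(1.0, max(0.0, pmf[o:].sum())))


def poisson_binomial_randomized_pvalue(probs, o: int, u: float) -> float:
    """Uniformized tail p-value ``P(X > o) + u * P(X = o)``.

    The exact tail p-value of a discrete statistic is conservative
    (stochastically larger than uniform under the null); with ``u`` drawn
    Uniform(0,1), this randomized version is exactly Uniform(0,1) whenever
    the Poisson binomial model holds, making it the appropriate quantity
    for calibration diagnostics such as KS uniformity checks.
    """
    pmf = poisson_binomial_pmf(probs)
    o = int(np.clip(o, 0, len(pmf) - 1))
    return float(pmf[o + 1 :].sum() + u * pmf[o])


def exclusive_coverage(event_matrix: pd.DataFrame, pathway_genes) -> float | None:
    """Fraction of covered samples with exactly one mutated member gene.

    Covered means >= 1 mutated member gene; returns None when no sample is
    covered (the pathway then fails the mutual-exclusivity filter).
    """
    members = [g for g in set(pathway_genes) if g in event_matrix.index]
    if not members:
        raise ParameterError("pathway has no gene in the event matrix")
    hits = event_matrix.loc[members].sum(axis=0)
    covered = int((hits >= 1).sum())
    if covered == 0:
        return None
    return float((hits == 1).sum() / covered)


def pathway_enrichment(
    event_matrix: pd.DataFrame,
    burdens: pd.Series,
    pathways: dict[str, set[str]],
    genome: GenomeModel,
    model: str = "poisson",
    fdr_threshold: float = 0.05,
    ec_threshold: float = 0.8,
    background_length: int | None = None,
) -> list[PathwayStats]:
    """Sample-level enrichment statistics for every pathway.

    The background length L_bg defaults to the total exon-block length of
    all genes in the pathway collection (the gene network actually tested),
    and per-sample burdens should be counted over the same background.
    A pathway is flagged enriched iff its BH q-value is below
    ``fdr_threshold`` and its exclusive coverage reaches ``ec_threshold``.
    Results are sorted by p-value; the computation is deterministic.
    """
    samples = list(event_matrix.columns)
    burdens = burdens.reindex(samples)
    if burdens.isna().any():
        raise ParameterError("burdens missing for some samples in the event matrix")
    if background_length is None:
        network_genes = set().union(*pathways.values()) if pathways else set()
        network_genes &= set(genome.gene_by_id)
        background_length = sum(
            genome.gene_by_id[g].coding_length for g in network_genes
        )
    if background_length <= 0:
        raise ParameterError("background length must be positive")

    results: list[PathwayStats] = []
    for pid, members in pathways.items():
        present = set(members) & set(genome.gene_by_id)
        all_present = present == set(members)
        if not present:
            logger.warning("pathway %s has no gene in the genome; skipped", pid)
            continue
        L_P = pathway_block_length(present, genome)
        probs = np.array(
            [
                sample_pathway_prob(int(burdens[s]), L_P, background_length, model)
                for s in samples
            ]
        )
        in_matrix = [g for g in present if g in event_matrix.index]
        if in_matrix:
            hits = event_matrix.loc[in_matrix].sum(axis=0)
            observed = int((hits >= 1).sum())
            ec = exclusive_coverage(event_matrix, in_matrix) if observed else None
        else:
            observed = 0
            ec = None
        pval = poisson_binomial_tail(probs, observed) if observed > 0 else 1.0
        results.append(
            PathwayStats(
                pathway_id=pid,
                block_length=L_P,
                member_genes=set(members),
                sample_probs=probs,
                expected=float(probs.sum()),
                observed=observed,
                pvalue=pval,
                exclusive_coverage=ec,
                all_genes_present=all_present,
            )
        )

    if results:
        pvals = np.array([r.pvalue for r in results])
        _, qvals, _, _ = multipletests(pvals, method="fdr_bh")
        for r, q in zip(results, qvals):
            r.qvalue = float(q)
            r.enriched = bool(
                q < fdr_threshold
                and r.exclusive_coverage is not None
                and r.exclusive_coverage >= ec_threshold
            )
    results.sort(key=lambda r: (r.pvalue, r.pathway_id))
    return results


def enrichment_to_frame(results: list[PathwayStats]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "pathway_id": r.pathway_id,
                "L_P": r.block_length,
                "n_genes": len(r.member_genes),
                "expected": r.expected,
                "observed": r.observed,
                "pvalue": r.pvalue,
                "qvalue": r.qvalue,
                "exclusive_coverage": (
                    np.nan if r.exclusive_coverage is None else r.exclusive_coverage
                ),
                "enriched": r.enriched,
            }
            for r in results
        ]
    )
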