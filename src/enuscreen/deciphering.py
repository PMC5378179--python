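"""Deciphering mutational signatures from 96-channel catalogs by NMF.

The deciphering procedure follows the standard signature-extraction
recipe: factorize the catalog matrix V (96 x samples) as V ~ S.E with
non-negative S (column-stochastic signatures) and E (exposures), using
multiplicative-update NMF under a generalized Kullback-Leibler objective
(appropriate for count data), with multiple random restarts; assess the
reproducibility of each signature by refitting on bootstrap-resampled
catalogs and measuring cosine similarity to the consensus; choose the
largest number of signatures whose mean stability stays above a floor.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment, nnls
from sklearn.decomposition import NMF

from .catalog import MutationalCatalog
from .errors import ParameterError


def cosine_similarity(a, b) -> float:
    """Cosine of the angle between two non-negative vectors; 1 iff proportional."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ParameterError("cosine similarity of a zero vector is undefined")
    return float(np.clip(a @ b / (na * nb), 0.0, 1.0))


@dataclass
class SignatureSet:
    """Result of deciphering at one value of k."""

    k: int
    signatures: np.ndarray  # (96, k), columns sum to 1
    exposures: np.ndarray  # (k, n_samples), non-negative
    stability: np.ndarray  # (k,) mean bootstrap cosine per signature
    reconstruction_error: float  # Frobenius norm of V - S.E
    sample_ids: list[str] = field(default_factory=list)

    @property
    def mean_stability(self) -> float:
        return float(self.stability.mean())


def _fit_nmf(V: np.ndarray, k: int, seed: int, objective: str, max_iter: int, tol: float):
    beta = "kullback-leibler" if objective == "kl" else "frobenius"
    model = NMF(
        n_components=k,
        init="random",
        solver="mu",
        beta_loss=beta,
        max_iter=max_iter,
        tol=tol,
        random_state=seed,
    )
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        W = model.fit_transform(V)
        H = model.components_
    return W, H, float(model.reconstruction_err_)


def _normalize(W: np.ndarray, H: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    scale = W.sum(axis=0)
    scale[scale == 0] = 1.0
    return W / scale, H * scale[:, None]


def decipher_signatures(
    catalogs: list[MutationalCatalog],
    k_range=(1, 2, 3),
    n_bootstrap: int = 100,
    n_restarts: int = 10,
    seed: int = 0,
    objective: str = "kl",
    stability_floor: float = 0.8,
    max_iter: int = 1000,
    tol: float = 1e-6,
) -> tuple[dict[int, SignatureSet], int]:
    """Decipher signatures for each k in ``k_range``; select k by stability.

    Returns (per-k results, selected k) where the selected k is the largest
    k whose mean bootstrap stability is at least ``stability_floor``.
    All-zero catalogs are dropped with a warning.
    """
    import logging

    logger = logging.getLogger(__name__)
    k_range = sorted(set(int(k) for k in k_range))
    if not k_range:
        raise ParameterError("k_range is empty")
    kept = [c for c in catalogs if c.total > 0]
    for c in catalogs:
        if c.total == 0:
            logger.warning("catalog %s is all-zero; dropped", c.sample_id)
    if len(kept) < 2:
        raise ParameterError("need at least 2 non-empty catalogs")
    n_samples = len(kept)
    for k in k_range:
        if k >= min(96, n_samples) and k != 1:
            raise ParameterError(f"k={k} must be < min(96, n_samples={n_samples})")

    V = np.stack([c.counts for c in kept], axis=1).astype(float)  # (96, n)
    sample_ids = [c.sample_id for c in kept]
    ss = np.random.SeedSequence(seed)
    results: dict[int, SignatureSet] = {}

    for k in k_range:
        k_ss = np.random.SeedSequence(seed, spawn_key=(k,))
        restart_seeds = k_ss.generate_state(n_restarts)
        best = None
        for rs in restart_seeds:
            W, H, err = _fit_nmf(V, k, int(rs % (2**31 - 1)), objective, max_iter, tol)
            if best is None or err < best[2]:
                best = (W, H, err)
        W, H, _ = best
        S, E = _normalize(W, H)
        frob = float(np.linalg.norm(V - S @ E))

        boot_rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(k, 1)))
        boot_seeds = np.random.SeedSequence(seed, spawn_key=(k, 2)).generate_state(
            max(n_bootstrap, 1)
        )
        cos_sums = np.zeros(k)
        n_boot_done = 0
        for b in range(n_bootstrap):
            Vb = np.empty_like(V)
            for j in range(n_samples):
                total = int(V[:, j].sum())
                p = V[:, j] / total
                Vb[:, j] = boot_rng.multinomial(total, p)
            Wb, Hb, _ = _fit_nmf(
                Vb, k, int(boot_seeds[b] % (2**31 - 1)), objective, max_iter, tol
            )
            Sb, _ = _normalize(Wb, Hb)
            # match bootstrap signatures to the consensus (max total cosine)
            cost = np.zeros((k, k))
            for i in range(k):
                for j in range(k):
                    si = S[:, i]
                    sj = Sb[:, j]
                    cost[i, j] = (
                        -cosine_similarity(si, sj)
                        if si.any() and sj.any()
                        else 0.0
                    )
            row, col = linear_sum_assignment(cost)
            for i, j in zip(row, col):
                cos_sums[i] += -cost[i, j]
            n_boot_done += 1
        stability = cos_sums / max(n_boot_done, 1) if n_boot_done else np.ones(k)
        results[k] = SignatureSet(
            k=k,
            signatures=S,
            exposures=E,
            stability=stability,
            reconstruction_error=frob,
            sample_ids=sample_ids,
        )

    selected = k_range[0]
    for k in k_range:
        if n_bootstrap == 0 or results[k].mean_stability >= stability_floor:
            selected = k
    return results, selected


def estimate_exposures(
    catalog: MutationalCatalog | np.ndarray, signatures: np.ndarray
) -> tuple[np.ndarray, float]:
    """Non-negative least-squares exposures of one catalog on fixed signatures.

    Solves ``argmin_{e >= 0} || v - S e ||_2``; returns (exposures, residual).
    """
    v = catalog.counts if isinstance(catalog, MutationalCatalog) else np.asarray(catalog)
    S = np.asarray(signatures, dtype=float)
    col_sums = S.sum(axis=0)
    if not np.allclose(col_sums[col_sums > 0], 1.0, atol=1e-6):
        raise ParameterError("signatures must be column-stochastic")
    e, residual = nnls(S, v.astype(float))
    return e, float(residual)
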