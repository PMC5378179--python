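"""96-channel mutational catalogs."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .channels import BASE_CODE, CHANNEL_NAMES, N_CHANNELS, context_alt_to_channel
from .variants import SNV, Variant

logger = logging.getLogger(__name__)


@dataclass
class MutationalCatalog:
    """Per-sample counts over the 96 substitution channels."""

    sample_id: str
    counts: np.ndarray

    def __post_init__(self):
        counts = np.asarray(self.counts, dtype=np.int64)
        if counts.shape != (N_CHANNELS,) or (counts < 0).any():
            raise ValueError("counts must be 96 non-negative integers")
        self.counts = counts

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def channel_of_variant(v: Variant) -> int | None:
    """96-channel index of an annotated SNV, or None if no context."""
    if v.vtype != SNV or not v.context:
        return None
    if "N" in v.context or len(v.context) != 3:
        return None
    five, ref, three = v.context
    alt = v.alt
    if v.ref in "AG":  # context already pyrimidine-normalized; flip alt too
        alt = {"A": "T", "C": "G", "G": "C", "T": "A"}[alt]
    ctx = (0 if ref == "C" else 16) + BASE_CODE[five] * 4 + BASE_CODE[three]
    return context_alt_to_channel(ctx, BASE_CODE[alt])


def build_catalog(variants: list[Variant], samples: list[str]) -> list[MutationalCatalog]:
    """Build one 96-channel catalog per sample from annotated variants.

    Each coding SNV with a defined trinucleotide context increments exactly
    one channel after pyrimidine normalization; indels and context-less
    records are skipped (with a warning for malformed contexts).
    """
    counts = {s: np.zeros(N_CHANNELS, dtype=np.int64) for s in samples}
    for v in variants:
        if v.clone_id not in counts or v.vtype != SNV:
            continue
        if v.context is not None and ("N" in v.context or len(v.context) != 3):
            logger.warning("%s:%d context %r skipped", v.chrom, v.pos, v.context)
            continue
        ch = channel_of_variant(v)
        if ch is not None:
            counts[v.clone_id][ch] += 1
    return [MutationalCatalog(s, counts[s]) for s in samples]


def catalogs_to_frame(catalogs: list[MutationalCatalog]) -> pd.DataFrame:
    """96 x n_samples count matrix with channel names as the index."""
    return pd.DataFrame(
        {c.sample_id: c.counts for c in catalogs}, index=list(CHANNEL_NAMES)
    )
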