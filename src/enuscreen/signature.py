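"""Mutational signature profiles over the 96 substitution channels."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .channels import CHANNEL_NAMES, N_CHANNELS, SUB_CLASSES
from .errors import ParameterError


@dataclass(frozen=True)
class SignatureProfile:
    """A probability distribution over the 96 substitution channels."""

    channel_probs: np.ndarray

    def __post_init__(self):
        probs = np.asarray(self.channel_probs, dtype=float)
        if probs.shape != (N_CHANNELS,):
            raise ParameterError(f"expected {N_CHANNELS} channel probabilities")
        if (probs < 0).any():
            raise ParameterError("channel probabilities must be non-negative")
        if abs(probs.sum() - 1.0) > 1e-9:
            raise ParameterError(f"channel probabilities sum to {probs.sum():.12f}, not 1")
        object.__setattr__(self, "channel_probs", probs)

    def class_totals(self) -> dict[str, float]:
        """Mass per six-class substitution type (C>A .. T>G)."""
        probs = self.channel_probs.reshape(6, 16)
        return {cls: float(probs[i].sum()) for i, cls in enumerate(SUB_CLASSES)}

    def to_series(self):
        import pandas as pd

        return pd.Series(self.channel_probs, index=list(CHANNEL_NAMES))


def signature_from_class_weights(class_weights) -> SignatureProfile:
    """Build a profile from six per-class weights, uniform within class.

    Weights are normalized to sum to 1; each class's mass is spread evenly
    over its 16 flanking contexts.
    """
    w = np.asarray(class_weights, dtype=float)
    if w.shape != (6,):
        raise ParameterError("expected 6 class weights (C>A, C>G, C>T, T>A, T>C, T>G)")
    if (w < 0).any() or w.sum() <= 0:
        raise ParameterError("class weights must be non-negative and not all zero")
    w = w / w.sum()
    probs = np.repeat(w / 16.0, 16)
    return SignatureProfile(probs)


def default_enu_signature(cg_fraction: float = 0.03) -> SignatureProfile:
    """The ENU-like substitution profile used as the simulator default.

    ENU alkylation yields point mutations across essentially all
    trinucleotide contexts; of the six substitution classes only C>G is
    depleted, at about 3% of substitutions.  The default therefore puts
    ``cg_fraction`` mass on C>G and spreads the remainder evenly over the
    other five classes, uniformly within each class.
    """
    if not 0 <= cg_fraction < 1:
        raise ParameterError("cg_fraction must be in [0, 1)")
    other = (1.0 - cg_fraction) / 5.0
    return signature_from_class_weights(
        [other, cg_fraction, other, other, other, other]
    )


def msi_like_signature() -> SignatureProfile:
    """A synthetic mismatch-repair-deficiency-like substitution profile.

    A stand-in contaminant process concentrated on C>T and T>C changes
    (the substitution component typical of hypermutator, MSI-like clones),
    used to exercise signature deciphering against a second process.  It
    is a constructed test profile, not a measured signature.
    """
    probs = np.zeros(96)
    # heavy C>T with a 3' G preference, moderate T>C, light C>A
    ct = np.full(16, 1.0)
    ct[2::4] = 4.0  # N[C>T]G contexts
    probs[32:48] = 0.60 * ct / ct.sum()
    probs[64:80] = 0.30 / 16
    probs[0:16] = 0.10 / 16
    return SignatureProfile(probs / probs.sum())
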