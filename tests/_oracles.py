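"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own code paths (channel tables,
DP convolutions, vectorized enumeration) so they can serve as external
references: exhaustive enumeration for the Poisson binomial, Biopython
translation for consequences, string-level context arithmetic for
channel rates, and union-find for clone grouping.
"""

import numpy as np
from Bio.Seq import Seq

COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}
CLASS_ORDER = ["C>A", "C>G", "C>T", "T>A", "T>C", "T>G"]
BASES = "ACGT"


def enumerate_poisson_binomial_tail(probs, o):
    """P(X >= o) by exhaustive enumeration of all 2^n Bernoulli outcomes."""
    probs = np.asarray(probs, dtype=float)
    n = len(probs)
    outcomes = np.arange(2**n)
    bits = (outcomes[:, None] >> np.arange(n)) & 1  # (2^n, n)
    weights = np.where(bits == 1, probs, 1 - probs).prod(axis=1)
    return float(weights[bits.sum(axis=1) >= o].sum())


def classify_snv_oracle(cds: str, pos0: int, alt: str) -> str:
    """Consequence of a single-base change by whole-protein translation."""
    before = str(Seq(cds).translate())
    mutated = cds[:pos0] + alt + cds[pos0 + 1 :]
    after = str(Seq(mutated).translate())
    codon_idx = pos0 // 3
    if after[codon_idx] == before[codon_idx]:
        return "synonymous"
    if after[codon_idx] == "*":
        return "nonsense"
    return "missense"


def channel_name_oracle(five: str, ref: str, three: str, alt: str) -> str:
    """96-channel name via explicit string-level pyrimidine normalization."""
    if ref in "AG":
        five, ref, three = COMP[three], COMP[ref], COMP[five]
        alt = COMP[alt]
    return f"{five}[{ref}>{alt}]{three}"


def opportunity_oracle(cds: str, rates_by_name: dict) -> dict:
    """Per-class opportunity sums by looping over every single-base change.

    Terminal bases (no complete in-CDS context) contribute rate 1.0.
    """
    out = {"R_syn": 0.0, "R_mis": 0.0, "R_non": 0.0}
    key = {"synonymous": "R_syn", "missense": "R_mis", "nonsense": "R_non"}
    for i, ref in enumerate(cds):
        for alt in BASES:
            if alt == ref:
                continue
            cls = classify_snv_oracle(cds, i, alt)
            if 0 < i < len(cds) - 1:
                name = channel_name_oracle(cds[i - 1], ref, cds[i + 1], alt)
                rate = rates_by_name[name]
            else:
                rate = 1.0
            out[key[cls]] += rate
    return out


def connected_components_oracle(nodes, edges):
    """Connected components via plain union-find."""
    parent = {n: n for n in nodes}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b in edges:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb
    groups = {}
    for n in nodes:
        groups.setdefault(find(n), set()).add(n)
    return sorted(groups.values(), key=lambda s: sorted(s)[0])
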