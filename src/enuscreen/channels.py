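"""The 96-channel trinucleotide substitution convention.

Every single-base substitution is expressed with the mutated pyrimidine of
the Watson-Crick pair (C or T); purine-reference calls are reverse
complemented.  Channels are ordered class-major: the six substitution
classes in the order C>A, C>G, C>T, T>A, T>C, T>G, and within each class
the 16 flanking contexts ordered by 5' base then 3' base, each A<C<G<T
(the layout conventionally used for signature bar charts).

Internally bases are encoded A=0, C=1, G=2, T=3.  A genomic site is
assigned one of 32 pyrimidine-normalized *context classes* (center base C
or T after normalization, times 16 flanks); a channel is a context class
plus one of the three possible alternate pyrimidine-frame bases.
"""

from __future__ import annotations

import numpy as np

BASES = "ACGT"
BASE_CODE = {b: i for i, b in enumerate(BASES)}
COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}
COMP_CODE = np.array([3, 2, 1, 0], dtype=np.uint8)  # A<->T, C<->G

SUB_CLASSES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")

# per class: (pyrimidine ref code, alt code)
_CLASS_REF_ALT = [(1, 0), (1, 2), (1, 3), (3, 0), (3, 1), (3, 2)]

N_CHANNELS = 96
N_CONTEXTS = 32  # 2 pyrimidine centers x 4 five-prime x 4 three-prime


def channel_name(idx: int) -> str:
    """Human-readable name like ``A[C>G]T`` for channel index 0..95."""
    cls, ctx = divmod(idx, 16)
    five, three = divmod(ctx, 4)
    ref, alt = _CLASS_REF_ALT[cls]
    return f"{BASES[five]}[{BASES[ref]}>{BASES[alt]}]{BASES[three]}"


CHANNEL_NAMES = tuple(channel_name(i) for i in range(N_CHANNELS))
CHANNEL_INDEX = {name: i for i, name in enumerate(CHANNEL_NAMES)}


def channel_class(idx: int) -> str:
    return SUB_CLASSES[idx // 16]


def context_class_of(five: int, center: int, three: int) -> int:
    """Context class (0..31) of a trinucleotide, normalizing purine centers.

    Codes are A=0,C=1,G=2,T=3. Purine-centered trinucleotides are reverse
    complemented so the center is always C or T.
    """
    if center in (0, 2):  # A or G -> flip strand
        five, center, three = COMP_CODE[three], COMP_CODE[center], COMP_CODE[five]
    pyr = 0 if center == 1 else 1  # C -> 0, T -> 1
    return pyr * 16 + five * 4 + three


def channel_of(five: int, ref: int, three: int, alt: int) -> int:
    """96-channel index of a substitution given its raw genomic context."""
    if ref in (0, 2):
        five, ref, three = COMP_CODE[three], COMP_CODE[ref], COMP_CODE[five]
        alt = int(COMP_CODE[alt])
    if ref == 1:  # C>A, C>G, C>T
        cls = {0: 0, 2: 1, 3: 2}[alt]
    else:  # T>A, T>C, T>G
        cls = {0: 3, 1: 4, 2: 5}[alt]
    return cls * 16 + five * 4 + three


def channel_to_context_alt(idx: int) -> tuple[int, int]:
    """Map a channel to (context class, pyrimidine-frame alt code)."""
    cls, ctx = divmod(idx, 16)
    ref, alt = _CLASS_REF_ALT[cls]
    pyr = 0 if ref == 1 else 1
    return pyr * 16 + ctx, alt


# context class + pyrimidine-frame alt -> channel, as a lookup table
_CTX_ALT_TO_CHANNEL = np.full((N_CONTEXTS, 4), -1, dtype=np.int64)
for _i in range(N_CHANNELS):
    _ctx, _alt = channel_to_context_alt(_i)
    _CTX_ALT_TO_CHANNEL[_ctx, _alt] = _i


def context_alt_to_channel(ctx: int, alt: int) -> int:
    ch = int(_CTX_ALT_TO_CHANNEL[ctx, alt])
    if ch < 0:
        raise ValueError(f"context {ctx} has no channel for alt code {alt}")
    return ch


def encode(seq: str) -> np.ndarray:
    """DNA string -> uint8 codes (A=0,C=1,G=2,T=3)."""
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    out = np.full(arr.shape, 255, dtype=np.uint8)
    for base, code in BASE_CODE.items():
        out[arr == ord(base)] = code
    if (out == 255).any():
        bad = chr(int(arr[out == 255][0]))
        raise ValueError(f"non-ACGT base {bad!r} in sequence")
    return out


def decode(codes: np.ndarray) -> str:
    lut = np.frombuffer(b"ACGT", dtype=np.uint8)
    return lut[codes].tobytes().decode("ascii")


def context_classes(codes: np.ndarray) -> np.ndarray:
    """Vectorized context class for interior positions of a coded sequence.

    Returns an int16 array of length ``len(codes)`` with the context class
    of positions 1..n-2 and -1 at the two terminal positions (which have no
    complete trinucleotide context within the sequence).
    """
    n = len(codes)
    out = np.full(n, -1, dtype=np.int16)
    if n < 3:
        return out
    five = codes[:-2].astype(np.int16)
    center = codes[1:-1].astype(np.int16)
    three = codes[2:].astype(np.int16)
    purine = (center == 0) | (center == 2)
    # strand-flip purine-centered sites
    f = np.where(purine, COMP_CODE[three], five)
    c = np.where(purine, COMP_CODE[center], center)
    t = np.where(purine, COMP_CODE[five], three)
    pyr = np.where(c == 1, 0, 16)
    out[1:-1] = pyr + f * 4 + t
    return out


def pyrimidine_context_str(five: str, ref: str, three: str) -> str:
    """Pyrimidine-normalized trinucleotide context as a 3-letter string."""
    if ref in "AG":
        five, ref, three = COMP[three], COMP[ref], COMP[five]
    return five + ref + three
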