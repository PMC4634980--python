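"""Small shared helpers: rounding, seeding, sequence utilities."""

from __future__ import annotations

import math
import zlib

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string."""
    return seq.translate(_COMPLEMENT)[::-1]


def round_half_away(x: float) -> int:
    """Round to nearest integer, ties away from zero (47/288*100 -> 16, 54/288*100 -> 19)."""
    return int(math.copysign(math.floor(abs(x) + 0.5), x))


def derive_seed(seed: int, stage: str) -> int:
    """Fan a global seed out to a per-stage seed via a fixed name hash.

    Deterministic across processes (unlike ``hash``) and always < 2**31.
    """
    return (int(seed) ^ zlib.crc32(stage.encode("utf-8"))) % (2**31)


def homopolymer_runs(seq: str, min_len: int = 1):
    """Yield (start, end, base) for maximal runs of identical bases.

    Coordinates are 1-based inclusive.
    """
    i = 0
    n = len(seq)
    while i < n:
        j = i
        while j + 1 < n and seq[j + 1] == seq[i]:
            j += 1
        if j - i + 1 >= min_len:
            yield (i + 1, j + 1, seq[i])
        i = j + 1
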