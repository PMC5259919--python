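"""Independent brute-force oracles used to cross-check the implementation.

These deliberately use the slowest, most literal formulation of each
rule (per-basepair set membership, exact rational arithmetic, run-length
scanning) and share no code with the package internals they verify.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb

import numpy as np


def per_bp_membership(
    intervals: list[tuple[int, int]], chrom_len: int
) -> np.ndarray:
    """Boolean per-basepair membership array for a set of (start, end) tuples."""
    mask = np.zeros(chrom_len, dtype=bool)
    for s, e in intervals:
        mask[max(0, s): max(0, e)] = True
    return mask


def bins_overlapping_mask(mask: np.ndarray, bin_size: int) -> set[int]:
    """Bin indices overlapping >= 1 marked bp (bins tile [0, len(mask)))."""
    hit = set()
    for pos in np.flatnonzero(mask):
        hit.add(int(pos) // bin_size)
    return hit


def runlength_dmrs(
    significant: list[bool], direction: list[str], chrom: list[str], max_gap: int
) -> list[tuple[int, ...]]:
    """Literal left-to-right scan producing tuples of member bin indices.

    A run extends while bins share chromosome and direction and no more
    than ``max_gap`` consecutive non-significant bins intervene.
    """
    runs: list[tuple[int, ...]] = []
    cur: list[int] = []
    gap = 0
    for i, sig in enumerate(significant):
        if not sig:
            gap += 1
            if gap > max_gap and cur:
                runs.append(tuple(cur))
                cur = []
            continue
        if cur and (
            chrom[i] != chrom[cur[-1]]
            or direction[i] != direction[cur[0]]
            or gap > max_gap
        ):
            runs.append(tuple(cur))
            cur = []
        cur.append(i)
        gap = 0
    if cur:
        runs.append(tuple(cur))
    return runs


def binom_tail_exact(coverage: int, mismatches: int, seq_error: Fraction) -> Fraction:
    """Exact-rational P[X >= mismatches | coverage, seq_error]."""
    return sum(
        Fraction(comb(coverage, k)) * seq_error**k * (1 - seq_error) ** (coverage - k)
        for k in range(mismatches, coverage + 1)
    )


def subtype_specific_rule(
    fractions: dict[str, float], min_in: float = 0.30, max_out: float = 0.10
) -> str | None:
    """Literal application of the >=min_in / <max_out carrier rule."""
    for st, f in fractions.items():
        others = [o for o in fractions if o != st]
        if f >= min_in and all(fractions[o] < max_out for o in others):
            return st
    return None
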