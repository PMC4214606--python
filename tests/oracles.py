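"""Independent oracles used by the tests.

These deliberately re-derive results by the most transparent method
available (memoized recursion, sort-and-scan, exhaustive enumeration) and
stay independent of the implementation paths they check.
"""

from __future__ import annotations

from functools import lru_cache

from Bio.Align import substitution_matrices

_BLOSUM62 = substitution_matrices.load("BLOSUM62")


def nw_affine_score(a: str, b: str, open_: float = 10.0, extend: float = 0.5) -> float:
    """Brute-force global alignment score with affine gaps and free end gaps.

    Gap of length L costs open_ + (L-1)*extend, except leading/trailing gap
    runs which are free.  Memoized recursion over (i, j, state) where state
    records whether the previous column was a gap in a, a gap in b, or a
    substitution; terminal gap freedom is handled by allowing either
    sequence's unconsumed tail to be dropped at zero cost.
    """

    @lru_cache(maxsize=None)
    def rec(i: int, j: int, state: str) -> float:
        if i == len(a) or j == len(b):
            return 0.0  # remaining tail is a free end gap
        options = [
            rec(i + 1, j + 1, "M") + float(_BLOSUM62[a[i], b[j]]),
            rec(i + 1, j, "X") - (extend if state == "X" else open_),
            rec(i, j + 1, "Y") - (extend if state == "Y" else open_),
        ]
        return max(options)

    # a free leading gap is a choice of starting offset in either sequence
    best = max(
        max(rec(i, 0, "S") for i in range(len(a) + 1)),
        max(rec(0, j, "S") for j in range(len(b) + 1)),
    )
    rec.cache_clear()
    return best


def n50_oracle(lengths: list[int]) -> int:
    """Sort-and-scan N50: walk lengths descending until half the total."""
    total = sum(lengths)
    acc = 0
    for length in sorted(lengths, reverse=True):
        acc += length
        if acc * 2 >= total:
            return length
    return 0


def maximal_runs(votes: list[str]) -> list[list[int]]:
    """Brute-force maximal runs of equal values; returns index groups."""
    runs: list[list[int]] = []
    for i, v in enumerate(votes):
        if runs and votes[runs[-1][-1]] == v:
            runs[-1].append(i)
        else:
            runs.append([i])
    return runs
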