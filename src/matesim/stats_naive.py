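"""Deliberately naive, string-based reference implementations of the summary
statistics.

These walk plain Python strings character by character and are used as an
independent oracle for the optimised packed-array implementations in
:mod:`matesim.stats`.  They are kept free of numpy vector tricks on purpose:
their value is that they cannot share a bug with the fast path.
"""

from __future__ import annotations

from typing import List, Sequence


def _check(seqs: Sequence[str]) -> None:
    if len(seqs) < 2:
        raise ValueError("need at least two sequences")
    if len({len(s) for s in seqs}) != 1:
        raise ValueError("sequences must share one length")


def seg_sites(seqs: Sequence[str]) -> int:
    _check(seqs)
    s = 0
    for site in range(len(seqs[0])):
        if len({seq[site] for seq in seqs}) > 1:
            s += 1
    return s


def harmonic_number(n_minus_1: int) -> float:
    return sum(1.0 / i for i in range(1, n_minus_1 + 1))


def watterson(seqs: Sequence[str]) -> float:
    return seg_sites(seqs) / harmonic_number(len(seqs) - 1)


def hamming(a: str, b: str) -> int:
    return sum(1 for x, y in zip(a, b) if x != y)


def pairwise_pi(seqs: Sequence[str]) -> float:
    _check(seqs)
    n = len(seqs)
    total = 0
    for i in range(n):
        for j in range(i + 1, n):
            total += hamming(seqs[i], seqs[j])
    return total / (n * (n - 1) / 2)


def haplotypes(seqs: Sequence[str]) -> int:
    _check(seqs)
    return len(set(seqs))


def allelic_het(seqs: Sequence[str]) -> float:
    _check(seqs)
    n = len(seqs)
    freqs: List[float] = [seqs.count(u) / n for u in set(seqs)]
    return n / (n - 1) * (1.0 - sum(p * p for p in freqs))


def nei_het(seqs: Sequence[str]) -> float:
    _check(seqs)
    n = len(seqs)
    length = len(seqs[0])
    total = 0.0
    for site in range(length):
        column = [seq[site] for seq in seqs]
        total += 1.0 - sum((column.count(b) / n) ** 2 for b in set(column))
    return total / length
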