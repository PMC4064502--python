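"""Summary statistics on a panel of sequences from one locus.

The battery comprises the number of segregating sites S, Watterson's
estimator θ_w = S / a_n (a_n = Σ_{i=1}^{n-1} 1/i), the mean pairwise
difference θ_π (nucleotide diversity in per-locus units), the number of
distinct haplotypes h, the unbiased gene (allelic) diversity over haplotypes
H_A = n/(n-1) · (1 − Σ p_k²), and Nei's mean per-site heterozygosity
H_N = (1/L) Σ_sites (1 − Σ q²).  Per-locus values are primary; per-site
variants (divide by L) are exposed alongside because axes in the literature
are often reported either way.

θ_π is computed through per-site allele counts — an exact identity with the
average over all n(n−1)/2 pairwise Hamming distances, at O(nL) instead of
O(n²L).  A deliberately naive string-based implementation of all six
statistics lives in :mod:`matesim.stats_naive` as an independent oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Union

import numpy as np

from .genetics import LocusClass, Sex
from .sequence import PackedSequence, unpack_codes

__all__ = [
    "ALL",
    "EmptyPanelError",
    "SequencePanel",
    "StatisticsError",
    "SummaryStats",
    "allelic_het",
    "collect_panel",
    "harmonic_number",
    "haplotypes",
    "nei_het",
    "pairwise_pi",
    "seg_sites",
    "summarize",
    "watterson",
]

#: sentinel: take the whole deme rather than a subsample
ALL = None


class StatisticsError(ValueError):
    """Raised when a statistic is requested on an invalid panel (n < 2)."""


class EmptyPanelError(ValueError):
    """Raised when sampling yields no carriers (e.g. a Y panel with no males)."""


@dataclass
class SequencePanel:
    """``n`` equal-length sequences from one locus, with carrier metadata."""

    locus_class: LocusClass
    locus_index: int
    length: int
    words: np.ndarray                      # (n, W) uint64
    individual_ids: np.ndarray             # (n,) int64
    sexes: np.ndarray                      # (n,) '<U6'
    copy_slots: np.ndarray                 # (n,) int64
    replicate: int = 0
    generation: int = 0

    @property
    def n(self) -> int:
        return int(self.words.shape[0])

    @classmethod
    def from_sequences(
        cls,
        sequences: Sequence[PackedSequence],
        locus_class: LocusClass = LocusClass.MT,
        locus_index: int = 0,
    ) -> "SequencePanel":
        lengths = {s.length for s in sequences}
        if len(lengths) != 1:
            raise ValueError("all panel sequences must share one length")
        (length,) = lengths
        words = np.stack([s.words for s in sequences])
        n = len(sequences)
        return cls(
            locus_class=locus_class,
            locus_index=locus_index,
            length=length,
            words=words,
            individual_ids=np.arange(n, dtype=np.int64),
            sexes=np.array(["?"] * n),
            copy_slots=np.zeros(n, dtype=np.int64),
        )

    def sequences(self) -> List[PackedSequence]:
        return [PackedSequence(self.length, w.copy()) for w in self.words]


def collect_panel(
    pop,
    locus_class: LocusClass,
    locus_index: int = 0,
    sample_size: Optional[int] = ALL,
    rng: Optional[np.random.Generator] = None,
) -> SequencePanel:
    """Collect the sequences carried at one locus, for the whole deme or for a
    random sample of individuals (without replacement).

    Sampling is by individual, then every copy the sampled carrier holds is
    taken: both autosomal copies, 2 X per female / 1 per male, 1 Y per male,
    1 mtDNA each.  A diploid sample of s individuals therefore yields n = 2s
    autosomal sequences.
    """
    if locus_class not in pop.pool:
        raise ValueError(f"no {locus_class} loci configured")
    n_ind = pop.size
    if sample_size is ALL or sample_size >= n_ind:
        chosen = np.arange(n_ind)
    else:
        if sample_size < 1:
            raise ValueError("sample_size must be >= 1")
        if rng is None:
            raise ValueError("sampling a subset requires an rng")
        chosen = np.sort(rng.choice(n_ind, size=sample_size, replace=False))

    arr = pop.pool[locus_class][:, :, locus_index, :]  # (N, slots, W)
    rows, ids, sexes, slots = [], [], [], []
    for i in chosen:
        female = bool(pop.is_female[i])
        if locus_class is LocusClass.AUTOSOMAL:
            take = (0, 1)
        elif locus_class is LocusClass.X:
            take = (0, 1) if female else (0,)
        elif locus_class is LocusClass.Y:
            take = () if female else (0,)
        else:
            take = (0,)
        for slot in take:
            rows.append(arr[i, slot])
            ids.append(int(pop.ids[i]))
            sexes.append("F" if female else "M")
            slots.append(slot)
    if not rows:
        raise EmptyPanelError(f"no carriers of {locus_class} among the sampled individuals")
    spec = next(s for s in pop.specs if s.locus_class is locus_class)
    return SequencePanel(
        locus_class=locus_class,
        locus_index=locus_index,
        length=spec.length,
        words=np.stack(rows),
        individual_ids=np.asarray(ids, dtype=np.int64),
        sexes=np.asarray(sexes),
        copy_slots=np.asarray(slots, dtype=np.int64),
        generation=pop.generation,
    )


@dataclass(frozen=True)
class SummaryStats:
    """Per-locus summary record; see the module docstring for definitions."""

    n: int
    L: int
    S: int
    theta_w: float
    pi: float
    h: int
    H_A: float
    H_N: float

    @property
    def theta_w_per_site(self) -> float:
        return self.theta_w / self.L

    @property
    def pi_per_site(self) -> float:
        return self.pi / self.L


def harmonic_number(n_minus_1: int) -> float:
    """a_n = Σ_{i=1}^{n-1} 1/i."""
    return float(np.sum(1.0 / np.arange(1, n_minus_1 + 1))) if n_minus_1 >= 1 else 0.0


def _site_counts(panel: SequencePanel) -> np.ndarray:
    codes = unpack_codes(panel.words, panel.length)  # (n, L)
    counts = np.empty((4, panel.length), dtype=np.int64)
    for a in range(4):
        counts[a] = (codes == a).sum(axis=0)
    return counts


def _require_pairable(panel: SequencePanel) -> None:
    if panel.n < 2:
        raise StatisticsError(f"statistics require n >= 2 sequences, got {panel.n}")


def seg_sites(panel: SequencePanel) -> int:
    """Number of sites carrying more than one allele."""
    _require_pairable(panel)
    counts = _site_counts(panel)
    return int((np.count_nonzero(counts, axis=0) > 1).sum())


def watterson(panel: SequencePanel) -> float:
    """Watterson's θ_w = S / a_n (per-locus units)."""
    _require_pairable(panel)
    return seg_sites(panel) / harmonic_number(panel.n - 1)


def pairwise_pi(panel: SequencePanel) -> float:
    """Mean pairwise Hamming distance θ_π over all n(n−1)/2 pairs."""
    _require_pairable(panel)
    n = panel.n
    counts = _site_counts(panel)
    mismatch_pairs = (n * n - (counts.astype(np.float64) ** 2).sum(axis=0)) / 2.0
    return float(mismatch_pairs.sum() / (n * (n - 1) / 2.0))


def _haplotype_counts(panel: SequencePanel) -> np.ndarray:
    _, counts = np.unique(panel.words, axis=0, return_counts=True)
    return counts


def haplotypes(panel: SequencePanel) -> int:
    """Number of distinct sequences (exact identity)."""
    _require_pairable(panel)
    return int(len(_haplotype_counts(panel)))


def allelic_het(panel: SequencePanel) -> float:
    """Unbiased gene diversity over haplotypes: n/(n−1) · (1 − Σ p²)."""
    _require_pairable(panel)
    n = panel.n
    p = _haplotype_counts(panel) / n
    return float(n / (n - 1) * (1.0 - np.sum(p**2)))


def nei_het(panel: SequencePanel) -> float:
    """Nei's mean per-site heterozygosity: mean over sites of 1 − Σ q²."""
    _require_pairable(panel)
    q = _site_counts(panel) / panel.n
    return float(np.mean(1.0 - np.sum(q**2, axis=0)))


def summarize(panel: SequencePanel) -> SummaryStats:
    """All six statistics in one pass over the panel."""
    _require_pairable(panel)
    n, length = panel.n, panel.length
    counts = _site_counts(panel)
    s = int((np.count_nonzero(counts, axis=0) > 1).sum())
    mismatch_pairs = (n * n - (counts.astype(np.float64) ** 2).sum(axis=0)) / 2.0
    pi = float(mismatch_pairs.sum() / (n * (n - 1) / 2.0))
    hap = _haplotype_counts(panel)
    p = hap / n
    q = counts / n
    return SummaryStats(
        n=n,
        L=length,
        S=s,
        theta_w=s / harmonic_number(n - 1),
        pi=pi,
        h=int(len(hap)),
        H_A=float(n / (n - 1) * (1.0 - np.sum(p**2))),
        H_N=float(np.mean(1.0 - np.sum(q**2, axis=0))),
    )
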