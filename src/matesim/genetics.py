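"""Genomes across the four locus classes and parent-to-offspring transmission.

An individual carries unlinked loci in four classes with sex-dependent copy
numbers:

* ``AUTOSOMAL`` — two copies per locus (slot 0 maternal, slot 1 paternal);
* ``X`` — two copies in females, one (maternal) in males;
* ``Y`` — one copy in males, none in females;
* ``MT`` — one maternally-inherited copy in everyone.

Storage is array-per-class: shape ``(n_individuals, slots, count, n_words)``
uint64, where ``slots`` is 2 for AUTOSOMAL/X and 1 for Y/MT.  Slots that a
carrier's sex does not use (a male's second X slot, a female's Y slot) are
kept all-zero and are never read.  :func:`transmit_batch` produces a whole
offspring cohort in one vectorized pass; :func:`transmit` is the
one-child wrapper over the same kernels.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence

import numpy as np

from .sequence import MutationModel, PackedSequence, encode, mutate_words, n_words

__all__ = [
    "Sex",
    "LocusClass",
    "LocusSpec",
    "Genome",
    "GenomePool",
    "founder_genome",
    "transmit",
    "transmit_batch",
    "slots_for",
    "carried_slots",
]


class Sex(enum.Enum):
    FEMALE = "female"
    MALE = "male"


class LocusClass(enum.Enum):
    AUTOSOMAL = "autosomal"
    X = "x"
    Y = "y"
    MT = "mt"


#: storage slots per locus for each class
_SLOTS = {
    LocusClass.AUTOSOMAL: 2,
    LocusClass.X: 2,
    LocusClass.Y: 1,
    LocusClass.MT: 1,
}


def slots_for(locus_class: LocusClass) -> int:
    return _SLOTS[locus_class]


def carried_slots(locus_class: LocusClass, sex: Sex) -> List[int]:
    """Slot indices actually carried by an individual of the given sex."""
    if locus_class is LocusClass.AUTOSOMAL:
        return [0, 1]
    if locus_class is LocusClass.X:
        return [0, 1] if sex is Sex.FEMALE else [0]
    if locus_class is LocusClass.Y:
        return [0] if sex is Sex.MALE else []
    return [0]  # MT


@dataclass(frozen=True)
class LocusSpec:
    """``count`` unlinked loci of one class, each ``length`` sites, mutating
    under ``model``."""

    locus_class: LocusClass
    count: int
    length: int
    model: MutationModel

    def __post_init__(self) -> None:
        if self.count < 0:
            raise ValueError("locus count must be >= 0")
        if self.length < 1:
            raise ValueError("locus length must be >= 1")

    @property
    def words(self) -> int:
        return n_words(self.length)

    @property
    def slots(self) -> int:
        return slots_for(self.locus_class)


#: per-class genotype arrays for a cohort: class -> (N, slots, count, W) uint64
GenomePool = Dict[LocusClass, np.ndarray]


def _spec_map(specs: Sequence[LocusSpec]) -> Dict[LocusClass, LocusSpec]:
    out: Dict[LocusClass, LocusSpec] = {}
    for spec in specs:
        if spec.locus_class in out:
            raise ValueError(f"duplicate LocusSpec for class {spec.locus_class}")
        out[spec.locus_class] = spec
    return out


def empty_pool(n: int, specs: Sequence[LocusSpec]) -> GenomePool:
    return {
        s.locus_class: np.zeros((n, s.slots, s.count, s.words), dtype=np.uint64)
        for s in specs
        if s.count > 0
    }


@dataclass
class Genome:
    """One individual's genotypes: per class an ``(slots, count, W)`` array."""

    sex: Sex
    data: GenomePool

    def copies(self, locus_class: LocusClass, locus_index: int = 0) -> List[PackedSequence]:
        """The sequences actually carried at one locus (respecting sex)."""
        arr = self.data[locus_class]
        length = self._lengths[locus_class]
        return [
            PackedSequence(length, arr[slot, locus_index].copy())
            for slot in carried_slots(locus_class, self.sex)
        ]

    # locus lengths are needed to wrap raw words back into sequences
    _lengths: Dict[LocusClass, int] = None  # type: ignore[assignment]

    @classmethod
    def from_arrays(cls, sex: Sex, data: GenomePool, specs: Sequence[LocusSpec]) -> "Genome":
        g = cls(sex=sex, data=data)
        g._lengths = {s.locus_class: s.length for s in specs}
        return g


def founder_genome(
    sex: Sex,
    specs: Sequence[LocusSpec],
    template: Optional[Mapping[LocusClass, str]] = None,
) -> Genome:
    """A founder genome with every carried copy equal to the class template.

    The default template is the all-'A' sequence of the configured length
    (whose packed representation is all-zero words), so a default founder
    population is perfectly monomorphic: S = 0 and h = 1 at every locus.
    """
    by_class = _spec_map(specs)
    data: GenomePool = {}
    for spec in by_class.values():
        if spec.count == 0:
            continue
        arr = np.zeros((spec.slots, spec.count, spec.words), dtype=np.uint64)
        if template is not None and spec.locus_class in template:
            seq = encode(template[spec.locus_class])
            if seq.length != spec.length:
                raise ValueError(
                    f"template for {spec.locus_class} has length {seq.length}, "
                    f"expected {spec.length}"
                )
            for slot in carried_slots(spec.locus_class, sex):
                arr[slot, :, :] = seq.words
        data[spec.locus_class] = arr
    return Genome.from_arrays(sex, data, specs)


def _mutate_subset(arr: np.ndarray, rows: np.ndarray, length: int,
                   model: MutationModel, rng: np.random.Generator) -> None:
    """Mutate ``arr[rows]`` where arr is (M, count, W); copies in and out."""
    if rows.size == 0 or arr.shape[1] == 0:
        return
    sub = np.ascontiguousarray(arr[rows])
    m, c, w = sub.shape
    mutate_words(sub.reshape(m * c, w), length, model, rng)
    arr[rows] = sub


def transmit_batch(
    parents: GenomePool,
    mother_idx: np.ndarray,
    father_idx: np.ndarray,
    child_is_female: np.ndarray,
    specs: Sequence[LocusSpec],
    rng: np.random.Generator,
) -> GenomePool:
    """Generate genotype arrays for a cohort of offspring.

    ``mother_idx``/``father_idx`` index rows of the parent arrays (mothers must
    be female carriers, fathers male).  Per offspring and autosomal locus one
    maternal and one paternal copy are chosen independently and uniformly; a
    maternal X is chosen uniformly from the mother's two, a daughter
    additionally receives the father's X, a son the father's Y, and everyone
    the mother's mtDNA.  Every transmitted copy then undergoes one round of
    K2P mutation under its class model.
    """
    mother_idx = np.asarray(mother_idx, dtype=np.int64)
    father_idx = np.asarray(father_idx, dtype=np.int64)
    child_is_female = np.asarray(child_is_female, dtype=bool)
    m = mother_idx.size
    if father_idx.size != m or child_is_female.size != m:
        raise ValueError("mother_idx, father_idx and child_is_female must align")

    daughters = np.flatnonzero(child_is_female)
    sons = np.flatnonzero(~child_is_female)
    all_rows = np.arange(m)
    children: GenomePool = {}

    for spec in specs:
        if spec.count == 0:
            continue
        cls, c, w, length, model = (
            spec.locus_class, spec.count, spec.words, spec.length, spec.model,
        )
        arr = parents[cls]
        child = np.zeros((m, spec.slots, c, w), dtype=np.uint64)
        cols = np.arange(c)

        if cls is LocusClass.AUTOSOMAL:
            mat_choice = rng.integers(0, 2, size=(m, c))
            pat_choice = rng.integers(0, 2, size=(m, c))
            child[:, 0] = arr[mother_idx[:, None], mat_choice, cols]
            child[:, 1] = arr[father_idx[:, None], pat_choice, cols]
            mutate_words(child.reshape(m * 2 * c, w), length, model, rng)
        elif cls is LocusClass.X:
            mat_choice = rng.integers(0, 2, size=(m, c))
            child[:, 0] = arr[mother_idx[:, None], mat_choice, cols]
            _mutate_subset(child[:, 0], all_rows, length, model, rng)
            if daughters.size:
                child[daughters, 1] = arr[father_idx[daughters], 0]
                _mutate_subset(child[:, 1], daughters, length, model, rng)
        elif cls is LocusClass.Y:
            if sons.size:
                child[sons, 0] = arr[father_idx[sons], 0]
                _mutate_subset(child[:, 0], sons, length, model, rng)
        else:  # MT
            child[:, 0] = arr[mother_idx, 0]
            _mutate_subset(child[:, 0], all_rows, length, model, rng)

        children[cls] = child
    return children


def transmit(
    mother: Genome,
    father: Genome,
    child_sex: Sex,
    specs: Sequence[LocusSpec],
    rng: np.random.Generator,
) -> Genome:
    """Produce one offspring genome from a mother and a father."""
    if mother.sex is not Sex.FEMALE:
        raise ValueError("mother must be female")
    if father.sex is not Sex.MALE:
        raise ValueError("father must be male")
    pool: GenomePool = {}
    for spec in specs:
        if spec.count == 0:
            continue
        cls = spec.locus_class
        if mother.data[cls].shape != father.data[cls].shape:
            raise ValueError(f"parent genomes disagree on {cls} layout")
        pool[cls] = np.stack([mother.data[cls], father.data[cls]])
    child_pool = transmit_batch(
        pool,
        mother_idx=np.array([0]),
        father_idx=np.array([1]),
        child_is_female=np.array([child_sex is Sex.FEMALE]),
        specs=specs,
        rng=rng,
    )
    data = {cls: arr[0] for cls, arr in child_pool.items()}
    return Genome.from_arrays(child_sex, data, specs)
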