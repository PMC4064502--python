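"""Individuals, the population container, demography schedules and the
one-generation update cycle.

Generations are discrete and non-overlapping: each step forms unions among the
current adults under the configured marriage rule, draws parents for the next
census (whose size is dictated by the demography schedule), transmits and
mutates genomes, and replaces the membership wholesale.  Offspring sex is
i.i.d. fair Bernoulli, with the whole sex vector redrawn in the rare event one
sex is absent — a conditioning applied identically under every mating system
so that cross-system comparisons stay fair.

The population's genotypes live in per-class packed arrays (see
:mod:`matesim.genetics`); :class:`Individual` objects are lightweight views
materialised on demand.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import List, Optional, Sequence

import numpy as np

from .genetics import (
    Genome,
    GenomePool,
    LocusSpec,
    Sex,
    empty_pool,
    founder_genome,
    transmit_batch,
)
from .mating import (
    MatingConfig,
    NoValidPairError,
    draw_parents_batch,
    form_unions,
)

__all__ = [
    "DemographyPhase",
    "Individual",
    "Population",
    "ScheduleExhaustedError",
    "SimulationError",
    "constant",
    "growth",
    "found_population",
    "size_at",
    "step_generation",
    "total_duration",
]


class ScheduleExhaustedError(RuntimeError):
    """The requested generation lies beyond the demography schedule."""


class SimulationError(RuntimeError):
    """A generation step could not be completed."""


@dataclass(frozen=True)
class DemographyPhase:
    """One piece of a piecewise demography: ``constant`` holds ``size_param``
    individuals for ``duration`` generations; ``linear_growth`` adds
    ``size_param`` individuals per generation (possibly negative) starting from
    the previous phase's final size."""

    kind: str  # "constant" | "linear_growth"
    duration: int
    size_param: int

    def __post_init__(self) -> None:
        if self.kind not in ("constant", "linear_growth"):
            raise ValueError(f"unknown phase kind {self.kind!r}")
        if self.duration < 1:
            raise ValueError("phase duration must be >= 1")


def constant(size: int, duration: int) -> DemographyPhase:
    return DemographyPhase("constant", duration, size)


def growth(per_generation: int, duration: int) -> DemographyPhase:
    return DemographyPhase("linear_growth", duration, per_generation)


def total_duration(schedule: Sequence[DemographyPhase]) -> int:
    return sum(p.duration for p in schedule)


def size_at(schedule: Sequence[DemographyPhase], t: int) -> int:
    """Census size dictated by the schedule at generation ``t`` (0-based)."""
    if not schedule:
        raise ValueError("empty demography schedule")
    if schedule[0].kind != "constant":
        raise ValueError("the first demography phase must be constant")
    if t < 0:
        raise ValueError("generation index must be >= 0")
    start = 0
    size = schedule[0].size_param
    for phase in schedule:
        end = start + phase.duration  # exclusive
        if phase.kind == "constant":
            phase_final = phase.size_param
            if phase_final < 2:
                raise ValueError("constant phase size must be >= 2")
            if t < end:
                return phase.size_param
        else:
            phase_final = size + phase.size_param * phase.duration
            if t < end:
                value = size + phase.size_param * (t - start + 1)
                if value < 2:
                    raise ValueError(f"schedule yields size {value} < 2 at t={t}")
                return value
        if min(size, phase_final) < 2:
            raise ValueError("schedule yields a population size below 2")
        size = phase_final
        start = end
    raise ScheduleExhaustedError(
        f"generation {t} is beyond the schedule ({total_duration(schedule)} generations)"
    )


@dataclass(frozen=True)
class Individual:
    id: int
    sex: Sex
    genome: Genome
    mother_id: Optional[int]
    father_id: Optional[int]


@dataclass
class Population:
    """A single deme at one generation, with its full simulation context."""

    generation: int
    ids: np.ndarray            # (N,) int64, unique within replicate
    is_female: np.ndarray      # (N,) bool
    mother_ids: np.ndarray     # (N,) int64, -1 for founders
    father_ids: np.ndarray     # (N,) int64, -1 for founders
    pool: GenomePool
    specs: List[LocusSpec]
    schedule: List[DemographyPhase]
    mating_config: MatingConfig
    rng: np.random.Generator
    next_id: int = 0
    buffer_pi_trajectory: Optional[List[float]] = field(default=None, repr=False)

    @property
    def size(self) -> int:
        return int(self.ids.size)

    @property
    def n_females(self) -> int:
        return int(self.is_female.sum())

    @property
    def n_males(self) -> int:
        return self.size - self.n_females

    def individual(self, i: int) -> Individual:
        data = {cls: arr[i].copy() for cls, arr in self.pool.items()}
        sex = Sex.FEMALE if self.is_female[i] else Sex.MALE
        mid, fid = int(self.mother_ids[i]), int(self.father_ids[i])
        return Individual(
            id=int(self.ids[i]),
            sex=sex,
            genome=Genome.from_arrays(sex, data, self.specs),
            mother_id=None if mid < 0 else mid,
            father_id=None if fid < 0 else fid,
        )

    @property
    def members(self) -> List[Individual]:
        return [self.individual(i) for i in range(self.size)]

    def validate(self) -> None:
        """Structural invariants: census vs schedule, sex-consistent slots."""
        if self.size != size_at(self.schedule, self.generation):
            raise AssertionError("census size does not match the schedule")
        males = ~self.is_female
        from .genetics import LocusClass

        if LocusClass.X in self.pool and males.any():
            if self.pool[LocusClass.X][males, 1].any():
                raise AssertionError("male carries a second X copy")
        if LocusClass.Y in self.pool and self.is_female.any():
            if self.pool[LocusClass.Y][self.is_female].any():
                raise AssertionError("female carries a Y copy")


def found_population(
    n: int,
    specs: Sequence[LocusSpec],
    schedule: Optional[Sequence[DemographyPhase]] = None,
    mating_config: Optional[MatingConfig] = None,
    sex_ratio: float = 0.5,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
    template=None,
) -> Population:
    """Create a founder population of ``n`` individuals at generation 0.

    ``floor(n * sex_ratio)`` founders are female.  All founders share the class
    template sequence (default all-'A'), so initial diversity is zero; use the
    buffering phase to inject standing variation.
    """
    if n < 2:
        raise ValueError("population size must be >= 2")
    if not 0.0 < sex_ratio < 1.0:
        raise ValueError("sex_ratio must be strictly between 0 and 1")
    n_f = math.floor(n * sex_ratio)
    if n_f == 0 or n_f == n:
        raise ValueError(f"sex_ratio {sex_ratio} leaves a single-sex population")
    if schedule is None:
        schedule = [constant(n, 2**31 - 1)]
    else:
        schedule = list(schedule)
        if size_at(schedule, 0) != n:
            raise ValueError("schedule size at generation 0 must equal n")
    if mating_config is None:
        mating_config = MatingConfig()
    if rng is None:
        rng = np.random.default_rng(seed)

    specs = list(specs)
    pool = empty_pool(n, specs)
    is_female = np.zeros(n, dtype=bool)
    is_female[:n_f] = True
    if template is not None:
        female = founder_genome(Sex.FEMALE, specs, template)
        male = founder_genome(Sex.MALE, specs, template)
        for cls in pool:
            pool[cls][is_female] = female.data[cls]
            pool[cls][~is_female] = male.data[cls]
    return Population(
        generation=0,
        ids=np.arange(n, dtype=np.int64),
        is_female=is_female,
        mother_ids=np.full(n, -1, dtype=np.int64),
        father_ids=np.full(n, -1, dtype=np.int64),
        pool=pool,
        specs=specs,
        schedule=list(schedule),
        mating_config=mating_config,
        rng=rng,
        next_id=n,
    )


def step_generation(pop: Population) -> Population:
    """Advance the population by one non-overlapping generation, in place."""
    t_next = pop.generation + 1
    n_next = size_at(pop.schedule, t_next)

    fem = np.flatnonzero(pop.is_female)
    mal = np.flatnonzero(~pop.is_female)
    if fem.size == 0 or mal.size == 0:
        raise SimulationError(f"generation {pop.generation}: a sex is absent")

    rng = pop.rng
    unions = form_unions(fem, mal, pop.mating_config, rng)

    while True:
        child_is_female = rng.random(n_next) < 0.5
        if child_is_female.any() and not child_is_female.all():
            break

    try:
        mo_pos, fa_pos = draw_parents_batch(
            unions,
            n_next,
            pop.mating_config,
            rng,
            female_mother_ids=pop.mother_ids[fem],
            female_father_ids=pop.father_ids[fem],
            male_mother_ids=pop.mother_ids[mal],
            male_father_ids=pop.father_ids[mal],
        )
    except NoValidPairError as err:
        raise SimulationError(f"generation {t_next}: {err}") from err

    mother_idx = fem[mo_pos]
    father_idx = mal[fa_pos]
    pop.pool = transmit_batch(
        pop.pool, mother_idx, father_idx, child_is_female, pop.specs, rng
    )
    pop.mother_ids = pop.ids[mother_idx]
    pop.father_ids = pop.ids[father_idx]
    pop.ids = np.arange(pop.next_id, pop.next_id + n_next, dtype=np.int64)
    pop.next_id += n_next
    pop.is_female = child_is_female
    pop.generation = t_next
    return pop
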