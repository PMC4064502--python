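"""Union formation and per-offspring parent selection under each marriage rule.

Four systems are supported:

* ``MONOGAMY`` — a uniform random perfect matching of min(N_f, N_m) exclusive
  couples is formed each generation; every offspring draws a couple uniformly.
* ``POLYGYNY`` — every female is assigned a uniformly random husband (males may
  hold several wives); an offspring draws its mother uniformly, the father is
  her husband.
* ``POLYANDRY`` — the mirror image of polygyny.
* ``POLYGAMY`` — no unions: an offspring draws an independent uniform mother
  and father (classical random mating).

Optional sibling avoidance rejects any candidate pair sharing at least one
parent id (full or half siblings) and redraws, up to ``max_rejections`` times
per offspring; exhausting the cap raises :class:`NoValidPairError` rather than
silently permitting an incestuous union.  Unions are re-formed every
generation; there are no persistent marriages.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "MatingSystem",
    "MatingConfig",
    "UnionSet",
    "NoValidPairError",
    "form_unions",
    "draw_parents",
    "draw_parents_batch",
    "are_siblings",
]


class MatingSystem(enum.Enum):
    MONOGAMY = "monogamy"
    POLYGAMY = "polygamy"
    POLYGYNY = "polygyny"
    POLYANDRY = "polyandry"


class NoValidPairError(RuntimeError):
    """No sibling-free parent pair could be drawn within the rejection cap."""


@dataclass(frozen=True)
class MatingConfig:
    system: MatingSystem = MatingSystem.POLYGAMY
    avoid_siblings: bool = False
    max_rejections: int = 1000

    def __post_init__(self) -> None:
        if self.max_rejections < 1:
            raise ValueError("max_rejections must be >= 1")


@dataclass(frozen=True)
class UnionSet:
    """Unions over female/male positions 0..N_f-1 / 0..N_m-1.

    ``pairs`` holds (female_pos, male_pos) couples under monogamy;
    ``husband_of`` maps each female to her husband under polygyny;
    ``wife_of`` maps each male to his wife under polyandry; polygamy keeps
    none of these (parents are drawn per offspring).
    """

    system: MatingSystem
    n_females: int
    n_males: int
    pairs: Optional[np.ndarray] = field(default=None, repr=False)
    husband_of: Optional[np.ndarray] = field(default=None, repr=False)
    wife_of: Optional[np.ndarray] = field(default=None, repr=False)


def form_unions(
    females: Sequence, males: Sequence, config: MatingConfig, rng: np.random.Generator
) -> UnionSet:
    """Form this generation's unions; see the module docstring for the rules."""
    n_f, n_m = len(females), len(males)
    if n_f == 0 or n_m == 0:
        raise ValueError("both sexes must be present to form unions")
    sys_ = config.system
    if sys_ is MatingSystem.MONOGAMY:
        k = min(n_f, n_m)
        fp = rng.permutation(n_f)[:k]
        mp = rng.permutation(n_m)[:k]
        return UnionSet(sys_, n_f, n_m, pairs=np.column_stack([fp, mp]))
    if sys_ is MatingSystem.POLYGYNY:
        return UnionSet(sys_, n_f, n_m, husband_of=rng.integers(0, n_m, size=n_f))
    if sys_ is MatingSystem.POLYANDRY:
        return UnionSet(sys_, n_f, n_m, wife_of=rng.integers(0, n_f, size=n_m))
    return UnionSet(sys_, n_f, n_m)  # POLYGAMY: drawn per offspring


def _draw(
    unions: UnionSet, size: int, rng: np.random.Generator
) -> Tuple[np.ndarray, np.ndarray]:
    sys_ = unions.system
    if sys_ is MatingSystem.MONOGAMY:
        u = rng.integers(0, len(unions.pairs), size=size)
        return unions.pairs[u, 0], unions.pairs[u, 1]
    if sys_ is MatingSystem.POLYGYNY:
        mothers = rng.integers(0, unions.n_females, size=size)
        return mothers, unions.husband_of[mothers]
    if sys_ is MatingSystem.POLYANDRY:
        fathers = rng.integers(0, unions.n_males, size=size)
        return unions.wife_of[fathers], fathers
    mothers = rng.integers(0, unions.n_females, size=size)
    fathers = rng.integers(0, unions.n_males, size=size)
    return mothers, fathers


def draw_parents_batch(
    unions: UnionSet,
    n_offspring: int,
    config: MatingConfig,
    rng: np.random.Generator,
    female_mother_ids: Optional[np.ndarray] = None,
    female_father_ids: Optional[np.ndarray] = None,
    male_mother_ids: Optional[np.ndarray] = None,
    male_father_ids: Optional[np.ndarray] = None,
) -> Tuple[np.ndarray, np.ndarray]:
    """Draw (mother_pos, father_pos) for a whole cohort.

    Positions index the female/male cohorts that formed the unions.  The four
    ``*_ids`` arrays carry the adults' own parent ids (-1 for founders) and are
    required when ``config.avoid_siblings`` is set.
    """
    mothers, fathers = _draw(unions, n_offspring, rng)
    if not config.avoid_siblings:
        return mothers, fathers
    if female_mother_ids is None or male_mother_ids is None:
        raise ValueError("sibling avoidance requires the adults' parent ids")

    def bad_mask(mo: np.ndarray, fa: np.ndarray) -> np.ndarray:
        shared_mother = (female_mother_ids[mo] == male_mother_ids[fa]) & (
            female_mother_ids[mo] >= 0
        )
        shared_father = (female_father_ids[mo] == male_father_ids[fa]) & (
            female_father_ids[mo] >= 0
        )
        return shared_mother | shared_father

    bad = bad_mask(mothers, fathers)
    rounds = 0
    while bad.any():
        rounds += 1
        if rounds > config.max_rejections:
            raise NoValidPairError(
                f"{int(bad.sum())} offspring could not be assigned sibling-free "
                f"parents within {config.max_rejections} redraws"
            )
        idx = np.flatnonzero(bad)
        mo, fa = _draw(unions, idx.size, rng)
        mothers[idx], fathers[idx] = mo, fa
        bad[idx] = bad_mask(mo, fa)
    return mothers, fathers


def draw_parents(
    unions: UnionSet,
    females: Sequence,
    males: Sequence,
    config: MatingConfig,
    rng: np.random.Generator,
) -> Tuple[int, int]:
    """Draw one (mother_id, father_id) pair from cohorts of Individuals."""
    fm = np.array([f.mother_id if f.mother_id is not None else -1 for f in females])
    ff = np.array([f.father_id if f.father_id is not None else -1 for f in females])
    mm = np.array([m.mother_id if m.mother_id is not None else -1 for m in males])
    mf = np.array([m.father_id if m.father_id is not None else -1 for m in males])
    mo, fa = draw_parents_batch(
        unions, 1, config, rng,
        female_mother_ids=fm, female_father_ids=ff,
        male_mother_ids=mm, male_father_ids=mf,
    )
    return females[int(mo[0])].id, males[int(fa[0])].id


def are_siblings(a, b) -> bool:
    """True iff two individuals share at least one parent id (full or half
    siblings); founders (no parent ids) are never siblings.  Note that
    ``are_siblings(x, x)`` is True for any non-founder x."""
    am = -1 if a.mother_id is None else a.mother_id
    af = -1 if a.father_id is None else a.father_id
    bm = -1 if b.mother_id is None else b.mother_id
    bf = -1 if b.father_id is None else b.father_id
    return (am == bm and am >= 0) or (af == bf and af >= 0)
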