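"""Marriage rules: union formation, parent draws, and sibling avoidance."""

import numpy as np
import pytest
from scipy.stats import chisquare, ttest_ind

from matesim import (
    LocusSpec,
    MatingConfig,
    MatingSystem,
    MutationModel,
    NoValidPairError,
    are_siblings,
    form_unions,
    found_population,
    step_generation,
)
from matesim.genetics import LocusClass
from matesim.mating import draw_parents_batch

MT_ONLY = [LocusSpec(LocusClass.MT, 1, 50, MutationModel(0.0))]


class TestFormUnions:
    def test_monogamy_perfect_matching(self, rng):
        unions = form_unions(range(5), range(5), MatingConfig(MatingSystem.MONOGAMY),
                             rng)
        assert len(unions.pairs) == 5
        assert len(set(unions.pairs[:, 0])) == 5
        assert len(set(unions.pairs[:, 1])) == 5

    def test_monogamy_min_rule_leaves_excess_unmatched(self, rng):
        unions = form_unions(range(3), range(7), MatingConfig(MatingSystem.MONOGAMY),
                             rng)
        assert len(unions.pairs) == 3
        assert len(set(unions.pairs[:, 1])) == 3  # 4 males unmatched

    def test_empty_sex_class_is_an_error(self, rng):
        with pytest.raises(ValueError):
            form_unions([], range(5), MatingConfig(MatingSystem.MONOGAMY), rng)

    def test_polygyny_wives_per_male_is_binomial(self, rng):
        """Independent uniform husband choice: wives-per-male ~ Binomial(50, 1/50)."""
        n_f = n_m = 50
        config = MatingConfig(MatingSystem.POLYGYNY)
        counts = np.zeros(n_m)
        draws = 2000
        for _ in range(draws):
            unions = form_unions(range(n_f), range(n_m), config, rng)
            counts += np.bincount(unions.husband_of, minlength=n_m)
        mean_wives = counts.sum() / (draws * n_m)
        assert mean_wives == pytest.approx(1.0)
        # variance of wives-per-male across draws matches Binomial(50, 1/50)
        var = np.var(
            [np.bincount(form_unions(range(n_f), range(n_m), config, rng).husband_of,
                         minlength=n_m) for _ in range(500)]
        )
        assert var == pytest.approx(50 * (1 / 50) * (49 / 50), rel=0.15)


class TestDrawParents:
    def test_polygamy_pairs_are_uniform(self, rng):
        """All 25 female x male pairs equiprobable over 10^4 draws."""
        unions = form_unions(range(5), range(5), MatingConfig(MatingSystem.POLYGAMY),
                             rng)
        mothers, fathers = draw_parents_batch(
            unions, 10_000, MatingConfig(MatingSystem.POLYGAMY), rng
        )
        table = np.zeros((5, 5))
        np.add.at(table, (mothers, fathers), 1)
        assert chisquare(table.ravel()).pvalue > 1e-3

    def test_fully_excluded_pair_set_raises(self, rng):
        """Two adults sharing a mother as the only possible pair -> error."""
        unions = form_unions([0], [0], MatingConfig(MatingSystem.POLYGAMY), rng)
        config = MatingConfig(MatingSystem.POLYGAMY, avoid_siblings=True,
                              max_rejections=50)
        with pytest.raises(NoValidPairError):
            draw_parents_batch(
                unions, 4, config, rng,
                female_mother_ids=np.array([7]), female_father_ids=np.array([1]),
                male_mother_ids=np.array([7]), male_father_ids=np.array([2]),
            )

    def test_founders_are_never_rejected(self, rng):
        unions = form_unions([0], [0], MatingConfig(MatingSystem.POLYGAMY), rng)
        config = MatingConfig(MatingSystem.POLYGAMY, avoid_siblings=True)
        mothers, fathers = draw_parents_batch(
            unions, 10, config, rng,
            female_mother_ids=np.array([-1]), female_father_ids=np.array([-1]),
            male_mother_ids=np.array([-1]), male_father_ids=np.array([-1]),
        )
        assert mothers.size == 10

    def test_polygyny_raises_male_offspring_variance(self):
        """Across replicate single generations, Var(male offspring count) is
        larger under polygyny than monogamy."""
        reps, n = 2000, 100

        def male_variance(system, seed):
            out = np.empty(reps)
            for rep in range(reps):
                rng = np.random.default_rng((seed, rep))
                fem = np.arange(n // 2)
                mal = np.arange(n // 2)
                unions = form_unions(fem, mal, MatingConfig(system), rng)
                _, fathers = draw_parents_batch(unions, n, MatingConfig(system), rng)
                out[rep] = np.var(np.bincount(fathers, minlength=n // 2))
            return out

        var_poly = male_variance(MatingSystem.POLYGYNY, 1)
        var_mono = male_variance(MatingSystem.MONOGAMY, 2)
        assert var_poly.mean() > var_mono.mean()
        p = ttest_ind(var_poly, var_mono, equal_var=False,
                      alternative="greater").pvalue
        assert p < 0.01


class TestSiblings:
    class Stub:
        def __init__(self, mother_id, father_id):
            self.mother_id, self.father_id = mother_id, father_id

    def test_half_siblings_share_one_parent(self):
        assert are_siblings(self.Stub(1, 2), self.Stub(1, 3))
        assert are_siblings(self.Stub(1, 2), self.Stub(4, 2))

    def test_unrelated_and_founders(self):
        assert not are_siblings(self.Stub(1, 2), self.Stub(3, 4))
        assert not are_siblings(self.Stub(None, None), self.Stub(None, None))

    def test_self_comparison_is_true_for_non_founders(self):
        x = self.Stub(1, 2)
        assert are_siblings(x, x)


class TestPedigreeInvariants:
    def test_monogamy_offspring_parents_appear_in_unions(self):
        """Under monogamy each generation's parent pairs form a matching:
        every mother has exactly one co-parent and vice versa."""
        pop = found_population(
            40, MT_ONLY, mating_config=MatingConfig(MatingSystem.MONOGAMY), seed=11
        )
        for _ in range(10):
            step_generation(pop)
            pairs = set(zip(pop.mother_ids.tolist(), pop.father_ids.tolist()))
            mothers = [m for m, _ in pairs]
            fathers = [f for _, f in pairs]
            assert len(mothers) == len(set(mothers))
            assert len(fathers) == len(set(fathers))

    def test_polygyny_mothers_map_to_a_single_father(self):
        pop = found_population(
            40, MT_ONLY, mating_config=MatingConfig(MatingSystem.POLYGYNY), seed=12
        )
        for _ in range(10):
            step_generation(pop)
            mapping = {}
            for m, f in zip(pop.mother_ids.tolist(), pop.father_ids.tolist()):
                assert mapping.setdefault(m, f) == f

    def test_avoidance_pedigrees_are_sibling_free_over_100_generations(self):
        config = MatingConfig(MatingSystem.POLYGAMY, avoid_siblings=True)
        pop = found_population(30, MT_ONLY, mating_config=config, seed=13)
        for _ in range(100):
            prev = {int(i): (int(m), int(f))
                    for i, m, f in zip(pop.ids, pop.mother_ids, pop.father_ids)}
            step_generation(pop)
            for mid, fid in zip(pop.mother_ids.tolist(), pop.father_ids.tolist()):
                (mm, mf), (fm, ff) = prev[mid], prev[fid]
                if mm >= 0:
                    assert not (mm == fm or mf == ff)
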