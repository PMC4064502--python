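"""Demography schedules, population construction, and the generation cycle."""

import numpy as np
import pytest

from matesim import (
    LocusSpec,
    MatingConfig,
    MatingSystem,
    MutationModel,
    ScheduleExhaustedError,
    constant,
    found_population,
    growth,
    size_at,
    step_generation,
)
from matesim.genetics import LocusClass


class TestSizeAt:
    SCHEDULE = [constant(100, 500), growth(2, 50), constant(200, 500)]

    def test_constant_phase_holds_size(self):
        assert size_at(self.SCHEDULE, 0) == 100
        assert size_at(self.SCHEDULE, 499) == 100

    def test_growth_phase_reaches_target(self):
        assert size_at(self.SCHEDULE, 500) == 102
        assert size_at(self.SCHEDULE, 549) == 200
        assert size_at(self.SCHEDULE, 550) == 200

    def test_zero_growth_equals_constant(self):
        flat = [constant(80, 10), growth(0, 10)]
        assert [size_at(flat, t) for t in range(20)] == [80] * 20

    def test_beyond_schedule_is_an_error(self):
        with pytest.raises(ScheduleExhaustedError):
            size_at(self.SCHEDULE, 1050)

    def test_shrinking_below_two_is_invalid(self):
        with pytest.raises(ValueError):
            size_at([constant(10, 5), growth(-3, 5)], 8)


class TestFoundPopulation:
    def test_even_split(self, four_class_specs, random_mating):
        pop = found_population(200, four_class_specs, mating_config=random_mating,
                               seed=0)
        assert pop.n_females == 100 and pop.n_males == 100

    def test_floor_rule_keeps_tiny_demes_viable(self, four_class_specs, random_mating):
        pop = found_population(3, four_class_specs, mating_config=random_mating, seed=0)
        assert pop.n_females == 1 and pop.n_males == 2

    def test_too_small_or_single_sex_is_an_error(self, four_class_specs):
        with pytest.raises(ValueError):
            found_population(1, four_class_specs, seed=0)
        with pytest.raises(ValueError):
            found_population(5, four_class_specs, sex_ratio=0.05, seed=0)

    def test_founders_have_no_parents_and_zero_diversity(
        self, four_class_specs, random_mating
    ):
        from matesim import collect_panel, summarize

        pop = found_population(50, four_class_specs, mating_config=random_mating,
                               seed=0)
        assert (pop.mother_ids == -1).all() and (pop.father_ids == -1).all()
        stats = summarize(collect_panel(pop, LocusClass.AUTOSOMAL, 0))
        assert stats.S == 0 and stats.h == 1


class TestStepGeneration:
    def test_census_follows_a_three_phase_schedule(self, random_mating):
        specs = [LocusSpec(LocusClass.MT, 1, 50, MutationModel(0.0))]
        schedule = [constant(30, 10), growth(2, 10), constant(50, 10)]
        pop = found_population(30, specs, schedule=schedule,
                               mating_config=random_mating, seed=3)
        for _ in range(29):
            step_generation(pop)
            assert pop.size == size_at(schedule, pop.generation)
            pop.validate()

    def test_no_mutation_stays_monomorphic(self, four_class_specs, random_mating):
        from matesim import collect_panel, seg_sites

        pop = found_population(40, four_class_specs, mating_config=random_mating,
                               seed=4)
        for _ in range(30):
            step_generation(pop)
        assert pop.size == 40
        for cls in pop.pool:
            assert seg_sites(collect_panel(pop, cls, 0)) == 0

    def test_same_seed_same_trajectory(self, random_mating):
        specs = [LocusSpec(LocusClass.MT, 1, 100, MutationModel(1e-3))]

        def run():
            pop = found_population(20, specs, mating_config=random_mating, seed=99)
            for _ in range(15):
                step_generation(pop)
            return pop

        a, b = run(), run()
        assert np.array_equal(a.pool[LocusClass.MT], b.pool[LocusClass.MT])
        assert np.array_equal(a.is_female, b.is_female)
        assert np.array_equal(a.mother_ids, b.mother_ids)

    def test_pedigree_points_to_previous_generation_adults(self, four_class_specs,
                                                           random_mating):
        pop = found_population(30, four_class_specs, mating_config=random_mating,
                               seed=6)
        for _ in range(10):
            prev_ids = pop.ids.copy()
            prev_female = {int(i): bool(f)
                           for i, f in zip(pop.ids, pop.is_female)}
            step_generation(pop)
            for mid, fid in zip(pop.mother_ids, pop.father_ids):
                assert int(mid) in prev_ids and prev_female[int(mid)] is True
                assert int(fid) in prev_ids and prev_female[int(fid)] is False

    def test_generation_counter_and_unique_ids(self, four_class_specs, random_mating):
        pop = found_population(10, four_class_specs, mating_config=random_mating,
                               seed=7)
        seen = set(pop.ids.tolist())
        for expected_t in range(1, 6):
            step_generation(pop)
            assert pop.generation == expected_t
            new = set(pop.ids.tolist())
            assert not (new & seen)
            seen |= new

    def test_mt_lineage_count_declines_under_drift(self):
        """Mean number of distinct mtDNA lineages declines monotonically."""
        specs = [LocusSpec(LocusClass.MT, 1, 64, MutationModel(0.0))]
        reps, gens, n = 200, 30, 40
        trajectories = np.zeros((reps, gens))
        for rep in range(reps):
            pop = found_population(
                n, specs, mating_config=MatingConfig(MatingSystem.POLYGAMY),
                seed=1000 + rep,
            )
            # distinct founder lineages: tag each founder's mtDNA uniquely
            for i in range(n):
                pop.pool[LocusClass.MT][i, 0, 0, 0] = np.uint64(i)
            for g in range(gens):
                step_generation(pop)
                trajectories[rep, g] = len(
                    np.unique(pop.pool[LocusClass.MT][:, 0, 0, 0])
                )
        means = trajectories.mean(axis=0)
        assert (np.diff(means) <= 0).all()
        assert means[-1] < means[0]
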