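import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from floodsim import ModelParams
from floodsim.engine import (
    PopulationState,
    build_breeding_pool,
    census,
    density_regulate,
    init_resident_population,
    reproduce,
    run_replicate,
    sample_migrant_cohort,
    step_generation,
    survival_step,
)
from floodsim.individuals import L1, L2, W1, W2


def make_population(alleles, rng, introduced=False):
    """Population with given (n, 2) allele codes and random sexes."""
    alleles = np.asarray(alleles, dtype=np.int8)
    n = alleles.shape[0]
    return PopulationState(
        alleles=alleles,
        is_female=rng.random(n) < 0.5,
        introduced=np.full(n, introduced),
        age=np.zeros(n, dtype=np.int32),
    )


class TestInitResidentPopulation:
    def test_founds_exactly_k_residents_with_w_alleles(self):
        pop = init_resident_population(ModelParams(K=1000, seed=3))
        assert pop.size == 1000
        assert np.isin(pop.alleles, [W1, W2]).all()
        assert not pop.introduced.any()
        assert (pop.age == 0).all()

    def test_degenerate_frequency_fixes_w1(self):
        pop = init_resident_population(ModelParams(K=200, resident_W2_freq=0.0, seed=0))
        assert (pop.alleles == W1).all()

    def test_founding_is_hardy_weinberg(self, rng):
        n = 10_000
        pop = init_resident_population(ModelParams(K=n, resident_W2_freq=0.5), rng)
        n_w2 = (pop.alleles == W2).sum(axis=1)
        for count, expected_p in [( (n_w2 == 0).sum(), 0.25),
                                  ( (n_w2 == 1).sum(), 0.5),
                                  ( (n_w2 == 2).sum(), 0.25)]:
            se = np.sqrt(expected_p * (1 - expected_p) * n)
            assert abs(count - expected_p * n) < 3 * se


class TestMigrantCohort:
    def test_zero_migration_is_empty(self, rng):
        assert sample_migrant_cohort(ModelParams(m=0.0), rng).size == 0

    def test_pulse_size_rounds_m_times_k(self, rng):
        cohort = sample_migrant_cohort(ModelParams(m=0.1, K=1000), rng)
        assert cohort.size == 100
        assert np.isin(cohort.alleles, [L1, L2]).all()
        assert cohort.introduced.all()

    def test_degenerate_frequency_fixes_l2(self, rng):
        cohort = sample_migrant_cohort(ModelParams(m=0.2, migrant_L2_freq=1.0), rng)
        assert (cohort.alleles == L2).all()

    def test_current_size_basis_scales_with_standing_population(self, rng):
        params = ModelParams(m=0.1, K=1000, pulse_basis="current")
        assert sample_migrant_cohort(params, rng, current_size=500).size == 50


class TestSurvivalStep:
    def test_certain_survival_preserves_population_and_ages(self, rng):
        pop = make_population([[W1, W2]] * 100, rng)
        out = survival_step(pop, ModelParams(base_survival=1.0), rng)
        assert out.size == 100
        assert (out.age == 1).all()
        assert (out.alleles == pop.alleles).all()

    def test_l2_homozygotes_survive_at_half_rate(self, rng):
        n = 10_000
        pop = make_population([[L2, L2]] * n, rng)
        out = survival_step(pop, ModelParams(base_survival=1.0), rng)
        se = np.sqrt(0.5 * 0.5 * n)
        assert abs(out.size - n / 2) < 3 * se

    def test_zero_survival_empties_population(self, rng):
        pop = make_population([[W1, W1]] * 50, rng)
        assert survival_step(pop, ModelParams(base_survival=0.0), rng).size == 0


class TestBreedingPool:
    def test_no_penalties_admits_everyone(self, rng, neutral_params):
        pop = make_population([[W1, L2]] * 200, rng)
        females, males = build_breeding_pool(pop, neutral_params, rng)
        assert females.size + males.size == 200
        assert females.is_female.all() and not males.is_female.any()

    def test_total_penalty_excludes_all_introduced(self, rng):
        pop = make_population([[L1, L2]] * 300, rng, introduced=True)
        params = ModelParams(mating_penalty=1.0, repro_mult_L2L2=1.0)
        females, males = build_breeding_pool(pop, params, rng)
        assert females.size == 0 and males.size == 0

    def test_half_penalty_admits_half_of_introduced(self, rng):
        n = 10_000
        pop = make_population([[L1, L1]] * n, rng, introduced=True)
        params = ModelParams(mating_penalty=0.5, repro_mult_L2L2=1.0)
        females, males = build_breeding_pool(pop, params, rng)
        se = np.sqrt(0.5 * 0.5 * n)
        assert abs((females.size + males.size) - n / 2) < 3 * se

    def test_descendants_of_migrants_are_not_penalized(self, rng):
        pop = make_population([[L1, L2]] * 400, rng, introduced=False)
        params = ModelParams(mating_penalty=1.0, repro_mult_L2L2=1.0)
        females, males = build_breeding_pool(pop, params, rng)
        assert females.size + males.size == 400


class TestReproduce:
    def _pools(self, rng, n=1000, codes=(W1, W1)):
        females = make_population([list(codes)] * n, rng)
        females.is_female[:] = True
        males = make_population([list(codes)] * n, rng)
        males.is_female[:] = False
        return females, males

    def test_empty_pool_produces_no_offspring(self, rng, neutral_params):
        females, males = self._pools(rng, n=10)
        empty = PopulationState.empty()
        assert reproduce(empty, males, neutral_params, rng).size == 0
        assert reproduce(females, empty, neutral_params, rng).size == 0

    def test_mean_offspring_matches_poisson_sum(self, rng):
        females, males = self._pools(rng, n=1000)
        params = ModelParams(mean_litter=2.0)
        offspring = reproduce(females, males, params, rng)
        se = np.sqrt(2.0 * 1000)  # sum of 1000 Poisson(2) litters
        assert abs(offspring.size - 2000) < 3 * se
        assert (offspring.alleles == W1).all()
        assert not offspring.introduced.any()
        assert (offspring.age == 0).all()

    def test_expected_fecundity_invariant_to_mating_rounds(self, rng):
        females, males = self._pools(rng, n=1000)
        params = ModelParams(mean_litter=2.0, multiple_paternity_factor=3)
        offspring = reproduce(females, males, params, rng)
        se = np.sqrt(2.0 * 1000)
        assert abs(offspring.size - 2000) < 3 * se

    def test_double_homozygote_pairings_produce_fifth_of_litter(self, rng):
        females, males = self._pools(rng, n=2000, codes=(L2, L2))
        params = ModelParams(mean_litter=2.0)
        offspring = reproduce(females, males, params, rng)
        expected = 2000 * 2.0 * 0.2
        se = np.sqrt(expected)
        assert abs(offspring.size - expected) < 4 * se


class TestDensityRegulate:
    def test_below_capacity_unchanged(self, rng):
        pop = make_population([[W1, W2]] * 800, rng)
        assert density_regulate(pop, ModelParams(K=1000), rng) is pop

    def test_culls_exactly_to_k(self, rng):
        pop = make_population([[W1, W2]] * 1500, rng)
        assert density_regulate(pop, ModelParams(K=1000), rng).size == 1000

    def test_culling_is_genotype_blind(self, rng):
        alleles = [[W1, W1]] * 5000 + [[L1, L1]] * 5000
        pop = make_population(alleles, rng)
        out = density_regulate(pop, ModelParams(K=1000), rng)
        kept_w = (out.alleles[:, 0] == W1).sum()
        # hypergeometric: draw 1000 of 10000, 5000 marked
        se = np.sqrt(1000 * 0.5 * 0.5 * (10000 - 1000) / (10000 - 1))
        assert abs(kept_w - 500) < 3 * se


class TestStepGeneration:
    def test_inert_dynamics_change_only_ages(self, rng):
        params = ModelParams(m=0.0, base_survival=1.0, mean_litter=0.0, K=500)
        pop = init_resident_population(params, rng)
        before = pop.alleles.copy()
        out, snap = step_generation(pop, params, rng)
        assert (out.alleles == before).all()
        assert (out.age == 1).all()
        assert snap.generation == 1

    def test_census_conserves_allele_count(self, rng):
        params = ModelParams(m=0.2, K=300, seed=5)
        pop = init_resident_population(params, rng)
        for _ in range(5):
            pop, snap = step_generation(pop, params, rng)
            assert sum(snap.counts.values()) == 2 * snap.pop_size

    def test_culling_contract_holds_at_capacity(self, rng):
        params = ModelParams(m=0.2, K=1000, seed=11)
        pop = init_resident_population(params, rng)
        for _ in range(5):
            pop, snap = step_generation(pop, params, rng)
            assert snap.pop_size == 1000  # pre-cull size >= K under defaults


@settings(max_examples=15, deadline=None, derandomize=True)
@given(
    m=st.floats(0.0, 0.8),
    base_survival=st.floats(0.0, 1.0),
    mean_litter=st.floats(0.0, 4.0),
    penalty=st.floats(0.0, 1.0),
    paternity=st.integers(1, 3),
    l2_freq=st.floats(0.0, 1.0),
)
def test_generation_step_invariants_hold_for_arbitrary_parameters(
    m, base_survival, mean_litter, penalty, paternity, l2_freq
):
    """Conservation and capacity invariants under arbitrary valid parameters."""
    params = ModelParams(
        K=80,
        m=m,
        generations=3,
        base_survival=base_survival,
        mean_litter=mean_litter,
        mating_penalty=penalty,
        multiple_paternity_factor=paternity,
        migrant_L2_freq=l2_freq,
        seed=99,
    )
    result = run_replicate(params)
    assert len(result.trajectory) == params.generations + 1
    for snap in result.trajectory:
        assert sum(snap.counts.values()) == 2 * snap.pop_size
        assert snap.pop_size <= params.K


class TestRunReplicate:
    def test_no_migration_never_collapses(self):
        result = run_replicate(ModelParams(m=0.0, K=300, generations=30, seed=2))
        assert not result.collapsed
        for snap in result.trajectory:
            assert snap.counts["L1"] == 0 and snap.counts["L2"] == 0
            assert snap.counts["W1"] + snap.counts["W2"] == 2 * snap.pop_size

    def test_high_migration_collapses_most_replicates(self):
        outcomes = [
            run_replicate(ModelParams(m=0.30, seed=s)).collapsed for s in range(8)
        ]
        assert sum(outcomes) >= 7

    def test_identical_seed_gives_bit_identical_trajectories(self):
        params = ModelParams(m=0.15, K=400, generations=20, seed=42)
        a, b = run_replicate(params), run_replicate(params)
        assert [c.counts for c in a.trajectory] == [c.counts for c in b.trajectory]
        assert a.collapse_generation == b.collapse_generation

    def test_resident_allele_loss_is_absorbing(self):
        result = run_replicate(ModelParams(m=0.3, seed=13))
        for label in ("W1", "W2"):
            counts = [c.counts[label] for c in result.trajectory]
            seen_zero = False
            for value in counts:
                if seen_zero:
                    assert value == 0
                seen_zero = seen_zero or value == 0
        if result.collapsed:
            snap = result.trajectory[result.collapse_generation]
            assert snap.counts["W1"] == 0 and snap.counts["W2"] == 0

    def test_extinction_with_no_migration_flags_extinct(self):
        params = ModelParams(m=0.0, K=50, generations=10, mean_litter=0.0, seed=1)
        result = run_replicate(params)
        assert result.extinct
        assert result.trajectory[-1].pop_size == 0


class TestNeutralDrift:
    def test_w2_frequency_is_a_martingale_and_residents_partition_the_census(
        self, neutral_params
    ):
        """With m = 0 and no selection, mean final W2 frequency stays at its
        founding value (drift has no direction), and both resident alleles
        can never be simultaneously lost: they partition all 2N copies."""
        params = neutral_params.replace(m=0.0, K=1000, generations=100)
        finals = []
        for seed in range(200):
            result = run_replicate(params.replace(seed=seed))
            final = result.trajectory[-1]
            total = 2 * final.pop_size
            assert final.counts["W1"] + final.counts["W2"] == total
            assert not result.collapsed
            finals.append(final.counts["W2"] / total)
        # binomial-style bound: per-replicate variance of a drifting
        # frequency is at most p(1-p) = 0.25
        se = np.sqrt(0.25 / 200)
        assert abs(np.mean(finals) - 0.5) < 3 * se
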