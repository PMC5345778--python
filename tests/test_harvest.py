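from dataclasses import replace
from itertools import permutations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mpabioecon.harvest import allocate_catch, check_moratorium, set_quota, survey_biomass
from mpabioecon.population import Population, initialize_population
from mpabioecon.scenarios import MPAScenario, scenario_status_quo
from tests.conftest import make_chain_domain


def _random_pop(lh, dom, seed, scale=1e5):
    rng = np.random.default_rng(seed)
    pop = Population.empty(dom.n_cells, lh)
    water = dom.water_eez_ids
    pop.counts[water, 1:, :] = rng.uniform(0, scale, size=(water.size, pop.counts.shape[1] - 1, 2))
    return pop


class TestSurvey:
    def test_full_census_is_exact(self, lh, mort, fishp, small_domain):
        pop = initialize_population(small_domain, lh, mort)
        full = replace(fishp, survey_fraction=1.0)
        est = survey_biomass(pop, small_domain, full, seed=0)
        assert est == pytest.approx(pop.total_biomass())

    def test_uniform_density_exact_for_any_sample(self, lh, fishp, small_domain):
        pop = Population.empty(small_domain.n_cells, lh)
        pop.counts[small_domain.water_eez_ids, 5, 1] = 1000.0
        for seed in range(5):
            est = survey_biomass(pop, small_domain, fishp, seed=seed)
            assert est == pytest.approx(pop.total_biomass())

    def test_design_unbiased(self, lh, mort, fishp, small_domain):
        pop = initialize_population(small_domain, lh, mort)
        truth = pop.total_biomass()
        ests = np.array([survey_biomass(pop, small_domain, fishp, seed=s)
                         for s in range(4000)])
        se = ests.std(ddof=1) / np.sqrt(len(ests))
        assert abs(ests.mean() - truth) < 4 * se


class TestQuota:
    def test_zero_estimate_zero_quota(self, fishp):
        assert set_quota(0.0, fishp) == 0.0

    def test_precautionary_fmsy_fraction(self, fishp):
        assert set_quota(100_000.0, fishp) == pytest.approx(100_000 * 0.28 * 2 / 3)

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(b=st.floats(0, 1e7), k=st.floats(0.1, 10))
    def test_linearity(self, fishp, b, k):
        assert set_quota(k * b, fishp) == pytest.approx(k * set_quota(b, fishp))


class TestMoratorium:
    @pytest.mark.parametrize("biomass,expected", [
        (9_999.0, True), (10_000.0, False), (0.0, True), (10_001.0, False),
    ])
    def test_strict_threshold(self, fishp, biomass, expected):
        assert check_moratorium(biomass, fishp) is expected


class TestAllocateCatch:
    def test_zero_quota_changes_nothing(self, lh, fishp, small_domain):
        pop = _random_pop(lh, small_domain, 0)
        scen = scenario_status_quo(small_domain)
        records, out, dist = allocate_catch(pop, 0.0, scen, small_domain, fishp)
        assert records == [] and dist is None
        np.testing.assert_array_equal(out.counts, pop.counts)

    def test_negative_quota_rejected(self, lh, fishp, small_domain):
        pop = _random_pop(lh, small_domain, 0)
        scen = scenario_status_quo(small_domain)
        with pytest.raises(ValueError):
            allocate_catch(pop, -1.0, scen, small_domain, fishp)

    def _fishable_biomass(self, pop, fishp, mask=None):
        ages = np.arange(pop.counts.shape[1])
        ok = (ages >= fishp.min_age_catch) & (pop.length >= fishp.min_length_catch)
        w = np.where(ok, pop.weight, 0.0)
        per_cell = (pop.counts.sum(axis=2) @ w) / 1000.0
        return per_cell if mask is None else per_cell[mask]

    @pytest.mark.parametrize("quota_scale", [0.1, 0.5, 2.0])
    def test_catch_equals_min_of_quota_and_fishable(self, lh, fishp, small_domain, quota_scale):
        for seed in range(3):
            pop = _random_pop(lh, small_domain, seed)
            scen = scenario_status_quo(small_domain)
            fishable = self._fishable_biomass(pop, fishp).sum()
            quota = quota_scale * fishable
            records, out, _ = allocate_catch(pop, quota, scen, small_domain, fishp)
            catch = sum(r.weight_t for r in records)
            assert catch == pytest.approx(min(quota, fishable), abs=1e-6)
            # mass balance: removal equals reported catch
            removed = pop.total_biomass() - out.total_biomass()
            assert removed == pytest.approx(catch, abs=1e-6)

    def test_protected_cells_never_fished(self, lh, fishp, small_domain):
        pop = _random_pop(lh, small_domain, 1)
        protect = frozenset(map(int, small_domain.water_eez_ids[:5]))
        scen = MPAScenario("mpa", protect, 0.0, [sorted(protect)])
        records, out, _ = allocate_catch(pop, 1e12, scen, small_domain, fishp)
        assert all(r.cell_id not in protect for r in records)
        ids = np.fromiter(protect, dtype=int)
        np.testing.assert_array_equal(out.counts[ids], pop.counts[ids])

    def test_undersized_and_young_fish_untouched(self, lh, fishp, small_domain):
        pop = _random_pop(lh, small_domain, 2)
        scen = scenario_status_quo(small_domain)
        _, out, _ = allocate_catch(pop, 1e12, scen, small_domain, fishp)
        ages = np.arange(pop.counts.shape[1])
        juvenile = (ages < fishp.min_age_catch) | (pop.length < fishp.min_length_catch)
        np.testing.assert_array_equal(out.counts[:, juvenile, :], pop.counts[:, juvenile, :])

    def test_cells_visited_in_distance_order(self, lh, fishp):
        dom = make_chain_domain(6)
        pop = Population.empty(dom.n_cells, lh)
        pop.counts[dom.water_eez_ids, 6, 1] = 1000.0
        scen = scenario_status_quo(dom)
        fishable = self._fishable_biomass(pop, fishp).sum()
        records, _, _ = allocate_catch(pop, 0.4 * fishable, scen, dom, fishp)
        dists = [r.dist_km for r in records]
        assert dists == sorted(dists)
        assert records[0].dist_km == dom.dist_to_shore[dom.water_eez_ids].min()

    def test_greedy_minimizes_catch_weighted_distance(self, lh, fishp):
        """No feasible allocation of the same total catch travels less."""
        dom = make_chain_domain(7)
        rng = np.random.default_rng(3)
        pop = Population.empty(dom.n_cells, lh)
        pop.counts[dom.water_eez_ids, 5, 1] = rng.uniform(100, 2000, 7)
        scen = scenario_status_quo(dom)
        avail = self._fishable_biomass(pop, fishp)
        quota = 0.6 * avail.sum()
        records, _, mean_dist = allocate_catch(pop, quota, scen, dom, fishp)
        total = sum(r.weight_t for r in records)
        for _ in range(300):  # random feasible allocations with the same total
            take = rng.uniform(0, avail)
            if take.sum() < total:
                continue
            take *= total / take.sum()
            if np.any(take > avail + 1e-9):
                continue
            alt = float((take * dom.dist_to_shore).sum() / total)
            assert mean_dist <= alt + 1e-9
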