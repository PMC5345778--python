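import math
from dataclasses import replace

import numpy as np
import pytest

from mpabioecon.params import FisheryParams
from mpabioecon.population import (Population, age_and_grow,
                                   beverton_holt_recruits, bh_max_recruits,
                                   draw_adult_mortality, draw_larval_mortality,
                                   enforce_carrying_capacity,
                                   initialize_population, length_to_weight,
                                   maturity_prob, spawn, vb_length)


class TestGrowth:
    def test_zero_length_at_t0(self, lh):
        assert vb_length(lh.t0, lh) == 0.0

    def test_monotone_approach_to_asymptote(self, lh):
        ages = np.arange(0, 60)
        L = vb_length(ages, lh)
        assert np.all(np.diff(L) > 0)
        assert L[-1] < lh.L_inf
        assert L[-1] > 0.99 * lh.L_inf

    def test_length_at_age_four(self, lh):
        # 120 * (1 - exp(-0.13 * 4))
        assert vb_length(4.0, lh) == pytest.approx(
            120.0 * (1.0 - math.exp(-0.52)), abs=1e-9)
        assert vb_length(4.0, lh) == pytest.approx(48.66, abs=0.01)

    def test_weight_of_a_metre_fish(self, lh):
        # 0.0085 g/cm^3 * 100^3 = 8500 g
        assert length_to_weight(100.0, lh) == pytest.approx(8.5)

    def test_weight_monotone_and_zero_at_zero(self, lh):
        assert length_to_weight(0.0, lh) == 0.0
        L = np.linspace(1, 150, 50)
        assert np.all(np.diff(length_to_weight(L, lh)) > 0)


class TestMaturity:
    def test_half_mature_at_midpoint(self, lh):
        assert maturity_prob(4.0, lh) == pytest.approx(0.5)

    @pytest.mark.parametrize("d", [0.5, 1.0, 2.0, 3.7])
    def test_logistic_symmetry(self, lh, d):
        assert maturity_prob(4 - d, lh) + maturity_prob(4 + d, lh) == pytest.approx(1.0)

    def test_onset_and_completion_ages(self, lh):
        # steepness ln(99)/2 puts 1% at age 2 and 99% at age 6
        assert maturity_prob(2.0, lh) == pytest.approx(0.01, abs=1e-9)
        assert maturity_prob(6.0, lh) == pytest.approx(0.99, abs=1e-9)


class TestSpawn:
    def _one_fish(self, lh, weight_kg, mature=True, count=1.0):
        pop = Population.empty(1, lh)
        age = 4
        pop.weight = pop.weight.copy()
        pop.weight[age] = weight_kg
        pop.counts[0, age, 1 if mature else 0] = count
        return pop

    def test_one_kg_female_produces_half_a_million_eggs(self, lh):
        females_only = replace(lh, female_fraction=1.0)
        pop = self._one_fish(females_only, 1.0)
        assert spawn(pop, females_only)[0] == pytest.approx(5e5)

    def test_default_sex_ratio_halves_output(self, lh):
        pop = self._one_fish(lh, 1.0)
        assert spawn(pop, lh)[0] == pytest.approx(2.5e5)

    def test_immature_fish_produce_nothing(self, lh):
        pop = self._one_fish(lh, 1.0, mature=False)
        assert np.all(spawn(pop, lh) == 0.0)

    def test_linear_in_abundance(self, lh):
        pop1 = self._one_fish(lh, 2.0, count=3.0)
        pop2 = self._one_fish(lh, 2.0, count=6.0)
        assert spawn(pop2, lh).sum() == pytest.approx(2 * spawn(pop1, lh).sum())


class TestMortalityDraws:
    def test_larval_support_and_mean(self, mort):
        m = draw_larval_mortality(10**5, mort, seed=1)
        assert np.all((m > 0) & (m < 1))
        assert np.all(m > 0.95)          # concentrated near 1 in practice
        assert m.mean() == pytest.approx(0.9988, abs=1e-4)

    def test_larval_spread_covers_reported_range(self, mort):
        m = draw_larval_mortality(10**6, mort, seed=2)
        assert m.min() < 0.9898 and m.max() > 0.9999

    def test_adult_truncation_and_moments(self, mort):
        m = draw_adult_mortality(10**6, mort, seed=3)
        assert np.all((m >= 0) & (m <= 1))
        assert m.mean() == pytest.approx(0.5938, abs=3 * 0.0517 / 1000)
        assert m.std() == pytest.approx(0.0517, rel=0.01)

    @pytest.mark.parametrize("fn", [draw_larval_mortality, draw_adult_mortality])
    def test_draw_count_precondition(self, fn, mort):
        with pytest.raises(ValueError):
            fn(0, mort)


class TestBevertonHolt:
    def test_zero_settlers_zero_capacity(self, lh, mort):
        assert beverton_holt_recruits(0.0, 100.0, lh, mort) == 0.0
        assert beverton_holt_recruits(1e6, 0.0, lh, mort) == 0.0

    def test_saturating_concave_and_bounded(self, lh, mort):
        S = np.logspace(0, 10, 60)
        R = beverton_holt_recruits(S, 172.0, lh, mort)
        r_max = bh_max_recruits(172.0, lh, mort)
        assert np.all(np.diff(R) >= 0)                      # non-decreasing
        slopes = np.diff(R) / np.diff(S)
        assert np.all(np.diff(slopes) <= 1e-12)             # concave
        assert np.all(R <= r_max + 1e-9)

    def test_low_density_slope(self, lh, mort):
        # R ~ bh_slope * S when far below capacity
        r = beverton_holt_recruits(1.0, 1e9, lh, mort)
        assert r == pytest.approx(mort.bh_slope, rel=1e-6)


class TestCarryingCapacityEnforcement:
    def test_below_capacity_untouched(self, lh, small_domain):
        pop = Population.empty(small_domain.n_cells, lh)
        pop.counts[small_domain.water_eez_ids[0], 5, 1] = 10.0
        out = enforce_carrying_capacity(pop, small_domain)
        np.testing.assert_array_equal(out.counts, pop.counts)

    def test_double_capacity_scaled_to_capacity(self, lh, small_domain):
        cell = int(small_domain.water_eez_ids[0])
        cap_kg = small_domain.K[cell] * small_domain.cell_area * 1000.0
        pop = Population.empty(small_domain.n_cells, lh)
        pop.counts[cell, 6, 1] = 2.0 * cap_kg / pop.weight[6]
        out = enforce_carrying_capacity(pop, small_domain)
        assert out.biomass_per_cell()[cell] * 1000.0 == pytest.approx(cap_kg)

    def test_never_increases_biomass(self, lh, small_domain, mort):
        pop = initialize_population(small_domain, lh, mort)
        out = enforce_carrying_capacity(pop, small_domain)
        assert out.total_biomass() <= pop.total_biomass() + 1e-9


class TestAgeAndGrow:
    def test_counts_conserved_and_lengths_advance(self, lh, small_domain, mort):
        pop = initialize_population(small_domain, lh, mort)
        out = age_and_grow(pop, lh)
        assert out.total_count() == pytest.approx(pop.total_count())
        # every surviving cohort is older, hence longer
        assert np.all(np.diff(out.length) >= 0)

    def test_cohort_mature_fraction_follows_ogive(self, lh):
        # a cohort tracked from age 1 matures along the logistic ogive
        pop = Population.empty(1, lh)
        pop.counts[0, 1, 0] = 10_000.0
        for step in range(9):
            pop = age_and_grow(pop, lh)
            a = 2 + step
            frac = pop.counts[0, a, 1] / pop.counts[0, a, :].sum()
            assert frac == pytest.approx(float(maturity_prob(a, lh)), abs=0.01)

    def test_no_reversion_to_immature(self, lh, small_domain, mort):
        pop = initialize_population(small_domain, lh, mort)
        out = age_and_grow(pop, lh)
        shifted_mature = np.zeros_like(pop.counts[:, :, 1])
        shifted_mature[:, 1:] = pop.counts[:, :-1, 1]
        shifted_mature[:, -1] += pop.counts[:, -1, 1]
        assert np.all(out.counts[:, :, 1] + 1e-9 >= shifted_mature)


class TestInitialization:
    def test_total_matches_initial_abundance(self, lh, mort, small_domain):
        pop = initialize_population(small_domain, lh, mort)
        assert pop.total_count() == pytest.approx(lh.initial_abun, rel=1e-9)

    def test_land_cells_empty(self, lh, mort, small_domain):
        pop = initialize_population(small_domain, lh, mort)
        assert pop.counts[small_domain.is_land].sum() == 0.0

    def test_snapshot_frame_columns(self, lh, mort, small_domain):
        df = initialize_population(small_domain, lh, mort).to_frame()
        assert list(df.columns) == ["cell_id", "age", "count", "length", "weight", "mature"]
        assert (df["count"] > 0).all()


def test_unfished_stock_settles_near_carrying_capacity(lh, mort):
    """Without fishing the stock reaches a stable level set by the K field.

    Beverton-Holt regulation with a finite low-density slope equilibrates
    below the hard cap; the attractor should be a large, stable fraction of
    total K rather than collapse or unbounded growth.
    """
    from mpabioecon.simulate import SimulationConfig, run_simulation
    from mpabioecon.scenarios import scenario_status_quo

    cfg = SimulationConfig(domain_n_x=10, domain_n_y=10, n_years=100,
                           fish=FisheryParams(fmsy=0.0))
    dom = cfg.build_domain()
    res = run_simulation(dom, scenario_status_quo(dom), cfg, seed=5)
    b = np.array([r.total_biomass for r in res.records])
    K_total = float((dom.K * dom.cell_area).sum())
    late = b[50:]
    assert 0.3 * K_total < late.mean() < 1.1 * K_total
    assert late.std() / late.mean() < 0.2      # fluctuates, does not trend away
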