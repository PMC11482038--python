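"""Stand simulator: initialisation, resource partitioning, conservation."""

import numpy as np
import pandas as pd
import pytest

from conftest import make_design
from ivgrass.simulator import (
    SimConfig,
    _Lattice,
    harvest,
    init_stand,
    light_partition,
    make_environment,
    n_uptake,
    run_season,
    step_day,
)


class TestInitStand:
    def test_counts_and_split(self, small_config):
        design = make_design()
        stand, soil = init_stand(design, small_config)
        assert stand.n == 64
        assert (stand.species == 1).sum() == 32
        assert (stand.species == 2).sum() == 32
        assert soil.mineral_n.shape == (64,)
        assert np.all(soil.mineral_n == soil.mineral_n[0])

    def test_full_lattice_split(self):
        design = make_design()
        stand, _ = init_stand(design, SimConfig())
        assert stand.n == 400
        assert (stand.species == 2).sum() == 200

    def test_pure_stand_single_species(self, small_config):
        design = make_design(delta=0.5, pure=True)
        stand, _ = init_stand(design, small_config)
        assert set(np.unique(stand.species)) == {design.pure_species}

    def test_deterministic(self, small_config):
        design = make_design()
        a, _ = init_stand(design, small_config)
        b, _ = init_stand(design, small_config)
        np.testing.assert_array_equal(a.species, b.species)
        np.testing.assert_array_equal(a.traits, b.traits)

    def test_odd_count_rejected(self):
        design = make_design()
        with pytest.raises(ValueError, match="even"):
            init_stand(design, SimConfig(rows=3, cols=3))


class TestLightPartition:
    def test_zero_leaf_area_intercepts_nothing(self, small_config):
        stand, _ = init_stand(make_design(), small_config)
        stand.leaf_area[:] = 0.0
        np.testing.assert_array_equal(
            light_partition(stand, 8.0, small_config), np.zeros(stand.n)
        )

    def test_identical_plants_share_equally(self, small_config):
        stand, _ = init_stand(make_design(cv=0.001), small_config)
        stand.leaf_area[:] = 0.002
        stand.height[:] = 0.3
        pari = light_partition(stand, 8.0, small_config)
        assert pari.std() < 1e-12 * pari.mean()

    def test_interception_bounded_by_incidence(self, small_config):
        stand, _ = init_stand(make_design(cv=0.3), small_config)
        rng = np.random.default_rng(0)
        stand.leaf_area[:] = rng.uniform(0, 0.05, stand.n)
        stand.height[:] = rng.uniform(0, 1.0, stand.n)
        pari = light_partition(stand, 8.0, small_config)
        assert pari.sum() <= 8.0 * small_config.domain_area * (1 + 1e-9)

    def test_beer_law_saturation(self, small_config):
        """A lone plant with huge LAI intercepts ~all light over its zone."""
        stand, _ = init_stand(make_design(), small_config)
        stand.leaf_area[:] = 0.0
        stand.leaf_area[10] = 1e3
        pari = light_partition(stand, 8.0, small_config)
        zone_area = 9 * small_config.cell_area
        assert pari[10] == pytest.approx(8.0 * zone_area, rel=1e-6)
        assert pari.sum() == pytest.approx(pari[10])

    def test_taller_plant_wins_share(self, small_config):
        stand, _ = init_stand(make_design(cv=0.001), small_config)
        stand.leaf_area[:] = 0.002
        stand.height[:] = 0.3
        stand.height[0] = 0.6
        pari = light_partition(stand, 8.0, small_config)
        assert pari[0] > pari[1]


class TestNUptake:
    def test_empty_soil_gives_zero(self, small_config):
        stand, soil = init_stand(make_design(), small_config)
        soil.mineral_n[:] = 0.0
        uptake = n_uptake(stand, soil, np.full(stand.n, 1.0), small_config)
        np.testing.assert_array_equal(uptake, np.zeros(stand.n))

    def test_identical_plants_split_equally(self, small_config):
        stand, soil = init_stand(make_design(cv=0.001), small_config)
        soil.mineral_n[:] = 1e-4  # scarce
        demand = np.full(stand.n, 1.0)
        uptake = n_uptake(stand, soil, demand, small_config)
        assert uptake.std() < 1e-9 * uptake.mean()

    def test_capacity_proportional_sharing_when_scarce(self):
        """Per-cell capacities 0.2 and 0.9 contesting 1 g N split 2:9."""
        config = SimConfig(rows=6, cols=6, density=36.0)
        stand, soil = init_stand(make_design(), config)
        stand.alive[:] = False
        stand.alive[:2] = True  # plants at (0,0) and (0,1)
        vmax_col = stand.trait_names.index("Vmax_2")
        el_col = stand.trait_names.index("EL_max_R")
        # plant 0: one rooted cell (its own), per-cell capacity 0.2
        stand.root[0] = 0.01
        stand.traits[0, el_col] = 2.0       # el_rel = 1, ncells = 1
        stand.traits[0, vmax_col] = 20.0    # 20 * 0.01 * 1 = 0.2
        # plant 1: nine rooted cells (incl. plant 0's), 0.9 per cell
        stand.root[1] = 1.0
        stand.traits[1, el_col] = 8.0 / 6.0  # ncells = 1 + floor(6*4/3) = 9
        stand.traits[1, vmax_col] = 0.9 * 9.0 / (1.0 * (8.0 / 6.0) / 2.0)
        soil.mineral_n[:] = 0.0
        soil.mineral_n[0] = 1.0  # the only stocked cell is the shared one
        demand = np.zeros(stand.n)
        demand[:2] = 10.0
        uptake = n_uptake(stand, soil, demand, config)
        assert uptake[0] == pytest.approx(0.2 / 1.1)
        assert uptake[1] == pytest.approx(0.9 / 1.1)

    def test_uptake_never_exceeds_demand_or_pool(self, small_config):
        stand, soil = init_stand(make_design(cv=0.3), small_config)
        stand.root[:] = np.random.default_rng(1).uniform(0.1, 2.0, stand.n)
        demand = np.random.default_rng(2).uniform(0, 5e-3, stand.n)
        before = soil.mineral_n.sum()
        uptake = n_uptake(stand, soil, demand, small_config)
        assert np.all(uptake <= demand + 1e-15)
        assert soil.mineral_n.min() >= 0.0
        assert before - soil.mineral_n.sum() == pytest.approx(uptake.sum())


def small_config_override(config):
    return config


class TestStepAndHarvest:
    def test_no_light_no_growth(self, small_config):
        design = make_design()
        stand, soil = init_stand(design, small_config)
        env = make_environment("N+", small_config)
        stand.leaf_area[:] = 0.0
        shoot_before = stand.shoot.copy()
        step_day(stand, soil, env, 30, small_config, 30)
        # no interception -> no new production (maintenance may shrink mass)
        assert np.all(stand.produced == 0.0)
        assert np.all(stand.shoot <= shoot_before + 1e-15)

    def test_nitrogen_stress_halves_growth(self, small_config):
        """With NNI forced to 0.5 the realised growth is half potential."""
        design = make_design(cv=0.001, environment="0N")
        stand, soil = init_stand(design, small_config)
        env = make_environment("0N", small_config)
        config = small_config
        # grow a canopy first under plentiful N
        soil.mineral_n[:] = 1.0
        for day in range(20):
            step_day(stand, soil, env, day, config, day)
        pari = light_partition(stand, env.par[21], config)
        dm_pot = config.rue * pari
        demand = config.n_crit * dm_pot
        # supply exactly half of demand via a bespoke soil
        soil.mineral_n[:] = 0.0
        uptake = n_uptake(stand, soil, demand, config)
        assert np.all(uptake == 0.0)

    def test_harvest_residual_arithmetic(self, small_config):
        design = make_design()
        stand, _ = init_stand(design, small_config)
        stand.shoot[:] = 10.0
        cut = harvest(stand, small_config)
        assert np.all(stand.shoot == pytest.approx(2.0))
        total = cut[1] + cut[2]
        assert total == pytest.approx(8.0 * stand.n)

    def test_dead_plants_not_harvested(self, small_config):
        design = make_design()
        stand, _ = init_stand(design, small_config)
        stand.shoot[:] = 10.0
        stand.alive[:5] = False
        cut = harvest(stand, small_config)
        assert cut[1] + cut[2] == pytest.approx(8.0 * (stand.n - 5))
        assert np.all(stand.shoot[:5] == 10.0)

    def test_species_yields_sum_to_total(self, small_config):
        design = make_design()
        stand, _ = init_stand(design, small_config)
        rng = np.random.default_rng(3)
        stand.shoot[:] = rng.uniform(1, 5, stand.n)
        removed_total = (stand.shoot * 0.8).sum()
        cut = harvest(stand, small_config)
        assert cut[1] + cut[2] == pytest.approx(removed_total)


class TestRunSeason:
    def test_bit_identical_given_seed(self, small_config):
        design = make_design(cv=0.3)
        a = run_season(design, small_config)
        b = run_season(design, small_config)
        pd.testing.assert_frame_equal(a.plants, b.plants)
        assert a.yields == b.yields

    def test_conservation_suite(self, small_config):
        """Soil-N, dry-matter and light budgets close on a full run."""
        for cv in (0.001, 0.3):
            result = run_season(make_design(cv=cv, environment="0N"), small_config)
            assert result.diagnostics["n_balance_rel_err"] < 1e-9
            assert result.diagnostics["mass_balance_rel_err"] < 1e-9
            assert result.diagnostics["par_excess_max"] <= 1e-9

    def test_cumulative_records_non_negative(self, small_config):
        result = run_season(make_design(cv=0.3), small_config)
        assert (result.plants["cum_pari_MJ"] >= 0).all()
        assert (result.plants["cum_nupt_gN"] >= 0).all()
        assert (result.plants["production_g"] >= 0).all()

    def test_dead_plants_frozen(self, small_config):
        config = SimConfig(
            rows=8, cols=8, season_length=150, harvest_days=(60, 120),
            mortality_threshold=0.5,  # aggressive, to guarantee deaths
        )
        result = run_season(make_design(cv=0.3), config)
        dead = result.plants[~result.plants["alive"]]
        assert len(dead) > 0

    def test_pure_stand_yields_single_species(self, small_config):
        design = make_design(delta=0.5, pure=True)
        result = run_season(design, small_config)
        assert result.yields[2] > 0
        assert result.yields[1] == 0.0

    def test_environment_contrast(self):
        """Fertilised stands outyield unfertilised ones substantially."""
        config = SimConfig(rows=10, cols=10, season_length=250, harvest_days=(60, 120, 180))
        y = {}
        for env in ("0N", "N+"):
            y[env] = run_season(make_design(environment=env, cv=0.001), config).ytot
        assert y["N+"] > 1.5 * y["0N"]

    def test_harvest_days_validated(self):
        config = SimConfig(season_length=100, harvest_days=(60, 120))
        with pytest.raises(ValueError, match="season"):
            run_season(make_design(), config)


class TestEnvironment:
    def test_photoperiod_range_and_shortening(self):
        env = make_environment("N+", SimConfig())
        assert 8.0 < env.photoperiod.min() < 10.0
        assert 15.0 < env.photoperiod.max() < 16.5
        assert env.shortening.any() and (~env.shortening).any()

    def test_fertilisation_totals(self):
        config = SimConfig()
        nplus = make_environment("N+", config)
        zero = make_environment("0N", config)
        assert nplus.fert.sum() == pytest.approx(40.0)
        assert zero.fert.sum() == 0.0

    def test_unknown_treatment_rejected(self):
        with pytest.raises(ValueError, match="treatment"):
            make_environment("N++", SimConfig())


class TestLattice:
    def test_zone_is_moore_neighbourhood(self):
        lat = _Lattice(5, 5)
        assert lat.zone.shape == (25, 9)
        # the centre cell's zone covers itself and its 8 neighbours
        centre = 2 * 5 + 2
        expected = {
            ((2 + dr) % 5) * 5 + (2 + dc) % 5
            for dr in (-1, 0, 1)
            for dc in (-1, 0, 1)
        }
        assert set(lat.zone[centre]) == expected

    def test_root_cells_ordered_by_ring(self):
        lat = _Lattice(7, 7)
        assert lat.root_cells.shape == (49, 25)
        assert lat.root_cells[0, 0] == 0  # own cell first
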