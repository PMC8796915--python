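import dataclasses
import math

import numpy as np
import pytest

from bemispread.landscape import Landscape
from bemispread.raster_io import GridSpec, RasterLayer
from bemispread.simulator import (
    DispersalParams,
    SimulationConfig,
    derive_rates,
    growth_step,
    merge_scenarios,
    migration_step,
    run_simulation,
)

from conftest import homogeneous_landscape


class TestDeriveRates:
    def test_average_scenario_values(self):
        r = derive_rates(54.30, 0.177, 25.0)
        assert r.Rc0 == pytest.approx(54.30 * 0.177, abs=1e-12)
        assert r.g_gen == pytest.approx(math.log(54.30 * 0.177), abs=1e-12)
        assert r.r_day == pytest.approx(math.log(54.30 * 0.177) / 25.0, abs=1e-12)
        assert r.g_gen == pytest.approx(r.generation_days * r.r_day, abs=1e-12)

    def test_replacement_reproduction_warns(self):
        with pytest.warns(UserWarning, match="declines"):
            r = derive_rates(1.0 / 0.177, 0.177, 25.0)
        assert r.Rc0 == pytest.approx(1.0)
        assert r.g_gen == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("bad", [dict(R0=-1), dict(R0=2, survival=0), dict(R0=2, generation_days=0)])
    def test_contract_violations(self, bad):
        kwargs = dict(R0=2.0, survival=0.5, generation_days=25.0)
        kwargs.update(bad)
        with pytest.raises(ValueError):
            derive_rates(**kwargs)


class TestGrowthStep:
    def density(self, ls, value):
        return RasterLayer(ls.spec, np.full(ls.shape, float(value)))

    def test_zero_is_absorbing_and_K_is_equilibrium(self, arena_21):
        rates = derive_rates(54.30)
        for form in ("logistic-clamped", "beverton-holt"):
            zero = growth_step(self.density(arena_21, 0.0), rates, arena_21, form)
            assert np.all(zero.values == 0.0)
            at_k = growth_step(self.density(arena_21, 10_000.0), rates, arena_21, form)
            assert np.allclose(at_k.values, 10_000.0)

    def test_logistic_below_and_at_clamp(self):
        ls = homogeneous_landscape(1, 1, k=1000.0)
        rates = derive_rates(54.30)
        low = growth_step(self.density(ls, 10.0), rates, ls, "logistic-clamped")
        assert low.values[0, 0] == pytest.approx(10.0 * (1 + rates.g_gen * 0.99), abs=1e-9)
        high = growth_step(self.density(ls, 900.0), rates, ls, "logistic-clamped")
        assert high.values[0, 0] == 1000.0  # unclamped value ~1103.7

    def test_negative_density_rejected(self, arena_21):
        with pytest.raises(ValueError, match="negative"):
            growth_step(self.density(arena_21, -1.0), derive_rates(54.30), arena_21)


class TestMigrationStep:
    def test_interior_deme_default_split(self):
        ls = homogeneous_landscape(3, 3)
        N = np.zeros((3, 3))
        N[1, 1] = 100.0
        out = migration_step(RasterLayer(ls.spec, N), ls, DispersalParams())
        assert out.values[1, 1] == pytest.approx(94.0)
        assert out.values[1, 0] == pytest.approx(3.0)  # west gets half of 6
        assert out.values[0, 1] == pytest.approx(1.0)
        assert out.values[1, 2] == pytest.approx(1.0)
        assert out.values[2, 1] == pytest.approx(1.0)

    def test_blocked_west_renormalizes_remaining(self):
        ls = homogeneous_landscape(3, 3)
        ls.friction.values[1, 0] = 1.0
        N = np.zeros((3, 3))
        N[1, 1] = 100.0
        out = migration_step(RasterLayer(ls.spec, N), ls, DispersalParams())
        assert out.values[1, 0] == 0.0
        for r, c in [(0, 1), (1, 2), (2, 1)]:
            assert out.values[r, c] == pytest.approx(2.0)

    def test_no_migration_identity(self, arena_21, rng):
        N = RasterLayer(arena_21.spec, rng.random(arena_21.shape) * 50)
        out = migration_step(N, arena_21, DispersalParams(m=0.0))
        assert np.allclose(out.values, N.values)

    def test_island_with_no_admissible_neighbors_keeps_emigrants(self):
        ls = homogeneous_landscape(3, 3)
        ls.friction.values[:] = 1.0
        ls.friction.values[1, 1] = 0.0
        N = np.zeros((3, 3))
        N[1, 1] = 80.0
        out = migration_step(RasterLayer(ls.spec, N), ls, DispersalParams())
        assert out.values[1, 1] == 80.0

    def test_deterministic_conservation_on_rough_landscape(self, rng):
        ls = homogeneous_landscape(30, 30)
        fric = rng.random((30, 30))
        fric[fric > 0.8] = 1.0
        ls.friction.values[:] = fric
        N = RasterLayer(ls.spec, rng.random((30, 30)) * 1e4)
        out = migration_step(N, ls, DispersalParams())
        assert abs(out.values.sum() - N.values.sum()) <= 1e-9 * N.values.sum()

    def test_stochastic_mode_conserves_and_reproduces(self, rng):
        ls = homogeneous_landscape(10, 10)
        N = RasterLayer(ls.spec, np.round(rng.random((10, 10)) * 500))
        params = DispersalParams(stochastic=True, seed=7)
        totals = []
        for rep in range(200):
            out = migration_step(N, ls, params, rng=np.random.default_rng(rep))
            totals.append(out.values.sum())
        # every replicate conserves the total exactly (integer moves)
        assert np.allclose(totals, N.values.sum())
        a = migration_step(N, ls, params, rng=np.random.default_rng(3)).values
        b = migration_step(N, ls, params, rng=np.random.default_rng(3)).values
        assert np.array_equal(a, b)


class TestRunSimulation:
    def test_single_deme_logistic_saturation(self):
        ls = homogeneous_landscape(1, 1, k=500.0)
        cfg = SimulationConfig(landscape=ls, rates=derive_rates(54.30),
                               origins=[(0, 0, 10.0)], n_generations=30)
        res = run_simulation(cfg)
        assert res.arrival.values[0, 0] == 0
        assert res.final.values[0, 0] == pytest.approx(500.0)
        assert sorted(res.snapshots) == [0, 5, 10, 15, 20, 25, 30]

    def test_isotropic_arrival_rotation_symmetric(self):
        ls = homogeneous_landscape(21, 21)
        cfg = SimulationConfig(landscape=ls, rates=derive_rates(54.30),
                               dispersal=DispersalParams.isotropic(),
                               origins=[(10, 10, 100.0)], n_generations=12)
        arr = run_simulation(cfg).arrival
        filled = np.where(arr.mask, -1, arr.values)
        for k in (1, 2, 3):
            assert np.array_equal(filled, np.rot90(filled, k))

    def test_densities_bounded_by_K_throughout(self):
        ls = homogeneous_landscape(15, 15, k=1000.0)
        ls.friction.values[7, :8] = 1.0  # partial wall to stress renormalization
        cfg = SimulationConfig(landscape=ls, rates=derive_rates(158.24),
                               origins=[(3, 3, 100.0)], n_generations=30, snapshot_every=1)
        res = run_simulation(cfg)
        for layer in res.snapshots.values():
            assert layer.values.min() >= 0.0
            assert layer.values.max() <= 1000.0 + 1e-9

    def test_friction_wall_splits_lattice(self):
        ls = homogeneous_landscape(15, 15)
        ls.friction.values[7, :] = 1.0
        cfg = SimulationConfig(landscape=ls, rates=derive_rates(158.24),
                               origins=[(2, 7, 100.0)], n_generations=30)
        res = run_simulation(cfg)
        assert np.all(res.snapshots[30].values[8:, :] == 0.0)
        assert np.all(res.arrival.mask[8:, :])

    def test_origin_on_blocked_deme_rejected(self):
        ls = homogeneous_landscape(5, 5)
        ls.friction.values[2, 2] = 1.0
        cfg_kwargs = dict(landscape=ls, rates=derive_rates(54.30), n_generations=5)
        with pytest.raises(ValueError, match="blocked"):
            run_simulation(SimulationConfig(origins=[(2, 2, 10.0)], **cfg_kwargs))
        with pytest.raises(ValueError, match="out of bounds"):
            run_simulation(SimulationConfig(origins=[(9, 0, 10.0)], **cfg_kwargs))

    def test_scale_invariance_of_arrival_times(self):
        base = homogeneous_landscape(11, 11, k=1000.0)
        scaled = homogeneous_landscape(11, 11, k=10_000.0)
        rates = derive_rates(54.30)
        res_a = run_simulation(SimulationConfig(
            landscape=base, rates=rates, origins=[(5, 5, 50.0)],
            n_generations=15, colonized_threshold=1.0))
        res_b = run_simulation(SimulationConfig(
            landscape=scaled, rates=rates, origins=[(5, 5, 500.0)],
            n_generations=15, colonized_threshold=10.0))
        assert np.array_equal(res_a.arrival.mask, res_b.arrival.mask)
        ok = ~res_a.arrival.mask
        assert np.array_equal(res_a.arrival.values[ok], res_b.arrival.values[ok])
        assert np.allclose(res_b.final.values, 10.0 * res_a.final.values, rtol=1e-9)


class TestMergeScenarios:
    def test_merge_is_idempotent_union_and_dominates_inputs(self):
        ls = homogeneous_landscape(9, 9)
        rates = derive_rates(54.30)
        runs = [
            run_simulation(SimulationConfig(landscape=ls, rates=rates,
                                            origins=[(4, c, 100.0)], n_generations=6))
            for c in (1, 7)
        ]
        merged = merge_scenarios(runs)
        same = merge_scenarios([runs[0], runs[0]])
        rel0 = runs[0].final.values / ls.K.values
        assert np.allclose(same.values, rel0)
        for run in runs:
            assert np.all(merged.values >= run.final.values / ls.K.values - 1e-12)
        assert merged.values.max() <= 1.0 + 1e-12
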