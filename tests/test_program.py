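"""Discovery/improvement orchestration and the factorial grid runner."""

from __future__ import annotations


import numpy as np
import pandas as pd
import pytest

from prebreedsim.program import (
    APPROACHES,
    STAGES,
    Scenario,
    SimSettings,
    full_grid,
    run_discovery,
    run_grid,
    run_improvement,
)
from tests.conftest import TINY_SETTINGS


def _scenario(**kw):
    base = dict(
        approach="Landrace",
        Ne=500,
        F=0.3,
        h2=0.5,
        platform="GBS10x@10K",
        seeds_per_landrace=1,
        n_selected_landraces=20,
        tested_seeds_per_landrace=10,
        n_synthetic_phenotypes=0,
    )
    base.update(kw)
    return Scenario(**base)


TINY = TINY_SETTINGS


def test_full_grid_enumerates_3456_scenarios():
    grid = full_grid()
    assert len(grid) == 3456
    assert len({s.scenario_id for s in grid}) == 3456


def test_scenario_validation_fails_fast():
    with pytest.raises(ValueError, match="unknown approach"):
        _scenario(approach="Elite")
    with pytest.raises(ValueError, match="pool_size"):
        TINY.validate_scenario(_scenario(tested_seeds_per_landrace=40))
    with pytest.raises(ValueError, match="more selected landraces"):
        TINY.validate_scenario(_scenario(n_selected_landraces=500))


@pytest.fixture(scope="module")
def tiny_discovery(tiny_world):
    world = tiny_world
    sc = _scenario(seeds_per_landrace=3)
    rng = np.random.default_rng(77)
    units, eq, records, ctx = run_discovery(sc, world, rng)
    return sc, world, units, eq, records, ctx


def test_discovery_training_population_size(tiny_discovery):
    sc, world, units, eq, records, ctx = tiny_discovery
    # 40 accessions x 3 seeds -> 120 training testcrosses; the ridge columns
    # match the platform's marker panel
    assert eq.effects.size == world.settings.platform(sc.platform).n_markers
    assert len(units) == world.settings.n_final_selected


def test_discovery_selected_units_come_from_distinct_accessions(tiny_world):
    sc = _scenario(approach="Landrace", tested_seeds_per_landrace=10)
    rng = np.random.default_rng(5)
    units, _, _, _ = run_discovery(sc, tiny_world, rng)
    # distinct accessions -> units are 10 distinct member objects with
    # pairwise-different origin signatures at chromosome 0
    ids = {id(u) for u in units}
    assert len(ids) == 10


def test_discovery_stage_records_cover_T_A_S(tiny_discovery):
    _, _, _, _, records, _ = tiny_discovery
    assert [r.stage for r in records] == ["T", "A", "S"]
    for r in records:
        assert np.isfinite(r.merit)
        assert 0.0 <= r.kinship_with_elite <= 1.0
        assert 0.0 <= r.heterozygosity <= 1.0


def test_dh_approach_units_are_homozygous(tiny_world):
    sc = _scenario(approach="LandraceDH")
    units, _, _, _ = run_discovery(sc, tiny_world, np.random.default_rng(8))
    assert all(u.heterozygosity() == 0.0 for u in units)


def test_landrace_elite_units_carry_half_elite_genome(tiny_world):
    from prebreedsim.metrics import segment_kinship

    sc = _scenario(approach="LandraceElite")
    units, _, records, _ = run_discovery(sc, tiny_world, np.random.default_rng(9))
    k = segment_kinship(units, tiny_world.elite.elite_hybrid, tiny_world.gmap)
    assert k == pytest.approx(0.25, abs=0.04)


def test_merit_at_seed_selection_grows_with_tested_seeds(tiny_world):
    """Testing more seeds per selected accession raises selection intensity,
    so stage-S merit is higher on average."""
    merits = {}
    for tested in (3, 10):
        vals = []
        for seed in range(6):
            sc = _scenario(tested_seeds_per_landrace=tested)
            _, _, records, _ = run_discovery(
                sc, tiny_world, np.random.default_rng(500 + seed)
            )
            vals.append(records[2].merit)
        merits[tested] = np.mean(vals)
    assert merits[10] > merits[3]


class TestImprovement:
    def _run(self, tiny_world, n_synth, trace=None, seed=31):
        sc = _scenario(n_synthetic_phenotypes=n_synth)
        rng = np.random.default_rng(seed)
        units, eq, _, ctx = run_discovery(sc, tiny_world, rng)
        recs = run_improvement(
            sc, units, eq, tiny_world, rng, ctx["sigma2_e"],
            ctx["platform"], ctx["panel_idx"], equation_trace=trace,
        )
        return recs

    def test_four_cycles_recorded(self, tiny_world):
        recs = self._run(tiny_world, 0)
        assert [r.stage for r in recs] == ["C1", "C2", "C3", "C4"]

    def test_without_retraining_discovery_equation_persists(self, tiny_world):
        trace: list = []
        self._run(tiny_world, 0, trace)
        assert trace == ["discovery"] * 4

    def test_retrained_equation_lags_one_cycle(self, tiny_world):
        trace: list = []
        self._run(tiny_world, 20, trace)
        assert trace == ["discovery", "cycle1", "cycle2", "cycle3"]

    def test_wrong_starting_count_fails(self, tiny_world):
        sc = _scenario()
        rng = np.random.default_rng(3)
        units, eq, _, ctx = run_discovery(sc, tiny_world, rng)
        with pytest.raises(ValueError, match="exactly"):
            run_improvement(sc, units[:5], eq, tiny_world, rng, ctx["sigma2_e"])


@pytest.fixture(scope="module")
def small_grid():
    scens = [
        _scenario(approach=a, n_synthetic_phenotypes=n)
        for a in ("Landrace", "LandraceElite")
        for n in (0, 20)
    ]
    return run_grid(scens, n_replicates=2, master_seed=99, settings=TINY)


class TestRunGrid:
    def test_rows_are_stages_by_replicates(self, small_grid):
        # 4 scenarios x 2 replicates x 7 stages
        assert len(small_grid) == 4 * 2 * 7
        assert set(small_grid["stage"]) == set(STAGES)
        counts = small_grid.groupby(["scenario_id", "replicate"]).size()
        assert (counts == 7).all()

    def test_rerun_reproduces_table_exactly(self, small_grid):
        scens = [
            _scenario(approach=a, n_synthetic_phenotypes=n)
            for a in ("Landrace", "LandraceElite")
            for n in (0, 20)
        ]
        again = run_grid(scens, n_replicates=2, master_seed=99, settings=TINY)
        pd.testing.assert_frame_equal(small_grid, again)

    def test_records_do_not_depend_on_other_scenarios_in_grid(self, small_grid):
        solo = run_grid(
            [_scenario(approach="Landrace", n_synthetic_phenotypes=20)],
            n_replicates=2,
            master_seed=99,
            settings=TINY,
        )
        merged = small_grid[
            small_grid.scenario_id.isin(solo.scenario_id.unique())
        ].reset_index(drop=True)
        pd.testing.assert_frame_equal(merged, solo)

    def test_duplicate_scenarios_rejected(self):
        sc = _scenario()
        with pytest.raises(ValueError, match="duplicate"):
            run_grid([sc, sc], n_replicates=1, master_seed=1, settings=TINY)
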