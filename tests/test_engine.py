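import math

import numpy as np
import pytest

import crossfeed as cf
from crossfeed.config import SimulationConfig, clone, default_panel
from crossfeed.engine import (
    SimulationOverflowError,
    StrainTable,
    attempt_divisions,
    death_step,
    place_daughter,
    uptake_window,
)
from crossfeed.lattice import CellLattice

SHAPE = (24, 24, 9)


def make_lattice():
    return CellLattice(SHAPE, strain_ids=["R", "G", "C"])


def table(advantage=0.0):
    return StrainTable.from_specs(list(default_panel(advantage, 0.0)))


def config(**kw):
    kw.setdefault("domain_um", (120.0, 120.0))
    kw.setdefault("community_height_um", 45.0)
    return SimulationConfig(**kw)


class TestUptakeWindow:
    def test_half_saturation(self):
        K = 1e-6
        got = uptake_window(vm=1.0, K=K, quota=10.0, store=0.0,
                            concentration=K, tu_hr=0.5)
        assert got == pytest.approx(0.25)  # vm/2 for half a time unit

    def test_zero_concentration(self):
        assert uptake_window(1.0, 1e-6, 10.0, 0.0, 0.0, 1.0) == 0.0

    def test_full_store_stops_consuming(self):
        assert uptake_window(1.0, 1e-6, 2.0, 2.0, 1.0, 1.0) == 0.0

    def test_clamped_to_remaining_quota_and_share(self):
        got = uptake_window(100.0, 1e-6, 2.0, 1.5, 1.0, 1.0, available=0.2)
        assert got == pytest.approx(0.2)


class TestPlaceDaughter:
    def test_adjacent_empty_site_no_push(self):
        lat = make_lattice()
        lat.add_cell((5, 5, 0), 0)
        rng = np.random.default_rng(0)
        ev = place_daughter(lat, (5, 5, 0), rng, config())
        assert not ev.vertical
        assert ev.pushed == []
        dx = abs(ev.daughter[0] - 5)
        dy = abs(ev.daughter[1] - 5)
        assert max(dx, dy) == 1 and ev.daughter[2] == 0

    def test_push_chain_along_shortest_path(self):
        lat = make_lattice()
        # a full 5x5 plug around the mother except one open row eastwards
        for dx in range(-2, 3):
            for dy in range(-2, 3):
                lat.add_cell((10 + dx, 10 + dy, 0), 0)
        rng = np.random.default_rng(1)
        n_before = lat.n_cells
        ev = place_daughter(lat, (10, 10, 0), rng, config())
        assert not ev.vertical
        # every cell still occupies a unique site
        occ = lat.grid >= 0
        assert occ.sum() == n_before
        assert lat.check_support()

    def test_enclosed_mother_buds_vertically(self):
        lat = make_lattice()
        # fill the whole bottom layer: no lateral empty site within radius 5
        for x in range(SHAPE[0]):
            for y in range(SHAPE[1]):
                lat.add_cell((x, y, 0), 0)
        rng = np.random.default_rng(2)
        ev = place_daughter(lat, (10, 10, 0), rng, config())
        assert ev.vertical
        # either directly above the mother (p=0.7 branch) or at a displaced
        # neighbor's site with its column pushed up (p=0.3 branch)
        assert ev.daughter[2] == 1 or (ev.daughter[2] == 0 and ev.pushed)

    def test_enclosed_vertical_split_statistics(self):
        ups = 0
        rng = np.random.default_rng(7)
        for _ in range(2000):
            lat = CellLattice((14, 14, 4), strain_ids=["R"])
            for x in range(14):
                for y in range(14):
                    lat.add_cell((x, y, 0), 0)
            ev = place_daughter(lat, (7, 7, 0), rng, config())
            if ev.daughter == (7, 7, 1):
                ups += 1
        assert abs(ups / 2000 - 0.7) < 0.03

    def test_equidistant_targets_chosen_uniformly(self):
        # mother with exactly two empty lateral neighbors, E and W
        rng = np.random.default_rng(3)
        picks = {(+1): 0, (-1): 0}
        for _ in range(10_000):
            lat = make_lattice()
            lat.add_cell((5, 5, 0), 0)
            for dx, dy in [(-1, -1), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 1)]:
                lat.add_cell((5 + dx, 5 + dy, 0), 0)
            ev = place_daughter(lat, (5, 5, 0), rng, config())
            picks[ev.daughter[0] - 5] += 1
        frac = picks[+1] / 10_000
        assert abs(frac - 0.5) < 0.02

    def test_ceiling_overflow_raises(self):
        lat = CellLattice((12, 12, 2), strain_ids=["R"])
        for x in range(12):
            for y in range(12):
                for z in range(2):
                    lat.add_cell((x, y, z), 0)
        rng = np.random.default_rng(0)
        with pytest.raises(SimulationOverflowError):
            place_daughter(lat, (6, 6, 0), rng, config())


class TestDivisions:
    def _ready_lattice(self, positions):
        lat = make_lattice()
        t = table()
        for pos in positions:
            i = lat.add_cell(pos, 0)
            lat._a.store_req[i] = t.alpha[0]
            lat._a.store_glu[i] = t.alpha_glu[0]
        return lat, t

    def test_no_cell_at_quota_no_events(self):
        lat = make_lattice()
        lat.add_cell((3, 3, 0), 0)
        events = attempt_divisions(lat, table(), np.random.default_rng(0), config())
        assert events == []
        assert lat.n_cells == 1

    def test_both_ready_cells_divide_once(self):
        lat, t = self._ready_lattice([(3, 3, 0), (9, 9, 0)])
        events = attempt_divisions(lat, t, np.random.default_rng(0), config())
        assert len(events) == 2
        assert lat.n_cells == 4
        # mothers' stores reset by one quota, daughters start empty
        assert np.all(lat.store_req[:2] == 0.0)
        assert np.all(lat.store_req[2:] == 0.0)

    def test_ledger_and_unique_sites(self):
        rng = np.random.default_rng(5)
        lat, t = self._ready_lattice(
            [(x, y, 0) for x in range(4, 10) for y in range(4, 10)]
        )
        initial = lat.n_cells
        events = attempt_divisions(lat, t, rng, config())
        assert lat.n_cells == initial + len(events)
        occ = lat.grid[lat.grid >= 0]
        assert len(np.unique(occ)) == lat.n_cells  # no overwrites
        assert lat.check_support()


class TestDeath:
    def test_zero_rate_no_deaths(self):
        strains = [clone(s, death_rate=0.0) for s in default_panel()]
        t = StrainTable.from_specs(strains)
        lat = make_lattice()
        for k in range(50):
            lat.add_cell((k % 20, k // 20, 0), k % 3)
        idx, _ = death_step(lat, t, 0.1, np.random.default_rng(0))
        assert idx.size == 0

    def test_binomial_death_counts(self):
        # p = 0.01 over 1e4 cells: mean 100, sd ~10
        strains = [clone(s, death_rate=0.1) for s in default_panel()]
        t = StrainTable.from_specs(strains)
        counts = []
        for seed in range(5):
            lat = CellLattice((40, 40, 8), strain_ids=["R", "G", "C"])
            k = 0
            for x in range(40):
                for y in range(40):
                    for z in range(7):
                        if k >= 10_000:
                            break
                        lat.add_cell((x, y, z), 0)
                        k += 1
            idx, _ = death_step(lat, t, 0.1, np.random.default_rng(seed))
            counts.append(idx.size)
        assert abs(np.mean(counts) - 100) < 30

    def test_only_on_death_releasers_release(self):
        t = table()
        lat = make_lattice()
        lat.add_cell((0, 0, 0), 0)  # cooperator: continuous releaser
        lat.add_cell((3, 0, 0), 2)  # cheater: no release
        lat.add_cell((6, 0, 0), 1)  # partner: releases on death
        strains = [clone(s, death_rate=5.0) for s in default_panel()]
        t = StrainTable.from_specs(strains)
        shape = (3, 8, 8, 3)
        idx, rel = death_step(lat, t, 0.2, np.random.default_rng(0),
                              release_shape=shape)
        assert idx.size == 3  # p = 1: all die
        assert rel[1].sum() == 0.0  # nobody releases adenine on death
        assert rel[0].sum() == pytest.approx(t.beta_eff[1])  # G's lysine only

    def test_invalid_probability_rejected(self):
        strains = [clone(s, death_rate=20.0) for s in default_panel()]
        t = StrainTable.from_specs(strains)
        lat = make_lattice()
        lat.add_cell((0, 0, 0), 0)
        with pytest.raises(Exception):
            death_step(lat, t, 0.1, np.random.default_rng(0))


def test_growth_rate_matches_r_max():
    """With death off and nutrients abundant, the population's log2
    growth rate approaches the configured maximum growth rate."""
    from crossfeed.config import MediumSpec
    from crossfeed.protocols import Protocol, run_liquid

    strains = [clone(s, death_rate=0.0) for s in default_panel(0.0, 0.0)]
    med = MediumSpec(supplemented_lysine=1e-3, supplemented_adenine=1e-3)
    sim = SimulationConfig(target_generations=4.0, max_hours=40.0, rng_seed=1)
    proto = Protocol(environment="liquid", liquid_n0=2000, liquid_mode="agents")
    traj = run_liquid(strains, med, sim, proto)
    s = traj.series
    # slope of generations vs time after the first division wave
    sel = s[s.generations > 0.8]
    slope = np.polyfit(sel.time_hr, sel.generations, 1)[0]  # doublings/hr
    r_max = strains[0].r_max
    assert abs(slope * math.log(2) - r_max) / r_max < 0.05
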