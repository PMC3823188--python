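import math

import numpy as np
import pytest

import crossfeed as cf
from crossfeed.config import InvalidSpecError, MediumSpec, SimulationConfig, clone
from crossfeed.engine import StrainTable
from crossfeed.fields import FieldState
from crossfeed.metrics import association_index
from crossfeed.protocols import (
    Protocol,
    init_periodic_lattice,
    init_random_lawn,
    init_spot,
    init_stripes,
    make_lattice,
    mix_community,
    run_liquid,
    run_spatial,
)


def cfg(**kw):
    kw.setdefault("domain_um", (180.0, 180.0))
    kw.setdefault("community_height_um", 90.0)
    return SimulationConfig(**kw)


@pytest.fixture
def panel():
    return list(cf.default_panel(0.02, 0.0))


class TestRandomLawn:
    def test_density_and_per_strain_counts(self, panel):
        lat = make_lattice(cfg(domain_um=(600.0, 600.0)), "RGC")
        rng = np.random.default_rng(0)
        init_random_lawn(lat, 3000.0, (1 / 3, 1 / 3, 1 / 3), rng)
        assert lat.n_cells == round(3000 * 0.36)
        counts = lat.counts()
        assert counts.sum() == lat.n_cells
        assert counts.max() - counts.min() <= 1  # exact 1:1:1 split
        assert (lat.pos[:, 2] == 0).all()

    def test_single_strain_ratio(self, panel):
        lat = make_lattice(cfg(), "RGC")
        init_random_lawn(lat, 2000.0, (1.0, 0.0, 0.0), np.random.default_rng(1))
        assert set(lat.strain) == {0}

    def test_determinism(self):
        a = make_lattice(cfg(), "RGC")
        b = make_lattice(cfg(), "RGC")
        init_random_lawn(a, 3000.0, (0.5, 0.25, 0.25), np.random.default_rng(9))
        init_random_lawn(b, 3000.0, (0.5, 0.25, 0.25), np.random.default_rng(9))
        assert np.array_equal(a.labels(), b.labels())

    def test_over_capacity_directs_to_spot(self):
        lat = make_lattice(cfg(), "RGC")
        with pytest.raises(InvalidSpecError, match="spot"):
            init_random_lawn(lat, 80_000.0, (1 / 3, 1 / 3, 1 / 3),
                             np.random.default_rng(0))


class TestPeriodicLattice:
    def test_equal_partner_access_and_unit_index(self):
        lat = make_lattice(cfg(domain_um=(360.0, 360.0)), "RGC")
        init_periodic_lattice(lat, (9, 3))
        lab = lat.labels()
        res = association_index(lab, 0, 2, 1, mode="full26")
        assert res.index == pytest.approx(1.0)
        assert res.mean_partner_a == res.mean_partner_b == 1.0
        # every cooperator and every cheater has exactly one partner
        # neighbor; strains are at 1:1:1
        counts = lat.counts()
        assert counts[0] == counts[1] == counts[2]

    def test_density_matches_motif_arithmetic(self):
        lat = make_lattice(cfg(domain_um=(360.0, 360.0)), "RGC")
        init_periodic_lattice(lat, (9, 3))
        area_mm2 = 0.36 * 0.36
        density = lat.n_cells / area_mm2
        motif_density = 3 / (27 * 25e-6)  # 3 cells per 9x3 sites of (5 um)^2
        assert density == pytest.approx(motif_density, rel=1e-9)
        assert density == pytest.approx(4444.4, rel=0.01)

    def test_indivisible_domain_rejected(self):
        lat = make_lattice(cfg(domain_um=(300.0, 300.0)), "RGC")
        with pytest.raises(InvalidSpecError):
            init_periodic_lattice(lat, (9, 7))


class TestStripes:
    def test_layout(self):
        lat = make_lattice(cfg(), "RGC")
        init_stripes(lat, 6, order=(0, 1, 2))
        lab = lat.labels()[:, :, 0]
        nx = lab.shape[0]
        x0 = (nx - 18) // 2
        assert (lab[x0 + 6 : x0 + 12] == 2).all()  # partner center
        assert (lab[x0 : x0 + 6] == 1).all()
        assert (lab[x0 + 12 : x0 + 18] == 3).all()
        assert (lab[: x0] == 0).all()
        # stripe widths exact: count occupied columns per strain
        assert (lab == 1).sum() == 6 * lab.shape[1]

    def test_order_argument_swaps_sides(self):
        lat = make_lattice(cfg(), "RGC")
        init_stripes(lat, 4, order=(2, 1, 0))
        lab = lat.labels()[:, :, 0]
        nx = lab.shape[0]
        x0 = (nx - 12) // 2
        assert (lab[x0 : x0 + 4] == 3).all()


class TestSpot:
    def test_layers_and_confinement(self):
        lat = make_lattice(cfg(domain_um=(360.0, 360.0), community_height_um=120.0), "RGC")
        rng = np.random.default_rng(0)
        init_spot(lat, 1e5, 150.0, (1 / 3, 1 / 3, 1 / 3), rng)
        foot = lat.inoculum_footprint
        h = lat.column_heights()
        assert (h[~foot] == 0).all()  # outside the disc: empty
        assert 2 <= h[foot].max() <= 3  # ~1e5 cells/mm^2 -> 2-3 layers
        assert lat.check_support()
        # multinomial-free exact thirds
        counts = lat.counts()
        assert counts.max() - counts.min() <= 1

    def test_count_matches_density(self):
        lat = make_lattice(cfg(domain_um=(360.0, 360.0), community_height_um=120.0), "RGC")
        init_spot(lat, 8e4, 150.0, (1 / 3, 1 / 3, 1 / 3), np.random.default_rng(1))
        expect = round(8e4 * math.pi * 0.075**2)
        assert lat.n_cells == expect


class TestMixing:
    def _grown_state(self, panel, seed=2):
        sim = cfg(rng_seed=seed, target_generations=1.5, max_hours=24.0)
        proto = Protocol(init="random_lawn", density=3000.0)
        traj = run_spatial(panel, MediumSpec.unsupplemented(), sim, proto)
        return traj.final_lattice, traj.final_fields

    def test_counts_and_fields_after_mix(self, panel):
        lat, fs = self._grown_state(panel)
        rng = np.random.default_rng(0)
        before = lat.counts(live_only=False).copy()
        occ = lat.occupancy() > 0
        pre_mean = fs.comm[0][occ].mean()
        pre_mass = fs.total_mass(0)
        glu_before = fs.comm[2].copy()
        mix_community(lat, fs, rng)
        assert np.array_equal(lat.counts(live_only=False), before)
        assert np.allclose(fs.comm[0][occ], pre_mean)
        assert fs.total_mass(0) == pytest.approx(pre_mass, rel=1e-12)
        assert np.array_equal(fs.comm[2], glu_before)  # glucose untouched
        assert lat.check_support()

    def test_association_near_one_after_mix(self, panel):
        vals = []
        for seed in range(4):
            lat, fs = self._grown_state(panel, seed=seed)
            mix_community(lat, fs, np.random.default_rng(seed))
            res = association_index(lat.labels(), 0, 2, 1)
            vals.append(res.index)
        assert abs(np.mean(vals) - 1.0) < 0.15


class TestRunSpatial:
    def test_seed_determinism_bitwise(self, panel):
        sim = cfg(rng_seed=42, target_generations=2.0, max_hours=24.0)
        proto = Protocol(init="random_lawn", density=3000.0)
        a = run_spatial(panel, MediumSpec.unsupplemented(), sim, proto)
        sim2 = cfg(rng_seed=42, target_generations=2.0, max_hours=24.0)
        b = run_spatial(panel, MediumSpec.unsupplemented(), sim2, proto)
        assert a.series.equals(b.series)
        assert all(
            np.array_equal(x[1], y[1]) for x, y in zip(a.snapshots, b.snapshots)
        )

    def test_generations_counter_non_decreasing_while_growing(self, panel):
        sim = cfg(rng_seed=1, target_generations=2.0, max_hours=24.0)
        proto = Protocol(init="random_lawn", density=3000.0)
        traj = run_spatial(panel, MediumSpec.supplemented(), sim, proto)
        g = traj.series.generations.to_numpy()
        assert traj.status in ("completed", "max_hours")
        live = traj.series[[c for c in traj.series if c.startswith("live_")]].sum(axis=1)
        growing = np.diff(live) >= 0
        assert np.all(np.diff(g)[growing] >= -1e-12)

    def test_extinction_is_terminal_status(self):
        # partners alone on unsupplemented medium: no adenine, certain death
        strains = [clone(s, death_rate=0.5 if s.id == "G" else s.death_rate)
                   for s in cf.default_panel()]
        sim = cfg(rng_seed=0, target_generations=6.0, max_hours=60.0)
        proto = Protocol(init="random_lawn", density=300.0, ratios=(0.0, 1.0, 0.0))
        traj = run_spatial(strains, MediumSpec.unsupplemented(), sim, proto)
        assert traj.status == "extinct"
        assert traj.series["live_G"].iloc[-1] == 0


class TestByproductMutualismGrid:
    def test_ratio_sweep_runs_or_reports_extinction(self, panel):
        """Zero-advantage producers/non-producers at 10:1, 1:1, 1:10 with
        the partner at one third: every configuration either grows or
        ends with a reported extinction, never an exception."""
        strains = list(cf.default_panel(0.0, 0.0))
        for rc in ((10, 1), (1, 1), (1, 10)):
            tot = 3 * (rc[0] + rc[1]) / 2
            ratios = (rc[0] / tot, 1 / 3, rc[1] / tot)
            sim = cfg(rng_seed=5, target_generations=3.0, max_hours=30.0)
            proto = Protocol(init="random_lawn", density=3000.0, ratios=ratios)
            traj = run_spatial(strains, MediumSpec.unsupplemented(), sim, proto)
            assert traj.status in ("completed", "extinct", "max_hours")


class TestRunLiquid:
    def test_expectation_zero_advantage_constant_ratio(self):
        strains = list(cf.default_panel(0.0, 0.0))
        med = MediumSpec(supplemented_lysine=1e-3, supplemented_adenine=1e-3)
        sim = SimulationConfig(target_generations=5.0, max_hours=40.0, rng_seed=0)
        proto = Protocol(environment="liquid", liquid_mode="expectation")
        traj = run_liquid(strains, med, sim, proto)
        r = traj.series.ratio.to_numpy()
        assert np.allclose(r, r[0], rtol=1e-9)

    def test_cheater_declines_cooperator_in_coch_liquid(self, panel):
        med = MediumSpec.unsupplemented()
        sim = SimulationConfig(target_generations=5.0, max_hours=80.0, rng_seed=2)
        proto = Protocol(environment="liquid", liquid_mode="expectation")
        traj = run_liquid(panel, med, sim, proto)
        r = traj.series.ratio.to_numpy()
        assert r[-1] < 1.0
        assert np.all(np.diff(r) <= 1e-12)  # monotone decline

    def test_programmed_advantage_slope_matches_closed_form(self):
        """With abundant lysine, a rate-multiplier advantage s makes the
        ratio fall by exactly 2^s per community generation; the
        expectation mode reproduces that slope."""
        s = 0.05
        strains = [clone(sp, death_rate=0.0) for sp in cf.default_panel(s, 0.0)]
        med = MediumSpec(supplemented_lysine=2e-3, supplemented_adenine=2e-3)
        sim = SimulationConfig(target_generations=7.0, max_hours=40.0, rng_seed=0)
        proto = Protocol(environment="liquid", liquid_mode="expectation")
        traj = run_liquid(strains, med, sim, proto)
        g = traj.series.generations.to_numpy()
        r = traj.series.ratio.to_numpy()
        sel = (g >= 1) & (g <= 6)
        slope = np.polyfit(g[sel], np.log(r[sel]), 1)[0]
        assert slope == pytest.approx(-s * math.log(2), rel=0.05)
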