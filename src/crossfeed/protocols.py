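"""Experiment drivers: initial cell distributions, spatial and liquid
growth, and periodic mixing.

Protocols reproduce the community setups: a random lawn of the three
strains on agarose, a symmetric periodic motif, three-stripe
initialization, a high-density inoculum spot (range expansion), the
periodically mixed community, and the well-mixed liquid coculture.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from . import fields as flds
from .config import MediumSpec, SimulationConfig, StrainSpec, InvalidSpecError
from .engine import StrainTable, attempt_divisions, death_step
from .fields import FieldState, LYS, ADE, GLU, _run_window, update_D
from .io import Trajectory
from .lattice import CellLattice
from .metrics import association_index, population_ratio

__all__ = [
    "Protocol",
    "make_lattice",
    "init_random_lawn",
    "init_periodic_lattice",
    "init_stripes",
    "init_spot",
    "mix_community",
    "run_spatial",
    "run_liquid",
]

_MONOLAYER_PER_MM2 = 1e6 / 25.0  # one 5 um cell per 25 um^2


@dataclass
class Protocol:
    """What to inoculate and how to run it."""

    init: str = "random_lawn"  # | periodic_lattice | stripes | spot
    density: float = 3000.0  # cells/mm^2
    ratios: tuple = (1 / 3, 1 / 3, 1 / 3)
    environment: str = "spatial"  # | "liquid"
    mixing_interval: float | None = None  # hr, spatial only
    spot_diameter_um: float = 150.0
    stripe_width_sites: int = 8
    stripe_order: tuple = (0, 1, 2)  # left, center, right strain indices
    lattice_spacing: tuple = (9, 3)  # periodic-motif tile, in sites
    liquid_n0: int = 2000
    liquid_density_per_ml: float = 5e6  # desk-scaled inoculation density
    liquid_mode: str = "agents"  # | "expectation"

    def __post_init__(self):
        if abs(sum(self.ratios) - 1.0) > 1e-9:
            raise InvalidSpecError("strain ratios must sum to 1")
        if self.density <= 0:
            raise InvalidSpecError("density must be positive")

    def to_dict(self):
        d = asdict(self)
        d["ratios"] = list(self.ratios)
        d["stripe_order"] = list(self.stripe_order)
        d["lattice_spacing"] = list(self.lattice_spacing)
        return d


def _roles(strains) -> tuple:
    """(cooperator, cheater, partner) indices: the partner requires
    adenine; the two lysine-requiring strains are focal, in panel order."""
    partner = next(i for i, s in enumerate(strains) if s.required_metabolite == "adenine")
    focal = [i for i, s in enumerate(strains) if i != partner]
    return focal[0], focal[1], partner


def make_lattice(config: SimulationConfig, strain_ids) -> CellLattice:
    b = int(config.community_grid // config.cell_pitch)
    shape = (
        int(config.domain_um[0] // config.cell_pitch),
        int(config.domain_um[1] // config.cell_pitch),
        int(config.community_height_um // config.cell_pitch),
    )
    return CellLattice(shape, sites_per_voxel=b, strain_ids=list(strain_ids))


def _domain_area_mm2(lattice: CellLattice, pitch=5.0) -> float:
    nx, ny, _ = lattice.shape
    return nx * ny * pitch**2 / 1e6


def _draw_strains(rng, n, ratios):
    """Strain labels hitting the requested ratios exactly (largest
    remainder), in random order; exact counts keep the initial focal
    ratio at its nominal value instead of multinomial-sampling it."""
    ratios = np.asarray(ratios, dtype=float)
    counts = np.floor(ratios * n).astype(int)
    rem = ratios * n - counts
    for k in np.argsort(-rem)[: n - counts.sum()]:
        counts[k] += 1
    labels = np.repeat(np.arange(len(ratios)), counts)
    return labels[rng.permutation(n)]


def assign_random_stores(lattice: CellLattice, table: StrainTable, rng) -> None:
    """Cells start from random initial storage of each required
    metabolite, uniform on [0, quota)."""
    n = lattice.n_cells
    s = lattice.strain
    lattice._a.store_req[:n] = rng.uniform(0.0, table.alpha[s])
    lattice._a.store_glu[:n] = rng.uniform(0.0, table.alpha_glu[s])


def init_random_lawn(lattice: CellLattice, density, ratios, rng) -> CellLattice:
    """Uniformly random monolayer lawn at the given density (cells/mm^2)."""
    if density > _MONOLAYER_PER_MM2:
        raise InvalidSpecError(
            f"density {density}/mm^2 exceeds monolayer capacity "
            f"({_MONOLAYER_PER_MM2:.0f}/mm^2); use the spot protocol for "
            "multi-layer inocula"
        )
    nx, ny, _ = lattice.shape
    n = round(density * _domain_area_mm2(lattice))
    sites = rng.choice(nx * ny, size=n, replace=False)
    kinds = _draw_strains(rng, n, ratios)
    for flat, k in zip(sites, kinds):
        lattice.add_cell((flat // ny, flat % ny, 0), int(k))
    return lattice


def init_periodic_lattice(lattice: CellLattice, spacing=(9, 3)) -> CellLattice:
    """Symmetric periodic motif: touching cooperator-partner-cheater
    triples tiled on a ``spacing`` grid of sites, so every cooperator
    and every cheater has exactly one partner neighbor (equal partner
    access; the initial association index is exactly 1).

    The default 9x3-site tile gives 3 cells per 675 um^2 = 4444
    cells/mm^2, the closest exactly-periodic density to 4400.
    """
    sx, sy = spacing
    nx, ny, _ = lattice.shape
    if nx % sx or ny % sy:
        raise InvalidSpecError(
            f"domain ({nx}x{ny} sites) is not divisible by the {sx}x{sy} motif"
        )
    if sx < 5:
        raise InvalidSpecError("motif tile must be at least 5 sites wide")
    for tx in range(nx // sx):
        for ty in range(ny // sy):
            x0, y0 = tx * sx, ty * sy
            lattice.add_cell((x0, y0, 0), 0)  # cooperator
            lattice.add_cell((x0 + 1, y0, 0), 1)  # partner
            lattice.add_cell((x0 + 2, y0, 0), 2)  # cheater
    return lattice


def init_stripes(lattice: CellLattice, stripe_width, order=(0, 1, 2)) -> CellLattice:
    """Three adjacent monolayer stripes: the center strain flanked by the
    other two (partner centered by default: order (R, G, C))."""
    nx, ny, _ = lattice.shape
    w = int(stripe_width)
    if 3 * w > nx:
        raise InvalidSpecError("three stripes do not fit the domain")
    x0 = (nx - 3 * w) // 2
    for band, strain in enumerate(order):
        for x in range(x0 + band * w, x0 + (band + 1) * w):
            for y in range(ny):
                lattice.add_cell((x, y, 0), int(strain))
    return lattice


def init_spot(lattice: CellLattice, density, diameter_um, ratios, rng,
              pitch=5.0) -> CellLattice:
    """High-density inoculum confined to a central disc; densities above
    monolayer capacity stack into additional complete layers with a
    random partial top layer.  Returns the lattice; the footprint mask
    is available as ``lattice.inoculum_footprint``."""
    nx, ny, nz = lattice.shape
    r_um = diameter_um / 2.0
    cx, cy = nx * pitch / 2.0, ny * pitch / 2.0
    xs = (np.arange(nx) + 0.5) * pitch
    ys = (np.arange(ny) + 0.5) * pitch
    foot = (xs[:, None] - cx) ** 2 + (ys[None, :] - cy) ** 2 <= r_um**2
    disc = np.argwhere(foot)
    n_disc = len(disc)
    area_mm2 = math.pi * (r_um / 1000.0) ** 2
    n = round(density * area_mm2)
    if n > n_disc * nz:
        raise InvalidSpecError("spot density exceeds domain capacity")
    kinds = _draw_strains(rng, n, ratios)
    placed = 0
    z = 0
    while placed < n:
        take = min(n_disc, n - placed)
        rows = disc if take == n_disc else disc[rng.choice(n_disc, take, replace=False)]
        for x, y in rows:
            lattice.add_cell((int(x), int(y), z), int(kinds[placed]))
            placed += 1
        z += 1
    lattice.inoculum_footprint = foot
    return lattice


def mix_community(lattice: CellLattice, field_state: FieldState, rng,
                  include_agarose: bool = False) -> None:
    """Complete randomization: the multiset of cells is permuted over the
    currently occupied sites, and the adenine and lysine concentrations
    in occupied community voxels are set to their pre-mix mean (glucose
    and the ledgers are untouched)."""
    n = lattice.n_cells
    if n:
        sites = lattice.pos.copy()
        perm = rng.permutation(n)
        new_pos = sites[perm]
        lattice.grid[:] = -1
        lattice._a.pos[:n] = new_pos
        lattice.grid[new_pos[:, 0], new_pos[:, 1], new_pos[:, 2]] = np.arange(
            n, dtype=np.int32
        )
    occ = lattice.occupancy() > 0
    for f in (LYS, ADE):
        if include_agarose:
            total = field_state.total_mass(f)
            vol = field_state.comm[f].size * field_state.Vc + \
                field_state.agar[f].size * field_state.Va
            field_state.comm[f] = total / vol
            field_state.agar[f] = total / vol
        elif occ.any():
            field_state.comm[f][occ] = field_state.comm[f][occ].mean()


def _init_lattice(strains, config, protocol, rng) -> CellLattice:
    lattice = make_lattice(config, [s.id for s in strains])
    if protocol.init == "random_lawn":
        init_random_lawn(lattice, protocol.density, protocol.ratios, rng)
    elif protocol.init == "periodic_lattice":
        init_periodic_lattice(lattice, protocol.lattice_spacing)
    elif protocol.init == "stripes":
        init_stripes(lattice, protocol.stripe_width_sites, protocol.stripe_order)
    elif protocol.init == "spot":
        init_spot(lattice, protocol.density, protocol.spot_diameter_um,
                  protocol.ratios, rng)
    else:
        raise InvalidSpecError(f"unknown init kind {protocol.init!r}")
    return lattice


def _provenance(strains, medium, config, protocol, extra=None):
    from dataclasses import asdict as dc_asdict

    doc = {
        "strains": [dc_asdict(s) for s in strains],
        "medium": dc_asdict(medium),
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in dc_asdict(config).items()},
        "protocol": protocol.to_dict(),
        "seed": config.rng_seed,
    }
    if extra:
        doc.update(extra)
    return doc


def _continuous_release_map(lattice, table, tu_hr, shape):
    """Per-voxel source mass per t_u from live continuously releasing
    cells (gamma_A x d x excess factor)."""
    rel = np.zeros(shape)
    gam = table.gamma_eff[lattice.strain]
    sel = lattice.alive & (gam > 0)
    if np.any(sel):
        idx = np.flatnonzero(sel)
        vox = lattice.voxel_index(lattice.pos[idx])
        rel_f = table.rel_field[lattice.strain[idx]]
        for f in range(3):
            fsel = rel_f == f
            if np.any(fsel):
                flat = np.bincount(vox[fsel], weights=gam[idx[fsel]] * tu_hr,
                                   minlength=rel[f].size)
                rel[f] += flat.reshape(rel[f].shape)
    return rel


def run_spatial(strains, medium: MediumSpec, config: SimulationConfig,
                protocol: Protocol) -> Trajectory:
    """Grow a spatial community: per τ window, diffusion/uptake/release
    over the window's t_u steps, then stochastic death, divisions with
    rearrangement, and a diffusivity update; mixing on schedule.

    Stops at the target generation count, the wall-clock cap, or
    community extinction (a terminal status, not an exception).
    """
    rng = np.random.default_rng(config.rng_seed)
    table = StrainTable.from_specs(strains, config.excess_release_factor)
    lattice = _init_lattice(strains, config, protocol, rng)
    assign_random_stores(lattice, table, rng)
    field_state = FieldState(config, medium)
    update_D(field_state, lattice)
    roles = _roles(strains)
    a, b, p = roles
    initial_live = lattice.live_total()
    if initial_live == 0:
        raise InvalidSpecError("no cells were inoculated")

    tu_s = config.diffusion_timestep_tu
    tau_hr = config.tau_hours
    n_tu = config.steps_per_tau
    mix_every = protocol.mixing_interval or config.mixing_interval
    next_mix = mix_every if mix_every else math.inf
    next_snap = config.snapshot_every_generation

    pending = np.zeros_like(field_state.comm)
    rows = []
    snapshots = [(0.0, lattice.labels())]
    t = 0.0
    status = "max_hours"

    def record(t):
        counts = lattice.counts(live_only=True)
        dead = lattice.counts(live_only=False) - counts
        live = int(counts.sum())
        gens = math.log2(live / initial_live) if live else -math.inf
        res = association_index(lattice.labels(), a, b, p, mode="full26")
        row = {
            "time_hr": t,
            "generations": gens,
            "ratio": population_ratio(counts, a, b),
            "association_3d": res.index,
        }
        for i, sid in enumerate(table.ids):
            row[f"live_{sid}"] = int(counts[i])
            row[f"dead_{sid}"] = int(dead[i])
        for f, name in enumerate(flds.FIELD_NAMES):
            row[f"mass_{name}"] = field_state.total_mass(f)
            row[f"released_{name}"] = field_state.released[f]
            row[f"consumed_{name}"] = field_state.consumed[f]
        rows.append(row)
        return live, gens

    record(0.0)
    while t < config.max_hours - 1e-9:
        release = pending / n_tu + _continuous_release_map(
            lattice, table, config.tu_hours, field_state.comm.shape
        )
        _run_window(field_state, lattice, table, tu_s, n_tu, release,
                    instant=config.instant_distribution)
        t += tau_hr
        _, pending = death_step(lattice, table, tau_hr, rng,
                                release_shape=field_state.comm.shape)
        attempt_divisions(lattice, table, rng, config)
        update_D(field_state, lattice)
        live, gens = record(t)
        if live == 0:
            status = "extinct"
            break
        if t >= next_mix - 1e-9:
            mix_community(lattice, field_state, rng)
            next_mix += mix_every
            snapshots.append((t, lattice.labels()))
        if gens >= next_snap:
            snapshots.append((t, lattice.labels()))
            next_snap += config.snapshot_every_generation
        if config.target_generations is not None and gens >= config.target_generations:
            status = "completed"
            break
    if snapshots[-1][0] != t:
        snapshots.append((t, lattice.labels()))

    extras = {}
    if hasattr(lattice, "inoculum_footprint"):
        extras["inoculum_footprint"] = lattice.inoculum_footprint
    traj = Trajectory(
        series=pd.DataFrame(rows),
        snapshots=snapshots,
        provenance=_provenance(strains, medium, config, protocol),
        strain_ids=list(table.ids),
        roles=roles,
        status=status,
        extras=extras,
    )
    traj.final_lattice = lattice
    traj.final_fields = field_state
    return traj


# ---------------------------------------------------------------------------
# Well-mixed liquid coculture
# ---------------------------------------------------------------------------


def run_liquid(strains, medium: MediumSpec, config: SimulationConfig,
               protocol: Protocol) -> Trajectory:
    """Well-mixed liquid coculture with the same uptake/quota/division/
    death/release rules but spatially uniform concentrations.

    ``protocol.liquid_mode`` selects the stochastic agent mode (default,
    matching the spatial engine) or the deterministic expectation mode
    (continuous populations, closed-form-friendly).
    """
    if protocol.liquid_mode == "agents":
        return _run_liquid_agents(strains, medium, config, protocol)
    if protocol.liquid_mode == "expectation":
        return _run_liquid_expectation(strains, medium, config, protocol)
    raise InvalidSpecError(f"unknown liquid mode {protocol.liquid_mode!r}")


def _liquid_setup(strains, medium, config, protocol):
    table = StrainTable.from_specs(strains, config.excess_release_factor)
    n0 = int(protocol.liquid_n0)
    volume_um3 = n0 / (protocol.liquid_density_per_ml / 1e12)  # 1 ml = 1e12 um^3
    conc = np.array([
        medium.supplemented_lysine, medium.supplemented_adenine,
        medium.initial_glucose,
    ])
    return table, n0, volume_um3, conc


def _liquid_record(rows, t, counts, initial_live, a, b):
    live = float(np.sum(counts))
    rows.append({
        "time_hr": t,
        "generations": math.log2(live / initial_live) if live > 0 else -math.inf,
        "ratio": math.inf if counts[b] == 0 else float(counts[a] / counts[b]),
        **{f"n_{i}": float(c) for i, c in enumerate(counts)},
    })
    return live


def _run_liquid_agents(strains, medium, config, protocol):
    rng = np.random.default_rng(config.rng_seed)
    table, n0, V, S = _liquid_setup(strains, medium, config, protocol)
    a, b, p = _roles(strains)
    n_strains = len(strains)
    strain = rng.choice(n_strains, size=n0,
                        p=np.asarray(protocol.ratios, dtype=float))
    alive = np.ones(n0, dtype=bool)
    store_req = rng.uniform(0.0, table.alpha[strain])
    store_glu = rng.uniform(0.0, table.alpha_glu[strain])

    tau = config.tau_hours
    n_inner = 8
    dt = tau / n_inner
    initial = float(n0)
    rows = []
    _liquid_record(rows, 0.0, np.bincount(strain, minlength=n_strains), initial, a, b)
    t = 0.0
    status = "max_hours"
    while t < config.max_hours - 1e-9:
        for _ in range(n_inner):
            # continuous release and uptake with shared-pool clamping
            for f in range(3):
                rel = table.gamma_eff * (table.rel_field == f)
                if np.any(rel > 0):
                    n_rel = np.bincount(strain[alive], minlength=n_strains)
                    S[f] += float(np.dot(rel, n_rel)) * dt / V
            for f, stores in ((0, store_req), (1, store_req), (2, store_glu)):
                if f < 2:
                    sel = alive & (table.req_field[strain] == f)
                    vm, K, quota = table.vm, table.K, table.alpha
                else:
                    sel = alive
                    vm, K, quota = table.vm_glu, table.K_glu, table.alpha_glu
                if not np.any(sel) or S[f] <= 0:
                    continue
                si = strain[sel]
                want = vm[si] * S[f] / (S[f] + K[si]) * dt
                want = np.minimum(want, quota[si] - stores[sel])
                want = np.maximum(want, 0.0)
                demand = want.sum()
                avail = S[f] * V
                scale = 1.0 if demand <= avail else avail / demand
                stores[sel] += want * scale
                S[f] -= demand * scale / V
                if S[f] < 0:
                    S[f] = 0.0
        t += tau
        # deaths
        pdie = table.death_rate * tau
        dies = alive & (rng.random(alive.size) < pdie[strain])
        if np.any(dies):
            alive[dies] = False
            for f in range(3):
                beta_tot = float(np.sum(table.beta_eff[strain[dies]] *
                                        (table.rel_field[strain[dies]] == f)))
                S[f] += beta_tot / V
        # divisions
        ready = alive & (store_req >= table.alpha[strain]) & \
            (store_glu >= table.alpha_glu[strain])
        if np.any(ready):
            store_req[ready] -= table.alpha[strain[ready]]
            store_glu[ready] -= table.alpha_glu[strain[ready]]
            kids = strain[ready]
            strain = np.concatenate([strain, kids])
            alive = np.concatenate([alive, np.ones(kids.size, dtype=bool)])
            store_req = np.concatenate([store_req, np.zeros(kids.size)])
            store_glu = np.concatenate([store_glu, np.zeros(kids.size)])
        counts = np.bincount(strain[alive], minlength=n_strains)
        live = _liquid_record(rows, t, counts, initial, a, b)
        if live == 0:
            status = "extinct"
            break
        if config.target_generations is not None and \
                rows[-1]["generations"] >= config.target_generations:
            status = "completed"
            break
    return Trajectory(
        series=pd.DataFrame(rows), snapshots=[],
        provenance=_provenance(strains, medium, config, protocol),
        strain_ids=[s.id for s in strains], roles=(a, b, p), status=status,
    )


def _run_liquid_expectation(strains, medium, config, protocol):
    """Deterministic continuum limit: per-capita division rate
    ln2 * min(v_req/alpha, v_glu/alpha_G), death at the configured rates,
    shared uniform metabolite pools."""
    table, n0, V, S = _liquid_setup(strains, medium, config, protocol)
    a, b, p = _roles(strains)
    n_strains = len(strains)
    N = n0 * np.asarray(protocol.ratios, dtype=float)
    tau = config.tau_hours
    n_inner = 8
    dt = tau / n_inner
    initial = float(N.sum())
    rows = []
    _liquid_record(rows, 0.0, N, initial, a, b)
    t = 0.0
    status = "max_hours"
    while t < config.max_hours - 1e-9:
        for _ in range(n_inner):
            v_req = np.array([
                table.vm[i] * S[table.req_field[i]] /
                (S[table.req_field[i]] + table.K[i]) for i in range(n_strains)
            ])
            v_glu = table.vm_glu * S[GLU] / (S[GLU] + table.K_glu)
            r = math.log(2) * np.minimum(v_req / table.alpha,
                                         v_glu / table.alpha_glu)
            dN = (r - table.death_rate) * N * dt
            # pools: consumption, continuous release, death release
            for f in (LYS, ADE):
                cons = float(np.sum(v_req * N * (table.req_field == f)))
                rel = float(np.sum(table.gamma_eff * N * (table.rel_field == f)))
                dead_rel = float(np.sum(table.beta_eff * table.death_rate * N *
                                        (table.rel_field == f)))
                S[f] = max(0.0, S[f] + (rel + dead_rel - cons) * dt / V)
            S[GLU] = max(0.0, S[GLU] - float(np.sum(v_glu * N)) * dt / V)
            N = np.maximum(N + dN, 0.0)
        t += tau
        live = _liquid_record(rows, t, N, initial, a, b)
        if live < 1e-6:
            status = "extinct"
            break
        if config.target_generations is not None and \
                rows[-1]["generations"] >= config.target_generations:
            status = "completed"
            break
    return Trajectory(
        series=pd.DataFrame(rows), snapshots=[],
        provenance=_provenance(strains, medium, config, protocol),
        strain_ids=[s.id for s in strains], roles=(a, b, p), status=status,
    )
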