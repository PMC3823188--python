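"""Per-τ cell updates: quota accumulation, division with rearrangement,
and stochastic death with metabolite release.

Division follows the observed budding rules: a cell that has gathered
its full metabolite quotas buds in the horizontal plane, pushing
neighbors one site outward along the shortest lateral path to empty
space; once it is enclosed (no reachable empty lateral site within a
five-cell radius) it buds directly upward with probability 0.7, or
displaces a random lateral neighbor's column upward otherwise.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

import numpy as np

from .config import StrainSpec, SimulationConfig, InvalidSpecError, LYSINE
from .lattice import CellLattice

__all__ = [
    "StrainTable",
    "DivisionEvent",
    "SimulationOverflowError",
    "uptake_window",
    "attempt_divisions",
    "place_daughter",
    "death_step",
]


class SimulationOverflowError(RuntimeError):
    """A displaced column reached the top of the simulation domain."""


@dataclass
class StrainTable:
    """Strain parameters flattened into arrays indexed by strain index."""

    ids: list
    req_field: np.ndarray  # 0 lysine, 1 adenine
    vm: np.ndarray  # max uptake of required metabolite incl. multiplier, fmol/hr
    K: np.ndarray
    alpha: np.ndarray
    vm_glu: np.ndarray
    K_glu: np.ndarray
    alpha_glu: np.ndarray
    gamma_eff: np.ndarray  # continuous release, fmol/hr (gamma * d * excess)
    beta_eff: np.ndarray  # on-death release, fmole (beta * excess)
    rel_field: np.ndarray  # field index released (1 - req_field)
    death_rate: np.ndarray  # 1/hr

    @classmethod
    def from_specs(cls, strains, excess_release_factor=1.0) -> "StrainTable":
        n = len(strains)
        t = cls(
            ids=[s.id for s in strains],
            req_field=np.zeros(n, dtype=np.int64),
            vm=np.zeros(n),
            K=np.zeros(n),
            alpha=np.zeros(n),
            vm_glu=np.zeros(n),
            K_glu=np.zeros(n),
            alpha_glu=np.zeros(n),
            gamma_eff=np.zeros(n),
            beta_eff=np.zeros(n),
            rel_field=np.zeros(n, dtype=np.int64),
            death_rate=np.zeros(n),
        )
        for i, s in enumerate(strains):
            t.req_field[i] = 0 if s.required_metabolite == LYSINE else 1
            t.rel_field[i] = 1 - t.req_field[i]
            t.vm[i] = s.max_uptake_rate
            t.K[i] = s.monod_K
            t.alpha[i] = s.quota_alpha
            t.vm_glu[i] = s.glucose_vm
            t.K_glu[i] = s.glucose_K
            t.alpha_glu[i] = s.glucose_quota
            if s.release_mode == "continuous":
                t.gamma_eff[i] = (
                    s.release_rate_gamma * s.release_fraction_d * excess_release_factor
                )
            elif s.release_mode == "on_death":
                t.beta_eff[i] = s.release_on_death_beta * excess_release_factor
            t.death_rate[i] = s.death_rate
        return t


def uptake_window(vm, K, quota, store, concentration, tu_hr, available=None):
    """Amount (fmole) one live cell consumes in one t_u.

    min(v_m S/(S+K) t_u, quota - store, its share of available mass);
    zero once the quota for that metabolite is met ("stops consuming").
    """
    if store >= quota or concentration <= 0:
        return 0.0
    want = vm * concentration / (concentration + K) * tu_hr
    want = min(want, quota - store)
    if available is not None:
        want = min(want, available)
    return want


@dataclass
class DivisionEvent:
    mother: tuple
    daughter: tuple
    pushed: list = field(default_factory=list)  # ordered positions shifted
    vertical: bool = False


_LATERAL = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def _shortest_lateral_path(lattice, mother, radius, rng):
    """BFS from the mother through occupied sites at its z-level to the
    nearest empty site; ties broken uniformly at random.

    Returns the list of sites from the first step to the empty target,
    or None if everything within ``radius`` is blocked (enclosure).
    """
    mx, my, mz = mother
    nx, ny, _ = lattice.shape
    grid = lattice.grid
    seen = {(mx, my)}
    parent = {}
    queue = deque([(mx, my, 0)])
    order = list(_LATERAL)
    while queue:
        x, y, dist = queue.popleft()
        if dist >= radius:
            continue
        rng.shuffle(order)
        for dx, dy in order:
            xx = (x + dx) % nx
            yy = (y + dy) % ny
            if (xx, yy) in seen:
                continue
            seen.add((xx, yy))
            parent[(xx, yy)] = (x, y)
            if grid[xx, yy, mz] == -1:
                # unwind path mother -> ... -> empty target
                path = [(xx, yy)]
                cur = (x, y)
                while cur != (mx, my):
                    path.append(cur)
                    cur = parent[cur]
                path.reverse()
                return [(px, py, mz) for px, py in path]
            queue.append((xx, yy, dist + 1))
    return None


def _settle(lattice, x, y, z_max):
    """The landing height in column (x, y): the column top, at most
    ``z_max``.  A cell budded or pushed over the edge of a taller column
    slides down to rest on the neighboring stack instead of floating."""
    z = z_max
    while z > 0 and lattice.grid[x, y, z - 1] == -1:
        z -= 1
    return z


def _shift_column_up(lattice, x, y, z_from):
    """Move the cell at (x, y, z_from) and everything above it up one site."""
    nz = lattice.shape[2]
    top = z_from
    while top < nz and lattice.grid[x, y, top] >= 0:
        top += 1
    if top >= nz:
        raise SimulationOverflowError(
            f"column ({x}, {y}) reached the domain ceiling (z={nz})"
        )
    for z in range(top - 1, z_from - 1, -1):
        idx = lattice.grid[x, y, z]
        if idx >= 0:
            lattice.move_cell(idx, (x, y, z + 1))


def place_daughter(lattice: CellLattice, mother_pos, rng, config: SimulationConfig):
    """Choose and clear a site for a new daughter next to its mother.

    Returns a :class:`DivisionEvent`; the daughter site is empty when
    this returns (the caller adds the cell).
    """
    mx, my, mz = mother_pos
    nx, ny, nz = lattice.shape
    path = _shortest_lateral_path(lattice, mother_pos, config.enclosure_radius_cells, rng)
    if path is not None:
        # whoever enters the empty end of the chain settles onto that
        # column's top rather than hanging in the air
        tx, ty, _ = path[-1]
        target = (tx, ty, _settle(lattice, tx, ty, mz))
        path = path[:-1] + [target]
        daughter = path[0]
        # shift the occupied chain one site outward (far end first)
        for i in range(len(path) - 1, 0, -1):
            idx = lattice.grid[path[i - 1][0], path[i - 1][1], mz]
            lattice.move_cell(idx, path[i])
        return DivisionEvent(mother=tuple(mother_pos), daughter=daughter,
                             pushed=path[1:], vertical=False)
    # enclosed: bud upward, or push a neighbor's column up
    if rng.random() < config.vertical_bud_probability:
        _shift_column_up(lattice, mx, my, mz + 1)
        daughter = (mx, my, mz + 1)
        if daughter[2] >= nz:
            raise SimulationOverflowError("domain ceiling reached")
        return DivisionEvent(mother=tuple(mother_pos), daughter=daughter,
                             pushed=[], vertical=True)
    occupied = [
        ((mx + dx) % nx, (my + dy) % ny)
        for dx, dy in _LATERAL
        if lattice.grid[(mx + dx) % nx, (my + dy) % ny, mz] >= 0
    ]
    if not occupied:
        # isolated tower top: the only displaceable direction is up
        _shift_column_up(lattice, mx, my, mz + 1)
        return DivisionEvent(mother=tuple(mother_pos), daughter=(mx, my, mz + 1),
                             pushed=[], vertical=True)
    x, y = occupied[rng.integers(len(occupied))]
    _shift_column_up(lattice, x, y, mz)
    return DivisionEvent(mother=tuple(mother_pos), daughter=(x, y, mz),
                         pushed=[(x, y, mz)], vertical=True)


def attempt_divisions(lattice: CellLattice, table: StrainTable, rng,
                      config: SimulationConfig):
    """Divide every live cell whose quotas (required metabolite and
    glucose) are both met; each mother divides at most once per τ and
    keeps any surplus stores.  Iteration order is randomized."""
    s = lattice.strain
    ready = (
        lattice.alive
        & (lattice.store_req >= table.alpha[s])
        & (lattice.store_glu >= table.alpha_glu[s])
    )
    idxs = np.flatnonzero(ready)
    if idxs.size == 0:
        return []
    events = []
    for i in rng.permutation(idxs):
        mother_pos = tuple(int(v) for v in lattice.pos[i])
        try:
            ev = place_daughter(lattice, mother_pos, rng, config)
        except SimulationOverflowError:
            if config.overflow_policy == "error":
                raise
            continue  # arrested at the ceiling; stores kept, retried later
        st = int(lattice.strain[i])
        lattice._a.store_req[i] -= table.alpha[st]
        lattice._a.store_glu[i] -= table.alpha_glu[st]
        lattice.add_cell(ev.daughter, st, store_req=0.0, store_glu=0.0)
        lattice.births += 1
        events.append(ev)
    return events


def death_step(lattice: CellLattice, table: StrainTable, tau_hr, rng,
               release_shape=None):
    """Kill each live cell independently with probability death_rate * τ.

    Partner-type cells (release on death) deposit their lysine payload
    at their community voxel; the returned per-voxel map is fed to the
    next window's diffusion steps.  Returns (dead cell indices,
    release map with shape (3, *community voxels)).
    """
    p = table.death_rate * tau_hr
    if np.any(p > 1):
        raise InvalidSpecError("death probability per window exceeds 1; reduce tau")
    n = lattice.n_cells
    release = None
    if release_shape is not None:
        release = np.zeros(release_shape)
    if n == 0:
        return np.zeros(0, dtype=np.int64), release
    draws = rng.random(n)
    dies = lattice.alive & (draws < p[lattice.strain])
    idxs = np.flatnonzero(dies)
    lattice._a.alive[idxs] = False
    if release is not None and idxs.size:
        beta = table.beta_eff[lattice.strain[idxs]]
        rel_f = table.rel_field[lattice.strain[idxs]]
        vox = lattice.voxel_index(lattice.pos[idxs])
        for f in range(3):
            sel = (rel_f == f) & (beta > 0)
            if np.any(sel):
                flat = np.bincount(vox[sel], weights=beta[sel],
                                   minlength=release[f].size)
                release[f] += flat.reshape(release[f].shape)
    return idxs, release
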