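"""Metabolite concentration fields on the dual-resolution grid.

Adenine, lysine, and glucose share one solver.  Each field lives on two
grids: a coarse one inside the agarose (60 um voxels, D = 360 um^2/s)
and a fine one covering the community and the air above it (15 um
voxels).  The community diffusivity is proportional to voxel occupancy
(0 ... 20 um^2/s at 27 cells); empty (air) voxels have D = 0, which
makes the community-air interface a no-flux boundary automatically.
Lateral boundaries are periodic, top and bottom are no-flux, and the
two grids exchange mass flux-conservatively at the agarose surface.
"""

from __future__ import annotations

import numpy as np

from . import _kernels
from .config import SimulationConfig, MediumSpec

__all__ = [
    "FIELD_NAMES",
    "LYS",
    "ADE",
    "GLU",
    "FieldState",
    "NumericalStabilityError",
    "step_fields",
    "update_D",
    "instant_distribution_step",
    "total_mass",
]

FIELD_NAMES = ("lysine", "adenine", "glucose")
LYS, ADE, GLU = 0, 1, 2


class NumericalStabilityError(RuntimeError):
    """A field went NaN or negative beyond roundoff after a step."""


class FieldState:
    """All three metabolite fields plus diffusivity and mass ledgers."""

    def __init__(self, config: SimulationConfig, medium: MediumSpec):
        self.config = config
        h_c = config.community_grid
        h_a = config.agarose_grid
        lx, ly = config.domain_um
        self.comm_shape = (
            int(lx // h_c),
            int(ly // h_c),
            int(config.community_height_um // h_c),
        )
        naz = max(1, int(round(medium.agarose_height / h_a)))
        self.agar_shape = (int(lx // h_a), int(ly // h_a), naz)
        self.ratio = int(h_a // h_c)
        self.h_c, self.h_a = h_c, h_a
        self.Vc = h_c**3
        self.Va = h_a**3
        self.comm = np.zeros((3,) + self.comm_shape, dtype=np.float64)
        self.agar = np.zeros((3,) + self.agar_shape, dtype=np.float64)
        # supplements and the shared resource start uniformly in the agarose
        self.agar[LYS] = medium.supplemented_lysine
        self.agar[ADE] = medium.supplemented_adenine
        self.agar[GLU] = medium.initial_glucose
        self.released = np.zeros(3)
        self.consumed = np.zeros(3)
        self.initial_mass = np.array([self.total_mass(f) for f in range(3)])
        self.D_comm = np.zeros(self.comm_shape)
        # scratch
        self._Tc = np.zeros(self.comm_shape)
        self._Ta = np.zeros(self.agar_shape)
        self._demand = np.zeros(self.comm_shape)

    # ------------------------------------------------------------------
    def total_mass(self, field: int) -> float:
        """Total amount (fmole) of one metabolite over both grids."""
        return float(self.comm[field].sum() * self.Vc + self.agar[field].sum() * self.Va)

    def mass_balance_error(self) -> float:
        """Relative ledger error max over fields:
        |mass - initial - released + consumed| / max(scale, 1)."""
        err = 0.0
        for f in range(3):
            scale = max(self.initial_mass[f] + self.released[f], 1.0)
            got = self.total_mass(f)
            expect = self.initial_mass[f] + self.released[f] - self.consumed[f]
            err = max(err, abs(got - expect) / scale)
        return err

    # ------------------------------------------------------------------
    def set_D_from_occupancy(self, occupancy: np.ndarray) -> None:
        """D in each community voxel is proportional to its occupancy
        (27 cells -> D_community_max); the uniform-D variant pins it to
        the agarose value everywhere."""
        cfg = self.config
        if cfg.uniform_D:
            self.D_comm[:] = cfg.D_agarose
        else:
            self.D_comm[:] = (occupancy / 27.0) * cfg.D_community_max

    def _substep_count(self, tu_s: float) -> int:
        cfg = self.config
        d_max = float(self.D_comm.max())
        rate_comm = 6.0 * d_max / self.h_c**2
        rate_agar = 6.0 * cfg.D_agarose / self.h_a**2
        if d_max > 0:
            k_int = 1.0 / (self.h_a / 2.0 / cfg.D_agarose + self.h_c / 2.0 / d_max)
            rate_comm += k_int * self.h_c**2 / self.Vc
        rate = max(rate_comm, rate_agar, 1e-12)
        return max(1, int(np.ceil(tu_s * rate / 0.8)))

    def window_coefficients(self, tu_s: float):
        """Face-transfer coefficients for one sub-step, recomputed after
        every occupancy/D update."""
        n_sub = self._substep_count(tu_s)
        dt = tu_s / n_sub
        D = self.D_comm
        h2 = self.h_c**2

        def harm(a, b):
            s = a + b
            out = np.zeros_like(a)
            nz = s > 0
            out[nz] = 2.0 * a[nz] * b[nz] / s[nz]
            return out

        cfx = dt * harm(D, np.roll(D, -1, axis=0)) / h2
        cfy = dt * harm(D, np.roll(D, -1, axis=1)) / h2
        cfz = np.zeros_like(D)
        cfz[:, :, :-1] = dt * harm(D[:, :, :-1], D[:, :, 1:]) / h2
        ca = dt * self.config.D_agarose / self.h_a**2
        # agarose-community interface: series resistance of half a coarse
        # voxel of agarose and half a fine voxel of community material
        D0 = D[:, :, 0]
        kint = np.zeros_like(D0)
        nz = D0 > 0
        kint[nz] = 1.0 / (self.h_a / 2.0 / self.config.D_agarose + self.h_c / 2.0 / D0[nz])
        mint = dt * self.h_c**2 * kint  # mass per unit concentration difference
        return n_sub, cfx, cfy, cfz, ca, mint

    # ------------------------------------------------------------------
    def check(self) -> None:
        for f in range(3):
            for name, arr in (("community", self.comm[f]), ("agarose", self.agar[f])):
                if np.isnan(arr).any():
                    vox = np.unravel_index(int(np.nanargmax(np.isnan(arr))), arr.shape)
                    raise NumericalStabilityError(
                        f"NaN in {FIELD_NAMES[f]} {name} field at voxel {vox}"
                    )
                mn = arr.min()
                if mn < -1e-9 * max(1.0, arr.max()):
                    vox = np.unravel_index(int(arr.argmin()), arr.shape)
                    raise NumericalStabilityError(
                        f"negative {FIELD_NAMES[f]} concentration {mn:g} in "
                        f"{name} field at voxel {vox}"
                    )


# ---------------------------------------------------------------------------
# Spec-level operations.  ``run_spatial`` drives the same kernel through
# whole τ windows; these single-t_u entry points are the public contract
# (and what the conservation and convergence tests exercise).
# ---------------------------------------------------------------------------


def _empty_groups():
    e_i = np.zeros(0, dtype=np.int64)
    e_f = np.zeros(0, dtype=np.float64)
    return (e_i, e_i, e_i, e_i, e_f, e_f, e_f)


def _build_groups(lattice, table):
    """Per-window consumer groups: (cell idx, voxel coords, v_m*t_u, K, quota)
    for lysine-requiring cells, adenine-requiring cells, and all live
    cells for glucose."""
    groups = {}
    alive = lattice.alive
    b = lattice.sites_per_voxel
    for field, sel in (
        (LYS, alive & (table.req_field[lattice.strain] == LYS)),
        (ADE, alive & (table.req_field[lattice.strain] == ADE)),
        (GLU, alive),
    ):
        idx = np.flatnonzero(sel).astype(np.int64)
        p = lattice.pos[idx]
        vi = (p[:, 0] // b).astype(np.int64)
        vj = (p[:, 1] // b).astype(np.int64)
        vk = (p[:, 2] // b).astype(np.int64)
        s = lattice.strain[idx]
        if field == GLU:
            vm = table.vm_glu[s]
            K = table.K_glu[s]
            quota = table.alpha_glu[s]
        else:
            vm = table.vm[s]
            K = table.K[s]
            quota = table.alpha[s]
        groups[field] = (idx, vi, vj, vk, vm.astype(np.float64), K.astype(np.float64), quota.astype(np.float64))
    return groups


def _run_window(fields: FieldState, lattice, table, tu_s, n_tu, release_map, instant=False):
    tu_hr = tu_s / 3600.0
    n_sub, cfx, cfy, cfz, ca, mint = fields.window_coefficients(tu_s)
    groups = _build_groups(lattice, table) if lattice is not None else {
        LYS: _empty_groups(), ADE: _empty_groups(), GLU: _empty_groups()
    }
    # scale v_m (fmol/hr) to an amount per t_u
    args = []
    for f in (LYS, ADE, GLU):
        idx, vi, vj, vk, vm, K, quota = groups[f]
        args.extend([idx, vi, vj, vk, vm * tu_hr, K, quota])
    release_sums = release_map.sum(axis=(1, 2, 3))
    store_req = lattice._a.store_req if lattice is not None else np.zeros(0)
    store_glu = lattice._a.store_glu if lattice is not None else np.zeros(0)
    _kernels.run_window(
        fields.comm,
        fields.agar,
        fields._Tc,
        fields._Ta,
        cfx,
        cfy,
        cfz,
        ca,
        mint,
        fields.ratio,
        fields.Vc,
        fields.Va,
        n_tu,
        n_sub,
        release_map,
        release_sums,
        *args,
        store_req,
        store_glu,
        fields._demand,
        fields.released,
        fields.consumed,
        instant,
    )
    fields.check()


def update_D(fields: FieldState, lattice) -> np.ndarray:
    """Refresh the spatially varying diffusion coefficient from lattice
    occupancy (called after every τ cell update)."""
    fields.set_D_from_occupancy(lattice.occupancy())
    return fields.D_comm


def step_fields(fields: FieldState, lattice, table, tu_s=None, release_map=None):
    """Advance every field by one physical timestep t_u: diffusion
    (internally sub-stepped), continuous and death release sources, and
    clamped Michaelis-Menten sinks.

    ``table`` is the :class:`~crossfeed.engine.StrainTable` built from the
    strain panel; ``release_map`` carries per-voxel source mass for this
    t_u (death release from the previous window plus continuous release).
    """
    if tu_s is None:
        tu_s = fields.config.diffusion_timestep_tu
    if release_map is None:
        release_map = np.zeros_like(fields.comm)
    _run_window(fields, lattice, table, tu_s, 1, release_map, instant=False)


def total_mass(fields: FieldState, field) -> float:
    """Sum of concentration x voxel volume over both grids."""
    if isinstance(field, str):
        field = FIELD_NAMES.index(field)
    return fields.total_mass(field)


def instant_distribution_step(fields: FieldState, lattice, table, tu_s=None, release_map=None):
    """Like :func:`step_fields`, but afterwards each field is replaced by
    its volume-weighted mean over community + agarose (the variant in
    which released metabolites reach all cells instantly)."""
    if tu_s is None:
        tu_s = fields.config.diffusion_timestep_tu
    if release_map is None:
        release_map = np.zeros_like(fields.comm)
    _run_window(fields, lattice, table, tu_s, 1, release_map, instant=True)
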