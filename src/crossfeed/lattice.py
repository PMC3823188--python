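"""3-D cell lattice: geometry, occupancy, and neighborhood queries.

Cells live on a cubic lattice of 5-um sites above the agarose surface
(z = 0 is the bottom layer, z grows upward).  The lateral (x, y) axes
are periodic; z is not.  At most one cell occupies a site; dead cells
persist in place, occupy volume, and block pushing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["CellLattice", "neighbors", "occupancy_fraction"]

_OFFSETS_26 = np.array(
    [
        (dx, dy, dz)
        for dx in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dz in (-1, 0, 1)
        if (dx, dy, dz) != (0, 0, 0)
    ],
    dtype=np.int64,
)
_OFFSETS_LATERAL8 = np.array(
    [(dx, dy, 0) for dx in (-1, 0, 1) for dy in (-1, 0, 1) if (dx, dy) != (0, 0)],
    dtype=np.int64,
)


def neighbors(pos, shape, mode="full26", plane_axis=None):
    """Neighbor sites of ``pos`` honoring periodic x/y wrap and finite z.

    Modes: ``lateral8`` (8 sites at the same z), ``full26`` (26 sites in
    3-D), ``planar8`` (8 sites within the 2-D section that holds the
    axis ``plane_axis`` fixed).  Out-of-domain z neighbors are dropped,
    not wrapped.
    """
    x, y, z = pos
    nx, ny, nz = shape
    if not (0 <= x < nx and 0 <= y < ny and 0 <= z < nz):
        raise IndexError(f"position {pos} outside lattice {shape}")
    if mode == "lateral8":
        offs = _OFFSETS_LATERAL8
    elif mode == "full26":
        offs = _OFFSETS_26
    elif mode == "planar8":
        if plane_axis is None:
            plane_axis = 1  # default: x-z cross-section
        offs = _OFFSETS_26[_OFFSETS_26[:, plane_axis] == 0]
        offs = offs[np.max(np.abs(offs), axis=1) == 1]
    else:
        raise ValueError(f"unknown neighborhood mode {mode!r}")
    out = []
    for dx, dy, dz in offs:
        zz = z + dz
        if zz < 0 or zz >= nz:
            continue
        out.append(((x + dx) % nx, (y + dy) % ny, zz))
    return out


def occupancy_fraction(lattice: "CellLattice", voxel) -> float:
    """Fraction of the 3x3x3 cell-site block of a community voxel that is
    occupied (live or dead); a full block holds 27 cells."""
    b = lattice.sites_per_voxel
    i, j, k = voxel
    block = lattice.grid[
        i * b : (i + 1) * b, j * b : (j + 1) * b, k * b : (k + 1) * b
    ]
    return float(np.count_nonzero(block >= 0)) / float(b**3)


@dataclass
class _Arrays:
    pos: np.ndarray  # (cap, 3) int32
    strain: np.ndarray  # (cap,) int16
    alive: np.ndarray  # (cap,) bool
    store_req: np.ndarray  # (cap,) float64, toward required-metabolite quota
    store_glu: np.ndarray  # (cap,) float64, toward glucose quota


class CellLattice:
    """Dense cell bookkeeping: a site grid plus per-cell record arrays.

    ``grid[x, y, z]`` holds -1 for an empty site or the integer cell
    index; per-cell arrays never shrink (dead cells keep their entry).
    """

    def __init__(self, shape_sites, sites_per_voxel=3, strain_ids=()):
        self.shape = tuple(int(s) for s in shape_sites)
        self.sites_per_voxel = int(sites_per_voxel)
        self.strain_ids = list(strain_ids)
        self.grid = np.full(self.shape, -1, dtype=np.int32)
        cap = 1024
        self._a = _Arrays(
            pos=np.zeros((cap, 3), dtype=np.int32),
            strain=np.zeros(cap, dtype=np.int16),
            alive=np.zeros(cap, dtype=bool),
            store_req=np.zeros(cap, dtype=np.float64),
            store_glu=np.zeros(cap, dtype=np.float64),
        )
        self.n_cells = 0
        self.births = 0

    # -- views over the live prefix ------------------------------------
    @property
    def pos(self):
        return self._a.pos[: self.n_cells]

    @property
    def strain(self):
        return self._a.strain[: self.n_cells]

    @property
    def alive(self):
        return self._a.alive[: self.n_cells]

    @property
    def store_req(self):
        return self._a.store_req[: self.n_cells]

    @property
    def store_glu(self):
        return self._a.store_glu[: self.n_cells]

    def _grow(self):
        a = self._a
        cap = len(a.strain) * 2
        self._a = _Arrays(
            pos=np.resize(a.pos, (cap, 3)),
            strain=np.resize(a.strain, cap),
            alive=np.resize(a.alive, cap),
            store_req=np.resize(a.store_req, cap),
            store_glu=np.resize(a.store_glu, cap),
        )

    def add_cell(self, pos, strain_idx, store_req=0.0, store_glu=0.0, alive=True) -> int:
        x, y, z = pos
        if self.grid[x, y, z] != -1:
            raise ValueError(f"site {pos} already occupied")
        if self.n_cells == len(self._a.strain):
            self._grow()
        i = self.n_cells
        self._a.pos[i] = pos
        self._a.strain[i] = strain_idx
        self._a.alive[i] = alive
        self._a.store_req[i] = store_req
        self._a.store_glu[i] = store_glu
        self.grid[x, y, z] = i
        self.n_cells += 1
        return i

    def move_cell(self, idx, new_pos) -> None:
        x, y, z = self._a.pos[idx]
        nxp = tuple(int(v) for v in new_pos)
        if self.grid[nxp] != -1:
            raise ValueError(f"target site {nxp} occupied")
        self.grid[x, y, z] = -1
        self.grid[nxp] = idx
        self._a.pos[idx] = nxp

    # -- queries ---------------------------------------------------------
    def counts(self, live_only=True) -> np.ndarray:
        """Cell counts per strain index."""
        n_strains = max(len(self.strain_ids), 1)
        sel = self.alive if live_only else np.ones(self.n_cells, dtype=bool)
        return np.bincount(self.strain[sel], minlength=n_strains)

    def live_total(self) -> int:
        return int(np.count_nonzero(self.alive))

    def voxel_shape(self):
        b = self.sites_per_voxel
        return tuple(s // b for s in self.shape)

    def voxel_index(self, positions) -> np.ndarray:
        """Flat community-voxel index (C order) for (N, 3) site positions."""
        b = self.sites_per_voxel
        vx = positions[:, 0] // b
        vy = positions[:, 1] // b
        vz = positions[:, 2] // b
        nvx, nvy, nvz = self.voxel_shape()
        return (vx * nvy + vy) * nvz + vz

    def occupancy(self) -> np.ndarray:
        """Occupied-site count (live + dead) per community voxel."""
        shape = self.voxel_shape()
        occ = np.zeros(shape[0] * shape[1] * shape[2], dtype=np.int64)
        if self.n_cells:
            idx = self.voxel_index(self.pos)
            occ = np.bincount(idx, minlength=occ.size)
        return occ.reshape(shape)

    def labels(self) -> np.ndarray:
        """Dense snapshot: 0 empty, strain_idx+1 for live, -(strain_idx+1) dead."""
        lab = np.zeros(self.shape, dtype=np.int8)
        if self.n_cells:
            p = self.pos
            code = (self.strain.astype(np.int16) + 1) * np.where(self.alive, 1, -1)
            lab[p[:, 0], p[:, 1], p[:, 2]] = code.astype(np.int8)
        return lab

    def column_heights(self) -> np.ndarray:
        """Top-most occupied z + 1 per (x, y) column (0 where empty)."""
        occ = self.grid >= 0
        nz = self.shape[2]
        any_occ = occ.any(axis=2)
        top = nz - np.argmax(occ[:, :, ::-1], axis=2)
        return np.where(any_occ, top, 0)

    def check_support(self) -> bool:
        """No cell floats: every occupied site at z>0 has an occupied site below."""
        occ = self.grid >= 0
        return bool(np.all(~occ[:, :, 1:] | occ[:, :, :-1]))
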