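"""Numba kernels for the reaction-diffusion inner loop.

One cell-update window (τ) contains many physical diffusion timesteps
(t_u); each t_u is itself sub-stepped so the explicit scheme respects
the 3-D stability bound even though t_u = 3.5 s with D = 360 um^2/s on
a 60 um grid does not.  All stochastic decisions stay outside these
kernels; given the same inputs they are bit-deterministic.

Field order everywhere: 0 = lysine, 1 = adenine, 2 = glucose.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["run_window"]


@njit(cache=True)
def _diffuse_comm(S, T, cfx, cfy, cfz):
    """One explicit sub-step on the community/air grid.

    Face coefficients already include dt/h^2 and the harmonic-mean
    diffusivity of the two voxels sharing the face (zero across faces
    bordering empty air, which makes the community-air boundary
    no-flux automatically).  x/y periodic, z no-flux.
    """
    nx, ny, nz = S.shape
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                T[i, j, k] = S[i, j, k]
    for i in range(nx):
        i2 = i + 1 if i + 1 < nx else 0
        for j in range(ny):
            j2 = j + 1 if j + 1 < ny else 0
            for k in range(nz):
                s = S[i, j, k]
                fx = cfx[i, j, k] * (S[i2, j, k] - s)
                T[i, j, k] += fx
                T[i2, j, k] -= fx
                fy = cfy[i, j, k] * (S[i, j2, k] - s)
                T[i, j, k] += fy
                T[i, j2, k] -= fy
                if k + 1 < nz:
                    fz = cfz[i, j, k] * (S[i, j, k + 1] - s)
                    T[i, j, k] += fz
                    T[i, j, k + 1] -= fz
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                S[i, j, k] = T[i, j, k]


@njit(cache=True)
def _diffuse_agar(S, T, ca):
    """One explicit sub-step in agarose (constant D, periodic x/y,
    no-flux top and bottom; the top face exchange with the community is
    handled separately)."""
    nx, ny, nz = S.shape
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                T[i, j, k] = S[i, j, k]
    for i in range(nx):
        i2 = i + 1 if i + 1 < nx else 0
        for j in range(ny):
            j2 = j + 1 if j + 1 < ny else 0
            for k in range(nz):
                s = S[i, j, k]
                fx = ca * (S[i2, j, k] - s)
                T[i, j, k] += fx
                T[i2, j, k] -= fx
                fy = ca * (S[i, j2, k] - s)
                T[i, j, k] += fy
                T[i, j2, k] -= fy
                if k + 1 < nz:
                    fz = ca * (S[i, j, k + 1] - s)
                    T[i, j, k] += fz
                    T[i, j, k + 1] -= fz
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                S[i, j, k] = T[i, j, k]


@njit(cache=True)
def _couple(Sc, Sa, mint, ratio, Vc, Va):
    """Flux-conservative exchange between each top agarose voxel and its
    ratio x ratio overlying community voxels.  ``mint[i, j]`` converts a
    concentration difference into moved mass (fmol) per sub-step; it is
    zero where the overlying voxel holds no cells."""
    nx = Sc.shape[0]
    ny = Sc.shape[1]
    ktop = Sa.shape[2] - 1
    for i in range(nx):
        ii = i // ratio
        for j in range(ny):
            jj = j // ratio
            m = mint[i, j] * (Sa[ii, jj, ktop] - Sc[i, j, 0])
            if m != 0.0:
                Sc[i, j, 0] += m / Vc
                Sa[ii, jj, ktop] -= m / Va


@njit(cache=True)
def _uptake_group(field, Vc, idx, vi, vj, vk, vmtu, K, quota, store, demand, want):
    """Clamped Michaelis-Menten uptake for one consumer group in one t_u.

    Per cell the demand is min(v_m S/(S+K) t_u, quota - store); when the
    summed demand in a voxel exceeds the mass it holds, the available
    mass is split in proportion to the unclamped demands.  Returns the
    total amount consumed."""
    n = idx.shape[0]
    consumed = 0.0
    for c in range(n):
        i = idx[c]
        s = store[i]
        q = quota[c]
        if s >= q:
            want[c] = 0.0
            continue
        S = field[vi[c], vj[c], vk[c]]
        if S <= 0.0:
            want[c] = 0.0
            continue
        w = vmtu[c] * S / (S + K[c])
        if w > q - s:
            w = q - s
        want[c] = w
        demand[vi[c], vj[c], vk[c]] += w
    for c in range(n):
        if want[c] <= 0.0:
            continue
        a = vi[c]
        b = vj[c]
        k = vk[c]
        d = demand[a, b, k]
        if d > 0.0:
            avail = field[a, b, k] * Vc
            scale = 1.0 if d <= avail else avail / d
            demand[a, b, k] = -(scale + 1.0)  # mark voxel, cache scale
            d = demand[a, b, k]
        scale = -d - 1.0
        take = want[c] * scale
        store[idx[c]] += take
        consumed += take
        field[a, b, k] -= take / Vc
        if field[a, b, k] < 0.0:
            field[a, b, k] = 0.0
    for c in range(n):
        if want[c] != 0.0:
            demand[vi[c], vj[c], vk[c]] = 0.0
    return consumed


@njit(cache=True)
def _flatten_mean(comm, agar, Vc, Va):
    tot = 0.0
    for v in comm.flat:
        tot += v * Vc
    for v in agar.flat:
        tot += v * Va
    vol = comm.size * Vc + agar.size * Va
    mean = tot / vol
    for i in range(comm.shape[0]):
        for j in range(comm.shape[1]):
            for k in range(comm.shape[2]):
                comm[i, j, k] = mean
    for i in range(agar.shape[0]):
        for j in range(agar.shape[1]):
            for k in range(agar.shape[2]):
                agar[i, j, k] = mean


@njit(cache=True)
def run_window(
    comm,
    agar,
    Tc,
    Ta,
    cfx,
    cfy,
    cfz,
    ca,
    mint,
    ratio,
    Vc,
    Va,
    n_tu,
    n_sub,
    release_map,
    release_sums,
    idx_l,
    vi_l,
    vj_l,
    vk_l,
    vmtu_l,
    K_l,
    quota_l,
    idx_a,
    vi_a,
    vj_a,
    vk_a,
    vmtu_a,
    K_a,
    quota_a,
    idx_g,
    vi_g,
    vj_g,
    vk_g,
    vmtu_g,
    K_g,
    quota_g,
    store_req,
    store_glu,
    demand,
    released,
    consumed,
    instant,
):
    """Advance all three fields and cell stores over one τ window
    (``n_tu`` physical timesteps of ``n_sub`` diffusion sub-steps each).

    ``release_map[f]`` is the per-voxel source mass added each t_u
    (continuous adenine release by live cooperators plus the lysine
    released by partner cells that died in the previous window, spread
    evenly over this window's t_u steps)."""
    want_l = np.empty(idx_l.shape[0], dtype=np.float64)
    want_a = np.empty(idx_a.shape[0], dtype=np.float64)
    want_g = np.empty(idx_g.shape[0], dtype=np.float64)
    nx, ny, nz = comm[0].shape
    for t in range(n_tu):
        for f in range(3):
            if release_sums[f] != 0.0:
                Sf = comm[f]
                Rf = release_map[f]
                for i in range(nx):
                    for j in range(ny):
                        for k in range(nz):
                            Sf[i, j, k] += Rf[i, j, k] / Vc
                released[f] += release_sums[f]
        for s in range(n_sub):
            for f in range(3):
                _diffuse_comm(comm[f], Tc, cfx, cfy, cfz)
                _diffuse_agar(agar[f], Ta, ca)
                _couple(comm[f], agar[f], mint, ratio, Vc, Va)
        if instant:
            for f in range(3):
                _flatten_mean(comm[f], agar[f], Vc, Va)
        consumed[0] += _uptake_group(
            comm[0], Vc, idx_l, vi_l, vj_l, vk_l, vmtu_l, K_l, quota_l,
            store_req, demand, want_l,
        )
        consumed[1] += _uptake_group(
            comm[1], Vc, idx_a, vi_a, vj_a, vk_a, vmtu_a, K_a, quota_a,
            store_req, demand, want_a,
        )
        consumed[2] += _uptake_group(
            comm[2], Vc, idx_g, vi_g, vj_g, vk_g, vmtu_g, K_g, quota_g,
            store_glu, demand, want_g,
        )
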