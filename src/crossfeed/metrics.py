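"""Quantification layer: partner association indexes, population ratios,
and fitness-advantage estimation.

The partner association index A is the ratio of the average number of
partner neighbors per focal cooperator to the average number of partner
neighbors per focal cheater, restricted to focal cells that border at
least one cell of a *different* population.  A > 1 means cooperators
sit next to more partners than cheaters do.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "AssociationResult",
    "association_index",
    "association_index_3d_timeseries",
    "population_ratio",
    "fitness_advantage",
    "region_split_metrics",
]


def _offsets(ndim: int, mode: str):
    if ndim == 3:
        if mode == "full26":
            return [
                (i, j, k)
                for i in (-1, 0, 1)
                for j in (-1, 0, 1)
                for k in (-1, 0, 1)
                if (i, j, k) != (0, 0, 0)
            ]
        if mode == "lateral8":
            return [
                (i, j, 0) for i in (-1, 0, 1) for j in (-1, 0, 1) if (i, j) != (0, 0)
            ]
        if mode == "face6":
            return [
                (1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)
            ]
    elif ndim == 2:
        if mode in ("planar8", "full26"):
            return [
                (i, j) for i in (-1, 0, 1) for j in (-1, 0, 1) if (i, j) != (0, 0)
            ]
        if mode in ("edge4", "face6"):
            return [(1, 0), (-1, 0), (0, 1), (0, -1)]
    raise ValueError(f"unsupported mode {mode!r} for {ndim}-D labels")


def _shift(arr: np.ndarray, offset, periodic) -> np.ndarray:
    """arr translated by -offset so out[x] = arr[x + offset]; non-periodic
    axes are zero-filled at the boundary."""
    out = arr
    for ax, (d, per) in enumerate(zip(offset, periodic)):
        if d == 0:
            continue
        out = np.roll(out, -d, axis=ax)
        if not per:
            sl = [slice(None)] * arr.ndim
            sl[ax] = slice(-d, None) if d > 0 else slice(None, -d)
            out = out.copy()
            out[tuple(sl)] = 0
    return out


def _neighbor_count(mask: np.ndarray, mode: str, periodic) -> np.ndarray:
    acc = np.zeros(mask.shape, dtype=np.int32)
    m = mask.astype(np.int32)
    for off in _offsets(mask.ndim, mode):
        acc += _shift(m, off, periodic)
    return acc


@dataclass
class AssociationResult:
    index: float  # nan when undefined
    n_focal_a: int  # qualifying focal cells of the first class
    n_focal_b: int
    mean_partner_a: float
    mean_partner_b: float
    mode: str
    status: str  # "ok" | "undefined"

    def __float__(self):
        return self.index


def _default_periodic(ndim: int):
    # lateral axes wrap, the vertical axis of a 3-D lattice does not;
    # 2-D sections default to fully periodic (top-views of a periodic
    # domain) -- pass ``periodic`` explicitly for cross-sections.
    return (True, True, False) if ndim == 3 else (True, True)


def association_index(
    labels: np.ndarray,
    focal_a: int,
    focal_b: int,
    partner: int,
    mode: str = "full26",
    periodic=None,
    include_dead: bool = False,
    focal_mask: np.ndarray | None = None,
) -> AssociationResult:
    """Partner association index of ``focal_a`` vs ``focal_b`` strains.

    ``labels`` is a 2-D section or 3-D lattice of strain codes as
    produced by :meth:`CellLattice.labels` (0 empty, strain index + 1
    live, negated when dead).  Strain arguments are 0-based indices.
    Focal cells qualify only when at least one neighbor belongs to a
    live different population; dead cells are excluded from focal and
    neighbor counts unless ``include_dead``.
    """
    if labels.ndim == 2 and mode == "full26":
        mode = "planar8"
    if periodic is None:
        periodic = _default_periodic(labels.ndim)
    lab = np.abs(labels) if include_dead else np.where(labels > 0, labels, 0)
    present = lab > 0
    n_any = _neighbor_count(present, mode, periodic)

    def _stats(code):
        is_f = lab == code
        n_same = _neighbor_count(is_f, mode, periodic)
        qual = is_f & ((n_any - n_same) > 0)
        if focal_mask is not None:
            qual = qual & focal_mask
        n_partner = _neighbor_count(lab == partner + 1, mode, periodic)
        return int(qual.sum()), float(n_partner[qual].sum())

    n_a, tot_a = _stats(focal_a + 1)
    n_b, tot_b = _stats(focal_b + 1)
    mean_a = tot_a / n_a if n_a else math.nan
    mean_b = tot_b / n_b if n_b else math.nan
    if n_a == 0 or n_b == 0 or mean_b == 0:
        return AssociationResult(math.nan, n_a, n_b, mean_a, mean_b, mode, "undefined")
    return AssociationResult(mean_a / mean_b, n_a, n_b, mean_a, mean_b, mode, "ok")


def association_index_3d_timeseries(trajectory, mode="full26", include_dead=False):
    """Full-26-neighborhood association index for every stored snapshot.

    Returns (times_hr, index values); undefined snapshots yield NaN.
    """
    a, b, p = trajectory.roles
    times, values = [], []
    for t, labels in trajectory.snapshots:
        res = association_index(labels, a, b, p, mode=mode, include_dead=include_dead)
        times.append(t)
        values.append(res.index)
    return np.asarray(times), np.asarray(values)


def population_ratio(counts, a: int, b: int) -> float:
    """Live-cell count ratio a : b; infinite when b is extinct."""
    counts = np.asarray(counts, dtype=float)
    if counts[b] == 0:
        return math.inf
    return float(counts[a] / counts[b])


def fitness_advantage(generations, ratios, g_start: float = 2.0, g_end: float = 6.0):
    """Percent-per-generation advantage of the denominator population.

    Least-squares slope of ln(ratio) against generations over
    [g_start, g_end], exponentiated minus one, times 100.  A ratio
    series (1+s)^g yields exactly 100*s.
    """
    g = np.asarray(generations, dtype=float)
    r = np.asarray(ratios, dtype=float)
    ok = np.isfinite(g) & np.isfinite(r) & (r > 0)
    g, r = g[ok], r[ok]
    if g.size < 2 or g.min() > g_start or g.max() < g_end:
        raise ValueError(
            f"ratio series does not cover generations [{g_start}, {g_end}]"
        )
    win = (g >= g_start) & (g <= g_end)
    if win.sum() < 2:
        raise ValueError("fewer than two samples inside the generation window")
    slope = np.polyfit(g[win], np.log(r[win]), 1)[0]
    return (math.exp(slope) - 1.0) * 100.0


def region_split_metrics(
    labels: np.ndarray,
    inoculum_footprint: np.ndarray,
    focal_a: int,
    focal_b: int,
    partner: int,
    mode: str = "full26",
):
    """Center vs expanding-front metrics for the range-expansion protocol.

    Columns inside the initial inoculum footprint are 'center'; occupied
    columns outside are 'expanding front'.  Returns a dict with the
    focal ratio, association index, and live-cell count per region.
    """
    if labels.ndim != 3:
        raise ValueError("expects a 3-D label lattice")
    foot = np.asarray(inoculum_footprint, dtype=bool)
    out = {}
    live = labels > 0
    for name, colmask in (("center", foot), ("front", ~foot)):
        mask3 = np.broadcast_to(colmask[:, :, None], labels.shape)
        n_a = int((live & mask3 & (labels == focal_a + 1)).sum())
        n_b = int((live & mask3 & (labels == focal_b + 1)).sum())
        n_tot = int((live & mask3).sum())
        ratio = math.inf if n_b == 0 and n_a > 0 else (
            math.nan if n_b == 0 else n_a / n_b
        )
        res = association_index(
            labels, focal_a, focal_b, partner, mode=mode, focal_mask=mask3
        )
        out[name] = {
            "ratio": ratio,
            "association": res,
            "n_live": n_tot,
            "n_focal_a": n_a,
            "n_focal_b": n_b,
        }
    return out
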