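"""Trajectory container, HDF5 persistence, and simple renderers.

A trajectory holds the dense per-window time series (counts, ratios,
association index, mass ledgers), sparse label snapshots, and enough
provenance (strains, medium, simulation config, protocol, seed) to
re-run the simulation bit-identically.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import h5py
import numpy as np
import pandas as pd
import yaml

__all__ = [
    "Trajectory",
    "save_trajectory",
    "load_trajectory",
    "render_topview",
    "render_cross_section",
]


@dataclass
class Trajectory:
    """Output of one simulation run."""

    series: pd.DataFrame
    snapshots: list  # [(time_hr, labels int8 array), ...]
    provenance: dict  # strains/medium/config/protocol dicts + seed
    strain_ids: list
    roles: tuple  # (focal cooperator, focal cheater, partner) strain indices
    status: str = "completed"  # | "extinct" | "max_hours"
    extras: dict = dc_field(default_factory=dict)  # e.g. inoculum footprint

    @property
    def final_labels(self) -> np.ndarray:
        return self.snapshots[-1][1]

    def final_counts(self) -> np.ndarray:
        row = self.series.iloc[-1]
        return np.array([row[f"live_{s}"] for s in self.strain_ids])

    def final_ratio(self) -> float:
        return float(self.series["ratio"].iloc[-1])


def save_trajectory(path, traj: Trajectory) -> None:
    """Write a trajectory to an HDF5 container (timestamps disabled so a
    save -> load -> save round trip is byte-identical)."""
    with h5py.File(path, "w", track_order=True) as f:
        g = f.create_group("series", track_order=True)
        for col in traj.series.columns:
            g.create_dataset(col, data=traj.series[col].to_numpy(), track_times=False)
        snaps = f.create_group("snapshots", track_order=True)
        for i, (t, labels) in enumerate(traj.snapshots):
            d = snaps.create_dataset(
                f"{i:05d}", data=labels, compression="gzip", shuffle=True,
                track_times=False,
            )
            d.attrs["time_hr"] = t
        f.attrs["provenance"] = yaml.safe_dump(traj.provenance, sort_keys=True)
        f.attrs["strain_ids"] = ",".join(traj.strain_ids)
        f.attrs["roles"] = np.asarray(traj.roles, dtype=np.int64)
        f.attrs["status"] = traj.status
        ex = f.create_group("extras", track_order=True)
        for k, v in sorted(traj.extras.items()):
            ex.create_dataset(k, data=np.asarray(v), track_times=False)


def load_trajectory(path) -> Trajectory:
    with h5py.File(path, "r") as f:
        series = pd.DataFrame({col: f["series"][col][...] for col in f["series"]})
        snapshots = []
        for key in sorted(f["snapshots"]):
            d = f["snapshots"][key]
            snapshots.append((float(d.attrs["time_hr"]), d[...]))
        extras = {k: f["extras"][k][...] for k in f.get("extras", {})}
        return Trajectory(
            series=series,
            snapshots=snapshots,
            provenance=yaml.safe_load(f.attrs["provenance"]),
            strain_ids=list(f.attrs["strain_ids"].split(",")),
            roles=tuple(int(v) for v in f.attrs["roles"]),
            status=str(f.attrs["status"]),
            extras=extras,
        )


# -- rendering ---------------------------------------------------------------

# channel per strain role: cooperator -> red, partner -> green, cheater -> blue
_DEAD_INTENSITY = 0.4


def _strain_channel(n_strains, roles):
    chan = {}
    a, b, p = roles
    chan[a] = 0
    chan[p] = 1
    chan[b] = 2
    extra = 0
    for s in range(n_strains):
        if s not in chan:
            chan[s] = extra % 3
            extra += 1
    return chan


def render_topview(labels: np.ndarray, roles=(0, 2, 1), mode: str = "stack_sum"):
    """Top view of a 3-D label lattice as an (nx, ny, 3) float RGB image.

    ``stack_sum``: per-column live-cell counts per strain, normalized to
    the image maximum (brighter = more cells stacked).  ``topmost``: the
    color of the highest cell in each column, dimmed when dead.
    """
    if labels.ndim != 3:
        raise ValueError("expects a 3-D label lattice")
    nx, ny, nz = labels.shape
    n_strains = int(np.abs(labels).max()) if labels.size else 0
    chan = _strain_channel(max(n_strains, 3), roles)
    img = np.zeros((nx, ny, 3))
    if mode == "stack_sum":
        for s in range(n_strains):
            img[:, :, chan[s]] += (labels == s + 1).sum(axis=2)
        peak = img.max()
        if peak > 0:
            img /= peak
    elif mode == "topmost":
        occ = labels != 0
        has = occ.any(axis=2)
        top = nz - 1 - np.argmax(occ[:, :, ::-1], axis=2)
        xx, yy = np.nonzero(has)
        codes = labels[xx, yy, top[xx, yy]]
        for x, y, c in zip(xx, yy, codes):
            inten = 1.0 if c > 0 else _DEAD_INTENSITY
            img[x, y, chan[abs(int(c)) - 1]] = inten
    else:
        raise ValueError(f"unknown top-view mode {mode!r}")
    return img


def render_cross_section(labels: np.ndarray, axis: str, coordinate: int,
                         roles=(0, 2, 1)):
    """Vertical cross-section (z by lateral axis); dead cells render at
    reduced intensity, matching how dim fluorescence marks dead cells."""
    if axis not in ("x", "y"):
        raise ValueError("axis must be 'x' or 'y'")
    ax = 0 if axis == "x" else 1
    if not 0 <= coordinate < labels.shape[ax]:
        raise IndexError(f"coordinate {coordinate} out of range on axis {axis}")
    sec = labels[coordinate] if ax == 0 else labels[:, coordinate]
    # sec: (lateral, z); render as (z, lateral) with z upward
    n_strains = int(np.abs(labels).max()) if labels.size else 0
    chan = _strain_channel(max(n_strains, 3), roles)
    nlat, nz = sec.shape
    img = np.zeros((nz, nlat, 3))
    for s in range(n_strains):
        img[:, :, chan[s]] += (sec.T == s + 1) * 1.0
        img[:, :, chan[s]] += (sec.T == -(s + 1)) * _DEAD_INTENSITY
    return img[::-1]  # z = 0 at the bottom of the image
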