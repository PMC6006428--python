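"""Architectural measurements on ring assemblies.

Difference maps between normalized ring densities, rotational register
between placement sets, cylindrical ring geometry (channel diameter,
outer diameter, axial extent) and head-to-tail adjacency of ring
oligomers.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .density import DensityMap, Pose, assert_same_grid
from .phantoms import BeadModel

__all__ = [
    "difference_map",
    "rotational_register",
    "ring_geometry",
    "head_to_tail_graph",
    "ring_region_masks",
]


def ring_region_masks(dmap: DensityMap, z_split_nm: float = 12.0) -> dict[str, DensityMap]:
    """Partition the grid into cytoplasmic (z > split), inner (|z| <=
    split) and nuclear (z < -split) ring regions along the pore axis."""
    n = dmap.shape[2]
    z = dmap.origin[2] + dmap.voxel_size * np.arange(n)
    zz = np.broadcast_to(z[None, None, :], dmap.shape)
    return {
        "CR": dmap.with_values((zz > z_split_nm).astype(np.uint8)),
        "IR": dmap.with_values((np.abs(zz) <= z_split_nm).astype(np.uint8)),
        "NR": dmap.with_values((zz < -z_split_nm).astype(np.uint8)),
    }


def difference_map(map_a: DensityMap, map_b: DensityMap,
                   mask: np.ndarray | None = None) -> DensityMap:
    """Voxelwise ``a - b`` after scaling both maps to zero mean and unit
    variance inside a common mask (whole grid by default).

    Exactly antisymmetric in its arguments.  The positive part of the
    result is the density present in ``a`` but not in ``b``.
    """
    assert_same_grid(map_a, map_b)
    if mask is None:
        mask = np.ones(map_a.shape, dtype=bool)

    def _z(v):
        sel = v[mask]
        sd = sel.std()
        return (v - sel.mean()) / (sd if sd > 0 else 1.0)

    out = _z(map_a.values.astype(float)) - _z(map_b.values.astype(float))
    res = map_a.with_values(out)
    res.meta["difference_of"] = (map_a.meta.get("model", "a"), map_b.meta.get("model", "b"))
    return res


def _azimuth_deg(t: np.ndarray) -> float:
    return float(np.degrees(np.arctan2(t[1], t[0])) % 360.0)


def rotational_register(
    placements_a: pd.DataFrame,
    placements_b: pd.DataFrame,
    symmetry_order: int,
    tolerance_deg: float = 5.0,
) -> dict:
    """Azimuthal phase offsets between two placement sets sharing an axis.

    For every placement in ``a`` the nearest placement of ``b`` modulo
    the symmetry unit angle (360/order) is found; offsets are folded
    into [-unit/2, unit/2).  The sets are declared in register when the
    median absolute offset is below ``tolerance_deg``.
    """
    if placements_a.empty or placements_b.empty:
        raise ValueError("placement sets must be non-empty")
    unit = 360.0 / symmetry_order
    az_a = [_azimuth_deg(r[["tx", "ty", "tz"]].to_numpy(float)) for _, r in placements_a.iterrows()]
    az_b = [_azimuth_deg(r[["tx", "ty", "tz"]].to_numpy(float)) for _, r in placements_b.iterrows()]
    offsets = []
    for a in az_a:
        d = [(a - b + unit / 2.0) % unit - unit / 2.0 for b in az_b]
        offsets.append(min(d, key=abs))
    med = float(np.median(np.abs(offsets)))
    return {
        "offsets_deg": offsets,
        "median_abs_offset_deg": med,
        "unit_deg": unit,
        "in_register": med < tolerance_deg,
    }


def ring_geometry(dmap: DensityMap, axis: int = 2,
                  threshold: float | None = None) -> dict:
    """Channel / ring geometry from cylindrically averaged profiles.

    The density is averaged over azimuth and over the axial direction to
    give a radial profile rho(r); the isovalue defaults to half of the
    profile maximum.  Inner diameter = 2 x first radius above threshold,
    outer diameter = 2 x last such radius; the axial extent is the
    above-threshold span of the (half-max-thresholded) axial profile.
    All values in nm.
    """
    v = dmap.values.astype(float)
    if not np.any(v > 0):
        raise ValueError("map has no positive density to measure")
    shape = np.array(dmap.shape)
    ctr = (shape - 1) / 2.0
    axes = [a for a in range(3) if a != axis]
    grids = np.meshgrid(*(np.arange(n) for n in shape), indexing="ij", sparse=True)
    r = np.sqrt(sum((np.broadcast_to(grids[a], dmap.shape).astype(float) - ctr[a]) ** 2
                    for a in axes)) * dmap.voxel_size
    dr = dmap.voxel_size
    nbin = int(np.ceil(r.max() / dr)) + 1
    rbin = np.minimum((r / dr).astype(int), nbin - 1)
    prof = np.bincount(rbin.ravel(), weights=v.ravel(), minlength=nbin)
    cnt = np.bincount(rbin.ravel(), minlength=nbin)
    prof = prof / np.maximum(cnt, 1)
    if threshold is None:
        threshold = 0.5 * prof.max()
    above = np.nonzero(prof >= threshold)[0]
    if len(above) == 0:
        raise ValueError("threshold leaves no density in the radial profile")
    radii = (above + 0.5) * dr  # bin centres
    axial = v.mean(axis=tuple(axes))
    ax_above = np.nonzero(axial >= 0.5 * axial.max())[0]
    extent = (ax_above[-1] - ax_above[0] + 1) * dmap.voxel_size
    return {
        "inner_diameter_nm": float(2 * radii[0]),
        "outer_diameter_nm": float(2 * radii[-1]),
        "axial_extent_nm": float(extent),
        "threshold": float(threshold),
    }


def head_to_tail_graph(
    placements: pd.DataFrame,
    subunit_model: BeadModel,
    contact_nm: float = 8.0,
) -> list[tuple[int, int]]:
    """Directed adjacency of ring copies: edge ``(i, j)`` when copy i's
    head bead lies within ``contact_nm`` of copy j's tail bead after
    posing.  A closed head-to-tail ring of n copies yields one n-cycle.
    """
    if subunit_model.head_index is None or subunit_model.tail_index is None:
        raise ValueError("subunit model lacks head/tail bead annotation")
    heads, tails = [], []
    for _, row in placements.iterrows():
        pose = Pose((row["alpha"], row["beta"], row["gamma"]),
                    (row["tx"], row["ty"], row["tz"]))
        moved = subunit_model.transformed(pose)
        heads.append(moved.positions[subunit_model.head_index])
        tails.append(moved.positions[subunit_model.tail_index])
    edges = []
    for i, h in enumerate(heads):
        for j, t in enumerate(tails):
            if i != j and np.linalg.norm(h - t) <= contact_nm:
                edges.append((i, j))
    return edges
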