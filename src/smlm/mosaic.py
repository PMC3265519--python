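"""Focal-plane alignment and field-of-view mosaic stitching.

Within one field of view (FOV), movies taken at stepped focal planes are
aligned in x/y by cross-correlating their 2D renders against the middle
plane, then in z by cross-correlating the overlapping axial slabs of their
3D renders (the 300 nm focal step is smaller than the ~800 nm detection
range, so adjacent planes share structure). Adjacent FOVs are aligned the
same way on their overlap regions, and the resulting pairwise-offset graph
is solved for absolute positions by equal-weight iterative relaxation,
which converges to the least-squares layout on a connected graph.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .registration import hist2d, hist3d, xcorr_shift, xcorr_shift_1d
from .tables import LocalizationTable

__all__ = [
    "TileOffset", "MosaicLayout",
    "align_focal_planes", "pairwise_tile_offsets", "solve_layout", "merge_mosaic",
]


@dataclass(frozen=True)
class TileOffset:
    """Measured translation (nm) aligning tile ``j`` to tile ``i``.

    Convention: adding (dx, dy, dz) to tile j's coordinates superimposes its
    overlap region on tile i's, i.e. consistent absolute positions satisfy
    p_j - p_i = offset(i, j). ``flagged`` marks offsets whose correlation
    peak was too weak to trust (structure-free overlap); those are excluded
    from the layout solve and left to manual override.
    """

    i: int
    j: int
    dx: float
    dy: float
    dz: float = 0.0
    confidence: float = 0.0
    source: str = "auto"  # auto | manual
    flagged: bool = False

    def __post_init__(self):
        if self.confidence < 0:
            raise ValueError("confidence must be >= 0")

    def reversed(self) -> "TileOffset":
        return replace(self, i=self.j, j=self.i,
                       dx=-self.dx, dy=-self.dy, dz=-self.dz)


@dataclass
class MosaicLayout:
    """Absolute 3D position (nm) per field of view, anchored at one FOV.

    ``residuals`` maps each solved edge (i, j) to the leftover
    |p_j - p_i - offset| after convergence.
    """

    positions: dict  # fov_id -> np.ndarray (3,)
    anchor: int
    iterations: int
    max_residual: float
    converged: bool
    residuals: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# correlation helpers on localization tables

def _xy_bounds(dfs, pad: float = 0.0):
    xmin = min(df["x_nm"].min() for df in dfs) - pad
    xmax = max(df["x_nm"].max() for df in dfs) + pad
    ymin = min(df["y_nm"].min() for df in dfs) - pad
    ymax = max(df["y_nm"].max() for df in dfs) + pad
    return xmin, xmax, ymin, ymax


def _z_shift_3d(df_ref: pd.DataFrame, df_mov: pd.DataFrame, xy_pixel: float,
                z_pixel: float, max_lag_px: int = 12):
    """z shift (nm) aligning df_mov to df_ref via 3D-render correlation.

    Both tables must already be xy-aligned; the correlation is summed over
    xy at each z lag, restricted to the overlapping z slab.
    """
    zmin = min(df_ref["z_nm"].min(), df_mov["z_nm"].min())
    zmax = max(df_ref["z_nm"].max(), df_mov["z_nm"].max())
    b = _xy_bounds([df_ref, df_mov])
    bounds = (*b, zmin, zmax + z_pixel)
    a = hist3d(df_ref["x_nm"], df_ref["y_nm"], df_ref["z_nm"], xy_pixel, z_pixel, bounds)
    m = hist3d(df_mov["x_nm"], df_mov["y_nm"], df_mov["z_nm"], xy_pixel, z_pixel, bounds)
    a = a - a.mean()
    m = m - m.mean()
    nz = a.shape[0]
    lags = np.arange(-min(max_lag_px, nz - 1), min(max_lag_px, nz - 1) + 1)
    c = np.empty(len(lags))
    for k, lag in enumerate(lags):
        if lag >= 0:
            c[k] = np.sum(a[lag:] * m[:nz - lag])
        else:
            c[k] = np.sum(a[:nz + lag] * m[-lag:])
    i = int(np.argmax(c))
    med = np.median(c)
    mad = np.median(np.abs(c - med))
    conf = float((c[i] - med) / (1.4826 * mad)) if mad > 0 else 0.0
    shift = float(lags[i])
    if 0 < i < len(c) - 1:
        denom = c[i - 1] - 2 * c[i] + c[i + 1]
        if abs(denom) > 1e-30:
            shift += float(np.clip(0.5 * (c[i - 1] - c[i + 1]) / denom, -1, 1))
    # a[z + lag] matching m[z] means m must move by +lag to match a
    return shift * z_pixel, conf


def align_focal_planes(tables, xy_pixel: float = 25.0, z_pixel: float = 50.0,
                       reference: int | None = None,
                       min_confidence: float = 5.0):
    """Align one FOV's focal-plane datasets and merge them.

    ``tables`` are LocalizationTables ordered by focal position (3D mode,
    z in absolute nm including the focal-plane step). Returns
    (master_table, offsets): x/y offsets come from 2D-render correlation
    against the middle plane, z offsets from 3D correlation of adjacent
    overlap slabs, accumulated outward from the reference. Planes whose
    correlation is below ``min_confidence`` are flagged rather than
    silently aligned.
    """
    tables = list(tables)
    if not tables:
        raise ValueError("no focal-plane tables given")
    ref = len(tables) // 2 if reference is None else reference
    dfs = [t.df for t in tables]
    bounds = _xy_bounds(dfs, pad=xy_pixel)
    ref_render = hist2d(dfs[ref]["x_nm"], dfs[ref]["y_nm"], xy_pixel, bounds)

    offsets = []
    shifted = []
    flagged_planes = set()
    for p, df in enumerate(dfs):
        if p == ref:
            offsets.append(TileOffset(ref, p, 0.0, 0.0, 0.0, np.inf))
            shifted.append(df.copy())
            continue
        r = hist2d(df["x_nm"], df["y_nm"], xy_pixel, bounds)
        (sy, sx), conf = xcorr_shift(ref_render, r)
        flag = conf < min_confidence
        if flag:
            flagged_planes.add(p)
            warnings.warn(
                f"focal plane {p}: correlation confidence {conf:.1f} below "
                f"floor; offset flagged for manual correction", stacklevel=2)
            sx = sy = 0.0
        out = df.copy()
        out["x_nm"] += sx * xy_pixel
        out["y_nm"] += sy * xy_pixel
        offsets.append(TileOffset(ref, p, sx * xy_pixel, sy * xy_pixel, 0.0,
                                  float(max(conf, 0.0)), flagged=flag))
        shifted.append(out)

    # z offsets: chain adjacent pairs outward from the reference plane
    dz_abs = {ref: 0.0}
    order = list(range(ref + 1, len(dfs))) + list(range(ref - 1, -1, -1))
    for p in order:
        q = p - 1 if p > ref else p + 1  # neighbor closer to the reference
        dz_pair, conf = _z_shift_3d(shifted[q], shifted[p], xy_pixel, z_pixel)
        if conf < min_confidence or p in flagged_planes:
            if p not in flagged_planes:
                flagged_planes.add(p)
                warnings.warn(
                    f"focal plane {p}: z-overlap correlation confidence "
                    f"{conf:.1f} below floor; flagged", stacklevel=2)
            dz_pair = 0.0
        dz_abs[p] = dz_abs[q] + dz_pair
        offsets[p] = replace(offsets[p], dz=dz_abs[p],
                             flagged=offsets[p].flagged or p in flagged_planes)

    merged = []
    for p, df in enumerate(shifted):
        out = df.copy()
        out["z_nm"] += dz_abs[p]
        out["plane"] = p
        merged.append(out)
    master = LocalizationTable(
        pd.concat(merged, ignore_index=True),
        pixel_size_nm=tables[0].pixel_size_nm,
        n_frames=max(t.n_frames for t in tables))
    master.metadata["plane_offsets"] = offsets
    return master, offsets


def pairwise_tile_offsets(tables: dict, adjacency, xy_pixel: float = 25.0,
                          z_pixel: float = 50.0, min_confidence: float = 5.0,
                          max_shift_nm: float = 300.0) -> list:
    """Cross-correlate overlap regions of adjacent FOVs.

    ``tables`` maps fov_id to its master LocalizationTable in nominal
    (stage) coordinates; ``adjacency`` lists (i, j) pairs with nonzero
    nominal overlap. Both tiles are rendered over the strict common
    bounding box and the correlation peak searched within
    ``max_shift_nm`` (the stage's return accuracy), which suppresses the
    window-edge maximum that thin quasi-1D structures otherwise produce.
    Confidence is the correlation-peak prominence; structure-free overlaps
    are flagged.
    """
    out = []
    for i, j in adjacency:
        if i == j:
            out.append(TileOffset(i, j, 0.0, 0.0, 0.0, np.inf))
            continue
        a, b = tables[i].df, tables[j].df
        xmin = max(a["x_nm"].min(), b["x_nm"].min())
        xmax = min(a["x_nm"].max(), b["x_nm"].max())
        ymin = max(a["y_nm"].min(), b["y_nm"].min())
        ymax = min(a["y_nm"].max(), b["y_nm"].max())
        if xmax <= xmin or ymax <= ymin:
            raise ValueError(f"tiles {i} and {j} have no nominal overlap")
        bounds = (xmin, xmax + xy_pixel, ymin, ymax + xy_pixel)
        sel_a = a[(a["x_nm"] >= bounds[0]) & (a["x_nm"] < bounds[1])
                  & (a["y_nm"] >= bounds[2]) & (a["y_nm"] < bounds[3])]
        sel_b = b[(b["x_nm"] >= bounds[0]) & (b["x_nm"] < bounds[1])
                  & (b["y_nm"] >= bounds[2]) & (b["y_nm"] < bounds[3])]
        ra = hist2d(sel_a["x_nm"], sel_a["y_nm"], xy_pixel, bounds)
        rb = hist2d(sel_b["x_nm"], sel_b["y_nm"], xy_pixel, bounds)
        # light smoothing only: the emitter speckle is what pins the
        # correlation along a tube's axis
        (sy, sx), conf = xcorr_shift(
            ra, rb, smooth=0.5,
            max_shift=max(int(np.ceil(max_shift_nm / xy_pixel)), 1))
        flag = conf < min_confidence
        dz = 0.0
        if not flag and sel_a["z_nm"].notna().all() and sel_b["z_nm"].notna().all() \
                and len(sel_a) and len(sel_b):
            moved = sel_b.copy()
            moved["x_nm"] += sx * xy_pixel
            moved["y_nm"] += sy * xy_pixel
            dz, zconf = _z_shift_3d(sel_a, moved, xy_pixel, z_pixel)
            if zconf < min_confidence:
                dz = 0.0
        if flag:
            warnings.warn(
                f"tiles ({i},{j}): overlap correlation confidence {conf:.1f} "
                "below floor; offset flagged for manual correction",
                stacklevel=2)
            sx = sy = 0.0
        out.append(TileOffset(i, j, sx * xy_pixel, sy * xy_pixel, dz,
                              float(max(conf, 0.0)), flagged=flag))
    return out


# ---------------------------------------------------------------------------
# global layout

def _components(nodes, edges):
    adj = {n: set() for n in nodes}
    for i, j in edges:
        adj[i].add(j)
        adj[j].add(i)
    seen = set()
    comps = []
    for n in nodes:
        if n in seen:
            continue
        stack, comp = [n], set()
        while stack:
            u = stack.pop()
            if u in comp:
                continue
            comp.add(u)
            stack.extend(adj[u] - comp)
        seen |= comp
        comps.append(sorted(comp))
    return comps


def solve_layout(offsets, tol: float = 1.0, max_iter: int = 10000,
                 anchor: int | None = None) -> MosaicLayout:
    """Solve pairwise offsets for absolute FOV positions.

    Iterative equal-weight relaxation: every FOV is repeatedly moved to the
    mean of (neighbor position - pairwise offset) over all its neighbors,
    with one anchor FOV held fixed, until the maximum per-iteration movement
    drops below ``tol`` nm or the iteration cap is hit. Manual-source
    offsets are honored as hard constraints by locking the two FOVs into a
    rigid cluster. On a connected graph this fixed point is the
    least-squares solution of the offset system.
    """
    nodes = sorted({o.i for o in offsets} | {o.j for o in offsets})
    if not nodes:
        raise ValueError("no offsets given")
    offsets = [o for o in offsets if o.i != o.j]
    if not offsets:  # isolated tile(s): place at origin
        return MosaicLayout(positions={n: np.zeros(3) for n in nodes},
                            anchor=nodes[0], iterations=0, max_residual=0.0,
                            converged=True)
    usable = [o for o in offsets if not o.flagged]

    # rigid clusters from manual constraints
    parent = {n: n for n in nodes}

    def find(n):
        while parent[n] != n:
            parent[n] = parent[parent[n]]
            n = parent[n]
        return n

    manual = [o for o in usable if o.source == "manual"]
    internal = {n: np.zeros(3) for n in nodes}  # node position within its cluster
    for o in manual:
        ri, rj = find(o.i), find(o.j)
        d = np.array([o.dx, o.dy, o.dz])
        if ri == rj:
            continue
        # attach rj's cluster so that internal[j] - internal[i] = d
        shift = internal[o.i] + d - internal[o.j]
        for n in nodes:
            if find(n) == rj:
                internal[n] = internal[n] + shift
        parent[rj] = ri

    clusters = sorted({find(n) for n in nodes})
    edges = []
    for o in usable:
        ci, cj = find(o.i), find(o.j)
        if ci == cj:
            continue
        d = np.array([o.dx, o.dy, o.dz]) + internal[o.i] - internal[o.j]
        edges.append((ci, cj, d))

    comps = _components(clusters, [(i, j) for i, j, _ in edges])
    if len(comps) > 1:
        raise ValueError(f"offset graph is disconnected: components {comps}")

    anchor = nodes[0] if anchor is None else anchor
    anchor_cluster = find(anchor)
    pos = {c: np.zeros(3) for c in clusters}
    neighbors = {c: [] for c in clusters}
    for ci, cj, d in edges:
        neighbors[ci].append((cj, -d))  # p_ci = p_cj - d
        neighbors[cj].append((ci, +d))  # p_cj = p_ci + d

    it = 0
    max_move = 0.0
    for it in range(1, max_iter + 1):
        max_move = 0.0
        for c in clusters:
            if c == anchor_cluster or not neighbors[c]:
                continue
            target = np.mean([pos[n] + d for n, d in neighbors[c]], axis=0)
            max_move = max(max_move, float(np.max(np.abs(target - pos[c]))))
            pos[c] = target
        if max_move < tol:
            break
    converged = max_move < tol
    if not converged:
        warnings.warn(
            f"layout relaxation did not converge within {max_iter} iterations "
            f"(last max movement {max_move:.2f} nm)", stacklevel=2)

    positions = {n: pos[find(n)] + internal[n] for n in nodes}
    shift0 = positions[anchor].copy()
    positions = {n: p - shift0 for n, p in positions.items()}

    residuals = {}
    for o in usable:
        d = np.array([o.dx, o.dy, o.dz])
        residuals[(o.i, o.j)] = float(
            np.max(np.abs(positions[o.j] - positions[o.i] - d)))
    max_res = max(residuals.values()) if residuals else 0.0
    return MosaicLayout(positions=positions, anchor=anchor, iterations=it,
                        max_residual=max_res, converged=converged,
                        residuals=residuals)


def merge_mosaic(tables: dict, layout: MosaicLayout) -> LocalizationTable:
    """Map every tile's localizations into the mosaic frame and concatenate.

    Provenance (fov_id, pass_id, plane when present) is retained per
    localization; counts are conserved.
    """
    parts = []
    for fov_id, table in tables.items():
        if fov_id not in layout.positions:
            raise ValueError(f"layout has no entry for fov {fov_id}")
        t = layout.positions[fov_id]
        df = table.df.copy()
        df["x_nm"] += t[0]
        df["y_nm"] += t[1]
        df["z_nm"] += t[2]
        df["fov_id"] = fov_id
        parts.append(df)
    if not parts:
        raise ValueError("no tiles to merge")
    first = next(iter(tables.values()))
    return LocalizationTable(pd.concat(parts, ignore_index=True),
                             pixel_size_nm=first.pixel_size_nm,
                             n_frames=max(t.n_frames for t in tables.values()))
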