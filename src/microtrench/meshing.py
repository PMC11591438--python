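"""Body-fitted block-structured quadrilateral meshes for trench channels.

The fluid domain is split into one rectangular block covering the clear
channel (y in [0, H]) and one ruled (transfinite) block per trench
(y in [-h, 0]) whose lateral edges follow the inclined sidewalls exactly —
no staircase approximation, so wall shear stress on sidewalls comes from a
boundary-aligned discretization.  Nodes on the y = 0 interface are shared
between blocks; grids are graded toward the walls.

Wetted-floor boundary edges are emitted in inlet->outlet traversal order and
carry the class and index of the :class:`~microtrench.geometry.Segment` they
discretize, which is what the WSS extraction consumes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .geometry import ChannelSpec, TrenchDesign, WettedProfile, build_wetted_profile

__all__ = ["Resolution", "RESOLUTIONS", "Mesh", "MeshError", "generate_mesh"]


class MeshError(RuntimeError):
    pass


@dataclass(frozen=True)
class Resolution:
    """Target spacings and grading for mesh generation.

    The base cell size is ``clear_height / ny_clear``; wall-adjacent spacing
    is refined by ``wall_refine`` (and further, down to ``min(h/3, ...)``,
    when a trench smaller than the base spacing must be resolved), growing
    geometrically with ratio ``growth`` away from walls and trench rims.
    """

    ny_clear: int = 12
    nx_open: int = 12
    wall_refine: float = 2.5
    growth: float = 1.35
    beta: float = 1.2          # tanh clustering inside trench openings
    nx_open_max: int = 48
    max_dx_factor: float = 12.0   # refuse openings coarser than this x base
    max_nodes: int = 120_000

    def scaled(self, f: float) -> "Resolution":
        return replace(
            self,
            ny_clear=max(4, round(self.ny_clear * f)),
            nx_open=max(6, round(self.nx_open * f)),
            nx_open_max=max(12, round(self.nx_open_max * f)),
            growth=max(1.08, 1.0 + (self.growth - 1.0) / f),
        )


RESOLUTIONS = {
    "sweep": Resolution(ny_clear=9, nx_open=9, nx_open_max=22, growth=1.5),
    "coarse": Resolution(),
    "medium": Resolution().scaled(1.5),
    "fine": Resolution().scaled(2.0),
}


def _geom_breakpoints(L, d0, d1, dmax, r):
    """Breakpoints on [0, L] whose spacings grow geometrically from d0 at
    the left end and d1 at the right end, capped at dmax; the sequence is
    rescaled to fill L exactly."""
    if L <= 0:
        return np.array([0.0, L])
    d0 = min(d0, L)
    d1 = min(d1, L)
    left, right = [], []
    dl, dr = d0, d1
    total = 0.0
    while total < L:
        if dl <= dr:
            step = min(dl, dmax)
            left.append(step)
            dl *= r
        else:
            step = min(dr, dmax)
            right.append(step)
            dr *= r
        total += step
    spac = np.array(left + right[::-1])
    spac *= L / spac.sum()
    return np.concatenate([[0.0], np.cumsum(spac)])


def _cluster(n: int, beta: float) -> np.ndarray:
    """n+1 points on [0,1], clustered toward both ends (tanh stretching)."""
    t = np.linspace(0.0, 1.0, n + 1)
    if beta <= 0:
        return t
    return 0.5 * (1.0 + np.tanh(beta * (2.0 * t - 1.0)) / math.tanh(beta))


@dataclass
class Mesh:
    """Unstructured view of the block mesh (shared corner nodes).

    ``quads`` are counter-clockwise; a boundary edge is addressed as
    (element, side) with side s joining local corners s and (s+1)%4, so the
    fluid always lies to the left of the edge direction.
    """

    nodes: np.ndarray            # (nn, 2)
    quads: np.ndarray            # (ne, 4) int
    inlet_edges: np.ndarray      # (k, 2) int (elem, side)
    outlet_edges: np.ndarray
    top_edges: np.ndarray
    wetted_edges: np.ndarray     # (k, 3) int (elem, side, seg_id), traversal order
    profile: WettedProfile
    wall_spacing: float          # characteristic wall-normal spacing at the floor

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_cells(self) -> int:
        return len(self.quads)

    def edge_nodes(self, elem: int, side: int) -> tuple[int, int]:
        q = self.quads[elem]
        return int(q[side]), int(q[(side + 1) % 4])

    def cell_areas(self) -> np.ndarray:
        p = self.nodes[self.quads]  # (ne,4,2)
        x, y = p[..., 0], p[..., 1]
        return 0.5 * np.abs(
            (x[:, 0] * y[:, 1] - x[:, 1] * y[:, 0])
            + (x[:, 1] * y[:, 2] - x[:, 2] * y[:, 1])
            + (x[:, 2] * y[:, 3] - x[:, 3] * y[:, 2])
            + (x[:, 3] * y[:, 0] - x[:, 0] * y[:, 3])
        )


def _x_blocks(design: TrenchDesign | None, channel: ChannelSpec,
              res: Resolution, profile: WettedProfile, base: float):
    """Partition the x axis into intervals with their breakpoint arrays.

    Returns a list of (kind, seg_ids, x_array): kind 'flat' (entrance/exit),
    'gap' (partition top) or 'open' (trench opening, seg_ids = (down, floor,
    up) profile segment indices).  Flat runs grade geometrically from the
    coarse interior spacing down to the adjacent opening's edge spacing, so
    trenches much smaller than the channel height stay resolved.
    """
    segs = profile.segments
    d_wall = base / res.wall_refine
    dmax = 2.0 * base
    out = []

    if design is None:
        s0 = segs[0]
        d2 = base if res.wall_refine == 1.0 else 2.0 * base
        out.append(("flat", (0,),
                    s0.x0 + _geom_breakpoints(s0.dx, d2, d2, d2, res.growth)))
        return out

    # opening breakpoint template per trench (all trenches identical)
    top_w = design.top_width
    n_open = int(np.clip(math.ceil(top_w / base), res.nx_open,
                         res.nx_open_max))
    if top_w / n_open > res.max_dx_factor * base:
        raise MeshError(
            f"trench opening {top_w:.3g} m cannot be resolved below "
            f"{res.max_dx_factor:g}x the base spacing {base:.3g} m "
            f"({n_open} cells); the design is outside this resolution's "
            "validity range")
    t = _cluster(n_open, res.beta)
    d_junc = min(top_w * (t[1] - t[0]), base)

    seg_ptr = 0
    if channel.entrance_length > 0:
        s0 = segs[seg_ptr]
        out.append(("flat", (seg_ptr,),
                    s0.x0 + _geom_breakpoints(s0.dx, dmax, d_junc, dmax,
                                              res.growth)))
        seg_ptr += 1
    for ti in range(design.n_trenches):
        down, floor, up = seg_ptr, seg_ptr + 1, seg_ptr + 2
        x0, x1 = segs[down].x0, segs[up].x1
        out.append(("open", (down, floor, up), x0 + (x1 - x0) * t))
        seg_ptr += 3
        if ti < design.n_trenches - 1 and design.gap > 0:
            sg = segs[seg_ptr]
            dg = min(d_junc, sg.dx / 3.0)
            out.append(("gap", (seg_ptr,),
                        sg.x0 + _geom_breakpoints(sg.dx, dg, dg, base,
                                                  res.growth)))
            seg_ptr += 1
    if channel.exit_length > 0:
        s0 = segs[seg_ptr]
        out.append(("flat", (seg_ptr,),
                    s0.x0 + _geom_breakpoints(s0.dx, d_junc, dmax, dmax,
                                              res.growth)))
    return out


def generate_mesh(design: TrenchDesign | None, channel: ChannelSpec,
                  resolution: Resolution | str = "coarse") -> Mesh:
    """Mesh the trench channel; ``design=None`` meshes the flat control.

    Raises :class:`MeshError` on degenerate cells (area below 1e-12 of the
    largest), reporting the cell index.
    """
    res = RESOLUTIONS[resolution] if isinstance(resolution, str) else resolution
    profile = build_wetted_profile(design, channel)
    H = channel.clear_height
    base = H / res.ny_clear
    blocks = _x_blocks(design, channel, res, profile, base)

    # --- global x grid of the upper block --------------------------------
    xs: list[np.ndarray] = []
    iv_slices = []  # (kind, seg_ids, column index range into global grid)
    start = 0
    for kind, seg_ids, bp in blocks:
        n = len(bp) - 1
        xs.append(bp if start == 0 else bp[1:])
        iv_slices.append((kind, seg_ids, start, start + n))
        start += n
    X = np.concatenate(xs)
    nx = len(X) - 1

    # --- y grids ----------------------------------------------------------
    d_wall = base / res.wall_refine
    if design is not None:
        d_floor = min(d_wall, max(design.height / 3.0, base / 50.0))
    else:
        d_floor = d_wall
    dmax_y = 1.5 * base if res.wall_refine > 1.0 else base
    Yu = _geom_breakpoints(H, d_floor, d_wall, dmax_y, res.growth)
    ny = len(Yu) - 1

    est_nodes = (nx + 1) * (ny + 1)
    trench_eta = None
    trench_meta = []
    if design is not None:
        h = design.height
        d_tfloor = min(d_wall, h / 3.0)
        dmax_t = max(dmax_y, h / 10.0)
        yt = _geom_breakpoints(h, d_tfloor, d_floor, dmax_t, res.growth)
        trench_eta = yt / h                       # 0 at floor, 1 at opening
        nyt = len(yt) - 1
        for kind, seg_ids, c0, c1 in iv_slices:
            if kind == "open":
                trench_meta.append((seg_ids, c0, c1, nyt))
                est_nodes += (c1 - c0 + 1) * nyt
    if est_nodes > res.max_nodes:
        f = math.sqrt(res.max_nodes / est_nodes)
        return generate_mesh(design, channel, res.scaled(f))

    # --- upper block nodes/quads ----------------------------------------
    nn_u = (nx + 1) * (ny + 1)

    def uid(i, j):
        return i * (ny + 1) + j

    nodes = [np.column_stack([np.repeat(X, ny + 1), np.tile(Yu, nx + 1)])]
    next_id = nn_u
    quads = []
    elem_of_upper = {}
    for i in range(nx):
        for j in range(ny):
            elem_of_upper[(i, j)] = len(quads)
            quads.append((uid(i, j), uid(i + 1, j), uid(i + 1, j + 1), uid(i, j + 1)))

    # --- trench blocks ---------------------------------------------------
    trench_elems = []  # per trench: dict (i,j)->elem, plus dims
    for (seg_down, seg_floor, seg_up), c0, c1, nyt in trench_meta:
        segs = profile.segments
        h = -segs[seg_floor].y0
        xf0, xf1 = segs[seg_floor].x0, segs[seg_floor].x1
        top_x = X[c0:c1 + 1]
        t_top = (top_x - top_x[0]) / (top_x[-1] - top_x[0])
        bot_x = xf0 + (xf1 - xf0) * t_top
        eta = trench_eta               # 0 at floor, 1 at opening
        nxo = c1 - c0
        ids = np.empty((nxo + 1, nyt + 1), dtype=np.int64)
        new_xy = []
        for j in range(nyt + 1):
            s = eta[j]
            if j == nyt:
                ids[:, j] = [uid(c0 + i, 0) for i in range(nxo + 1)]
                continue
            xr = (1 - s) * bot_x + s * top_x
            yr = -(1 - s) * h
            for i in range(nxo + 1):
                ids[i, j] = next_id
                new_xy.append((xr[i], yr))
                next_id += 1
        if new_xy:
            nodes.append(np.asarray(new_xy))
        emap = {}
        for i in range(nxo):
            for j in range(nyt):
                emap[(i, j)] = len(quads)
                quads.append((ids[i, j], ids[i + 1, j], ids[i + 1, j + 1], ids[i, j + 1]))
        trench_elems.append((emap, nxo, nyt))

    nodes = np.concatenate(nodes, axis=0)
    quads = np.asarray(quads, dtype=np.int64)

    # --- boundary edges --------------------------------------------------
    inlet = np.array([(elem_of_upper[(0, j)], 3) for j in range(ny)], dtype=np.int64)
    outlet = np.array([(elem_of_upper[(nx - 1, j)], 1) for j in range(ny)], dtype=np.int64)
    top = np.array([(elem_of_upper[(i, ny - 1)], 2) for i in range(nx)], dtype=np.int64)

    wetted: list[tuple[int, int, int]] = []
    ti = 0
    for kind, seg_ids, c0, c1 in iv_slices:
        if kind in ("flat", "gap"):
            sid = seg_ids[0]
            for i in range(c0, c1):
                wetted.append((elem_of_upper[(i, 0)], 0, sid))
        else:
            seg_down, seg_floor, seg_up = seg_ids
            emap, nxo, nyt = trench_elems[ti]
            ti += 1
            for j in range(nyt - 1, -1, -1):       # descend the left sidewall
                wetted.append((emap[(0, j)], 3, seg_down))
            for i in range(nxo):                    # cross the floor
                wetted.append((emap[(i, 0)], 0, seg_floor))
            for j in range(nyt):                    # climb the right sidewall
                wetted.append((emap[(nxo - 1, j)], 1, seg_up))
    wetted = np.asarray(wetted, dtype=np.int64)

    mesh = Mesh(
        nodes=nodes, quads=quads,
        inlet_edges=inlet, outlet_edges=outlet, top_edges=top,
        wetted_edges=wetted, profile=profile,
        wall_spacing=float(Yu[1] - Yu[0]),
    )
    areas = mesh.cell_areas()
    bad = np.where(areas < 1e-12 * areas.max())[0]
    if len(bad):
        raise MeshError(f"degenerate cell(s), first index {int(bad[0])}")
    # positive orientation check (signed area of first triangle of each quad)
    p = nodes[quads]
    cross = (p[:, 1, 0] - p[:, 0, 0]) * (p[:, 3, 1] - p[:, 0, 1]) - \
            (p[:, 1, 1] - p[:, 0, 1]) * (p[:, 3, 0] - p[:, 0, 0])
    if np.any(cross <= 0):
        raise MeshError(f"negatively oriented cell, index {int(np.argmin(cross))}")
    return mesh
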