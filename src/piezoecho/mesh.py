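"""Graded multi-resolution orthogonal grids and discrete differential operators.

The simulation domain is tiled by axis-aligned cubic cells ("cell complexes").
A uniform base grid of edge length ``base_h`` may be locally refined by
octant splits up to two extra levels (halving the edge each time), with
2:1 grading: face-adjacent cells never differ by more than one refinement
level.  Field values live at cell barycenters.

Topological relations between cells are tracked in six sparse neighbor
matrices, one per (axis, direction).  For a same-level neighbor the row holds
a single 1; a coarse cell facing four finer cells holds interpolation weights
1/4; a fine cell reading its single coarser neighbor holds weight 1; domain
boundary rows are zero.  From these the discrete divergence and gradient
operators are assembled in their raw (topological) form

    div    = 3 D - N_xx+ - N_yy+ - N_zz+
    grad_c = D - N_cc-

together with scaled variants that divide by the face-pair distance (and,
for the divergence, flip the sign) so that scaled div(grad) reproduces the
standard 7-point Laplacian on uniform interiors.

Indexing is 0-based and lexicographic with x fastest; cells are half-open
boxes [x_i, x_{i+1}) x [y_j, y_{j+1}) x [z_k, z_{k+1}).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, List, Optional, Sequence, Tuple, Union

import numpy as np
import scipy.sparse as sp
from scipy.spatial import cKDTree

__all__ = [
    "MultiResGrid",
    "NeighborMatrices",
    "DifferentialOperators",
    "build_grid",
    "refine",
    "face_adjacency",
    "neighbor_matrices",
    "differential_operators",
    "save_grid",
    "load_grid",
]

MAX_LEVEL = 2  # three resolution levels: h, h/2, h/4

_AXES = ("x", "y", "z")
_DIRS = ("+", "-")


class GridError(ValueError):
    pass


@dataclass
class MultiResGrid:
    """Graded orthogonal cell complex.

    centers : (N, 3) cell barycenters, m
    h       : (N,) cell edge lengths, m
    level   : (N,) refinement level in {0, 1, 2}
    """

    origin: np.ndarray
    extent: np.ndarray          # box edge lengths, m
    base_h: float
    centers: np.ndarray
    h: np.ndarray
    level: np.ndarray

    @property
    def n_cells(self) -> int:
        return self.centers.shape[0]

    @property
    def volumes(self) -> np.ndarray:
        """Per-cell volume V = h^3, m^3."""
        return self.h ** 3

    def copy(self) -> "MultiResGrid":
        return MultiResGrid(self.origin.copy(), self.extent.copy(), self.base_h,
                            self.centers.copy(), self.h.copy(), self.level.copy())


@dataclass
class NeighborMatrices:
    """Six sparse (N x N) neighbor matrices, one per (axis, direction)."""

    xp: sp.csr_matrix
    xm: sp.csr_matrix
    yp: sp.csr_matrix
    ym: sp.csr_matrix
    zp: sp.csr_matrix
    zm: sp.csr_matrix

    def get(self, axis: str, direction: str) -> sp.csr_matrix:
        return getattr(self, axis + ("p" if direction == "+" else "m"))

    def all(self) -> List[sp.csr_matrix]:
        return [self.xp, self.xm, self.yp, self.ym, self.zp, self.zm]


@dataclass
class DifferentialOperators:
    """Raw and scaled discrete differential operators.

    ``div``/``grad_*`` are the raw topological forms; ``sgrad_*`` divide the
    backward difference by the face-pair distance; ``sdiv_*`` are the
    per-component scaled forward-difference divergences (sign-flipped raw
    form) so that sum_c sdiv_c @ sgrad_c is the 7-point Laplacian on uniform
    interiors.
    """

    D: sp.csr_matrix
    div: sp.csr_matrix
    grad_x: sp.csr_matrix
    grad_y: sp.csr_matrix
    grad_z: sp.csr_matrix
    sgrad_x: sp.csr_matrix
    sgrad_y: sp.csr_matrix
    sgrad_z: sp.csr_matrix
    sdiv_x: sp.csr_matrix
    sdiv_y: sp.csr_matrix
    sdiv_z: sp.csr_matrix

    def sgrad(self) -> Tuple[sp.csr_matrix, sp.csr_matrix, sp.csr_matrix]:
        return (self.sgrad_x, self.sgrad_y, self.sgrad_z)

    def sdiv(self) -> Tuple[sp.csr_matrix, sp.csr_matrix, sp.csr_matrix]:
        return (self.sdiv_x, self.sdiv_y, self.sdiv_z)


def build_grid(extent: Sequence[float], base_h: float,
               origin: Sequence[float] = (0.0, 0.0, 0.0)) -> MultiResGrid:
    """Uniform level-0 grid over an axis-aligned box.

    ``extent`` gives the box edge lengths (m); each must be a positive
    multiple of ``base_h`` within 1e-9 relative tolerance.
    """
    extent = np.asarray(extent, dtype=float)
    origin = np.asarray(origin, dtype=float)
    if base_h <= 0:
        raise GridError("base_h must be positive")
    counts = extent / base_h
    n = np.rint(counts).astype(int)
    for ax in range(3):
        if n[ax] < 1 or abs(counts[ax] - n[ax]) > 1e-9 * max(1.0, counts[ax]):
            raise GridError(
                f"extent along {_AXES[ax]} ({extent[ax]}) is not a positive "
                f"multiple of base_h ({base_h})")
    # lexicographic, x fastest
    ix, iy, iz = np.meshgrid(np.arange(n[0]), np.arange(n[1]), np.arange(n[2]),
                             indexing="ij")
    idx = np.stack([ix.ravel(order="F"), iy.ravel(order="F"), iz.ravel(order="F")], axis=1)
    order = np.lexsort((idx[:, 0], idx[:, 1], idx[:, 2]))
    idx = idx[order]
    centers = origin + (idx + 0.5) * base_h
    n_cells = int(np.prod(n))
    return MultiResGrid(origin=origin, extent=extent, base_h=float(base_h),
                        centers=centers, h=np.full(n_cells, float(base_h)),
                        level=np.zeros(n_cells, dtype=int))


def face_adjacency(grid: MultiResGrid) -> List[Tuple[np.ndarray, np.ndarray]]:
    """Face-adjacent cell pairs per (axis, direction).

    Returns a list of six (rows, cols) index arrays ordered
    (x+, x-, y+, y-, z+, z-): ``cols[k]`` is a face neighbor of ``rows[k]``
    in that direction.  Two cells are face-adjacent when they touch along an
    axis and their cross-sections overlap with positive area.
    """
    c, h = grid.centers, grid.h
    tol = 1e-9 * grid.base_h
    tree = cKDTree(c)
    # face-adjacent centers are within ~1.66*h_max of each other
    pairs = tree.query_pairs(r=1.8 * float(h.max()) + tol, output_type="ndarray")
    out: List[Tuple[List[int], List[int]]] = [([], []) for _ in range(6)]
    if pairs.size:
        i, j = pairs[:, 0], pairs[:, 1]
        half = 0.5 * (h[i] + h[j])
        gap = c[j] - c[i]                       # (P, 3)
        for ax in range(3):
            touching = np.abs(np.abs(gap[:, ax]) - half) < tol
            perp = [a for a in range(3) if a != ax]
            ok = touching
            for a in perp:
                lo = np.maximum(c[i, a] - h[i] / 2, c[j, a] - h[j] / 2)
                hi = np.minimum(c[i, a] + h[i] / 2, c[j, a] + h[j] / 2)
                ok = ok & (hi - lo > tol)
            sel = np.flatnonzero(ok)
            pos = gap[sel, ax] > 0
            # j in +ax of i
            out[2 * ax][0].extend(i[sel[pos]]); out[2 * ax][1].extend(j[sel[pos]])
            out[2 * ax][0].extend(j[sel[~pos]]); out[2 * ax][1].extend(i[sel[~pos]])
            # j in -ax of i (mirror)
            out[2 * ax + 1][0].extend(i[sel[~pos]]); out[2 * ax + 1][1].extend(j[sel[~pos]])
            out[2 * ax + 1][0].extend(j[sel[pos]]); out[2 * ax + 1][1].extend(i[sel[pos]])
    return [(np.asarray(r, dtype=int), np.asarray(s, dtype=int)) for r, s in out]


def is_graded(grid: MultiResGrid) -> bool:
    """True when no face-adjacent pair differs by more than one level."""
    for rows, cols in face_adjacency(grid):
        if rows.size and np.any(np.abs(grid.level[rows] - grid.level[cols]) > 1):
            return False
    return True


def _split_cells(grid: MultiResGrid, which: np.ndarray) -> MultiResGrid:
    """Replace each selected cell by its 8 octant children."""
    keep = np.ones(grid.n_cells, dtype=bool)
    keep[which] = False
    offs = np.array([[sx, sy, sz] for sz in (-1, 1) for sy in (-1, 1) for sx in (-1, 1)],
                    dtype=float)
    new_centers = (grid.centers[which, None, :] +
                   offs[None, :, :] * (grid.h[which, None, None] / 4.0)).reshape(-1, 3)
    new_h = np.repeat(grid.h[which] / 2.0, 8)
    new_level = np.repeat(grid.level[which] + 1, 8)
    return MultiResGrid(
        origin=grid.origin, extent=grid.extent, base_h=grid.base_h,
        centers=np.vstack([grid.centers[keep], new_centers]),
        h=np.concatenate([grid.h[keep], new_h]),
        level=np.concatenate([grid.level[keep], new_level]),
    )


Region = Union[np.ndarray, Sequence[Sequence[float]], Callable[[np.ndarray], np.ndarray]]


def _region_mask(grid: MultiResGrid, region: Region) -> np.ndarray:
    if callable(region):
        return np.asarray(region(grid.centers), dtype=bool)
    box = np.asarray(region, dtype=float)  # (3, 2) [lo, hi] per axis
    if box.shape != (3, 2):
        raise GridError("region box must be a (3, 2) [lo, hi] array")
    tol = 1e-9 * grid.base_h
    lo = np.maximum(grid.centers - grid.h[:, None] / 2, box[None, :, 0])
    hi = np.minimum(grid.centers + grid.h[:, None] / 2, box[None, :, 1])
    return np.all(hi - lo > tol, axis=1)


def refine(grid: MultiResGrid, region: Region, target_level: int) -> MultiResGrid:
    """Refine every cell intersecting ``region`` to ``target_level``, graded.

    Cells are split into octants until they reach the target level; 2:1
    grading is enforced by propagating splits across faces so that no
    face-adjacent pair differs by more than one level.
    """
    if not 0 <= target_level <= MAX_LEVEL:
        raise GridError(f"target_level must be in [0, {MAX_LEVEL}]")
    g = grid.copy()
    while True:
        to_split = np.zeros(g.n_cells, dtype=bool)
        mask = _region_mask(g, region)
        to_split |= mask & (g.level < target_level)
        for rows, cols in face_adjacency(g):
            if rows.size:
                viol = g.level[cols] - g.level[rows] > 1
                to_split[rows[viol]] = True
        which = np.flatnonzero(to_split)
        if which.size == 0:
            return g
        g = _split_cells(g, which)


def neighbor_matrices(grid: MultiResGrid) -> NeighborMatrices:
    """Assemble the six sparse neighbor matrices of a graded grid.

    Row l of N_{cc,d} holds 1 at its single same-or-coarser-level neighbor,
    interpolation weights 1/4 at each of four finer face neighbors, or is
    all-zero at the domain boundary; row sums are in {0, 1}.
    """
    adj = face_adjacency(grid)
    for rows, cols in adj:
        if rows.size and np.any(np.abs(grid.level[rows] - grid.level[cols]) > 1):
            raise GridError("grid is not graded (face-level jump > 1)")
    n = grid.n_cells
    mats = []
    for rows, cols in adj:
        if rows.size:
            counts = np.bincount(rows, minlength=n).astype(float)
            weights = 1.0 / counts[rows]
            m = sp.csr_matrix((weights, (rows, cols)), shape=(n, n))
        else:
            m = sp.csr_matrix((n, n))
        mats.append(m)
    return NeighborMatrices(*mats)


def _row_distance(grid: MultiResGrid, nbr: sp.csr_matrix) -> np.ndarray:
    """Per-row face-pair distance: average of own h and weighted neighbor h."""
    nbr = nbr.tocsr()
    nbr_h = nbr @ grid.h            # weighted mean neighbor edge (0 where empty)
    has = np.diff(nbr.indptr) > 0
    dist = np.ones(grid.n_cells)
    dist[has] = 0.5 * (grid.h[has] + nbr_h[has])
    return dist


def _row_scale(grid: MultiResGrid, mat: sp.csr_matrix, nbr: sp.csr_matrix,
               sign: float) -> sp.csr_matrix:
    """Scale rows by sign/distance, zeroing rows without a neighbor."""
    has = (np.diff(nbr.tocsr().indptr) > 0).astype(float)
    scale = sign * has / _row_distance(grid, nbr)
    return sp.diags(scale) @ mat


def differential_operators(grid: MultiResGrid,
                           nbrs: Optional[NeighborMatrices] = None) -> DifferentialOperators:
    """Raw and scaled discrete divergence/gradient operators of a graded grid."""
    if nbrs is None:
        nbrs = neighbor_matrices(grid)
    n = grid.n_cells
    if nbrs.xp.shape != (n, n):
        raise GridError("neighbor matrices inconsistent with grid size")
    D = sp.identity(n, format="csr")
    div = (3 * D - nbrs.xp - nbrs.yp - nbrs.zp).tocsr()
    grads = {ax: (D - nbrs.get(ax, "-")).tocsr() for ax in _AXES}
    sgrads = {ax: _row_scale(grid, grads[ax], nbrs.get(ax, "-"), +1.0) for ax in _AXES}
    # per-component forward-difference divergence: -(D - N_cc+)/dist
    sdivs = {ax: _row_scale(grid, (D - nbrs.get(ax, "+")).tocsr(), nbrs.get(ax, "+"), -1.0)
             for ax in _AXES}
    return DifferentialOperators(
        D=D, div=div,
        grad_x=grads["x"], grad_y=grads["y"], grad_z=grads["z"],
        sgrad_x=sgrads["x"], sgrad_y=sgrads["y"], sgrad_z=sgrads["z"],
        sdiv_x=sdivs["x"], sdiv_y=sdivs["y"], sdiv_z=sdivs["z"],
    )


def save_grid(grid: MultiResGrid, path: str,
              nbrs: Optional[NeighborMatrices] = None) -> None:
    """Serialize a grid (and optionally its neighbor matrices) to HDF5."""
    import h5py

    with h5py.File(path, "w") as f:
        f.attrs["base_h"] = grid.base_h
        f.create_dataset("origin", data=grid.origin)
        f.create_dataset("extent", data=grid.extent)
        f.create_dataset("centers", data=grid.centers)
        f.create_dataset("h", data=grid.h)
        f.create_dataset("level", data=grid.level)
        if nbrs is not None:
            for name, m in zip(("xp", "xm", "yp", "ym", "zp", "zm"), nbrs.all()):
                coo = m.tocoo()
                grp = f.create_group(f"neighbors/{name}")
                grp.create_dataset("row", data=coo.row)
                grp.create_dataset("col", data=coo.col)
                grp.create_dataset("data", data=coo.data)


def load_grid(path: str) -> MultiResGrid:
    import h5py

    with h5py.File(path, "r") as f:
        return MultiResGrid(
            origin=f["origin"][()], extent=f["extent"][()],
            base_h=float(f.attrs["base_h"]), centers=f["centers"][()],
            h=f["h"][()], level=f["level"][()].astype(int),
        )
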