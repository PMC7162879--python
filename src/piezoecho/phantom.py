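"""Acoustic scene construction from grey-level slice stacks or synthetic geometry.

A phantom enters the pipeline as a stack of 2D grey-level anatomical slices.
Each slice is smoothed with a 5x5 Gaussian mask, grey levels are clustered
into tissue labels (k-means on intensity), isolated voxels are absorbed into
their surroundings, and the labeled volume is mapped onto a simulation grid
by majority vote to produce per-cell density, velocity and attenuation-law
maps.  Tissue interfaces are recovered by radial ray marching from each
tissue's centroid; the radial direction at the hit provides the surface
normal.

The synthetic-scene generator replaces external anatomical data with three
reproducible scenes: a homogeneous box, a water tank with a source plane at
one wall, and a layered breast analog (skin/fat/breast hemispherical shells
on a chest-wall slab, immersed in water).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from . import materials as mat
from .materials import MaterialProperties
from .mesh import MultiResGrid, build_grid

__all__ = [
    "LabeledVolume",
    "BoundarySurface",
    "AcousticScene",
    "smooth_and_segment",
    "extract_boundary",
    "assign_properties",
    "synthetic_scene",
    "grey_stack",
]


@dataclass
class LabeledVolume:
    """Per-voxel integer tissue labels on a regular raster.

    ``labels`` is indexed [i, j, k] with slice index k; ``spacing`` holds the
    voxel pitch per axis in metres and ``origin`` the corner of voxel
    (0, 0, 0).  Labels form a contiguous set {0..k-1}, 0 = background.
    """

    labels: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.labels.shape

    def voxel_centers(self, mask: Optional[np.ndarray] = None) -> np.ndarray:
        idx = np.argwhere(mask if mask is not None else np.ones(self.shape, bool))
        return self.origin + (idx + 0.5) * self.spacing


@dataclass
class BoundarySurface:
    """Point cloud on a tissue (or implant-layer) interface with unit normals."""

    tissue: int
    points: np.ndarray            # (M, 3), m
    normals: np.ndarray           # (M, 3), outward unit normals
    centroid: np.ndarray          # (3,), m
    inward_normals: Optional[np.ndarray] = None
    name: str = ""

    def __post_init__(self) -> None:
        norms = np.linalg.norm(self.normals, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise ValueError("surface normals must be unit length")


@dataclass
class AcousticScene:
    """Per-cell acoustic property maps over a grid, plus interface surfaces."""

    grid: MultiResGrid
    rho: np.ndarray               # kg/m^3 per cell
    v: np.ndarray                 # m/s per cell
    a: np.ndarray                 # dB MHz^-y cm^-1 per cell
    y: np.ndarray                 # attenuation exponent per cell
    surfaces: List[BoundarySurface] = field(default_factory=list)
    background: MaterialProperties = field(default_factory=lambda: mat.get_material("Water"))
    meta: Dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = self.grid.n_cells
        for name in ("rho", "v", "a", "y"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (n,):
                raise ValueError(f"{name} map must have one value per cell")
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{name} map contains non-finite values")
            setattr(self, name, arr)
        self._tree: Optional[cKDTree] = None

    # -- background / derived maps -------------------------------------
    @property
    def rho0(self) -> float:
        return self.background.rho

    def gamma0(self, frequency: float) -> complex:
        return mat.propagation_coefficient(self.background, frequency).gamma

    def gamma_map(self, frequency: float) -> np.ndarray:
        return mat.propagation_coefficient_map(self.a, self.y, self.v, frequency)

    def contrasts(self, frequency: float) -> mat.ContrastMaps:
        return mat.contrast_maps(self.rho, self.gamma_map(frequency),
                                 self.rho0, self.gamma0(frequency))

    def alpha_map(self, frequency: float) -> np.ndarray:
        """Per-cell attenuation in Np/m at ``frequency``."""
        return mat.power_law_attenuation_np_per_m(self.a, self.y, frequency)

    # -- point sampling (used by the ray tracer) -----------------------
    def cell_at(self, point: np.ndarray) -> int:
        """Index of the cell containing ``point`` (-1 outside the domain)."""
        g = self.grid
        p = np.asarray(point, dtype=float)
        if np.any(p < g.origin - 1e-12) or np.any(p > g.origin + g.extent + 1e-12):
            return -1
        if self._tree is None:
            self._tree = cKDTree(g.centers)
        _, idx = self._tree.query(p, k=min(8, g.n_cells))
        for i in np.atleast_1d(idx):
            if np.all(np.abs(p - g.centers[i]) <= g.h[i] / 2 + 1e-12):
                return int(i)
        return int(np.atleast_1d(idx)[0])

    def copy_maps(self) -> Dict[str, np.ndarray]:
        return {k: getattr(self, k).copy() for k in ("rho", "v", "a", "y")}


# ---------------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------------

def smooth_and_segment(slices: Sequence[np.ndarray], n_tissues: int,
                       sigma: float = 1.0, spacing: Sequence[float] = (1e-3,) * 3,
                       seed: int = 0) -> LabeledVolume:
    """Smooth a grey-level slice stack and cluster it into tissue labels.

    Each slice is convolved with a 5x5 Gaussian mask (sigma in pixels,
    reflection padding), grey levels are clustered with k-means into
    ``n_tissues`` labels ordered by increasing mean intensity, and isolated
    single-voxel islands are reassigned to the majority label of their six
    face neighbors.
    """
    from sklearn.cluster import KMeans

    slices = [np.asarray(s, dtype=float) for s in slices]
    if len(slices) == 0:
        raise ValueError("empty slice stack")
    shape0 = slices[0].shape
    if any(s.shape != shape0 for s in slices):
        raise ValueError("all slices must have the same shape")
    if n_tissues < 1:
        raise ValueError("n_tissues must be >= 1")

    radius = 2  # 5x5 mask
    smoothed = [ndimage.gaussian_filter(s, sigma=sigma, mode="reflect",
                                        truncate=radius / sigma) for s in slices]
    vol = np.stack(smoothed, axis=-1)  # (rows, cols, slices) -> (i, j, k)
    values = vol.reshape(-1, 1)
    n_distinct = np.unique(values).size
    if n_tissues > n_distinct:
        raise ValueError(
            f"n_tissues={n_tissues} exceeds the {n_distinct} distinct grey levels")
    if n_tissues == 1:
        labels = np.zeros(vol.shape, dtype=int)
    else:
        km = KMeans(n_clusters=n_tissues, n_init=10, random_state=seed)
        fit_values = values
        if values.shape[0] > 100_000:   # subsample for the fit, predict all
            rng = np.random.default_rng(seed)
            fit_values = values[rng.choice(values.shape[0], 100_000, replace=False)]
        km.fit(fit_values)
        order = np.argsort(km.cluster_centers_.ravel(), kind="stable")
        remap = np.empty(n_tissues, dtype=int)
        remap[order] = np.arange(n_tissues)   # lower intensity -> lower label
        labels = remap[km.predict(values)].reshape(vol.shape)
    labels = _remove_isolated(labels)
    return LabeledVolume(labels=labels, spacing=np.asarray(spacing, dtype=float))


def _remove_isolated(labels: np.ndarray) -> np.ndarray:
    """Reassign single-voxel islands to the majority of their face neighbors."""
    out = labels.copy()
    structure = ndimage.generate_binary_structure(3, 1)  # 6-connectivity
    for lab in np.unique(labels):
        comp, n = ndimage.label(labels == lab, structure=structure)
        if n == 0:
            continue
        sizes = np.bincount(comp.ravel())
        singles = np.flatnonzero(sizes == 1)
        for c in singles:
            if c == 0:
                continue
            (i, j, k), = np.argwhere(comp == c)
            nbr = []
            for d in (-1, 1):
                for ax in range(3):
                    idx = [i, j, k]
                    idx[ax] += d
                    if 0 <= idx[ax] < labels.shape[ax]:
                        nbr.append(labels[tuple(idx)])
            nbr = [x for x in nbr if x != lab]
            if nbr:
                vals, counts = np.unique(nbr, return_counts=True)
                out[i, j, k] = vals[np.argmax(counts)]
    return out


# ---------------------------------------------------------------------------
# boundary extraction
# ---------------------------------------------------------------------------

def _fibonacci_sphere(n: int) -> np.ndarray:
    k = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * k / n)
    theta = np.pi * (1 + 5 ** 0.5) * k
    return np.stack([np.sin(phi) * np.cos(theta),
                     np.sin(phi) * np.sin(theta),
                     np.cos(phi)], axis=1)


def extract_boundary(volume: LabeledVolume, tissue: int,
                     n_directions: int = 2048) -> BoundarySurface:
    """Boundary point cloud of a tissue by radial marching from its centroid.

    Line segments spread radially (Fibonacci-sphere directions) from the
    tissue's geometric centroid in half-voxel steps until the label changes;
    the terminal point is kept and the radial direction serves as the
    outward normal.  Non-star-convex tissues keep the first transition per
    direction (with a warning).
    """
    mask = volume.labels == tissue
    count = int(mask.sum())
    if count == 0:
        raise ValueError(f"tissue {tissue} absent from volume")
    centers = volume.voxel_centers(mask)
    centroid = centers.mean(axis=0)

    if count == 1:
        # degenerate single-voxel tissue: six face centers, axis normals
        half = volume.spacing / 2.0
        pts, nrm = [], []
        for ax in range(3):
            for s in (+1.0, -1.0):
                n_hat = np.zeros(3)
                n_hat[ax] = s
                pts.append(centroid + s * half[ax] * n_hat * np.abs(n_hat))
                nrm.append(n_hat)
        return BoundarySurface(tissue=tissue, points=np.asarray(pts),
                               normals=np.asarray(nrm), centroid=centroid)

    def label_at(p: np.ndarray) -> int:
        idx = np.floor((p - volume.origin) / volume.spacing).astype(int)
        if np.any(idx < 0) or np.any(idx >= volume.labels.shape):
            return -1
        return int(volume.labels[tuple(idx)])

    if label_at(centroid) != tissue:
        warnings.warn(f"tissue {tissue} centroid lies outside the tissue "
                      "(non-star-convex); marching from nearest tissue voxel")
        centroid = centers[np.argmin(np.linalg.norm(centers - centroid, axis=1))]

    step = float(volume.spacing.min()) / 2.0
    max_steps = int(np.ceil(np.linalg.norm(volume.labels.shape * volume.spacing) / step)) + 2
    dirs = _fibonacci_sphere(n_directions)
    points, normals = [], []
    for d in dirs:
        p = centroid.copy()
        for _ in range(max_steps):
            p = p + step * d
            if label_at(p) != tissue:
                points.append(p)
                normals.append(d)
                break
    return BoundarySurface(tissue=tissue, points=np.asarray(points),
                           normals=np.asarray(normals), centroid=centroid)


# ---------------------------------------------------------------------------
# property assignment
# ---------------------------------------------------------------------------

def _cell_of_points(grid: MultiResGrid, pts: np.ndarray) -> np.ndarray:
    """Containing cell index for each point (nearest-center with containment check)."""
    tree = cKDTree(grid.centers)
    k = min(8, grid.n_cells)
    _, idx = tree.query(pts, k=k)
    idx = np.atleast_2d(idx)
    inside = np.abs(pts[:, None, :] - grid.centers[idx]) <= grid.h[idx][:, :, None] / 2 + 1e-12
    ok = np.all(inside, axis=2)
    first = np.argmax(ok, axis=1)
    out = idx[np.arange(len(pts)), first]
    out[~ok.any(axis=1)] = idx[~ok.any(axis=1), 0]
    return out


def assign_properties(volume: LabeledVolume, table: Mapping[int, MaterialProperties],
                      grid: MultiResGrid,
                      background: Optional[MaterialProperties] = None) -> AcousticScene:
    """Map a labeled volume onto a grid by per-cell majority vote.

    Each cell receives the acoustic properties of the majority label among
    the voxels whose centers it covers (ties to the smaller label); cells
    covering no voxel get the background material.  Materials without an
    attenuation law (piezo solids) are treated as lossless (a=0, y=1).
    """
    present = np.unique(volume.labels)
    missing = [int(l) for l in present if l not in table]
    if missing:
        raise ValueError(f"unmapped labels: {missing}")
    if background is None:
        background = table.get(0, mat.get_material("Water"))

    pts = volume.voxel_centers()
    lab = volume.labels.ravel()  # argwhere order == C order of ones mask
    # voxel_centers uses np.argwhere over the full mask -> C order, consistent:
    lab = volume.labels[tuple(np.argwhere(np.ones(volume.shape, bool)).T)]
    cells = _cell_of_points(grid, pts)
    n = grid.n_cells
    n_labels = int(present.max()) + 1
    counts = np.zeros((n, n_labels), dtype=np.int64)
    np.add.at(counts, (cells, lab), 1)
    majority = np.argmax(counts, axis=1)      # argmax ties -> smaller label
    covered = counts.sum(axis=1) > 0

    def props(m: MaterialProperties) -> Tuple[float, float, float, float]:
        return (m.rho, m.v, m.a if m.a is not None else 0.0,
                m.y if m.y is not None else 1.0)

    rho = np.empty(n); v = np.empty(n); a = np.empty(n); yy = np.empty(n)
    rho[:], v[:], a[:], yy[:] = props(background)
    for l in present:
        sel = covered & (majority == l)
        rho[sel], v[sel], a[sel], yy[sel] = props(table[int(l)])
    return AcousticScene(grid=grid, rho=rho, v=v, a=a, y=yy,
                         background=background,
                         meta={"labels": majority, "covered": covered})


# ---------------------------------------------------------------------------
# synthetic scenes
# ---------------------------------------------------------------------------

def _round_up(x: float, h: float) -> float:
    return float(np.ceil(x / h - 1e-9) * h)


def synthetic_scene(kind: str, params: Optional[Dict] = None,
                    seed: int = 0) -> Tuple[LabeledVolume, AcousticScene]:
    """Generate a reproducible synthetic scene.

    kind = "homogeneous": single-material box.
    kind = "water_tank": homogeneous water box (default 0.30 x 0.25 x 0.25 m,
        the experimental tank footprint) with the source plane centred on the
        x=0 wall and a movable receiver position stored in ``scene.meta``.
    kind = "layered_breast": hemispherical breast analog with concentric
        skin/fat/breast shells resting on a chest-wall (muscle) slab,
        immersed in water.

    Identical ``seed`` and params yield bit-identical volumes.
    """
    params = dict(params or {})
    rng = np.random.default_rng(seed)

    if kind in ("homogeneous", "water_tank"):
        if kind == "water_tank":
            extent = np.asarray(params.pop("extent", (0.30, 0.25, 0.25)), float)
            material = mat.get_material(params.pop("material", "Water"))
            base_h = float(params.pop("base_h", 0.01))
        else:
            extent = np.asarray(params.pop("extent", (0.05, 0.05, 0.05)), float)
            material = params.pop("material", mat.get_material("Water"))
            if isinstance(material, str):
                material = mat.get_material(material)
            base_h = float(params.pop("base_h", 0.005))
        if np.any(extent <= 0):
            raise ValueError("extent must be positive")
        spacing = np.asarray(params.pop("spacing", (base_h / 2,) * 3), float)
        grid = build_grid(extent, base_h)
        shape = np.maximum(np.rint(extent / spacing).astype(int), 1)
        volume = LabeledVolume(labels=np.zeros(shape, dtype=int), spacing=spacing)
        scene = assign_properties(volume, {0: material}, grid, background=material)
        scene.meta["kind"] = kind
        scene.meta["seed"] = seed
        scene.meta["source_center"] = np.array([0.0, extent[1] / 2, extent[2] / 2])
        scene.meta["source_normal"] = np.array([1.0, 0.0, 0.0])
        scene.meta["receiver"] = np.array([extent[0] * 0.5, extent[1] / 2, extent[2] / 2])
        return volume, scene

    if kind == "layered_breast":
        skin = float(params.pop("skin_mm", 2.0)) * 1e-3
        fat = float(params.pop("fat_mm", 10.0)) * 1e-3
        breast = float(params.pop("breast_mm", 18.0)) * 1e-3
        slab = float(params.pop("slab_mm", 10.0)) * 1e-3
        base_h = float(params.pop("base_h", 0.005))
        margin = float(params.pop("margin_mm", 5.0)) * 1e-3
        radius = skin + fat + breast
        ex = _round_up(2 * radius + 2 * margin, base_h)
        ez = _round_up(radius + slab + 2 * margin, base_h)
        extent = np.array(params.pop("extent", (ex, ex, ez)), float)
        spacing = np.asarray(params.pop("spacing", (base_h / 2.5,) * 3), float)
        shape = np.maximum(np.rint(extent / spacing).astype(int), 1)
        ii, jj, kk = np.indices(shape)
        pts = (np.stack([ii, jj, kk], axis=-1) + 0.5) * spacing
        center = np.array([extent[0] / 2, extent[1] / 2, slab + margin])
        r = np.linalg.norm(pts - center, axis=-1)
        labels = np.zeros(shape, dtype=int)
        labels[pts[..., 2] <= slab + margin] = 4                      # chest wall
        upper = pts[..., 2] > slab + margin
        labels[upper & (r <= radius)] = 1                             # skin
        labels[upper & (r <= radius - skin)] = 2                      # fat
        labels[upper & (r <= radius - skin - fat)] = 3                # breast
        volume = LabeledVolume(labels=labels, spacing=spacing)
        table = {0: mat.get_material("Water"), 1: mat.get_material("Breast"),
                 2: mat.get_material("Fat"), 3: mat.get_material("Breast"),
                 4: mat.get_material("Muscle")}
        # skin is not a Table row; fall back to breast-tissue values unless given
        if "skin_material" in params:
            table[1] = mat.get_material(params.pop("skin_material"))
        grid = build_grid(extent, base_h)
        scene = assign_properties(volume, table, grid,
                                  background=mat.get_material("Water"))
        for lab in (1, 2, 3, 4):
            try:
                scene.surfaces.append(extract_boundary(volume, lab,
                                                       n_directions=params.get("n_directions", 512)))
            except ValueError:
                pass
        scene.meta.update(kind=kind, seed=seed, breast_center=center,
                          breast_radius=radius)
        # source transducer in contact with the skin at the dome apex,
        # aimed down the dome axis (as in the experimental breast phantom)
        scene.meta["source_center"] = center + np.array([0.0, 0.0, radius])
        scene.meta["source_normal"] = np.array([0.0, 0.0, -1.0])
        return volume, scene

    raise ValueError(f"unknown scene kind {kind!r}")


def grey_stack(volume: LabeledVolume, levels: Optional[Sequence[float]] = None,
               noise: float = 0.0, seed: int = 0) -> List[np.ndarray]:
    """Render a labeled volume as a grey-level slice stack (for segmentation I/O)."""
    n_labels = int(volume.labels.max()) + 1
    if levels is None:
        levels = np.linspace(0.0, 255.0, n_labels)
    levels = np.asarray(levels, dtype=float)
    rng = np.random.default_rng(seed)
    grey = levels[volume.labels]
    if noise > 0:
        grey = grey + rng.normal(0.0, noise, size=grey.shape)
    return [grey[:, :, k] for k in range(grey.shape[2])]
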