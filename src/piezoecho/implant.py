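"""Implantable double-piezo-layer devices as nested layered solids.

An implant is a small solid (lens, disk or cone; default bounding box
1 cm x 1 cm x 0.5 cm) built from three nested layers: a bio-compatible PDMS
shell, an outer piezoelectric layer and an inner piezoelectric core.  Layer
interfaces are inset copies of the outer shape: each deeper interface is
offset inward by the cumulative layer thickness on the lateral and front
(axis-facing) surfaces, with a shared base plane, mirroring a coated
transducer stack.  Every interface carries a dense surface point cloud with
analytic outward normals (and their negatives as inward normals) for the ray
tracer.

Allowed inner/outer material pairs: PZN-PT or PZT-5A inside; LiNbO3, BaTiO3
or PVDF outside.  Allowed inner/outer thickness pairs (mm): 0.5/1, 1/2,
1.5/3, 2/4, 2.5/5.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from . import materials as mat
from .materials import MaterialProperties
from .mesh import refine as mesh_refine
from .phantom import AcousticScene, BoundarySurface, _cell_of_points

__all__ = ["ImplantSpec", "Layer", "LayeredSolid", "build_implant", "embed", "remove"]

SHAPES = ("lens", "disk", "cone")
MATERIAL_PAIRS = {("PZN-PT", "LiNbO3"), ("PZN-PT", "BaTiO3"), ("PZN-PT", "PVDF"),
                  ("PZT-5A", "LiNbO3"), ("PZT-5A", "BaTiO3"), ("PZT-5A", "PVDF")}
THICKNESS_PAIRS_MM = ((0.5, 1.0), (1.0, 2.0), (1.5, 3.0), (2.0, 4.0), (2.5, 5.0))

#: default sample spacing: quarter wavelength at 10 MHz in soft tissue (~1500 m/s)
DEFAULT_SPACING = 1500.0 / 10e6 / 4.0


@dataclass(frozen=True)
class ImplantSpec:
    """Geometry, materials and placement of a double-piezo-layer implant."""

    shape: str = "lens"
    inner_material: str = "PZT-5A"
    outer_material: str = "LiNbO3"
    inner_thickness_mm: float = 1.0
    outer_thickness_mm: float = 2.0
    dimensions: Tuple[float, float, float] = (0.01, 0.01, 0.005)  # m, (dx, dy, axis)
    position: Tuple[float, float, float] = (0.0, 0.0, 0.0)        # base-plane centre, m
    axis: Tuple[float, float, float] = (0.0, 0.0, 1.0)            # orientation unit axis
    pdms_thickness_mm: float = 0.5
    sample_spacing: Optional[float] = None

    def __post_init__(self) -> None:
        if self.shape not in SHAPES:
            raise ValueError(f"shape must be one of {SHAPES}")
        if (self.inner_material, self.outer_material) not in MATERIAL_PAIRS:
            raise ValueError(
                f"material pair {self.inner_material}/{self.outer_material} not allowed; "
                f"allowed pairs: {sorted(MATERIAL_PAIRS)}")
        pair = (self.inner_thickness_mm, self.outer_thickness_mm)
        if pair not in THICKNESS_PAIRS_MM:
            raise ValueError(f"thickness pair {pair} mm not in {THICKNESS_PAIRS_MM}")
        ax = np.asarray(self.axis, float)
        if not np.linalg.norm(ax) > 0:
            raise ValueError("orientation axis must be nonzero")


@dataclass
class Layer:
    """One implant layer interface: material + sampled surface with normals."""

    name: str
    material: MaterialProperties
    points: np.ndarray            # (M, 3) world coordinates, m
    outward_normals: np.ndarray   # (M, 3) unit
    inset: float                  # cumulative inset from the bounding surface, m

    @property
    def inward_normals(self) -> np.ndarray:
        return -self.outward_normals


@dataclass
class LayeredSolid:
    """Nested implant layers (PDMS shell, outer piezo, inner piezo core)."""

    spec: ImplantSpec
    layers: List[Layer]
    rotation: np.ndarray          # local -> world rotation matrix
    base_center: np.ndarray       # world position of the base-plane centre

    def contains(self, points: np.ndarray, inset: float) -> np.ndarray:
        """Boolean mask of world points inside the interface at ``inset``."""
        local = (np.asarray(points, float) - self.base_center) @ self.rotation
        return _inside(self.spec, local, inset)

    def bounding_box(self) -> np.ndarray:
        pts = np.vstack([l.points for l in self.layers])
        return np.stack([pts.min(axis=0), pts.max(axis=0)], axis=1)

    def surfaces(self) -> List[BoundarySurface]:
        out = []
        for l in self.layers:
            out.append(BoundarySurface(
                tissue=-1, points=l.points, normals=l.outward_normals,
                centroid=l.points.mean(axis=0),
                inward_normals=l.inward_normals, name=f"implant:{l.name}"))
        return out


def _shape_dims(spec: ImplantSpec, inset: float) -> Tuple[float, float, float]:
    """(radius, z_lo, z_hi) of the interface inset from the bounding surface."""
    dx, dy, h = spec.dimensions
    radius = min(dx, dy) / 2.0 - inset
    z_lo, z_hi = 0.0, h - inset      # shared base plane at z = 0
    if radius <= 0 or z_hi - z_lo <= 0:
        raise ValueError(
            f"layer inset {inset * 1e3:.2f} mm exceeds bounding dimensions "
            f"{tuple(round(d * 1e3, 2) for d in spec.dimensions)} mm")
    return radius, z_lo, z_hi


def _inside(spec: ImplantSpec, local: np.ndarray, inset: float,
            tol: float = 0.0) -> np.ndarray:
    radius, z_lo, z_hi = _shape_dims(spec, inset)
    x, y, z = local[..., 0], local[..., 1], local[..., 2]
    r = np.hypot(x, y)
    height = z_hi - z_lo
    if spec.shape == "disk":
        return (r <= radius + tol) & (z >= z_lo - tol) & (z <= z_hi + tol)
    if spec.shape == "cone":
        rmax = radius * np.clip(1.0 - (z - z_lo) / height, 0.0, 1.0)
        return (z >= z_lo - tol) & (z <= z_hi + tol) & (r <= rmax + tol)
    # lens: paraboloid cap z = z_lo + height*(1 - (r/radius)^2)
    zcap = z_lo + height * np.clip(1.0 - (r / radius) ** 2, 0.0, 1.0)
    return (z >= z_lo - tol) & (r <= radius + tol) & (z <= zcap + tol)


def _disk_samples(radius: float, z: float, spacing: float, sign: float):
    """Points + normals over a flat disk at height z, normal sign * +z."""
    n_r = max(int(np.ceil(radius / spacing)), 1)
    pts = [np.array([[0.0, 0.0, z]])]
    for i in range(1, n_r + 1):
        r = radius * i / n_r
        n_t = max(int(np.ceil(2 * np.pi * r / spacing)), 4)
        t = 2 * np.pi * np.arange(n_t) / n_t
        pts.append(np.stack([r * np.cos(t), r * np.sin(t), np.full(n_t, z)], axis=1))
    pts = np.vstack(pts)
    normals = np.zeros_like(pts)
    normals[:, 2] = sign
    return pts, normals


def _local_surface(spec: ImplantSpec, inset: float, spacing: float):
    """Sample one interface in local coordinates with outward normals."""
    radius, z_lo, z_hi = _shape_dims(spec, inset)
    height = z_hi - z_lo
    pts_list, nrm_list = [], []

    base_pts, base_nrm = _disk_samples(radius, z_lo, spacing, -1.0)
    pts_list.append(base_pts)
    nrm_list.append(base_nrm)

    if spec.shape == "disk":
        top_pts, top_nrm = _disk_samples(radius, z_hi, spacing, +1.0)
        pts_list.append(top_pts); nrm_list.append(top_nrm)
        n_z = max(int(np.ceil(height / spacing)), 2)
        zs = z_lo + height * (np.arange(n_z) + 0.5) / n_z
        n_t = max(int(np.ceil(2 * np.pi * radius / spacing)), 8)
        t = 2 * np.pi * np.arange(n_t) / n_t
        ring = np.stack([np.cos(t), np.sin(t)], axis=1)
        side = np.concatenate(
            [np.column_stack([radius * ring, np.full(n_t, z)]) for z in zs])
        nside = np.concatenate(
            [np.column_stack([ring, np.zeros(n_t)]) for _ in zs])
        pts_list.append(side); nrm_list.append(nside)
    elif spec.shape == "cone":
        # lateral surface r(z) = radius*(1 - (z - z_lo)/height); outward
        # normal ~ (x/r * height, y/r * height, radius) normalised
        slant = np.hypot(radius, height)
        n_s = max(int(np.ceil(slant / spacing)), 2)
        for i in range(n_s):
            frac = (i + 0.5) / n_s
            z = z_lo + height * frac
            r = radius * (1.0 - frac)
            n_t = max(int(np.ceil(2 * np.pi * max(r, spacing) / spacing)), 4)
            t = 2 * np.pi * np.arange(n_t) / n_t
            cx, sx = np.cos(t), np.sin(t)
            pts_list.append(np.stack([r * cx, r * sx, np.full(n_t, z)], axis=1))
            nrm = np.stack([cx * height, sx * height, np.full(n_t, radius)], axis=1)
            nrm_list.append(nrm / np.linalg.norm(nrm, axis=1, keepdims=True))
        pts_list.append(np.array([[0.0, 0.0, z_hi]]))
        nrm_list.append(np.array([[0.0, 0.0, 1.0]]))
    else:  # lens (paraboloid cap)
        # z = z_lo + height*(1 - (r/radius)^2); gradient of
        # f = z - z_lo - height*(1 - r^2/radius^2) is (2*height*x/R^2, ..., 1)
        n_r = max(int(np.ceil(radius / spacing)), 2)
        pts_list.append(np.array([[0.0, 0.0, z_hi]]))
        nrm_list.append(np.array([[0.0, 0.0, 1.0]]))
        for i in range(1, n_r + 1):
            r = radius * i / n_r
            z = z_lo + height * (1.0 - (r / radius) ** 2)
            n_t = max(int(np.ceil(2 * np.pi * r / spacing)), 6)
            t = 2 * np.pi * np.arange(n_t) / n_t
            cx, sx = np.cos(t), np.sin(t)
            pts_list.append(np.stack([r * cx, r * sx, np.full(n_t, z)], axis=1))
            nrm = np.stack([2 * height * r * cx / radius ** 2,
                            2 * height * r * sx / radius ** 2,
                            np.ones(n_t)], axis=1)
            nrm_list.append(nrm / np.linalg.norm(nrm, axis=1, keepdims=True))
    return np.vstack(pts_list), np.vstack(nrm_list)


def _rotation_to(axis: np.ndarray) -> np.ndarray:
    """Rotation matrix mapping local +z onto ``axis`` (Rodrigues)."""
    a = axis / np.linalg.norm(axis)
    z = np.array([0.0, 0.0, 1.0])
    v = np.cross(z, a)
    c = float(np.dot(z, a))
    if np.linalg.norm(v) < 1e-12:
        return np.eye(3) if c > 0 else np.diag([1.0, -1.0, -1.0])
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx / (1.0 + c)


def build_implant(spec: ImplantSpec) -> LayeredSolid:
    """Construct the nested layered solid of an implant spec.

    Layers, outermost first: PDMS shell (bounding surface), outer piezo
    (inset by the PDMS thickness) and inner piezo core (inset further by the
    outer piezo thickness).  Raises when the cumulative insets exceed the
    bounding dimensions.
    """
    spacing = spec.sample_spacing or DEFAULT_SPACING
    insets = [0.0,
              spec.pdms_thickness_mm * 1e-3,
              (spec.pdms_thickness_mm + spec.outer_thickness_mm) * 1e-3]
    names = ["pdms", spec.outer_material, spec.inner_material]
    mats = [mat.get_material("PDMS"), mat.get_material(spec.outer_material),
            mat.get_material(spec.inner_material)]
    rot = _rotation_to(np.asarray(spec.axis, float))
    base = np.asarray(spec.position, float)
    layers = []
    for name, material, inset in zip(names, mats, insets):
        pts, nrm = _local_surface(spec, inset, spacing)
        layers.append(Layer(name=name, material=material,
                            points=base + pts @ rot.T,
                            outward_normals=nrm @ rot.T, inset=inset))
    return LayeredSolid(spec=spec, layers=layers, rotation=rot, base_center=base)


def embed(scene: AcousticScene, solid: LayeredSolid, refine_level: int = 2,
          corridor: bool = True) -> AcousticScene:
    """Embed an implant into a scene, refining the mesh around it.

    Cells inside each layer interface get that layer's material (innermost
    wins); the layer surfaces are appended to the scene surface list.  With
    ``refine_level`` > 0 the mesh is refined to that level in a padded box
    around the implant plus, when a source position is known, the corridor
    connecting the source to the implant.  The pre-implant property maps (on
    the refined grid) are stashed in ``meta`` so :func:`remove` can restore
    them.
    """
    g = scene.grid
    bbox = solid.bounding_box()
    lo, hi = bbox[:, 0], bbox[:, 1]
    if np.any(lo < g.origin - 1e-12) or np.any(hi > g.origin + g.extent + 1e-12):
        raise ValueError("implant does not fit inside the scene domain")
    src = scene.meta.get("source_center")
    if src is not None and solid.contains(np.asarray(src)[None, :], 0.0)[0]:
        raise ValueError("implant overlaps the source transducer")

    if refine_level > 0:
        pad = g.base_h / 2
        box = np.stack([lo - pad, hi + pad], axis=1)
        grid = mesh_refine(g, box, refine_level)
        if corridor and src is not None:
            # the finest elements cover the source-implant corridor
            mid = 0.5 * (lo + hi)
            clo = np.minimum(mid, src) - pad / 2
            chi = np.maximum(mid, src) + pad / 2
            grid = mesh_refine(grid, np.stack([clo, chi], axis=1), refine_level)
    else:
        grid = g.copy()

    # resample pre-implant maps onto the (possibly refined) grid
    old_cells = _cell_of_points(g, grid.centers)
    maps = {k: getattr(scene, k)[old_cells] for k in ("rho", "v", "a", "y")}
    original = {k: m.copy() for k, m in maps.items()}

    def props(m: MaterialProperties):
        return (m.rho, m.v, m.a if m.a is not None else 0.0,
                m.y if m.y is not None else 1.0)

    for layer in solid.layers:   # outermost -> innermost: innermost wins
        sel = solid.contains(grid.centers, layer.inset)
        maps["rho"][sel], maps["v"][sel], maps["a"][sel], maps["y"][sel] = props(layer.material)

    new_scene = AcousticScene(
        grid=grid, rho=maps["rho"], v=maps["v"], a=maps["a"], y=maps["y"],
        surfaces=list(scene.surfaces) + solid.surfaces(),
        background=scene.background,
        meta={**scene.meta, "implants": scene.meta.get("implants", []) + [solid.spec],
              "pre_implant_maps": original, "n_pre_implant_surfaces": len(scene.surfaces)},
    )
    return new_scene


def remove(scene: AcousticScene) -> AcousticScene:
    """Undo the most recent :func:`embed` (restores stored property maps)."""
    if "pre_implant_maps" not in scene.meta:
        raise ValueError("scene has no embedded implant to remove")
    maps = scene.meta["pre_implant_maps"]
    n_keep = scene.meta.get("n_pre_implant_surfaces", len(scene.surfaces))
    meta = {k: v for k, v in scene.meta.items()
            if k not in ("pre_implant_maps", "n_pre_implant_surfaces")}
    meta["implants"] = meta.get("implants", [])[:-1]
    return AcousticScene(grid=scene.grid, rho=maps["rho"].copy(), v=maps["v"].copy(),
                         a=maps["a"].copy(), y=maps["y"].copy(),
                         surfaces=scene.surfaces[:n_keep],
                         background=scene.background, meta=meta)
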