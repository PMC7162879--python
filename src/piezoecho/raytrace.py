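"""Ray-tracing forward operator: refraction, amplitude splitting, echoes.

Acoustic rays leave the source transducer over a forward cone, travel in
straight segments through the per-cell medium maps of an
:class:`~piezoecho.phantom.AcousticScene`, and interact with the scene's
interface surfaces (tissue boundaries, implant layers).  At every interface
hit, Snell's law (refraction index n = v_background / v_medium) sets the
transmitted angle, the 3D refracted direction follows the vector form with
the interface normal, and the amplitude splits into a reflected part
Υ^R = R·Υ and a transmitted part Υ^T = (1-R)·Υ, where
R = (z2 - z1)/(z2 + z1) is the normal-incidence impedance reflection
coefficient, so Υ = Υ^T + Υ^R holds exactly.  (The physically standard
pressure transmission T = 1 + R is available via ``pressure_continuity``.)

Per segment of length Δ a ray accumulates a time delay Δ/v, an attenuation
factor exp(-α Δ) (power-law α at the excitation frequency) and Δ/λ
wavelengths; rays die after a prescribed number of wavelengths (default
1000), when their amplitude falls below threshold, or on domain exit.
Interface hits are accepted inside a tolerance sphere of radius
0.5·(4500 m/s)/frequency, 4500 m/s being the average propagation velocity
over the tissues and piezo materials used.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.spatial import cKDTree

from .materials import reflection_coefficient
from .phantom import AcousticScene
from .scattering import SourceTransducer

__all__ = [
    "Ray",
    "Interaction",
    "EchoRecord",
    "TraceLimits",
    "snell",
    "refract_direction",
    "split_amplitude",
    "trace_rays",
    "collect_echo",
]

#: average propagation velocity (m/s) over employed tissues and piezos,
#: fixing the interface-hit tolerance sphere radius 0.5 * V_AVG / f.
V_AVG = 4500.0

AMPLITUDE_THRESHOLD = 1e-5     # 10 uV in volt-equivalent amplitude units
RECORD_CAP = 1200              # max echo records kept (largest amplitudes)


@dataclass
class Ray:
    """Directed amplitude-carrying ray segment chain."""

    origin: np.ndarray                 # start of the *current* segment, m
    direction: np.ndarray              # unit
    amplitude: float = 1.0             # nominal amplitude Υ (signed by reflections)
    delay: float = 0.0                 # accumulated sum(Δpath / v), s
    attenuation: float = 1.0           # accumulated exp(-Σ α Δpath) ∈ (0, 1]
    wavelengths: float = 0.0           # Δpath / λ accumulated
    generation: int = 0                # number of interface events
    end: Optional[np.ndarray] = None   # termination point (set when finished)
    start_state: Tuple[float, float] = (0.0, 1.0)  # (delay, attenuation) at segment start
    alive: bool = True

    def __post_init__(self) -> None:
        self.direction = np.asarray(self.direction, float)
        n = np.linalg.norm(self.direction)
        if not abs(n - 1.0) < 1e-9:
            self.direction = self.direction / n
        self.origin = np.asarray(self.origin, float)


@dataclass
class Interaction:
    """One interface event: incident ray splits into reflected/transmitted."""

    point: np.ndarray
    surface: int
    incident: Ray
    reflected: Optional[Ray]
    transmitted: Optional[Ray]


@dataclass(frozen=True)
class EchoRecord:
    """A ray arrival at the detection aperture."""

    time: float            # s
    amplitude: float       # V-equivalent (signed)
    aperture: float        # detector diameter used, m


@dataclass(frozen=True)
class TraceLimits:
    max_wavelengths: float = 1000.0
    amplitude_threshold: float = AMPLITUDE_THRESHOLD
    max_generation: int = 10
    max_rays: int = 50000


def snell(n1: float, n2: float, theta_in: float) -> Optional[float]:
    """Refraction angle from Snell's law; None on total internal reflection."""
    s = n1 * math.sin(theta_in) / n2
    if abs(s) > 1.0:
        return None
    return math.asin(s)


def refract_direction(r_hat: np.ndarray, n_hat: np.ndarray,
                      n1: float, n2: float) -> Optional[np.ndarray]:
    """3D refracted direction at an interface; None on total internal reflection.

    r' = (n1/n2) [N x (-N x r)] - N sqrt(1 - (n1/n2)^2 (N x r)·(N x r)),
    with N oriented against the incident ray (r·N < 0).  Grazing incidence
    (|r x N| = 1) with n1 > n2 is treated as TIR.
    """
    r_hat = np.asarray(r_hat, float)
    n_hat = np.asarray(n_hat, float)
    eta = n1 / n2
    cross = np.cross(n_hat, r_hat)
    radicand = 1.0 - eta ** 2 * float(cross @ cross)
    if radicand < 0.0:
        return None
    out = eta * np.cross(n_hat, -cross) - n_hat * math.sqrt(radicand)
    return out / np.linalg.norm(out)


def split_amplitude(amp: float, z1: float, z2: float,
                    pressure_continuity: bool = False) -> Tuple[float, float]:
    """(transmitted, reflected) amplitudes at an impedance step.

    Default conserves the nominal amplitude, Υ^T + Υ^R = Υ (T = 1 - R);
    ``pressure_continuity`` switches to the standard T = 1 + R.
    """
    R = reflection_coefficient(z1, z2)
    reflected = R * amp
    transmitted = (1.0 + R) * amp if pressure_continuity else (1.0 - R) * amp
    return transmitted, reflected


class _SurfaceIndex:
    """KD-tree over all scene surface points with per-point normals."""

    def __init__(self, scene: AcousticScene):
        pts, nrm, sid = [], [], []
        for i, s in enumerate(scene.surfaces):
            pts.append(s.points)
            nrm.append(s.normals)
            sid.append(np.full(len(s.points), i))
        self.empty = not pts
        if not self.empty:
            self.points = np.vstack(pts)
            self.normals = np.vstack(nrm)
            self.surface_id = np.concatenate(sid)
            self.tree = cKDTree(self.points)

    def query(self, p: np.ndarray, tol: float):
        if self.empty:
            return None
        d, i = self.tree.query(p, k=1, distance_upper_bound=tol)
        if not np.isfinite(d):
            return None
        return int(i), float(d)


def _exit_length(origin: np.ndarray, direction: np.ndarray,
                 lo: np.ndarray, hi: np.ndarray) -> float:
    """Length along the ray to the domain box boundary."""
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = (lo - origin) / direction
        t2 = (hi - origin) / direction
    t = np.where(np.isfinite(t1), np.maximum(t1, t2), np.inf)
    return float(np.min(t))


def trace_rays(scene: AcousticScene, source: SourceTransducer, frequency: float,
               n_rays: int = 256, limits: Optional[TraceLimits] = None,
               cone_half_angle: float = np.deg2rad(30.0), seed: int = 0,
               source_amplitude: float = 10.0,
               pressure_continuity: bool = False,
               ) -> Tuple[List[Ray], List[Interaction]]:
    """Trace rays from the source through the scene.

    Rays are emitted from uniformly sampled points of the source disk with
    directions drawn uniformly in solid angle inside a forward cone (default
    half-angle 30 degrees) about the source normal; each carries amplitude
    ``source_amplitude / n_rays``.  Returns the finished rays (each holding
    its terminal segment and accumulated delay/attenuation) and the list of
    interface interactions.
    """
    if limits is None:
        limits = TraceLimits()
    rng = np.random.default_rng(seed)
    surf = _SurfaceIndex(scene)
    g = scene.grid
    lo = g.origin
    hi = g.origin + g.extent
    tol = 0.5 * V_AVG / frequency
    step = tol / 2.0
    alpha_map = scene.alpha_map(frequency)
    v_map = scene.v
    z_map = scene.rho * scene.v
    v_bg = scene.background.v

    def medium(p: np.ndarray) -> Tuple[float, float, float]:
        """(v, alpha, z) at a point; background outside the grid."""
        i = scene.cell_at(p)
        if i < 0:
            return v_bg, 0.0, scene.rho0 * v_bg
        return float(v_map[i]), float(alpha_map[i]), float(z_map[i])

    # emission: uniform points on the source disk, cone directions
    k = rng.random(n_rays)
    r = source.radius * np.sqrt(rng.random(n_rays))
    t = 2 * np.pi * rng.random(n_rays)
    u = np.array([1.0, 0.0, 0.0])
    if abs(source.normal @ u) > 0.9:
        u = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(source.normal, u); e1 /= np.linalg.norm(e1)
    e2 = np.cross(source.normal, e1)
    origins = (source.center + r[:, None] * np.cos(t)[:, None] * e1
               + r[:, None] * np.sin(t)[:, None] * e2)
    cos_t = 1.0 - rng.random(n_rays) * (1.0 - math.cos(cone_half_angle))
    sin_t = np.sqrt(1.0 - cos_t ** 2)
    phi = 2 * np.pi * rng.random(n_rays)
    dirs = (cos_t[:, None] * source.normal
            + sin_t[:, None] * np.cos(phi)[:, None] * e1
            + sin_t[:, None] * np.sin(phi)[:, None] * e2)
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)

    amp0 = source_amplitude / n_rays
    queue: List[Ray] = [Ray(origin=o, direction=d, amplitude=amp0)
                        for o, d in zip(origins, dirs)]
    finished: List[Ray] = []
    interactions: List[Interaction] = []
    spawned = n_rays

    while queue:
        ray = queue.pop()
        p = ray.origin.copy()
        ray.start_state = (ray.delay, ray.attenuation)
        exit_len = _exit_length(p, ray.direction, lo, hi)
        travelled = 0.0
        cooldown = 2.0 * tol if ray.generation > 0 else 0.0
        hit = None
        while True:
            remaining = exit_len - travelled
            if remaining <= 0:
                break
            d_step = min(step, remaining)
            p = p + d_step * ray.direction
            v, alpha, _ = medium(p)
            ray.delay += d_step / v
            ray.attenuation *= math.exp(-alpha * d_step)
            ray.wavelengths += d_step * frequency / v
            travelled += d_step
            if ray.wavelengths >= limits.max_wavelengths:
                break
            if abs(ray.amplitude) * ray.attenuation < limits.amplitude_threshold:
                break
            if travelled < cooldown:
                continue
            found = surf.query(p, tol)
            if found is not None:
                hit = found
                break
        ray.end = p
        finished.append(ray)
        if hit is None or ray.generation >= limits.max_generation:
            continue
        idx, _ = hit
        n_hat = surf.normals[idx]
        if float(ray.direction @ n_hat) > 0:
            n_hat = -n_hat            # use the normal facing the incident ray
        hp = surf.points[idx]
        v1, _, z1 = medium(hp - tol * ray.direction)
        v2, _, z2 = medium(hp + tol * ray.direction)
        n1, n2 = v_bg / v1, v_bg / v2
        trans_amp, refl_amp = split_amplitude(ray.amplitude, z1, z2,
                                              pressure_continuity)
        refl_dir = ray.direction - 2.0 * float(ray.direction @ n_hat) * n_hat
        trans_dir = refract_direction(ray.direction, n_hat, n1, n2)
        transmitted = None
        if trans_dir is None:
            # total internal reflection: the transmitted branch folds into
            # the reflected one so that Υ = Υ^T + Υ^R still holds
            refl_amp = ray.amplitude
        reflected = replace(ray, origin=p.copy(), direction=refl_dir,
                            amplitude=refl_amp, generation=ray.generation + 1,
                            end=None, alive=True)
        if spawned < limits.max_rays and abs(refl_amp) * ray.attenuation >= limits.amplitude_threshold:
            queue.append(reflected)
            spawned += 1
        if trans_dir is not None:
            transmitted = replace(ray, origin=p.copy(), direction=trans_dir,
                                  amplitude=trans_amp, generation=ray.generation + 1,
                                  end=None, alive=True)
            if spawned < limits.max_rays and abs(trans_amp) * ray.attenuation >= limits.amplitude_threshold:
                queue.append(transmitted)
                spawned += 1
        interactions.append(Interaction(point=hp.copy(), surface=surf.surface_id[idx],
                                        incident=ray, reflected=reflected,
                                        transmitted=transmitted))
    return finished, interactions


def collect_echo(rays: Sequence[Ray], detector_center: np.ndarray,
                 aperture_diameter: float, frequency: float,
                 detector_normal: Optional[np.ndarray] = None,
                 threshold: float = AMPLITUDE_THRESHOLD,
                 cap: int = RECORD_CAP) -> List[EchoRecord]:
    """Convert rays crossing the detector disk into echo records.

    A ray is recorded when its terminal segment crosses the detector plane
    within ``aperture_diameter``/2 of the center.  The record carries the
    linearly interpolated arrival delay and amplitude Υ x attenuation at
    the crossing.  Records below ``threshold`` (10 uV-equivalent) are
    dropped and at most ``cap`` records (the largest amplitudes) are kept.
    """
    c = np.asarray(detector_center, float)
    if detector_normal is None:
        detector_normal = np.array([0.0, 0.0, 1.0])
    n = np.asarray(detector_normal, float)
    n = n / np.linalg.norm(n)
    records: List[EchoRecord] = []
    for ray in rays:
        if ray.end is None:
            continue
        seg = ray.end - ray.origin
        seg_len = float(np.linalg.norm(seg))
        if seg_len == 0:
            continue
        d = seg / seg_len
        denom = float(d @ n)
        if denom >= -1e-12:
            continue                 # only rays arriving against the detector normal
        t = float((c - ray.origin) @ n) / denom
        if not 0.0 <= t <= seg_len:
            continue
        hit = ray.origin + t * d
        if np.linalg.norm(hit - c) > aperture_diameter / 2.0:
            continue
        f = t / seg_len
        d0, a0 = ray.start_state
        delay = d0 + f * (ray.delay - d0)
        atten = a0 * (ray.attenuation / a0) ** f if a0 > 0 else ray.attenuation
        amp = ray.amplitude * atten
        if abs(amp) < threshold:
            continue
        records.append(EchoRecord(time=delay, amplitude=float(amp),
                                  aperture=float(aperture_diameter)))
    records.sort(key=lambda r: abs(r.amplitude), reverse=True)
    return records[:cap]
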