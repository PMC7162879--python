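"""Scenario configuration and orchestration of both forward operators.

A scenario bundles a scene, an optional implant, a source, and sweep lists
(frequencies in [1, 10] MHz, detection aperture diameters in
[0.01, 0.07] m, material/thickness pairs), plus solver settings.  Running a
scenario builds the scene, embeds the implant, runs the requested
operator(s), and writes field maps (HDF5), echo waveforms and per-
(frequency, aperture) metric tables (CSV), together with a machine-readable
manifest of the run.
"""

from __future__ import annotations

import json
import hashlib
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__, materials as mat
from . import implant as implant_mod
from . import raytrace as rt
from . import scattering as sca
from . import signals as sig
from .phantom import AcousticScene, synthetic_scene

__all__ = ["ScenarioConfig", "run_scenario", "load_config",
           "reference_breast_scenario", "reference_tank_scenario"]

log = logging.getLogger("piezoecho")

FREQ_RANGE = (1e6, 10e6)
APERTURE_RANGE = (0.01, 0.07)
DEFAULT_APERTURES = tuple(np.round(np.arange(0.01, 0.0701, 0.01), 3))


@dataclass
class ScenarioConfig:
    """Validated scenario description (all defaults overridable)."""

    scene_kind: str = "water_tank"
    scene_params: Dict = field(default_factory=dict)
    implant: Optional[Dict] = None              # ImplantSpec kwargs
    frequencies: Sequence[float] = (5e6,)
    apertures: Sequence[float] = DEFAULT_APERTURES
    regime: str = "pulse"                       # pulse | harmonic
    source_radius: float = 0.005
    source_position: Optional[Sequence[float]] = None
    source_normal: Optional[Sequence[float]] = None
    run_scattering: bool = True
    run_raytrace: bool = True
    max_iter: int = 100
    tol: float = 0.10
    cg_variant: str = "cgnr"
    n_rays: int = 256
    max_wavelengths: float = 1000.0
    seed: int = 0
    outdir: str = "piezoecho_out"
    allow_out_of_range: bool = False

    def validate(self) -> None:
        if self.scene_kind not in ("water_tank", "layered_breast", "homogeneous"):
            raise ValueError(f"unknown scene kind {self.scene_kind!r}")
        if self.regime not in ("pulse", "harmonic"):
            raise ValueError("regime must be 'pulse' or 'harmonic'")
        self.frequencies = [float(f) for f in self.frequencies]
        self.apertures = [float(a) for a in self.apertures]
        if not self.allow_out_of_range:
            for f in self.frequencies:
                if not FREQ_RANGE[0] <= f <= FREQ_RANGE[1]:
                    raise ValueError(f"frequency {f} outside {FREQ_RANGE} Hz")
            for a in self.apertures:
                if not APERTURE_RANGE[0] - 1e-12 <= a <= APERTURE_RANGE[1] + 1e-12:
                    raise ValueError(f"aperture {a} outside {APERTURE_RANGE} m")
        if self.implant is not None:
            implant_mod.ImplantSpec(**self.implant)   # raises on invalid spec


def load_config(path: str) -> ScenarioConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    cfg = ScenarioConfig(**data)
    cfg.validate()
    return cfg


def _hash_maps(scene: AcousticScene) -> str:
    h = hashlib.sha256()
    for k in ("rho", "v", "a", "y"):
        h.update(np.ascontiguousarray(getattr(scene, k)).tobytes())
    return h.hexdigest()[:16]


def build_scene(config: ScenarioConfig):
    """Stage 1: synthetic scene + optional implant embedding."""
    volume, scene = synthetic_scene(config.scene_kind, dict(config.scene_params),
                                    seed=config.seed)
    if config.source_position is not None:
        scene.meta["source_center"] = np.asarray(config.source_position, float)
    if config.source_normal is not None:
        scene.meta["source_normal"] = np.asarray(config.source_normal, float)
    if config.implant is not None:
        solid = implant_mod.build_implant(implant_mod.ImplantSpec(**config.implant))
        scene = implant_mod.embed(scene, solid)
    return volume, scene


def reference_breast_scenario(seed: int = 0, frequency: float = 5e6):
    """Layered-breast scene with the reference lens implant, plus its source.

    The lens implant (PZT-5A inner / LiNbO3 outer, 1 mm / 2 mm layers,
    1 x 1 x 0.5 cm bounding box) sits 1 cm above the dome centre facing the
    source transducer at the skin apex; the mesh is refined to the finest
    level around the implant and the source corridor (< 5000 cells).
    """
    _, scene = synthetic_scene("layered_breast", seed=seed)
    center = scene.meta["breast_center"]
    spec = implant_mod.ImplantSpec(
        shape="lens", inner_material="PZT-5A", outer_material="LiNbO3",
        inner_thickness_mm=1.0, outer_thickness_mm=2.0,
        position=tuple(center + np.array([0.0, 0.0, 0.01])), axis=(0, 0, 1))
    scene = implant_mod.embed(scene, implant_mod.build_implant(spec))
    source = sca.SourceTransducer(center=scene.meta["source_center"],
                                  normal=scene.meta["source_normal"],
                                  frequency=frequency)
    return scene, source


def reference_tank_scenario(seed: int = 0, frequency: float = 5e6,
                            standoff: float = 0.04):
    """Desk-scale water tank with a lens implant ``standoff`` metres on-axis
    from the source (the experimental stand-off range is 1-7 cm)."""
    extent = (0.05, 0.05, round(standoff + 0.03, 3))
    _, scene = synthetic_scene("homogeneous",
                               {"extent": extent, "base_h": 0.005}, seed=seed)
    src_center = np.array([extent[0] / 2, extent[1] / 2, extent[2]])
    scene.meta["source_center"] = src_center
    scene.meta["source_normal"] = np.array([0.0, 0.0, -1.0])
    spec = implant_mod.ImplantSpec(
        shape="lens", inner_material="PZT-5A", outer_material="LiNbO3",
        inner_thickness_mm=1.0, outer_thickness_mm=2.0,
        position=(extent[0] / 2, extent[1] / 2, extent[2] - standoff - 0.005),
        axis=(0, 0, 1))
    scene = implant_mod.embed(scene, implant_mod.build_implant(spec))
    source = sca.SourceTransducer(center=src_center,
                                  normal=scene.meta["source_normal"],
                                  frequency=frequency)
    return scene, source


def run_scenario(config: ScenarioConfig) -> Dict:
    """Run the configured stages and write the results bundle.

    Returns a dict with the scene, per-frequency scattering results, the
    echo metric table and the manifest; the same contents are written under
    ``config.outdir``.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {"package": "piezoecho", "version": __version__,
                "seed": config.seed, "config": asdict(config),
                "completed": [], "timings_s": {}}
    results: Dict = {"manifest": manifest}

    t0 = time.perf_counter()
    volume, scene = build_scene(config)
    pre_hash = _hash_maps(scene)
    manifest["completed"].append("build_scene")
    manifest["timings_s"]["build_scene"] = round(time.perf_counter() - t0, 3)
    manifest["n_cells"] = int(scene.grid.n_cells)
    results["scene"] = scene
    results["volume"] = volume
    log.info("scene %s built: %d cells", config.scene_kind, scene.grid.n_cells)

    src_center = scene.meta.get("source_center")
    src_normal = scene.meta.get("source_normal")
    if src_center is None:
        raise ValueError("scene defines no source position and none was configured")

    try:
        if config.run_scattering:
            t0 = time.perf_counter()
            scattering_rows = []
            fields = {}
            for f in config.frequencies:
                source = sca.SourceTransducer(center=src_center, normal=src_normal,
                                              radius=config.source_radius, frequency=f)
                total, scattered, state = sca.cg_solve(
                    scene, source, max_iter=config.max_iter, tol=config.tol,
                    variant=config.cg_variant)
                fields[f] = {"total": total, "scattered": scattered, "state": state}
                scattering_rows.append({
                    "frequency_hz": f, "iterations": state.iterations,
                    "error": state.errors[-1], "converged": state.converged})
                log.info("scattering %.1f MHz: err=%.3f in %d iters",
                         f / 1e6, state.errors[-1], state.iterations)
            results["scattering"] = fields
            pd.DataFrame(scattering_rows).to_csv(outdir / "scattering_convergence.csv",
                                                 index=False)
            _write_fields(outdir / "fields.h5", scene, fields)
            manifest["completed"].append("scattering")
            manifest["timings_s"]["scattering"] = round(time.perf_counter() - t0, 3)

        if config.run_raytrace:
            t0 = time.perf_counter()
            rows = []
            echoes = {}
            limits = rt.TraceLimits(max_wavelengths=config.max_wavelengths)
            for f in config.frequencies:
                source = sca.SourceTransducer(center=src_center, normal=src_normal,
                                              radius=config.source_radius, frequency=f)
                rays, interactions = rt.trace_rays(
                    scene, source, f, n_rays=config.n_rays, limits=limits,
                    seed=config.seed)
                template = (sig.gaussian_pulse(f) if config.regime == "pulse"
                            else sig.harmonic_excitation(f))
                for ap in config.apertures:
                    records = rt.collect_echo(rays, src_center, ap, f,
                                              detector_normal=src_normal)
                    echo = sig.synthesize_echo(records, template)
                    energy, peak, n_inter, _ = sig.echo_metrics(echo, records=records)
                    rows.append({"frequency_hz": f, "aperture_m": ap,
                                 "n_interactions": n_inter, "energy": energy,
                                 "peak": peak})
                    echoes[(f, ap)] = echo
                log.info("raytrace %.1f MHz: %d rays, %d interactions",
                         f / 1e6, len(rays), len(interactions))
            metrics = pd.DataFrame(rows)
            metrics.to_csv(outdir / "echo_metrics.csv", index=False)
            results["echo_metrics"] = metrics
            results["echoes"] = echoes
            if echoes:
                _write_echoes(outdir / "echoes.csv", echoes)
            manifest["completed"].append("raytrace")
            manifest["timings_s"]["raytrace"] = round(time.perf_counter() - t0, 3)
    finally:
        manifest["scene_maps_unchanged"] = _hash_maps(scene) == pre_hash
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)
    return results


def _write_fields(path: Path, scene: AcousticScene, fields: Dict) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("centers", data=scene.grid.centers)
        f.create_dataset("h", data=scene.grid.h)
        for freq, d in fields.items():
            grp = f.create_group(f"f_{freq / 1e6:g}MHz")
            grp.create_dataset("total", data=d["total"].values)
            grp.create_dataset("scattered", data=d["scattered"].values)
            grp.create_dataset("errors", data=np.asarray(d["state"].errors))


def _write_echoes(path: Path, echoes: Dict) -> None:
    cols = {}
    times = None
    for (f, ap), w in echoes.items():
        times = w.times
        cols[f"{f / 1e6:g}MHz_{ap * 100:g}cm"] = w.samples
    df = pd.DataFrame({"time_s": times, **cols})
    df.to_csv(path, index=False)


def field_map_image(scene: AcousticScene, values: np.ndarray, axis: int,
                    coordinate: float, path: str, floor_db: float = -80.0) -> None:
    """Write a log-scale magnitude slice image of a per-cell field."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    g = scene.grid
    sel = np.abs(g.centers[:, axis] - coordinate) <= g.h / 2
    axes = [a for a in range(3) if a != axis]
    mag = np.abs(values[sel])
    ref = mag.max() if mag.size and mag.max() > 0 else 1.0
    db = 20.0 * np.log10(np.maximum(mag / ref, 10 ** (floor_db / 20.0)))
    fig, ax = plt.subplots(figsize=(5, 4))
    sc_ = ax.scatter(g.centers[sel, axes[0]], g.centers[sel, axes[1]],
                     c=db, s=8, marker="s", cmap="inferno")
    fig.colorbar(sc_, ax=ax, label="dB re max")
    ax.set_aspect("equal")
    ax.set_xlabel("xyz"[axes[0]] + " (m)")
    ax.set_ylabel("xyz"[axes[1]] + " (m)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
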