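"""Snell refraction, amplitude splitting, ray marching, echo collection."""

import numpy as np
import pytest

from piezoecho import implant as imp
from piezoecho import phantom as ph
from piezoecho import raytrace as rt
from piezoecho.scattering import SourceTransducer


def random_incident(rng):
    r = rng.normal(size=3)
    r /= np.linalg.norm(r)
    n = rng.normal(size=3)
    n /= np.linalg.norm(n)
    if r @ n > 0:
        n = -n
    return r, n


class TestSnell:
    def test_matched_indices(self):
        assert rt.snell(1.4, 1.4, 0.3) == pytest.approx(0.3, rel=1e-12)

    def test_arcsin_half(self):
        # n1 sin(theta) = 0.5 into n2 = 1 -> pi/6
        assert rt.snell(1.0, 1.0, np.arcsin(0.5)) == pytest.approx(np.pi / 6)

    def test_total_internal_reflection(self):
        assert rt.snell(2.0, 1.0, np.pi / 3) is None


class TestRefractDirection:
    def test_normal_incidence_continues_straight(self):
        n = np.array([0.0, 0.0, 1.0])
        out = rt.refract_direction(-n, n, 1.0, 1.7)
        assert np.allclose(out, -n, atol=1e-12)

    def test_matched_indices_identity_over_random_geometries(self):
        rng = np.random.default_rng(10)
        for _ in range(100):
            r, n = random_incident(rng)
            if abs(r @ n) < 1e-6:
                continue
            out = rt.refract_direction(r, n, 1.23, 1.23)
            assert np.allclose(out, r, atol=1e-12)

    def test_unit_norm_over_incidence_sweep(self):
        n = np.array([0.0, 0.0, 1.0])
        for deg in np.arange(0.0, 89.5, 0.5):
            t = np.deg2rad(deg)
            r = np.array([np.sin(t), 0.0, -np.cos(t)])
            out = rt.refract_direction(r, n, 1.0, 1.5)
            assert abs(np.linalg.norm(out) - 1.0) < 1e-12

    def test_snell_angle_recovered(self):
        n = np.array([0.0, 0.0, 1.0])
        t_in = np.deg2rad(35.0)
        r = np.array([np.sin(t_in), 0.0, -np.cos(t_in)])
        out = rt.refract_direction(r, n, 1.0, 1.4)
        t_out = np.arccos(abs(out @ n))
        assert t_out == pytest.approx(rt.snell(1.0, 1.4, t_in), abs=1e-12)

    def test_tir_returns_none(self):
        n = np.array([0.0, 0.0, 1.0])
        r = np.array([np.sin(1.2), 0.0, -np.cos(1.2)])
        assert rt.refract_direction(r, n, 2.0, 1.0) is None

    def test_slab_crossing_exits_parallel(self):
        """Two refractions at matched parallel interfaces invert each other."""
        n = np.array([0.0, 0.0, 1.0])
        rng = np.random.default_rng(4)
        for _ in range(50):
            t = rng.uniform(0, 0.6)
            phi = rng.uniform(0, 2 * np.pi)
            r = np.array([np.sin(t) * np.cos(phi), np.sin(t) * np.sin(phi), -np.cos(t)])
            inside = rt.refract_direction(r, n, 1.0, 1.5)
            out = rt.refract_direction(inside, n, 1.5, 1.0)
            assert np.allclose(out, r, atol=1e-10)

    def test_mirror_composition_restores_direction(self):
        rng = np.random.default_rng(6)
        for _ in range(50):
            r, n = random_incident(rng)
            m = r - 2 * (r @ n) * n
            back = m - 2 * (m @ -n) * -n
            assert np.allclose(back, r, atol=1e-12)


class TestSplitAmplitude:
    def test_matched_interface_passes_everything(self):
        assert rt.split_amplitude(2.0, 1.5, 1.5) == (2.0, 0.0)

    def test_tissue_linbo3_values(self):
        t, r = rt.split_amplitude(1.0, 1.5, 34.15)
        assert r == pytest.approx(0.915, abs=1e-3)
        assert t == pytest.approx(0.085, abs=1e-3)

    def test_conservation_exact(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            amp = rng.normal()
            z1, z2 = rng.uniform(0.5, 50, size=2)
            t, r = rt.split_amplitude(amp, z1, z2)
            assert t + r == pytest.approx(amp, rel=1e-14, abs=1e-14)

    def test_rigid_boundary_limit(self):
        t, r = rt.split_amplitude(1.0, 1.5, 1e12)
        assert r == pytest.approx(1.0, abs=1e-9)
        assert t == pytest.approx(0.0, abs=1e-9)

    def test_pressure_continuity_variant(self):
        t, r = rt.split_amplitude(1.0, 1.0, 3.0)
        tp, rp = rt.split_amplitude(1.0, 1.0, 3.0, pressure_continuity=True)
        assert rp == r == 0.5
        assert t == 0.5 and tp == 1.5


class TestTraceRays:
    def test_homogeneous_scene_straight_rays_exact_delay(self, small_tank):
        src = SourceTransducer(center=small_tank.meta["source_center"],
                               normal=small_tank.meta["source_normal"], frequency=1e6)
        rays, interactions = rt.trace_rays(small_tank, src, 1e6, n_rays=32, seed=0)
        assert interactions == []
        for ray in rays:
            plen = np.linalg.norm(ray.end - ray.origin)
            assert ray.delay == pytest.approx(plen / 1482.0, rel=1e-12)
            alpha = small_tank.alpha_map(1e6)[0]
            assert ray.attenuation == pytest.approx(np.exp(-alpha * plen), rel=1e-10)
            assert ray.generation == 0

    def test_determinism_same_seed(self, small_tank):
        src = SourceTransducer(center=small_tank.meta["source_center"],
                               normal=small_tank.meta["source_normal"], frequency=2e6)
        r1, _ = rt.trace_rays(small_tank, src, 2e6, n_rays=16, seed=9)
        r2, _ = rt.trace_rays(small_tank, src, 2e6, n_rays=16, seed=9)
        assert len(r1) == len(r2)
        for a, b in zip(r1, r2):
            assert np.array_equal(a.end, b.end) and a.delay == b.delay

    def test_interaction_amplitude_conservation(self, small_tank):
        """Υ = Υ^T + Υ^R at every interface event with both children."""
        solid = imp.build_implant(imp.ImplantSpec(
            shape="disk", position=(0.02, 0.02, 0.015), sample_spacing=3e-4))
        sc = imp.embed(small_tank, solid, refine_level=0)
        src = SourceTransducer(center=sc.meta["source_center"],
                               normal=sc.meta["source_normal"], frequency=2e6)
        rays, interactions = rt.trace_rays(sc, src, 2e6, n_rays=128, seed=1)
        assert len(interactions) > 0
        for it in interactions:
            if it.reflected is not None and it.transmitted is not None:
                total = it.reflected.amplitude + it.transmitted.amplitude
                assert total == pytest.approx(it.incident.amplitude, rel=1e-12)


class TestCollectEcho:
    def _ray_through(self, z0, amp, offset=0.0):
        """Straight downward-arriving ray crossing z=0 at (offset, 0)."""
        origin = np.array([offset, 0.0, z0])
        end = np.array([offset, 0.0, -0.01])
        ray = rt.Ray(origin=origin, direction=np.array([0.0, 0.0, -1.0]),
                     amplitude=amp, delay=z0 / 1500.0, attenuation=1.0)
        ray.end = end
        ray.start_state = (0.0, 1.0)
        return ray

    def test_geometric_miss_not_recorded(self):
        rays = [self._ray_through(0.02, 1.0, offset=1.0)]
        recs = rt.collect_echo(rays, np.zeros(3), 0.01, 1e6,
                               detector_normal=[0, 0, 1])
        assert recs == []

    def test_threshold_drops_5uv_arrival(self):
        rays = [self._ray_through(0.02, 5e-6)]
        recs = rt.collect_echo(rays, np.zeros(3), 0.05, 1e6,
                               detector_normal=[0, 0, 1])
        assert recs == []

    def test_cap_keeps_exactly_1200_largest(self):
        rays = [self._ray_through(0.02, 1e-4 + i * 1e-7) for i in range(1201)]
        recs = rt.collect_echo(rays, np.zeros(3), 0.05, 1e6,
                               detector_normal=[0, 0, 1])
        assert len(recs) == 1200
        amps = sorted(abs(r.amplitude) for r in recs)
        assert amps[0] > 1e-4  # the smallest arrival was the one dropped

    def test_aperture_monotonicity(self, small_tank):
        solid = imp.build_implant(imp.ImplantSpec(
            shape="disk", position=(0.02, 0.02, 0.015), sample_spacing=3e-4))
        sc = imp.embed(small_tank, solid, refine_level=0)
        src = SourceTransducer(center=sc.meta["source_center"],
                               normal=sc.meta["source_normal"], frequency=2e6)
        rays, _ = rt.trace_rays(sc, src, 2e6, n_rays=256, seed=2)
        counts = [len(rt.collect_echo(rays, src.center, ap, 2e6,
                                      detector_normal=src.normal))
                  for ap in np.arange(0.01, 0.0701, 0.01)]
        assert all(b >= a for a, b in zip(counts, counts[1:]))
        assert counts[-1] > 0

    def test_arrival_time_not_before_direct_path(self, small_tank):
        solid = imp.build_implant(imp.ImplantSpec(
            shape="disk", position=(0.02, 0.02, 0.015), sample_spacing=3e-4))
        sc = imp.embed(small_tank, solid, refine_level=0)
        src = SourceTransducer(center=sc.meta["source_center"],
                               normal=sc.meta["source_normal"], frequency=2e6)
        rays, _ = rt.trace_rays(sc, src, 2e6, n_rays=256, seed=2)
        recs = rt.collect_echo(rays, src.center, 0.05, 2e6, detector_normal=src.normal)
        # implant top face is 20 mm below the source
        direct = 2 * (0.04 - 0.02) / 1482.0
        vmax = max(sc.v)
        for r in recs:
            assert r.time >= 2 * (0.04 - 0.02) / vmax
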