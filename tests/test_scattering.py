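"""Green kernel, incident field, forward operator, conjugate gradient."""

import numpy as np
import pytest

from piezoecho import materials as mat
from piezoecho import phantom as ph
from piezoecho import scattering as sca


def perturbed_scene(n=5, extent=0.025, seed=0, rel=0.02):
    """Homogeneous water box with small random property perturbations."""
    _, scene = ph.synthetic_scene("homogeneous",
                                  {"extent": (extent,) * 3, "base_h": extent / n})
    rng = np.random.default_rng(seed)
    scene.rho = scene.rho * (1 + rel * rng.normal(size=scene.rho.shape))
    scene.v = scene.v * (1 + rel * rng.normal(size=scene.v.shape))
    return scene


class TestGreensFunction:
    def test_lossless_closed_form_and_scaling(self):
        g1 = sca.greens_function(np.array([1.0, 0, 0]), 0.0)
        assert g1 == pytest.approx(1 / (4 * np.pi), rel=1e-12)
        g2 = sca.greens_function(np.array([0, 2.0, 0]), 0.0)
        assert g2 == pytest.approx(g1 / 2, rel=1e-12)

    def test_lossy_modulus(self):
        gamma = 3.0 + 100.0j
        g = sca.greens_function(np.array([0, 0, 0.5]), gamma)
        assert abs(g) == pytest.approx(np.exp(-3.0 * 0.5) / (4 * np.pi * 0.5), rel=1e-12)

    def test_reciprocity(self):
        gamma = 1.0 + 50.0j
        d = np.array([0.01, -0.02, 0.003])
        assert sca.greens_function(d, gamma) == sca.greens_function(-d, gamma)

    def test_singularity_raises(self):
        with pytest.raises(ZeroDivisionError):
            sca.greens_function(np.zeros(3), 0.0)


class TestIncidentField:
    def test_zero_strength_gives_zero_field(self, small_tank):
        src = sca.SourceTransducer(center=small_tank.meta["source_center"],
                                   normal=small_tank.meta["source_normal"],
                                   frequency=1e6, strength=0.0)
        p = sca.incident_field(small_tank.grid, src, 1000.0, 0.0)
        assert np.all(p.values == 0)

    def test_single_point_source_decays_as_inverse_distance(self, small_tank):
        src = sca.SourceTransducer(center=small_tank.meta["source_center"],
                                   normal=small_tank.meta["source_normal"],
                                   frequency=1e6, n_points=1, radius=1e-9)
        p = sca.incident_field(small_tank.grid, src, 1000.0, 0.0)
        g = small_tank.grid
        on_axis = (np.abs(g.centers[:, 0] - 0.0175) < 1e-9) & \
                  (np.abs(g.centers[:, 1] - 0.0175) < 1e-9)
        cells = np.flatnonzero(on_axis)
        r = np.linalg.norm(g.centers[cells] - src.points[0], axis=1)
        ratio = np.abs(p.values[cells]) * r
        assert np.allclose(ratio, ratio[0], rtol=1e-9)

    def test_superposition_over_source_points(self, small_tank):
        kw = dict(center=small_tank.meta["source_center"],
                  normal=small_tank.meta["source_normal"], frequency=1e6)
        two = sca.SourceTransducer(n_points=2, **kw)
        total = np.zeros(small_tank.grid.n_cells, dtype=complex)
        for pt in two.points:
            one = sca.SourceTransducer(n_points=1, radius=1e-9, **kw)
            one.points = pt[None, :]
            one.s = np.array([1.0])
            one.dS = two.dS
            total += sca.incident_field(small_tank.grid, one, 1000.0, 0.0).values
        full = sca.incident_field(small_tank.grid, two, 1000.0, 0.0).values
        assert np.allclose(full, total, rtol=1e-12)


class TestOperator:
    def test_zero_contrast_is_identity(self, small_tank):
        op = sca.ScatteringOperator(small_tank.grid, small_tank.contrasts(1e6),
                                    small_tank.gamma0(1e6))
        rng = np.random.default_rng(0)
        x = rng.normal(size=op.n_cells) + 1j * rng.normal(size=op.n_cells)
        assert np.allclose(op.apply(x), x, rtol=1e-12)

    def test_single_scatterer_one_term_evaluation(self, small_tank):
        """delta input at a single contrasted cell: output differs at cell j
        by -G(r_j - r_s) c V (lossless kernel, hand-evaluated sum)."""
        g = small_tank.grid
        s = g.n_cells // 2
        c = 1e4 + 2e3j
        dgamma = np.zeros(g.n_cells, dtype=complex)
        dgamma[s] = c
        contrasts = mat.ContrastMaps(delta_rho=np.zeros(g.n_cells),
                                     delta_gamma=dgamma, rho0=1000.0, gamma0=0.0)
        op = sca.ScatteringOperator(g, contrasts, 0.0)
        p = np.zeros(g.n_cells, dtype=complex)
        p[s] = 1.0
        out = op.apply(p)
        j = s + 1
        expected = -sca.greens_function(g.centers[j] - g.centers[s], 0.0) * c * g.volumes[s]
        assert out[j] == pytest.approx(expected, rel=1e-12)

    def test_linearity(self):
        scene = perturbed_scene()
        op = sca.ScatteringOperator(scene.grid, scene.contrasts(1e6), scene.gamma0(1e6))
        rng = np.random.default_rng(1)
        n = op.n_cells
        p1 = rng.normal(size=n) + 1j * rng.normal(size=n)
        p2 = rng.normal(size=n) + 1j * rng.normal(size=n)
        a, b = 2.3 - 0.7j, -1.1 + 0.4j
        lhs = op.apply(a * p1 + b * p2)
        rhs = a * op.apply(p1) + b * op.apply(p2)
        assert np.allclose(lhs, rhs, rtol=1e-12)

    def test_adjoint_inner_product_identity(self):
        scene = perturbed_scene(seed=3)
        op = sca.ScatteringOperator(scene.grid, scene.contrasts(2e6), scene.gamma0(2e6))
        rng = np.random.default_rng(2)
        n = op.n_cells
        x = rng.normal(size=n) + 1j * rng.normal(size=n)
        y = rng.normal(size=n) + 1j * rng.normal(size=n)
        lhs = np.vdot(y, op.apply(x))
        rhs = np.vdot(op.apply_adjoint(y), x)
        assert abs(lhs - rhs) / abs(lhs) < 1e-10

    def test_mismatched_grid_rejected(self, small_tank):
        scene = perturbed_scene()
        op = sca.ScatteringOperator(scene.grid, scene.contrasts(1e6), scene.gamma0(1e6))
        p = sca.PressureField(np.zeros(small_tank.grid.n_cells))
        with pytest.raises(ValueError, match="grids differ"):
            sca.scattering_apply(p, scene, op.ops, op.contrasts, op.gamma0, operator=op)


class TestConjugateGradient:
    def test_zero_contrast_scene_converges_immediately(self, small_tank):
        src = sca.SourceTransducer(center=small_tank.meta["source_center"],
                                   normal=small_tank.meta["source_normal"],
                                   frequency=1e6)
        total, scattered, state = sca.cg_solve(small_tank, src)
        assert state.converged and state.iterations == 1
        assert state.errors[-1] == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(scattered.values, 0.0, atol=1e-9)

    @pytest.mark.parametrize("seed", [0, 7])
    def test_cg_matches_dense_direct_solve(self, seed):
        """CGNR solution vs dense linear solve on a random-contrast scene."""
        scene = perturbed_scene(n=6, seed=seed)      # 216 cells
        src = sca.SourceTransducer(center=[0.0125, 0.0125, 0.025],
                                   normal=[0, 0, -1], frequency=2e6)
        g0 = scene.gamma0(2e6)
        op = sca.ScatteringOperator(scene.grid, scene.contrasts(2e6), g0)
        p_inc = sca.incident_field(scene.grid, src, scene.rho0, g0)
        direct = np.linalg.solve(op.dense(), p_inc.values)
        total, _, state = sca.cg_solve(scene, src, max_iter=3000, tol=1e-9,
                                       variant="cgnr", operator=op, p_inc=p_inc)
        rel = np.linalg.norm(total.values - direct) / np.linalg.norm(direct)
        assert rel < 1e-6

    def test_error_history_monotone_on_perturbed_scene(self):
        scene = perturbed_scene(n=6, seed=1)
        src = sca.SourceTransducer(center=[0.0125, 0.0125, 0.025],
                                   normal=[0, 0, -1], frequency=2e6)
        _, _, state = sca.cg_solve(scene, src, max_iter=60, tol=1e-8, variant="cgnr")
        e = np.array(state.errors)
        assert np.all(np.diff(e) <= 1e-12)

    def test_scattered_equals_total_minus_incident(self):
        scene = perturbed_scene(n=5, seed=2)
        src = sca.SourceTransducer(center=[0.0125, 0.0125, 0.025],
                                   normal=[0, 0, -1], frequency=2e6)
        g0 = scene.gamma0(2e6)
        p_inc = sca.incident_field(scene.grid, src, scene.rho0, g0)
        total, scattered, _ = sca.cg_solve(scene, src, max_iter=50, tol=1e-6,
                                           p_inc=p_inc)
        assert np.allclose(scattered.values, total.values - p_inc.values, rtol=1e-12)


def test_form_factor_limits():
    # resolved-grid limit: the cell-averaged kernel reduces to G*V
    assert sca._form_factor(np.array([1e-9]))[0] == pytest.approx(1.0)
    # self term reduces to the mean of 1/(4 pi r) over the sphere as gamma->0
    h = np.array([0.01])
    r_eq = sca.equivalent_radius(h)
    assert sca._self_term(h, 0.0)[0] == pytest.approx(3 / (8 * np.pi * r_eq[0]))
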