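import numpy as np
import pytest

from eitshape.forward import (
    ConductivityField,
    ForwardSolver,
    InjectionPattern,
    MeasurementVector,
    assemble_stiffness,
    jacobian,
    measure,
    measurement_pairs,
    n_measurements,
    ntd_matrix,
)
from eitshape.mesh import DomainSpec, TriMesh, build_disk_mesh
from eitshape.phantoms import rasterize, sample_phantom


class TestStiffness:
    def test_constant_nullspace(self, coarse_mesh):
        K = assemble_stiffness(ConductivityField.homogeneous(coarse_mesh))
        assert np.abs(K @ np.ones(coarse_mesh.n_nodes)).max() < 1e-12
        assert (abs(K - K.T)).max() < 1e-12

    def test_linear_in_sigma(self, coarse_mesh):
        f1 = ConductivityField.homogeneous(coarse_mesh, 1.0)
        f3 = ConductivityField.homogeneous(coarse_mesh, 3.0)
        K1, K3 = assemble_stiffness(f1), assemble_stiffness(f3)
        assert np.abs((3 * K1 - K3).toarray()).max() < 1e-12

    def test_single_triangle_cotangent_formula(self):
        # right triangle (0,0)-(1,0)-(0,1): the P1 element matrix is
        # [[1, -1/2, -1/2], [-1/2, 1/2, 0], [-1/2, 0, 1/2]]
        mesh = TriMesh(
            nodes=np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0]]),
            triangles=np.array([[0, 1, 2]]),
            boundary_nodes=np.array([0, 1, 2]),
            electrode_nodes=np.array([0, 1, 2]),
            h=1.0,
        )
        K = assemble_stiffness(ConductivityField.homogeneous(mesh)).toarray()
        expected = np.array([[1, -0.5, -0.5], [-0.5, 0.5, 0], [-0.5, 0, 0.5]])
        assert np.allclose(K, expected, atol=1e-14)

    def test_nonpositive_sigma_rejected(self, coarse_mesh):
        with pytest.raises(ValueError):
            ConductivityField(coarse_mesh, np.zeros(coarse_mesh.n_triangles))


class TestSolvePattern:
    def test_zero_current_zero_potential(self, coarse_mesh):
        f = ConductivityField.homogeneous(coarse_mesh)
        sol = ForwardSolver(f).solve_pattern(InjectionPattern(0, 8, amplitude=0.0))
        assert np.abs(sol.u).max() < 1e-14

    def test_boundary_mean_grounded(self, training_mesh):
        f = ConductivityField.homogeneous(training_mesh)
        sol = ForwardSolver(f).solve_pattern(InjectionPattern(0, 1))
        assert abs(sol.u[training_mesh.boundary_nodes].mean()) < 1e-10

    def test_conductivity_scaling(self, training_mesh):
        s1 = ForwardSolver(ConductivityField.homogeneous(training_mesh, 1.0))
        s2 = ForwardSolver(ConductivityField.homogeneous(training_mesh, 2.0))
        u1 = s1.solve_pattern(InjectionPattern(3, 4)).u
        u2 = s2.solve_pattern(InjectionPattern(3, 4)).u
        assert np.allclose(u2, u1 / 2, atol=1e-10)

    def test_homogeneous_disk_matches_log_potential(self):
        """Boundary potentials match the analytic two-point-source solution
        u = (1/pi)(log|x - z_sink| - log|x - z_src|) up to a constant."""
        errs = []
        for h in (0.08, 0.04):
            mesh = build_disk_mesh(DomainSpec(), h)
            solver = ForwardSolver(ConductivityField.homogeneous(mesh))
            sol = solver.solve_pattern(InjectionPattern(0, 8))  # angle 0 and pi
            b = mesh.boundary_nodes
            keep = ~np.isin(b, mesh.electrode_nodes[[0, 8]])
            xb = mesh.nodes[b[keep]]
            ua = (
                np.log(np.linalg.norm(xb - [-1.0, 0.0], axis=1))
                - np.log(np.linalg.norm(xb - [1.0, 0.0], axis=1))
            ) / np.pi
            uh = sol.u[b[keep]]
            ua -= ua.mean()
            uh -= uh.mean()
            errs.append(np.linalg.norm(uh - ua) / np.linalg.norm(ua))
        assert errs[0] <= 0.02
        assert errs[1] < errs[0]


class TestMeasure:
    @pytest.mark.parametrize("L,total,per", [(4, 4, 1), (8, 40, 5), (16, 208, 13)])
    def test_protocol_counts(self, L, total, per):
        assert n_measurements(L) == total == L * (L - 3)
        pairs = measurement_pairs(L)
        assert len(pairs) == total
        for s in range(L):
            assert sum(1 for p, _ in pairs if p == s) == per

    def test_vector_length_16_electrodes(self, training_mesh):
        m = measure(ConductivityField.homogeneous(training_mesh))
        assert len(m) == 208

    def test_reciprocity(self, training_mesh, rng):
        """Swapping drive and measurement dipoles leaves the value unchanged."""
        ph = sample_phantom(rng, 2)
        solver = ForwardSolver(rasterize(ph, training_mesh))
        U = solver.electrode_potentials()
        # voltage on pair k when driving pair s == voltage on pair s driving k
        V = U - U.mean(axis=1, keepdims=True)
        D = V[:, :-1] - V[:, 1:]
        L = training_mesh.n_electrodes
        for s, k in [(0, 5), (2, 9), (7, 12)]:
            assert D[s, k] == pytest.approx(D[k, s], rel=1e-8, abs=1e-12)


class TestNtD:
    def test_symmetry(self, training_mesh, rng):
        ph = sample_phantom(rng, 3)
        M = ntd_matrix(rasterize(ph, training_mesh)).matrix
        assert np.linalg.norm(M - M.T) <= 1e-8 * np.linalg.norm(M)

    def test_scaling_law(self, training_mesh):
        M1 = ntd_matrix(ConductivityField.homogeneous(training_mesh, 1.0)).matrix
        Mc = ntd_matrix(ConductivityField.homogeneous(training_mesh, 2.5)).matrix
        assert np.abs(Mc - M1 / 2.5).max() < 1e-8

    def test_monotonicity_on_nested_fields(self, training_mesh, rng):
        """sigma_a <= sigma_b elementwise implies NtD(a) - NtD(b) is PSD."""
        for _ in range(5):
            ph = sample_phantom(rng, 2)
            fa = rasterize(ph, training_mesh)
            bump = rng.uniform(0, 1, size=training_mesh.n_triangles)
            fb = ConductivityField(training_mesh, fa.sigma + bump)
            diff = ntd_matrix(fa).matrix - ntd_matrix(fb).matrix
            w = np.linalg.eigvalsh(diff)
            assert w[0] >= -1e-8 * np.linalg.norm(ntd_matrix(fa).matrix)


class TestJacobian:
    def test_shape_contract(self, training_mesh):
        J = jacobian(ConductivityField.homogeneous(training_mesh))
        assert J.shape == (208, training_mesh.n_triangles)

    def test_matches_finite_differences(self, coarse_mesh, rng):
        sigma = np.ones(coarse_mesh.n_triangles)
        J = jacobian(ConductivityField(coarse_mesh, sigma))
        eps = 1e-5
        for T in rng.choice(coarse_mesh.n_triangles, 6, replace=False):
            sp = sigma.copy()
            sp[T] += eps
            sm = sigma.copy()
            sm[T] -= eps
            fd = (
                measure(ConductivityField(coarse_mesh, sp)).values
                - measure(ConductivityField(coarse_mesh, sm)).values
            ) / (2 * eps)
            assert np.linalg.norm(fd - J[:, T]) <= 1e-3 * np.linalg.norm(fd)

    def test_inverse_square_scaling(self, coarse_mesh):
        """m scales as 1/c under sigma -> c*sigma, so J scales as 1/c^2."""
        J1 = jacobian(ConductivityField.homogeneous(coarse_mesh, 1.0))
        J2 = jacobian(ConductivityField.homogeneous(coarse_mesh, 2.0))
        assert np.abs(J2 - J1 / 4).max() < 1e-10 * np.abs(J1).max()


def test_measurement_vector_validates_length():
    with pytest.raises(ValueError):
        MeasurementVector(np.zeros(10), n_electrodes=16)
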