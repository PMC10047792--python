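"""FEM forward solver for the EIT problem under the adjacent-pair protocol.

The governing equation is the elliptic conductivity equation
``div(sigma grad u) = 0`` on the unit disk with Neumann boundary data given
by injected currents and the grounding condition that the boundary potential
has zero mean.  Electrodes are idealised points: unit current enters at the
source electrode node and leaves at its right-hand neighbour (the sink).

For ``L`` electrodes each of the ``L`` adjacent source-sink patterns is
driven in turn, and the voltage difference across every adjacent electrode
pair not touching the drive pair is recorded: ``L - 3`` values per pattern,
``L*(L-3)`` in total (13 and 208 for ``L = 16``).

The discretisation is P1 (nodal potentials) with piecewise-constant
conductivity per triangle.  One sparse LU factorisation per conductivity is
reused across all drive patterns, and the same solves provide the
Neumann-to-Dirichlet matrix and the adjoint-method Jacobian.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .mesh import TriMesh

__all__ = [
    "ConductivityField",
    "InjectionPattern",
    "ForwardSolution",
    "MeasurementVector",
    "NtDMatrix",
    "ForwardSolver",
    "assemble_stiffness",
    "solve_pattern",
    "measure",
    "ntd_matrix",
    "jacobian",
    "measurement_pairs",
    "n_measurements",
]

SIGMA_LO_DEFAULT = 0.05
SIGMA_HI_DEFAULT = 20.0


@dataclass
class ConductivityField:
    """Piecewise-constant conductivity on the triangles of a mesh.

    Conductivity is dimensionless, bounded away from zero and infinity:
    ``0 < sigma_lo <= sigma <= sigma_hi``.
    """

    mesh: TriMesh
    sigma: np.ndarray
    sigma_lo: float = SIGMA_LO_DEFAULT
    sigma_hi: float = SIGMA_HI_DEFAULT

    def __post_init__(self) -> None:
        self.sigma = np.asarray(self.sigma, dtype=np.float64)
        if self.sigma.shape != (self.mesh.n_triangles,):
            raise ValueError(
                f"sigma length {self.sigma.shape} != triangle count "
                f"{self.mesh.n_triangles}"
            )
        if not np.all(np.isfinite(self.sigma)):
            raise ValueError("sigma contains non-finite entries")
        if np.any(self.sigma <= 0):
            raise ValueError("sigma must be strictly positive")
        if np.any(self.sigma < self.sigma_lo) or np.any(self.sigma > self.sigma_hi):
            raise ValueError(
                f"sigma outside admissible bounds [{self.sigma_lo}, {self.sigma_hi}]"
            )

    @classmethod
    def homogeneous(cls, mesh: TriMesh, value: float = 1.0) -> "ConductivityField":
        return cls(mesh, np.full(mesh.n_triangles, float(value)))


@dataclass(frozen=True)
class InjectionPattern:
    """Adjacent source-sink current injection: +I at source, -I at sink."""

    source: int
    sink: int
    amplitude: float = 1.0

    def __post_init__(self) -> None:
        if self.source == self.sink:
            raise ValueError("source and sink must differ")


@dataclass
class ForwardSolution:
    """Nodal potentials for one injection pattern, grounded to zero boundary mean."""

    u: np.ndarray
    pattern: InjectionPattern


@dataclass
class MeasurementVector:
    """Adjacent-pair voltage differences, pattern-major.

    ``values[s * (L-3) + j]`` is the j-th retained difference
    ``u(e_k) - u(e_{k+1})`` under drive pattern ``s`` (source ``s``, sink
    ``s+1 mod L``), where pairs containing the source or sink are skipped.
    """

    values: np.ndarray
    n_electrodes: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        L = self.n_electrodes
        if self.values.shape != (L * (L - 3),):
            raise ValueError(
                f"expected {L * (L - 3)} measurements for L={L}, "
                f"got {self.values.shape}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite measurement values")

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class NtDMatrix:
    """Discrete Neumann-to-Dirichlet operator on mean-free electrode currents.

    The basis consists of the ``L - 1`` adjacent-pair dipole currents
    ``g_j = e_j - e_{j+1}`` (j = 0..L-2), which span all mean-free electrode
    current patterns.  Entry (i, j) is ``g_i . V_j`` where ``V_j`` are the
    mean-free electrode voltages produced by ``g_j``.
    """

    matrix: np.ndarray
    basis: str = "adjacent-dipole (e_j - e_{j+1}, j=0..L-2)"

    def __post_init__(self) -> None:
        M = np.asarray(self.matrix, dtype=np.float64)
        nrm = np.linalg.norm(M)
        if nrm > 0 and np.linalg.norm(M - M.T) / nrm > 1e-8:
            raise ValueError("NtD matrix not symmetric within tolerance")
        self.matrix = 0.5 * (M + M.T)


def measurement_pairs(L: int) -> list[tuple[int, int]]:
    """(pattern, pair) index pairs retained by the adjacent protocol.

    For drive pattern ``s`` (source ``s``, sink ``s+1``), pair ``k`` (the
    difference across electrodes ``k`` and ``k+1 mod L``) is retained iff
    neither electrode is the source or the sink.
    """
    out = []
    for s in range(L):
        drive = {s, (s + 1) % L}
        for k in range(L):
            if {k, (k + 1) % L} & drive:
                continue
            out.append((s, k))
    return out


def n_measurements(L: int) -> int:
    """Number of measurements of the adjacent protocol: ``L * (L - 3)``."""
    return L * (L - 3)


def _element_matrices(mesh: TriMesh) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-triangle geometric stiffness, areas, and basis gradients (cached).

    Returns ``(G, areas, grads)`` where ``G[t]`` is the 3x3 element stiffness
    for unit conductivity, ``areas[t]`` the triangle area, and ``grads[t]``
    the (3, 2) gradients of the barycentric basis functions.
    """
    if "elem" not in mesh._cache:
        p = mesh.nodes[mesh.triangles]  # (T, 3, 2)
        e1 = p[:, 1] - p[:, 0]
        e2 = p[:, 2] - p[:, 0]
        det = e1[:, 0] * e2[:, 1] - e1[:, 1] * e2[:, 0]  # 2*area, positive
        areas = 0.5 * det
        # gradients of barycentric coordinates
        g = np.empty((len(p), 3, 2))
        g[:, 1, 0] = e2[:, 1] / det
        g[:, 1, 1] = -e2[:, 0] / det
        g[:, 2, 0] = -e1[:, 1] / det
        g[:, 2, 1] = e1[:, 0] / det
        g[:, 0] = -g[:, 1] - g[:, 2]
        G = areas[:, None, None] * np.einsum("tid,tjd->tij", g, g)
        mesh._cache["elem"] = (G, areas, g)
    return mesh._cache["elem"]


def assemble_stiffness(field: ConductivityField) -> sp.csr_matrix:
    """P1 stiffness matrix for ``div(sigma grad u)`` with per-triangle sigma.

    Symmetric positive semi-definite with a one-dimensional null space (the
    constants), as appropriate for the pure-Neumann problem.
    """
    mesh = field.mesh
    G, _, _ = _element_matrices(mesh)
    vals = (field.sigma[:, None, None] * G).ravel()
    tri = mesh.triangles
    rows = np.repeat(tri, 3, axis=1).ravel()
    cols = np.tile(tri, (1, 3)).ravel()
    K = sp.coo_matrix((vals, (rows, cols)), shape=(mesh.n_nodes, mesh.n_nodes))
    return K.tocsr()


class ForwardSolver:
    """Factorised forward operator for one conductivity field.

    Grounds the pure-Neumann system with a Lagrange multiplier enforcing
    zero mean of the potential over the boundary nodes, then reuses a single
    sparse LU factorisation across all ``L`` adjacent drive patterns.
    """

    def __init__(self, field: ConductivityField):
        self.field = field
        self.mesh = field.mesh
        K = assemble_stiffness(field)
        n = self.mesh.n_nodes
        bnodes = self.mesh.boundary_nodes
        c = np.zeros(n)
        c[bnodes] = 1.0 / len(bnodes)
        A = sp.bmat(
            [[K, sp.csr_matrix(c[:, None])], [sp.csr_matrix(c[None, :]), None]],
            format="csc",
        )
        self._A = A
        try:
            self._lu = spla.splu(A)
        except RuntimeError as exc:  # pragma: no cover - defensive
            raise RuntimeError(
                f"singular forward system (nodes={n}, h={self.mesh.h}): {exc}"
            ) from exc
        self._pattern_solutions: np.ndarray | None = None

    # -- core solves ------------------------------------------------------

    def solve_pattern(self, pattern: InjectionPattern) -> ForwardSolution:
        """Solve the grounded Neumann problem for one source-sink pattern."""
        L = self.mesh.n_electrodes
        if not (0 <= pattern.source < L and 0 <= pattern.sink < L):
            raise ValueError(f"pattern electrodes outside [0, {L})")
        n = self.mesh.n_nodes
        b = np.zeros(n + 1)
        b[self.mesh.electrode_nodes[pattern.source]] += pattern.amplitude
        b[self.mesh.electrode_nodes[pattern.sink]] -= pattern.amplitude
        x = self._lu.solve(b)
        res = np.linalg.norm(self._A @ x - b)
        if res > 1e-10 * max(1.0, np.linalg.norm(b)):
            raise RuntimeError(
                f"forward solve residual {res:.2e} exceeds tolerance "
                f"(nodes={n}, h={self.mesh.h})"
            )
        return ForwardSolution(u=x[:-1], pattern=pattern)

    def pattern_solutions(self) -> np.ndarray:
        """Nodal solutions for all L adjacent patterns, shape ``(L, n_nodes)``.

        Pattern ``s`` drives unit current from electrode ``s`` into its
        right-hand neighbour ``s+1 mod L``.  Cached.
        """
        if self._pattern_solutions is None:
            L = self.mesh.n_electrodes
            n = self.mesh.n_nodes
            enodes = self.mesh.electrode_nodes
            B = np.zeros((n + 1, L))
            for s in range(L):
                B[enodes[s], s] += 1.0
                B[enodes[(s + 1) % L], s] -= 1.0
            X = self._lu.solve(B)
            self._pattern_solutions = X[:-1].T
        return self._pattern_solutions

    # -- derived quantities ----------------------------------------------

    def electrode_potentials(self) -> np.ndarray:
        """Electrode potentials under each pattern, shape ``(L, L)`` = (pattern, electrode)."""
        return self.pattern_solutions()[:, self.mesh.electrode_nodes]

    def measure(self) -> MeasurementVector:
        """Full adjacent-protocol measurement vector (length ``L*(L-3)``)."""
        L = self.mesh.n_electrodes
        U = self.electrode_potentials()
        vals = [
            U[s, k] - U[s, (k + 1) % L] for s, k in measurement_pairs(L)
        ]
        return MeasurementVector(np.array(vals), n_electrodes=L)

    def ntd_matrix(self) -> NtDMatrix:
        """Discrete NtD matrix on the adjacent-dipole current basis."""
        L = self.mesh.n_electrodes
        U = self.electrode_potentials()  # (pattern, electrode)
        V = U - U.mean(axis=1, keepdims=True)  # mean-free electrode voltages
        # entry (i, j) = g_i . V_j = V[j, i] - V[j, i+1] with g_i = e_i - e_{i+1}
        D = V[:, :-1] - V[:, 1:]  # (pattern j, dipole i)
        return NtDMatrix(D[: L - 1, :].T)

    def jacobian(self) -> np.ndarray:
        """Derivative of ``measure()`` w.r.t. each triangle's conductivity.

        Adjoint formula: the sensitivity of the (drive ``s``, pair ``k``)
        voltage difference to ``sigma_T`` is ``-area_T * grad(u_k) . grad(u_s)``
        on triangle ``T``; the adjoint fields are the unit dipole solutions,
        which coincide with the drive-pattern solutions, so no extra solves
        are needed.  Shape ``(L*(L-3), T)``.
        """
        mesh = self.mesh
        L = mesh.n_electrodes
        _, areas, g = _element_matrices(mesh)
        X = self.pattern_solutions()  # (L, n)
        ut = X[:, mesh.triangles]  # (L, T, 3)
        grads = np.einsum("ltv,tvd->ltd", ut, g)  # (L, T, 2)
        pairs = measurement_pairs(L)
        J = np.empty((len(pairs), mesh.n_triangles))
        for row, (s, k) in enumerate(pairs):
            J[row] = -areas * np.einsum("td,td->t", grads[k], grads[s])
        return J


# -- module-level functional surface -------------------------------------


def solve_pattern(field: ConductivityField, pattern: InjectionPattern) -> ForwardSolution:
    return ForwardSolver(field).solve_pattern(pattern)


def measure(field: ConductivityField) -> MeasurementVector:
    return ForwardSolver(field).measure()


def ntd_matrix(field: ConductivityField) -> NtDMatrix:
    return ForwardSolver(field).ntd_matrix()


def jacobian(field: ConductivityField) -> np.ndarray:
    return ForwardSolver(field).jacobian()
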