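"""Unit-disk triangulation, electrode placement and mesh utilities.

The imaging domain is the unit disk with ``L`` point electrodes on its
boundary.  Electrode ``k`` sits at angle ``2*pi*k/L`` (counterclockwise,
0-based); the "right-hand neighbour" of electrode ``k`` is ``(k+1) % L``.
Meshes are conforming P1 triangulations built from concentric rings of
nodes and a Delaunay triangulation; conductivity lives on triangles (P0),
potentials on nodes (P1).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial import Delaunay

__all__ = [
    "DomainSpec",
    "TriMesh",
    "ConfigurationError",
    "build_disk_mesh",
    "triangle_centroids",
    "connected_components",
    "TRAINING_H",
    "FINE_H",
]

#: Stock refinements: the mesh used for simulating training data and a finer
#: mesh for super-resolution evaluation.
TRAINING_H = 0.08
FINE_H = 0.035


def _cross2(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """z-component of the cross product of stacked 2-vectors."""
    return a[..., 0] * b[..., 1] - a[..., 1] * b[..., 0]


class ConfigurationError(ValueError):
    """Raised when a mesh/electrode configuration cannot be realised."""


@dataclass(frozen=True)
class DomainSpec:
    """Geometry of the imaging domain.

    Parameters
    ----------
    dimension : int
        Spatial dimension. 2 or 3 accepted at type level; mesh construction
        supports 2 only.
    radius : float
        Domain radius; the experiments use the unit disk.
    n_electrodes : int
        Number of point electrodes ``L`` on the boundary, at angles
        ``2*pi*k/L``.
    """

    dimension: int = 2
    radius: float = 1.0
    n_electrodes: int = 16

    def __post_init__(self) -> None:
        if self.dimension not in (2, 3):
            raise ValueError(f"dimension must be 2 or 3, got {self.dimension}")
        if self.radius <= 0:
            raise ValueError("radius must be positive")
        if self.n_electrodes < 4:
            raise ValueError("need at least 4 electrodes")


@dataclass
class TriMesh:
    """Conforming triangulation of the unit disk.

    Attributes
    ----------
    nodes : (N, 2) float array
        Node coordinates, unit-disk units, origin at the centre.
    triangles : (T, 3) int array
        0-based node indices, counterclockwise (positive signed area).
    boundary_nodes : (B,) int array
        Boundary node indices ordered counterclockwise starting near angle 0.
    electrode_nodes : (L,) int array
        One boundary node per electrode.
    h : float
        Target edge length used to build the mesh.
    """

    nodes: np.ndarray
    triangles: np.ndarray
    boundary_nodes: np.ndarray
    electrode_nodes: np.ndarray
    h: float
    _cache: dict = field(default_factory=dict, repr=False, compare=False)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_triangles(self) -> int:
        return len(self.triangles)

    @property
    def n_electrodes(self) -> int:
        return len(self.electrode_nodes)

    def signed_areas(self) -> np.ndarray:
        """Signed area of every triangle (positive for CCW orientation)."""
        p = self.nodes[self.triangles]
        return 0.5 * _cross2(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0])

    def edge_to_triangles(self) -> dict[tuple[int, int], list[int]]:
        """Map each undirected edge to the triangles containing it (cached)."""
        if "edge2tri" not in self._cache:
            e2t: dict[tuple[int, int], list[int]] = {}
            for t, (a, b, c) in enumerate(self.triangles):
                for u, v in ((a, b), (b, c), (c, a)):
                    key = (u, v) if u < v else (v, u)
                    e2t.setdefault(key, []).append(t)
            self._cache["edge2tri"] = e2t
        return self._cache["edge2tri"]

    def triangle_neighbors(self) -> list[list[int]]:
        """Edge-adjacent triangle neighbours for every triangle (cached)."""
        if "neighbors" not in self._cache:
            nbrs: list[list[int]] = [[] for _ in range(self.n_triangles)]
            for tris in self.edge_to_triangles().values():
                if len(tris) == 2:
                    a, b = tris
                    nbrs[a].append(b)
                    nbrs[b].append(a)
            self._cache["neighbors"] = nbrs
        return self._cache["neighbors"]

    def validate(self) -> None:
        """Check the structural invariants; raise ``ValueError`` on failure."""
        r = np.linalg.norm(self.nodes, axis=1)
        if not np.all(r <= 1 + 1e-9):
            raise ValueError("node outside closed unit disk")
        if not np.all(self.signed_areas() > 0):
            raise ValueError("triangle with nonpositive signed area")
        if not np.all(np.isin(self.electrode_nodes, self.boundary_nodes)):
            raise ValueError("electrode node not on boundary")
        if len(np.unique(self.electrode_nodes)) != len(self.electrode_nodes):
            raise ValueError("duplicate electrode nodes")
        # every boundary edge belongs to exactly one triangle
        bset = set(self.boundary_nodes.tolist())
        nb = len(self.boundary_nodes)
        for i in range(nb):
            u = self.boundary_nodes[i]
            v = self.boundary_nodes[(i + 1) % nb]
            key = (u, v) if u < v else (v, u)
            tris = self.edge_to_triangles().get(key, [])
            if len(tris) != 1:
                raise ValueError(f"boundary edge {key} in {len(tris)} triangles")
        del bset


def build_disk_mesh(spec: DomainSpec, h: float) -> TriMesh:
    """Triangulate the unit disk with target edge length ``h``.

    Nodes are laid out on concentric rings spaced ``~h`` apart (alternate
    rings rotated half a step to avoid degenerate quads) and triangulated
    with Delaunay.  The outermost ring carries the boundary nodes; its count
    is rounded to a multiple of ``L`` so each electrode angle ``2*pi*k/L``
    coincides with a boundary node.

    Raises
    ------
    ConfigurationError
        If ``h`` is so coarse that the boundary cannot host ``L`` distinct
        electrode nodes.
    """
    if spec.dimension != 2:
        raise ConfigurationError("mesh construction supports dimension 2 only")
    if not 0 < h < 1:
        raise ValueError(f"target edge length must be in (0, 1), got {h}")
    L = spec.n_electrodes

    n_raw = int(round(2 * np.pi / h))
    if n_raw < L:
        raise ConfigurationError(
            f"h={h} yields only {n_raw} boundary nodes; cannot host {L} electrodes"
        )
    n_boundary = L * max(1, int(round(n_raw / L)))

    n_rings = max(1, int(round(1.0 / h)))
    pts = [np.zeros((1, 2))]
    for j in range(1, n_rings + 1):
        r = j / n_rings
        if j == n_rings:
            n_j = n_boundary
            offset = 0.0
        else:
            n_j = max(6, int(round(2 * np.pi * r / h)))
            offset = (j % 2) * np.pi / n_j
        ang = 2 * np.pi * np.arange(n_j) / n_j + offset
        pts.append(np.column_stack([r * np.cos(ang), r * np.sin(ang)]))
    nodes = np.vstack(pts)

    tri = Delaunay(nodes)
    triangles = tri.simplices.copy()
    # enforce CCW orientation
    p = nodes[triangles]
    areas = 0.5 * _cross2(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0])
    flip = areas < 0
    triangles[flip] = triangles[flip][:, [0, 2, 1]]
    # drop degenerate slivers (cocircular artefacts), if any
    p = nodes[triangles]
    areas = 0.5 * _cross2(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0])
    triangles = triangles[areas > 1e-12]

    boundary = np.arange(len(nodes) - n_boundary, len(nodes))
    # outermost ring was generated in CCW order starting at angle 0
    electrode_nodes = boundary[
        (np.arange(L) * n_boundary) // L
    ]

    mesh = TriMesh(
        nodes=nodes,
        triangles=triangles,
        boundary_nodes=boundary,
        electrode_nodes=electrode_nodes,
        h=h,
    )
    mesh.validate()
    return mesh


def triangle_centroids(mesh: TriMesh) -> np.ndarray:
    """Centroid (vertex mean) of every triangle, shape ``(T, 2)``."""
    return mesh.nodes[mesh.triangles].mean(axis=1)


def connected_components(
    mesh: TriMesh, element_flags: Sequence[bool] | np.ndarray
) -> list[np.ndarray]:
    """Partition flagged triangles into maximal edge-connected components.

    Two triangles are adjacent iff they share a full edge (sharing only a
    vertex does not connect them).  Components are returned sorted by their
    smallest contained triangle index; each component is a sorted int array.
    """
    flags = np.asarray(element_flags, dtype=bool)
    if flags.shape != (mesh.n_triangles,):
        raise ValueError(
            f"flags length {flags.shape} != triangle count {mesh.n_triangles}"
        )
    nbrs = mesh.triangle_neighbors()
    seen = np.zeros(mesh.n_triangles, dtype=bool)
    components: list[np.ndarray] = []
    for start in np.flatnonzero(flags):
        if seen[start]:
            continue
        stack = [int(start)]
        seen[start] = True
        comp = []
        while stack:
            t = stack.pop()
            comp.append(t)
            for nb in nbrs[t]:
                if flags[nb] and not seen[nb]:
                    seen[nb] = True
                    stack.append(nb)
        components.append(np.array(sorted(comp), dtype=np.int64))
    components.sort(key=lambda c: int(c[0]))
    return components
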