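"""Linear tetrahedral meshes (4-node constant-strain elements).

Node coordinates are millimetres.  Connectivity is 0-based in memory; the
Abaqus-style readers/writers in :mod:`fabrifem.io` translate to the 1-based
on-disk convention.  Every tetrahedron is stored with positive signed
volume under the ordering ``det([p1-p0, p2-p0, p3-p0]) > 0``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

# faces of a tet in local node indices (outward for positively oriented tets)
_TET_FACES = np.array([[0, 2, 1], [0, 1, 3], [1, 2, 3], [0, 3, 2]])


@dataclass
class TetMesh:
    nodes: np.ndarray                       # (n, 3) float, mm
    tets: np.ndarray                        # (m, 4) int, 0-based
    node_sets: dict = field(default_factory=dict)
    element_sets: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.nodes = np.asarray(self.nodes, dtype=float).reshape(-1, 3)
        self.tets = np.asarray(self.tets, dtype=np.int64).reshape(-1, 4)
        if self.tets.size and (self.tets.min() < 0 or self.tets.max() >= len(self.nodes)):
            raise ValueError("tet connectivity references nodes out of range")
        self.node_sets = {k: np.asarray(v, dtype=np.int64) for k, v in self.node_sets.items()}
        self.element_sets = {k: np.asarray(v, dtype=np.int64) for k, v in self.element_sets.items()}

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_elements(self) -> int:
        return len(self.tets)

    def tet_volumes(self) -> np.ndarray:
        p = self.nodes[self.tets]
        d = p[:, 1:] - p[:, :1]
        return np.linalg.det(d) / 6.0

    def centroids(self) -> np.ndarray:
        return self.nodes[self.tets].mean(axis=1)

    def bbox(self) -> np.ndarray:
        return np.stack([self.nodes.min(axis=0), self.nodes.max(axis=0)])

    def orient_positive(self) -> None:
        """Swap local nodes 2,3 of inverted tets so all volumes are positive."""
        vol = self.tet_volumes()
        bad = vol < 0
        if np.any(bad):
            self.tets[bad] = self.tets[bad][:, [0, 1, 3, 2]]
        if np.any(np.isclose(self.tet_volumes(), 0.0)):
            raise ValueError("mesh contains degenerate (zero-volume) tets")

    def boundary_triangles(self) -> np.ndarray:
        """Triangles appearing in exactly one tet (the free surface)."""
        faces = self.tets[:, _TET_FACES].reshape(-1, 3)
        key = np.sort(faces, axis=1)
        _, idx, counts = np.unique(key, axis=0, return_index=True, return_counts=True)
        return faces[idx[counts == 1]]

    def boundary_nodes(self) -> np.ndarray:
        return np.unique(self.boundary_triangles())

    def surface_euler_characteristic(self) -> int:
        """V - E + F of the boundary surface (2 for a topological ball)."""
        tris = self.boundary_triangles()
        v = len(np.unique(tris))
        edges = np.sort(tris[:, [[0, 1], [1, 2], [2, 0]]].reshape(-1, 2), axis=1)
        e = len(np.unique(edges, axis=0))
        return v - e + len(tris)
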