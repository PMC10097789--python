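"""Synthetic trabecular-like volumes and surrogate meshes.

These generators stand in for micro-CT data and segmented femur meshes
so every pipeline stage is testable without external downloads:

* ``rod_lattice_volume`` — a periodic lattice of axis-aligned struts
  whose per-axis radii set the microstructural anisotropy (thicker
  struts along an axis give the largest MIL along that axis);
* ``gaussian_field_volume`` — thresholded correlated noise emulating
  irregular trabecular texture with a controllable BV/TV and, through
  anisotropic correlation lengths, controllable fabric;
* ``box_mesh`` — a structured tet mesh of a box (6 tets per hexahedron);
* ``femur_like_mesh`` — a deliberately crude proximal-femur surrogate
  (spherical head centred at the origin + angled neck + shaft) carrying
  all the node/element sets the load tables reference.

All stochastic generation is keyed by a single integer seed.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .mesh import TetMesh
from .tables import MUSCLES
from .volume import BinaryVolume

# 6-tet decomposition of a hexahedron around the main diagonal v000-v111;
# shared-face diagonals agree between neighbouring cells, so the mesh conforms.
_HEX_TO_TETS = np.array([
    [0, 1, 3, 7], [0, 3, 2, 7], [0, 2, 6, 7],
    [0, 6, 4, 7], [0, 4, 5, 7], [0, 5, 1, 7],
])
# hex corner offsets in (i, j, k); corner index bit order: x + 2y + 4z
_HEX_CORNERS = np.array([
    [0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0],
    [0, 0, 1], [1, 0, 1], [0, 1, 1], [1, 1, 1],
])


def rod_lattice_volume(shape, strut_radii_um, spacing_um: float,
                       voxel_size_um: float) -> BinaryVolume:
    """Union of axis-aligned cylinders on a periodic lattice.

    ``strut_radii_um[a]`` is the radius of the struts running along axis
    ``a``; the BV/TV of the result is the exact bone-voxel fraction.
    """
    shape = tuple(int(s) for s in shape)
    radii = np.asarray(strut_radii_um, dtype=float).reshape(3)
    if min(shape) < 1:
        raise ValueError("degenerate shape")
    if np.any(radii <= 0) or np.any(radii >= spacing_um / 2):
        raise ValueError("strut radii must satisfy 0 < r < spacing/2")
    if min(shape) * voxel_size_um < 3 * spacing_um:
        raise ValueError("shape too small: need >= 3 lattice periods per axis")
    coords = [(np.arange(n) + 0.5) * voxel_size_um for n in shape]

    def offgrid(c):
        # distance to the nearest lattice line position along one axis
        return np.abs((c + spacing_um / 2) % spacing_um - spacing_um / 2)

    dx, dy, dz = (offgrid(c) for c in coords)
    X2 = dx[:, None, None] ** 2
    Y2 = dy[None, :, None] ** 2
    Z2 = dz[None, None, :] ** 2
    bone = (Y2 + Z2 <= radii[0] ** 2) | (X2 + Z2 <= radii[1] ** 2) | (X2 + Y2 <= radii[2] ** 2)
    return BinaryVolume(bone, voxel_size_um)


def gaussian_field_volume(shape, correlation_lengths_um, target_bvtv: float,
                          seed: int, voxel_size_um: float = 82.0) -> BinaryVolume:
    """Thresholded smoothed Gaussian noise with an exact-quantile BV/TV.

    Anisotropic correlation lengths elongate the solid phase, moving the
    fabric eigen-directions onto the stretched axes.  The same seed
    gives a bitwise-identical volume.
    """
    if not 0 < target_bvtv < 1:
        raise ValueError("target_bvtv must lie strictly between 0 and 1 "
                         "(all-empty/all-solid volumes are unreachable)")
    shape = tuple(int(s) for s in shape)
    sigmas = np.asarray(correlation_lengths_um, dtype=float) / voxel_size_um
    rng = np.random.default_rng(seed)
    field = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=sigmas,
                                    mode="wrap")
    thr = np.quantile(field, 1.0 - target_bvtv)
    return BinaryVolume(field >= thr, voxel_size_um)


def _box_nodes_tets(extent_mm, target_edge_mm):
    extent = np.asarray(extent_mm, dtype=float).reshape(3)
    if np.any(extent <= 0):
        raise ValueError("extent must be positive")
    if target_edge_mm > extent.min():
        raise ValueError("target_edge exceeds the smallest box extent")
    ncell = np.maximum(np.rint(extent / target_edge_mm).astype(int), 1)
    axes = [np.linspace(0, extent[a], ncell[a] + 1) for a in range(3)]
    nx, ny, nz = ncell + 1
    X, Y, Z = np.meshgrid(*axes, indexing="ij")
    nodes = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])

    def nid(i, j, k):
        return (i * ny + j) * nz + k

    return nodes, axes, ncell, nid


def box_mesh(extent_mm, target_edge_mm: float) -> TetMesh:
    """Structured tet mesh of an axis-aligned box anchored at the origin.

    Each grid hexahedron is split into 6 tets sharing its main diagonal.
    Face node sets ``xmin, xmax, ymin, ymax, zmin, zmax`` are created.
    """
    nodes, axes, ncell, nid = _box_nodes_tets(extent_mm, target_edge_mm)
    tets = []
    for i in range(ncell[0]):
        for j in range(ncell[1]):
            for k in range(ncell[2]):
                corner = np.array([nid(i + o[0], j + o[1], k + o[2]) for o in _HEX_CORNERS])
                tets.extend(corner[t] for t in _HEX_TO_TETS)
    mesh = TetMesh(nodes, np.array(tets))
    mesh.orient_positive()
    extent = np.asarray(extent_mm, dtype=float)
    tol = 1e-9 * max(extent.max(), 1.0)
    for a, name in enumerate("xyz"):
        mesh.node_sets[f"{name}min"] = np.flatnonzero(np.abs(nodes[:, a]) < tol)
        mesh.node_sets[f"{name}max"] = np.flatnonzero(np.abs(nodes[:, a] - extent[a]) < tol)
    mesh.element_sets["bone"] = np.arange(mesh.n_elements)
    return mesh


def _capsule_distance(pts, a, b, r):
    ab = b - a
    t = np.clip(((pts - a) @ ab) / (ab @ ab), 0.0, 1.0)
    closest = a + t[:, None] * ab
    return np.linalg.norm(pts - closest, axis=1) - r


# attachment anchor directions/offsets (mm at scale 1) around the trochanters;
# anatomically plausible but invented patches — only topology matters here.
_ATTACHMENT_ANCHORS = {
    "Glut_max1": (34, -16, 6), "Glut_max2": (34, -22, 2), "Glut_max3": (34, -28, -4),
    "Glut_med1": (32, -12, 8), "Glut_med2": (33, -14, 0), "Glut_med3": (32, -12, -8),
    "Glut_min1": (30, -18, 9), "Glut_min2": (31, -20, 0), "Glut_min3": (30, -18, -9),
    "Iliacus": (10, -30, 6), "Psoas": (10, -32, -4), "Pect": (12, -40, 2),
    "Perif": (26, -16, -10), "Quadfem": (28, -30, -10), "Gem": (26, -24, -11),
}


def femur_like_mesh(scale: float = 1.0, target_edge_mm: float = 4.0,
                    attachment_radius_mm: float = 7.0) -> TetMesh:
    """Parametric proximal-femur surrogate with head centre at the origin.

    The solid is the union of a spherical head (r = 16 mm x scale), an
    angled neck capsule and a shaft capsule; it is voxelized on a
    structured grid and split into tets.  Node sets: ``distal_fixed``
    (distal shaft cross-section), ``joint_surface`` (superior head cap)
    and one attachment set per muscle of the load tables.  Element set
    ``tendon_cartilage`` is the one-element-thick boundary layer at the
    attachments; all remaining tets form ``bone``.
    """
    if scale <= 0:
        raise ValueError("scale must be positive")
    rh, rn, rs = 16.0 * scale, 9.5 * scale, 12.5 * scale
    head_c = np.zeros(3)
    neck_end = np.array([20.0, -22.0, 0.0]) * scale
    distal = np.array([20.0, -70.0, 0.0]) * scale

    lo = np.array([-rh - 2, distal[1], -rh - 2])
    hi = np.array([neck_end[0] + rs + 2, rh + 2, rh + 2])
    extent = hi - lo
    nodes, axes, ncell, nid = _box_nodes_tets(extent, target_edge_mm)
    nodes = nodes + lo

    centers = (
        np.stack(np.meshgrid(*[(ax[:-1] + ax[1:]) / 2 for ax in axes], indexing="ij"),
                 axis=-1).reshape(-1, 3) + lo
    )
    inside = (
        (np.linalg.norm(centers - head_c, axis=1) <= rh)
        | (_capsule_distance(centers, head_c, neck_end, rn) <= 0)
        | (_capsule_distance(centers, neck_end, distal, rs) <= 0)
    ).reshape(tuple(ncell))

    tets = []
    for i, j, k in np.argwhere(inside):
        corner = np.array([nid(i + o[0], j + o[1], k + o[2]) for o in _HEX_CORNERS])
        tets.extend(corner[t] for t in _HEX_TO_TETS)
    tets = np.array(tets)
    used, inv = np.unique(tets, return_inverse=True)
    mesh = TetMesh(nodes[used], inv.reshape(tets.shape))
    mesh.orient_positive()
    if mesh.n_elements == 0:
        raise ValueError("meshing failure: no cells inside the surrogate solid")

    bnodes = mesh.boundary_nodes()
    bpos = mesh.nodes[bnodes]
    ymin = mesh.nodes[:, 1].min()
    mesh.node_sets["distal_fixed"] = np.flatnonzero(mesh.nodes[:, 1] < ymin + 1e-6)
    on_head = np.abs(np.linalg.norm(bpos, axis=1) - rh) < 0.75 * target_edge_mm
    cap = bnodes[on_head & (bpos[:, 1] > 0.35 * rh)]
    if len(cap) == 0:
        raise ValueError("meshing failure: empty joint-surface cap")
    mesh.node_sets["joint_surface"] = cap

    attach_nodes = set()
    for muscle in MUSCLES:
        anchor = np.array(_ATTACHMENT_ANCHORS[muscle], dtype=float) * scale
        d = np.linalg.norm(bpos - anchor, axis=1)
        sel = bnodes[d <= attachment_radius_mm * scale]
        if len(sel) == 0:
            sel = bnodes[np.argsort(d)[:3]]
        mesh.node_sets[muscle] = sel
        attach_nodes.update(sel.tolist())

    touches = np.array([any(int(n) in attach_nodes for n in tet) for tet in mesh.tets])
    mesh.element_sets["tendon_cartilage"] = np.flatnonzero(touches)
    mesh.element_sets["bone"] = np.flatnonzero(~touches)
    return mesh
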