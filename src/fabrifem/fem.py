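"""Static linear-elastic solver on C3D4 (constant-strain) tet meshes.

Units: coordinates mm, moduli MPa (= N/mm^2), forces N, displacements
mm, so the stiffness assembles directly in N/mm.  The joint reaction is
routed through 2-node axial rod (truss) elements from a centre node to
the joint-surface node set, which distributes the load over the head cap
without contact mechanics.  Muscle point forces are split equally over
their attachment node sets.  Distal fixation clamps a node set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .mesh import TetMesh


@dataclass
class LinearSystem:
    K: sp.csr_matrix                 # N/mm, symmetric
    f: np.ndarray                    # N
    fixed_dofs: np.ndarray           # global dof indices
    fixed_values: np.ndarray         # prescribed displacements, mm
    n_nodes: int                     # including any rod centre node
    center_node: int | None = None   # joint-centre node index, if rods present
    rods: np.ndarray | None = None   # (r, 2) rod connectivity


@dataclass
class FieldResult:
    u: np.ndarray          # (n_nodes, 3) displacements, mm
    strain: np.ndarray     # (m, 6) Voigt, engineering shear
    stress: np.ndarray     # (m, 6) Voigt, MPa
    residual: float        # ||K u - f|| / ||f||
    reactions: np.ndarray = field(default=None)   # (n_nodes, 3), N


def element_stiffness(nodes4: np.ndarray, C: np.ndarray):
    """12x12 stiffness Ke = V * B^T C B of one constant-strain tet.

    Returns (Ke, B, V).  Raises on inverted or degenerate elements.
    """
    p = np.asarray(nodes4, dtype=float).reshape(4, 3)
    M4 = np.column_stack([np.ones(4), p])
    V = np.linalg.det(p[1:] - p[0]) / 6.0
    if V <= 0:
        raise ValueError(f"tet has non-positive volume {V}")
    grads = np.linalg.inv(M4)[1:, :]           # (3, 4): d N_a / d x_i
    B = np.zeros((6, 12))
    for a in range(4):
        bx, by, bz = grads[:, a]
        B[0, 3 * a] = bx
        B[1, 3 * a + 1] = by
        B[2, 3 * a + 2] = bz
        B[3, 3 * a + 1] = bz
        B[3, 3 * a + 2] = by
        B[4, 3 * a] = bz
        B[4, 3 * a + 2] = bx
        B[5, 3 * a] = by
        B[5, 3 * a + 1] = bx
    Ke = V * B.T @ C @ B
    return Ke, B, V


def element_operators(mesh: TetMesh):
    """B operators and volumes for all tets (strain recovery and assembly)."""
    Bs = np.empty((mesh.n_elements, 6, 12))
    Vs = np.empty(mesh.n_elements)
    for e, tet in enumerate(mesh.tets):
        try:
            _, B, V = element_stiffness(mesh.nodes[tet], np.eye(6))
        except ValueError as err:
            raise ValueError(f"element {e}: {err}") from err
        Bs[e], Vs[e] = B, V
    return Bs, Vs


def assemble_stiffness(mesh: TetMesh, materials, n_nodes_total: int | None = None) -> sp.csr_matrix:
    """Assemble the global sparse stiffness from per-element materials."""
    if len(materials) != mesh.n_elements:
        raise ValueError("one ElementMaterial required per element")
    n = n_nodes_total or mesh.n_nodes
    ndof = 3 * n
    nnz = mesh.n_elements * 144
    rows = np.empty(nnz, dtype=np.int64)
    cols = np.empty(nnz, dtype=np.int64)
    vals = np.empty(nnz)
    for e, (tet, mat) in enumerate(zip(mesh.tets, materials)):
        Ke, _, _ = element_stiffness(mesh.nodes[tet], mat.C_global)
        dofs = (3 * tet[:, None] + np.arange(3)).reshape(12)
        rows[e * 144:(e + 1) * 144] = np.repeat(dofs, 12)
        cols[e * 144:(e + 1) * 144] = np.tile(dofs, 12)
        vals[e * 144:(e + 1) * 144] = Ke.reshape(-1)
    K = sp.coo_matrix((vals, (rows, cols)), shape=(ndof, ndof)).tocsr()
    return 0.5 * (K + K.T)


def rod_stiffness_entries(nodes: np.ndarray, center: np.ndarray,
                          surface_nodes: np.ndarray, stiffness: float,
                          center_index: int):
    """Truss-element stiffness triplets tying the centre node to a cap.

    Each rod contributes k * (n n^T) on its axis direction; a force
    applied at the centre node is then transmitted so the vector sum of
    the surface tractions equals the applied force (static equilibrium).
    """
    if len(surface_nodes) == 0:
        raise ValueError("joint surface node set is empty")
    rows, cols, vals = [], [], []
    for sn in surface_nodes:
        axis = nodes[sn] - center
        L = np.linalg.norm(axis)
        if L <= 0:
            raise ValueError(f"zero-length rod to node {sn}")
        n = axis / L
        kblock = stiffness * np.outer(n, n)
        for (na, nb, sign) in ((center_index, center_index, 1.0), (sn, sn, 1.0),
                               (center_index, sn, -1.0), (sn, center_index, -1.0)):
            for i in range(3):
                for j in range(3):
                    rows.append(3 * na + i)
                    cols.append(3 * nb + j)
                    vals.append(sign * kblock[i, j])
    return np.array(rows), np.array(cols), np.array(vals)


def default_rod_stiffness(mesh: TetMesh, materials, factor: float = 1e3) -> float:
    """factor x the stiffest element's axial stiffness (saturation regime)."""
    Emax = max(float(np.max(m.C_global)) for m in materials)
    edge = float(np.cbrt(np.mean(np.abs(mesh.tet_volumes()))))
    return factor * Emax * edge


def apply_loads(mesh: TetMesh, load_case, n_nodes_total: int,
                center_node: int | None = None) -> np.ndarray:
    """Nodal force vector: muscle forces split equally per attachment set,
    the joint reaction applied at the rod centre node (or the surface set
    directly when no rods are used)."""
    f = np.zeros(3 * n_nodes_total)
    for ml in load_case.muscle_loads:
        if ml.attachment_set not in mesh.node_sets:
            raise ValueError(f"missing attachment node set '{ml.attachment_set}'")
        nodes = mesh.node_sets[ml.attachment_set]
        share = ml.direction * ml.magnitude_N / len(nodes)
        for n in nodes:
            f[3 * n:3 * n + 3] += share
    reaction = load_case.reaction_vector()
    if center_node is not None:
        f[3 * center_node:3 * center_node + 3] += reaction
    else:
        nodes = mesh.node_sets[load_case.joint_surface_set]
        for n in nodes:
            f[3 * n:3 * n + 3] += reaction / len(nodes)
    return f


def build_system(mesh: TetMesh, materials, load_case=None, fix_set: str = "distal_fixed",
                 rod_stiffness: float | None = None, use_rods: bool = True) -> LinearSystem:
    """Assemble stiffness, rods, loads and constraints into a LinearSystem."""
    center_node = None
    rods = None
    n_total = mesh.n_nodes
    K = assemble_stiffness(mesh, materials, n_nodes_total=mesh.n_nodes + (1 if use_rods and load_case is not None else 0))
    if use_rods and load_case is not None:
        center_node = mesh.n_nodes
        n_total = mesh.n_nodes + 1
        surface = mesh.node_sets[load_case.joint_surface_set]
        k_rod = rod_stiffness or default_rod_stiffness(mesh, materials)
        r, c, v = rod_stiffness_entries(mesh.nodes, load_case.joint_center_mm,
                                        surface, k_rod, center_node)
        K = (K + sp.coo_matrix((v, (r, c)), shape=K.shape).tocsr())
        rods = np.column_stack([np.full(len(surface), center_node), surface])
    f = (apply_loads(mesh, load_case, n_total, center_node)
         if load_case is not None else np.zeros(3 * n_total))
    if fix_set not in mesh.node_sets:
        raise ValueError(f"missing fixation node set '{fix_set}'")
    fixed = (3 * mesh.node_sets[fix_set][:, None] + np.arange(3)).reshape(-1)
    return LinearSystem(K=K, f=f, fixed_dofs=fixed, fixed_values=np.zeros(len(fixed)),
                        n_nodes=n_total, center_node=center_node, rods=rods)


def solve_static(system: LinearSystem, mesh: TetMesh, materials,
                 residual_tol: float = 1e-8) -> FieldResult:
    """Direct sparse solve with eliminated constraints; recover fields."""
    ndof = 3 * system.n_nodes
    free = np.setdiff1d(np.arange(ndof), system.fixed_dofs)
    u = np.zeros(ndof)
    u[system.fixed_dofs] = system.fixed_values
    K = system.K.tocsc()
    rhs = system.f[free] - K[np.ix_(free, system.fixed_dofs)] @ system.fixed_values
    Kff = K[np.ix_(free, free)].tocsc()
    try:
        lu = spla.splu(Kff)
    except RuntimeError as err:
        raise ValueError(f"singular constrained system: {err}") from err
    uf = lu.solve(rhs)
    if not np.all(np.isfinite(uf)):
        raise ValueError("singular constrained system: mesh is under-constrained")
    denom = np.linalg.norm(rhs) or 1.0
    # iterative refinement with extended-precision residuals absorbs the
    # conditioning penalty of the stiff rod elements
    Kld = Kff.astype(np.longdouble)
    rhs_ld = rhs.astype(np.longdouble)
    uld = uf.astype(np.longdouble)
    for _ in range(5):
        r = rhs_ld - Kld @ uld
        if float(np.linalg.norm(r.astype(np.float64))) / denom < 1e-13:
            break
        uld = uld + lu.solve(r.astype(np.float64))
    uf = uld.astype(np.float64)
    u[free] = uf
    residual = float(np.linalg.norm((rhs_ld - Kld @ uld).astype(np.float64)) / denom)
    if residual > residual_tol * 1e4:
        raise ValueError(f"solver residual {residual:.2e} unacceptably large")
    Bs, _ = element_operators(mesh)
    ue = u[:3 * mesh.n_nodes].reshape(-1, 3)[mesh.tets].reshape(mesh.n_elements, 12)
    strain = np.einsum("eij,ej->ei", Bs, ue)
    stress = np.einsum("eij,ej->ei", np.array([m.C_global for m in materials]), strain)
    reactions = (system.K @ u - system.f).reshape(-1, 3)
    return FieldResult(u=u.reshape(-1, 3), strain=strain, stress=stress,
                       residual=residual, reactions=reactions)


def total_strain_energy(result: FieldResult, mesh: TetMesh) -> float:
    """Sum over elements of W_e * V_e (MPa * mm^3 = N mm)."""
    _, Vs = element_operators(mesh)
    We = 0.5 * np.einsum("ei,ei->e", result.stress, result.strain)
    return float(We @ Vs)


def face_traction_loads(mesh: TetMesh, node_set: str, traction: np.ndarray,
                        n_nodes_total: int | None = None) -> np.ndarray:
    """Consistent nodal forces for a uniform traction (MPa) on the boundary
    triangles whose three corners all belong to ``node_set``."""
    traction = np.asarray(traction, dtype=float).reshape(3)
    sel = set(mesh.node_sets[node_set].tolist())
    f = np.zeros(3 * (n_nodes_total or mesh.n_nodes))
    used = 0
    for tri in mesh.boundary_triangles():
        if all(int(n) in sel for n in tri):
            p = mesh.nodes[tri]
            area = 0.5 * np.linalg.norm(np.cross(p[1] - p[0], p[2] - p[0]))
            for n in tri:
                f[3 * n:3 * n + 3] += traction * area / 3.0
            used += 1
    if used == 0:
        raise ValueError(f"no boundary triangles found inside node set '{node_set}'")
    return f
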