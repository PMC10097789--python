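"""Zysset-Curnier orthotropic elasticity for trabecular bone.

The law maps an element's bone volume fraction rho = BV/TV and the
normalized fabric eigenvalues (m1, m2, m3), sum m_i = 3, to orthotropic
engineering constants::

    E_i   = E0 * rho**k * (m_i**2)**l
    nu_ij = nu0 * (m_i / m_j)**l
    G_ij  = G0 * rho**k * (m_i * m_j)**l

With m = (1, 1, 1) the law degenerates to isotropy with E = E0 * rho**k
and nu = nu0.  The Voigt order used throughout the package is
(11, 22, 33, 23, 31, 12) with engineering shear strains (gamma = 2 eps).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np

VOIGT_ORDER = ((0, 0), (1, 1), (2, 2), (1, 2), (2, 0), (0, 1))


@dataclass
class MaterialCard:
    """Tissue constants and the density thresholds of the material mapping.

    Defaults are the published constants for human trabecular bone tissue
    (E0 = 22500 MPa, nu0 = 0.3, G0 = 8650 MPa, k = 1.9, l = 0.99) together
    with the BV/TV rules: above ``rho_hi`` an element is treated as compact
    cortical bone with the printed isotropic modulus ``E_cortical``; at or
    below ``rho_lo`` the fabric is unreliable and the element is isotropic
    with the density floored at ``rho_lo``.
    """

    E0: float = 22500.0          # MPa
    nu0: float = 0.3
    G0: float = 8650.0           # MPa
    k: float = 1.9
    l: float = 0.99
    rho_lo: float = 0.1
    rho_hi: float = 0.9
    rho_cortical: float = 0.95
    E_cortical: float = 22500.0  # MPa, printed value for compact bone
    nu_cortical: float = 0.3
    E_tendon: float = 5.0        # MPa, tendon / joint cartilage layer
    nu_tendon: float = 0.3

    def __post_init__(self) -> None:
        if self.E0 <= 0 or self.G0 <= 0:
            raise ValueError("E0 and G0 must be positive")
        if not 0 < self.nu0 < 0.5:
            raise ValueError("nu0 must lie in (0, 0.5)")
        if self.k <= 0 or self.l <= 0:
            raise ValueError("exponents k and l must be positive")
        if not self.rho_lo < self.rho_hi:
            raise ValueError("rho_lo must be below rho_hi")


@dataclass
class EngineeringConstants:
    """Orthotropic engineering constants in the material (fabric) frame."""

    E: np.ndarray        # (3,) Young's moduli, MPa
    nu: np.ndarray       # (3, 3), nu[i, j] = nu_ij for i != j; diagonal 0
    G: np.ndarray        # (3,) shear moduli (G23, G31, G12), MPa

    def __post_init__(self) -> None:
        self.E = np.asarray(self.E, dtype=float).reshape(3)
        self.nu = np.asarray(self.nu, dtype=float).reshape(3, 3)
        self.G = np.asarray(self.G, dtype=float).reshape(3)
        if np.any(self.E <= 0) or np.any(self.G <= 0):
            raise ValueError("Young's and shear moduli must be positive")


class Model(str, enum.Enum):
    """The three constitutive mappings compared by the pipeline."""

    ANISOTROPIC = "anisotropic"   # heterogeneous orthotropic (fabric-based)
    ISO_HETERO = "iso_hetero"     # heterogeneous isotropic (BV/TV only)
    ISO_HOMO = "iso_homo"         # homogeneous isotropic (mean BV/TV)


@dataclass
class ElementMaterial:
    element_id: int
    model_tag: str               # anisotropic | iso_hetero | iso_homo | cortical | tendon
    rho: float
    C_global: np.ndarray         # (6, 6) stiffness in global frame, MPa
    S_local: np.ndarray          # (6, 6) compliance in the material frame, 1/MPa
    frame: np.ndarray = field(default_factory=lambda: np.eye(3))


def engineering_constants(card: MaterialCard, rho: float, m) -> EngineeringConstants:
    """Evaluate the power law at density ``rho`` and fabric eigenvalues ``m``."""
    m = np.asarray(m, dtype=float).reshape(3)
    if not 0 < rho <= 1:
        raise ValueError(f"rho must lie in (0, 1], got {rho}")
    if np.any(m <= 0):
        raise ValueError("fabric eigenvalues must be positive")
    scale = card.E0 * rho**card.k
    E = scale * (m**2) ** card.l
    nu = np.zeros((3, 3))
    G = np.zeros(3)
    pairs = ((1, 2), (2, 0), (0, 1))
    for i in range(3):
        for j in range(3):
            if i != j:
                nu[i, j] = card.nu0 * (m[i] / m[j]) ** card.l
    for a, (i, j) in enumerate(pairs):
        G[a] = card.G0 * rho**card.k * (m[i] * m[j]) ** card.l
    return EngineeringConstants(E=E, nu=nu, G=G)


def compliance_matrix(ec: EngineeringConstants, sym_tol: float = 1e-8) -> np.ndarray:
    """Orthotropic compliance in Voigt order (11,22,33,23,31,12), eng. shear."""
    E, nu, G = ec.E, ec.nu, ec.G
    S = np.zeros((6, 6))
    for i in range(3):
        S[i, i] = 1.0 / E[i]
        for j in range(3):
            if i != j:
                # column j of the normal block: -nu_ji / E_j
                S[i, j] = -nu[j, i] / E[j]
    S[3, 3], S[4, 4], S[5, 5] = 1.0 / G[0], 1.0 / G[1], 1.0 / G[2]
    asym = np.abs(S - S.T).max() / np.abs(S).max()
    if asym > sym_tol:
        raise ValueError(
            f"compliance asymmetry {asym:.2e} exceeds {sym_tol:.0e}; "
            "engineering constants violate nu_ij/E_i = nu_ji/E_j"
        )
    return 0.5 * (S + S.T)


def stiffness_matrix(ec: EngineeringConstants) -> np.ndarray:
    return np.linalg.inv(compliance_matrix(ec))


def isotropic_stiffness(E: float, nu: float) -> np.ndarray:
    """Isotropic 6x6 stiffness (engineering-shear Voigt convention)."""
    lam = E * nu / ((1 + nu) * (1 - 2 * nu))
    mu = E / (2 * (1 + nu))
    C = np.zeros((6, 6))
    C[:3, :3] = lam
    C[np.arange(3), np.arange(3)] += 2 * mu
    C[np.arange(3, 6), np.arange(3, 6)] = mu
    return C


def isotropic_compliance(E: float, nu: float) -> np.ndarray:
    S = np.full((3, 3), -nu / E)
    S[np.arange(3), np.arange(3)] = 1.0 / E
    out = np.zeros((6, 6))
    out[:3, :3] = S
    out[np.arange(3, 6), np.arange(3, 6)] = 2 * (1 + nu) / E
    return out


def _voigt_to_tensor_stiffness(C: np.ndarray) -> np.ndarray:
    T = np.zeros((3, 3, 3, 3))
    for a, (i, j) in enumerate(VOIGT_ORDER):
        for b, (k, l) in enumerate(VOIGT_ORDER):
            for ii, jj in ((i, j), (j, i)):
                for kk, ll in ((k, l), (l, k)):
                    T[ii, jj, kk, ll] = C[a, b]
    return T


def _tensor_to_voigt_stiffness(T: np.ndarray) -> np.ndarray:
    C = np.zeros((6, 6))
    for a, (i, j) in enumerate(VOIGT_ORDER):
        for b, (k, l) in enumerate(VOIGT_ORDER):
            C[a, b] = T[i, j, k, l]
    return C


def rotate_stiffness(C_local: np.ndarray, frame: np.ndarray) -> np.ndarray:
    """Express a stiffness given in the material frame in global axes.

    ``frame`` columns are the material axis directions in global
    coordinates (right-handed orthonormal triad, det = +1).
    """
    R = np.asarray(frame, dtype=float).reshape(3, 3)
    if not np.allclose(R.T @ R, np.eye(3), atol=1e-8):
        raise ValueError("frame is not orthonormal")
    if np.linalg.det(R) < 0:
        raise ValueError("frame must be right-handed (det = +1)")
    T = _voigt_to_tensor_stiffness(np.asarray(C_local, dtype=float))
    Tg = np.einsum("ip,jq,kr,ls,pqrs->ijkl", R, R, R, R, T)
    return _tensor_to_voigt_stiffness(Tg)


def assign_materials(mesh, structures, model, card: MaterialCard | None = None):
    """Build per-element stiffness for one of the three material models.

    ``structures`` is a list of :class:`fabrifem.fabric.ElementStructure`,
    one per tet of ``mesh``.  Elements of the ``tendon_cartilage`` set get
    the soft isotropic tendon/cartilage properties regardless of model.
    """
    card = card or MaterialCard()
    model = Model(model)
    if len(structures) != mesh.n_elements:
        raise ValueError(
            f"need one structure per element ({mesh.n_elements}), got {len(structures)}"
        )
    tendon = set(np.asarray(mesh.element_sets.get("tendon_cartilage", [])).tolist())
    solid = [s for s in structures if s.element_id not in tendon]
    mean_rho = float(np.mean([s.rho for s in solid])) if solid else 0.0

    C_tendon = isotropic_stiffness(card.E_tendon, card.nu_tendon)
    S_tendon = isotropic_compliance(card.E_tendon, card.nu_tendon)
    C_cort = isotropic_stiffness(card.E_cortical, card.nu_cortical)
    S_cort = isotropic_compliance(card.E_cortical, card.nu_cortical)

    _ones = np.ones(3)

    def iso(rho_eff: float):
        # the law's own isotropic reduction (m = 1): keeps the printed G0,
        # so model 1 with unit fabric matches model 2 exactly
        S = compliance_matrix(engineering_constants(card, rho_eff, _ones))
        return np.linalg.inv(S), S

    rho_homo = max(mean_rho, 1e-12)

    out = []
    for s in structures:
        eid = s.element_id
        if eid in tendon:
            out.append(ElementMaterial(eid, "tendon", s.rho, C_tendon, S_tendon))
            continue
        rho = s.rho
        if model is Model.ISO_HOMO:
            C, S = iso(rho_homo)
            out.append(ElementMaterial(eid, "iso_homo", rho, C, S))
            continue
        if rho > card.rho_hi:
            out.append(ElementMaterial(eid, "cortical", rho, C_cort.copy(), S_cort.copy()))
            continue
        degenerate = s.fabric is None
        if model is Model.ISO_HETERO or rho <= card.rho_lo or degenerate:
            C, S = iso(max(rho, card.rho_lo))
            tag = "iso_hetero" if model is Model.ISO_HETERO else "anisotropic"
            out.append(ElementMaterial(eid, tag, rho, C, S))
            continue
        ec = engineering_constants(card, rho, s.fabric.m)
        S = compliance_matrix(ec)
        C_local = np.linalg.inv(S)
        C = rotate_stiffness(C_local, s.fabric.frame)
        out.append(ElementMaterial(eid, "anisotropic", rho, C, S, frame=s.fabric.frame))
    return out
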