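"""Mechanostat-oriented field post-processing.

Derives the scalar and tensor summaries used to compare constitutive
models: major principal (abs) stress/strain with eigenvectors, von Mises
equivalent stress, strain energy density rescaled to tissue level by
BV/TV (w = W / (BV/TV)), Frost-zone classification of the stimulus, and
path profiles sampled through the element-constant fields.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

FROST_ZONES = ("disuse", "dead_zone", "modeling", "microdamage", "fracture")


@dataclass
class FrostThresholds:
    """Mechanostat thresholds (MESr, MESm, MESp, Fx) in the three measures.

    Ranges are stored as printed; the classifier uses the conservative
    edge of each range: tissue stays in disuse until w exceeds the MESr
    range's upper bound, and enters modeling at the MESm range's lower
    bound.  The Fx strain-energy entry is kept verbatim and only serves
    as the microdamage/fracture boundary; it is never derived from the
    strain entry.
    """

    strain_ustrain: dict
    stress_MPa: dict
    sed_MPa: dict

    def __post_init__(self) -> None:
        b = self.classification_bounds()
        if not np.all(np.diff(b) > 0):
            raise ValueError("Frost SED boundaries must be strictly increasing")

    def classification_bounds(self) -> np.ndarray:
        """SED boundaries between successive zones (MPa)."""
        return np.array(
            [
                self.sed_MPa["MESr"][1],   # leave disuse
                self.sed_MPa["MESm"][0],   # enter modeling
                self.sed_MPa["MESp"][0],   # enter microdamage
                self.sed_MPa["Fx"][0],     # enter fracture
            ]
        )


@dataclass
class EnergyDensity:
    W: float      # apparent (continuum) strain energy density, MPa
    w: float      # tissue-level density, MPa
    f_t: float    # bone tissue volume fraction (= BV/TV)


@dataclass
class PathProfile:
    points: np.ndarray      # (n, 3) station coordinates, mm
    p: np.ndarray           # (n,) arclength coordinate, mm
    element: np.ndarray     # (n,) containing element id, -1 outside the mesh
    data: pd.DataFrame      # per-station sampled fields (NaN outside)


def _check_symmetric(T: np.ndarray, tol: float = 1e-9) -> np.ndarray:
    T = np.asarray(T, dtype=float).reshape(3, 3)
    if np.abs(T - T.T).max() > tol * max(np.abs(T).max(), 1.0):
        raise ValueError("tensor is not symmetric")
    return 0.5 * (T + T.T)


def principal_abs(tensor: np.ndarray) -> tuple[float, np.ndarray]:
    """Signed principal value of largest magnitude and its eigenvector.

    Ties between an equal-magnitude tensile and compressive principal
    value are broken toward the compressive (negative) one.
    """
    T = _check_symmetric(tensor)
    vals, vecs = np.linalg.eigh(T)
    lo, hi = vals[0], vals[-1]
    if abs(lo) >= abs(hi):          # compression-first tie break
        val, vec = lo, vecs[:, 0]
    else:
        val, vec = hi, vecs[:, -1]
    if vec[np.argmax(np.abs(vec))] < 0:
        vec = -vec
    return float(val), vec


def von_mises(stress: np.ndarray) -> float:
    """Equivalent von Mises stress of a symmetric 3x3 stress tensor."""
    s = _check_symmetric(stress)
    dev = s - np.trace(s) / 3.0 * np.eye(3)
    return float(np.sqrt(1.5 * np.sum(dev * dev)))


def voigt_to_tensor(v: np.ndarray, engineering_shear: bool) -> np.ndarray:
    """(11,22,33,23,31,12) Voigt vector to symmetric 3x3."""
    v = np.asarray(v, dtype=float).reshape(6)
    f = 0.5 if engineering_shear else 1.0
    return np.array(
        [
            [v[0], f * v[5], f * v[4]],
            [f * v[5], v[1], f * v[3]],
            [f * v[4], f * v[3], v[2]],
        ]
    )


def strain_energy_density(stress_v, strain_v, rho: float) -> EnergyDensity:
    """W = 1/2 sigma : eps (Voigt, engineering shear) and w = W / rho."""
    if not rho > 0:
        raise ValueError("rho must be positive; degenerate elements must be excluded upstream")
    stress_v = np.asarray(stress_v, dtype=float).reshape(6)
    strain_v = np.asarray(strain_v, dtype=float).reshape(6)
    # engineering shear strains make the plain dot product the full contraction
    W = 0.5 * float(stress_v @ strain_v)
    return EnergyDensity(W=W, w=W / rho, f_t=rho)


def frost_classify(w, thresholds: FrostThresholds):
    """Classify tissue-level SED stimulus values into Frost zones.

    Boundaries are inclusive on the lower edge: w equal to a boundary
    belongs to the upper zone.
    """
    w_arr = np.asarray(w, dtype=float)
    if np.any(w_arr < 0):
        raise ValueError("strain energy density must be non-negative")
    idx = np.searchsorted(thresholds.classification_bounds(), w_arr, side="right")
    if w_arr.ndim == 0:
        return FROST_ZONES[int(idx)]
    return np.array(FROST_ZONES, dtype=object)[idx]


def _barycentric_locate(mesh, points: np.ndarray, tol: float = 1e-9) -> np.ndarray:
    """Containing tet per point (-1 if outside), via barycentric tests."""
    p0 = mesh.nodes[mesh.tets[:, 0]]
    T = np.transpose(mesh.nodes[mesh.tets[:, 1:]] - p0[:, None, :], (0, 2, 1))
    Tinv = np.linalg.inv(T)                       # (m, 3, 3)
    out = np.full(len(points), -1, dtype=np.int64)
    for i, pt in enumerate(points):
        lam = np.einsum("mij,mj->mi", Tinv, pt - p0)
        ok = (lam.min(axis=1) >= -tol) & (lam.sum(axis=1) <= 1 + tol)
        hits = np.flatnonzero(ok)
        if hits.size:
            out[i] = hits[0]
    return out


def sample_path(mesh, cell_data: dict, polyline: np.ndarray, step: float) -> PathProfile:
    """Sample element-constant fields along a polyline, every ``step`` mm.

    Fields are taken from the containing element without interpolation
    (C3D4 fields are element-wise constant); stations outside the mesh
    are reported as NaN, never extrapolated.
    """
    poly = np.asarray(polyline, dtype=float).reshape(-1, 3)
    if len(poly) < 2:
        raise ValueError("polyline needs at least two points")
    seg = np.linalg.norm(np.diff(poly, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    total = cum[-1]
    p = np.arange(0.0, total + 1e-12, step)
    pts = np.empty((len(p), 3))
    for i, pi in enumerate(p):
        j = min(np.searchsorted(cum, pi, side="right"), len(seg))
        t = (pi - cum[j - 1]) / seg[j - 1]
        pts[i] = poly[j - 1] + t * (poly[j] - poly[j - 1])
    elem = _barycentric_locate(mesh, pts)
    if np.all(elem < 0):
        raise ValueError("polyline does not intersect the mesh")
    cols = {}
    for name, values in cell_data.items():
        values = np.asarray(values, dtype=float)
        col = np.full(len(p), np.nan)
        inside = elem >= 0
        col[inside] = values[elem[inside]]
        cols[name] = col
    df = pd.DataFrame({"p_mm": p, **cols})
    return PathProfile(points=pts, p=p, element=elem, data=df)


def modulus_ratio_exact(m1_m3, l: float = 0.99):
    """E1/E3 from the power law: (m1/m3)**(2 l)."""
    return np.asarray(m1_m3, dtype=float) ** (2 * l)


def modulus_ratio_approx(m1_m3):
    """Small-exponent approximation E1/E3 ~ (m1/m3)**2 (valid for l ~ 1)."""
    return np.asarray(m1_m3, dtype=float) ** 2


def modulus_ratio_report(structures, l: float = 0.99) -> pd.DataFrame:
    """Tabulate m1/m3 and both modulus-ratio forms for fabric structures.

    Degenerate (fabric-free) entries are skipped with a warning.
    """
    rows = []
    skipped = 0
    for s in structures:
        if s.fabric is None:
            skipped += 1
            continue
        r = s.fabric.m[0] / s.fabric.m[2]
        rows.append(
            {
                "element_id": s.element_id,
                "m1_m3": r,
                "E1_E3_exact": float(modulus_ratio_exact(r, l)),
                "E1_E3_approx": float(modulus_ratio_approx(r)),
            }
        )
    if skipped:
        warnings.warn(f"skipped {skipped} degenerate fabric entries", stacklevel=2)
    return pd.DataFrame(rows)
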