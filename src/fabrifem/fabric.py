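"""Mean-intercept-length (MIL) fabric estimation.

For a cubic window of a binarized trabecular volume, parallel test lines
are cast in a quasi-uniform set of hemisphere directions; along each
direction the MIL is the total test-line length inside the window
divided by the number of bone/marrow interface crossings.  A second
order fabric tensor H is fitted by least squares to the Harrigan-Mann
ellipsoid

    MIL(w)^(-2) = w^T H w ,

so the direction of the largest MIL carries the smallest eigenvalue h of
H and, through M = H^(-1/2), the largest eigenvalue mu of M — i.e. the
stiffest material direction.  The eigenvalues of M are normalized to
m_i = mu_i / mean(mu), so m1 + m2 + m3 = 3.

The MIL variant implemented here uses plain total-length / crossings
(lines clipped to the window, a crossing being any 0<->1 transition of
the sampled phase); directions without any crossing are flagged invalid
rather than extrapolated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .volume import BinaryVolume


@dataclass
class MILSamples:
    """Directional MIL measurements for one sampling window."""

    directions: np.ndarray      # (n, 3) unit vectors
    mil_um: np.ndarray          # (n,) mean intercept length, um; NaN where invalid
    valid: np.ndarray           # (n,) bool, False where no crossings were seen
    window_bvtv: float
    degenerate: bool = False    # single-phase window

    @property
    def n_valid(self) -> int:
        return int(np.count_nonzero(self.valid))


@dataclass
class FabricResult:
    """Fabric tensors and their spectral summary for one window."""

    H: np.ndarray          # (3, 3) SPD, units um^-2
    M: np.ndarray          # (3, 3) SPD, = H^(-1/2)
    mu: np.ndarray         # (3,) eigenvalues of M, descending
    m: np.ndarray          # (3,) normalized eigenvalues, sum = 3
    frame: np.ndarray      # (3, 3) columns = eigenvectors matching mu, det = +1

    @property
    def degree_of_anisotropy(self) -> float:
        return float(self.m[0] / self.m[2])


@dataclass
class ElementStructure:
    """Per-element microstructural parameters mapped from the volume."""

    element_id: int
    rho: float                      # BV/TV of the sampling window
    fabric: FabricResult | None     # None when the window is degenerate

    @property
    def degenerate(self) -> bool:
        return self.fabric is None


def fibonacci_hemisphere(n: int) -> np.ndarray:
    """n quasi-uniform unit directions on the upper hemisphere (z >= 0)."""
    i = np.arange(n) + 0.5
    z = i / n                                  # uniform in z over (0, 1)
    phi = np.pi * (1 + 5**0.5) * i
    r = np.sqrt(1 - z**2)
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def _orthonormal_basis(w: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    a = np.array([1.0, 0.0, 0.0]) if abs(w[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    u = np.cross(w, a)
    u /= np.linalg.norm(u)
    return u, np.cross(w, u)


def mil_directional(grid: np.ndarray, directions: np.ndarray,
                    line_spacing: float = 2.0, sample_step: float = 0.5):
    """MIL per direction on a boolean subgrid, in voxel units.

    Returns (mil, valid): mean intercept length (voxel units, NaN where
    no crossings) and a validity mask.
    """
    dims = np.array(grid.shape, dtype=float)
    center = (dims - 1) / 2.0
    radius = 0.5 * float(np.linalg.norm(dims))
    n_lines = max(int(np.ceil(2 * radius / line_spacing)), 1)
    offs = (np.arange(n_lines) - (n_lines - 1) / 2.0) * line_spacing
    t = np.arange(-radius, radius + sample_step, sample_step)

    mil = np.full(len(directions), np.nan)
    valid = np.zeros(len(directions), dtype=bool)
    for d, w in enumerate(directions):
        u, v = _orthonormal_basis(w)
        a, b = np.meshgrid(offs, offs, indexing="ij")
        origins = center + a.reshape(-1, 1) * u + b.reshape(-1, 1) * v
        pts = origins[:, None, :] + t[None, :, None] * w    # (L, S, 3)
        inside = np.all((pts >= -0.5) & (pts <= dims - 0.5), axis=2)
        idx = np.clip(np.rint(pts).astype(np.int64), 0, (dims - 1).astype(np.int64))
        vals = grid[idx[..., 0], idx[..., 1], idx[..., 2]]
        pair = inside[:, 1:] & inside[:, :-1]
        crossings = np.count_nonzero((vals[:, 1:] != vals[:, :-1]) & pair)
        length = np.count_nonzero(pair) * sample_step
        if crossings > 0:
            mil[d] = length / crossings
            valid[d] = True
    return mil, valid


def compute_mil(volume: BinaryVolume, window, n_directions: int = 128,
                line_spacing: float = 2.0) -> MILSamples:
    """Directional MIL for an axis-aligned window of ``volume``.

    ``window`` is a pair (lo_mm, hi_mm) of world coordinates or ``None``
    for the whole volume.  ``line_spacing`` is in voxels.
    """
    if window is None:
        grid = volume.data
    else:
        lo, hi = (np.asarray(x, dtype=float) for x in window)
        ilo = np.maximum(np.rint(volume.world_to_voxel(lo)).astype(int), 0)
        ihi = np.minimum(np.rint(volume.world_to_voxel(hi)).astype(int) + 1,
                         volume.shape)
        if np.any(ihi - ilo < 1):
            raise ValueError("window lies outside the volume")
        grid = volume.data[ilo[0]:ihi[0], ilo[1]:ihi[1], ilo[2]:ihi[2]]
    bvtv = float(np.count_nonzero(grid)) / grid.size
    dirs = fibonacci_hemisphere(n_directions)
    if bvtv in (0.0, 1.0):
        return MILSamples(dirs, np.full(n_directions, np.nan),
                          np.zeros(n_directions, bool), bvtv, degenerate=True)
    mil_vox, valid = mil_directional(grid, dirs, line_spacing=line_spacing)
    samples = MILSamples(dirs, mil_vox * volume.voxel_size_um, valid, bvtv)
    if samples.n_valid < 9:
        raise ValueError(
            f"only {samples.n_valid} directions produced crossings; "
            "need >= 9 for the 6-parameter fabric fit"
        )
    return samples


def fit_fabric(samples: MILSamples, eig_floor: float = 1e-8) -> FabricResult:
    """Least-squares Harrigan-Mann fit MIL(w)^(-2) = w^T H w.

    H is symmetrized by construction and projected to SPD with a relative
    eigenvalue floor; M, mu, m and the eigenframe follow.
    """
    if samples.degenerate:
        raise ValueError("cannot fit fabric to a degenerate (single-phase) window")
    w = samples.directions[samples.valid]
    mil = samples.mil_um[samples.valid]
    if len(w) < 9:
        raise ValueError("need >= 9 valid directions for the fabric fit")
    A = np.column_stack([
        w[:, 0] ** 2, w[:, 1] ** 2, w[:, 2] ** 2,
        2 * w[:, 0] * w[:, 1], 2 * w[:, 0] * w[:, 2], 2 * w[:, 1] * w[:, 2],
    ])
    if np.linalg.matrix_rank(A) < 6:
        raise ValueError("MIL directions are degenerate (coplanar); fit is singular")
    coef, *_ = np.linalg.lstsq(A, mil**-2.0, rcond=None)
    H = np.array([
        [coef[0], coef[3], coef[4]],
        [coef[3], coef[1], coef[5]],
        [coef[4], coef[5], coef[2]],
    ])
    lam, vec = np.linalg.eigh(H)
    if lam.max() <= 0:
        raise ValueError(f"indefinite fabric fit, eigenvalues {lam}")
    lam_f = np.maximum(lam, eig_floor * lam.max())
    if np.any(lam <= 0):
        lam = lam_f
    H = vec @ np.diag(lam) @ vec.T
    mu_all = lam**-0.5
    order = np.argsort(mu_all)[::-1]            # mu descending
    mu = mu_all[order]
    frame = vec[:, order]
    # deterministic sign convention, then enforce a right-handed triad
    for c in range(3):
        if frame[np.argmax(np.abs(frame[:, c])), c] < 0:
            frame[:, c] = -frame[:, c]
    if np.linalg.det(frame) < 0:
        frame[:, 2] = -frame[:, 2]
    M = vec @ np.diag(lam**-0.5) @ vec.T
    m = 3.0 * mu / mu.sum()
    return FabricResult(H=H, M=M, mu=mu, m=m, frame=frame)


def element_structure(volume: BinaryVolume, mesh, window_size_mm: float = 2.5,
                      n_directions: int = 128, line_spacing: float = 2.0):
    """Map BV/TV and fabric onto every element of a tet mesh.

    A cubic window of ``window_size_mm`` is centred at each element
    centroid; its bone fraction gives rho and its directional MIL the
    fabric.  Windows that are single-phase or yield too few crossing
    directions are flagged degenerate (fabric ``None``), never
    extrapolated.  Deterministic given inputs.
    """
    half = window_size_mm / 2.0
    out = []
    for eid, c in enumerate(mesh.centroids()):
        if not volume.contains_point(c):
            raise ValueError(f"element {eid} centroid {c} lies outside the volume")
        window = (c - half, c + half)
        try:
            samples = compute_mil(volume, window, n_directions=n_directions,
                                  line_spacing=line_spacing)
        except ValueError:
            # mixed window but too few crossing directions: unreliable fabric
            lo, hi = window
            ilo = np.maximum(np.rint(volume.world_to_voxel(lo)).astype(int), 0)
            ihi = np.minimum(np.rint(volume.world_to_voxel(hi)).astype(int) + 1,
                             volume.shape)
            grid = volume.data[ilo[0]:ihi[0], ilo[1]:ihi[1], ilo[2]:ihi[2]]
            out.append(ElementStructure(eid, float(np.count_nonzero(grid)) / grid.size, None))
            continue
        if samples.degenerate:
            out.append(ElementStructure(eid, samples.window_bvtv, None))
        else:
            out.append(ElementStructure(eid, samples.window_bvtv, fit_fabric(samples)))
    return out
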