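"""Shared primitives for node/edge featurization."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: fixed ordering of the five per-residue virtual atoms
VIRTUAL_ATOM_ORDER = ("N", "C", "CA", "O", "R")

RBF_N_CENTERS = 16
RBF_MIN = 0.0
RBF_MAX = 20.0


class FeaturizationError(ValueError):
    pass


def rbf_encode(distances: np.ndarray, n_centers: int = RBF_N_CENTERS,
               lo: float = RBF_MIN, hi: float = RBF_MAX) -> np.ndarray:
    """Gaussian radial basis encoding; sigma equals the center spacing.

    A distance exactly at a center yields 1.0 for that basis function.
    """
    centers = np.linspace(lo, hi, n_centers)
    sigma = centers[1] - centers[0]
    d = np.asarray(distances, dtype=float)[..., None]
    return np.exp(-((d - centers) ** 2) / (2.0 * sigma ** 2))


@dataclass
class LocalFrame:
    """Backbone-derived orthonormal frame at a residue.

    z is the unit normal of the N-CA-C plane, x is C-N Gram-Schmidt
    orthogonalised against z, y completes the right-handed system.
    ``basis`` has the axes as columns (det +1).
    """

    origin: np.ndarray
    basis: np.ndarray
    Q: np.ndarray = field(default=None)  # (5, 3) virtual-atom coordinates

    def validate(self, tol: float = 1e-6) -> None:
        err = np.abs(self.basis.T @ self.basis - np.eye(3)).max()
        if err > tol or np.linalg.det(self.basis) < 0:
            raise FeaturizationError(f"frame basis not orthonormal (err={err:.2e})")


def local_frame(residue) -> LocalFrame:
    """Build the local frame of a residue from its virtual atoms."""
    va = residue.virtual_atoms
    if va is None:
        raise FeaturizationError(
            f"residue {residue.comp_id}{residue.author_number} lacks virtual atoms"
        )
    n, ca, c = va["N"], va["CA"], va["C"]
    z = np.cross(n - ca, c - ca)
    nz = np.linalg.norm(z)
    if nz < 1e-8:
        raise FeaturizationError("degenerate backbone geometry (collinear N, CA, C)")
    z = z / nz
    x = c - n
    x = x - np.dot(x, z) * z
    x /= np.linalg.norm(x)
    y = np.cross(z, x)
    basis = np.stack([x, y, z], axis=1)
    q = np.stack([va[k] for k in VIRTUAL_ATOM_ORDER])
    frame = LocalFrame(origin=ca.copy(), basis=basis, Q=q)
    frame.validate()
    return frame


def rotation_to_quaternion(rot: np.ndarray) -> np.ndarray:
    """Unit quaternion (w, x, y, z) with w >= 0 from a rotation matrix."""
    m = rot
    t = np.trace(m)
    if t > 0:
        s = np.sqrt(t + 1.0) * 2
        q = np.array([0.25 * s, (m[2, 1] - m[1, 2]) / s,
                      (m[0, 2] - m[2, 0]) / s, (m[1, 0] - m[0, 1]) / s])
    else:
        i = int(np.argmax(np.diag(m)))
        if i == 0:
            s = np.sqrt(1.0 + m[0, 0] - m[1, 1] - m[2, 2]) * 2
            q = np.array([(m[2, 1] - m[1, 2]) / s, 0.25 * s,
                          (m[0, 1] + m[1, 0]) / s, (m[0, 2] + m[2, 0]) / s])
        elif i == 1:
            s = np.sqrt(1.0 + m[1, 1] - m[0, 0] - m[2, 2]) * 2
            q = np.array([(m[0, 2] - m[2, 0]) / s, (m[0, 1] + m[1, 0]) / s,
                          0.25 * s, (m[1, 2] + m[2, 1]) / s])
        else:
            s = np.sqrt(1.0 + m[2, 2] - m[0, 0] - m[1, 1]) * 2
            q = np.array([(m[1, 0] - m[0, 1]) / s, (m[0, 2] + m[2, 0]) / s,
                          (m[1, 2] + m[2, 1]) / s, 0.25 * s])
    q = q / np.linalg.norm(q)
    if q[0] < 0:
        q = -q
    return q


def quaternion_to_rotation(q: np.ndarray) -> np.ndarray:
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])
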