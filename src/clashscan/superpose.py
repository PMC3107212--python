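"""Rigid-body superposition by Kearsley's quaternion method.

The optimal rotation minimizing the C-alpha RMSD between two matched point
sets is found as the eigenvector of a symmetric 4x4 matrix built from the
coordinate differences and sums of the centered point sets; the smallest
eigenvalue equals the residual sum of squares, so the minimum RMSD is
sqrt(lambda_min / N). The quaternion eigenvector always encodes a proper
rotation (det +1), which makes the method reflection-safe by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from clashscan.structio import StructureModel


class DegenerateGeometryError(ValueError):
    """Raised for point sets that do not determine a unique superposition."""


@dataclass(frozen=True)
class RigidTransform:
    rotation: np.ndarray  # (3, 3), proper orthonormal
    translation: np.ndarray  # (3,)
    rmsd: float
    n_points: int

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation

    def inverse(self) -> "RigidTransform":
        rot = self.rotation.T
        return RigidTransform(rot, -rot @ self.translation, self.rmsd, self.n_points)

    def flat(self) -> list:
        """Twelve numbers: row-major rotation followed by the translation."""
        return [*self.rotation.ravel().tolist(), *self.translation.tolist()]


def _quat_to_matrix(q: np.ndarray) -> np.ndarray:
    w, x, y, z = q
    return np.array([
        [w * w + x * x - y * y - z * z, 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), w * w - x * x + y * y - z * z, 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), w * w - x * x - y * y + z * z],
    ])


def kearsley_superpose(coords_fixed: np.ndarray, coords_moving: np.ndarray) -> RigidTransform:
    """Least-squares rigid transform mapping ``coords_moving`` onto ``coords_fixed``.

    Both arrays must have shape (N, 3) with N >= 3 and the points must not be
    collinear. Returns the transform together with the achieved RMSD.
    """
    fixed = np.asarray(coords_fixed, dtype=float)
    moving = np.asarray(coords_moving, dtype=float)
    if fixed.shape != moving.shape or fixed.ndim != 2 or fixed.shape[1] != 3:
        raise ValueError("point sets must both have shape (N, 3)")
    n = fixed.shape[0]
    if n < 3:
        raise DegenerateGeometryError("need at least 3 point pairs")
    cf = fixed.mean(axis=0)
    cm = moving.mean(axis=0)
    x = fixed - cf
    y = moving - cm
    sv = np.linalg.svd(x, compute_uv=False)
    if sv[1] <= 1e-8 * max(1.0, sv[0]):
        raise DegenerateGeometryError("points are (near-)collinear; rotation is underdetermined")

    d = y - x  # differences
    s = y + x  # sums
    xm, ym, zm = d.T
    xp, yp, zp = s.T
    k = np.empty((4, 4))
    k[0, 0] = np.dot(xm, xm) + np.dot(ym, ym) + np.dot(zm, zm)
    k[0, 1] = k[1, 0] = np.dot(yp, zm) - np.dot(ym, zp)
    k[0, 2] = k[2, 0] = np.dot(xm, zp) - np.dot(xp, zm)
    k[0, 3] = k[3, 0] = np.dot(xp, ym) - np.dot(xm, yp)
    k[1, 1] = np.dot(yp, yp) + np.dot(zp, zp) + np.dot(xm, xm)
    k[1, 2] = k[2, 1] = np.dot(xm, ym) - np.dot(xp, yp)
    k[1, 3] = k[3, 1] = np.dot(xm, zm) - np.dot(xp, zp)
    k[2, 2] = np.dot(xp, xp) + np.dot(zp, zp) + np.dot(ym, ym)
    k[2, 3] = k[3, 2] = np.dot(ym, zm) - np.dot(yp, zp)
    k[3, 3] = np.dot(xp, xp) + np.dot(yp, yp) + np.dot(zm, zm)

    eigvals, eigvecs = np.linalg.eigh(k)
    q = eigvecs[:, 0]
    if q[0] < 0:  # both quaternion signs encode the same rotation
        q = -q
    rot = _quat_to_matrix(q)
    translation = cf - rot @ cm
    # evaluate the RMSD from the transformed coordinates rather than from
    # sqrt(lambda_min / N): identical in exact arithmetic, but the direct form
    # avoids square-root-amplified eigenvalue round-off near zero residual
    rmsd = float(np.sqrt(((moving @ rot.T + translation - fixed) ** 2).sum() / n))
    return RigidTransform(rot, translation, rmsd, n)


def apply_transform(model: StructureModel, t: RigidTransform) -> StructureModel:
    """Return a copy of ``model`` with every atom position rotated and translated."""
    out = model.copy()
    for _, _, atom in out.iter_atoms():
        atom.position = t.rotation @ atom.position + t.translation
    return out


def passes_rmsd_filter(t: RigidTransform, max_rmsd: float = 7.0) -> bool:
    """True iff the achieved RMSD is strictly below ``max_rmsd``."""
    return t.rmsd < max_rmsd
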