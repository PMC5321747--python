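"""Rigid transforms (ZYZ Euler + voxel shifts) and volume resampling under them.

Conventions: Euler angles (phi, theta, psi) are intrinsic ZYZ in degrees;
shifts are in voxels along the in-memory (x, y, z) axes.  ``apply`` first
rotates the volume about the voxel floor(N/2) and then translates, i.e. a
point at position x in the input appears at ``R (x - c) + c + s`` in the
output.  Transforms map the particle frame to the reference frame throughout
the package.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial.transform import Rotation

from .volmap import center_voxel


@dataclass(frozen=True)
class RigidTransform:
    euler: tuple[float, float, float] = (0.0, 0.0, 0.0)
    shift: tuple[float, float, float] = (0.0, 0.0, 0.0)

    @property
    def rotation(self) -> Rotation:
        return Rotation.from_euler("ZYZ", self.euler, degrees=True)

    def matrix(self) -> np.ndarray:
        return self.rotation.as_matrix()

    @staticmethod
    def from_rotation(rot: Rotation, shift=(0.0, 0.0, 0.0)) -> "RigidTransform":
        with warnings.catch_warnings():
            # gimbal lock at theta = 0/180 is fine: any (phi, psi) split works
            warnings.simplefilter("ignore", UserWarning)
            phi, theta, psi = rot.as_euler("ZYZ", degrees=True)
        return RigidTransform((float(phi), float(theta), float(psi)),
                              tuple(float(s) for s in shift))

    @staticmethod
    def identity() -> "RigidTransform":
        return RigidTransform()

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self ∘ other: apply `other` first, then `self`."""
        r1, r2 = other.matrix(), self.matrix()
        s = r2 @ np.asarray(other.shift) + np.asarray(self.shift)
        return RigidTransform.from_rotation(Rotation.from_matrix(r2 @ r1), s)

    def inverse(self) -> "RigidTransform":
        rinv = self.matrix().T
        return RigidTransform.from_rotation(
            Rotation.from_matrix(rinv), -rinv @ np.asarray(self.shift)
        )


def apply_transform(values: np.ndarray, t: RigidTransform, order: int = 1) -> np.ndarray:
    """Resample a volume under a rigid transform (trilinear by default).

    Voxels pulled from outside the input grid are zero-filled.
    """
    c = center_voxel(values.shape)
    rinv = t.matrix().T
    offset = c - rinv @ (c + np.asarray(t.shift))
    return ndimage.affine_transform(
        values, rinv, offset=offset, order=order, mode="constant", cval=0.0,
        prefilter=(order > 1),
    )


def rotate_support(support: np.ndarray, rot: Rotation) -> np.ndarray:
    """Rotate a centered binary Fourier support; returns a float mask in [0,1].

    Real-space rotation of a volume rotates its Fourier transform by the same
    rotation, so pose bookkeeping uses the identical matrix here.
    """
    t = RigidTransform.from_rotation(rot)
    out = apply_transform(support.astype(np.float32), t)
    return np.clip(out, 0.0, 1.0)


def euler_grid(step: float) -> list[tuple[float, float, float]]:
    """Global ZYZ search grid: phi, psi over [0, 360), theta over [0, 180].

    At the poles (theta = 0 or 180) phi and psi are degenerate, so only
    phi = 0 rows are kept there.  Deterministic ordering (lowest index wins
    on score ties downstream).
    """
    phis = np.arange(0.0, 360.0, step)
    thetas = np.arange(0.0, 180.0 + 1e-9, step)
    psis = np.arange(0.0, 360.0, step)
    grid = []
    for theta in thetas:
        at_pole = theta < 1e-9 or theta > 180.0 - 1e-9
        for phi in phis if not at_pole else [0.0]:
            for psi in psis:
                grid.append((float(phi), float(theta), float(psi)))
    return grid


def euler_neighborhood(euler, step: float) -> list[tuple[float, float, float]]:
    """3×3×3 grid of Euler triplets around `euler` with spacing `step`.

    The center point (offset 0) is included first so a refinement can never
    score worse than the incumbent pose.
    """
    phi0, theta0, psi0 = euler
    out = [(float(phi0), float(theta0), float(psi0))]
    offs = (-step, 0.0, step)
    for dp in offs:
        for dt in offs:
            for ds in offs:
                if dp == dt == ds == 0.0:
                    continue
                out.append((float(phi0 + dp), float(np.clip(theta0 + dt, 0.0, 180.0)),
                            float(psi0 + ds)))
    return out


def random_rotations(n: int, rng: np.random.Generator) -> list[Rotation]:
    """Uniform rotations on SO(3) via normalized Gaussian quaternions."""
    q = rng.standard_normal((n, 4))
    q /= np.linalg.norm(q, axis=1, keepdims=True)
    return [Rotation.from_quat(qi) for qi in q]
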