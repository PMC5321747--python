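"""Tilt-scheme description, missing-wedge Fourier supports, and subtomograms.

Single-axis tomography samples, at each tilt angle, the central plane of
Fourier space perpendicular to the beam.  A tilt series from ``tilt_min`` to
``tilt_max`` therefore leaves a wedge of Fourier space unmeasured (the
"missing wedge"); for the standard ±60° scheme the wedge occupies one third
of Fourier space.  Supports are binary masks on the centered Fourier grid
(DC at voxel floor(N/2)).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .transforms import RigidTransform
from .volmap import DensityMap


@dataclass(frozen=True)
class WedgeSpec:
    """Single-axis tilt scheme.  Defaults mirror a −60°…+60°, 2° acquisition."""

    tilt_min: float = -60.0
    tilt_max: float = 60.0
    increment: float = 2.0
    tilt_axis: tuple[float, float, float] = (0.0, 1.0, 0.0)

    def __post_init__(self) -> None:
        if not self.tilt_min < self.tilt_max:
            raise ValueError("tilt_min must be < tilt_max")
        a = np.asarray(self.tilt_axis, dtype=float)
        n = np.linalg.norm(a)
        if n == 0:
            raise ValueError("tilt_axis must be a nonzero vector")
        if abs(a[2] / n) > 0.99:
            raise ValueError("tilt_axis may not be parallel to the beam (z)")


def make_wedge_support(w: WedgeSpec, box: int | tuple[int, int, int]) -> np.ndarray:
    """Binary missing-wedge support on the centered Fourier grid.

    A Fourier voxel k is sampled iff some tilt angle in [tilt_min, tilt_max]
    places the measurement plane through it: with beam b(θ) rotating about
    the tilt axis, k is on the θ-plane when k·b(θ) = 0.  Writing k's
    component in the plane perpendicular to the tilt axis in polar form, the
    sampling condition reduces to a wedge test on that polar angle.  Voxels
    on the tilt axis itself (zero in-plane component) are sampled by every
    tilt.  The support is centro-symmetric (Friedel symmetry).
    """
    shape = (box, box, box) if np.isscalar(box) else tuple(box)
    if min(shape) < 8:
        raise ValueError("box must be at least 8 voxels")
    a = np.asarray(w.tilt_axis, dtype=float)
    a = a / np.linalg.norm(a)
    b0 = np.array([0.0, 0.0, 1.0])  # untilted beam
    u = b0 - (b0 @ a) * a
    u /= np.linalg.norm(u)
    v = np.cross(a, u)

    centers = [n // 2 for n in shape]
    axes = [np.arange(n, dtype=float) - c for n, c in zip(shape, centers)]
    kx, ky, kz = np.meshgrid(*axes, indexing="ij")
    ku = kx * u[0] + ky * u[1] + kz * u[2]
    kv = kx * v[0] + ky * v[1] + kz * v[2]

    # tilt angle that would sample k: theta ≡ atan2(kv, ku) + 90 (mod 180)
    omega = np.degrees(np.arctan2(kv, ku))
    t = np.mod(omega + 90.0 + 90.0, 180.0) - 90.0
    inside = (t >= w.tilt_min) & (t <= w.tilt_max)
    inside |= np.hypot(ku, kv) < 1e-9  # on the tilt axis
    if w.tilt_max - w.tilt_min >= 180.0 - 1e-9:
        inside[:] = True
    return inside


def apply_support(values: np.ndarray, support: np.ndarray) -> np.ndarray:
    """Zero Fourier coefficients outside a centered support (a projection)."""
    f = np.fft.fftn(values)
    f *= np.fft.ifftshift(support)
    return np.fft.ifftn(f).real


@dataclass
class Subtomogram:
    """One particle volume plus its acquisition wedge and alignment state."""

    map: DensityMap
    wedge: WedgeSpec
    pose: RigidTransform = field(default_factory=RigidTransform)
    score: float | None = None
    class_label: int | None = None
    noise_seed: int | None = None

    def __post_init__(self) -> None:
        if self.score is not None and not -1.0 - 1e-6 <= self.score <= 1.0 + 1e-6:
            raise ValueError(f"alignment score {self.score} outside [-1, 1]")
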