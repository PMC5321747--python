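"""3D density-map container and I/O.

Maps live in memory as float32 arrays indexed ``(x, y, z)`` — the order gemmi
uses for CCP4/MRC grids (nu, nv, nw), so files written by EMDB-style tools
round-trip without axis shuffling.  Voxel size is isotropic (Å per voxel); the
map origin is the position of voxel (0, 0, 0) in Å, stored in MRC header words
50–52.  Rotations everywhere in the package are taken about the voxel
``floor(N/2)`` on each axis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import gemmi
import numpy as np
from scipy import ndimage


class MapFormatError(ValueError):
    """Raised when an MRC/CCP4 file cannot be interpreted as a density map."""


@dataclass
class DensityMap:
    """A 3D scalar field with physical metadata.

    Parameters
    ----------
    values : ndarray
        Scalar grid indexed (x, y, z); converted to float32.
    voxel_size : float
        Isotropic voxel edge in Å, > 0.
    origin : tuple of float
        Position of voxel (0, 0, 0) in Å.
    label : str
        Free-text provenance.
    """

    values: np.ndarray
    voxel_size: float
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    label: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float32)
        if self.values.ndim != 3:
            raise ValueError(f"expected a 3D grid, got {self.values.ndim}D")
        if not self.voxel_size > 0:
            raise ValueError(f"voxel_size must be > 0, got {self.voxel_size}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("density values contain NaN/Inf")
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def copy(self, **changes) -> "DensityMap":
        out = replace(self, **changes)
        if "values" not in changes:
            out.values = self.values.copy()
        return out


@dataclass
class VolumeMask:
    """A [0, 1]-valued weight volume (focus / exclusion / analysis mask)."""

    values: np.ndarray
    voxel_size: float
    role: str = "focus"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float32)
        if self.values.min() < -1e-6 or self.values.max() > 1 + 1e-6:
            raise ValueError("mask values must lie in [0, 1]")
        self.values = np.clip(self.values, 0.0, 1.0)
        if self.role not in ("focus", "exclusion", "analysis"):
            raise ValueError(f"unknown mask role {self.role!r}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape


def read_map(path) -> DensityMap:
    """Read an MRC/CCP4 volume (optionally gzipped).

    Voxel size is derived from the header cell length divided by the grid
    size; a format error names the offending header field.
    """
    try:
        ccp4 = gemmi.read_ccp4_map(str(path))
    except (RuntimeError, ValueError, OSError) as exc:
        raise MapFormatError(f"cannot read MRC/CCP4 map {path}: {exc}") from exc
    grid = ccp4.grid
    values = np.array(grid.array, dtype=np.float32)
    sx, sy, sz = grid.spacing
    if not (sx > 0 and sy > 0 and sz > 0):
        raise MapFormatError(f"non-positive voxel spacing in header cell: {grid.spacing}")
    if abs(sx - sy) > 1e-3 * sx or abs(sx - sz) > 1e-3 * sx:
        raise MapFormatError(f"anisotropic voxel size unsupported: {grid.spacing}")
    if not np.all(np.isfinite(values)):
        raise MapFormatError("map data contain non-finite values")
    origin = tuple(ccp4.header_float(w) for w in (50, 51, 52))
    return DensityMap(values, float(sx), origin, label=str(path))


def write_map(m: DensityMap, path) -> None:
    """Write a map as MRC mode 2 (32-bit float), P1 cell = grid × voxel."""
    ccp4 = gemmi.Ccp4Map()
    ccp4.grid = gemmi.FloatGrid(np.ascontiguousarray(m.values, dtype=np.float32))
    nx, ny, nz = m.shape
    ccp4.grid.unit_cell = gemmi.UnitCell(
        nx * m.voxel_size, ny * m.voxel_size, nz * m.voxel_size, 90, 90, 90
    )
    ccp4.grid.spacegroup = gemmi.SpaceGroup("P1")
    ccp4.update_ccp4_header()
    for w, o in zip((50, 51, 52), m.origin):
        ccp4.set_header_float(w, float(o))
    ccp4.write_ccp4_map(str(path))


def resample_map(
    m: DensityMap,
    target_voxel: float,
    target_shape: tuple[int, int, int] | None = None,
    target_origin: tuple[float, float, float] | None = None,
) -> DensityMap:
    """Trilinearly interpolate a map onto a new grid.

    The output grid has ``target_voxel`` Å voxels and ``target_shape`` dims
    (defaults to the source shape).  Physical coordinates are preserved:
    output voxel *i* samples the source at position origin + i·voxel.  Voxels
    that fall outside the source support are filled with the source mean edge
    value (``mode='nearest'``); an error is raised if the grids do not overlap
    at all.
    """
    if not target_voxel > 0:
        raise ValueError("target_voxel must be > 0")
    if target_shape is None:
        target_shape = m.shape
    if target_origin is None:
        target_origin = m.origin
    # identity fast path
    if (
        abs(target_voxel - m.voxel_size) < 1e-12
        and tuple(target_shape) == m.shape
        and all(abs(a - b) < 1e-9 for a, b in zip(target_origin, m.origin))
    ):
        return m.copy()

    axes_src = [m.origin[d] + m.voxel_size * np.arange(m.shape[d]) for d in range(3)]
    axes_tgt = [
        target_origin[d] + target_voxel * np.arange(target_shape[d]) for d in range(3)
    ]
    for d in range(3):
        if axes_tgt[d][-1] < axes_src[d][0] or axes_tgt[d][0] > axes_src[d][-1]:
            raise ValueError(
                f"target grid does not overlap source support on axis {d}"
            )
    # fractional source indices of the target grid
    coords = np.meshgrid(
        *[(axes_tgt[d] - m.origin[d]) / m.voxel_size for d in range(3)],
        indexing="ij",
    )
    out = ndimage.map_coordinates(
        m.values.astype(np.float64), np.stack(coords), order=1, mode="nearest"
    )
    return DensityMap(
        out.astype(np.float32), target_voxel, target_origin,
        label=f"{m.label} resampled@{target_voxel:g}A",
    )


def _radial_freq_grid(shape: tuple[int, int, int], voxel_size: float) -> np.ndarray:
    """|k| in 1/Å on the centered Fourier grid (DC at floor(N/2))."""
    axes = [np.fft.fftshift(np.fft.fftfreq(n, d=voxel_size)) for n in shape]
    kx, ky, kz = np.meshgrid(*axes, indexing="ij")
    return np.sqrt(kx * kx + ky * ky + kz * kz)


def raised_cosine_lowpass(
    shape: tuple[int, int, int], voxel_size: float, resolution: float, width_voxels: float = 2.0
) -> np.ndarray:
    """Centered raised-cosine low-pass transfer function.

    Unity up to ``1/resolution − w/2``, cosine falloff to zero at
    ``1/resolution + w/2`` where ``w`` spans `width_voxels` Fourier voxels.
    The soft edge suppresses the real-space ringing a hard cutoff would inject
    into downstream difference maps.
    """
    r = _radial_freq_grid(shape, voxel_size)
    cutoff = 1.0 / resolution
    w = width_voxels / (max(shape) * voxel_size)  # Fourier voxel = 1/(N·voxel)
    lo, hi = cutoff - w / 2, cutoff + w / 2
    h = np.ones(shape)
    h[r >= hi] = 0.0
    band = (r > lo) & (r < hi)
    h[band] = 0.5 * (1 + np.cos(np.pi * (r[band] - lo) / (hi - lo)))
    return h


def apply_fourier_filter(values: np.ndarray, transfer_centered: np.ndarray) -> np.ndarray:
    f = np.fft.fftn(values)
    f *= np.fft.ifftshift(transfer_centered)
    return np.fft.ifftn(f).real


def lowpass_filter(m: DensityMap, resolution: float) -> DensityMap:
    """Low-pass a map to `resolution` Å with a raised-cosine edge.

    The DC term is untouched, so the map mean is preserved.  `resolution`
    must be at least the Nyquist limit (2 × voxel size).
    """
    if resolution < 2 * m.voxel_size:
        raise ValueError(
            f"resolution {resolution} Å below Nyquist {2 * m.voxel_size} Å"
        )
    h = raised_cosine_lowpass(m.shape, m.voxel_size, resolution)
    out = apply_fourier_filter(m.values.astype(np.float64), h)
    return DensityMap(out.astype(np.float32), m.voxel_size, m.origin,
                      label=f"{m.label} lp@{resolution:g}A")


def bin_map(m: DensityMap, factor: int) -> DensityMap:
    """Downsample by block averaging (shape must be divisible by factor)."""
    if factor == 1:
        return m.copy()
    nx, ny, nz = m.shape
    if any(n % factor for n in m.shape):
        raise ValueError(f"shape {m.shape} not divisible by bin factor {factor}")
    v = m.values.reshape(nx // factor, factor, ny // factor, factor, nz // factor, factor)
    out = v.mean(axis=(1, 3, 5))
    return DensityMap(out.astype(np.float32), m.voxel_size * factor, m.origin,
                      label=f"{m.label} bin{factor}")


def center_voxel(shape: tuple[int, int, int]) -> np.ndarray:
    """Rotation center: voxel floor(N/2) on each axis."""
    return np.array([n // 2 for n in shape], dtype=float)
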