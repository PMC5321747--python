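"""Fourier shell correlation and threshold-crossing resolution estimation.

Two conventions are supported: half-set FSC between maps averaged from the
two halves of a dataset (resolution read at FSC = 0.5) and Fourier shell
cross-resolution of a map against an external reference (read at
FSC = 0.33).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .particles import Subtomogram
from .volmap import DensityMap

HALF_SET_THRESHOLD = 0.5
CROSS_THRESHOLD = 0.33


@dataclass
class FSCCurve:
    shell_center_freq: np.ndarray  # 1/Å
    correlation: np.ndarray
    n_coefficients: np.ndarray
    voxel_size: float
    thresholds: dict = field(
        default_factory=lambda: {"half_set": HALF_SET_THRESHOLD, "cross": CROSS_THRESHOLD}
    )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "freq": self.shell_center_freq,
            "fsc": self.correlation,
            "n": self.n_coefficients,
        })


def fsc(a: DensityMap, b: DensityMap, shell_width: float = 1.0) -> FSCCurve:
    """Fourier shell correlation between two maps on the same grid.

    Per shell s of `shell_width` Fourier voxels:
    Re(Σ F_a conj(F_b)) / sqrt(Σ|F_a|² Σ|F_b|²).
    """
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    if abs(a.voxel_size - b.voxel_size) > 1e-6:
        raise ValueError("voxel size mismatch")
    shape = a.shape
    fa = np.fft.fftshift(np.fft.fftn(a.values.astype(np.float64)))
    fb = np.fft.fftshift(np.fft.fftn(b.values.astype(np.float64)))

    centers = [n // 2 for n in shape]
    axes = [np.arange(n, dtype=float) - c for n, c in zip(shape, centers)]
    kx, ky, kz = np.meshgrid(*axes, indexing="ij")
    r = np.sqrt(kx * kx + ky * ky + kz * kz)
    nyq = min(shape) // 2
    shell = np.floor(r / shell_width).astype(int)
    n_shells = int(math.floor(nyq / shell_width))
    valid = shell < n_shells
    idx = shell[valid]

    num = np.bincount(idx, weights=(fa * np.conj(fb)).real[valid], minlength=n_shells)
    pa = np.bincount(idx, weights=(np.abs(fa) ** 2)[valid], minlength=n_shells)
    pb = np.bincount(idx, weights=(np.abs(fb) ** 2)[valid], minlength=n_shells)
    cnt = np.bincount(idx, minlength=n_shells)
    den = np.sqrt(pa * pb)
    corr = np.divide(num, den, out=np.zeros(n_shells), where=den > 0)

    # shell center frequency in 1/Å: (s + 0.5)·width Fourier voxels
    fstep = 1.0 / (min(shape) * a.voxel_size)
    freqs = (np.arange(n_shells) + 0.5) * shell_width * fstep
    return FSCCurve(freqs, corr, cnt, a.voxel_size)


def resolution_at(curve: FSCCurve, threshold: float) -> tuple[float, bool]:
    """Resolution (Å) at the first crossing below `threshold`.

    The crossing frequency is found by linear interpolation between the two
    bracketing shells; resolution is its reciprocal.  If the curve never
    drops below the threshold, returns (2 × voxel size, True): the Nyquist
    limit with a no-crossing flag.  The second return value flags that case.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must be in (0, 1)")
    c, f = np.asarray(curve.correlation), np.asarray(curve.shell_center_freq)
    if c.size == 0:
        raise ValueError("empty FSC curve")
    below = np.flatnonzero(c < threshold)
    if below.size == 0:
        return 2.0 * curve.voxel_size, True
    i = int(below[0])
    if i == 0:
        return 1.0 / f[0], False
    f0, f1, c0, c1 = f[i - 1], f[i], c[i - 1], c[i]
    fx = f0 + (c0 - threshold) * (f1 - f0) / (c0 - c1)
    return float(1.0 / fx), False


def plot_fsc(curve: FSCCurve, path, title: str = "FSC") -> None:
    """Render an FSC curve with its 0.5/0.33 threshold lines to PNG."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.plot(curve.shell_center_freq, curve.correlation, lw=1.5)
    for name, thr in curve.thresholds.items():
        ax.axhline(thr, ls="--", lw=0.8, label=f"{name} ({thr})")
    ax.set_xlabel("spatial frequency (1/Å)")
    ax.set_ylabel("FSC")
    ax.set_ylim(-0.1, 1.05)
    ax.set_title(title)
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def halfset_split(
    subtomos: list[Subtomogram], seed: int = 0
) -> tuple[list[Subtomogram], list[Subtomogram]]:
    """Deterministic even/odd split after a seeded shuffle (sizes differ ≤1)."""
    if len(subtomos) < 2:
        raise ValueError("need at least 2 particles to split")
    order = np.random.default_rng(seed).permutation(len(subtomos))
    even = [subtomos[i] for i in order[0::2]]
    odd = [subtomos[i] for i in order[1::2]]
    return even, odd
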