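"""Wedge-aware scoring, alignment, template matching, and averaging.

The pairwise kernel is a constrained cross-correlation: volumes are compared
only over the Fourier coefficients both have actually measured (the
intersection of their missing-wedge supports), after optional real-space
masking.  With full supports and the DC term excluded this reduces exactly to
the Pearson correlation of voxel values, which is the oracle the tests use.

Alignment searches a deterministic ZYZ Euler grid; per orientation the
translation is found by FFT cross-correlation restricted to a maximum shift.
Averaging divides the Fourier-space sum of pose-rotated particles by the sum
of their rotated wedge supports (clamped from below), the standard
wedge-compensated average.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .particles import Subtomogram, WedgeSpec, make_wedge_support
from .transforms import (
    RigidTransform,
    apply_transform,
    euler_grid,
    euler_neighborhood,
    rotate_support,
)
from .volmap import DensityMap, VolumeMask, bin_map, raised_cosine_lowpass


def _as_values(x) -> np.ndarray:
    if isinstance(x, (DensityMap, VolumeMask)):
        return x.values
    return np.asarray(x)


def _as_support(s, shape) -> np.ndarray:
    if s is None:
        return np.ones(shape, dtype=bool)
    s = _as_values(s)
    return s > 0.5 if s.dtype != bool else s


def _dc_index(shape) -> tuple[int, ...]:
    return tuple(n // 2 for n in shape)


def constrained_cc(a, b, support_a=None, support_b=None, mask=None) -> float:
    """Constrained cross-correlation of two equally shaped volumes.

    Both volumes are multiplied by the real-space `mask` (if given), Fourier
    transformed, and correlated over the intersection of their centered
    Fourier supports with the DC coefficient excluded.  With full supports
    this equals the plain Pearson correlation of (masked) voxel values.
    Returns a value in [-1, 1]; raises if the support intersection is empty.
    """
    av, bv = _as_values(a).astype(np.float64), _as_values(b).astype(np.float64)
    if av.shape != bv.shape:
        raise ValueError(f"shape mismatch: {av.shape} vs {bv.shape}")
    if mask is not None:
        mv = _as_values(mask)
        av, bv = av * mv, bv * mv
    inter = _as_support(support_a, av.shape) & _as_support(support_b, av.shape)
    inter = inter.copy()
    inter[_dc_index(av.shape)] = False
    if not inter.any():
        raise ValueError("empty Fourier support intersection (disjoint wedges)")
    fa = np.fft.fftshift(np.fft.fftn(av))[inter]
    fb = np.fft.fftshift(np.fft.fftn(bv))[inter]
    num = float(np.sum(fa * np.conj(fb)).real)
    den = math.sqrt(float(np.sum(np.abs(fa) ** 2)) * float(np.sum(np.abs(fb) ** 2)))
    if den == 0.0:
        return 0.0
    return float(np.clip(num / den, -1.0, 1.0))


def bandpass_transfer(shape, voxel_size, low_res=None, high_res=None) -> np.ndarray:
    """Centered band-pass transfer: pass between 1/low_res and 1/high_res.

    `low_res` is the low-resolution (coarse) cutoff in Å (None: keep all low
    frequencies), `high_res` the high-resolution cutoff (None: up to
    Nyquist).  Raised-cosine edges of 2 Fourier voxels.
    """
    h = np.ones(shape)
    if high_res is not None:
        h = h * raised_cosine_lowpass(shape, voxel_size, high_res)
    if low_res is not None:
        h = h * (1.0 - raised_cosine_lowpass(shape, voxel_size, low_res))
    return h


def _shift_allowed_mask(shape, max_shift: float) -> np.ndarray:
    """Boolean mask over the circular cross-correlation volume marking
    wrapped shifts with |s_d| <= max_shift on every axis."""
    axes = []
    for n in shape:
        idx = np.arange(n, dtype=float)
        idx[idx > n / 2] -= n
        axes.append(np.abs(idx) <= max_shift)
    mx, my, mz = np.meshgrid(*axes, indexing="ij")
    return mx & my & mz


class _Scorer:
    """Precomputes per-particle FFTs for repeated orientation scoring.

    All volumes share one acquisition wedge (axis-aligned in the particle
    frame); the combined wedge × band-pass transfer is applied to both the
    particle and each rotated reference so the score is a constrained
    correlation over the measured band.
    """

    def __init__(self, volumes, wedge_support, voxel_size, bandpass=(None, None),
                 max_shift=6.0):
        shape = volumes[0].shape
        transfer = bandpass_transfer(shape, voxel_size, *bandpass)
        if wedge_support is not None:
            transfer = transfer * wedge_support
        transfer[_dc_index(shape)] = 0.0
        self._transfer_us = np.fft.ifftshift(transfer)
        self.shape = shape
        self.n_vox = int(np.prod(shape))
        self._allowed = _shift_allowed_mask(shape, max_shift)
        self._pf = []
        self._pnorm = []
        for v in volumes:
            f = np.fft.fftn(np.asarray(v, dtype=np.float64)) * self._transfer_us
            self._pf.append(f.astype(np.complex64))
            self._pnorm.append(math.sqrt(float(np.sum(np.abs(f) ** 2))))

    def ref_fft(self, ref_values) -> tuple[np.ndarray, float]:
        f = np.fft.fftn(np.asarray(ref_values, dtype=np.float64)) * self._transfer_us
        return f, math.sqrt(float(np.sum(np.abs(f) ** 2)))

    def score(self, i: int, ref_f, ref_norm) -> tuple[float, np.ndarray]:
        """Best score and integer shift of particle i against a prepared
        (already rotated into the particle frame) reference."""
        den = self._pnorm[i] * ref_norm
        if den == 0.0:
            return 0.0, np.zeros(3)
        cc = np.fft.ifftn(self._pf[i] * np.conj(ref_f)).real * self.n_vox / den
        cc = np.where(self._allowed, cc, -np.inf)
        flat = int(np.argmax(cc))
        idx = np.unravel_index(flat, self.shape)
        shift = np.array(
            [s - n if s > n / 2 else s for s, n in zip(idx, self.shape)], dtype=float
        )
        return float(cc[idx]), shift


def _pose_from_candidate(euler, shift_particle) -> RigidTransform:
    # particle(x) ~ rot_ref(x - s): particle = apply((R^-1, s), ref)
    # => pose (particle -> ref) = (R, -R s)
    r = Rotation.from_euler("ZYZ", euler, degrees=True)
    return RigidTransform(tuple(float(e) for e in euler),
                          tuple(-r.as_matrix() @ shift_particle))


def align_particles(
    volumes,
    ref_values,
    candidates,
    wedge_support,
    voxel_size,
    max_shift=6.0,
    bandpass=(None, None),
    per_particle_candidates=False,
) -> tuple[list[RigidTransform], list[float]]:
    """Exhaustively score orientation candidates for a set of particles.

    `candidates` is either one Euler list shared by all particles (the
    rotated reference FFT is then computed once per orientation) or, with
    `per_particle_candidates`, one list per particle.  Ties break to the
    lowest candidate index.  Returns per-particle best pose and score.
    """
    scorer = _Scorer(volumes, wedge_support, voxel_size, bandpass, max_shift)
    n = len(volumes)
    best_score = [-np.inf] * n
    best_pose = [RigidTransform()] * n

    if per_particle_candidates:
        for i in range(n):
            for euler in candidates[i]:
                rinv = Rotation.from_euler("ZYZ", euler, degrees=True).inv()
                rr = apply_transform(np.asarray(ref_values, dtype=np.float64),
                                     RigidTransform.from_rotation(rinv))
                rf, rnorm = scorer.ref_fft(rr)
                sc, shift = scorer.score(i, rf, rnorm)
                if sc > best_score[i]:
                    best_score[i] = sc
                    best_pose[i] = _pose_from_candidate(euler, shift)
    else:
        ref64 = np.asarray(ref_values, dtype=np.float64)
        for euler in candidates:
            rinv = Rotation.from_euler("ZYZ", euler, degrees=True).inv()
            rr = apply_transform(ref64, RigidTransform.from_rotation(rinv))
            rf, rnorm = scorer.ref_fft(rr)
            rf = rf.astype(np.complex64)
            for i in range(n):
                sc, shift = scorer.score(i, rf, rnorm)
                if sc > best_score[i]:
                    best_score[i] = sc
                    best_pose[i] = _pose_from_candidate(euler, shift)
    return best_pose, [float(s) for s in best_score]


def align_pair(
    s: Subtomogram,
    ref: DensityMap,
    angular_step: float,
    max_shift: float = 6.0,
    bandpass=(None, None),
    candidates=None,
) -> tuple[RigidTransform, float]:
    """Align one subtomogram to a reference over a global Euler grid.

    Exhaustive over `candidates` (default: the full ZYZ grid at
    `angular_step`); per orientation the translation is the FFT
    cross-correlation arg-max within `max_shift` voxels.  Deterministic:
    score ties resolve to the lowest grid index.
    """
    if candidates is None:
        if not angular_step > 0:
            raise ValueError("angular_step must be > 0")
        candidates = euler_grid(angular_step)
    support = make_wedge_support(s.wedge, s.map.shape)
    poses, scores = align_particles(
        [s.map.values], ref.values, candidates, support, s.map.voxel_size,
        max_shift=max_shift, bandpass=bandpass,
    )
    return poses[0], scores[0]


def wedge_compensated_average(
    subtomos: list[Subtomogram],
    poses: list[RigidTransform] | None = None,
    eps_frac: float = 0.1,
) -> DensityMap:
    """Average particles in Fourier space with missing-wedge compensation.

    A = Σ_i R_i(F_i) / max(Σ_i R_i(W_i), ε), ε = `eps_frac` · n.  R_i rotates
    particle i (data and wedge support) into the reference frame using its
    pose; the clamp keeps barely sampled Fourier voxels from exploding.
    """
    if not subtomos:
        raise ValueError("cannot average an empty particle list")
    if poses is None:
        poses = [s.pose for s in subtomos]
    shape = subtomos[0].map.shape
    num = np.zeros(shape, dtype=np.complex128)
    den = np.zeros(shape, dtype=np.float64)
    support_cache: dict = {}
    for s, pose in zip(subtomos, poses):
        aligned = apply_transform(s.map.values.astype(np.float64), pose)
        num += np.fft.fftshift(np.fft.fftn(aligned))
        key = s.wedge
        if key not in support_cache:
            support_cache[key] = make_wedge_support(s.wedge, shape).astype(np.float64)
        den += rotate_support(support_cache[key], pose.rotation)
    eps = eps_frac * len(subtomos)
    avg = np.fft.ifftn(np.fft.ifftshift(num / np.maximum(den, eps))).real
    m0 = subtomos[0].map
    return DensityMap(avg.astype(np.float32), m0.voxel_size, m0.origin, label="average")


def iterative_average(
    subtomos: list[Subtomogram],
    ref0: DensityMap,
    schedule=None,
    max_shift: float = 6.0,
    bandpass=(None, None),
) -> tuple[DensityMap, list[RigidTransform], list[float], list[dict]]:
    """Iteratively align particles to an evolving reference and average.

    `schedule` is a list of iteration settings ``{"step": deg, "local":
    bool, "bin": int}``: a non-local iteration searches the full Euler grid
    at `step` (optionally on `bin`-times downsampled volumes for speed); a
    local iteration searches the 3×3×3 Euler neighborhood of each particle's
    current pose.  Default: one coarse global pass at 30° binned 2×, then
    local refinements at 15° and 7.5° at full sampling.  Returns the final
    wedge-compensated average, per-particle poses and scores, and a
    per-iteration history (mean score).
    """
    if not subtomos:
        raise ValueError("cannot align an empty particle list")
    if schedule is None:
        schedule = [
            {"step": 30.0, "local": False, "bin": 2},
            {"step": 15.0, "local": True, "bin": 1},
            {"step": 7.5, "local": True, "bin": 1},
        ]
    ref = ref0
    poses = [s.pose for s in subtomos]
    scores = [0.0] * len(subtomos)
    history = []
    wedge = subtomos[0].wedge
    voxel = subtomos[0].map.voxel_size
    for it, setting in enumerate(schedule):
        step = float(setting["step"])
        local = bool(setting.get("local", False))
        binf = int(setting.get("bin", 1))
        if binf > 1:
            vols = [bin_map(s.map, binf).values for s in subtomos]
            refv = bin_map(ref, binf).values
            shape = vols[0].shape
            shift_cap = max(1.0, max_shift / binf)
        else:
            vols = [s.map.values for s in subtomos]
            refv = ref.values
            shape = vols[0].shape
            shift_cap = max_shift
        support = make_wedge_support(wedge, shape)
        if local:
            cands = [euler_neighborhood(p.euler, step) for p in poses]
            new_poses, scores = align_particles(
                vols, refv, cands, support, voxel * binf,
                max_shift=shift_cap, bandpass=bandpass, per_particle_candidates=True,
            )
        else:
            new_poses, scores = align_particles(
                vols, refv, euler_grid(step), support, voxel * binf,
                max_shift=shift_cap, bandpass=bandpass,
            )
        if binf > 1:
            new_poses = [
                RigidTransform(p.euler, tuple(np.asarray(p.shift) * binf))
                for p in new_poses
            ]
        poses = new_poses
        ref = wedge_compensated_average(subtomos, poses)
        history.append({"iteration": it, "mean_score": float(np.mean(scores)),
                        **setting})
    for s, p, sc in zip(subtomos, poses, scores):
        s.pose, s.score = p, float(np.clip(sc, -1.0, 1.0))
    return ref, poses, scores, history


def template_match(
    tomogram: DensityMap,
    template: DensityMap,
    w: WedgeSpec,
    angular_step: float = 30.0,
    n_peaks: int = 500,
    lowpass: float | None = 50.0,
    candidates=None,
) -> pd.DataFrame:
    """Locate template instances by locally normalized cross-correlation.

    The tomogram and each rotated template are wedge-filtered (and low-pass
    filtered to `lowpass` Å, mirroring template matching against coarse
    references); correlation is locally normalized under a spherical mask of
    the template radius.  Peaks are returned after non-maximum suppression
    with that radius as exclusion zone, sorted by descending score:
    DataFrame columns (x, y, z, phi, theta, psi, score).
    """
    tshape = template.shape
    big = tomogram.shape
    if any(t > b for t, b in zip(tshape, big)):
        raise ValueError("template must not exceed the tomogram")
    if candidates is None:
        candidates = euler_grid(angular_step)
    radius = min(tshape) / 2.0

    transfer = np.ones(big)
    if lowpass is not None and lowpass >= 2 * tomogram.voxel_size:
        transfer = raised_cosine_lowpass(big, tomogram.voxel_size, lowpass)
    transfer = transfer * make_wedge_support(w, big)
    transfer_us = np.fft.ifftshift(transfer)

    tomo_f = np.fft.fftn(tomogram.values.astype(np.float64)) * transfer_us
    tomo = np.fft.ifftn(tomo_f).real
    ft = np.fft.fftn(tomo)
    ft2 = np.fft.fftn(tomo * tomo)

    # spherical mask centered at the box center, embedded in the big box
    c = np.array([n // 2 for n in big], dtype=float)
    grids = np.meshgrid(*[np.arange(n, dtype=float) for n in big], indexing="ij")
    r = np.sqrt(sum((g - cc) ** 2 for g, cc in zip(grids, c)))
    msk = (r <= radius).astype(np.float64)
    n_m = msk.sum()
    fm = np.fft.fftn(np.fft.ifftshift(msk))
    local_sum = np.fft.ifftn(ft * np.conj(fm)).real
    local_sum2 = np.fft.ifftn(ft2 * np.conj(fm)).real
    local_var = np.maximum(local_sum2 - local_sum**2 / n_m, 0.0)

    pad = np.zeros(big)
    lo = [(b - t) // 2 for b, t in zip(big, tshape)]
    sl = tuple(slice(l, l + t) for l, t in zip(lo, tshape))

    best = np.full(big, -np.inf)
    best_ori = np.zeros(big, dtype=np.int32)
    for oi, euler in enumerate(candidates):
        rinv = Rotation.from_euler("ZYZ", euler, degrees=True).inv()
        rt = apply_transform(template.values.astype(np.float64),
                             RigidTransform.from_rotation(rinv))
        pad[:] = 0.0
        pad[sl] = rt
        tw = np.fft.ifftn(np.fft.fftn(np.fft.ifftshift(pad)) * transfer_us).real
        tw *= np.fft.ifftshift(msk)
        tw -= tw.sum() / n_m * np.fft.ifftshift(msk)
        sig_t = math.sqrt(float((tw**2).sum()))
        if sig_t == 0.0:
            continue
        cc = np.fft.ifftn(ft * np.conj(np.fft.fftn(tw))).real
        score = cc / (np.sqrt(np.maximum(local_var, 1e-30)) * sig_t)
        score[local_var < 1e-12] = 0.0
        upd = score > best
        best[upd] = score[upd]
        best_ori[upd] = oi

    # non-maximum suppression
    order = np.argsort(best, axis=None)[::-1]
    taken: list[np.ndarray] = []
    rows = []
    for flat in order:
        if len(rows) >= n_peaks:
            break
        pos = np.array(np.unravel_index(flat, big), dtype=float)
        if any(np.linalg.norm(pos - t) < radius for t in taken):
            continue
        taken.append(pos)
        e = candidates[best_ori[tuple(pos.astype(int))]]
        rows.append({"x": pos[0], "y": pos[1], "z": pos[2],
                     "phi": e[0], "theta": e[1], "psi": e[2],
                     "score": float(best[tuple(pos.astype(int))])})
    return pd.DataFrame(rows, columns=["x", "y", "z", "phi", "theta", "psi", "score"])


def write_poses(subtomos: list[Subtomogram], path) -> None:
    """Poses/scores/classes as TSV: one row per particle."""
    rows = []
    for i, s in enumerate(subtomos):
        rows.append({
            "particle": i, "phi": s.pose.euler[0], "theta": s.pose.euler[1],
            "psi": s.pose.euler[2], "dx": s.pose.shift[0], "dy": s.pose.shift[1],
            "dz": s.pose.shift[2],
            "score": float("nan") if s.score is None else s.score,
            "class": -1 if s.class_label is None else s.class_label,
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.6g")
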