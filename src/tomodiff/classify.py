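"""Focused-mask constrained-PCA classification of occupancy states.

Aligned particles are compared pairwise with the constrained correlation
kernel under a real-space focus mask; the resulting similarity matrix is
double-centered, eigen-decomposed, and the leading-coordinate embedding is
clustered with k-means.  Successive rounds with different focus masks peel a
heterogeneous dataset into occupancy classes (e.g. OST present/absent, then
TRAP present/absent within the OST-containing class).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import eigh
from sklearn.cluster import KMeans

from .particles import Subtomogram, apply_support, make_wedge_support
from .transforms import RigidTransform, apply_transform, rotate_support
from .volmap import DensityMap, VolumeMask, raised_cosine_lowpass


@dataclass
class ClassificationResult:
    labels: np.ndarray
    fractions: np.ndarray
    eigenvalues: np.ndarray
    focus_mask_id: str = ""
    degenerate: bool = False
    heterogeneous: bool = True
    retained_class: int | None = None
    particle_indices: np.ndarray | None = None  # indices into the full dataset

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        self.fractions = np.asarray(self.fractions, dtype=float)
        if self.labels.size and abs(self.fractions.sum() - 1.0) > 1e-9:
            raise ValueError("class fractions must sum to 1")


def _aligned_values(subtomos, poses) -> list[np.ndarray]:
    return [
        apply_transform(s.map.values.astype(np.float64), p)
        for s, p in zip(subtomos, poses)
    ]


def cc_matrix(
    subtomos: list[Subtomogram],
    poses: list[RigidTransform],
    ref: DensityMap,
    focus: VolumeMask,
    lowpass: float | None = None,
    aligned: list[np.ndarray] | None = None,
) -> np.ndarray:
    """Pairwise constrained-correlation matrix of pose-aligned particles.

    Each particle is rotated/shifted into the reference frame and compared
    as a *deviation from the reference*: the reference is rotated into the
    particle's frame, filtered by its missing wedge, and rotated back, so
    the subtracted model carries exactly the same wedge loss and
    interpolation blur as the particle.  The focus-masked residuals are then
    correlated over the intersection of the two rotated wedge supports (DC
    excluded), optionally restricted to a low-pass ball of `lowpass` Å (a
    large speed and robustness win for big datasets).  Particles that agree
    with the reference contribute near-zero residual correlations; particles
    sharing a deviation (e.g. the same missing subunit) correlate strongly —
    the block structure the eigen-embedding separates.  Passing an all-zero
    reference degrades gracefully to the plain masked correlation of the
    aligned particles.  Diagonal is exactly 1; the matrix is symmetric.
    """
    n = len(subtomos)
    if n == 0:
        raise ValueError("no particles")
    if len(poses) != n:
        raise ValueError("one pose per particle required")
    fv = focus.values.astype(np.float64)
    if fv.max() <= 0:
        raise ValueError("empty focus mask")
    shape = subtomos[0].map.shape
    voxel = subtomos[0].map.voxel_size

    keep = np.ones(shape, dtype=bool)
    if lowpass is not None:
        keep = raised_cosine_lowpass(shape, voxel, lowpass) > 0.5
    keep[tuple(d // 2 for d in shape)] = False  # exclude DC
    sel = np.flatnonzero(keep.ravel())

    if aligned is None:
        aligned = _aligned_values(subtomos, poses)
    refv = ref.values.astype(np.float64)
    support_cache: dict = {}
    F = np.empty((n, sel.size), dtype=np.complex128)
    W = np.empty((n, sel.size), dtype=np.float64)
    for i, (s, p, av) in enumerate(zip(subtomos, poses, aligned)):
        key = s.wedge
        if key not in support_cache:
            support_cache[key] = make_wedge_support(s.wedge, shape)
        sup = support_cache[key]
        # wedge-matched model of this particle: ref -> particle frame ->
        # missing-wedge filter -> back to reference frame
        ref_in_particle = apply_transform(refv, p.inverse())
        reproj = apply_transform(apply_support(ref_in_particle, sup), p)
        f = np.fft.fftshift(np.fft.fftn((av - reproj) * fv)).ravel()[sel]
        wrot = rotate_support(sup.astype(np.float64), p.rotation) > 0.5
        W[i] = wrot.ravel()[sel]
        F[i] = f * W[i]

    S = W @ W.T                          # intersecting coefficient counts
    if np.any(S <= 0):
        bad = np.argwhere(S <= 0)
        raise ValueError(f"empty Fourier support intersection for pair {tuple(bad[0])}")
    G = (F @ F.conj().T).real            # Σ_S F_i conj(F_j)
    P = (np.abs(F) ** 2)                 # |F_i|² already zero outside W_i
    N = P @ W.T                          # Σ |F_i|² over W_i ∩ W_j
    den = np.sqrt(N * N.T)
    C = np.divide(G, den, out=np.zeros_like(G), where=den > 0)
    C = np.clip((C + C.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(C, 1.0)
    return C


def cpca_classify(
    matrix: np.ndarray,
    n_components: int = 4,
    k: int = 2,
    seed: int = 0,
    null_ratio: float = 2.0,
) -> ClassificationResult:
    """Classify particles from a similarity matrix.

    Double-centers the matrix (Gower), eigen-decomposes, embeds particles in
    the top `n_components` coordinates scaled by sqrt(eigenvalue), and runs
    k-means (10 restarts, fixed seed).  A (near-)zero leading eigenvalue is
    flagged as degenerate.  When the leading eigenvalue does not stand out
    from the bulk spectrum (λ1 < `null_ratio`·λ2) the matrix carries no
    detectable heterogeneity: splitting would only partition noise, so a
    single class is returned with ``heterogeneous=False``.  Deterministic
    for a fixed seed.
    """
    C = np.asarray(matrix, dtype=float)
    n = C.shape[0]
    if C.shape != (n, n):
        raise ValueError("matrix must be square")
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > n:
        raise ValueError(f"k={k} exceeds n_particles={n}")
    if n_components < 1:
        raise ValueError("n_components must be >= 1")

    H = np.eye(n) - np.ones((n, n)) / n
    B = H @ C @ H
    B = (B + B.T) / 2.0
    evals, evecs = eigh(B)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    m = min(n_components, n)
    lam = np.clip(evals[:m], 0.0, None)
    X = evecs[:, :m] * np.sqrt(lam)

    degenerate = bool(evals[0] <= 1e-10 * max(n, 1))
    heterogeneous = True
    if n > 2 and not degenerate:
        bulk = max(float(evals[1]), 1e-30)
        heterogeneous = bool(evals[0] >= null_ratio * bulk)
    if k == 1 or degenerate or not heterogeneous:
        labels = np.zeros(n, dtype=int)
    else:
        km = KMeans(n_clusters=k, n_init=10, random_state=seed)
        labels = km.fit_predict(X)
    fractions = np.bincount(labels, minlength=k) / n
    return ClassificationResult(labels, fractions, evals[: max(m, k)],
                                degenerate=degenerate, heterogeneous=heterogeneous)


def _class_presence_means(aligned, labels, focus_values) -> np.ndarray:
    """Mean density inside the focus mask per class (presence statistic)."""
    fsum = focus_values.sum()
    per_particle = np.array([float((a * focus_values).sum()) / fsum for a in aligned])
    k = labels.max() + 1
    return np.array([
        per_particle[labels == c].mean() if np.any(labels == c) else -np.inf
        for c in range(k)
    ])


@dataclass
class ClassificationRound:
    focus: VolumeMask
    k: int = 2
    retain: str = "present"  # "present" (higher focus density), "absent", or "all"
    name: str = ""
    lowpass: float | None = None


def classify_pipeline(
    subtomos: list[Subtomogram],
    poses: list[RigidTransform],
    ref: DensityMap,
    rounds: list[ClassificationRound],
    n_components: int = 4,
    seed: int = 0,
) -> list[ClassificationResult]:
    """Successive focused classification rounds.

    Each round classifies only the particles retained by the previous round
    (initially all).  With the default ``retain="present"`` rule the class
    with the higher mean density inside the focus mask is carried forward —
    the present/absent dichotomy of occupancy sorting.  Per-round fractions
    refer to the particles entering that round.  Raises if `rounds` is empty
    or a retained class comes up empty.
    """
    if not rounds:
        raise ValueError("rounds must be non-empty")
    if len(poses) != len(subtomos):
        raise ValueError("one pose per particle required")
    aligned_all = _aligned_values(subtomos, poses)
    current = np.arange(len(subtomos))
    results: list[ClassificationResult] = []
    for ri, rnd in enumerate(rounds):
        if current.size == 0:
            raise ValueError(f"retained class empty before round {ri}")
        sub = [subtomos[i] for i in current]
        sub_poses = [poses[i] for i in current]
        sub_aligned = [aligned_all[i] for i in current]
        C = cc_matrix(sub, sub_poses, ref, rnd.focus, lowpass=rnd.lowpass,
                      aligned=sub_aligned)
        res = cpca_classify(C, n_components=n_components,
                            k=min(rnd.k, len(sub)), seed=seed + ri)
        res.focus_mask_id = rnd.name or f"round{ri}"
        res.particle_indices = current.copy()
        if rnd.retain == "all" or res.degenerate or res.fractions.size == 1:
            retained = np.arange(len(sub))
            res.retained_class = int(np.argmax(res.fractions))
        else:
            means = _class_presence_means(sub_aligned, res.labels,
                                          rnd.focus.values.astype(np.float64))
            c = int(np.argmax(means)) if rnd.retain == "present" else int(np.argmin(means))
            res.retained_class = c
            retained = np.flatnonzero(res.labels == c)
            if retained.size == 0:
                raise ValueError(f"retained class empty in round {ri}")
        for local_i, lab in zip(current, res.labels):
            subtomos[local_i].class_label = int(lab)
        results.append(res)
        current = current[retained]
    return results
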