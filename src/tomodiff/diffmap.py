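"""Normalized difference-density mapping with σ-significance localization.

Two density maps are filtered to a common resolution, brought onto a common
grid and orientation, normalized to zero mean / unit standard deviation over
an analysis region, and subtracted.  The difference is expressed in units of
its own standard deviation (σ), so a feature "at 7σ" is seven difference-map
standard deviations away from zero — the significance convention used to
localize missing subunits.  Super-threshold voxels are grouped into
connected components and tabulated (peak σ, volume, centroid, bounding-box
diameter, locality flag).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage import measure

from .align import align_particles, constrained_cc
from .transforms import RigidTransform, apply_transform, euler_grid, euler_neighborhood
from .volmap import DensityMap, VolumeMask, lowpass_filter, resample_map

#: bounding-box diameter (nm) at or below which a component counts as localized
LOCALIZATION_LIMIT_NM = 8.0

_COMPONENT_COLUMNS = [
    "component", "peak_sigma", "volume_voxels", "volume_nm3",
    "centroid_x", "centroid_y", "centroid_z", "bbox_diameter_nm", "localized",
]


@dataclass
class DifferenceResult:
    diff_map: DensityMap          # σ units
    sigma: float                  # std of the raw difference (intensity units)
    analysis_mask: VolumeMask
    components: pd.DataFrame
    params: dict = field(default_factory=dict)
    identical_maps: bool = False


def normalize_map(m: DensityMap, region: VolumeMask | None = None) -> DensityMap:
    """Affine-rescale a map to mean 0, std 1 over `region` (population std).

    Voxels outside the region get the same affine transform.  Raises on zero
    variance or a region smaller than 100 voxels (whole box if region=None).
    """
    if region is None:
        sel = np.ones(m.shape, dtype=bool)
    else:
        sel = region.values > 0.5
    if sel.sum() < 100:
        raise ValueError(f"normalization region covers only {int(sel.sum())} voxels (<100)")
    v = m.values.astype(np.float64)
    mu = float(v[sel].mean())
    sd = float(v[sel].std())
    if sd == 0.0:
        raise ValueError("zero variance in normalization region")
    return DensityMap(((v - mu) / sd).astype(np.float32), m.voxel_size, m.origin,
                      label=f"{m.label} normalized")


def rigid_fit_maps(
    a: DensityMap,
    b: DensityMap,
    angular_range: float = 10.0,
    step: float = 2.0,
    max_shift: float = 6.0,
) -> tuple[RigidTransform, float]:
    """Rigidly fit map `b` onto map `a` by exhaustive local search.

    Orientations cover ±`angular_range`° around identity at `step`°
    (all three ZYZ angles); per orientation the translation is the FFT
    cross-correlation arg-max within `max_shift` voxels.  Returns the
    transform mapping b onto a and the achieved correlation.  Identical maps
    return the identity with correlation 1.
    """
    if a.shape != b.shape:
        raise ValueError("maps must share a grid; resample first")
    offs = np.arange(-angular_range, angular_range + 1e-9, step)
    candidates = [(float(p), float(t), float(s)) for p in offs for t in offs for s in offs]
    # put identity first for deterministic preference on ties
    candidates.sort(key=lambda e: (abs(e[0]) + abs(e[1]) + abs(e[2])))
    poses, scores = align_particles(
        [b.values], a.values, candidates, None, a.voxel_size, max_shift=max_shift
    )
    return poses[0], scores[0]


def sigma_components(
    diff_values: np.ndarray,
    voxel_size: float,
    k_sigma: float,
    sign: str = "both",
    min_volume: int | None = None,
    connectivity: int = 26,
    analysis_mask: np.ndarray | None = None,
    localization_limit_nm: float = LOCALIZATION_LIMIT_NM,
) -> pd.DataFrame:
    """Connected super-threshold components of a σ-unit difference map.

    `sign` selects density reductions (below −kσ), gains (above +kσ) or
    both.  Components smaller than `min_volume` voxels are dropped (default:
    the voxel count of a (1.5 nm)³ cube at the working voxel size).  A
    component is flagged localized when its bounding-box diagonal is at most
    `localization_limit_nm`.  Rows sorted by |peak σ| descending.
    """
    if not k_sigma > 0:
        raise ValueError("k_sigma must be > 0")
    if sign not in ("reduction", "gain", "both"):
        raise ValueError(f"unknown sign {sign!r}")
    if connectivity not in (6, 26):
        raise ValueError("connectivity must be 6 or 26")
    if min_volume is None:
        min_volume = max(1, int(round((15.0 / voxel_size) ** 3)))
    d = np.asarray(diff_values, dtype=np.float64)
    if analysis_mask is not None:
        d = np.where(analysis_mask > 0.5, d, 0.0)

    rows = []
    jobs = []
    if sign in ("reduction", "both"):
        jobs.append(("reduction", d <= -k_sigma))
    if sign in ("gain", "both"):
        jobs.append(("gain", d >= k_sigma))
    conn = 3 if connectivity == 26 else 1
    for _, above in jobs:
        lab = measure.label(above, connectivity=conn)
        for region in measure.regionprops(lab):
            if region.area < min_volume:
                continue
            sel = lab == region.label
            vals = d[sel]
            peak = float(vals[np.argmax(np.abs(vals))])
            lo = np.array(region.bbox[:3]); hi = np.array(region.bbox[3:])
            diam_nm = float(np.linalg.norm(hi - lo) * voxel_size / 10.0)
            cen = np.array(region.centroid) * voxel_size
            rows.append({
                "peak_sigma": peak,
                "volume_voxels": int(region.area),
                "volume_nm3": float(region.area * (voxel_size / 10.0) ** 3),
                "centroid_x": cen[0], "centroid_y": cen[1], "centroid_z": cen[2],
                "bbox_diameter_nm": diam_nm,
                "localized": diam_nm <= localization_limit_nm,
            })
    rows.sort(key=lambda r: -abs(r["peak_sigma"]))
    for i, r in enumerate(rows):
        r["component"] = i
    return pd.DataFrame(rows, columns=_COMPONENT_COLUMNS)


def difference_map(
    a: DensityMap,
    b: DensityMap,
    resolution: float,
    exclusion: VolumeMask | None = None,
    prealigned: bool = False,
    k_sigma: float = 4.0,
    sign: str = "both",
    min_volume: int | None = None,
    connectivity: int = 26,
    fit_angular_range: float = 10.0,
    fit_step: float = 2.0,
) -> DifferenceResult:
    """σ-normalized difference map a − b with component localization.

    Fixed pipeline order: low-pass both maps to `resolution` Å → resample b
    onto a's grid → rigid-fit b onto a (skipped when `prealigned`) → zero
    the exclusion region in both (if given) → normalize both to mean 0 /
    std 1 over the analysis region (whole box minus exclusion) → subtract →
    divide by the standard deviation σ of the difference over the analysis
    region.  Convention: `a` is the map under study (e.g. a
    subunit-deficient average) and `b` the reference it is compared against
    (e.g. the wild-type average); density the studied map lacks relative to
    the reference therefore shows up as a negative feature — a "density
    reduction" — while extra density shows up as a gain.
    """
    for m in (a, b):
        if resolution < 2 * m.voxel_size:
            raise ValueError(
                f"resolution {resolution} Å below Nyquist of a map "
                f"({2 * m.voxel_size} Å)"
            )
    af = lowpass_filter(a, resolution)
    bf = lowpass_filter(b, resolution)
    resampled = bf.shape != af.shape or abs(bf.voxel_size - af.voxel_size) > 1e-9
    if resampled:
        bf = resample_map(bf, af.voxel_size, af.shape, af.origin)
    fit = RigidTransform()
    if not prealigned:
        fit, _ = rigid_fit_maps(af, bf, angular_range=fit_angular_range, step=fit_step)
        if any(abs(e) > 1e-12 for e in (*fit.euler, *fit.shift)):
            bf = DensityMap(
                apply_transform(bf.values.astype(np.float64), fit).astype(np.float32),
                bf.voxel_size, bf.origin, label=bf.label,
            )

    analysis = np.ones(af.shape, dtype=np.float32)
    if exclusion is not None:
        excl = exclusion.values
        if excl.shape != af.shape:
            raise ValueError("exclusion mask shape mismatch")
        analysis *= (1.0 - excl) >= 0.5
        av = af.values * (1.0 - excl)
        bv = bf.values * (1.0 - excl)
        af = DensityMap(av, af.voxel_size, af.origin, label=af.label)
        bf = DensityMap(bv, bf.voxel_size, bf.origin, label=bf.label)
    region = VolumeMask(analysis, af.voxel_size, role="analysis")

    params = {
        "resolution": resolution, "k_sigma": k_sigma, "sign": sign,
        "connectivity": connectivity,
        "min_volume": (min_volume if min_volume is not None
                       else max(1, int(round((15.0 / af.voxel_size) ** 3)))),
        "prealigned": prealigned, "resampled": resampled,
        "fit_euler": fit.euler, "fit_shift": fit.shift,
    }

    sel = analysis > 0.5
    try:
        an = normalize_map(af, region)
        bn = normalize_map(bf, region)
    except ValueError:
        zero = DensityMap(np.zeros(af.shape, np.float32), af.voxel_size, af.origin,
                          label="difference (degenerate)")
        return DifferenceResult(zero, 0.0, region,
                                pd.DataFrame(columns=_COMPONENT_COLUMNS),
                                params, identical_maps=True)
    diff = an.values.astype(np.float64) - bn.values.astype(np.float64)
    sigma = float(diff[sel].std())
    # the normalized inputs have unit std; a residual five orders below that
    # is numerical quantization, not density difference
    if sigma <= 1e-5:
        zero = DensityMap(np.zeros(af.shape, np.float32), af.voxel_size, af.origin,
                          label="difference (identical maps)")
        return DifferenceResult(zero, 0.0, region,
                                pd.DataFrame(columns=_COMPONENT_COLUMNS),
                                params, identical_maps=True)
    dmap = DensityMap((diff / sigma).astype(np.float32), af.voxel_size, af.origin,
                      label="difference (sigma units)")
    table = sigma_components(
        dmap.values, af.voxel_size, k_sigma, sign=sign, min_volume=min_volume,
        connectivity=connectivity, analysis_mask=analysis,
    )
    return DifferenceResult(dmap, sigma, region, table, params)
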