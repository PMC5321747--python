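"""Synthetic translocon phantoms and tilt-limited, noisy subtomogram datasets.

The phantom is a caricature of an ER membrane-bound ribosome–translocon
complex: a large globular body for the 80S ribosome sitting on a membrane
slab, with small Gaussian blobs for the Sec61 channel, the TRAP subunits
(TRAPα/β lumenal, TRAPγ reaching to the cytosolic face, TRAPδ at the
OST-facing periphery) and the OST complex.  It makes no claim of structural
fidelity — its job is to give every downstream stage (alignment,
classification, FSC, difference mapping) a ground truth with known poses and
known subunit occupancy.

Subtomograms are simulated directly as rotate → missing-wedge filter →
additive white Gaussian noise; tomographic projection/back-projection is
deliberately not modelled, since the wedge filter is the property that
matters to wedge-aware averaging.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import erf

from .particles import Subtomogram, WedgeSpec, apply_support, make_wedge_support
from .transforms import RigidTransform, apply_transform, random_rotations
from .volmap import DensityMap, VolumeMask, center_voxel


@dataclass(frozen=True)
class GaussianComponent:
    """An isotropic Gaussian blob: center in Å relative to the box center."""

    name: str
    center: tuple[float, float, float]
    gaussian_sd: float  # Å
    amplitude: float


def default_components() -> list[GaussianComponent]:
    # membrane plane at z = -70 Å; ribosome above it, translocon in/below it
    return [
        GaussianComponent("ribosome", (0.0, 0.0, 40.0), 60.0, 1.0),
        GaussianComponent("Sec61", (0.0, 0.0, -70.0), 15.0, 0.9),
        GaussianComponent("TRAPab", (35.0, 20.0, -80.0), 12.0, 0.9),
        GaussianComponent("TRAPg", (40.0, -5.0, -50.0), 10.0, 0.9),
        GaussianComponent("TRAPd", (50.0, 45.0, -90.0), 10.0, 0.9),
        GaussianComponent("OST", (15.0, 70.0, -80.0), 18.0, 0.9),
    ]


@dataclass
class PhantomSpec:
    """Geometry of the synthetic complex.

    Defaults: 48³ box at 5 Å/voxel (240 Å across) — coarse enough for
    second-scale tests, fine enough to resolve 10 Å-sd subunit blobs.
    """

    box_size: int = 48
    voxel_size: float = 5.0
    components: list[GaussianComponent] = field(default_factory=default_components)
    membrane_z: float = -70.0
    membrane_thickness: float = 40.0
    membrane_amplitude: float = 0.5
    membrane_softness: float = 8.0  # Å, erf edge width

    def __post_init__(self) -> None:
        half = self.box_size * self.voxel_size / 2
        for c in self.components:
            if c.amplitude < 0:
                raise ValueError(f"component {c.name}: amplitude must be >= 0")
            if any(abs(x) >= half for x in c.center):
                raise ValueError(f"component {c.name}: center {c.center} outside box")
        names = [c.name for c in self.components]
        if len(set(names)) != len(names):
            raise ValueError("duplicate component names")

    def component_names(self) -> list[str]:
        return [c.name for c in self.components]


def _grid_coords(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    c = center_voxel((spec.box_size,) * 3)
    ax = [(np.arange(spec.box_size) - c[d]) * spec.voxel_size for d in range(3)]
    return np.meshgrid(*ax, indexing="ij")


def build_phantom(
    spec: PhantomSpec,
    present: dict[str, bool] | set[str] | None = None,
    membrane: bool = True,
) -> DensityMap:
    """Evaluate the analytic phantom on the grid.

    `present` selects which components to include (default: all).  The map
    is a plain sum, so omitting a component subtracts exactly that
    component's Gaussian field.
    """
    names = set(spec.component_names())
    if present is None:
        included = names
    elif isinstance(present, dict):
        unknown = set(present) - names
        if unknown:
            raise ValueError(f"unknown component(s): {sorted(unknown)}")
        included = {n for n in names if present.get(n, True)}
    else:
        unknown = set(present) - names
        if unknown:
            raise ValueError(f"unknown component(s): {sorted(unknown)}")
        included = set(present)

    gx, gy, gz = _grid_coords(spec)
    out = np.zeros_like(gx)
    for c in spec.components:
        if c.name not in included or c.amplitude == 0:
            continue
        r2 = (gx - c.center[0]) ** 2 + (gy - c.center[1]) ** 2 + (gz - c.center[2]) ** 2
        out += c.amplitude * np.exp(-r2 / (2 * c.gaussian_sd**2))
    if membrane and spec.membrane_amplitude > 0:
        h = spec.membrane_thickness / 2
        s = spec.membrane_softness * math.sqrt(2)
        slab = 0.5 * (erf((gz - spec.membrane_z + h) / s) - erf((gz - spec.membrane_z - h) / s))
        out += spec.membrane_amplitude * slab
    return DensityMap(out.astype(np.float32), spec.voxel_size, label="phantom")


def component_mask(
    spec: PhantomSpec, names: list[str] | str, radius_sd: float = 2.5, soft_edge: float = 10.0
) -> VolumeMask:
    """Focus mask: union of spheres of radius ``radius_sd·sd`` around the
    named components, with a cosine soft edge of `soft_edge` Å."""
    if isinstance(names, str):
        names = [names]
    by_name = {c.name: c for c in spec.components}
    unknown = set(names) - set(by_name)
    if unknown:
        raise ValueError(f"unknown component(s): {sorted(unknown)}")
    gx, gy, gz = _grid_coords(spec)
    m = np.zeros_like(gx)
    for n in names:
        c = by_name[n]
        r = np.sqrt((gx - c.center[0]) ** 2 + (gy - c.center[1]) ** 2 + (gz - c.center[2]) ** 2)
        r0 = radius_sd * c.gaussian_sd
        w = np.where(
            r <= r0, 1.0,
            np.where(r >= r0 + soft_edge, 0.0, 0.5 * (1 + np.cos(np.pi * (r - r0) / soft_edge))),
        )
        m = np.maximum(m, w)
    return VolumeMask(m.astype(np.float32), spec.voxel_size, role="focus")


@dataclass
class DatasetSpec:
    """Dataset-level simulation parameters.

    `occupancy` maps a component name or a group name (see `groups`) to a
    Bernoulli presence probability; one flag is drawn per key per particle
    and expanded to the member components.  Components not covered by any
    key are always present.  Defaults encode the occupancy mixture of the
    study conditions: OST on 58% of particles, TRAP on 76% (so 24% of the
    OST-containing class lacks TRAP under independent draws).
    """

    n_particles: int = 200
    occupancy: dict[str, float] = field(
        default_factory=lambda: {"OST": 0.58, "TRAP": 0.76}
    )
    groups: dict[str, list[str]] = field(
        default_factory=lambda: {"TRAP": ["TRAPab", "TRAPg", "TRAPd"]}
    )
    snr: float = 0.7
    seed: int = 0
    max_shift: float = 4.0  # voxels, uniform per axis

    def __post_init__(self) -> None:
        if self.n_particles < 0:
            raise ValueError("n_particles must be >= 0")
        for k, p in self.occupancy.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"occupancy[{k!r}] = {p} outside [0, 1]")
        if not self.snr > 0:
            raise ValueError("snr must be > 0")
        covered: set[str] = set()
        for key in self.occupancy:
            members = set(self.groups.get(key, [key]))
            if covered & members:
                raise ValueError(f"occupancy key {key!r} overlaps another key's components")
            covered |= members

    def expand_flags(self, key_flags: dict[str, bool], all_names: list[str]) -> dict[str, bool]:
        flags = {n: True for n in all_names}
        for key, on in key_flags.items():
            for member in self.groups.get(key, [key]):
                if member in flags:
                    flags[member] = bool(on)
        return flags


def simulate_subtomogram(
    phantom: DensityMap,
    t: RigidTransform,
    w: WedgeSpec,
    snr: float | None,
    seed: int,
    support: np.ndarray | None = None,
) -> Subtomogram:
    """Rotate/shift the phantom by `t`, apply the missing wedge, add noise.

    `t` is the placement transform (applied to the phantom); the ground-truth
    alignment pose of the resulting particle is ``t.inverse()``.  Noise is
    white Gaussian with variance equal to the wedge-filtered signal variance
    inside the particle region (phantom > 10% of max) divided by `snr`;
    ``snr=None`` disables noise.
    """
    if snr is not None and not snr > 0:
        raise ValueError("snr must be > 0")
    placed = apply_transform(phantom.values.astype(np.float64), t)
    if support is None:
        support = make_wedge_support(w, phantom.shape)
    signal = apply_support(placed, support)
    if snr is not None and np.isfinite(snr):
        region = placed > 0.1 * placed.max()
        if not region.any():
            region = np.ones_like(placed, dtype=bool)
        noise_sd = math.sqrt(float(np.var(signal[region])) / snr)
        rng = np.random.default_rng(seed)
        signal = signal + rng.normal(0.0, noise_sd, size=signal.shape)
    m = DensityMap(signal.astype(np.float32), phantom.voxel_size, phantom.origin,
                   label="subtomogram")
    return Subtomogram(map=m, wedge=w, pose=t.inverse(), noise_seed=seed)


_GT_FLOAT_COLS = ("phi", "theta", "psi", "dx", "dy", "dz")


def generate_dataset(
    spec: DatasetSpec, phantom_spec: PhantomSpec, w: WedgeSpec
) -> tuple[list[Subtomogram], pd.DataFrame]:
    """Simulate a dataset with known poses and occupancy.

    Returns the particles and a ground-truth table with one row per particle:
    the true pose (particle → reference frame, ZYZ degrees + voxel shifts),
    per-component presence flags, and the per-particle noise seed.
    Deterministic for a fixed `spec.seed`.
    """
    rng = np.random.default_rng(spec.seed)
    names = phantom_spec.component_names()
    support = make_wedge_support(w, (phantom_spec.box_size,) * 3)
    phantom_cache: dict[tuple, DensityMap] = {}

    subtomos: list[Subtomogram] = []
    rows = []
    rotations = random_rotations(spec.n_particles, rng)
    for i in range(spec.n_particles):
        shift = rng.uniform(-spec.max_shift, spec.max_shift, size=3)
        key_flags = {k: bool(rng.random() < p) for k, p in spec.occupancy.items()}
        noise_seed = int(rng.integers(2**31))
        flags = spec.expand_flags(key_flags, names)
        key = tuple(flags[n] for n in names)
        if key not in phantom_cache:
            phantom_cache[key] = build_phantom(phantom_spec, flags)
        placement = RigidTransform.from_rotation(rotations[i], shift)
        s = simulate_subtomogram(
            phantom_cache[key], placement, w, spec.snr, noise_seed, support=support
        )
        subtomos.append(s)
        pose = s.pose
        rows.append(
            {"particle": i,
             **dict(zip(_GT_FLOAT_COLS, (*pose.euler, *pose.shift))),
             **{f"{n}_present": int(flags[n]) for n in names},
             "noise_seed": noise_seed}
        )
    columns = (["particle", *_GT_FLOAT_COLS]
               + [f"{n}_present" for n in names] + ["noise_seed"])
    table = pd.DataFrame(rows, columns=columns)
    return subtomos, table


def write_ground_truth(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_ground_truth(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def poses_from_table(table: pd.DataFrame) -> list[RigidTransform]:
    return [
        RigidTransform((r.phi, r.theta, r.psi), (r.dx, r.dy, r.dz))
        for r in table.itertuples()
    ]
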