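"""Synthetic lesion-bearing 4D BOLD phantom with ground truth.

The phantom emulates the situation the detection method targets: a
spatially contiguous lesion whose voxels share a distinct, coherent
low-frequency time course, embedded in a "head" that also contains a few
network-like confound sources, slow per-voxel drift, and additive white
Gaussian noise.  Every source mask, every source time course and the
brain mask are returned alongside the series, so each downstream stage
can be validated against exact ground truth.

The generative model for voxel v at frame t is::

    y(v,t) = baseline(v)
           + A_tumor * s_tumor(t) * 1[v in tumor]
           + sum_k A_net * s_k(t)  * 1[v in network_k]
           + drift_slope(v) * tau(t)
           + eps(v,t),   eps ~ N(0, noise_sd^2)

where every source time course s is a unit-variance, zero-mean sum of
three sinusoids with frequencies drawn uniformly from a low-frequency
band (default 0.01-0.03 Hz, the canonical resting-state BOLD band) and
random phases, and tau is a linear ramp over the scan spanning [-1/2, 1/2].

The lesion is mildly heterogeneous: its two halves (split along the
first axis through the lesion centre) carry correlated but not identical
time courses, ``s_half = (s_common ± g * s_diff) / sqrt(1 + g^2)`` with
``g = tumor_heterogeneity``.  This emulates intra-tumor compartments
(e.g. active rim vs. core) whose BOLD signals share a dominant common
fluctuation.  The differential mode is weak, so a low ICA model order
represents the lesion as one component while a high model order can
split it into per-compartment components — the model-order trade-off the
TNCs sweep exists to resolve.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .errors import SpecError
from .imaging import BinaryMask, Series4D, VoxelGrid

__all__ = ["PhantomSpec", "PhantomOutput", "generate_phantom", "phantom_presets", "PRESET_NAMES"]


@dataclass(frozen=True)
class PhantomSpec:
    """Full description of a synthetic acquisition.

    Geometry is given in voxel units on an isotropic grid; amplitudes are in
    arbitrary signal units relative to ``noise_sd``.
    """

    shape: tuple[int, int, int] = (24, 24, 24)
    voxel_size_mm: float = 3.0
    n_frames: int = 120
    tr_seconds: float = 2.0
    head_semiaxes: tuple[float, float, float] = (11.0, 11.0, 11.0)
    tumor_center: tuple[float, float, float] = (16.0, 13.0, 12.0)
    tumor_semiaxes: tuple[float, float, float] = (5.0, 4.0, 4.0)
    tumor_amplitude: float = 3.0
    tumor_band_hz: tuple[float, float] = (0.01, 0.03)
    tumor_heterogeneity: float = 0.2
    n_networks: int = 12
    network_semiaxes: tuple[float, float, float] = (2.5, 2.5, 2.5)
    network_amplitude: float = 3.0
    baseline: float = 100.0
    drift_amplitude: float = 1.0
    noise_sd: float = 1.0
    rng_seed: int = 0

    def __post_init__(self):
        if self.noise_sd <= 0:
            raise SpecError("noise_sd must be positive")
        if self.n_frames < 2:
            raise SpecError("n_frames must be >= 2")
        if not 0 < self.tumor_band_hz[0] < self.tumor_band_hz[1]:
            raise SpecError("tumor_band_hz must be an increasing positive interval")
        center = np.asarray(self.shape, float) / 2.0
        # tumor ellipsoid must lie strictly inside the head ellipsoid
        d = np.abs(np.asarray(self.tumor_center) - center) + np.asarray(self.tumor_semiaxes)
        if np.any(d >= np.asarray(self.head_semiaxes)):
            raise SpecError(
                "tumor ellipsoid is not strictly inside the head ellipsoid: "
                f"extent {tuple(d)} vs head semiaxes {self.head_semiaxes}"
            )

    @property
    def grid(self) -> VoxelGrid:
        return VoxelGrid.isotropic(self.shape, self.voxel_size_mm)


@dataclass(frozen=True)
class PhantomOutput:
    series: Series4D
    truth_tumor: BinaryMask
    truth_networks: list[BinaryMask]
    truth_time_courses: dict[str, np.ndarray] = field(repr=False)
    brain: BinaryMask = None  # type: ignore[assignment]
    spec: PhantomSpec = None  # type: ignore[assignment]


def ellipsoid_mask(grid: VoxelGrid, center, semiaxes) -> BinaryMask:
    """Voxels whose centres satisfy sum(((x-c)/a)^2) <= 1."""
    idx = np.indices(grid.shape, dtype=float)
    c = np.asarray(center, float).reshape(3, 1, 1, 1)
    a = np.asarray(semiaxes, float).reshape(3, 1, 1, 1)
    return BinaryMask(grid, (((idx - c) / a) ** 2).sum(axis=0) <= 1.0)


def _band_limited_course(rng: np.random.Generator, n_frames: int, tr: float, band_hz) -> np.ndarray:
    """Zero-mean unit-variance sum of 3 random sinusoids inside the band."""
    t = np.arange(n_frames) * tr
    freqs = rng.uniform(band_hz[0], band_hz[1], size=3)
    phases = rng.uniform(0.0, 2.0 * np.pi, size=3)
    s = np.sin(2.0 * np.pi * freqs[:, None] * t[None, :] + phases[:, None]).sum(axis=0)
    s -= s.mean()
    sd = s.std()
    if sd < 1e-12:  # pathological phase cancellation; fall back to a single sinusoid
        s = np.sin(2.0 * np.pi * freqs[0] * t)
        s -= s.mean()
        sd = s.std()
    return s / sd


def _place_networks(spec: PhantomSpec, head: BinaryMask, tumor: BinaryMask,
                    rng: np.random.Generator) -> list[BinaryMask]:
    """Non-overlapping ellipsoidal 'functional network' blobs away from the tumor.

    Candidate centres are taken from a regular lattice inside the head
    (shuffled by the phantom RNG) and accepted greedily when the blob lies
    fully inside the head and clear of the lesion and of already placed
    blobs, so placement is deterministic per seed and cannot dither.
    """
    from scipy import ndimage

    grid = spec.grid
    center = np.asarray(spec.shape, float) / 2.0
    semi = np.asarray(spec.network_semiaxes, float)
    avoid = ndimage.binary_dilation(tumor.data, np.ones((3, 3, 3), bool))
    # spacing one voxel beyond the blob diameter keeps neighbouring candidates disjoint
    step = int(np.ceil(2.0 * float(np.max(semi)))) + 1
    offsets = np.arange(-np.max(spec.head_semiaxes), np.max(spec.head_semiaxes) + 1, step)
    candidates = [center + np.array(o) for o in
                  np.stack(np.meshgrid(offsets, offsets, offsets), axis=-1).reshape(-1, 3)]
    rng.shuffle(candidates)
    taken = np.zeros(grid.shape, bool)
    out: list[BinaryMask] = []
    for c in candidates:
        if len(out) == spec.n_networks:
            break
        m = ellipsoid_mask(grid, c, semi)
        if (m.data & ~head.data).any() or (m.data & avoid).any() or (m.data & taken).any():
            continue
        taken |= m.data
        out.append(m)
    if len(out) < spec.n_networks:
        raise SpecError(
            f"could only place {len(out)} of {spec.n_networks} network blobs; "
            "head too small for the requested geometry")
    return out


def generate_phantom(spec: PhantomSpec) -> PhantomOutput:
    """Render the phantom described by ``spec``; bit-identical for equal spec+seed."""
    rng = np.random.default_rng(spec.rng_seed)
    grid = spec.grid
    center = np.asarray(spec.shape, float) / 2.0
    head = ellipsoid_mask(grid, center, spec.head_semiaxes)
    tumor = ellipsoid_mask(grid, spec.tumor_center, spec.tumor_semiaxes)
    networks = _place_networks(spec, head, tumor, rng)

    T = spec.n_frames
    names = ["tumor"] + [f"network_{k}" for k in range(spec.n_networks)] + ["tumor_diff"]
    raw = np.column_stack([
        _band_limited_course(rng, T, spec.tr_seconds, spec.tumor_band_hz)
        for _ in names])
    # orthogonalise the courses so each source carries its nominal variance
    # share (narrow-band random sinusoid sums are otherwise correlated);
    # combinations of in-band sinusoids remain in-band
    q = np.linalg.qr(raw)[0]
    q = q - q.mean(axis=0, keepdims=True)
    q = q / q.std(axis=0, keepdims=True)
    courses: dict[str, np.ndarray] = {n: q[:, i].copy() for i, n in enumerate(names)}

    data = np.zeros(grid.shape + (T,), dtype=float)
    data += spec.baseline * head.data[..., None]
    # two-compartment lesion: common course plus a weak differential course
    g = spec.tumor_heterogeneity
    norm = np.sqrt(1.0 + g * g)
    half_a = tumor.data & (np.arange(grid.shape[0])[:, None, None] < spec.tumor_center[0])
    half_b = tumor.data & ~half_a
    s_a = (courses["tumor"] + g * courses["tumor_diff"]) / norm
    s_b = (courses["tumor"] - g * courses["tumor_diff"]) / norm
    data += spec.tumor_amplitude * (half_a[..., None] * s_a + half_b[..., None] * s_b)
    for k, net in enumerate(networks):
        data += spec.network_amplitude * net.data[..., None] * courses[f"network_{k}"]
    ramp = np.linspace(-0.5, 0.5, T)
    slopes = rng.uniform(-1.0, 1.0, size=grid.shape) * spec.drift_amplitude
    data += (slopes * head.data)[..., None] * ramp
    data += rng.normal(0.0, spec.noise_sd, size=data.shape)

    series = Series4D(grid, data, tr_seconds=spec.tr_seconds)
    return PhantomOutput(series=series, truth_tumor=tumor, truth_networks=networks,
                         truth_time_courses=courses, brain=head, spec=spec)


PRESET_NAMES = ("small_fast", "default", "hard_low_cnr")


def phantom_presets(name: str) -> PhantomSpec:
    """Named study conditions.

    ``small_fast``
        24^3 grid, 120 frames: a full sweep completes in minutes on one CPU.
    ``default``
        32^3 grid, 150 frames: the standard evaluation phantom.
    ``hard_low_cnr``
        like ``default`` but with a lesion amplitude close to the noise floor.
    """
    if name == "small_fast":
        return PhantomSpec(network_semiaxes=(2.0, 2.0, 2.0))
    if name == "default":
        return PhantomSpec(
            shape=(32, 32, 32),
            n_frames=150,
            head_semiaxes=(13.0, 13.0, 13.0),
            tumor_center=(21.0, 18.0, 16.0),
            tumor_semiaxes=(5.0, 4.0, 4.0),
        )
    if name == "hard_low_cnr":
        return PhantomSpec(
            shape=(32, 32, 32),
            n_frames=150,
            head_semiaxes=(13.0, 13.0, 13.0),
            tumor_center=(21.0, 18.0, 16.0),
            tumor_semiaxes=(5.0, 4.0, 4.0),
            tumor_amplitude=1.0,
        )
    raise KeyError(f"unknown phantom preset {name!r}; choose from {PRESET_NAMES}")


def write_phantom(out: PhantomOutput, out_dir) -> dict:
    """Write NIfTI volumes plus JSON/TSV sidecars for a generated phantom."""
    from pathlib import Path

    import pandas as pd

    from .imaging import write_volume

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "bold": out_dir / "bold.nii.gz",
        "truth_tumor": out_dir / "truth_tumor.nii.gz",
        "brain": out_dir / "brain.nii.gz",
        "spec": out_dir / "phantom_spec.json",
        "time_courses": out_dir / "truth_time_courses.tsv",
    }
    write_volume(out.series, paths["bold"])
    write_volume(out.truth_tumor, paths["truth_tumor"])
    write_volume(out.brain, paths["brain"])
    for k, net in enumerate(out.truth_networks):
        p = out_dir / f"truth_network_{k}.nii.gz"
        write_volume(net, p)
        paths[f"truth_network_{k}"] = p
    paths["spec"].write_text(json.dumps(asdict(out.spec), indent=2) + "\n")
    pd.DataFrame(out.truth_time_courses).to_csv(paths["time_courses"], sep="\t", index=False)
    return {k: str(v) for k, v in paths.items()}
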