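"""Synthetic 3D multi-channel niche scenes with known ground truth.

Emulates the two architectures the pipeline must distinguish:

* **fed** (ordered chamber): a dense glial membrane sheet at a shallow
  depth (the "top layer" under the blood-brain barrier), a chequerboard
  of vertical chamber walls descending from it, NSC nuclei (spheres) in a
  band just beneath the sheet, and neuron nuclei in a deeper band.
* **starved** (collapsed): glial sheet, NSCs and neurons all concentrated
  in one shared mid-depth band, with sparse walls and reduced membrane
  amplitude.

Scenes are rendered as clean geometry, optionally Gaussian-blurred, then
corrupted with additive Gaussian noise clipped at zero. Every scene comes
with a :class:`GroundTruth` carrying the true per-role peak depths
(sub-slice argmax of the expected — blurred but noise-free — depth
profile, located by a cubic-spline interpolator independent of the
pipeline's parabolic estimator), true object counts, and
the integrated supra-threshold glial intensity of the clean render at a
stated threshold. Generation is fully deterministic for a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np

from .stack_io import ImageStack, RegionOfInterest

__all__ = [
    "SceneConfig",
    "GroundTruth",
    "generate_scene",
    "fed_preset",
    "starved_preset",
    "intermediate_preset",
]

MIN_SHAPE = (24, 64, 64)
#: wall intensity as a fraction of the sheet (membrane) amplitude
WALL_AMPLITUDE_FRACTION = 0.4
#: spacing of the chequerboard wall grid, pixels
WALL_PITCH = 12


@dataclass
class SceneConfig:
    """Full parameterization of one synthetic niche scene.

    Depths and bands are in slice units and may be fractional; radii in
    voxels (isotropic). ``nsc_centers`` may pin object positions
    explicitly; otherwise ``nsc_count`` centres are drawn uniformly in
    ``nsc_depth_band`` with rejection of overlaps. Amplitudes are
    arbitrary intensity units; ``noise_sd`` is the additive Gaussian
    noise scale and ``blur_sigma`` an isotropic Gaussian blur (0 = none).
    """

    shape: tuple[int, int, int] = (30, 128, 128)
    z_spacing: float = 1.0
    glia_top_depth: float = 8.0
    glia_sheet_thickness: float = 1.2
    chamber_wall_density: float = 0.7
    wall_z_extent: tuple[float, float] | None = None
    nsc_centers: list[tuple[float, float, float]] | None = None
    nsc_count: int = 12
    nsc_depth_band: tuple[float, float] = (11.0, 14.0)
    nsc_radius: float = 4.0
    neuron_depth_band: tuple[float, float] = (16.0, 24.0)
    neuron_count: int = 40
    neuron_radius: float = 3.0
    membrane_amplitude: float = 1.0
    nuclei_amplitude: float = 1.0
    noise_sd: float = 0.05
    blur_sigma: float = 0.7
    trachea: bool = False
    seed: int = 0
    condition: str = "fed"

    def __post_init__(self) -> None:
        nz, ny, nx = self.shape
        if nz < 3 or ny < 1 or nx < 1:
            raise ValueError(f"invalid shape {self.shape}")
        if self.membrane_amplitude <= 0 or self.nuclei_amplitude <= 0:
            raise ValueError("amplitudes must be positive")
        if self.noise_sd < 0 or self.blur_sigma < 0:
            raise ValueError("noise_sd and blur_sigma must be non-negative")
        if not (0.0 <= self.chamber_wall_density <= 1.0):
            raise ValueError("chamber_wall_density must lie in [0, 1]")
        if not (0.0 <= self.glia_top_depth <= nz - 1):
            raise ValueError("glia_top_depth outside stack")
        for name, band in (
            ("nsc_depth_band", self.nsc_depth_band),
            ("neuron_depth_band", self.neuron_depth_band),
        ):
            z0, z1 = band
            if not (0.0 <= z0 <= z1 <= nz - 1):
                raise ValueError(f"{name} {band} outside stack or inverted")
        if self.nsc_centers is not None:
            for c in self.nsc_centers:
                self._check_center(c, self.nsc_radius)

    def _check_center(self, center, radius) -> None:
        nz, ny, nx = self.shape
        z, y, x = center
        if not (
            radius <= z <= nz - 1 - radius
            and radius <= y <= ny - 1 - radius
            and radius <= x <= nx - 1 - radius
        ):
            raise ValueError(f"object at {center} (r={radius}) out of bounds")

    def canonical_roi(self) -> RegionOfInterest:
        """ROI a user would draw: full plane, minus the tracheal margin if present."""
        _, ny, nx = self.shape
        y0 = 10 if self.trachea else 0
        return RegionOfInterest(y0, ny, 0, nx)

    def as_dict(self) -> dict:
        d = asdict(self)
        d["shape"] = list(self.shape)
        return d


@dataclass
class GroundTruth:
    """What the generator actually placed, for verifying the pipeline.

    ``peak_depth`` holds the sub-slice argmax (dense cubic-spline) of each
    role's expected mean-intensity-vs-depth profile — the deterministic
    blurred clean geometry, so noise is the only deviation a measurement
    has to overcome.
    ``glia_suprathreshold_intensity`` is the summed intensity of clean
    (pre-blur, pre-noise) glial voxels at or above ``glia_threshold``.
    """

    peak_depth: dict[str, float]
    nsc_count: int
    neuron_count: int
    nsc_centers: list[tuple[float, float, float]]
    neuron_centers: list[tuple[float, float, float]]
    nsc_radius: float
    neuron_radius: float
    glia_threshold: float
    glia_suprathreshold_intensity: float

    def as_dict(self) -> dict:
        d = asdict(self)
        d["nsc_centers"] = [list(c) for c in self.nsc_centers]
        d["neuron_centers"] = [list(c) for c in self.neuron_centers]
        return d


def _place_spheres(
    rng: np.random.Generator,
    shape: tuple[int, int, int],
    count: int,
    band: tuple[float, float],
    radius: float,
    min_separation: float,
    max_tries: int = 20000,
) -> list[tuple[float, float, float]]:
    """Rejection-sample non-overlapping sphere centres within a depth band.

    Depths follow a triangular density peaked at the band centre, so a
    populated band contributes a unimodal bump — a *peak* — to the depth
    profile rather than the flat plateau uniform placement would give.
    In-plane positions are uniform.
    """
    nz, ny, nx = shape
    zlo = max(band[0], radius)
    zhi = min(band[1], nz - 1 - radius)
    if zhi < zlo:
        raise ValueError(f"depth band {band} too close to stack boundary for r={radius}")
    centers: list[tuple[float, float, float]] = []
    tries = 0
    while len(centers) < count:
        tries += 1
        if tries > max_tries:
            raise ValueError(
                f"could not place {count} non-overlapping spheres of r={radius} "
                f"in band {band}; scene too crowded"
            )
        z = rng.triangular(zlo, 0.5 * (zlo + zhi), zhi) if zhi > zlo else zlo
        y = rng.uniform(radius + 1, ny - 2 - radius)
        x = rng.uniform(radius + 1, nx - 2 - radius)
        ok = all(
            (z - c[0]) ** 2 + (y - c[1]) ** 2 + (x - c[2]) ** 2 >= min_separation**2
            for c in centers
        )
        if ok:
            centers.append((z, y, x))
    return centers


def _render_spheres(
    volume: np.ndarray,
    centers: list[tuple[float, float, float]],
    radius: float,
    amplitude: float,
) -> None:
    """Paint solid spheres (voxel centre inside radius) with np.maximum."""
    nz, ny, nx = volume.shape
    r = radius
    for zc, yc, xc in centers:
        z0, z1 = max(0, math.floor(zc - r)), min(nz, math.ceil(zc + r) + 1)
        y0, y1 = max(0, math.floor(yc - r)), min(ny, math.ceil(yc + r) + 1)
        x0, x1 = max(0, math.floor(xc - r)), min(nx, math.ceil(xc + r) + 1)
        zz, yy, xx = np.ogrid[z0:z1, y0:y1, x0:x1]
        mask = (zz - zc) ** 2 + (yy - yc) ** 2 + (xx - xc) ** 2 <= r**2
        box = volume[z0:z1, y0:y1, x0:x1]
        np.maximum(box, np.where(mask, amplitude, 0.0), out=box)


def _wall_mask(
    rng: np.random.Generator, ny: int, nx: int, density: float
) -> np.ndarray:
    """Chequerboard chamber-wall footprint: a pixel grid thinned to *density*."""
    grid = np.zeros((ny, nx), dtype=bool)
    grid[::WALL_PITCH, :] = True
    grid[:, ::WALL_PITCH] = True
    if density >= 1.0:
        return grid
    keep = rng.random((ny, nx)) < density
    return grid & keep


def _true_peaks(expected: np.ndarray) -> dict[str, float]:
    """Sub-slice argmax of each role's expected (noise-free) depth profile.

    The expected image is the clean geometry after the configured blur —
    deterministic given the placed objects — so its plane-mean profile is
    the true signal the pipeline estimates from the noisy render. The
    continuous peak is located by a dense cubic-spline argmax, an
    interpolator independent of the three-point parabolic estimator.
    """
    from scipy.interpolate import CubicSpline

    nz = expected.shape[0]
    z = np.arange(nz, dtype=float)
    dense = np.arange(0.0, nz - 1 + 1e-9, 1e-3)
    peaks: dict[str, float] = {}
    for role, c in (("glia", 0), ("nsc", 1), ("neuron", 2)):
        profile = expected[..., c].mean(axis=(1, 2))
        spline = CubicSpline(z, profile)
        peaks[role] = float(dense[np.argmax(spline(dense))])
    return peaks


def generate_scene(config: SceneConfig) -> tuple[ImageStack, GroundTruth]:
    """Render one scene and its ground truth. Deterministic for a fixed seed."""
    rng = np.random.default_rng(config.seed)
    nz, ny, nx = config.shape

    nsc_centers = config.nsc_centers
    if nsc_centers is None:
        nsc_centers = _place_spheres(
            rng,
            config.shape,
            config.nsc_count,
            config.nsc_depth_band,
            config.nsc_radius,
            min_separation=2 * config.nsc_radius + 2,
        )
    neuron_centers = _place_spheres(
        rng,
        config.shape,
        config.neuron_count,
        config.neuron_depth_band,
        config.neuron_radius,
        min_separation=2 * config.neuron_radius + 2,
    )

    clean = np.zeros((nz, ny, nx, 3), dtype=np.float64)

    # glial channel: horizontal top sheet (Gaussian z-profile) ...
    zgrid = np.arange(nz, dtype=float)
    sheet = config.membrane_amplitude * np.exp(
        -((zgrid - config.glia_top_depth) ** 2)
        / (2.0 * config.glia_sheet_thickness**2)
    )
    clean[..., 0] = sheet[:, None, None]
    # ... plus vertical chamber walls descending to the bottom of the neuron band
    walls = _wall_mask(rng, ny, nx, config.chamber_wall_density)
    if config.wall_z_extent is not None:
        wz0, wz1 = config.wall_z_extent
    else:
        wz0, wz1 = config.glia_top_depth, config.neuron_depth_band[1]
    wall_slices = (zgrid >= wz0) & (zgrid <= wz1)
    wall_amp = WALL_AMPLITUDE_FRACTION * config.membrane_amplitude
    glia = clean[..., 0]
    glia[wall_slices] = np.maximum(glia[wall_slices], wall_amp * walls[None])

    if config.trachea:
        # bright off-target tube along X near the image edge, to be excluded by ROI
        glia[:, 0:5, :] = np.maximum(glia[:, 0:5, :], 2.0 * config.membrane_amplitude)

    _render_spheres(clean[..., 1], nsc_centers, config.nsc_radius, config.nuclei_amplitude)
    _render_spheres(
        clean[..., 2], neuron_centers, config.neuron_radius, config.nuclei_amplitude
    )

    # the expected image: clean geometry after the configured blur, before noise
    expected = clean
    if config.blur_sigma > 0:
        from scipy.ndimage import gaussian_filter

        expected = np.stack(
            [gaussian_filter(clean[..., c], config.blur_sigma) for c in range(3)],
            axis=-1,
        )

    glia_threshold = 0.5 * wall_amp
    truth = GroundTruth(
        peak_depth=_true_peaks(expected),
        nsc_count=len(nsc_centers),
        neuron_count=len(neuron_centers),
        nsc_centers=[tuple(c) for c in nsc_centers],
        neuron_centers=[tuple(c) for c in neuron_centers],
        nsc_radius=config.nsc_radius,
        neuron_radius=config.neuron_radius,
        glia_threshold=glia_threshold,
        glia_suprathreshold_intensity=float(
            clean[..., 0][clean[..., 0] >= glia_threshold].sum()
        ),
    )

    voxels = expected
    if config.noise_sd > 0:
        voxels = voxels + rng.normal(0.0, config.noise_sd, size=voxels.shape)
    voxels = np.clip(voxels, 0.0, None)

    stack = ImageStack(
        voxels=voxels,
        channel_roles={"glia": 0, "nsc": 1, "neuron": 2},
        z_spacing=config.z_spacing,
        specimen_id=f"sim-{config.condition}-{config.seed}",
        condition=config.condition,
    )
    return stack, truth


def _check_shape(shape: tuple[int, int, int]) -> float:
    nz, ny, nx = shape
    if nz < MIN_SHAPE[0] or ny < MIN_SHAPE[1] or nx < MIN_SHAPE[2]:
        raise ValueError(f"shape {shape} below minimum {MIN_SHAPE}")
    scale = nz / 30.0
    # band centres sit at 8, 12.5 and 20 slices (x scale); neighbouring
    # bands must stay >= 3 slices apart for the peaks to be resolvable
    if min(4.5 * scale, 7.5 * scale) < 3.0:
        raise ValueError(f"shape {shape} too small to separate depth bands by 3 slices")
    return scale


def _area_counts(ny: int, nx: int) -> tuple[int, int]:
    area_ratio = (ny * nx) / (128 * 128)
    return max(4, round(12 * area_ratio)), max(10, round(40 * area_ratio))


def fed_preset(shape: tuple[int, int, int] = (30, 128, 128), seed: int = 0) -> SceneConfig:
    """Ordered-chamber scene: glial sheet shallow, NSCs mid, neurons deep.

    At the default shape the sheet sits at slice 8, the NSC band spans
    slices 11-14 and the neuron band slices 16-24; other shapes scale the
    depths with slice count and the object counts with plane area.
    """
    scale = _check_shape(shape)
    nz, ny, nx = shape
    nsc_count, neuron_count = _area_counts(ny, nx)
    return SceneConfig(
        shape=shape,
        glia_top_depth=8.0 * scale,
        glia_sheet_thickness=1.2,
        chamber_wall_density=0.7,
        nsc_count=nsc_count,
        nsc_depth_band=(11.0 * scale, 14.0 * scale),
        nsc_radius=4.0,
        neuron_depth_band=(16.0 * scale, 24.0 * scale),
        neuron_count=neuron_count,
        neuron_radius=3.0,
        membrane_amplitude=1.0,
        nuclei_amplitude=1.0,
        noise_sd=0.05,
        blur_sigma=0.7,
        seed=seed,
        condition="fed",
    )


def starved_preset(
    shape: tuple[int, int, int] = (30, 128, 128), seed: int = 0
) -> SceneConfig:
    """Collapsed scene: all three signals share one mid-depth band; walls
    sparse and membrane amplitude reduced relative to the fed preset."""
    scale = _check_shape(shape)
    nz, ny, nx = shape
    zc = 12.5 * scale
    nsc_count, neuron_count = _area_counts(ny, nx)
    return SceneConfig(
        shape=shape,
        glia_top_depth=zc,
        glia_sheet_thickness=1.2,
        chamber_wall_density=0.1,
        wall_z_extent=(zc - 2.0, zc + 2.0),
        nsc_count=nsc_count,
        nsc_depth_band=(zc - 1.0, zc + 1.0),
        nsc_radius=4.0,
        neuron_depth_band=(zc - 1.0, zc + 1.0),
        neuron_count=neuron_count,
        neuron_radius=3.0,
        membrane_amplitude=0.45,
        nuclei_amplitude=1.0,
        noise_sd=0.05,
        blur_sigma=0.7,
        seed=seed,
        condition="starved",
    )


def intermediate_preset(
    shape: tuple[int, int, int] = (30, 128, 128), seed: int = 0
) -> SceneConfig:
    """Partially remodelled scene (early reactivation): partial walls,
    intermediate membrane amplitude, NSC and neuron bands closer together."""
    scale = _check_shape(shape)
    nz, ny, nx = shape
    nsc_count, neuron_count = _area_counts(ny, nx)
    return SceneConfig(
        shape=shape,
        glia_top_depth=9.0 * scale,
        glia_sheet_thickness=1.2,
        chamber_wall_density=0.4,
        nsc_count=nsc_count,
        nsc_depth_band=(11.5 * scale, 14.0 * scale),
        nsc_radius=4.0,
        neuron_depth_band=(14.5 * scale, 20.0 * scale),
        neuron_count=neuron_count,
        neuron_radius=3.0,
        membrane_amplitude=0.7,
        nuclei_amplitude=1.0,
        noise_sd=0.05,
        blur_sigma=0.7,
        seed=seed,
        condition="intermediate",
    )
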