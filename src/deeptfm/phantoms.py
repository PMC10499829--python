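"""Synthetic ground-truth fluorescence volumes.

Two generators emulate the statistical structure of the training data used to
drive the forward simulator:

* **bead mixtures** — spheres of radius 1.5 px and 6 px (0.5 μm / 2 μm at the
  reference pixel size) with base intensities drawn from Normal(1, 0.1) and
  small-bead intensities boosted 5×, sparsely and collision-free in the field
  of view;
* **vessel-like volumes** — connected random-walk tubes with radii uniform in
  1–7 px, post-processed with an intensity threshold (a configurable fraction
  of the maximum, standing in for an 8-bit threshold of 190) and normalized to
  unit maximum.

A third operation slices any supplied 3-D stack into axial training
sub-volumes: intensities clipped at a ceiling, a window of fixed depth slid
with a fixed z-stride, and only windows whose mean strictly exceeds a gate
(default: the global mean of the clipped stack) retained.

All generators are pure functions of (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .io import get_logger

__all__ = [
    "ObjectVolume",
    "BeadSpec",
    "PlacementError",
    "generate_beads_volume",
    "generate_vessel_volume",
    "render_tube",
    "extract_training_subvolumes",
]

logger = get_logger(__name__)


class PlacementError(RuntimeError):
    """Raised when beads cannot be placed collision-free in the given shape."""


@dataclass
class ObjectVolume:
    """A non-negative 3-D fluorophore distribution on a voxel grid.

    ``intensity`` is indexed (z, y, x) in arbitrary fluorescence units.
    ``voxel_size`` is (dx, dy, dz) in μm.  ``origin_z`` is the axial position
    of the first plane in μm relative to the tissue surface (negative =
    below the surface).
    """

    intensity: np.ndarray
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin_z: float = 0.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.intensity = np.asarray(self.intensity, dtype=np.float32)
        if self.intensity.ndim != 3:
            raise ValueError("intensity must be a 3-D (z, y, x) array")
        if np.any(self.intensity < 0):
            raise ValueError("intensity must be non-negative everywhere")
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel_size components must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.intensity.shape


@dataclass
class BeadSpec:
    """Bead-mixture parameters (lengths in pixels, intensities dimensionless).

    ``density_small`` / ``density_large`` are beads per 100×100 px² of focal
    area; the defaults put roughly 13 small and 6 large beads in a 256×256
    field of view.  Explicit counts override the densities when given.
    """

    radius_small_px: float = 1.5
    radius_large_px: float = 6.0
    intensity_mean: float = 1.0
    intensity_sd: float = 0.1
    small_bead_gain: float = 5.0
    density_small: float = 2.0
    density_large: float = 1.0
    n_small: int | None = None
    n_large: int | None = None
    seed: int = 0

    def __post_init__(self):
        if self.radius_small_px <= 0 or self.radius_large_px <= 0:
            raise ValueError("bead radii must be positive")
        if self.intensity_sd < 0:
            raise ValueError("intensity_sd must be non-negative")
        if self.small_bead_gain <= 0:
            raise ValueError("small_bead_gain must be positive")
        if self.density_small < 0 or self.density_large < 0:
            raise ValueError("densities must be non-negative")
        for n in (self.n_small, self.n_large):
            if n is not None and n < 0:
                raise ValueError("bead counts must be non-negative")


def _bead_counts(spec: BeadSpec, shape: tuple[int, int, int]) -> tuple[int, int]:
    area = shape[1] * shape[2] / 1e4  # units of 100×100 px²
    n_small = spec.n_small if spec.n_small is not None else int(round(spec.density_small * area))
    n_large = spec.n_large if spec.n_large is not None else int(round(spec.density_large * area))
    return n_small, n_large


def _stamp_sphere(vol: np.ndarray, center: np.ndarray, radius: float, value: float) -> None:
    """Add an anti-aliased sphere: voxel value = linear edge coverage × value.

    Coverage ramps linearly from 1 at distance r−0.5 to 0 at r+0.5, a cheap
    but smooth approximation of the exact voxel/sphere overlap fraction.
    Overlapping structures combine by maximum (fluorophores do not stack in
    these phantoms; beads are non-overlapping anyway).
    """
    lo = np.maximum(np.floor(center - radius - 1).astype(int), 0)
    hi = np.minimum(np.ceil(center + radius + 2).astype(int), vol.shape)
    if np.any(lo >= hi):
        return
    zz, yy, xx = np.meshgrid(
        *(np.arange(lo[i], hi[i]) for i in range(3)), indexing="ij"
    )
    d = np.sqrt(
        (zz - center[0]) ** 2 + (yy - center[1]) ** 2 + (xx - center[2]) ** 2
    )
    cov = np.clip(radius + 0.5 - d, 0.0, 1.0)
    region = vol[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    np.maximum(region, (cov * value).astype(np.float32), out=region)


def generate_beads_volume(
    spec: BeadSpec,
    shape: tuple[int, int, int],
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0),
    max_attempts: int = 10_000,
) -> ObjectVolume:
    """Generate a sparse, collision-free mixture of small and large beads.

    Beads are placed by rejection sampling with centers kept one radius away
    from the lateral faces; axially a bead may be clipped by the volume (the
    imaged sub-volume is a thin slab of a thicker sample).  A pair is
    accepted only if the center distance is at least the sum of radii.  Base
    intensities are drawn from Normal(intensity_mean, intensity_sd)
    truncated at zero, and small-bead intensities are multiplied by
    ``small_bead_gain``.
    """
    shape = tuple(int(s) for s in shape)
    n_small, n_large = _bead_counts(spec, shape)
    rng = np.random.default_rng(spec.seed)
    vol = np.zeros(shape, dtype=np.float32)
    if n_small + n_large == 0:
        return ObjectVolume(vol, voxel_size, meta={"n_small": 0, "n_large": 0})

    # Large beads first: they are the hardest to place.
    wanted = [(spec.radius_large_px, False)] * n_large + [
        (spec.radius_small_px, True)
    ] * n_small
    for radius, _ in wanted:
        if any(2 * radius >= s for s in shape[1:]):
            raise PlacementError(
                f"lateral shape {shape[1:]} cannot contain a bead of radius {radius} px"
            )

    centers: list[np.ndarray] = []
    radii: list[float] = []
    small_flags: list[bool] = []
    for radius, is_small in wanted:
        placed = False
        for _ in range(max_attempts):
            c = np.array(
                [
                    rng.uniform(0, shape[0] - 1),
                    rng.uniform(radius, shape[1] - radius),
                    rng.uniform(radius, shape[2] - radius),
                ],
                dtype=float,
            )
            if all(
                np.linalg.norm(c - c0) >= radius + r0
                for c0, r0 in zip(centers, radii)
            ):
                centers.append(c)
                radii.append(radius)
                small_flags.append(is_small)
                placed = True
                break
        if not placed:
            raise PlacementError(
                f"could not place a bead of radius {radius} px after "
                f"{max_attempts} attempts in shape {shape}"
            )

    base = np.clip(
        rng.normal(spec.intensity_mean, spec.intensity_sd, size=len(centers)),
        0.0,
        None,
    )
    for c, r, is_small, b in zip(centers, radii, small_flags, base):
        value = b * (spec.small_bead_gain if is_small else 1.0)
        _stamp_sphere(vol, c, r, value)

    meta = {
        "n_small": n_small,
        "n_large": n_large,
        "centers": np.array(centers).tolist(),
        "radii": radii,
        "seed": spec.seed,
    }
    return ObjectVolume(vol, voxel_size, meta=meta)


# ---------------------------------------------------------------------------
# Vessels
# ---------------------------------------------------------------------------

def render_tube(
    vol: np.ndarray,
    points: np.ndarray,
    radius: float,
    intensity: float,
) -> None:
    """Rasterize a tube of given radius along a polyline of (z, y, x) points.

    The tube is stamped as overlapping anti-aliased spheres at sub-radius
    spacing, so any straight segment has circular cross-sections of the
    requested radius.
    """
    points = np.asarray(points, dtype=float)
    for a, b in zip(points[:-1], points[1:]):
        seg = b - a
        length = float(np.linalg.norm(seg))
        n_steps = max(int(np.ceil(length / max(radius * 0.4, 0.4))), 1)
        for t in np.linspace(0.0, 1.0, n_steps + 1):
            _stamp_sphere(vol, a + t * seg, radius, intensity)


def generate_vessel_volume(
    radius_range_px: tuple[float, float] = (1.0, 7.0),
    intensity_threshold: float = 190.0 / 255.0,
    shape: tuple[int, int, int] = (64, 128, 128),
    seed: int = 0,
    n_vessels: int | None = None,
    rescale: float = 1.0,
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> ObjectVolume:
    """Grow connected random-walk tubes and apply the vessel post-processing.

    Each vessel is a persistent random walk with a radius sampled uniformly in
    ``radius_range_px`` and an intensity in [0.6, 1], with thin vessels biased
    dim so that thresholding preferentially removes the finest structures.
    After rendering: voxels below ``intensity_threshold`` (a fraction of the
    volume maximum) are zeroed, the volume is optionally rescaled by trilinear
    resampling (``rescale``), and the result is normalized to maximum 1.
    """
    rmin, rmax = radius_range_px
    if not (0 < rmin <= rmax):
        raise ValueError("radius range must satisfy 0 < min <= max")
    if not (0.0 <= intensity_threshold <= 1.0):
        raise ValueError("intensity_threshold is a fraction of max, in [0, 1]")
    shape = tuple(int(s) for s in shape)
    rng = np.random.default_rng(seed)
    if n_vessels is None:
        n_vessels = max(3, int(round(shape[1] * shape[2] / 3000)))

    vol = np.zeros(shape, dtype=np.float32)
    extent = np.array(shape, dtype=float)
    for _ in range(n_vessels):
        radius = rng.uniform(rmin, rmax)
        # dim thin vessels: intensity rises with radius, with random spread
        frac = (radius - rmin) / max(rmax - rmin, 1e-9)
        intensity = np.clip(0.6 + 0.3 * frac + rng.normal(0, 0.08), 0.4, 1.0)
        pos = rng.uniform(0, 1, size=3) * extent
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        step = max(2.0, radius)
        n_steps = int(rng.integers(20, 60))
        pts = [pos.copy()]
        for _ in range(n_steps):
            direction = direction + 0.4 * rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            pos = pos + direction * step
            pos = np.clip(pos, -2 * rmax, extent + 2 * rmax)
            pts.append(pos.copy())
        render_tube(vol, np.array(pts), radius, float(intensity))

    if rescale != 1.0:
        vol = ndimage.zoom(vol, rescale, order=1)
        vol = np.clip(vol, 0.0, None)

    vmax = float(vol.max())
    if vmax > 0 and intensity_threshold > 0:
        # keep only voxels strictly above the threshold
        vol[vol <= intensity_threshold * vmax] = 0.0
        vmax = float(vol.max())
    if vmax > 0:
        vol /= vmax
    return ObjectVolume(
        vol.astype(np.float32),
        voxel_size,
        meta={"seed": seed, "n_vessels": n_vessels, "threshold": intensity_threshold},
    )


# ---------------------------------------------------------------------------
# Training sub-volume extraction
# ---------------------------------------------------------------------------

def extract_training_subvolumes(
    stack: ObjectVolume,
    subvol_depth: int,
    z_stride: int = 5,
    clip_at: float = 20.0,
    mean_gate: float | None = None,
) -> list[ObjectVolume]:
    """Slide an axial window over a stack and keep only "interesting" windows.

    Intensities above ``clip_at`` are clipped to ``clip_at`` (enhancing fine
    structure relative to bright somata).  Windows of ``subvol_depth`` planes
    start every ``z_stride`` planes; a window is kept only when its mean
    intensity strictly exceeds ``mean_gate`` (default: the mean of the whole
    clipped stack).  An empty result is valid and merely logged.
    """
    if z_stride < 1:
        raise ValueError("z_stride must be >= 1")
    depth = stack.shape[0]
    if depth < subvol_depth:
        raise ValueError(
            f"stack depth {depth} is smaller than subvol_depth {subvol_depth}"
        )
    clipped = np.minimum(stack.intensity, np.float32(clip_at))
    gate = float(clipped.mean()) if mean_gate is None else float(mean_gate)
    dz = stack.voxel_size[2]
    out: list[ObjectVolume] = []
    for start in range(0, depth - subvol_depth + 1, z_stride):
        window = clipped[start:start + subvol_depth]
        if float(window.mean()) > gate:
            out.append(
                ObjectVolume(
                    window.copy(),
                    stack.voxel_size,
                    origin_z=stack.origin_z + start * dz,
                    meta={"z_start": start, "clip_at": clip_at, "mean_gate": gate},
                )
            )
    if not out:
        logger.info(
            "no sub-volumes exceeded the mean gate %.4g (depth=%d, stride=%d)",
            gate, subvol_depth, z_stride,
        )
    return out
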