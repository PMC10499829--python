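"""Excitation/emission point-spread functions and binary DMD pattern sets.

The instrument's PSFs are approximated by a separable 3-D Gaussian
(lateral sigma = 0.325 * lambda / (sqrt(2) * NA**0.91), axial
sigma = 0.532 * lambda / sqrt(2) * 1 / (n - sqrt(n^2 - NA^2)) — the standard
Gaussian approximation of a diffraction-limited widefield PSF).  For
two-photon excitation the intensity profile is squared before normalization,
which sharpens the excitation PSF relative to the emission PSF.  Measured PSF
volumes can be substituted via :func:`deeptfm.io.read_stack`; nothing
downstream depends on the Gaussian form.

DMD patterns are binary images on the focal-plane grid.  Generated patterns
are i.i.d. Bernoulli(fill_fraction) per pixel (default 32 patterns at fill
0.5); measured pattern stacks can be loaded from multi-page TIFF and
binarized (Otsu by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import tifffile
from skimage.filters import threshold_otsu

__all__ = [
    "PSFVolume",
    "PatternSet",
    "make_gaussian_psf",
    "gaussian_psf_sigmas",
    "make_random_patterns",
    "load_patterns",
    "save_patterns",
]


@dataclass
class PSFVolume:
    """A non-negative, unit-sum, centered 3-D PSF sampled on a voxel grid."""

    amplitude: np.ndarray  # (z, y, x)
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    kind: str = "emission"

    def __post_init__(self):
        self.amplitude = np.asarray(self.amplitude, dtype=np.float64)
        if self.amplitude.ndim != 3:
            raise ValueError("PSF amplitude must be 3-D (z, y, x)")
        total = float(self.amplitude.sum())
        if not np.isfinite(total) or total <= 0:
            raise ValueError("PSF must have a finite positive total")
        if np.any(self.amplitude < 0):
            raise ValueError("PSF must be non-negative")
        self.amplitude = self.amplitude / total
        center = tuple((s - 1) // 2 for s in self.amplitude.shape)
        if tuple(np.unravel_index(np.argmax(self.amplitude), self.amplitude.shape)) != center:
            raise ValueError("PSF peak must sit at the geometric center voxel")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.amplitude.shape


def gaussian_psf_sigmas(na: float, wavelength_um: float, refractive_index: float) -> tuple[float, float]:
    """Lateral and axial Gaussian sigmas (μm) of the diffraction-limited PSF."""
    if not 0 < na < refractive_index:
        raise ValueError("need 0 < NA < refractive index")
    if wavelength_um <= 0:
        raise ValueError("wavelength must be positive")
    sigma_xy = 0.325 * wavelength_um / (np.sqrt(2.0) * na ** 0.91)
    sigma_z = (
        0.532 * wavelength_um / np.sqrt(2.0)
        / (refractive_index - np.sqrt(refractive_index ** 2 - na ** 2))
    )
    return float(sigma_xy), float(sigma_z)


def make_gaussian_psf(
    na: float,
    wavelength_um: float,
    refractive_index: float,
    shape: tuple[int, int, int],
    voxel_size: tuple[float, float, float],
    kind: str = "emission",
) -> PSFVolume:
    """Separable Gaussian PSF on an odd-sized (z, y, x) grid, unit total.

    ``kind='excitation'`` squares the intensity profile before normalization
    (two-photon excitation is proportional to intensity squared).
    """
    if kind not in ("excitation", "emission"):
        raise ValueError("kind must be 'excitation' or 'emission'")
    shape = tuple(int(s) for s in shape)
    if any(s < 1 or s % 2 == 0 for s in shape):
        raise ValueError("PSF grid sizes must be odd so the peak is centered")
    sigma_xy, sigma_z = gaussian_psf_sigmas(na, wavelength_um, refractive_index)
    dx, dy, dz = voxel_size
    nz, ny, nx = shape
    z = (np.arange(nz) - (nz - 1) // 2) * dz
    y = (np.arange(ny) - (ny - 1) // 2) * dy
    x = (np.arange(nx) - (nx - 1) // 2) * dx
    gz = np.exp(-0.5 * (z / sigma_z) ** 2)
    gy = np.exp(-0.5 * (y / sigma_xy) ** 2)
    gx = np.exp(-0.5 * (x / sigma_xy) ** 2)
    psf = gz[:, None, None] * gy[None, :, None] * gx[None, None, :]
    if kind == "excitation":
        psf = psf ** 2
    return PSFVolume(psf, voxel_size, kind)


# ---------------------------------------------------------------------------
# DMD patterns
# ---------------------------------------------------------------------------

@dataclass
class PatternSet:
    """A stack of T binary DMD patterns on the focal-plane grid."""

    patterns: np.ndarray  # (T, H, W), values in {0, 1}
    fill_fraction: float = 0.5
    source: str | int = 0
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        arr = np.asarray(self.patterns)
        if arr.ndim != 3 or arr.shape[0] < 1:
            raise ValueError("patterns must be a (T, H, W) stack with T >= 1")
        uniques = np.unique(arr)
        if not np.all(np.isin(uniques, (0, 1))):
            raise ValueError("pattern pixels must all be 0 or 1")
        self.patterns = arr.astype(np.uint8)

    @property
    def t_count(self) -> int:
        return self.patterns.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.patterns.shape[1:]


def make_random_patterns(
    t_count: int = 32,
    shape: tuple[int, int] = (256, 256),
    fill_fraction: float = 0.5,
    seed: int = 0,
) -> PatternSet:
    """T independent Bernoulli(fill_fraction) binary patterns, seeded."""
    if not 0 < fill_fraction < 1:
        raise ValueError("fill_fraction must be in (0, 1)")
    if t_count < 1:
        raise ValueError("t_count must be >= 1")
    rng = np.random.default_rng(seed)
    pats = (rng.random((int(t_count), *shape)) < fill_fraction).astype(np.uint8)
    return PatternSet(pats, fill_fraction, source=seed, meta={"seed": seed})


def save_patterns(path, patterns: PatternSet) -> None:
    """Write a pattern stack to multi-page TIFF (uint8 0/1)."""
    tifffile.imwrite(path, patterns.patterns.astype(np.uint8),
                     photometric="minisblack")


def load_patterns(path, threshold: float | str = "otsu") -> PatternSet:
    """Load a measured or saved pattern stack from a multi-page image file.

    Non-binary stacks are binarized at ``threshold`` (a number, or ``'otsu'``
    for Otsu's method on the whole stack).  Every page must be 2-D, share one
    shape, and excite at least one pixel.
    """
    arr = tifffile.imread(path)
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3:
        raise ValueError(f"pattern file must hold 2-D pages, got ndim={arr.ndim}")
    arr = arr.astype(np.float64)
    values = np.unique(arr)
    if not np.all(np.isin(values, (0, 1))):
        thr = threshold_otsu(arr) if threshold == "otsu" else float(threshold)
        arr = (arr > thr).astype(np.uint8)
    else:
        arr = arr.astype(np.uint8)
    for t in range(arr.shape[0]):
        if not arr[t].any():
            raise ValueError(f"pattern page {t} is all zero; a pattern must excite something")
    fill = float(arr.mean())
    return PatternSet(arr, fill, source=str(path))
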