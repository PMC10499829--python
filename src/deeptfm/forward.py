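"""The full forward imaging model and the paired-dataset builder.

A patterned measurement is

    Y_t(x,y,z) = {((exPSF *3D H_t) ∘ X0) *2D sPSF(z)} *3D emPSF
    frame_t    = detect( photons_per_unit * Y_t(:,:,z_focal) )

i.e. the binary DMD pattern is projected through the excitation PSF (each
axial slice of exPSF is 2-D convolved with H_t, so planes away from the focus
see a defocused pattern), multiplied into the object, blurred plane-by-plane
with the scattering PSF at each plane's own depth, blurred with the emission
PSF in 3-D, read out at the focal plane, and finally detected on the EMCCD.
The training target (the point-scanning ground truth) is the noise-free
(exPSF *3D X0) image at the focal plane.

All convolutions are zero-padded FFT convolutions with 'same' output.  The
focal plane defaults to the center plane of the object volume; the sPSF for
plane i is taken at depth z0_focal + (i - i_focal) * dz, so planes deeper
than the focus scatter more than planes above it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.signal import fftconvolve

from . import emccd, io
from .phantoms import ObjectVolume
from .psf import PSFVolume, PatternSet
from .scatter_mc import ScatteringMedium, ScatteringPSFStack, build_spsf_stack

__all__ = [
    "MeasurementStack",
    "patterned_excitation",
    "pstpm_image",
    "simulate_deep_frame",
    "simulate_measurement_stack",
    "build_dataset",
    "spsf_depths_for_object",
]


@dataclass
class MeasurementStack:
    """T patterned detector images paired with the focal-plane ground truth."""

    measurements: np.ndarray          # (T, H, W)
    ground_truth: np.ndarray          # (H, W), >= 0
    focal_plane_index: int
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.measurements = np.asarray(self.measurements, dtype=np.float32)
        self.ground_truth = np.asarray(self.ground_truth, dtype=np.float32)
        if self.measurements.ndim != 3:
            raise ValueError("measurements must be (T, H, W)")
        if self.measurements.shape[1:] != self.ground_truth.shape:
            raise ValueError("measurements and ground truth must share the lateral grid")
        if np.any(self.ground_truth < 0):
            raise ValueError("ground truth must be non-negative")

    @property
    def t_count(self) -> int:
        return self.measurements.shape[0]


def _conv2_same(image: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    return fftconvolve(image, kernel, mode="same")


def patterned_excitation(ex_psf: PSFVolume, pattern: np.ndarray) -> np.ndarray:
    """3-D patterned excitation field on the pattern's lateral grid.

    The binary pattern lives at the focal plane; plane j of the output is the
    2-D convolution of the pattern with axial slice j of the excitation PSF
    (the 3-D convolution of exPSF with the pattern sheet).  Output is
    non-negative, shape (Z_psf, H, W).
    """
    pattern = np.asarray(pattern, dtype=np.float64)
    if pattern.ndim != 2:
        raise ValueError("pattern must be a 2-D image")
    out = np.empty((ex_psf.shape[0], *pattern.shape), dtype=np.float64)
    for j in range(ex_psf.shape[0]):
        out[j] = _conv2_same(pattern, ex_psf.amplitude[j])
    return np.clip(out, 0.0, None)


def _axial_conv_at_plane(volume: np.ndarray, psf: PSFVolume, plane: int) -> np.ndarray:
    """Slice ``plane`` of the 3-D convolution volume *3D psf (same output)."""
    nz = psf.shape[0]
    c = (nz - 1) // 2
    out = np.zeros(volume.shape[1:], dtype=np.float64)
    for j in range(nz):
        src = plane + (j - c)
        if 0 <= src < volume.shape[0]:
            out += _conv2_same(volume[src], psf.amplitude[nz - 1 - j])
    return out


def pstpm_image(obj: ObjectVolume, ex_psf: PSFVolume, focal_plane: int | None = None) -> np.ndarray:
    """Noise-free point-scanning image: (exPSF *3D X0) at the focal plane."""
    vol = np.asarray(obj.intensity, dtype=np.float64)
    if focal_plane is None:
        focal_plane = (vol.shape[0] - 1) // 2
    return np.clip(_axial_conv_at_plane(vol, ex_psf, focal_plane), 0.0, None)


def spsf_depths_for_object(
    obj_nz: int,
    dz: float,
    focal_depth_um: float,
    focal_plane: int | None = None,
) -> np.ndarray:
    """Depth below the surface of every object plane, clipped at 0.

    Plane i sits at focal_depth + (i - i_focal) * dz; planes nominally above
    the surface (shallow objects) are assigned depth 0.
    """
    if focal_plane is None:
        focal_plane = (obj_nz - 1) // 2
    depths = focal_depth_um + (np.arange(obj_nz) - focal_plane) * dz
    return np.clip(depths, 0.0, None)


def simulate_deep_frame(
    obj: ObjectVolume,
    pattern: np.ndarray,
    ex_psf: PSFVolume,
    em_psf: PSFVolume,
    spsf_stack: ScatteringPSFStack | None,
    focal_plane: int | None = None,
    camera: emccd.CameraModel | None = None,
    lut: emccd.EMGainLUT | None = None,
    photons_per_unit: float = 1.0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """One patterned frame: excite, scatter, blur, extract focus, detect.

    ``spsf_stack`` must provide one image per object plane (or None for a
    delta sPSF, i.e. no scattering).  Without a camera the noise-free focal
    image Y_t(:,:,z_focal) is returned in object-intensity units.
    """
    vol = np.asarray(obj.intensity, dtype=np.float64)
    nz = vol.shape[0]
    if pattern.shape != vol.shape[1:]:
        raise ValueError("pattern grid must match the object's lateral grid")
    if ex_psf.shape[0] != nz:
        raise ValueError(
            f"excitation PSF has {ex_psf.shape[0]} planes but the object has {nz}; "
            "extract sub-volumes matching the exPSF axial extent"
        )
    if focal_plane is None:
        focal_plane = (nz - 1) // 2
    if not 0 <= focal_plane < nz:
        raise ValueError("focal plane outside the volume")
    if spsf_stack is not None and len(spsf_stack.images) not in (1, nz):
        raise ValueError("spsf_stack must cover every object plane (or be a single image)")

    excitation = patterned_excitation(ex_psf, pattern)
    excited = excitation * vol
    if spsf_stack is not None:
        scattered = np.empty_like(excited)
        for i in range(nz):
            k = spsf_stack.images[0] if len(spsf_stack.images) == 1 else spsf_stack.images[i]
            scattered[i] = _conv2_same(excited[i], k)
    else:
        scattered = excited
    frame = np.clip(_axial_conv_at_plane(scattered, em_psf, focal_plane), 0.0, None)
    if camera is None:
        return frame
    return emccd.detect(frame * photons_per_unit, camera, lut=lut, rng=rng)


def simulate_measurement_stack(
    obj: ObjectVolume,
    patterns: PatternSet,
    ex_psf: PSFVolume,
    em_psf: PSFVolume,
    spsf_stack: ScatteringPSFStack | None,
    camera: emccd.CameraModel | None = None,
    lut: emccd.EMGainLUT | None = None,
    photons_per_unit: float = 1.0,
    seed: int = 0,
    focal_plane: int | None = None,
) -> MeasurementStack:
    """T patterned frames with independent noise draws, plus the ground truth."""
    nz = obj.shape[0]
    if focal_plane is None:
        focal_plane = (nz - 1) // 2
    frames = []
    for t in range(patterns.t_count):
        rng = np.random.default_rng(io.substream(seed, "detect", t))
        frames.append(
            simulate_deep_frame(
                obj, patterns.patterns[t].astype(np.float64), ex_psf, em_psf,
                spsf_stack, focal_plane, camera, lut, photons_per_unit, rng,
            )
        )
    gt = pstpm_image(obj, ex_psf, focal_plane)
    provenance = {
        "seed": seed,
        "photons_per_unit": photons_per_unit,
        "t_count": patterns.t_count,
        "camera": None if camera is None else {
            "g_em": camera.g_em, "n_stages": camera.n_stages,
            "dark_mean": camera.dark_mean, "read_sigma": camera.read_sigma,
        },
        "spsf_depths": None if spsf_stack is None else np.asarray(spsf_stack.depths).tolist(),
    }
    return MeasurementStack(
        measurements=np.stack(frames),
        ground_truth=gt,
        focal_plane_index=focal_plane,
        provenance=provenance,
    )


# ---------------------------------------------------------------------------
# Dataset builder
# ---------------------------------------------------------------------------

def _normalize_stack(stack: MeasurementStack, percentile: float = 99.9):
    """Per-stack normalization for learning: measurements by their own
    high percentile, ground truth by its maximum.  Factors are returned so
    reconstructions can be mapped back to physical units."""
    m_scale = float(np.percentile(stack.measurements, percentile))
    if m_scale <= 0:
        m_scale = 1.0
    g_scale = float(stack.ground_truth.max())
    if g_scale <= 0:
        g_scale = 1.0
    return (
        stack.measurements / m_scale,
        stack.ground_truth / g_scale,
        m_scale,
        g_scale,
    )


def build_dataset(
    objects: list[ObjectVolume],
    out_dir: str | Path,
    patterns: PatternSet,
    ex_psf: PSFVolume,
    em_psf: PSFVolume,
    spsf_stack: ScatteringPSFStack | None,
    camera: emccd.CameraModel | None,
    lut: emccd.EMGainLUT | None = None,
    photons_per_unit: float = 1.0,
    seed: int = 0,
    split: tuple[int, int] = (4, 1),
    n_test: int = 0,
    depth_sls: float | None = None,
    normalize: bool = True,
) -> Path:
    """Simulate one measurement stack per object and write HDF5 shards.

    The first ``n_test`` objects form a held-out test split; the remainder is
    divided train:val in the given ratio (default 4:1) in object order.
    Returns the path to the manifest JSON, which records every shard, its
    split, its seed, and enough parameters to rebuild the dataset.
    """
    if not objects:
        raise ValueError("need at least one object volume")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    n = len(objects)
    n_trainval = n - n_test
    if n_trainval < 1:
        raise ValueError("n_test leaves no training objects")
    n_val = int(round(n_trainval * split[1] / (split[0] + split[1])))
    n_train = n_trainval - n_val

    shards = []
    for i, obj in enumerate(objects):
        stack_seed = int(io.substream(seed, "stack", i).generate_state(1)[0] & 0x7FFFFFFF)
        stack = simulate_measurement_stack(
            obj, patterns, ex_psf, em_psf, spsf_stack, camera, lut,
            photons_per_unit, seed=stack_seed,
        )
        if normalize:
            meas, gt, m_scale, g_scale = _normalize_stack(stack)
        else:
            meas, gt, m_scale, g_scale = stack.measurements, stack.ground_truth, 1.0, 1.0
        if i < n_test:
            part = "test"
        elif i < n_test + n_train:
            part = "train"
        else:
            part = "val"
        name = f"stack_{i:05d}.h5"
        io.write_h5_stack(
            out_dir / name,
            {"measurements": meas.astype(np.float32), "ground_truth": gt.astype(np.float32)},
            attrs={
                "split": part,
                "seed": stack_seed,
                "m_scale": m_scale,
                "g_scale": g_scale,
                "focal_plane_index": stack.focal_plane_index,
                "depth_sls": -1.0 if depth_sls is None else float(depth_sls),
                "provenance": stack.provenance,
            },
        )
        shards.append({"file": name, "split": part, "seed": stack_seed})

    manifest = {
        "n_objects": n,
        "split_ratio": list(split),
        "n_train": n_train,
        "n_val": n_val,
        "n_test": n_test,
        "t_count": patterns.t_count,
        "depth_sls": depth_sls,
        "photons_per_unit": photons_per_unit,
        "seed": seed,
        "normalize": normalize,
        "shards": shards,
    }
    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2))
    return manifest_path


def load_dataset(manifest_path: str | Path, split: str | None = None):
    """Load (measurements, ground_truth) arrays for one split into memory.

    Returns (X, Y) with X of shape (n, T, H, W) and Y of shape (n, 1, H, W).
    """
    manifest_path = Path(manifest_path)
    manifest = json.loads(manifest_path.read_text())
    root = manifest_path.parent
    xs, ys = [], []
    for shard in manifest["shards"]:
        if split is not None and shard["split"] != split:
            continue
        data, _ = io.read_h5_stack(root / shard["file"])
        xs.append(data["measurements"])
        ys.append(data["ground_truth"][None])
    if not xs:
        return (
            np.zeros((0, manifest["t_count"], 1, 1), np.float32),
            np.zeros((0, 1, 1, 1), np.float32),
        )
    return np.stack(xs).astype(np.float32), np.stack(ys).astype(np.float32)
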