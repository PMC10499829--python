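"""Monte Carlo simulation of the scattering point-spread function (sPSF).

A point emitter sits at depth z0 below the tissue surface (surface = z = 0
plane, tissue at z < 0).  Photons are launched isotropically, propagate by
exponential hops (path length s = -ln(1 - rnd)/mu_s) and Henyey–Greenstein
spins (anisotropy g = mean deflection cosine; uniform azimuth), until they
cross the surface.  A photon whose exit direction lies inside the objective's
acceptance cone (sin(theta) <= NA / n_tissue; no surface refraction is
modeled) is traced straight back along its final direction to the launch
plane and binned at that lateral position: that is where the imaging system,
focused on the launch plane, believes the photon originated.  The normalized
2-D histogram of these apparent origins is the sPSF at depth z0.

The medium has no absorption.  Because an unbounded 3-D random walk is
transient, photons are terminated as lost once they exceed a step cap or
wander deeper than ``z0 + kill_depth_mfp`` mean free paths; both caps sit far
outside the region that can contribute to the within-NA, in-grid sPSF.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import io

__all__ = [
    "ScatteringMedium",
    "ScatteringPSFStack",
    "sample_hop",
    "sample_deflection",
    "spin_direction",
    "simulate_spsf",
    "build_spsf_stack",
    "radial_second_moment",
]


@dataclass(frozen=True)
class ScatteringMedium:
    """Tissue optical parameters: scattering coefficient (1/μm), anisotropy,
    refractive index.  The scattering length (mean free path) is 1/mu_s."""

    mu_s: float = 0.02
    g: float = 0.9
    n_tissue: float = 1.33

    def __post_init__(self):
        if self.mu_s <= 0:
            raise ValueError("mu_s must be positive")
        if not -1 < self.g < 1:
            raise ValueError("anisotropy g must lie in (-1, 1)")
        if self.n_tissue < 1:
            raise ValueError("n_tissue must be >= 1")

    @property
    def scattering_length(self) -> float:
        return 1.0 / self.mu_s


def sample_hop(rnd1, mu_s: float):
    """Exponential hop length s = -ln(1 - rnd1)/mu_s for rnd1 in [0, 1)."""
    rnd1 = np.asarray(rnd1, dtype=float)
    if np.any(rnd1 < 0) or np.any(rnd1 >= 1):
        raise ValueError("rnd1 must lie in [0, 1); rnd1 = 1 gives an infinite hop")
    s = -np.log1p(-rnd1) / mu_s
    return float(s) if s.ndim == 0 else s


def sample_deflection(rnd2, g: float):
    """Henyey–Greenstein deflection cosine from a uniform draw.

    cos(theta) = (1 + g^2 - ((1 - g^2)/(1 - g + 2 g rnd2))^2) / (2 g) for
    g != 0; the g -> 0 limit is the isotropic cos(theta) = 2 rnd2 - 1.
    Results are clamped to [-1, 1] against roundoff.
    """
    rnd2 = np.asarray(rnd2, dtype=float)
    if np.any(rnd2 < 0) or np.any(rnd2 > 1):
        raise ValueError("rnd2 must lie in [0, 1]")
    if abs(g) < 1e-12:
        cos_t = 2.0 * rnd2 - 1.0
    else:
        term = (1.0 - g * g) / (1.0 - g + 2.0 * g * rnd2)
        cos_t = (1.0 + g * g - term * term) / (2.0 * g)
    cos_t = np.clip(cos_t, -1.0, 1.0)
    return float(cos_t) if cos_t.ndim == 0 else cos_t


def spin_direction(u: np.ndarray, cos_theta, psi):
    """Rotate unit direction(s) by deflection theta and azimuth psi.

    Standard photon-transport update; the numerically stable special case is
    used where |u_z| ~ 1.  Accepts a single direction (3,) or a batch (n, 3);
    output is unit length.
    """
    u = np.asarray(u, dtype=float)
    single = u.ndim == 1
    u = np.atleast_2d(u)
    cos_t = np.atleast_1d(np.asarray(cos_theta, dtype=float))
    psi = np.atleast_1d(np.asarray(psi, dtype=float))
    sin_t = np.sqrt(np.clip(1.0 - cos_t * cos_t, 0.0, None))
    cos_p, sin_p = np.cos(psi), np.sin(psi)
    ux, uy, uz = u[:, 0], u[:, 1], u[:, 2]
    out = np.empty_like(u)
    near_pole = np.abs(uz) > 0.99999
    # general case
    denom = np.sqrt(np.clip(1.0 - uz * uz, 1e-30, None))
    out[:, 0] = sin_t * (ux * uz * cos_p - uy * sin_p) / denom + ux * cos_t
    out[:, 1] = sin_t * (uy * uz * cos_p + ux * sin_p) / denom + uy * cos_t
    out[:, 2] = -sin_t * cos_p * denom + uz * cos_t
    # polar special case
    if np.any(near_pole):
        sgn = np.sign(uz[near_pole])
        out[near_pole, 0] = (sin_t * cos_p)[near_pole]
        out[near_pole, 1] = (sin_t * sin_p)[near_pole]
        out[near_pole, 2] = (sgn * cos_t[near_pole])
    out /= np.linalg.norm(out, axis=1, keepdims=True)
    return out[0] if single else out


@dataclass
class ScatteringPSFStack:
    """Per-depth sPSF images (each unit-sum) with bookkeeping."""

    images: np.ndarray  # (D, H, W)
    depths: np.ndarray  # μm
    pixel_size: float
    acceptance: np.ndarray  # accepted / launched per depth
    photons_launched: int
    meta: dict = field(default_factory=dict)

    def image_at(self, depth: float) -> np.ndarray:
        idx = int(np.argmin(np.abs(self.depths - depth)))
        return self.images[idx]

    def save(self, path) -> None:
        io.write_h5_stack(
            path,
            {
                "images": self.images.astype(np.float32),
                "depths": np.asarray(self.depths, dtype=np.float64),
                "acceptance": np.asarray(self.acceptance, dtype=np.float64),
            },
            attrs={
                "pixel_size": self.pixel_size,
                "photons_launched": self.photons_launched,
                **self.meta,
            },
        )

    @classmethod
    def load(cls, path) -> "ScatteringPSFStack":
        data, attrs = io.read_h5_stack(path)
        pixel_size = float(attrs.pop("pixel_size"))
        launched = int(attrs.pop("photons_launched"))
        return cls(
            images=data["images"],
            depths=data["depths"],
            pixel_size=pixel_size,
            acceptance=data["acceptance"],
            photons_launched=launched,
            meta=attrs,
        )


def _isotropic_directions(rng: np.random.Generator, n: int, hemisphere: bool) -> np.ndarray:
    """Isotropic unit vectors; upper hemisphere (u_z > 0) when requested."""
    uz = rng.uniform(0.0 if hemisphere else -1.0, 1.0, n)
    phi = rng.uniform(0.0, 2.0 * np.pi, n)
    r = np.sqrt(np.clip(1.0 - uz * uz, 0.0, None))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), uz])


def simulate_spsf(
    medium: ScatteringMedium,
    z0: float,
    na: float = 1.0,
    n_photons: int = 1_000_000,
    shape: tuple[int, int] = (63, 63),
    pixel_size: float = 1.0,
    seed: int | np.random.SeedSequence = 0,
    launch: str = "hemisphere",
    max_steps: int = 10_000,
    kill_depth_mfp: float = 20.0,
    batch_size: int = 500_000,
) -> tuple[np.ndarray, float]:
    """Simulate one sPSF image at depth ``z0`` (μm).

    Returns the unit-sum (H, W) histogram of apparent photon origins on the
    launch plane, centered on the source, together with the acceptance
    fraction (photons exiting within the NA cone, per photon emitted over the
    full sphere: with ``launch='hemisphere'`` the downward half of the
    emission sphere never returns, so the fraction is halved).

    ``z0 = 0`` is the degenerate no-propagation case: the sPSF is a discrete
    delta at the source pixel.
    """
    if z0 < 0:
        raise ValueError("z0 must be >= 0")
    if n_photons < 1:
        raise ValueError("n_photons must be >= 1")
    if launch not in ("hemisphere", "full"):
        raise ValueError("launch must be 'hemisphere' or 'full'")
    rng = np.random.default_rng(seed)
    H, W = shape
    hist = np.zeros((H, W), dtype=np.float64)
    sin_max = min(na / medium.n_tissue, 1.0)
    cos_min = np.sqrt(1.0 - sin_max * sin_max)
    z_kill = z0 + kill_depth_mfp / medium.mu_s
    n_accepted = 0

    remaining = n_photons
    while remaining > 0:
        n = min(remaining, batch_size)
        remaining -= n
        pos = np.zeros((n, 3))
        pos[:, 2] = -z0
        d = _isotropic_directions(rng, n, hemisphere=(launch == "hemisphere"))
        exit_xy = []
        exit_dir = []
        active = np.arange(n)
        if z0 == 0.0:
            # already at the surface: record the launch directions directly
            up = d[:, 2] > 0
            exit_xy.append(pos[up, :2])
            exit_dir.append(d[up])
            active = active[:0]
        steps = 0
        while active.size and steps < max_steps:
            steps += 1
            s = sample_hop(rng.random(active.size), medium.mu_s)
            dz = d[active, 2]
            z = pos[active, 2]
            # photons that would cross z = 0 on this hop: truncate the hop
            crossing = (dz > 0) & (z + dz * s >= 0.0)
            if np.any(crossing):
                idx = active[crossing]
                t = -pos[idx, 2] / d[idx, 2]
                exit_xy.append(pos[idx, :2] + d[idx, :2] * t[:, None])
                exit_dir.append(d[idx])
            surviving = active[~crossing]
            pos[surviving] += d[surviving] * s[~crossing][:, None]
            # kill strays that are too deep to matter
            alive = pos[surviving, 2] > -z_kill
            surviving = surviving[alive]
            if surviving.size:
                cos_t = sample_deflection(rng.random(surviving.size), medium.g)
                psi = rng.uniform(0.0, 2.0 * np.pi, surviving.size)
                d[surviving] = spin_direction(d[surviving], cos_t, psi)
            active = surviving

        if exit_xy:
            xy = np.concatenate(exit_xy, axis=0)
            dirs = np.concatenate(exit_dir, axis=0)
            uz = dirs[:, 2]
            ok = uz >= cos_min
            xy, dirs, uz = xy[ok], dirs[ok], uz[ok]
            n_accepted += int(ok.sum())
            # straight-line backpropagation to the launch plane
            back = xy - dirs[:, :2] * (z0 / uz)[:, None]
            col = np.round(back[:, 0] / pixel_size).astype(int) + (W - 1) // 2
            row = np.round(back[:, 1] / pixel_size).astype(int) + (H - 1) // 2
            in_grid = (row >= 0) & (row < H) & (col >= 0) & (col < W)
            np.add.at(hist, (row[in_grid], col[in_grid]), 1.0)

    denom = n_photons * (2 if launch == "hemisphere" else 1)
    acceptance = n_accepted / denom
    total = hist.sum()
    if total == 0:
        raise RuntimeError(
            "no photons were accepted into the sPSF histogram; "
            "increase n_photons, the NA, or the grid size"
        )
    return hist / total, acceptance


def build_spsf_stack(
    medium: ScatteringMedium,
    depths,
    na: float = 1.0,
    n_photons: int = 1_000_000,
    shape: tuple[int, int] = (63, 63),
    pixel_size: float = 1.0,
    seed: int = 0,
    **kwargs,
) -> ScatteringPSFStack:
    """One :func:`simulate_spsf` per depth with independent sub-seeds.

    The per-depth sub-seed is a stable function of (seed, depth), so a
    duplicated depth reproduces the identical image.
    """
    depths = np.asarray(sorted(float(d) for d in depths))
    if np.any(depths < 0):
        raise ValueError("depths must be >= 0")
    images = np.empty((len(depths), *shape), dtype=np.float64)
    acceptance = np.empty(len(depths))
    for i, z0 in enumerate(depths):
        sub = io.substream(seed, "spsf", int(round(z0 * 1000)))
        images[i], acceptance[i] = simulate_spsf(
            medium, z0, na, n_photons, shape, pixel_size, seed=sub, **kwargs
        )
    return ScatteringPSFStack(
        images=images,
        depths=depths,
        pixel_size=pixel_size,
        acceptance=acceptance,
        photons_launched=n_photons,
        meta={
            "mu_s": medium.mu_s,
            "g": medium.g,
            "n_tissue": medium.n_tissue,
            "na": na,
            "seed": seed,
        },
    )


def radial_second_moment(image: np.ndarray, pixel_size: float = 1.0) -> float:
    """Mean squared radial distance (μm²) of an sPSF about the grid center."""
    image = np.asarray(image, dtype=float)
    H, W = image.shape
    y = (np.arange(H) - (H - 1) // 2) * pixel_size
    x = (np.arange(W) - (W - 1) // 2) * pixel_size
    r2 = y[:, None] ** 2 + x[None, :] ** 2
    return float((image * r2).sum() / image.sum())
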