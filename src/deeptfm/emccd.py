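"""Stochastic EMCCD detection.

Per pixel the detected signal is

    Y_out = f_EM(Poisson(Y_shot) + Poisson(Y_dark)) + Normal(0, sigma_read)

where f_EM is the electron-multiplication register: N cascaded stages, each
adding Binomial(x, alpha) secondary electrons to its x input electrons.  The
mean gain is g_EM = (1 + alpha)^N and the cascade's excess noise factor is

    F^2 = 2 (g_EM - 1) g_EM^(-(N+1)/N) + 1/g_EM

(-> 2 in the high-gain limit), so the output obeys

    mean  = g_EM (Y_shot + Y_dark)
    var   = g_EM^2 F^2 (Y_shot + Y_dark) + sigma_read^2 .

Simulating the full cascade per pixel is slow, so the output distribution of
f_EM is pre-tabulated for every integer input up to ``lut_max_input`` and
sampled from during detection; larger inputs (rare) fall back to the direct
cascade.  Read noise can drive individual pixels negative; values are left
unclipped so the mean law stays unbiased (a display clip is available).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import io

__all__ = [
    "CameraModel",
    "EMGainLUT",
    "excess_noise_factor",
    "em_cascade_once",
    "em_cascade",
    "build_em_lut",
    "detect",
]


@dataclass(frozen=True)
class CameraModel:
    """EMCCD parameters.  ``alpha`` is derived from (g_em, n_stages) unless
    given, in which case the pair must be consistent to 0.1%."""

    g_em: float = 300.0
    n_stages: int = 512
    alpha: float | None = None
    dark_mean: float = 0.2        # expected dark electrons / pixel / exposure
    read_sigma: float = 60.0      # read-noise standard deviation, electrons
    lut_max_input: int = 200

    def __post_init__(self):
        if self.g_em < 1:
            raise ValueError("g_em must be >= 1")
        if self.n_stages < 1:
            raise ValueError("n_stages must be >= 1")
        if self.dark_mean < 0 or self.read_sigma < 0:
            raise ValueError("dark_mean and read_sigma must be non-negative")
        if self.alpha is None:
            object.__setattr__(
                self, "alpha", self.g_em ** (1.0 / self.n_stages) - 1.0
            )
        else:
            if not 0 <= self.alpha < 1:
                raise ValueError("alpha must lie in [0, 1)")
            implied = (1.0 + self.alpha) ** self.n_stages
            if abs(implied - self.g_em) > 1e-3 * self.g_em:
                raise ValueError(
                    f"(1 + alpha)^N = {implied:.4g} disagrees with g_em = "
                    f"{self.g_em:.4g} by more than 0.1%"
                )


def excess_noise_factor(g_em: float, n_stages: int) -> float:
    """F² of an N-stage EM register with mean gain g_em."""
    if g_em < 1 or n_stages < 1:
        raise ValueError("need g_em >= 1 and n_stages >= 1")
    return float(
        2.0 * (g_em - 1.0) * g_em ** (-(n_stages + 1.0) / n_stages) + 1.0 / g_em
    )


def em_cascade(x_in: np.ndarray, alpha: float, n_stages: int, rng: np.random.Generator) -> np.ndarray:
    """Vectorized EM cascade: each stage adds Binomial(x, alpha) electrons."""
    x = np.asarray(x_in, dtype=np.int64)
    if np.any(x < 0):
        raise ValueError("electron counts must be non-negative")
    x = x.copy()
    for _ in range(n_stages):
        x += rng.binomial(x, alpha)
    return x


def em_cascade_once(x_in: int, alpha: float, n_stages: int, rng: np.random.Generator) -> int:
    """One pixel through the N-stage cascade."""
    return int(em_cascade(np.asarray([x_in]), alpha, n_stages, rng)[0])


@dataclass
class EMGainLUT:
    """Empirical output distributions of f_EM for inputs 0..lut_max_input.

    ``samples[x]`` holds ``n_draws`` draws of f_EM(x).  Rows are built from a
    single-electron cascade pool: electrons traverse the register
    independently, so f_EM(x) is distributed as the sum of x independent
    single-electron outputs, and row x is assembled as sums of x picks from
    the pool (row 0 is identically zero).
    """

    samples: np.ndarray  # (lut_max_input + 1, n_draws) int64
    g_em: float
    alpha: float
    n_stages: int
    meta: dict = field(default_factory=dict)

    @property
    def max_input(self) -> int:
        return self.samples.shape[0] - 1

    @property
    def n_draws(self) -> int:
        return self.samples.shape[1]

    def sample(self, counts: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        """Draw one f_EM output per entry of the integer array ``counts``.

        Inputs above ``max_input`` are pushed through the direct cascade (and
        logged); everything else is a table lookup.
        """
        counts = np.asarray(counts, dtype=np.int64)
        out = np.empty(counts.shape, dtype=np.int64)
        small = counts <= self.max_input
        idx = rng.integers(0, self.n_draws, size=int(small.sum()))
        out[small] = self.samples[counts[small], idx]
        if np.any(~small):
            io.get_logger(__name__).info(
                "%d pixel(s) exceeded lut_max_input=%d; using direct cascade",
                int((~small).sum()), self.max_input,
            )
            out[~small] = em_cascade(counts[~small], self.alpha, self.n_stages, rng)
        return out

    def save(self, path) -> None:
        io.write_h5_stack(
            path,
            {"samples": self.samples},
            attrs={
                "g_em": self.g_em,
                "alpha": self.alpha,
                "n_stages": self.n_stages,
                **self.meta,
            },
        )

    @classmethod
    def load(cls, path) -> "EMGainLUT":
        data, attrs = io.read_h5_stack(path)
        return cls(
            samples=data["samples"].astype(np.int64),
            g_em=float(attrs.pop("g_em")),
            alpha=float(attrs.pop("alpha")),
            n_stages=int(attrs.pop("n_stages")),
            meta=attrs,
        )


def build_em_lut(
    camera: CameraModel,
    n_draws: int = 10_000,
    pool_size: int = 100_000,
    seed: int | np.random.Generator = 0,
) -> EMGainLUT:
    """Tabulate f_EM output distributions for inputs 0..camera.lut_max_input."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pool = em_cascade(
        np.ones(pool_size, dtype=np.int64), camera.alpha, camera.n_stages, rng
    )
    rows = np.zeros((camera.lut_max_input + 1, n_draws), dtype=np.int64)
    for x in range(1, camera.lut_max_input + 1):
        picks = rng.integers(0, pool_size, size=(x, n_draws))
        rows[x] = pool[picks].sum(axis=0)
    return EMGainLUT(
        samples=rows,
        g_em=camera.g_em,
        alpha=float(camera.alpha),
        n_stages=camera.n_stages,
        meta={"n_draws": n_draws, "pool_size": pool_size},
    )


def detect(
    photon_image: np.ndarray,
    camera: CameraModel,
    lut: EMGainLUT | None = None,
    rng: np.random.Generator | int | None = None,
    deterministic: bool = False,
    clip_negative: bool = False,
) -> np.ndarray:
    """Detect an expected-signal-electron image on the simulated EMCCD.

    ``deterministic=True`` replaces every stochastic stage by its mean — the
    output is exactly ``g_em * (photon_image + dark_mean)`` — which is the
    noise-free mode used in forward-model reduction checks.
    """
    img = np.asarray(photon_image, dtype=np.float64)
    if np.any(img < 0):
        raise ValueError("expected photon image must be non-negative")
    if deterministic:
        out = camera.g_em * (img + camera.dark_mean)
        return out.astype(np.float64)
    if rng is None or isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    shot = rng.poisson(img)
    dark = rng.poisson(camera.dark_mean, size=img.shape)
    electrons = shot + dark
    if lut is not None:
        amplified = lut.sample(electrons, rng)
    else:
        amplified = em_cascade(electrons, camera.alpha, camera.n_stages, rng)
    out = amplified + rng.normal(0.0, camera.read_sigma, size=img.shape)
    if clip_negative:
        out = np.clip(out, 0.0, None)
    return out
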