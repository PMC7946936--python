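"""Widefield fluorescence forward model.

A camera frame is modelled as

    M = bin( PSF * (rho . I) )  +  noise,

i.e. the fluorophore density ``rho`` excited by the illumination intensity
``I`` on the fine grid, blurred by the detection PSF, integrated over camera
pixels (sum binning), scaled to photons and corrupted by Poisson shot noise
plus Gaussian read noise.  All stages are deterministic given their seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import signal, special

from .scenes import Scene
from .speckle import SpecklePattern

__all__ = [
    "PSFModel",
    "FrameStack",
    "widefield_psf",
    "acquire_frame",
    "acquire_stack",
    "diffraction_limited",
    "normalize_frames",
]


@dataclass(frozen=True)
class PSFModel:
    """Detection intensity PSF sampled on a grid of pitch dx [nm].

    ``kernel`` is nonnegative and sums to 1.
    """

    kernel: np.ndarray
    dx: float
    na: float
    wavelength_em: float
    model: str = "airy"

    def __post_init__(self):
        k = np.asarray(self.kernel)
        if np.any(k < 0):
            raise ValueError("PSF kernel must be nonnegative")
        if not np.isclose(k.sum(), 1.0, atol=1e-9):
            raise ValueError("PSF kernel must sum to 1")

    @property
    def radius_px(self) -> int:
        return self.kernel.shape[0] // 2

    @property
    def airy_radius(self) -> float:
        """First Airy zero 0.61 lambda / NA [nm]."""
        return 0.61 * self.wavelength_em / self.na


def widefield_psf(
    na: float,
    wavelength_em: float,
    dx: float,
    radius: int | None = None,
    model: str = "airy",
) -> PSFModel:
    """Detection PSF for a widefield objective.

    ``airy``: paraxial intensity PSF (2 J1(v)/v)^2 with
    v = 2 pi NA r / lambda, truncated at ``radius`` pixels (default: 1.5
    Airy-zero radii, which keeps > 97% of the energy) and normalised to
    sum 1.  ``gaussian``: isotropic Gaussian with sigma = 0.21 lambda / NA.
    Requires dx < lambda / (4 NA) so the PSF is Nyquist-sampled.
    """
    if na <= 0:
        raise ValueError("NA must be positive")
    if dx >= wavelength_em / (4 * na):
        raise ValueError(
            f"dx = {dx} nm undersamples the PSF (need dx < lambda/(4 NA) = "
            f"{wavelength_em / (4 * na):.1f} nm)"
        )
    r_airy = 0.61 * wavelength_em / na
    if radius is None:
        radius = int(np.ceil(1.5 * r_airy / dx))
    coords = np.arange(-radius, radius + 1) * dx
    r = np.hypot(coords[None, :], coords[:, None])
    if model == "airy":
        v = 2 * np.pi * na * r / wavelength_em
        with np.errstate(divide="ignore", invalid="ignore"):
            amp = np.where(v > 1e-12, 2 * special.j1(v) / np.where(v > 1e-12, v, 1.0), 1.0)
        kernel = amp**2
    elif model == "gaussian":
        sigma = 0.21 * wavelength_em / na
        kernel = np.exp(-(r**2) / (2 * sigma**2))
    else:
        raise ValueError("model must be 'airy' or 'gaussian'")
    kernel /= kernel.sum()
    return PSFModel(kernel=kernel, dx=dx, na=na, wavelength_em=wavelength_em, model=model)


@dataclass
class FrameStack:
    """A sequence of camera frames with pixel pitch dx_c [nm] and metadata."""

    frames: np.ndarray  # (M, h, w) counts
    dx_c: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        f = np.asarray(self.frames)
        if f.ndim != 3:
            raise ValueError("frames must be a (M, h, w) array")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]


def _bin_sum(img: np.ndarray, b: int) -> np.ndarray:
    if b == 1:
        return img
    h, w = img.shape
    if h % b or w % b:
        raise ValueError(f"image shape {img.shape} not divisible by binning {b}")
    return img.reshape(h // b, b, w // b, b).sum(axis=(1, 3))


def expected_frame(
    scene: Scene,
    pattern: SpecklePattern | np.ndarray,
    psf: PSFModel,
    binning: int = 1,
    photons_scale: float = 1.0,
    background: float = 0.0,
) -> np.ndarray:
    """Noiseless expected camera image bin(PSF * (rho I)) * photons + background."""
    inten = pattern.intensity if isinstance(pattern, SpecklePattern) else np.asarray(pattern)
    if inten.shape != scene.density.shape:
        raise ValueError("illumination grid does not match the scene grid")
    if binning < 1:
        raise ValueError("binning must be >= 1")
    emission = scene.density * inten
    blurred = signal.fftconvolve(emission, psf.kernel, mode="same")
    np.clip(blurred, 0.0, None, out=blurred)  # FFT round-off
    return photons_scale * _bin_sum(blurred, binning) + background


def acquire_frame(
    scene: Scene,
    pattern: SpecklePattern | np.ndarray,
    psf: PSFModel,
    binning: int = 1,
    photons_scale: float = 1.0,
    background: float = 0.0,
    read_sd: float = 0.0,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """One noisy camera frame of the scene under the given illumination.

    Poisson noise acts on the expected photon count (signal + background);
    Gaussian read noise of standard deviation ``read_sd`` is added on top.
    Deterministic given ``seed`` (or an explicit ``rng``).
    """
    expected = expected_frame(scene, pattern, psf, binning, photons_scale, background)
    if rng is None:
        rng = np.random.default_rng(seed)
    noisy = rng.poisson(expected).astype(float)
    if read_sd > 0:
        noisy += rng.normal(0.0, read_sd, size=noisy.shape)
    return noisy


def acquire_stack(
    scene: Scene,
    patterns: Sequence[SpecklePattern | np.ndarray],
    psf: PSFModel,
    binning: int = 1,
    photons_scale: float = 1.0,
    background: float = 0.0,
    read_sd: float = 0.0,
    seed: int | None = None,
) -> FrameStack:
    """Acquire one frame per illumination pattern.

    Per-frame noise generators are spawned from ``seed`` so the stack is
    bit-reproducible and any single frame can be regenerated independently.
    """
    if len(patterns) == 0:
        raise ValueError("need at least one illumination pattern")
    child_seeds = np.random.SeedSequence(seed).spawn(len(patterns))
    frames = []
    pat_meta = []
    for pat, ss in zip(patterns, child_seeds):
        frames.append(
            acquire_frame(
                scene, pat, psf, binning, photons_scale, background, read_sd,
                rng=np.random.default_rng(ss),
            )
        )
        pat_meta.append(getattr(pat, "meta", {}) | {"seed": getattr(pat, "seed", None)}
                        if isinstance(pat, SpecklePattern) else {})
    dx_c = scene.dx_f * binning
    return FrameStack(
        frames=np.stack(frames),
        dx_c=dx_c,
        meta={
            "photons_scale": photons_scale,
            "background": background,
            "read_sd": read_sd,
            "seed": seed,
            "binning": binning,
            "dx_f": scene.dx_f,
            "patterns": pat_meta,
        },
    )


def diffraction_limited(stack: FrameStack) -> np.ndarray:
    """Pixelwise mean over all frames — the widefield (diffraction-limited) image."""
    if stack.n_frames == 0:
        raise ValueError("empty stack")
    return stack.frames.mean(axis=0)


def normalize_frames(
    stack: FrameStack,
    background: float | None = None,
    per_frame: bool = True,
) -> FrameStack:
    """Intensity normalisation: subtract background, divide by the mean.

    ``background`` defaults to the value recorded in the stack metadata.

    ``per_frame=True`` divides each frame by its own mean — appropriate when
    the excitation power fluctuates from frame to frame (the acquisition
    situation the intensity-normalised stacks address).  With a constant
    excitation power, the frame mean of a sparse scene is dominated by how
    the speckle happens to sample the emitters; dividing by it then couples
    the emitters' estimated illuminations (their summed intensity is forced
    constant) and measurably biases joint object/illumination estimates.
    ``per_frame=False`` instead scales the whole stack by its global mean,
    preserving genuine frame-to-frame signal variation.
    """
    if background is None:
        background = float(stack.meta.get("background", 0.0))
    frames = stack.frames.astype(float) - background
    np.clip(frames, 0.0, None, out=frames)
    if per_frame:
        means = frames.mean(axis=(1, 2), keepdims=True)
        if np.any(means == 0):
            raise ValueError("cannot normalise a frame with zero mean")
        frames = frames / means
    else:
        mean = frames.mean()
        if mean == 0:
            raise ValueError("cannot normalise an empty stack")
        frames = frames / mean
    return FrameStack(
        frames=frames, dx_c=stack.dx_c,
        meta=stack.meta | {"normalized": True, "background": 0.0,
                           "per_frame": per_frame},
    )
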