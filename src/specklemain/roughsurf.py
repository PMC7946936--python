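"""Gaussian-correlated random rough surfaces.

The sputtered multilayer's top surface is modelled as a zero-mean Gaussian
random field with a Gaussian autocorrelation exp(-r^2 / C_l^2), parameterised
by the RMS height and the 1/e correlation length C_l measured by AFM.
Surfaces are synthesised spectrally (white noise shaped by the square root
of the Gaussian power spectrum), which implies periodic (wrap-around)
correlation at the map edges.  The RMS is enforced exactly by rescaling;
C_l is met only in distribution (finite-sample error of a few percent at
512^2, larger for small maps).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["HeightMap", "generate_height_map", "surface_statistics"]


@dataclass(frozen=True)
class HeightMap:
    """A square, zero-mean surface height map [nm] on a grid of pitch dx [nm]."""

    heights: np.ndarray
    dx: float
    seed: int | None = None
    target_rms: float | None = None
    target_corr_length: float | None = None

    def __post_init__(self):
        h = np.asarray(self.heights)
        if h.ndim != 2 or h.shape[0] != h.shape[1]:
            raise ValueError("height map must be a square 2-D grid")

    @property
    def n(self) -> int:
        return self.heights.shape[0]

    @property
    def extent(self) -> float:
        return self.n * self.dx


def generate_height_map(
    n: int, dx: float, rms: float, corr_length: float, seed: int | None = None
) -> HeightMap:
    """Generate an n x n Gaussian-correlated surface.

    Parameters
    ----------
    n : grid size in pixels (>= 32).
    dx : pixel pitch [nm].
    rms : target RMS height [nm]; enforced exactly by rescaling.
    corr_length : target 1/e autocorrelation radius C_l [nm]; must exceed
        2*dx so the correlation structure is resolved.
    seed : integer seed; the map is deterministic given the seed.
    """
    if n < 32:
        raise ValueError("n must be >= 32")
    if dx <= 0:
        raise ValueError("dx must be positive")
    if rms < 0:
        raise ValueError("rms must be >= 0")
    if corr_length <= 2 * dx:
        raise ValueError(
            f"corr_length = {corr_length} nm is undersampled at dx = {dx} nm "
            "(need corr_length > 2*dx)"
        )
    if rms == 0:
        return HeightMap(np.zeros((n, n)), dx, seed, 0.0, corr_length)

    rng = np.random.default_rng(seed)
    noise = rng.standard_normal((n, n))
    k = 2 * np.pi * np.fft.fftfreq(n, d=dx)
    k2 = k[:, None] ** 2 + k[None, :] ** 2
    # ACF exp(-r^2/C_l^2)  <->  PSD proportional to exp(-k^2 C_l^2 / 4)
    amplitude = np.exp(-k2 * corr_length**2 / 8.0)
    h = np.fft.ifft2(np.fft.fft2(noise) * amplitude).real
    h -= h.mean()
    std = h.std()
    if std > 0:
        h *= rms / std
    return HeightMap(h, dx, seed, rms, corr_length)


def radial_autocorrelation(map: HeightMap) -> tuple[np.ndarray, np.ndarray]:
    """Radially averaged, normalised autocorrelation of the height map.

    Returns (r [nm], C(r)) with C(0) = 1, computed via the FFT
    (Wiener-Khinchin, periodic boundary) and averaged over rings one pixel
    wide.  Raises for a flat map (autocorrelation undefined).
    """
    h = map.heights - map.heights.mean()
    var = np.mean(h * h)
    if var == 0:
        raise ValueError("autocorrelation undefined for a flat map")
    n = map.n
    acf = np.fft.ifft2(np.abs(np.fft.fft2(h)) ** 2).real / (n * n) / var
    x = np.fft.fftfreq(n, d=1.0 / n) * map.dx  # signed lags [nm]
    rr = np.hypot(x[:, None], x[None, :])
    nbins = n // 2
    idx = np.minimum((rr / map.dx + 0.5).astype(int), nbins)
    sums = np.bincount(idx.ravel(), weights=acf.ravel(), minlength=nbins + 1)
    counts = np.bincount(idx.ravel(), minlength=nbins + 1)
    prof = sums[:nbins] / counts[:nbins]
    r = np.arange(nbins) * map.dx
    return r, prof


def surface_statistics(map: HeightMap) -> tuple[float, float]:
    """Measured (rms [nm], correlation length [nm]) of a height map.

    The RMS is the standard deviation of the heights; the correlation length
    is the radius at which the radially averaged normalised autocorrelation
    first falls below 1/e (linear interpolation between rings).  For a flat
    map returns (0, nan).
    """
    h = np.asarray(map.heights, dtype=float)
    if h.size == 0:
        raise ValueError("empty height map")
    rms = float(h.std())
    if rms == 0:
        return 0.0, float("nan")
    r, prof = radial_autocorrelation(map)
    target = 1.0 / np.e
    below = np.nonzero(prof < target)[0]
    if len(below) == 0 or below[0] == 0:
        return rms, float("nan")
    i = below[0]
    # linear interpolation between ring i-1 and ring i
    f = (prof[i - 1] - target) / (prof[i - 1] - prof[i])
    return rms, float(r[i - 1] + f * (r[i] - r[i - 1]))
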