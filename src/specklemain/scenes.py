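"""Synthetic ground-truth scenes: bead pairs, bead clusters, quantum-dot
fields and filament-like objects on a fine fluorophore-density grid.

A :class:`Scene` stores the nonnegative fluorophore density rho on a square
grid of pitch ``dx_f`` [nm].  Beads (nominal diameter 46 nm) are rendered as
uniform disks with anti-aliased (linear sub-pixel coverage) edges, each
normalised to unit total density so that the imaging photon budget is
specified per bead per frame.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy import ndimage
from scipy.interpolate import CubicSpline

__all__ = [
    "Scene",
    "two_bead_scene",
    "bead_cluster_scene",
    "qdot_scene",
    "filament_scene",
    "FOUR_BEAD_LAYOUT",
]

BEAD_DIAMETER_DEFAULT = 46.0  # nm, Fluoresbrite YG carboxylate beads
DEFAULT_DX_F = 5.0  # nm fine-grid pitch


@dataclass(frozen=True)
class Scene:
    """Fluorophore density map rho >= 0 on a fine grid of pitch dx_f [nm]."""

    density: np.ndarray
    dx_f: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        rho = np.asarray(self.density)
        if rho.ndim != 2:
            raise ValueError("scene density must be a 2-D grid")
        if not np.all(np.isfinite(rho)) or np.any(rho < 0):
            raise ValueError("scene density must be finite and nonnegative")

    @property
    def n(self) -> int:
        return self.density.shape[0]

    @property
    def extent(self) -> float:
        return self.n * self.dx_f


def _grid_coords(n: int, dx: float) -> tuple[np.ndarray, np.ndarray]:
    """Physical coordinates [nm] of pixel centres, origin at the grid centre."""
    c = (np.arange(n) - (n - 1) / 2) * dx
    return c, c


def _render_disk(
    rho: np.ndarray, x: np.ndarray, y: np.ndarray, cx: float, cy: float,
    radius: float, dx: float,
) -> None:
    """Accumulate a unit-integral anti-aliased disk centred at (cx, cy) [nm]."""
    r = np.hypot(x[None, :] - cx, y[:, None] - cy)
    # linear edge coverage over one pixel width
    cover = np.clip((radius - r) / dx + 0.5, 0.0, 1.0)
    total = cover.sum()
    if total == 0:
        raise ValueError("bead lies outside the grid or is smaller than a pixel")
    rho += cover / total


def two_bead_scene(
    separation: float,
    diameter: float = BEAD_DIAMETER_DEFAULT,
    dx_f: float = DEFAULT_DX_F,
    n: int = 256,
) -> Scene:
    """Two beads separated by exactly ``separation`` nm along x, centred.

    Each bead is a uniform disk of the given diameter with unit total
    density.
    """
    if separation <= 0:
        raise ValueError("separation must be positive")
    if separation + diameter >= n * dx_f:
        raise ValueError("separation + diameter exceeds the grid extent")
    x, y = _grid_coords(n, dx_f)
    rho = np.zeros((n, n))
    for cx in (-separation / 2, separation / 2):
        _render_disk(rho, x, y, cx, 0.0, diameter / 2, dx_f)
    return Scene(rho, dx_f, meta={
        "kind": "two_beads", "separation": separation, "diameter": diameter,
        "positions": [(-separation / 2, 0.0), (separation / 2, 0.0)],
    })


#: Default four-bead layout [nm]: minimum pairwise distance exactly 80 nm.
FOUR_BEAD_LAYOUT = ((-40.0, 0.0), (40.0, 0.0), (-10.0, 120.0), (100.0, -90.0))


def bead_cluster_scene(
    positions=None,
    diameter: float = BEAD_DIAMETER_DEFAULT,
    dx_f: float = DEFAULT_DX_F,
    n: int = 256,
) -> Scene:
    """Beads at explicit (x, y) positions [nm] about the grid centre.

    With ``positions=None`` uses the default four-bead layout whose closest
    pair is 80 nm apart.  Overlapping beads are allowed but warned about.
    """
    if positions is None:
        positions = FOUR_BEAD_LAYOUT
    positions = [tuple(map(float, p)) for p in positions]
    if len(positions) < 1:
        raise ValueError("need at least one bead position")
    for (a, b) in combinations(positions, 2):
        if np.hypot(a[0] - b[0], a[1] - b[1]) < diameter:
            warnings.warn("overlapping beads in cluster scene")
            break
    x, y = _grid_coords(n, dx_f)
    rho = np.zeros((n, n))
    for cx, cy in positions:
        _render_disk(rho, x, y, cx, cy, diameter / 2, dx_f)
    return Scene(rho, dx_f, meta={
        "kind": "bead_cluster", "positions": positions, "diameter": diameter,
    })


def qdot_scene(
    density_per_um2: float,
    seed: int | None = None,
    dx_f: float = DEFAULT_DX_F,
    n: int = 256,
    emitter_diameter: float = 10.0,
) -> Scene:
    """Poisson-distributed point emitters (quantum dots) rasterised as small disks.

    The emitter count is Poisson with mean density * area; positions are
    uniform over the grid.  Deterministic given ``seed``.
    """
    if density_per_um2 <= 0:
        raise ValueError("density must be positive")
    rng = np.random.default_rng(seed)
    extent = n * dx_f
    area_um2 = (extent / 1000.0) ** 2
    count = rng.poisson(density_per_um2 * area_um2)
    x, y = _grid_coords(n, dx_f)
    rho = np.zeros((n, n))
    margin = emitter_diameter / 2 + dx_f
    half = extent / 2 - margin
    for _ in range(count):
        cx, cy = rng.uniform(-half, half, size=2)
        _render_disk(rho, x, y, cx, cy, emitter_diameter / 2, dx_f)
    return Scene(rho, dx_f, meta={
        "kind": "qdots", "density_per_um2": density_per_um2,
        "count": int(count), "seed": seed,
    })


def filament_scene(
    seed: int | None = None,
    n_filaments: int = 3,
    width: float = 100.0,
    dx_f: float = DEFAULT_DX_F,
    n: int = 256,
    n_waypoints: int = 5,
) -> Scene:
    """Smooth random curvilinear filaments with a Gaussian cross-section.

    Each filament is a cubic spline through ``n_waypoints`` random waypoints,
    rasterised along its arc and blurred to a FWHM of ``width`` nm.
    Deterministic given ``seed``.
    """
    if n_filaments < 1:
        raise ValueError("need at least one filament")
    rng = np.random.default_rng(seed)
    extent = n * dx_f
    rho = np.zeros((n, n))
    for _ in range(n_filaments):
        pts = rng.uniform(0.1 * extent, 0.9 * extent, size=(n_waypoints, 2))
        t = np.linspace(0, 1, n_waypoints)
        spline = CubicSpline(t, pts)
        dense = spline(np.linspace(0, 1, 50 * n_waypoints))
        ix = np.clip((dense[:, 0] / dx_f).astype(int), 0, n - 1)
        iy = np.clip((dense[:, 1] / dx_f).astype(int), 0, n - 1)
        np.add.at(rho, (iy, ix), 1.0)
    sigma_px = width / 2.355 / dx_f
    rho = ndimage.gaussian_filter(rho, sigma_px)
    rho = np.clip(rho, 0.0, None)
    total = rho.sum()
    if total > 0:
        rho *= n_filaments / total  # unit density per filament
    return Scene(rho, dx_f, meta={
        "kind": "filaments", "n_filaments": n_filaments, "width": width,
        "seed": seed,
    })


def measure_bead_positions(scene: Scene, n_beads: int) -> list[tuple[float, float]]:
    """Centroid positions [nm] of the brightest blobs, for geometry round-trips."""
    rho = scene.density
    labels, nlab = ndimage.label(rho > rho.max() * 0.1)
    if nlab < n_beads:
        raise ValueError(f"found only {nlab} blobs, expected {n_beads}")
    sums = ndimage.sum_labels(rho, labels, index=range(1, nlab + 1))
    order = np.argsort(sums)[::-1][:n_beads]
    cents = ndimage.center_of_mass(rho, labels, index=[i + 1 for i in order])
    n = scene.n
    out = []
    for cy, cx in cents:
        out.append((
            (cx - (n - 1) / 2) * scene.dx_f,
            (cy - (n - 1) / 2) * scene.dx_f,
        ))
    return out
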