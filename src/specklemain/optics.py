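"""Multilayer optics of the hyperbolic-metamaterial (HMM) substrate.

This module covers the plane-wave optics of a stratified Ag/SiO2 stack:

* dispersive material permittivities (a bundled Johnson & Christy 1972
  tabulation for silver; constant refractive indices for dielectrics),
* exact transfer-matrix reflection/transmission of an arbitrary stack,
* effective-medium (EMT) permittivities of a metal/dielectric multilayer,
* the Bloch dispersion of the periodic multilayer and the in-plane
  wavevector bandwidth it supports,
* isofrequency curves (air / EMT / Bloch) and the SIM resolution budget
  f = f_det + f_illum.

Conventions used throughout the package: time dependence e^{-i omega t},
so passive materials have Im(eps) >= 0 and the layer-normal wavevector is
the principal square root with Im(kz) >= 0.  All lengths are nanometres,
spatial frequencies cycles/nm, wavevectors rad/nm.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Literal, Sequence

import numpy as np

__all__ = [
    "OpticalMaterial",
    "LayerStack",
    "UnitCell",
    "IsofrequencyCurve",
    "ResolutionBudget",
    "TmmResult",
    "silver",
    "silica",
    "glass",
    "air",
    "paper_stack",
    "paper_unit_cell",
    "tmm_coefficients",
    "tmm_amplitude",
    "emt_permittivities",
    "bloch_kz",
    "isofrequency_curve",
    "max_k_support",
    "resolution_budget",
]

Polarization = Literal["TE", "TM"]


class OpticalMaterial:
    """A material described either by a constant refractive index or by a
    tabulated complex refractive index (n, k) versus wavelength.

    Tabulated materials are interpolated linearly in wavelength; querying
    outside the table range raises ``ValueError``.
    """

    def __init__(
        self,
        name: str,
        *,
        index: complex | None = None,
        table: tuple[np.ndarray, np.ndarray] | None = None,
    ):
        if (index is None) == (table is None):
            raise ValueError("give exactly one of index= or table=")
        self.name = name
        self._index = index
        if table is not None:
            wl, nk = (np.asarray(table[0], float), np.asarray(table[1], complex))
            if wl.ndim != 1 or wl.shape != nk.shape:
                raise ValueError("table must be two equal-length 1-D arrays")
            if not np.all(np.diff(wl) > 0):
                raise ValueError(f"{name}: table wavelengths must be strictly increasing")
            if np.any(nk.imag < 0):
                raise ValueError(f"{name}: passive material requires k >= 0")
            self._wl, self._nk = wl, nk
        else:
            self._wl = self._nk = None

    @classmethod
    def from_index(cls, name: str, n: complex) -> "OpticalMaterial":
        return cls(name, index=complex(n))

    @classmethod
    def from_nk_table(cls, name: str, wavelength_nm, n, k) -> "OpticalMaterial":
        nk = np.asarray(n, float) + 1j * np.asarray(k, float)
        return cls(name, table=(np.asarray(wavelength_nm, float), nk))

    @classmethod
    def from_csv(cls, name: str, path) -> "OpticalMaterial":
        """Load a whitespace/comma separated (wavelength_nm, n, k) table."""
        rows = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.replace(",", " ").split()
                try:
                    rows.append([float(p) for p in parts])
                except ValueError:
                    continue  # header row
        data = np.asarray(rows, dtype=float)
        if data.ndim != 2 or data.shape[1] < 2:
            raise ValueError(f"cannot parse material table {path}")
        if data.shape[1] == 2:  # (wavelength, n) — lossless
            return cls.from_nk_table(name, data[:, 0], data[:, 1], np.zeros(len(data)))
        return cls.from_nk_table(name, data[:, 0], data[:, 1], data[:, 2])

    def refractive_index(self, wavelength: float) -> complex:
        if self._index is not None:
            if wavelength <= 0:
                raise ValueError("wavelength must be positive")
            return self._index
        wl = float(wavelength)
        if wl < self._wl[0] or wl > self._wl[-1]:
            raise ValueError(
                f"wavelength {wl} nm outside tabulated range "
                f"[{self._wl[0]:.1f}, {self._wl[-1]:.1f}] nm for material {self.name!r}"
            )
        nr = np.interp(wl, self._wl, self._nk.real)
        ni = np.interp(wl, self._wl, self._nk.imag)
        return complex(nr, ni)

    def permittivity(self, wavelength: float) -> complex:
        """Complex relative permittivity eps = (n + ik)^2 at ``wavelength`` [nm]."""
        n = self.refractive_index(wavelength)
        return n * n

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        kind = "const" if self._index is not None else "table"
        return f"OpticalMaterial({self.name!r}, {kind})"


def _load_silver() -> OpticalMaterial:
    ref = resources.files("specklemain.data") / "ag_johnson_christy_1972.csv"
    with resources.as_file(ref) as path:
        return OpticalMaterial.from_csv("Ag (Johnson & Christy 1972)", path)


#: Bundled silver tabulation (Johnson & Christy 1972), the package default.
silver = _load_silver()
#: Sputtered silica modelled with a constant index n = 1.46.
silica = OpticalMaterial.from_index("SiO2", 1.46)
#: Coverslip glass, constant index n = 1.52.
glass = OpticalMaterial.from_index("glass", 1.52)
air = OpticalMaterial.from_index("air", 1.0)
vacuum = air


@dataclass(frozen=True)
class LayerStack:
    """An ordered stack of finite layers between two half spaces.

    ``layers`` runs from the incidence (superstrate) side towards the
    substrate.  Thicknesses are in nm and must be positive and finite.
    """

    layers: Sequence[tuple[OpticalMaterial, float]]
    superstrate: OpticalMaterial = air
    substrate: OpticalMaterial = glass

    def __post_init__(self):
        for mat, d in self.layers:
            if not (np.isfinite(d) and d > 0):
                raise ValueError(f"layer thickness must be positive and finite, got {d}")

    @property
    def total_thickness(self) -> float:
        return float(sum(d for _, d in self.layers))


def paper_stack(
    n_pairs: int = 3,
    d_metal: float = 10.0,
    d_diel: float = 4.0,
    *,
    superstrate: OpticalMaterial = air,
    substrate: OpticalMaterial = glass,
) -> LayerStack:
    """The sputtered HMM: ``n_pairs`` of {Ag ``d_metal`` / SiO2 ``d_diel``} on glass."""
    layers = [(silver, d_metal), (silica, d_diel)] * n_pairs
    return LayerStack(layers=layers, superstrate=superstrate, substrate=substrate)


@dataclass(frozen=True)
class UnitCell:
    """One period of a two-layer (metal/dielectric) multilayer."""

    material_1: OpticalMaterial
    d_1: float
    material_2: OpticalMaterial
    d_2: float

    def __post_init__(self):
        if self.d_1 <= 0 or self.d_2 <= 0:
            raise ValueError("layer thicknesses must be positive")

    @property
    def period(self) -> float:
        return self.d_1 + self.d_2

    @property
    def fill_fraction(self) -> float:
        return self.d_1 / self.period


def paper_unit_cell(period: float = 20.0, fill: float = 0.5) -> UnitCell:
    """Ag/SiO2 unit cell; by default 20 nm period at equal fill (10/10 nm)."""
    if not 0 < fill < 1:
        raise ValueError("fill fraction must lie in (0, 1)")
    return UnitCell(silver, fill * period, silica, (1 - fill) * period)


# ---------------------------------------------------------------------------
# Transfer matrix method
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TmmResult:
    r: complex
    t: complex
    R: float
    T: float
    A: float


def _kz(eps: complex, k0: float, k_parallel: float) -> complex:
    """Layer-normal wavevector, principal branch with Im(kz) >= 0."""
    kz = np.sqrt(complex(eps) * k0 * k0 - k_parallel * k_parallel)
    if kz.imag < 0:
        kz = -kz
    return kz


def _admittance(eps: complex, kz: complex, polarization: Polarization) -> complex:
    # TE fields are tracked by E amplitude (q = kz), TM by H amplitude
    # (q = kz/eps); both give Fresnel r = (q_i - q_j)/(q_i + q_j).
    return kz if polarization == "TE" else kz / eps


def tmm_coefficients(
    stack: LayerStack,
    wavelength: float,
    k_parallel: float = 0.0,
    polarization: Polarization = "TM",
) -> TmmResult:
    """Reflection/transmission of a stratified stack at one plane-wave channel.

    Parameters
    ----------
    wavelength : excitation wavelength [nm].
    k_parallel : in-plane wavevector [rad/nm], real and >= 0.  Must describe a
        propagating wave in the superstrate (k_parallel <= n_sup * k0),
        otherwise the incident power normalisation is undefined.
    polarization : "TE" (s) or "TM" (p).

    Returns
    -------
    TmmResult with the amplitude coefficients r, t (E amplitude for TE,
    H amplitude for TM), power reflectance R, power transmittance T (with the
    substrate/superstrate flux factor applied) and absorbance A = 1 - R - T.
    """
    if polarization not in ("TE", "TM"):
        raise ValueError("polarization must be 'TE' or 'TM'")
    if k_parallel < 0:
        raise ValueError("k_parallel must be >= 0")
    k0 = 2 * np.pi / wavelength
    eps_sup = stack.superstrate.permittivity(wavelength)
    eps_sub = stack.substrate.permittivity(wavelength)
    n_sup = np.sqrt(eps_sup)
    if abs(n_sup.imag) > 1e-12:
        raise ValueError("superstrate must be lossless for power normalisation")
    if k_parallel > n_sup.real * k0 + 1e-12:
        raise ValueError(
            "evanescent incidence in the superstrate: k_parallel exceeds n_sup*k0"
        )

    r, t, q_sup, q_sub = _rt_amplitudes(stack, wavelength, k_parallel, polarization)
    R = float(abs(r) ** 2)
    flux = np.real(q_sub) / np.real(q_sup)
    T = float(abs(t) ** 2 * flux)
    A = 1.0 - R - T
    return TmmResult(r=complex(r), t=complex(t), R=R, T=T, A=float(A))


def _rt_amplitudes(
    stack: LayerStack,
    wavelength: float,
    k_parallel: float,
    polarization: Polarization,
) -> tuple[complex, complex, complex, complex]:
    """Amplitude r, t and the superstrate/substrate admittances of a stack.

    Forward/backward amplitude transfer matrix M = I_01 P_1 I_12 ... I_{N,sub};
    the tracked amplitude is E for TE, H for TM.
    """
    k0 = 2 * np.pi / wavelength
    eps_list = (
        [stack.superstrate.permittivity(wavelength)]
        + [mat.permittivity(wavelength) for mat, _ in stack.layers]
        + [stack.substrate.permittivity(wavelength)]
    )
    kz_list = [_kz(e, k0, k_parallel) for e in eps_list]
    q_list = [_admittance(e, kz, polarization) for e, kz in zip(eps_list, kz_list)]

    def interface(qi: complex, qj: complex) -> np.ndarray:
        rij = (qi - qj) / (qi + qj)
        tij = 2 * qi / (qi + qj)
        return np.array([[1.0, rij], [rij, 1.0]], dtype=complex) / tij

    M = interface(q_list[0], q_list[1])
    for j, (_, d) in enumerate(stack.layers, start=1):
        delta = kz_list[j] * d
        P = np.array(
            [[np.exp(-1j * delta), 0.0], [0.0, np.exp(1j * delta)]], dtype=complex
        )
        M = M @ P @ interface(q_list[j], q_list[j + 1])
    return M[1, 0] / M[0, 0], 1.0 / M[0, 0], q_list[0], q_list[-1]


def tmm_amplitude(
    stack: LayerStack,
    wavelength: float,
    k_parallel: float = 0.0,
    polarization: Polarization = "TM",
) -> complex:
    """Transmission amplitude t of a stack at any real in-plane wavevector.

    Unlike :func:`tmm_coefficients`, no incident-power normalisation is
    attempted, so ``k_parallel`` may exceed the superstrate light line
    (evanescent input channel).  This is the analytic continuation used in
    near-field optics: poles/peaks of |t(k)| beyond k0 mark the guided and
    surface-plasmon resonances of the finite stack.
    """
    if polarization not in ("TE", "TM"):
        raise ValueError("polarization must be 'TE' or 'TM'")
    if k_parallel < 0:
        raise ValueError("k_parallel must be >= 0")
    _, t, _, _ = _rt_amplitudes(stack, wavelength, k_parallel, polarization)
    return complex(t)


# ---------------------------------------------------------------------------
# Effective medium and Bloch dispersion
# ---------------------------------------------------------------------------


def emt_permittivities(
    f: float, eps_m: complex, eps_d: complex, *, tol: float = 1e-12
) -> tuple[complex, complex]:
    """Effective-medium permittivities of a metal/dielectric multilayer.

    ``f`` is the metal fill fraction.  Returns ``(eps_parallel, eps_perp)``:
    the in-plane component f*eps_m + (1-f)*eps_d and the out-of-plane
    component eps_m*eps_d / (f*eps_d + (1-f)*eps_m).
    """
    if not 0 <= f <= 1:
        raise ValueError("fill fraction must lie in [0, 1]")
    eps_m = complex(eps_m)
    eps_d = complex(eps_d)
    eps_par = f * eps_m + (1 - f) * eps_d
    denom = f * eps_d + (1 - f) * eps_m
    if abs(denom) < tol * max(abs(eps_m), abs(eps_d), 1.0):
        raise ZeroDivisionError("singular EMT mixture: f*eps_d + (1-f)*eps_m ~ 0")
    eps_perp = eps_m * eps_d / denom
    return eps_par, eps_perp


def bloch_kz(
    cell: UnitCell,
    wavelength: float,
    k_parallel: float,
    polarization: Polarization = "TM",
) -> complex:
    """Bloch wavevector K of the infinite periodic multilayer.

    Solves cos(K*Lambda) = cos(k1 d1) cos(k2 d2)
                           - (eta + 1/eta)/2 * sin(k1 d1) sin(k2 d2),
    with k_i the layer-normal wavevectors and eta the polarization-dependent
    impedance ratio (TM: eta = eps2 k1 / (eps1 k2); TE: eta = k1/k2).  The
    branch is chosen with Im(K) >= 0 and Re(K)*Lambda in [0, pi].
    """
    k0 = 2 * np.pi / wavelength
    e1 = cell.material_1.permittivity(wavelength)
    e2 = cell.material_2.permittivity(wavelength)
    k1 = _kz(e1, k0, k_parallel)
    k2 = _kz(e2, k0, k_parallel)
    # guard the grazing degeneracy kz -> 0 (eta would be 0/0); the dispersion
    # is continuous there, so a tiny positive kz keeps the limit
    tiny = 1e-9 * k0
    if abs(k1) < tiny:
        k1 = complex(tiny)
    if abs(k2) < tiny:
        k2 = complex(tiny)
    if polarization == "TM":
        eta = (e2 * k1) / (e1 * k2)
    elif polarization == "TE":
        eta = k1 / k2
    else:
        raise ValueError("polarization must be 'TE' or 'TM'")
    c = np.cos(k1 * cell.d_1) * np.cos(k2 * cell.d_2) - 0.5 * (eta + 1.0 / eta) * np.sin(
        k1 * cell.d_1
    ) * np.sin(k2 * cell.d_2)
    K = np.arccos(complex(c)) / cell.period  # principal branch: Re in [0, pi]
    if K.imag < 0:
        K = np.conj(-K) if K.real < 0 else np.conj(K)
        K = K if K.imag >= 0 else -K
    if K.real < 0:
        K = -np.conj(K)
    return complex(K)


@dataclass(frozen=True)
class IsofrequencyCurve:
    model: Literal["air", "EMT", "Bloch"]
    wavelength: float
    kx_over_k0: np.ndarray
    kz_over_k0: np.ndarray


def isofrequency_curve(
    model: Literal["air", "EMT", "Bloch"],
    wavelength: float,
    kx_over_k0: np.ndarray,
    *,
    cell: UnitCell | None = None,
    eps_parallel: complex | None = None,
    eps_perp: complex | None = None,
    polarization: Polarization = "TM",
) -> IsofrequencyCurve:
    """k_z(k_x) at fixed frequency for air, an EMT slab, or a Bloch multilayer.

    Air: k_z = sqrt(k0^2 - k_x^2).  EMT (TM extraordinary wave):
    k_x^2/eps_perp + k_z^2/eps_parallel = k0^2.  Bloch: k_z = bloch_kz.
    All wavevectors normalised to k0 = 2*pi/wavelength.
    """
    kx = np.asarray(kx_over_k0, dtype=float)
    if not np.all(np.isfinite(kx)):
        raise ValueError("k_x grid must be finite")
    k0 = 2 * np.pi / wavelength
    if model == "air":
        kz = np.sqrt((1.0 - kx**2).astype(complex))
    elif model == "EMT":
        if eps_parallel is None or eps_perp is None:
            if cell is None:
                raise ValueError("EMT model needs eps_parallel/eps_perp or a cell")
            eps_parallel, eps_perp = emt_permittivities(
                cell.fill_fraction,
                cell.material_1.permittivity(wavelength),
                cell.material_2.permittivity(wavelength),
            )
        kz = np.sqrt(eps_parallel * (1.0 - kx.astype(complex) ** 2 / eps_perp))
        # forward-propagation branch for plotting: Re(kz) >= 0 (Im >= 0 on
        # the purely evanescent axis)
        flip = (kz.real < 0) | ((kz.real == 0) & (kz.imag < 0))
        kz = np.where(flip, -kz, kz)
    elif model == "Bloch":
        if cell is None:
            raise ValueError("Bloch model needs a unit cell")
        kz = np.array(
            [bloch_kz(cell, wavelength, x * k0, polarization) / k0 for x in kx],
            dtype=complex,
        )
    else:
        raise ValueError(f"unknown model {model!r}")
    return IsofrequencyCurve(model=model, wavelength=wavelength, kx_over_k0=kx, kz_over_k0=kz)


def max_k_support(
    cell: UnitCell,
    wavelength: float,
    attenuation_threshold: float = 1.0,
    *,
    polarization: Polarization = "TM",
    k_step: float = 0.05,
) -> float:
    """Largest in-plane wavevector (units of k0) carried by the multilayer.

    Scans k_parallel/k0 from 0 to pi/(Lambda*k0) in steps of ``k_step`` and
    returns the largest value whose Bloch mode satisfies
    Im(K)*Lambda < attenuation_threshold, i.e. attenuates by less than
    ~1/e per ``1/attenuation_threshold`` periods.  Returns 0 with a warning
    if no scanned wavevector qualifies.
    """
    if attenuation_threshold <= 0:
        raise ValueError("attenuation_threshold must be > 0")
    k0 = 2 * np.pi / wavelength
    k_edge = np.pi / (cell.period * k0)
    grid = np.arange(0.0, k_edge + 1e-12, k_step)
    best = None
    for kx in grid:
        K = bloch_kz(cell, wavelength, kx * k0, polarization)
        if K.imag * cell.period < attenuation_threshold:
            best = kx
    if best is None:
        warnings.warn("no in-plane wavevector satisfies the attenuation criterion")
        return 0.0
    return float(best)


# ---------------------------------------------------------------------------
# SIM resolution budget
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ResolutionBudget:
    """Additive SIM spatial-frequency budget f = f_det + f_illum [cycles/nm]."""

    f_det: float
    f_illum: float

    @property
    def f(self) -> float:
        return self.f_det + self.f_illum

    @property
    def min_resolvable_period(self) -> float:
        if self.f == 0:
            return np.inf
        return 1.0 / self.f

    @property
    def ratio(self) -> float:
        """Resolution-extension factor over detection alone, f / f_det."""
        return self.f / self.f_det


def resolution_budget(
    na_det: float,
    lambda_det: float,
    k_illum_max_over_k0: float,
    lambda_illum: float,
) -> ResolutionBudget:
    """SIM frequency budget from detection NA and illumination k-bandwidth.

    f_det = 2*NA/lambda_det is the incoherent detection cutoff; the
    illumination *intensity* pattern formed by interfering waves of in-plane
    wavevector up to k_max*k0 carries frequencies up to
    f_illum = 2*k_max/lambda_illum.
    """
    if na_det <= 0:
        raise ValueError("detection NA must be positive")
    if k_illum_max_over_k0 < 0:
        raise ValueError("illumination k-bandwidth must be >= 0")
    f_det = 2.0 * na_det / lambda_det
    f_illum = 2.0 * k_illum_max_over_k0 / lambda_illum
    return ResolutionBudget(f_det=f_det, f_illum=f_illum)
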