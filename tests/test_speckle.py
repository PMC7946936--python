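"""Speckle synthesis: incident fields, HMM transfer, propagation, statistics."""

import numpy as np
import pytest

from specklemain import optics as op
from specklemain import speckle as sp
from specklemain.roughsurf import generate_height_map


class TestIncidentField:
    def test_zero_na_is_a_single_normal_wave(self):
        inc = sp.incident_field(488.0, 0.0, 1, seed=0)
        assert inc.kx[0] == 0.0 and inc.ky[0] == 0.0
        f = sp.speckle_field(inc, None, None, n=64, dx=5.0, z=10.0)
        assert np.allclose(np.abs(f), np.abs(f[0, 0]))

    def test_components_stay_inside_the_na_disk(self):
        inc = sp.incident_field(488.0, 0.2, 500, seed=1)
        k0 = 2 * np.pi / 488.0
        assert np.all(np.hypot(inc.kx, inc.ky) <= 0.2 * k0 + 1e-12)

    def test_seed_determinism(self):
        a = sp.incident_field(488.0, 0.2, 50, seed=9)
        b = sp.incident_field(488.0, 0.2, 50, seed=9)
        np.testing.assert_array_equal(a.amplitudes, b.amplitudes)
        np.testing.assert_array_equal(a.kx, b.kx)

    def test_free_space_speckle_is_fully_developed(self):
        """Many-mode free-space speckle has contrast (std/mean) near 1.

        The field of view must span many speckle grains (grain size
        ~ lambda / 2 NA ~ 1.2 um here) for the spatial contrast estimate
        to be meaningful.
        """
        contrasts = []
        for seed in range(10):
            inc = sp.incident_field(488.0, 0.2, 100, seed=seed)
            pat = sp.speckle_pattern(inc, None, None, n=256, dx=40.0, z=0.0)
            contrasts.append(pat.intensity.std() / pat.intensity.mean())
        assert np.mean(contrasts) == pytest.approx(1.0, abs=0.15)

    def test_single_angle_wave_sets_kparallel(self):
        w = sp.single_angle_wave(488.0, 30.0)
        k0 = 2 * np.pi / 488.0
        assert w.kx[0] == pytest.approx(k0 * 0.5)


class TestTransmittedSpectrum:
    def test_flat_surface_single_wave_stays_specular(self, hmm_stack, unit_cell):
        """No roughness: a normal plane wave transmits as one component."""
        flat = generate_height_map(64, 5.0, 0.0, 35.0, seed=0)
        inc = sp.single_angle_wave(488.0, 0.0)
        spec = sp.hmm_transmitted_spectrum(inc, hmm_stack, flat, cell=unit_cell)
        nonzero = np.abs(spec.values) > 1e-14
        assert nonzero.sum() == 1
        field = sp.field_above_surface(spec, 10.0)
        inten = np.abs(field) ** 2
        t0 = op.tmm_amplitude(hmm_stack, 488.0, 0.0, "TM")
        assert np.allclose(inten, abs(t0) ** 2, rtol=1e-6)

    def test_spectral_support_bound(self, hmm_stack, unit_cell, transfer_488):
        """Energy beyond NA k0 + Bloch band + roughness extent is < 1%."""
        rough = generate_height_map(250, 2.0, 1.1, 35.0, seed=2)
        inc = sp.incident_field(488.0, 0.2, 64, seed=5)
        spec = sp.hmm_transmitted_spectrum(
            inc, hmm_stack, rough, cell=unit_cell, transfer=transfer_488
        )
        k0 = spec_k0 = 2 * np.pi / 488.0
        k_band = op.max_k_support(unit_cell, 488.0) * k0
        k_rough = 3 * 2.0 / 35.0  # PSD down to e^-9
        k_lim = 0.2 * k0 + k_band + k_rough
        k_abs = spec.k_abs()
        power = np.abs(spec.values) ** 2
        frac = power[k_abs > k_lim].sum() / power.sum()
        assert frac < 0.01

    def test_roughness_creates_subdiffraction_intensity_content(
        self, hmm_stack, unit_cell, transfer_488
    ):
        """|E|^2 spectrum extends beyond 2 k0 with the HMM, unlike free space."""
        rough = generate_height_map(250, 2.0, 1.1, 35.0, seed=3)
        inc = sp.incident_field(488.0, 0.2, 64, seed=4)
        hmm_pat = sp.speckle_pattern(inc, hmm_stack, rough, transfer=transfer_488)
        free_pat = sp.speckle_pattern(inc, None, None, n=250, dx=2.0, z=10.0)
        f2k0 = 2.0 / 488.0  # intensity frequency of a 2 k0 field pair [cyc/nm]

        def frac_beyond(pat):
            freqs, mtf = sp.radial_mtf(pat, window=True)
            return mtf[freqs > f2k0 * 1.1].sum() / mtf[freqs > 0].sum()

        assert frac_beyond(hmm_pat) > 0.2
        assert frac_beyond(free_pat) < 0.1
        assert frac_beyond(hmm_pat) > 5 * frac_beyond(free_pat)

    def test_free_space_control_respects_the_diffraction_limit(self):
        """Without the HMM, intensity frequencies stay below 2 NA_inc/lambda."""
        inc = sp.incident_field(488.0, 0.2, 100, seed=4)
        pat = sp.speckle_pattern(inc, None, None, n=256, dx=40.0, z=0.0)
        freqs, mtf = sp.radial_mtf(pat, window=True)
        cutoff = 2 * 0.2 / 488.0
        frac = mtf[freqs > cutoff * 1.2].sum() / mtf[freqs > 0].sum()
        assert frac < 0.01

    def test_grid_mismatch_rejected(self, hmm_stack, unit_cell):
        rough = generate_height_map(64, 5.0, 1.1, 35.0, seed=0)
        inc = sp.single_angle_wave(488.0, 0.0)
        with pytest.raises(ValueError, match="grid"):
            sp.hmm_transmitted_spectrum(inc, hmm_stack, rough, n=128, cell=unit_cell)


class TestPropagation:
    def test_z_zero_is_identity(self):
        rng = np.random.default_rng(0)
        values = rng.standard_normal((32, 32)) + 1j * rng.standard_normal((32, 32))
        spec = sp.AngularSpectrum(values=values, dx=5.0, wavelength=488.0)
        f0 = sp.field_above_surface(spec, 0.0)
        np.testing.assert_allclose(f0, spec.to_field(), rtol=1e-12)

    def test_evanescent_decay_closed_form(self):
        """A |k| = 10 k0 component decays by exp(-sqrt(99) k0 z) at z = 10 nm."""
        lam, z = 488.0, 10.0
        k0 = 2 * np.pi / lam
        n, dx = 128, 2.0
        kax = 2 * np.pi * np.fft.fftfreq(n, dx)
        target = 10.0 * k0
        ik = int(np.argmin(np.abs(kax - target)))
        values = np.zeros((n, n), complex)
        values[0, ik] = 1.0
        spec = sp.AngularSpectrum(values=values, dx=dx, wavelength=lam)
        f = sp.field_above_surface(spec, z)
        k_actual = abs(kax[ik])
        expected = np.exp(-np.sqrt(k_actual**2 - k0**2) * z)
        assert np.max(np.abs(f)) == pytest.approx(expected, rel=1e-9)

    def test_intensity_invariant_to_global_phase(self):
        rng = np.random.default_rng(1)
        f = rng.standard_normal((16, 16)) + 1j * rng.standard_normal((16, 16))
        p1 = sp.speckle_intensity(f, 2.0)
        p2 = sp.speckle_intensity(f * np.exp(1j * 0.7), 2.0)
        np.testing.assert_allclose(p1.intensity, p2.intensity, rtol=1e-12)

    def test_all_zero_field_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            sp.speckle_intensity(np.zeros((8, 8), complex), 2.0)


class TestPatternStatistics:
    def test_unit_mean_and_nonnegative(self, hmm_stack, transfer_488):
        rough = generate_height_map(128, 5.0, 1.1, 35.0, seed=6)
        pat = sp.speckle_pattern(
            sp.single_angle_wave(488.0, 0.0), hmm_stack, rough, transfer=transfer_488
        )
        assert pat.intensity.mean() == pytest.approx(1.0, rel=1e-12)
        assert pat.intensity.min() >= 0.0

    def test_bit_identical_reruns(self, hmm_stack, transfer_488):
        rough = generate_height_map(128, 5.0, 1.1, 35.0, seed=6)
        inc = sp.incident_field(488.0, 0.2, 32, seed=8)
        a = sp.speckle_pattern(inc, hmm_stack, rough, transfer=transfer_488)
        b = sp.speckle_pattern(inc, hmm_stack, rough, transfer=transfer_488)
        np.testing.assert_array_equal(a.intensity, b.intensity)

    def test_pattern_changes_with_angle_and_wavelength(self, hmm_stack, unit_cell):
        """Tunability: tilting or re-colouring the beam changes the speckle."""
        rough = generate_height_map(200, 2.5, 1.1, 35.0, seed=7)
        base = sp.speckle_pattern(
            sp.single_angle_wave(500.0, 0.0), hmm_stack, rough, cell=unit_cell
        )
        tilted = sp.speckle_pattern(
            sp.single_angle_wave(500.0, 45.0), hmm_stack, rough, cell=unit_cell
        )
        recoloured = sp.speckle_pattern(
            sp.single_angle_wave(600.0, 0.0), hmm_stack, rough, cell=unit_cell
        )
        assert sp.cross_correlation(base, tilted) < 0.99
        assert sp.cross_correlation(base, recoloured) < 0.99

    def test_radial_mtf_trivials(self):
        uniform = sp.SpecklePattern(np.ones((64, 64)), dx=2.0, z=0.0, wavelength=488.0)
        _, prof = sp.radial_mtf(uniform)
        assert np.allclose(prof, 0.0)

        n, dx, period_px = 64, 2.0, 8
        x = np.arange(n)
        inten = 1.0 + 0.5 * np.cos(2 * np.pi * x / period_px)[None, :] * np.ones((n, 1))
        pat = sp.SpecklePattern(inten / inten.mean(), dx=dx, z=0.0, wavelength=488.0)
        freqs, prof = sp.radial_mtf(pat)
        dominant = freqs[np.argmax(prof)]
        assert dominant == pytest.approx(1.0 / (period_px * dx), rel=1e-6)


class TestCrossCorrelation:
    def test_self_correlation_is_one(self, rng):
        inten = np.clip(1 + rng.standard_normal((32, 32)), 0, None)
        p = sp.SpecklePattern(inten / inten.mean(), dx=2.0, z=0.0, wavelength=488.0)
        assert sp.cross_correlation(p, p) == pytest.approx(1.0)

    def test_independent_patterns_uncorrelated(self, rng):
        a = np.clip(1 + rng.standard_normal((64, 64)), 0, None)
        b = np.clip(1 + rng.standard_normal((64, 64)), 0, None)
        pa = sp.SpecklePattern(a / a.mean(), dx=2.0, z=0.0, wavelength=488.0)
        pb = sp.SpecklePattern(b / b.mean(), dx=2.0, z=0.0, wavelength=488.0)
        assert abs(sp.cross_correlation(pa, pb)) < 0.1

    def test_constant_pattern_rejected(self):
        c = sp.SpecklePattern(np.ones((16, 16)), dx=2.0, z=0.0, wavelength=488.0)
        with pytest.raises(ValueError, match="constant"):
            sp.cross_correlation(c, c)


class TestDecorrelation:
    def test_flat_surface_never_decorrelates(self, hmm_stack, unit_cell):
        """Pure specular transmission: correlation stays 1, sentinel returned."""
        with pytest.warns(UserWarning):
            out = sp.decorrelation_angle(
                hmm_stack, 488.0, rms=0.0, n=64, dx=5.0, cell=unit_cell,
                n_seeds=1, max_angle=5.0,
            )
        assert np.isnan(out)

    def test_monotone_decay_and_crossing_scale(self, hmm_stack, transfer_488):
        """Correlation decays monotonically with angle on a reduced grid."""
        rough = generate_height_map(250, 4.0, 1.1, 35.0, seed=0)
        ref = sp.speckle_pattern(
            sp.single_angle_wave(488.0, 0.0), hmm_stack, rough, transfer=transfer_488
        )
        corr = [
            sp.cross_correlation(
                ref,
                sp.speckle_pattern(
                    sp.single_angle_wave(488.0, th), hmm_stack, rough,
                    transfer=transfer_488,
                ),
            )
            for th in (2.0, 6.0, 10.0, 14.0, 18.0)
        ]
        assert all(np.diff(corr) < 0.02), corr
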