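"""Multilayer optics: materials, transfer matrix, EMT, Bloch dispersion."""

import numpy as np
import pytest

from specklemain import optics as op


class TestMaterials:
    def test_constant_index_squares_to_permittivity(self):
        assert op.silica.permittivity(488.0) == pytest.approx(1.46**2)
        assert op.silica.permittivity(633.0) == pytest.approx(2.1316)

    def test_vacuum_identity(self):
        assert op.vacuum.permittivity(500.0) == pytest.approx(1.0 + 0.0j)

    def test_silver_visible_is_a_lossy_metal(self):
        eps = op.silver.permittivity(488.0)
        assert eps.real < -5.0
        assert eps.imag > 0.0

    def test_table_out_of_range_names_material(self):
        with pytest.raises(ValueError, match="Johnson"):
            op.silver.permittivity(50.0)

    def test_table_wavelengths_must_increase(self):
        with pytest.raises(ValueError, match="increasing"):
            op.OpticalMaterial.from_nk_table("bad", [500.0, 400.0], [1, 1], [0, 0])

    def test_passive_requires_nonnegative_k(self):
        with pytest.raises(ValueError, match="passive"):
            op.OpticalMaterial.from_nk_table("gainy", [400.0, 500.0], [1, 1], [0, -0.1])


class TestTmm:
    def test_empty_stack_is_transparent(self):
        st = op.LayerStack(layers=[], superstrate=op.air, substrate=op.air)
        res = op.tmm_coefficients(st, 488.0, 0.0, "TM")
        assert res.r == pytest.approx(0.0, abs=1e-14)
        assert res.t == pytest.approx(1.0, abs=1e-14)
        assert res.T == pytest.approx(1.0, abs=1e-14)

    @pytest.mark.parametrize("pol", ["TE", "TM"])
    @pytest.mark.parametrize("sin_theta", [0.0, 0.3, 0.7])
    def test_single_interface_matches_fresnel(self, pol, sin_theta):
        """Air/glass interface against the analytic Fresnel formulas."""
        n2 = 1.5
        st = op.LayerStack(
            layers=[], superstrate=op.air,
            substrate=op.OpticalMaterial.from_index("glass15", n2),
        )
        lam = 500.0
        k0 = 2 * np.pi / lam
        kpar = sin_theta * k0
        cos1 = np.sqrt(1 - sin_theta**2)
        cos2 = np.sqrt(1 - (sin_theta / n2) ** 2)
        if pol == "TE":
            r_fresnel = (cos1 - n2 * cos2) / (cos1 + n2 * cos2)
        else:
            r_fresnel = (n2 * cos1 - cos2) / (n2 * cos1 + cos2)
        res = op.tmm_coefficients(st, lam, kpar, pol)
        assert res.R == pytest.approx(r_fresnel**2, abs=1e-12)
        assert res.T == pytest.approx(1 - r_fresnel**2, abs=1e-12)

    def test_normal_incidence_air_glass_reflectance(self):
        st = op.LayerStack(
            layers=[], superstrate=op.air,
            substrate=op.OpticalMaterial.from_index("glass15", 1.5),
        )
        assert op.tmm_coefficients(st, 488.0).R == pytest.approx(0.04, abs=1e-12)

    @pytest.mark.parametrize("lam", [405.0, 488.0, 532.0, 633.0])
    @pytest.mark.parametrize("pol", ["TE", "TM"])
    def test_energy_conservation_lossy_stack(self, lam, pol):
        st = op.paper_stack()
        for sin_t in (0.0, 0.4, 0.8):
            res = op.tmm_coefficients(st, lam, sin_t * 2 * np.pi / lam, pol)
            assert res.R + res.T + res.A == pytest.approx(1.0, abs=1e-12)
            assert res.A >= 0.0

    def test_lossless_stack_absorbs_nothing(self):
        mgf2 = op.OpticalMaterial.from_index("MgF2", 1.38)
        st = op.LayerStack(layers=[(mgf2, 120.0), (op.silica, 80.0)],
                           superstrate=op.air, substrate=op.glass)
        res = op.tmm_coefficients(st, 550.0, 0.3 * 2 * np.pi / 550.0, "TE")
        assert res.A == pytest.approx(0.0, abs=1e-10)

    @pytest.mark.parametrize("pol", ["TE", "TM"])
    def test_transmittance_reciprocity(self, pol):
        """T is unchanged when the stack is traversed in reverse."""
        fwd = op.paper_stack()
        rev = op.LayerStack(layers=list(reversed(fwd.layers)),
                            superstrate=fwd.substrate, substrate=fwd.superstrate)
        lam, sin_t = 488.0, 0.5
        kpar = sin_t * 2 * np.pi / lam
        T1 = op.tmm_coefficients(fwd, lam, kpar, pol).T
        T2 = op.tmm_coefficients(rev, lam, kpar, pol).T
        assert T1 == pytest.approx(T2, rel=1e-10)

    def test_evanescent_superstrate_incidence_rejected(self):
        st = op.paper_stack()
        with pytest.raises(ValueError, match="evanescent"):
            op.tmm_coefficients(st, 488.0, 1.5 * 2 * np.pi / 488.0)

    def test_paper_stack_transmission_matches_measured_values(self):
        """3 pairs {10 nm Ag / 4 nm SiO2} on glass: ~15% at 488, ~30% at 405."""
        st = op.paper_stack()
        assert op.tmm_coefficients(st, 488.0).T == pytest.approx(0.15, abs=0.08)
        assert op.tmm_coefficients(st, 405.0).T == pytest.approx(0.30, abs=0.08)

    def test_amplitude_variant_matches_tmm_in_propagating_range(self):
        st = op.paper_stack()
        lam, kpar = 488.0, 0.6 * 2 * np.pi / 488.0
        t1 = op.tmm_coefficients(st, lam, kpar, "TM").t
        t2 = op.tmm_amplitude(st, lam, kpar, "TM")
        assert t1 == pytest.approx(t2, rel=1e-12)


class TestEmt:
    def test_pure_phase_limits(self):
        eps_m, eps_d = -9.0 + 0.3j, 2.1316
        par, perp = op.emt_permittivities(0.0, eps_m, eps_d)
        assert par == pytest.approx(eps_d) and perp == pytest.approx(eps_d)
        par, perp = op.emt_permittivities(1.0, eps_m, eps_d)
        assert par == pytest.approx(eps_m) and perp == pytest.approx(eps_m)

    def test_agsio2_mixture_is_hyperbolic(self):
        eps_m = op.silver.permittivity(488.0)
        eps_d = op.silica.permittivity(488.0)
        e_par, e_perp = op.emt_permittivities(10 / 14, eps_m, eps_d)
        assert e_par.real < 0 < e_perp.real

    def test_singular_mixture_raises(self):
        with pytest.raises(ZeroDivisionError):
            op.emt_permittivities(0.5, -2.0 + 0j, 2.0 + 0j)


class TestBloch:
    def test_homogeneous_limit_exact(self):
        diel = op.OpticalMaterial.from_index("n2", 2.0)
        cell = op.UnitCell(diel, 7.0, diel, 13.0)
        lam = 500.0
        K = op.bloch_kz(cell, lam, 0.0, "TM")
        assert K == pytest.approx(2.0 * 2 * np.pi / lam, rel=1e-12)

    @pytest.mark.parametrize("kx_over_k0", [0.5, 1.5])
    def test_converges_to_emt_as_period_shrinks(self, kx_over_k0):
        """Bloch kz approaches the EMT extraordinary-wave kz as period -> 0."""
        lam = 488.0
        k0 = 2 * np.pi / lam
        kpar = kx_over_k0 * k0
        eps_m = op.silver.permittivity(lam)
        eps_d = op.silica.permittivity(lam)
        e_par, e_perp = op.emt_permittivities(0.5, eps_m, eps_d)
        kz_emt = np.sqrt(e_par * (k0**2 - kpar**2 / e_perp))
        if kz_emt.imag < 0:
            kz_emt = -kz_emt
        errors = []
        for j in range(1, 7):
            period = 20.0 / 2**j
            cell = op.paper_unit_cell(period, 0.5)
            errors.append(abs(op.bloch_kz(cell, lam, kpar, "TM") - kz_emt))
        assert all(np.diff(errors) < 0), errors
        assert errors[-1] < 0.02 * abs(kz_emt)

    def test_band_reaches_ten_k0_at_488(self, unit_cell):
        kmax = op.max_k_support(unit_cell, 488.0)
        assert 8.0 <= kmax <= 12.0

    def test_air_cell_supports_only_the_light_cone(self):
        # thick enough that one period's 1/e attenuation sits at the light line
        aircell = op.UnitCell(op.air, 100.0, op.air, 100.0)
        kmax = op.max_k_support(aircell, 488.0)
        assert kmax == pytest.approx(1.0, abs=0.08)

    def test_bandwidth_shrinks_with_period(self):
        lam = 488.0
        kmaxes = [op.max_k_support(op.paper_unit_cell(p, 0.5), lam)
                  for p in (14.0, 20.0, 28.0, 40.0)]
        assert all(np.diff(kmaxes) <= 0), kmaxes

    def test_no_supported_mode_warns_and_returns_zero(self):
        cell = op.paper_unit_cell()
        with pytest.warns(UserWarning):
            assert op.max_k_support(cell, 488.0, attenuation_threshold=1e-9) == 0.0


class TestIsofrequency:
    def test_air_circle(self):
        curve = op.isofrequency_curve("air", 488.0, np.array([0.0, 0.6, 1.0]))
        assert curve.kz_over_k0[0] == pytest.approx(1.0)
        assert curve.kz_over_k0[1] == pytest.approx(0.8)
        assert abs(curve.kz_over_k0[2]) == pytest.approx(0.0, abs=1e-12)

    def test_hyperbolic_emt_branch_opens(self):
        """With eps_par < 0 < eps_perp, Re(kz) grows with kx."""
        kx = np.linspace(0.0, 6.0, 25)
        eps_perp = 5.6 + 0.1j
        curve = op.isofrequency_curve(
            "EMT", 488.0, kx, eps_parallel=-3.5 + 0.15j, eps_perp=eps_perp
        )
        rez = curve.kz_over_k0.real
        band = kx > np.sqrt(eps_perp.real) + 0.2  # beyond the cutoff kx = sqrt(eps_perp)
        assert np.all(np.diff(rez[band]) > 0)
        assert rez[band][-1] > 2.0  # far exceeds the free-space circle

    def test_bloch_curve_uses_cell_dispersion(self, unit_cell):
        kx = np.array([0.0, 5.0])
        curve = op.isofrequency_curve("Bloch", 488.0, kx, cell=unit_cell)
        k0 = 2 * np.pi / 488.0
        expected = op.bloch_kz(unit_cell, 488.0, 5.0 * k0, "TM") / k0
        assert curve.kz_over_k0[1] == pytest.approx(expected)


class TestResolutionBudget:
    def test_widefield_limit(self):
        b = op.resolution_budget(1.5, 520.0, 0.0, 488.0)
        assert b.f == b.f_det
        assert b.ratio == pytest.approx(1.0)

    def test_traditional_sim_doubles_resolution(self):
        """f_illum = f_det gives exactly a factor-2 extension."""
        na, lam = 1.5, 520.0
        f_det = 2 * na / lam
        k_equiv = f_det * 488.0 / 2  # illumination bandwidth matching f_det
        b = op.resolution_budget(na, lam, k_equiv, 488.0)
        assert b.ratio == pytest.approx(2.0, rel=1e-12)

    def test_hmm_budget_hand_computed(self):
        """NA 1.5 / 520 nm detection plus 10 k0 illumination at 488 nm."""
        b = op.resolution_budget(1.5, 520.0, 10.0, 488.0)
        assert b.f_det == pytest.approx(2 * 1.5 / 520.0)
        assert b.f_illum == pytest.approx(20.0 / 488.0)
        assert b.f == pytest.approx(2 * 1.5 / 520.0 + 20.0 / 488.0)
        assert b.min_resolvable_period == pytest.approx(1.0 / b.f)

    def test_additive_and_homogeneous(self):
        b1 = op.resolution_budget(1.0, 500.0, 3.0, 500.0)
        b2 = op.resolution_budget(2.0, 500.0, 6.0, 500.0)
        assert b2.f == pytest.approx(2 * b1.f)
        assert b1.f >= max(b1.f_det, b1.f_illum)
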