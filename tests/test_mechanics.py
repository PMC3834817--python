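"""Continuum-mechanics primitives against closed forms and brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from visemech import mechanics as M
from visemech.params import MechParams, ParameterError

from .oracles import (discretized_buckling_force, discretized_elastica_energy,
                      discretized_teardrop_ratio)


class TestBuckling:
    def test_nine_piconewton_buckling_length(self, params):
        """The ~9 pN A-T base-pairing force buckles dsDNA at 14.5 nm (42.5 bp)."""
        h = M.buckling_length(9.0, params)
        assert h == pytest.approx(14.5, abs=0.1)
        assert M.buckling_length_bp(9.0, params) == pytest.approx(42.5, abs=0.3)
        assert M.buckling_force(14.5, params) == pytest.approx(9.0, abs=0.05)

    @given(h=st.floats(1.0, 200.0))
    @settings(max_examples=50, deadline=None)
    def test_force_scales_inverse_square_and_inverts(self, h):
        params = MechParams()
        f = M.buckling_force(h, params)
        assert M.buckling_force(2 * h, params) == pytest.approx(f / 4, rel=1e-12)
        assert M.buckling_length(f, params) == pytest.approx(h, rel=1e-12)

    def test_matches_discretized_rod_stability_oracle(self, params):
        f = M.buckling_force(10.0, params)
        f_oracle = discretized_buckling_force(10.0, params.kappa)
        assert f == pytest.approx(f_oracle, rel=2e-3)
        # closed-form cross-check of the derived example
        assert M.buckling_length(18.88, params) == pytest.approx(10.0, abs=0.01)

    @pytest.mark.parametrize("bad", [0.0, -1.0])
    def test_domain_errors(self, params, bad):
        with pytest.raises(M.DomainError):
            M.buckling_force(bad, params)
        with pytest.raises(M.DomainError):
            M.buckling_length(bad, params)


class TestArcEnergy:
    def test_64bp_minicircle_is_about_43_kbt(self, params):
        contour = 64 * params.rise_ds
        e = M.arc_bending_energy(contour, contour / (2 * np.pi), params)
        assert 41.0 <= e <= 44.0
        assert e == pytest.approx(2 * np.pi ** 2 * params.lp_ds / contour, rel=1e-12)

    def test_straight_rod_limit_and_discretized_sum(self, params):
        assert M.arc_bending_energy(10.0, 1e9, params) < 1e-15
        # piecewise-constant-curvature chain: N segments each bent by L/(R N)
        L, R, n = 10.0, 5.0, 1000
        ds = L / n
        chain = n * params.kappa / (2 * ds) * (ds / R) ** 2 / params.kbt
        assert M.arc_bending_energy(L, R, params) == pytest.approx(chain, rel=1e-3)

    def test_domain_errors(self, params):
        with pytest.raises(M.DomainError):
            M.arc_bending_energy(-1.0, 5.0, params)


class TestElastica:
    def test_straight_rod_has_zero_energy_and_curvature(self, params):
        sol = M.elastica_profile(13.6, 13.6, params)
        assert sol.energy == 0.0
        assert sol.max_curvature == 0.0

    @pytest.mark.parametrize("h_bp", [20, 30, 40, 48])
    @pytest.mark.parametrize("frac", [0.5, 0.7, 0.9, 0.99])
    def test_energy_matches_discretized_chain_oracle(self, params, h_bp, frac):
        h = h_bp * params.rise_ds
        e = M.elastica_energy(h, frac * h, params)
        e_oracle = discretized_elastica_energy(h, frac * h, params.kappa) / params.kbt
        assert e == pytest.approx(e_oracle, rel=0.01)

    def test_energy_decreases_with_extension(self, params):
        h = 13.6
        x = np.linspace(0.05 * h, h, 200)
        e = M.elastica_energy(h, x, params)
        assert np.all(np.diff(e) < 0)
        assert e[-1] == 0.0

    def test_initial_slope_equals_buckling_force(self, params):
        """Near the straight state, dE/dx -> -F_c (the Euler threshold)."""
        h = 13.6
        x1, x2 = 0.999 * h, 0.9999 * h
        slope = -(M.elastica_energy(h, x2, params) - M.elastica_energy(h, x1, params)) \
            / (x2 - x1) * params.kbt
        assert slope == pytest.approx(M.buckling_force(h, params), rel=0.02)

    def test_shape_arclength_and_curvature_consistency(self, params):
        sol = M.elastica_profile(13.6, 0.8 * 13.6, params, n_points=801)
        seg = np.diff(sol.shape[:, 1:], axis=0)
        arclen = np.sum(np.hypot(seg[:, 0], seg[:, 1]))
        assert arclen == pytest.approx(13.6, rel=1e-4)
        # peak curvature from finite differences of the tangent angle
        theta = np.arctan2(seg[:, 1], seg[:, 0])
        ds = 13.6 / 800
        c_num = np.max(np.abs(np.diff(theta))) / ds          # rad/nm
        c_reported = np.radians(sol.max_curvature) / params.rise_ds
        assert c_reported == pytest.approx(c_num, rel=1e-2)
        assert sol.end_to_end == pytest.approx(sol.shape[-1, 1], abs=1e-6)

    def test_domain_errors(self, params):
        with pytest.raises(M.DomainError):
            M.elastica_profile(10.0, 0.0, params)
        with pytest.raises(M.DomainError):
            M.elastica_profile(10.0, 10.5, params)


class TestMinicircle:
    def test_teardrop_releases_28_8_percent(self, params):
        """One flexible hinge relaxes a minicircle by 28.8%; two release it all."""
        circle = M.minicircle_energy(64, 0, params)
        teardrop = M.minicircle_energy(64, 1, params)
        assert (1 - teardrop / circle) * 100 == pytest.approx(28.8, abs=0.1)
        assert M.minicircle_energy(64, 2, params) == 0.0

    def test_teardrop_ratio_matches_discretized_chain(self):
        assert M.teardrop_energy_ratio() == pytest.approx(
            discretized_teardrop_ratio(), rel=5e-3)

    def test_ratio_is_pure_geometry(self, params):
        ratios = [
            M.minicircle_energy(bp, 1, p) / M.minicircle_energy(bp, 0, p)
            for bp in (50, 64, 100, 300)
            for p in (params, MechParams(lp_ds=20.0))
        ]
        assert np.ptp(ratios) < 1e-4

    def test_domain_errors(self, params):
        with pytest.raises(M.DomainError):
            M.minicircle_energy(64, 3, params)
        with pytest.raises(M.DomainError):
            M.minicircle_energy(2, 0, params)


class TestSsChain:
    def test_relaxed_chain_has_zero_force_and_energy(self, params):
        assert M.ss_chain_force(10, 0.0, params) == 0.0
        assert M.ss_chain_energy(10, 0.0, params) == 0.0

    def test_langevin_fractional_extension_at_9pN(self, params):
        """coth(Fb/kBT) - kBT/(Fb) at 9 pN and b=1.5 nm is ~0.70."""
        n, L = 20, 20 * params.ss_contour_per_nt
        # invert: find extension where force is 9 pN
        x = np.linspace(0, 0.95 * L, 4000)
        f = M.ss_chain_force(n, x, params)
        xi = np.interp(9.0, f, x) / L
        u = 9.0 * params.ss_kuhn / params.kbt
        langevin = (1 / np.tanh(u) - 1 / u) * (1 + 9.0 / params.ss_stretch_mod)
        assert xi == pytest.approx(langevin, rel=1e-3)
        assert langevin == pytest.approx(0.70, abs=0.01)

    def test_energy_derivative_is_force(self, params):
        n = 12
        L = n * params.ss_contour_per_nt
        for xi in (0.2, 0.5, 0.8):
            x = xi * L
            dx = 1e-4
            dEdx = (float(M.ss_chain_energy(n, x + dx, params))
                    - float(M.ss_chain_energy(n, x - dx, params))) / (2 * dx) \
                * params.kbt
            assert dEdx == pytest.approx(float(M.ss_chain_force(n, x, params)),
                                         rel=5e-3)

    def test_extensivity(self, params):
        e1 = float(M.ss_chain_energy(8, 2.0, params))
        e2 = float(M.ss_chain_energy(16, 4.0, params))
        assert e2 == pytest.approx(2 * e1, rel=1e-9)

    @given(xi=st.floats(0.01, 0.9))
    @settings(max_examples=30, deadline=None)
    def test_force_extension_round_trip(self, xi):
        params = MechParams()
        n = 10
        x = xi * n * params.ss_contour_per_nt
        f = float(M.ss_chain_force(n, x, params))
        # invert through the same tabulated law: monotone, so unique
        xs = np.linspace(0, 0.97 * n * params.ss_contour_per_nt, 3000)
        fs = M.ss_chain_force(n, xs, params)
        assert np.interp(f, fs, xs) == pytest.approx(x, rel=2e-3, abs=1e-3)

    def test_overstretching_raises_or_is_infinite(self, params):
        with pytest.raises(M.DomainError):
            M.ss_chain_force(4, 4 * params.ss_contour_per_nt * 1.5, params)
        assert np.isinf(M.ss_chain_energy(0, 1.0, params))

    def test_unzipping_plateau_and_calibration(self, params):
        """dg_bp_stem=1.3 puts the stem plateau at 10.0 pN (~the 9 pN A-T force)."""
        assert M.unzipping_plateau_force(params) == pytest.approx(9.93, abs=0.05)
        cal = M.calibrate_stem_energy(params, force=9.0)
        assert M.unzipping_plateau_force(cal) == pytest.approx(9.0, abs=1e-3)


class TestParams:
    def test_invariants_rejected(self):
        with pytest.raises(ParameterError):
            MechParams(lp_ds=-1.0)
        with pytest.raises(ParameterError):
            MechParams(lp_melt=50.0)  # melted region stiffer than duplex
        with pytest.raises(ParameterError):
            MechParams(temperature=0.0)

    def test_kappa_unit_round_trip(self, params):
        # kappa in pN nm^2; dividing by kBT recovers the persistence length
        assert params.kappa / params.kbt == pytest.approx(params.lp_ds, rel=1e-12)

    def test_config_round_trip_and_unknown_key(self, params):
        from visemech.params import params_from_config, params_to_config
        assert params_from_config(params_to_config(params)) == params
        with pytest.raises(ParameterError, match="no_such"):
            params_from_config({"dsDNA": {"no_such_key": 1.0}})
        with pytest.raises(ParameterError, match="section"):
            params_from_config({"unknown_section": {}})
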