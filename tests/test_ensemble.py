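"""The statistical-mechanical vise ensemble: states, energies, FRET curves, fits."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from visemech import ensemble as E
from visemech import mechanics as M
from visemech.ensemble import (DesignError, FretCurve, GridSpec, Mismatch,
                               ViseDesign)


class TestDesign:
    def test_geometry_validation(self):
        with pytest.raises(DesignError):
            ViseDesign(loop_len=30, target_len=31)
        with pytest.raises(DesignError):
            ViseDesign(loop_len=30, target_len=20, at_block=60)
        with pytest.raises(DesignError):
            Mismatch(code="XY")

    def test_tether_split(self):
        even = ViseDesign(loop_len=46, target_len=42)
        assert even.tether_nts == (2, 2) and not even.odd_split
        odd = ViseDesign(loop_len=46, target_len=41)
        assert odd.tether_nts == (2, 3) and odd.odd_split


class TestFretEfficiency:
    def test_forster_form(self):
        assert E.fret_efficiency(6.2, 6.2) == 0.5
        assert E.fret_efficiency(12.4, 6.2) == pytest.approx(1 / 65)
        assert E.fret_efficiency(0.0, 6.2) == 1.0

    @given(r=st.floats(0.0, 30.0))
    @settings(max_examples=40, deadline=None)
    def test_bounded_and_decreasing(self, r):
        e = E.fret_efficiency(r, 6.2)
        assert 0.0 <= e <= 1.0
        assert E.fret_efficiency(r + 0.5, 6.2) < e or e == 0.0


class TestStateGrid:
    def test_candidate_count_is_grid_product(self, params):
        sg = E.enumerate_states(ViseDesign(loop_len=36, target_len=24), params)
        assert sg.n_candidates == len(sg.x) * len(sg.r) * len(sg.m)
        assert 0 < sg.n_feasible < sg.n_candidates

    def test_target_equal_to_loop_forces_dyes_to_span_target(self, params):
        """With 0-nt tethers every feasible state has the dyes at the target ends."""
        sg = E.enumerate_states(ViseDesign(loop_len=30, target_len=30), params)
        ix, ir, _ = np.nonzero(np.isfinite(sg.energy))
        assert np.all(np.abs(sg.x[ix] - sg.r[ir]) < sg.grid.dr / 2 + 1e-9)

    def test_min_energy_state_matches_exhaustive_oracle(self, params):
        """Brute-force recomputation over the grid finds the same ground state."""
        design = ViseDesign(loop_len=30, target_len=18)
        grid = GridSpec(dx=0.25, dr=0.25)
        sg = E.enumerate_states(design, params, grid)
        t1, t2 = design.tether_nts
        best, best_e = None, np.inf
        for i, x in enumerate(sg.x):
            for j, r in enumerate(sg.r):
                if r > x:
                    continue
                for k, m in enumerate(sg.m):
                    e = (m * params.dg_bp_stem
                         + float(M.ss_chain_energy(2 * m, r, params))
                         + (1.5 * np.log(2 * m) if m else 0.0)
                         + float(M.ss_chain_energy(t1 + t2, x - r, params))
                         + float(E.target_bend_weight_energy(
                             design.target_len * params.rise_ds, x, params)))
                    if e < best_e:
                        best_e, best = e, (i, j, k)
        i, j, k = np.unravel_index(np.argmin(sg.energy), sg.energy.shape)
        assert (i, j, k) == best
        assert sg.energy[i, j, k] == pytest.approx(best_e, abs=1e-9)

    def test_strained_short_loop_ground_state_stays_zipped(self, params):
        """At loop 30 / h 18 the ground state keeps m=0, but thermal unzipping begins."""
        design = ViseDesign(loop_len=30, target_len=18)
        sg = E.enumerate_states(design, params)
        assert sg.min_energy_state().m == 0
        assert E.wlc_summary(design, params).mean_m > 0.05

    def test_slack_design_keeps_stem_zipped(self, params):
        sg = E.enumerate_states(ViseDesign(loop_len=50, target_len=20), params)
        state = sg.min_energy_state()
        assert state.m == 0 and state.r_dye == 0.0


class TestStateEnergy:
    def test_terms_sum_to_total_and_match_primitives(self, params):
        design = ViseDesign(loop_len=46, target_len=42)
        h_nm = 42 * params.rise_ds
        state = E.ConformationState(m=10, x_target=0.85 * h_nm, r_dye=5.0)
        total, terms = E.state_energy(state, design, params)
        assert total == pytest.approx(sum(terms.values()), abs=1e-10)
        assert terms["stem"] == pytest.approx(10 * params.dg_bp_stem)
        assert terms["ss_stem"] == pytest.approx(
            float(M.ss_chain_energy(20, 5.0, params)))
        assert terms["bend"] == pytest.approx(
            float(M.elastica_energy(h_nm, 0.85 * h_nm, params)))
        t1, t2 = design.tether_nts
        assert terms["ss_tethers"] == pytest.approx(
            float(M.ss_chain_energy(t1 + t2, 0.85 * h_nm - 5.0, params)))

    def test_reference_state_energy_vanishes_when_slack(self, params):
        """Zipped stem + straight target: only the tether entropy remains, ~0 when slack."""
        design = ViseDesign(loop_len=50, target_len=4)
        h_nm = 4 * params.rise_ds
        total, terms = E.state_energy(
            E.ConformationState(m=0, x_target=h_nm, r_dye=0.0), design, params)
        assert terms["stem"] == terms["ss_stem"] == terms["bend"] == 0.0
        assert total == pytest.approx(0.0, abs=0.1)  # residual FJC entropy only

    def test_infeasible_geometry_is_infinite_not_silent(self, params):
        design = ViseDesign(loop_len=36, target_len=34)
        total, _ = E.state_energy(
            E.ConformationState(m=0, x_target=34 * params.rise_ds, r_dye=0.0),
            design, params)
        assert np.isinf(total)  # 1-nt tethers cannot span ~5.8 nm each


class TestPredictedCurves:
    def test_large_loops_show_buckling_minimum_at_40(self, params):
        for loop in (46, 50):
            curve = E.predict_fret_curve(loop, range(20, min(loop, 48) + 1), params)
            assert curve.local_minimum(min_depth=0.02) == 40
            assert np.all((curve.e >= 0) & (curve.e <= 1))

    def test_small_loops_decrease_monotonically(self, params):
        for loop in (30, 36):
            curve = E.predict_fret_curve(loop, range(18, loop + 1), params)
            assert np.all(np.diff(curve.e) < 0)
        curve40 = E.predict_fret_curve(40, range(18, 41), params)
        assert curve40.local_minimum(min_depth=0.01) is None
        assert curve40.e[-1] < 0.2 < curve40.e[0]

    def test_rigid_target_never_buckles(self, params):
        """lp -> large removes the minimum: FRET decreases monotonically."""
        rigid = params.replace(lp_ds=500.0)
        curve = E.predict_fret_curve(46, range(20, 47), rigid)
        assert curve.local_minimum(min_depth=0.01) is None

    def test_grid_refinement_converges(self, params):
        coarse = E.predict_fret_curve(36, (24, 30, 34), params,
                                      grid=GridSpec(dx=0.1, dr=0.1))
        fine = E.predict_fret_curve(36, (24, 30, 34), params,
                                    grid=GridSpec(dx=0.05, dr=0.05))
        assert np.max(np.abs(coarse.e - fine.e)) < 0.005

    def test_prediction_is_deterministic(self, params):
        a = E.predict_fret_curve(36, (24, 30), params)
        E.clear_curve_cache()
        b = E.predict_fret_curve(36, (24, 30), params)
        np.testing.assert_array_equal(a.e, b.e)

    def test_curve_validation(self):
        with pytest.raises(ValueError):
            FretCurve("loop36", "c", np.array([24, 24]), np.array([0.5, 0.5]))
        with pytest.raises(ValueError):
            FretCurve("loop36", "c", np.array([24, 30]), np.array([0.5, 1.5]))


class TestScaleFit:
    def _model(self, params):
        return [E.predict_fret_curve(36, range(24, 37, 2), params)]

    def test_identity_and_linearity(self, params):
        model = self._model(params)
        fits = E.fit_scale_factors(model, model)
        assert fits["loop36"].scale == pytest.approx(1.0, abs=1e-12)
        doubled = [FretCurve("loop36", "x2", c.target_len, np.clip(c.e, 0, 0.5) * 2)
                   for c in model]
        halfmodel = [FretCurve("loop36", "m", c.target_len, np.clip(c.e, 0, 0.5))
                     for c in model]
        fits = E.fit_scale_factors(halfmodel, doubled)
        assert fits["loop36"].scale == pytest.approx(2.0, abs=1e-12)

    def test_matches_grid_scan_oracle(self, params):
        rng = np.random.default_rng(7)
        model = self._model(params)
        noisy = [FretCurve("loop36", "n", c.target_len,
                           np.clip(0.8 * c.e + rng.normal(0, 0.05, c.e.size), 0, 1))
                 for c in model]
        a_fit = E.fit_scale_factors(model, noisy)["loop36"].scale
        grid = np.arange(0.0, 3.0, 1e-4)
        sse = [np.sum((noisy[0].e - a * model[0].e) ** 2) for a in grid]
        assert a_fit == pytest.approx(grid[int(np.argmin(sse))], abs=1e-4)

    def test_disjoint_curves_raise(self, params):
        model = self._model(params)
        other = [FretCurve("loop30", "c", np.array([20]), np.array([0.5]))]
        with pytest.raises(ValueError):
            E.fit_scale_factors(model, other)


class TestPersistenceLengthFit:
    def test_noise_free_self_recovery(self, params):
        measured = [E.predict_fret_curve(46, range(30, 47, 2), params)]
        fit = E.fit_persistence_length(measured, params,
                                       np.arange(40.5, 53.0, 1.5))
        assert fit.lp_hat == pytest.approx(46.5, abs=0.1)
        assert fit.scale_factors["loop46"] == pytest.approx(1.0, abs=1e-9)

    def test_lp_where_minimum_shifts_to_30bp(self, params):
        """Softening the duplex to ~25 nm moves the buckling minimum to 30 bp."""
        lp = E.lp_for_minimum_at(30, (36, 40), params, np.arange(18.0, 31.0, 1.0))
        assert 22.0 <= lp <= 27.0

    def test_unbracketed_scan_raises(self, params):
        with pytest.raises(ValueError, match="never places"):
            E.lp_for_minimum_at(30, (36,), params, np.arange(40.0, 46.0, 2.0))
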