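import numpy as np
import pytest
import sympy as sp
from hypothesis import given, settings
from hypothesis import strategies as st

from liverfat import (ModelConstants, TissueState, free_water_fraction_from_t1,
                      mass_ratio_from_pdff, mass_ratio_from_tmff, model_curves,
                      observed_t1, pdff_from_mass_ratio, pdff_to_tmff,
                      signal_ratio_factor, tissue_water_nonhealthy,
                      tmff_from_mass_ratio, tmff_mr, tmff_to_pdff)


class TestSignalRatioFactor:
    def test_literature_constants_give_point_seven(self, constants):
        assert signal_ratio_factor(constants) == pytest.approx(0.7035, abs=1e-4)
        assert round(signal_ratio_factor(constants), 1) == 0.7

    def test_identity_when_densities_equal(self):
        c = ModelConstants(rho_F=100.0, rho_W=100.0, D_F=1.0, D_W=1.0)
        assert signal_ratio_factor(c) == 1.0

    def test_inverse_proportional_to_fat_density(self, constants):
        doubled = constants.replace(D_F=2 * constants.D_F)
        assert signal_ratio_factor(doubled) == pytest.approx(
            signal_ratio_factor(constants) / 2)


class TestPdffTmffConversions:
    def test_zero_fat_maps_to_zero(self, constants):
        assert pdff_from_mass_ratio(0.0, constants) == 0.0
        assert tmff_from_mass_ratio(0.0, 0.711) == 0.0
        assert pdff_to_tmff(0.0, 0.5, constants) == 0.0

    def test_quarter_tmff_at_full_water_reads_as_19_percent_pdff(
            self, constants):
        # the canonical worked example: TMFF 25% at L_W = 1 -> PDFF 19%
        assert tmff_from_mass_ratio(1 / 3, 1.0) == pytest.approx(0.25)
        pdff = tmff_to_pdff(0.25, 1.0, constants)
        assert round(100 * pdff) == 19

    def test_mass_ratio_from_tmff_matches_root_find(self, constants):
        # numeric inversion oracle on the TMFF map
        from scipy.optimize import brentq
        r = brentq(lambda rm: tmff_from_mass_ratio(rm, 0.711) - 0.25, 0, 100)
        assert mass_ratio_from_tmff(0.25, 0.711) == pytest.approx(r, rel=1e-9)
        assert r == pytest.approx(0.4689, abs=1e-4)

    @pytest.mark.parametrize("lw", [0.3, 0.711, 1.0])
    def test_round_trips_are_identity(self, constants, lw):
        p = np.linspace(0.0, 0.95, 40)
        back = pdff_from_mass_ratio(mass_ratio_from_pdff(p, constants),
                                    constants)
        np.testing.assert_allclose(back, p, atol=1e-12)
        t = pdff_to_tmff(p, lw, constants)
        np.testing.assert_allclose(tmff_to_pdff(t, lw, constants), p,
                                   atol=1e-12)

    def test_healthy_water_near_identity(self, constants):
        p = np.linspace(0.0, 0.4, 1000)
        t = pdff_to_tmff(p, 0.711, constants)
        assert np.max(np.abs(t - p)) < 0.01

    def test_pdff_one_has_no_inverse(self, constants):
        with pytest.raises(ValueError):
            mass_ratio_from_pdff(1.0, constants)
        with pytest.raises(ValueError):
            mass_ratio_from_tmff(1.0, 0.711)

    @settings(max_examples=200, deadline=None)
    @given(rm=st.floats(0.0, 50.0), lw=st.floats(0.05, 1.0))
    def test_tmff_monotone_in_mass_ratio_and_water(self, rm, lw):
        t = tmff_from_mass_ratio(rm, lw)
        assert 0.0 <= t < 1.0
        assert tmff_from_mass_ratio(rm + 0.1, lw) >= t
        assert tmff_from_mass_ratio(rm, min(lw + 0.05, 1.0)) >= t


class TestTwoPoolT1:
    def test_pool_endpoints(self, constants):
        assert free_water_fraction_from_t1(constants.T1_free,
                                           constants) == pytest.approx(1.0)
        assert free_water_fraction_from_t1(constants.T1_bound,
                                           constants) == pytest.approx(0.0)

    def test_illustrative_linear_solve(self):
        c = ModelConstants(T1_free=4000.0, T1_bound=250.0)
        assert free_water_fraction_from_t1(632.0, c) == pytest.approx(
            0.6447, abs=1e-4)

    def test_forward_inverse_consistency(self, constants):
        w = np.linspace(0.0, 1.0, 50)
        t1 = observed_t1(w, constants)
        np.testing.assert_allclose(
            free_water_fraction_from_t1(t1, constants), w, atol=1e-12)

    def test_out_of_range_t1_clipped_with_warning(self, constants):
        with pytest.warns(UserWarning, match="clipped"):
            w = free_water_fraction_from_t1(2 * constants.T1_free, constants)
        assert w == 1.0

    def test_degenerate_pools_rejected(self):
        c = ModelConstants(T1_free=1000.0, T1_bound=999.999999)
        object.__setattr__(c, "T1_bound", 1000.0)  # bypass ctor check
        with pytest.raises(ValueError, match="degenerate"):
            free_water_fraction_from_t1(500.0, c)


class TestNonHealthyTissueWater:
    def test_healthy_identity_for_every_k(self, constants):
        w_healthy = constants.L_W_healthy / (constants.L_W_healthy
                                             + constants.L_B_healthy)
        for k in np.linspace(0, 1, 11):
            lw = tissue_water_nonhealthy(w_healthy, constants, k=float(k))
            assert lw == pytest.approx(constants.L_W_healthy, abs=1e-12)

    def test_k_zero_reduces_to_total_water_scaling(self):
        c = ModelConstants(L_W_healthy=0.711, L_B_healthy=0.08)
        lw = tissue_water_nonhealthy(0.92, c, k=0.0)
        assert lw == pytest.approx(0.92 * 0.791, abs=1e-12)
        assert lw == pytest.approx(0.7278, abs=1e-4)

    def test_k_one_closed_form(self):
        c = ModelConstants(L_W_healthy=0.711, L_B_healthy=0.08)
        lw = tissue_water_nonhealthy(0.92, c, k=1.0)
        assert lw == pytest.approx(0.92 * 0.08 / (1 - 0.92), abs=1e-9)

    def test_result_above_one_clipped_with_warning(self):
        c = ModelConstants(L_W_healthy=0.711, L_B_healthy=0.08)
        with pytest.warns(UserWarning, match="clipped"):
            lw = tissue_water_nonhealthy(0.99, c, k=1.0)
        assert lw == 1.0

    def test_compartment_bookkeeping_derivation(self):
        """Symbolic re-derivation of the non-healthy water formula.

        Free water rises by delta; a fraction k of that change is drawn
        from the non-water compartment and 1-k from bound water.  The free
        water fraction of the resulting state must invert to the
        implemented expression.
        """
        L_W, L_B, k, delta, W = sp.symbols("L_W L_B k delta W", positive=True)
        lw_new = L_W + delta
        lb_new = L_B - (1 - k) * delta
        w_expr = lw_new / (lw_new + lb_new)
        sol = sp.solve(sp.Eq(W, w_expr), delta)
        assert len(sol) == 1
        lw_from_w = sp.simplify(lw_new.subs(delta, sol[0]))
        printed = W * (L_B + L_W - k * L_W) / (1 - k * W)
        assert sp.simplify(lw_from_w - printed) == 0


class TestTmffMr:
    def test_healthy_t1_is_k_independent(self, constants):
        w_healthy = constants.L_W_healthy / (constants.L_W_healthy
                                             + constants.L_B_healthy)
        t1 = observed_t1(w_healthy, constants)
        out = tmff_mr(0.2, t1, constants)
        expected = pdff_to_tmff(0.2, constants.L_W_healthy, constants)
        for val in out.values():
            assert val == pytest.approx(expected, abs=1e-9)

    def test_zero_pdff_stays_zero(self, constants):
        assert all(v == 0.0 for v in tmff_mr(0.0, 700.0, constants).values())

    def test_elevated_water_correction_raises_estimate(self, constants):
        # PDFF at fixed TMFF decreases in L_W, so correcting for elevated
        # water must raise the fat-fraction estimate
        elevated = constants.L_W_healthy + 0.08
        w_f = elevated / (elevated + constants.L_B_healthy)
        t1 = observed_t1(w_f, constants)
        uncorrected = pdff_to_tmff(0.15, constants.L_W_healthy, constants)
        out = tmff_mr(0.15, t1, constants)
        assert all(v > uncorrected for v in out.values())


class TestModelCurves:
    def test_all_curves_pass_through_origin(self, constants):
        curve_a, _ = model_curves(constants)
        origin = curve_a.iloc[0]
        assert origin["tmff"] == 0.0
        assert all(origin[c] == 0.0 for c in curve_a.columns if c != "tmff")

    def test_pdff_decreases_with_water_at_fixed_tmff(self, constants):
        curve_a, _ = model_curves(
            constants, lw_values=(0.6, 0.7, 0.8, 0.9, 1.0))
        body = curve_a[curve_a["tmff"] > 0]
        cols = [c for c in curve_a.columns if c != "tmff"]
        vals = body[cols].to_numpy()
        assert np.all(np.diff(vals, axis=1) < 0)

    def test_full_water_curve_hits_worked_example(self, constants):
        curve_a, _ = model_curves(constants, tmff_grid=[0.25],
                                  lw_values=(1.0,))
        assert round(100 * curve_a["pdff_Lw_1"].iloc[0]) == 19

    def test_t1_curves_converge_at_healthy_point(self, constants):
        _, curve_b = model_curves(constants)
        w_healthy = constants.L_W_healthy / (constants.L_W_healthy
                                             + constants.L_B_healthy)
        t1_h = observed_t1(w_healthy, constants)
        _, curve_at_h = model_curves(constants, t1_grid_ms=[t1_h])
        k_cols = [c for c in curve_at_h.columns if c.startswith("Lw_k_")]
        vals = curve_at_h[k_cols].to_numpy().ravel()
        np.testing.assert_allclose(vals, constants.L_W_healthy, atol=1e-9)
        assert len(k_cols) == 6


class TestTissueState:
    def test_water_fraction_consistency(self):
        ts = TissueState(L_W=0.711, L_B=0.08, L_N=0.209)
        assert ts.W_F == pytest.approx(0.711 / 0.791)
        assert ts.W_F + ts.W_B == pytest.approx(1.0)

    def test_partition_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum"):
            TissueState(L_W=0.5, L_B=0.1, L_N=0.2)
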