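"""Linkage relation and global two-state denaturation fitting."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import rnclink as rl
from rnclink.constants import rt_kcal
from rnclink.folding_thermo import two_state_signal
from rnclink.synthetic_data import CurveTruth, DenaturationGroundTruth, simulate_denaturation


class TestLinkage:
    @pytest.mark.parametrize(
        "p_b,expected",
        [(0.0, 0.0), (0.90, -1.295), (0.8311, -1.000)],
    )
    def test_unfolded_state_stabilization_values(self, p_b, expected):
        res = rl.unfolded_state_stabilization(p_b, temperature=283.0)
        assert res.delta_g == pytest.approx(expected, abs=2e-3)

    def test_one_kcal_requires_over_eighty_percent_binding(self):
        p = rl.required_binding_for_destabilization(1.0, temperature=283.0)
        assert p == pytest.approx(0.831, abs=1e-3)
        assert p > 0.80

    def test_small_destabilization_limit(self):
        assert rl.required_binding_for_destabilization(1e-9) == pytest.approx(0.0, abs=1e-8)

    @given(st.floats(min_value=0.0, max_value=0.999))
    @settings(max_examples=50, deadline=None)
    def test_forward_inverse_are_exact_inverses(self, p_b):
        res = rl.unfolded_state_stabilization(p_b)
        if res.destabilization > 0:
            back = rl.required_binding_for_destabilization(res.destabilization)
            assert back == pytest.approx(p_b, abs=1e-12)

    def test_strictly_decreasing_and_concave_in_p(self):
        p = np.linspace(0.0, 0.99, 200)
        dg = np.array([rl.unfolded_state_stabilization(x).delta_g for x in p])
        assert (np.diff(dg) < 0).all()
        assert (np.diff(dg, 2) < 0).all()

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            rl.unfolded_state_stabilization(1.0)
        with pytest.raises(ValueError):
            rl.required_binding_for_destabilization(-0.5)


class TestPredictStabilityShift:
    def test_equal_populations_cancel(self):
        assert rl.predict_stability_shift(0.4, 0.4, 4.0) == pytest.approx(4.0)

    def test_printed_short_linker_populations(self):
        pred = rl.predict_stability_shift(0.90, 0.22, 4.0, temperature=283.0)
        assert pred == pytest.approx(2.84, abs=5e-3)

    def test_consistency_with_linkage(self):
        pred = rl.predict_stability_shift(0.8311, 0.0, 4.0, temperature=283.0)
        assert pred == pytest.approx(3.0, abs=2e-3)  # lowered by exactly 1 kcal/mol

    def test_domain(self):
        with pytest.raises(ValueError, match="pb_wt"):
            rl.predict_stability_shift(1.0, 0.2, 4.0)


def simulate_pair(seed, noise=0.02, dg=(6.0, 2.0), m=1.67, grid=None, kind="fraction"):
    if grid is None:
        grid = np.linspace(0.0, 5.5, 12)
    alpha = [(0.04, 0.92), (0.05, 0.90)] if kind == "fraction" else [(-12.0, 22.0), (-12.5, 22.5)]
    truth = DenaturationGroundTruth(
        m=m,
        curves=[
            CurveTruth("a", dg[0], *alpha[0], noise_sd=noise, kind=kind),
            CurveTruth("b", dg[1], *alpha[1], noise_sd=noise, kind=kind),
        ],
    )
    return simulate_denaturation(truth, grid, seed=seed)


class TestTwoStateGlobalFit:
    def test_noiseless_curve_yields_product_of_m_and_midpoint(self):
        grid = np.linspace(0.0, 5.5, 12)
        truth = DenaturationGroundTruth(
            m=1.67, curves=[CurveTruth("c", 4.008, 0.03, 0.9, noise_sd=1e-6)]
        )
        (curve,) = simulate_denaturation(truth, grid, seed=0)
        fit = rl.two_state_global_fit([curve])
        dg, _ = fit.dg("c")
        assert dg == pytest.approx(4.008, abs=1e-3)
        assert fit.m == pytest.approx(1.67, abs=1e-3)
        assert fit.per_curve["d50"].iloc[0] == pytest.approx(2.40, abs=1e-3)

    def test_identical_curves_fit_identically(self):
        grid = np.linspace(0.0, 5.5, 12)
        truth = DenaturationGroundTruth(
            m=1.67, curves=[CurveTruth("c", 4.0, 0.03, 0.9, noise_sd=1e-6)]
        )
        (c1,) = simulate_denaturation(truth, grid, seed=0)
        c2 = rl.DenaturationCurve(
            label="c2", denaturant=c1.denaturant, signal=c1.signal,
            signal_error=c1.signal_error,
        )
        single = rl.two_state_global_fit([c1])
        joint = rl.two_state_global_fit([c1, c2])
        assert joint.m == pytest.approx(single.m, abs=1e-6)
        assert joint.dg("c")[0] == pytest.approx(joint.dg("c2")[0], abs=1e-6)

    def test_recovery_of_shared_m_and_gap_within_two_se(self):
        curves = simulate_pair(seed=5)
        fit = rl.two_state_global_fit(curves)
        assert fit.m == pytest.approx(1.67, abs=2 * fit.m_se)
        ddg, se = rl.stability_difference(fit, "a", "b")
        assert ddg == pytest.approx(4.0, abs=2 * se)

    def test_cross_modality_consistency(self):
        cd = simulate_pair(seed=6, noise=0.44, kind="cd")
        peg = simulate_pair(seed=7, noise=0.018, kind="fraction")
        fit_cd = rl.two_state_global_fit(cd)
        fit_peg = rl.two_state_global_fit(peg)
        d_cd, se_cd = rl.stability_difference(fit_cd, "a", "b")
        d_peg, se_peg = rl.stability_difference(fit_peg, "a", "b")
        assert abs(d_cd - d_peg) < 2 * np.hypot(se_cd, se_peg)

    def test_matches_grid_search_oracle_on_noiseless_curve(self):
        """Optimizer equals a brute-force (m, D50) grid with analytic baselines."""
        grid = np.linspace(0.0, 5.5, 12)
        truth = DenaturationGroundTruth(
            m=1.8, curves=[CurveTruth("c", 4.5, 0.06, 0.85, noise_sd=1e-9)]
        )
        (curve,) = simulate_denaturation(truth, grid, seed=0)
        best = (np.inf, None, None)
        for m in np.linspace(1.0, 2.6, 161):
            for d50 in np.linspace(1.0, 4.0, 301):
                f = two_state_signal(grid, d50, m, 0.0, 1.0)
                design = np.column_stack([np.ones_like(grid), f])
                coef, res, *_ = np.linalg.lstsq(design, curve.signal, rcond=None)
                sse = float(res[0]) if len(res) else float(
                    ((curve.signal - design @ coef) ** 2).sum()
                )
                if sse < best[0]:
                    best = (sse, m, d50)
        fit = rl.two_state_global_fit([curve])
        assert fit.m == pytest.approx(best[1], abs=0.01)
        assert fit.per_curve["d50"].iloc[0] == pytest.approx(best[2], abs=0.01)

    def test_masked_points_never_influence_fit(self):
        curves = simulate_pair(seed=8, dg=(3.3, 1.0), grid=np.arange(0, 4.51, 0.5))
        cutoffs = {"a": 3.0, "b": 3.0}
        fit1 = rl.two_state_global_fit(curves, m_fixed=1.67, urea_cutoff=cutoffs)
        # arbitrarily corrupt every masked-out point
        for c in curves:
            c.signal[c.denaturant >= 3.0] += np.linspace(5, -3, (c.denaturant >= 3.0).sum())
        fit2 = rl.two_state_global_fit(curves, m_fixed=1.67, urea_cutoff=cutoffs)
        np.testing.assert_allclose(fit1.params, fit2.params, rtol=1e-12)

    def test_masked_rnc_pair_recovers_reduced_gap(self):
        curves = simulate_pair(
            seed=9, noise=0.027, dg=(3.3, 1.0), grid=np.arange(0, 4.51, 0.5)
        )
        fit = rl.two_state_global_fit(
            curves, m_fixed=1.67, urea_cutoff={"a": 3.0, "b": 3.0}
        )
        ddg, se = rl.stability_difference(fit, "a", "b")
        assert ddg == pytest.approx(2.3, abs=2 * se)

    def test_too_few_masked_points_rejected(self):
        curves = simulate_pair(seed=10, grid=np.linspace(0, 5.5, 8))
        with pytest.raises(ValueError, match="mask"):
            rl.two_state_global_fit(curves, urea_cutoff={"a": 2.0, "b": 2.0})

    def test_replicate_calibration_bias_and_coverage(self):
        """Shared-m estimator: small bias and ~95% CI coverage at 2% noise."""
        n_rep = 200
        ms, ses, hits = [], [], 0
        for seed in range(n_rep):
            fit = rl.two_state_global_fit(simulate_pair(seed=1000 + seed))
            ms.append(fit.m)
            ses.append(fit.m_se)
            if abs(fit.m - 1.67) <= 1.96 * fit.m_se:
                hits += 1
        bias = abs(np.mean(ms) - 1.67)
        assert bias < 0.5 * np.mean(ses)
        assert 0.90 <= hits / n_rep <= 1.0
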