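import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from synscreen.surfaces import (bliss_expected, chou_talalay_ci,
                                chou_talalay_surface, fit_edges, hsa_expected,
                                loewe_expected, loewe_surface, min_viability,
                                score_matrix, score_all_models)

from conftest import matrix_from_surface, symmetric_fit


class TestBlissHsa:
    @pytest.mark.parametrize("va,vb,expected", [
        (0.5, 0.5, 0.25), (1.0, 0.7, 0.7), (0.0, 0.3, 0.0),
    ])
    def test_bliss(self, va, vb, expected):
        assert bliss_expected(va, vb) == pytest.approx(expected)

    @pytest.mark.parametrize("va,vb,expected", [
        (0.3, 0.7, 0.3), (0.4, 0.4, 0.4), (1.0, 0.2, 0.2),
    ])
    def test_hsa(self, va, vb, expected):
        assert hsa_expected(va, vb) == pytest.approx(expected)

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            bliss_expected(-0.1, 0.5)
        with pytest.raises(ValueError):
            hsa_expected(0.5, -0.1)

    def test_overgrowth_clamped_with_warning(self):
        with pytest.warns(UserWarning):
            assert bliss_expected(1.3, 0.5) == pytest.approx(0.5)

    @given(va=st.floats(0, 1), vb=st.floats(0, 1))
    @settings(max_examples=100, deadline=None)
    def test_hsa_dominates_bliss_wellwise(self, va, vb):
        assert hsa_expected(va, vb) >= bliss_expected(va, vb) - 1e-12


class TestLoewe:
    def test_zero_dose_reduces_to_monotherapy(self):
        fa, fb = symmetric_fit(1.0), symmetric_fit(2.0)
        assert loewe_expected(fa, fb, 0.7, 0.0) == pytest.approx(
            fa.predict(0.7))
        assert loewe_expected(fa, fb, 0.0, 0.7) == pytest.approx(
            fb.predict(0.7))

    def test_closed_form_equal_potency_ratio(self):
        # ec50_a=1, ec50_b=2 at doses (1, 2): 2v/(1-v) = 1 gives v = 1/3
        fa, fb = symmetric_fit(1.0), symmetric_fit(2.0)
        assert loewe_expected(fa, fb, 1.0, 2.0) == pytest.approx(
            1.0 / 3.0, abs=1e-9)

    def test_sham_combination_invariance(self):
        # a drug combined with itself behaves like the drug at the summed dose
        fit = symmetric_fit(0.8, h=1.6)
        for da, db in [(0.2, 0.5), (1.0, 1.0), (0.05, 2.0)]:
            assert loewe_expected(fit, fit, da, db) == pytest.approx(
                fit.predict(da + db), abs=1e-9)

    def test_emax_floor_falls_back_to_hsa(self):
        fa = symmetric_fit(0.1, einf=0.55)
        fb = symmetric_fit(0.1, einf=0.6)
        # huge doses ask for an effect below both floors
        surface, n_fallback = loewe_surface(fa, fb, np.array([50.0]),
                                            np.array([50.0]))
        assert n_fallback == 1
        assert surface[0, 0] == pytest.approx(
            min(fa.predict(50.0), fb.predict(50.0)))

    def test_solver_matches_dense_grid_search(self, rng):
        # independent oracle: scan v at 1e-5 resolution for the root
        vgrid = np.linspace(1e-5, 1 - 1e-5, 100_000)
        for _ in range(20):
            fa = symmetric_fit(10 ** rng.uniform(-1.5, 0.5),
                               h=rng.uniform(0.5, 3))
            fb = symmetric_fit(10 ** rng.uniform(-1.5, 0.5),
                               h=rng.uniform(0.5, 3))
            da = 10 ** rng.uniform(-1.5, 0.5)
            db = 10 ** rng.uniform(-1.5, 0.5)
            resid = np.abs(da / fa.inverse(vgrid) + db / fb.inverse(vgrid) - 1)
            v_grid = vgrid[np.argmin(resid)]
            assert loewe_expected(fa, fb, da, db) == pytest.approx(
                v_grid, abs=1e-4)

    def test_unidentifiable_fit_rejected(self):
        from synscreen.doseresponse import HillFit
        flat = HillFit(1.0, 1.0, np.nan, np.nan, 0.0, 0, True, False)
        with pytest.raises(ValueError):
            loewe_expected(flat, symmetric_fit(1.0), 1.0, 1.0)


class TestChouTalalay:
    def test_single_agent_identity(self):
        fa, fb = symmetric_fit(1.0, h=1.3), symmetric_fit(2.0)
        dose = 0.7
        fa_obs = 1.0 - fa.predict(dose)  # affected fraction on A's scale
        assert chou_talalay_ci(fa, fb, dose, 0.0, fa_obs) == pytest.approx(
            1.0, abs=1e-9)

    def test_mutually_nonexclusive_formula(self):
        # identical drugs Dm=1, m=1 at (0.5, 0.5) and fa=0.5:
        # CI = 0.5 + 0.5 + 0.25
        f = symmetric_fit(1.0)
        assert chou_talalay_ci(f, f, 0.5, 0.5, 0.5) == pytest.approx(1.25)

    def test_stronger_observed_effect_lowers_ci(self):
        f = symmetric_fit(1.0)
        ci_matched = chou_talalay_ci(f, f, 0.5, 0.5, 0.5)
        ci_stronger = chou_talalay_ci(f, f, 0.5, 0.5, 0.8)
        assert ci_stronger < ci_matched

    def test_extreme_fa_clamped(self):
        f = symmetric_fit(1.0)
        assert np.isfinite(chou_talalay_ci(f, f, 0.5, 0.5, 1.0))
        assert np.isfinite(chou_talalay_ci(f, f, 0.5, 0.5, 0.0))


class TestScoreMatrix:
    def test_observed_equals_expected_scores_zero(self):
        fa, fb = symmetric_fit(0.5), symmetric_fit(0.8)
        m = matrix_from_surface(fa, fb, 1.0, 1.0)
        expected = m.combo_block().copy()
        res = score_matrix(m, expected, "bliss")
        assert res.score_sum == pytest.approx(0.0, abs=1e-12)

    def test_uniform_deviation_sums_linearly(self):
        fa, fb = symmetric_fit(0.5), symmetric_fit(0.8)
        m = matrix_from_surface(fa, fb, 1.0, 1.0)
        expected = m.combo_block() + 0.01
        res = score_matrix(m, expected, "bliss")
        assert res.score_sum == pytest.approx(36.0)
        assert res.score_synergy_only == pytest.approx(36.0)
        assert res.score_antagonism_only == pytest.approx(0.0)

    def test_matches_brute_force_double_loop(self, rng):
        fa, fb = symmetric_fit(0.4), symmetric_fit(1.2)
        noise = lambda va, vb, da, db: va * vb + rng.uniform(-0.2, 0.2)
        m = matrix_from_surface(fa, fb, 2.0, 2.0, combo_fn=noise)
        expected = rng.uniform(0, 1, (6, 6))
        res = score_matrix(m, expected, "bliss")
        obs = m.combo_block()
        total = syn = ant = 0.0
        for i in range(6):
            for j in range(6):
                d = (expected[i, j] - obs[i, j]) * 100
                total += d
                syn += d if d > 0 else 0.0
                ant += d if d < 0 else 0.0
        assert res.score_sum == pytest.approx(total)
        assert res.score_synergy_only == pytest.approx(syn)
        assert res.score_antagonism_only == pytest.approx(ant)
        assert res.score_sum == pytest.approx(
            res.score_synergy_only + res.score_antagonism_only, abs=1e-9)

    def test_shape_mismatch_rejected(self):
        m = matrix_from_surface(symmetric_fit(0.5), symmetric_fit(0.8), 1, 1)
        with pytest.raises(ValueError, match="shape"):
            score_matrix(m, np.zeros((5, 6)), "bliss")


class TestMinViability:
    def test_uniform_matrix(self):
        m = matrix_from_surface(symmetric_fit(1.0), symmetric_fit(1.0), 1, 1,
                                combo_fn=lambda *a: 1.0)
        assert min_viability(m) == pytest.approx(1.0)

    def test_single_deep_well(self):
        def fn(va, vb, da, db):
            return 0.05 if (da > 0.9 and db > 0.9) else va * vb
        m = matrix_from_surface(symmetric_fit(5.0), symmetric_fit(5.0), 1, 1,
                                combo_fn=fn)
        assert min_viability(m) == pytest.approx(0.05)

    def test_masked_wells_skipped(self):
        m = matrix_from_surface(symmetric_fit(0.5), symmetric_fit(0.5), 1, 1)
        block_min = np.nanmin(m.combo_block())
        # mask the deepest combination well; minimum moves to the next one
        idx = np.unravel_index(np.nanargmin(m.viability[0, 1:, 1:]),
                               (6, 6))
        m.viability[0, idx[0] + 1, idx[1] + 1] = np.nan
        assert min_viability(m) > block_min


class TestNullity:
    def test_sham_combination_loewe_score_near_zero(self):
        # drug combined with itself, data generated from the shared curve
        fit = symmetric_fit(0.5, h=1.4)
        sham = lambda va, vb, da, db: fit.predict(da + db)
        m = matrix_from_surface(fit, fit, 1.0, 1.0, combo_fn=sham)
        surface, _ = loewe_surface(fit, fit, m.axis_a[1:], m.axis_b[1:])
        res = score_matrix(m, surface, "loewe")
        assert abs(res.score_sum) < 0.1 * res.n_wells

    def test_exact_product_data_scores_zero_bliss(self):
        fa, fb = symmetric_fit(0.3), symmetric_fit(0.9)
        m = matrix_from_surface(fa, fb, 1.0, 1.0)
        res = score_all_models(m, fa, fb)["bliss"]
        assert res.score_sum == pytest.approx(0.0, abs=1e-9)


def test_fit_edges_recovers_generating_curves():
    fa = symmetric_fit(0.3, h=1.5, einf=0.1)
    fb = symmetric_fit(0.9, h=0.9)
    m = matrix_from_surface(fa, fb, 3.0, 9.0, n_replicates=2)
    ga, gb = fit_edges(m)
    assert ga.ec50 == pytest.approx(fa.ec50, rel=1e-3)
    assert gb.ec50 == pytest.approx(fb.ec50, rel=1e-3)
    assert ga.h == pytest.approx(fa.h, rel=1e-3)


def test_chou_talalay_surface_shape_and_sign(rng):
    fa, fb = symmetric_fit(0.5), symmetric_fit(0.5)
    # stronger-than-independent kill: CI below 1 in the interior
    syn = lambda va, vb, da, db: max(va * vb - 0.2, 0.01)
    m = matrix_from_surface(fa, fb, 2.0, 2.0, combo_fn=syn)
    ci = chou_talalay_surface(fa, fb, m)
    assert ci.shape == (6, 6)
    assert np.nanmedian(ci) < 1.0
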