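"""Dissolution: sampling correction, f1/f2 statistics, release-model fits."""

import math

import numpy as np
import pytest

from oralbe.dissolution import (
    DissolutionProfile,
    ReleaseModel,
    correct_cumulative,
    f1_factor,
    f2_factor,
    fit_release_model,
    fraction_dissolved,
    read_profiles_csv,
    release_hazard,
    similarity_verdict,
    verdict_from_factors,
    write_profiles_csv,
)
from oralbe.synthetic_data import DissolutionTruth, gen_dissolution


def profile(values, times=None, **kw):
    values = np.asarray(values, dtype=float)
    if times is None:
        times = np.arange(1, values.shape[-1] + 1, dtype=float) * 5.0
    return DissolutionProfile(times=times, percent_dissolved=values, **kw)


class TestCorrectCumulative:
    def test_hand_summation(self):
        p = correct_cumulative([1.0, 2.0, 3.0], sample_volume=5.0,
                               vessel_volume=900.0, dose=5.0,
                               times=[5.0, 10.0, 15.0])
        masses_ug = p.percent_dissolved[0] / 100.0 * 5.0 * 1000.0
        assert masses_ug == pytest.approx([900.0, 1805.0, 2715.0])

    def test_no_withdrawal_limit(self):
        p = correct_cumulative([1.0, 2.0], 0.0, 900.0, 5.0, times=[5.0, 10.0])
        masses_ug = p.percent_dissolved[0] / 100.0 * 5000.0
        assert masses_ug == pytest.approx([900.0, 1800.0])

    def test_constant_concentration_increments_by_withdrawn_mass(self):
        c, vs = 2.0, 5.0
        p = correct_cumulative([c] * 5, vs, 900.0, 10.0,
                               times=[5, 10, 15, 20, 25])
        masses = p.percent_dissolved[0] / 100.0 * 10000.0
        assert np.diff(masses) == pytest.approx(vs * c)

    def test_negative_concentration_names_time_point(self):
        with pytest.raises(ValueError, match="index 1"):
            correct_cumulative([1.0, -0.5, 2.0], 5.0, 900.0, 5.0,
                               times=[5.0, 10.0, 15.0])


class TestSimilarityFactors:
    def test_identical_profiles(self):
        r = np.array([30.0, 60.0, 80.0])
        assert f1_factor(r, r) == 0.0
        assert f2_factor(r, r) == pytest.approx(100.0)

    def test_hand_arithmetic_example(self):
        r, t = [50.0, 80.0, 95.0], [45.0, 85.0, 90.0]
        assert f1_factor(r, t) == pytest.approx(15.0 / 225.0 * 100.0, abs=5e-3)
        assert f2_factor(r, t) == pytest.approx(
            50.0 * math.log10(100.0 / math.sqrt(26.0)), abs=5e-3
        )

    def test_mismatched_grids_rejected(self):
        with pytest.raises(ValueError):
            f1_factor([1.0, 2.0], [1.0, 2.0, 3.0])

    @pytest.mark.parametrize("offset", [2.0, 5.0, 10.0, 20.0])
    def test_f1_grows_and_f2_shrinks_with_offset(self, offset):
        r = np.array([20.0, 40.0, 60.0, 70.0])
        smaller = (f1_factor(r, r + offset - 1.0), f2_factor(r, r + offset - 1.0))
        larger = (f1_factor(r, r + offset), f2_factor(r, r + offset))
        assert larger[0] > smaller[0]
        assert larger[1] < smaller[1]


class TestVerdict:
    def test_waived_when_both_rapid(self):
        t = np.array([5.0, 10.0, 15.0, 30.0])
        ref = profile([[60.0, 80.0, 90.0, 95.0]], t)
        tst = profile([[55.0, 82.0, 88.0, 94.0]], t)
        res = similarity_verdict(ref, tst)
        assert res.rapid_both and res.verdict == "waived"

    def test_identical_slow_profiles_pass(self):
        vals = [[10.0, 30.0, 50.0, 70.0]]
        res = similarity_verdict(profile(vals), profile(vals))
        assert res.verdict == "pass"
        assert res.f1 == 0.0 and res.f2 == pytest.approx(100.0)

    def test_printed_factor_pairs_reproduce_decision_table(self):
        # (rapid_both, f1, f2) -> decision, as published for the four
        # formulation/medium combinations
        rows = [
            (True, 5.08, 70.80, {"pass", "waived"}),
            (False, 15.92, 45.40, {"fail"}),
            (False, 14.16, 53.81, {"pass"}),
            (False, 13.24, 54.59, {"pass"}),
        ]
        for rapid, f1, f2, expected in rows:
            assert verdict_from_factors(f1, f2, rapid) in expected

    def test_agrees_with_brute_force_thresholds_on_random_pairs(self, rng):
        t = np.arange(1.0, 11.0) * 10.0
        for _ in range(1000):
            r = np.sort(rng.uniform(5.0, 84.0, size=10))
            d = rng.normal(0.0, rng.uniform(0.5, 15.0), size=10)
            tv = np.clip(r + d, 0.0, 84.9)
            ref, tst = profile([r], t), profile([tv], t)
            res = similarity_verdict(ref, tst)
            f1, f2 = f1_factor(r, tv), f2_factor(r, tv)
            assert res.verdict == ("pass" if (f1 < 15 and f2 > 50) else "fail")

    def test_point_selection_stops_after_both_exceed_85(self):
        t = np.array([5.0, 10.0, 20.0, 30.0, 45.0])
        ref = profile([[40.0, 70.0, 90.0, 95.0, 96.0]], t)
        tst = profile([[35.0, 65.0, 88.0, 94.0, 95.0]], t)
        res = similarity_verdict(ref, tst)
        assert res.included_times == (5.0, 10.0, 20.0)
        res_all = similarity_verdict(ref, tst, apply_85_rule=False)
        assert res_all.n_points == 5

    def test_different_grids_rejected(self):
        ref = profile([[10.0, 20.0, 30.0]], np.array([5.0, 10.0, 15.0]))
        tst = profile([[10.0, 20.0, 30.0]], np.array([5.0, 10.0, 20.0]))
        with pytest.raises(ValueError, match="grid"):
            similarity_verdict(ref, tst)

    def test_too_few_points_rejected(self):
        ref = profile([[90.0, 95.0, 96.0, 96.0]], np.array([5.0, 10.0, 15.0, 20.0]))
        with pytest.raises(ValueError, match="usable"):
            similarity_verdict(ref, ref)


class TestReleaseModel:
    def test_noiseless_weibull_recovered_to_four_figures(self):
        truth = DissolutionTruth(94.9, 7.0, weibull_beta=1.4, noise_sd=0.0)
        prof = gen_dissolution(truth, seed=0)
        fit = fit_release_model(prof, "weibull")
        assert fit.plateau == pytest.approx(94.9, rel=1e-4)
        assert fit.td == pytest.approx(7.0, rel=1e-4)
        assert fit.beta == pytest.approx(1.4, rel=1e-4)

    def test_first_order_is_nested_weibull(self):
        truth = DissolutionTruth(80.0, 10.0, weibull_beta=1.0, noise_sd=0.0)
        prof = gen_dissolution(truth, seed=0)
        fo = fit_release_model(prof, "first-order")
        wb = fit_release_model(prof, "weibull")
        assert fo.beta == 1.0
        assert fo.td == pytest.approx(wb.td, rel=1e-3)
        assert fo.plateau == pytest.approx(wb.plateau, rel=1e-3)

    def test_tabulated_clamps_to_plateau_beyond_last_point(self):
        prof = profile([[10.0, 40.0, 70.0, 80.0]])
        tab = fit_release_model(prof, "tabulated")
        assert fraction_dissolved(tab, 1e5) == pytest.approx(0.80)

    def test_fraction_dissolved_boundaries(self):
        m = ReleaseModel(family="weibull", plateau=94.9, td=5.0, beta=1.0)
        assert fraction_dissolved(m, 0.0) == 0.0
        assert fraction_dissolved(m, 1e6) == pytest.approx(0.949)

    def test_fraction_dissolved_monotone(self):
        m = ReleaseModel(family="weibull", plateau=90.0, td=12.0, beta=0.8)
        t = np.linspace(0.0, 300.0, 100)
        v = [fraction_dissolved(m, ti) for ti in t]
        assert np.all(np.diff(v) >= 0)

    def test_normalized_hazard_reconstructs_release_curve(self):
        # integrating h(t) over remaining solid must reproduce F(t)/F_inf
        m = ReleaseModel(family="weibull", plateau=80.0, td=20.0, beta=1.0)
        t_h = np.linspace(0.0, 2.0, 2001)   # h
        surv = np.ones_like(t_h)
        for i in range(1, len(t_h)):
            h = release_hazard(m, t_h[i - 1])
            surv[i] = surv[i - 1] * (1.0 - h * (t_h[i] - t_h[i - 1]))
        released = 1.0 - surv
        expect = [fraction_dissolved(m, ti * 60.0) / 0.80 for ti in t_h]
        assert released == pytest.approx(expect, abs=2e-3)


class TestCsvRoundTrip:
    def test_write_read_identity(self, tmp_path):
        truth = DissolutionTruth(94.9, 4.0, medium="FaSSIF", label="amlodipine-single")
        prof = gen_dissolution(truth, seed=3)
        path = tmp_path / "profiles.csv"
        write_profiles_csv([prof], str(path))
        (back,) = read_profiles_csv(str(path))
        assert back.label == prof.label and back.medium == prof.medium
        np.testing.assert_allclose(back.times, prof.times)
        np.testing.assert_allclose(back.percent_dissolved, prof.percent_dissolved)
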