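"""Trial engine: systemic model, NCA, population summaries, comparisons, fitting."""

import math
from dataclasses import replace

import numpy as np
import pytest

from oralbe.gut_absorption import DoseEvent, SolverOptions
from oralbe.synthetic_data import PopulationCV, dose_event_for
from oralbe.trial_engine import (
    EstimationProblem,
    ObservedDataset,
    SubjectParameters,
    TrialDesign,
    compare_groups,
    estimate_parameters,
    pk_parameters,
    run_trial,
    simulate_subject,
    summarize_pk,
)


class TestPkParameters:
    def test_hand_trapezoid(self):
        cmax, tmax, auc = pk_parameters([0.0, 1.0, 2.0, 3.0], [0.0, 10.0, 5.0, 2.5])
        assert cmax == 10.0 and tmax == 1.0
        assert auc == pytest.approx(16.25)

    def test_constant_profile(self):
        cmax, tmax, auc = pk_parameters([0.0, 2.0, 4.0], [3.0, 3.0, 3.0])
        assert cmax == 3.0 and tmax == 0.0
        assert auc == pytest.approx(12.0)

    def test_monotone_rising_tmax_is_last_time(self):
        _, tmax, _ = pk_parameters([0.0, 1.0, 2.0], [1.0, 2.0, 3.0])
        assert tmax == 2.0

    def test_all_zero_profile(self):
        cmax, tmax, auc = pk_parameters([0.0, 1.0], [0.0, 0.0])
        assert cmax == 0.0 and math.isnan(tmax) and auc == 0.0


class TestSummaries:
    def test_geometric_mean(self):
        s = summarize_pk([1.0, 10.0, 100.0], [1.0, 2.0, 3.0], [1.0, 1.0, 2.0])
        assert s.cmax_geomean == pytest.approx(10.0)

    def test_single_subject_range_collapses(self):
        s = summarize_pk([2.0], [5.0], [1.5])
        assert s.auc_range == (5.0, 5.0) and s.tmax_range == (1.5, 1.5)

    def test_lognormal_geomean_recovery(self, rng):
        mu, sigma = 1.2, 0.4
        x = rng.lognormal(mu, sigma, size=10000)
        s = summarize_pk(x, x, x)
        assert s.cmax_geomean == pytest.approx(math.exp(mu), rel=0.02)
        assert s.cmax_gsd == pytest.approx(math.exp(sigma), rel=0.02)


class TestSimulateSubject:
    def test_zero_dose_gives_zero_profile(self, amlodipine_dose):
        de = replace(amlodipine_dose, dose=0.0)
        d = TrialDesign(dose_event=de, prandial_state="fasted")
        s = simulate_subject(d)
        assert np.all(s.concentrations == 0.0)

    def test_dose_linearity_without_pgp(self, amlodipine_dose):
        d1 = TrialDesign(dose_event=amlodipine_dose, prandial_state="fasted")
        d2 = TrialDesign(dose_event=replace(amlodipine_dose, dose=10.0),
                         prandial_state="fasted")
        s1, s2 = simulate_subject(d1), simulate_subject(d2)
        np.testing.assert_allclose(s2.concentrations[1:], 2.0 * s1.concentrations[1:],
                                   rtol=5e-3)
        assert s2.auc == pytest.approx(2.0 * s1.auc, rel=5e-3)

    def test_bolus_matches_one_compartment_closed_form(self, amlodipine):
        de = dose_event_for(amlodipine, "single")
        d = TrialDesign(dose_event=de, prandial_state="fasted")
        s = simulate_subject(d, absorption="bolus")
        bp = amlodipine.bp_ratio
        v = amlodipine.vss * 70.0 / bp
        cl = amlodipine.clpo_l_per_h / bp * amlodipine.retrograde_fa
        expected = de.dose / v * np.exp(-cl / v * s.times) / bp * 1000.0
        np.testing.assert_allclose(s.concentrations, expected, rtol=1e-3)

    def test_auc_equals_f_dose_over_cl_in_terminal_limit(self, amlodipine):
        de = dose_event_for(amlodipine, "single")
        d = TrialDesign(dose_event=de, prandial_state="fasted", duration=600.0,
                        sampling_times=np.linspace(0.0, 600.0, 1201))
        s = simulate_subject(d)
        q, bp = 90.0, amlodipine.bp_ratio
        x = amlodipine.clpo_l_per_h / bp * amlodipine.retrograde_fa
        cl_b = q * x / (q + x)
        fh = 1.0 - cl_b / q
        auc_pred = s.fa * s.fg * fh * de.dose / (cl_b * bp) * 1000.0
        assert s.auc == pytest.approx(auc_pred, rel=0.02)


class TestRunTrial:
    def test_single_subject_zero_cv_summary_equals_subject(self, amlodipine_dose):
        d = TrialDesign(dose_event=amlodipine_dose, prandial_state="fasted",
                        n_subjects=1,
                        population_cv={"cv_cl": 0, "cv_vss": 0,
                                       "cv_gut_cyp": 0, "cv_liver_cyp": 0})
        tr = run_trial(d)
        s = tr.subjects[0]
        assert tr.summary.cmax_geomean == pytest.approx(s.cmax)
        assert tr.summary.auc_median == pytest.approx(s.auc)

    def test_same_seed_reproduces_trial(self, amlodipine_dose):
        d = TrialDesign(dose_event=amlodipine_dose, prandial_state="fasted",
                        n_subjects=3, seed=11)
        a, b = run_trial(d), run_trial(d)
        np.testing.assert_array_equal(
            a.subjects[2].concentrations, b.subjects[2].concentrations
        )
        assert a.summary == b.summary


class TestCompareGroups:
    def test_identical_groups_t_zero(self):
        r = compare_groups([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r["t"] == pytest.approx(0.0)
        assert r["gmr"] == pytest.approx(1.0)

    def test_welch_t_matches_hand_formula(self):
        a = np.array([10.0, 12.0, 14.0, 16.0])
        b = np.array([11.0, 13.0, 15.0, 21.0])
        r = compare_groups(a, b, welch=True)
        se = math.sqrt(a.var(ddof=1) / len(a) + b.var(ddof=1) / len(b))
        assert r["t"] == pytest.approx((a.mean() - b.mean()) / se)

    def test_pooled_t_matches_hand_formula(self):
        a = np.array([5.0, 7.0, 9.0])
        b = np.array([6.0, 8.0, 13.0])
        r = compare_groups(a, b, welch=False)
        sp2 = ((len(a) - 1) * a.var(ddof=1) + (len(b) - 1) * b.var(ddof=1)) / (
            len(a) + len(b) - 2
        )
        se = math.sqrt(sp2 * (1.0 / len(a) + 1.0 / len(b)))
        assert r["t"] == pytest.approx((a.mean() - b.mean()) / se)

    def test_p_decreases_with_shift(self, rng):
        base = rng.normal(10.0, 1.0, size=50)
        ps = [compare_groups(base, base + shift)["p"] for shift in (0.2, 0.5, 1.0)]
        assert ps[0] > ps[1] > ps[2]

    def test_zero_variance_exact_equality_report(self):
        r = compare_groups([2.0, 2.0], [2.0, 2.0])
        assert r["t"] is None and r["equal"] is True


class TestEstimation:
    def test_objective_near_zero_at_truth(self, amlodipine, amlodipine_dose):
        d = TrialDesign(dose_event=amlodipine_dose, prandial_state="fasted",
                        sampling_times=np.array([0.5, 1, 2, 4, 8, 12, 24.0]),
                        solver=SolverOptions(rtol=1e-8, atol=1e-10))
        sim = simulate_subject(d)
        obs = ObservedDataset(times=sim.times, concentrations=sim.concentrations,
                              dose_event=amlodipine_dose)
        # bounds centered on the true values: the first (center) start is truth
        problem = EstimationProblem(
            datasets=[obs], free_parameters=("peff", "vss"),
            bounds={"peff": (0.5 * amlodipine.peff, 1.5 * amlodipine.peff),
                    "vss": (0.5 * amlodipine.vss, 1.5 * amlodipine.vss)},
            n_starts=1, maxfev=60, xtol=1e-3, ftol=1e-6,
        )
        res = estimate_parameters(problem)
        rel = res.objective / float(np.sum(sim.concentrations**2))
        assert rel < 1e-4
        assert res.values["peff"] == pytest.approx(amlodipine.peff, rel=0.05)

    def test_invalid_problem_rejected(self, amlodipine_dose):
        with pytest.raises(ValueError):
            EstimationProblem(datasets=[], free_parameters=("peff",),
                              bounds={"peff": (1e-5, 1e-3)})
        obs = ObservedDataset(times=np.array([1.0]), concentrations=np.array([1.0]),
                              dose_event=amlodipine_dose)
        with pytest.raises(ValueError):
            EstimationProblem(datasets=[obs], free_parameters=("nope",),
                              bounds={"nope": (0.1, 1.0)})


class TestDesignSerialization:
    def test_yaml_round_trip_reproduces_simulation(self, atorvastatin_dose, tmp_path):
        from oralbe.trial_engine import load_design, save_design

        design = TrialDesign(dose_event=atorvastatin_dose, prandial_state="fed",
                             n_subjects=2, seed=3)
        path = tmp_path / "design.yaml"
        save_design(design, str(path))
        back = load_design(str(path))
        assert back.prandial_state == "fed" and back.seed == 3
        a = simulate_subject(design)
        b = simulate_subject(back)
        np.testing.assert_allclose(a.concentrations, b.concentrations, rtol=1e-12)


class TestExports:
    def test_absorption_time_series_frame(self, atorvastatin, atorvastatin_dose):
        from oralbe.gut_absorption import build_physiology, simulate_gut

        r = simulate_gut(atorvastatin, atorvastatin_dose, build_physiology("fasted"))
        df = r.to_frame()
        assert set(df["region"].unique()) >= {"stomach", "duodenum", "colon"}
        assert {"solid_mg", "dissolved_mg", "portal_rate_mg_h"} <= set(df.columns)

    def test_trial_plot_written(self, amlodipine_dose, tmp_path):
        from oralbe.plots import plot_trial_profiles, trial_bands

        tr = run_trial(TrialDesign(dose_event=amlodipine_dose,
                                   prandial_state="fasted", n_subjects=3, seed=1))
        t, mean, lo, hi = trial_bands(tr)
        assert np.all(lo <= hi)
        out = tmp_path / "trial.png"
        plot_trial_profiles([tr], labels=["fasted"], path=str(out))
        assert out.exists() and out.stat().st_size > 0
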