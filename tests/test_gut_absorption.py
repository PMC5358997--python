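"""Gut model: physiology invariants, rate laws, limits, conservation, mechanism."""

from dataclasses import replace

import numpy as np
import pytest
from scipy.linalg import expm

from oralbe.compound import CompoundProfile
from oralbe.dissolution import ReleaseModel
from oralbe.gut_absorption import (
    N_SI,
    DoseEvent,
    SolverOptions,
    build_physiology,
    gastric_release_scale,
    pgp_efflux_rate,
    segment_ka,
    simulate_gut,
)


def neutral_compound(peff=1e-4, **kw):
    defaults = dict(
        name="probe", ionization_class="neutral", mw=400.0, logp=2.0, pka=(),
        fu=0.5, bp_ratio=1.0, vss=1.0, clpo=10.0, peff=peff,
    )
    defaults.update(kw)
    return CompoundProfile(**defaults)


def release(td_min=5.0, plateau=100.0, beta=1.0):
    family = "first-order" if beta == 1.0 else "weibull"
    return ReleaseModel(family=family, plateau=plateau, td=td_min, beta=beta)


def dose_event(compound, dose=10.0, td_min=5.0):
    m = release(td_min)
    return DoseEvent(compound=compound, dose=dose, formulation="single",
                     release={"FaSSIF": m, "FeSSIF": m})


class TestPhysiology:
    def test_fed_gastric_emptying_slower(self):
        assert (build_physiology("fed").gastric_emptying_halflife
                > build_physiology("fasted").gastric_emptying_halflife)

    def test_cyp_gradient_strictly_decreasing(self):
        w = build_physiology("fasted").cyp3a4_weights
        assert np.all(np.diff(w) < 0) and w.sum() == pytest.approx(1.0)

    def test_pgp_gradient_nondecreasing(self):
        w = build_physiology("fasted").pgp_weights
        assert np.all(np.diff(w) >= 0) and w.sum() == pytest.approx(1.0)

    def test_small_intestine_mean_transit(self):
        phys = build_physiology("fasted")
        mean_h = sum(1.0 / s.transit_rate for s in phys.segments)
        assert mean_h == pytest.approx(3.3, rel=1e-9)

    def test_fed_gastric_ph_higher(self):
        assert build_physiology("fed").gastric_ph > build_physiology("fasted").gastric_ph

    def test_yaml_round_trip(self, tmp_path):
        phys = build_physiology("fed")
        phys.save(str(tmp_path / "phys.yaml"))
        import yaml

        d = yaml.safe_load((tmp_path / "phys.yaml").read_text())
        assert d["prandial_state"] == "fed"
        assert len(d["segments"]) == N_SI


class TestSegmentKa:
    def test_hand_conversion(self):
        assert segment_ka(1.35e-4, 1.25) == pytest.approx(0.7776, rel=1e-3)

    def test_zero_permeability(self):
        assert segment_ka(0.0, 1.25) == 0.0

    def test_doubling_radius_halves_ka(self):
        assert segment_ka(1e-4, 2.5) == pytest.approx(segment_ka(1e-4, 1.25) / 2.0)


class TestPgpRate:
    ARGS = dict(jmax=151.0, km=115.0, raf=8.7, weight=0.2, area=200.0, mw=588.2)

    def test_linear_regime_below_km(self):
        low = pgp_efflux_rate(0.01, **self.ARGS)
        expected = (self.ARGS["raf"] * self.ARGS["weight"] * self.ARGS["jmax"]
                    * self.ARGS["area"] * 60e-9 * self.ARGS["mw"]) * 0.01 / 115.0
        assert low == pytest.approx(expected, rel=1e-3)

    def test_saturation_above_km(self):
        vmax = (self.ARGS["raf"] * self.ARGS["weight"] * self.ARGS["jmax"]
                * self.ARGS["area"] * 60e-9 * self.ARGS["mw"])
        assert pgp_efflux_rate(1e6, **self.ARGS) == pytest.approx(vmax, rel=1e-3)

    def test_half_saturation_at_km(self):
        vmax = pgp_efflux_rate(1e9, **self.ARGS)
        assert pgp_efflux_rate(115.0, **self.ARGS) == pytest.approx(vmax / 2.0, rel=1e-3)


class TestGastricReleaseScale:
    def test_weak_acid_suppressed(self, atorvastatin):
        assert gastric_release_scale(atorvastatin, 1.8) < 0.02

    def test_base_unaffected(self, amlodipine):
        assert gastric_release_scale(amlodipine, 1.8) == 1.0

    def test_neutral_unaffected(self):
        assert gastric_release_scale(neutral_compound(), 1.8) == 1.0


class TestSimulateGut:
    def test_no_metabolism_high_permeability_absorbs_everything(self):
        c = neutral_compound(peff=5e-4)
        r = simulate_gut(c, dose_event(c, td_min=1.0), build_physiology("fasted"))
        assert r.fa == pytest.approx(1.0, abs=1e-3)
        assert r.fg == pytest.approx(1.0, abs=1e-9)

    def test_zero_permeability_absorbs_nothing(self):
        c = neutral_compound(peff=0.0)
        r = simulate_gut(c, dose_event(c), build_physiology("fasted"))
        assert r.fa == 0.0
        assert np.all(r.portal_input_rate == 0.0)

    def test_mass_conserved(self, atorvastatin, atorvastatin_dose):
        r = simulate_gut(atorvastatin, atorvastatin_dose, build_physiology("fasted"))
        assert abs(r.mass_check - 1.0) < 1e-6

    def test_regional_fa_sums_to_fa(self, atorvastatin, atorvastatin_dose):
        r = simulate_gut(atorvastatin, atorvastatin_dose, build_physiology("fed"))
        assert np.sum(r.regional_fa) == pytest.approx(r.fa, abs=1e-9)

    def test_fa_monotone_in_peff(self):
        fas = []
        for peff in (1e-5, 5e-5, 1e-4):
            c = neutral_compound(peff=peff)
            fas.append(simulate_gut(c, dose_event(c),
                                    build_physiology("fasted")).fa)
        assert fas[0] < fas[1] < fas[2]

    def test_fed_shifts_atorvastatin_absorption_distally(
        self, atorvastatin, atorvastatin_dose
    ):
        fasted = simulate_gut(atorvastatin, atorvastatin_dose,
                              build_physiology("fasted"))
        fed = simulate_gut(atorvastatin, atorvastatin_dose, build_physiology("fed"))
        idx = np.arange(8)
        site = lambda r: np.sum(idx * r.regional_fa) / np.sum(r.regional_fa)
        assert site(fed) > site(fasted)
        assert fed.fraction_metabolized < fasted.fraction_metabolized
        assert fed.fg > fasted.fg

    def test_flat_cyp_gradient_removes_most_of_the_food_effect_on_fg(
        self, atorvastatin, atorvastatin_dose
    ):
        # nearly-uniform (epsilon-graded) weights isolate the gradient as the
        # mechanism behind the fed/fasted fg difference
        eps = 1e-9
        w = 1.0 + eps * np.arange(N_SI, 0, -1)
        w /= w.sum()
        graded_diff = (
            simulate_gut(atorvastatin, atorvastatin_dose, build_physiology("fed")).fg
            - simulate_gut(atorvastatin, atorvastatin_dose,
                           build_physiology("fasted")).fg
        )
        flat_fed = replace(build_physiology("fed"), cyp3a4_weights=w)
        flat_fasted = replace(build_physiology("fasted"), cyp3a4_weights=w)
        flat_diff = (
            simulate_gut(atorvastatin, atorvastatin_dose, flat_fed).fg
            - simulate_gut(atorvastatin, atorvastatin_dose, flat_fasted).fg
        )
        assert abs(flat_diff) < 0.35 * abs(graded_diff)

    def test_instantaneous_release_matches_linear_cat_oracle(self):
        """Predissolved, metabolism-free runs must match a 9-compartment
        linear transit-absorption model solved by matrix exponential."""
        c = neutral_compound(peff=8e-5)
        phys = build_physiology("fasted")
        opts = SolverOptions(predissolved=True)
        r = simulate_gut(c, dose_event(c), phys, options=opts)

        # oracle: states = dissolved in stomach, 7 SI segments, colon
        k_ge = np.log(2.0) / phys.gastric_emptying_halflife
        kt = np.array([s.transit_rate for s in phys.segments])
        ka = np.array([segment_ka(c.peff, s.radius) for s in phys.segments])
        ka_col = segment_ka(c.peff, phys.colon_radius) * phys.colon_ka_scale
        n = 9
        A = np.zeros((n, n))
        A[0, 0] = -k_ge
        A[1, 0] = k_ge
        for i in range(N_SI):
            A[1 + i, 1 + i] = -(kt[i] + ka[i])
            if i < N_SI - 1:
                A[2 + i, 1 + i] = kt[i]
        A[8, 7] = kt[-1]
        A[8, 8] = -(phys.colon_exit_rate + ka_col)
        # augmented system accumulates absorbed amounts per segment
        absorb = np.zeros((8, n))
        absorb[:7, 1:8] = np.diag(ka)
        absorb[7, 8] = ka_col
        M = np.block([[A, np.zeros((n, 8))], [absorb, np.zeros((8, 8))]])
        z0 = np.zeros(n + 8)
        z0[0] = 1.0
        z = expm(M * 24.0) @ z0
        fa_oracle = float(np.sum(z[n:]))
        assert r.fa == pytest.approx(fa_oracle, rel=1e-3)
        np.testing.assert_allclose(r.regional_fa, z[n:], rtol=5e-3, atol=1e-6)

    def test_solver_failure_reports_context(self, atorvastatin, atorvastatin_dose):
        with pytest.raises(ValueError):
            bad = replace(build_physiology("fasted"), gastric_emptying_halflife=-1.0)
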