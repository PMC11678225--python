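"""Therapeutic window, recovery, exposure matching, statistics, sensitivity."""

from dataclasses import replace

import numpy as np
import pytest
from scipy.optimize import brentq

import canipbpk as cp
from canipbpk.population import PopulationConfig, generate_population
from canipbpk.protocol import (
    STANDARD_REGIMEN,
    TherapeuticWindow,
    _holm,
    adjust_infusion_rate,
    compare_groups,
    dunn_test,
    recovery_time,
    sensitivity_analysis,
    window_compliance,
)
from canipbpk.simulator import ConcentrationProfile, DoseRegimen, closed_form_onecomp, simulate
from canipbpk.validation import auc_from_arrays

WINDOW = TherapeuticWindow()


def profile_from(times_min, conc):
    return ConcentrationProfile(times=np.asarray(times_min) / 60.0,
                                concentrations=np.asarray(conc, dtype=float))


class TestTherapeuticWindow:
    def test_default_ordering(self):
        w = TherapeuticWindow()
        assert w.recovery_threshold < w.lower < w.induction_target < w.upper < w.adverse_threshold

    def test_rejects_scrambled_values(self):
        with pytest.raises(ValueError):
            TherapeuticWindow(lower=4.7, upper=2.5)

    def test_loads_from_shipped_fixture(self):
        w = cp.load_window()
        assert (w.lower, w.upper) == (2.5, 4.7)
        assert w.recovery_threshold == 2.15 and w.adverse_threshold == 6.5


class TestRecoveryTime:
    def test_already_below_threshold_is_zero(self):
        p = profile_from(np.arange(0, 120), np.full(120, 1.0))
        assert recovery_time(p, WINDOW, from_time=0.5) == 0.0

    def test_exponential_decay_closed_form(self):
        """Half-life arithmetic: 4.30 falling at k=0.02/min halves in 34.66 min."""
        t_min = np.arange(0.0, 300.0, 0.1)
        p = profile_from(t_min, 4.30 * np.exp(-0.02 * t_min))
        rec = recovery_time(p, WINDOW, from_time=0.0)
        assert rec == pytest.approx(np.log(2.0) / 0.02, abs=0.05)

    def test_censored_returns_none(self):
        p = profile_from(np.arange(0, 60), np.full(60, 3.0))
        assert recovery_time(p, WINDOW, from_time=0.0) is None

    def test_from_time_outside_span_rejected(self):
        p = profile_from(np.arange(0, 60), np.full(60, 3.0))
        with pytest.raises(ValueError):
            recovery_time(p, WINDOW, from_time=5.0)


class TestWindowCompliance:
    def test_counting(self):
        t = np.linspace(0, 1, 5)
        profs = [
            ConcentrationProfile(times=t, concentrations=np.full_like(t, c))
            for c in (3.0, 2.6, 4.0, 5.0)  # 3 of 4 inside
        ]
        res = window_compliance(profs, 0.5, WINDOW)
        assert res.fraction_in == pytest.approx(0.75)
        assert res.fraction_above_upper == pytest.approx(0.25)
        assert res.fraction_above_adverse == 0.0

    def test_all_at_induction_target(self):
        t = np.linspace(0, 1, 5)
        profs = [ConcentrationProfile(times=t, concentrations=np.full_like(t, 3.0))] * 4
        res = window_compliance(profs, 0.5, WINDOW)
        assert res.fraction_in == 1.0 and res.fraction_above_upper == 0.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            window_compliance([], 0.5, WINDOW)


class TestGroupStatistics:
    def test_identical_groups_not_significant(self):
        g = {"a": [1.0, 2.0, 3.0, 4.0], "b": [1.0, 2.0, 3.0, 4.0]}
        res = compare_groups(g)
        assert res.kruskal_p > 0.05

    def test_hand_ranked_h_statistic(self):
        """Groups {1,2,3} vs {4,5,6}: rank sums 6 and 15 give H = 3.857."""
        res = compare_groups({"lo": [1.0, 2.0, 3.0], "hi": [4.0, 5.0, 6.0]})
        h_hand = 12.0 / (6 * 7) * (6.0**2 / 3 + 15.0**2 / 3) - 3 * 7
        assert res.kruskal_h == pytest.approx(h_hand)

    def test_dunn_z_matches_hand_computation(self):
        d = dunn_test({"lo": [1.0, 2.0, 3.0], "hi": [4.0, 5.0, 6.0]}, adjust=None)
        # mean ranks 2 and 5; variance base N(N+1)/12 = 3.5 (no ties)
        se = np.sqrt(3.5 * (1 / 3 + 1 / 3))
        assert d["z"].iloc[0] == pytest.approx((2.0 - 5.0) / se)

    def test_all_tied_reported_not_crashed(self):
        res = compare_groups({"a": [2.0, 2.0, 2.0], "b": [2.0, 2.0, 2.0]})
        assert res.degenerate and np.isnan(res.kruskal_p)

    def test_holm_adjustment_known_vector(self):
        adj = _holm(np.array([0.01, 0.04, 0.03]))
        assert adj == pytest.approx([0.03, 0.06, 0.06])

    def test_validates_input(self):
        with pytest.raises(ValueError):
            compare_groups({"a": [1.0, 2.0]})
        with pytest.raises(ValueError):
            compare_groups({"a": [1.0, 2.0], "b": [1.0]})


class TestAdjustInfusionRate:
    def test_zero_impairment_returns_reference_rate(self, calibrated, template):
        drug, cal = calibrated
        pop = generate_population(PopulationConfig(n=20, seed=4), cal.cl_per_kg,
                                  template=template)
        res = adjust_infusion_rate(0.0, STANDARD_REGIMEN, drug, pop, horizon_h=13.0)
        assert res.adjusted_rate == STANDARD_REGIMEN.infusion_rate
        assert res.auc0_3_ratio_to_healthy == pytest.approx(1.0)

    def test_matches_healthy_exposure_within_tolerance(self, calibrated, template):
        drug, cal = calibrated
        pop = generate_population(PopulationConfig(n=60, seed=4), cal.cl_per_kg,
                                  template=template)
        res = adjust_infusion_rate(0.6, STANDARD_REGIMEN, drug, pop, horizon_h=13.0)
        assert res.adjusted_rate < STANDARD_REGIMEN.infusion_rate
        assert abs(res.auc0_3_ratio_to_healthy - 1.0) < 0.02
        assert res.kruskal_p_auc0_3 > 0.05  # exposure equalized
        assert res.kruskal_p_auc3_12 < 0.05  # elimination still differs

    def test_one_compartment_closed_form_oracle(self, onecomp_template, onecomp_drug):
        """The bisected rate agrees with the analytic exposure-matching rate."""
        cl_per_kg = 30.0
        ind = cp.make_individual(10.5, cl_per_kg, template=onecomp_template)
        pop = [replace(ind, subject_id=f"s{i}") for i in range(4)]
        impairment = 0.5
        res = adjust_infusion_rate(
            impairment, STANDARD_REGIMEN, onecomp_drug, pop,
            impairment_mode="plasma", horizon_h=13.0,
        )
        # analytic counterpart on the one-compartment closed form
        bw = 10.5
        vol = 0.095 * bw * 1000.0
        t_end = STANDARD_REGIMEN.infusion_end_min / 60.0
        grid = np.arange(0.0, 13.0, 1.0 / 120.0)

        def auc_cf(cl_ml_min, rate):
            prof = closed_form_onecomp(
                5.0 * bw, vol, cl_ml_min, grid, bolus_duration_s=60.0,
                infusion_rate_mg_min=rate * bw, infusion_start_min=1.0,
                infusion_duration_min=180.0,
            )
            return auc_from_arrays(prof.times, prof.concentrations, 0.0, t_end)

        cl = cl_per_kg * bw
        target = auc_cf(cl, STANDARD_REGIMEN.infusion_rate)
        rate_analytic = brentq(
            lambda r: auc_cf(cl * (1 - impairment), r) - target, 1e-6, 0.13
        )
        assert res.adjusted_rate == pytest.approx(rate_analytic, rel=0.01)

    def test_rejects_invalid_impairment(self, calibrated, template):
        drug, cal = calibrated
        pop = generate_population(PopulationConfig(n=5, seed=1), cal.cl_per_kg,
                                  template=template)
        with pytest.raises(ValueError):
            adjust_infusion_rate(1.0, STANDARD_REGIMEN, drug, pop)


@pytest.fixture(scope="module")
def arm_profiles(calibrated):
    drug, cal = calibrated
    ind = cp.make_individual(10.5, cal.cl_per_kg)
    out = {}
    for imp in (0.0, 0.3, 0.6):
        subject = cp.apply_impairment(ind, imp) if imp else ind
        out[imp] = simulate(subject, drug, STANDARD_REGIMEN, horizon_h=20.0)
    return out


class TestImpairmentMonotonicity:
    def test_auc_strictly_increasing_in_impairment(self, arm_profiles):
        t_end = STANDARD_REGIMEN.infusion_end_min / 60.0
        aucs = [cp.auc(p, 0.0, t_end) for p in arm_profiles.values()]
        assert aucs[0] < aucs[1] < aucs[2]

    def test_recovery_nondecreasing_in_impairment(self, arm_profiles):
        t_end = STANDARD_REGIMEN.infusion_end_min / 60.0
        recs = [recovery_time(p, WINDOW, from_time=t_end) for p in arm_profiles.values()]
        assert all(r is not None for r in recs)
        assert recs[0] < recs[1] < recs[2]


class TestSensitivity:
    def test_inert_parameter_has_zero_sensitivity(self, calibrated):
        drug, cal = calibrated
        (res,) = sensitivity_analysis(["solubility_ref"], drug, cal.cl_per_kg,
                                      horizon_h=6.0)
        assert res.applicable and res.s_auc == pytest.approx(0.0, abs=1e-9)

    def test_unknown_parameter_reported_not_zeroed(self, calibrated):
        drug, cal = calibrated
        (res,) = sensitivity_analysis(["gill_volume"], drug, cal.cl_per_kg)
        assert not res.applicable and res.s_auc is None

    def test_clearance_sensitivity_is_minus_one_in_onecomp_limit(
        self, onecomp_template, onecomp_drug
    ):
        (res,) = sensitivity_analysis(
            ["clearance"], onecomp_drug, 100.0 / 10.5,
            template=onecomp_template, horizon_h=12.0,
        )
        # central difference of AUC ~ 1/CL at delta=0.1 evaluates to -1.0101
        assert res.s_auc == pytest.approx(-1.0, abs=0.02)

    def test_rejects_nonpositive_delta(self, calibrated):
        drug, cal = calibrated
        with pytest.raises(ValueError):
            sensitivity_analysis(["clearance"], drug, cal.cl_per_kg, relative_delta=0.0)


class TestRunFullAnalysis:
    def test_small_end_to_end_bundle(self, tmp_path):
        from canipbpk.protocol import AnalysisConfig, run_full_analysis

        cfg = AnalysisConfig(seed=5, n=24, impairments=(0.4,),
                             include_sensitivity=False, horizon_h=13.0)
        bundle = run_full_analysis(cfg)
        assert len(bundle.table1) == 9
        (adj,) = bundle.adjustments
        assert adj.adjusted_rate < STANDARD_REGIMEN.infusion_rate
        assert bundle.unadjusted["recovery_min"].is_monotonic_increasing
        bundle.save(tmp_path)
        for name in ("table1_repro.csv", "unadjusted_arms.csv", "summary.json",
                     "healthy_median_profile.csv"):
            assert (tmp_path / name).exists()
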