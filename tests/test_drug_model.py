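"""Partition coefficients, clearance calibration, and hepatic impairment."""

import io
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import canipbpk as cp
from canipbpk.drug_model import (
    CalibrationError,
    _fu_tissue,
    realized_clearance_from_process,
    process_coefficient_from_realized,
)
from canipbpk.physiology import OrganSpec
from canipbpk.simulator import DoseRegimen, simulate
from canipbpk.validation import StudyRecord


def organ(name="t", fw=0.7, fnl=0.1, fph=0.01, fpr=0.1, **kw):
    return OrganSpec(name=name, volume_fraction=kw.get("vol", 0.1),
                     flow_fraction=kw.get("flow", 0.1),
                     f_water=fw, f_neutral_lipid=fnl, f_phospholipid=fph, f_protein=fpr)


PLASMA = organ("plasma", fw=0.945, fnl=0.0035, fph=0.00225, fpr=0.07, vol=0.0, flow=0.0)


class TestComputeKp:
    @pytest.mark.parametrize("method", ["standard", "nobind"])
    @pytest.mark.parametrize("kp_scale", [1.0, 0.25, 2.0])
    def test_symmetry_organ_equals_plasma(self, drug0, method, kp_scale):
        """Identical tissue and plasma composition must give Kp = kp_scale."""
        d = replace(drug0, kp_scale=kp_scale)
        same = replace(PLASMA, name="twin")
        assert cp.compute_kp(d, same, PLASMA, method=method) == pytest.approx(kp_scale)

    def test_hand_evaluated_formula(self):
        """Term-by-term evaluation of the documented scheme at P=1000, fu=1."""
        d = cp.DrugParameters(logp=3.0, fu_plasma=1.0, kp_scale=1.0)
        tissue = organ(fw=0.3, fnl=0.5, fph=0.1, fpr=0.0)
        plasma = organ("plasma", fw=0.94, fnl=0.003, fph=0.002, fpr=0.0)
        p = 1000.0
        mem = 0.3 * p + 0.7
        expected = (p * 0.5 + mem * 0.1 + 0.3) / (p * 0.003 + mem * 0.002 + 0.94)
        assert cp.compute_kp(d, tissue, plasma) == pytest.approx(expected, rel=1e-12)

    def test_lipophilic_drug_partitions_into_fat(self, drug0):
        """With the propofol parameters, fat-rich tissue out-partitions watery tissue."""
        fat = organ("fat", fw=0.18, fnl=0.79, fph=0.002, fpr=0.05)
        watery = organ("lean", fw=0.79, fnl=0.02, fph=0.016, fpr=0.13)
        assert cp.compute_kp(drug0, fat, PLASMA) > cp.compute_kp(drug0, watery, PLASMA)

    def test_rejects_unknown_method_and_bad_plasma(self, drug0):
        with pytest.raises(ValueError):
            cp.compute_kp(drug0, organ(), PLASMA, method="rodgers")
        empty_plasma = organ("plasma", fw=0.0, fnl=0.0, fph=0.0, fpr=0.0)
        with pytest.raises(ValueError):
            cp.compute_kp(drug0, organ(), empty_plasma)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        fw=st.floats(0.05, 0.9),
        fnl=st.floats(0.0, 0.5),
        fph=st.floats(0.0, 0.1),
        fpr=st.floats(0.0, 0.2),
        scale=st.floats(0.05, 3.0),
    )
    def test_kp_positive_and_scale_linear(self, fw, fnl, fph, fpr, scale):
        """Kp > 0 for any admissible composition, and linear in kp_scale."""
        d1 = cp.DrugParameters(kp_scale=1.0)
        ds = cp.DrugParameters(kp_scale=scale)
        t = organ(fw=fw, fnl=fnl, fph=fph, fpr=fpr)
        k1 = cp.compute_kp(d1, t, PLASMA)
        assert k1 > 0
        assert cp.compute_kp(ds, t, PLASMA) == pytest.approx(scale * k1, rel=1e-12)

    def test_fu_tissue_reduces_with_protein(self):
        assert _fu_tissue(0.02, 0.14, 0.07) == pytest.approx(1.0 / (1.0 + 49.0 * 2.0))
        assert _fu_tissue(1.0, 0.2, 0.07) == 1.0  # fully unbound drug stays unbound


class TestPartitionSet:
    def test_one_kp_per_organ(self, drug0, template):
        phys = cp.build_reference_dog(10.5, template=template)
        ps = cp.partition_set(drug0, phys)
        assert set(ps.kp_by_organ) == set(phys.organ_map)
        assert all(v > 0 for v in ps.kp_by_organ.values())


class TestCalibrateClearance:
    def test_dose_over_auc_arithmetic(self, drug0, studies):
        """28 mg/kg over 13.81 µg·h/mL is 33.79 mL/min/kg."""
        phys = cp.build_reference_dog(10.5)
        res = cp.calibrate_clearance(drug0, phys, studies, check=False)
        assert res.cl_per_kg == pytest.approx(28.0 * 1000.0 / 13.81 / 60.0, rel=1e-12)
        assert res.cl_per_kg == pytest.approx(33.79, abs=0.02)
        assert res.spec_input_per_kg == 47.08  # carried, not used as-is

    def test_identity_when_auc_matches_set_clearance(self, drug0):
        """A study whose predicted AUC encodes CL directly returns that CL."""
        cl_set = 30.0  # mL/min/kg
        regimen = DoseRegimen(bolus_dose=4.0, infusion_rate=0.4, infusion_duration_min=60.0)
        study = StudyRecord(
            study_id="direct", label="direct", regimen=regimen, body_weight=10.0,
            n_animals=1, role="development",
            predicted_auclast=regimen.total_dose_per_kg * 1000.0 / cl_set / 60.0,
        )
        phys = cp.build_reference_dog(10.0)
        res = cp.calibrate_clearance(drug0, phys, [study], reference_study_id="direct",
                                     check=False)
        assert res.cl_per_kg == pytest.approx(cl_set, rel=1e-12)

    def test_idempotent(self, drug0, studies):
        phys = cp.build_reference_dog(10.5)
        a = cp.calibrate_clearance(drug0, phys, studies, check=False)
        b = cp.calibrate_clearance(drug0, phys, studies, check=False)
        assert a.cl_per_kg == b.cl_per_kg

    def test_simulation_check_passes_after_full_calibration(self, calibrated):
        drug, cal = calibrated
        assert cal.relative_error is not None and cal.relative_error < 0.05

    def test_requires_infusion_study(self, drug0, studies):
        phys = cp.build_reference_dog(10.5)
        with pytest.raises(ValueError):
            cp.calibrate_clearance(drug0, phys, studies,
                                   reference_study_id="zoran_1993", check=False)


class TestKpScaleCalibration:
    def test_hits_window_target_and_is_reproducible(self, calibrated):
        drug, cal = calibrated
        ind = cp.make_individual(10.5, cal.cl_per_kg)
        prof = simulate(ind, drug, cp.STANDARD_REGIMEN, horizon_h=3.2)
        t_end = cp.STANDARD_REGIMEN.infusion_end_min / 60.0
        target = np.sqrt(2.5 * 4.7)
        assert prof.at(t_end) == pytest.approx(target, abs=0.02)
        assert 2.5 <= prof.at(t_end) <= 4.7
        again = cp.calibrate_kp_scale(replace(drug, kp_scale=1.0), cal.cl_per_kg)
        assert again.kp_scale == pytest.approx(drug.kp_scale, abs=1e-3)


class TestApplyImpairment:
    def test_zero_impairment_is_identity(self, calibrated):
        _, cal = calibrated
        ind = cp.make_individual(10.5, cal.cl_per_kg)
        assert cp.apply_impairment(ind, 0.0) is ind

    def test_plasma_mode_arithmetic(self):
        ind = cp.make_individual(10.0, 33.8)
        hit = cp.apply_impairment(ind, 0.8)
        assert hit.cl_per_kg == pytest.approx(6.76)
        assert hit.impairment == 0.8
        assert hit.physiology is ind.physiology  # everything else untouched

    @pytest.mark.parametrize("bad", [-0.1, 1.0, 1.5])
    def test_rejects_out_of_range(self, bad):
        ind = cp.make_individual(10.0, 33.8)
        with pytest.raises(ValueError):
            cp.apply_impairment(ind, bad)

    def test_process_mode_compresses_via_flow_limitation(self, drug0):
        """Scaling the hepatic coefficient leaves more realized clearance."""
        ind = cp.make_individual(10.5, 33.79)
        q_h = ind.physiology.hepatic_blood_flow
        k = process_coefficient_from_realized(ind.cl_plasma, q_h, drug0.bp_ratio)
        expected = realized_clearance_from_process(0.2 * k, q_h, drug0.bp_ratio)
        hit = cp.apply_impairment(ind, 0.8, mode="process", drug=drug0)
        assert hit.cl_plasma == pytest.approx(expected, rel=1e-12)
        plasma_mode = cp.apply_impairment(ind, 0.8, mode="plasma")
        assert hit.cl_plasma > plasma_mode.cl_plasma  # compression
        # round trip of the well-stirred inversion
        assert realized_clearance_from_process(k, q_h, drug0.bp_ratio) == pytest.approx(
            ind.cl_plasma
        )

    def test_steady_state_concentration_scales_inversely(self, onecomp_template, onecomp_drug):
        """80% impairment at constant rate gives exactly 5x the healthy Css."""
        cl_per_kg = 30.0
        ind = cp.make_individual(10.5, cl_per_kg, template=onecomp_template)
        regimen = DoseRegimen(bolus_dose=0.0, infusion_rate=0.13,
                              infusion_duration_min=360.0, infusion_start_min=0.0)
        healthy = simulate(ind, onecomp_drug, regimen, horizon_h=6.0)
        impaired = simulate(cp.apply_impairment(ind, 0.8), onecomp_drug, regimen,
                            horizon_h=6.0)
        ratio = impaired.at(6.0) / healthy.at(6.0)
        assert ratio == pytest.approx(5.0, rel=1e-3)
        assert healthy.at(6.0) == pytest.approx(0.13 * 1000.0 / cl_per_kg, rel=1e-3)


def test_drug_round_trip_and_invariants(drug0):
    buf = io.StringIO()
    cp.dump_drug(drug0, buf)
    again = cp.load_drug(io.StringIO(buf.getvalue()))
    assert again == drug0
    with pytest.raises(ValueError):
        cp.DrugParameters(fu_plasma=0.0)
    with pytest.raises(ValueError):
        cp.DrugParameters(bp_ratio=-1.0)
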