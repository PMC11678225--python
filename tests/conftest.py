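"""Shared fixtures: calibrated model and degenerate one-compartment setups."""

from __future__ import annotations

import copy

import pytest

import canipbpk as cp


@pytest.fixture(scope="session")
def drug0():
    """Uncalibrated propofol parameters as shipped."""
    return cp.load_drug()


@pytest.fixture(scope="session")
def studies():
    return cp.load_studies()


@pytest.fixture(scope="session")
def calibrated(drug0, studies):
    """(drug with calibrated kp_scale, CalibrationResult) - shared, expensive."""
    return cp.calibrate_model(drug0, studies)


@pytest.fixture(scope="session")
def template():
    return cp.load_template()


def make_onecomp_template(volume_ml_per_kg: float = 95.0) -> dict:
    """Template whose PBPK system collapses to one well-mixed compartment.

    Organ volumes are negligible, organ compositions equal plasma (Kp =
    kp_scale), and cardiac output is enormous so all pools mix instantly; the
    total volume is the blood volume. Used as the closed-form oracle's
    counterpart.
    """
    tpl = copy.deepcopy(cp.load_template())
    plasma = tpl["plasma"]
    for entry in tpl["organs"]:
        entry["volume_fraction"] = 1e-7
        for key in ("f_water", "f_neutral_lipid", "f_phospholipid", "f_protein"):
            entry[key] = plasma[key]
    tpl["venous_blood_fraction"] = volume_ml_per_kg / 1000.0 * 0.6
    tpl["arterial_blood_fraction"] = volume_ml_per_kg / 1000.0 * 0.4
    tpl["cardiac_output_ml_min_ref"] = 1.0e6
    return tpl


@pytest.fixture(scope="session")
def onecomp_template():
    return make_onecomp_template()


@pytest.fixture(scope="session")
def onecomp_drug(drug0):
    """Drug with neutral partitioning and B:P 1 for the one-compartment limit."""
    from dataclasses import replace

    return replace(drug0, kp_scale=1.0, bp_ratio=1.0)
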