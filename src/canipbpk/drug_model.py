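"""Propofol parameters, tissue partitioning, and clearance calibration.

Distribution is perfusion-limited, so each tissue is characterized by a single
tissue:plasma partition coefficient (Kp) predicted from tissue composition and
the drug's lipophilicity, with a protein-binding correction. A single global
factor ``kp_scale`` multiplies every Kp; it is the model's distribution
calibration knob and absorbs differences between composition tables.

Elimination is a hepatic plasma-clearance term. The *realized* total plasma
clearance (dose / AUC-infinity, referenced to venous plasma) is the quantity
the model controls: `calibrate_clearance` fixes it from a reference study's
dose-over-AUC arithmetic, and the simulator back-computes the liver
elimination coefficient from the well-stirred relation

    CL_realized = k_liver / (1 + k_liver / (B:P * Q_hepatic))

so that realized clearance is exact by construction. Hepatic impairment
scales realized plasma clearance directly by (1 - impairment).
"""

from __future__ import annotations

import importlib.resources
import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import yaml

from .physiology import CaninePhysiology, OrganSpec, build_reference_dog

__all__ = [
    "DrugParameters",
    "PartitionSet",
    "Individual",
    "CalibrationResult",
    "CalibrationError",
    "load_drug",
    "dump_drug",
    "compute_kp",
    "partition_set",
    "make_individual",
    "apply_impairment",
    "calibrate_clearance",
    "calibrate_kp_scale",
]

KP_METHODS = ("standard", "nobind")


class CalibrationError(RuntimeError):
    """Raised when a calibration step cannot reach its target."""


@dataclass(frozen=True)
class DrugParameters:
    """Substance parameters; see the shipped ``propofol.yaml``.

    ``hepatic_clearance_spec`` (mL/min/kg) is carried as the whole-body-model
    specification input it is; the elimination actually used is the realized
    plasma clearance set by :func:`calibrate_clearance`. ``pka_acid`` and
    ``solubility_ref`` are inert metadata for a neutral (pKa 11.1) compound in
    a flow-limited i.v. model.
    """

    name: str = "propofol"
    molecular_weight: float = 178.27  # g/mol
    pka_acid: float = 11.1
    logp: float = 3.49
    solubility_ref: float = 0.12  # mg/mL
    bp_ratio: float = 2.36  # blood:plasma concentration ratio
    fu_plasma: float = 0.02  # unbound fraction in plasma
    hepatic_clearance_spec: float = 47.08  # mL/min/kg, specification input
    kp_scale: float = 1.0  # global partition calibration factor

    def __post_init__(self) -> None:
        if not (0.0 < self.fu_plasma <= 1.0):
            raise ValueError(f"fu_plasma must lie in (0, 1], got {self.fu_plasma}")
        if self.bp_ratio <= 0:
            raise ValueError("bp_ratio must be positive")
        if self.hepatic_clearance_spec < 0:
            raise ValueError("hepatic_clearance_spec must be nonnegative")
        if self.molecular_weight <= 0:
            raise ValueError("molecular_weight must be positive")
        if self.kp_scale <= 0:
            raise ValueError("kp_scale must be positive")


_DRUG_FIELDS = (
    "name",
    "molecular_weight",
    "pka_acid",
    "logp",
    "solubility_ref",
    "bp_ratio",
    "fu_plasma",
    "hepatic_clearance_spec",
    "kp_scale",
)


def load_drug(path_or_stream=None) -> DrugParameters:
    """Load drug parameters from YAML; defaults to the shipped propofol file."""
    if path_or_stream is None:
        ref = importlib.resources.files("canipbpk.data").joinpath("propofol.yaml")
        with ref.open("r") as fh:
            raw = yaml.safe_load(fh)
    elif hasattr(path_or_stream, "read"):
        raw = yaml.safe_load(path_or_stream)
    else:
        with open(path_or_stream) as fh:
            raw = yaml.safe_load(fh)
    kwargs = {k: raw[k] for k in _DRUG_FIELDS if k in raw}
    return DrugParameters(**kwargs)


def dump_drug(drug: DrugParameters, path_or_stream) -> None:
    data = {k: getattr(drug, k) for k in _DRUG_FIELDS}
    text = yaml.safe_dump(data, sort_keys=True)
    if hasattr(path_or_stream, "write"):
        path_or_stream.write(text)
    else:
        with open(path_or_stream, "w") as fh:
            fh.write(text)


# ---------------------------------------------------------------------------
# partition coefficients


def _fu_tissue(fu_plasma: float, f_protein_tissue: float, f_protein_plasma: float) -> float:
    """Tissue unbound fraction from the plasma protein-binding ratio."""
    if f_protein_plasma <= 0:
        return 1.0
    ratio = (1.0 - fu_plasma) / fu_plasma * (f_protein_tissue / f_protein_plasma)
    return 1.0 / (1.0 + ratio)


def compute_kp(
    drug: DrugParameters,
    organ: OrganSpec,
    plasma_composition: OrganSpec,
    method: str = "standard",
) -> float:
    """Tissue:plasma partition coefficient for one organ.

    Default (``standard``) scheme:

        Kp = kp_scale
             * [P*f_nl,t + (0.3P + 0.7)*f_ph,t + f_w,t]
               / [P*f_nl,p + (0.3P + 0.7)*f_ph,p + f_w,p]
             * fu_plasma / fu_tissue

    with P = 10**logP, where the phospholipid term treats membranes as 30%
    lipid-like / 70% water-like, and fu_tissue follows from scaling plasma
    protein binding by the tissue:plasma protein ratio:

        fu_t = 1 / (1 + ((1 - fu_p)/fu_p) * (f_pr,t / f_pr,p))

    ``nobind`` omits the binding correction (homogenate partitioning only).
    Both satisfy Kp = kp_scale whenever the organ composition equals the
    plasma composition.
    """
    if method not in KP_METHODS:
        raise ValueError(f"unknown Kp method {method!r}; available: {KP_METHODS}")
    for spec in (organ, plasma_composition):
        for attr in ("f_water", "f_neutral_lipid", "f_phospholipid", "f_protein"):
            if getattr(spec, attr) < 0:
                raise ValueError(f"{spec.name}: negative composition fraction {attr}")
    p = 10.0 ** drug.logp
    mem = 0.3 * p + 0.7

    def homogenate(spec: OrganSpec) -> float:
        return p * spec.f_neutral_lipid + mem * spec.f_phospholipid + spec.f_water

    denom = homogenate(plasma_composition)
    if denom <= 0:
        raise ValueError("plasma composition gives a zero partition denominator")
    kp = homogenate(organ) / denom
    if method == "standard":
        fu_t = _fu_tissue(drug.fu_plasma, organ.f_protein, plasma_composition.f_protein)
        fu_p_eff = _fu_tissue(
            drug.fu_plasma, plasma_composition.f_protein, plasma_composition.f_protein
        )
        kp *= fu_p_eff / fu_t
    return drug.kp_scale * kp


@dataclass(frozen=True)
class PartitionSet:
    """One Kp per organ of a physiology."""

    kp_by_organ: dict[str, float]
    method: str

    def __post_init__(self) -> None:
        bad = {k: v for k, v in self.kp_by_organ.items() if not (v > 0)}
        if bad:
            raise ValueError(f"non-positive partition coefficients: {bad}")

    def __getitem__(self, organ: str) -> float:
        return self.kp_by_organ[organ]


def partition_set(
    drug: DrugParameters, phys: CaninePhysiology, method: str = "standard"
) -> PartitionSet:
    kps = {o.name: compute_kp(drug, o, phys.plasma, method=method) for o in phys.organs}
    return PartitionSet(kp_by_organ=kps, method=method)


# ---------------------------------------------------------------------------
# individuals and impairment


@dataclass(frozen=True)
class Individual:
    """One virtual dog: physiology plus realized total plasma clearance.

    ``cl_plasma`` is the whole-body realized plasma clearance in mL/min
    (dose / AUC-infinity referenced to venous plasma). ``impairment`` records
    the hepatic-impairment fraction already folded into ``cl_plasma``;
    ``multipliers`` records any population variability multipliers applied.
    """

    physiology: CaninePhysiology
    cl_plasma: float  # mL/min, realized
    subject_id: str = "ref"
    impairment: float = 0.0
    multipliers: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.cl_plasma < 0:
            raise ValueError("realized clearance must be nonnegative")

    @property
    def cl_per_kg(self) -> float:
        """Realized plasma clearance in mL/min/kg."""
        return self.cl_plasma / self.physiology.body_weight


def make_individual(
    body_weight: float,
    cl_per_kg: float,
    template: dict | None = None,
    subject_id: str = "ref",
    lumped: bool = False,
) -> Individual:
    phys = build_reference_dog(body_weight, template=template, lumped=lumped)
    return Individual(
        physiology=phys, cl_plasma=cl_per_kg * body_weight, subject_id=subject_id
    )


def realized_clearance_from_process(k_process: float, hepatic_blood_flow: float,
                                    bp_ratio: float) -> float:
    """Realized plasma clearance produced by a hepatic elimination coefficient.

    Well-stirred flow limitation: CL = k / (1 + k / (B:P * Q_hepatic)); the
    realized clearance saturates at the hepatic plasma-equivalent flow.
    """
    cap = bp_ratio * hepatic_blood_flow
    return k_process / (1.0 + k_process / cap)


def process_coefficient_from_realized(cl_plasma: float, hepatic_blood_flow: float,
                                      bp_ratio: float) -> float:
    """Invert the well-stirred relation (cl must stay below B:P * Q_hepatic)."""
    cap = bp_ratio * hepatic_blood_flow
    if cl_plasma >= cap:
        raise ValueError(
            f"plasma clearance {cl_plasma:.1f} mL/min is at or above the hepatic "
            f"flow ceiling {cap:.1f} mL/min"
        )
    return cl_plasma / (1.0 - cl_plasma / cap)


def apply_impairment(
    individual: Individual,
    impairment: float,
    mode: str = "plasma",
    drug: DrugParameters | None = None,
) -> Individual:
    """Return a copy with hepatic function reduced by ``impairment``.

    ``mode="plasma"`` scales the realized total plasma clearance directly to
    (1 - impairment) times the healthy value. ``mode="process"`` scales the
    hepatic elimination coefficient (the knob a whole-body simulator exposes)
    by (1 - impairment); hepatic flow limitation then compresses the realized
    reduction (e.g. an 80% process reduction leaves ~29% of realized clearance
    rather than 20%). Process mode needs ``drug`` for the blood:plasma ratio.
    """
    if not (0.0 <= impairment < 1.0):
        raise ValueError(f"impairment must lie in [0, 1), got {impairment!r}")
    if mode not in ("plasma", "process"):
        raise ValueError(f"unknown impairment mode {mode!r}")
    if impairment == 0.0:
        return individual
    if individual.impairment != 0.0:
        raise ValueError("individual already carries an impairment; start from healthy")
    if mode == "plasma":
        cl = individual.cl_plasma * (1.0 - impairment)
    else:
        if drug is None:
            raise ValueError("process-mode impairment needs the drug parameters (B:P ratio)")
        q_h = individual.physiology.hepatic_blood_flow
        k = process_coefficient_from_realized(individual.cl_plasma, q_h, drug.bp_ratio)
        cl = realized_clearance_from_process(k * (1.0 - impairment), q_h, drug.bp_ratio)
    return replace(individual, cl_plasma=cl, impairment=impairment)


# ---------------------------------------------------------------------------
# calibration


@dataclass(frozen=True)
class CalibrationResult:
    """Outcome of the clearance calibration.

    ``cl_per_kg`` is the realized total plasma clearance the simulator will
    reproduce exactly; ``spec_input_per_kg`` is the whole-body model's printed
    hepatic-clearance input, retained as metadata. The gap between the two is
    a documented output (flow limitation inside a well-stirred liver raises
    the required elimination coefficient above the realized clearance).
    """

    cl_per_kg: float  # mL/min/kg realized plasma clearance
    kp_scale: float
    reference_study_id: str
    spec_input_per_kg: float
    simulated_auc: float | None  # µg·h/mL, verification simulation
    target_auc: float | None  # µg·h/mL, the reference study's predicted AUClast
    relative_error: float | None


def _total_dose_per_kg(study) -> float:
    dose = study.regimen.bolus_dose + study.regimen.infusion_rate * study.regimen.infusion_duration_min
    for rate, _start, duration in study.regimen.extra_infusions:
        dose += rate * duration
    return dose


def calibrate_clearance(
    drug: DrugParameters,
    phys: CaninePhysiology,
    reference_studies: Sequence,
    reference_study_id: str = "nolan_reid_1993",
    check: bool = True,
    tol: float = 0.05,
) -> CalibrationResult:
    """Set realized plasma clearance from a reference study's dose/AUC.

    The liver elimination term is chosen (inside the simulator, via the
    well-stirred inversion) so the realized total plasma clearance equals
    total dose per kg divided by the reference study's predicted AUC-infinity.
    With ``check=True`` the reference design is re-simulated and the achieved
    AUClast compared against the target; a residual above ``tol`` raises
    :class:`CalibrationError`.
    """
    candidates = {s.study_id: s for s in reference_studies}
    if reference_study_id not in candidates:
        raise ValueError(f"reference study {reference_study_id!r} not among supplied studies")
    study = candidates[reference_study_id]
    if study.regimen.infusion_rate <= 0:
        raise ValueError("clearance calibration requires an infusion study")
    if study.predicted_auclast is None or study.predicted_auclast <= 0:
        raise ValueError("reference study has no usable predicted AUClast")
    # mg/kg -> µg/kg over µg·h/mL -> mL/h/kg -> mL/min/kg
    cl_per_kg = _total_dose_per_kg(study) * 1000.0 / study.predicted_auclast / 60.0

    simulated = rel_err = None
    if check:
        from . import simulator, validation  # deferred: simulator imports this module

        ind = Individual(
            physiology=build_reference_dog(study.body_weight),
            cl_plasma=cl_per_kg * study.body_weight,
            subject_id=reference_study_id,
        )
        prof = simulator.simulate(ind, drug, study.regimen, horizon_h=24.0)
        simulated = validation.auc(prof, 0.0, 24.0)
        rel_err = abs(simulated - study.predicted_auclast) / study.predicted_auclast
        if rel_err > tol:
            raise CalibrationError(
                f"calibration residual {rel_err:.3%} exceeds {tol:.1%} "
                f"(simulated {simulated:.2f} vs target {study.predicted_auclast:.2f} µg·h/mL)"
            )

    return CalibrationResult(
        cl_per_kg=cl_per_kg,
        kp_scale=drug.kp_scale,
        reference_study_id=reference_study_id,
        spec_input_per_kg=drug.hepatic_clearance_spec,
        simulated_auc=simulated,
        target_auc=study.predicted_auclast,
        relative_error=rel_err,
    )


def calibrate_kp_scale(
    drug: DrugParameters,
    cl_per_kg: float,
    target_conc: float | None = None,
    body_weight: float = 10.5,
    regimen=None,
    bracket: tuple[float, float] = (0.01, 3.0),
    xtol: float = 1e-4,
) -> DrugParameters:
    """Calibrate the global Kp factor against the maintenance target.

    Finds kp_scale such that the reference dog's venous plasma concentration
    at the end of the standard maintenance infusion (5 mg/kg bolus +
    0.13 mg/kg/min for 3 h) equals ``target_conc``. The default target is the
    geometric midpoint of the 2.5-4.7 µg/mL maintenance window,
    sqrt(2.5 * 4.7) ~= 3.43 µg/mL (concentration windows are ratio-scaled
    quantities). The end-of-infusion concentration decreases monotonically
    with kp_scale, so a bracketing root-finder is used. Returns a copy of
    ``drug`` with the calibrated kp_scale.
    """
    from scipy.optimize import brentq

    from . import simulator  # deferred

    if target_conc is None:
        target_conc = math.sqrt(2.5 * 4.7)
    if regimen is None:
        regimen = simulator.DoseRegimen(
            bolus_dose=5.0, bolus_duration_s=60.0, infusion_rate=0.13, infusion_duration_min=180.0
        )
    t_end_h = regimen.infusion_end_min / 60.0

    def c_end(scale: float) -> float:
        d = replace(drug, kp_scale=scale)
        ind = make_individual(body_weight, cl_per_kg)
        prof = simulator.simulate(ind, d, regimen, horizon_h=t_end_h + 0.1)
        import numpy as np

        return float(np.interp(t_end_h, prof.times, prof.concentrations))

    lo, hi = bracket
    f_lo, f_hi = c_end(lo) - target_conc, c_end(hi) - target_conc
    if f_lo * f_hi > 0:
        raise CalibrationError(
            f"kp_scale target {target_conc} µg/mL not bracketed in {bracket}: "
            f"C_end({lo})={f_lo + target_conc:.2f}, C_end({hi})={f_hi + target_conc:.2f}"
        )
    scale = brentq(lambda s: c_end(s) - target_conc, lo, hi, xtol=xtol)
    return replace(drug, kp_scale=float(scale))


def calibrate_model(
    drug: DrugParameters,
    studies: Sequence,
    reference_study_id: str = "nolan_reid_1993",
    template: dict | None = None,
    check_tol: float = 0.05,
) -> tuple[DrugParameters, CalibrationResult]:
    """Full calibration chain: clearance arithmetic, Kp scale, verification.

    1. realized plasma clearance from the reference study's dose / predicted
       AUC arithmetic;
    2. global kp_scale from the maintenance-window target;
    3. verification by re-simulating the reference design with the calibrated
       model (raises CalibrationError above ``check_tol``).

    Returns the calibrated drug parameters and the final calibration record.
    """
    phys = build_reference_dog(10.5, template=template)
    first = calibrate_clearance(
        drug, phys, studies, reference_study_id=reference_study_id, check=False
    )
    drug_cal = calibrate_kp_scale(drug, first.cl_per_kg)
    final = calibrate_clearance(
        drug_cal, phys, studies, reference_study_id=reference_study_id,
        check=True, tol=check_tol,
    )
    return drug_cal, final
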