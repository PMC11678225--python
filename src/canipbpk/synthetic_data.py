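"""Pseudo-observed study datasets and shipped fixtures.

The concentration-time profiles behind the nine literature studies are not
redistributable, so validation-stage code is exercised against synthetic
stand-ins: the study design is simulated with optionally perturbed parameters
and multiplicative log-normal residual noise (the standard error model for
concentration assays) is applied per sample. Each dataset ships with a
ground-truth sidecar so parameter-recovery tests can close the loop.

Default sampling schedule: every 2 min for the first 30 min, every 15 min
thereafter to 8 h — a dense schedule typical of the source-study designs,
whose true schedules are not printed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .drug_model import DrugParameters, dump_drug, load_drug, make_individual
from .physiology import dump_template, load_template
from .simulator import simulate
from .validation import StudyRecord, auc_from_arrays, load_studies

__all__ = [
    "SyntheticStudySpec",
    "VirtualStudy",
    "default_sampling_times",
    "make_virtual_study",
    "nca_clearance",
    "make_fixture_tables",
]


def default_sampling_times(horizon_h: float = 8.0) -> np.ndarray:
    """Sampling grid in hours: 2-min spacing to 30 min, then 15-min spacing."""
    early = np.arange(2.0, 30.0 + 1e-9, 2.0) / 60.0
    late = np.arange(45.0, horizon_h * 60.0 + 1e-9, 15.0) / 60.0
    return np.concatenate([early, late])


@dataclass(frozen=True)
class SyntheticStudySpec:
    """Recipe for one pseudo-observed dataset."""

    base_design: StudyRecord
    parameter_perturbation: Mapping[str, float] = field(default_factory=dict)
    residual_cv: float = 0.15
    sampling_times: np.ndarray | None = None  # h; default dense schedule
    n_subjects: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.residual_cv < 0:
            raise ValueError("residual_cv must be nonnegative")
        if self.sampling_times is not None:
            t = np.asarray(self.sampling_times, dtype=float)
            if t.ndim != 1 or t.size == 0 or np.any(np.diff(t) <= 0):
                raise ValueError("sampling times must be strictly increasing")
            object.__setattr__(self, "sampling_times", t)


@dataclass(frozen=True)
class VirtualStudy:
    """Observations plus the ground truth that generated them."""

    observations: pd.DataFrame  # subject_id, time_h, conc_ug_per_ml
    truth: dict

    def write(self, obs_path, truth_path=None) -> None:
        self.observations.to_csv(obs_path, index=False)
        if truth_path is not None:
            import json

            with open(truth_path, "w") as fh:
                json.dump(self.truth, fh, indent=2, default=float)


def make_virtual_study(
    spec: SyntheticStudySpec,
    drug: DrugParameters,
    cl_per_kg: float,
    template: dict | None = None,
    horizon_h: float = 8.0,
) -> VirtualStudy:
    """Simulate a study design and overlay proportional log-normal noise.

    ``parameter_perturbation`` multiplies named parameters before simulation
    (currently ``clearance`` and drug fields such as ``kp_scale``); the noisy
    observations and the true generating parameters are both returned.
    Sampling beyond the simulation horizon is rejected.
    """
    times = (
        spec.sampling_times
        if spec.sampling_times is not None
        else default_sampling_times(horizon_h)
    )
    if times[-1] > horizon_h + 1e-9:
        raise ValueError(
            f"sampling extends to {times[-1]:.2f} h beyond the {horizon_h} h horizon"
        )
    pert = dict(spec.parameter_perturbation)
    cl_true = cl_per_kg * pert.pop("clearance", 1.0)
    drug_true = drug
    for name, mult in pert.items():
        if not hasattr(drug_true, name):
            raise ValueError(f"unknown perturbation target {name!r}")
        drug_true = replace(drug_true, **{name: getattr(drug_true, name) * mult})

    design = spec.base_design
    rng = np.random.default_rng(spec.seed)
    sigma = np.sqrt(np.log1p(spec.residual_cv**2)) if spec.residual_cv > 0 else 0.0
    frames = []
    ind = make_individual(design.body_weight, cl_true, template=template)
    grid = np.unique(np.concatenate([[1e-6], times]))
    prof = simulate(ind, drug_true, design.regimen, grid=grid, horizon_h=horizon_h)
    pred = np.interp(times, prof.times, prof.concentrations)
    for j in range(spec.n_subjects):
        noise = (
            np.exp(rng.standard_normal(len(times)) * sigma - 0.5 * sigma * sigma)
            if sigma > 0
            else np.ones(len(times))
        )
        frames.append(
            pd.DataFrame(
                {
                    "subject_id": f"{design.study_id}_s{j:02d}",
                    "time_h": times,
                    "conc_ug_per_ml": pred * noise,
                }
            )
        )
    truth = {
        "study_id": design.study_id,
        "cl_per_kg": cl_true,
        "kp_scale": drug_true.kp_scale,
        "residual_cv": spec.residual_cv,
        "seed": spec.seed,
        "body_weight": design.body_weight,
        "total_dose_per_kg": design.regimen.total_dose_per_kg,
    }
    return VirtualStudy(observations=pd.concat(frames, ignore_index=True), truth=truth)


def nca_clearance(observations: pd.DataFrame, total_dose_per_kg: float) -> float:
    """Non-compartmental plasma clearance (mL/min/kg) from dense sampling.

    Dose over trapezoidal AUC to the last sample, averaged over subjects.
    Adequate for dense schedules where the extrapolated tail is negligible.
    """
    cls = []
    for _sid, grp in observations.groupby("subject_id", sort=False):
        t = grp["time_h"].to_numpy()
        c = grp["conc_ug_per_ml"].to_numpy()
        a = auc_from_arrays(t, c, float(t[0]), float(t[-1]))
        # add the leading triangle from t=0 (conc 0 at dose start) coarsely:
        a += 0.5 * t[0] * c[0]
        cls.append(total_dose_per_kg * 1000.0 / a / 60.0)
    return float(np.mean(cls))


def make_fixture_tables(outdir) -> dict[str, Path]:
    """Write copies of the shipped fixtures (drug, studies, physiology, window).

    Returns the written paths. Files round-trip bit-identically through the
    package loaders/dumpers.
    """
    import importlib.resources
    import shutil

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name in ("propofol.yaml", "studies.yaml", "canine_physiology.yaml", "window.yaml"):
        ref = importlib.resources.files("canipbpk.data").joinpath(name)
        dest = out / name
        with ref.open("rb") as src, open(dest, "wb") as dst:
            shutil.copyfileobj(src, dst)
        paths[name] = dest
    return paths
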