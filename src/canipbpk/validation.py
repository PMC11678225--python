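"""Model performance verification: NCA exposure and fold-error metrics.

The exposure metric is the linear trapezoidal AUC of a concentration profile.
Predictive performance is summarized by the geometric mean fold error of
AUClast over a set of studies,

    GMFE = 10 ** (1/n * sum_i log10(AUC_pred,i / AUC_obs,i)),

which as printed is a *signed* geometric mean ratio (under-predictions can
cancel over-predictions). The conventional GMFE applies |log10| per term and
is always >= 1. Both variants are computed and labelled; they answer
different questions (bias vs accuracy), and the discrepancy between them on
skewed ratio sets is surfaced in the comparison table's notes rather than
silently resolved.
"""

from __future__ import annotations

import importlib.resources
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .simulator import ConcentrationProfile, DoseRegimen

__all__ = [
    "StudyRecord",
    "load_studies",
    "auc",
    "auc_from_arrays",
    "gmfe",
    "pred_obs_table",
]


@dataclass(frozen=True)
class StudyRecord:
    """One literature study: design plus predicted/observed AUClast."""

    study_id: str
    label: str
    regimen: DoseRegimen
    body_weight: float  # kg
    n_animals: int
    role: str  # development | validation
    observed_auclast: float | None = None  # µg·h/mL
    predicted_auclast: float | None = None  # µg·h/mL

    def __post_init__(self) -> None:
        if self.role not in ("development", "validation"):
            raise ValueError(f"role must be development|validation, got {self.role!r}")
        for attr in ("observed_auclast", "predicted_auclast"):
            v = getattr(self, attr)
            if v is not None and v <= 0:
                raise ValueError(f"{attr} must be positive when present, got {v}")


def load_studies(path_or_stream=None) -> list[StudyRecord]:
    """Load study records; defaults to the shipped nine-study fixture."""
    if path_or_stream is None:
        ref = importlib.resources.files("canipbpk.data").joinpath("studies.yaml")
        with ref.open("r") as fh:
            raw = yaml.safe_load(fh)
    elif hasattr(path_or_stream, "read"):
        raw = yaml.safe_load(path_or_stream)
    else:
        with open(path_or_stream) as fh:
            raw = yaml.safe_load(fh)
    out = []
    for entry in raw["studies"]:
        regimen = DoseRegimen(
            bolus_dose=float(entry["bolus_dose"]),
            bolus_duration_s=float(entry.get("bolus_duration_s", 60.0)),
            infusion_rate=float(entry.get("infusion_rate", 0.0)),
            infusion_duration_min=float(entry.get("infusion_duration_min", 0.0)),
            extra_infusions=tuple(
                tuple(float(x) for x in seg) for seg in entry.get("extra_infusions", [])
            ),
        )
        out.append(
            StudyRecord(
                study_id=entry["study_id"],
                label=entry.get("label", entry["study_id"]),
                regimen=regimen,
                body_weight=float(entry["body_weight"]),
                n_animals=int(entry["n_animals"]),
                role=entry["role"],
                observed_auclast=entry.get("observed_auclast"),
                predicted_auclast=entry.get("predicted_auclast"),
            )
        )
    return out


def auc_from_arrays(times_h: np.ndarray, conc: np.ndarray, t0: float, t1: float) -> float:
    """Linear trapezoidal AUC (µg·h/mL) between t0 and t1 hours.

    Bounds must lie within the grid span; values at the bounds are linearly
    interpolated so that AUC is exactly additive over adjacent windows.
    """
    times_h = np.asarray(times_h, dtype=float)
    conc = np.asarray(conc, dtype=float)
    if not t0 < t1:
        raise ValueError(f"need t0 < t1, got ({t0}, {t1})")
    if t0 < times_h[0] - 1e-12 or t1 > times_h[-1] + 1e-12:
        raise ValueError(
            f"window [{t0}, {t1}] h outside grid span [{times_h[0]}, {times_h[-1]}] h"
        )
    inner = (times_h > t0) & (times_h < t1)
    t = np.concatenate(([t0], times_h[inner], [t1]))
    c = np.concatenate(
        ([np.interp(t0, times_h, conc)], conc[inner], [np.interp(t1, times_h, conc)])
    )
    return float(np.trapezoid(c, t))


def auc(profile: ConcentrationProfile, t0: float, t1: float) -> float:
    """Trapezoidal AUC of a profile between t0 and t1 hours (µg·h/mL)."""
    return auc_from_arrays(profile.times, profile.concentrations, t0, t1)


def gmfe(pairs: Iterable[tuple[float, float]], absolute: bool = False) -> float:
    """Geometric mean fold error over (predicted, observed) AUC pairs.

    ``absolute=False`` gives the signed variant exactly as defined above (a
    geometric mean ratio, can be < 1); ``absolute=True`` applies |log10| per
    term (standard GMFE, always >= 1, equal to 1 iff every ratio is 1).
    """
    logs = []
    for pred, obs in pairs:
        if pred <= 0 or obs <= 0:
            raise ValueError(f"AUC values must be positive, got ({pred}, {obs})")
        term = math.log10(pred / obs)
        logs.append(abs(term) if absolute else term)
    if not logs:
        raise ValueError("gmfe needs at least one (predicted, observed) pair")
    return 10.0 ** (sum(logs) / len(logs))


def pred_obs_table(
    studies: Sequence[StudyRecord],
    simulated_auclast: Mapping[str, float] | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Per-study predicted/observed comparison plus pooled GMFE.

    ``simulated_auclast`` maps study_id to this package's simulated AUClast
    (µg·h/mL); when omitted, the studies' stored predictions are compared
    against their observations (pure table arithmetic). Studies with missing
    inputs are listed with NaN ratios, not dropped and not fatal.

    Returns the table and a summary dict with both GMFE variants and notes.
    """
    rows = []
    pairs = []
    missing = []
    for s in studies:
        if simulated_auclast is not None:
            pred = simulated_auclast.get(s.study_id)
        else:
            pred = s.predicted_auclast
        obs = s.observed_auclast
        ratio = pred / obs if (pred and obs) else float("nan")
        if pred and obs:
            pairs.append((pred, obs))
        else:
            missing.append(s.study_id)
        rows.append(
            {
                "study_id": s.study_id,
                "label": s.label,
                "role": s.role,
                "predicted_auclast": pred,
                "observed_auclast": obs,
                "ratio": ratio,
            }
        )
    table = pd.DataFrame(rows)
    summary = {
        "gmfe_signed": gmfe(pairs) if pairs else float("nan"),
        "gmfe_absolute": gmfe(pairs, absolute=True) if pairs else float("nan"),
        "n_pairs": len(pairs),
        "missing_studies": missing,
        "notes": (
            "gmfe_signed is the printed definition (signed logs; a geometric mean "
            "ratio in which over- and under-predictions cancel); gmfe_absolute is "
            "the conventional fold-error magnitude and is >= gmfe_signed."
        ),
    }
    return table, summary
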