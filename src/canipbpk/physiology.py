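"""Canine whole-body anatomy and physiology.

The data model is a set of organ compartments, each described as a fraction of
body weight (volume), a fraction of cardiac output (blood flow), and a tissue
composition (water / neutral lipid / phospholipid / protein mass fractions).
A reference template for an adult dog is shipped as a YAML data file; organ
volumes scale linearly with body weight, and cardiac output (hence all organ
flows) scales allometrically with BW^0.75.

The organ-level numbers are an implementation source assembled from published
canine physiology compilations (Davies & Morris-style reference tables and
standard tissue-composition tables); they are deliberately unremarkable, and
the downstream clearance / partition calibration absorbs residual differences
from any particular physiology database.
"""

from __future__ import annotations

import importlib.resources
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import yaml

__all__ = [
    "OrganSpec",
    "CaninePhysiology",
    "ValidationCheck",
    "ValidationReport",
    "load_template",
    "dump_template",
    "build_reference_dog",
    "validate_physiology",
    "PORTAL_ORGANS",
]

#: organs whose venous outflow drains into the liver via the portal vein
PORTAL_ORGANS = ("gut", "spleen")

#: organs the template must cover at minimum
REQUIRED_ORGANS = frozenset(
    {
        "lung",
        "liver",
        "kidney",
        "brain",
        "heart",
        "muscle",
        "fat",
        "skin",
        "gut",
        "spleen",
        "bone",
        "rest",
    }
)


@dataclass(frozen=True)
class OrganSpec:
    """One perfusion-limited compartment.

    ``volume_fraction`` is the organ volume as a fraction of body weight
    (1 kg/L tissue density assumed), ``flow_fraction`` the fraction of cardiac
    output perfusing the organ (1.0 for lung, which sits in series and receives
    the whole cardiac output; 0 for non-perfusion pseudo-compartments such as
    plasma). ``f_*`` are tissue composition mass fractions used by the
    partition-coefficient schemes.
    """

    name: str
    volume_fraction: float
    flow_fraction: float
    f_water: float
    f_neutral_lipid: float
    f_phospholipid: float
    f_protein: float

    def __post_init__(self) -> None:
        for attr in (
            "volume_fraction",
            "flow_fraction",
            "f_water",
            "f_neutral_lipid",
            "f_phospholipid",
            "f_protein",
        ):
            v = getattr(self, attr)
            if not math.isfinite(v) or v < 0.0 or v > 1.0:
                raise ValueError(f"{self.name}: {attr}={v!r} outside [0, 1]")

    @property
    def composition_sum(self) -> float:
        return self.f_water + self.f_neutral_lipid + self.f_phospholipid + self.f_protein


@dataclass(frozen=True)
class CaninePhysiology:
    """A single virtual dog: organ compartments plus blood pools.

    Volumes are mL, flows mL/min. ``organs`` covers every tissue compartment
    (including lung); systemic organ flow fractions sum to 1 at the venous
    pool. ``plasma`` carries the plasma composition used as the reference
    phase by the partition schemes.
    """

    body_weight: float  # kg
    cardiac_output: float  # mL/min
    hematocrit: float
    organs: tuple[OrganSpec, ...]
    plasma: OrganSpec
    venous_blood_volume: float  # mL
    arterial_blood_volume: float  # mL

    def __post_init__(self) -> None:
        if not math.isfinite(self.body_weight) or self.body_weight <= 0:
            raise ValueError(f"body_weight must be positive and finite, got {self.body_weight!r}")
        if self.cardiac_output <= 0:
            raise ValueError("cardiac_output must be positive")

    @property
    def organ_map(self) -> dict[str, OrganSpec]:
        return {o.name: o for o in self.organs}

    def organ(self, name: str) -> OrganSpec:
        try:
            return self.organ_map[name]
        except KeyError:
            raise KeyError(f"physiology has no organ {name!r}") from None

    def organ_volume(self, name: str) -> float:
        """Absolute organ volume in mL (1 kg/L density)."""
        return self.organ(name).volume_fraction * self.body_weight * 1000.0

    def organ_flow(self, name: str) -> float:
        """Absolute organ blood flow in mL/min."""
        return self.organ(name).flow_fraction * self.cardiac_output

    @property
    def hepatic_blood_flow(self) -> float:
        """Total liver inflow (hepatic artery + portal vein), mL/min."""
        names = ("liver",) + PORTAL_ORGANS
        return sum(self.organ_flow(n) for n in names)

    def with_volume_multipliers(self, multipliers: Mapping[str, float]) -> "CaninePhysiology":
        """Return a copy with selected organ volume fractions scaled.

        Used by the population generator to perturb e.g. muscle and fat
        volumes; other organs and flows are untouched.
        """
        new_organs = []
        for o in self.organs:
            m = multipliers.get(o.name, 1.0)
            new_organs.append(replace(o, volume_fraction=o.volume_fraction * m) if m != 1.0 else o)
        return replace(self, organs=tuple(new_organs))


@dataclass(frozen=True)
class ValidationCheck:
    name: str
    passed: bool
    detail: str


@dataclass(frozen=True)
class ValidationReport:
    checks: tuple[ValidationCheck, ...]

    @property
    def passed(self) -> bool:
        return all(c.passed for c in self.checks)

    def failures(self) -> list[ValidationCheck]:
        return [c for c in self.checks if not c.passed]


# ---------------------------------------------------------------------------
# template handling


def _template_to_dict(template: dict) -> dict:
    return template


def load_template(path_or_stream=None) -> dict:
    """Load a physiology template; defaults to the shipped canine reference."""
    if path_or_stream is None:
        ref = importlib.resources.files("canipbpk.data").joinpath("canine_physiology.yaml")
        with ref.open("r") as fh:
            return yaml.safe_load(fh)
    if hasattr(path_or_stream, "read"):
        return yaml.safe_load(path_or_stream)
    with open(path_or_stream) as fh:
        return yaml.safe_load(fh)


def dump_template(template: dict, path_or_stream) -> None:
    """Write a template with stable key order (round-trips bit-identically)."""
    text = yaml.safe_dump(template, sort_keys=True, default_flow_style=False)
    if hasattr(path_or_stream, "write"):
        path_or_stream.write(text)
    else:
        with open(path_or_stream, "w") as fh:
            fh.write(text)


def _organ_from_entry(entry: Mapping) -> OrganSpec:
    return OrganSpec(
        name=entry["name"],
        volume_fraction=float(entry["volume_fraction"]),
        flow_fraction=float(entry["flow_fraction"]),
        f_water=float(entry["f_water"]),
        f_neutral_lipid=float(entry["f_neutral_lipid"]),
        f_phospholipid=float(entry["f_phospholipid"]),
        f_protein=float(entry["f_protein"]),
    )


# lumping map for the documented fast "lumped" mode: portal organs, liver and
# lung must stay resolved; everything else is pooled into richly/slowly
# perfused compartments
_LUMPS = {
    "kidney": "richly",
    "brain": "richly",
    "heart": "richly",
    "rest": "richly",
    "muscle": "slowly",
    "fat": "slowly",
    "skin": "slowly",
    "bone": "slowly",
}


def _lump_organs(organs: Iterable[OrganSpec]) -> tuple[OrganSpec, ...]:
    kept: list[OrganSpec] = []
    pools: dict[str, list[OrganSpec]] = {}
    for o in organs:
        tgt = _LUMPS.get(o.name)
        if tgt is None:
            kept.append(o)
        else:
            pools.setdefault(tgt, []).append(o)
    for tgt, members in pools.items():
        vol = sum(m.volume_fraction for m in members)
        flow = sum(m.flow_fraction for m in members)
        # volume-weighted composition keeps total tissue binding comparable
        kept.append(
            OrganSpec(
                name=tgt,
                volume_fraction=vol,
                flow_fraction=flow,
                f_water=sum(m.f_water * m.volume_fraction for m in members) / vol,
                f_neutral_lipid=sum(m.f_neutral_lipid * m.volume_fraction for m in members) / vol,
                f_phospholipid=sum(m.f_phospholipid * m.volume_fraction for m in members) / vol,
                f_protein=sum(m.f_protein * m.volume_fraction for m in members) / vol,
            )
        )
    return tuple(kept)


def build_reference_dog(
    body_weight: float,
    template: dict | None = None,
    flow_exponent: float | None = None,
    lumped: bool = False,
) -> CaninePhysiology:
    """Build a body-weight-scaled reference dog.

    Organ volumes scale linearly with body weight; cardiac output (and with it
    every organ flow) scales as ``(BW / BW_ref) ** flow_exponent`` with the
    standard allometric exponent 0.75 by default.
    """
    if not isinstance(body_weight, (int, float)) or not math.isfinite(body_weight):
        raise ValueError(f"body weight must be a finite number, got {body_weight!r}")
    if body_weight <= 0:
        raise ValueError(f"body weight must be positive, got {body_weight!r} kg")
    tpl = template if template is not None else load_template()
    if flow_exponent is None:
        flow_exponent = float(tpl.get("flow_exponent", 0.75))
    bw_ref = float(tpl["bw_reference_kg"])
    co = float(tpl["cardiac_output_ml_min_ref"]) * (body_weight / bw_ref) ** flow_exponent
    organs = tuple(_organ_from_entry(e) for e in tpl["organs"])
    if lumped:
        organs = _lump_organs(organs)
    missing = REQUIRED_ORGANS - {o.name for o in organs}
    if missing and not lumped:
        raise ValueError(f"template is missing required organs: {sorted(missing)}")
    plasma_entry = dict(tpl["plasma"])
    plasma = OrganSpec(
        name="plasma",
        volume_fraction=0.0,
        flow_fraction=0.0,
        f_water=float(plasma_entry["f_water"]),
        f_neutral_lipid=float(plasma_entry["f_neutral_lipid"]),
        f_phospholipid=float(plasma_entry["f_phospholipid"]),
        f_protein=float(plasma_entry["f_protein"]),
    )
    bw_ml = body_weight * 1000.0
    return CaninePhysiology(
        body_weight=float(body_weight),
        cardiac_output=co,
        hematocrit=float(tpl.get("hematocrit", 0.45)),
        organs=organs,
        plasma=plasma,
        venous_blood_volume=float(tpl["venous_blood_fraction"]) * bw_ml,
        arterial_blood_volume=float(tpl["arterial_blood_fraction"]) * bw_ml,
    )


def validate_physiology(phys: CaninePhysiology) -> ValidationReport:
    """Check conservation invariants; reports, never raises or mutates."""
    checks: list[ValidationCheck] = []

    lung = phys.organ_map.get("lung")
    checks.append(
        ValidationCheck(
            "lung_flow",
            lung is not None and abs(lung.flow_fraction - 1.0) < 1e-9,
            "lung receives total cardiac output in series"
            if lung is not None
            else "no lung compartment",
        )
    )

    systemic = [o for o in phys.organs if o.name != "lung"]
    flow_sum = sum(o.flow_fraction for o in systemic)
    checks.append(
        ValidationCheck(
            "flow_conservation",
            abs(flow_sum - 1.0) <= 1e-6,
            f"systemic flow fractions sum to {flow_sum:.6f} (must be 1 within 1e-6)",
        )
    )

    total_ml = (
        sum(o.volume_fraction for o in phys.organs) * phys.body_weight * 1000.0
        + phys.venous_blood_volume
        + phys.arterial_blood_volume
    )
    frac = total_ml / (phys.body_weight * 1000.0)
    checks.append(
        ValidationCheck(
            "volume_conservation",
            0.85 < frac < 1.05,
            f"organ + blood volume is {frac:.3f} x body weight (must lie in (0.85, 1.05))",
        )
    )

    bad = [o.name for o in phys.organs if o.composition_sum > 1.0 + 1e-9]
    checks.append(
        ValidationCheck(
            "composition_fractions",
            not bad,
            "tissue composition fractions sum to <= 1"
            if not bad
            else f"composition fractions exceed 1 in: {bad}",
        )
    )

    neg = [o.name for o in phys.organs if min(o.volume_fraction, o.flow_fraction) < 0]
    checks.append(
        ValidationCheck(
            "nonnegative",
            not neg,
            "all volume/flow fractions nonnegative" if not neg else f"negative fractions in {neg}",
        )
    )

    return ValidationReport(tuple(checks))
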