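"""Whole-body flow-limited ODE system and dosing.

Every tissue is a well-stirred, perfusion-limited compartment:

    V_t dC_t/dt = Q_t (C_art - (C_t / Kp_t) B:P)

with the lung in series between the venous and arterial blood pools, the
liver receiving hepatic-arterial plus portal (gut + spleen) inflow and losing
drug through a plasma-clearance term, and i.v. input (bolus and infusions as
zero-order rates) entering the venous pool. The reported concentration is
venous blood divided by the blood:plasma ratio.

Because the system is linear and time-invariant with piecewise-constant
inputs, the default integrator propagates the exact solution with matrix
exponentials (augmented-matrix form for the forced segments); there is no
truncation error at grid nodes. An adaptive stiff solver (``method="ivp"``)
is retained as an independent cross-check. A cumulative "eliminated" state is
carried so mass balance is checkable at every node.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.linalg import expm

from .drug_model import DrugParameters, Individual, partition_set
from .physiology import PORTAL_ORGANS

__all__ = [
    "DoseRegimen",
    "ConcentrationProfile",
    "PBPKSystem",
    "build_system",
    "simulate",
    "simulate_matrix",
    "mass_balance",
    "closed_form_onecomp",
    "default_grid_min",
]

#: fine-grid horizon (min): 1-s steps during the bolus, 5-s steps to here,
#: 1-min steps afterwards
_FINE_END_MIN = 10.0
_STEP_BOLUS_MIN = 1.0 / 60.0
_STEP_FINE_MIN = 5.0 / 60.0
_STEP_COARSE_MIN = 1.0


@dataclass(frozen=True)
class DoseRegimen:
    """Bolus + zero-order infusion schedule, in per-kg units.

    ``bolus_dose`` mg/kg over ``bolus_duration_s`` seconds; the maintenance
    infusion runs at ``infusion_rate`` mg/kg/min for ``infusion_duration_min``
    starting at ``infusion_start_min`` (default: bolus end). Staged designs
    add ``extra_infusions`` entries (rate mg/kg/min, start min, duration min).
    """

    bolus_dose: float = 0.0
    bolus_duration_s: float = 60.0
    infusion_rate: float = 0.0
    infusion_duration_min: float = 0.0
    infusion_start_min: float | None = None
    extra_infusions: tuple[tuple[float, float, float], ...] = ()

    def __post_init__(self) -> None:
        if min(self.bolus_dose, self.bolus_duration_s, self.infusion_rate,
               self.infusion_duration_min) < 0:
            raise ValueError("dose quantities must be nonnegative")
        if self.bolus_dose > 0 and self.bolus_duration_s < 1.0:
            raise ValueError("bolus must be administered over at least 1 s")
        if self.infusion_start_min is not None and self.infusion_start_min < 0:
            raise ValueError("infusion_start_min must be nonnegative")
        for entry in self.extra_infusions:
            if len(entry) != 3 or min(entry) < 0:
                raise ValueError(f"bad extra infusion entry {entry!r}")

    @property
    def bolus_end_min(self) -> float:
        return self.bolus_duration_s / 60.0 if self.bolus_dose > 0 else 0.0

    @property
    def infusion_start(self) -> float:
        if self.infusion_start_min is not None:
            return self.infusion_start_min
        return self.bolus_end_min

    @property
    def infusion_end_min(self) -> float:
        """End of the last infusion segment (min after bolus start)."""
        end = self.bolus_end_min
        if self.infusion_rate > 0 and self.infusion_duration_min > 0:
            end = max(end, self.infusion_start + self.infusion_duration_min)
        for _rate, start, duration in self.extra_infusions:
            end = max(end, start + duration)
        return end

    @property
    def total_dose_per_kg(self) -> float:
        dose = self.bolus_dose + self.infusion_rate * self.infusion_duration_min
        for rate, _start, duration in self.extra_infusions:
            dose += rate * duration
        return dose

    def scaled(self, factor: float) -> "DoseRegimen":
        """All dose quantities multiplied by ``factor`` (timings unchanged)."""
        return replace(
            self,
            bolus_dose=self.bolus_dose * factor,
            infusion_rate=self.infusion_rate * factor,
            extra_infusions=tuple(
                (rate * factor, start, dur) for rate, start, dur in self.extra_infusions
            ),
        )

    def with_rate(self, infusion_rate: float) -> "DoseRegimen":
        return replace(self, infusion_rate=infusion_rate)

    def segments(self) -> list[tuple[float, float, float]]:
        """Piecewise-constant per-kg input: (t0_min, t1_min, rate mg/kg/min)."""
        raw: list[tuple[float, float, float]] = []
        if self.bolus_dose > 0:
            dur = self.bolus_duration_s / 60.0
            raw.append((0.0, dur, self.bolus_dose / dur))
        if self.infusion_rate > 0 and self.infusion_duration_min > 0:
            raw.append(
                (self.infusion_start, self.infusion_start + self.infusion_duration_min,
                 self.infusion_rate)
            )
        for rate, start, duration in self.extra_infusions:
            if rate > 0 and duration > 0:
                raw.append((start, start + duration, rate))
        if not raw:
            return []
        bounds = sorted({t for seg in raw for t in seg[:2]})
        out = []
        for t0, t1 in zip(bounds[:-1], bounds[1:]):
            rate = sum(r for a, b, r in raw if a <= t0 and t1 <= b)
            out.append((t0, t1, rate))
        return out


@dataclass(frozen=True)
class ConcentrationProfile:
    """Venous (or arterial) plasma concentration vs time for one subject."""

    times: np.ndarray  # h, strictly increasing
    concentrations: np.ndarray  # µg/mL plasma
    subject_id: str = "ref"
    regimen: DoseRegimen | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        c = np.asarray(self.concentrations, dtype=float)
        if t.shape != c.shape:
            raise ValueError("times and concentrations must have equal length")
        if t.size > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("time grid must be strictly increasing")
        if np.any(c < 0):
            raise ValueError("negative concentrations in profile")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "concentrations", c)

    def at(self, time_h: float) -> float:
        """Linear interpolation at ``time_h`` (within the grid span)."""
        if time_h < self.times[0] or time_h > self.times[-1]:
            raise ValueError(f"time {time_h} h outside grid span")
        return float(np.interp(time_h, self.times, self.concentrations))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subject_id": self.subject_id,
                "time_h": self.times,
                "conc_ug_per_ml": self.concentrations,
            }
        )

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @staticmethod
    def read_csv(path) -> list["ConcentrationProfile"]:
        df = pd.read_csv(path)
        out = []
        for sid, grp in df.groupby("subject_id", sort=False):
            out.append(
                ConcentrationProfile(
                    times=grp["time_h"].to_numpy(),
                    concentrations=grp["conc_ug_per_ml"].to_numpy(),
                    subject_id=str(sid),
                )
            )
        return out


# ---------------------------------------------------------------------------
# system assembly


@dataclass(frozen=True)
class PBPKSystem:
    """The assembled linear system dx/dt = A x + b(t) for one subject."""

    A: np.ndarray  # per-minute rate matrix, includes cumulative elimination row
    volumes: np.ndarray  # mL per state (blood pools & tissues; 0 for elim row)
    labels: tuple[str, ...]
    venous: int
    arterial: int
    elim: int
    body_weight: float
    bp_ratio: float


def liver_elimination_coefficient(cl_plasma: float, hepatic_blood_flow: float,
                                  bp_ratio: float) -> float:
    """Invert the well-stirred relation: k such that realized CL = target.

    Realized plasma clearance in this model is
    ``CL = k / (1 + k / (B:P * Q_h))``, capped at the hepatic plasma-equivalent
    flow ``B:P * Q_h``; the target must stay below that ceiling.
    """
    cap = bp_ratio * hepatic_blood_flow
    if cl_plasma >= cap:
        raise ValueError(
            f"target plasma clearance {cl_plasma:.1f} mL/min exceeds the hepatic "
            f"flow ceiling {cap:.1f} mL/min; physiologically unreachable"
        )
    return cl_plasma / (1.0 - cl_plasma / cap)


def build_system(individual: Individual, drug: DrugParameters,
                 kp_method: str = "standard") -> PBPKSystem:
    phys = individual.physiology
    kps = partition_set(drug, phys, method=kp_method)
    bp = drug.bp_ratio
    co = phys.cardiac_output

    systemic = [o for o in phys.organs if o.name != "lung"]
    labels = ["venous", "arterial", "lung"] + [o.name for o in systemic] + ["eliminated"]
    idx = {name: i for i, name in enumerate(labels)}
    n = len(labels)
    iv, ia, il = idx["venous"], idx["arterial"], idx["lung"]
    ielim = idx["eliminated"]

    vols = np.zeros(n)
    vols[iv] = phys.venous_blood_volume
    vols[ia] = phys.arterial_blood_volume
    vols[il] = phys.organ_volume("lung")
    for o in systemic:
        vols[idx[o.name]] = phys.organ_volume(o.name)

    # outflow blood-concentration coefficient per tissue state: c_out = coef * amount
    out_coef = np.zeros(n)
    out_coef[il] = bp / (kps["lung"] * vols[il])
    for o in systemic:
        out_coef[idx[o.name]] = bp / (kps[o.name] * vols[idx[o.name]])

    A = np.zeros((n, n))
    # venous pool: collects systemic outflows (liver handles the portal bed)
    A[iv, iv] -= co / vols[iv]
    # lung in series
    A[il, iv] += co / vols[iv]
    A[il, il] -= co * out_coef[il]
    A[ia, il] += co * out_coef[il]
    A[ia, ia] -= co / vols[ia]

    q_liver_art = phys.organ_flow("liver")
    q_portal = {name: phys.organ_flow(name) for name in PORTAL_ORGANS}
    q_hep_total = q_liver_art + sum(q_portal.values())
    iliv = idx["liver"]

    for o in systemic:
        i = idx[o.name]
        q = phys.organ_flow(o.name)
        A[i, ia] += q / vols[ia]  # arterial inflow
        A[i, i] -= q * out_coef[i]  # venous outflow
        if o.name in PORTAL_ORGANS:
            A[iliv, i] += q * out_coef[i]  # portal drainage into the liver
        elif o.name == "liver":
            # liver outflow carries the combined hepatic flow
            A[i, i] -= (q_hep_total - q) * out_coef[i]
            A[iv, i] += q_hep_total * out_coef[i]
        else:
            A[iv, i] += q * out_coef[i]

    # hepatic elimination on the liver plasma-equivalent concentration
    k_liv = liver_elimination_coefficient(individual.cl_plasma, q_hep_total, bp)
    plasma_eq = 1.0 / (kps["liver"] * vols[iliv])
    A[iliv, iliv] -= k_liv * plasma_eq
    A[ielim, iliv] += k_liv * plasma_eq

    return PBPKSystem(
        A=A,
        volumes=vols,
        labels=tuple(labels),
        venous=iv,
        arterial=ia,
        elim=ielim,
        body_weight=phys.body_weight,
        bp_ratio=bp,
    )


# ---------------------------------------------------------------------------
# grids and propagation


def default_grid_min(regimen: DoseRegimen, horizon_min: float) -> np.ndarray:
    """Output nodes: 1-s steps during the bolus, 5-s to 10 min, then 1-min."""
    events = {0.0, horizon_min, min(_FINE_END_MIN, horizon_min)}
    for t0, t1, _r in regimen.segments():
        events.update((t0, t1))
    bounds = sorted(t for t in events if 0.0 <= t <= horizon_min)
    nodes = [0.0]
    for t0, t1 in zip(bounds[:-1], bounds[1:]):
        if t1 <= regimen.bolus_end_min + 1e-12:
            step = _STEP_BOLUS_MIN
        elif t1 <= _FINE_END_MIN + 1e-12:
            step = _STEP_FINE_MIN
        else:
            step = _STEP_COARSE_MIN
        k = max(1, int(math.ceil((t1 - t0) / step - 1e-9)))
        nodes.extend(t0 + (t1 - t0) * (i + 1) / k for i in range(k))
    return np.array(nodes)


def _interval_rates(regimen: DoseRegimen, nodes_min: np.ndarray) -> np.ndarray:
    """Per-kg input rate (mg/kg/min) on each inter-node interval."""
    # the node grid always contains every segment boundary, so interval
    # midpoints classify intervals unambiguously
    mids = 0.5 * (nodes_min[:-1] + nodes_min[1:])
    rates = np.zeros_like(mids)
    for t0, t1, r in regimen.segments():
        rates[(mids >= t0) & (mids <= t1)] += r
    return rates


def _propagate(
    systems: Sequence[PBPKSystem],
    regimen: DoseRegimen,
    nodes_min: np.ndarray,
    keep_states: bool = False,
):
    """Exact propagation of every subject over the shared node grid.

    Returns (times_h, conc µg/mL array of shape n_subjects x n_nodes) and,
    if requested, the full state trajectories (n_subjects x n_nodes x n_state).
    """
    nsub = len(systems)
    nstate = systems[0].A.shape[0]
    rates = _interval_rates(regimen, nodes_min)
    steps = np.diff(nodes_min)

    X = np.zeros((nsub, nstate))
    conc = np.zeros((nsub, len(nodes_min)))
    states = np.zeros((nsub, len(nodes_min), nstate)) if keep_states else None

    vven = np.array([s.volumes[s.venous] for s in systems])
    iven = systems[0].venous  # identical layout across subjects
    bps = np.array([s.bp_ratio for s in systems])
    bws = np.array([s.body_weight for s in systems])

    cache: dict[tuple[float, float], tuple[np.ndarray, np.ndarray]] = {}

    def operators(h: float, rate_perkg: float):
        key = (round(h, 12), round(rate_perkg, 12))
        if key not in cache:
            E = np.empty((nsub, nstate, nstate))
            c = np.zeros((nsub, nstate))
            if rate_perkg == 0.0:
                for i, s in enumerate(systems):
                    E[i] = expm(s.A * h)
            else:
                M = np.zeros((nstate + 1, nstate + 1))
                for i, s in enumerate(systems):
                    M[:nstate, :nstate] = s.A * h
                    M[:nstate, nstate] = 0.0
                    M[iven, nstate] = rate_perkg * bws[i] * h
                    Eaug = expm(M)
                    E[i] = Eaug[:nstate, :nstate]
                    c[i] = Eaug[:nstate, nstate]
            cache[key] = (E, c)
        return cache[key]

    for j, (h, r) in enumerate(zip(steps, rates)):
        E, c = operators(h, r)
        X = np.einsum("nij,nj->ni", E, X) + c
        conc[:, j + 1] = X[:, iven] / vven / bps * 1000.0
        if keep_states:
            states[:, j + 1, :] = X

    # exact propagation keeps the Metzler system nonnegative up to roundoff
    if conc.min() < -1e-9 * max(conc.max(), 1.0):
        raise RuntimeError(f"negative concentration state ({conc.min():.3e}) in propagation")
    np.clip(conc, 0.0, None, out=conc)

    times_h = nodes_min / 60.0
    if keep_states:
        return times_h, conc, states
    return times_h, conc


def _simulate_ivp(system: PBPKSystem, regimen: DoseRegimen, nodes_min: np.ndarray) -> np.ndarray:
    """Adaptive stiff integration (cross-check path), piecewise over segments."""
    from scipy.integrate import solve_ivp

    nstate = system.A.shape[0]
    rates = _interval_rates(regimen, nodes_min)
    bounds = [0]
    for j in range(1, len(rates)):
        if rates[j] != rates[j - 1]:
            bounds.append(j)
    bounds.append(len(rates))

    x = np.zeros(nstate)
    out = np.zeros((len(nodes_min), nstate))
    b = np.zeros(nstate)
    for k in range(len(bounds) - 1):
        j0, j1 = bounds[k], bounds[k + 1]
        t0, t1 = nodes_min[j0], nodes_min[j1]
        b[:] = 0.0
        b[system.venous] = rates[j0] * system.body_weight
        sol = solve_ivp(
            lambda t, y: system.A @ y + b,
            (t0, t1),
            x,
            method="LSODA",
            rtol=1e-6,
            atol=1e-9,
            t_eval=nodes_min[j0 : j1 + 1],
            jac=lambda t, y: system.A,
        )
        if not sol.success:
            raise RuntimeError(f"stiff solver failed on [{t0}, {t1}] min: {sol.message}")
        out[j0 : j1 + 1] = sol.y.T
        x = sol.y[:, -1]
    return out


def simulate(
    individual: Individual,
    drug: DrugParameters,
    regimen: DoseRegimen,
    grid: np.ndarray | None = None,
    horizon_h: float = 12.0,
    method: str = "expm",
    site: str = "venous",
    kp_method: str = "standard",
) -> ConcentrationProfile:
    """Simulate one subject and return the plasma concentration profile.

    ``grid`` (hours) overrides the default output grid; event times are always
    inserted internally so zero-order on/off switches stay exact. ``site``
    selects venous (default) or arterial plasma.
    """
    if site not in ("venous", "arterial"):
        raise ValueError(f"unknown sampling site {site!r}")
    system = build_system(individual, drug, kp_method=kp_method)

    if grid is None:
        nodes = default_grid_min(regimen, horizon_h * 60.0)
        out_mask = np.ones(len(nodes), dtype=bool)
    else:
        grid = np.asarray(grid, dtype=float)
        if grid.ndim != 1 or grid.size == 0 or np.any(np.diff(grid) <= 0) or grid[0] < 0:
            raise ValueError("grid must be a strictly increasing 1-D array of hours >= 0")
        horizon_min = grid[-1] * 60.0
        events = {0.0, horizon_min}
        for t0, t1, _r in regimen.segments():
            if t0 < horizon_min:
                events.update((t0, min(t1, horizon_min)))
        nodes = np.unique(np.concatenate([grid * 60.0, np.array(sorted(events))]))
        out_mask = np.isin(nodes, grid * 60.0)

    if method == "expm":
        times_h, conc = _propagate([system], regimen, nodes)
        conc = conc[0]
    elif method == "ivp":
        states = _simulate_ivp(system, regimen, nodes)
        i = system.venous if site == "venous" else system.arterial
        conc = states[:, i] / system.volumes[i] / system.bp_ratio * 1000.0
        conc = np.clip(conc, 0.0, None)
        times_h = nodes / 60.0
    else:
        raise ValueError(f"unknown method {method!r}")

    if site == "arterial" and method == "expm":
        # re-run keeping states to read the arterial pool
        _, _, states = _propagate([system], regimen, nodes, keep_states=True)
        conc = states[0, :, system.arterial] / system.volumes[system.arterial] / system.bp_ratio * 1000.0
        conc = np.clip(conc, 0.0, None)

    return ConcentrationProfile(
        times=times_h[out_mask],
        concentrations=conc[out_mask],
        subject_id=individual.subject_id,
        regimen=regimen,
    )


def simulate_matrix(
    individuals: Sequence[Individual],
    drug: DrugParameters,
    regimen: DoseRegimen,
    horizon_h: float = 12.0,
    kp_method: str = "standard",
    nodes_min: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate many subjects on a shared grid; returns (times_h, n x T array).

    ``nodes_min`` overrides the default grid (it must contain every dose event
    of ``regimen``), allowing several regimens to share one grid.
    """
    if not individuals:
        raise ValueError("no individuals supplied")
    systems = [build_system(ind, drug, kp_method=kp_method) for ind in individuals]
    nodes = nodes_min if nodes_min is not None else default_grid_min(regimen, horizon_h * 60.0)
    times_h, conc = _propagate(systems, regimen, nodes)
    return times_h, conc


def mass_balance(
    individual: Individual,
    drug: DrugParameters,
    regimen: DoseRegimen,
    horizon_h: float = 12.0,
) -> pd.DataFrame:
    """Administered vs (in body + eliminated) drug amount at every node."""
    system = build_system(individual, drug)
    nodes = default_grid_min(regimen, horizon_h * 60.0)
    _, _, states = _propagate([system], regimen, nodes, keep_states=True)
    states = states[0]
    bw = system.body_weight
    administered = np.zeros(len(nodes))
    for t0, t1, r in regimen.segments():
        administered += r * bw * np.clip(nodes - t0, 0.0, t1 - t0)
    eliminated = states[:, system.elim]
    in_body = states.sum(axis=1) - eliminated
    return pd.DataFrame(
        {
            "time_h": nodes / 60.0,
            "administered_mg": administered,
            "in_body_mg": in_body,
            "eliminated_mg": eliminated,
        }
    )


# ---------------------------------------------------------------------------
# one-compartment analytic oracle


def closed_form_onecomp(
    dose_mg: float,
    volume_ml: float,
    clearance_ml_min: float,
    times_h: np.ndarray,
    bolus_duration_s: float = 0.0,
    infusion_rate_mg_min: float = 0.0,
    infusion_start_min: float = 0.0,
    infusion_duration_min: float = 0.0,
    subject_id: str = "onecomp",
) -> ConcentrationProfile:
    """Exact analytic bolus/infusion superposition for one compartment.

    ``dose_mg`` is given as an instantaneous bolus when ``bolus_duration_s``
    is 0, otherwise as a zero-order input over that duration. Concentrations
    are returned in µg/mL.
    """
    if volume_ml <= 0 or clearance_ml_min <= 0:
        raise ValueError("volume and clearance must be positive")
    t = np.asarray(times_h, dtype=float) * 60.0  # minutes
    k = clearance_ml_min / volume_ml
    c = np.zeros_like(t)

    def zero_order(rate_mg_min: float, start: float, duration: float) -> np.ndarray:
        rel = t - start
        during = (rel >= 0) & (rel <= duration)
        after = rel > duration
        out = np.zeros_like(t)
        css = rate_mg_min / clearance_ml_min
        out[during] = css * (1.0 - np.exp(-k * rel[during]))
        out[after] = css * (1.0 - np.exp(-k * duration)) * np.exp(-k * (rel[after] - duration))
        return out

    if dose_mg > 0:
        if bolus_duration_s > 0:
            dur = bolus_duration_s / 60.0
            c += zero_order(dose_mg / dur, 0.0, dur)
        else:
            c += dose_mg / volume_ml * np.exp(-k * np.clip(t, 0.0, None)) * (t >= 0)
    if infusion_rate_mg_min > 0 and infusion_duration_min > 0:
        c += zero_order(infusion_rate_mg_min, infusion_start_min, infusion_duration_min)

    return ConcentrationProfile(
        times=np.asarray(times_h, dtype=float),
        concentrations=c * 1000.0,
        subject_id=subject_id,
    )
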