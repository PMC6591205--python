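"""Event-driven simulation of a treatment scenario.

A :class:`Scenario` combines a dosing regimen (instantaneous central
boluses), an optional surgical resection that shrinks the primary lesion
to a residual nodule with preserved cell proportions, an optional
adjuvant regimen, and an output time grid.  Integration restarts at every
event time so dose impulses and resection are applied exactly.

Tumor response is summarized by the equivalent spherical diameter and a
RECIST-style classification (CR/PR/SD/PD plus a pseudo-progression flag)
on the percent change of the primary-lesion diameter.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .model import (ModelError, ModelState, STATE_NAMES, SynapseOccupancy,
                    TumorImmuneModel, synapse_occupancy, tumor_diameter,
                    tumor_volume_mm3)
from .parameters import ModelParameters, PKParameters
from .pk import DoseEvent, dose_to_concentration, merge_regimens

__all__ = ["Scenario", "SimulationResult", "SimulationError", "simulate",
           "apply_resection", "percent_change", "classify_recist",
           "RECIST_PR_THRESHOLD", "RECIST_PD_THRESHOLD"]

#: RECIST 1.1 thresholds on percent diameter change (boundary inclusive).
RECIST_PR_THRESHOLD = -30.0
RECIST_PD_THRESHOLD = 20.0

#: Cancer-cell count below which a lesion is clamped to zero when the
#: integrator detects the downward crossing (continuous-model extinction).
EXTINCTION_CELLS = 0.5


class SimulationError(RuntimeError):
    """Integrator failure; carries the last valid time reached."""

    def __init__(self, message: str, last_time: float | None = None):
        super().__init__(message)
        self.last_time = last_time


@dataclass
class Scenario:
    """Treatment scenario: dosing, optional resection, optional adjuvant."""

    label: str = "scenario"
    regimen: list[DoseEvent] = field(default_factory=list)
    resection_day: float | None = None
    residual_volume: float = 1.0          # mm^3 nodule left at resection
    adjuvant_regimen: list[DoseEvent] = field(default_factory=list)
    horizon: float = 365.0                # days
    output_grid: np.ndarray | None = None # defaults to daily sampling
    metastasis: bool = False              # second undetected 1 mm^3 lesion
    met_volume: float = 1.0               # mm^3, initial metastasis volume

    def __post_init__(self) -> None:
        if self.horizon <= 0:
            raise ValueError("horizon must be positive")
        if self.resection_day is not None and not (
                0 <= self.resection_day < self.horizon):
            raise ValueError("resection_day must lie in [0, horizon)")
        for ev in list(self.regimen) + list(self.adjuvant_regimen):
            if not 0 <= ev.time <= self.horizon:
                raise ValueError(f"dose at day {ev.time} outside [0, horizon]")
        if self.output_grid is None:
            self.output_grid = np.arange(0.0, self.horizon + 0.5, 1.0)
        else:
            self.output_grid = np.asarray(self.output_grid, dtype=float)

    def all_doses(self) -> list[DoseEvent]:
        return merge_regimens(list(self.regimen), list(self.adjuvant_regimen))


@dataclass
class SimulationResult:
    """Trajectory-level outputs of one scenario run."""

    times: np.ndarray                 # days
    diameter: np.ndarray              # primary-lesion diameter, mm
    pct_change: np.ndarray            # % change vs baseline diameter
    states: pd.DataFrame              # all state components over time
    occupancy: pd.DataFrame           # synapse occupancy columns over time
    recist: str                       # CR | PR | SD | PD
    pseudo_progression: bool
    cancer_free: bool                 # primary lesion < 1 cell at horizon
    event_log: list[dict]             # applied doses / resection / extinction
    scenario_label: str = ""
    total_burden_cells: np.ndarray | None = None  # all lesions, cells

    @property
    def final_diameter(self) -> float:
        return float(self.diameter[-1])

    @property
    def final_pct_change(self) -> float:
        return float(self.pct_change[-1])


def percent_change(diameter: np.ndarray) -> np.ndarray:
    """Percent change of a diameter series relative to its baseline."""
    d = np.asarray(diameter, dtype=float)
    if d.size == 0 or d[0] <= 0:
        raise ValueError("baseline diameter must be positive")
    return 100.0 * (d - d[0]) / d[0]


def classify_recist(diameter: np.ndarray, d_detect: float
                    ) -> tuple[str, bool]:
    """RECIST-style category from a diameter trajectory.

    Evaluated at the final time against baseline: CR if the final
    diameter falls below the detection limit, PR if the change is <= -30%,
    PD if >= +20%, SD otherwise (boundaries inclusive; single-lesion
    model, so the absolute +5 mm PD qualifier is omitted).  The
    pseudo-progression flag is set when the trajectory first crosses the
    PD threshold but the final category is CR or PR.
    """
    d = np.asarray(diameter, dtype=float)
    if d.size < 2:
        raise ValueError("diameter series must have length >= 2")
    pct = percent_change(d)
    final_pct = pct[-1]
    if d[-1] < d_detect:
        category = "CR"
    elif final_pct <= RECIST_PR_THRESHOLD:
        category = "PR"
    elif final_pct >= RECIST_PD_THRESHOLD:
        category = "PD"
    else:
        category = "SD"
    ever_progressed = bool(np.any(pct[:-1] >= RECIST_PD_THRESHOLD))
    pseudo = ever_progressed and category in ("CR", "PR")
    return category, pseudo


def apply_resection(state: ModelState, residual_volume: float,
                    p: ModelParameters) -> ModelState:
    """Surgical resection leaving a residual nodule.

    Every tumor-compartment species is scaled by
    residual_volume / V_T(before), preserving the proportions of cancer
    and immune cells in the remaining nodule; TdLN, central, and
    peripheral compartments are untouched.  If the tumor is already at or
    below the residual volume the state is returned unchanged (warned).
    """
    v_before = tumor_volume_mm3(state.C, p)
    if v_before <= residual_volume:
        warnings.warn("tumor already at or below residual volume; "
                      "resection is a no-op", stacklevel=2)
        return state
    r = residual_volume / v_before
    scaled = {name: getattr(state, name) * r
              for name in ("C", "A_ag", "A_self", "APC_T", "mAPC_T",
                           "Teff_T", "Treg_T", "Ab_T")}
    out = ModelState(**{**{n: getattr(state, n) for n in STATE_NAMES},
                        **scaled})
    return out


def _resect_vector(y: np.ndarray, model: TumorImmuneModel,
                   residual_volume: float) -> np.ndarray:
    """Resection on the raw state vector (primary lesion only)."""
    p = model.p
    ix = model.index
    v_before = tumor_volume_mm3(y[ix["C"]], p)
    if v_before <= residual_volume:
        warnings.warn("tumor already at or below residual volume; "
                      "resection is a no-op", stacklevel=2)
        return y
    r = residual_volume / v_before
    y = y.copy()
    if model.n_clone_states:
        nc = model.n_clone_states
        names = (["C", "A_self", "APC_T", "mAPC_T", "Treg_T", "Ab_T"]
                 + [f"A_ag_{i}" for i in range(nc)]
                 + [f"Teff_T_{i}" for i in range(nc)])
    else:
        names = ["C", "A_ag", "A_self", "APC_T", "mAPC_T", "Teff_T",
                 "Treg_T", "Ab_T"]
    for n in names:
        y[ix[n]] *= r
    return y


def _lesion_columns(model: TumorImmuneModel) -> list[str]:
    cols = ["C"]
    if model.metastasis:
        cols.append("C_m")
    return cols


def simulate(p: ModelParameters, pk: PKParameters, scenario: Scenario,
             initial: ModelState | np.ndarray | None = None,
             model: TumorImmuneModel | None = None,
             initial_diameter_mm: float = 30.0,
             rtol: float = 1e-6) -> SimulationResult:
    """Integrate the coupled model over a scenario.

    Deterministic given its inputs.  Integration restarts at every dose
    and at resection so impulses are exact; a lesion whose cancer-cell
    count crosses :data:`EXTINCTION_CELLS` downward is clamped to zero
    (the continuous model cannot otherwise eradicate a lesion).
    """
    if model is None:
        model = TumorImmuneModel(p, pk, metastasis=scenario.metastasis)
    ix = model.index
    if initial is None:
        y = model.initial_state(diameter_mm=initial_diameter_mm,
                                met_volume_mm3=scenario.met_volume)
    elif isinstance(initial, ModelState):
        if model.metastasis or model.n_clone_states:
            raise ModelError("ModelState initial requires the pooled "
                             "single-lesion configuration")
        y = initial.to_array()
    else:
        y = np.asarray(initial, dtype=float).copy()
        if y.shape != (model.n_states,):
            raise ModelError("initial state has wrong length for model")
    if np.any(y < 0):
        raise ModelError("initial state must be non-negative")

    grid = scenario.output_grid
    horizon = float(scenario.horizon)

    # breakpoints: dose times, resection, horizon
    events: dict[float, list[tuple[str, float]]] = {}
    for ev in scenario.all_doses():
        events.setdefault(float(ev.time), []).append(("dose", ev.amount))
    if scenario.resection_day is not None:
        events.setdefault(float(scenario.resection_day), []).append(
            ("resection", scenario.residual_volume))
    breaks = sorted(set([0.0, horizon]) | set(events))
    breaks = [b for b in breaks if 0.0 <= b <= horizon]

    atol = np.full(model.n_states, 1e-3)          # cell species
    for name in model.state_names:
        if name.startswith(("A_", "Ab")):
            atol[ix[name]] = 1e-6                 # nM species

    lesion_idx = [ix[c] for c in _lesion_columns(model)]

    times_out: list[float] = []
    states_out: list[np.ndarray] = []
    event_log: list[dict] = []

    def record(t: float, yv: np.ndarray) -> None:
        times_out.append(t)
        states_out.append(np.maximum(yv, 0.0))

    for t0, t1 in zip(breaks[:-1], breaks[1:]):
        # apply instantaneous events scheduled at t0
        for kind, value in events.get(t0, []):
            before = y.copy()
            if kind == "dose":
                y[ix["Ab_C"]] += dose_to_concentration(value, pk)
            else:
                y = _resect_vector(y, model, value)
            event_log.append({"time": t0, "event": kind, "value": value,
                              "Ab_C_before": float(before[ix["Ab_C"]]),
                              "Ab_C_after": float(y[ix["Ab_C"]])})
        if t1 <= t0:
            continue
        seg_grid = grid[(grid > t0) & (grid <= t1)]
        if t0 == breaks[0] and grid.size and grid[0] == t0:
            record(t0, y)
        t_seg = t0
        while t_seg < t1 - 1e-12:
            ext_events = []
            for li in lesion_idx:
                if y[li] >= EXTINCTION_CELLS:
                    def make_ev(i):
                        def ev_fun(t, yy):
                            return yy[i] - EXTINCTION_CELLS
                        ev_fun.terminal = True
                        ev_fun.direction = -1.0
                        return ev_fun
                    ext_events.append((li, make_ev(li)))
            t_eval = seg_grid[(seg_grid > t_seg) & (seg_grid <= t1)]
            # t1 is appended so the segment-end state is exact even when
            # the output grid does not land on the break point
            t_solve = (np.append(t_eval, t1)
                       if (t_eval.size == 0 or t_eval[-1] < t1) else t_eval)
            sol = solve_ivp(model.rhs, (t_seg, t1), y, method="LSODA",
                            t_eval=t_solve,
                            events=[e for _, e in ext_events] or None,
                            rtol=rtol, atol=atol, dense_output=False)
            if not sol.success and sol.status != 1:
                raise SimulationError(
                    f"integration failed in [{t_seg}, {t1}]: {sol.message}",
                    last_time=float(sol.t[-1]) if sol.t.size else t_seg)
            hit = (sol.status == 1)
            sol_t = np.asarray(sol.t)
            if sol_t.size:
                grid_mask = np.isin(sol_t, t_eval)
                for tt, yy in zip(sol_t[grid_mask],
                                  np.asarray(sol.y).T[grid_mask]):
                    record(float(tt), yy)
            if hit:
                # clamp the extinct lesion to zero and continue the segment
                fired = [(te[0], k) for k, te in enumerate(sol.t_events)
                         if te.size]
                t_end, k_first = min(fired)
                li = ext_events[k_first][0]
                y = np.maximum(sol.y_events[k_first][0], 0.0)
                y[li] = 0.0
                event_log.append({"time": float(t_end), "event": "extinction",
                                  "value": model.state_names[li]})
                t_seg = float(t_end)
                if t_seg >= t1 - 1e-12:
                    break
            else:
                y = np.maximum(sol.y[:, -1], 0.0)
                t_seg = t1

    times = np.asarray(times_out)
    Y = np.vstack(states_out)
    states = pd.DataFrame(Y, columns=list(model.state_names))
    states.insert(0, "time", times)

    diam = np.array([tumor_diameter(c, p) for c in Y[:, ix["C"]]])
    occ_rows = [synapse_occupancy(ab, p) for ab in Y[:, ix["Ab_T"]]]
    occupancy = pd.DataFrame({
        "time": times,
        "frac_pd1_free_of_ab": [o.frac_pd1_free_of_ab for o in occ_rows],
        "engaged_density": [o.engaged_density for o in occ_rows],
        "inhibition": [o.inhibition for o in occ_rows],
    })
    pct = percent_change(diam)
    category, pseudo = classify_recist(diam, p.d_detect)
    burden = Y[:, lesion_idx].sum(axis=1) if len(lesion_idx) > 1 else None

    return SimulationResult(
        times=times, diameter=diam, pct_change=pct, states=states,
        occupancy=occupancy, recist=category, pseudo_progression=pseudo,
        cancer_free=bool(Y[-1, ix["C"]] < 1.0), event_log=event_log,
        scenario_label=scenario.label, total_burden_cells=burden)
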