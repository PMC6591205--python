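"""Physiology-based four-compartment antibody pharmacokinetics.

Permeability-surface (PS) exchange between the central (plasma)
compartment and tumor, peripheral, and lymph-node tissue, with
first-order systemic clearance from central.  Tumor exchange scales with
current tumor volume: PS_tumor_eff = PS_tumor * (V_T / V_tumor_ref), so
the tumor concentration relaxes toward sigma_tumor * Ab_C at the fixed
rate PS_tumor / V_tumor_ref regardless of lesion size.

Doses are instantaneous central boluses (infusions are short relative to
the 14-day dosing interval); :func:`dose_to_concentration` converts an
mg/kg dose to the resulting nM increment of the central concentration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .parameters import PKParameters, ParameterError

__all__ = ["pk_rhs", "pk_tissue_rate", "pk_central_rate",
           "dose_to_concentration", "DoseEvent", "build_regimen"]


def pk_tissue_rate(ab_central: float, ab_tissue: float, PS: float,
                   V: float, sigma: float) -> float:
    """d(Ab_tissue)/dt for one PS-exchange tissue, nM/day."""
    return (PS / V) * (sigma * ab_central - ab_tissue)


def pk_central_rate(ab_central: float, tissue_fluxes: float,
                    pk: PKParameters) -> float:
    """d(Ab_C)/dt given the summed tissue exchange fluxes (nM*mL/day)."""
    return -(pk.CL / pk.V_central) * ab_central - tissue_fluxes / pk.V_central


def pk_rhs(ab_states, V_T: float, pk: PKParameters) -> np.ndarray:
    """Antibody concentration derivatives (nM/day).

    Parameters
    ----------
    ab_states : sequence (Ab_C, Ab_P, Ab_T, Ab_LN) in nM
    V_T : current tumor fluid volume in mL (> 0)

    With CL = 0 the total amount V_C*Ab_C + V_P*Ab_P + V_T*Ab_T +
    V_LN*Ab_LN is conserved exactly.
    """
    if V_T <= 0:
        raise ParameterError("V_T must be positive")
    ab_c, ab_p, ab_t, ab_ln = (float(a) for a in ab_states)
    ps_tumor_eff = pk.PS_tumor * (V_T / pk.V_tumor_ref)
    flux_p = pk.PS_peripheral * (pk.sigma_peripheral * ab_c - ab_p)
    flux_t = ps_tumor_eff * (pk.sigma_tumor * ab_c - ab_t)
    flux_ln = pk.PS_LN * (pk.sigma_LN * ab_c - ab_ln)
    d_c = pk_central_rate(ab_c, flux_p + flux_t + flux_ln, pk)
    d_p = flux_p / pk.V_peripheral
    d_t = flux_t / V_T
    d_ln = flux_ln / pk.V_LN
    return np.array([d_c, d_p, d_t, d_ln])


def dose_to_concentration(dose_mg_per_kg: float, pk: PKParameters) -> float:
    """Central-compartment concentration increment (nM) from an mg/kg bolus.

    dose [mg/kg] * BW [kg] -> grams; / MW -> moles; / V_central [L] ->
    molar; * 1e9 -> nM.
    """
    if dose_mg_per_kg < 0:
        raise ParameterError("dose must be non-negative")
    if pk.MW <= 0 or pk.V_central <= 0:
        raise ParameterError("MW and V_central must be positive")
    grams = dose_mg_per_kg * pk.BW * 1e-3
    moles = grams / pk.MW
    molar = moles / (pk.V_central * 1e-3)
    return molar * 1e9


@dataclass(frozen=True, order=True)
class DoseEvent:
    """A single instantaneous infusion event."""

    time: float            # days
    amount: float          # mg/kg

    def __post_init__(self):
        if self.time < 0 or self.amount < 0:
            raise ParameterError("dose time and amount must be non-negative")


def build_regimen(amount: float, interval: float, start: float,
                  n_doses: int) -> list[DoseEvent]:
    """Equally spaced dosing schedule: doses at start + k*interval.

    Biweekly nivolumab corresponds to interval=14.  Duplicate times (from
    merging schedules) collapse with summed amounts.
    """
    if interval <= 0:
        raise ParameterError("interval must be positive")
    if n_doses < 0 or int(n_doses) != n_doses:
        raise ParameterError("n_doses must be a non-negative integer")
    events = [DoseEvent(time=start + k * interval, amount=amount)
              for k in range(int(n_doses))]
    return merge_regimens(events)


def merge_regimens(*regimens) -> list[DoseEvent]:
    """Concatenate dose lists, summing amounts at coincident times."""
    flat: list[DoseEvent] = []
    for r in regimens:
        flat.extend(r if isinstance(r, (list, tuple)) else [r])
    by_time: dict[float, float] = {}
    for ev in flat:
        by_time[ev.time] = by_time.get(ev.time, 0.0) + ev.amount
    return [DoseEvent(time=t, amount=a) for t, a in sorted(by_time.items())]
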