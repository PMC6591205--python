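"""Mechanistic and pharmacokinetic parameter containers.

All rates are per day, cell counts in cells, soluble species in nM,
surface densities in molecules/um^2, volumes in mm^3 (tumor geometry)
or mL (fluid compartments), lengths in mm.

The baseline values are order-of-magnitude literature-style defaults,
calibrated so that the default virtual cohort spans the full range of
RECIST outcomes (CR/PR/SD/PD and pseudo-progression) under biweekly
anti-PD-1 dosing.  They are meant as a self-consistent reference
parameterization of this model, not as measurements.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field, fields
from typing import Any, Iterator


class ParameterError(ValueError):
    """Raised when a parameter set violates its domain invariants."""


@dataclass
class ModelParameters:
    """Mechanistic parameters of the tumor-immune checkpoint model.

    Groups (in field order): tumor growth and Teff killing; antigenicity
    (TMB-linked clone count, MHC binding); antigen release and peptide
    handling; APC supply/maturation/migration; T-cell priming, expansion,
    trafficking and exhaustion; PD-1 synapse; tumor geometry.
    """

    # -- tumor growth & killing -------------------------------------------
    k_growth: float = 0.02        # logistic growth rate, 1/day
    C_max: float = 1e11           # carrying capacity, cells
    k_death0: float = 0.002       # basal (non-immune) cancer death, 1/day
    k_kill: float = 18.0          # max killing per Teff, 1/day
    K_TC: float = 1e6             # half-saturation cancer count for killing
    # -- antigenicity ------------------------------------------------------
    n_clones: int = 100           # TMB-linked activatable Teff clone count
    n_treg_clones: float = 50.0   # Treg clone count
    Kd_ag: float = 30.0           # MHC/neoantigen dissociation constant, nM
    Kd_self: float = 500.0        # MHC/self-peptide dissociation constant, nM
    M_total: float = 2000.0       # MHC molecules per mAPC
    K_M: float = 20.0             # half-saturation antigenic pMHC per mAPC
    # -- antigen release & peptide handling --------------------------------
    k_ag_release: float = 1e-9    # antigenic protein released per dying cell
                                  # per clone, nM*mL/cell
    k_self_release: float = 5e-7  # self protein released per dying cell, nM*mL/cell
    k_uptake: float = 10.0        # protein uptake into APC, 1/day
    k_pep_deg: float = 10.0       # intracellular peptide turnover, 1/day
    k_A_deg: float = 0.2          # extracellular protein degradation, 1/day
    k_drain: float = 0.1          # lymphatic drainage of tumor antigen, 1/day
    K_A_mat: float = 10.0         # antigen half-saturation for APC maturation, nM
    K_A_LN: float = 1.0           # LN antigen half-saturation for Treg induction, nM
    # -- APC compartment ---------------------------------------------------
    k_apc_in: float = 100.0       # immature APC supply per tumor volume,
                                  # cells/(mm^3*day)
    k_apc_death: float = 0.2      # immature APC death, 1/day
    k_mat: float = 1.0            # max APC maturation rate, 1/day
    k_mig: float = 0.5            # mAPC migration to TdLN, 1/day
    k_mapc_death: float = 0.3     # mAPC death, 1/day
    n_LN: int = 10                # number of tumor-draining lymph nodes
    # -- T cells -----------------------------------------------------------
    rho_nCD8: float = 5e5         # naive CD8 density in blood, cells/mL
    rho_nCD4: float = 1e6         # naive CD4 density in blood, cells/mL
    rho_ref: float = 5e5          # reference naive density, cells/mL
    k_prime: float = 3e-3         # CD8 priming rate per mAPC, 1/day
    k_prime_reg: float = 100.0    # Treg induction scale, cells/day
    k_pro: float = 3.5            # max activated T-cell proliferation, 1/day
    T_clone_cap: float = 2e4      # expansion capacity per clone per node, cells
    k_egress: float = 1.0         # LN egress to blood, 1/day
    k_infil: float = 7e-7         # extravasation per vessel density and
                                  # tumor volume, 1/day per (vessels/mm^3)/mm^3
    gamma_vasc: float = 100.0     # tumor vessel density, vessels/mm^3
    k_trans_P: float = 0.5        # blood -> peripheral T-cell transfer, 1/day
    k_T_death: float = 0.1        # circulating/peripheral T-cell death, 1/day
    k_treg_death: float = 0.1     # intratumoral Treg death, 1/day
    k_texh_base: float = 0.02     # basal Teff death in tumor, 1/day
    k_texh_treg: float = 1.5      # max Treg-mediated Teff exhaustion, 1/day
    k_texh_pd1: float = 1.0       # max PD-1-mediated Teff exhaustion, 1/day
    K_reg: float = 6e7            # Treg half-saturation for suppression, cells
    # -- PD-1 synapse ------------------------------------------------------
    rho_PD1: float = 100.0        # PD-1 density on Teff, molecules/um^2
    rho_PDL1: float = 300.0       # PD-L1 density on cancer cells, molecules/um^2
    rho_PDL2: float = 30.0        # PD-L2 density, molecules/um^2
    Kd_PDL1: float = 40.0         # 2D PD-1:PD-L1 Kd, molecules/um^2
    Kd_PDL2: float = 8.0          # 2D PD-1:PD-L2 Kd, molecules/um^2
    Kd_ab: float = 2.0            # nivolumab:PD-1 Kd, nM
    K50_syn: float = 30.0         # half-effect engaged density, molecules/um^2
    n_hill: float = 2.0           # Hill exponent of checkpoint inhibition
    # -- geometry ----------------------------------------------------------
    vol_cell: float = 1e-6        # cancer cell volume, mm^3
    f_cellularity: float = 0.5    # cancer-cell volume fraction of tumor
    d_detect: float = 2.0         # detection-limit diameter, mm

    _POSITIVE_EXEMPT = frozenset({"n_clones"})  # n_clones may be 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for f in fields(self):
            if f.name.startswith("_"):
                continue
            v = getattr(self, f.name)
            if not isinstance(v, (int, float)) or isinstance(v, bool):
                raise ParameterError(f"{f.name} must be numeric, got {v!r}")
            if not math.isfinite(v):
                raise ParameterError(f"{f.name} must be finite, got {v!r}")
            if f.name in self._POSITIVE_EXEMPT:
                if v < 0:
                    raise ParameterError(f"{f.name} must be >= 0, got {v}")
            elif v <= 0:
                raise ParameterError(f"{f.name} must be > 0, got {v}")
        if not 0 < self.f_cellularity <= 1:
            raise ParameterError("f_cellularity must lie in (0, 1]")
        if self.n_hill < 1:
            raise ParameterError("n_hill must be >= 1")
        if int(self.n_clones) != self.n_clones:
            raise ParameterError("n_clones must be an integer")
        if self.n_LN < 1 or int(self.n_LN) != self.n_LN:
            raise ParameterError("n_LN must be an integer >= 1")

    # -- convenience -------------------------------------------------------
    def replace(self, **overrides: float) -> "ModelParameters":
        unknown = set(overrides) - {f.name for f in fields(self)}
        if unknown:
            raise ParameterError(f"unknown parameter(s): {sorted(unknown)}")
        return dataclasses.replace(self, **overrides)

    def to_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)
                if not f.name.startswith("_")}

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "ModelParameters":
        unknown = set(d) - {f.name for f in fields(cls)}
        if unknown:
            raise ParameterError(f"unknown parameter(s): {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_json(cls, path: str) -> "ModelParameters":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass
class PKParameters:
    """Four-compartment antibody transport parameters.

    Permeability-surface (PS) exchange between the central compartment and
    each tissue, first-order systemic clearance from central, and the
    bookkeeping needed to convert an mg/kg infusion into a central-
    compartment concentration increment.  Tumor exchange scales with the
    current tumor volume relative to ``V_tumor_ref``.
    """

    V_central: float = 3000.0     # plasma volume, mL
    V_peripheral: float = 3000.0  # accessible peripheral fluid, mL
    V_tumor_ref: float = 10.0     # reference tumor volume for PS scaling, mL
    V_LN: float = 10.0            # TdLN fluid volume (all nodes), mL
    PS_tumor: float = 20.0        # tumor exchange at V_tumor_ref, mL/day
    PS_peripheral: float = 300.0  # peripheral exchange, mL/day
    PS_LN: float = 5.0            # TdLN exchange, mL/day
    sigma_tumor: float = 0.3      # tumor partition factor
    sigma_peripheral: float = 0.6
    sigma_LN: float = 0.5
    CL: float = 200.0             # systemic clearance, mL/day
    MW: float = 146000.0          # antibody molecular weight, g/mol
    BW: float = 70.0              # body weight, kg

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not isinstance(v, (int, float)) or isinstance(v, bool):
                raise ParameterError(f"{f.name} must be numeric, got {v!r}")
            if not math.isfinite(v) or v <= 0:
                raise ParameterError(f"{f.name} must be positive and finite")
        for name in ("sigma_tumor", "sigma_peripheral", "sigma_LN"):
            if getattr(self, name) > 1:
                raise ParameterError(f"{name} must be <= 1")

    def replace(self, **overrides: float) -> "PKParameters":
        unknown = set(overrides) - {f.name for f in fields(self)}
        if unknown:
            raise ParameterError(f"unknown PK parameter(s): {sorted(unknown)}")
        return dataclasses.replace(self, **overrides)

    def to_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "PKParameters":
        unknown = set(d) - {f.name for f in fields(cls)}
        if unknown:
            raise ParameterError(f"unknown PK parameter(s): {sorted(unknown)}")
        return cls(**d)


#: The 30 parameters varied in the global (PSA) sensitivity analysis.
#: TMB (n_clones) and MHC/antigen affinity (Kd_ag) are members; in
#: patient-specific runs they are fixed from the patient record and the
#: remaining 28 are sampled.
PSA_PARAMETERS: tuple[str, ...] = (
    "k_growth", "C_max", "k_death0", "k_kill", "K_TC",
    "n_clones", "n_treg_clones", "Kd_ag", "Kd_self", "M_total",
    "K_M", "k_ag_release", "k_apc_in", "k_mat", "k_mig",
    "k_mapc_death", "n_LN", "rho_nCD8", "rho_nCD4", "k_prime",
    "k_prime_reg", "k_pro", "k_egress", "k_infil", "gamma_vasc",
    "k_texh_base", "k_texh_pd1", "k_texh_treg", "K_reg", "k_T_death",
)

#: Parameters that must be rounded to integers after log-normal sampling.
INTEGER_PARAMETERS: frozenset[str] = frozenset({"n_clones", "n_LN"})


def iter_parameter_names() -> Iterator[str]:
    for f in fields(ModelParameters):
        if not f.name.startswith("_"):
            yield f.name
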