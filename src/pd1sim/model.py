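"""Tumor-immune mechanistic model: state, rate laws, and ODE right-hand side.

The model spans four physiological compartments — tumor, tumor-draining
lymph node (TdLN), central (blood), and peripheral — and couples:

* logistic tumor growth with basal death and Teff-mediated killing,
* antigen release by dying cancer cells (neoantigenic share scaled by the
  TMB-linked clone count, self share by total protein),
* APC supply proportional to tumor volume, antigen-driven maturation, and
  mAPC migration split equally over the draining nodes,
* competitive peptide-MHC loading on mAPC (quasi-steady peptide pools),
* T-cell priming in the TdLN, proliferation, egress, blood distribution,
  extravasation into the tumor, and exhaustion (basal, Treg-mediated,
  and PD-1-checkpoint-mediated),
* a PD-1/PD-L1/PD-L2 immunological-synapse equilibrium blocked by
  anti-PD-1 antibody, which gates both killing and exhaustion,
* four-compartment antibody pharmacokinetics (see :mod:`pd1sim.pk`).

The pooled-clone default collapses all antigen-specific T-cell clones into
single species (19 states).  Two optional configurations expand the state:
``n_clone_states`` resolves antigen/pMHC/Teff species per clone (for
clonality-resolved outputs), and ``metastasis`` duplicates the tumor block
as a second small lesion sharing the systemic compartments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields

import numpy as np

from .parameters import ModelParameters, PKParameters
from .pk import pk_tissue_rate, pk_central_rate

__all__ = [
    "ModelState", "SynapseOccupancy", "ModelError",
    "peptide_mhc_loading", "synapse_occupancy", "killing_rate",
    "priming_rates", "tumor_diameter", "tumor_volume_mm3",
    "TumorImmuneModel", "STATE_NAMES",
]


class ModelError(ValueError):
    """Domain or numerical error raised by model-level operations."""


#: State ordering of the pooled-clone, single-lesion configuration.
STATE_NAMES: tuple[str, ...] = (
    # tumor
    "C", "A_ag", "A_self", "APC_T", "mAPC_T", "Teff_T", "Treg_T", "Ab_T",
    # TdLN (per representative node)
    "mAPC_LN", "A_LN", "aT", "aTreg", "Ab_LN",
    # central (blood)
    "Teff_C", "Treg_C", "Ab_C",
    # peripheral
    "Teff_P", "Treg_P", "Ab_P",
)


@dataclass
class ModelState:
    """Pooled-clone model state across the four compartments.

    Cell species in cells, soluble species in nM.  TdLN quantities are per
    representative draining node.
    """

    C: float = 0.0          # cancer cells
    A_ag: float = 0.0       # antigenic (neoantigen) protein in tumor, nM
    A_self: float = 0.0     # self protein in tumor, nM
    APC_T: float = 0.0      # immature APC in tumor
    mAPC_T: float = 0.0     # mature APC in tumor
    Teff_T: float = 0.0     # effector CD8 T cells in tumor
    Treg_T: float = 0.0     # regulatory T cells in tumor
    Ab_T: float = 0.0       # antibody in tumor, nM
    mAPC_LN: float = 0.0    # mature APC per TdLN
    A_LN: float = 0.0       # drained soluble antigen in TdLN, nM
    aT: float = 0.0         # activated CD8 per TdLN
    aTreg: float = 0.0      # activated/induced Treg per TdLN
    Ab_LN: float = 0.0      # antibody in TdLN, nM
    Teff_C: float = 0.0     # effector CD8 in blood
    Treg_C: float = 0.0     # Treg in blood
    Ab_C: float = 0.0       # antibody in blood, nM
    Teff_P: float = 0.0     # effector CD8 in peripheral tissues
    Treg_P: float = 0.0     # Treg in peripheral tissues
    Ab_P: float = 0.0       # antibody in peripheral tissues, nM

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in STATE_NAMES], dtype=float)

    @classmethod
    def from_array(cls, y: np.ndarray) -> "ModelState":
        y = np.asarray(y, dtype=float)
        if y.shape != (len(STATE_NAMES),):
            raise ModelError(
                f"expected state vector of length {len(STATE_NAMES)}, "
                f"got shape {y.shape}")
        return cls(**dict(zip(STATE_NAMES, map(float, y))))

    def validate(self, p: ModelParameters | None = None) -> None:
        for f in fields(self):
            if getattr(self, f.name) < 0:
                raise ModelError(f"state component {f.name} is negative")
        if p is not None and self.C > p.C_max * (1 + 1e-9):
            raise ModelError("C exceeds carrying capacity")


@dataclass(frozen=True)
class SynapseOccupancy:
    """Checkpoint engagement in the Teff:cancer-cell synapse."""

    frac_pd1_free_of_ab: float  # fraction of PD-1 not bound by antibody
    engaged_density: float      # PD-1:PD-L1 + PD-1:PD-L2, molecules/um^2
    inhibition: float           # Hill-transformed checkpoint signal in [0, 1]


def peptide_mhc_loading(peptide_pools, kds, m_total: float) -> np.ndarray:
    """Competitive loading of peptide species onto a fixed MHC pool.

    Species i with intracellular pool ``P_i`` (nM-equivalent) and MHC
    dissociation constant ``Kd_i`` is presented at

        M_i = m_total * (P_i/Kd_i) / (1 + sum_j P_j/Kd_j)

    molecules per mAPC, so the total presented never reaches ``m_total``
    and every species competes with every other.
    """
    P = np.asarray(peptide_pools, dtype=float)
    Kd = np.asarray(kds, dtype=float)
    if P.shape != Kd.shape or P.ndim != 1:
        raise ModelError("peptide pools and kds must be 1-D and equal length")
    if np.any(P < 0):
        raise ModelError("peptide pools must be non-negative")
    if np.any(Kd <= 0) or m_total <= 0:
        raise ModelError("kds and m_total must be positive")
    ratio = P / Kd
    return m_total * ratio / (1.0 + ratio.sum())


def _solve_free_pd1(R: float, L1: float, L2: float,
                    Kd1: float, Kd2: float) -> float:
    """Free PD-1 density at the two-ligand competitive binding equilibrium.

    Solves g(Rf) = Rf*(1 + L1/(Kd1+Rf) + L2/(Kd2+Rf)) - R = 0 for the free
    receptor density Rf.  g is strictly increasing and concave on
    [0, R] with g(0) = -R <= 0 and g(R) >= 0, so Newton started at R
    converges monotonically from above.
    """
    if R <= 0.0:
        return 0.0
    rf = R
    for _ in range(100):
        d1 = Kd1 + rf
        d2 = Kd2 + rf
        g = rf * (1.0 + L1 / d1 + L2 / d2) - R
        gp = 1.0 + L1 * Kd1 / (d1 * d1) + L2 * Kd2 / (d2 * d2)
        step = g / gp
        rf_new = rf - step
        if rf_new < 0.0:
            rf_new = 0.5 * rf
        if abs(rf_new - rf) <= 1e-14 * max(rf, 1.0):
            return rf_new
        rf = rf_new
    raise ModelError(
        f"synapse equilibrium failed to converge: R={R}, L1={L1}, L2={L2}, "
        f"Kd1={Kd1}, Kd2={Kd2}, last Rf={rf}")


def synapse_occupancy(ab_tumor: float, p: ModelParameters) -> SynapseOccupancy:
    """Checkpoint engagement given tumor antibody concentration.

    Antibody binding to PD-1 is treated as a fast equilibrium: the
    fraction of PD-1 free of antibody is 1/(1 + Ab/Kd_ab).  The remaining
    PD-1 equilibrates with PD-L1 and PD-L2 by 2-D competitive binding,
    and the engaged density drives a Hill inhibition signal.
    """
    if ab_tumor < 0:
        raise ModelError("ab_tumor must be non-negative")
    frac_free = 1.0 / (1.0 + ab_tumor / p.Kd_ab)
    R = p.rho_PD1 * frac_free
    rf = _solve_free_pd1(R, p.rho_PDL1, p.rho_PDL2, p.Kd_PDL1, p.Kd_PDL2)
    x = rf * p.rho_PDL1 / (p.Kd_PDL1 + rf)
    y = rf * p.rho_PDL2 / (p.Kd_PDL2 + rf)
    engaged = x + y
    inhibition = engaged ** p.n_hill / (engaged ** p.n_hill + p.K50_syn ** p.n_hill)
    return SynapseOccupancy(frac_pd1_free_of_ab=frac_free,
                            engaged_density=engaged,
                            inhibition=inhibition)


def killing_rate(C: float, Teff_T: float, occ: SynapseOccupancy,
                 p: ModelParameters) -> float:
    """Cancer-cell death flux by Teff killing, cells/day.

    Saturates in cancer-cell number and is suppressed by checkpoint
    engagement in the synapse.
    """
    if C < 0 or Teff_T < 0:
        raise ModelError("C and Teff_T must be non-negative")
    if C == 0.0:
        return 0.0
    return p.k_kill * Teff_T * (C / (C + p.K_TC)) * (1.0 - occ.inhibition)


def priming_rates(state: ModelState, pmhc_ag: float,
                  p: ModelParameters) -> tuple[float, float]:
    """T-cell activation fluxes in one TdLN, cells/day.

    Teff priming requires mature APC displaying antigenic pMHC and scales
    linearly with the TMB-linked clone count and the naive CD8 density;
    Treg induction is driven by soluble antigen presented by LN-resident
    immature APC and scales with the Treg clone count and naive CD4
    density.  Naive T cells are a constant boundary condition.
    """
    if pmhc_ag < 0:
        raise ModelError("pmhc_ag must be non-negative")
    teff_flux = (p.k_prime * state.mAPC_LN * (pmhc_ag / (pmhc_ag + p.K_M))
                 * p.n_clones * (p.rho_nCD8 / p.rho_ref))
    treg_flux = (p.k_prime_reg * (state.A_LN / (state.A_LN + p.K_A_LN))
                 * p.n_treg_clones * (p.rho_nCD4 / p.rho_ref))
    return teff_flux, treg_flux


def tumor_volume_mm3(C: float, p: ModelParameters) -> float:
    """Tumor volume in mm^3 from cancer-cell count and cellularity."""
    return C * p.vol_cell / p.f_cellularity


def tumor_diameter(C: float, p: ModelParameters) -> float:
    """Equivalent spherical tumor diameter in mm."""
    if C < 0:
        raise ModelError("C must be non-negative")
    v = tumor_volume_mm3(C, p)
    return (6.0 * v / math.pi) ** (1.0 / 3.0)


# ---------------------------------------------------------------------------
# Assembled right-hand side
# ---------------------------------------------------------------------------

class TumorImmuneModel:
    """Assembled ODE system for one virtual patient.

    Parameters
    ----------
    params, pk
        Mechanistic and antibody-transport parameters.
    n_clone_states
        If given (>= 1), antigen, pMHC, and Teff species are resolved per
        T-cell clone; antigen release is distributed over clones with a
        geometric immunodominance profile.  Mutually exclusive with
        ``metastasis``.
    metastasis
        If True, a second tumor lesion (independent initial volume)
        shares the TdLN/central/peripheral compartments; pooled clones.
    clone_dominance
        Geometric decay ratio of per-clone antigen shares in per-clone
        mode (1.0 = equal shares).
    """

    def __init__(self, params: ModelParameters, pk: PKParameters,
                 n_clone_states: int | None = None,
                 metastasis: bool = False,
                 clone_dominance: float = 0.9):
        if n_clone_states is not None and metastasis:
            raise ModelError("per-clone mode does not support metastasis")
        if n_clone_states is not None and n_clone_states < 1:
            raise ModelError("n_clone_states must be >= 1")
        self.p = params
        self.pk = pk
        self.n_clone_states = n_clone_states
        self.metastasis = metastasis
        if n_clone_states:
            w = clone_dominance ** np.arange(n_clone_states)
            self.clone_weights = w / w.sum()
        self.state_names = self._build_names()
        self.index = {n: i for i, n in enumerate(self.state_names)}
        self.n_states = len(self.state_names)

    # -- layout ------------------------------------------------------------
    def _build_names(self) -> tuple[str, ...]:
        if self.n_clone_states:
            nc = self.n_clone_states
            names = ["C", "A_self", "APC_T", "mAPC_T", "Treg_T", "Ab_T"]
            names += [f"A_ag_{i}" for i in range(nc)]
            names += [f"Teff_T_{i}" for i in range(nc)]
            names += ["mAPC_LN", "A_LN", "aTreg", "Ab_LN"]
            names += [f"aT_{i}" for i in range(nc)]
            names += ["Treg_C", "Ab_C"]
            names += [f"Teff_C_{i}" for i in range(nc)]
            names += ["Treg_P", "Ab_P"]
            names += [f"Teff_P_{i}" for i in range(nc)]
            return tuple(names)
        names = list(STATE_NAMES)
        if self.metastasis:
            names += [f"{n}_m" for n in
                      ("C", "A_ag", "A_self", "APC_T", "mAPC_T",
                       "Teff_T", "Treg_T", "Ab_T")]
        return tuple(names)

    def initial_state(self, diameter_mm: float = 30.0,
                      met_volume_mm3: float = 1.0) -> np.ndarray:
        """Resting initial condition: tumor of the given diameter, no
        immune engagement, no antibody."""
        p = self.p
        y = np.zeros(self.n_states)
        vol = math.pi / 6.0 * diameter_mm ** 3
        y[self.index["C"]] = vol * p.f_cellularity / p.vol_cell
        if self.metastasis:
            y[self.index["C_m"]] = met_volume_mm3 * p.f_cellularity / p.vol_cell
        return y

    # -- right-hand side ---------------------------------------------------
    def rhs(self, t: float, y: np.ndarray) -> np.ndarray:
        if not np.all(np.isfinite(y)):
            raise ModelError(f"non-finite state at t={t}")
        if self.n_clone_states:
            return self._rhs_clonal(t, y)
        return self._rhs_pooled(t, y)

    def _rhs_pooled(self, t: float, y: np.ndarray) -> np.ndarray:
        p, pk = self.p, self.pk
        ix = self.index
        yc = np.maximum(y, 0.0)  # rate laws evaluated on the admissible cone
        dy = np.zeros_like(y)

        lesions = [""] + (["_m"] if self.metastasis else [])
        mapc_mig_total = 0.0    # mAPC flux into each node, cells/day
        a_ln_src = 0.0          # antigen drainage into each node, nM/day
        infil = {}
        cargo_ag = 0.0          # mAPC-flux-weighted antigen cargo
        cargo_self = 0.0
        cargo_w = 0.0
        ab_central_exch = 0.0   # net antibody flux out of central, nmol/day

        for s in lesions:
            C = yc[ix["C" + s]]
            A_ag = yc[ix["A_ag" + s]]
            A_self = yc[ix["A_self" + s]]
            APC = yc[ix["APC_T" + s]]
            mAPC = yc[ix["mAPC_T" + s]]
            Teff = yc[ix["Teff_T" + s]]
            Treg = yc[ix["Treg_T" + s]]
            Ab_T = yc[ix["Ab_T" + s]]

            V_mm3 = tumor_volume_mm3(C, p)
            V_mL = max(V_mm3, 1e-9) / 1000.0

            occ = synapse_occupancy(Ab_T, p)
            kill = killing_rate(C, Teff, occ, p)
            death_total = p.k_death0 * C + kill

            dy[ix["C" + s]] = p.k_growth * C * (1.0 - C / p.C_max) - death_total

            clear = p.k_A_deg + p.k_drain
            dy[ix["A_ag" + s]] = (p.k_ag_release * p.n_clones * death_total
                                  / V_mL - clear * A_ag)
            dy[ix["A_self" + s]] = (p.k_self_release * death_total / V_mL
                                    - clear * A_self)

            A_tot = A_ag + A_self
            mat = p.k_mat * A_tot / (A_tot + p.K_A_mat)
            dy[ix["APC_T" + s]] = (p.k_apc_in * V_mm3 - mat * APC
                                   - p.k_apc_death * APC)
            dy[ix["mAPC_T" + s]] = mat * APC - (p.k_mig + p.k_mapc_death) * mAPC

            mig = p.k_mig * mAPC
            mapc_mig_total += mig / p.n_LN
            a_ln_src += p.k_drain * (A_ag + A_self) * V_mL / (p.n_LN * pk.V_LN)
            cargo_ag += mig * A_ag
            cargo_self += mig * A_self
            cargo_w += mig

            inf = p.k_infil * p.gamma_vasc * V_mm3
            infil[s] = inf
            texh = (p.k_texh_base
                    + p.k_texh_treg * Treg / (Treg + p.K_reg)
                    + p.k_texh_pd1 * occ.inhibition * C / (C + p.K_TC))
            dy[ix["Teff_T" + s]] = inf * yc[ix["Teff_C"]] - texh * Teff
            dy[ix["Treg_T" + s]] = inf * yc[ix["Treg_C"]] - p.k_treg_death * Treg

            # antibody exchange with central, tumor PS scaled by volume
            ps_eff = pk.PS_tumor * (V_mL / pk.V_tumor_ref)
            flux = ps_eff * (pk.sigma_tumor * yc[ix["Ab_C"]] - Ab_T)  # nmol/day-ish
            ab_central_exch += flux
            dy[ix["Ab_T" + s]] = pk_tissue_rate(
                yc[ix["Ab_C"]], Ab_T, pk.PS_tumor, pk.V_tumor_ref * 1.0,
                pk.sigma_tumor)  # rate = (PS/Vref)*(sigma*AbC - AbT)

        # TdLN (per representative node)
        mAPC_LN = yc[ix["mAPC_LN"]]
        A_LN = yc[ix["A_LN"]]
        aT = yc[ix["aT"]]
        aTreg = yc[ix["aTreg"]]
        dy[ix["mAPC_LN"]] = mapc_mig_total - p.k_mapc_death * mAPC_LN
        dy[ix["A_LN"]] = a_ln_src - p.k_A_deg * A_LN

        # peptide cargo presented by LN mAPC: flux-weighted tumor antigen
        if cargo_w > 0.0:
            A_ag_eff = cargo_ag / cargo_w
            A_self_eff = cargo_self / cargo_w
        else:
            A_ag_eff = A_self_eff = 0.0
        P_ag = p.k_uptake * A_ag_eff / p.k_pep_deg
        P_self = p.k_uptake * A_self_eff / p.k_pep_deg
        pmhc = peptide_mhc_loading([P_ag, P_self], [p.Kd_ag, p.Kd_self],
                                   p.M_total)
        pmhc_ag = float(pmhc[0])

        ln_state = ModelState(mAPC_LN=mAPC_LN, A_LN=A_LN)
        prime_T, prime_reg = priming_rates(ln_state, pmhc_ag, p)
        sat_M = pmhc_ag / (pmhc_ag + p.K_M)
        sat_A = A_LN / (A_LN + p.K_A_LN)
        # clonal expansion saturates at the per-node precursor-limited
        # capacity: clones x per-clone burst size x relative naive supply
        cap8 = p.T_clone_cap * p.n_clones * (p.rho_nCD8 / p.rho_ref)
        cap4 = p.T_clone_cap * p.n_treg_clones * (p.rho_nCD4 / p.rho_ref)
        pro8 = (p.k_pro * sat_M * max(1.0 - aT / cap8, -1.0)
                if cap8 > 0 else 0.0)
        pro4 = (p.k_pro * sat_A * max(1.0 - aTreg / cap4, -1.0)
                if cap4 > 0 else 0.0)
        dy[ix["aT"]] = prime_T + (pro8 - p.k_egress) * aT
        dy[ix["aTreg"]] = prime_reg + (pro4 - p.k_egress) * aTreg

        # central & peripheral T cells
        Teff_C = yc[ix["Teff_C"]]
        Treg_C = yc[ix["Treg_C"]]
        inf_total = sum(infil.values())
        out_C = inf_total + p.k_trans_P + p.k_T_death
        dy[ix["Teff_C"]] = p.n_LN * p.k_egress * aT - out_C * Teff_C
        dy[ix["Treg_C"]] = p.n_LN * p.k_egress * aTreg - out_C * Treg_C
        dy[ix["Teff_P"]] = p.k_trans_P * Teff_C - p.k_T_death * yc[ix["Teff_P"]]
        dy[ix["Treg_P"]] = p.k_trans_P * Treg_C - p.k_T_death * yc[ix["Treg_P"]]

        # antibody PK: central, LN, peripheral (tumor handled per lesion)
        Ab_C = yc[ix["Ab_C"]]
        dy[ix["Ab_LN"]] = pk_tissue_rate(Ab_C, yc[ix["Ab_LN"]], pk.PS_LN,
                                         pk.V_LN, pk.sigma_LN)
        dy[ix["Ab_P"]] = pk_tissue_rate(Ab_C, yc[ix["Ab_P"]], pk.PS_peripheral,
                                        pk.V_peripheral, pk.sigma_peripheral)
        dy[ix["Ab_C"]] = pk_central_rate(
            Ab_C,
            tissue_fluxes=ab_central_exch
            + pk.PS_LN * (pk.sigma_LN * Ab_C - yc[ix["Ab_LN"]])
            + pk.PS_peripheral * (pk.sigma_peripheral * Ab_C - yc[ix["Ab_P"]]),
            pk=pk)
        return dy

    def _rhs_clonal(self, t: float, y: np.ndarray) -> np.ndarray:
        p, pk = self.p, self.pk
        ix = self.index
        nc = self.n_clone_states
        yc = np.maximum(y, 0.0)
        dy = np.zeros_like(y)

        sl = {k: slice(ix[f"{k}_0"], ix[f"{k}_0"] + nc)
              for k in ("A_ag", "Teff_T", "aT", "Teff_C", "Teff_P")}
        C = yc[ix["C"]]
        A_self = yc[ix["A_self"]]
        A_ag = yc[sl["A_ag"]]
        Teff_T = yc[sl["Teff_T"]]
        Treg_T = yc[ix["Treg_T"]]
        Ab_T = yc[ix["Ab_T"]]

        V_mm3 = tumor_volume_mm3(C, p)
        V_mL = max(V_mm3, 1e-9) / 1000.0
        occ = synapse_occupancy(Ab_T, p)
        kill = killing_rate(C, float(Teff_T.sum()), occ, p)
        death_total = p.k_death0 * C + kill

        dy[ix["C"]] = p.k_growth * C * (1.0 - C / p.C_max) - death_total
        clear = p.k_A_deg + p.k_drain
        dy[sl["A_ag"]] = (p.k_ag_release * p.n_clones * self.clone_weights
                          * death_total / V_mL - clear * A_ag)
        dy[ix["A_self"]] = p.k_self_release * death_total / V_mL - clear * A_self

        APC = yc[ix["APC_T"]]
        mAPC = yc[ix["mAPC_T"]]
        A_tot = float(A_ag.sum()) + A_self
        mat = p.k_mat * A_tot / (A_tot + p.K_A_mat)
        dy[ix["APC_T"]] = p.k_apc_in * V_mm3 - (mat + p.k_apc_death) * APC
        dy[ix["mAPC_T"]] = mat * APC - (p.k_mig + p.k_mapc_death) * mAPC

        mAPC_LN = yc[ix["mAPC_LN"]]
        A_LN = yc[ix["A_LN"]]
        dy[ix["mAPC_LN"]] = p.k_mig * mAPC / p.n_LN - p.k_mapc_death * mAPC_LN
        dy[ix["A_LN"]] = (p.k_drain * (A_tot) * V_mL / (p.n_LN * pk.V_LN)
                          - p.k_A_deg * A_LN)

        pools = np.concatenate([p.k_uptake * A_ag / p.k_pep_deg,
                                [p.k_uptake * A_self / p.k_pep_deg]])
        kds = np.concatenate([np.full(nc, p.Kd_ag), [p.Kd_self]])
        pmhc = peptide_mhc_loading(pools, kds, p.M_total)
        pmhc_ag = pmhc[:nc]
        sat_M = pmhc_ag / (pmhc_ag + p.K_M)

        aT = yc[sl["aT"]]
        prime_T = (p.k_prime * mAPC_LN * sat_M * (p.rho_nCD8 / p.rho_ref))
        cap8 = p.T_clone_cap * (p.rho_nCD8 / p.rho_ref)  # per clone
        pro8 = p.k_pro * sat_M * np.maximum(1.0 - aT / cap8, -1.0)
        dy[sl["aT"]] = prime_T + (pro8 - p.k_egress) * aT
        sat_A = A_LN / (A_LN + p.K_A_LN)
        prime_reg = (p.k_prime_reg * sat_A * p.n_treg_clones
                     * (p.rho_nCD4 / p.rho_ref))
        aTreg = yc[ix["aTreg"]]
        cap4 = p.T_clone_cap * p.n_treg_clones * (p.rho_nCD4 / p.rho_ref)
        pro4 = p.k_pro * sat_A * (1.0 - aTreg / cap4) if cap4 > 0 else 0.0
        dy[ix["aTreg"]] = prime_reg + (pro4 - p.k_egress) * aTreg

        Teff_C = yc[sl["Teff_C"]]
        Treg_C = yc[ix["Treg_C"]]
        inf = p.k_infil * p.gamma_vasc * V_mm3
        out_C = inf + p.k_trans_P + p.k_T_death
        dy[sl["Teff_C"]] = p.n_LN * p.k_egress * aT - out_C * Teff_C
        dy[ix["Treg_C"]] = p.n_LN * p.k_egress * aTreg - out_C * Treg_C
        dy[sl["Teff_P"]] = p.k_trans_P * Teff_C - p.k_T_death * yc[sl["Teff_P"]]
        dy[ix["Treg_P"]] = p.k_trans_P * Treg_C - p.k_T_death * yc[ix["Treg_P"]]

        texh = (p.k_texh_base + p.k_texh_treg * Treg_T / (Treg_T + p.K_reg)
                + p.k_texh_pd1 * occ.inhibition * C / (C + p.K_TC))
        dy[sl["Teff_T"]] = inf * Teff_C - texh * Teff_T
        dy[ix["Treg_T"]] = inf * Treg_C - p.k_treg_death * Treg_T

        Ab_C = yc[ix["Ab_C"]]
        ps_eff = pk.PS_tumor * (V_mL / pk.V_tumor_ref)
        dy[ix["Ab_T"]] = pk_tissue_rate(Ab_C, Ab_T, pk.PS_tumor,
                                        pk.V_tumor_ref, pk.sigma_tumor)
        dy[ix["Ab_LN"]] = pk_tissue_rate(Ab_C, yc[ix["Ab_LN"]], pk.PS_LN,
                                         pk.V_LN, pk.sigma_LN)
        dy[ix["Ab_P"]] = pk_tissue_rate(Ab_C, yc[ix["Ab_P"]], pk.PS_peripheral,
                                        pk.V_peripheral, pk.sigma_peripheral)
        dy[ix["Ab_C"]] = pk_central_rate(
            Ab_C,
            tissue_fluxes=ps_eff * (pk.sigma_tumor * Ab_C - Ab_T)
            + pk.PS_LN * (pk.sigma_LN * Ab_C - yc[ix["Ab_LN"]])
            + pk.PS_peripheral * (pk.sigma_peripheral * Ab_C - yc[ix["Ab_P"]]),
            pk=pk)
        return dy

    # -- derived outputs ---------------------------------------------------
    def clonality(self, y: np.ndarray) -> float:
        """Blood CD8 clonality.

        Per-clone mode: 1 - H/ln(n) over the blood Teff clone distribution
        (Shannon-evenness-based clonality as used for TCR sequencing).
        Pooled mode: the expanded fraction of the blood CD8 pool,
        Teff_C / (Teff_C + naive CD8 in central volume) — a monotone proxy
        for sequencing clonality when clone identity is not resolved.
        """
        if self.n_clone_states:
            nc = self.n_clone_states
            i0 = self.index["Teff_C_0"]
            counts = np.maximum(y[i0:i0 + nc], 0.0)
            total = counts.sum()
            if nc == 1 or total <= 0:
                return 0.0
            f = counts[counts > 0] / total
            H = -(f * np.log(f)).sum()
            return float(1.0 - H / math.log(nc))
        teff_c = max(float(y[self.index["Teff_C"]]), 0.0)
        naive = self.p.rho_nCD8 * self.pk.V_central
        return teff_c / (teff_c + naive)
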