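# Methods

## Model structure

The simulator follows one virtual patient as a system of ordinary
differential equations across four physiological compartments: the tumor,
a representative tumor-draining lymph node (TdLN), the central (blood)
compartment, and a lumped periphery.  The pooled-clone default has 19
state variables; optional configurations expand the antigen/T-cell
species per clone (for clonality-resolved outputs) or duplicate the tumor
block as a second, initially 1 mm³ lesion sharing the systemic
compartments (an undetected micrometastasis).

Units throughout: days, cells, nM for soluble species, molecules/µm² for
synapse surface densities, mm³/mm for tumor geometry, mL for fluid
compartments.

### Tumor

Cancer cells grow logistically (`k_growth`, capacity `C_max`) and die
from a basal rate plus Teff killing.  Killing saturates in cancer-cell
number, `k_kill·Teff·C/(C+K_TC)`, and is multiplied by `1−f_PD1`, the
checkpoint signal from the synapse model.  Tumor volume is
`C·vol_cell/f_cellularity` and the reported diameter is that of the
equivalent sphere.  With the default `K_TC = 1e6` cells, killing is
saturated over nearly the whole clinically visible size range, which
makes the *per-capita* kill rate at quasi-steady state independent of
lesion size — a deliberate choice so that sustained dosing can eradicate
small residual lesions (the adjuvant-therapy question) instead of always
stalling at a microscopic equilibrium.

### Antigen release and presentation

Total cell-death flux releases antigenic protein (proportional to the
TMB-linked clone count `n_clones`) and self protein into the tumor
interstitium, where both are cleared and drained to the TdLN.  Intracellular
peptide pools in APCs are treated as quasi-steady
(`P = k_uptake·A/k_pep_deg`), and peptides compete for a fixed MHC pool
per mature APC:

    M_i = M_total · (P_i/Kd_i) / (1 + Σ_j P_j/Kd_j)

so presentation of the neoantigen falls both when its K_d rises and when
self peptide is abundant.  Immature APC supply is proportional to tumor
volume; maturation is antigen-driven; mature APCs migrate to the nodes,
split equally over `n_LN`.

### T cells

Priming of CD8 T cells in the node requires mature APCs displaying
antigenic pMHC (half-saturation `K_M`) and scales linearly with
`n_clones` and the naive CD8 blood density (naive pools are a constant
boundary condition, entering relative to `rho_ref`).  Activated cells
proliferate at `k_pro` gated by the same pMHC signal, and the expansion
saturates at a precursor-limited capacity

    cap = T_clone_cap · n_clones · (rho_nCD8/rho_ref)

per node (analogously for Tregs with `n_treg_clones` and `rho_nCD4`).
This capacity is the mechanism by which TMB and naive T-cell density
control the attainable effector pool — without it the expansion loop is
unbounded and every virtual patient is eradicated regardless of TMB.
Egressed cells enter the blood, transfer to the periphery, and
extravasate into the tumor at `k_infil·gamma_vasc·V_T`.  Intratumoral
Teff die at a basal rate plus a Treg-occupancy term
(`k_texh_treg·Treg/(Treg+K_reg)`) plus a checkpoint term
(`k_texh_pd1·f_PD1·C/(C+K_TC)`).  Treg induction in the node is driven by
drained soluble antigen presented by node-resident immature APCs.

### Checkpoint synapse

Antibody binding to PD-1 is a fast equilibrium: the PD-1 fraction free of
drug is `1/(1+Ab_T/Kd_ab)`.  The remaining PD-1 density R equilibrates
with PD-L1 and PD-L2 by two-dimensional competitive binding,

    (R−x−y)(L1−x) = Kd_PDL1·x,   (R−x−y)(L2−y) = Kd_PDL2·y,

solved for the free-receptor density by a damped-safe Newton iteration on
the equivalent scalar equation (monotone and concave, so convergence is
guaranteed from the upper end point; tolerance 1e-14 relative).  The
engaged density e = x+y drives `f_PD1 = e^n/(e^n + K50_syn^n)`.  Setting
`rho_PDL2 = 0` recovers a single-ligand model.

### Antibody pharmacokinetics

A permeability–surface (PS) exchange model: central clearance `CL`, and
for each tissue `dAb_i/dt = (PS_i/V_i)(σ_i·Ab_C − Ab_i)`.  Tumor exchange
scales with current tumor volume (`PS_tumor·V_T/V_tumor_ref`), which
makes the tumor concentration relax at a size-independent rate.  With
clearance off, total antibody amount is conserved exactly.  This simple
PS form was chosen over a two-pore formalism because the only coupling
that matters downstream is the tumor antibody concentration; a finer PK
model can be swapped in behind `pk_rhs`.  The PK defaults (volumes,
PS values, σ, CL=200 mL/day, MW 146 kDa, BW 70 kg) are placeholders at
physiological orders of magnitude, not fitted values.  Doses are
instantaneous central boluses; 3 mg/kg ≈ 479 nM in a 3 L central volume.

## Simulation engine

Integration uses LSODA (stiff-capable) at rtol 1e-6 with per-species
absolute tolerances (1e-3 cells, 1e-6 nM), restarted at every dose and at
resection so impulses are exact.  Resection scales every tumor-compartment
species by `residual_volume/V_T`, preserving composition.  Because a
continuous ODE can never reach zero cells, a lesion whose cancer-cell
count crosses 0.5 downward triggers an integrator event and is clamped to
zero; "cancer-free" additionally requires fewer than one cell at the
horizon.  RECIST 1.1 thresholds are applied to the percent change of the
final diameter (PR ≤ −30%, PD ≥ +20%, boundaries inclusive), CR when the
final diameter is below the 2 mm detection limit; the single-lesion
absolute +5 mm PD qualifier is omitted.  Pseudo-progression is flagged
when a trajectory first crosses +20% but ends in CR/PR.

## Parameterization

Baseline values are order-of-magnitude literature-style choices (cell
kinetic rates ~0.01–1/day, naive T-cell densities ~5×10⁵–10⁶ /mL, NSCLC
growth rate 0.02/day, 30 mm baseline tumor), calibrated as a set so that
the default virtual cohort exhibits the full range of RECIST outcomes
under biweekly dosing, with the TMB response threshold between ~25 and
~190 alterations and no complete responses without treatment.  They are a
self-consistent reference parameterization of this model, not
measurements; all are overridable from configuration.  The
`RECIST_SHOWCASE` fixtures document parameter sets that deterministically
produce CR, PR, SD, PD, and pseudo-progression: the PR case overrides
`K_TC` upward so killing desaturates as the tumor shrinks and the
trajectory stalls at a small stable size; the pseudo-progression case
pairs fast growth (`k_growth = 0.05`) with a strong but slower-arriving
response.

## Sampling and statistics

* **LHS with log-normal transform.**  Each parameter column occupies all
  n probability strata, mapped through `GM·exp(Φ⁻¹(p)·ln GSD)`.  The
  global sensitivity analysis varies 30 parameters with GSD 1.5;
  virtual-patient replicates use half the GSD on the log scale (√1.5)
  for the 28 parameters not fixed by the patient record.  Integer
  parameters (clone count, node count) are rounded after the transform.
* **PRCC.**  Rank-transform everything (average ranks on ties),
  residualize each parameter and the output on the remaining parameters,
  correlate the residuals; significance from
  `t = r·√(df/(1−r²))`, df = n−2−(k−1).  An explicit normal-equations
  oracle in the test suite pins the implementation to 1e-10.
* **Top-down concordance.**  Pearson correlation of Savage scores
  (`S_i = Σ_{j≥rank_i} 1/j`, averaged over tied blocks).
* **Hypothesis tests.**  Kruskal-Wallis (tie-corrected, χ² reference)
  with pairwise two-sided rank-sum post-hocs Bonferroni-multiplied by the
  number of pairs; Wilcoxon signed-rank exact for n ≤ 25, corrected
  normal approximation otherwise.  These delegate to scipy.stats; the
  test suite checks them against exact enumeration.
* **Prediction intervals.** Median and empirical 20th/80th percentiles
  (type-7 linear interpolation), the 60% interval used in per-patient
  summaries.

Virtual patients fix (TMB → `n_clones` one-to-one, K_d) and share one LHS
design across scenario arms, so arms are paired replicate by replicate.
A replicate is reproducible in isolation by regenerating the design from
the same seed and taking its row.  The synthetic cohort generator mirrors
the published input ranges: TMB log-uniform on [10, 400] (covering the
26/190 decision points), K_d uniform on [12.4, 88.3] nM with exactly one
outlier patient at 733 nM.

## What the synthetic data do and do not show

The generator emulates the *measured input ranges* of a small neoadjuvant
trial population, not its joint distribution: TMB and K_d are sampled
independently, replicate-level parameter uncertainty is synthetic
(half-GSD log-normals around one baseline), and initial tumor size is
fixed at 30 mm because per-patient sizes are not modeled.  Passing tests
therefore demonstrate internal consistency and the qualitative response
structure (TMB thresholds, affinity effects, scenario orderings), not
calibration to any real cohort's outcome rates.

## Problem sizes and numerical choices

The acceptance checks run the sensitivity analysis at n = 500 (signs and
p < 0.01 for the six headline parameters), the response map on a 3×3
TMB × K_d grid at 50 paired replicates per cell with a 5-percentage-point
one-sided slack on median monotonicity (medians of paired replicates are
still stochastic), and the scenario orderings at 100 replicates; the
reporting script uses n = 300 / 30-replicate cohorts.  These sizes were
chosen to keep a desk-scale run in minutes; all scale up by argument.
Ties in the adjuvant-vs-neoadjuvant comparison (both arms curing the
metastasis, burden < 1 cell) are excluded from the sign test.

## Known limitations

No IFNγ→PD-L1 feedback, macrophages/MDSCs, germline antigens, spatial
structure, target-mediated drug disposition, or population-PK covariates.
The node count `n_LN` is nearly neutral in the pooled configuration
(per-node quantities scale inversely with it), so its sensitivity rank is
not meaningful here.  Clonality in pooled mode is a proxy (expanded
fraction of the blood CD8 pool), not a sequencing-derived clonality; the
per-clone configuration computes a Shannon-evenness clonality but at a
substantially larger state dimension.  SBML export is not provided.
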