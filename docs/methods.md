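# Methods

## The model

`adrenosim` simulates steroid biosynthesis in stimulated NCI-H295R
adrenocortical cells as a deterministic ODE system in two well-mixed
compartments: the culture medium (constant volume, default 2.0 mL, a
typical 6-well format) and the total intracellular space (growing with the
cell population). The state comprises 7 cholesterol/oxysterol pools and 14
steroids, each steroid present in both compartments — 35 concentrations in
nmol/L, time in hours.

**Cholesterol supply.** Medium cholesterol (CHOL) is taken up first-order
into the intracellular free pool (CHOC), which exchanges with an ester
store (CHOS; accumulation `kf_acc`/`kb_acc`, hydrolase release `k_CEH`)
and with mitochondrial cholesterol (CHOM; `kf_MTR`/`kb_MTR`). CHOM
partitions onward to a CYP11A1-remote pool (CHOR) using the same
`kf_MTR`/`kb_MTR` constants — the 42-item kinetic inventory carries no
dedicated constant for this leg, so the mitochondrial transfer constants
are reused. StAR-mediated localization (`kf_loc`/`kb_loc`) moves CHOR to
the CYP11A1-proximal pool (CHON) that feeds side-chain cleavage; this is
the rate-limiting delivery step. An irreversible oxysterol bypass
(`k_OxysterolSynthesis`) drains CHOC into a sink (OXY), representing
cholesterol lost to non-steroidogenic oxidation.

**Enzymatic reactions.** The C21 pathway has 17 reactions catalysed by 9
enzymes (CYP11A1, CYP17H, CYP17L, HSD3B2, CYP21A2, CYP11B1, CYP11B2,
HSD17B3, CYP19A1). All but CYP11B2 use shared-site rapid-equilibrium
kinetics with competing substrates:

    v_i = a · Vmax_i · (S_i/Km_i) / (1 + Σ_j S_j/Km_j),

where the sum runs over all substrates of the same enzyme and `a` is a
relative-activity multiplier (the handle used for mechanism-of-action
inference). This form makes each substrate a competitive inhibitor of its
siblings, which is what couples the Δ5/Δ4 branches and the
mineralocorticoid/glucocorticoid split. CYP11B2 (CORTICO → ALDO) is
modelled first-order; with one substrate and concentrations far below
saturation, a single rate constant is the identifiable description.

**Transport and growth.** Each steroid diffuses passively between cell and
medium with a per-steroid clearance `kdiff` (mL/h): the molar flux is
`kdiff · (C_cell − C_medium)`, divided by the receiving compartment volume.
Cell number and mean single-cell volume follow exponential laws
`N(t) = N0 e^{gN t}`, `v(t) = v0 e^{gv t}`; intracellular concentrations
are diluted at rate `gN + gv` (switchable via
`KineticParameterSet.dilution`). With the switch on, dilution exactly
offsets volume growth in the amount bookkeeping, so total moles over both
compartments (including OXY) are conserved — the test suite verifies drift
below 1e-6 over 72 h, and the right-hand side satisfies the amount balance
identically at random states.

## Integration

The solver is classic fourth-order Runge-Kutta with a rate-controlled
variable step, `dt = clamp(c / max|rate|, 1e-5, 1e-2)` hours, where
`max|rate|` is the largest absolute flux (nmol/L/h) at the step start.
`c = 100 nmol/L` keeps the per-step relative change of the fastest pool
well under 0.1% at the default model's concentration scale (~2e5 nmol/L).
Segments land exactly on record times by shortening the final step, so
objectives evaluated on the sampling grid never interpolate. `error_ratio`
re-runs the model at fixed steps spanning the dt range and reports the
worst pointwise relative deviation from the adaptive run (floor 1e-12 to
avoid 0/0); for the shipped model it stays below 1e-8 across
dt ∈ {1e-5, 1e-4, 1e-3, 1e-2}. Enzymatic and first-order fluxes treat
negative excursions as zero substrate, which makes the explicit scheme
self-quenching near depletion instead of oscillating.

The numerical core (`_core.py`) is numba-compiled; ensembles of parameter
sets/activity vectors (GA children, sensitivity perturbations, scan cells)
integrate in a single compiled batch.

## Calibration

The objective is the normalized least-squares distance

    NLSD = Σ_h Σ_i Σ_j (X^exp_hij − X^sim_hij)² / (X^max_hi)²

over compartments, species (cholesterol + 14 steroids), and the sampling
times {0, 8, 24, 48, 72} h, with `X^max` the per-trace maximum of the
measured means. Points below the lower limit of quantification are
excluded — never imputed. Replicates (default N = 4) enter as per-time
means; the normalization makes the objective invariant to per-species unit
changes. The measured "intracellular cholesterol" observable is mapped to
the sum of the model's intracellular pools (CHOS+CHOC+CHOM+CHON+CHOR),
since a bulk assay cannot resolve localization.

`fit_parameters` runs Levenberg-Marquardt on log10-transformed free
parameters (all are positive and span decades); with explicit bounds it
switches to the trust-region reflective variant, since plain LM is
unbounded. Initial states are equilibrated from the t=0 data: medium
concentrations from measurement, intracellular steroids at the equilibrium
of the transport law (equal to medium for the symmetric clearance; the
helper accepts asymmetric influx/efflux constants, giving
`C_cell = kf·M/kb`), cholesterol pools from the configured initial table.

`fitting_sensitivity` scores each static parameter by the relative
finite-difference effect of a +10% perturbation on the objective,
`|NLSD(1.1x) − NLSD(x)| / (0.1 · NLSD(x))`, falling back to an absolute
scale (flagged) when the baseline objective is zero.

## Mechanism-of-action estimation

The input is the fold change (treated/control) of the 12 LC-MS steroids'
medium concentrations at 72 h. Eight enzyme activities are estimated
(CYP19A1 fixed at 1) in log10 space within [1/100, 100] — symmetric for
inhibition and activation. The fitness is the normalized squared residual
`Σ ((FC_obs − FC_sim)/FC_obs)²` over quantified steroids; a raw-SSR switch
exists. Censored steroids drop out of the objective, and the result
carries per-enzyme identifiability flags when the informative downstream
steroid is censored (e.g., CYP11B2 is unidentifiable once ALDO is below
the LLOQ).

Step 1 is a real-coded GA: population 100 initialized log-uniform in
bounds, JGG generation alternation (6 parents sampled without replacement,
25 children by REX, best 6 children replace exactly the parents), and
termination below 0.1 or at 1000 generations — these defaults follow the
published protocol for this estimator class. REX samples children as
`centroid + Σ ξ_k (parent_k − centroid)` with i.i.d. ξ of mean 0 and
variance 1/(k−1); the default ξ is uniform on ±√(3/(k−1)) (a Gaussian
variant sits behind a flag). Step 2 polishes the GA optimum with
Levenberg-Marquardt on the same residuals in log space, clipped back to
bounds; the LM result is kept only if it improves the objective. A
duplicate-run mode repeats the whole optimization from an independent seed
and reports both results as a numerical-stability check.

Supporting statistics: per-steroid two-sample Welch t-tests with
Bonferroni correction (significant at adjusted p < 0.01), and hierarchical
clustering of compound profiles with Ward linkage on standardized
Euclidean distances (column variances floored for constant features).

## Dynamic sensitivity and the phenotype scan

Dynamic sensitivity is the one-sided finite difference
`S_{x,y}(t) = (Δy/y)/(Δx/x)` with Δx/x = +0.1, evaluated every 6 h to
72 h from one perturbed forward simulation per parameter (42-parameter
inventory). The default reported compartment is the medium (the displayed
convention); intracellular sensitivities are available through the same
interface. Parameters are ranked by the total trapezoidal area under
|S(t)| summed over steroids, taking S = 0 at t = 0; the unsigned area is
used because sensitivities that change sign mid-course would otherwise
cancel in an importance score.

The 2-D scan perturbs CYP17H and HSD3B2 multipliers over 0–200% in 10%
steps (441 cells, one batch integration) and classifies each cell by net
72-h medium production: a steroid is "produced" when its increase over the
run is at least θ (default 0.01) of the baseline increase. Net production
rather than the raw final concentration is used because measured t=0
concentrations are nonzero: residual initial material would otherwise mark
a dead branch as producing. Categories: all 14 produced → all-steroid;
otherwise by the marker steroids ALDO (mineralocorticoid) and DCORT+CORT
(glucocorticoid) → mineralocorticoid-only, glucocorticoid-only,
both-corticoid, or terminated-upstream when neither marker branch runs.
θ = 0.01 keeps the baseline trivially all-producing and is exposed as a
flag; baseline categories are stable for θ ∈ [0.005, 0.02].

## Synthetic data

The generator emulates the assay design: sampling at {0, 8, 24, 48, 72} h,
two compartments, 4 replicate wells per point, multiplicative log-normal
noise with unit mean (σ² = ln(1+CV²), default CV 10% — LC-MS-like, keeps
concentrations positive), and per-steroid LLOQ censoring with the highest
limits on the trace steroids (ALDO 0.2, TESTO 0.1, E2 0.01 nmol/L; 0.05
otherwise — placeholders, as real assay limits are instrument-specific).
Fold-change profiles are built from independently noised treated and
control arms, censoring each arm before the ratio. The inhibitor panel
mixes null compounds with one/two-enzyme inhibitors whose planted activity
follows `1/(1 + dose/IC50)`, IC50 drawn log-uniformly so the top dose
reaches ≥90% inhibition; the truth table makes it a closed-loop benchmark
(generate → estimate → compare).

What synthetic data does not emulate: real inter-well correlation,
drift/batch effects, matrix effects in quantification, cytotoxic
confounding, and receptor-mediated (non-enzymatic) drug action. Passing
recovery tests therefore demonstrates the estimator's correctness and
conditioning under the assay's statistical design, not performance on any
particular laboratory's measurements.

## Default parameters and problem sizes

The shipped parameter table is plausibility-checked, not measured: orders
of magnitude were chosen so that (i) the simulated 72-h medium profile
reproduces the characteristic ranking of stimulated H295R cells
(PREG > CORTICO > CORT ≫ ALDO, with DHEA/TESTO/E2 as trace species),
(ii) intracellular steroid levels sit near or above the Michaelis
constants so substrate competition is active and CHON saturates CYP11A1,
and (iii) the model's fastest effective timescales (≲1/h) keep the
explicit integrator within its 1e-8 error contract across the dt range.
Quantitative work should replace it with a set calibrated to the user's
own time courses (`adrenosim fit`).

Recovery studies in the test suite and the acceptance script run the GA at
a reduced budget (120 generations, population 50, versus the 1000×100
defaults) — for planted single- and two-enzyme mechanisms the LM polish
converges from that basin, and the smaller budget keeps the full benchmark
battery fast. Calibration recovery uses 10 noisy replicates at 5% CV with
three free maximum velocities.

## Known limitations

* Receptor signalling (ACTH/forskolin/angiotensin II) is implicit in the
  calibrated parameters; stimulation cannot be varied independently.
* CYP11B2 is first-order, so ALDO-side substrate competition is absent.
* The phenotype categories depend on the reconstruction threshold θ; cells
  on category boundaries can switch at extreme θ choices.
* The default parameter set is non-authoritative (above); quantitative
  boundary positions in the 2-D scan are properties of the parameter set,
  not of the package.
* SBML export is not implemented; the CSV/JSON parameter tables and the
  declarative reaction table are the interchange surface.
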