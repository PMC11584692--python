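# Methods

## The model

`bmecsim` implements a mechanistic, ODE-based model of brain microvascular
endothelial cell (BMEC) signaling, built to study how the cell's functional
phenotype is decided under oxygen–glucose deprivation and reoxygenation
(OGD/R), the standard in-vitro surrogate of ischemic stroke with
reperfusion. The network couples five pathway modules:

* **Inflammation** — TNFα/TNFR and LPS/TLR4 receptor activation, TRAF6 and
  RIPK1 ubiquitination converging on TAK1→IKK, IκB·NFκB dissociation and
  nuclear NFκB with the two canonical negative feedbacks (NFκB-induced A20
  suppressing TRAF6/RIPK1 activation; NFκB-induced IκB mRNA resequestering
  NFκB), plus TAK1-driven p38/JNK/ERK and NFκB-driven secretion of IL-6,
  IL-1β and CCL2.
* **Cell survival** — VEGFR with two phosphosites (pY1175→PLCγ→MEK→ERK and
  Ca²⁺ release→eNOS, PLCγ→AMPK→ULK; pY951→PI3K→AKT), Ang1/Tie2→AKT and ERK,
  FGF/FGFR→PI3K/AKT and PLCγ→PKC→MEK→ERK, and Wnt-dependent stabilization
  of β-catenin.
* **Hypoxia regulation** — O₂-dependent prolyl-hydroxylase (PHD) activity
  degrading HIF1α/HIF2α; nuclear HIFs drive Lon, BDNF, SEMA3G and Ang2
  synthesis and stabilize p53; p53 feeds the MDM2 negative feedback, the
  TIGAR→NADPH antioxidant arm and the BAX→caspase-3 apoptotic arm.
* **Metabolism** — a conserved ATP⇌AMP pool with aerobic (glucose- and
  O₂-dependent) and anaerobic (glucose- and PFKFB3-dependent) regeneration;
  AMPK activation by the AMP/ATP ratio; hypoxic PFKFB3 induction.
* **Oxidative stress** — the succinate–SDH–ROS axis at the model's center:
  low O₂ reverses net SDH flux so succinate accumulates roughly linearly
  during OGD; restored O₂ drives rapid succinate oxidation, and the
  associated reverse electron transport produces a ROS burst. ROS induces
  iNOS→NO, combines with NO to ONOO⁻, oxidizes BH4 to BH2 (which amplifies
  ROS through uncoupling), activates the Keap1/NRF2 defense that clears
  ROS, degrades the tight-junction proteins ZO-1 and Claudin5, activates
  IKK (`kp_IKK_ROS`, the crosstalk into inflammation) and perturbs
  ER–cytosol Ca²⁺ exchange.

All kinetics are mass action multiplied by saturating (Michaelis/Hill)
regulator factors; every flux is nonnegative for nonnegative states. The
network has 91 species and 191 reactions/parameters. Units: relative
copy-number units for proteins (quiescent pools normalized to 1 where no
absolute scale is needed), relative units for metabolites and radicals, O₂
as dissolved fraction (0.21 control), glucose in mmol/L (5.05 control),
ligands in molecules per cell (media doses converted from ng/ml via
molecular weight and plating density), time in hours.

## Quiescent state by construction

Rather than searching for parameters that keep the model still under
control conditions, the builder *balances* the network: one designated
rate constant per species (usually its basal synthesis or its
deactivation rate) is solved in closed form so that the declared reference
state has exactly zero net flux under the control environment. The
reference state is therefore an exact fixed point, and the required
stability — every species within 0.9×–1.1× of its initial value over 168 h
of control culture — holds by construction and is verified numerically
(observed drift is ~10⁻⁷ over 7 days, dominated by integrator tolerance).
`find_quiescent_state` still performs the verification honestly and, for
perturbed parameterizations, falls back to damped fixed-point refinement
with an explicit failure report.

## Protocols and state handoff

A protocol is a sequence of phases, each clamping the environment (O₂,
glucose) and optionally adding ligand boluses at phase start. Phases are
integrated sequentially with the terminal state of one phase (plus boluses)
seeding the next, reproducing the experimental media-change procedure for
OGD→reoxygenation. "Close to zero" deprivation is quantified as O₂ = 0.001
and glucose = 0.05 mmol/L — hard zeros sit on the singular boundary of the
saturating uptake terms and create needless stiffness; both values are
configurable. Runs are preceded by a 24 h control pre-equilibration (a
declared default; the state at its end is the run's own normalization
baseline). Integration uses LSODA with rtol 10⁻⁶ and per-species absolute
tolerances of 10⁻⁹ × species scale; numerically negative values are clamped
to zero after integration with a logged count (> 0.1 % clamped samples
raises a warning).

## Scoring

Module outputs and composite scores follow the standard products of
normalized markers: inflammation = IL-6·IL-1β·CCL2, growth =
Ang2·SEMA3G·BDNF, tight junction = ZO-1·Claudin5; proliferation score =
Ang2·SEMA3G·BDNF·ZO-1·Claudin5, damage score =
IL-6·IL-1β·CCL2·ROS·ONOO⁻·caspase-3, and the cell-function (CF) score is
proliferation/damage, all equal to 1 at the control baseline.

Secreted cytokines are scored as **cumulative secretion**: the integral of
the secretion flux since stimulus onset, normalized to the control
cumulative secretion over the same elapsed time. This preserves the
physical meaning of "secretion over the experiment" (a transient episode is
not erased by media clearance) while keeping the state variables themselves
at steady state under control conditions — a cumulative state variable
would grow without bound and contradict quiescence. In the phenotype grid,
markers are sampled at the end of each reoxygenation period (the grid's
sampling convention is not uniquely determined by its labelling;
end-of-period is the declared choice), log2-transformed with a floor of
10⁻⁶ × baseline.

## Sensitivity analysis

Latin hypercube sampling assigns every parameter a multiplier in
[0.5, 2.0] with exact per-column stratification. Each sample is an
intrinsic variant of the model: the whole run, including pre-equilibration
and baseline, uses the scaled parameters, and scores are normalized to the
sample's own baseline. PRCC is computed from the precision matrix of the
rank correlation matrix (equivalent to rank-residual regression, which the
test suite verifies to 10⁻⁶ with an independent implementation), with a
residual-regression fallback for rank-deficient cases, and p-values from
the t approximation with df = n − 2 − (k − 1); Benjamini–Hochberg adjusted
p-values are reported alongside raw ones. The default summary statistic is
the output at the end of reoxygenation; AUC over the protocol is available.
Failed samples become missing values, are excluded from PRCC with a logged
count, and may not exceed 5 % of the design.

The reference analysis depth is 5000 samples; the shipped analysis script
defaults to 1000 and the test suite uses 200–500, sizes chosen so the full
pipeline runs on a laptop in minutes. PRCC rankings at n=500 over 191
parameters carry sampling noise of roughly ±0.1, so rank-based checks are
formulated as top-k membership rather than exact order.

## Virtual cohorts and interventions

A virtual cell multiplies a chosen set of sensitive parameters (default:
the 12 parameters that consistently dominate the CF-score PRCC — succinate
turnover, RET ROS production, SDH level, the Keap1/NRF2 axis, TIGAR
turnover and IκB mRNA turnover) by i.i.d. N(1, 0.25²) draws
rejection-resampled into [0.5, 2.0]. Heterogeneity is intrinsic: each
cell's scores are normalized to its own pre-equilibrated baseline, so
heterogeneity does not masquerade as dysfunction.

An intervention is modelled as an **acute pharmacological modulation**: the
target group's parameters are additionally multiplied from stimulus onset
onward, while pre-equilibration and the normalization baseline use the
cell's own parameters — as in the experiments, where the inhibitor is
added together with the insult. (Re-equilibrating the intervention into
the baseline instead would cancel static amplifications under
fold-normalization and would correspond to a lifelong genetic change
rather than a drug.) Target groups: succinate → `kt_Succinate`; p53 → its
basal/HIF-/ROS-driven synthesis rates; HIF1α → `kt_HIF1a`, `kon_HIF1a`;
IκB → its transcription/translation rates. Cohort interventions draw one
uniform multiplier in [0.5, 0.8] per cell (variability in efficacy);
"enhance" mode uses the reciprocal range. Population summaries are per-cell
endpoint-CF fold changes (treated/control, paired by cell id): median,
quartiles, fraction strictly > 1, histogram.

A note on direction: succinate inhibition is protective monotonically;
p53 and HIF1α inhibition are protective at moderate strength but the
benefit shrinks and can reverse below ~0.5× because strong inhibition also
removes the p53→TIGAR→NADPH antioxidant arm. This is an emergent property
of the network, not a fitted behavior.

## Calibration

All observations are relative levels; residuals are computed on normalized
scales only. `to_max` datasets are compared after normalizing both data
and prediction to their maxima **over the dataset's timepoints** (matching
how an experimenter normalizes a measured series); `to_baseline` divides
by the pre-stimulus control value. The objective is the weighted sum of
squared residuals over all datasets, one simulation per distinct protocol,
with a large finite penalty (10⁶ per dataset) for failed simulations.

Optimization is a bounded generalized pattern search in log-parameter
space (so the 0.5×–2× bounds are a symmetric box and steps are relative):
opportunistic polling over ±coordinate directions with the last successful
direction tried first, mesh doubling on success (capped at the initial
mesh), halving on failure, termination on mesh collapse below 10⁻³ or the
iteration budget. The search is deterministic under a seed and never
returns a point worse than its start. The two-stage workflow (module-wise
fit, then global refinement) is supported by calling the fitter with a
module's datasets and parameters first, then with the full corpus.

Parameter-recovery experiments target kinetically identifiable rates
(decay/turnover constants such as `koh_HIF1a`, `kd_Succinate`,
`kd_IKB_mrna`, `kd_iNOS`): pure synthesis-rate scalings largely cancel
under fold normalization and are structurally hard to recover from
relative data — a genuine identifiability property of normalized corpora,
not an optimizer limitation.

## Synthetic data

The generator emulates the structure of the experimental calibration
corpus: sparse normalized time courses (8–13 points each) under TNFα
100 ng/ml, LPS 300 ng/ml, VEGF 50 ng/ml, FGF 1 µg/ml, 1 % O₂ hypoxia and
OGD 6 h/R 24 h, totalling 574 points across 52 datasets and all five
modules. Noise is multiplicative lognormal (default σ = 0.05), matching
densitometry/ELISA-style positive data with roughly constant CV; additive
Gaussian is available. Every dataset records its generating parameters, so
recovery tests are self-contained.

What the generator does **not** emulate: replicate-to-replicate biological
variability beyond a constant CV, systematic digitization bias, batch
effects, non-uniform sampling error, or measurement saturation. Passing
recovery tests therefore demonstrates correctness of the fitting machinery
and identifiability under idealized noise, not performance on real blots.

## Shape fixtures

The qualitative OGD/R dynamics the model must reproduce are encoded as
machine-checkable constraints, all collected in
`bmecsim.synthetic.default_shape_fixtures` (windows and tolerances in one
place): succinate monotone accumulation on [1, 6] h and ≥ 50 % of the rise
oxidized within 2 h of reoxygenation; ROS maximum after reox onset; pAMPK
with two peaks (one in OGD, one in the 4–8 h post-reox window, i.e.
10–14 h) at prominence ≥ 0.5× baseline; p53 ≥ 1.2× at end of OGD and final
value within 0.8–1.2× baseline; HIF1α ≥ 1.2× at end of OGD and declining
in reox; cytokine cumulative secretion non-decreasing in OGD duration
(1, 3, 6 h at fixed 24 h reox); growth factors closer to baseline at 24 h
than at 1 h of reox; caspase-3 declining across reox after 3 h OGD but
within 10 % of its reox-period maximum after 24 h OGD; ZO-1/Claudin5 below
0.9× baseline after OGD 6/R 24 with FGF co-treatment attenuating the loss
by at least 0.05.

## Design choices where the design was open

* **Apoptotic commitment** is carried by BAX: p53-driven induction plus a
  steep self-amplification term makes BAX bistable. Sustained p53 during
  long OGD (≥ ~12 h) latches BAX high and caspase-3 follows into a flat
  high plateau; short-OGD transients stay below threshold and reverse.
  This reproduces duration-dependent irreversibility without an explicit
  commitment timer.
* **Tight-junction persistence**: ZO-1/Claudin5 turn over on a timescale
  of days (basal rates ~10⁻⁴ h⁻¹), so burst damage is effectively permanent
  within a 30 h protocol; AKT protects by suppressing ROS-driven
  degradation rather than by resynthesis. Both choices keep the damage
  readout monotone in insult duration, as observed.
* **pAMPK second peak** emerges from delayed nitrosative inhibition of
  aerobic ATP regeneration: the ROS burst induces iNOS over hours, NO+ROS
  form ONOO⁻ peaking ~4–6 h post-reox, ONOO⁻ suppresses oxidative
  phosphorylation, the AMP/ATP ratio rises again and AMPK reactivates.
* **O₂ and glucose are clamped environment inputs** during phases (not
  consumed state variables); intracellular consumption acts on downstream
  fluxes only. This matches incubator-controlled experiments where media
  reservoirs are effectively infinite.
* Supplementary-level rate equations for the published model are not
  available in the main text; this network is an original reconstruction
  that satisfies the documented wiring and the qualitative dynamics gate,
  with baseline parameters derived by balancing. The published species/
  reaction counts are treated as descriptive metadata.

## Numerical choices and limitations

Tolerances: rtol 10⁻⁶/atol 10⁻⁹·scale for production runs; invariance
tests (phase splitting, SBML round trip) use rtol 10⁻⁹ so solver error
sits well below the asserted 10⁻⁶ agreement. Ties in target ranking break
lexicographically. Degenerate cases are defined explicitly: constant
outputs get PRCC 0 with p 1; rank-deficient correlation matrices fall back
to residual regression; zero-duration protocol phases are omitted.

Known limitations: no spatial/PDE transport, no multi-cell neurovascular
crosstalk, no stochastic simulation, no pharmacokinetics of actual drugs
(interventions are parameter multipliers), no mapping from the continuous
CF score to categorical cell fates, and single-condition identifiability
of synthesis rates is limited by fold-normalized data (see Calibration).
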