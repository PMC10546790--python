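# Methods

`lemnaflux` implements steady-state ¹³C metabolic flux analysis (¹³C-MFA)
for photomixotrophic duckweed (*Lemna gibba*) cultures grown on glucose
under two nitrogen regimes: inorganic nitrogen (INS, nitrate/ammonium) and
organic nitrogen (ONS, glutamine). This note records the models, the
numerical choices, and what the synthetic-data studies do and do not
demonstrate.

## Physiological rate equations

Exponential growth is summarized by the specific growth rate
µ = (ln A_t − ln A_0)/t from frond-area endpoints, with doubling time
ln 2/µ. Specific substrate uptake rates follow
v = (S₀ − S)/(D − D₀)·µ (amounts in µmol, dry weights in g, consumption
positive). The atmospheric CO₂ uptake rate is inferred from the
carbon-molar enrichment balance

    f_BM = (6 v_Glc e_Glc + 5 v_Gln e_nat + v_CO2 e_nat) /
           (6 v_Glc + 5 v_Gln + v_CO2)

solved for v_CO2; natural abundance e_nat is fixed at 0.011 and the
40:60 [U-¹³C₆]:unlabeled glucose medium has e_Glc = 0.403. The inferred
rate is the gross uptake of unlabeled atmospheric CO₂, not the net CO₂
balance. Uncertainty is propagated by Gaussian resampling of the inputs
(infeasible draws with f_BM ≤ e_nat are rejected and redrawn, preserving
the domain of the formula; composition fractions are instead truncated at
zero, preserving mass positivity).

Biomass sink fluxes are composition-derived: flux = (g/g fraction) ×
(mol monomer per g component) × µ × 10⁶, with cell wall counted as a glucan
of anhydroglucose residues (162.14 g/mol), lipid as triacylglycerol split
into a glycerol moiety and C₂ acyl units, and protein distributed over the
amino-acid sinks via a shipped generic plant-protein composition table
(a synthetic stand-in; real analyses should supply their own). The default
per-condition composition is back-derived from the published sink fluxes
and growth rates and is documented as a reconstruction, normalized to stay
below unit mass with the implied fluxes kept exact.

## Reference network

The shipped "lemna-core" network is a reduced (≈60 reaction) version of the
study's central-metabolism model, keeping every topological feature the
flux results depend on: glycolysis and the complete oxidative + regenerative
pentose-phosphate pathway duplicated in cytosol and plastid (duckweeds lack
the xylulose-5-phosphate translocator, so the cytosolic OPPP must cycle
locally); hexose-, triose-, PGA- and PEP-phosphate translocators (no
pentose-phosphate transport); the Calvin–Benson–Bassham cycle with RuBisCO
carboxylation and oxygenation (fixed 1000:1 by a ratio constraint —
photorespiration is suppressed under photomixotrophy) and a lumped
photorespiratory salvage; a mitochondrial TCA cycle with a merged OAA/Mal
pool and 50:50 fumarate-symmetry scrambling implemented as two parallel
atom-mapped reactions constrained to equal flux; reversible PEP
carboxylation (PEPC forward / PEPCK reverse); glutamine entry via
Gln ↔ Glu ↔ 2-oxoglutarate; and the 22 biomass sinks with standard
biosynthetic carbon origins (e.g. Val = 2 pyruvate − CO₂). Every reaction
conserves carbon-atom multisets; sinks route their carbon into explicit
external product pools (serine C3 lost in glycine synthesis goes to an
explicit one-carbon pool rather than CO₂). All fluxes carry ±3000
µmol·g⁻¹·h⁻¹ bounds — far above any physiological value — to keep the
futile-cycle directions of the flux polytope bounded.

Three CO₂-pool configurations: **A** has a single cellular CO₂ pool with
efflux only (no atmospheric uptake possible); **B** adds a separate
``CO2_RBC`` pool consumed by RuBisCO, with independent atmospheric uptake
and release plus a reversible mixing reaction with cellular CO₂; **C** is
topologically B but treats the measured glucose, glutamine and CO₂ uptake
rates as flux measurements. A single cellular CO₂ pool is shared across
compartments, and the TCA cycle is strictly mitochondrial; both are
deliberate lumpings.

The network text format is line-oriented TSV with ``Metab#abc`` atom maps
(one letter per carbon, educt-side letters assigned left-to-right, C1
first); fixed fluxes and ratio constraints live in header lines.

## Labeling simulation

Steady-state MIDs are computed by EMU decomposition: the minimal set of
elementary metabolite units reachable backward from the measured fragments
is compiled once, and each EMU size level is solved as one dense linear
system assembled from precomputed index arrays (≈300 EMUs and ~2 ms per
simulation for the full network and 27-fragment panel). Reversible
reactions enter as forward/backward pairs with fwd = max(net,0)+xch,
bwd = max(−net,0)+xch. Fluxes below 10⁻⁹ are clamped to 10⁻⁹ so that
zero-flux subnetworks stay numerically solvable; the clamp is far below
any influential magnitude.

A brute-force full-positional-isotopomer fixed-point solver (guarded to
≤2²⁰ states) serves as an independent oracle; EMU and oracle agree to
<10⁻⁸ on all shipped toy networks and on 20 random flux states of a
mid-size toy. The fixed-point sweep renormalizes each distribution every
iteration: condensation reactions make the iteration expansive in the
distribution-sum direction, and without the projection floating-point
drift grows exponentially.

## Measurement model and corrections

Substrate labeling is specified as mixtures of positional species with a
per-position purity (default glucose: 80:10:10 unlabeled/[1-¹³C]/[U-¹³C₆]
at 99% purity; its average enrichment computes to 12.5%). Measured
fragments carry the analyte's skeleton carbon subset plus the elemental
formula of the derivative side chains; natural isotopologue distributions
of C, H, N, O, S and Si are built from standard terrestrial abundances
(¹³C fixed at the conventional 1.1%).

Two corrections connect raw GC-MS fragment MIDs and skeleton MIDs:
nonnegative least-squares deconvolution of the derivative natural
distribution, and removal of the 3.3% unlabeled-inoculum biomass share
(applied after the derivative correction). Both are exact inverses of
their forward operations on clean data, and standard deviations are
propagated through the linearized deconvolution (the correction amplifies
raw noise by roughly 1.5–2×).

Fitting, however, compares simulations to the **raw** MIDs through the
forward measurement model (inoculum mixing then derivative convolution,
truncated to the recorded mass window of skeleton+3 masses): the inverse
corrections make corrected-scale errors correlated and slightly biased,
which would distort the chi-square goodness-of-fit statistic. The
corrections remain the tool for enrichment reporting and for users with
already-corrected data.

Because measured fractions are normalized, additive intensity noise of SD
σ becomes correlated and heteroscedastic on the fraction scale
(covariance σ²·J·Jᵀ with J = I − m·1ᵀ). Measurements that carry their
intensity-noise SD are therefore whitened per fragment onto the k−1
independent error coordinates (eigen-SDs floored like ordinary SDs),
which makes the SSR statistic exactly consistent with the
degrees-of-freedom rule (one group subtracted per fragment) and removes
the estimator bias that naive per-entry weighting causes. Measurements
without a noise model fall back to per-entry SD weighting.

## Flux estimation

Free fluxes parameterize the steady-state space as v = v₀ + N q with N a
null-space basis of the stoichiometric/ratio/fixed-flux constraint matrix;
any expanded vector satisfies the balances to ~10⁻⁹ relative and the ratio
constraints exactly. Exchange fluxes are optimized on the bounded
transform xch = s·t/(1−t), t ∈ [0, 0.95] with scale s = 100
µmol·g⁻¹·h⁻¹ (the raw 0–1 transform alone cannot reach the
several-hundred range the CO₂-pool mixing exchange requires).

The objective is the variance-weighted SSR over MID entries (SDs floored
at 1% on the fractional scale) plus measured net fluxes, minimized by
trust-region-reflective least squares with finite-difference gradients and
hinge penalties for the (rarely active) irreversibility bounds. Restarts
draw free-flux start points as Gaussian perturbations (several magnitude
scales) around a minimum-norm feasible center, with xch01 uniform on
[0, 0.9]; LP-vertex starts were rejected because polytope vertices are
extreme flux patterns from which the labeling landscape is flat. The
best-of-restarts solution is kept with a full restart log; runs are
deterministic given a seed. Degrees of freedom follow the counting rule
"MID measurements − measurement groups + flux measurements − free net and
exchange fluxes" (one group per fragment; no per-group scale factors are
fitted), and a fit is accepted when SSR does not exceed the 90% chi-square
quantile (boundary inclusive).

Alternative optima are explored by parameter continuation: a flux (or
linear combination) is pinned across a grid by adding one linear
constraint to the basis, each point warm-started from the best fit; the
reported interval is where SSR stays within the 1-dof 90% quantile of the
optimum.

## Monte-Carlo uncertainty and aggregation

Flux uncertainty comes from refitting noise-corrupted replicates
(Gaussian noise at the floored SDs, clipped and renormalized for MIDs)
with multi-start optimization; each replicate includes the base best fit
as a warm start, and replicates may stop early once they pass the
chi-square threshold. Sample statistics (n−1 SDs) over replicate best
fits give per-flux uncertainties. Because the cytosol/plastid split of
glycolysis and the OPPP is poorly resolved by proteinogenic labeling
data, results are reported on the aggregated (uncompartmentalized) view:
reactions identical after merging compartments are summed, transporters
between merged pools become zero rows, and the same linear map applied to
every ensemble member yields the combined-flux SDs — strongly
anticorrelated splits therefore aggregate to tight combined estimates.
Flux ratios (e.g. OPPP decarboxylation over RuBisCO carboxylation) and
the atmospheric fraction of the RuBisCO CO₂ pool
(atmospheric influx / (atmospheric influx + forward mixing inflow), on
the forward-flux formulation) are computed per member and summarized the
same way.

## Synthetic study design

The generator reproduces the study conditions: measured uptake rates and
the 22 published sink fluxes fixed exactly; remaining free net fluxes
solved against regime anchors (combined OPPP flux of 128.1 (INS) / 141.4
(ONS) µmol·g⁻¹·h⁻¹, equal cytosol/plastid OPPP split, OPPP/RuBisCO ratio
0.60, atmospheric CO₂-pool fraction 0.58/0.60, measured atmospheric
influx) with a small ridge on undetermined splits; PEPC direction
(forward under INS, reverse under ONS) emerges from the fixed sink
demands and is asserted, not forced — its magnitude is set by the OAA/Mal
balance. Exchange fluxes are seeded draws (2–25) except the CO₂ mixing
exchange, which realizes the atmospheric-fraction anchor exactly. The
measurement panel is 27 fragments from 16 analytes (amino acids as TBDMS
fragments, starch/cell-wall/sucrose hexoses, glycerol, the fatty-acid
C1–C2 unit) — a documented stand-in with the study's counts, since the
exact published fragment list is not enumerable from the text. Noise is
Gaussian (SD 0.01, the floor value), clipped at zero and renormalized;
this clips small mass bins and hence biases dominant fractions down by up
to ~0.8 SD — a deliberate emulation of nonnegative measured fractions,
bounded by test.

What passing these studies shows: the simulator is exact against an
independent oracle; the estimator recovers a known truth of realistic
magnitude and geometry from noise-free data, and its Monte-Carlo
uncertainty covers the truth at the published operating point from noisy
data; the configuration contrast (no atmospheric uptake vs. a separate
RuBisCO CO₂ pool) is detected by the chi-square rule. What it does not
show: anything about real instrument artifacts (retention, overlapping
fragments, drift), about the adequacy of the reduced network for real
*L. gibba* data, or about the exact published flux values, whose raw
measurements are not available.

## Known limitations and problem sizes

* The atmospheric share of the RuBisCO CO₂ pool is weakly identified by
  the default fragment panel: near-equivalent flux states exist in which
  the plastidic pentose-phosphate exchanges run to isotopic equilibrium
  and the CO₂-pool mixing vanishes (atmospheric fraction → 1), changing
  the SSR by only ~10 units across the whole 0.58–1.0 range at 1%
  noise. Single-dataset estimates of the fraction therefore scatter
  widely and sit against the upper boundary for unlucky noise draws, and
  Monte-Carlo ensembles — which condition on one dataset — understate
  that scatter; the correlated drift also pulls the combined OPPP flux
  low. Noise-free fits recover the generating fraction exactly, so this
  is an information limit of the panel at this noise level, not a model
  defect. Interpreting this quantity on real data requires either richer
  positional measurements or profile-based (not ensemble-SD) intervals.
* The 90% chi-square acceptance rate calibrates to roughly 85% rather
  than 90% on repeated synthetic datasets: the renormalization of
  measured fractions makes a small part of the residual variance
  unabsorbable under the prescribed group-counting rule.
* Fits and Monte-Carlo runs in the tests and the acceptance script are
  scaled down (10–14 restarts per fit, 10 replicates × 20 restarts for
  Monte-Carlo, 2000-iteration cap mapped to 400 optimizer iterations);
  these sizes recover the anchors and are the package's default desk
  scale. Library defaults keep the study-scale values (100 restarts,
  2000 iterations, 20 replicates × 50 restarts).
* Linearized covariance-matrix confidence intervals are not implemented;
  only Monte-Carlo and parameter continuation are.
* Isotopically nonstationary labeling (¹³CO₂ pulse designs) is out of
  scope; the simulator is strictly steady-state.
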