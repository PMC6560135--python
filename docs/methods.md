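# Methods

This note documents the models, numerical choices, defaults and known
limitations of the package. All empirical statements below are computed
by the test suite or the analysis scripts.

## Growth and rate estimation

The growth model is deterministic exponential growth at constant rate,
`dB/dt = μB`, with the coupled substrate model `dG/dt = −r_glc·B` and
product model `dC/dt = +r_sec·B`. Fits use nonlinear least squares on
the untransformed closed forms (`scipy.optimize`), not log-linear
regression, so that the OD and glucose series can share μ and B0 in one
objective; the log-linear slope and the endpoint concentrations provide
initial guesses, which are exact on noiseless data.

* **Fitting window.** Points with 0 < OD < 1 (configurable
  `od_ceiling`), and, for cultures that received an addition,
  t ≥ addition time. Growth rates are determined from optical densities
  below 1 because the instrument and the constant-μ assumption both
  degrade above it.
* **Exponentiality check.** R² of ln OD vs t must exceed 0.98
  (configurable); failures raise a warning and set a flag on the fit but
  are not fatal. At the default OD noise (0.005 OD600) the check
  occasionally flags genuinely exponential curves because the relative
  noise at OD ≈ 0.02 is large; that is intentional — the flag marks fits
  a careful experimenter would inspect.
* **Joint fit weighting.** The OD and concentration series live on
  different scales (OD600 vs mM), so the joint objective reweights the
  two residual blocks by per-series noise estimates, iterated twice;
  noise variances are estimated with a degrees-of-freedom correction
  (two of the four shared parameters charged to each series). Parameter
  covariances come from the weighted Jacobian; the resulting ±2 SE
  intervals cover the generative parameters at ≈ 93–95% in the recovery
  study (200 experiments × 4 replicates), the expected small-sample
  coverage of a 2-SE interval at ~11 residual degrees of freedom.
* **Secretion fits.** μ and B0 are held fixed at the growth-fit values
  and only C0 and the rate are estimated — the model is then linear in
  its parameters and solved exactly by least squares. Whether B0 should
  be re-estimated for product fits is genuinely open; holding it fixed
  keeps all rates tied to one biomass trajectory.
* **Aggregation.** Replicates are reported as mean ± 2 SEM. Note the
  exact coverage of a ±2 SEM interval with n = 4 replicates is
  P(|t₃| < 2) = 86.1%, not 95%; the 95% figure applies asymptotically
  (or to the per-fit ±2 SE intervals above). The recovery study reports
  both coverages.
* **Units.** Rates in mM OD600⁻¹ h⁻¹ convert to specific fluxes
  (mmol gDW⁻¹ h⁻¹) by dividing by the biomass factor, default
  0.47 gDW L⁻¹ per OD600 (a standard *E. coli* value; configurable —
  the choice cancels in any within-study comparison).

## Inhibition statistics

`i = (μ_control − μ_acetate)/μ_control`. Values outside [0, 1]
(stimulated or negative growth) are allowed but flagged.

The bootstrap equality test resamples each of the four replicate sets
(two strains × control/acetate) with replacement, n_boot = 10,000 by
default, computes an index per strain per resample from the resampled
means, and forms the index-difference distribution d\*. The p-value is
the upper-tail probability, under d\* recentred at zero, of exceeding
the observed difference in magnitude: p = P(d\* − mean(d\*) ≥ |d_obs|).
Because the null distribution is two-sided, a cutoff of 0.03 (0.005)
corresponds to an overall level of 0.06 (0.01), and significance calls
use those cutoffs. Percentile 95% intervals of the per-strain index
distributions are reported (percentile, not BCa — the simplest
convention, labelled as such). The resampling unit is the replicate
growth rate, not a residual.

**Known small-sample property (left as a red test deliberately).** The
non-studentized bootstrap is anti-conservative for small replicate
counts: the resampled-mean variance underestimates the sampling variance
by (n−1)/n, and the percentile threshold treats an estimated scale as
known. At n = 4 the rejection event at the 0.03 cutoff is
|d_obs| > 1.881·√(3/4)·ŝ ≈ 1.63·ŝ, a t-like statistic with ~12
effective degrees of freedom, giving a true level of ≈ 0.12 rather than
0.06. The calibration study measures 0.110 over 600 null simulations,
and `test_bootstrap_type_one_error_calibration` fails accordingly: the
test documents the property of the method at the study's replicate
count instead of papering over it. The level approaches the nominal
0.06 as replicates increase.

Welch's t test (via `scipy.stats.ttest_ind(equal_var=False)`) handles
growth-rate and yield comparisons; the test suite checks it against the
Welch–Satterthwaite formulas coded from first principles.

Dose–response curves are summarized by μ(c) = b + a·e^{−kc} with
b, a, k ≥ 0. The baseline b is the growth rate at saturating acetate;
at c = 0 the curve equals b + a. The estimator of b carries a small
negative bias (~0.01 h⁻¹ at noise SD 0.01) from the b↔k trade-off —
stated in the corresponding test.

## Assay quantification

One straight line per read phase (ordinary least squares), both
extrapolated to the enzyme-addition time; ΔA = A2 − A1 there. The
drift correction is exact for any linear drift (property-tested over
random slopes). Concentration = (ΔA_met/ΔA_std)·C_std·dilution, with
dilution = (V_culture + V_added)/V_culture, default 52/50 for a 2 ml
addition into 50 ml. Negative computed ΔA (read noise around zero) is
clamped to 0 mM with a warning — a physical floor. Both phases are
extrapolated; extrapolating only one would leave the other phase's
drift in ΔA. Reporter concentration is background-corrected
fluorescence divided by OD600, flagged when background exceeds signal.

## Constraint-based flux analysis

The model container stores N, bounds, subsystem labels, metabolite
formulas (carbon counts are parsed from them), the biomass and
maintenance reactions, and the medium set. SBML L3/FBC I/O goes through
cobrapy (subsystems persist via the groups extension); a documented
JSON dialect covers the same fields exactly. An acetate-anion transport
reaction can be appended for models that lack one.

Condition constraints, in order: non-medium uptake bounds zeroed; O₂
uptake capped (default 20 mmol gDW⁻¹ h⁻¹); unmeasured, non-medium
secretions closed (CO₂/water-type exchanges stay open); measured
exchanges bounded to mean ± 2 SEM; the acetate exchange left at model
defaults when excess acetate was supplied (its net flux is then not a
reliable measurement); the theoretical CO₂ exchange from the carbon
mass balance Σ uptake·C − Σ secretion·C − μ·(biomass carbon); the
non-growth maintenance flux fixed; user-supplied extra bounds last.
The carbon balance is skipped under excess acetate, where it cannot be
closed. The growth rate enters the L1 objective as a soft term by
default (with hard-fixing as an option) — the printed LP treats it like
any other measurement; for flux-space *sampling* the biomass flux is
instead bounded to the measured rate ± 2 SEM, since the sampled
distributions are conditioned on the measured growth rate.

Both LPs (L1-MFA with explicit u⁺/u⁻ slack variables, and FBA) are
solved with HiGHS via `scipy.optimize.linprog`. Defaults: feasibility
1e-9, optimality 1e-8. Alternate optima are expected (the chain example
has a whole interval of optimizers); one optimizer plus the unique
objective are returned, and flux uncertainty is delegated to sampling.
Tests check the objective against a grid-scan oracle, an independent
bound-splitting LP formulation, and cobrapy's optimizer (FBA).

## Flux-space sampling

`v = v0 + K·α` with v0 an interior point (max-slack LP) and K a null
space basis of N augmented with rows pinning fluxes whose bounds
coincide. Sampling is coordinate hit-and-run in a rounded coordinate
system: a pilot chain (100·d steps, two rounds) estimates the sample
covariance of α, whose Cholesky factor whitens the polytope — a
covariance-based stand-in for ellipsoidal rounding with the same
distributional contract. Defaults: 10,000 recorded draws, burn-in
1,000, thinning 10 (the published procedure states none; these are
conventions). Degenerate (zero-dimensional) polytopes return the point
mass. Every draw satisfies N·v = 0 within 1e-8 and bounds within 1e-9
(asserted in tests); on analytic polytopes (segment, simplex) the
sampled moments match the closed forms within Monte Carlo error.

Per-reaction modes use a Freedman–Diaconis histogram, ties broken
toward the bin nearest the median; zero-variance samples return the
constant. The cross-condition comparison selects reactions by
subsystem annotation (pentose phosphate pathway, anaplerotic reactions,
glycolysis/gluconeogenesis, pyruvate metabolism, citric acid cycle),
divides modes by the condition's growth rate, and reports squared
Pearson correlation. Modes of nearly flat marginals (e.g. a futile
cycle that is free over a wide interval) are weakly identified; the
embedded network therefore carries finite capacities on the acetate
branch (Pta-AckA 20, Acs 2 mmol gDW⁻¹ h⁻¹ — Acs is
catabolite-repressed during growth on glucose).

## Synthetic data

The generator emulates: exponential growth from OD 0.02 with
replicate-specific rates drawn at 3% CV (matching typical replicate
SEMs; the noise model itself is a convention, as no magnitudes are
published); glucose/product series from the closed forms; additive
Gaussian measurement noise (defaults 0.005 OD600, 0.15 mM — instrument-
scale conventions); concentrations floored at 0 mM; and the mid-culture
addition of acetate (or blank medium) as a step that dilutes OD and
concentrations by V/(V+ΔV) (50/52), raises acetate by the nominal
amount, and optionally switches the growth rate. Defaults: μ = 0.65
h⁻¹, G0 = 16.65 mM (3 g/L glucose), Y = 0.09 OD/mM, sampling every 30
min for 6 h — chosen so the OD < 1 window ends before glucose
exhaustion, where the constant-μ model itself would break. All draws
derive from a single seed; equal seeds give bit-identical output.

It does **not** emulate: lag or stationary phases, growth–substrate
feedback (growth continues in the closed form even if glucose runs out
— hence the grid default above), intracellular dynamics, pH/pO₂
trajectories, or non-Gaussian instrument error. Passing recovery tests
therefore demonstrate correctness of the estimators under the stated
model, not robustness to lag phases or model misspecification.

Toy networks: the embedded deterministic "mini-central-carbon" fixture
(14 reactions, 9 metabolites) sketches glucose uptake → glycolysis →
{pentose-phosphate, pyruvate, TCA-like oxidation, anaplerosis, acetate}
branches with a biomass sink (30 mmol C per gDW, flux on the scale of
μ in h⁻¹) and fixed maintenance; its hand-balanced reference flux uses
dyadic rationals so N·v = 0 holds exactly in floating point. Random
toy networks require n_reactions ≥ n_internal_metabolites + 2 (uptake,
chain, secretion and biomass must all fit) and carry a known feasible
reference flux on the backbone with zero-flux random extra conversions.

## Pipeline

One YAML config drives simulate → fit → rates → stats → dose → mfa →
sample; every stage writes its outputs to the run directory and
downstream stages read those files back, so any stage can be re-run
from disk. All seeds derive from the single top-level seed; the
report contains no timestamps, so identical (config, seed) give
byte-identical reports. Problem sizes in the shipped configuration
(four replicates, 10,000 bootstrap resamples, 2,000 sampler draws, the
embedded 14-reaction network) are sized for a single-CPU desk run; all
are configurable upward.

## Known limitations

* No loopless/thermodynamic constraints in the flux model; futile
  cycles are handled only by capacity bounds.
* The literature-derived extra reaction constraints used in
  genome-scale applications are supplied by the user (the
  `extra_constraints` mechanism), not shipped.
* No multiple-testing correction (none is applied in the underlying
  protocol); no BCa bootstrap intervals.
* The bootstrap equality test's small-sample anti-conservatism
  (see above) is a property of the method, reported rather than
  patched.
* No formal MCMC convergence diagnostics beyond moment stabilization
  on analytic polytopes.
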