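# Methods

## Scope and model

`chloroflux` analyses transient ¹³C-labelling experiments in photosynthetic
micro-organisms: a culture at metabolic steady state is switched at t = 0 to a
medium whose inorganic carbon (CO₂/HCO₃⁻) carries a known ¹³C enrichment *a*,
and mass-isotopomer distributions (MIDs) of central-metabolism intermediates
are sampled over seconds (Calvin–Benson cycle kinetics) to hours (end-product
synthesis).  The package covers the full path from raw MID tables to flux
estimates:

1. MID normalization and natural-abundance correction;
2. enrichment-kinetics analytics (slopes, reference regressions, clustering,
   classical MDS);
3. simple flux estimators (minimum assimilation, PEPC bound, end-product
   synthesis rates, starch turnover, protein synthesis, lipid index);
4. isotopically non-stationary metabolic flux analysis (INST-MFA) over an
   atom-transition network via elementary-metabolite-unit (EMU)
   decomposition.

Throughout, *metabolic* stationarity is assumed — pools `P` (µmol g⁻¹ DW) and
fluxes `v` (µmol g⁻¹ DW s⁻¹) are constant and every internal metabolite is
flux-balanced — while the *isotopic* state evolves.  Enrichment is stored as
a fraction in [0, 1] (Σᵢ i·mᵢ / n per n-carbon fragment) and converted to
percent only in reports.  The canonical flux unit is nmol C equivalents
g⁻¹ DW s⁻¹.

## Natural-abundance correction

The measured MID of a fragment is modelled as `measured = C · true`, where
column *j* of `C` is the binomial distribution of extra mass from the
`n − j` unlabelled carbons at natural ¹³C abundance (default p13 = 0.0107),
optionally convolved with extra-atom binomials for derivatized GC-MS
fragments (off by default; fragment compositions are instrument-specific).
The inverse problem is solved by non-negative least squares and renormalized,
which guarantees a valid MID on noisy input at the cost of a small positive
bias when true channel values sit at zero; downstream estimators that are
sensitive to this floor subtract the t = 0 blank.  With p13 = 0 the
correction is the identity; forward convolution followed by correction
recovers arbitrary MIDs on ≤ 8 carbons to 1e-9 (the matrix is
well-conditioned for p13 < 0.5).

## Atom-transition networks and simulation

Networks are written one reaction per line
(`name: A + B -> C + D | ab + c : cab, d`); lower-case letters track
individual carbons.  Three presets ship with the package: `minimal_chain`
(CO₂ → A → B → sink), `cbc_toy` (10 internal metabolites: carboxylation,
triose/pentose rearrangement with the transketolase/aldolase
cleavage–condensation steps, starch and sucrose export, lower glycolysis,
PEPC anaplerosis to malate) and `cbc_full` (22 metabolites, adding
photorespiration, explicit pentose phosphates and TCA-derived amino acids).
Preset fluxes are balanced exactly (residual < 1e-9) and sized so that the
gross carbon input (~315 nmol C g⁻¹ DW s⁻¹ for `cbc_toy` at 50% medium
enrichment) and pool turnover times (~1 s for RuBP to minutes for malate)
fall in the range reported for green microalgae.

Two simulation engines share one contract:

* **Exhaustive isotopomer integration** tracks all 2ⁿ positional isotopomers
  per metabolite — exponential in carbon count, tractable for the presets
  (≤ 7 carbons), and used purely as the reference oracle.
* **EMU simulation** decomposes the network backwards from the measured
  fragments into the minimal set of elementary metabolite units; each EMU's
  MID obeys `P dX/dt = Σ_r v_r (source_r − X)` with convolution sources when
  a product's atoms originate from several substrate molecules.  The engines
  agree to < 1e-6 on all presets.

The accurate path integrates with LSODA at rtol 1e-8 / atol 1e-10
(configurable).  Fitting uses a fixed-step RK4 kernel compiled with numba
(default dt = 0.1 s, automatically shortened to the fastest pool turnover for
stability); at dt = 0.1 the discretization error (~1e-6 in MID units) is
three orders of magnitude below the measurement noise it is fitted against.

Dilution — the fraction *d* of a measured pool that never labels
(compartmental or non-photosynthetic subpools) — is applied at measurement:
`measured = (1 − d)·simulated + d·unlabelled`, capping the enrichment plateau
at `(1 − d)·a`.

## Synthetic-data generator

The generator emulates the statistical structure the analysis assumes, with a
step input at t = 0 and 50% medium enrichment by default:

* near-linear 0–40 s enrichment rise in CBC intermediates and slow malate
  labelling (from the `cbc_toy` dynamics themselves);
* saturating long-course (15–300 min) curves in four kinetic families
  (plateaus 60/42/25/3% with time constants 10/45/160/500 min), plateauing
  below 100% as unlabelled subpools dilute the signal;
* starch ¹³C gain concurrent with ¹²C loss under continuous turnover;
* protein-bound amino-acid enrichment lagging the free pool,
  `dE_b/dt = (PSR/100 h⁻¹)(E_free − E_b)`;
* truncated-Gaussian MID noise (clip at 0, renormalize), seeded; natural
  abundance is convolved in *before* noise, since instrument noise acts on
  the observed channels.

Within the long-course families the curve-parameter jitter is small (1%
relative) compared with the independent per-point noise (sd 0.01), making the
planted clusters compact and near-spherical — the regime the gap statistic is
designed for.  Correlated within-family parameter variation instead produces
elongated clusters that k-means profitably splits, and the gap criterion then
selects more, finer clusters; that regime is a property of the data, not an
estimator failure, and is deliberately not the default.

What the generator does **not** emulate: chromatographic artefacts and
envelope overlap, pool-size drift over the labelling window (diel or
light-stress dynamics), compartment-specific transport beyond the dilution
parameter, and day-length-scale starch cycling.  Passing tests therefore
demonstrate correctness of the estimators under their stated model, not
robustness to instrument-level artefacts.

## Kinetics analytics

Replicate enrichments are averaged per time point before fitting (limits
outlier-replicate leverage).  Pulse slopes are OLS over 0–40 s including the
(0, 0) origin (label introduction is effectively lag-free).  Regression of a
metabolite on a reference (DHAP-like triose-phosphate trace) uses OLS *with*
intercept over the shared 5–40 s points, reporting slope and Pearson r.
Slope sets between species/conditions are compared by a two-sided paired
t-test; identical or constant-offset sets raise a degenerate-test signal
rather than returning an infinite statistic.

Clustering is k-means (Euclidean, on percent-enrichment trajectories, 100
restarts, fixed seed), with k chosen by the Tibshirani gap statistic against
a uniform per-feature reference (B = 100 bootstrap datasets; the reference
fits use 10 restarts — one decade fewer than the data fits — which leaves the
reference dispersion estimate unchanged on these problem sizes at a tenth of
the cost).  Selection rule: smallest k with gap(k) ≥ gap(k+1) − se(k+1).
Clusters are renumbered by descending enrichment at the earliest time point,
so cluster 1 is always the fastest-labelling family.  The ordination is
classical (Torgerson) MDS — double-centred squared Euclidean distances,
eigendecomposition, negative eigenvalues clipped — with the axis sign fixed
by making each axis's largest-magnitude loading positive; it is cross-checked
against principal-coordinates analysis from scikit-bio in the test suite.

## Flux estimators

* **Minimum assimilation**: for each early time point,
  `rate(t) = Σ_met E(t)·P·n_C / t`; the maximum over time points is divided
  by the medium enrichment.  A true lower bound on gross carbon input for
  noise-free data; on noisy data the 1/t weighting at 5 s amplifies
  pool-weighted enrichment errors, so replicate averaging and blank
  subtraction matter.
* **Minimum PEPC flux**: the same estimator restricted to malate and
  aspartate.
* **Product synthesis rates**: OLS slope of `E(t)·P` over 30–120 min
  (window configurable; galactose-like slow products may use 0–300 min),
  times the carbon ratio (12 for sucrose, 6 for hexoses), in
  nmol C g⁻¹ DW s⁻¹.
* **Starch turnover**: synthesis = content × (¹³C fractional slope) × 6;
  degradation = −content × (¹²C fractional slope) × 6;
  net ≡ synthesis − degradation, and
  %¹²C-from-starch = 100 × degradation / assimilation.
* **Protein flux**: (PSR/100)·protein content·0.43 (carbon mass fraction of
  protein), converted via 12 g mol⁻¹.  PSR itself is estimated from the
  slope of protein-bound enrichment divided by the precursor (free
  amino-acid) enrichment — the time-averaged free enrichment over the fit
  window by default, its final value optionally ("plateau" mode).  The
  estimator is a first-order approximation valid while bound enrichment
  remains small against the free pool; sampling windows of ~2 h at a few
  percent per hour keep the bias below 1%.
* **Lipid synthesis index**: lipid mass fraction × specific growth rate — a
  bulk index, not a flux.
* Uncertainties propagate by first-order (delta) rules; the ratio
  propagation is verified against Monte Carlo at cv < 0.2.

## INST-MFA

The fit minimizes `SSR = Σ ((measured − predicted)/sd)²` over the EMU forward
model.  Steady-state balance is built in by parameterizing fluxes through an
orthonormal null-space basis of the stoichiometric matrix (`v = Nθ`); pools
are fitted on a log scale within three decades of their reference values;
dilutions, when enabled, on [0, 1].  Net-flux non-negativity is enforced by
penalty residuals while the forward model sees negative trial fluxes clipped
at zero (the unclipped dynamics would be exponentially unstable).
Measurement errors follow the conservative rule: per metabolite and time
point, the maximum replicate standard deviation over all mass channels,
floored at 0.001.  Estimation restarts from 50 random initial vectors by
default (fluxes log-uniform within two decades of the network scale projected
onto the balance null space; pools jittered ±1.5 natural-log units), keeping
the best SSR; the trust-region reflective solver uses finite-difference
Jacobians.

**Identifiability.** Transient MIDs constrain only turnover ratios `v/P`:
scaling all fluxes and pools jointly leaves the labelling dynamics unchanged.
Absolute scale therefore comes from data — independently measured synthesis
rates (starch, sucrose) and measured pool sizes enter the SSR as additional
residual terms (rates as Gaussian, pools as lognormal errors).  Pools remain
fitted parameters throughout; without any anchor the engine still runs but
reports the flat directions it detects from the Jacobian's singular spectrum.

**Inference.** Every fit carries linearized (Wald) 95% intervals from the
Gauss–Newton covariance, mapped to reaction space through the null-space
basis.  Profile-likelihood intervals re-optimize all remaining parameters
while one reaction flux is stepped until the SSR exceeds
`SSR_min + χ²₀.₉₅(1)`, with geometric expansion plus bisection to 1e-3 of the
flux scale; profiles that stay below the threshold to the search limit are
flagged unbounded (structural non-identifiability).  The χ² verdict is
two-sided at α = 0.05 — an SSR below the lower quantile (overstated errors or
overfitting) is rejected just like a gross misfit.  Degrees of freedom are
counted as residuals minus free parameters, with all mass channels included;
since each MID's channels sum to one, this overstates the effective residual
count slightly, which is conservative in combination with the max-channel
error rule.

**Recovery performance** (the problem sizes the test suite runs): on
`cbc_toy` with 4 time points (5/10/20/40 s), 3 replicates at MID noise
sd 0.005, rate anchors at 5% and pool measurements at 10%, 20 seeded trials
at 6 restarts give ≥ 90% per-flux CI coverage; the misses concentrate in the
weakly identified common cycle-scale direction, where Wald intervals are
known to undercover slightly.  Six restarts reach the same optima as larger
restart counts on this landscape; the default of 50 is kept for user-facing
fits.

## Numerical choices and degenerate inputs

* ODE tolerances: rtol 1e-8 / atol 1e-10 (accurate path); RK4 dt 0.1 s
  capped at one fastest-turnover time (fitting path).
* NNLS for MID correction; ill-conditioned correction matrices
  (cond > 1e12) raise instead of returning noise.
* All-zero intensity vectors raise an empty-measurement error; zero-variance
  references, zero free-pool enrichment and zero assimilation raise explicit
  errors rather than returning infinities.
* Every stochastic operation takes an explicit seed; k-means ties are broken
  by the best-inertia restart under that seed; identical runs are
  byte-identical.
* Starch trajectories truncate at zero with a depletion signal rather than
  going negative.

## Known limitations

* The INST-MFA engine targets desk-scale networks (tens of metabolites); it
  uses finite-difference Jacobians and makes no attempt at the full feature
  set of dedicated tools (no parallel tempering, no gradient-free global
  search, no metabolic-steady-state ¹³C MFA mode).
* Wald CIs mildly undercover along weakly identified directions; profile
  intervals are available but cost one re-optimization per probe.
* The minimum-flux estimators are bounds only in expectation on noisy data.
* 3PGA-type subcompartmentation artefacts (a metabolite reading consistently
  low against its network neighbours) are left uncorrected; no adjustment is
  applied beyond the optional dilution parameter.
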