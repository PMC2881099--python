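# Methods

## The problem

Mortality atlases for small areas (here: municipalities) face two linked
difficulties.  Counts per area, year, gender and age group are tiny — often
zero — so crude rates are wildly unstable; and aggregating years or ages to
stabilize them destroys exactly the dynamic, stratum-specific picture that
health planning needs.  The standard remedy is hierarchical Bayesian
smoothing in the Besag–York–Mollié tradition: borrow strength across
neighboring areas through a spatially structured prior, across all areas
through an exchangeable one, and across years through an explicit trend
model, fitting each gender × age-group stratum separately.

## Models

For stratum *i*, municipality *m* and year *t*, observed deaths are

    O_imt ~ Poisson(mu_imt)

with two variants distinguished only by the offset:

* **rate model**: `mu = p_imt · exp(eta)`, so `exp(eta)` is the specific
  mortality rate (per person-year);
* **rate-ratio model**: `mu = (p_imt · R_it) · exp(eta)`, so `exp(eta)` is
  the ratio of the area's rate to the national reference rate `R_it`
  (the offset is the expected number of deaths).

The second variant exists because smoothing the rate ratio directly is not
the same as dividing a smoothed rate by the reference rate; the package's
test suite demonstrates the inequality on a two-area panel.

The shared linear predictor on the log scale is

    eta_mt = β0 + β1·t' + β2·t'² + S_m + H_m + δ_m·t'

with `t' = (year − center)/scale`, by default centered mid-period and scaled
to the half-range so `t' ∈ [−1, 1]`.  A quadratic captures most mortality
trends; higher degrees exist for DIC comparison.  Components:

* `S` — spatially structured effects with an intrinsic CAR (ICAR) prior:
  log density `((n − c)/2)·log τ_S − (τ_S/2)·Σ_{i~j}(S_i − S_j)²`, where
  `c` is the number of connected components of the adjacency graph (the
  Laplacian's rank deficiency);
* `H` — exchangeable heterogeneity, `H_m ~ N(0, 1/τ_H)`;
* `δ` — municipality-specific differential time trends.  By default δ is
  itself ICAR-structured (neighboring municipalities have similar trend
  deviations); an exchangeable alternative sits behind
  `ModelSpec(delta_structure="iid")`.  δ multiplies only the linear term:
  curvature is global, so each area's trend is a monotone deviation that
  can be classified by direction.

Priors: improper flat on β0; `N(0, V_β)` with `V_β = 1e5` on the remaining
coefficients (a vague prior; the precision-parameterized convention
`N(0, 0.00001)` read as a variance would be absurdly informative);
`Gamma(0.5, 0.0005)` on each precision — a common vague disease-mapping
choice — configurable per precision.

Missing cells (see Cleaning) are skipped in the likelihood, never imputed.

## Identifiability and centering

The ICAR prior is flat along the constant direction of each graph
component, which collides with the flat intercept.  After every sweep the
sampler subtracts the mean of `S` (per component) and folds it into β0, and
likewise the mean of δ into β1.  For a connected map this leaves the linear
predictor bit-for-bit unchanged; for multi-component graphs the
per-component means are still forced to zero, β0 absorbs only their common
part, and η/μ are recomputed — a constraint enforcement rather than an
exact reparameterization.  Isolated areas contribute nothing to the CAR
quadratic form and are pinned to zero by their own component's centering.

## Sampler

A bespoke Metropolis-within-Gibbs engine (`stmort.mcmc`):

* **Coefficients**: scalar random-walk Metropolis with sufficient column
  statistics (a β-step costs O(T), not O(M·T)).
* **Fields**: single-site random-walk Metropolis, vectorized over
  graph-coloring classes.  Within one class (an independent set) the full
  conditionals are mutually independent given the rest of the state — the
  CAR prior couples only neighbors, the likelihood only an area's own
  cells — so the simultaneous block is exactly a sequence of single-site
  updates.  `H` needs no coloring at all.
* **Precisions**: conjugate Gibbs draws,
  `τ ~ Gamma(a + (n−c)/2, b + q/2)` for CAR fields (`q` the pairwise
  quadratic) and `Gamma(a + n/2, b + Σφ²/2)` for exchangeable ones.
* **S/H decomposition moves.**  The likelihood sees only `S + H`, so the
  split between the structured and unstructured fields is a notoriously
  slowly-mixing direction.  Two likelihood-invariant moves fix this:
  an exact Gibbs *interchange* `(S_m + c, H_m − c)` whose full conditional
  is Gaussian (applied per coloring class), and a global Metropolis
  *rescale* `H' = rH, S' = S + (1 − r)H` with log-symmetric proposals and
  Jacobian `r^M`, which crosses the variance-decomposition funnel in one
  step.  Two rounds of these moves are interleaved with the precision
  Gibbs updates per sweep; without them the precision chains show
  excursions of thousands of iterations into a collapsed-H mode.
* **Adaptation**: proposal scales adapt multiplicatively toward a 20–50%
  acceptance band during burn-in only and are frozen afterwards, so the
  stationary law of the recorded draws is untouched.
* **Initialization**: β0 at the log pooled crude rate (or pooled SMR),
  other coefficients zero, fields drawn `N(0, 0.1²)`, precisions at their
  prior means; additional chains get a fixed +0.2·chain offset on β0 so the
  starting points are overdispersed.  A non-finite initial posterior
  triggers retries with halved dispersion, then a hard error.
* **Sweep order** (fixed): β's → S → H → split moves → δ → precisions
  (interleaved with split moves) → centering → record.  Deviance
  `D = −2 log L` (with the Stirling constant) is recorded each kept
  iteration after centering.  η and μ are maintained incrementally and
  recomputed exactly every 200 sweeps to bound floating-point drift.

Defaults: 2 chains, 1000 burn-in, 10,000 retained draws, thinning 1.
Chains are bitwise-reproducible from their seeds.

## Diagnostics and model choice

* **Brooks–Gelman PSRF**: `R̂_c = sqrt(((n−1)/n + (m+1)/(m·n)·B/W) ·
  df/(df−2))` with the moment-matched degrees of freedom of the
  t-approximation; the uncorrected value is reported alongside.  Constant
  chains report 1 with a warning; 1.1 is the logged alarm threshold, never
  a hard failure.  Precisions are monitored on the log scale: their
  posteriors are heavy-tailed and the variance-based statistic (and
  especially its df correction) is unstable on the raw scale.
* **DIC**: `Dbar + pD` with `pD = Dbar − Dhat`, `Dhat` evaluated at the
  posterior mean of all parameters on the identified (centered) scale.
  When comparing time-trend degrees the package sums DIC over the
  per-stratum fits: a single superfluous coefficient changes DIC by
  roughly `+1` in expectation but with a chi-square(1) fluctuation that
  exceeds the penalty about 16% of the time, so a one-stratum comparison
  is close to a coin flip while the twelve-stratum total is reliable.

## Decision rules

* **Excess mortality** (rate-ratio fit): per area and year, the exceedance
  probability `P(RR > 1)` (fraction of draws strictly above 1) is banded at
  0.05/0.20/0.80/0.95: `>0.95` significant excess; `(0.80, 0.95]` at risk;
  `[0.20, 0.80]` similar to reference; `[0.05, 0.20)` low risk; `<0.05`
  significantly low.  Prose statements of such rules are ambiguous about
  strictness at the boundaries; the conventions above are centralized in
  `classify_excess` and asserted exactly by tests.
* **Trend** (rate fit): per area, the posterior of the average log-rate
  slope over the window — on a symmetric centered grid this is `β1 + δ_m`;
  the implementation averages the exact derivative over the year grid so
  asymmetric panels are handled too.  An area is increasing (decreasing)
  when the posterior probability of a positive (negative) slope reaches
  0.95, else non-significant.  The 0.95 level is configurable.
* **Quartile maps**: linear-interpolation quartiles; bins are half-open
  `[Q_{k−1}, Q_k)` with bin 4 closed above, so a constant map lands in bin
  4 and is flagged degenerate.  The interquartile range accompanies every
  map.  Rates are reported per 10,000 inhabitants (per 1,000 for the
  under-1 group); everything upstream of `postprocess` is per person.

## Synthetic data

`stmort.synthetic_data` emulates the registry this kind of analysis runs
on, with known ground truth:

* a 22×35 rook lattice by default (770 areas, the size of the motivating
  region) or any supplied graph;
* years 1981–2006; strata = 2 genders × 7 age groups (under-1 through 85+);
* log-uniform municipal populations (default 50–20,000 per stratum),
  reproducing the heavy small-area size heterogeneity of real panels;
* reference rates declining geometrically per stratum at realistic Spanish
  orders of magnitude (e.g. 65–74 males near 250/10,000 falling ~1.5%/yr;
  infant mortality falling ~5%/yr), with male/female multipliers giving a
  rate ratio near 2 at older ages;
* default coefficients aligned with the reference law so the true rate
  ratio is centered on 1; CAR-sampled `S` (via the Laplacian
  eigendecomposition, exact per-component sum-to-zero), normal `H`,
  CAR-sampled `δ`;
* registry errors: a configurable fraction of cells has its *population*
  replaced by an integer strictly below its deaths — the anomaly is a
  denominator failure, so death counts stay model-consistent.  Default
  per-cell fractions are calibrated so the per-area prevalence over 26
  years matches the reported registry anomaly (≈19.3% of areas for 85+
  males, 6.4% for 85+ females, ≈1.7% and below elsewhere).

What the generator does **not** emulate: unregistered migration flows,
census revisions correlated in time, age-heaping, or covariate-driven risk
gradients.  Passing tests therefore certify the statistical machinery —
not that any real registry satisfies the model.

### Validation scenarios

* **Parameter recovery** (`reference_recovery_scenario`): 10×10 lattice,
  15 years, one 75–84-like stratum (baseline rate `exp(−2.8)`),
  populations log-uniform 4,000–12,000.  The scenario is deliberately
  information-rich (3,000–11,000 deaths per area over the window): it is a
  validation of the machinery, sized so the posterior slope uncertainty per
  area (~0.02 after spatial pooling) gives the trend rule its designed
  power at ±0.05 slopes while hierarchical shrinkage keeps the
  false-direction rate on null areas low.  δ is a designed three-level
  field (+0.05 in one 4×4 corner block, −0.05 in the opposite block, 0
  elsewhere) rather than a CAR draw, so "strong-slope" and "null" areas
  are exactly known; the reference value for τ_δ is the precision the
  realized field implies, `(n − c)/q(δ)`.  τ_S = 10 and τ_H = 16 keep both
  field scales (marginal sd ≈ 0.2–0.3) well above the per-area measurement
  error so the variance decomposition is genuinely identified.
  Recovery point estimates for precisions are posterior medians (the
  posteriors are strongly right-skewed).
* **Decision-rule calibration** (`calibration_scenario`): 8×8 lattice, 10
  years, expected deaths ≥ 20–45 per area-year; all fields pinned to zero
  (true RR ≡ 1) or a 4×4 block at `S = log 1.5` (true RR = 1.5).
* **Model choice** (`dic_study_scenario`): 12 strata on a 4×5 map from a
  purely quadratic trend, fitted with trend-only models of degree 2 and 3.

## Numerical choices

* Masked cells are implemented by zeroing both O and the offset, so all
  masked sums are plain sums and a missing cell contributes exactly 0.
* `μ = 0` with `O > 0` on an observed cell yields a log posterior of −∞
  (a validly rejected state); NaN/overflow raises `NumericalError` — the
  two are never conflated.
* Quartiles and five-number summaries use NumPy's linear-interpolation
  percentiles.
* CAR field simulation truncates Laplacian eigenvalues at `1e−9·λ_max` to
  identify the null space.
* Ties in `classify_trend` (draws exactly 0) count toward neither
  direction.

## Known limitations

* The variance split between S and H remains weakly identified when
  per-area counts are small; the posterior then defers to the gamma
  hyperpriors and precision estimates can be off by large factors even
  though S + H (and every downstream map) is well estimated.
* Single-site Metropolis mixes slowly for very large maps; the engine is
  comfortable at the hundreds-of-areas scale this analysis targets, not at
  tens of thousands.
* DIC is reported because it is the conventional criterion in this
  literature; its known optimism for hierarchical models is not corrected.
* The CLI stores posterior fields in compressed NumPy archives next to the
  CSV outputs; these are runtime artifacts, not exchange formats.
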