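# Methods

This note documents the models implemented in `reefguest`, the defaults and
the reasoning behind them, what the synthetic generator does and does not
emulate, and the numerical choices that matter for reproducibility.

## Input model

The raw input is a literature edge list: one row per record of a guest
species found inhabiting a host sponge, with the marine ecoregion (MEOW
name), the record's coordinates (WGS84 decimal degrees) and a bibliographic
reference.  Rows failing validation (out-of-range coordinates, empty names)
are collected and reported together, never silently dropped.  Host names
are kept only when identified to species level: the filter accepts binomials
of the form `Genus species`, optionally with a parenthesised subgenus
(`Callyspongia (Cladochalina) aculeata`), and rejects open nomenclature
(`Ircinia sp.`/`spp.`) and single-token names.  This regex filter
deliberately avoids any taxonomic name service; synonymy resolution is the
caller's responsibility.

Records collapse to a binary hosts × guests incidence matrix **A** — a link
is present iff at least one record reports the pair, because the underlying
literature mixes incompatible sampling effort, so link frequency carries no
comparable signal.  Hosts and guests are ordered lexicographically so every
seeded downstream algorithm sees a deterministic layout.  A "location" in
dataset summaries is a coordinate pair rounded to 3 decimal places
(~100 m); the precision is configurable since the literature never defines
a location operationally.

## Network-level structure

**Nestedness** is NODF: for every unordered pair of rows (and of columns),
the paired overlap 100·|N_i ∩ N_j| / k_min contributes when the two
marginal totals differ and zero when they are equal (the decreasing-fill
clause); the score averages the full set of row pairs and column pairs
together.  A perfectly nested staircase with distinct marginals scores 100;
a saturated matrix scores 0.

**Modularity** is Barber's bipartite Q = (1/m) Σ_ij (A_ij − k_i d_j/m)
δ(g_i, g_j), maximised by simulated annealing over single-species module
reassignments: Metropolis acceptance exp(ΔQ/T), geometric cooling over the
step budget, a configurable number of restarts, and a final greedy
hill-climb so the reported partition is a local maximum under single-node
moves.  Q is tracked incrementally through per-module link counts and
degree sums, which makes each move O(degree).  The default budget of 10⁵
steps saturates matrices with a few hundred species; it is a flag
(`--steps`) everywhere.  A single-module partition has Q = 0 exactly (the
configuration-model identity), which the test-suite uses as an anchor.

**Null model.** The default ensemble conserves the matrix dimensions and
the number of links (ones placed uniformly at random), i.e. connectance is
fixed while marginals are free.  A curveball-trade model that conserves
every row and column total exactly is provided for sensitivity analysis.
Significance is the one-sided upper tail with the (r+1)/(n+1) continuity
correction, so p is never zero and its floor is 1/(n_null+1).  For
modularity, every null matrix is optimised with the same step budget as the
observed one; anything else would bias the comparison.  When the null
distribution has zero spread the z-score is reported as NaN while p is
still defined.

## Species-level descriptors

Seven complementary descriptors per host sponge, all computed on the full
bipartite graph over hosts ∪ guests (a one-mode projection is available
behind a `projection` switch, but the definitions used speak of paths
between any two species, which the full graph preserves):

- **degree** — row sum of **A**;
- **betweenness** — Brandes shortest-path betweenness, Freeman-normalised
  over (n−1)(n−2)/2 pairs including unreachable ones;
- **closeness** — (reachable − 1)/Σ geodesic distances within the species'
  connected component, 0 for isolated vertices;
- **Katz** — row sums of Σ_{t≥1} α^t A_full^t, evaluated in closed form as
  (I − αA_full)^{−1}·1 − 1.  α must be below 1/λ_max; the default
  0.9·(1/λ_max) keeps the walk series convergent while weighting long
  indirect paths as strongly as possible.  The closed form is checked
  against a truncated power series in the tests;
- **among-module connectivity c** — the participation coefficient
  1 − Σ_s (k_is/k_i)², evenness of a species' links across modules;
- **within-module degree z** — the species' link count into its own module,
  standardised against the members of that module (0 when the module's
  within-degrees have zero spread);
- **nestedness contribution cn** — the focal species' row is replaced
  n_rand times by a random row of equal degree, partners drawn without
  replacement with probability ∝ (row-fill + column-fill)/2 of the original
  matrix (the probabilistic-null cell weights); cn is the z-score of the
  observed NODF against that randomised distribution, 0 when the sd is 0
  (e.g. a saturated row admits only one arrangement).  Default n_rand is
  1,000; it is the pipeline's single heaviest knob and is exposed as
  `--cni-n-rand`.

Guests receive descriptor values internally, but only host rows are
exported: importance is scored for the sponges.

## The importance index

The seven descriptors are collapsed by classical metric scaling (principal
coordinate ordination): squared Euclidean distances between descriptor
rows, Gower double-centering, eigendecomposition; axis scores are
eigenvector·√eigenvalue and the variance share of an axis is its
eigenvalue over the sum of positive eigenvalues.  On Euclidean distances
this is exactly a centered principal-component analysis, which the tests
exploit as an independent oracle.  Negative eigenvalues cannot arise from
Euclidean input, so one beyond tolerance triggers a contract assertion
rather than a silent correction.

Columns are **not** z-scored before the distance computation by default.
The index is meant to be dominated by a single axis (the generalist–
specialist gradient), and that dominance comes from the descriptors'
natural scales, where degree and Katz — the count-like descriptors — carry
the spread; on study-scale synthetic tables the unstandardized ordination
concentrates ~95% of the variance on axis 1 versus ~60% standardized.  The
z-scored variant remains one flag away (`standardize`), and a constant
column under standardization is dropped with a warning rather than
producing 0/0.

Axis 1 is sign-oriented so its correlation with degree is positive, the
scores are shifted to start at zero, and the square root is taken:
importance = √(PCO1 − min PCO1).  The transform is monotone, so rankings
are preserved; the minimum-scoring host has importance exactly 0.

## Accumulated geographic area

Around every occurrence record a circular buffer of 10 m² (radius
√(10/π) ≈ 1.784 m) is intersected with the reef polygons and the
reef-covered areas are accumulated per species, reported in km².  Buffers
are built in a per-record spherical Lambert azimuthal equal-area projection
(authalic radius 6 371 007.181 m): at metre scale, degree-space buffers are
numerically degenerate while the local equal-area frame is exact to well
below 0.1% (the tests check translation invariance and a Monte-Carlo area
oracle).  The circle is approximated with 256 segments, which biases the
area low by ~1 part in 10⁴.

Overlapping buffers are **summed**, not unioned, by default — each record
contributes its own area to the accumulated total — with a `union_overlaps`
flag that unions a species' reef-cropped buffers first (in the frame of the
species' first record) so exact duplicates count once.  At 10 m² per record
the two modes differ appreciably only for coincident records.  Invalid
reef polygons are repaired by zero-width buffering at load; unrecoverable
geometries are skipped loudly.  No GBIF or reef-atlas retrieval is
performed; occurrences and reef polygons are inputs.

## Trait models

**GLM.**  Importance is regressed on accumulated area with a log-link
Poisson-family GLM fitted by IRLS (statsmodels backend, convergence at
deviance change < 1e-8).  The response is continuous and non-negative, so
this is a quasi-likelihood fit: the estimating equations never require an
integer response, and the point estimates coincide with the Poisson MLE for
integer data — the tests verify the fit against a direct numerical
maximisation of the Poisson log-likelihood.  Coefficients, Fisher standard
errors, z = coefficient/se, and residual/null deviance are reported; the
all-zero response (log-mean unbounded below) is a hard error.

**ANOVA.**  One-way fixed-effects ANOVA of importance across morphology
classes and across taxonomic orders; F and p come from the standard
sums-of-squares decomposition, with group means reported alongside both
the standard error of the mean (default, matching the "mean ± s.e."
reporting convention) and the SD, since the two are easy to confuse in
published tables.  Degrees of freedom are always reported from the data.
All-identical values yield F = 0, p = 1; zero within-group variance with
singleton groups is a guarded error.

**Publication-effort screen.**  Publication counts per ecoregion are
treated as a meta-analysis of proportions against the dataset total:
logit-transformed proportions with large-sample variances (0.5 continuity
correction for empty regions), inverse-variance random-effects pooling with
a maximum-likelihood between-region variance τ², Cochran's Q heterogeneity
test, and the Thompson–Sharp small-study test — a weighted regression of
the effect on its standard error with multiplicative overdispersion,
reporting the slope's t-test.  The implementation is validated against
closed-form weighted-least-squares normal equations.

## Synthetic data generator

The generator emulates the statistical features the pipeline must detect:

- **planted nested + modular structure** — exactly
  round(connectance·R·C) cells are drawn without replacement with weight
  (u_i·v_j)^s inside planted blocks, where u, v are linear rank decays
  1 − (i−1)/n and s is `nestedness_strength`; hosts and guests are assigned
  to blocks round-robin and a `module_mixing` fraction of realised links is
  rewired to uniformly random cells.  Defaults are study-scale: 76 hosts ×
  268 guests, connectance 745/(76·268) ≈ 0.0366, s = 2 (hub-dominated,
  right-skewed host degrees), 5 modules, 30% mixing;
- **margin repair** — under a right-skewed gradient, specialist species
  have expected degree below one, so empty rows/columns are expected in any
  finite draw.  Rather than rejecting whole matrices (which essentially
  never succeeds jointly across all margins), empty margins are repaired by
  relocating links from species that can spare them, conserving the fill
  exactly; irreparable draws are redrawn.  The repair conditions the
  ensemble on occupied margins, which inflates NODF very slightly relative
  to an unconditioned fill null — measurable at low connectance, negligible
  at the densities used in the tests;
- **traits** — morphology is sampled per host with class log-odds
  proportional to log(effect)·standardised log-degree, so class-conditional
  expected degree follows `morphology_effects`.  Default effects
  (Cup-like 3.0, Massive 2.5, Erect 0.8, Crust-like 0.5) were calibrated
  once so the morphology ANOVA operates at high power (~0.9 at 40 hosts)
  while all-equal effects give a nominal type-I rate; orders are assigned
  uniformly at random (no taxonomic signal, matching the null finding the
  order ANOVA is meant to be able to return);
- **occurrences** — counts per host are geometric (overdispersed,
  support ≥ 1) with mean 3·degree^area_coupling (coupling 1 by default, 0
  decouples them), coordinates uniform inside randomly placed rectangular
  reef polygons in a Caribbean-like bounding box.

What the generator does **not** emulate: real species names and synonymy
noise, MEOW ecoregion geometry (ecoregion labels are multinomial), spatial
autocorrelation of records, true reef shapes, and correlated
incompleteness between regions.  Passing tests therefore demonstrate that
the methods recover planted statistical structure at realistic scales and
rates — not that the biological conclusions transfer to any particular
empirical dataset.

## Problem sizes and numerical choices

The test-suite and the acceptance script scale simulations to the signal
being measured rather than to the full study throughout: parameter-recovery
sweeps use 15–40-host networks with reduced annealing budgets (2–20×10³
steps) and reduced cni randomizations (25–150), sizes at which the planted
effects are comfortably detectable and a few hundred replicates run in
minutes.  Tolerances: Katz closed form vs power series 1e-10; PCoA vs PCA
1e-8; GLM vs numerical MLE 1e-4; exact identities (NODF anchors, Barber Q
anchors, ANOVA sums of squares) at 1e-12 or machine precision.  The
annealing temperature schedule (T₀ = 0.02, geometric cooling to 1e-4·T₀
over the budget, 2 restarts) was chosen for reliable recovery of planted
blocks on the test matrices; it is exposed, not hard-coded.

## Known limitations

- The study-reproduction tier requires the deposited interaction table;
  without it the corresponding test fails by design rather than being
  skipped, so the gap is visible.
- The curveball null is run with a fixed number of trade sweeps (5·R),
  adequate for mixing at the matrix sizes used here but not adaptively
  diagnosed.
- The annealer's module count is bounded by min(R, C) initial labels;
  pathological optima with more modules than that are not reachable.
- `union_overlaps` evaluates a species' union in the frame of its first
  record; for species spanning whole ocean basins the mode mixes frames,
  though the induced error at 1.8 m buffer radius is immaterial.
- The Poisson-family GLM reports Fisher standard errors without a
  dispersion correction; with strongly overdispersed continuous responses
  the z-values are optimistic (the slope sign and fit are unaffected).
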