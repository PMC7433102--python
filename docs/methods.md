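# Methods

This note documents the statistical machinery, the synthetic-data
generator's design, the numerical choices, and the limits of what the test
suite demonstrates.

## Climate window statistics

A species' climate is the unweighted mean over its range cells of the
monthly grid, giving a `(years x 12)` series per variable (temperature,
precipitation). For a breeding window *w* (inclusive month interval,
wrap-around permitted, months taken from the same calendar year — no
cross-year splicing):

* **ambient value**: median of the pooled `{x_{y,m} : y = 1..Y, m ∈ w}`;
* **seasonality**: `(1/Y) Σ_y Var_m(x_{y,m})`, the mean over years of the
  within-year sample variance across the window's months;
* **interannual fluctuation**: `(1/|w|) Σ_{m∈w} Var_y(x_{y,m})`, the mean
  over window months of that month's across-year sample variance.

All variances are sample (n−1) variances. A one-month window has no
within-year spread; its seasonality is defined as 0 and flagged
(`degenerate_seasonality`) rather than dropped, so one-month breeders stay
in every analysis. A breeding season with unknown end closes in December.
Cells are averaged before any statistic is taken (the alternative —
pooling cell-months — is not offered because the per-species series is the
unit every downstream model consumes). Cell means are unweighted;
area-weighted extraction is a possible extension, not implemented.

The **consecutive-month null** recomputes seasonality for windows of the
observed length at every start month. The default mode enumerates all 12
cyclic placements (the sample space is tiny; sampling only adds noise);
a sampling mode exists for API symmetry. The observed value's quantile
counts ties as `≤`. Full-year windows are degenerate (observed ≡ null) and
are excluded with a flag from group-level summaries.

## Phylogenetic regressions

**PGLS.** `y = Xβ + e`, `e ~ N(0, σ² V)` with
`V = D^{1/2} C(θ) D^{1/2}`, where `C` is the residual correlation implied
by the tree and `D = diag(w_i)` holds optional per-species variance
weights. Two correlation families:

* **Ornstein–Uhlenbeck**: `C_ij = exp(-α d_ij)` with `d_ij` the patristic
  distance. Large `α` (fast mean reversion) erases phylogenetic
  correlation; the fit then collapses to OLS.
* **Pagel's lambda**: off-diagonal Brownian covariances scaled by `λ`,
  normalised to a correlation matrix. `λ = 0` is a star tree, `λ = 1`
  Brownian motion. The ML bound is 1.1 so that empirical estimates
  slightly above 1 are representable.

`σ²` and `β` have closed-form ML profiles; the correlation parameter is
maximised by bounded scalar search — on `log α` over `[10⁻⁴, 10⁴]/T`
(`T` = tree depth) with `xatol = 10⁻⁸`, or on `λ ∈ [0, 1.1]` with an
explicit boundary check at 0. Coefficient tests are t-tests on `n − p`
residual degrees of freedom with `Var(β̂) = (XᵀV⁻¹X)⁻¹ · RSS/(n−p)`
(z-tests would differ negligibly at the sample sizes involved). Rank
deficiency raises an error naming the collinear columns.

**Range-size weights.** On log10-transformed areas `a`,
`w_i = a_i / min_j a_j`; residual variance scales with `w_i`, so the
largest ranges — whose range-averaged climate is least representative —
get the least influence. The formula requires `log10(min area) > 0`,
i.e. areas above one areal unit; smaller values raise an error rather
than silently flipping sign.

**Binary traits in GLS.** The 0/1 SDS can enter a linear GLS either as a
response (linear-probability fit) or as a predictor with the climate
variable as response. The package's headline fit uses climate-as-response
(`fit_sds_model(direction="climate_on_sds")`): the OU residual model then
describes the evolution of the climate trait, and the slope is the TSD−GSD
offset in °C (or mm), which is the interpretable scale. The other
direction is available as an option.

**Variance heterogeneity.** The "phylogeny-corrected ANOVA on spread":
null = one residual variance; alternative = a free variance multiplier per
group (reference fixed at 1), both fitted by ML with the group factor in
the mean (so the contrast isolates the variance difference and is not
contaminated by a mean shift) and the OU rate re-estimated in each model.
`2Δlog L` is referred to chi-square with (groups − 1) df. The alternative
is optimised jointly over `(log α, log ψ_g)` by Nelder–Mead started at the
null solution, and its log-likelihood is floored at the null's (the null
is a boundary point of the alternative).

**Phylogenetic logistic regression.** For binary responses, the Firth
score `Xᵀ(y − μ + h(½ − μ))` is whitened by an OU working correlation
`R = exp(-α d)`: the update solves the GLS normal equations with
covariance `W^{-1/2} R W^{-1/2}`, `W = diag(μ(1−μ))`, and the hat
diagonal `h` from the independence information matrix. On a star tree
(`R = I`) the iteration is exactly ordinary Firth logistic regression —
verified in the tests against an independent direct maximiser of the
penalised likelihood. The penalty keeps estimates finite under complete
separation (flagged when fitted probabilities pin to 0/1). `α` defaults
to the ML rate from a linear-probability PGLS of the same data; Wald z
tests are reported. This is a working-correlation estimator in the
spirit of established phylogenetic logistic methods, not a full
marginal-likelihood fit; its p-values are approximate, which is
acceptable for the d-separation tests it serves.

**Phylogenetic signal.** Pagel's lambda for a single trait is the ML
`λ` of an intercept-only GLS, with a 1-df likelihood-ratio test against
`λ = 0`.

## d-separation path analysis

For each candidate DAG the basis set contains one claim per non-adjacent
vertex pair `(X, Y)`, conditioning on the union of both vertices' parents;
the claim's response is the pair's later vertex in topological order
(deterministic, and matches directional regression practice). Claims are
tested by OU-PGLS (continuous response) or the phylogenetic logistic fit
(binary response); continuous variables are z-scored before fitting so
path coefficients are comparable across edges, binary 0/1 codes are left
untouched. The claim p-values combine into Fisher's
`C = −2 Σ ln p_i ~ χ²(2k)` under the DAG; zero p-values are clamped to
the smallest positive float with a warning.

Models are ranked by `CICc = C + 2qn/(n − 1 − q)` with `q` = number of
directed edges (the parameters estimated are the path coefficients; an
edges-plus-vertices convention exists in the literature and can be
mimicked by adjusting `q` externally). Akaike-style weights
`∝ exp(−ΔCICc/2)` are normalised over the model set; models with
`ΔCICc ≤ 2` are retained (threshold configurable). *Full* averaging
weights each edge coefficient over the retained models, counting 0 for a
model lacking the edge, with weights renormalised over the retained set.

The built-in `ABCD` set contains the four three-variable chains over
{SDS, ambient temperature, breeding-season length}: A `sds→temp→length`,
B `sds→length→temp`, C `temp→sds→length`, D `temp→length→sds`. The
five-model life-history set has no canonical topologies, so it must be
supplied by the user as edge lists.

## Synthetic-study generator

The generator produces, under one seed, a complete internally consistent
study; its defaults are the conditions every calibration and power check
runs under: 213 species, 30 years of monthly climate, exactly 11
GSD→TSD transitions, and a +3 °C TSD warm shift (the kind of offset the
comparative literature reports for temperature-dependent taxa).

* **Tree**: birth–death (default pure birth, rate 1) conditioned on the
  exact tip count, rescaled to unit depth — OU rates are therefore quoted
  per unit tree depth. The simulator stops at the n-th speciation, so
  tips are extended by the exponential waiting time to the next event to
  restore strictly positive terminal branches.
* **SDS**: a continuous-time two-state process simulated branch-wise.
  With a transition target, rates default to one-way gains
  (`q01 = target / total tree length`, `q10 = 0` — a GSD root with derived
  TSD clades) and realisations are rejection-sampled (cap 10,000 attempts)
  until the change count matches exactly. Transitions are naturally
  clustered by tree shape. The realised TSD fraction varies between
  seeds — the process conditions on the transition count, not on where
  transitions fall.
* **Climate**: `T = base − gradient·|lat| + amp(lat)·cos(2π(m − peak)/12)
  + ε_year + ε_month`, with latitude the row index mapped linearly to
  [−60°, 60°], amplitude increasing poleward, the seasonal peak
  phase-flipped in the southern hemisphere, and independent year-level and
  month-level Gaussian noise. Precipitation is analogous with a
  nonnegativity clamp.
* **Ranges**: a latent habitat-preference trait evolves along the tree
  under OU; its normal quantile maps onto the distribution of cell
  *warm-season* temperatures (climatological warmest 4 consecutive
  months), TSD species get the configured warm shift added, and the range
  grows as a seeded breadth-first blob (lognormal size) from a cell near
  the target temperature. Using warm-season rather than annual-mean
  temperature as the placement scale makes the configured shift carry
  into the breeding-window statistic the analysis actually measures;
  phylogenetic conservation of habitat mirrors the strong signal real
  range climates show. With a zero shift and random windows the two SDS
  groups are exchangeable — the null construction used for calibration.
* **Windows**: lengths drawn from a configurable distribution (default:
  68 % short 1–4 months, 32 % long 5–12 months, uniform within bands);
  placed on the warmest months (default), the stablest (minimum
  within-year variance, used to exercise the null-window analysis), or
  uniformly at random. Ties break to the earliest start, with a relative
  tolerance of 1e−9 so floating-point summation order cannot break exact
  ties.
* **Life history**: three OU traits sharing a latent "size" component,
  each observed with probability 0.6 (≈22 % complete cases, ≈94 % with at
  least one trait — matching the structure of real compilations where the
  Z-score index earns its keep). Viviparity is assigned to the
  coldest-range GSD species (plus one TSD species), reproducing the
  viviparity–GSD–cold confounding that motivates oviparous-only
  reanalyses.

**What the generator does not emulate**: real geodesy (cells are unit
squares, no ocean masks or coastlines), topography, spatially correlated
climate noise, range fragmentation or dispersal, and any particular
empirical distribution of range sizes. Passing tests therefore
demonstrate the *statistical machinery* — calibration, recovery,
reductions — under a faithful abstraction of the study design, not the
empirical conclusions of any real dataset, which depend on curated
occurrence data, shapefiles and climate archives outside this package's
scope.

## Pipeline conventions

* The life-history index z-scores each trait over its non-missing species
  and averages the available Z scores per species, so partially observed
  species keep an index; all-missing or constant columns are excluded
  with a warning.
* The reference-temperature comparison (breeding-length categories
  against 25 °C) uses a one-sample Wilcoxon signed-rank test — a constant
  reference has no second sample to rank — with Benjamini–Hochberg
  correction across groups; groups under 3 species are skipped and
  flagged.
* Continent jackknife: one refit per left-out continent; a continent
  absent from the data is a no-op flagged as identical to the full fit;
  removals leaving < 10 species still run but are flagged.
* Family-constrained subsampling: for each fraction (0.9→0.6 by default)
  and replicate, `floor(f·n)` species are drawn — one guaranteed
  representative per family first, the rest uniformly without
  replacement; fractions that cannot honour the constraint raise.
* Every reader rejects rather than coerces (row-numbered errors for bad
  codings, explicit gap lists for missing climate months) and every
  exclusion is enumerated in the outputs. Period bounds are inclusive on
  both ends. GeoJSON polygons are rasterized by cell-centre containment —
  deterministic and adequate at coarse grid scales; overlap-fraction
  rasterization is out of scope.

## Problem sizes and determinism

All simulations derive from a single integer seed (sub-seeds via
`numpy.random.SeedSequence`), and repeated runs are bit-identical. The
acceptance checks use the sizes at which their properties are stated:
n = 200 species with 200 replicates for effect recovery and path-model
calibration, 50 replicates for lambda recovery, 100 species for the
null-window construction. Unit tests use smaller trees (40–150 tips) and
fewer replicates, sized so the whole suite runs in about a minute.

## Known limitations

* The OU and lambda fits are ML, not REML; variance components are mildly
  biased at small n (the contrasts and coverage checks show this is
  immaterial at n ≥ 40).
* The phylogenetic logistic regression is a penalised working-correlation
  estimator; its p-values are approximate (calibration is verified
  empirically in the path-analysis tests).
* Mk conditioning fixes the number of transitions, not their placement,
  so group sizes fluctuate across seeds.
* No measurement-error model, multivariate responses, within-species
  replication, or alternative tree topologies.
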