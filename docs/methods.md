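# Methods

## The analysis model

fcgraph treats a participant's resting-state functional connectome as a
complete, undirected, weighted graph: nodes are parcels, and the weight
of edge (i, j) is the absolute value of the run-averaged Fisher z
correlation between the two parcels' time series. The analysis asks,
for each of eight graph measures, whether the measure varies with
loneliness, age, or their product across participants, after adjusting
for nuisance covariates, with inference by within-site permutation.

### Connectome construction

Each run's frames × parcels matrix is column-standardized (mean 0,
SD 1, n−1 denominator), fully correlated, and Fisher z-transformed with
|r| clipped at 1 − 1e−7 so duplicated parcels degrade gracefully
instead of producing infinities. Runs are averaged element-wise in z
space (the variance-stabilized scale on which averaging correlations is
defensible). Weights stay in z units; nothing is back-transformed to r,
and no thresholding or sparsification is applied — the measures below
are all defined for complete weighted graphs. The diagonal is fixed at
zero everywhere (no self-loops). Three weighting schemes are exposed:
`abs` (default), `positive_only` (max(z, 0)) and `negative_only`
(|min(z, 0)|); by construction abs = positive_only + negative_only.

### Graph measures and their conventions

Distances use edge length 1/w with zero-weight edges treated as absent;
shortest paths are Dijkstra's (delegated to scipy's csgraph for the
distance matrix). Choices that a reader might otherwise have to
reverse-engineer from code:

* **Normalized strength** is s_i/(n−1). On a complete graph this equals
  s_i/k_i, so the ambiguity between the two normalizations is moot.
* **Average shortest path length** averages over ordered pairs i ≠ j;
  a disconnected pair is an error rather than an arbitrary constant
  (complete abs-weight graphs are always connected).
* **Betweenness** is Brandes' algorithm with endpoints excluded,
  shortest-path ties split proportionally to path multiplicity, and
  undirected normalization 2/((n−1)(n−2)); graphs with n < 3 return
  zeros.
* **Eigenvector centrality** is the leading eigenvector of the weight
  matrix itself (not of distances), computed by power iteration
  (tolerance 1e−10 in the sup norm, 1000 iterations max), entries
  nonnegative, Euclidean norm 1. For nonnegative irreducible matrices
  the iteration converges by Perron–Frobenius; non-convergence raises.
* **Clustering** is the Onnela geometric-mean form with weights
  normalized by the single global maximum weight, matching the common
  reference implementations; C_i = 0 when a node has fewer than two
  nonzero-weight neighbors.
* **Participation** uses strengths (weighted degree). On a complete
  weighted graph the binary degree is constant, which would make a
  binary-degree participation coefficient degenerate; the strength form
  is the meaningful reading. Isolated nodes get P_i = 0.
* **Modularity** is Newman's Q on the *fixed* 12-network partition —
  no community detection — including the i = j null-model terms with
  observed self-weight zero. The two-clique fixture (two disjoint unit
  edges, two communities) pins this convention testably at Q = 0.5.

### Permutation GLM

The design contains an intercept; mean-centered loneliness and age and
their product (centering decorrelates the product from the main effects
without changing the permutation p of the interaction); sex, MoCA,
mean FD and gray-matter volume as covariates; and K−1 site dummies. An
`adjusted` model adds marital and household status, mirroring analyses
restricted to participants with complete socio-demographic data; rows
with missing values are dropped listwise and counted. Sites serve
simultaneously as fixed effects, exchangeability blocks and variance
groups — the standard configuration when a multi-site study both
adjusts for site and permutes within site.

The statistic is the Aspin–Welch v: the OLS contrast estimate divided
by a heteroscedasticity-adjusted standard error in which each variance
group b contributes weight (Σ_{i∈b} (1 − h_ii)) / RSS_b, i.e. its share
of residual degrees of freedom (apportioned by leverage) over its
residual sum of squares. With one variance group v is algebraically the
classical t, which the tests assert to 1e−10.

Permutation follows Freedman–Lane: the nuisance-only model (everything
except the contrast column) is fitted, its residuals are permuted
within blocks, the nuisance fit is added back, and the full model is
refitted. p-values are two-tailed with the +1 offset,
p = (1 + #{|v*| ≥ |v|})/(1 + B), so p > 0 and the test is exact-valid;
family-wise error is controlled per metric and contrast by the
permutation distribution of max_node |v*|. When the number of distinct
within-block permutations is below the requested B, the test enumerates
all of them exhaustively (with a warning) instead of sampling. The
reported z is the signed inverse-normal transform of the two-tailed
permutation p — a permutation-calibrated effect summary, not a
parametric statistic.

### Behavioral statistics

Welch's heteroscedastic ANOVA uses the Satterthwaite-type fractional
denominator df (k²−1)/(3Σ(1−w_i/W)²/(n_i−1)); for two groups it equals
the squared Welch t exactly. Games–Howell comparisons use pairwise
Welch df and the studentized range distribution. The multivariable
model z-scores continuous predictors (family income is natural-log
transformed first, reflecting its skew) and reference-codes categorical
ones (female, married, living-with-others, employed, high-school-or-
below as references); binary dummies are deliberately *not*
standardized, so their coefficients read as outcome-SD differences
between groups. The equal-variance one-way ANOVA is also provided, and
the choice between it and the Welch form is an explicit user decision
rather than an automatic Levene gate, which would hide an analysis
choice inside the software.

## The synthetic cohort generator

The generator emulates the *design* of a multi-site lifespan study —
ages uniform on [36, 100], four sites, four runs of 300 frames, 12
functional networks — not the biophysics of BOLD. Signals are
stationary multivariate Gaussian draws from a participant-specific
target correlation matrix (an AR(1) temporal option exists, off by
default); there is no hemodynamic model, no scanner noise floor, and
no spatial autocorrelation within parcels.

The target matrix is block-modular: within-network correlation
ρ_w − γ_age·z_age (defaults ρ_w = 0.5, γ_age = 0.1 per SD of age),
between-network ρ_b = 0.1. The loneliness×age interaction is planted by
shifting all edges inside a designated node's within-network
neighborhood — its own within-network edges and the edges among its
network peers — by γ_int·z_lone·z_age. Because z_age is centered at the
age midpoint, the sign of the loneliness association reverses there,
reproducing a cross-over interaction. The modulation deliberately
includes the designated node's own within-network edges: modulating
only the peer–peer edges leaves a complete graph's clustering
coefficient nearly untouched (those edges enter a vanishing fraction of
the Onnela triangle terms), far below any detectable effect size.

Two structural details matter and are worth stating plainly:

* **Anchor edges.** One edge per network is pinned at a constant high
  correlation (0.8). Real connectomes have a stable extreme tail of
  very strong edges (e.g. homotopic pairs) that does not track global
  age effects. Without such a tail, the graph's maximum weight — the
  Onnela normalizer — is itself modulated by the planted effects, and
  the clustering coefficient of *every* node moves opposite to the
  planted direction. The anchors keep the normalizer stable so the
  planted within-network weakening shows up as lower clustering, the
  behavior real aging data exhibit.
* **Clipping and PSD repair.** Modulated within-network entries are
  clipped to [ρ_b, 0.7] — within-network connectivity degrades toward,
  not below, the between-network background, and stays under the
  anchors — and between entries to ±0.7. The matrix is then projected
  to the nearest PSD matrix by eigenvalue clipping at 1e−10 and
  re-normalization to unit diagonal. If the repair moves any entry by
  more than a tolerance (0.25 by default) the requested structure is
  deemed unattainable and generation fails loudly rather than silently
  sampling from something else.

The loneliness T-score is 50 + 10·(linear predictor) + noise, with the
residual variance chosen so the marginal SD is ≈ 10; default
standardized effects are −0.24 (age), +0.25 (male), +0.31 (unmarried),
+0.32 (living alone). Motion traces are six-parameter random walks
(step SD 0.02 mm; rotations two orders smaller) with optional injected
1 mm single-frame displacement spikes controlling the flagged fraction.

What passing tests on this generator show — and what they do not: they
validate the *statistical machinery* (calibration of the permutation
test under a true null with site structure, power and sign recovery
against known ground truth, every metric's numerical correctness) on
data with the planted covariance structure. They cannot certify
preprocessing choices, parcellation quality, or effect sizes in real
populations, where nuisance structure (autocorrelation, motion
artifacts correlated with age, site-by-age confounds) is richer than
the generator's.

## Study problem sizes

The replicate studies use a reduced desk-scale design — 50 nodes over
the 12 networks, N = 200, 4 sites, 500 permutations — chosen so that
500 null replicates and 100 planted-effect replicates of the *full*
pipeline (generation through GLM) complete in minutes on one CPU while
keeping every structural feature of the full-size analysis. The
power-study interaction strength (γ_int = −0.5 on two designated nodes,
the third member of each of the first two networks) was calibrated once
against the generator so the realized standardized interaction on
designated-node clustering exceeds 0.4, the conventional threshold for
a "strong" planted effect in this kind of recovery study; the measured
standardized effects are ≈ −0.6.

## Known limitations

* The Gaussian generator has no temporal autocorrelation by default;
  permutation validity with strongly autocorrelated noise at the
  *participant* level is not exercised (exchangeability across
  participants, which the test relies on, is unaffected).
* The mean-FD covariate is computed over all frames including flagged
  ones; scrubbing before correlation exists as an option but is off by
  default, so FD-correlated artifacts are only modeled through the
  covariate.
* Exhaustive permutation enumeration is only attempted when the count
  is below the requested B; block structures with huge but asymmetric
  factorial counts are always sampled with replacement across draws.
* The CLI's staged file interface stores matrices as TSV; at hundreds
  of parcels these files are large, and the in-memory `run_pipeline`
  path is preferred for simulation studies.
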