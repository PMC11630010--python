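# Methods

## Scope and data model

The pipeline operates on two county-indexed percentage tables: age-adjusted
prevalence of chronic conditions, and risk-factor shares. County identifiers
are opaque strings (FIPS codes keep leading zeros). All cells are validated
to [0, 100]; numeric cells outside that range are an error naming the row
and column, while missing/non-numeric cells follow the configured policy
(`drop_row` complete-case by default, with the dropped count logged, or
`error`). The two tables are inner-joined on county; the analysis is
listwise complete-case across all columns, so every correlation and
regression uses the same n and the networks are built from one coherent
sample.

## Edge construction

**Disease–disease.** Pearson r for every unordered pair, two-sided p from
the t distribution with n−2 df (`scipy.stats.pearsonr`). An edge exists iff
p < `p_threshold` (default 0.05, per-test, no multiplicity correction: with
66 pairs at county-level sample sizes nearly all pairs are decisively
significant and a correction would not change the network). Edge weight is
|r| with the signed value retained as an attribute: downstream strength and
fitness sums are degree-style and must be nonnegative, and a node with many
strong negative correlations should count as strongly connected, not weakly.

**Disease–factor.** One OLS per disease on all 10 factors (statsmodels),
with response and predictors z-scored (ddof = 1) so the coefficients are
standardized betas — comparable across factors and diseases and commensurate
with |r| in the integrated graph. Classical homoskedastic standard errors,
two-sided t p-values, per-coefficient significance at `p_threshold`.
Rank-deficient designs are rejected naming the collinear columns; condition
numbers above 1e8 warn (county risk factors such as poverty and education
are themselves correlated).

**Integration.** Plain node/edge union with weights carried over bitwise;
node class (disease/factor) and edge kind are preserved, and the bipartite
invariant (no factor–factor edges) is re-checked. An optional per-kind
min–max rescaling exists as a sensitivity switch but is off by default:
both weight families are unitless effect sizes in [0, ~1].

## Overlapping community detection

Fitness of a node set G in the weighted graph:

    f_G = k_in / (k_in + k_out)^alpha

with k_in twice the total internal edge weight and k_out the total boundary
weight. On unit-weight graphs this reduces to the classic degree-based
local-fitness method. Defaults: alpha = 1.0 (the standard resolution; larger
alpha gives smaller communities), beta = 0.5 for merging. Both are exposed
as CLI flags; on a 22-node network a small grid around these defaults is
cheap and recommended when calibrating against known patterns.

Expansion from a seed adds, at each step, the adjacent node with the largest
strictly positive fitness gain `f(G∪{i}) − f(G∖{i})`; ties break to the
lexicographically smallest label so a fixed seed gives a fixed community.
After each insertion every member is re-checked and removed if its removal
strictly raises fitness — with two deliberate restrictions:

- **the seed is anchored** (never removed): each expansion returns the
  seed's natural community, which guarantees the cover loop terminates and
  covers every node;
- **removals must keep the community connected** in the host graph, so a
  community is always a connected set.

The result is a single-move local maximum of f over connected supersets and
anchored subsets; the test suite verifies this against an independent
brute-force oracle on hundreds of random graphs. The removal step itself can
be disabled (`lfm_removal=False`) for a strictly additive variant; with it
off, local maximality under removal is no longer guaranteed. Seeds are drawn
uniformly at random among uncovered nodes from the run RNG (the only source
of randomness in the whole pipeline); a `--deterministic-seeds` mode picks
the highest-strength uncovered node instead. Isolated nodes become singleton
communities with fitness 0 and are reported, not dropped.

Merging is greedy: while any pair of communities has overlap similarity
`S = |G1∩G2| / min(|G1|, |G2|)` strictly above beta, the most-similar pair
(first in index order on ties) is unioned and fitness recomputed. The final
communities are sorted by node labels, making outputs byte-stable for a
fixed seed.

## Importance metrics and roles

Strength is the sum of incident weights. Influence is neighbor-normalized,
`NI_i = Σ_j A_ij / D_j`: each tie counts by how large a share it is of the
neighbor's total connectivity, so influence is bounded by the degree and
sits near 1 for uniformly embedded nodes (exactly 1 on uniform-weight
regular graphs). A literal product variant `Σ_j A_ij · D_j` is implemented
for comparison; it scales like strength² and exceeds the observed 0.4–1.2
influence range of the reference county network by an order of magnitude,
which is why the quotient form is the default. Metrics are computed on the
disease-only subnetwork by default (matching how the reference node table
behaves; `metrics_scope="full"` switches to the integrated graph).

Roles partition the diseases with bridge taking precedence: a disease in ≥2
merged communities is a bridge regardless of its metrics; among the rest the
top-k by influence (k = 3 default) are core, the remainder general. An
absolute influence cutoff (`core_threshold`) replaces top-k when set.
Changing k moves only the core/general boundary, never bridge membership.
The published reference tables (node metrics and the four-community cover of
the 2020 US county analysis), shipped in `mccnet.reference` as fixed inputs,
reproduce the published taxonomy under this rule: ranked by influence the
top three non-bridge diseases are exactly diabetes, CKD and CHD, with COPD
fourth — the k = 3 rule is a reconstruction consistent with that table, not
a published formula.

## Synthetic data generator

The generator emulates the structure the pipeline consumes: ~3,143 county
rows; factors as independent Gaussians on the percent scale (an optional
factor correlation matrix is accepted — real county covariates are
correlated); each disease as a standardized latent
`y_d = Σ_f β_df·z(F_f) + e_d` with residuals drawn from a block correlation
matrix (`within_block_r` = 0.8 inside a planted block, `between_block_r` =
0.05 across, both checked for positive semi-definiteness at construction)
scaled by `noise_sd` = 0.8, then mapped to percent via per-column base
mean/SD and clipped to [0, 100]. Clipping above 1% of cells aborts
generation, since heavy clipping distorts the target correlations. Defaults:
12 diseases in 4 epidemiologically themed blocks (cardiometabolic–renal,
cardiovascular, respiratory–metabolic, psychosocial), 10 factors at the
locations/spreads typical of US county tables; the spreads for the two most
right-skewed covariates (minority share, low education) are tightened so a
Gaussian respects the clip tolerance — a deliberate normality limitation.
With β's of 0.3–0.4 and `noise_sd` 0.8, total same-block correlations land
near 0.87 and factor-mediated cross-block correlations near 0.15, a
realistic regime in which the planted blocks are recoverable but not
trivially separated.

Ground truth ships with every draw: the implied disease correlation matrix
`corr(B·R_f·Bᵀ + σ²·R_e)`, the implied standardized coefficients
`β_df / sd(y_d)` (what a correctly standardized OLS should estimate), and
the planted cover (one community per block plus the factors acting on it; a
factor acting on several blocks belongs to several communities). Recovery is
scored by symmetric best-match overlap similarity between detected and
planted covers, restricted to nodes the ground truth assigns — a factor with
no planted effects has no ground-truth community, and its detected singleton
carries no recovery information.

What passing these benchmarks does **not** show about real data: no spatial
autocorrelation between counties, no survey-estimation artifacts, no
skewness/truncation beyond mild clipping, and linear dependence only — real
county tables violate all four to some degree.

## Problem sizes and numerics

The shipped benchmarks use n = 3,000–3,143 counties, 20 seeds for the
stochastic recovery checks, 200 random graphs (≤8 nodes) for the exhaustive
local-maximality oracle, and 100 random covers for the merge contract;
together they run in seconds. Floating-point contracts: edge lists are
written at 17 significant digits (lossless round-trip), strength
conservation and the quotient-influence identities hold to 1e-12, and
correlation/regression layers match closed-form textbook oracles to 1e-10.
Degenerate inputs: zero-variance columns, rank-deficient designs, empty
county intersections and non-PSD block specifications are all rejected with
named errors rather than propagated as NaNs.

## Known limitations

- Ecological analysis: county-level co-prevalence, not individual-level
  multimorbidity; nothing here supports individual-level causal claims.
- The LFM cover depends on seed order; determinism is provided via the run
  seed (or strength-ordered seeding), not via uniqueness of the optimum.
- alpha and beta for the reference four-pattern solution are not published;
  reproducing it is a calibration exercise over a small grid, not a
  default-run guarantee.
- Significance thresholds are per-test; with larger variable sets a
  multiplicity-aware edge rule would be needed.
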