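# Methods

This note documents the models, the numerical choices, what the synthetic
data does and does not emulate, and the package's known limitations. It
states no empirical result beyond what the test suite and
`scripts/acceptance.py` themselves compute.

## Diversity and ordination

Alpha diversity is computed from integer counts. Chao1 uses the
bias-corrected form S_obs + F1(F1−1)/(2(F2+1)), which stays finite when no
doubletons exist — the situation small fixtures and shallow samples hit
constantly. ACE uses the conventional rare-abundance cutoff of 10. Shannon
entropy is reported in nats (−Σ p ln p) and Simpson as the Gini–Simpson
probability 1 − Σ p². Chao1 and ACE refuse non-integer input because both
estimators read singleton/doubleton counts, which rescaled data destroys.

Bray–Curtis is d(i,j) = Σ|x_i − x_j| / Σ(x_i + x_j) on counts or
proportions. PCoA Gower-centers −d²/2 and eigen-decomposes; negative
eigenvalues (Bray–Curtis is not generally Euclidean-embeddable) are kept
in the eigenvalue report but excluded from coordinates, and proportions
explained are taken over the positive spectrum only. This is checked
against scikit-bio's PCoA in the test suite.

ANOSIM uses midranks for tied distances (deterministic) and the permutation
p-value (1 + #{R_perm ≥ R_obs})/(1 + n_permutations). The denominator of R
is n(n−1)/4 — i.e. half the number of pairs — which is the normalization
under which complete separation yields R = 1 and R ∈ [−1, 1]; the test
suite verifies the statistic against exhaustive enumeration of all 720
relabelings of a six-sample matrix, and its type-I error against 1000 null
simulations.

## Co-occurrence networks

The construction pipeline is the dominant convention in soil microbiome
work: aggregate to genus, drop taxa present in fewer than one third of
samples, Spearman ρ across samples, keep edges with |ρ| ≥ 0.6 and
BH-adjusted p ≤ 0.05. All four thresholds are parameters; the defaults
matter because published topology tables are not reproducible without
making them explicit. Edge sign is sign(ρ); weight is |ρ|.

Average degree and density are closed forms of (N, L). Both the unweighted
mean degree 2L/N and the weighted 2Σw/N are reported separately because
published tables often conflate them — of the eight printed networks in
the study system this package mirrors, only five satisfy 2L/N at printed
rounding, and those five are the cells the acceptance script pins.

Modularity runs Louvain on absolute weights (community detection ignoring
sign, matching common practice in network visualization tools), taking the
best of 10 seeded restarts. Best-of-restarts never decreases and is exact
on small graphs — verified against brute-force enumeration of all
partitions of 7- and 8-node two-clique graphs.

## Assembly null models

βMNTD between samples i and j is the abundance-weighted mean, over the
taxa of each sample, of the patristic distance to the nearest taxon
present in the other sample, averaged over both directions — equivalent to
`picante::comdistnt(..., abundance.weighted=TRUE)`, which the test suite
calls through R as an independent oracle.

βNTI standardizes observed βMNTD against 999 (default) random
permutations of taxon labels across tree tips; the null standard deviation
uses ddof = 1. Pairs with zero null spread (a star phylogeny, or two
samples sharing every taxon) are flagged NaN, excluded from process
fractions, and logged — they carry no phylogenetic signal either way.
βNTI is invariant to rescaling all branch lengths (observed and null scale
together), asserted on a 16-tip tree.

Raup–Crick(Bray) assembles null community pairs that preserve each
sample's richness and total count: taxa are drawn without replacement with
probability proportional to occurrence frequency across all samples
(Gumbel top-k sampling, which vectorizes across null replicates), each
drawn taxon is seeded with one individual, and the remaining individuals
are assigned multinomially in proportion to regional relative abundance.
RC = 2·[P(null < obs) + 0.5·P(null = obs)] − 1.

The five-process partition applies βNTI first (|βNTI| > 2 → heterogeneous
or homogeneous selection by sign) and RC second (±0.95), with "drift and
others" as the residual; fractions are computed over within-group sample
pairs. A group is deterministic-dominated when the two selection fractions
sum above 0.5. Both cutoffs, like the null counts, sit in `RunConfig`.

Performance: the tip-shuffle null is evaluated in chunked, fully
vectorized form (per pair, a (chunk × |i| × |j|) distance block reduced by
min), so the default study scale — 20 samples, 300 taxa, 999 nulls,
within-group pairs — runs in roughly ten seconds per community on one
core. These sizes were chosen as the package's desk-scale defaults.

## Multifunctionality and enzyme stoichiometry

Min–max standardization maps each indicator to [0, 1] across plots; a
constant indicator is mapped to 0.5 with a warning instead of failing the
panel (it carries no ranking information, and dropping it silently would
change N). EF is the arithmetic mean of a group's standardized indicators;
EMF is the mean over all N indicators, which makes it exactly the
n_group/N-weighted mean of the EF indices — asserted numerically on 1000
random panels. Both indices are invariant to positive affine rescaling of
any indicator, so unit choices cannot move them.

The default 17-indicator grouping is carbon (soil/stem/leaf total C,
sucrase), nitrogen (soil/stem/leaf total N, urease), phosphorus
(soil/stem/leaf total P, alkaline and acid phosphatase) and productivity
(plant height, stem and leaf biomass, crown width); the grouping is a
plain dict and fully configurable.

Enzyme vectors use x = CEs/PEs and y = CEs/NEs with CEs = sucrase,
NEs = urease, PEs = alkaline + acid phosphatase. VL = √(x² + y²); longer
vectors mean stronger microbial carbon limitation. The vector angle is
where conventions genuinely diverge: the formula circulating in the
literature is written in spreadsheet style, and spreadsheet ATAN2 takes
(x, y) — the reverse of the C math library's (y, x). The package defaults
to the spreadsheet reading, VA = degrees·arctan(y/x), exposes `math` and
`both`, and the two are complementary (they sum to 90°, asserted
numerically). The 45° boundary — nitrogen limitation below, phosphorus
above — is the same under either convention at unit ratios, which is why
the acceptance script pins exactly that point. Ratios are taken on raw
activities by default with a flag for log-transformed activities, since
source descriptions rarely say which was used.

## ANOVA letters, RDA, PLS-PM

LSD letters: pairwise t-tests use the pooled ANOVA mean square error with
N − k degrees of freedom; the compact letter display lays one letter over
each maximal run, in descending-mean order, of groups that are all
mutually non-significant, absorbing nested runs. Sharing a letter
therefore implies non-significance (asserted against the pairwise p matrix
across randomized panels); the converse holds for adjacent groups.

RDA centers Y and standardizes X, eigen-decomposes the fitted values of
the multivariate regression, and reports the trace ratio as variance
explained. Community responses are Hellinger-transformed relative
abundances by default (flag to disable) — the standard choice that makes
Euclidean-based ordination behave sensibly on abundance data. Rank
deficiency in X is an error that names the collinear columns. In the full
pipeline the explanatory set is EF-C, EF-N, EF-P, EMF and pH; the
productivity index is deliberately excluded because EMF is an exact
weighted mean of all four EF indices and including all of them makes X
singular by construction.

PLS-PM implements mode A with the centroid inner scheme: outer weights are
correlations of manifests with the block's inner estimate; inner weights
are signs of score correlations between path-connected blocks; iteration
stops when the largest change in normalized outer weights drops below
1e−6 (default, max 300 iterations; non-convergence is an error). Score
signs are fixed by positive correlation with the unweighted sum of the
block's manifests, which makes results independent of plot order and of
the random seed. Path coefficients are per-block OLS on standardized
scores (standardized partial coefficients); GoF = √(mean communality ×
mean R²); bootstrap (seeded, default 499 resamples) gives per-path normal-
approximation two-sided p-values. Single-indicator blocks pass through as
standardized columns. In the pipeline, the bacterial and fungal community
blocks are measured by the first two PCoA axes of the Bray–Curtis matrix —
the diversity-index alternative is a one-line change in the blocks map.

## The synthetic-data generators

Defaults mirror the study design: 4 altitude groups × 5 replicate plots,
300 taxa, sequencing depth 10,000. Trees are ultrametric pure-birth
(successive random joins, exponential waiting times). Traits evolve by
Brownian motion along the tree and are standardized across tips, so niche
conservatism — the assumption βNTI needs — holds by construction.

Community regimes and the choices behind their parameters:

* **Selection** (heterogeneous/homogeneous): log-abundance combines a
  Dirichlet-perturbed metacommunity (concentration 10 per taxon-share)
  with a Gaussian fitness penalty of niche width 0.5 trait SD around the
  sample's environment. Heterogeneous selection spreads environments over
  [−2, 2]; homogeneous selection uses a common optimum of +1.5 rather than
  0 because a Brownian trait places many unrelated lineages near its
  center, and filtering toward the center would produce little of the
  phylogenetic clustering the regime is meant to plant.
* **Drift**: Dirichlet-multinomial around the shared metacommunity with
  concentration 3 per taxon-share — enough demographic noise that
  replicate communities have distinct presence sets (without which the
  tip-shuffling null has zero spread), while keeping |βNTI| > 2 rates at
  or below the nominal 10% in calibration tests.
* **Dispersal limitation**: every sample draws its own independent
  log-normal regional pool, giving turnover far above the Raup–Crick null.
* **Homogenizing dispersal**: every sample is a multinomial draw from the
  identical pool, giving turnover below the null.

The metacommunity log-abundance SD is 2.0, making communities realistically
uneven and sparse at depth 10⁴ (roughly a third to a half of taxa present
per sample).

Planted network modules use shared latent factors, orthogonalized across
samples so modules are independent by construction rather than only in
expectation; member taxa load at ±1.2 on the factor over 0.3 residual
noise, and background taxa carry most of the community mass so that
closure-induced (compositional) correlations between unrelated taxa stay
well below any sensible edge cutoff.

The function panel draws latent block scores from user-supplied structural
equations over the ordered blocks (altitude → pH, microbial axes →
EF-C/EF-N/EF-P/EF-Prod → EMF), with residual variances solved analytically
so every latent has unit variance — the planted coefficients are then
directly comparable to standardized PLS path estimates. Manifests are
loading 0.9 × latent + 0.3 × noise mapped onto plausible measurement
scales (the affine part is irrelevant after min–max standardization).

What the generators do **not** emulate: sequencing error and chimeras,
compositional bias of primers, overdispersion beyond the Dirichlet,
spatial autocorrelation within groups, and any coupling between the
community tables and the function panel (the pipeline links them only
through the fitted models). Passing recovery tests therefore demonstrates
correctness of the estimators under their own assumptions, not field
realism.

## Aggregation choices in recovery tests

Planted-path recovery is asserted on the mean estimate across 10
generator seeds at n = 200 plots (per-seed estimates have sampling SD
around 0.04–0.07 for standardized coefficients at this n, so a per-seed
bound of ±0.12 would be a test of luck rather than of the estimator).
Assembly-regime recovery is asserted per seed (the dominant-regime call is
far above the noise floor) and required in at least 8 of 10 seeds.

## Known limitations

* Homogeneous selection produces clearly negative βNTI only when the
  common optimum selects a coherent clade; with centrally placed optima the
  signal is weak. This mirrors the method's real-world behavior, not a
  generator defect.
* In mixed-regime tables, the Raup–Crick regional pool includes all
  groups, so neutral groups can lean toward RC < 0 (their members are more
  similar than a draw from the pooled region); the stochastic/deterministic
  dominance call is unaffected.
* The fungal-community assembly analysis requires a phylogeny like the
  bacterial one; ITS-based trees are notoriously unreliable, and runs
  without a tree simply skip the assembly stage rather than substituting a
  taxonomy-only variant.
* RDA biplot scores are correlations with site scores (scaling-free
  summary), not the tri-plot scaling conventions of dedicated ordination
  software.
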