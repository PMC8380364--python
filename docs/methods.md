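# Methods

This note documents the statistical models implemented in `microlmp`,
their assumptions, the defaults and why, and what the synthetic-data
experiments do and do not demonstrate.

## Phenotype

Lean meat percentage is computed from two ultrasound measurements taken
at ~120 kg body weight by the linear grading model

    LMP = 0.54 · (80.95 − 16.44 · bf + 4.693 · LMA)

with backfat `bf` in mm and loin-muscle area `LMA` in cm² (the
conventional units for this model family; the function is affine, so unit
errors surface as implausible percentages rather than silent bias — no
clamping is applied). Inputs are assumed already adjusted to constant
weight by the measurement software; no re-adjustment is attempted.

Association scans use the residual `adj_p` of LMP on additive sex and
batch fixed effects with intercept (reference coding, least squares).
Additivity is the simplest model consistent with "corrected for sex and
batch"; interactions are deliberately not fitted. A single-level factor
is dropped with a warning; collinear indicator columns are resolved by
the pseudoinverse, which leaves fitted values (hence residuals)
unambiguous.

## Two-part association model

Relative abundances are zero-inflated and heavy-tailed, so each taxon is
tested twice against `adj_p`:

* **Binary part.** OLS of `adj_p` on the 0/1 detection indicator
  (detection = count > 0 in the raw table, not a post-normalization
  epsilon). The slope equals the detected-minus-undetected mean
  difference; the p-value is the slope's two-sided t-test, identical to
  the pooled-variance two-sample t. Undefined unless both classes have
  ≥ 2 samples.
* **Quantitative part.** OLS of `adj_p` on abundance among detected
  samples only. Abundances are log₁₀-transformed (configurable: `rank`
  or `identity`) and z-scored, so β₂ is in phenotype units per SD of log
  abundance. The log transform addresses the right tail; rank is the
  robust alternative. Undefined below 3 detected samples or at zero
  variance.
* **Meta part.** Unweighted Z: `Z = Σ zᵢ/√k`, computed only when both
  parts are defined. The default conversion is the *signed* two-sided
  one, `zᵢ = sign(βᵢ)·Φ⁻¹(1 − Pᵢ/2)`, so concordant effects reinforce and
  discordant effects cancel; the sign-blind literal conversion
  `zᵢ = Φ⁻¹(Pᵢ)` is available behind `signed=False` for audit, but it
  rewards discordant effects and is not recommended.

The final statistic is `p_final = min(p_binary, p_quant, p_meta)` over
defined parts. This minimum is anti-conservative under the null (the
three tests are dependent but not identical), which is why significance
is never read from `p_final` directly.

### Permutation FDR

`adj_p` is permuted across samples B times (seeded) and the full scan is
recomputed per permutation. For a threshold t,

    FDR(t) = mean_b #{permuted p_final ≤ t} / max(1, #{observed p_final ≤ t})

and a taxon's `q_perm` is the minimum estimated FDR over thresholds at or
above its own `p_final`, clipped to [0, 1] and made monotone. This is the
standard pooled-exceedance permutation-FDR construction. B ≥ 100 is
enforced (the estimate is too coarse below); the production default is
B = 1000 with the significance threshold FDR < 0.01. Permuting the
phenotype preserves the full dependence structure among taxa, so the
calibration is valid despite the min-P statistic.

## Enterotyping

Genus-level profiles are compared by the square root of the
Jensen–Shannon divergence (natural log), computed via the entropy
identity `JSD(x,y) = H((x+y)/2) − (H(x)+H(y))/2`; the square root is a
metric on the simplex and finite with zeros (no pseudocounts needed).
Raw-JSD mode exists for comparison with older workflows.

Clustering is classic PAM: greedy BUILD followed by best-improvement
SWAP until no exchange lowers the total medoid-distance cost. Ties break
toward the lowest index, making results order-stable; the algorithm is
deterministic. k is selected over 2–10 by the Calinski–Harabasz index
computed purely from the distance matrix through the Huygens/Gower
identity (W = Σ_clusters (1/n_c)Σ_{i<j∈c} d²; B = T − W), with the mean
silhouette reported as a robustness diagnostic, not a selection
criterion. Perfect-duplicate clusterings give W = 0 and CH = +inf. Each
cluster is labelled by the genus with the highest mean relative
abundance (lexicographic tie-break with warning).

## SparCC and co-abundance groups

SparCC estimates correlations of the unobserved *basis* (absolute)
abundances from the log-ratio variances `t_ij = var log(x_i/x_j)`, which
are invariant to the compositional closure. Under the sparsity
assumption, basis variances solve the linear system with matrix
`(D−2)I + 11ᵀ`, and `ρ_ij = (ω_i + ω_j − t_ij)/(2√(ω_iω_j))`, clipped to
[−1, 1]. Strongly correlated pairs violate sparsity, so the strongest
pair above the exclusion threshold (default 0.1) is iteratively removed
from the system and the variances re-solved, up to 10 rounds. Counting
noise is integrated out by resampling fractions from a per-sample
Dirichlet posterior with uniform prior (counts + 1), default 20
resamples, aggregated by the entrywise median (robust to occasional
negative-variance draws). Exact mode (`n_resamples=0`, zero-free tables)
uses observed fractions and is exactly scale-invariant. Non-positive
basis variances flag a taxon; its correlations are reported NaN. The
system needs D > 3 taxa.

CAGs are Ward-linkage clusters of the dissimilarity `d = (1−ρ)/2`
(mapping [−1, 1] to [0, 1]; `1−ρ` is exposed as an alternative). The cut
count is a user parameter; a scan mode reports the PERMANOVA pseudo-F and
p for each candidate cut and selects the smallest count whose grouping is
significant at the chosen α — one defensible reading of validating a CAG
count by PERMANOVA; thresholds 0.01 and 0.005 both appear in practice
and α is therefore a parameter, not a constant. Note that a group of
mutually *negatively* correlated taxa (a co-exclusion group) is not
compact in this dissimilarity — its members are farther from each other
(0.75) than from unrelated taxa (0.5) — so such planted structure is
recoverable only as "not belonging to any positive block".

PERMANOVA uses the distance-based sums of squares
`SS_total = (1/n)Σ_{i<j} d²`, `SS_within = Σ_g (1/n_g)Σ_{i<j∈g} d²`,
pseudo-F with (g−1, n−g) degrees of freedom, and the add-one permutation
estimator `p = (1 + #{F_perm ≥ F_obs})/(1 + n_perm)`, so the smallest
attainable p at 999 permutations is 0.001. Group labels are permuted;
groups of size 1 are rejected.

CAG abundance is the per-sample sum of member relative abundances (mass
conserving); CAG–phenotype association is Spearman with tie correction,
BH-adjusted across CAGs.

## Networks

Edges come from either the magnitude threshold `|ρ| > τ` (default 0.5)
or the PCIT triad filter: for every triad the three first-order partial
correlations are computed, the average ratio ε of partial to marginal
forms the tolerance, and an edge is dropped when some third node
dominates it on both legs. Zero correlations are excluded before triad
evaluation; |r| = 1 is clamped for the partials. Both rules are exposed
because practice varies in whether thresholded SparCC edges, PCIT
survivors, or both define the drawn network.

Topology metrics are computed on the unweighted graph, per connected
component: betweenness normalized by (n_c−1)(n_c−2)/2, closeness
(n_c−1)/Σd, eccentricity as the max within-component distance (isolated
nodes: closeness and eccentricity 0), plus graph-level mean degree, mean
eccentricity and Freeman degree centralization
`Σ(deg_max − deg_v)/((n−1)(n−2))`. Hubs are ranked by the mean of
min–max-normalized degree, betweenness and closeness — an explicit
package convention, since the combination rule behind "hub taxa" is
rarely stated; ties break by raw degree then id.

## Synthetic cohorts

The generator emulates the data a 16S study of a few hundred pigs would
produce. Basis abundances are log-normal: a Gaussian copula on the log
scale carries a block-structured correlation matrix (assembled from the
configured blocks, projected to the nearest PSD correlation matrix by
eigenvalue clipping and re-normalization, with the Frobenius repair
distance reported). Per-taxon baseline log-means are N(0, 1.5²) by
default, creating realistic abundance heterogeneity; enterotype
components multiply their dominant taxa by a fold change, and dominant
taxa are pinned to the abundant tail of the baseline distribution
(enterotype drivers are common genera, and a dominance fold applied to a
rare taxon would not dominate anything). Compositions are closed,
counts drawn multinomially at fixed depth, and a per-taxon dropout
probability is applied post-multinomially (detection failure independent
of composition). The phenotype is the additive model the two-part scan
assumes: intercept + sex + batch + Σ β₁·presence + β₂·z(log₁₀ abundance
among detected) + Gaussian noise, and backfat/loin-area measurements are
reported so the grading formula reproduces the simulated LMP exactly.
Everything is deterministic given the seed.

The default reference cohort is 300 samples × 120 taxa at depth 20,000
with two enterotype components (60/40, fold 15), three correlation
blocks (ρ = 0.7, 0.7, −0.5) and five effect taxa; 5% dropout.

What the generator does **not** model: sequencing error and chimeras,
phylogenetic signal, batch effects on the *microbiome* (only on the
phenotype), overdispersion beyond the log-normal-multinomial hierarchy,
and taxon-taxon interactions beyond pairwise correlation. Passing
recovery tests on this generator shows the estimators are correct under
their own assumptions — log-normal compositional data is exactly
SparCC's generative model, so these are fair but friendly conditions —
not that real cohorts will behave as cleanly.

## Validation experiment sizes and numerical choices

* Null calibration: 200 cohorts of 300 samples × 50 taxa at depth
  10,000 with 30% dropout (so both detection classes are populated);
  KS uniformity and type-I error per part.
* FDR control: 100 null cohorts at B = 200; power: five planted β₁ = 2
  effects at n = 400, residual sd 0.5, B = 200. Production analyses
  should use B = 1000.
* SparCC recovery: n = 500, D = 30, depth 20,000, within-taxon log-sd 1
  and baseline log-mean sd 1 (comparable basis variances — the
  estimator-validation condition). The maximum of ~435 null correlation
  estimates at n = 500 fluctuates around 0.14, so the null level is
  judged on the mean of that maximum over five replicate cohorts rather
  than a single draw.
* Enterotype recovery: 150 samples, two components at fold 50 (high
  separation), expecting exact label recovery; the default-fixture fold
  of 15 gives the partial overlap (ARI ≈ 0.85) a real cohort would show.
* p-values at exactly 0 or 1 are clamped to [1e−300, 1−1e−16] before
  normal quantiles; OLS p-values with zero residual variance are
  reported as 0 (perfect fit); eigenvalues below 0 are clipped in the
  PSD repair; Ward and PAM are deterministic with lowest-index
  tie-breaks.

## Known limitations

* The quantitative part assumes a linear effect of log abundance among
  carriers; saturating or threshold effects will be attenuated.
* The permutation FDR pools exceedances across taxa; taxa with very
  different null distributions of `p_final` (extreme detection
  imbalance) are calibrated jointly, not per taxon.
* The CAG scan's "smallest significant cut" rule is one defensible
  convention; with strong structure many cuts are significant and the
  rule returns the coarsest.
* PCIT's triad test is a heuristic filter, not an inference procedure;
  it has no error-rate guarantee.
* SparCC assumes most pairs are uncorrelated; dense correlation
  structure biases the basis-variance solution even with exclusion.
* Zeros are SparCC's hard case: a dropout zero on an otherwise abundant
  taxon becomes an extreme log-fraction outlier under the Dirichlet
  posterior and inflates the log-ratio variances, attenuating estimated
  correlations well below their basis values (at 10% dropout a planted
  0.7 can shrink to ~0.3). The abundance filter before CAG construction
  mitigates but does not remove this; correlation-recovery claims hold
  for low-dropout data.
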