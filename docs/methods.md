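# Methods

This note documents the statistical models, the synthetic-data generator,
and the numerical decisions behind `codami`, in the spirit of a package
vignette: what each stage assumes, which knobs matter, and what the test
suite does and does not demonstrate about real data.

## Compositional primitives

All log-ratio work uses the centered log-ratio (CLR),
`clr(x)_i = ln(x_i / g(x))` with `g` the geometric mean over **all** parts
of the row; no sub-composition re-centering and no isometric log-ratio
basis is used anywhere. Zeros are handled by multiplicative replacement:
zeros become δ and the non-zero parts of a row with z zeros are rescaled by
(1 − z·δ), so closure is preserved exactly. The default
δ = 0.5 × (smallest observed non-zero proportion) is conventional and
configurable. Aitchison distance is the Euclidean distance between CLR
vectors, giving perturbation invariance on the simplex.

Gated cytometry tables go through the three-step USS transform: unzero
(multiplicative replacement within each sibling block), stabilize (CLR
within each sibling block — for a two-child gate the two CLR columns are
exact negatives, so the redundant complement column is dropped), and
standardize (columnwise z-score; constant columns are dropped with a
warning). The stabilization step could in principle be a logit rather than
a blockwise CLR; CLR was chosen because it generalizes identically to
blocks of any size and reduces to half the logit for two children.
Variance-sensitive association measures (proportionality) consume the
transform stopped after step 2, since z-scoring would distort the
variance ratios that ρ is built from.

## Synthetic-data generator

The generator emulates a postnatal co-development study: four ordered
timepoints (labels P7, P14, P24, 8W at ages 7/14/24/56 days), two sexes,
six replicates per sex per timepoint (so 12 animals per timepoint enter
each regression, matching the design it imitates).

**Microbiome.** 48 taxa by default (28 in named successional families, 20
flat commensals), each with a baseline log abundance drawn N(0, 1).
Expected log abundance follows Gaussian bumps over age ("waves"):
Lactobacillaceae and Streptococcaceae peak at day 7, Bacteroidaceae at day
14, Muribaculaceae plateaus post-weaning (peak 56, width 28). Counts are
Dirichlet-multinomial: composition = softmax(log abundances), one
concentration parameter per timepoint (default 30 at P7, 150 later — the
first timepoint is noisier), depth Poisson around 20k reads at P7 and 50k
later. Dirichlet-multinomial was preferred over a log-normal-Poisson
because overdispersion is then a single interpretable parameter per
timepoint.

**Cytometry.** A depth-4 gating tree (CD45 → CD3⁺CD19⁻/CD3⁻CD19⁺ →
CD4/CD8 quadrant → FoxP3/RORγT functional quadrant). Per internal node,
child fractions are Dirichlet with mean = softmax(log baseline +
per-timepoint logit offsets) and a fixed precision (40–70); planted trends
mirror the qualitative biology (T-cell fraction and CD8⁺ share rising
post-weaning, RORγT⁺ helpers appearing at weaning).

**Coupling.** Latent per-sample standard Gaussians are added, scaled by a
loading, to a taxon's log abundance and/or to a gated child's logit before
sampling. Injecting the signal on the log/logit scale *before* sampling
means it survives the CLR transform, so recovery is well-defined. The
taxon side receives the signed loading and the cell side its magnitude, so
negative loadings plant anti-coupled pairs. Couplings sharing a factor
name form modules.

**What the generator does not emulate:** taxonomic misclassification,
litter/cage random effects (pre-weaning littermate pooling is treated as a
single sample, as in the design it imitates), batch effects and spillover
in cytometry, and zero inflation beyond what the Dirichlet-multinomial
produces. Passing tests therefore demonstrate correctness of the
statistics under a clean compositional model, not robustness to those
artifacts.

**Named scenario configurations.**

- `null_config` — the exchangeable null for type-I calibration: wave
  amplitudes zero **and** equal depth/dispersion across timepoints. The
  second part matters: for Dirichlet-multinomial data
  E[log q_i] = ψ(c·p_i) − ψ(c), which is non-linear in the concentration
  c, so groups with different dispersion differ in transformed-scale means
  even at zero amplitude — a genuine difference, not a type-I error
  setting.
- `spike_in_config` — one +2 log2 step planted between P14 and P24 on an
  otherwise-null background, with the planted taxon pinned at baseline log
  abundance 1.5 (a few percent mean share, an established community
  member). Detection of fold changes on much rarer taxa (< 0.5 % share) is
  limited by per-sample Dirichlet noise of several log2 units, which no
  estimator can remove; empirically, consensus differential-abundance hits
  in data of this kind are dominant community members.
- `coupled_config` / `demo_config` — five microbe–immune couplings at
  loading 1.5 anchored on populous gates (a factor loaded on a 4 % gate is
  mostly swallowed by the gate's own sampling noise), optionally plus two
  disjoint five-taxon modules and the full wave/trend structure.

## Retain–resolve and diversity

Round 1 keeps taxa with prevalence ≥ 10 % of samples **and** mean relative
abundance ≥ 0.01 % (both configurable; the method's published uses do not
fix numeric thresholds, so these defaults aim at the qualitative behavior:
a small retained set and a large agglomerated remainder). The remainder is
agglomerated to genus, re-filtered, and failures merge into one `other`
row; per-sample totals are conserved exactly and an audit trail records
every taxon's assignment. Alpha diversity offers Shannon, inverse Simpson
and observed richness, plus a Chao1 estimate as a simple nonparametric
stand-in for model-based richness estimation. PERMANOVA uses the standard
within/between partition of squared distances, free permutation of labels,
p = (1 + #{F* ≥ F}) / (B + 1), and runs pairwise contrasts only when the
omnibus p < 0.01 (BH-adjusted).

## Consensus differential abundance

Both models regress a log-scale response on
[intercept | orthonormal age-polynomial contrasts (degree 3, built by
Gram–Schmidt on the true ages 7/14/24/56, hence "weighted" by the actual
spacing) | centered sex]. Model A's response is the CLR of the closed
counts (zero-replaced on the proportion scale, which makes the model
*exactly* invariant to per-sample count scaling); its compositional bias
correction subtracts the across-taxa mode of each coefficient, estimated
by the half-sample-midpoint rule (deterministic, robust). Model B's
response is log(count + 1) minus per-sample offsets estimated by
alternating taxon-wise fits with median-residual updates; the
design-spanned component of the offsets is unidentifiable (it is absorbed
by the saturated timepoint design), so offsets are residualized against
the design each iteration and the residual shared shift is removed by
median coefficient centering — the two halves of the sampling-fraction
correction. Iteration stops when offsets change by < 1e−6 (cap 50).

Wald tests use HC3 (leverage-adjusted) heteroscedasticity-robust
covariances because the study conditions genuinely put more dispersion at
the first timepoint; adjacent-interval contrasts are linear maps of the
polynomial coefficients, reported in log2 units, BH-corrected within each
(model, interval) family. The consensus set intersects the two models'
significant taxa at q < 0.01 and |effect| > 1 per interval. Measured under
the exchangeable null: type-I ≈ 0.04–0.06 for both models at α = 0.05.

## Nested cytometry testing

Each internal gating node is a small composition. Two siblings → beta
regression; three or more → Dirichlet regression in the alternative
parameterization (means via multinomial logit with the first component as
reference, scalar precision φ via log link, concentrations α_c = μ_c φ).
Fitting is L-BFGS-B on the exact likelihood with analytic gradients,
convergence tolerance 1e−8, up to five random restarts; variance matrices
come from finite differences of the analytic gradient. Boundary
proportions are shrunk by (y(n−1) + 1/k)/n, the k-component extension of
the standard beta-regression adjustment (it preserves row sums and reduces
to (y(n−1)+0.5)/n at k = 2).

Because a Dirichlet block assumes negative dependence among siblings,
nodes whose components are significantly *positively* correlated
(one-sided Pearson tests, Bonferroni across the C(k,2) pairs so the
familywise spurious-split rate stays at α = 0.05) are split into the
positively correlated set versus the remainder and tested as a two-level
sub-tree on renormalized fractions.

The global test fits, per block, a common-mean null against a full model
with the age-polynomial contrasts in the mean (precision intercept-only in
both); Λ_overall sums the per-block LRTs, df sums the per-block
(k−1)·q. With ~13 parameters per quadrant node and a few dozen samples the
plain χ²(df) reference is anticonservative (measured type-I 0.08–0.09), so
the p-value is read from a Satterthwaite-scaled χ² whose scale and df are
matched to the mean and variance of Λ over 40 parametric-bootstrap
datasets drawn from the fitted per-block nulls. Measured type-I 0.06 at
α = 0.05 with uniform null p-values (KS p ≈ 0.5); `n_bartlett=0` restores
the uncorrected reference. Follow-up tests regress each component with
beta regression on timepoint and report reverse-difference
(sequential-interval) Wald contrasts, BH-corrected within tissue; they are
gated on a significant global test by default (configurable).

## Integration and networks

The Mantel test correlates the off-diagonal entries of two distance
matrices (Aitchison for the microbiome, Euclidean on USS-transformed
cytometry) with a one-sided permutation p-value; with strata given (sex),
labels permute only within strata — the within-block-permutation reading
of a covariate-stratified ("partial") Mantel test, which is what
stratified permutation actually delivers.

Proportionality ρ(i,j) = 1 − var(clrᵢ − clrⱼ)/(var clrᵢ + var clrⱼ) is
computed on the column-concatenation of the *separately* CLR-transformed
datasets. Only positive ρ is thresholded (default 0.45): reciprocal
proportionality is not robust to the reference choice. The FDR attached to
a cutoff is estimated by permutation — every feature column independently
row-shuffled, which preserves marginals while breaking all cross-feature
association — as mean permuted exceedances over observed exceedances,
clipped to [0, 1]. The signed network uses Spearman correlations on the
same CLR data (t-approximation p-values, BH across all pairs, |r| > 0.6
and q < 0.01), with a bootstrap support fraction per edge and an automated
leave-one-out influence screen (an edge must stay above threshold under
every single-sample deletion) replacing manual scatter-plot triage.

## Null-model validation

Erdős–Rényi G(n, m) graphs are sampled uniformly (m distinct pairs chosen
without replacement) and matched on the observed node and edge count.
Metric conventions are chosen to be mutually consistent: APL averages BFS
path lengths over *connected ordered pairs*; betweenness is unnormalized,
per node, with each unordered pair counted once, which makes
mean betweenness = (n−1)(APL−1)/2 an exact identity on connected graphs
(asserted to 1e−9 in the tests and used as an ensemble cross-check);
ACC averages local clustering with degree-<2 nodes contributing 0;
modularity is Louvain at resolution 1 with a fixed seed and is therefore
algorithm-dependent. Z-tests compare each observed metric with the null
ensemble's mean and standard deviation.

Correlation matrices convert to dissimilarities as d = √(2(1−r)) — the
cor2dist convention, Euclidean for a proper correlation matrix; the
squared form 2(1−r) is available behind a flag. Ward linkage then builds a
dendrogram, and k is chosen as the smallest number of clusters whose
by-cluster matrix (block means; within-cluster blocks average off-diagonal
entries only) correlates at least 0.85 with the observed matrix over the
off-diagonal; if no k qualifies, k_max is returned flagged.

## Problem sizes used by the test and acceptance suites

Calibration suites use 200–250 replicates per test at the study's sample
sizes (24–48 samples); null-ensemble targets use 1000 random graphs;
recovery suites use 20–50 replicates. These sizes keep the full suite
around four minutes while leaving Monte-Carlo error well inside the
asserted margins. All simulations are seeded; reruns are bit-identical.

## Known limitations

- The nested-test small-sample correction calibrates the *global* test;
  per-block p-values in the subtree table keep the plain χ² reference and
  remain slightly anticonservative at these sample sizes.
- Model B's log(count+1) response is not exactly scale-invariant for
  low-count taxa (the pseudocount breaks the log identity near zero);
  model A is exact, which is one reason the two-model consensus is used.
- Consensus differential abundance has abundance-dependent power: 4-fold
  changes on taxa below ~0.5 % mean share are usually undetectable at
  these depths and replicate counts.
- Proportionality attenuates when the two features' CLR variances differ
  strongly (it is bounded by the variance ratio), so couplings to very
  small gated populations are systematically harder to recover.
- No mixed models: littermate pooling, cage and batch effects are outside
  the model family.
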