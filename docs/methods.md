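# Methods

## Phenotype and group selection

The oxidative stress index is OSI = TOS / T-AOC after converting both
assay concentrations to a common scale (TOS arrives in uM, T-AOC in mM;
both are harmonized to uM before division).  T-AOC must be strictly
positive — a non-positive antioxidant capacity is an invalid assay value
and raises rather than propagating an infinite ratio.

High/low oxidative-stress groups (HOS/LOS, default k = 9 per group) are
the OSI extremes, adjusted for covariate balance: starting from the k
lowest and k highest OSI animals, the selector greedily swaps a selected
animal for a next-ranked unused candidate (considering a window of 10
candidates per tail) whenever any matching covariate — milk yield,
parity, body condition score by default — differs between groups at
p ≤ 0.10 by pooled-variance t test, keeping the swap that most improves
the worst covariate p-value.  The procedure is deterministic, invariant
to sample order, and raises with the best attempt when no balanced
assignment exists.  Two-group phenotype comparisons use Student's t test
(pooled variance); three or more groups use one-way ANOVA with
unadjusted pairwise t tests as the post-hoc report.  Significance bands:
P ≤ 0.05 significant, 0.05 < P ≤ 0.10 a trend.

## Relationship matrix and microbiability

The microbial relationship matrix is M = ZZᵀ/N over the filtered genus
table, where each taxon column of Z is centered and divided by its
population (divide-by-n) standard deviation; zero-variance taxa are
dropped (with a warning) and excluded from N.  The population-variance
convention makes trace(M) = n and the mean diagonal 1, so the variance
ratio is directly interpretable; the divisor is otherwise a free choice,
and this one matches common microbial/genomic relationship-matrix
practice.  M is symmetric, positive semidefinite, has zero row sums (it
is singular by construction), and is invariant to rescaling any taxon.

The variance-component model y = Xc + m + e with cov(m) = σ²ₘM is fitted
by restricted maximum likelihood.  Implementation: eigendecompose
M = U D Uᵀ once; rotate ỹ = Uᵀy, X̃ = UᵀX; for a variance ratio
λ = σ²ₘ/σ²ₑ the covariance is diagonal (weights 1 + λdᵢ), the GLS fixed
effects and σ̂²ₑ = RSS_w/(n − p) are closed-form, and the profile REML
criterion is

    ℓ(λ) = −½[(n−p)·ln(2π σ̂²ₑ) + Σ ln(1+λdᵢ) + ln det(X̃ᵀW⁻¹X̃) + (n−p)]

maximized over ln λ ∈ [ln 1e−6, ln 1e6]: a 201-point log-spaced grid
brackets the optimum, then bounded scalar minimization refines it to a
tolerance of 1e−8 on ln λ.  Solutions at either bound carry a
`boundary` flag (lower bound: no detectable microbial variance).  A
response lying exactly in the fixed-effect column space is detected up
front and returned as a degenerate fit (both variances zero) rather than
sent to the optimizer.  Microbiability is reported as
σ²ₘ/(σ²ₘ + σ²ₑ) — the model-based phenotypic variance convention, chosen
because the sample variance of y mixes in fixed-effect variation; the
convention is echoed in every fit report and run manifest so results can
be restated under the other convention if desired.  Covariates default
to parity (numeric) and milk yield; factor coding can be supplied by
passing dummy columns.  No standard error is attached to the point
estimate by default; a seeded parametric bootstrap
(`bootstrap_microbiability`) is available.

## Abundance filtering

Counts are converted to relative abundances per sample (all-zero samples
are errors).  The prevalence filter retains taxa whose relative
abundance is strictly greater than 0.01% in strictly more than 50% of
samples — both boundaries read as strict inequalities from the rule's
wording — and returns the removal list.  Filtered tables are **not**
re-closed: every downstream consumer standardizes taxa independently, so
re-closure would silently change results.  The filter is idempotent and
order-independent.

## Differential features

Taxa: a Kruskal–Wallis screen with tie correction, then a bootstrapped
LDA effect size; a taxon is significant iff P < 0.05 AND LDA score > 2.
At small sample sizes the screen's p-values are exact, computed by
enumerating all multiset assignments of the pooled ranks to the observed
group sizes (cached per rank multiset; used whenever the assignment
count is ≤ 200,000, which covers the 9 + 9 design's 48,620); larger
designs use the chi-square approximation.  The LDA score follows the
LEfSe recipe: rows rescaled to per-million of sample total; 30 bootstrap
rounds, each drawing a stratified two-thirds subsample without
replacement and fitting a shrinkage-regularized linear discriminant
(lsqr solver, Ledoit–Wolf shrinkage — stable when features outnumber
samples); per-feature effect 0.5·(|w_f·d| + |Δ_f|) with w_f the
discriminant coefficient, d the projected class-mean difference, Δ_f the
raw class-mean difference; score = log10(1 + mean effect).  The formula
is fixed and seeded so scores are bit-reproducible; no claim of
numerical identity to any external implementation is made, only that
the score-2 threshold operates on the conventional per-million scale.
There is no subclass stage (the design has none).

Metabolites and pathway/KO abundances: two-sided Wilcoxon rank-sum,
exact for tie-free groups of ≤ 25, normal approximation with tie and
continuity corrections otherwise; significant at raw P < 0.05.  Fold
changes are HOS/LOS; on log-transformed tables the fold change is
exp(mean log difference) — the geometric-mean ratio on the original
scale — since an arithmetic ratio of logs is meaningless.  On raw tables
with a non-positive group mean, a flagged pseudo-count ratio (offset =
half the smallest positive intensity) is reported.  Benjamini–Hochberg
columns are always emitted for transparency, but the significance flags
follow the raw-p conventions above.

## Metabolome processing

"Detected" means non-missing and > 0 (no detection floor is defined
upstream).  The QC filter removes features detected in fewer than half
the QC injections, then features whose QC relative standard deviation
(population SD / mean over detected values) strictly exceeds 30% (with a
1e−12 round-off guard so a feature at exactly 30% is retained).  PQN
divides each biological sample by the median over features of its ratio
to the reference profile — the feature-wise median of the QC samples
(median of all samples if none) — which removes per-sample dilution
exactly in the noiseless case; features with a non-positive reference
are excluded from the quotient and logged.  Intensities are then
natural-log transformed with offset = half the minimum positive value,
recorded in the result.  State transitions are enforced
(raw → pqn → pqn+log).

Origins partition features into host, microbiota, cometabolism and
others (= drug + food + environment + unknown; unannotated features are
unknown); counts always sum to the feature total.  Enrichment runs per
origin category: with N category features, K in the pathway and n
differential, the p-value is the hypergeometric tail P(X ≥ k); k = 0
gives p = 1 identically, and a saturated differential set (n = N) makes
every pathway p = 1.

## Networks

Within each group, all pairwise Spearman correlations are computed
(tie-corrected t-approximation p-values), BH-adjusted across pairs, and
edges retained at adjusted p < 0.05 AND |rho| > 0.70.  Constant taxa are
excluded from pairing.  A shared edge between two networks requires the
same unordered pair AND the same correlation sign — an edge flipping
sign between groups is a difference, not a similarity.  Closeness is
harmonic (mean of inverse shortest-path distances), which is
well-defined on the disconnected graphs co-occurrence analysis
routinely produces; eigenvector centrality is computed on each
network's largest connected component via a dense symmetric
eigendecomposition (sparse iterative solvers fail on the few-node
components these graphs typically have).  Feature-phenotype Spearman
panels use exact permutation p-values for n ≤ 8 (all n! orderings,
cached per rank multiset) and the t-approximation above, with
significance stars at 0.05 / 0.01 / 0.001.

## Synthetic-data generator

The generator emulates the study's inputs with recorded ground truth.

* **Abundances**: logistic-normal — latent per-taxon log-abundances
  μₐ + 0.6·zₐ with z from a one-factor-per-block model giving requested
  within-block correlations, then closure.  μₐ is log-uniform over
  [1e−5, 5e−2], so marginal abundances span over three orders of
  magnitude and the 0.01% filter has real work to do.  The latent log-SD
  of 0.6 (geometric SD ≈ 1.8) is a realistic within-taxon dispersion for
  genus tables and makes a planted 4-fold shift reliably detectable at
  n = 9 + 9, which is the regime the differential stage is meant to
  exercise.  A logistic-normal (rather than Dirichlet) model was chosen
  because it supports controllable correlation blocks for the network
  stage.
* **Phenotypes**: drawn from exactly the model the estimator assumes —
  OSI = mean + covariate effects + m + e with cov(m) = σ²ₘM built from
  the generated abundances, σ²ₘ = m²·total_variance (defaults: mean
  0.66, total variance 0.09, true m² 0.431 — the study's operating
  point).  Covariates mirror the cohort (milk yield 36.9 ± 8.04 kg/d;
  parity integer 1–5 around 2.75 ± 0.94; BCS 2.75 ± 0.35) and enter
  with small slopes (0.02 per parity, 0.005 per kg/d).  The OSI draw is
  not clipped (clipping would bias variance-component recovery); instead
  TOS is left missing on the rare non-positive draws so concentration
  invariants hold.
* **Two-group study**: the k lowest/highest OSI animals are the planned
  LOS/HOS groups, so one group's OSI stochastically dominates the
  other's by construction.  Planted taxon folds (defaults 4, 4, 2, 0.5,
  0.25, 0.25) multiply the taxon in every above-median-OSI animal before
  re-closure — differential taxa track oxidative-stress *state*, so any
  extreme HOS selection carries the full effect regardless of matching
  swaps.  Default planted taxa attach to mid-abundance taxa outside the
  correlation blocks (observable genera that survive the filter, keeping
  differential and network signals separable).  Planted metabolite log2
  fold changes (defaults ±0.36…±1.2) shift the HOS samples' base
  profiles; the annotation assigns origin categories at fecal-metabolome
  proportions and collects the planted metabolites into one pathway
  ("pw_glutathione", emulating the amino-acid/glutathione cluster) for
  the enrichment stage.
* **Metabolome**: sample = base profile × dilution × multiplicative
  lognormal noise (CV 0.15); QC injections = base × noise at the chosen
  QC RSD (0.10); dilution factors log-uniform in [0.5, 2]; 5% of
  features blanked in > 50% of QC injections to exercise the presence
  filter.
* One global seed is split into fixed per-stage substreams so stages can
  be regenerated independently; identical seeds give bit-identical
  outputs.

What the generator does **not** emulate: sequencing depth and count
noise (abundances are exact compositions), taxonomic misassignment,
zero inflation beyond what closure induces, batch/run-order drift in
the metabolome, and real biochemical pathway structure.  Passing tests
therefore demonstrate estimator correctness and calibration under the
stated generative model, not robustness to those artifacts.

## Problem sizes and numerical choices

Recovery simulations use n = 400 cows × 150 genera × 20 seeds per true
value {0, 0.2, 0.431, 0.6} — large enough that the mean-recovery band
(±0.05) reflects estimator bias rather than sampling noise, while a full
sweep runs in seconds.  At the cohort size (n = 63) a single
microbiability estimate has an SD of roughly 0.15 and should be read
accordingly; the analysis scripts print the generator truth next to the
estimate for this reason.  Under the null (m² = 0), REML puts roughly
90% of estimates at ≤ 0.05 (about half exactly at the boundary), the
standard behavior of a variance ratio estimated at the edge of its
parameter space.  The end-to-end round trip uses the 400-cow design
with a single-replicate tolerance of ±0.15.

Other numerics: the REML grid/refinement tolerances above; exact-test
enumeration limits (≤ 200,000 assignments for Kruskal–Wallis, n ≤ 8 for
Spearman permutations, ≤ 25 per group for exact Wilcoxon); BH via the
standard step-up; hypergeometric tails via the survival function;
degenerate inputs (constant features, identical groups, zero-variance
taxa) resolve to p = 1 / exclusion with flags rather than NaNs.

## Known limitations

Single microbial kernel only (no joint host-genetics + microbiome
model); no Bayesian variance components; no compositionality-aware
correlation (SparCC-style) — networks are plain Spearman as specified;
LDA effect sizes are reproducible but implementation-defined, so scores
from other LEfSe implementations will differ in value (the threshold
semantics match); covariate matching is a greedy heuristic and can fail
on strongly confounded cohorts (it then reports its best attempt);
pathway enrichment treats pathways as flat feature sets.
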