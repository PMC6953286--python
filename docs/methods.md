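# Methods

## Scope and model

`cohortsig` implements an unsupervised multi-stage analysis of a samples ×
features table in which every feature carries exactly one modality label
and missingness is allowed both entry-wise and as whole-modality blocks.
The working assumptions are those of the underlying statistics: after
rank-inverse-normal transformation (INT) and covariate correction,
features are approximately Gaussian; associations of interest are
monotone (hence Spearman); the conditional-independence structure of a
module's central features is well described by a sparse Gaussian
graphical model; and individuals' biomarker profiles are comparable under
the correlation distance, i.e. the *shape* of a signature matters, not
its per-individual offset or scale.

## Pre-processing

- **INT convention.** Blom offset c = 3/8: Φ⁻¹((r − 3/8)/(n + 1/4)) with
  average ranks for ties. The transform requires ≥ 3 non-missing values
  and a non-constant vector; missing entries stay missing.
- **When INT applies.** Always for abundance modalities (default:
  `microbiome`), otherwise when the modal value occupies strictly more
  than 40% of non-missing samples. The boundary is strict: exactly 40%
  does not trigger the transform.
- **Covariate correction.** Six covariates (age, sex, PC1–PC4), complete
  covariates required. Per feature: a joint OLS fit on all six over
  complete cases; covariates with coefficient p < α (default 0.01) are
  selected; the feature is replaced by residuals of a *refit* on the
  selected covariates only. The two-stage refit avoids leaving
  non-significant covariate structure in the stored coefficients. The
  p-values come from the joint fit rather than marginal fits — the joint
  fit is what "significantly associated among the six" means here; a
  marginal variant would double-count shared covariate variance.
- **Validation reuse.** The stored intercept+coefficients are subtracted
  from the validation data without refitting. INT, being rank-based, is
  recomputed within the validation cohort when flagged.
- **Degenerate features.** A constant feature is an error by default
  (`on_degenerate="raise"`); the pipeline driver uses `"drop"`, which
  skips the feature with a warning and records the skip in the model.
- **Microbiome summaries.** Species richness counts abundances strictly
  above 10⁻⁴; Shannon diversity is −Σ p ln p in nats over renormalized
  positive abundances.

## Association network

Spearman ρ on pairwise-complete observations (re-ranked per pair when
missingness intersects the pair; a vectorized single-ranking path is used
when the whole matrix is complete, where both paths agree to 1e-12).
Two-sided p from the t approximation t = ρ√((n−2)/(1−ρ²)); an exact
permutation p would be infeasible at the pair counts involved and the t
approximation is accurate for n ≥ 30, which is also the minimum
complete-pair count for a pair to be tested. One global BH family at
q = 0.05 over all computed cross-modality pairs. Edge weight is −ln p
(natural log; only relative weights matter to modularity), with p floored
at 1e-300 to keep weights finite. Within-modality pairs are never tested.
Metabolome–clinical-lab edges are retained in the network structure but
flagged `excluded` and removed before community detection, so that two
platforms measuring near-identical analytes do not dominate the module
structure.

## Consensus modules

Louvain (networkx implementation, seeded) on the detection graph.
Repeat runs use seeds 1..n_runs (default 300); the consensus matrix
counts co-assignments; the consensus partition is the maximum-modularity
run with ties broken toward the lowest seed — a deterministic and
reproducible choice among the natural options (first run, re-clustered
consensus). Module ids are renumbered by decreasing size. Modularity is
the weighted Newman form Q = Σ_c [W_c/W − (S_c/2W)²].

Multi-membership: a node with ≥ margin (default 20) more unweighted
significant-edge neighbours in another module than in its own joins that
module as well; counting uses the same detection edge set (excluded edges
are not counted) because the rule operates during module identification.
The per-module consistency score is the mean pairwise co-assignment
frequency of the module's features, in [0, 1].

## Markov network and key biomarkers

Eigenvector centrality by shifted power iteration ((A + I)v, tolerance
1e-10) on the module subgraph with −ln p weights; on disconnected input
only the largest component is scored (others 0) — consensus modules are
near-connected by construction, and a per-component normalization is not
meaningful when components differ in size. Scores are max-normalized;
ties break by feature id.

The top-k central features (k configurable; pipeline default 40, clamped
to the module size) are mean-imputed *then* INT-transformed — in that
order, so the imputed value is the pre-transform mean and the transform
sees one tie block at it. The imputation fraction is reported.

Graphical Lasso minimizes −log det Θ + tr(SΘ) + λΣ_{i≠j}|Θ_ij| over
positive-definite Θ, with S the 1/n empirical covariance of the
standardized columns (sklearn solver). λ = 0 returns S⁻¹ directly. λ is
chosen by extended BIC (γ = 0.5) over a 15-point log grid from
max|offdiag S| down two decades; the scan stops after three consecutive
EBIC deteriorations because the path is effectively unimodal and the
smallest-λ fits are the slowest. Edges are off-diagonal entries with
|Θ_ij| > 1e-8 (numerical-zero threshold), annotated with the partial
correlation −Θ_ij/√(Θ_ii Θ_jj).

Key biomarkers are the features with at least one edge to a different
modality; within-modality edges are kept in the network but do not by
themselves qualify a feature. Expert-opinion overrides (replace one
selected biomarker with a stated near-interchangeable feature) are
applied afterwards and reported alongside the pre-override set.

## Stratification

Key-biomarker columns are z-scored with the sample SD (ddof = 1); the
means/SDs are stored and reused to place validation individuals in the
same signature space. Missing entries are completed by softImpute-style
iterative soft-thresholded SVD (missing cells start at 0; relative-change
tolerance 1e-6; rank cap min(n, p) − 1; the shrinkage is picked on a
small grid by masked-entry holdout error when not given). Observed
entries are never altered.

Individuals are clustered by complete linkage under the correlation
distance; the dendrogram is cut at the lowest merge height at which every
cluster holds ≥ min_size (default 50) individuals. "Lowest" is read as
the smallest qualifying height — the finest such stratification; cuts
leaving a single cluster do not qualify, and when no multi-cluster cut
qualifies the K = 1 fallback is returned with a warning. Because the rule
takes the *lowest* qualifying height, it can split a large homogeneous
subset into two qualifying halves; this is a property of the rule, not of
the data, and the membership diagnostics (median correlation distance
from each individual to each subset, closest subset, agreement rate)
expose it.

Representative signatures are per-subset, per-biomarker medians (midpoint
convention for even sizes). Validation assignment minimizes the
correlation distance to the signatures; ties break toward the lower
subset id and are flagged; constant profiles are unassignable. Validation
features absent from a registry are imputed by lasso regression
(LassoCV) on the shared features, with the cross-validated R² per target
reported.

## Enrichment and outcomes

- **Fisher's exact test.** Exact two-sided hypergeometric for 2×2;
  Monte-Carlo otherwise, sampling tables with the observed margins
  (Patefield algorithm via scipy's `random_table`) and applying the
  add-one estimator p = (1 + #{tables at most as probable})/(R + 1), so a
  simulated p is never exactly 0. Default 10⁶ replicates.
- **Logistic enrichment.** Subset-vs-rest logistic regression per
  feature; Wald z and p. Perfect separation triggers a Firth-penalized
  refit (Jeffreys-prior score correction) rather than dropping the
  feature, and is flagged.
- **Bonferroni.** Significant iff p < α/m with m the tests actually
  performed.
- **Transitions.** Baseline→follow-up counts, row-normalized rates,
  stay-rate = trace/total. Rows with no baseline individuals are flagged.
- **Adjusted incidence.** Logistic regression of incident disease on
  subset membership plus baseline covariates, Wald p for membership.
- **Cross-module overlap.** |a∩b|/|a| (with the reciprocal also
  returned), permutation p over relabellings of the second assignment —
  a permutation test is the natural choice when only "more overlap than
  chance" is asserted.

## Synthetic-cohort generator

The generator emulates the *structure* the analysis assumes, not any real
cohort's marginals:

- Latent factor per planted module; module features are
  loading·factor + N(0, 1 − loading²) noise (unit marginal variance), so
  a loading of 0.7 means within-module correlations near 0.5. Module
  features are drawn round-robin across modalities, guaranteeing every
  module spans ≥ 2 modalities.
- Planted subsets shift the first module's features by ±effect_size
  along per-subset sign patterns. Patterns are mutually orthogonal,
  non-constant Hadamard rows (tiled to the signature length): orthogonality
  maximizes between-subset separation under the correlation distance and
  makes the subsets identifiable by construction; the constant row is
  excluded because a uniform shift is invisible to profile correlation.
- Covariate effects add β·covariate to a seeded random half of the
  features, giving the correction stage true positives and true
  negatives.
- Microbiome columns are mapped through a per-sample softmax (with an
  implicit remainder category, so sums stay < 1) on a doubled latent
  scale, then floored at 10⁻⁵ to exact zeros — heavy-tailed, tie-rich
  compositions of the kind the conditional-INT rule targets.
- Missingness: entry-wise missing-at-random plus whole-modality blocks
  for a sampled fraction of individuals.
- Disease labels are Bernoulli with subset-specific prevalence; follow-up
  visits resample each individual's subset from a row-stochastic
  transition matrix and regenerate features (fresh noise, same planted
  structure, same covariates).

Defaults (600 individuals; 120 features over five modalities; two
24-feature modules at loading 0.7; four subsets at effect size 1.0; 5%
missingness plus a 15% microbiome block; 30% disease prevalence in the
last subset vs 5% elsewhere; mostly-stay transitions with one precursor
state draining into the at-risk state) are calibration choices meant to
be realistic for deep-phenotyping cohorts — effect sizes of real
biomarker signatures are not published quantities, so these settings are
deliberate constructions, fixed once.

What the generator does **not** emulate: real metabolite/taxon marginal
distributions beyond non-Gaussianity, genotypes, platform batch effects,
twin relatedness, informative (non-random) missingness, or continuous
severity gradients within subsets. Passing tests therefore demonstrate
the pipeline's correctness and calibration under its own assumptions, not
performance on any particular real cohort.

## Verification sizes

The test suite and the acceptance script size their simulations for a
single CPU: 20 null cohorts of n = 200 for FDR control; n = 300 with 300
consensus runs for module recovery; five replicate cohorts of n = 600
(10% missingness) for stratification recovery, validation assignment and
diagnostics — reported as means over the replicates, since the lowest-cut
rule makes single-cohort ARI stochastic; p = 15 / n = 400 for
Graphical-Lasso support recovery; n = 1000 × 20 replicates for enrichment
power; n = 800 for transition-rate estimation; and a reduced
configuration (n = 250, 46 features) for the bit-identical determinism
check.

## Known limitations

- The t-approximate Spearman p is slightly conservative for heavily tied
  compositional features at moderate n.
- Glasso support recovery is not consistent under strong chains: L1
  shrinkage of strong edges can induce small compensating entries where
  the truth is conditionally independent (visible in the chain fixtures
  at link strength 0.6). EBIC's sparsity preference mitigates this.
- The lowest-qualifying-cut rule over-splits large homogeneous subsets
  (see Stratification); consumers should read K together with the
  membership diagnostics.
- Eigenvector centrality on a weighted graph reflects −ln p weights;
  extremely small p-values can concentrate centrality on a few hub
  features.
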