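# Methods

## The consistency degree

`condegree` quantifies how coherently a binary clinical endpoint partitions
samples in gene-expression space.  The statistic is built in four stages:

1. **Gene ranking.**  Every gene is scored by the absolute Spearman rank
   correlation |ρ| between its expression across samples and the 0/1
   endpoint.  Absolute value is used because anti-correlated genes carry the
   same information and the downstream PCA is sign-blind; ties are broken
   lexicographically on the gene identifier so the ranking is deterministic.
   Constant genes are dropped (they have no defined rank correlation).

2. **Gene-set fixing by variance contribution.**  Rather than thresholding a
   correlation p-value, the correlated gene set is fixed by scanning
   prefixes of the ranking (k = k_min … k_max, default 5 … min(500, G),
   step 1) and keeping the prefix whose first principal component carries
   the largest share of total variance, λ₁/Σλ (the variance-contribution
   rate).  Columns are mean-centred but not variance-scaled before PCA —
   scaling would distort the very contribution rate the scan maximises; a
   `scale` switch exposes the alternative.  On ties the smallest prefix
   wins.  An RBF-kernel variant (median-pairwise-squared-distance bandwidth,
   leading eigenvalue share of the doubly centred kernel matrix) is
   available; linear PCA is the default.

3. **Projection and ordering.**  Samples are projected onto the first
   principal component of the selected submatrix.  The component sign is
   fixed so the class-1 mean score is at least the class-0 mean score (any
   fixed convention works — the change-point model is sign-symmetric — but a
   convention makes runs reproducible).  Scores are then arranged as the
   class-0 block followed by the class-1 block; the class boundary sits at
   position n₀.

4. **Boundary change-point posterior, bootstrapped.**  A Bayesian
   change-point analysis of the ordered scores yields the posterior
   probability of a change at each position.  One bootstrap replicate
   resamples scores with replacement *within each class* (class sizes, and
   hence the boundary position, preserved), randomly orders scores within
   each block, runs the sampler, and records the posterior change
   probability at the boundary.  The **consistency degree** is the median of
   these boundary posteriors over `bootstrap_reps` replicates (default
   10,000 for final scoring).  Within-block order randomisation matters
   because the model sees an ordered series while samples within a class
   are exchangeable.

Gene selection is performed once on the full data, not per bootstrap
replicate: the gene set is fixed before the change-point stage, and
re-selecting inside a 10,000-replicate bootstrap would be computationally
prohibitive without changing what the statistic measures.

## The change-point engine

The engine is a product-partition model in the Barry–Hartigan style.  For a
series x₁…x_n, change indicators U₁…U_{n−1} cut it into contiguous blocks;
within a block observations are N(μ_r, σ²) and the block mean has prior
N(μ₀, σ₀²/n_r) (variance inversely proportional to block length, which is
what makes the marginal collapse).  With w = σ²/(σ² + σ₀²), flat priors on
μ₀ and log σ², and uniform priors p ~ U(0, p₀), w ~ U(0, w₀), the marginal
of the data given a partition with b blocks is proportional to

    ∫₀^{p₀} p^{b−1}(1−p)^{n−b} dp · ∫₀^{w₀} w^{(b−1)/2} (W + Bw)^{−(n−1)/2} dw,

where W and B are the within- and between-block sums of squares
(W + B = total SS, so only the between share B/T enters — the model is
exactly location/scale free, and the sampler's output is bit-identical
under affine maps of the input at a fixed seed).

**Defaults** p₀ = w₀ = 0.2, burnin = 50, sweeps = 500 follow the
conventional defaults of the fast implementation this engine mirrors.  The
Gibbs sweep updates each U_i from its conditional odds; `change_prob` is
the post-burnin frequency of U_i = 1 and `posterior_mean` the post-burnin
average of fitted block means.

**Numerics.**  The p-integral is an incomplete beta function (closed form).
The w-integral reduces, via t = Bw/(W+Bw), to
W^{a−β} B^{−a} Β(a,b′) I_{t₀}(a,b′) with a = (b+1)/2, β = (n−1)/2,
b′ = (n−b−2)/2, valid for b ≤ n−3; for b ≥ n−2 (bounded integrand) a
64-node Gauss–Legendre rule in log space is used.  Inside the compiled
sampler kernel, ln I is linearly interpolated on two 4096-point grids — one
in ln t₀ and one in ln(1−t₀), because I_{t₀}(a, b′) has a fractional-power
cusp at t₀ → 1 — precomputed per (n, p₀, w₀); worst-case interpolation
error is below 10⁻³ in log-odds, negligible against Monte-Carlo noise.  A
test cross-checks the closed form against adaptive quadrature to 10⁻⁸.

**Degenerate inputs.**  If the series is globally constant the data term is
uninformative and the posterior reduces to the prior (positions are
exchangeable).  If a partition fits the data perfectly (W = 0, e.g. exact
ties forming constant blocks) the w-integral diverges for b ≤ n−2; the
kernel replaces it by a δ-truncated value with a fixed large −ln δ, which
makes the posterior concentrate on the *coarsest* perfect-fit partition —
the correct σ → 0 limit, and an Occam tie-break among perfect fits.

**Exact oracle.**  For n ≤ 12, `bh_exact` enumerates all 2^{n−1} indicator
vectors with the non-interpolated integrals and serves as the reference:
the sampler agrees with it to < 0.05 in every change probability at 20,000
sweeps (tested on random n = 8 series), and reversal symmetry holds exactly
for the enumerator.

**Reproducibility.**  Bootstrap replicates get chain seeds from a
`SeedSequence` spawned off the user seed, so runs are deterministic and
replicate-order independent.

## Milestone cutoff redefinition

A milestone endpoint dichotomises survival at a day cutoff c: label 1 =
event by c (a death exactly at c counts), label 0 = follow-up reaching c,
censored before c = excluded (standard milestone practice; a switch can
instead count early-censored samples as class 0 for sensitivity checks).
Candidate cutoffs are the distinct observed times yielding at least
`min_per_class` (default 10) samples per class.  Each candidate's
consistency degree is computed with a shared base seed; the argmax (ties →
smallest cutoff, the clinically conservative choice) redefines the
endpoint.

Two throughput choices, both exposed as parameters:

* the candidate grid is thinned to an evenly spaced subset of at most
  `max_candidates` (default 25) — the degree-vs-cutoff curve is smooth at
  the 10%-of-scale resolution the scan is asked about, and the enrichment
  null (below) adapts through N;
* the scan stage runs the engine at sweeps = 150, burnin = 30 and
  `scan_reps` = 200: the median over bootstrap replicates absorbs per-chain
  Monte-Carlo noise, so shorter chains trade per-replicate precision for
  scan throughput.  The winning cutoff is re-scored at full settings
  (`final_reps`, default 10,000).

**Significance.**  The redefinition is repeated on n bootstrap resamples of
the cohort (default 1,000); k counts resamples whose best cutoff matches
the original (exact match by default; a `match_window` in days absorbs
candidate-grid shift under resampling).  Under the null that the chosen
cutoff is arbitrary among the N candidates, k ~ Binomial(n, 1/N), and the
reported p-value is the upper tail P(X ≥ k).  No interval estimate is
attempted: the cutoff–degree relationship is neither linear nor continuous,
which is exactly why the recurrence test is used.

## Validity and unpredictability analyses

* `validity_test` — per-endpoint summary = mean of the top-k (default 10)
  external-validation MCCs; one-sided ("greater") Spearman and Kendall
  tests of consistency degrees against these summaries.
* `impute_low_coverage` — samples predicted by fewer than 50 classifiers
  get error rate 0.5 (their observed rate is unreliable).
* `select_unpredictable` — error rate ≥ cutoff (inclusive at the boundary
  for determinism), with optional conjunctive top-k and
  maximum-model-count filters; defaults mirror the 0.9 (trend analyses)
  and 0.97 (strict unpredictability) conventions.
* `os_efs_gap_test` — one-sided rank-sum test that OS−EFS gaps are smaller
  among unpredictable samples; exact permutation enumeration (midranks)
  when both groups have ≤ 25 samples and the enumeration is tractable,
  otherwise the tie-corrected normal approximation.
* `km_quantile` — product-limit survival estimate (via lifelines); the
  q-quantile milestone is the smallest observed time with S(t) ≤ q, and a
  curve that never reaches q returns NaN rather than raising.
* `score_position_report` — the numeric table behind "where do
  unpredictable samples sit": each sample's PC1 score against the
  class-block posterior means.

## Synthetic data

The generator exists so every stage is testable without downloads; its
defaults are the package's study conditions.

**Two-class.**  A per-sample latent trait L = effect·y + N(0,1) carries the
class shift on top of unit within-class biological variance, as in a
co-expressed signature module.  Each of `n_informative` (default 20 of 150)
genes is a·L + √(1−a²)·ε with |a| ~ U(correlation, 1) (default
correlation = 0.8) and random sign, so a full-loading gene shifts by
`effect` (default 3) in per-gene-SD units and informative genes correlate
pairwise by aᵢaⱼ.  The factor structure matters: with independent gene
noise the first component would average noise away and the projected
separation would grow like √k, saturating the degree at 1 for any
realistic effect; with a shared latent trait the component recovers L and
the separation stays ≈ effect, which is both the realistic behaviour of
co-regulated signatures and the regime where the statistic is informative.
Class sizes default to 30 + 30.  effect = 0 is an exact null.

**Survival.**  Latent milestone classes of sizes n₀/n₁ (default 40/40
in the recovery experiments) are assigned at random; class 1 draws event
times from an exponential truncated to (0, true_cutoff] with rate
0.5/true_cutoff — a mild rate, so events spread through the whole window;
the planted milestone is only identifiable if late events exist near both
sides of it — and class 0 draws true_cutoff + Exp(mean true_cutoff/2).
Censoring replaces a record with a uniform time before its event at rate
`censoring_rate` (default 0.1).  Informative genes follow the latent class
through the same factor model.

**What passing tests do not show.**  The generator has no probe effects,
batch structure, heavy-tailed noise, class imbalance beyond what is
configured, or informative censoring; results on it demonstrate the
machinery's correctness and sensitivity, not performance on any real
cohort.

## Problem sizes used in the shipped experiments

Control and monotonicity experiments use 30+30 samples, 150 genes,
200 bootstrap replicates; cutoff recovery uses 80 samples, a ≤25-point
candidate grid and 200 scan replicates per candidate; the recurrence test
in the reproduction script uses 40 resamples at reduced scan settings with
a 45-day match window.  These sizes were chosen so the full reproduction
runs on a single CPU in minutes while leaving every comparison far from
its decision boundary.

## Known limitations

* The degree is a point estimate; no interval is reported (the bootstrap
  distribution is returned for inspection).
* The global product-partition model is used even though the boundary
  question is binary; a max-one-change variant would be a model restriction,
  not implemented.
* Gene selection is not repeated inside the bootstrap, so selection
  uncertainty is not propagated into the degree.
* Expression values are taken as-is (log-scale vs linear is upstream's
  responsibility), and missing expression values are rejected rather than
  imputed.
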