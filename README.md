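# condegree

**How coherently does a clinical endpoint partition patients in
gene-expression space?**

Microarray- and RNA-seq-based classifiers of clinical outcomes rest on the
assumption that the endpoint (ER status, a survival milestone, treatment
response, …) corresponds to a real structure in the transcriptome.  When it
does not, no amount of model tuning helps: the endpoint itself caps the
achievable accuracy.  `condegree` computes a probability-valued statistic —
the **consistency degree** — that measures this endpoint/expression
coherence *before* any classifier is built, and uses the same machinery to
*redefine* survival-milestone endpoints so they align better with the
expression profile.

The package is aimed at statisticians and bioinformaticians working with
labelled expression cohorts (MAQC-II-style training sets and their kin).

## The statistic

For a binary endpoint y over samples with expression matrix X:

1. rank genes by |ρ|, the absolute Spearman correlation with y;
2. fix the correlated gene set by scanning prefixes of the ranking and
   maximising the first principal component's variance-contribution rate
   λ₁/Σλ (linear or RBF-kernel PCA);
3. project samples onto that component and order the scores class-0 block
   first, class-1 block second;
4. run a Bayesian change-point analysis (product-partition model in the
   Barry–Hartigan style: block means integrated out, uniform priors
   p ~ U(0, 0.2) on the change probability and w ~ U(0, 0.2) on the
   variance ratio) and read off the posterior probability of a change point
   at the class boundary;
5. bootstrap step 4 within classes (10,000 replicates by default, scores
   randomly re-ordered within each block) — the **consistency degree** is
   the median boundary posterior, a number in [0, 1].

Degrees near 1 mean the endpoint cuts the expression profile cleanly
(positive-control endpoints such as patient sex score ≈ 1); degrees near
the null band (≲ 0.2) mean the labelling is essentially arbitrary with
respect to the transcriptome, and models built on it will disappoint
regardless of algorithm.

For an orderable index such as survival days, any observed time is a
candidate milestone cutoff; `condegree` scans all candidates, redefines the
endpoint at the degree-maximising cutoff, and assesses it with an
upper-tail binomial enrichment test on how often that cutoff recurs among
bootstrap re-definitions (null success probability 1/N over N candidates).

See `docs/methods.md` for the model, the closed-form integrals, numerical
conventions and the synthetic-data design.

## Worked example

Simulate a 30+30-sample cohort whose 20 informative genes share a latent
trait shifted 3 SD between classes, then score the endpoint:

```console
$ condegree --seed 7 simulate two-class --out-dir sim
$ condegree --seed 7 score -e sim/expression.tsv -c sim/clinical.tsv \
      --endpoint class --reps 2000 -o score_out
consistency degree [class]: 0.9560 (prefix 6, contribution 0.972)
```

A degree of 0.956 says the endpoint is highly consistent with the profile:
in 2,000 within-class bootstrap replicates the median posterior probability
of a change point at the class boundary was 0.956.  The selector fixed a
6-gene prefix whose first component carries 97.2% of the variance.
Permuting the labels of the same matrix drops the degree into the null
band (≈ 0.03).

Survival milestone redefinition on a cohort with a planted 900-day
milestone class:

```console
$ condegree --seed 7 simulate survival --out-dir surv --n0 40 --n1 40 --effect 2.5
$ condegree --seed 7 redefine -e surv/expression.tsv -c surv/clinical.tsv \
      --time-col days --event-col event --final-reps 2000 --boot-n 40 \
      --match-window 45 -o redef_out
best cutoff: 823.886 days (degree 0.6233, N=25)
enrichment: k=27/40, p=1.3e-28
```

The scan recovered a cutoff within 9% of the planted 900 days; 27 of 40
bootstrap re-definitions landed within the 45-day match window of it,
which under the uniform-cutoff null (success probability 1/25) gives an
enrichment p-value of 1.3e-28.  `redef_out_scan.tsv` holds the full
degree-vs-cutoff curve, `redef_out_summary.tsv` the summary row, and every
run writes a JSON manifest (parameters, seed, versions).

The same functionality is available as scikit-learn-style estimators:

```python
from condegree import ConsistencyScorer, MilestoneCutoffScanner

scorer = ConsistencyScorer(bootstrap_reps=2000, random_state=7).fit(X, y)
scorer.degree_          # the consistency degree
scorer.bootstrap_values_
scanner = MilestoneCutoffScanner(random_state=7).fit(X, (days, event))
scanner.best_cutoff_, scanner.final_degree_
```

plus validity utilities (`validity_test`, one-sided Spearman/Kendall tests
of degrees against top-10 external-validation MCCs), unpredictable-sample
selection from per-sample error-rate tables (`select_unpredictable`,
`impute_low_coverage`), the one-sided OS−EFS gap rank-sum test and
Kaplan–Meier milestone quantiles (`km_quantile`).

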