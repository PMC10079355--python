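# metasurv

Meta-learned deep Cox survival analysis on integrated multi-omics data,
with DeepLIFT attribution and a gene-set co-enrichment statistic.

## The problem

Pan-cancer survival modelling faces two compounding difficulties: each
cancer type contributes few patients relative to the number of molecular
features ("big P, small N"), and the types differ enough that pooling them
into one training set blurs the signal. `metasurv` addresses both with
model-agnostic meta-learning (MAML): a feed-forward risk network is
meta-trained across many source cancer-type *tasks* so that a handful of
gradient steps adapts it to a new target type, and the adapted model is
scored on a held-out query set per task. Multi-omics input (clinical,
transcriptomic and proteomic blocks) is integrated by imputation, label
encoding, z-scoring and a 0.7 Pearson-correlation redundancy filter.

The risk model is a four-layer ReLU network `f_theta(x)` producing a scalar
log-risk `eta`, trained with the negative Cox partial log-likelihood

    L(theta) = -(1/d) * sum_{i: C_i = 1} [ eta_i - log sum_{j: Y_j >= Y_i} exp(eta_j) ]

where `Y_i` is the time to event, `C_i` the event indicator, and `d` the
number of observed events. Performance is reported as Harrell-style
concordance (ties in predicted risk excluded from numerator and
denominator) and the IPCW integrated Brier score with a Breslow baseline
hazard.

For interpretability, DeepLIFT (Rescale rule) decomposes
`f(x) - f(reference)` into per-feature contribution scores that sum exactly
to the output difference; the reference is a cohort statistic (by default
the per-feature median over deceased patients). Scores feed two standard
enrichment routes (a pre-ranked `.rnk` list and a mean-score-filtered gene
list) and a *co-enrichment* statistic: for each gene set, the fraction of
members lying within a window `W = floor(N/10)` of the set's highest-ranked
member in the score-sorted list, compared against permuted orderings.

Because real pan-cancer data cannot ship with the package, a first-class
synthetic-cohort generator reproduces the relevant structure: 17 tasks with
support sizes 16-840 and 30-patient query sets, per-task censoring from 30
to 86%, three feature blocks of very different widths, correlated feature
groups, missing values, categorical clinical features, and exponential
proportional-hazards event times driven by a sparse, partly task-shared
coefficient vector whose transcriptomic entries live inside planted gene
sets.

## Worked example

```python
import numpy as np
from metasurv.experiments import run_meta_vs_direct_replicate
from metasurv.synthetic import CohortSpec, generate_cohort, generate_scores_with_planted_clusters
from metasurv.coenrichment import GeneSetCollection, coenrichment_test

r = run_meta_vs_direct_replicate(seed=0)
print(f"meta C-index   {r.meta_c_index:.3f}")
print(f"direct C-index {r.direct_c_index:.3f}")

truth = generate_cohort(CohortSpec(
    n_tasks=2, n_target_tasks=1, support_sizes=(20, 20), query_size=10,
    block_dims=(4, 2000, 4), n_signal_features=60, n_planted_sets=5,
    planted_set_size=40, censoring_target=0.3, correlation_groups=0, seed=3,
)).truth
scores = generate_scores_with_planted_clusters(truth, noise_sd=0.0, seed=4)
rep = coenrichment_test(scores.to_numpy(), list(scores.index),
                        GeneSetCollection(truth.planted_set_membership),
                        percentile=50, R=100, seed=5)
print(f"sorted fraction {rep.mean_sorted_fraction:.2f}  "
      f"random fraction {rep.mean_random_fraction:.2f}  p = {rep.p_value:.3f}")
```

prints

```
meta C-index   0.660
direct C-index 0.628
sorted fraction 1.00  random fraction 0.11  p = 0.010
```

The first two lines say the meta-trained, target-fine-tuned model orders
the 3 x 30 target query patients' survival better than a single network
trained on all pooled source data. The last line is the co-enrichment
positive control: with noiseless planted scores every set member falls
inside the anchor window of the score-sorted list (fraction 1.0), while
randomly permuted lists put only ~11% of members there, so the permutation
p-value is the smallest attainable at R = 100.

A CLI mirrors the library: `metasurv simulate`, `metasurv preprocess`,
`metasurv run-all`, `metasurv compare` and `metasurv coenrich` (see
`metasurv --help`).

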