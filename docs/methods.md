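# Methods

## Model

The risk model is a feed-forward network with three ReLU hidden layers and
a linear scalar output (four weight layers), mapping a standardized feature
vector to a log-risk `eta`. It generalises the linear predictor of the Cox
proportional-hazards model: the hazard is `h0(t) * exp(eta)`, and the
partial likelihood depends only on the ordering of risks within risk sets.
The training loss is the negative partial log-likelihood averaged over the
`d` observed events,

    L = -(1/d) * sum_{i: C_i=1} [ eta_i - log sum_{j: Y_j >= Y_i} exp(eta_j) ],

with the Breslow convention for ties (the risk set `Y_j >= Y_i` is taken
literally, so tied patients appear in each other's risk sets). The mean
(rather than sum) over events keeps learning rates comparable across tasks
whose event counts range from a handful to several hundred. The
log-sum-exp is computed with a max shift. A batch with zero observed events
contributes loss 0 with a warning — this happens legitimately on tiny,
heavily censored support sets.

All gradients are exact analytic backpropagation in numpy. Gradient
correctness is enforced by finite-difference tests; those tests use
networks with non-zero random biases, because zero-initialised biases put
dead samples' pre-activations exactly at the ReLU kink, where the loss is
not differentiable and central differences average two one-sided slopes.

## Meta-learning

Training follows MAML. Each task is split into a support set (adaptation)
and a 30-patient query set (evaluation). The inner loop takes plain
gradient steps `theta' = theta - alpha * grad L_support(theta)` with SGD at
`alpha = 0.01` (default one step); the outer loop updates the shared
initialisation with Adam at `1e-4` on the sum of post-adaptation query
losses across tasks (all source tasks every iteration — with ~14 tasks
batching is unnecessary).

The second-order meta-gradient `prod_i (I - alpha H_i) g_query` is computed
with central finite-difference Hessian-vector products of the support loss
(`Hv ~ [g(theta + eps v) - g(theta - eps v)] / 2 eps`, `eps` scaled to the
vector norm), exact to O(eps^2) at two extra gradient evaluations per task
and step. A `first_order` flag drops the curvature term (FOMAML); the two
agree as `alpha -> 0`, which is asserted in tests.

**Stopping.** The outer loss on source query sets decreases monotonically
long after generalisation to *unseen* tasks has peaked — the initialisation
memorises the source queries, and adaptation behaviour on new tasks
degrades (on some seeds the representation even becomes anti-concordant on
new tasks). A plateau rule on the outer loss therefore never fires at the
right time. `meta_train` accepts held-out *meta-validation tasks*: every 25
iterations the post-adaptation query loss on those tasks is evaluated
(never used for gradients), and training stops after 6 checks without
improvement, restoring the best parameters. The benchmark experiments hold
out 2 of the 14 source tasks for this purpose. Without validation tasks the
plateau rule (tolerance 1e-4 over 50 iterations, cap 1000) applies.

**Fine-tuning.** Target-task adaptation reuses the inner-loop SGD
(`alpha = 0.01`) on the target support set; the benchmark uses 200 steps.
All layers are updated. Fine-tuning depth matters far more than its
learning rate here: target support sets of ~300 patients support
substantial task-specific learning.

**Direct-learning baseline.** One network of the same architecture trained
on all pooled source support data with Adam. The named 5-fold structure is
used for model selection only: each fold in turn serves as validation for
early stopping (patience 10), and the final model is retrained on the full
pool for the mean best-epoch count, then evaluated on each target's query
set without adaptation.

## Evaluation metrics

*Concordance index*: comparable pairs are `(i, j)` with `Y_i < Y_j` and
patient `i` uncensored; concordant when `eta_i > eta_j`. Pairs with exactly
tied predicted risks are counted separately and excluded from both
numerator and denominator (the literal ratio of concordant to
concordant-plus-discordant pairs); a `ties="harrell"` option scores them
1/2 for comparability with other software, and is validated against
scikit-survival on tie-free data.

*Integrated Brier score*: survival probabilities come from a Breslow
baseline hazard estimated on the (adapted) support set,
`S(t|x) = exp(-Lambda0(t) e^eta)`. The Brier score at horizon `t` uses
inverse-probability-of-censoring weights from a Kaplan-Meier estimate `G`
of the censoring distribution, evaluated left-continuously at event times
(Graf convention), and is integrated over 100 equally spaced points between
the 5th and 95th percentiles of observed query times by the trapezoid rule,
normalised by the grid span. Grid points where `G` reaches zero are
truncated with a warning. The implementation is cross-checked against
scikit-survival's IPCW Brier score.

A percentile bootstrap over query patients (seeded, default 1000
replicates) provides confidence intervals for the C-index; how the
motivating analysis formed its interval estimates is not stated, so the
bootstrap is offered as one defensible interpretation.

## DeepLIFT attribution

Rescale rule only: linear layers pass multipliers through their weights
(biases cancel in differences), and each ReLU uses
`m = (relu(z) - relu(z0)) / (z - z0)` when `|z - z0| > 1e-7`, otherwise the
gradient at the reference. Per-feature contributions
`phi_i = m_i (x_i - x0_i)` satisfy summation-to-delta exactly by
construction (up to the epsilon guard, enforced at 1e-6 in tests). The
reference is the per-feature median or mean over the deceased (`C=1`) or
censored (`C=0`) stratum; the default is the median over deceased patients,
the variant that yielded the most enriched pathways in the motivating
analysis. Cohort-level scores average per-patient contributions over query
patients (configurable to median, or to other cohorts); attribution order
(score-then-aggregate) is fixed and recorded.

Exports: a two-column tab-separated ranked list (GSEA pre-ranked `.rnk`
dialect) and a filtered list of features scoring at or above the mean score
(g:Profiler query), with a JSON sidecar recording the reference strategy
and the downstream significance conventions (adjusted p < 0.05 for
g:Profiler, FDR q < 0.25 for GSEA). Running those tools is out of scope.

## Co-enrichment statistic

From per-gene scores, the universe at percentile `p` is the top
`floor(n (100 - p) / 100)` genes (rank-based, ties broken by name): from
13 960 genes the 50th/70th/90th percentiles select 6980/4188/1396 genes,
with window sizes `W = floor(N/10)` of 698/418/139. For each gene set with
at least 30 members in the universe, the anchor is the member appearing
earliest in the score-sorted list, and the set's fraction is the share of
its other members within +/-W positions of the anchor (the anchor is
excluded from the denominator; windows truncate at list boundaries). The
null repeats the identical statistic on R (default 100) seeded permutations
of the universe; the permutation p-value is
`(1 + #{perm mean >= observed mean}) / (R + 1)`. Using many permutations
instead of a single random ordering gives a calibrated null; calibration
(uniform p-values under random scores) is asserted by a KS test. Per-set
fractions are averaged; a pooled-across-sets mode exists behind a flag.

## Synthetic cohorts

The generator emulates the *shape* of an integrated pan-cancer cohort, not
its biology. Defaults: 17 tasks (14 source, 3 target) with support sizes
(16, 840, 139, 290, 95, 27, 175, 395, 286, 189, 68, 18, 361, 302; 308,
308, 320) and 30-patient query sets; per-task censoring targets from 29.8%
to 86.1%; three blocks — clinical-like (20 features, 5 of them
small-cardinality categorical levels), transcriptomic-like (wide), and
proteomic-like (mid-width). Event times are exponential proportional
hazards, `T ~ Exp(rate = exp(eta)/s)` with scale `s = 10`: the simplest law
that is exactly PH, making the generative concordance available in closed
form (`P(T_i < T_j | eta) = sigmoid(eta_i - eta_j)`). Censoring is
independent uniform on `[0, c]` with `c` solved per task by bisection on
the realised draws so the achieved censoring fraction matches the target to
within a few points. Missing values are injected completely at random into
numeric cells of the clinical and proteomic blocks (the transcriptomic
block needs no imputation); equicorrelated feature groups (rho = 0.5 by
default, configurable) give the correlation filter work to do and sit
outside the planted sets so filtering does not eat the signal.

The risk is linear: `eta_i = x_i . beta_task`, with transcriptomic signal
features confined to disjoint planted gene sets of >= 30 members (so the
positive controls survive the co-enrichment size filter) and optional
clinical/proteomic signal features for block-complementarity experiments.
Task coefficients are the shared vector plus a per-task Gaussian
perturbation on the signal support.

Planted-cluster scores for the co-enrichment positive control give each
set's members a set-level centre plus `N(0, noise_sd)` noise, with
background features at `N(0, sqrt(1 + noise_sd^2))` — the background
spread tracks the member noise so that the large-noise limit is genuinely
structureless (a fixed unit-variance background would let large member
noise dominate both tails of the ranking and *create* apparent clustering).

What passing these tests does **not** show about real data: the generator
draws Gaussian features with at most equicorrelated blocks, while real
omics are heavy-tailed, batch-affected and pervasively correlated; its
censoring is independent of risk; and its task heterogeneity is a Gaussian
perturbation of a shared linear signal, far milder than biology. Results on
it validate the machinery and the direction of effects, not clinical
performance levels.

## Benchmark experiment conditions

The meta-vs-direct benchmark (`metasurv.experiments`) uses 200 features
across blocks (20, 140, 40), 44 signal features (40 transcriptomic inside
two 30-gene planted sets, 2 clinical, 2 proteomic) at coefficients
+/-0.25 — a latent risk sd of ~1.66 and a generative concordance of ~0.8 —
and per-task perturbations at sd 0.5 (twice the shared scale), i.e.
genuinely heterogeneous tasks, the regime in which pooled training is known
to suffer. Networks are 32-16-8; the experiments use the first-order
meta-gradient for speed (the library default remains second-order). These
problem sizes were chosen once as the package's benchmark conditions and
are what the acceptance script reruns.

## Numerical choices and edge cases

- z-scoring uses sample sd (ddof = 1); "standardized" assertions use 1e-8.
- KNN imputation (k = 1): Euclidean distance over mutually observed numeric
  features; distance ties go to the lowest row index; rows sharing no
  observed feature with any donor fall back to the column median; an
  all-missing column is an error naming the column.
- The correlation filter is a greedy scan in column order keeping the
  earlier feature, on absolute correlation (|r| > 0.7); deterministic,
  order-stable, idempotent. Column order therefore encodes priority.
- Label encoding maps category levels to 0..L-1 in lexicographic order.
- Integration inner-joins patients, prefixes colliding feature names with
  their block tag, then re-z-scores and re-filters the merged matrix.
- Percentile selection is rank-based with name tie-breaks; window fractions
  are in [0, 1] and monotone in W by construction.
- Meta-training aborts on a non-finite outer loss and returns the last
  finite parameters.

## Known limitations

- Efron tie handling, time-varying covariates and competing risks are out
  of scope; ties use the Breslow convention.
- "Four-layered" is interpreted as four weight layers (three hidden plus
  output); hidden widths are configurable because the architecture source
  fixes only depth and activation.
- The Brier score requires survival probabilities the Cox-style network
  does not output directly; the Breslow-baseline recipe on the adapted
  support set is one standard choice among several.
- The co-enrichment anchor is the first set member in sorted order for the
  sorted list and in permuted order for random lists; denominator excludes
  the anchor. Other anchor conventions would shift absolute fractions but
  not the sorted-vs-random contrast.
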