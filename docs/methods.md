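# Methods

This note records the models the package implements, the conventions and
parameter choices behind them, what the synthetic worlds do and do not
emulate, and the numerical decisions a maintainer would want to know.

## Counting conventions

All statistics operate on report-level 2×2 counts: a report contributes at
most 1 to c_ij, c_i+, c_+j and c_++ regardless of how many times a drug or
event is coded on it. Duplicate report versions (same primary ID) are
resolved to the version with the latest receipt date, ties broken by file
order. Rows with an empty drug or event cell, or an unparseable date, are
dropped with a logged count. Identifiers are opaque strings; vocabulary
normalization is out of scope.

## Classical disproportionality methods

* **PRR, ROR** use the standard log-scale Wald 95% intervals; signalling
  criteria PRR025 > 1, ROR025 > 1. Zero cells raise a degenerate-table
  error unless the optional Haldane +0.5 correction (applied to all four
  cells, off by default) is enabled.
* **IC (BCPNN)** uses the original delta-method posterior mean and
  variance with beta priors whose first-shape hyperparameters are all 1
  (so the marginal prior totals are 2 and the joint-cell prior total is
  tied to the margins, making the prior IC expectation 0). The bound is
  E(IC) − z·SD with z = 1.96 by default; z = 1.645 is one argument away,
  since conventions differ on whether "IC05" means a 5th percentile or a
  95%-interval endpoint. Signal ⇔ bound > 0.
* **EBGM** is the two-component gamma–Poisson shrinker: λ ~ mixture of
  Gamma(α₁,β₁) and Gamma(α₂,β₂) with weight P, counts Poisson(λ·E_ij)
  given E_ij = c_i+·c_+j/c_++. Hyperparameters maximize the marginal
  negative-binomial mixture likelihood from the classical start
  (0.2, 0.1, 2, 4, 1/3), via L-BFGS-B on log/logit-transformed parameters
  with a Nelder–Mead polish. Shapes and rates are bounded in [1e-3, 1e3]:
  outside that range a component degenerates numerically (the unbounded
  optimum for tightly null data is a spike with α → ∞) and posterior
  quantiles become unreliable. EBGM = exp(Σ w_k(ψ(shape_k) − ln rate_k));
  EB05/EB95 by Brent root-finding on the posterior mixture CDF (absolute
  tolerance 1e-8). Signal ⇔ EB05 ≥ 2.

## The pharmacological network model

The known drug–ADE associations of the training period form a bipartite
graph. For a candidate pair (d, a), with the edge (d, a) itself always
excluded, 14 features in three families are computed (the registry is
pluggable so alternative definitions can be swapped in without touching the
model):

* network — drug degree; ADE degree; number of ADE-linked drugs sharing an
  event with d; Jaccard-weighted neighbor-link score; preferential
  attachment; fraction of d's events covered by the ADE-linked drugs'
  events;
* taxonomic — fraction of d's k = 10 nearest taxonomy neighbors linked to
  a; mean taxonomy similarity (shared-prefix length / longer code length)
  to the ADE-linked drugs; mean shared-prefix depth; prevalence of the ADE
  link within d's top-level taxonomy class;
* intrinsic — mean and max fingerprint Tanimoto (|AND|/|OR|, 0/0 := 0) to
  the ADE-linked drugs; mean and max protein-target Jaccard overlap.

A logistic regression on these features gives P(A_j | D_i). Selection is
backward-stepwise by AIC from the full set; the reported cv_auc is the mean
out-of-fold AUC of a label-stratified 10-fold split with an explicit seed;
final coefficients are refit on all data. Perfect separation falls back to
a small ridge penalty (1e-6) with a warning.

**Training protocol.** Naively using the known edges themselves as training
positives leaks an artifact: with own-edge exclusion, a positive's drug
degree is systematically one lower than a negative's for the same drug, and
the model learns that instead of the biology. The pipeline therefore trains
on a time split *within* the training window — the feature graph comes from
the first half, labels from the full window — so edges that emerged later
(including drugs absent from the graph, the situation of newly marketed
drugs at prediction time) are represented among the positives. Training
negatives are pairs sampled among drugs observed in the window, excluding
everything known by the window's end (2 negatives per positive).

## Propensity-score adjustment of P(A_j)

Co-medication is the measured confounder: principal components of the
centered report × drug matrix (index drug's column excluded — a drug must
not predict its own exposure; exclusion is exact rank-1 score arithmetic on
a decomposition computed once per database) summarize each report's
prescription profile. The number of components is the smallest explaining
80% of variance, capped at 20 — with cluster-structured co-prescription the
cap binds, and 20 components comfortably span the cluster space. A
logistic regression of exposure on the scores gives PS_k; the outcome
regression `logit P(ADE) = β0 + β1·Drug + β2·PS` is fitted per pair.
Logistic fits use a step-halved Newton iteration started at the base rate
(rare outcomes diverge from a zero start), with the generic ridge-guarded
fit as fallback.

**Offset convention for P(A_j).** The adjusted marginal is an average of
per-report sigmoids; which offsets enter is configurable. The default is
the standardized no-exposure marginal, `mean_k sigmoid(β0 + β2·PS_k)` — a
g-computation estimate of the event probability *were the index drug's
association absent*, with the confounder distribution kept. The
alternative `literal` mode sums the frequency offset logit(c_+j/c_++), β0
and β1 unconditionally into every predictor; it is retained behind a flag
for comparison, but adding the drug's own fitted effect into the
no-association probability suppresses exactly the pairs with genuine
effects (it inverts the intended ranking in simulation), and the double
baseline pushes P(A_j) toward rate² — hence not the default. The mean
(rather than an unnormalized sum over the K reports) is what makes the
quantity a probability.

## IC_PNM

Point: log2(P(A|D)/P(A)), probabilities clipped 1e-12 from the boundaries.
Bound: point − 2/(√(c_ij+1)·ln 2), i.e. the ratio multiplied by
exp(−2/√(c_ij+1)) — a penalty that shrinks as evidence accumulates and
converges to the point estimate; the penalty function is injectable so
alternative width conventions are one-line swaps. Signal ⇔ bound ≥ 2. Note
the threshold's asymptotic meaning: bound ≥ 2 at large counts corresponds
to a four-fold ratio on the log2 scale.

## Evaluation

AUC is the Mann–Whitney rank statistic with midrank tie handling; Youden's
index is maximized over midpoint cutoffs (± sentinels), ties broken toward
higher specificity; threshold sweeps classify score ≥ t; top-K lists break
score ties by identifier; Pearson and Spearman correlations are both
reported since conventions differ. Pairs a method cannot score (zero-count
pairs for PRR/ROR) are excluded from that method's metrics with the
coverage fraction reported; a worst-rank imputation mode exists for
sensitivity analysis. The evaluated quantity defaults to each method's
signalling bound (the quantity practitioners threshold), with the point
estimate one flag away.

## The synthetic worlds

The generator produces the simplest world containing everything the method
claims to exploit (an informative prior) and correct for (co-medication
confounding):

* Drugs belong to prescription/similarity clusters; fingerprints, targets
  and taxonomy codes are noisy copies of cluster prototypes, and true
  signals are placed preferentially within (cluster, syndrome-ADE)
  combinations. `attribute_informativeness` (default 0.8) dials how far
  attributes and signal placement align; at 0 the attributes are pure
  noise.
* Reports draw a cluster, then exposures (within-cluster drugs boosted
  5-fold by default) and events: each study ADE fires with probability
  baseline × Π RR over exposed true-signal drugs × the cluster confounder
  effect; each cluster has one confounder ADE multiplied by
  2^strength in its reports, creating confounded null pairs.
* Study-ADE baselines (0.001–0.006) and exposure rates (0.001–0.01) put
  median pair counts in the single digits over 10⁵ reports — the sparse
  regime of real reporting databases, where shrinkage and priors matter.
  30 background events (rates 0.05–0.2) stand in for the vast majority of
  dictionary terms outside any study set, so every report naturally has
  ≥ 1 event and the ≥1-event guarantee (empty rows are redrawn) distorts
  study-ADE marginals by only ~2%.
* A quarter of true pairs are **silent**: real associations by the
  reference standard that are not expressed as elevated reporting. Real
  reference sets have exactly this property (mild, expected or
  under-reported reactions show no disproportionality), and it is why
  count-based methods plateau and an attribute-informed prior can help.
  Without it, counts would be a sufficient statistic for truth and no
  prior could ever win.
* Half the drugs launch during the study period (entry times 0.25–0.7 of
  the timeline); their associations cannot be known at training time and
  form the early-detection positives.
* The benchmark's "known associations at training time" are the true pairs
  with ≥ 2 reports in the chronological training prefix (first 20% of
  reports) — an emulation of curated knowledge that accrues with observed
  evidence. A purely statistical screen is provided for real data, but at
  prefix scale it mostly harvests chance co-occurrences, which real curated
  training sets do not contain.
* Reference sets: positives = true pairs not yet known; negatives =
  sampled clean nulls plus up to 60 confounded nulls.

What the generator does **not** emulate: reporting-delay and
stimulated-reporting dynamics, duplicate submissions, demographic
covariates, dose, indication bias, and vocabulary noise. Passing the
simulation benchmark therefore shows the machinery works when its
assumptions hold — informative attributes and cluster-shaped confounding —
not that the same margins will be observed on any particular real database.

## Problem sizes used by the test suite and acceptance script

The method-ordering benchmark runs the default study conditions (200
drugs, 20 study ADEs, 100,000 reports per world, informativeness 0.8,
confounding strength 1) over 10 seeds in the test suite and 5 seeds in the
acceptance script. The confounding-correction experiment uses its own
scenario — no true signals, strength 2, K = 50,000, count-dense rates
(baselines 0.01–0.03, exposures 0.005–0.03) and 20-fold within-cluster
co-prescription — the setting of a quantitative bias analysis on a
well-reported pair within a densely co-prescribed class, where systematic
bias dominates the sampling-noise floor and the prescription profile
actually carries the confounder information the PS needs. Determinism is
checked by running the simulate/score/evaluate pipeline twice in fresh
processes at a reduced world size and hashing the outputs.

## Known limitations

* The 14-feature registry is a reconstruction of the three named feature
  families; definitions are pluggable precisely so alternative sets can be
  swapped in.
* PS adjustment is regression adjustment only (no matching/stratification),
  and the PS is linear-logistic in the PC scores; residual confounding
  remains when the prescription profile only weakly identifies the
  confounder.
* Wald intervals for PRR/ROR and the delta-method IC variance are the
  conventional companions of these statistics, not exact small-sample
  intervals.
* The EBGM prior fit can be multi-modal; the fixed classical start plus
  bounded optimization makes it reproducible rather than provably global.
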