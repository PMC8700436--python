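# Methods

## Model and scope

`anblearn` treats classification as learning a generative Bayesian network
B = (G, Θ) over discrete variables V = {X0, X1, …, Xn} with X0 the class.
The joint factorizes as P(V) = Π_i P(X_i | Pa_i), and a fitted network
classifies by the class posterior, which depends only on the Markov
blanket of X0 (its parents, children, and the children's other parents).

Two structure spaces are searched exactly:

* **GBN** — every DAG over V;
* **ANB** — augmented naive Bayes: Pa_0 = ∅ and X0 ∈ Pa_i for every
  feature, with arbitrary (acyclic) feature–feature edges.

The ANB space always contains an I-map of the true distribution (the
complete ANB), so a consistent score finds the fewest-parameter ANB I-map
asymptotically. When additionally (i) the true distribution is faithful to
some DAG, (ii) every feature lies in the Markov blanket of X0, and (iii)
every blanket member is adjacent to X0, the optimal ANB is
classification-equivalent to the true structure: it asymptotically yields
the same class posterior while keeping the class variable parentless, which
is exactly what stabilizes parameter estimation on small samples. When
those assumptions fail, the learned ANB still converges to the best ANB
I-map, but its posterior need not coincide with the truth's.

## Scoring

All scores are natural-log BDeu with hyperparameters N′/(r_i q_Pai) and a
single equivalent sample size N′ (`ScoreParams.ess`, default 1.0 — the
value that lets the data dominate the prior). The local score is computed
with `scipy.special.gammaln` in double precision; an all-zero table scores
exactly 0, and fractional (expected) counts are accepted since log-Gamma is
defined on the reals. BDeu is score-equivalent: Markov-equivalent DAGs
receive equal scores, so the search effectively optimizes over equivalence
classes. Scores are cached per (child, parent set); parent sets with more
than 10^7 joint configurations are rejected outright rather than risking
silent overflow.

The Bayes factor for the zero-order independence test is the difference of
two local scores, log BF(X0, X_i) = Score(CFT(X0, ∅)) − Score(CFT(X0,
{X_i})); it is never exponentiated internally.

## The dynamic program

Phase 1 scores every admissible (child, parent set) pair; phase 2 builds
best-parent tables g_i*(S) over the subset lattice in ascending numeric
(hence ascending-subset) order; phase 3 finds, for every subset, the best
sink — the variable that can be made childless at the least cost — and the
optimum is reconstructed by peeling sinks off the full set. In ANB mode the
lattice spans features only; the class's constant marginal score is dropped
during the search and restored in the reported network score. Iteration
counts of the three phases are instrumented and exposed
(`dp_work_counts`); the ANB lattice is strictly smaller than the GBN
lattice on the same variables.

Tie-breaking is deterministic and documented: among equal-scoring parent
candidates the smaller set wins, then the smaller bit-mask encoding; among
equal-scoring sinks the lowest variable index wins. The default variable
cap is 25 (tables are O(n·2^n) memory); no max-parents option exists in
exact mode because it would void the optimality guarantee.

`brute_force_optimum` is an independent oracle, not a fallback: it
enumerates all topological orders with every parent subset drawn from the
predecessors, which covers every admissible DAG, and is capped at 5
variables (GBN) or 5 features (ANB). Exact float agreement with the DP is
not expected when the argmaxes are distinct score-equivalent structures
(different summation orders differ in the last ulp); agreement is checked
to 1e-9, far below any score gap between non-equivalent structures.

## Parameters and classification

`fit_eap` applies θ̂_ijk = (N′_ijk + N_ijk)/(N′_ij + N_j). The default
prior (`PriorSpec.ess = 1.0`, i.e. N′_ijk = 1/(r_i q_Pai)) coincides with
the BDeu score's hyperparameters; under it the EAP product is the Bayesian
predictive distribution, so Markov-equivalent structures fitted on the same
data give identical class posteriors (classification equivalence at finite
N). Unseen parent configurations fall back to the uniform prior-only
estimate — that is what the formula yields at zero counts, no extra
smoothing is added. Posteriors are accumulated in log space and normalized
by log-sum-exp; prediction ties break to the lowest class index.

## Feature selection and tuning

The PC screen performs exactly n zero-order Bayes-factor tests (no
conditioning sets — higher-order tests are less reliable at fixed N) and
removes X_i when log BF > ln δ. Larger δ therefore removes *fewer*
features: the kept set grows monotonically with δ. The grid N′ ∈ {1, 2, 5},
δ ∈ {3, 20, 150} is tuned by two-fold cross-validated accuracy of the full
pipeline (select → exact ANB → EAP → classify), with the same N′ shared by
the test statistic and the structure score. Ties prefer smaller N′, then
smaller δ (weaker prior, more inclusive selection). Folds are a seeded
unstratified shuffle. If every feature is removed, the pipeline returns the
class-marginal classifier — the only total behavior. Within
`cross_validate_accuracy(..., method="fsanb")` the tuning is nested inside
each training fold; `fit_fsanb` on a whole dataset tunes once.

## Preprocessing

CSV rows containing the missing marker `"?"` (or an empty cell) are
deleted before anything else; no imputation. Declared continuous columns
are binarized at the whole-column sample median (before any train/test
split), with ties at the median going to the low bin. Categorical states
are sorted lexicographically and indexed from 1. Columns with a single
observed state are rejected. Parent configurations are enumerated in a
fixed mixed-radix order (ascending parent index, last parent fastest)
shared by frequency tables, CPTs, and the BIF/JSON writers, so every
artifact is bit-reproducible.

## Synthetic generator and evaluation protocol

`random_discrete_network` draws a random DAG (uniform parent subsets of a
random topological order, bounded by `max_parents`) with CPT rows from a
symmetric Dirichlet(1). A child's CPT is resampled until, for every parent
and every configuration of the remaining parents, the rows across that
parent's states differ by at least 0.1 in total variation
(`min_parent_effect`). This keeps fixtures strictly faithful: a parent
whose effect can vanish puts the distribution arbitrarily close to
unfaithfulness, where no finite sample identifies the structure. With
`anb_like=True` the generator emits ground truths satisfying the three
assumptions above (class parentless and adjacent to every feature). What
the generator does *not* emulate: real datasets' mixed cardinalities with
dominant states, deterministic or near-deterministic mechanisms (present
in the bundled chest-clinic network, which is the designated
assumption-violating benchmark), missingness, and selection bias — so
passing recovery tests speak to correctness of the algorithms, not to
field performance on arbitrary data.

Evaluation follows a two-axis protocol over growing sample sizes:

* **SHD** between the learned ANB and the population-optimal ANB, both
  reduced to equivalence-class patterns (CPDAGs: v-structure edges plus
  the closure under the standard orientation rules) and compared pairwise
  by edge status. The population-optimal reference is computed by running
  the same exact ANB search on expected counts N_ref · P(config) under the
  generating network's exact joint (N_ref = 10^6), which removes sampling
  noise from the oracle.
* **Class-posterior KLD**, Σ_x P_ref(x) Σ_c P_b(c|x) ln[P_b(c|x)/P_a(c|x)],
  with b the true structure EAP-fitted on the same training sample and a
  the learned model, x enumerated exactly over all feature configurations
  (capped at 2^20) and weighted by the generating network's exact feature
  marginal. Fitting the true structure on the same sample is the only
  reading under which the divergence can reach exactly 0 at finite N once
  the learned structure is classification-equivalent to the truth.
  Rounding can push an identically-zero sum a few 1e-17 below zero; totals
  in (−1e-12, 0) are clamped to 0.

## Numerical and design choices

* Natural-log everywhere; ratios exponentiated only for display.
* CPT row normalization tolerated to 1e-6 on file input, 1e-9 after
  fitting; posterior normalization is exact by construction (log-sum-exp).
* CPDAG computation is rule-based at every size; the exhaustive-orientation
  construction exists in the test suite as an oracle, since it is
  exponential in edge count.
* SHD is defined on CPDAGs (direction mismatch counts 1, presence/absence
  counts 1); raw-DAG comparison can be done by comparing `edges()`
  directly, but the pattern-based distance is the default because the
  search is only identified up to Markov equivalence.
* All randomness flows through `numpy.random.default_rng` seeds; every
  public stochastic function takes an explicit seed.

## Problem sizes

The bundled protocols run at deliberately modest scale: exactness batteries
use 2–5 variables where exhaustive enumeration is feasible; recovery
studies use ≤8-variable networks at up to 10^5 samples with a 10^6
pseudo-count reference. These sizes exercise every code path while keeping
the whole suite fast on one CPU.

## Known limitations

* Exact search memory is O(n·2^n): beyond ~20 features the DP is the wrong
  tool, and the cap refuses rather than degrades.
* The score assumes complete data; rows with missing values are dropped,
  which biases estimates when missingness is informative.
* The Bayes-factor screen is zero-order by design: a feature independent
  of the class marginally but dependent conditionally (e.g. a pure
  interaction partner) will be discarded.
* Recovery of the *weakest* edge of a generating network is governed by
  its signal at the given sample size; fixtures whose smallest parent
  effect sits near the generator's 0.1 floor can need more than 10^5
  samples for the last edge, even though the score is consistent and the
  classification divergence is already negligible there.
* Discriminative (conditional-likelihood) learning, >2-bin discretization,
  and imputation are out of scope.
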