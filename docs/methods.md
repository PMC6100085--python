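# Methods

## Model and scoring

A causal Bayesian network over discrete variables `X_1 … X_n` is a DAG
plus, per node, a conditional probability table with one row per parent
configuration (rows ordered lexicographically in the parent states, last
parent fastest-varying). Structure learning maximizes the Cooper–Herskovits
(K2) marginal likelihood of the data under uniform Dirichlet priors. The
local score implemented is

```
ln g(X_i, π_i) = Σ_j [ lnΓ(r_i) − lnΓ(N_ij + r_i) + Σ_k lnΓ(N_ijk + 1) ]
```

with the structure score the sum of local scores. Three numerical choices:

* **Log-gamma, not factorials.** Literal factorials overflow beyond counts
  of ~170; `gammaln` is exact to machine precision at the relevant
  magnitudes, and the acceptance suite pins it to an exact
  rational-arithmetic oracle (`fractions.Fraction` with integer
  factorials) at small sample sizes, worst observed error ~1e-15.
* **Observed configurations only.** Parent configurations with `N_ij = 0`
  contribute exactly zero, so the count table is materialized only over
  configurations present in the data; a node with many high-cardinality
  parents never allocates its full `q_i`-row table.
* **Dropped structure-prior constant.** The uniform prior over structures
  multiplies every score equally and cannot change an argmax.

Greedy K2 under an order adds, per node, the single predecessor with the
largest strictly positive gain (`> 1e-12`, ties broken by earliest order
position) until nothing improves or the parent cap μ is reached. μ defaults
to 4 and is configurable everywhere; results are insensitive to it on the
sparse ground truths used here. Local scores are memoized in a cache keyed
on (node, frozen parent set) shared across all orders in a search run —
different orders revisit the same queries constantly, and this cache is the
dominant cost saver of the whole package.

## Order search

**Distance.** Two orders are compared by counting, for every variable, the
variables that precede it in *both* orders; the distance is
`n(n−1)/2 − overlap`. This equals the Kendall-tau pair-disagreement count
(verified exhaustively in tests), hence is a genuine metric: identical
orders are at distance 0, reversed orders at `n(n−1)/2`. Using the raw
overlap itself as a "distance" would cluster maximally different orders
together, so the complement is taken.

**Clustering.** Permutations have no mean, so k-means is replaced by a
PAM-style k-medoids (seeded initialization, assignment/update alternation
capped at 50 rounds, empty clusters re-seeded from the farthest member of a
non-singleton donor). After the partition settles, the *best-scoring*
member of each cluster — not the medoid — is marked as the cluster center,
matching the "optimal individual as center" convention of brain-storm
optimization. The population is re-clustered every iteration.

**Generation.** Per iteration, each member proposes one candidate built
from a single cluster (its center, or a random member) or from the fusion
of two clusters (their centers, or random members), clusters drawn with
probability proportional to size. Fusion is rank-averaging: each variable's
key is the mean of its two positions plus a ~1e-6 uniform jitter that
breaks ties uniformly; the merged order sorts the keys. Perturbation
applies `max(1, round(ξ·n))` random insertion moves — a discrete stand-in
for adding scaled Gaussian noise to a real vector, chosen because the
number of moves preserves the schedule's explore→exploit semantics:
`ξ = logsig((0.5·max_iteration − t)/k)·U(0,1)` starts near a full uniform
draw and decays to zero past the midpoint. The slope `k` defaults to 20; a
candidate replaces its member only if strictly better, so the best-score
trace is non-decreasing. With probability 0.2 per iteration one cluster
center is replaced by a fresh random order (re-seeding). Defaults
(population 50, 5 clusters, 100 iterations, stall limit 20, generation
probabilities 0.8/0.4/0.5) follow common brain-storm-optimization practice;
all are configurable, and an optional evaluation budget allows matched-cost
comparisons between searchers.

**Baselines.** Random restart scores fresh random orders in batches and
stops after 10 consecutive batches without improvement. The genetic
baseline uses order crossover (OX), tournament selection and one-elite
survival; its defaults apply exactly one insertion move to every offspring
and keep the tournament binary. That choice is deliberate: order spaces
induced by the K2 score are full of near-ties, and stronger selection with
rare mutation collapses the population onto one plateau before the optimum
is reached.

## Direction learning

K2 cannot see past a Markov equivalence class, so edges of the learned
skeleton are oriented by additive-noise-model asymmetry on continuous
mechanism data: `X_i = f(parents) + ε` with ε independent of the parents is
(generically) fittable only in the causal direction. Per sub-skeleton (a
target plus all its skeleton neighbors), every candidate parent set of size
1..3 is fitted by kernel ridge regression (RBF kernel, bandwidth from the
median pairwise distance of the standardized regressors, ridge strength
from a 3-fold cross-validated grid over {1e-3, 1e-2, 1e-1, 1}), and
residual independence is tested by HSIC with RBF kernels and a permutation
null (default 200 permutations, add-one p-value, level α = 0.05).

Two design points deserve emphasis:

* **Union of accepted sets.** When a target has several mutually
  independent parents, regressing on one of them leaves the others'
  contribution in the residual — which is still independent of the
  regressor, so each true parent is accepted *on its own*. Taking only the
  smallest accepted set would therefore orient a strict subset; the
  emitted parents are the union of all accepted candidate sets. Supersets
  that include children are rejected naturally (regressing on a child
  makes the residual depend on the regressors).
* **Deterministic-fit guard.** A noiseless functional relation leaves
  residuals that consist purely of the regularized fit's tiny smooth bias;
  the scale-free HSIC would flag that bias as dependence. A fit whose
  residual standard deviation is below 1% of the target's is accepted as
  an exact function (p set to 1).

The regression is kernel ridge rather than Gaussian-process regression and
the test is unconditional HSIC: the decision rule — accept iff residuals ⫫
candidates — only ever needs a posterior-mean regressor and a marginal
independence test, and both choices are deterministic given a seed. The
discrete pipeline does not use this stage at all (the ANM asymmetry as
fitted here is a continuous-data mechanism); it keeps the directions of the
K2 DAG found under the optimal order.

## Framework

Below a dimension threshold (default 50) one global BSO+K2 pass is run.
At or above it, a reduced-budget provisional pass builds a provisional
skeleton, per-node neighborhood blocks are learned separately, and the
block results are merged: a pair directed anywhere and undirected elsewhere
stays directed; a pair directed both ways across blocks is demoted to
undirected and logged; if the merged directed subgraph contains a cycle,
cycle edges are demoted starting with the fewest supporting blocks (ties:
latest added) until acyclic. Continuous input is quantile-discretized
(3 bins) for the count-based skeleton phase only; the ANM stage always sees
the raw values.

## Synthetic data

The generators define the test conditions for every stage:

* `random_dag` draws edges from earlier to later nodes of a hidden random
  permutation (acyclic by construction, in-degree capped) and CPT rows from
  Dirichlet(1,…,1) — flat over the simplex, so dependence strengths vary
  realistically from draw to draw, including occasionally undetectably
  weak edges.
* `forward_sample` is ancestral sampling through the CPTs in topological
  order; its marginals are tested against brute-force enumeration of the
  joint.
* `anm_sample` makes roots pure noise and non-roots a sum of per-parent
  cubic-plus-linear terms (coefficients U(0.5, 1.5), parent columns
  standardized so chains do not blow up) plus non-Gaussian noise — uniform
  `amplitude·U(−1,1)` by default, or a variance-matched Laplace draw;
  amplitudes are drawn per node from U(0.5, 1). Gaussian noise is
  deliberately excluded: in the linear limit the ANM direction is
  unidentifiable under Gaussianity, and the defaults keep the orientation
  problem well-posed.

What the generators do *not* emulate: latent confounders, selection bias,
time-series dependence, measurement noise on discrete states, and the
deterministic or near-deterministic CPTs common in expert-built benchmark
networks. Passing tests therefore demonstrate correctness of the machinery
and recoverability under faithful, confounder-free sampling — not
performance on any particular real-world network.

## Problem sizes and determinism

The test and acceptance workloads use problems where independent oracles
are exhaustively computable — 4-variable order/DAG enumerations (24 orders,
543 DAGs), 5-node recovery at N = 2000, an 8-node searcher comparison at a
2000-evaluation budget, and 300-sample ANM pairs — with 10 repetitions
where a rate or mean is asserted. Every stochastic component flows through
an explicitly seeded `numpy` generator; no global random state is touched,
and sub-seeds are derived via `SeedSequence` spawning so stages are
independent but reproducible.

## Known limitations

* Greedy K2 under the best order is not guaranteed to find the best
  structure consistent with that order (pathological parity-type
  mechanisms defeat single-parent gains); the order-space/DAG-space
  equivalence asserted in the acceptance suite holds for generic CPTs.
* The ANM stage assumes causal sufficiency and continuous mechanisms; it
  abstains (leaves edges undirected) rather than guessing when no
  candidate set passes.
* The split/merge path trades global coherence for tractability: block
  results can conflict, and the demotion rules resolve conflicts
  conservatively (toward undirectedness).
* BIF support is a minimal table-form subset — enough to round-trip the
  package's own networks and read simple benchmark files, not a full
  grammar.
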