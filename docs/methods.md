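# Methods

## Graphs, messages and scales

A model is a product of factors over variables.  The graph stores factors
as nodes and variables as edges; an edge holds at most two node
attachments, and `normalize_shared_variables` rewrites any variable shared
by more than two factors as a *chain* of arity-3 equality nodes
(`x → x, x__1, x__2, …`).  A chain rather than a star keeps every node at
arity 3 and makes traces reproducible; auxiliary copies carry an `origin`
pointer back to the variable they duplicate and are flagged as auxiliary in
reported marginal sets.  Observed variables are represented by attaching an
observation-terminal node that emits a delta message `δ(o − ô)`, so
observation handling is ordinary message passing rather than a special
case; when normalization moves a terminal onto an auxiliary copy, the
observed value moves with it.

Messages are unnormalized beliefs with explicit scale.  Gaussians are held
in exponential form `b(x) = exp(−½xᵀWx + hᵀx + g)` with an absolute offset
`g`: products are parameter additions, improper beliefs (singular `W`, e.g.
the likelihood message of a low-dimensional observation on a
higher-dimensional state) flow through equality fusion and gain pullbacks
without approximation, and convolution with an improper operand is done by
exact marginalization of the joint exponential form.  Categorical beliefs
live in log space with max-subtraction.  The vacuous belief is a distinct
symbolic unit element, never a wide Gaussian.  The scale bookkeeping is what
makes "closing the box around the whole graph" return the evidence: on an
acyclic graph, the log-normalizer of the forward/backward product on any
edge of a connected component is that component's log evidence.

During *iterated* (loopy) sweeps, scales would otherwise compound around
cycles without bound and eventually absorb the informative part of the
message in floating point; the scheduler therefore strips scales from
messages when executing repeated sweeps.  Evidence computation runs its own
single tree pass with scales intact, so nothing is lost.

## Update rules

Sum-product messages are exact tensor contractions for table factors
(computed in log space) and closed forms for the linear-Gaussian nodes:
addition (means and variances add), subtraction, gain forward
(`m → a·m`, `v → a²v`; matrix gains use `Am`, `AVAᵀ`), gain backward via
the canonical form `W → AᵀWA` (valid for rank-deficient gains), equality
(precision-weighted fusion = Bayes' rule), and Gaussian priors.  A scalar
quadrature fallback exists for oracle duty and is never the production
path.  The variational rule emits `ν(target) ∝ exp(E_q[log f])` under the
current *marginals* of the other edges; at equality and prior nodes it
degenerates to sum-product (the expected log of a delta-product factor is
log-linear in the messages).

The Gaussian gain message used in transition-gain learning is the quadratic
form of `E_q[log N(s_t | β s_{t−1}, θ_s)]` in β: precision
`E[s_{t−1}²]/θ_s` and mean `m_{t−1}m_t / E[s_{t−1}²]`, with the mean-field
cross moment `E[s_{t−1}s_t] = m_{t−1}m_t`.  This form was validated against
a numerical-integration oracle (the message mean equals the maximizer of the
numerically integrated expected log-density to 1e−6) before being relied
on.  A structured (chain-block) alternative would use the smoothed cross
covariance; the mean-field version is the one implemented, and its bias is
negligible when observations pin the states (see study conditions below).

## Schedules

Tree schedules are generated by dependency recursion from terminals and
half-edges toward the targets and are exact in one pass (sum-product
theorem).  Full sweeps cover both directions of every edge — 2·|edges|
steps, counting the vacuous injection at a half-edge as a step — in
dependency order on trees and lexicographic (node id, edge id) order on
loopy graphs, starting from vacuous messages, Gauss–Seidel style.
Convergence is declared when the largest change in marginal parameters
(means and covariances, or probabilities) falls below `tol` (default 1e−8,
`max_sweeps` 50).  Damping is available but off by default.  Tie-breaks are
lexicographic throughout so traces are reproducible.

`partition_acyclic` honors builder-supplied sublayer labels — the 2a/2b
split of a hierarchical layer and the 2a/2b/2c split of an active-inference
layer are modeling choices, not derivable graph properties — and falls back
to a greedy union-find forest cover for unlabeled graphs.

## Free energy

`F[q]` is evaluated against the graph's *logical* factorization: the
conditional densities of the model the graph represents, recorded by the
builders (for Gaussian chains) or derived from the table/prior nodes (for
discrete graphs).  Working at this level avoids the ill-defined expected
log-deltas that the primitive decomposition (gain + noise-addition +
equality) would produce under a factorized proposal.  Proposals are block
partitions of the hidden variables: per-variable blocks (naive mean field,
the default) or joint categorical blocks; Gaussian block expectations are
evaluated analytically, never by sampling.  Coordinate updates
`q_i ∝ exp(E_{q_{j≠i}}[log p])` are exact minimizers, so the free energy is
non-increasing by construction; this is asserted at 1e−9 per step in the
tests.  `decompose` splits `F` into surprise plus divergence and treats a
divergence below −1e−9 as an inconsistency error.

A caveat that matters in practice: with factorized proposals,
`E_q[log f]` diverges if `q` puts joint mass on a zero of a table factor.
The shipped discrete demos therefore use strictly positive (softened)
tables whenever free energy is evaluated on mean-field proposals.

## Gain learning

`learn_gain` alternates (i) exact coordinate updates of every per-state
Gaussian marginal in time order with (ii) the fused gain update — prior
times the per-slice gain messages — and records the free energy each sweep.
Initialization is one filtering pass at the prior-mean gain.  Time slices
whose observation carries no evidence (missing value, or infinite
observation noise) contribute **no** gain message: naive mean field would
otherwise manufacture spurious gain precision out of unobserved slices, and
with nothing to explain the posterior should be the prior, which this
choice makes exact in the vacuous-likelihood limit.  When no slice is
informative the routine returns the prior immediately.

Study conditions for gain recovery: true gain β = 0.8, n = 200 steps,
process noise θ_s = 1, observation noise θ_o = 0.1, prior β ~ N(0, 1),
state prior N(0, 1).  Observation noise an order of magnitude below process
noise keeps the states close to observed, which is the regime in which a
scalar-gain demo is interpretable and in which the mean-field cross-moment
approximation is benign.

## Hierarchical and active-inference layers

Layers are categorical: likelihood `A[o,s]`, controlled transition
`B[s',s,u]`, parent-conditioned initial-state prior `D[s₀,parent]` and
control priors `G[u,parent]` (optional; uniform if absent), with a temporal
nesting ratio `steps_per_parent` (2 in the shipped three-layer demo, 1
step at the top; arbitrary ratios supported).  The Gaussian family for a
single layer is covered by the LGDS builder.  Inference runs top-down
prediction and bottom-up correction passes over the labeled acyclic
sublayers, iterated to a fixed point.

Parent-conditioned priors make layers loopy, so converged marginals are
Bethe-style approximations, not exact posteriors.  Exactness-against-
enumeration checks therefore run on instances whose topology (or effective
topology after clamping) admits exact propagation: hierarchies with
state-independent control priors are trees, and in the active-inference
toy the clamped parent context cuts every loop informationally (delta
messages make the loop-closing edges constant), which the tests confirm by
machine-precision agreement with enumeration.  Loopy instances are checked
separately for convergence, closeness to enumeration (tolerance 0.05), and
information ordering.

The information-ordering check — clamping the slow parent state to its
simulated value sharpens beliefs about fast bottom-layer states — holds *in
expectation over realizations*, not per seed (conditioning can legitimately
increase the posterior entropy of a particular realization).  The test
instance is a "copy hierarchy" (each layer tends to copy its parent's
state; sharp top-down conditioning, weak in-layer likelihoods) averaged
over 8 seeds.

The DTAI layer implements the policy model literally: preference priors `C`
(over mirror observations, conditioned on the parent) and `D̄` (over mirror
states) terminate a mirror chain whose `A`/`B` tables are the *same arrays*
as the executed chain's (tied, not copied).  `dtai_step` runs the phases in
order — priors, mirror forward simulation, backward pass treating the
preferences as observations, control inference (the policy prior over
controls is read out here, before any evidence), executed-chain prediction,
evidence absorption and correction, and upward passes (one extra mirror
pass by default, more via `sweeps`).  The free energy of the mean-field
proposal assembled from the current marginals is evaluated after the
prediction phase and after the correction phase; absorption reduced it on
every tested instance.  Prior learning is a conjugate pseudo-count update:
counts grow by `learning_rate × (child marginal ⊗ parent marginal)` and the
table renormalizes per parent column, so the total pseudo-count grows by
exactly the learning rate per update.

Where a control edge connects only the mirror and executed transition
factors it needs no equality junction (two attachments); the combined
posterior is simply the forward/backward product on that edge.

## Oracles

Three independent references, sharing no rule code with the engine:
exhaustive enumeration for discrete graphs (vectorized tensor summation,
refusing state spaces above 10⁷ configurations, order-permutation
self-check), joint-Gaussian posteriors by assembling the precision matrix
and conditioning on observations, and the classical Kalman predict/update
recursion with the prediction-error evidence decomposition.  Tolerance
budget: 1e−10 for discrete agreement, 1e−9 for Gaussian chains.

## Problem sizes

The shipped checks use: 100 random trees of ≤6 variables × ≤4 states;
100-step scalar and 2-D Kalman runs; n = 200 gain-recovery series over 20
seeds; a three-layer ratio-2 hierarchy (≤2²⁵ configurations before
clamping, enumerated only with observations attached); and 2-state toys for
the active-inference layer.  These sizes keep exhaustive oracles exact and
the full suite fast on a single CPU.

## Known limitations

* Sum-product on loopy graphs is approximate (as everywhere); no Bethe
  free energy is reported — `F` always refers to an explicit proposal.
* Variational messages for continuous factors cover the linear-Gaussian
  family (including the gain message); there is no general exponential-
  family VMP.
* Structured Gaussian proposal blocks (whole chains) are not implemented;
  Gaussian proposals are per-variable.
* `gaussian_exact` requires fixed (non-random) gains; graphs with a gain
  *variable* are handled by the variational path only.
* Composite nodes always pass messages internally; no custom composite
  update rules.
* Multi-layer DTAI stacks (policy layers at several depths simultaneously)
  are not orchestrated by `dtai_step`, which drives one policy layer below
  a given (possibly clamped) parent context.
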