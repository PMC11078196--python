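# Methods

## Hypergraph dynamical systems

A hypergraph `H` on `N` nodes stores its hyperedges grouped by cardinality
`d ∈ {2, …, k}`; the topological order `k` is the largest cardinality. The
system state is a vector `x ∈ ℝ^N`, and node `i` evolves by summing, over
every hyperedge containing `i`, a per-size update function `f_d` applied with
`i` as the distinguished center argument and the remaining member states as
an unordered multiset. `f_1` is fixed to zero: only interactions drive the
dynamics. Equivalently, per size `d`, the state is lifted into edge-local
coordinates by the `(d·M_d) × N` lifting matrix `L_d` (one 0/1 indicator
block per edge, rows within a block ordered by ascending node index), the
nonlinear update is applied blockwise, and the transpose projects the
updates back onto nodes. The per-node summation is the production code path;
the lift–update–project route is implemented independently and the two are
checked against each other to 1e−12 in the tests.

All nodes act identically: `f_d` is symmetric in its last `d−1` arguments.
This is the key structural assumption; systems with a priori node classes
are out of scope.

## Interaction kernels and generative order

The named dynamics are assembled from a `p`-ary kernel `φ^p`:
edges of size `d ≤ p` apply the full-arity kernel, and edges of size `d > p`
sum the kernel over all `(p−1)`-subsets of the neighbor multiset. Kernels
(center `y`, neighbors `y_j`):

| name | formula | state space | initial law |
|---|---|---|---|
| kuramoto | `sin(Σ_j (y_j − y))` | phases | uniform [−π, π] |
| si | `(1 − y) Π_j y_j` | infection prob. | uniform [0, 1] |
| mcm | `exp(λ(ȳ − y)) · Σ_j (y_j − y)`, `λ = −1` | opinions | Beta(2, 5) |
| diffusion | `Σ_j (y_j − y)` | reals | uniform [−1, 1] |

`ȳ` is the mean of all `p` member values of the kernel (center included).
The multi-way consensus model's printed form is typographically ambiguous
about whether the exponent averages over the kernel arity or the edge size;
averaging over the kernel's own `p` arguments keeps each kernel
self-contained per arity and is the convention used throughout. The MCM
initial law must be right-skewed for the reinforcement term to matter;
Beta(2, 5) is a simple such law and is configurable. `full_kuramoto` wraps
the sine around the whole within-edge phase sum at every size (order cap
`k`): for `d ≥ 3` that update does not decompose, so its dynamical order
equals the edge size.

`verify_decomposition` certifies a claimed decomposition numerically: it
draws argument tuples uniformly from a kernel-appropriate domain ((0, 1]^d
for the log-product family, [−π, π]^d for sine kernels, [0, 1]^d otherwise)
and reports the maximum absolute residual between `f_d` and its subset
expansion. Residuals at round-off level (< 1e−10) certify; residuals bounded
away from zero (> 0.1 for the full-sine coupling at d = 3) are
counterexamples. This is a sampling check on a domain, not a symbolic proof;
for the families shipped here the identities are exact, so the distinction
is immaterial.

## Synthetic data

The Erdős–Rényi generator enumerates every candidate node subset per size
and draws one Bernoulli each — exact per-subset probabilities, feasible at
the reference scale (20 nodes; inclusion probabilities 0.1 / 0.01 / 0.001
for pairs / triples / quadruples, giving expected counts 19 / 11.4 / 4.8 and
topological order 4 with ~99% probability per draw). Two observation
scenarios:

- **point**: one fresh hypergraph per sample, one initial state from the
  dynamics' law, and the exact right-hand side as the derivative (reference
  scale: 500 samples);
- **trajectory**: one hypergraph per trajectory, forward-Euler integration
  (Δ = 0.01, 100 steps; reference scale 25 trajectories = 2500 tuples),
  derivatives by forward time difference — which, under Euler data, equal
  the right-hand side at the stored states to round-off.

The generator emulates the study conditions exactly but none of the
frictions of real data: no observation noise, no irregular sampling, no
unobserved nodes, and derivative access (point scenario) that real
experiments rarely have. Passing tests therefore demonstrate correctness of
the machinery and recoverability of order under clean conditions, not
robustness to measurement error.

Cross-validation folds partition samples **by hypergraph**, so temporally
correlated samples of one trajectory never straddle a train/test boundary;
fold sizes differ by at most one hypergraph.

## The learnable model

For each size `d` the model holds one MLP with `m = min(p_model, d)` inputs,
two tanh hidden layers of width 32, and a scalar linear output (Glorot
initialization). The symmetrized per-edge update averages the MLP over input
orderings; for `p_model < d` it additionally sums over neighbor subsets.
The implementation uses the identity

    (1/(d−1)!) Σ_{orderings π} Σ_{leading subsets} MLP(y_1, …)
      = Σ_{unordered subsets v} (1/(m−1)!) Σ_{orderings of v} MLP(y_1, …)

so each subset is enumerated once and only its `(m−1)!` orderings are
averaged; the exhaustive `(d−1)!` permutation average is kept as a test
oracle. Symmetry is exact by construction (and bit-exact in
`symmetric_eval`, which canonicalizes the neighbor order before
enumeration). The factorial cost of symmetrization is why orders above ~5
are impractical; the shipped experiments use `k = 4`.

Training minimizes `Σ_i ‖M̂(x⁽ⁱ⁾) − ẋ⁽ⁱ⁾‖₁ + λ‖θ‖₂²` (the penalty is the
squared L2 norm, i.e. weight decay; `λ` defaults to 1e−5 and can instead be
selected from a grid via an 80/20 validation split). Optimization is Adam
with subgradients of the L1 term. Because L1 subgradients keep constant
magnitude regardless of residual size, a constant step keeps the parameters
bouncing at a step-size-limited floor; a cosine learning-rate decay (3e−2
down to 1% of that) removes the floor. Minibatches of 16 samples give
several Adam steps per epoch and converge markedly faster per unit compute
than full-batch; 600 epochs is the default budget. These optimizer settings
were chosen by held-out fit quality on the pairwise dynamics at desk scale
(100 samples), where the best achievable MAE is limited only by optimization.
Derivative targets are used exactly as generated — no input or target
normalization — since all shipped dynamics have O(1) scales.

Gradient evaluation is vectorized: each (hypergraph, size) pair is compiled
once into gather/scatter index arrays mapping flattened node states to MLP
input rows and MLP outputs back to node slots, so a whole dataset evaluates
in a handful of matrix products per size.

## Order selection

For candidate orders `p_model ∈ {2, …, k}`, k-fold cross-validation records
the held-out pointwise MAE of predicted derivatives (point data) or the
rollout MAE against held-out trajectories (trajectory data; the model is
integrated from the ground-truth initial state over the same horizon and
the absolute state error is averaged over time points, nodes, then systems
— a diverging rollout counts as infinite for its system). The per-order
loss entering the score is the mean across folds; the lowest single fold is
also stored. The model-corrected performance

    MC-perf(p_model | X) = exp(−L/L_max) · exp(−p_model/k)

is maximized, ties going to the smaller order. Properties relied on: the
score is strictly decreasing in `L` at fixed order and in the order at fixed
`L`, lies in (0, 1], and is invariant to rescaling all losses by a common
factor (so the choice of MAE units cannot affect selection).

Learned-kernel surfaces are compared to the generating kernel after
removing a fitted constant offset: additive constants can migrate between
approximators of different arities without changing any model output on
fixed-degree nodes, so the offset is not identifiable and not meaningful.

## Problem sizes and reproducibility

The shipped experiment configurations run cross-validated three-order
selection on 100-sample point datasets (5 folds, 600 epochs) for diffusion
and pairwise Kuramoto, and 200-sample datasets (3 folds, 300 epochs, three
replicate seeds) for SI generated with 4-ary kernels — about 45 fits and
roughly a quarter of an hour on one CPU in total, a deliberate reduction
from the reference scale of 500 samples and 10 folds. At this scale the
selection outcomes are stable across seeds in our runs: diffusion and
pairwise Kuramoto select order 2, SI at `p = 4` selects order 3 (an
order-3 model already captures the dynamics because each additional
multiplicand in [0, 1] shrinks the infection term, and the complexity
penalty then prefers it). All randomness flows through explicit integer
seeds via `numpy.random.SeedSequence`; training is deterministic given the
seed.

## Known limitations

- No stochastic (event-driven) epidemic simulation; the SI model here is the
  deterministic mean-field ODE.
- Fixed-step forward Euler only, matching the data-generating scheme so
  learned-model rollouts are compared like-for-like; stiff dynamics would
  need smaller Δ.
- Symmetrization cost grows factorially with the order cap; `k ≤ 5` in
  practice.
- The real contact-pattern workflow ships only the hyperedge-list loader and
  order truncation; no dataset is bundled, and truncation drops oversized
  hyperedges entirely rather than expanding them into sub-edges.
- MC-perf compares only the candidate orders supplied; it ranks, it does not
  test goodness of fit in absolute terms.
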