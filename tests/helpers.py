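"""Independent brute-force oracles used to cross-check the implementation."""

from itertools import permutations

import numpy as np

from hyperdyn import Hypergraph, KernelFamily


def rhs_bruteforce(H: Hypergraph, family: KernelFamily, x: np.ndarray) -> np.ndarray:
    """Naive per-edge, per-center summation of the update functions."""
    xdot = np.zeros(H.num_nodes)
    for d in H.sizes:
        for edge in H.edges(d):
            for i in edge:
                nb = [x[j] for j in edge if j != i]
                xdot[i] += family.f(d, x[i], nb)
    return xdot


def clique_rhs_kuramoto(H: Hypergraph, x: np.ndarray) -> np.ndarray:
    """Pairwise-Kuramoto derivative on the clique expansion of a hypergraph.

    Every hyperedge contributes sin(x_j - x_i) for each ordered member pair,
    so the effective adjacency counts co-membership multiplicity.
    """
    N = H.num_nodes
    A = np.zeros((N, N))
    for edge in H.all_edges():
        for i in edge:
            for j in edge:
                if i != j:
                    A[i, j] += 1.0
    diff = x[None, :] - x[:, None]  # diff[i, j] = x_j - x_i
    return (A * np.sin(diff)).sum(axis=1)


def symmetric_eval_permutation_oracle(model, d, y_center, neighbors):
    """Symmetrized update via the explicit average over all (d-1)! orderings.

    For each neighbor ordering, sums the order-m approximator over the
    leading-order subsequences of that ordering, then averages — the
    literal symmetrization, independent of the model's subset fast path.
    """
    from itertools import combinations

    m = min(model.p_model, d)
    nb = list(neighbors)
    total = 0.0
    count = 0
    for perm in permutations(nb):
        fprime = 0.0
        for sub in combinations(range(d - 1), m - 1):
            inputs = np.array([[y_center, *(perm[i] for i in sub)]])
            y, _ = model.mlps[d].forward(inputs)
            fprime += float(y[0])
        total += fprime
        count += 1
    return total / count
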