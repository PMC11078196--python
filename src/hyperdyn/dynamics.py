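"""Interaction kernels, hypergraph dynamical systems, and order verification.

A hypergraph dynamical system couples a topology (a :class:`~hyperdyn.hypergraph.Hypergraph`)
with a family of per-edge update functions ``f_d`` that are symmetric in all
but their first (center) argument.  Node ``i`` evolves as

    dx_i/dt = sum over hyperedges E containing i of f_d(x_i, {{x_j : j in E, j != i}})

The update functions are assembled from a *p-ary kernel* ``phi^p``: on edges of
size ``d <= p`` the full-arity kernel is applied directly, while on larger
edges ``f_d`` is the sum of ``phi^p`` over all (p-1)-subsets of the neighbor
multiset.  The smallest ``p`` for which such a decomposition reproduces every
``f_d`` is the *dynamical order* of the system; :func:`verify_decomposition`
checks a claimed decomposition numerically.

Four named kernel families are provided: Kuramoto phase coupling
(synchronization), susceptible–infected contagion, a multi-way consensus model
with homophily reinforcement (MCM), and linear diffusion, plus the
non-decomposable full-edge Kuramoto coupling and a log-product family used as
an analytically reducible example.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Callable, Sequence

import numpy as np

from .hypergraph import Hypergraph, lifting_matrix

__all__ = [
    "Kernel",
    "KernelFamily",
    "Trajectory",
    "kernel_value",
    "full_kuramoto_f",
    "make_family",
    "rhs",
    "rhs_lifted",
    "euler_integrate",
    "verify_decomposition",
    "sample_initial_state",
    "KERNEL_NAMES",
]

KERNEL_NAMES = ("kuramoto", "si", "mcm", "diffusion", "full_kuramoto", "log_product")


@dataclass(frozen=True)
class Kernel:
    """A p-ary interaction kernel ``phi^p(y_center, neighbors)``.

    The arity ``p`` is implicit: it is one plus the number of neighbor values
    passed to :meth:`evaluate`.  All kernels are invariant to permutations of
    the neighbor multiset.

    Formulas (center value ``y``, neighbor values ``y_1 .. y_{p-1}``):

    - ``kuramoto`` / ``full_kuramoto``: ``sin(sum_j (y_j - y))`` — the sum runs
      over all ``p`` member values; the center's own difference contributes 0.
    - ``si``: ``(1 - y) * prod_j y_j`` over the ``p-1`` neighbors.
    - ``mcm``: ``exp(lam * (mean of all p member values - y)) * sum_j (y_j - y)``
      with homophily coefficient ``lam`` (default -1).
    - ``diffusion``: ``sum_j (y_j - y)``.
    - ``log_product``: ``log(y * prod_j y_j)`` (positive arguments).
    """

    name: str
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.name not in KERNEL_NAMES:
            raise ValueError(f"unknown kernel {self.name!r}; known: {KERNEL_NAMES}")

    @property
    def lam(self) -> float:
        return float(self.params.get("lam", -1.0))

    def evaluate(self, y_center: float, neighbors: Sequence[float]) -> float:
        """Scalar kernel value; ``neighbors`` must be non-empty."""
        nb = np.asarray(neighbors, dtype=float)
        if nb.size == 0:
            raise ValueError("kernel needs at least one neighbor value")
        return float(self.evaluate_rows(float(y_center), nb[None, :])[0])

    def evaluate_rows(self, y_center: np.ndarray | float, nb: np.ndarray) -> np.ndarray:
        """Vectorized evaluation: ``nb`` has one neighbor multiset per row."""
        y = np.asarray(y_center, dtype=float)
        name = self.name
        if name in ("kuramoto", "full_kuramoto"):
            return np.sin(nb.sum(axis=-1) - nb.shape[-1] * y)
        if name == "si":
            return (1.0 - y) * nb.prod(axis=-1)
        if name == "mcm":
            p = nb.shape[-1] + 1
            mean_all = (nb.sum(axis=-1) + y) / p
            return np.exp(self.lam * (mean_all - y)) * (nb.sum(axis=-1) - nb.shape[-1] * y)
        if name == "diffusion":
            return nb.sum(axis=-1) - nb.shape[-1] * y
        if name == "log_product":
            return np.log(y) + np.log(nb).sum(axis=-1)
        raise ValueError(f"unknown kernel {name!r}")


def kernel_value(kernel: Kernel, y_center: float, neighbors: Sequence[float]) -> float:
    """Evaluate ``kernel`` at a single (center, neighbor-multiset) argument."""
    return kernel.evaluate(y_center, neighbors)


def full_kuramoto_f(d: int) -> Callable[[float, Sequence[float]], float]:
    """The size-``d`` full-edge Kuramoto update ``sin(sum_i (y_i - y_center))``.

    The sine wraps the whole within-edge phase sum, so for ``d >= 3`` this
    update does not decompose into lower-arity functions: its dynamical order
    equals the edge size.  At ``d = 2`` it coincides with the pairwise
    Kuramoto kernel.
    """
    if d < 2:
        raise ValueError(f"edge size must be >= 2, got {d}")
    kern = Kernel("full_kuramoto")

    def f(y_center: float, neighbors: Sequence[float]) -> float:
        nb = np.asarray(neighbors, dtype=float)
        if nb.size != d - 1:
            raise ValueError(f"expected {d - 1} neighbors, got {nb.size}")
        return kern.evaluate(y_center, nb)

    return f


@dataclass(frozen=True)
class KernelFamily:
    """Per-size update functions assembled from an order-``p`` kernel.

    ``f_1`` is identically zero.  For edge size ``d <= order_cap`` the update
    is the full-arity kernel; for ``d > order_cap`` it is the sum of the
    kernel over all ``(order_cap - 1)``-subsets of the neighbor multiset, so
    the resulting system has dynamical order at most ``order_cap``.
    """

    kernel: Kernel
    order_cap: int
    max_size: int

    def __post_init__(self) -> None:
        if not 2 <= self.order_cap:
            raise ValueError(f"order_cap must be >= 2, got {self.order_cap}")
        if self.max_size < self.order_cap:
            raise ValueError(
                f"max_size {self.max_size} smaller than order_cap {self.order_cap}"
            )

    def f(self, d: int, y_center: float, neighbors: Sequence[float]) -> float:
        """Update ``f_d`` for one (center, neighbor-multiset) argument."""
        nb = np.asarray(neighbors, dtype=float)
        if nb.size != d - 1:
            raise ValueError(f"f_{d} expects {d - 1} neighbors, got {nb.size}")
        return float(self.f_rows(d, float(y_center), nb[None, :])[0])

    def f_rows(self, d: int, y_center: np.ndarray | float, nb: np.ndarray) -> np.ndarray:
        """Vectorized ``f_d``: one neighbor multiset per row of ``nb``."""
        p = self.order_cap
        if d <= p:
            return self.kernel.evaluate_rows(y_center, nb)
        out = None
        for sub in combinations(range(d - 1), p - 1):
            term = self.kernel.evaluate_rows(y_center, nb[..., sub])
            out = term if out is None else out + term
        return out


def make_family(dynamics_name: str, p: int, k: int, **params) -> KernelFamily:
    """Build the named dynamics restricted to ``p``-ary update functions.

    ``full_kuramoto`` ignores ``p`` and uses full-arity couplings on every
    edge size up to ``k`` (order cap ``k``).
    """
    if dynamics_name == "full_kuramoto":
        return KernelFamily(Kernel("full_kuramoto", params), order_cap=k, max_size=k)
    return KernelFamily(Kernel(dynamics_name, params), order_cap=p, max_size=k)


def rhs(H: Hypergraph, family: KernelFamily, x: np.ndarray) -> np.ndarray:
    """State derivative of the hypergraph dynamical system at state ``x``.

    Per-node summation form: every hyperedge containing node ``i``
    contributes ``f_d`` with ``i`` as center.
    """
    x = np.asarray(x, dtype=float)
    if x.shape != (H.num_nodes,):
        raise ValueError(f"state has shape {x.shape}, expected ({H.num_nodes},)")
    xdot = np.zeros(H.num_nodes)
    for d in H.sizes:
        edges = np.asarray(H.edges(d), dtype=int)
        if edges.size == 0:
            continue
        states = x[edges]  # (M, d)
        for pos in range(d):
            centers = states[:, pos]
            nb = np.delete(states, pos, axis=1)
            np.add.at(xdot, edges[:, pos], family.f_rows(d, centers, nb))
    return xdot


def rhs_lifted(H: Hypergraph, family: KernelFamily, x: np.ndarray) -> np.ndarray:
    """Derivative via the lift–update–project route ``sum_d L_d^T F_d(L_d x)``.

    Algebraically identical to :func:`rhs`; kept as an independent formulation
    (explicit lifting matrices, per-edge update blocks) for cross-checking.
    """
    x = np.asarray(x, dtype=float)
    if x.shape != (H.num_nodes,):
        raise ValueError(f"state has shape {x.shape}, expected ({H.num_nodes},)")
    xdot = np.zeros(H.num_nodes)
    for d in H.sizes:
        L = lifting_matrix(H, d)
        if L.num_edges == 0:
            continue
        y = L.lift(x)  # (M, d)
        upd = np.empty_like(y)
        for alpha in range(L.num_edges):
            for pos in range(d):
                nb = np.delete(y[alpha], pos)
                upd[alpha, pos] = family.f(d, y[alpha, pos], nb)
        xdot += L.project(upd)
    return xdot


@dataclass
class Trajectory:
    """Forward-Euler trajectory: ``states[t]`` is the state after ``t`` steps."""

    states: np.ndarray  # (steps + 1, N)
    dt: float

    @property
    def steps(self) -> int:
        return self.states.shape[0] - 1

    @property
    def num_nodes(self) -> int:
        return self.states.shape[1]


def euler_integrate(
    H: Hypergraph,
    family: KernelFamily,
    x0: np.ndarray,
    dt: float,
    steps: int,
    vector_field: Callable[[Hypergraph, KernelFamily, np.ndarray], np.ndarray] = rhs,
) -> Trajectory:
    """Integrate the system with the explicit (forward) Euler scheme.

    ``states[t+1] = states[t] + dt * vector_field(states[t])``; row 0 is
    ``x0``.  Aborts with a diagnostic if a non-finite state appears.
    """
    if dt <= 0:
        raise ValueError(f"dt must be positive, got {dt}")
    if steps < 1:
        raise ValueError(f"steps must be >= 1, got {steps}")
    x0 = np.asarray(x0, dtype=float)
    states = np.empty((steps + 1, H.num_nodes))
    states[0] = x0
    for t in range(steps):
        with np.errstate(over="ignore", invalid="ignore"):
            states[t + 1] = states[t] + dt * vector_field(H, family, states[t])
        if not np.all(np.isfinite(states[t + 1])):
            raise FloatingPointError(
                f"non-finite state at step {t + 1} (dt={dt}); integration aborted"
            )
    return Trajectory(states=states, dt=dt)


def verify_decomposition(
    f: Callable[[float, Sequence[float]], float],
    phi: Kernel | Callable[[float, Sequence[float]], float],
    p: int,
    d: int,
    n_samples: int = 1000,
    rng_seed: int | np.random.Generator = 0,
    domain: tuple[float, float] = (0.0, 1.0),
) -> float:
    """Max residual of the claimed ``p``-ary decomposition of a size-``d`` update.

    Draws ``n_samples`` random argument tuples ``(y_1, .., y_d)`` uniformly
    from ``domain`` and returns the maximum absolute difference between
    ``f(y_1, {{y_2..y_d}})`` and the expansion
    ``sum over (p-1)-subsets v of the neighbors of phi(y_1, v)``.
    A residual at round-off level certifies the decomposition at order ``p``
    on that domain; a residual bounded away from zero is a counterexample.
    """
    if not 2 <= p <= d:
        raise ValueError(f"need 2 <= p <= d, got p={p}, d={d}")
    rng = np.random.default_rng(rng_seed)
    lo, hi = domain
    if lo >= hi:
        raise ValueError(f"empty domain {domain}")
    phi_eval = phi.evaluate if isinstance(phi, Kernel) else phi
    worst = 0.0
    samples = rng.uniform(lo, hi, size=(n_samples, d))
    # open interval at lo guards kernels with singularities at the boundary
    samples = np.nextafter(samples, hi)
    for row in samples:
        y1, s = row[0], row[1:]
        expansion = sum(
            phi_eval(y1, [s[i] for i in sub]) for sub in combinations(range(d - 1), p - 1)
        )
        worst = max(worst, abs(f(y1, s) - expansion))
    return worst


def sample_initial_state(
    dynamics_name: str, N: int, rng: int | np.random.Generator
) -> np.ndarray:
    """Draw an initial state from the distribution conventional for a dynamics.

    Kuramoto phases are uniform on [-pi, pi]; SI infection probabilities
    uniform on [0, 1]; MCM opinions follow a right-skewed Beta(2, 5) on
    [0, 1] (group reinforcement only matters for skewed opinion profiles);
    diffusion states are uniform on [-1, 1].
    """
    rng = np.random.default_rng(rng)
    if dynamics_name in ("kuramoto", "full_kuramoto"):
        return rng.uniform(-np.pi, np.pi, size=N)
    if dynamics_name == "si":
        return rng.uniform(0.0, 1.0, size=N)
    if dynamics_name == "mcm":
        return rng.beta(2.0, 5.0, size=N)
    if dynamics_name == "diffusion":
        return rng.uniform(-1.0, 1.0, size=N)
    raise ValueError(f"unknown dynamics {dynamics_name!r}")
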