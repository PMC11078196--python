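"""Learnable hypergraph-dynamics model with order-capped symmetric approximators.

For each hyperedge size ``d`` up to the topological order ``k``, the model
carries one multilayer perceptron with ``m = min(p_model, d)`` inputs that
approximates the local update function.  The per-edge update is made exactly
symmetric in the neighbor arguments by averaging the MLP over all orderings;
when ``p_model < d`` the update is additionally summed over all
``(p_model - 1)``-subsets of the neighbor multiset, so an order-``p_model``
model can only represent dynamics whose interactions decompose into
``p_model``-ary terms.  Comparing fit quality across ``p_model`` is what lets
the effective interaction order be read off from data
(:mod:`hyperdyn.selection`).

Implementation note: the permutation average of the ordered-subset sum equals
the sum over *unordered* subsets of the order-averaged MLP (a counting
identity), so the forward pass enumerates each subset once and averages its
``(m-1)!`` orderings instead of touching all ``(d-1)!`` input permutations.
The exhaustive permutation average is retained in tests as the oracle.

The MLPs, their backpropagation and the Adam optimizer are implemented
directly on numpy arrays; the whole model fits in a few thousand parameters.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from itertools import combinations, permutations
from pathlib import Path
from typing import Sequence

import numpy as np

from .datasets import TrainingSet
from .dynamics import Trajectory
from .hypergraph import Hypergraph

__all__ = ["MLP", "HyDyGNNModel", "TrainConfig", "TrainLog", "train", "rollout"]

_DTYPE = np.float64


class MLP:
    """Tiny fully connected network: tanh hidden layers, scalar linear output."""

    def __init__(self, dims: Sequence[int], rng: np.random.Generator):
        self.dims = tuple(int(x) for x in dims)
        self.weights: list[np.ndarray] = []
        self.biases: list[np.ndarray] = []
        for n_in, n_out in zip(self.dims[:-1], self.dims[1:]):
            bound = math.sqrt(6.0 / (n_in + n_out))  # Glorot uniform
            self.weights.append(rng.uniform(-bound, bound, size=(n_in, n_out)).astype(_DTYPE))
            self.biases.append(np.zeros(n_out, dtype=_DTYPE))

    def forward(self, X: np.ndarray, want_cache: bool = False):
        """Evaluate on a batch; returns ``(y, cache)`` with ``y`` shape ``(B,)``."""
        a = np.asarray(X, dtype=_DTYPE)
        acts = [a]
        n_layers = len(self.weights)
        for li, (W, b) in enumerate(zip(self.weights, self.biases)):
            z = a @ W + b
            a = z if li == n_layers - 1 else np.tanh(z)
            acts.append(a)
        y = acts[-1][:, 0]
        return (y, acts if want_cache else None)

    def backward(self, cache: list[np.ndarray], dy: np.ndarray):
        """Gradients of ``sum(dy * y)`` w.r.t. weights and biases."""
        grads_W: list[np.ndarray] = [None] * len(self.weights)
        grads_b: list[np.ndarray] = [None] * len(self.biases)
        delta = dy[:, None].astype(_DTYPE)
        for li in range(len(self.weights) - 1, -1, -1):
            a_prev = cache[li]
            grads_W[li] = a_prev.T @ delta
            grads_b[li] = delta.sum(axis=0)
            if li > 0:
                delta = (delta @ self.weights[li].T) * (1.0 - cache[li] ** 2)
        return grads_W, grads_b

    def parameters(self) -> list[np.ndarray]:
        return self.weights + self.biases

    @property
    def num_parameters(self) -> int:
        return sum(p.size for p in self.parameters())


def _row_template(d: int, m: int):
    """Within-edge index rows realizing the symmetrized order-``m`` update.

    For every center position and every ordered arrangement of ``m - 1`` of
    the remaining positions, one row ``(center, arrangement...)``; the output
    accumulates with weight ``1/(m-1)!`` (the ordering average).
    """
    rows: list[tuple[int, ...]] = []
    outs: list[int] = []
    for c in range(d):
        others = [i for i in range(d) if i != c]
        for sub in combinations(others, m - 1):
            for perm in permutations(sub):
                rows.append((c, *perm))
                outs.append(c)
    return np.asarray(rows, dtype=int), np.asarray(outs, dtype=int), 1.0 / math.factorial(m - 1)


class HyDyGNNModel:
    """Order-``p_model`` learnable hypergraph dynamics.

    Parameters
    ----------
    k
        Maximum hyperedge size the model accepts (topological order).
    p_model
        Interaction order of the approximators, ``2 <= p_model <= k``.
    hidden_layout
        Hidden-layer widths of each per-size MLP.
    rng_seed
        Seed for weight initialization.
    """

    def __init__(
        self,
        k: int,
        p_model: int,
        hidden_layout: Sequence[int] = (32, 32),
        rng_seed: int = 0,
    ):
        if not 2 <= p_model <= k:
            raise ValueError(f"need 2 <= p_model <= k, got p_model={p_model}, k={k}")
        self.k = int(k)
        self.p_model = int(p_model)
        self.hidden_layout = tuple(int(h) for h in hidden_layout)
        self.rng_seed = int(rng_seed)
        rng = np.random.default_rng(rng_seed)
        self.mlps: dict[int, MLP] = {}
        for d in range(2, k + 1):
            m = min(p_model, d)
            self.mlps[d] = MLP((m, *self.hidden_layout, 1), rng)

    # ---------------------------------------------------------------- basics
    def parameters(self) -> list[np.ndarray]:
        """All weight arrays, sizes ascending (the flattened θ of the model)."""
        out: list[np.ndarray] = []
        for d in sorted(self.mlps):
            out.extend(self.mlps[d].parameters())
        return out

    def theta_sq_norm(self) -> float:
        return float(sum((p**2).sum() for p in self.parameters()))

    def reinitialized(self, rng_seed: int | None = None) -> "HyDyGNNModel":
        """Fresh model with the same architecture (optionally a new seed)."""
        return HyDyGNNModel(
            self.k,
            self.p_model,
            hidden_layout=self.hidden_layout,
            rng_seed=self.rng_seed if rng_seed is None else rng_seed,
        )

    # ------------------------------------------------------------ evaluation
    def symmetric_eval(self, d: int, y_center: float, neighbors: Sequence[float]) -> float:
        """Symmetrized per-edge update ``f̂_d`` for one center/neighbor multiset."""
        if d not in self.mlps:
            raise ValueError(f"edge size {d} outside model range 2..{self.k}")
        nb = np.asarray(neighbors, dtype=float)
        if nb.size != d - 1:
            raise ValueError(f"f̂_{d} expects {d - 1} neighbors, got {nb.size}")
        # canonical ordering makes the output bit-identical, not merely equal
        # to round-off, under neighbor permutations
        nb = np.sort(nb)
        m = min(self.p_model, d)
        inputs = [
            (y_center, *(nb[i] for i in perm))
            for sub in combinations(range(d - 1), m - 1)
            for perm in permutations(sub)
        ]
        y, _ = self.mlps[d].forward(np.asarray(inputs, dtype=float))
        return float(y.sum() / math.factorial(m - 1))

    def _edge_rows(self, H: Hypergraph):
        """Per-hypergraph gather/scatter plan, cached on the hypergraph object."""
        cache = getattr(H, "_hydygnn_rows", None)
        key = (self.p_model, self.k)
        if cache is None:
            cache = {}
            object.__setattr__(H, "_hydygnn_rows", cache)
        if key not in cache:
            plan: dict[int, tuple[np.ndarray, np.ndarray, float]] = {}
            for d in H.sizes:
                if d > self.k:
                    raise ValueError(f"hyperedge size {d} exceeds model order cap k={self.k}")
                edges = np.asarray(H.edges(d), dtype=int)
                if edges.size == 0:
                    continue
                tmpl, outs, w = _row_template(d, min(self.p_model, d))
                cols = edges[:, tmpl].reshape(-1, tmpl.shape[1])
                out_nodes = edges[:, outs].reshape(-1)
                plan[d] = (cols, out_nodes, w)
            cache[key] = plan
        return cache[key]

    def forward(self, H: Hypergraph, x: np.ndarray) -> np.ndarray:
        """Predicted derivative vector for state ``x`` on hypergraph ``H``."""
        x = np.asarray(x, dtype=float)
        if x.shape != (H.num_nodes,):
            raise ValueError(f"state has shape {x.shape}, expected ({H.num_nodes},)")
        pred = np.zeros(H.num_nodes)
        for d, (cols, out_nodes, w) in self._edge_rows(H).items():
            y, _ = self.mlps[d].forward(x[cols])
            np.add.at(pred, out_nodes, w * y)
        return pred

    # ------------------------------------------------- compiled batched path
    def compile_batch(self, dataset: TrainingSet) -> "CompiledBatch":
        """Flatten a training set into global gather/scatter index arrays."""
        N = dataset.num_nodes
        per_size: dict[int, list[tuple[np.ndarray, np.ndarray]]] = {}
        per_size_sample: dict[int, list[np.ndarray]] = {}
        for i in range(len(dataset)):
            H = dataset.hypergraphs[dataset.system_index[i]]
            for d, (cols, out_nodes, w) in self._edge_rows(H).items():
                per_size.setdefault(d, []).append((cols + i * N, out_nodes + i * N))
                per_size_sample.setdefault(d, []).append(
                    np.full(cols.shape[0], i, dtype=int)
                )
        plans: dict[int, tuple[np.ndarray, np.ndarray, np.ndarray, float]] = {}
        for d, chunks in per_size.items():
            cols = np.concatenate([c for c, _ in chunks], axis=0)
            outs = np.concatenate([o for _, o in chunks], axis=0)
            samples = np.concatenate(per_size_sample[d], axis=0)
            plans[d] = (cols, outs, samples, _row_weight(d, self.p_model))
        return CompiledBatch(
            num_samples=len(dataset), num_nodes=N, plans=plans,
            X=dataset.X, Xdot=dataset.Xdot,
        )

    def predict(self, dataset: TrainingSet) -> np.ndarray:
        """Predicted derivatives for every sample of a training set, shape ``(S, N)``."""
        batch = self.compile_batch(dataset)
        pred, _ = _batch_forward(self, batch, want_cache=False)
        return pred.reshape(len(dataset), dataset.num_nodes)

    def loss(self, dataset: TrainingSet, l2_lambda: float = 0.0) -> float:
        """Summed L1 prediction error plus ``l2_lambda`` times the squared θ norm."""
        if len(dataset) == 0:
            raise ValueError("empty batch")
        pred = self.predict(dataset)
        return float(np.abs(pred - dataset.Xdot).sum() + l2_lambda * self.theta_sq_norm())

    # ---------------------------------------------------------- persistence
    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "k": self.k,
            "p_model": self.p_model,
            "hidden_layout": list(self.hidden_layout),
            "rng_seed": self.rng_seed,
            "mlps": {
                str(d): {
                    "dims": list(mlp.dims),
                    "weights": [w.tolist() for w in mlp.weights],
                    "biases": [b.tolist() for b in mlp.biases],
                }
                for d, mlp in self.mlps.items()
            },
        }
        text = json.dumps(payload)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "HyDyGNNModel":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        payload = json.loads(text)
        model = cls(
            payload["k"],
            payload["p_model"],
            hidden_layout=payload["hidden_layout"],
            rng_seed=payload.get("rng_seed", 0),
        )
        for d_str, layer in payload["mlps"].items():
            mlp = model.mlps[int(d_str)]
            mlp.weights = [np.asarray(w, dtype=_DTYPE) for w in layer["weights"]]
            mlp.biases = [np.asarray(b, dtype=_DTYPE) for b in layer["biases"]]
        return model


def _row_weight(d: int, p_model: int) -> float:
    return 1.0 / math.factorial(min(p_model, d) - 1)


@dataclass
class CompiledBatch:
    """Index arrays for evaluating a model on a whole training set at once."""

    num_samples: int
    num_nodes: int
    # per size d: (input node columns (R, m), output slots (R,), row sample id (R,), weight)
    plans: dict[int, tuple[np.ndarray, np.ndarray, np.ndarray, float]]
    X: np.ndarray
    Xdot: np.ndarray


def _batch_forward(model: HyDyGNNModel, batch: CompiledBatch, want_cache: bool,
                   row_mask: dict[int, np.ndarray] | None = None):
    x_flat = batch.X.reshape(-1)
    pred = np.zeros(batch.num_samples * batch.num_nodes)
    caches = {}
    for d, (cols, outs, samples, w) in batch.plans.items():
        if row_mask is not None:
            sel = row_mask[d]
            cols, outs = cols[sel], outs[sel]
        y, cache = model.mlps[d].forward(x_flat[cols], want_cache=want_cache)
        np.add.at(pred, outs, w * y)
        if want_cache:
            caches[d] = (cache, outs, w)
    return pred, caches


@dataclass
class TrainConfig:
    """Optimization settings for :func:`train`.

    ``l2_lambda`` weights the squared-L2 parameter penalty added to the L1
    data term.  If ``lambda_grid`` holds more than one value, the penalty
    weight is chosen by a hyperparameter search: an 80/20 split of the
    training hypergraphs, one fit per candidate, the value with the lowest
    held-out mean absolute error wins and the model is refit on all data.
    """

    epochs: int = 600
    learning_rate: float = 3e-2
    lr_decay: float = 1e-2  # final lr fraction of a cosine schedule; 1.0 = constant
    batch_size: int | None = 16  # None = full batch
    l2_lambda: float = 1e-5
    lambda_grid: tuple[float, ...] | None = None
    hidden_layout: tuple[int, ...] = (32, 32)
    rng_seed: int = 0
    early_stop_patience: int | None = None
    val_fraction: float = 0.2

    def __post_init__(self) -> None:
        if self.l2_lambda < 0:
            raise ValueError("l2_lambda must be >= 0")


@dataclass
class TrainLog:
    epoch_losses: list[float]
    l2_lambda: float
    lambda_search: dict[float, float] | None = None


class _Adam:
    def __init__(self, params: list[np.ndarray], lr: float):
        self.lr = lr
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0
        self.b1, self.b2, self.eps = 0.9, 0.999, 1e-8

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m += (1.0 - self.b1) * (g - m)
            v += (1.0 - self.b2) * (g * g - v)
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def _fit(model: HyDyGNNModel, train_set: TrainingSet, cfg: TrainConfig,
         l2_lambda: float, val_set: TrainingSet | None = None) -> list[float]:
    batch = model.compile_batch(train_set)
    params = model.parameters()
    opt = _Adam(params, cfg.learning_rate)
    rng = np.random.default_rng(cfg.rng_seed)
    S = len(train_set)
    use_minibatch = cfg.batch_size is not None and cfg.batch_size < S
    losses: list[float] = []
    best_val = math.inf
    best_params: list[np.ndarray] | None = None
    stall = 0
    lr0 = cfg.learning_rate
    for epoch in range(cfg.epochs):
        # cosine decay: L1 sign gradients keep a constant magnitude, so the
        # asymptotic parameter error tracks the step size — anneal it.
        frac = 0.5 * (1.0 + math.cos(math.pi * epoch / max(1, cfg.epochs - 1)))
        opt.lr = lr0 * (cfg.lr_decay + (1.0 - cfg.lr_decay) * frac)
        if use_minibatch:
            order = rng.permutation(S)
            epoch_loss = 0.0
            for start in range(0, S, cfg.batch_size):
                sel_samples = order[start : start + cfg.batch_size]
                in_batch = np.zeros(S, dtype=bool)
                in_batch[sel_samples] = True
                row_mask = {d: in_batch[plan[2]] for d, plan in batch.plans.items()}
                epoch_loss += _grad_step(model, batch, opt, l2_lambda, row_mask, sel_samples)
            losses.append(epoch_loss)
        else:
            losses.append(_grad_step(model, batch, opt, l2_lambda, None, None))
        if not math.isfinite(losses[-1]):
            raise FloatingPointError(
                f"training loss diverged (non-finite) at epoch {epoch}; "
                "reduce the learning rate or check the data scale"
            )
        if val_set is not None and cfg.early_stop_patience is not None:
            val = float(np.abs(model.predict(val_set) - val_set.Xdot).mean())
            if val < best_val - 1e-12:
                best_val, stall = val, 0
                best_params = [p.copy() for p in model.parameters()]
            else:
                stall += 1
                if stall >= cfg.early_stop_patience:
                    break
    if best_params is not None:
        for p, bp in zip(model.parameters(), best_params):
            p[...] = bp
    return losses


def _grad_step(model, batch: CompiledBatch, opt: _Adam, l2_lambda: float,
               row_mask, sel_samples) -> float:
    pred, caches = _batch_forward(model, batch, want_cache=True, row_mask=row_mask)
    resid = pred - batch.Xdot.reshape(-1)
    if sel_samples is not None:
        keep = np.zeros(batch.num_samples, dtype=bool)
        keep[sel_samples] = True
        resid *= np.repeat(keep, batch.num_nodes)
    dpred = np.sign(resid)
    params: list[np.ndarray] = []
    grads: list[np.ndarray] = []
    for d in sorted(model.mlps):
        mlp = model.mlps[d]
        if d in caches:
            cache, outs, w = caches[d]
            gW, gb = mlp.backward(cache, w * dpred[outs])
        else:
            gW = [np.zeros_like(W) for W in mlp.weights]
            gb = [np.zeros_like(b) for b in mlp.biases]
        for p, g in zip(mlp.weights + mlp.biases, gW + gb):
            params.append(p)
            grads.append(g + 2.0 * l2_lambda * p)
    opt.step(params, grads)
    return float(np.abs(resid).sum() + l2_lambda * model.theta_sq_norm())


def train(
    model: HyDyGNNModel, dataset: TrainingSet, cfg: TrainConfig | None = None
) -> tuple[HyDyGNNModel, TrainLog]:
    """Fit the model by Adam on the regularized L1 empirical risk.

    The loss is the sum over samples of the L1 norm of the derivative
    residual plus ``l2_lambda * ||θ||²``.  With a multi-valued
    ``cfg.lambda_grid`` the penalty weight is selected on a validation split
    first (see :class:`TrainConfig`).  Returns the fitted model (mutated in
    place) and a log of per-epoch losses.
    """
    cfg = cfg or TrainConfig()
    if len(dataset) == 0:
        raise ValueError("empty training set")
    search: dict[float, float] | None = None
    l2 = cfg.l2_lambda
    if cfg.lambda_grid is not None and len(cfg.lambda_grid) > 1:
        search = {}
        rng = np.random.default_rng(cfg.rng_seed)
        systems = np.unique(dataset.system_index)
        perm = rng.permutation(len(systems))
        n_val = max(1, int(round(cfg.val_fraction * len(systems))))
        val_systems = set(systems[perm[:n_val]].tolist())
        val_mask = np.isin(dataset.system_index, list(val_systems))
        fit_part = dataset.subset(np.flatnonzero(~val_mask))
        val_part = dataset.subset(np.flatnonzero(val_mask))
        for lam in cfg.lambda_grid:
            probe = model.reinitialized()
            _fit(probe, fit_part, cfg, lam)
            search[lam] = float(np.abs(probe.predict(val_part) - val_part.Xdot).mean())
        l2 = min(cfg.lambda_grid, key=lambda lam: search[lam])
    val_set = None
    fit_set = dataset
    if cfg.early_stop_patience is not None:
        rng = np.random.default_rng(cfg.rng_seed + 1)
        systems = np.unique(dataset.system_index)
        perm = rng.permutation(len(systems))
        n_val = max(1, int(round(cfg.val_fraction * len(systems))))
        val_systems = set(systems[perm[:n_val]].tolist())
        val_mask = np.isin(dataset.system_index, list(val_systems))
        if val_mask.any() and not val_mask.all():
            fit_set = dataset.subset(np.flatnonzero(~val_mask))
            val_set = dataset.subset(np.flatnonzero(val_mask))
    losses = _fit(model, fit_set, cfg, l2, val_set=val_set)
    return model, TrainLog(epoch_losses=losses, l2_lambda=l2, lambda_search=search)


def rollout(
    model: HyDyGNNModel, H: Hypergraph, x0: np.ndarray, dt: float, steps: int
) -> Trajectory:
    """Forward-Euler integration using the learned model as the vector field."""
    if dt <= 0:
        raise ValueError(f"dt must be positive, got {dt}")
    if steps < 1:
        raise ValueError(f"steps must be >= 1, got {steps}")
    x0 = np.asarray(x0, dtype=float)
    states = np.empty((steps + 1, H.num_nodes))
    states[0] = x0
    for t in range(steps):
        states[t + 1] = states[t] + dt * model.forward(H, states[t])
        if not np.all(np.isfinite(states[t + 1])):
            raise FloatingPointError(f"non-finite state at rollout step {t + 1}")
    return Trajectory(states=states, dt=dt)
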