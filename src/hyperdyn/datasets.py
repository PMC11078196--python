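"""Synthetic training data for hypergraph-dynamics learning, plus splits.

Two observation scenarios are supported:

- *point*: each sample is an independently generated Erdős–Rényi hypergraph
  with one random initial state and the exact derivative of the dynamics at
  that state (one sample per hypergraph);
- *trajectory*: each hypergraph carries a forward-Euler trajectory, and the
  derivative at each time point is the forward time difference
  ``(x(t + dt) - x(t)) / dt`` (under exact Euler data the two coincide).

Cross-validation folds are always partitioned *by hypergraph*, so temporally
correlated samples from one trajectory never straddle a train/test boundary.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .dynamics import euler_integrate, make_family, rhs, sample_initial_state
from .hypergraph import (
    Hypergraph,
    generate_er_hypergraph,
    read_hyperedge_list,
    write_hyperedge_list,
)

__all__ = [
    "TrainingSet",
    "DEFAULT_ER_PROBS",
    "make_point_dataset",
    "make_trajectory_dataset",
    "kfold_split",
    "save_dataset",
    "load_dataset",
]

#: Per-cardinality inclusion probabilities of the reference synthetic ensemble
#: (20-node hypergraphs; pair edges 0.1, triples 0.01, quadruples 0.001).
DEFAULT_ER_PROBS: dict[int, float] = {2: 0.1, 3: 0.01, 4: 0.001}
DEFAULT_NUM_NODES = 20


@dataclass
class TrainingSet:
    """Paired (state, derivative) samples over a collection of hypergraphs.

    ``X`` and ``Xdot`` are ``(S, N)`` arrays; ``system_index[i]`` says which
    entry of ``hypergraphs`` sample ``i`` was generated on.  ``meta`` records
    provenance: dynamics name, generation order ``p``, scenario, ``dt``, seed.
    """

    hypergraphs: list[Hypergraph]
    X: np.ndarray
    Xdot: np.ndarray
    system_index: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.Xdot = np.asarray(self.Xdot, dtype=float)
        self.system_index = np.asarray(self.system_index, dtype=int)
        if self.X.shape != self.Xdot.shape:
            raise ValueError("X and Xdot shapes differ")
        if self.X.shape[0] != self.system_index.shape[0]:
            raise ValueError("system_index length mismatch")
        for H in self.hypergraphs:
            if H.num_nodes != self.X.shape[1]:
                raise ValueError("all hypergraphs must share the sample node count")

    def __len__(self) -> int:
        return self.X.shape[0]

    @property
    def num_nodes(self) -> int:
        return self.X.shape[1]

    def subset(self, idx: Sequence[int]) -> "TrainingSet":
        """View of selected samples (hypergraph list is shared, not copied)."""
        idx = np.asarray(idx, dtype=int)
        return TrainingSet(
            hypergraphs=self.hypergraphs,
            X=self.X[idx],
            Xdot=self.Xdot[idx],
            system_index=self.system_index[idx],
            meta=dict(self.meta),
        )


def _spawn_seeds(rng_seed: int, n: int) -> list[np.random.Generator]:
    ss = np.random.SeedSequence(rng_seed)
    return [np.random.default_rng(child) for child in ss.spawn(n)]


def make_point_dataset(
    n_systems: int,
    dynamics_name: str,
    p: int,
    hypergraph_params: Mapping | None = None,
    rng_seed: int = 0,
) -> TrainingSet:
    """Point-based data: one fresh hypergraph + one (state, derivative) pair each.

    The derivative is the exact right-hand side of the dynamics at the sampled
    state, as if states and their instantaneous rates were observed directly.
    """
    if n_systems < 1:
        raise ValueError("n_systems must be >= 1")
    params = dict(hypergraph_params or {})
    N = int(params.get("num_nodes", DEFAULT_NUM_NODES))
    probs = dict(params.get("probs", DEFAULT_ER_PROBS))
    k = max(probs)
    family = make_family(dynamics_name, p, k)
    rngs = _spawn_seeds(rng_seed, n_systems)

    hypergraphs: list[Hypergraph] = []
    X = np.empty((n_systems, N))
    Xdot = np.empty((n_systems, N))
    for i, rng in enumerate(rngs):
        H = generate_er_hypergraph(N, probs, rng)
        x = sample_initial_state(dynamics_name, N, rng)
        hypergraphs.append(H)
        X[i] = x
        Xdot[i] = rhs(H, family, x)
    return TrainingSet(
        hypergraphs=hypergraphs,
        X=X,
        Xdot=Xdot,
        system_index=np.arange(n_systems),
        meta={
            "dynamics": dynamics_name,
            "p": p,
            "scenario": "point",
            "dt": None,
            "seed": rng_seed,
            "num_nodes": N,
            "probs": probs,
        },
    )


def make_trajectory_dataset(
    n_traj: int,
    steps: int,
    dt: float,
    dynamics_name: str,
    p: int,
    hypergraph_params: Mapping | None = None,
    rng_seed: int = 0,
) -> TrainingSet:
    """Trajectory-based data: forward-Euler runs with forward-difference derivatives.

    One hypergraph per trajectory; each of the first ``steps`` time points
    yields a sample, so the set holds ``n_traj * steps`` tuples (e.g. 25
    trajectories of 100 steps give 2500 training tuples).
    """
    if steps < 1:
        raise ValueError("steps must be >= 1")
    params = dict(hypergraph_params or {})
    N = int(params.get("num_nodes", DEFAULT_NUM_NODES))
    probs = dict(params.get("probs", DEFAULT_ER_PROBS))
    k = max(probs)
    family = make_family(dynamics_name, p, k)
    rngs = _spawn_seeds(rng_seed, n_traj)

    hypergraphs: list[Hypergraph] = []
    X = np.empty((n_traj * steps, N))
    Xdot = np.empty((n_traj * steps, N))
    system_index = np.empty(n_traj * steps, dtype=int)
    for i, rng in enumerate(rngs):
        H = generate_er_hypergraph(N, probs, rng)
        x0 = sample_initial_state(dynamics_name, N, rng)
        traj = euler_integrate(H, family, x0, dt, steps)
        hypergraphs.append(H)
        rows = slice(i * steps, (i + 1) * steps)
        X[rows] = traj.states[:-1]
        Xdot[rows] = np.diff(traj.states, axis=0) / dt
        system_index[rows] = i
    return TrainingSet(
        hypergraphs=hypergraphs,
        X=X,
        Xdot=Xdot,
        system_index=system_index,
        meta={
            "dynamics": dynamics_name,
            "p": p,
            "scenario": "trajectory",
            "dt": dt,
            "steps": steps,
            "seed": rng_seed,
            "num_nodes": N,
            "probs": probs,
        },
    )


def kfold_split(
    dataset: TrainingSet, k: int, rng_seed: int = 0
) -> list[tuple[np.ndarray, np.ndarray]]:
    """K-fold partition of sample indices, grouped by hypergraph.

    All samples of one hypergraph land in the same fold; fold sizes (counted
    in hypergraphs) differ by at most one.  Returns ``k`` pairs of
    (train_indices, test_indices) covering every sample exactly once.
    """
    n_systems = len(dataset.hypergraphs)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n_systems:
        raise ValueError(f"k={k} exceeds the number of distinct hypergraphs ({n_systems})")
    rng = np.random.default_rng(rng_seed)
    order = rng.permutation(n_systems)
    fold_of_system = np.empty(n_systems, dtype=int)
    for pos, sys in enumerate(order):
        fold_of_system[sys] = pos % k
    fold_of_sample = fold_of_system[dataset.system_index]
    splits = []
    for f in range(k):
        test = np.flatnonzero(fold_of_sample == f)
        train = np.flatnonzero(fold_of_sample != f)
        splits.append((train, test))
    return splits


def save_dataset(dataset: TrainingSet, directory: str | Path) -> None:
    """Serialize a training set to a directory of plain-text artifacts.

    Layout: ``meta.json``, ``samples.csv`` (sample index, system index, then
    per-node state and derivative columns), and ``systems/h<i>.txt``
    hyperedge lists.
    """
    directory = Path(directory)
    (directory / "systems").mkdir(parents=True, exist_ok=True)
    meta = dict(dataset.meta)
    meta["n_systems"] = len(dataset.hypergraphs)
    meta["n_samples"] = len(dataset)
    (directory / "meta.json").write_text(json.dumps(meta, indent=2))
    N = dataset.num_nodes
    frame = pd.DataFrame(
        {
            "sample": np.arange(len(dataset)),
            "system": dataset.system_index,
            **{f"x{j}": dataset.X[:, j] for j in range(N)},
            **{f"xdot{j}": dataset.Xdot[:, j] for j in range(N)},
        }
    )
    frame.to_csv(directory / "samples.csv", index=False)
    for i, H in enumerate(dataset.hypergraphs):
        write_hyperedge_list(H, directory / "systems" / f"h{i}.txt", sidecar=True)


def load_dataset(directory: str | Path) -> TrainingSet:
    """Load a training set written by :func:`save_dataset`."""
    directory = Path(directory)
    meta = json.loads((directory / "meta.json").read_text())
    frame = pd.read_csv(directory / "samples.csv")
    N = int(meta["num_nodes"])
    X = frame[[f"x{j}" for j in range(N)]].to_numpy()
    Xdot = frame[[f"xdot{j}" for j in range(N)]].to_numpy()
    system_index = frame["system"].to_numpy()
    hypergraphs = [
        read_hyperedge_list(directory / "systems" / f"h{i}.txt")
        for i in range(int(meta["n_systems"]))
    ]
    meta.pop("n_systems", None)
    meta.pop("n_samples", None)
    if "probs" in meta:
        meta["probs"] = {int(d): float(v) for d, v in meta["probs"].items()}
    return TrainingSet(
        hypergraphs=hypergraphs, X=X, Xdot=Xdot, system_index=system_index, meta=meta
    )
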