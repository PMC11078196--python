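"""Hypergraph container, size-grouped bookkeeping, lifting operators and I/O.

A hypergraph is stored as a node count plus hyperedges grouped by cardinality
``d``.  For each size group the *lifting operator* ``L_d`` stacks one 0/1
indicator block per hyperedge; ``L_d @ x`` collects the states of the nodes of
every size-``d`` hyperedge into edge-local coordinates, and ``L_d.T`` projects
per-edge updates back onto the nodes by summation.  This is the topological
half of a hypergraph dynamical system; the dynamics half lives in
:mod:`hyperdyn.dynamics`.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "Hypergraph",
    "LiftingOperator",
    "topological_order",
    "lifting_matrix",
    "generate_er_hypergraph",
    "read_hyperedge_list",
    "write_hyperedge_list",
    "truncate_to_order",
]


@dataclass
class Hypergraph:
    """A hypergraph with 0-based node indices and edges grouped by cardinality.

    Parameters
    ----------
    num_nodes
        Number of nodes ``N``; node indices run over ``0 .. N-1``.
    edges_by_size
        Mapping from cardinality ``d >= 2`` to the hyperedges of that size,
        each a collection of ``d`` distinct node indices.  Edges are stored
        sorted (within-edge ascending, groups sorted lexicographically) so two
        hypergraphs with the same edge sets compare and hash identically.
    node_labels
        Optional original labels (e.g. from a hyperedge-list file); purely
        cosmetic, all computation uses the integer indices.
    """

    num_nodes: int
    edges_by_size: dict[int, list[tuple[int, ...]]]
    node_labels: list[str] | None = None

    def __post_init__(self) -> None:
        if self.num_nodes <= 0:
            raise ValueError(f"num_nodes must be positive, got {self.num_nodes}")
        canonical: dict[int, list[tuple[int, ...]]] = {}
        for d, edges in self.edges_by_size.items():
            d = int(d)
            if d < 2:
                raise ValueError(f"hyperedge size must be >= 2, got {d}")
            seen: set[tuple[int, ...]] = set()
            group: list[tuple[int, ...]] = []
            for e in edges:
                edge = tuple(sorted(int(v) for v in e))
                if len(set(edge)) != len(edge):
                    raise ValueError(f"hyperedge {e} has repeated nodes")
                if len(edge) != d:
                    raise ValueError(
                        f"hyperedge {e} stored under size {d} has {len(edge)} members"
                    )
                if edge[0] < 0 or edge[-1] >= self.num_nodes:
                    raise ValueError(
                        f"hyperedge {e} contains a node outside [0, {self.num_nodes - 1}]"
                    )
                if edge in seen:
                    continue
                seen.add(edge)
                group.append(edge)
            canonical[d] = sorted(group)
        self.edges_by_size = canonical

    @property
    def sizes(self) -> list[int]:
        """Cardinalities with at least one hyperedge, ascending."""
        return sorted(d for d, g in self.edges_by_size.items() if g)

    def edges(self, d: int) -> list[tuple[int, ...]]:
        """Hyperedges of size ``d`` (empty list if the group is absent)."""
        return self.edges_by_size.get(d, [])

    def num_edges(self, d: int | None = None) -> int:
        if d is not None:
            return len(self.edges(d))
        return sum(len(g) for g in self.edges_by_size.values())

    def all_edges(self) -> Iterator[tuple[int, ...]]:
        for d in self.sizes:
            yield from self.edges_by_size[d]

    def fingerprint(self) -> tuple:
        """Hashable identity of the topology (used for operator caching)."""
        return (
            self.num_nodes,
            tuple((d, tuple(self.edges_by_size[d])) for d in self.sizes),
        )


@dataclass
class LiftingOperator:
    """Stacked indicator blocks mapping node states to edge-local coordinates.

    ``matrix`` has shape ``(d * M_d, N)``; rows ``alpha*d .. alpha*d + d - 1``
    are the unit rows of the nodes of edge ``alpha`` in ``edge_node_order``
    (ascending node index).  ``matrix.T @ matrix`` is diagonal with entry
    ``i`` equal to the number of size-``d`` edges containing node ``i``.
    """

    size: int
    num_edges: int
    matrix: np.ndarray
    edge_node_order: list[tuple[int, ...]] = field(default_factory=list)

    def lift(self, x: np.ndarray) -> np.ndarray:
        """Return the lifted state, shape ``(M_d, d)`` (one row per edge)."""
        return (self.matrix @ x).reshape(self.num_edges, self.size)

    def project(self, updates: np.ndarray) -> np.ndarray:
        """Sum per-edge, per-position updates (shape ``(M_d, d)``) onto nodes."""
        return self.matrix.T @ updates.reshape(-1)


def topological_order(H: Hypergraph) -> int:
    """Cardinality of the largest hyperedge of ``H``."""
    sizes = H.sizes
    if not sizes:
        raise ValueError("hypergraph has no hyperedges; topological order undefined")
    return sizes[-1]


def lifting_matrix(H: Hypergraph, d: int) -> LiftingOperator:
    """Build the size-``d`` lifting operator of ``H``.

    An empty (or absent) size group yields a zero-row operator.
    """
    if d < 2:
        raise ValueError(f"hyperedge size must be >= 2, got {d}")
    edges = H.edges(d)
    M = len(edges)
    mat = np.zeros((d * M, H.num_nodes))
    for alpha, edge in enumerate(edges):
        for pos, node in enumerate(edge):
            mat[alpha * d + pos, node] = 1.0
    return LiftingOperator(size=d, num_edges=M, matrix=mat, edge_node_order=list(edges))


def generate_er_hypergraph(
    num_nodes: int,
    probs: Mapping[int, float],
    rng_seed: int | np.random.Generator,
) -> Hypergraph:
    """Sample an Erdős–Rényi hypergraph with per-cardinality edge probabilities.

    Every candidate node subset of size ``d`` is included independently with
    probability ``probs[d]``.  Candidate subsets are enumerated exhaustively in
    lexicographic order, so the draw is exactly Bernoulli-per-subset and
    reproducible given the seed.

    Parameters
    ----------
    num_nodes
        Number of nodes ``N``.
    probs
        Mapping ``d -> probability`` for each hyperedge cardinality, e.g.
        ``{2: 0.1, 3: 0.01, 4: 0.001}``.
    rng_seed
        Integer seed or a :class:`numpy.random.Generator`.
    """
    rng = np.random.default_rng(rng_seed)
    edges_by_size: dict[int, list[tuple[int, ...]]] = {}
    for d in sorted(probs):
        p = float(probs[d])
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"probability for size {d} must be in [0, 1], got {p}")
        if d < 2:
            raise ValueError(f"hyperedge size must be >= 2, got {d}")
        if num_nodes < d:
            raise ValueError(f"num_nodes={num_nodes} smaller than hyperedge size {d}")
        candidates = list(combinations(range(num_nodes), d))
        keep = rng.random(len(candidates)) < p
        edges_by_size[d] = [candidates[i] for i in np.flatnonzero(keep)]
    return Hypergraph(num_nodes=num_nodes, edges_by_size=edges_by_size)


def truncate_to_order(H: Hypergraph, k_max: int) -> Hypergraph:
    """Drop all hyperedges of cardinality greater than ``k_max``."""
    if k_max < 2:
        raise ValueError(f"k_max must be >= 2, got {k_max}")
    kept = {d: list(g) for d, g in H.edges_by_size.items() if d <= k_max}
    return Hypergraph(
        num_nodes=H.num_nodes, edges_by_size=kept, node_labels=H.node_labels
    )


def _sidecar_path(path: Path) -> Path:
    return path.with_name(path.name + ".meta.json")


def write_hyperedge_list(H: Hypergraph, path: str | Path, sidecar: bool = False) -> None:
    """Write ``H`` as plain text, one hyperedge per line.

    Node labels (original labels if present, else the integer indices) are
    separated by single spaces; edges appear grouped by ascending size.  With
    ``sidecar=True`` a ``<name>.meta.json`` file records the node count and
    label list so isolated nodes survive a round trip.
    """
    path = Path(path)
    labels = H.node_labels or [str(i) for i in range(H.num_nodes)]
    with path.open("w") as fh:
        for edge in H.all_edges():
            fh.write(" ".join(labels[v] for v in edge) + "\n")
    if sidecar:
        meta = {"num_nodes": H.num_nodes, "node_labels": labels}
        _sidecar_path(path).write_text(json.dumps(meta))


def read_hyperedge_list(path: str | Path) -> Hypergraph:
    """Read a plain-text hyperedge list (one edge per line).

    Labels are split on whitespace and/or commas and mapped to 0-based
    contiguous indices in order of first appearance.  Duplicate edges are
    dropped with a logged warning; a line with fewer than two distinct labels
    raises a parse error naming the line number.  If a ``<name>.meta.json``
    sidecar exists, its node count and label order take precedence.
    """
    path = Path(path)
    label_to_idx: dict[str, int] = {}
    labels: list[str] = []
    num_nodes: int | None = None
    side = _sidecar_path(path)
    if side.exists():
        meta = json.loads(side.read_text())
        labels = [str(s) for s in meta["node_labels"]]
        label_to_idx = {s: i for i, s in enumerate(labels)}
        num_nodes = int(meta["num_nodes"])

    edges_by_size: dict[int, list[tuple[int, ...]]] = {}
    seen: set[tuple[int, ...]] = set()
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            tokens = line.replace(",", " ").split()
            if not tokens:
                continue
            idx: list[int] = []
            for tok in tokens:
                if tok not in label_to_idx:
                    label_to_idx[tok] = len(labels)
                    labels.append(tok)
                idx.append(label_to_idx[tok])
            edge = tuple(sorted(set(idx)))
            if len(edge) < 2:
                raise ValueError(
                    f"{path}:{lineno}: hyperedge needs >= 2 distinct nodes, got {line!r}"
                )
            if edge in seen:
                logger.warning("%s:%d: duplicate hyperedge %s dropped", path, lineno, edge)
                continue
            seen.add(edge)
            edges_by_size.setdefault(len(edge), []).append(edge)
    n = num_nodes if num_nodes is not None else len(labels)
    return Hypergraph(num_nodes=n, edges_by_size=edges_by_size, node_labels=labels)


def degree_vector(H: Hypergraph, d: int) -> np.ndarray:
    """Number of size-``d`` hyperedges each node belongs to."""
    deg = np.zeros(H.num_nodes, dtype=int)
    for edge in H.edges(d):
        for v in edge:
            deg[v] += 1
    return deg
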