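"""Cross-validated multi-order fitting, MC-perf scoring and order selection.

The effective interaction order of an observed hypergraph dynamics is
estimated by fitting models of increasing order ``p_model`` and scoring each
with the *model-corrected performance*

    MC-perf(p_model | X) = exp(-L / L_max) * exp(-p_model / k)

where ``L`` is the cross-validated loss of the order-``p_model`` model,
``L_max`` the largest loss among the candidates, and ``k`` the topological
order.  The first factor rewards fit quality on a scale-free footing, the
second penalizes model order; the argmax (smallest order on ties) is the
selected effective order.  Under-ordered models cannot represent the
higher-arity couplings and score poorly; over-ordered models fit but pay the
complexity penalty.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .datasets import TrainingSet, kfold_split, make_point_dataset, make_trajectory_dataset
from .dynamics import Kernel, Trajectory, make_family, sample_initial_state
from .hypergraph import Hypergraph
from .model import HyDyGNNModel, TrainConfig, rollout, train

__all__ = [
    "OrderSelectionReport",
    "pointwise_mae",
    "trajectory_mae",
    "cross_validate",
    "mc_perf",
    "select_effective_order",
    "run_experiment",
]


def pointwise_mae(predicted: np.ndarray, truth: np.ndarray) -> float:
    """Mean absolute error over all samples and nodes."""
    predicted = np.asarray(predicted, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if predicted.shape != truth.shape:
        raise ValueError(f"shape mismatch: {predicted.shape} vs {truth.shape}")
    return float(np.abs(predicted - truth).mean())


def trajectory_mae(
    model: HyDyGNNModel,
    test_systems: Sequence[tuple[Hypergraph, Trajectory | np.ndarray]],
    dt: float,
    steps: int | None = None,
) -> float:
    """Mean absolute state error of model rollouts against ground-truth runs.

    Each test system supplies a hypergraph and its ground-truth trajectory;
    the model is integrated from the same initial state over the same horizon
    (or ``steps``, if given) and the absolute state error is averaged over
    time points and nodes, then over systems.  A diverging rollout counts as
    infinite for its system, with a warning.
    """
    per_system: list[float] = []
    for H, truth in test_systems:
        states = truth.states if isinstance(truth, Trajectory) else np.asarray(truth)
        horizon = states.shape[0] - 1 if steps is None else min(steps, states.shape[0] - 1)
        try:
            pred = rollout(model, H, states[0], dt, horizon)
        except FloatingPointError:
            warnings.warn("model rollout diverged; trajectory MAE set to inf for this system")
            per_system.append(float("inf"))
            continue
        per_system.append(float(np.abs(pred.states - states[: horizon + 1]).mean()))
    if not per_system:
        raise ValueError("no test systems supplied")
    return float(np.mean(per_system))


def _systems_of(dataset: TrainingSet, sample_idx: np.ndarray):
    """Reassemble per-system ground-truth trajectories from trajectory samples."""
    dt = dataset.meta.get("dt")
    systems = []
    for sys in np.unique(dataset.system_index[sample_idx]):
        rows = sample_idx[dataset.system_index[sample_idx] == sys]
        states = np.vstack(
            [dataset.X[rows], dataset.X[rows[-1]] + dt * dataset.Xdot[rows[-1]]]
        )
        systems.append((dataset.hypergraphs[sys], states))
    return systems


def cross_validate(
    dataset: TrainingSet,
    candidate_orders: Sequence[int],
    n_folds: int,
    cfg: TrainConfig | None = None,
    loss: str = "pointwise",
    fold_seed: int = 0,
) -> dict[int, list[float]]:
    """Held-out loss of each candidate model order under k-fold CV.

    Folds partition samples by hypergraph.  For every order and fold a fresh
    model is trained on the fold's training part and evaluated on its held-out
    part with the pointwise MAE of predicted derivatives (``loss="pointwise"``)
    or, for trajectory data, the rollout MAE against the held-out trajectories
    (``loss="trajectory"``).
    """
    cfg = cfg or TrainConfig()
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    if loss not in ("pointwise", "trajectory"):
        raise ValueError(f"unknown loss {loss!r}")
    probs = dataset.meta.get("probs")
    if probs:
        k = max(int(d) for d in probs)
    else:
        k = max((max(H.sizes, default=2) for H in dataset.hypergraphs), default=2)
    splits = kfold_split(dataset, n_folds, rng_seed=fold_seed)
    results: dict[int, list[float]] = {}
    for order in candidate_orders:
        fold_losses: list[float] = []
        for fold, (train_idx, test_idx) in enumerate(splits):
            seed = int(
                np.random.SeedSequence([cfg.rng_seed, order, fold]).generate_state(1)[0]
                % (2**31)
            )
            model = HyDyGNNModel(
                k=k, p_model=order, hidden_layout=cfg.hidden_layout, rng_seed=seed
            )
            fold_cfg = TrainConfig(**{**cfg.__dict__, "rng_seed": seed})
            train(model, dataset.subset(train_idx), fold_cfg)
            if loss == "pointwise":
                test = dataset.subset(test_idx)
                fold_losses.append(pointwise_mae(model.predict(test), test.Xdot))
            else:
                systems = _systems_of(dataset, test_idx)
                fold_losses.append(trajectory_mae(model, systems, dataset.meta["dt"]))
        results[int(order)] = fold_losses
    return results


def mc_perf(losses: Mapping[int, float], k: int) -> dict[int, float]:
    """Model-corrected performance score per candidate order.

    ``exp(-L / L_max) * exp(-p / k)`` with ``L_max`` the maximum supplied
    loss.  Scores lie in ``(0, 1]``; the normalization makes them invariant
    to a common rescaling of the losses.
    """
    if not losses:
        raise ValueError("no losses supplied")
    vals = {int(p): float(L) for p, L in losses.items()}
    for p, L in vals.items():
        if not np.isfinite(L) or L < 0:
            raise ValueError(f"loss for order {p} must be finite and >= 0, got {L}")
    L_max = max(vals.values())
    scores = {}
    for p, L in vals.items():
        ratio = L / L_max if L_max > 0 else 0.0
        scores[p] = float(np.exp(-ratio) * np.exp(-p / k))
    return scores


@dataclass
class OrderSelectionReport:
    """Per-order cross-validation losses, MC-perf scores and the selected order."""

    candidate_orders: list[int]
    per_order_losses: dict[int, list[float]]
    aggregate_loss: dict[int, float]  # mean held-out loss across folds
    best_fold_loss: dict[int, float]  # lowest single-fold loss (alternative aggregate)
    L_max: float
    mc_perf: dict[int, float]
    selected_order: int
    meta: dict = field(default_factory=dict)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "candidate_orders": self.candidate_orders,
            "per_order_losses": {str(p): v for p, v in self.per_order_losses.items()},
            "aggregate_loss": {str(p): v for p, v in self.aggregate_loss.items()},
            "best_fold_loss": {str(p): v for p, v in self.best_fold_loss.items()},
            "L_max": self.L_max,
            "mc_perf": {str(p): v for p, v in self.mc_perf.items()},
            "selected_order": self.selected_order,
            "meta": self.meta,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


def select_effective_order(report: "OrderSelectionReport | Mapping[int, float]") -> int:
    """Order with the highest MC-perf score; ties break toward the smaller order."""
    scores = report.mc_perf if isinstance(report, OrderSelectionReport) else report
    if not scores:
        raise ValueError("no scores supplied")
    best_p, best_s = None, -np.inf
    for p in sorted(int(q) for q in scores):
        s = float(scores[p])
        if s > best_s + 0.0:  # strict improvement required, so ties keep the smaller p
            best_p, best_s = p, s
    return best_p


def build_report(
    fold_losses: Mapping[int, Sequence[float]], k: int, meta: dict | None = None
) -> OrderSelectionReport:
    """Assemble a report from raw per-order fold losses."""
    orders = sorted(int(p) for p in fold_losses)
    aggregate = {p: float(np.mean(fold_losses[p])) for p in orders}
    best_fold = {p: float(np.min(fold_losses[p])) for p in orders}
    scores = mc_perf(aggregate, k)
    return OrderSelectionReport(
        candidate_orders=orders,
        per_order_losses={p: list(map(float, fold_losses[p])) for p in orders},
        aggregate_loss=aggregate,
        best_fold_loss=best_fold,
        L_max=max(aggregate.values()),
        mc_perf=scores,
        selected_order=select_effective_order(scores),
        meta=dict(meta or {}),
    )


_SURFACE_DOMAIN = {
    "kuramoto": (-np.pi, np.pi),
    "full_kuramoto": (-np.pi, np.pi),
    "si": (0.0, 1.0),
    "mcm": (0.0, 1.0),
    "diffusion": (-1.0, 1.0),
}


def _write_artifacts(config, dataset, report, out_dir: Path, k: int, cfg: TrainConfig):
    """Final full-data fits per order; kernel-surface grids and example rollouts."""
    dynamics = config["dynamics"]
    p_gen = int(config.get("p", 2))
    family = make_family(dynamics, p_gen, k)
    lo, hi = _SURFACE_DOMAIN.get(dynamics, (0.0, 1.0))
    grid = np.linspace(lo, hi, int(config.get("surface_grid", 41)))
    rows = []
    rollout_frames = []
    for order in report.candidate_orders:
        model = HyDyGNNModel(k=k, p_model=order, hidden_layout=cfg.hidden_layout,
                             rng_seed=cfg.rng_seed)
        train(model, dataset, cfg)
        model.to_json(out_dir / f"model_p{order}.json")
        for y1 in grid:
            for y2 in grid:
                rows.append(
                    {
                        "p_model": order,
                        "y1": y1,
                        "y2": y2,
                        "true": family.kernel.evaluate(y1, [y2]),
                        "learned": model.symmetric_eval(2, y1, [y2]),
                    }
                )
        # example long-horizon rollout against the ground truth (Euler, same dt)
        H = dataset.hypergraphs[0]
        rng = np.random.default_rng(cfg.rng_seed)
        x0 = sample_initial_state(dynamics, H.num_nodes, rng)
        dt = float(dataset.meta.get("dt") or config.get("dt", 0.01))
        steps = int(config.get("rollout_steps", 200))
        from .dynamics import euler_integrate

        truth = euler_integrate(H, family, x0, dt, steps)
        try:
            pred = rollout(model, H, x0, dt, steps)
            pred_states = pred.states
        except FloatingPointError:
            pred_states = np.full_like(truth.states, np.nan)
        frame = pd.DataFrame(
            {
                "p_model": order,
                "t": np.repeat(np.arange(steps + 1) * dt, H.num_nodes),
                "node": np.tile(np.arange(H.num_nodes), steps + 1),
                "truth": truth.states.reshape(-1),
                "predicted": pred_states.reshape(-1),
            }
        )
        rollout_frames.append(frame)
    pd.DataFrame(rows).to_csv(out_dir / "kernel_surfaces.csv", index=False)
    pd.concat(rollout_frames).to_csv(out_dir / "example_rollouts.csv", index=False)
    if config.get("plots"):
        _plot_artifacts(out_dir, report)


def _plot_artifacts(out_dir: Path, report: OrderSelectionReport) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    surfaces = pd.read_csv(out_dir / "kernel_surfaces.csv")
    orders = report.candidate_orders
    fig, axes = plt.subplots(len(orders), 2, figsize=(7, 3 * len(orders)), squeeze=False)
    for row, order in enumerate(orders):
        sub = surfaces[surfaces.p_model == order]
        n = int(np.sqrt(len(sub)))
        for col, what in enumerate(("true", "learned")):
            z = sub[what].to_numpy().reshape(n, n)
            im = axes[row][col].imshow(z, origin="lower")
            axes[row][col].set_title(f"p_model={order}: {what}")
            fig.colorbar(im, ax=axes[row][col])
    fig.tight_layout()
    fig.savefig(out_dir / "kernel_surfaces.png", dpi=100)
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(5, 3))
    ax.bar([str(p) for p in orders], [report.mc_perf[p] for p in orders])
    ax.set_xlabel("model order")
    ax.set_ylabel("MC-perf")
    fig.tight_layout()
    fig.savefig(out_dir / "mc_perf.png", dpi=100)
    plt.close(fig)


def run_experiment(config: Mapping | str | Path, out_dir: str | Path | None = None):
    """Generate data, cross-validate candidate orders, and select the effective order.

    ``config`` is a mapping (or path to a YAML file) with keys: ``dynamics``,
    ``p`` (generation order), ``scenario`` (``point``/``trajectory``),
    ``n_systems`` or ``n_traj``/``steps``/``dt``, ``candidate_orders``,
    ``n_folds``, ``seed``, optional ``hypergraph_params`` and training
    overrides (``epochs``, ``learning_rate``, ``l2_lambda``, ``lambda_grid``,
    ``hidden_layout``, ``batch_size``).  With ``artifacts: true`` and an
    output directory, final per-order fits, kernel-surface grids and example
    rollouts are written alongside the report.
    """
    if not isinstance(config, Mapping):
        import yaml

        config = yaml.safe_load(Path(config).read_text())
    config = dict(config)
    dynamics = config["dynamics"]
    p_gen = int(config.get("p", 2))
    scenario = config.get("scenario", "point")
    seed = int(config.get("seed", 0))
    hg_params = config.get("hypergraph_params")

    if scenario == "point":
        dataset = make_point_dataset(
            int(config.get("n_systems", 100)), dynamics, p_gen, hg_params, rng_seed=seed
        )
        loss = "pointwise"
    elif scenario == "trajectory":
        dataset = make_trajectory_dataset(
            int(config.get("n_traj", 25)),
            int(config.get("steps", 100)),
            float(config.get("dt", 0.01)),
            dynamics,
            p_gen,
            hg_params,
            rng_seed=seed,
        )
        loss = config.get("loss", "trajectory")
    else:
        raise ValueError(f"unknown scenario {scenario!r}")

    k = max(dataset.meta["probs"]) if dataset.meta.get("probs") else max(
        max(H.sizes, default=2) for H in dataset.hypergraphs
    )
    overrides: dict = {"rng_seed": seed}
    for key in ("epochs", "learning_rate", "lr_decay", "batch_size", "l2_lambda",
                "hidden_layout", "lambda_grid"):
        if key in config and config[key] is not None:
            value = config[key]
            if key in ("hidden_layout", "lambda_grid"):
                value = tuple(value)
            overrides[key] = value
    cfg = TrainConfig(**overrides)
    candidate_orders = list(config.get("candidate_orders", range(2, k + 1)))
    n_folds = int(config.get("n_folds", 5))
    fold_losses = cross_validate(
        dataset, candidate_orders, n_folds, cfg, loss=loss, fold_seed=seed
    )
    report = build_report(
        fold_losses,
        k,
        meta={
            "dynamics": dynamics,
            "p": p_gen,
            "scenario": scenario,
            "loss": loss,
            "n_folds": n_folds,
            "seed": seed,
            "n_samples": len(dataset),
        },
    )
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        report.to_json(out_dir / "report.json")
        pd.DataFrame(
            [
                {"p_model": p, "fold": f, "loss": L}
                for p, Ls in report.per_order_losses.items()
                for f, L in enumerate(Ls)
            ]
        ).to_csv(out_dir / "folds.csv", index=False)
        if config.get("artifacts"):
            _write_artifacts(config, dataset, report, out_dir, k, cfg)
    return report
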