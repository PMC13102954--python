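"""The bi-level meta-learning loop.

Inner loop: a task-specific learner starts from the shared initialization
theta0 and takes ``n_steps`` full-batch gradient-descent steps on the task's
support set.  Outer loop: the mean query loss of the adapted learners is
differentiated with respect to theta0 (through the inner steps in
second-order mode, or treating the adapted parameters as constants of theta0
in the cheaper first-order approximation) and theta0 takes one Adam step.

Training additionally runs the adaptive task sampler (a learned scorer over
per-task difficulty statistics) before each meta-update, and regularizes by
injecting uniform label noise into the selected tasks' support and query
labels.  Test time: adapt on the new task's support set, predict its query.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from autograd import grad as _agrad

from ._optim import Adam
from .metrics import MetricsReport, regression_report
from .tasks import Task, TaskSplit, sample_support_query

logger = logging.getLogger(__name__)

__all__ = [
    "MetaState",
    "MetaTrainConfig",
    "NoiseConfig",
    "evaluate_tasks",
    "finetune_and_predict",
    "inject_label_noise",
    "inner_adapt",
    "inner_adapt_batch",
    "meta_train",
    "outer_update",
    "task_meta_grad",
    "validation_loss",
]


@dataclass(frozen=True)
class NoiseConfig:
    """Uniform label-noise regularization: y -> y + eps, eps ~ U(-sigma, sigma).

    sigma is in p-scale units; the default 0.1 is a few percent of the
    typical p-scale label range.
    """

    sigma: float = 0.1
    apply_to: str = "both"  # support | query | both

    def __post_init__(self):
        if not (np.isfinite(self.sigma) and self.sigma >= 0):
            raise ValueError("sigma must be finite and >= 0")
        if self.apply_to not in ("support", "query", "both"):
            raise ValueError("apply_to must be support, query or both")


def inject_label_noise(records: Sequence, noise: NoiseConfig, rng: np.random.Generator) -> list:
    """Return copies of ``records`` with i.i.d. U(-sigma, sigma) label shifts."""
    if noise.sigma == 0:
        return list(records)
    eps = rng.uniform(-noise.sigma, noise.sigma, size=len(records))
    return [replace(r, affinity=r.affinity + float(e)) for r, e in zip(records, eps)]


def _noisy_task(task: Task, noise: NoiseConfig, rng: np.random.Generator) -> Task:
    """Apply label noise to a task's support and/or query records (copies)."""
    records = list(task.records)
    idx: list[int] = []
    if noise.apply_to in ("support", "both"):
        idx += list(task.support_idx)
    if noise.apply_to in ("query", "both"):
        idx += list(task.query_idx)
    noisy = inject_label_noise([records[i] for i in idx], noise, rng)
    for i, r in zip(idx, noisy):
        records[i] = r
    return replace(task, records=tuple(records))


# -- inner loop -------------------------------------------------------------

def inner_adapt_batch(learner, theta, batch, alpha: float, n_steps: int):
    """Functional inner loop; traceable so outer grads can flow through it."""
    g = _agrad(lambda th: learner.loss_batch(th, batch))
    for _ in range(n_steps):
        theta = theta - alpha * g(theta)
    return theta


def inner_adapt(learner, theta0, support: Sequence, alpha: float | None = None,
                n_steps: int | None = None) -> np.ndarray:
    """n_steps of full-batch gradient descent on the support set.

    Returns the adapted parameters; theta0 is not mutated.
    """
    if not support:
        raise ValueError("empty support set")
    alpha = alpha if alpha is not None else learner.config.inner_lr
    n_steps = n_steps if n_steps is not None else learner.config.n_inner_steps
    if alpha <= 0 or n_steps < 0:
        raise ValueError("need alpha > 0 and n_steps >= 0")
    batch = learner.make_batch(support)
    return np.asarray(inner_adapt_batch(learner, np.asarray(theta0, dtype=np.float64), batch, alpha, n_steps))


def task_meta_grad(learner, theta0, support_batch, query_batch, alpha: float,
                   n_steps: int, mode: str = "second_order") -> np.ndarray:
    """Gradient of the post-adaptation query loss with respect to theta0.

    second_order differentiates through the inner gradient steps; first_order
    evaluates the query gradient at the adapted parameters, treating them as
    detached from theta0 (the classic first-order approximation).
    """
    theta0 = np.asarray(theta0, dtype=np.float64)
    if mode == "second_order":
        def objective(th):
            th_i = inner_adapt_batch(learner, th, support_batch, alpha, n_steps)
            return learner.loss_batch(th_i, query_batch)
        return np.asarray(_agrad(objective)(theta0))
    if mode == "first_order":
        th_i = np.asarray(inner_adapt_batch(learner, theta0, support_batch, alpha, n_steps))
        return np.asarray(_agrad(lambda th: learner.loss_batch(th, query_batch))(th_i))
    raise ValueError(f"unknown mode {mode!r}")


def outer_update(learner, theta0, selected_tasks: Sequence[Task], alpha: float | None = None,
                 beta: float | None = None, n_steps: int | None = None,
                 mode: str = "second_order", optimizer=None,
                 aggregate: str = "mean") -> np.ndarray:
    """One meta-step of theta0 from the aggregated post-adaptation query losses.

    The expectation over tasks is realized as the arithmetic mean of the
    selected batch (``aggregate="sum"`` switches to the summed objective).
    With no optimizer given, a plain gradient step of rate beta is taken.
    """
    if not selected_tasks:
        raise ValueError("no tasks selected for the outer update")
    alpha = alpha if alpha is not None else learner.config.inner_lr
    beta = beta if beta is not None else learner.config.outer_lr
    n_steps = n_steps if n_steps is not None else learner.config.n_inner_steps
    grads = []
    for task in selected_tasks:
        if not task.query_idx:
            raise ValueError(f"task {task.target_id} has an empty query set")
        sb = learner.make_batch(task.support)
        qb = learner.make_batch(task.query)
        grads.append(task_meta_grad(learner, theta0, sb, qb, alpha, n_steps, mode))
    meta_grad = np.sum(grads, axis=0)
    if aggregate == "mean":
        meta_grad = meta_grad / len(grads)
    elif aggregate != "sum":
        raise ValueError("aggregate must be 'mean' or 'sum'")
    theta0 = np.asarray(theta0, dtype=np.float64)
    if optimizer is not None:
        return optimizer.step(theta0, meta_grad)
    return theta0 - beta * meta_grad


def validation_loss(learner, theta0, tasks: Sequence[Task], alpha: float,
                    n_steps: int) -> float:
    """Mean post-adaptation query loss over tasks (model-selection signal)."""
    losses = []
    for task in tasks:
        th = inner_adapt(learner, theta0, task.support, alpha, n_steps)
        losses.append(learner.loss(th, task.query))
    return float(np.mean(losses))


# -- training schedule ------------------------------------------------------

@dataclass
class MetaTrainConfig:
    """Schedule and sampler settings for meta-training.

    Defaults follow the benchmark protocol: 10 outer epochs of 100
    meta-updates, 5 inner steps, candidate pool B=16 with N_slct=8 resampled
    by the adapter.
    """

    epochs: int = 10
    updates_per_epoch: int = 100
    batch_candidates: int = 16  # B
    n_select: int = 8  # N_slct
    support_size: int = 5
    mode: str = "second_order"
    aggregate: str = "mean"
    use_adapter: bool = True
    adapter_hidden: int = 8
    adapter_lr: float = 0.01
    val_batch: int = 4  # validation tasks sampled per adapter update
    similarity: str = "cosine"


@dataclass
class MetaState:
    """The evolving (theta0, phi) pair plus history and the best checkpoint."""

    theta0: np.ndarray
    adapter_phi: np.ndarray | None
    k: int = 0
    history: list = field(default_factory=list)
    val_curve: list = field(default_factory=list)
    best_theta0: np.ndarray | None = None
    best_val_loss: float = np.inf

    def record_validation(self, val_loss: float) -> None:
        self.val_curve.append(val_loss)
        if val_loss < self.best_val_loss:
            self.best_val_loss = val_loss
            self.best_theta0 = self.theta0.copy()


def _episode(task: Task, support_size: int, rng: np.random.Generator) -> Task:
    return sample_support_query(task, support_size, rng)


def meta_train(learner, split: TaskSplit, config: MetaTrainConfig | None = None,
               noise: NoiseConfig | None = None, seed: int = 0,
               log_file=None) -> MetaState:
    """Run the full meta-training schedule; returns the final MetaState.

    Per meta-update: draw B candidate tasks uniformly and a fresh
    support/query episode for each; compute per-task statistics; update the
    adapter by its one-step hypergradient and resample N_slct tasks with the
    refreshed weights; inject label noise; take one outer Adam step on
    theta0.  After each epoch the mean validation query loss selects the
    best checkpoint.
    """
    from .adaptive_sampler import (Adapter, adapter_scores, sample_tasks,
                                   task_statistics, update_adapter)

    config = config or MetaTrainConfig()
    noise = noise or NoiseConfig()
    if not split.train or not split.validation:
        raise ValueError("meta_train needs non-empty train and validation task lists")
    rng = np.random.default_rng(seed)
    theta0 = learner.init_flat(seed)
    adapter = Adapter(hidden=config.adapter_hidden)
    phi = adapter.init_flat(seed + 1) if config.use_adapter else None
    optimizer = Adam(learner.config.outer_lr)
    state = MetaState(theta0=theta0, adapter_phi=phi)
    alpha, n_steps = learner.config.inner_lr, learner.config.n_inner_steps

    B = config.batch_candidates
    if B > len(split.train):
        logger.warning("candidate pool B=%d clipped to %d train tasks", B, len(split.train))
        B = len(split.train)
    n_select = min(config.n_select, B)

    for epoch in range(config.epochs):
        for _ in range(config.updates_per_epoch):
            cand_idx = rng.choice(len(split.train), size=B, replace=False)
            episodes = [_episode(split.train[i], config.support_size, rng) for i in cand_idx]
            stats = [task_statistics(learner, state.theta0, ep, alpha, n_steps,
                                     similarity=config.similarity)
                     for ep in episodes]
            if config.use_adapter:
                val_idx = rng.choice(len(split.validation),
                                     size=min(config.val_batch, len(split.validation)),
                                     replace=False)
                val_eps = [_episode(split.validation[i], config.support_size, rng)
                           for i in val_idx]
                phi = update_adapter(
                    adapter, phi, learner, state.theta0, episodes, stats, val_eps,
                    alpha=alpha, meta_beta=learner.config.outer_lr,
                    adapter_beta=config.adapter_lr, n_steps=n_steps, mode=config.mode,
                )
                state.adapter_phi = phi
                weights = adapter_scores(adapter, phi, stats)
                if not np.all(np.isfinite(weights)):
                    logger.warning("non-finite adapter weights at update %d; "
                                   "falling back to uniform", state.k + 1)
                    weights = np.full(B, 1.0 / B)
            else:
                weights = np.full(B, 1.0 / B)
            selected = sample_tasks(weights, n_select, rng)
            noisy = [_noisy_task(episodes[i], noise, rng) for i in selected]
            state.theta0 = outer_update(
                learner, state.theta0, noisy, alpha=alpha, n_steps=n_steps,
                mode=config.mode, optimizer=optimizer, aggregate=config.aggregate,
            )
            state.k += 1
            entry = {
                "k": state.k,
                "epoch": epoch,
                "candidates": [split.train[i].target_id for i in cand_idx],
                "weights": [float(w) for w in weights],
                "selected": [split.train[cand_idx[i]].target_id for i in selected],
                "query_loss": [float(s.query_loss_adapted) for s in stats],
                "grad_similarity": [float(s.grad_similarity) for s in stats],
            }
            state.history.append(entry)
            if log_file is not None:
                import json

                log_file.write(json.dumps(entry) + "\n")
        # epoch-level model selection on the validation tasks
        val_rng = np.random.default_rng(seed * 100003 + epoch)
        val_eps = [_episode(t, config.support_size, val_rng) for t in split.validation]
        state.record_validation(validation_loss(learner, state.theta0, val_eps, alpha, n_steps))
    return state


def finetune_and_predict(learner, theta0, test_task: Task, alpha: float | None = None,
                         n_steps: int | None = None) -> tuple[np.ndarray, MetricsReport]:
    """Adapt on the test task's support set and score its query set."""
    if not test_task.support_idx or not test_task.query_idx:
        raise ValueError(f"task {test_task.target_id} needs non-empty support and query")
    th = inner_adapt(learner, theta0, test_task.support, alpha, n_steps)
    preds = learner.predict(th, test_task.query)
    labels = np.array([r.affinity for r in test_task.query])
    return preds, regression_report(labels, preds)


def evaluate_tasks(learner, theta0, tasks: Sequence[Task], support_size: int,
                   seed: int = 0, alpha: float | None = None,
                   n_steps: int | None = None) -> list[MetricsReport]:
    """Episode each task, fine-tune, and report per-task regression metrics."""
    rng = np.random.default_rng(seed)
    reports = []
    for task in tasks:
        ep = sample_support_query(task, support_size, rng)
        _, report = finetune_and_predict(learner, theta0, ep, alpha, n_steps)
        reports.append(report)
    return reports
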