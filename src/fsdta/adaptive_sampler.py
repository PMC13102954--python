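"""The adaptive task module: learned difficulty-aware task sampling.

Each candidate task in a meta-batch is summarized by two statistics: the
query loss after inner adaptation (how hard the task currently is) and the
similarity between the support-set and query-set loss gradients at theta0
(how well within-task adaptation is expected to generalize).  A small
learned adapter g_phi maps the statistics to a softmax weight per task, and
N_slct tasks are resampled with those weights to form the meta-batch — an
"easy-to-hard" curriculum that emerges rather than being hand-coded.

The adapter is trained by bi-level optimization with a one-step
approximation: form the virtual meta-parameters that one weight-modulated
meta-step would produce, measure the validation loss there, and step phi
against the gradient of that loss through the weights.  Because the virtual
step is linear in the weights, the hypergradient is the exact chain rule
d L_val / d phi = sum_i (dL_val/d omega_i) * (d omega_i / d phi).

The two bidirectional recurrent extractors (one per statistic channel) score
each task independently; weights over a batch of tasks with identical
statistics are therefore exactly uniform, making the module exchangeable
over the candidate order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import autograd.numpy as anp
import numpy as np
from autograd import grad as _agrad

from ._optim import ParamSpec, glorot
from .meta_engine import inner_adapt_batch, task_meta_grad
from .tasks import Task

logger = logging.getLogger(__name__)

__all__ = [
    "Adapter",
    "AdapterState",
    "SamplingDecision",
    "TaskStats",
    "adapter_scores",
    "adapter_validation_loss",
    "sample_tasks",
    "task_statistics",
    "update_adapter",
]


@dataclass(frozen=True)
class TaskStats:
    """The adapter's two inputs for one candidate task."""

    query_loss_adapted: float
    grad_similarity: float

    def __post_init__(self):
        if not (np.isfinite(self.query_loss_adapted) and np.isfinite(self.grad_similarity)):
            raise ValueError("task statistics must be finite")


@dataclass(frozen=True)
class AdapterState:
    """Adapter parameters phi as a flat vector with its layout."""

    flat: np.ndarray
    spec: ParamSpec


@dataclass(frozen=True)
class SamplingDecision:
    weights: np.ndarray
    selected: tuple[int, ...]

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=np.float64)
        if np.any(w < 0) or abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("weights must be a probability vector")
        if len(set(self.selected)) != len(self.selected):
            raise ValueError("selected indices must be unique")
        object.__setattr__(self, "weights", w)


def _sigmoid(x):
    return 0.5 * (anp.tanh(0.5 * x) + 1.0)


class Adapter:
    """g_phi: (query loss, gradient similarity) per task -> sampling weights.

    Two bidirectional LSTM extractors, one per statistic channel; the
    per-task forward/backward hidden states of both channels are
    concatenated and scored by a linear head, then softmax-normalized over
    the candidate batch.
    """

    CHANNELS = ("loss", "sim")
    DIRECTIONS = ("f", "b")

    def __init__(self, hidden: int = 8):
        self.hidden = hidden
        items = []
        for ch in self.CHANNELS:
            for d in self.DIRECTIONS:
                items += [
                    (f"{ch}_{d}_Wx", (4 * hidden,)),
                    (f"{ch}_{d}_b", (4 * hidden,)),
                ]
        items += [("head_w", (4 * hidden,)), ("head_b", (1,))]
        self.spec = ParamSpec.from_items(items)

    @property
    def n_params(self) -> int:
        return self.spec.n_params

    def init_flat(self, seed: int = 0) -> np.ndarray:
        rng = np.random.default_rng(seed)
        named = {}
        for name, shape in zip(self.spec.names, self.spec.shapes):
            if name.endswith("_b") or name == "head_b":
                named[name] = np.zeros(shape)
            else:
                named[name] = rng.normal(0.0, 0.5, size=shape)
        return self.spec.flatten(named)

    def init_state(self, seed: int = 0) -> AdapterState:
        return AdapterState(flat=self.init_flat(seed), spec=self.spec)

    def _cell(self, x, Wx, b):
        # one LSTM step from zero state on a scalar input
        H = self.hidden
        gates = x * Wx + b
        i = _sigmoid(gates[:, 0:H])
        f = _sigmoid(gates[:, H : 2 * H])  # noqa: F841 - forget gate unused from zero state
        g = anp.tanh(gates[:, 2 * H : 3 * H])
        o = _sigmoid(gates[:, 3 * H : 4 * H])
        c = i * g
        return o * anp.tanh(c)

    @staticmethod
    def _standardize(x):
        # batch-relative z-score keeps the LSTM gates out of saturation when
        # early-training losses are large; a constant channel maps to zeros,
        # which preserves exact uniformity for all-equal statistics
        sd = np.std(x)
        return (x - np.mean(x)) / sd if sd > 0 else np.zeros_like(x)

    def scores_traced(self, phi, losses, sims):
        """Softmax weights over the batch; differentiable w.r.t. phi."""
        p = self.spec.unflatten(phi)
        feats = []
        for ch, x in (("loss", self._standardize(losses)), ("sim", self._standardize(sims))):
            x = anp.reshape(x, (-1, 1))
            for d in self.DIRECTIONS:
                feats.append(self._cell(x, p[f"{ch}_{d}_Wx"], p[f"{ch}_{d}_b"]))
        h = anp.concatenate(feats, axis=1)  # (B, 4H)
        s = anp.dot(h, p["head_w"]) + p["head_b"][0]
        s = s - anp.max(s)
        e = anp.exp(s)
        return e / anp.sum(e)


def adapter_scores(adapter: Adapter, phi, stats: list[TaskStats]) -> np.ndarray:
    """Probability vector over the candidate batch (sums to 1 exactly)."""
    if not stats:
        raise ValueError("need at least one candidate task")
    losses = np.array([s.query_loss_adapted for s in stats], dtype=np.float64)
    sims = np.array([s.grad_similarity for s in stats], dtype=np.float64)
    w = np.asarray(adapter.scores_traced(np.asarray(phi, dtype=np.float64), losses, sims))
    return w / w.sum()


def task_statistics(learner, theta0, task: Task, alpha: float, n_steps: int,
                    similarity: str = "cosine") -> TaskStats:
    """Post-adaptation query loss and support<->query gradient similarity.

    The similarity is the cosine of the two flat loss gradients at theta0
    (``similarity="dot"`` keeps the raw inner product); a zero-norm gradient
    yields similarity 0.
    """
    if not task.support_idx or not task.query_idx:
        raise ValueError(f"task {task.target_id} needs non-empty support and query")
    theta0 = np.asarray(theta0, dtype=np.float64)
    sb = learner.make_batch(task.support)
    qb = learner.make_batch(task.query)
    th_i = np.asarray(inner_adapt_batch(learner, theta0, sb, alpha, n_steps))
    qloss = float(learner.loss_batch(th_i, qb))
    gs = np.asarray(_agrad(lambda th: learner.loss_batch(th, sb))(theta0))
    gq = np.asarray(_agrad(lambda th: learner.loss_batch(th, qb))(theta0))
    if similarity == "dot":
        sim = float(gs @ gq)
    else:
        ns, nq = np.linalg.norm(gs), np.linalg.norm(gq)
        if ns == 0 or nq == 0:
            logger.info("zero-norm gradient in task %s; similarity set to 0", task.target_id)
            sim = 0.0
        else:
            sim = float(gs @ gq / (ns * nq))
    return TaskStats(query_loss_adapted=qloss, grad_similarity=sim)


def sample_tasks(weights, n_slct: int, rng: np.random.Generator) -> list[int]:
    """Weighted sampling without replacement (sequential, renormalizing).

    If the remaining probability mass underflows to zero (a saturated
    softmax can emit an exact one-hot), the leftover draws fall back to
    uniform over the not-yet-chosen indices.
    """
    w = np.asarray(weights, dtype=np.float64).copy()
    if not 1 <= n_slct <= w.size:
        raise ValueError(f"n_slct must be in [1, {w.size}]")
    chosen: list[int] = []
    for _ in range(n_slct):
        total = w.sum()
        if total > 0:
            i = int(rng.choice(w.size, p=w / total))
        else:
            remaining = [j for j in range(w.size) if j not in chosen]
            i = int(rng.choice(remaining))
        chosen.append(i)
        w[i] = 0.0
    return chosen


def _val_loss_fn(learner, val_tasks, alpha, n_steps):
    batches = [(learner.make_batch(t.support), learner.make_batch(t.query)) for t in val_tasks]

    def val_loss(theta):
        total = 0.0
        for sb, qb in batches:
            th = inner_adapt_batch(learner, theta, sb, alpha, n_steps)
            total = total + learner.loss_batch(th, qb)
        return total / len(batches)

    return val_loss


def _candidate_meta_grads(learner, theta0, candidate_tasks, alpha, n_steps, mode):
    grads = []
    for t in candidate_tasks:
        sb = learner.make_batch(t.support)
        qb = learner.make_batch(t.query)
        grads.append(task_meta_grad(learner, theta0, sb, qb, alpha, n_steps, mode))
    return grads


def adapter_validation_loss(adapter: Adapter, phi, learner, theta0, candidate_tasks,
                            stats, val_tasks, alpha: float, meta_beta: float,
                            n_steps: int, mode: str = "second_order",
                            meta_grads=None) -> float:
    """Validation loss at the virtual meta-parameters theta0_tilde(phi).

    theta0_tilde = theta0 - meta_beta * sum_i omega_i(phi) * g_i, with g_i the
    per-candidate meta-gradients (constants in phi).  This is the exact
    function whose phi-gradient ``update_adapter`` follows; the test suite
    finite-differences it.
    """
    theta0 = np.asarray(theta0, dtype=np.float64)
    if meta_grads is None:
        meta_grads = _candidate_meta_grads(learner, theta0, candidate_tasks, alpha, n_steps, mode)
    omega = adapter_scores(adapter, phi, stats)
    theta_tilde = theta0 - meta_beta * np.sum([w * g for w, g in zip(omega, meta_grads)], axis=0)
    return float(_val_loss_fn(learner, val_tasks, alpha, n_steps)(theta_tilde))


def update_adapter(adapter: Adapter, phi, learner, theta0, candidate_tasks, stats,
                   val_tasks, alpha: float, meta_beta: float, adapter_beta: float,
                   n_steps: int, mode: str = "second_order",
                   max_grad_norm: float = 10.0) -> np.ndarray:
    """One hypergradient step on phi against the validation loss.

    Steps: (1) per-candidate meta-gradients g_i; (2) virtual meta-step
    theta0_tilde(phi) weighting each task's contribution by omega_i(phi);
    (3) exact gradient v of the validation loss (through validation inner
    adaptation) at theta0_tilde; (4) chain rule dL/d omega_i = -meta_beta *
    g_i.v, back through the softmax scores to phi; (5) one step of rate
    ``adapter_beta``.
    """
    if not candidate_tasks or not val_tasks:
        raise ValueError("need non-empty candidate and validation task lists")
    phi = np.asarray(phi, dtype=np.float64)
    if adapter_beta == 0:
        return phi
    theta0 = np.asarray(theta0, dtype=np.float64)
    meta_grads = _candidate_meta_grads(learner, theta0, candidate_tasks, alpha, n_steps, mode)
    losses = np.array([s.query_loss_adapted for s in stats], dtype=np.float64)
    sims = np.array([s.grad_similarity for s in stats], dtype=np.float64)
    omega = np.asarray(adapter.scores_traced(phi, losses, sims))
    theta_tilde = theta0 - meta_beta * np.sum([w * g for w, g in zip(omega, meta_grads)], axis=0)
    v = np.asarray(_agrad(_val_loss_fn(learner, val_tasks, alpha, n_steps))(theta_tilde))
    coeff = np.array([-meta_beta * float(g @ v) for g in meta_grads])

    def surrogate(ph):
        return anp.sum(coeff * adapter.scores_traced(ph, losses, sims))

    hyper = np.asarray(_agrad(surrogate)(phi))
    # early-training loss spikes can make the coefficients explode; a norm
    # clip keeps phi from saturating the softmax into a degenerate one-hot
    norm = np.linalg.norm(hyper)
    if max_grad_norm is not None and norm > max_grad_norm:
        logger.info("hypergradient norm %.2g clipped to %.2g", norm, max_grad_norm)
        hyper = hyper * (max_grad_norm / norm)
    return phi - adapter_beta * hyper
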