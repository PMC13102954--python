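"""The task-level affinity regressor f_theta(protein, drug).

Drug path: a two-layer graph neural network (GCN, GAT, GIN, or the hybrid
GAT_GCN: an attention layer followed by a convolutional layer with
concatenated max+mean pooling) over the atom graph.  Protein path: token
embedding plus a three-layer 1-D convolutional network with global max
pooling.  The pooled features are concatenated and passed through a dense
head to a scalar p-scale affinity.

Everything is functional in the parameters: ``predict``, ``loss`` and
``grad`` all take the flat parameter vector explicitly, because the
meta-learning inner loop must evaluate losses at both the shared
initialization and the task-adapted parameters, and because second-order
meta-gradients differentiate through the inner gradient steps.  Gradients
come from reverse-mode automatic differentiation (autograd), which also
supports the nested differentiation the outer loop needs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import autograd.numpy as anp
import numpy as np
from autograd import grad as _agrad

from ._optim import ParamSpec, glorot
from .featurization import AffinityRecord, FeaturizationConfig

__all__ = [
    "ARCHITECTURES",
    "BaseLearner",
    "LearnerConfig",
    "LinearProbe",
    "ParameterSet",
    "ProbeRecord",
    "load_checkpoint",
    "save_checkpoint",
]

ARCHITECTURES = ("GCN", "GAT", "GIN", "GAT_GCN")


@dataclass(frozen=True)
class LearnerConfig:
    """Architecture and optimization hyperparameters of the base learner.

    ``inner_lr`` (alpha) is the per-task gradient-descent rate used for
    support-set adaptation; ``outer_lr`` (beta) drives the meta-update of the
    shared initialization; ``n_inner_steps`` full-batch support steps are
    taken per adaptation.
    """

    arch: str = "GCN"
    graph_hidden: tuple[int, int] = (64, 128)
    conv_channels: tuple[int, int, int] = (32, 32, 32)
    conv_kernels: tuple[int, int, int] = (3, 3, 3)
    protein_embed: int = 32
    head_hidden: int = 128
    protein_vocab: int = 27
    inner_lr: float = 0.01
    outer_lr: float = 0.001
    n_inner_steps: int = 5

    def __post_init__(self):
        if self.arch not in ARCHITECTURES:
            raise ValueError(f"unknown arch {self.arch!r}; choose from {ARCHITECTURES}")

    @classmethod
    def tiny(cls, arch: str = "GCN", **overrides) -> "LearnerConfig":
        """Desk-scale widths: runs in milliseconds, same code path."""
        defaults = dict(
            arch=arch,
            graph_hidden=(4, 4),
            conv_channels=(4, 4, 4),
            conv_kernels=(3, 3, 3),
            protein_embed=4,
            head_hidden=8,
        )
        defaults.update(overrides)
        return cls(**defaults)


@dataclass(frozen=True)
class ParameterSet:
    """Named view over a flat parameter vector (round trip is lossless)."""

    flat: np.ndarray
    spec: ParamSpec
    arch: str

    @property
    def flat_view(self) -> np.ndarray:
        return self.flat

    @property
    def named(self) -> dict:
        return self.spec.unflatten(self.flat)


class _Batch:
    """Precomputed constant tensors for one list of records."""

    __slots__ = ("node_feats", "adj", "norm_adj", "att_mask", "pool_mean", "node_mask", "tokens", "labels", "n_graphs")

    def __init__(self, records: Sequence[AffinityRecord], n_feat: int, min_prot_len: int):
        if not records:
            raise ValueError("empty record list")
        feats, sizes, edges_all = [], [], []
        offset = 0
        for r in records:
            g = r.drug
            if g.node_features.shape[1] != n_feat:
                raise ValueError(
                    f"drug graph has {g.node_features.shape[1]} features, learner expects {n_feat}"
                )
            feats.append(g.node_features)
            sizes.append(g.n_atoms)
            for i, j in g.edges:
                edges_all.append((i + offset, j + offset))
            offset += g.n_atoms
        n_nodes = offset
        G = len(records)
        self.n_graphs = G
        self.node_feats = np.concatenate(feats, axis=0)
        adj = np.zeros((n_nodes, n_nodes))
        for i, j in edges_all:
            adj[i, j] = adj[j, i] = 1.0
        self.adj = adj
        a_hat = adj + np.eye(n_nodes)
        d = a_hat.sum(axis=1)
        d_inv_sqrt = 1.0 / np.sqrt(d)
        self.norm_adj = a_hat * d_inv_sqrt[:, None] * d_inv_sqrt[None, :]
        self.att_mask = a_hat > 0
        self.pool_mean = np.zeros((G, n_nodes))
        self.node_mask = np.zeros((G, n_nodes), dtype=bool)
        start = 0
        for gi, sz in enumerate(sizes):
            self.pool_mean[gi, start : start + sz] = 1.0 / sz
            self.node_mask[gi, start : start + sz] = True
            start += sz
        # trim protein tokens to the longest true length in the batch (but at
        # least min_prot_len so all 'valid' convolutions stay non-empty)
        toks = np.stack([r.protein.tokens for r in records])
        lmax = max(min_prot_len, max(r.protein.true_length for r in records))
        self.tokens = toks[:, : min(lmax, toks.shape[1])]
        self.labels = np.array([r.affinity for r in records], dtype=np.float64)


def _relu(x):
    return anp.maximum(x, 0.0)


def _leaky_relu(x, slope=0.2):
    return anp.maximum(x, 0.0) + slope * anp.minimum(x, 0.0)


def _gat_layer(h, W, a_src, a_dst, b, mask):
    wh = anp.dot(h, W)
    e = _leaky_relu(anp.dot(wh, a_src)[:, None] + anp.dot(wh, a_dst)[None, :])
    scores = anp.where(mask, e, -1e9)
    scores = scores - anp.max(scores, axis=1, keepdims=True)
    exp = anp.exp(scores) * mask
    alpha = exp / anp.sum(exp, axis=1, keepdims=True)
    return _relu(anp.dot(alpha, wh) + b)


def _conv1d(x, W, b, k):
    # x: (B, L, C_in); W: (k*C_in, C_out) -> (B, L-k+1, C_out)
    L = x.shape[1]
    cols = anp.concatenate([x[:, j : L - k + 1 + j, :] for j in range(k)], axis=2)
    return _relu(anp.dot(cols, W) + b)


class BaseLearner:
    """Affinity regressor with an explicit flat-parameter contract."""

    def __init__(self, config: LearnerConfig | None = None,
                 featurization: FeaturizationConfig | None = None):
        self.config = config or LearnerConfig()
        self.featurization = featurization or FeaturizationConfig()
        self.n_feat = self.featurization.n_feat
        self.spec = self._build_spec()

    # -- parameter layout ---------------------------------------------------
    def _build_spec(self) -> ParamSpec:
        c = self.config
        g1, g2 = c.graph_hidden
        items: list[tuple[str, tuple]] = []
        if c.arch == "GCN":
            items += [("g1_W", (self.n_feat, g1)), ("g1_b", (g1,)),
                      ("g2_W", (g1, g2)), ("g2_b", (g2,))]
            drug_out = g2
        elif c.arch == "GAT":
            items += [("g1_W", (self.n_feat, g1)), ("g1_asrc", (g1,)), ("g1_adst", (g1,)), ("g1_b", (g1,)),
                      ("g2_W", (g1, g2)), ("g2_asrc", (g2,)), ("g2_adst", (g2,)), ("g2_b", (g2,))]
            drug_out = g2
        elif c.arch == "GIN":
            items += [("g1_eps", ()), ("g1_W1", (self.n_feat, g1)), ("g1_b1", (g1,)),
                      ("g1_W2", (g1, g1)), ("g1_b2", (g1,)),
                      ("g2_eps", ()), ("g2_W1", (g1, g2)), ("g2_b1", (g2,)),
                      ("g2_W2", (g2, g2)), ("g2_b2", (g2,))]
            drug_out = g2
        else:  # GAT_GCN: attention layer then convolutional layer, max+mean pooling
            items += [("g1_W", (self.n_feat, g1)), ("g1_asrc", (g1,)), ("g1_adst", (g1,)), ("g1_b", (g1,)),
                      ("g2_W", (g1, g2)), ("g2_b", (g2,))]
            drug_out = 2 * g2
        ch, ks = c.conv_channels, c.conv_kernels
        items += [("emb", (c.protein_vocab, c.protein_embed))]
        c_in = c.protein_embed
        for li, (co, k) in enumerate(zip(ch, ks), start=1):
            items += [(f"conv{li}_W", (k * c_in, co)), (f"conv{li}_b", (co,))]
            c_in = co
        items += [("head_W1", (drug_out + ch[-1], c.head_hidden)), ("head_b1", (c.head_hidden,)),
                  ("head_W2", (c.head_hidden, 1)), ("head_b2", (1,))]
        return ParamSpec.from_items(items)

    @property
    def n_params(self) -> int:
        return self.spec.n_params

    @property
    def min_prot_len(self) -> int:
        return sum(k - 1 for k in self.config.conv_kernels) + 1

    def init_params(self, seed: int = 0) -> ParameterSet:
        """Deterministic Glorot/zero initialization of all parameters."""
        rng = np.random.default_rng(seed)
        named = {}
        for name, shape in zip(self.spec.names, self.spec.shapes):
            if not shape:  # scalar (GIN epsilon)
                named[name] = np.zeros(())
            elif name == "emb":
                named[name] = rng.normal(0.0, 0.1, size=shape)
            elif name.endswith(("_b", "_b1", "_b2")) or name.endswith(("asrc", "adst")):
                named[name] = (rng.normal(0.0, 0.1, size=shape)
                               if name.endswith(("asrc", "adst")) else np.zeros(shape))
            else:
                named[name] = glorot(rng, shape)
        return ParameterSet(flat=self.spec.flatten(named), spec=self.spec, arch=self.config.arch)

    def init_flat(self, seed: int = 0) -> np.ndarray:
        return self.init_params(seed).flat

    # -- forward ------------------------------------------------------------
    def make_batch(self, records: Sequence[AffinityRecord]) -> _Batch:
        return _Batch(records, self.n_feat, self.min_prot_len)

    def _drug_forward(self, p, batch: _Batch):
        c = self.config
        h = batch.node_feats
        if c.arch == "GCN":
            h = _relu(anp.dot(batch.norm_adj, anp.dot(h, p["g1_W"])) + p["g1_b"])
            h = _relu(anp.dot(batch.norm_adj, anp.dot(h, p["g2_W"])) + p["g2_b"])
            return anp.dot(batch.pool_mean, h)
        if c.arch == "GAT":
            h = _gat_layer(h, p["g1_W"], p["g1_asrc"], p["g1_adst"], p["g1_b"], batch.att_mask)
            h = _gat_layer(h, p["g2_W"], p["g2_asrc"], p["g2_adst"], p["g2_b"], batch.att_mask)
            return anp.dot(batch.pool_mean, h)
        if c.arch == "GIN":
            for li in ("g1", "g2"):
                agg = (1.0 + p[f"{li}_eps"]) * h + anp.dot(batch.adj, h)
                h = _relu(anp.dot(agg, p[f"{li}_W1"]) + p[f"{li}_b1"])
                h = _relu(anp.dot(h, p[f"{li}_W2"]) + p[f"{li}_b2"])
            return anp.dot(batch.pool_mean, h)
        # GAT_GCN
        h = _gat_layer(h, p["g1_W"], p["g1_asrc"], p["g1_adst"], p["g1_b"], batch.att_mask)
        h = _relu(anp.dot(batch.norm_adj, anp.dot(h, p["g2_W"])) + p["g2_b"])
        # materialize the (graphs, nodes, feat) broadcast via multiply so the
        # reverse pass unbroadcasts correctly, then mask out foreign nodes
        h3 = np.ones((batch.n_graphs, 1, 1)) * anp.expand_dims(h, 0)
        masked = anp.where(batch.node_mask[:, :, None], h3, -1e9)
        h_max = anp.max(masked, axis=1)
        h_mean = anp.dot(batch.pool_mean, h)
        return anp.concatenate([h_max, h_mean], axis=1)

    def _protein_forward(self, p, batch: _Batch):
        x = p["emb"][batch.tokens]  # (B, L, D)
        for li, k in enumerate(self.config.conv_kernels, start=1):
            x = _conv1d(x, p[f"conv{li}_W"], p[f"conv{li}_b"], k)
        return anp.max(x, axis=1)

    def predict_batch(self, flat, batch: _Batch):
        p = self.spec.unflatten(flat)
        z = anp.concatenate([self._drug_forward(p, batch), self._protein_forward(p, batch)], axis=1)
        h = _relu(anp.dot(z, p["head_W1"]) + p["head_b1"])
        return anp.reshape(anp.dot(h, p["head_W2"]) + p["head_b2"], (-1,))

    def loss_batch(self, flat, batch: _Batch):
        resid = self.predict_batch(flat, batch) - batch.labels
        return anp.mean(resid**2)

    # -- record-level convenience wrappers ----------------------------------
    def predict(self, flat, records: Sequence[AffinityRecord]) -> np.ndarray:
        return np.asarray(self.predict_batch(np.asarray(flat), self.make_batch(records)))

    def loss(self, flat, records: Sequence[AffinityRecord]) -> float:
        return float(self.loss_batch(np.asarray(flat), self.make_batch(records)))

    def grad(self, flat, records: Sequence[AffinityRecord]) -> np.ndarray:
        batch = self.make_batch(records)
        return np.asarray(_agrad(lambda th: self.loss_batch(th, batch))(np.asarray(flat, dtype=np.float64)))


@dataclass(frozen=True)
class ProbeRecord:
    """A scalar observation for the analytic linear-probe learner."""

    x: float
    affinity: float


class LinearProbe:
    """One-parameter learner f(x) = theta * x with squared loss.

    Small enough that inner steps, meta-gradients and hypergradients have
    closed forms, which the test suite checks against the full machinery.
    """

    n_params = 1

    def __init__(self):
        self.config = None
        self.spec = ParamSpec.from_items([("theta", (1,))])

    def init_flat(self, seed: int = 0) -> np.ndarray:
        return np.array([np.random.default_rng(seed).normal()])

    class _ProbeBatch:
        __slots__ = ("x", "labels")

        def __init__(self, records):
            self.x = np.array([r.x for r in records], dtype=np.float64)
            self.labels = np.array([r.affinity for r in records], dtype=np.float64)

    def make_batch(self, records):
        if not records:
            raise ValueError("empty record list")
        return self._ProbeBatch(records)

    def predict_batch(self, flat, batch):
        return flat[0] * batch.x

    def loss_batch(self, flat, batch):
        return anp.mean((self.predict_batch(flat, batch) - batch.labels) ** 2)

    def predict(self, flat, records):
        return np.asarray(self.predict_batch(np.asarray(flat), self.make_batch(records)))

    def loss(self, flat, records):
        return float(self.loss_batch(np.asarray(flat), self.make_batch(records)))

    def grad(self, flat, records):
        batch = self.make_batch(records)
        return np.asarray(_agrad(lambda th: self.loss_batch(th, batch))(np.asarray(flat, dtype=np.float64)))


def save_checkpoint(path, flat: np.ndarray, learner_config: LearnerConfig,
                    featurization: FeaturizationConfig, extra: dict | None = None) -> None:
    """Named-tensor archive (.npz) with a JSON sidecar of the configs."""
    learner = BaseLearner(learner_config, featurization)
    named = learner.spec.unflatten(np.asarray(flat))
    np.savez(path, **{k: np.asarray(v) for k, v in named.items()})
    sidecar = {
        "learner_config": asdict(learner_config),
        "featurization": {"max_len": featurization.max_len, "input_unit": featurization.input_unit.value},
        "extra": extra or {},
    }
    with open(str(path) + ".json", "w") as fh:
        json.dump(sidecar, fh, indent=1)


def load_checkpoint(path) -> tuple[np.ndarray, LearnerConfig]:
    with open(str(path) + ".json") as fh:
        sidecar = json.load(fh)
    cfg_d = sidecar["learner_config"]
    for key in ("graph_hidden", "conv_channels", "conv_kernels"):
        cfg_d[key] = tuple(cfg_d[key])
    config = LearnerConfig(**cfg_d)
    learner = BaseLearner(config)
    with np.load(path) as npz:
        named = {k: npz[k] for k in npz.files}
    for name, shape in zip(learner.spec.names, learner.spec.shapes):
        if tuple(np.shape(named[name])) != shape:
            raise ValueError(f"checkpoint shape mismatch for {name}")
    return learner.spec.flatten(named), config
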