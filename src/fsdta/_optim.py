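"""Flat-parameter utilities and a minimal Adam optimizer.

All learners expose their parameters as one flat float64 vector so the
meta-learning algebra (inner gradient steps, meta-gradients, hypergradients)
can be written as plain vector arithmetic.  ``ParamSpec`` maps a fixed name
order to slices of that vector, losslessly both ways.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import autograd.numpy as anp
import numpy as np


@dataclass(frozen=True)
class ParamSpec:
    """Fixed name -> shape layout over a flat parameter vector."""

    names: tuple[str, ...]
    shapes: tuple[tuple[int, ...], ...]

    @classmethod
    def from_items(cls, items) -> "ParamSpec":
        names, shapes = zip(*items) if items else ((), ())
        return cls(tuple(names), tuple(tuple(s) for s in shapes))

    @property
    def sizes(self) -> tuple[int, ...]:
        return tuple(int(np.prod(s)) if s else 1 for s in self.shapes)

    @property
    def n_params(self) -> int:
        return sum(self.sizes)

    def unflatten(self, flat):
        """Flat vector -> dict of named (autograd-traceable) views."""
        out, offset = {}, 0
        for name, shape, size in zip(self.names, self.shapes, self.sizes):
            chunk = flat[offset : offset + size]
            out[name] = anp.reshape(chunk, shape) if shape else chunk[0]
            offset += size
        return out

    def flatten(self, named) -> np.ndarray:
        return np.concatenate([np.ravel(np.asarray(named[n], dtype=np.float64)) for n in self.names])


class Adam:
    """Adam on a flat vector; state is explicit so runs are reproducible."""

    def __init__(self, lr: float, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = self.v = None
        self.t = 0

    def step(self, params: np.ndarray, grad: np.ndarray) -> np.ndarray:
        if self.m is None:
            self.m = np.zeros_like(params)
            self.v = np.zeros_like(params)
        self.t += 1
        self.m = self.beta1 * self.m + (1 - self.beta1) * grad
        self.v = self.beta2 * self.v + (1 - self.beta2) * grad**2
        mhat = self.m / (1 - self.beta1**self.t)
        vhat = self.v / (1 - self.beta2**self.t)
        return params - self.lr * mhat / (np.sqrt(vhat) + self.eps)


class SGD:
    def __init__(self, lr: float):
        self.lr = lr

    def step(self, params: np.ndarray, grad: np.ndarray) -> np.ndarray:
        return params - self.lr * grad


def glorot(rng: np.random.Generator, shape) -> np.ndarray:
    fan_in = shape[0] if len(shape) > 1 else shape[0]
    fan_out = shape[-1]
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)
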