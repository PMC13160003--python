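"""Trainable projection head mapping frozen base embeddings to the unit sphere.

The base protein embeddings (e.g. from a pretrained protein language model)
are treated as fixed features.  A small multi-layer perceptron f_theta maps
them to R^D and the output is l2-normalized, so similarity in the learned
space is the inner product of unit vectors (cosine).

Implemented directly in NumPy: forward, reverse-mode gradients, and an Adam
optimizer.  Gradients are exercised against central finite differences in the
test suite.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

_ACTIVATIONS = ("tanh", "relu", "identity")


@dataclass
class ProjectionConfig:
    """Architecture of the projection head.

    ``hidden`` defaults to two layers of ``max(output_dim, input_dim // 2)``
    units with a smooth (tanh) nonlinearity; all of it is configurable.
    """

    input_dim: int
    output_dim: int = 128
    hidden: tuple[int, ...] | None = None
    activation: str = "tanh"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.input_dim < 1:
            raise ValueError(f"input_dim must be >= 1, got {self.input_dim}")
        if self.output_dim < 2:
            raise ValueError(f"output_dim must be >= 2, got {self.output_dim}")
        if self.hidden is None:
            h = max(self.output_dim, self.input_dim // 2)
            self.hidden = (h, h)
        self.hidden = tuple(int(h) for h in self.hidden)
        if any(h < 1 for h in self.hidden):
            raise ValueError(f"hidden sizes must be >= 1, got {self.hidden}")
        if self.activation not in _ACTIVATIONS:
            raise ValueError(f"activation must be one of {_ACTIVATIONS}")

    @property
    def layer_dims(self) -> list[tuple[int, int]]:
        dims = [self.input_dim, *self.hidden, self.output_dim]
        return list(zip(dims[:-1], dims[1:]))


class DegenerateEmbeddingError(ValueError):
    """Raised when a pre-normalization output is (numerically) zero."""


def _act(name: str, x: np.ndarray) -> np.ndarray:
    if name == "tanh":
        return np.tanh(x)
    if name == "relu":
        return np.maximum(x, 0.0)
    return x


def _act_grad(name: str, x: np.ndarray, a: np.ndarray) -> np.ndarray:
    # a = activation(x), reused where cheaper
    if name == "tanh":
        return 1.0 - a * a
    if name == "relu":
        return (x > 0).astype(x.dtype)
    return np.ones_like(x)


@dataclass
class Projector:
    """MLP parameters plus forward / backward passes."""

    config: ProjectionConfig
    weights: list[np.ndarray] = field(default_factory=list)
    biases: list[np.ndarray] = field(default_factory=list)

    def n_params(self) -> int:
        return sum(w.size for w in self.weights) + sum(b.size for b in self.biases)

    # -- forward ---------------------------------------------------------

    def forward_raw(self, x: np.ndarray, cache: list | None = None) -> np.ndarray:
        """Affine/activation stack without the final normalization.

        ``cache``, if supplied, collects intermediates for :meth:`backward`.
        """
        x = np.atleast_2d(np.asarray(x, dtype=np.float64))
        if x.shape[1] != self.config.input_dim:
            raise ValueError(
                f"input dim {x.shape[1]} != configured {self.config.input_dim}")
        h = x
        n_layers = len(self.weights)
        for i, (w, b) in enumerate(zip(self.weights, self.biases)):
            pre = h @ w + b
            if i < n_layers - 1:
                a = _act(self.config.activation, pre)
            else:
                a = pre  # linear output layer
            if cache is not None:
                cache.append((h, pre, a))
            h = a
        return h

    def project(self, x: np.ndarray) -> np.ndarray:
        """Map base embeddings to unit vectors in R^D (rows are proteins)."""
        single = np.asarray(x).ndim == 1
        u = self.forward_raw(x)
        norms = np.linalg.norm(u, axis=1, keepdims=True)
        if np.any(norms < 1e-12):
            raise DegenerateEmbeddingError(
                "projection produced a zero vector; cannot l2-normalize")
        z = u / norms
        return z[0] if single else z

    def project_with_cache(self, x: np.ndarray) -> tuple[np.ndarray, dict]:
        cache: list = []
        u = self.forward_raw(x, cache=cache)
        norms = np.linalg.norm(u, axis=1, keepdims=True)
        if np.any(norms < 1e-12):
            raise DegenerateEmbeddingError(
                "projection produced a zero vector; cannot l2-normalize")
        z = u / norms
        return z, {"layers": cache, "u": u, "norms": norms, "z": z}

    # -- backward --------------------------------------------------------

    def backward(self, cache: dict, dz: np.ndarray) -> tuple[list[np.ndarray], list[np.ndarray]]:
        """Gradients of a scalar loss w.r.t. weights and biases.

        ``dz`` is dL/dz for the normalized outputs ``z`` from
        :meth:`project_with_cache`.  Normalization backprop:
        du = (dz - (dz . z) z) / ||u||.
        """
        z, norms = cache["z"], cache["norms"]
        dz = np.asarray(dz, dtype=np.float64)
        du = (dz - np.sum(dz * z, axis=1, keepdims=True) * z) / norms
        dws = [np.zeros_like(w) for w in self.weights]
        dbs = [np.zeros_like(b) for b in self.biases]
        grad = du
        n_layers = len(self.weights)
        for i in range(n_layers - 1, -1, -1):
            h, pre, a = cache["layers"][i]
            if i < n_layers - 1:
                grad = grad * _act_grad(self.config.activation, pre, a)
            dws[i] = h.T @ grad
            dbs[i] = np.sum(grad, axis=0)
            grad = grad @ self.weights[i].T
        return dws, dbs

    # -- persistence -----------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Write a single self-describing JSON file (config + parameters)."""
        payload = {
            "config": {
                "input_dim": self.config.input_dim,
                "output_dim": self.config.output_dim,
                "hidden": list(self.config.hidden),
                "activation": self.config.activation,
                "seed": self.config.seed,
            },
            "weights": [w.tolist() for w in self.weights],
            "biases": [b.tolist() for b in self.biases],
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path: str | Path) -> "Projector":
        payload = json.loads(Path(path).read_text())
        cfg = ProjectionConfig(
            input_dim=payload["config"]["input_dim"],
            output_dim=payload["config"]["output_dim"],
            hidden=tuple(payload["config"]["hidden"]),
            activation=payload["config"]["activation"],
            seed=payload["config"]["seed"],
        )
        proj = cls(config=cfg)
        proj.weights = [np.asarray(w, dtype=np.float64) for w in payload["weights"]]
        proj.biases = [np.asarray(b, dtype=np.float64) for b in payload["biases"]]
        return proj


def init_projector(config: ProjectionConfig) -> Projector:
    """Seeded Glorot-uniform initialization; same config + seed => identical parameters."""
    rng = np.random.default_rng(config.seed)
    proj = Projector(config=config)
    for fan_in, fan_out in config.layer_dims:
        limit = np.sqrt(6.0 / (fan_in + fan_out))
        proj.weights.append(rng.uniform(-limit, limit, size=(fan_in, fan_out)))
        proj.biases.append(np.zeros(fan_out))
    return proj


class Adam:
    """Adam optimizer over a projector's parameter list."""

    def __init__(self, projector: Projector, lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.projector = projector
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        params = projector.weights + projector.biases
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]

    def step(self, dws: Sequence[np.ndarray], dbs: Sequence[np.ndarray]) -> None:
        self.t += 1
        params = self.projector.weights + self.projector.biases
        grads = list(dws) + list(dbs)
        bc1 = 1.0 - self.beta1 ** self.t
        bc2 = 1.0 - self.beta2 ** self.t
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m *= self.beta1
            m += (1 - self.beta1) * g
            v *= self.beta2
            v += (1 - self.beta2) * g * g
            p -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
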