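"""Small fully-connected autoencoders trained with Adagrad, in NumPy.

The embedding model needs only modest multilayer perceptrons (20-marker
input, tens of hidden units), so the forward/backward passes are written
directly against BLAS-backed matrix products: Glorot-uniform
initialisation, ReLU hidden activations, linear bottleneck and output,
and the Adagrad update rule with a per-parameter accumulated squared
gradient.  Everything is float32 and seeded, so a training run is exactly
reproducible.
"""

from __future__ import annotations

import numpy as np

DTYPE = np.float32


def glorot_uniform(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out)).astype(DTYPE)


class Adagrad:
    """Adagrad with per-parameter accumulators (initial accumulator 0)."""

    def __init__(self, params: list[np.ndarray], learning_rate: float = 0.1,
                 eps: float = 1e-8):
        self.params = params
        self.lr = float(learning_rate)
        self.eps = eps
        self.accum = [np.zeros_like(p) for p in params]

    def step(self, grads: list[np.ndarray]) -> None:
        for p, g, a in zip(self.params, grads, self.accum):
            a += g * g
            p -= self.lr * g / (np.sqrt(a) + self.eps)


class Autoencoder:
    """Symmetric MLP autoencoder: input -> hidden... -> latent -> ...hidden -> input.

    Hidden layers use ReLU; the bottleneck and the reconstruction output
    are linear.  ``forward`` caches activations so ``backward`` can inject
    a gradient both at the output (reconstruction loss) and directly at
    the bottleneck code (clustering loss).
    """

    def __init__(self, n_inputs: int, hidden_layers: tuple[int, ...],
                 latent_dim: int, seed: int):
        rng = np.random.default_rng(seed)
        dims = [n_inputs, *hidden_layers, latent_dim, *reversed(hidden_layers), n_inputs]
        self.dims = dims
        self.latent_index = len(hidden_layers) + 1  # activation index of the code
        self.W = [glorot_uniform(rng, dims[i], dims[i + 1]) for i in range(len(dims) - 1)]
        self.b = [np.zeros(dims[i + 1], dtype=DTYPE) for i in range(len(dims) - 1)]
        # ReLU on every layer except bottleneck and final output
        self.relu = [
            i != self.latent_index - 1 and i != len(dims) - 2
            for i in range(len(dims) - 1)
        ]

    @property
    def params(self) -> list[np.ndarray]:
        return [*self.W, *self.b]

    def forward(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray, list[np.ndarray]]:
        """Return (latent, reconstruction, activation cache)."""
        a = np.ascontiguousarray(x, dtype=DTYPE)
        cache = [a]
        for i, (W, b) in enumerate(zip(self.W, self.b)):
            a = a @ W + b
            if self.relu[i]:
                np.maximum(a, 0.0, out=a)
            cache.append(a)
        return cache[self.latent_index], cache[-1], cache

    def encode(self, x: np.ndarray, batch: int = 65536) -> np.ndarray:
        out = []
        for start in range(0, len(x), batch):
            a = np.ascontiguousarray(x[start : start + batch], dtype=DTYPE)
            for i in range(self.latent_index):
                a = a @ self.W[i] + self.b[i]
                if self.relu[i]:
                    np.maximum(a, 0.0, out=a)
            out.append(a)
        return np.concatenate(out, axis=0)

    def backward(self, cache: list[np.ndarray], d_recon: np.ndarray,
                 d_latent: np.ndarray | None = None) -> list[np.ndarray]:
        """Backprop; gradients ordered like :attr:`params`."""
        gW: list[np.ndarray | None] = [None] * len(self.W)
        gb: list[np.ndarray | None] = [None] * len(self.b)
        delta = np.ascontiguousarray(d_recon, dtype=DTYPE)
        for i in range(len(self.W) - 1, -1, -1):
            if self.relu[i]:
                delta = delta * (cache[i + 1] > 0)
            gW[i] = cache[i].T @ delta
            gb[i] = delta.sum(axis=0)
            if i > 0:
                delta = delta @ self.W[i].T
                if i == self.latent_index and d_latent is not None:
                    # inject clustering-loss gradient at the bottleneck code
                    delta = delta + d_latent.astype(DTYPE)
        return [*gW, *gb]
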