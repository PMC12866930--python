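"""Small neural-network building blocks on top of :mod:`scdropgan.tensor`.

Linear layers, multilayer perceptrons and an Adam optimizer — enough for
the encoder/decoder of the variational generator and the embedder/heads of
the multi-task discriminator.
"""

from __future__ import annotations

import numpy as np

from .tensor import Tensor

__all__ = ["Linear", "MLP", "Adam"]

_ACTS = {
    "relu": lambda t: t.relu(),
    "tanh": lambda t: t.tanh(),
    "sigmoid": lambda t: t.sigmoid(),
    "softplus": lambda t: t.softplus(),
    "identity": lambda t: t,
}


class Linear:
    """Affine layer y = x W + b with He-style initialization."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 zero_init: bool = False):
        if zero_init:
            w = np.zeros((n_in, n_out))
        else:
            w = rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_in, n_out))
        self.W = Tensor(w, requires_grad=True)
        self.b = Tensor(np.zeros(n_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.W + self.b

    def parameters(self) -> list[Tensor]:
        return [self.W, self.b]


class MLP:
    """Stack of Linear layers with a common hidden activation.

    ``out_activation`` applies after the last layer ('identity' by default);
    ``zero_init_last`` zero-initializes the final layer so the network starts
    as the constant-zero map (used for the encoder's log-variance head).
    """

    def __init__(self, dims: list[int], rng: np.random.Generator,
                 activation: str = "relu", out_activation: str = "identity",
                 zero_init_last: bool = False):
        self.layers = []
        for i, (a, b) in enumerate(zip(dims[:-1], dims[1:])):
            last = i == len(dims) - 2
            self.layers.append(Linear(a, b, rng, zero_init=zero_init_last and last))
        self.act = _ACTS[activation]
        self.out_act = _ACTS[out_activation]

    def __call__(self, x) -> Tensor:
        if not isinstance(x, Tensor):
            x = Tensor(np.asarray(x, dtype=np.float64))
        for layer in self.layers[:-1]:
            x = self.act(layer(x))
        return self.out_act(self.layers[-1](x))

    def parameters(self) -> list[Tensor]:
        return [p for layer in self.layers for p in layer.parameters()]


class Adam:
    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
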