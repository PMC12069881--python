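"""Minimal dense networks with manual backprop and Adam, in numpy.

Small fully connected networks (two hidden layers by default) are all
the actor/critic pair needs at this problem scale; forward passes cache
activations, ``backward`` accumulates parameter gradients and returns
the gradient with respect to the input (needed to differentiate the
critic with respect to the action).
"""

from __future__ import annotations

import numpy as np


class MLP:
    """ReLU hidden layers, linear output, optional tanh head."""

    def __init__(self, sizes: list[int], tanh_head: bool = False,
                 rng: np.random.Generator | None = None):
        rng = rng if rng is not None else np.random.default_rng(0)
        self.sizes = list(sizes)
        self.tanh_head = tanh_head
        self.W = []
        self.b = []
        for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
            # He initialization for the ReLU stack
            self.W.append(rng.normal(0, np.sqrt(2.0 / fan_in), (fan_in, fan_out)))
            self.b.append(np.zeros(fan_out))
        self.zero_grad()

    # -- parameter plumbing -------------------------------------------------

    def parameters(self) -> list[np.ndarray]:
        return self.W + self.b

    def gradients(self) -> list[np.ndarray]:
        return self.gW + self.gb

    def zero_grad(self) -> None:
        self.gW = [np.zeros_like(w) for w in self.W]
        self.gb = [np.zeros_like(b) for b in self.b]

    def copy_from(self, other: "MLP") -> None:
        for p, q in zip(self.parameters(), other.parameters()):
            p[...] = q

    def clone(self) -> "MLP":
        m = MLP(self.sizes, self.tanh_head)
        m.copy_from(self)
        return m

    # -- forward / backward -------------------------------------------------

    def forward(self, x: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(np.asarray(x, dtype=float))
        self._acts = [x]
        h = x
        last = len(self.W) - 1
        for i, (w, b) in enumerate(zip(self.W, self.b)):
            z = h @ w + b
            if i < last:
                z = np.maximum(z, 0.0)
            elif self.tanh_head:
                z = np.tanh(z)
            self._acts.append(z)
            h = z
        return h

    __call__ = forward

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        """Backprop ``grad_out`` (∂L/∂output); accumulates parameter grads
        and returns ∂L/∂input."""
        g = np.atleast_2d(np.asarray(grad_out, dtype=float))
        last = len(self.W) - 1
        for i in range(last, -1, -1):
            out = self._acts[i + 1]
            if i == last:
                if self.tanh_head:
                    g = g * (1.0 - out * out)
            else:
                g = g * (out > 0)
            a_in = self._acts[i]
            self.gW[i] += a_in.T @ g
            self.gb[i] += g.sum(axis=0)
            g = g @ self.W[i].T
        return g


class Adam:
    """Adam over one or more MLPs."""

    def __init__(self, nets: list[MLP], lr: float = 3e-4,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.nets = nets
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        params = [p for n in nets for p in n.parameters()]
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]

    def step(self) -> None:
        self.t += 1
        params = [p for n in self.nets for p in n.parameters()]
        grads = [g for n in self.nets for g in n.gradients()]
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m[...] = self.b1 * m + (1 - self.b1) * g
            v[...] = self.b2 * v + (1 - self.b2) * g * g
            mhat = m / (1 - self.b1 ** self.t)
            vhat = v / (1 - self.b2 ** self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
        for n in self.nets:
            n.zero_grad()
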