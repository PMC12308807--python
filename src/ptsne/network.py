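"""Minimal feedforward network with reverse-mode gradients, in NumPy.

The embedder is deliberately small — a stack of dense layers with an
elementwise nonlinearity and a linear output — so forward evaluation,
backpropagation and the Adam update are implemented directly.  Keeping the
whole computation in NumPy makes training bitwise-reproducible under a
fixed seed on a given platform.
"""

from __future__ import annotations

import numpy as np

__all__ = ["MLP", "Adam", "ACTIVATIONS"]


def _relu(x):
    return np.maximum(x, 0.0)


def _relu_grad(x, _y):
    return (x > 0.0).astype(x.dtype)


def _tanh(x):
    return np.tanh(x)


def _tanh_grad(_x, y):
    return 1.0 - y**2


def _identity(x):
    return x


def _identity_grad(x, _y):
    return np.ones_like(x)


ACTIVATIONS = {
    "relu": (_relu, _relu_grad),
    "tanh": (_tanh, _tanh_grad),
    "identity": (_identity, _identity_grad),
}


class MLP:
    """Dense feedforward map ``R^m -> R^d`` with hidden nonlinearities.

    Parameters
    ----------
    layer_dims : sequence of int
        ``[input_dim, hidden..., output_dim]``.
    activation : str
        Hidden-layer nonlinearity; the output layer is always linear.
    rng : numpy.random.Generator
        Source of the weight initialization (He-style scaling for the
        rectifier, Glorot for tanh).
    """

    def __init__(self, layer_dims, activation: str, rng: np.random.Generator):
        if activation not in ACTIVATIONS:
            raise ValueError(
                f"unknown activation {activation!r}; choose from {sorted(ACTIVATIONS)}"
            )
        self.layer_dims = [int(d) for d in layer_dims]
        if len(self.layer_dims) < 2 or min(self.layer_dims) < 1:
            raise ValueError(f"invalid layer dims {layer_dims}")
        self.activation = activation
        self.weights: list[np.ndarray] = []
        self.biases: list[np.ndarray] = []
        gain = 2.0 if activation == "relu" else 1.0
        for fan_in, fan_out in zip(self.layer_dims[:-1], self.layer_dims[1:]):
            scale = np.sqrt(gain / fan_in)
            self.weights.append(rng.normal(0.0, scale, size=(fan_in, fan_out)))
            self.biases.append(np.zeros(fan_out))
        self._cache: list[tuple[np.ndarray, np.ndarray]] | None = None

    @property
    def n_layers(self) -> int:
        return len(self.weights)

    def forward(self, X: np.ndarray, cache: bool = False) -> np.ndarray:
        act, _ = ACTIVATIONS[self.activation]
        h = X
        saved = []
        for k, (W, b) in enumerate(zip(self.weights, self.biases)):
            pre = h @ W + b
            out = pre if k == self.n_layers - 1 else act(pre)
            if cache:
                saved.append((h, pre))
            h = out
        if cache:
            self._cache = saved
        return h

    def backward(self, grad_out: np.ndarray) -> list[tuple[np.ndarray, np.ndarray]]:
        """Gradients of the loss w.r.t. every (W, b), from d(loss)/d(output).

        Requires a preceding ``forward(..., cache=True)`` on the same batch.
        """
        if self._cache is None:
            raise RuntimeError("backward() requires forward(cache=True) first")
        _, act_grad = ACTIVATIONS[self.activation]
        grads: list[tuple[np.ndarray, np.ndarray]] = [None] * self.n_layers
        delta = grad_out
        for k in range(self.n_layers - 1, -1, -1):
            h_in, pre = self._cache[k]
            if k != self.n_layers - 1:
                act, _ = ACTIVATIONS[self.activation]
                delta = delta * act_grad(pre, act(pre))
            grads[k] = (h_in.T @ delta, delta.sum(axis=0))
            if k > 0:
                delta = delta @ self.weights[k].T
        self._cache = None
        return grads

    # --- (de)serialization -------------------------------------------------
    def state(self) -> dict:
        out = {"layer_dims": np.asarray(self.layer_dims)}
        for k, (W, b) in enumerate(zip(self.weights, self.biases)):
            out[f"W{k}"] = W
            out[f"b{k}"] = b
        return out

    @classmethod
    def from_state(cls, state: dict, activation: str) -> "MLP":
        dims = [int(d) for d in state["layer_dims"]]
        net = cls(dims, activation, np.random.default_rng(0))
        for k in range(net.n_layers):
            W, b = np.asarray(state[f"W{k}"]), np.asarray(state[f"b{k}"])
            if W.shape != net.weights[k].shape:
                raise ValueError(
                    f"layer {k} weight shape {W.shape} does not match expected "
                    f"{net.weights[k].shape}"
                )
            net.weights[k] = W
            net.biases[k] = b
        return net


class Adam:
    """Adam optimizer with the standard defaults (b1=0.9, b2=0.999, eps=1e-8)."""

    def __init__(self, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self._m: list[np.ndarray] | None = None
        self._v: list[np.ndarray] | None = None

    def step(self, net: MLP, grads: list[tuple[np.ndarray, np.ndarray]]) -> None:
        flat_params = []
        flat_grads = []
        for k in range(net.n_layers):
            flat_params += [net.weights[k], net.biases[k]]
            flat_grads += [grads[k][0], grads[k][1]]
        if self._m is None:
            self._m = [np.zeros_like(p) for p in flat_params]
            self._v = [np.zeros_like(p) for p in flat_params]
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, g, m, v in zip(flat_params, flat_grads, self._m, self._v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g**2
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
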