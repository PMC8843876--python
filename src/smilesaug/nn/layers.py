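"""Trainable layers: dense, 1-D convolution, GRU and LSTM recurrences.

Weight matrices use Glorot-uniform initialization; biases start at zero
(the LSTM forget gate at one, the usual stabilizing choice). Recurrent
layers expose a per-timestep ``step`` so stacked architectures can run
all layers inside one loop over the sequence.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, conv1d


def _glorot(rng: np.random.Generator, shape: tuple[int, ...]) -> Tensor:
    fan_in, fan_out = shape[-2], shape[-1]
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return Tensor(rng.uniform(-limit, limit, size=shape), requires_grad=True)


class Dense:
    """Affine map ``x @ W + b`` with optional activation handled by the caller."""

    def __init__(self, rng: np.random.Generator, n_in: int, n_out: int):
        self.weight = _glorot(rng, (n_in, n_out))
        self.bias = Tensor(np.zeros(n_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias

    def parameters(self) -> list[Tensor]:
        return [self.weight, self.bias]


class Conv1D:
    """1-D convolution over the sequence axis with ReLU left to the caller."""

    def __init__(
        self,
        rng: np.random.Generator,
        n_in: int,
        n_out: int,
        kernel: int,
        padding: str = "same",
    ):
        fan = kernel * n_in
        limit = np.sqrt(6.0 / (fan + n_out))
        self.weight = Tensor(
            rng.uniform(-limit, limit, size=(kernel, n_in, n_out)), requires_grad=True
        )
        self.bias = Tensor(np.zeros(n_out), requires_grad=True)
        self.padding = padding

    def __call__(self, x: Tensor) -> Tensor:
        return conv1d(x, self.weight, self.bias, self.padding)

    def parameters(self) -> list[Tensor]:
        return [self.weight, self.bias]


class GRULayer:
    """Gated recurrent unit.

    Gate order in the fused input projection is (update z, reset r,
    candidate h). The hidden update is
    ``h_t = z * h_{t-1} + (1 - z) * tanh(W_h x_t + U_h (r * h_{t-1}))``.
    """

    n_gates = 3

    def __init__(self, rng: np.random.Generator, n_in: int, n_hidden: int):
        self.n_hidden = n_hidden
        self.w_in = _glorot(rng, (n_in, 3 * n_hidden))
        self.w_rec = _glorot(rng, (n_hidden, 3 * n_hidden))
        self.bias = Tensor(np.zeros(3 * n_hidden), requires_grad=True)

    def initial_state(self, n_batch: int) -> Tensor:
        return Tensor(np.zeros((n_batch, self.n_hidden)))

    def project_inputs(self, x: Tensor) -> Tensor:
        """Fused input projection for all timesteps: (N, T, 3H)."""
        n, t, c = x.data.shape
        return (x.reshape(n * t, c) @ self.w_in + self.bias).reshape(n, t, 3 * self.n_hidden)

    def step(self, xp_t: Tensor, state: Tensor) -> tuple[Tensor, Tensor]:
        h = self.n_hidden
        rec = state @ self.w_rec
        z = (xp_t[:, 0:h] + rec[:, 0:h]).sigmoid()
        r = (xp_t[:, h : 2 * h] + rec[:, h : 2 * h]).sigmoid()
        candidate = (xp_t[:, 2 * h : 3 * h] + (r * state) @ self.w_rec[:, 2 * h : 3 * h]).tanh()
        new_state = z * state + (1.0 - z) * candidate
        return new_state, new_state

    def parameters(self) -> list[Tensor]:
        return [self.w_in, self.w_rec, self.bias]


class LSTMLayer:
    """Long short-term memory unit with forget-gate bias initialized to 1.

    Gate order is (input i, forget f, cell g, output o);
    ``c_t = f * c_{t-1} + i * g`` and ``h_t = o * tanh(c_t)``.
    """

    n_gates = 4

    def __init__(self, rng: np.random.Generator, n_in: int, n_hidden: int):
        self.n_hidden = n_hidden
        self.w_in = _glorot(rng, (n_in, 4 * n_hidden))
        self.w_rec = _glorot(rng, (n_hidden, 4 * n_hidden))
        bias = np.zeros(4 * n_hidden)
        bias[n_hidden : 2 * n_hidden] = 1.0
        self.bias = Tensor(bias, requires_grad=True)

    def initial_state(self, n_batch: int) -> tuple[Tensor, Tensor]:
        zero = np.zeros((n_batch, self.n_hidden))
        return (Tensor(zero), Tensor(zero.copy()))

    def project_inputs(self, x: Tensor) -> Tensor:
        n, t, c = x.data.shape
        return (x.reshape(n * t, c) @ self.w_in + self.bias).reshape(n, t, 4 * self.n_hidden)

    def step(self, xp_t: Tensor, state: tuple[Tensor, Tensor]) -> tuple[Tensor, tuple[Tensor, Tensor]]:
        h_prev, c_prev = state
        n = self.n_hidden
        gates = xp_t + h_prev @ self.w_rec
        i = gates[:, 0:n].sigmoid()
        f = gates[:, n : 2 * n].sigmoid()
        g = gates[:, 2 * n : 3 * n].tanh()
        o = gates[:, 3 * n : 4 * n].sigmoid()
        c = f * c_prev + i * g
        h = o * c.tanh()
        return h, (h, c)

    def parameters(self) -> list[Tensor]:
        return [self.w_in, self.w_rec, self.bias]
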