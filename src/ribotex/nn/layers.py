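"""Layer blueprints for the recurrent/convolutional classifiers.

Each layer owns its parameter tensors (lazily built on first call, once
the input width is known) and maps a :class:`~ribotex.nn.autograd.Tensor`
to another.  Recurrent layers consume (batch, time, channels) input and
return either the final hidden state or the full hidden sequence.
"""

from __future__ import annotations

import numpy as np

from . import autograd as ag
from .autograd import Tensor


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int, shape) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Layer:
    """Base: subclasses implement ``build`` and ``forward``."""

    def __init__(self) -> None:
        self.params: list[Tensor] = []
        self.built = False

    def build(self, input_shape: tuple, rng: np.random.Generator) -> None:  # pragma: no cover
        pass

    def __call__(self, x: Tensor, *, train: bool = False,
                 rng: np.random.Generator | None = None) -> Tensor:
        if not self.built:
            if rng is None:
                raise ValueError("layer must be built with an rng on first call")
            self.build(x.shape, rng)
            self.built = True
        return self.forward(x, train=train, rng=rng)

    def forward(self, x, *, train, rng):  # pragma: no cover
        raise NotImplementedError


class Dense(Layer):
    def __init__(self, units: int, activation: str | None = None):
        super().__init__()
        self.units = units
        self.activation = activation

    def build(self, input_shape, rng):
        c = input_shape[-1]
        self.W = Tensor(_glorot(rng, c, self.units, (c, self.units)))
        self.b = Tensor(np.zeros(self.units))
        self.params = [self.W, self.b]

    def forward(self, x, *, train, rng):
        out = ag.add(ag.matmul(x, self.W), self.b)
        if self.activation == "relu":
            out = ag.relu(out)
        elif self.activation == "tanh":
            out = ag.tanh(out)
        elif self.activation is not None:
            raise ValueError(f"unknown activation {self.activation!r}")
        return out


class Dropout(Layer):
    def __init__(self, rate: float = 0.2):
        super().__init__()
        self.rate = rate
        self.built = True

    def forward(self, x, *, train, rng):
        if not train or self.rate == 0.0:
            return x
        mask = (rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return ag.mul(x, Tensor(mask))


class Flatten(Layer):
    def __init__(self):
        super().__init__()
        self.built = True

    def forward(self, x, *, train, rng):
        return ag.reshape(x, (x.shape[0], -1))


class _Recurrent(Layer):
    n_gates = 1  # combined-gate width multiplier

    def __init__(self, units: int, return_sequences: bool = False):
        super().__init__()
        self.units = units
        self.return_sequences = return_sequences

    def build(self, input_shape, rng):
        c, u, gw = input_shape[-1], self.units, self.n_gates * self.units
        self.W = Tensor(_glorot(rng, c, u, (c, gw)))
        self.U = Tensor(_glorot(rng, u, u, (u, gw)))
        self.b = Tensor(np.zeros(gw))
        self.params = [self.W, self.U, self.b]

    def forward(self, x, *, train, rng):
        B, T = x.shape[0], x.shape[1]
        h = Tensor(np.zeros((B, self.units)))
        state = self.init_state(B)
        outputs = []
        # pre-projecting the whole input sequence keeps the per-step tape short
        xw = ag.matmul(ag.reshape(x, (B * T, x.shape[2])), self.W)
        xw = ag.reshape(xw, (B, T, self.n_gates * self.units))
        for t in range(T):
            pre = ag.add(ag.add(xw[:, t, :], ag.matmul(h, self.U)), self.b)
            h, state = self.step(pre, h, state)
            if self.return_sequences:
                outputs.append(h)
        return ag.stack(outputs, axis=1) if self.return_sequences else h

    def init_state(self, batch):
        return None

    def step(self, pre, h, state):  # pragma: no cover
        raise NotImplementedError


class SimpleRNN(_Recurrent):
    n_gates = 1

    def step(self, pre, h, state):
        return ag.tanh(pre), state


class GRU(_Recurrent):
    """Gated recurrent unit (reset gate applied inside the candidate).

    Note: the candidate projection here uses U on (r * h), realized by
    splitting U's columns, matching the standard formulation.
    """

    n_gates = 3

    def build(self, input_shape, rng):
        super().build(input_shape, rng)

    def forward(self, x, *, train, rng):
        # GRU needs (r*h) @ U_h, so the generic pre-projection only covers x
        B, T = x.shape[0], x.shape[1]
        u = self.units
        h = Tensor(np.zeros((B, u)))
        xw = ag.matmul(ag.reshape(x, (B * T, x.shape[2])), self.W)
        xw = ag.reshape(xw, (B, T, 3 * u))
        outputs = []
        for t in range(T):
            xt = xw[:, t, :]
            hu = ag.matmul(h, self.U[:, :2 * u])
            zr = ag.add(ag.add(xt[:, :2 * u], hu), self.b[:2 * u])
            z = ag.sigmoid(zr[:, :u])
            r = ag.sigmoid(zr[:, u:2 * u])
            cand = ag.add(ag.add(xt[:, 2 * u:],
                                 ag.matmul(ag.mul(r, h), self.U[:, 2 * u:])),
                          self.b[2 * u:])
            hh = ag.tanh(cand)
            one_minus_z = ag.sub(Tensor(np.ones((B, u))), z)
            h = ag.add(ag.mul(one_minus_z, h), ag.mul(z, hh))
            if self.return_sequences:
                outputs.append(h)
        return ag.stack(outputs, axis=1) if self.return_sequences else h


class LSTM(_Recurrent):
    n_gates = 4

    def init_state(self, batch):
        return Tensor(np.zeros((batch, self.units)))

    def step(self, pre, h, c):
        u = self.units
        i = ag.sigmoid(pre[:, :u])
        f = ag.sigmoid(pre[:, u:2 * u])
        o = ag.sigmoid(pre[:, 2 * u:3 * u])
        g = ag.tanh(pre[:, 3 * u:])
        c_new = ag.add(ag.mul(f, c), ag.mul(i, g))
        h_new = ag.mul(o, ag.tanh(c_new))
        return h_new, c_new


class Bidirectional(Layer):
    """Run a recurrent layer forward and backward in time; concat outputs."""

    def __init__(self, layer_cls, units: int, return_sequences: bool = False):
        super().__init__()
        self.fwd = layer_cls(units, return_sequences=return_sequences)
        self.bwd = layer_cls(units, return_sequences=return_sequences)
        self.return_sequences = return_sequences
        self.built = True

    @property
    def sublayers(self):
        return [self.fwd, self.bwd]

    def forward(self, x, *, train, rng):
        yf = self.fwd(x, train=train, rng=rng)
        yb = self.bwd(ag.flip(x, axis=1), train=train, rng=rng)
        if self.return_sequences:
            yb = ag.flip(yb, axis=1)
        self.params = self.fwd.params + self.bwd.params
        return ag.concat([yf, yb], axis=-1)


class Conv1D(Layer):
    def __init__(self, filters: int = 32, kernel: int = 3, activation: str = "relu"):
        super().__init__()
        self.filters = filters
        self.kernel = kernel
        self.activation = activation

    def build(self, input_shape, rng):
        c = input_shape[-1]
        fan_in = self.kernel * c
        self.W = Tensor(_glorot(rng, fan_in, self.filters,
                                (self.kernel, c, self.filters)))
        self.b = Tensor(np.zeros(self.filters))
        self.params = [self.W, self.b]

    def forward(self, x, *, train, rng):
        out = ag.conv1d(x, self.W, self.b)
        if self.activation == "relu":
            out = ag.relu(out)
        return out


class MaxPool1D(Layer):
    def __init__(self, pool: int = 2):
        super().__init__()
        self.pool = pool
        self.built = True

    def forward(self, x, *, train, rng):
        return ag.max_pool1d(x, self.pool)


def collect_params(layers) -> list[Tensor]:
    out: list[Tensor] = []
    for layer in layers:
        if isinstance(layer, Bidirectional):
            for sub in layer.sublayers:
                out.extend(sub.params)
        else:
            out.extend(layer.params)
    return out
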