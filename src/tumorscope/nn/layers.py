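"""Network building blocks: convolution, dense, LSTM and attention layers.

Weights are initialised from a truncated normal distribution (values beyond
two standard deviations are redrawn), which stabilises early adversarial
training.  Every layer takes an explicit :class:`numpy.random.Generator` so a
whole model is reproducible from one seed.
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, concat

__all__ = [
    "Module", "Linear", "Conv2d", "Conv3d", "Sequential", "LSTM",
    "AdditiveAttention", "truncated_normal",
]


def truncated_normal(rng: np.random.Generator, shape, std: float) -> np.ndarray:
    """Normal(0, std) with values beyond 2 std redrawn."""
    out = rng.normal(0.0, std, size=shape)
    bad = np.abs(out) > 2 * std
    while bad.any():
        out[bad] = rng.normal(0.0, std, size=int(bad.sum()))
        bad = np.abs(out) > 2 * std
    return out


class Module:
    """Minimal parameter container with recursive discovery."""

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        seen: set[int] = set()
        for value in vars(self).values():
            for p in _collect(value):
                if id(p) not in seen:
                    seen.add(id(p))
                    params.append(p)
        return params

    def n_parameters(self) -> int:
        return sum(p.size for p in self.parameters())

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> dict[str, np.ndarray]:
        return {str(i): p.data.copy() for i, p in enumerate(self.parameters())}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = self.parameters()
        if len(state) != len(params):
            raise ValueError(
                f"state has {len(state)} arrays, model has {len(params)}")
        for i, p in enumerate(params):
            arr = np.asarray(state[str(i)], dtype=np.float64)
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for parameter {i}")
            p.data = arr.copy()

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def _collect(value) -> list[Tensor]:
    if isinstance(value, Tensor) and value.requires_grad:
        return [value]
    if isinstance(value, Module):
        return value.parameters()
    if isinstance(value, (list, tuple)):
        out = []
        for v in value:
            out.extend(_collect(v))
        return out
    return []


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        std = np.sqrt(2.0 / n_in)
        self.weight = Tensor(truncated_normal(rng, (n_in, n_out), std),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(n_out), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class Conv2d(Module):
    def __init__(self, c_in: int, c_out: int, kernel: int,
                 rng: np.random.Generator, dilation: int = 1,
                 padding: str = "same"):
        std = np.sqrt(2.0 / (c_in * kernel * kernel))
        self.weight = Tensor(
            truncated_normal(rng, (c_out, c_in, kernel, kernel), std),
            requires_grad=True)
        self.bias = Tensor(np.zeros(c_out), requires_grad=True)
        self.dilation = dilation
        self.padding = padding

    def forward(self, x: Tensor) -> Tensor:
        return x.conv2d(self.weight, self.bias, dilation=self.dilation,
                        padding=self.padding)


class Conv3d(Module):
    def __init__(self, c_in: int, c_out: int, kernel: int,
                 rng: np.random.Generator, dilation: int = 1,
                 padding: str = "same"):
        std = np.sqrt(2.0 / (c_in * kernel**3))
        self.weight = Tensor(
            truncated_normal(rng, (c_out, c_in, kernel, kernel, kernel), std),
            requires_grad=True)
        self.bias = Tensor(np.zeros(c_out), requires_grad=True)
        self.dilation = dilation
        self.padding = padding

    def forward(self, x: Tensor) -> Tensor:
        return x.conv3d(self.weight, self.bias, dilation=self.dilation,
                        padding=self.padding)


class Sequential(Module):
    def __init__(self, *layers):
        self.layers = list(layers)

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x) if isinstance(layer, Module) else layer(x)
        return x


class LSTM(Module):
    """Stacked LSTM over a (T, d) sequence, returning all hidden states.

    Dropout (inverted, applied between stacked layers during training only)
    follows the usual recurrent-regularisation recipe.
    """

    def __init__(self, n_in: int, n_hidden: int, rng: np.random.Generator,
                 n_layers: int = 1, dropout: float = 0.0):
        self.n_hidden = n_hidden
        self.n_layers = n_layers
        self.dropout = dropout
        self.cells = []
        for layer in range(n_layers):
            d = n_in if layer == 0 else n_hidden
            std = 1.0 / np.sqrt(d + n_hidden)
            w_x = Tensor(truncated_normal(rng, (d, 4 * n_hidden), std),
                         requires_grad=True)
            w_h = Tensor(truncated_normal(rng, (n_hidden, 4 * n_hidden), std),
                         requires_grad=True)
            b = np.zeros(4 * n_hidden)
            b[n_hidden:2 * n_hidden] = 1.0  # forget-gate bias
            self.cells.append((w_x, w_h, Tensor(b, requires_grad=True)))

    def forward(self, seq: Tensor, rng: np.random.Generator | None = None,
                training: bool = False) -> Tensor:
        """seq: (T, d) -> hidden states (T, n_hidden) of the top layer."""
        T = seq.shape[0]
        nh = self.n_hidden
        states = [seq[t].reshape(1, -1) for t in range(T)]
        for layer, (w_x, w_h, b) in enumerate(self.cells):
            h = Tensor(np.zeros((1, nh)))
            c = Tensor(np.zeros((1, nh)))
            outputs = []
            for t in range(T):
                gates = states[t] @ w_x + h @ w_h + b
                i = gates[:, 0:nh].sigmoid()
                f = gates[:, nh:2 * nh].sigmoid()
                g = gates[:, 2 * nh:3 * nh].tanh()
                o = gates[:, 3 * nh:4 * nh].sigmoid()
                c = f * c + i * g
                h = o * c.tanh()
                outputs.append(h)
            states = outputs
            if (training and self.dropout > 0.0 and rng is not None
                    and layer < self.n_layers - 1):
                keep = 1.0 - self.dropout
                states = [
                    s * Tensor(rng.binomial(1, keep, size=(1, nh)) / keep)
                    for s in states
                ]
        return concat([s for s in states], axis=0)


class AdditiveAttention(Module):
    """Additive (Bahdanau-style) attention over a stack of hidden states."""

    def __init__(self, n_hidden: int, n_att: int, rng: np.random.Generator):
        self.proj = Linear(n_hidden, n_att, rng)
        self.score = Linear(n_att, 1, rng)

    def forward(self, hidden: Tensor) -> tuple[Tensor, Tensor]:
        """hidden: (T, n_hidden) -> (context (n_hidden,), weights (T,))."""
        e = self.score(self.proj(hidden).tanh()).reshape(-1)  # (T,)
        e_shift = e - float(e.data.max())  # numeric stability, constant shift
        w = e_shift.exp()
        w = w / w.sum()
        context = (w.reshape(-1, 1) * hidden).sum(axis=0)
        return context, w
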