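"""Layer building blocks on top of the autodiff engine."""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, concat, conv2d, global_avg_pool, maxpool2d, relu, sigmoid, tanh

__all__ = ["Module", "Conv2D", "Dense", "GRU", "MaxPool2D"]


class Module:
    """Base class with recursive parameter discovery and (de)serialization."""

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        seen: set[int] = set()
        def is_param(v):
            # leaf tensors only: computed tensors cached on a module
            # (e.g. feature maps kept for CAM) are not parameters
            return isinstance(v, Tensor) and v.requires_grad and not v._parents

        for value in self.__dict__.values():
            found: list[Tensor] = []
            if is_param(value):
                found = [value]
            elif isinstance(value, Module):
                found = value.parameters()
            elif isinstance(value, (list, tuple)):
                for v in value:
                    if isinstance(v, Module):
                        found.extend(v.parameters())
                    elif is_param(v):
                        found.append(v)
            for p in found:
                if id(p) not in seen:
                    seen.add(id(p))
                    params.append(p)
        return params

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def _norm_layers(self) -> list["Module"]:
        found, seen = [], set()
        stack = [self]
        while stack:
            mod = stack.pop()
            if id(mod) in seen:
                continue
            seen.add(id(mod))
            if hasattr(mod, "running_mean"):
                found.append(mod)
            for value in mod.__dict__.values():
                if isinstance(value, Module):
                    stack.append(value)
                elif isinstance(value, (list, tuple)):
                    stack.extend(v for v in value if isinstance(v, Module))
        return found

    def get_state(self) -> list[np.ndarray]:
        state = [p.data.copy() for p in self.parameters()]
        for bn in self._norm_layers():
            state += [bn.running_mean.copy(), bn.running_var.copy()]
        return state

    def set_state(self, state: list[np.ndarray]) -> None:
        params = self.parameters()
        norms = self._norm_layers()
        if len(state) != len(params) + 2 * len(norms):
            raise ValueError("state does not match parameter list")
        for p, s in zip(params, state):
            if p.data.shape != s.shape:
                raise ValueError("parameter shape mismatch in checkpoint")
            p.data = s.astype(np.float32).copy()
        for i, bn in enumerate(norms):
            bn.running_mean = state[len(params) + 2 * i].astype(np.float32).copy()
            bn.running_var = state[len(params) + 2 * i + 1].astype(np.float32).copy()

    def set_training(self, flag: bool) -> None:
        """Recursively switch batch-norm layers between batch and running
        statistics."""
        for value in self.__dict__.values():
            if isinstance(value, Module):
                value.set_training(flag)
            elif isinstance(value, (list, tuple)):
                for v in value:
                    if isinstance(v, Module):
                        v.set_training(flag)
        if hasattr(self, "training"):
            self.training = flag

    def save(self, path) -> None:
        np.savez(path, *self.get_state())

    def load(self, path) -> None:
        with np.load(path) as f:
            self.set_state([f[k] for k in f.files])


def _glorot(rng: np.random.Generator, shape, fan_in, fan_out) -> Tensor:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return Tensor(rng.uniform(-limit, limit, size=shape), requires_grad=True)


class Conv2D(Module):
    def __init__(self, c_in: int, c_out: int, kernel, rng: np.random.Generator,
                 stride: int = 1, padding: str = "same",
                 activation: str | None = "relu", batch_norm: bool = False):
        kh, kw = (kernel, kernel) if isinstance(kernel, int) else kernel
        fan_in = kh * kw * c_in
        self.w = _glorot(rng, (kh, kw, c_in, c_out), fan_in, kh * kw * c_out)
        self.b = None if batch_norm else Tensor(np.zeros(c_out), requires_grad=True)
        self.bn = BatchNorm2D(c_out) if batch_norm else None
        self.stride = stride
        self.padding = padding
        self.activation = activation

    def __call__(self, x: Tensor) -> Tensor:
        y = conv2d(x, self.w, self.b, stride=self.stride, padding=self.padding)
        if self.bn is not None:
            y = self.bn(y)
        return relu(y) if self.activation == "relu" else y


class BatchNorm2D(Module):
    """Per-channel batch normalization for (B, H, W, C) tensors.

    Uses batch statistics while ``training`` is True and running
    averages otherwise.
    """

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = Tensor(np.ones(channels), requires_grad=True)
        self.beta = Tensor(np.zeros(channels), requires_grad=True)
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self.momentum = momentum
        self.eps = eps
        self.training = False

    def __call__(self, x: Tensor) -> Tensor:
        if self.training:
            mu = x.data.mean(axis=(0, 1, 2))
            var = x.data.var(axis=(0, 1, 2))
            self.running_mean = (self.momentum * self.running_mean
                                 + (1 - self.momentum) * mu)
            self.running_var = (self.momentum * self.running_var
                                + (1 - self.momentum) * var)
        else:
            mu, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x.data - mu) * inv
        out_data = xhat * self.gamma.data + self.beta.data
        gamma, beta = self.gamma, self.beta
        training = self.training
        n = x.data.size // x.data.shape[-1]

        def backward(g):
            if gamma.requires_grad:
                gamma._accum(np.sum(g * xhat, axis=(0, 1, 2)))
            if beta.requires_grad:
                beta._accum(np.sum(g, axis=(0, 1, 2)))
            if x.requires_grad:
                gxhat = g * gamma.data
                if training:
                    # full batch-norm gradient (batch statistics depend on x)
                    dx = (gxhat
                          - gxhat.mean(axis=(0, 1, 2))
                          - xhat * (gxhat * xhat).mean(axis=(0, 1, 2))) * inv
                else:
                    dx = gxhat * inv
                x._accum(dx.astype(np.float32))

        return x._make(out_data, (x, gamma, beta), backward)


class MaxPool2D(Module):
    def __init__(self, pool: int = 2, stride: int | None = None):
        self.pool = pool
        self.stride = stride

    def __call__(self, x: Tensor) -> Tensor:
        return maxpool2d(x, self.pool, self.stride)


class Dense(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 activation: str | None = None):
        self.w = _glorot(rng, (n_in, n_out), n_in, n_out)
        self.b = Tensor(np.zeros(n_out), requires_grad=True)
        self.activation = activation

    def __call__(self, x: Tensor) -> Tensor:
        y = x @ self.w + self.b
        if self.activation == "relu":
            return relu(y)
        if self.activation == "sigmoid":
            return sigmoid(y)
        return y


class GRU(Module):
    """Gated recurrent unit over a sequence of (batch, features) steps.

    Update-gate convention: h_t = z_t * h_{t-1} + (1 - z_t) * c_t.
    Returns the final hidden state (batch, hidden).
    """

    def __init__(self, n_in: int, hidden: int, rng: np.random.Generator):
        self.hidden = hidden
        # input-to-hidden and hidden-to-hidden weights for the z, r, c gates
        self.wx = _glorot(rng, (n_in, 3 * hidden), n_in, 3 * hidden)
        self.wh = _glorot(rng, (hidden, 3 * hidden), hidden, 3 * hidden)
        self.b = Tensor(np.zeros(3 * hidden), requires_grad=True)

    def __call__(self, steps: list[Tensor]) -> Tensor:
        B = steps[0].shape[0]
        H = self.hidden
        h = Tensor(np.zeros((B, H), dtype=np.float32))
        for x_t in steps:
            gx = x_t @ self.wx + self.b
            gh = h @ self.wh
            z = sigmoid(_slice_cols(gx, 0, H) + _slice_cols(gh, 0, H))
            r = sigmoid(_slice_cols(gx, H, 2 * H) + _slice_cols(gh, H, 2 * H))
            c = tanh(_slice_cols(gx, 2 * H, 3 * H) + r * _slice_cols(gh, 2 * H, 3 * H))
            h = z * h + (1.0 - z) * c
        return h

    @property
    def candidate_input_weights(self) -> np.ndarray:
        """Input weights feeding the candidate-state gate, shape (n_in, hidden)."""
        H = self.hidden
        return self.wx.data[:, 2 * H:3 * H]


def _slice_cols(x: Tensor, lo: int, hi: int) -> Tensor:
    def backward(g):
        if x.requires_grad:
            full = np.zeros_like(x.data)
            full[:, lo:hi] = g
            x._accum(full)

    return x._make(x.data[:, lo:hi], (x,), backward)
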