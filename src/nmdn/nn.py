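"""Small neural-network layer library on top of :mod:`nmdn.autodiff`.

Layers follow the familiar module pattern: parameters are discovered
recursively, ``train()``/``eval()`` toggle batch-norm statistics and dropout,
and an Adam optimizer updates parameter tensors in place.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor

__all__ = ["Module", "Linear", "BatchNorm1d", "Dropout", "ReLU", "Sequential", "MLP", "Adam", "ssp"]


class Module:
    def __init__(self):
        self.training = True

    def modules(self):
        yield self
        for v in self.__dict__.values():
            if isinstance(v, Module):
                yield from v.modules()
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        yield from item.modules()

    def parameters(self) -> list[Tensor]:
        params = []
        for m in self.modules():
            for v in m.__dict__.values():
                if isinstance(v, Tensor) and v.requires_grad:
                    params.append(v)
        return params

    def train(self):
        for m in self.modules():
            m.training = True
        return self

    def eval(self):
        for m in self.modules():
            m.training = False
        return self

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()

    # -- flat state dict of raw arrays (for checkpoints) ----------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        out = {}
        self._collect_state("", out)
        return out

    def _collect_state(self, prefix: str, out: dict):
        for k, v in self.__dict__.items():
            key = f"{prefix}{k}"
            if isinstance(v, Tensor):
                out[key] = v.data.copy()
            elif isinstance(v, np.ndarray):
                out[key] = v.copy()
            elif isinstance(v, Module):
                v._collect_state(key + ".", out)
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        item._collect_state(f"{key}.{i}.", out)

    def load_state_dict(self, state: dict[str, np.ndarray]):
        self._load_state("", state)

    def _load_state(self, prefix: str, state: dict):
        for k, v in self.__dict__.items():
            key = f"{prefix}{k}"
            if isinstance(v, Tensor) and key in state:
                v.data = np.array(state[key], dtype=np.float64)
            elif isinstance(v, np.ndarray) and key in state:
                self.__dict__[k] = np.array(state[key])
            elif isinstance(v, Module):
                v._load_state(key + ".", state)
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        item._load_state(f"{key}.{i}.", state)

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Linear(Module):
    """Affine map with Kaiming-uniform initialization."""

    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator):
        super().__init__()
        bound = np.sqrt(6.0 / in_dim)
        self.weight = Tensor(rng.uniform(-bound, bound, (in_dim, out_dim)), requires_grad=True)
        self.bias = Tensor(np.zeros(out_dim), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class BatchNorm1d(Module):
    """Batch normalization over the leading axis.

    Training mode uses batch statistics and updates running estimates;
    eval mode uses the (frozen) running estimates, so inference is a
    deterministic function of the input.
    """

    def __init__(self, dim: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.gamma = Tensor(np.ones(dim), requires_grad=True)
        self.beta = Tensor(np.zeros(dim), requires_grad=True)
        self.running_mean = np.zeros(dim)
        self.running_var = np.ones(dim)
        self.momentum = momentum
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        if self.training:
            mu = x.mean(axis=0, keepdims=True)
            centered = x - mu
            var = (centered * centered).mean(axis=0, keepdims=True)
            n = x.shape[0]
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mu.data.ravel()
            unbiased = var.data.ravel() * (n / max(n - 1, 1))
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * unbiased
            xhat = centered / (var + self.eps).sqrt()
        else:
            xhat = (x - Tensor(self.running_mean)) / Tensor(np.sqrt(self.running_var + self.eps))
        return xhat * self.gamma + self.beta


class Dropout(Module):
    def __init__(self, p: float, rng: np.random.Generator):
        super().__init__()
        self.p = float(p)
        self._rng = rng

    def forward(self, x: Tensor) -> Tensor:
        if not self.training or self.p <= 0.0:
            return x
        keep = 1.0 - self.p
        mask = self._rng.random(x.shape) < keep
        return x * Tensor(mask / keep)


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.relu()


class Sequential(Module):
    def __init__(self, layers: list[Module]):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x)
        return x


class MLP(Module):
    """Stack of ``n_layers`` blocks: linear -> batch-norm -> ReLU -> dropout."""

    def __init__(self, in_dim: int, hidden_dim: int, n_layers: int, dropout: float,
                 rng: np.random.Generator, batch_norm: bool = True):
        super().__init__()
        layers: list[Module] = []
        d = in_dim
        for _ in range(n_layers):
            layers.append(Linear(d, hidden_dim, rng))
            if batch_norm:
                layers.append(BatchNorm1d(hidden_dim))
            layers.append(ReLU())
            layers.append(Dropout(dropout, rng))
            d = hidden_dim
        self.net = Sequential(layers)
        self.out_dim = hidden_dim

    def forward(self, x: Tensor) -> Tensor:
        return self.net(x)


def ssp(x: Tensor) -> Tensor:
    """Shifted softplus, SSP(x) = ln(e^x + 1) - ln 2; SSP(0) = 0."""
    return x.softplus() - float(np.log(2.0))


class Adam:
    def __init__(self, params: list[Tensor], lr: float = 1e-4,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.zero_grad()
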