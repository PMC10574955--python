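"""Layer / optimizer layer over the autograd engine."""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, batchnorm2d, conv2d, relu

__all__ = ["Module", "Conv2d", "BatchNorm2d", "ReLU", "Identity", "Sequential", "SGD"]


class Module:
    """Base class: parameter/buffer registration via attribute assignment."""

    def __init__(self):
        self._params: dict[str, Tensor] = {}
        self._buffers: dict[str, np.ndarray] = {}
        self._modules: dict[str, "Module"] = {}
        self.training = True

    def __setattr__(self, name, value):
        if isinstance(value, Module):
            self.__dict__.setdefault("_modules", {})[name] = value
        elif isinstance(value, Tensor) and value.requires_grad:
            self.__dict__.setdefault("_params", {})[name] = value
        object.__setattr__(self, name, value)

    def parameters(self) -> list[Tensor]:
        out = list(self._params.values())
        for m in self._modules.values():
            out.extend(m.parameters())
        return out

    def named_state(self, prefix: str = "") -> dict[str, np.ndarray]:
        state = {prefix + k: v.data for k, v in self._params.items()}
        state.update({prefix + k: v for k, v in self._buffers.items()})
        for name, m in self._modules.items():
            state.update(m.named_state(prefix + name + "."))
        return state

    def load_state(self, state: dict[str, np.ndarray], prefix: str = "") -> None:
        for k, t in self._params.items():
            t.data[...] = state[prefix + k]
        for k in self._buffers:
            self._buffers[k][...] = state[prefix + k]
            object.__setattr__(self, k, self._buffers[k])
        for name, m in self._modules.items():
            m.load_state(state, prefix + name + ".")

    def train(self, mode: bool = True):
        self.training = mode
        for m in self._modules.values():
            m.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def _pair(v) -> tuple[int, int]:
    return (v, v) if isinstance(v, int) else tuple(v)


class Conv2d(Module):
    """Convolution with optional per-axis dilation; He-initialized weights."""

    def __init__(self, cin, cout, kernel_size, stride=1, dilation=1, bias=True,
                 rng: np.random.Generator | None = None):
        super().__init__()
        kh, kw = _pair(kernel_size)
        self.stride = _pair(stride)
        self.dilation = _pair(dilation)
        rng = rng or np.random.default_rng(0)
        fan_in = cin * kh * kw
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(cout, cin, kh, kw))
        self.weight = Tensor(w.astype(np.float32), requires_grad=True)
        self.bias = Tensor(np.zeros(cout, dtype=np.float32), requires_grad=True) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, self.stride, self.dilation)


class BatchNorm2d(Module):
    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.momentum = momentum
        self.eps = eps
        self.gamma = Tensor(np.ones(channels, dtype=np.float32), requires_grad=True)
        self.beta = Tensor(np.zeros(channels, dtype=np.float32), requires_grad=True)
        self._buffers["running_mean"] = np.zeros(channels, dtype=np.float32)
        self._buffers["running_var"] = np.ones(channels, dtype=np.float32)

    def forward(self, x: Tensor) -> Tensor:
        return batchnorm2d(
            x, self.gamma, self.beta,
            self._buffers["running_mean"], self._buffers["running_var"],
            self.training, self.momentum, self.eps,
        )


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return relu(x)


class Identity(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x


class Sequential(Module):
    def __init__(self, *layers: Module):
        super().__init__()
        self.layers = list(layers)
        for i, layer in enumerate(layers):
            self._modules[str(i)] = layer

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x)
        return x


class SGD:
    """SGD with momentum and decoupled-from-nothing L2 weight decay (classic form)."""

    def __init__(self, params: list[Tensor], lr: float, momentum: float = 0.9,
                 weight_decay: float = 0.0):
        self.params = params
        self.lr = lr
        self.momentum = momentum
        self.weight_decay = weight_decay
        self._velocity = [np.zeros_like(p.data) for p in params]

    def step(self) -> None:
        for p, v in zip(self.params, self._velocity):
            if p.grad is None:
                continue
            g = p.grad + self.weight_decay * p.data
            v *= self.momentum
            v += g
            p.data -= self.lr * v
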