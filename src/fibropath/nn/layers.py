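"""Neural-network layers on top of the autodiff engine.

Layers follow NCHW layout and hold their parameters as ``Tensor`` objects
with ``requires_grad=True``. ``Module.parameters()`` walks attributes and
sub-modules recursively. Initialisation draws from a ``numpy.random.Generator``
passed explicitly — no global RNG state anywhere in the stack.
"""

from __future__ import annotations

import numpy as np

from . import tensor as T
from .tensor import Tensor


class Module:
    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        seen: set[int] = set()
        self._collect(params, seen)
        return params

    def _collect(self, params, seen):
        if id(self) in seen:
            return
        seen.add(id(self))
        for v in vars(self).values():
            if isinstance(v, Tensor) and v.requires_grad:
                if id(v) not in seen:
                    seen.add(id(v))
                    params.append(v)
            elif isinstance(v, Module):
                v._collect(params, seen)
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        item._collect(params, seen)
                    elif isinstance(item, Tensor) and item.requires_grad:
                        if id(item) not in seen:
                            seen.add(id(item))
                            params.append(item)

    def modules(self) -> list["Module"]:
        mods: list[Module] = []

        def walk(m):
            mods.append(m)
            for v in vars(m).values():
                if isinstance(v, Module):
                    walk(v)
                elif isinstance(v, (list, tuple)):
                    for item in v:
                        if isinstance(item, Module):
                            walk(item)

        walk(self)
        return mods

    def set_training(self, flag: bool) -> None:
        for m in self.modules():
            if hasattr(m, "training"):
                m.training = flag

    def n_parameters(self) -> int:
        return int(sum(p.size for p in self.parameters()))

    def state_arrays(self) -> dict[str, np.ndarray]:
        """Flat name -> array mapping for checkpointing."""
        out: dict[str, np.ndarray] = {}
        for i, p in enumerate(self.parameters()):
            out[f"p{i}"] = p.data
        return out

    def load_state_arrays(self, state: dict[str, np.ndarray]) -> None:
        for i, p in enumerate(self.parameters()):
            arr = np.asarray(state[f"p{i}"])
            if arr.shape != p.data.shape:
                raise ValueError(f"checkpoint shape mismatch at p{i}")
            p.data = arr.astype(np.float64)

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def he_init(rng: np.random.Generator, shape, fan_in: int) -> Tensor:
    std = np.sqrt(2.0 / fan_in)
    return Tensor(rng.normal(0.0, std, size=shape), requires_grad=True)


class Conv2d(Module):
    """Cross-correlation with He-initialised weights, lowered to im2col+matmul."""

    def __init__(self, cin, cout, kernel, stride=1, padding=0, rng=None, bias=True):
        self.cin, self.cout = cin, cout
        self.kernel = (kernel, kernel) if isinstance(kernel, int) else tuple(kernel)
        self.stride = stride
        self.padding = padding
        kh, kw = self.kernel
        fan_in = cin * kh * kw
        rng = rng if rng is not None else np.random.default_rng(0)
        self.weight = he_init(rng, (cout, fan_in), fan_in)
        self.bias = Tensor(np.zeros(cout), requires_grad=True) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        n, c, h, w = x.shape
        kh, kw = self.kernel
        sh, sw = (self.stride, self.stride) if isinstance(self.stride, int) else self.stride
        ph, pw = (self.padding, self.padding) if isinstance(self.padding, int) else self.padding
        ho = (h + 2 * ph - kh) // sh + 1
        wo = (w + 2 * pw - kw) // sw + 1
        cols = T.im2col(x, self.kernel, self.stride, self.padding)  # (N, CKK, L)
        flat = T.reshape(T.transpose(cols, (0, 2, 1)), (n * ho * wo, c * kh * kw))
        y = T.matmul(flat, T.transpose(self.weight, (1, 0)))
        if self.bias is not None:
            y = y + self.bias
        return T.transpose(T.reshape(y, (n, ho * wo, self.cout)), (0, 2, 1)).reshape(
            (n, self.cout, ho, wo)
        )


class Dense(Module):
    def __init__(self, nin, nout, rng=None):
        rng = rng if rng is not None else np.random.default_rng(0)
        self.weight = he_init(rng, (nin, nout), nin)
        self.bias = Tensor(np.zeros(nout), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return T.matmul(x, self.weight) + self.bias


class LeakyReLU(Module):
    def __init__(self, slope=0.2):
        self.slope = slope

    def forward(self, x):
        return T.leaky_relu(x, self.slope)


class ReLU(Module):
    def forward(self, x):
        return T.relu(x)


class Flatten(Module):
    def forward(self, x):
        return T.reshape(x, (x.shape[0], int(np.prod(x.shape[1:]))))


class Upsample(Module):
    """Nearest-neighbour upsampling by an integer factor."""

    def __init__(self, factor=2):
        self.factor = factor

    def forward(self, x):
        n, c, h, w = x.shape
        k = self.factor
        y = T.reshape(x, (n, c, h, 1, w, 1))
        y = T.broadcast_to(y, (n, c, h, k, w, k))
        return T.reshape(y, (n, c, h * k, w * k))


class AvgPool2d(Module):
    """Non-overlapping average pooling (stride = kernel)."""

    def __init__(self, kernel=2):
        self.kernel = kernel

    def forward(self, x):
        n, c, h, w = x.shape
        k = self.kernel
        y = T.reshape(x, (n, c, h // k, k, w // k, k))
        return T.tmean(y, axis=(3, 5))


class MaxPool2d(Module):
    """Max pooling with arbitrary kernel/stride/padding via im2col."""

    def __init__(self, kernel, stride=None, padding=0):
        self.kernel = kernel
        self.stride = stride if stride is not None else kernel
        self.padding = padding

    def forward(self, x):
        n, c, h, w = x.shape
        k = self.kernel
        s = self.stride
        p = self.padding
        ho = (h + 2 * p - k) // s + 1
        wo = (w + 2 * p - k) // s + 1
        cols = T.im2col(x, k, s, p)  # (N, C*k*k, Ho*Wo)
        cols = T.reshape(cols, (n, c, k * k, ho * wo))
        return T.reshape(T.tmax(cols, axis=2), (n, c, ho, wo))


class GlobalAvgPool(Module):
    def forward(self, x):
        return T.tmean(x, axis=(2, 3))


class BatchNorm2d(Module):
    def __init__(self, channels, eps=1e-5, momentum=0.1):
        self.gamma = Tensor(np.ones((1, channels, 1, 1)), requires_grad=True)
        self.beta = Tensor(np.zeros((1, channels, 1, 1)), requires_grad=True)
        self.running_mean = np.zeros((1, channels, 1, 1))
        self.running_var = np.ones((1, channels, 1, 1))
        self.eps = eps
        self.momentum = momentum
        self.training = True

    def forward(self, x):
        if self.training:
            m = T.tmean(x, axis=(0, 2, 3), keepdims=True)
            v = T.tmean((x - m) ** 2, axis=(0, 2, 3), keepdims=True)
            self.running_mean = (
                (1 - self.momentum) * self.running_mean + self.momentum * m.data
            )
            self.running_var = (
                (1 - self.momentum) * self.running_var + self.momentum * v.data
            )
        else:
            m, v = Tensor(self.running_mean), Tensor(self.running_var)
        xhat = (x - m) * ((v + Tensor(self.eps)) ** -0.5)
        return self.gamma * xhat + self.beta


class PixelNorm(Module):
    """Per-pixel feature-vector normalisation (progressive-GAN trick)."""

    def __init__(self, eps=1e-8):
        self.eps = eps

    def forward(self, x):
        ms = T.tmean(x ** 2, axis=1, keepdims=True)
        return x * ((ms + Tensor(self.eps)) ** -0.5)


class MinibatchStdDev(Module):
    """Append one channel holding the batch-wide feature std (critic trick)."""

    def forward(self, x):
        n, c, h, w = x.shape
        m = T.tmean(x, axis=0, keepdims=True)
        var = T.tmean((x - m) ** 2, axis=0, keepdims=True)
        std = T.tmean((var + Tensor(1e-8)) ** 0.5)  # scalar
        chan = T.broadcast_to(T.reshape(std, (1, 1, 1, 1)), (n, 1, h, w))
        return T.concat([x, chan], axis=1)


class Sequential(Module):
    def __init__(self, *layers):
        self.layers = list(layers)

    def forward(self, x):
        for layer in self.layers:
            x = layer(x)
        return x

    def __iter__(self):
        return iter(self.layers)


def softmax(logits: Tensor) -> Tensor:
    shift = Tensor(logits.data.max(axis=1, keepdims=True))
    e = T.exp(logits - shift)
    return e * (T.tsum(e, axis=1, keepdims=True) ** -1.0)


def cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean negative log-likelihood of integer ``labels``."""
    shift = Tensor(logits.data.max(axis=1, keepdims=True))
    z = logits - shift
    logp = z - T.log(T.tsum(T.exp(z), axis=1, keepdims=True))
    onehot = np.zeros(logits.shape)
    onehot[np.arange(len(labels)), np.asarray(labels, dtype=int)] = 1.0
    return -T.tmean(T.tsum(logp * Tensor(onehot), axis=1))
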