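"""Neural-network building blocks on top of the autodiff tensor."""

from __future__ import annotations

import numpy as np

from .tensor import Tensor, avg_pool, concat, convnd, upsample_nearest


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(np.asarray(data, dtype=np.float32), requires_grad=True)


class Module:
    """Minimal module container: parameter discovery, train/eval mode,
    flat state dict of numpy arrays."""

    def __init__(self):
        self.training = True

    def _children(self):
        for name, value in vars(self).items():
            if isinstance(value, Module):
                yield name, value
            elif isinstance(value, (list, tuple)):
                for i, v in enumerate(value):
                    if isinstance(v, Module):
                        yield f"{name}.{i}", v

    def named_parameters(self, prefix: str = ""):
        for name, value in vars(self).items():
            if isinstance(value, Parameter):
                yield prefix + name, value
        for name, child in self._children():
            yield from child.named_parameters(prefix + name + ".")

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def train(self):
        self.training = True
        for _, c in self._children():
            c.train()
        return self

    def eval(self):
        self.training = False
        for _, c in self._children():
            c.eval()
        return self

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: p.data.copy() for k, p in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        if set(params) != set(state):
            raise ValueError("state dict keys do not match module parameters")
        for k, p in params.items():
            p.data = np.asarray(state[k], dtype=np.float32).reshape(p.shape)

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def _he(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return rng.standard_normal(shape).astype(np.float32) * np.sqrt(2.0 / fan_in)


class Conv(Module):
    """N-d convolution; kernel/stride/pad are isotropic ints."""

    def __init__(self, cin, cout, kernel=3, stride=1, pad=1, ndim=2, rng=None, bias=True):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        kshape = (cout, cin) + (kernel,) * ndim
        self.weight = Parameter(_he(rng, kshape, cin * kernel**ndim))
        self.bias = Parameter(np.zeros(cout)) if bias else None
        self.stride, self.pad = stride, pad

    def forward(self, x: Tensor) -> Tensor:
        return convnd(x, self.weight, self.bias, stride=self.stride, pad=self.pad)


class Linear(Module):
    def __init__(self, fin, fout, rng=None, bias=True):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.weight = Parameter(_he(rng, (fin, fout), fin))
        self.bias = Parameter(np.zeros(fout)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        y = x.matmul(self.weight)
        return y + self.bias if self.bias is not None else y


class InstanceNorm(Module):
    """Per-sample, per-channel normalisation over spatial axes with an
    optional learned affine."""

    def __init__(self, channels, ndim=2, affine=True, eps=1e-5):
        super().__init__()
        self.eps = eps
        self.ndim = ndim
        shape = (1, channels) + (1,) * ndim
        self.gamma = Parameter(np.ones(shape)) if affine else None
        self.beta = Parameter(np.zeros(shape)) if affine else None

    def forward(self, x: Tensor) -> Tensor:
        axes = tuple(range(2, 2 + self.ndim))
        mu = x.mean(axis=axes, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=axes, keepdims=True)
        y = xc / (var + self.eps).sqrt()
        if self.gamma is not None:
            y = y * self.gamma + self.beta
        return y

    def normalise_only(self, x: Tensor) -> Tensor:
        """Normalisation without the affine (used by SPADE blocks)."""
        axes = tuple(range(2, 2 + self.ndim))
        mu = x.mean(axis=axes, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=axes, keepdims=True)
        return xc / (var + self.eps).sqrt()


class Sequential(Module):
    def __init__(self, *mods):
        super().__init__()
        self.mods = list(mods)

    def forward(self, x):
        for m in self.mods:
            x = m(x) if isinstance(m, Module) else m(x)
        return x


class LeakyReLU(Module):
    def __init__(self, slope=0.2):
        super().__init__()
        self.slope = slope

    def forward(self, x):
        return x.leaky_relu(self.slope)


class ReLU(Module):
    def forward(self, x):
        return x.relu()


class Sigmoid(Module):
    def forward(self, x):
        return x.sigmoid()


class Upsample(Module):
    def __init__(self, scale=2):
        super().__init__()
        self.scale = scale

    def forward(self, x):
        return upsample_nearest(x, self.scale)


class AvgPool(Module):
    def __init__(self, k=2):
        super().__init__()
        self.k = k

    def forward(self, x):
        return avg_pool(x, self.k)


class CrossAttention(Module):
    """Single-head cross-attention: spatial features attend to a short
    context token sequence (the conditioning)."""

    def __init__(self, channels: int, ctx_dim: int, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.q = Linear(channels, channels, rng=rng, bias=False)
        self.k = Linear(ctx_dim, channels, rng=rng, bias=False)
        self.v = Linear(ctx_dim, channels, rng=rng, bias=False)
        self.out = Linear(channels, channels, rng=rng)
        self.scale = 1.0 / np.sqrt(channels)

    def forward(self, x: Tensor, ctx: Tensor) -> Tensor:
        """x: (N, C, *spatial); ctx: (N, S, ctx_dim).  Residual output."""
        N, C = x.shape[:2]
        spatial = x.shape[2:]
        L = int(np.prod(spatial))
        xf = x.reshape(N, C, L).transpose(0, 2, 1)  # (N, L, C)
        q = self.q(xf)
        k = self.k(ctx)
        v = self.v(ctx)
        attn = (q.matmul(k.transpose(0, 2, 1)) * self.scale).softmax(axis=-1)
        y = self.out(attn.matmul(v))  # (N, L, C)
        y = y.transpose(0, 2, 1).reshape((N, C) + spatial)
        return x + y


__all__ = [
    "Parameter", "Module", "Conv", "Linear", "InstanceNorm", "Sequential",
    "LeakyReLU", "ReLU", "Sigmoid", "Upsample", "AvgPool", "CrossAttention",
    "Tensor", "concat",
]
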