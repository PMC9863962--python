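"""Neural-network modules built on the autodiff tensor.

Follows the usual Module/parameters() convention.  Initialisation is
He-normal for convolutions and linear layers; every module draws from the
`numpy.random.Generator` handed to it so whole networks are reproducible
from a single seed.
"""

from __future__ import annotations

import numpy as np

from .tensor import Tensor


class Module:
    training: bool = True

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for v in self.__dict__.values():
            if isinstance(v, Tensor) and v.requires_grad:
                params.append(v)
            elif isinstance(v, Module):
                params.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
        return params

    def modules(self) -> list["Module"]:
        mods = [self]
        for v in self.__dict__.values():
            if isinstance(v, Module):
                mods.extend(v.modules())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        mods.extend(item.modules())
        return mods

    def train(self) -> "Module":
        for m in self.modules():
            m.training = True
        return self

    def eval(self) -> "Module":
        for m in self.modules():
            m.training = False
        return self

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def state_arrays(self) -> list[np.ndarray]:
        """All learnable + running-stat arrays, in traversal order."""
        arrs = [p.data for p in self.parameters()]
        for m in self.modules():
            if isinstance(m, BatchNorm2d):
                arrs.extend([m.running_mean, m.running_var])
        return arrs

    def load_state_arrays(self, arrs: list[np.ndarray]) -> None:
        it = iter(arrs)
        for p in self.parameters():
            p.data = np.asarray(next(it), dtype=np.float32).reshape(p.data.shape)
        for m in self.modules():
            if isinstance(m, BatchNorm2d):
                m.running_mean = np.asarray(next(it), dtype=np.float32)
                m.running_var = np.asarray(next(it), dtype=np.float32)

    def __call__(self, x: Tensor) -> Tensor:
        return self.forward(x)


class Identity(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.relu()


class Sequential(Module):
    def __init__(self, *mods: Module):
        self.mods = list(mods)

    def forward(self, x: Tensor) -> Tensor:
        for m in self.mods:
            x = m(x)
        return x

    def __len__(self):
        return len(self.mods)

    def __getitem__(self, i):
        return self.mods[i]


class Conv2d(Module):
    def __init__(self, cin: int, cout: int, k: int, stride: int = 1,
                 padding: int = 0, bias: bool = True, *, rng: np.random.Generator):
        fan_in = cin * k * k
        std = np.sqrt(2.0 / fan_in)
        self.weight = Tensor(rng.normal(0.0, std, (cout, cin, k, k)).astype(np.float32),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(cout, np.float32), requires_grad=True) if bias else None
        self.stride, self.padding = stride, padding

    def forward(self, x: Tensor) -> Tensor:
        return x.conv2d(self.weight, self.bias, stride=self.stride, padding=self.padding)


class Linear(Module):
    def __init__(self, cin: int, cout: int, *, rng: np.random.Generator):
        std = np.sqrt(2.0 / cin)
        self.weight = Tensor(rng.normal(0.0, std, (cin, cout)).astype(np.float32),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(cout, np.float32), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class BatchNorm2d(Module):
    """Batch normalisation over N,H,W with running statistics for eval.

    Implemented as one fused autodiff node with the analytic gradient
    (cheaper than composing it from primitive ops)."""

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Tensor(np.ones(channels, np.float32), requires_grad=True)
        self.beta = Tensor(np.zeros(channels, np.float32), requires_grad=True)
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self.momentum, self.eps = momentum, eps

    def forward(self, x: Tensor) -> Tensor:
        C = x.shape[-1]
        axes = (0, 1, 2)
        gamma, beta = self.gamma, self.beta
        g4 = gamma.data
        b4 = beta.data
        if self.training:
            mu = x.data.mean(axis=axes, keepdims=True)
            var = x.data.var(axis=axes, keepdims=True)
            m = self.momentum
            self.running_mean = ((1 - m) * self.running_mean
                                 + m * mu.reshape(C).astype(np.float32))
            self.running_var = ((1 - m) * self.running_var
                                + m * var.reshape(C).astype(np.float32))
        else:
            mu = self.running_mean.reshape(1, 1, 1, C)
            var = self.running_var.reshape(1, 1, 1, C)
        inv_sd = 1.0 / np.sqrt(var + self.eps)
        xhat = (x.data - mu) * inv_sd
        out_data = xhat * g4 + b4
        training = self.training

        def backward(g):
            if gamma.requires_grad:
                gamma._accum((g * xhat).sum(axis=axes))
            if beta.requires_grad:
                beta._accum(g.sum(axis=axes))
            if x.requires_grad:
                if training:
                    gm = g.mean(axis=axes, keepdims=True)
                    gxm = (g * xhat).mean(axis=axes, keepdims=True)
                    x._accum(g4 * inv_sd * (g - gm - xhat * gxm))
                else:
                    x._accum(g4 * inv_sd * g)

        out = Tensor(out_data, requires_grad=any(
            t.requires_grad for t in (x, gamma, beta)),
            _prev=tuple(t for t in (x, gamma, beta) if t.requires_grad))
        if out.requires_grad:
            out._backward = backward
        return out


class MaxPool2(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.maxpool2()


class UpsampleNearest2(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.upsample_nearest2()


def conv_bn_relu(cin: int, cout: int, k: int, stride: int = 1, padding: int = 0,
                 *, rng: np.random.Generator) -> Sequential:
    return Sequential(
        Conv2d(cin, cout, k, stride=stride, padding=padding, bias=False, rng=rng),
        BatchNorm2d(cout),
        ReLU(),
    )
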