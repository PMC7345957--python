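"""Layer and optimizer primitives on top of the autograd core."""

from __future__ import annotations

import numpy as np

from . import autograd as ag
from .autograd import Parameter, Tensor

__all__ = ["Module", "Conv2d", "InstanceNorm2d", "Dense", "Adam"]


class Module:
    """Parameter container with recursive collection."""

    def parameters(self):
        out = []
        for v in self.__dict__.values():
            if isinstance(v, Parameter):
                out.append(v)
            elif isinstance(v, Module):
                out.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        out.extend(item.parameters())
                    elif isinstance(item, Parameter):
                        out.append(item)
        return out

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def state_arrays(self):
        return [p.data.copy() for p in self.parameters()]

    def load_state_arrays(self, arrays):
        params = self.parameters()
        if len(arrays) != len(params):
            raise ValueError("parameter count mismatch")
        for p, a in zip(params, arrays):
            if p.data.shape != np.asarray(a).shape:
                raise ValueError("parameter shape mismatch")
            p.data = np.asarray(a, dtype=np.float64).copy()


class Conv2d(Module):
    def __init__(self, c_in: int, c_out: int, k: int = 3, stride: int = 1, padding=None, rng=None):
        rng = rng or np.random.default_rng(0)
        fan_in = c_in * k * k
        self.weight = Parameter(rng.standard_normal((c_out, c_in, k, k)) * np.sqrt(2.0 / fan_in))
        self.bias = Parameter(np.zeros(c_out))
        self.stride = stride
        self.padding = k // 2 if padding is None else padding

    def __call__(self, x: Tensor) -> Tensor:
        return ag.conv2d(x, self.weight, self.bias, self.stride, self.padding)


class InstanceNorm2d(Module):
    def __init__(self, c: int):
        self.gamma = Parameter(np.ones(c))
        self.beta = Parameter(np.zeros(c))

    def __call__(self, x: Tensor) -> Tensor:
        return ag.instance_norm(x, self.gamma, self.beta)


class Dense(Module):
    def __init__(self, f_in: int, f_out: int, rng=None):
        rng = rng or np.random.default_rng(0)
        self.weight = Parameter(rng.standard_normal((f_in, f_out)) * np.sqrt(2.0 / f_in))
        self.bias = Parameter(np.zeros(f_out))

    def __call__(self, x: Tensor) -> Tensor:
        return ag.matmul(x, self.weight) + self.bias


class Adam:
    """Adam with the standard bias correction."""

    def __init__(self, params, lr: float = 1e-3, betas=(0.9, 0.999), eps: float = 1e-8):
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
            p.grad = None
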