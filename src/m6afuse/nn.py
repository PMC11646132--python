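"""Layer and optimizer primitives on top of :mod:`m6afuse.autodiff`.

Initialization follows He (fan-in scaled normal) for convolutions and
linear layers because every feature-producing convolution is followed by a
ReLU.  All randomness is drawn from an explicitly passed
``numpy.random.Generator`` so identical seeds yield bitwise-identical
parameters.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, conv1d, embedding, matmul


class Module:
    """Container with recursive parameter discovery (framework idiom)."""

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        seen: set[int] = set()
        self._collect(params, seen)
        return params

    def _collect(self, out: list[Tensor], seen: set[int]) -> None:
        for value in vars(self).values():
            self._collect_value(value, out, seen)

    @staticmethod
    def _collect_value(value, out, seen) -> None:
        if isinstance(value, Tensor) and value.requires_grad:
            if id(value) not in seen:
                seen.add(id(value))
                out.append(value)
        elif isinstance(value, Module):
            value._collect(out, seen)
        elif isinstance(value, (list, tuple)):
            for v in value:
                Module._collect_value(v, out, seen)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def state_arrays(self) -> list[np.ndarray]:
        return [p.data for p in self.parameters()]

    def load_state_arrays(self, arrays) -> None:
        params = self.parameters()
        if len(arrays) != len(params):
            raise ValueError("parameter count mismatch when loading state")
        for p, a in zip(params, arrays):
            if p.data.shape != a.shape:
                raise ValueError("parameter shape mismatch when loading state")
            p.data = np.array(a, dtype=p.data.dtype)


class Conv1d(Module):
    """Stride-1 1-D convolution layer with symmetric padding."""

    def __init__(self, in_channels: int, out_channels: int, kernel: int,
                 pad: int = 0, *, rng: np.random.Generator, dtype=np.float32,
                 bias: bool = True, gain: float = 1.0):
        self.pad = pad
        fan_in = in_channels * kernel
        std = gain * np.sqrt(2.0 / fan_in)
        self.weight = Tensor(
            rng.normal(0.0, std, (out_channels, in_channels, kernel)).astype(dtype),
            requires_grad=True,
        )
        self.bias = (
            Tensor(np.zeros(out_channels, dtype=dtype), requires_grad=True)
            if bias else None
        )

    def __call__(self, x: Tensor) -> Tensor:
        return conv1d(x, self.weight, self.bias, pad=self.pad)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, *,
                 rng: np.random.Generator, dtype=np.float32, gain: float = 1.0):
        std = gain * np.sqrt(2.0 / in_features)
        self.weight = Tensor(
            rng.normal(0.0, std, (in_features, out_features)).astype(dtype),
            requires_grad=True,
        )
        self.bias = Tensor(np.zeros(out_features, dtype=dtype), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return matmul(x, self.weight) + self.bias


class Embedding(Module):
    """Integer-code embedding with a frozen all-zero padding row.

    Row 0 is the padding symbol: it is initialized to zero and excluded
    from gradient updates, so the padded prefix of a sequence contributes
    no learnable signal.
    """

    def __init__(self, vocab: int, dim: int, *, rng: np.random.Generator,
                 dtype=np.float32, pad_code: int = 0, gain: float = 1.0):
        w = rng.normal(0.0, gain, (vocab, dim)).astype(dtype)
        w[pad_code] = 0.0
        self.pad_code = pad_code
        self.weight = Tensor(w, requires_grad=True)

    def __call__(self, codes: np.ndarray) -> Tensor:
        return embedding(codes, self.weight, freeze_rows=(self.pad_code,))


class Adam:
    """Adam optimizer (Kingma & Ba) with bias correction."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1 ** self.t
        b2t = 1.0 - self.beta2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= self.beta1
            m += (1.0 - self.beta1) * g
            v *= self.beta2
            v += (1.0 - self.beta2) * g * g
            p.data -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
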