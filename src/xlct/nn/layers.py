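"""Network building blocks on top of the autodiff engine."""

from __future__ import annotations

import numpy as np

from . import autograd as ag
from .autograd import Tensor


class Module:
    """Base class: parameter collection and train/eval mode propagation."""

    def __init__(self):
        self.training = True

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

    def train(self) -> None:
        for m in self.modules():
            m.training = True

    def eval(self) -> None:
        for m in self.modules():
            m.training = False

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    def state_arrays(self) -> dict[str, np.ndarray]:
        """Flat name -> array mapping of parameters and buffers (for checkpoints)."""
        out: dict[str, np.ndarray] = {}

        def visit(mod: Module, prefix: str) -> None:
            for name, v in mod.__dict__.items():
                key = f"{prefix}{name}"
                if isinstance(v, Tensor) and v.requires_grad:
                    out[key] = v.data
                elif isinstance(v, np.ndarray):
                    out[key] = v
                elif isinstance(v, Module):
                    visit(v, key + ".")
                elif isinstance(v, (list, tuple)):
                    for i, item in enumerate(v):
                        if isinstance(item, Module):
                            visit(item, f"{key}.{i}.")

        visit(self, "")
        return out

    def load_state_arrays(self, state: dict[str, np.ndarray]) -> None:
        mine = self.state_arrays()
        if set(mine) != set(state):
            missing = set(mine) ^ set(state)
            raise KeyError(f"checkpoint/model mismatch on keys: {sorted(missing)[:5]}")

        def visit(mod: Module, prefix: str) -> None:
            for name, v in mod.__dict__.items():
                key = f"{prefix}{name}"
                if isinstance(v, Tensor) and v.requires_grad:
                    v.data = state[key].astype(v.data.dtype).reshape(v.shape)
                elif isinstance(v, np.ndarray):
                    mod.__dict__[name] = state[key].astype(v.dtype).reshape(v.shape)
                elif isinstance(v, Module):
                    visit(v, key + ".")
                elif isinstance(v, (list, tuple)):
                    for i, item in enumerate(v):
                        if isinstance(item, Module):
                            visit(item, f"{key}.{i}.")

        visit(self, "")


class Conv3d(Module):
    """Stride-1 3x3x3 (by default) convolution, He-normal init."""

    def __init__(self, c_in: int, c_out: int, kernel: int = 3, pad: int | None = None,
                 rng: np.random.Generator | None = None, dtype=np.float32):
        super().__init__()
        rng = rng or np.random.default_rng()
        fan_in = c_in * kernel**3
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in),
                       size=(c_out, c_in, kernel, kernel, kernel))
        self.w = Tensor(w.astype(dtype), requires_grad=True)
        self.b = Tensor(np.zeros(c_out, dtype=dtype), requires_grad=True)
        self.pad = kernel // 2 if pad is None else pad

    def __call__(self, x: Tensor) -> Tensor:
        return ag.conv3d(x, self.w, self.b, pad=self.pad)


class Linear(Module):
    def __init__(self, f_in: int, f_out: int,
                 rng: np.random.Generator | None = None, dtype=np.float32):
        super().__init__()
        rng = rng or np.random.default_rng()
        w = rng.normal(0.0, np.sqrt(2.0 / f_in), size=(f_in, f_out))
        self.w = Tensor(w.astype(dtype), requires_grad=True)
        self.b = Tensor(np.zeros(f_out, dtype=dtype), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return ag.matmul(x, self.w) + self.b


class BatchNorm3d(Module):
    """Per-channel batch normalization over (N, D, H, W) with running stats."""

    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5,
                 dtype=np.float32):
        super().__init__()
        self.gamma = Tensor(np.ones(c, dtype=dtype), requires_grad=True)
        self.beta = Tensor(np.zeros(c, dtype=dtype), requires_grad=True)
        self.running_mean = np.zeros(c, dtype=dtype)
        self.running_var = np.ones(c, dtype=dtype)
        self.momentum = momentum
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        axes = (0, 2, 3, 4)
        shape = (1, -1, 1, 1, 1)
        if self.training:
            mu = ag.mean(x, axis=axes, keepdims=True)
            var = ag.mean((x - mu) ** 2, axis=axes, keepdims=True)
            m = self.momentum
            self.running_mean = ((1 - m) * self.running_mean
                                 + m * mu.data.reshape(-1))
            self.running_var = ((1 - m) * self.running_var
                                + m * var.data.reshape(-1))
            xhat = (x - mu) * (var + self.eps) ** -0.5
        else:
            mu = self.running_mean.reshape(shape)
            var = self.running_var.reshape(shape)
            xhat = (x - mu) * (1.0 / np.sqrt(var + self.eps))
        return xhat * ag.reshape(self.gamma, shape) + ag.reshape(self.beta, shape)


class ChannelAttention(Module):
    """Dual-descriptor channel attention: parallel global average- and
    max-pooled descriptors pass through a shared two-layer MLP; the summed
    logits gate the channels through a sigmoid."""

    def __init__(self, c: int, reduction: int = 4,
                 rng: np.random.Generator | None = None, dtype=np.float32):
        super().__init__()
        hidden = max(c // reduction, 1)
        self.fc1 = Linear(c, hidden, rng=rng, dtype=dtype)
        self.fc2 = Linear(hidden, c, rng=rng, dtype=dtype)

    def __call__(self, x: Tensor) -> Tensor:
        avg = ag.mean(x, axis=(2, 3, 4))
        mx = ag.amax(x, axis=(2, 3, 4))
        gate = ag.sigmoid(self.fc2(ag.relu(self.fc1(avg)))
                          + self.fc2(ag.relu(self.fc1(mx))))
        return x * ag.reshape(gate, (x.shape[0], x.shape[1], 1, 1, 1))


class Adam:
    """Adam optimizer with bias correction."""

    def __init__(self, params: list[Tensor], lr: float = 2e-5,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def step(self) -> None:
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
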