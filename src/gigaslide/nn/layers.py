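"""Parameterized building blocks on top of the autodiff tape.

A Module is a named, ordered dict of parameters (plus submodules); state is
saved/loaded through flat ``{dotted.name: array}`` mappings so checkpoints
are a plain key-value format.
"""

from __future__ import annotations

import numpy as np

from .tensor import Tensor, gelu, layer_norm


class Module:
    def __init__(self):
        self._params: dict[str, Tensor] = {}
        self._modules: dict[str, "Module"] = {}

    def __setattr__(self, name, value):
        if isinstance(value, Tensor) and value.requires_grad:
            self.__dict__.setdefault("_params", {})[name] = value
        elif isinstance(value, Module):
            self.__dict__.setdefault("_modules", {})[name] = value
        object.__setattr__(self, name, value)

    def named_parameters(self, prefix: str = "") -> dict[str, Tensor]:
        out = {prefix + k: v for k, v in self._params.items()}
        for name, mod in self._modules.items():
            out.update(mod.named_parameters(prefix + name + "."))
        return out

    def parameters(self) -> list[Tensor]:
        return list(self.named_parameters().values())

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.named_parameters().items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = self.named_parameters()
        missing = set(params) ^ set(state)
        if missing:
            raise KeyError(f"state keys do not match parameters: {sorted(missing)}")
        for k, v in params.items():
            arr = np.asarray(state[k])
            if arr.shape != v.data.shape:
                raise ValueError(f"shape mismatch for {k}: {arr.shape} vs {v.data.shape}")
            v.data = arr.astype(v.data.dtype, copy=True)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None


class ModuleList(Module):
    def __init__(self, modules=()):
        super().__init__()
        self._items: list[Module] = []
        for m in modules:
            self.append(m)

    def append(self, module: Module) -> None:
        self._modules[str(len(self._items))] = module
        self._items.append(module)

    def __iter__(self):
        return iter(self._items)

    def __len__(self):
        return len(self._items)

    def __getitem__(self, i):
        return self._items[i]


def _param(rng: np.random.Generator, *shape, scale: float | None = None) -> Tensor:
    if scale is None:
        scale = 1.0 / np.sqrt(shape[0]) if len(shape) > 1 else 0.02
    return Tensor(rng.normal(0.0, scale, size=shape).astype(np.float64), requires_grad=True)


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator, bias: bool = True):
        super().__init__()
        self.weight = _param(rng, d_in, d_out)
        self.bias = Tensor(np.zeros(d_out), requires_grad=True) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        y = x @ self.weight
        return y + self.bias if self.bias is not None else y


class LayerNorm(Module):
    def __init__(self, dim: int):
        super().__init__()
        self.gain = Tensor(np.ones(dim), requires_grad=True)
        self.bias = Tensor(np.zeros(dim), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return layer_norm(x, self.gain, self.bias)


class Embedding(Module):
    """Learned lookup table; rows gathered by integer index."""

    def __init__(self, n: int, dim: int, rng: np.random.Generator):
        super().__init__()
        self.table = _param(rng, n, dim, scale=0.02)

    def __call__(self, idx: np.ndarray) -> Tensor:
        return self.table[np.asarray(idx, dtype=np.intp)]


class MLP(Module):
    """Transformer feed-forward: Linear -> GELU -> Linear, width ratio 4."""

    def __init__(self, dim: int, rng: np.random.Generator, ratio: int = 4):
        super().__init__()
        self.fc1 = Linear(dim, ratio * dim, rng)
        self.fc2 = Linear(ratio * dim, dim, rng)

    def __call__(self, x: Tensor) -> Tensor:
        return self.fc2(gelu(self.fc1(x)))
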