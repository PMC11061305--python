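"""Minimal reverse-mode automatic differentiation on numpy arrays.

This is the tensor core the segmentation layers are built on: a ``Tensor``
wrapping a float64 ndarray with a gradient slot, a handful of differentiable
primitives (broadcasting arithmetic, batched matmul, reductions, slicing,
padding, pooling/upsampling, 2-D convolution), and a ``Module``/``Parameter``
object model plus an Adam optimizer.  Everything runs on the CPU in double
precision; the operator set is exactly what the attention blocks and the
U-Net backbone need, nothing more.
"""

from __future__ import annotations

import numpy as np


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` back down to ``shape`` after numpy broadcasting."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy array with reverse-mode gradient tracking."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False, _prev: tuple = ()):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._prev = _prev

    # -- construction helpers -------------------------------------------------

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    # -- autograd engine ------------------------------------------------------

    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(grad, dtype=np.float64)
        else:
            self.grad += grad

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Backpropagate from this tensor through the recorded graph."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for child in node._prev:
                if id(child) not in seen:
                    stack.append((child, False))
        self._accumulate(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- arithmetic -----------------------------------------------------------

    def __add__(self, other) -> "Tensor":
        other = astensor(other)
        out = Tensor(self.data + other.data, _prev=(self, other))

        def _bw(g):
            self._accumulate(_unbroadcast(g, self.data.shape))
            other._accumulate(_unbroadcast(g, other.data.shape))

        out._backward = _bw
        return out

    __radd__ = __add__

    def __neg__(self) -> "Tensor":
        out = Tensor(-self.data, _prev=(self,))
        out._backward = lambda g: self._accumulate(-g)
        return out

    def __sub__(self, other) -> "Tensor":
        return self + (-astensor(other))

    def __rsub__(self, other) -> "Tensor":
        return astensor(other) + (-self)

    def __mul__(self, other) -> "Tensor":
        other = astensor(other)
        out = Tensor(self.data * other.data, _prev=(self, other))

        def _bw(g):
            self._accumulate(_unbroadcast(g * other.data, self.data.shape))
            other._accumulate(_unbroadcast(g * self.data, other.data.shape))

        out._backward = _bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other) -> "Tensor":
        other = astensor(other)
        out = Tensor(self.data / other.data, _prev=(self, other))

        def _bw(g):
            self._accumulate(_unbroadcast(g / other.data, self.data.shape))
            other._accumulate(
                _unbroadcast(-g * self.data / other.data**2, other.data.shape)
            )

        out._backward = _bw
        return out

    def __rtruediv__(self, other) -> "Tensor":
        return astensor(other) / self

    def __matmul__(self, other) -> "Tensor":
        other = astensor(other)
        out = Tensor(self.data @ other.data, _prev=(self, other))

        def _bw(g):
            self._accumulate(
                _unbroadcast(g @ np.swapaxes(other.data, -1, -2), self.data.shape)
            )
            other._accumulate(
                _unbroadcast(np.swapaxes(self.data, -1, -2) @ g, other.data.shape)
            )

        out._backward = _bw
        return out

    # -- shape manipulation ---------------------------------------------------

    def reshape(self, *shape) -> "Tensor":
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = Tensor(self.data.reshape(shape), _prev=(self,))
        out._backward = lambda g: self._accumulate(g.reshape(self.data.shape))
        return out

    def moveaxis(self, src, dst) -> "Tensor":
        out = Tensor(np.moveaxis(self.data, src, dst), _prev=(self,))
        out._backward = lambda g: self._accumulate(np.moveaxis(g, dst, src))
        return out

    def swapaxes(self, a, b) -> "Tensor":
        out = Tensor(np.swapaxes(self.data, a, b), _prev=(self,))
        out._backward = lambda g: self._accumulate(np.swapaxes(g, a, b))
        return out

    def __getitem__(self, idx) -> "Tensor":
        out = Tensor(self.data[idx], _prev=(self,))
        parts = idx if isinstance(idx, tuple) else (idx,)
        basic = all(isinstance(p, (slice, int, type(Ellipsis), type(None)))
                    for p in parts)

        def _bw(g):
            full = np.zeros_like(self.data)
            if basic:   # slices never alias, so plain assignment-add suffices
                full[idx] += g
            else:
                np.add.at(full, idx, g)
            self._accumulate(full)

        out._backward = _bw
        return out

    # -- reductions -----------------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), _prev=(self,))

        def _bw(g):
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.data.shape).copy())
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.data.shape).copy())

        out._backward = _bw
        return out

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in np.atleast_1d(axis)]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    # -- elementwise nonlinearities ------------------------------------------

    def exp(self) -> "Tensor":
        out = Tensor(np.exp(self.data), _prev=(self,))
        out._backward = lambda g: self._accumulate(g * out.data)
        return out

    def log(self) -> "Tensor":
        out = Tensor(np.log(self.data), _prev=(self,))
        out._backward = lambda g: self._accumulate(g / self.data)
        return out

    def sigmoid(self) -> "Tensor":
        s = 1.0 / (1.0 + np.exp(-np.clip(self.data, -500, 500)))
        out = Tensor(s, _prev=(self,))
        out._backward = lambda g: self._accumulate(g * s * (1.0 - s))
        return out

    def relu(self) -> "Tensor":
        out = Tensor(np.maximum(self.data, 0.0), _prev=(self,))
        out._backward = lambda g: self._accumulate(g * (self.data > 0))
        return out

    def clip(self, lo: float, hi: float) -> "Tensor":
        out = Tensor(np.clip(self.data, lo, hi), _prev=(self,))
        mask = (self.data >= lo) & (self.data <= hi)
        out._backward = lambda g: self._accumulate(g * mask)
        return out


def astensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


# ---------------------------------------------------------------------------
# composite / structural ops
# ---------------------------------------------------------------------------


def softmax(t: Tensor, axis: int = -1) -> Tensor:
    """Numerically stable softmax (per-position max subtracted as a constant;
    softmax is invariant to the shift, so the gradient is unchanged)."""
    m = Tensor(t.data.max(axis=axis, keepdims=True))
    e = (t - m).exp()
    return e / e.sum(axis=axis, keepdims=True)


def concat(tensors: list[Tensor], axis: int = 0) -> Tensor:
    tensors = [astensor(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                 _prev=tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]

    def _bw(g):
        start = 0
        for t, s in zip(tensors, sizes):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(start, start + s)
            t._accumulate(g[tuple(sl)])
            start += s

    out._backward = _bw
    return out


def take(t: Tensor, idx: np.ndarray) -> Tensor:
    """Gather rows ``t[idx]`` with scatter-add backward (used to expand
    relative-offset positional tables into pairwise tables)."""
    out = Tensor(t.data[idx], _prev=(t,))

    def _bw(g):
        full = np.zeros_like(t.data)
        np.add.at(full, idx, g)
        t._accumulate(full)

    out._backward = _bw
    return out


def pad2d(t: Tensor, p: int) -> Tensor:
    """Zero-pad the last two axes by ``p`` on each side."""
    width = [(0, 0)] * (t.ndim - 2) + [(p, p), (p, p)]
    out = Tensor(np.pad(t.data, width), _prev=(t,))
    sl = (Ellipsis, slice(p, -p), slice(p, -p))
    out._backward = lambda g: t._accumulate(g[sl])
    return out


def avg_pool2d(t: Tensor) -> Tensor:
    """2x2 average pooling over the last two axes (sides must be even)."""
    *lead, H, W = t.shape
    x = t.reshape(*lead, H // 2, 2, W // 2, 2)
    return x.mean(axis=(t.ndim - 1, t.ndim + 1))


def upsample2(t: Tensor) -> Tensor:
    """Nearest-neighbour 2x upsampling of the last two axes."""
    *lead, H, W = t.shape
    data = np.repeat(np.repeat(t.data, 2, axis=-2), 2, axis=-1)
    out = Tensor(data, _prev=(t,))

    def _bw(g):
        g = g.reshape(*lead, H, 2, W, 2)
        t._accumulate(g.sum(axis=(-3, -1)))

    out._backward = _bw
    return out


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None, padding: int = 0) -> Tensor:
    """2-D convolution (cross-correlation), stride 1.

    ``x`` is (B, C, H, W), ``w`` is (O, C, kh, kw); output (B, O, H', W').
    Built from slicing + batched matmul primitives so the backward pass
    comes for free.
    """
    x = astensor(x)
    w = astensor(w)
    O, C, kh, kw = w.shape
    if padding:
        x = pad2d(x, padding)
    B, _, Hp, Wp = x.shape
    Ho, Wo = Hp - kh + 1, Wp - kw + 1
    out = None
    for ki in range(kh):
        for kj in range(kw):
            patch = x[:, :, ki:ki + Ho, kj:kj + Wo]          # (B,C,Ho,Wo)
            flat = patch.reshape(B, C, Ho * Wo)
            wk = w[:, :, ki, kj]                             # (O,C)
            term = wk @ flat                                 # (B,O,Ho*Wo)
            out = term if out is None else out + term
    out = out.reshape(B, O, Ho, Wo)
    if b is not None:
        out = out + astensor(b).reshape(1, O, 1, 1)
    return out


# ---------------------------------------------------------------------------
# modules, parameters, optimizer
# ---------------------------------------------------------------------------


class Parameter(Tensor):
    """A tensor registered as learnable."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Tree of parameters with recursive traversal, in attribute order."""

    def parameters(self) -> list[Parameter]:
        # dedupe by identity so weight-shared submodules are stepped once
        seen: set[int] = set()
        out: list[Parameter] = []
        for _, p in self.named_parameters():
            if id(p) not in seen:
                seen.add(id(p))
                out.append(p)
        return out

    def named_parameters(self, prefix: str = "") -> list[tuple[str, Parameter]]:
        found: list[tuple[str, Parameter]] = []
        for name, val in vars(self).items():
            key = f"{prefix}{name}"
            if isinstance(val, Parameter):
                found.append((key, val))
            elif isinstance(val, Module):
                found.extend(val.named_parameters(prefix=f"{key}."))
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        found.extend(item.named_parameters(prefix=f"{key}.{i}."))
                    elif isinstance(item, Parameter):
                        found.append((f"{key}.{i}", item))
        return found

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: p.data.copy() for k, p in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = dict(self.named_parameters())
        missing = set(own) - set(state)
        if missing:
            raise KeyError(f"missing parameters in state dict: {sorted(missing)}")
        for k, p in own.items():
            arr = np.asarray(state[k], dtype=np.float64)
            if arr.shape != p.data.shape:
                raise ValueError(
                    f"shape mismatch for {k}: checkpoint {arr.shape} vs model {p.data.shape}"
                )
            p.data = arr.copy()

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Adam:
    """Adam optimizer with the usual defaults (beta1=0.9, beta2=0.999)."""

    def __init__(self, params: list[Parameter], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

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


class SGD:
    """Plain stochastic gradient descent (optional alternative to Adam)."""

    def __init__(self, params: list[Parameter], lr: float = 1e-3):
        self.params = list(params)
        self.lr = lr

    def step(self) -> None:
        for p in self.params:
            if p.grad is not None:
                p.data = p.data - self.lr * p.grad
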