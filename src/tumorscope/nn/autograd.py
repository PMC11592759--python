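"""Reverse-mode automatic differentiation over numpy arrays.

A deliberately small tape-based engine: every :class:`Tensor` wraps a float64
numpy array and remembers how to push gradients back to its parents.  All
networks in this package (segmentation policy, critics, detection head,
sequence encoder, volume generator) are built from the primitives here, which
keeps the whole training stack dependency-free and lets gradient correctness
be verified against central finite differences at double precision.

Only the operations the package needs are implemented; convolutions use an
explicit loop over kernel taps (kernels are 3x3 or 3x3x3 here, so at most 27
vectorised numpy updates), which is exact and fast at the image sizes this
toolkit targets.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "stack", "no_grad", "is_grad_enabled"]

_GRAD_ENABLED = True


class no_grad:
    """Context manager disabling graph construction (inference mode)."""

    def __enter__(self):
        global _GRAD_ENABLED
        self._prev = _GRAD_ENABLED
        _GRAD_ENABLED = False
        return self

    def __exit__(self, *exc):
        global _GRAD_ENABLED
        _GRAD_ENABLED = self._prev
        return False


def is_grad_enabled() -> bool:
    return _GRAD_ENABLED


def _as_array(x) -> np.ndarray:
    if isinstance(x, Tensor):
        raise TypeError("expected raw array, got Tensor")
    return np.asarray(x, dtype=np.float64)


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (reverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple = ()

    # ------------------------------------------------------------------ infra
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def zero_grad(self) -> None:
        self.grad = None

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def _make(self, data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if _GRAD_ENABLED and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def backward(self, grad=None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("grad must be supplied for non-scalar output")
            grad = np.ones_like(self.data)
        else:
            grad = np.asarray(grad, dtype=np.float64)

        # iterative topological sort (post-order DFS, recursion-free)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack_: list[tuple[Tensor, bool]] = [(self, False)]
        while stack_:
            node, processed = stack_.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack_.append((node, True))
            for p in node._parents:
                stack_.append((p, False))

        self.grad = grad if self.grad is None else self.grad + grad
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accum(self, grad: np.ndarray) -> None:
        grad = _unbroadcast(grad, self.data.shape)
        self.grad = grad if self.grad is None else self.grad + grad

    # ------------------------------------------------------------- arithmetic
    def __add__(self, other):
        other = Tensor._lift(other)
        out = self._make(self.data + other.data, (self, other), None)

        def backward(g):
            if self.requires_grad:
                self._accum(g)
            if other.requires_grad:
                other._accum(g)

        out._backward = backward if out.requires_grad else None
        return out

    __radd__ = __add__

    def __neg__(self):
        out = self._make(-self.data, (self,), None)

        def backward(g):
            self._accum(-g)

        out._backward = backward if out.requires_grad else None
        return out

    def __sub__(self, other):
        return self + (-Tensor._lift(other))

    def __rsub__(self, other):
        return Tensor._lift(other) + (-self)

    def __mul__(self, other):
        other = Tensor._lift(other)
        out = self._make(self.data * other.data, (self, other), None)

        def backward(g):
            if self.requires_grad:
                self._accum(g * other.data)
            if other.requires_grad:
                other._accum(g * self.data)

        out._backward = backward if out.requires_grad else None
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = Tensor._lift(other)
        out = self._make(self.data / other.data, (self, other), None)

        def backward(g):
            if self.requires_grad:
                self._accum(g / other.data)
            if other.requires_grad:
                other._accum(-g * self.data / other.data**2)

        out._backward = backward if out.requires_grad else None
        return out

    def __rtruediv__(self, other):
        return Tensor._lift(other) / self

    def __pow__(self, p: float):
        out = self._make(self.data**p, (self,), None)

        def backward(g):
            self._accum(g * p * self.data ** (p - 1))

        out._backward = backward if out.requires_grad else None
        return out

    def __matmul__(self, other):
        other = Tensor._lift(other)
        out = self._make(self.data @ other.data, (self, other), None)

        def backward(g):
            if self.requires_grad:
                self._accum(g @ np.swapaxes(other.data, -1, -2))
            if other.requires_grad:
                other._accum(np.swapaxes(self.data, -1, -2) @ g)

        out._backward = backward if out.requires_grad else None
        return out

    # ------------------------------------------------------------ elementwise
    def exp(self):
        val = np.exp(self.data)
        out = self._make(val, (self,), None)

        def backward(g):
            self._accum(g * val)

        out._backward = backward if out.requires_grad else None
        return out

    def log(self):
        out = self._make(np.log(self.data), (self,), None)

        def backward(g):
            self._accum(g / self.data)

        out._backward = backward if out.requires_grad else None
        return out

    def tanh(self):
        val = np.tanh(self.data)
        out = self._make(val, (self,), None)

        def backward(g):
            self._accum(g * (1.0 - val**2))

        out._backward = backward if out.requires_grad else None
        return out

    def sigmoid(self):
        val = 1.0 / (1.0 + np.exp(-self.data))
        out = self._make(val, (self,), None)

        def backward(g):
            self._accum(g * val * (1.0 - val))

        out._backward = backward if out.requires_grad else None
        return out

    def relu(self):
        mask = self.data > 0
        out = self._make(self.data * mask, (self,), None)

        def backward(g):
            self._accum(g * mask)

        out._backward = backward if out.requires_grad else None
        return out

    def leaky_relu(self, slope: float = 0.2):
        factor = np.where(self.data > 0, 1.0, slope)
        out = self._make(self.data * factor, (self,), None)

        def backward(g):
            self._accum(g * factor)

        out._backward = backward if out.requires_grad else None
        return out

    # -------------------------------------------------------------- reductions
    def sum(self, axis=None, keepdims=False):
        out = self._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), None)

        def backward(g):
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape).copy())
            else:
                if not keepdims:
                    g = np.expand_dims(g, axis)
                self._accum(np.broadcast_to(g, self.data.shape).copy())

        out._backward = backward if out.requires_grad else None
        return out

    def mean(self, axis=None, keepdims=False):
        if axis is None:
            n = self.data.size
        else:
            axes = (axis,) if isinstance(axis, int) else axis
            n = int(np.prod([self.data.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) / float(n)

    # ------------------------------------------------------------ shape moves
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = self._make(self.data.reshape(shape), (self,), None)

        def backward(g):
            self._accum(g.reshape(self.data.shape))

        out._backward = backward if out.requires_grad else None
        return out

    def transpose(self, axes):
        out = self._make(self.data.transpose(axes), (self,), None)
        inv = np.argsort(axes)

        def backward(g):
            self._accum(g.transpose(inv))

        out._backward = backward if out.requires_grad else None
        return out

    def __getitem__(self, idx):
        out = self._make(self.data[idx], (self,), None)

        def backward(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            self._accum(full)

        out._backward = backward if out.requires_grad else None
        return out

    def take_pixels(self, row_idx: np.ndarray, col_idx: np.ndarray):
        """Gather pixels from a (C, H, W) tensor: result (C, *idx.shape)."""
        out = self._make(self.data[:, row_idx, col_idx], (self,), None)

        def backward(g):
            full = np.zeros_like(self.data)
            np.add.at(full, (slice(None), row_idx, col_idx), g)
            self._accum(full)

        out._backward = backward if out.requires_grad else None
        return out

    # ---------------------------------------------------------- convolutions
    def conv2d(self, weight: "Tensor", bias: "Tensor | None" = None,
               dilation: int = 1, padding: str = "same"):
        """2-D cross-correlation. x: (N,C,H,W), weight: (O,C,kh,kw), stride 1."""
        x, w = self, weight
        N, C, H, W = x.data.shape
        O, Cw, kh, kw = w.data.shape
        if C != Cw:
            raise ValueError(f"channel mismatch: input {C}, weight {Cw}")
        d = int(dilation)
        if padding == "same":
            ph, pw = d * (kh - 1) // 2, d * (kw - 1) // 2
        elif padding == "valid":
            ph = pw = 0
        else:
            raise ValueError(f"unknown padding {padding!r}")
        xp = np.pad(x.data, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
        Ho = H + 2 * ph - d * (kh - 1)
        Wo = W + 2 * pw - d * (kw - 1)
        out_data = np.zeros((N, O, Ho, Wo))
        for i in range(kh):
            for j in range(kw):
                patch = xp[:, :, i * d:i * d + Ho, j * d:j * d + Wo]
                out_data += np.einsum("nchw,oc->nohw", patch, w.data[:, :, i, j],
                                      optimize=True)
        if bias is not None:
            out_data += bias.data.reshape(1, O, 1, 1)
        parents = (x, w) if bias is None else (x, w, bias)
        out = self._make(out_data, parents, None)

        def backward(g):
            if x.requires_grad:
                gx = np.zeros_like(xp)
                for i in range(kh):
                    for j in range(kw):
                        gx[:, :, i * d:i * d + Ho, j * d:j * d + Wo] += np.einsum(
                            "nohw,oc->nchw", g, w.data[:, :, i, j], optimize=True)
                if ph or pw:
                    gx = gx[:, :, ph:ph + H, pw:pw + W]
                x._accum(gx)
            if w.requires_grad:
                gw = np.zeros_like(w.data)
                for i in range(kh):
                    for j in range(kw):
                        patch = xp[:, :, i * d:i * d + Ho, j * d:j * d + Wo]
                        gw[:, :, i, j] = np.einsum("nohw,nchw->oc", g, patch,
                                                   optimize=True)
                w._accum(gw)
            if bias is not None and bias.requires_grad:
                bias._accum(g.sum(axis=(0, 2, 3)))

        out._backward = backward if out.requires_grad else None
        return out

    def conv3d(self, weight: "Tensor", bias: "Tensor | None" = None,
               dilation: int = 1, padding: str = "same"):
        """3-D cross-correlation. x: (N,C,D,H,W), weight: (O,C,kd,kh,kw)."""
        x, w = self, weight
        N, C, D, H, W = x.data.shape
        O, Cw, kd, kh, kw = w.data.shape
        if C != Cw:
            raise ValueError(f"channel mismatch: input {C}, weight {Cw}")
        dl = int(dilation)
        if padding == "same":
            pd, ph, pw = (dl * (kd - 1) // 2, dl * (kh - 1) // 2, dl * (kw - 1) // 2)
        elif padding == "valid":
            pd = ph = pw = 0
        else:
            raise ValueError(f"unknown padding {padding!r}")
        xp = np.pad(x.data, ((0, 0), (0, 0), (pd, pd), (ph, ph), (pw, pw)))
        Do = D + 2 * pd - dl * (kd - 1)
        Ho = H + 2 * ph - dl * (kh - 1)
        Wo = W + 2 * pw - dl * (kw - 1)
        out_data = np.zeros((N, O, Do, Ho, Wo))
        for a in range(kd):
            for i in range(kh):
                for j in range(kw):
                    patch = xp[:, :, a * dl:a * dl + Do, i * dl:i * dl + Ho,
                               j * dl:j * dl + Wo]
                    out_data += np.einsum("ncdhw,oc->nodhw", patch,
                                          w.data[:, :, a, i, j], optimize=True)
        if bias is not None:
            out_data += bias.data.reshape(1, O, 1, 1, 1)
        parents = (x, w) if bias is None else (x, w, bias)
        out = self._make(out_data, parents, None)

        def backward(g):
            if x.requires_grad:
                gx = np.zeros_like(xp)
                for a in range(kd):
                    for i in range(kh):
                        for j in range(kw):
                            gx[:, :, a * dl:a * dl + Do, i * dl:i * dl + Ho,
                               j * dl:j * dl + Wo] += np.einsum(
                                "nodhw,oc->ncdhw", g, w.data[:, :, a, i, j],
                                optimize=True)
                gx = gx[:, :, pd:pd + D, ph:ph + H, pw:pw + W]
                x._accum(gx)
            if w.requires_grad:
                gw = np.zeros_like(w.data)
                for a in range(kd):
                    for i in range(kh):
                        for j in range(kw):
                            patch = xp[:, :, a * dl:a * dl + Do,
                                       i * dl:i * dl + Ho, j * dl:j * dl + Wo]
                            gw[:, :, a, i, j] = np.einsum("nodhw,ncdhw->oc", g,
                                                          patch, optimize=True)
                w._accum(gw)
            if bias is not None and bias.requires_grad:
                bias._accum(g.sum(axis=(0, 2, 3, 4)))

        out._backward = backward if out.requires_grad else None
        return out

    # ------------------------------------------------------- pooling/resizing
    def avg_pool2d(self, k: int = 2):
        N, C, H, W = self.data.shape
        if H % k or W % k:
            raise ValueError(f"pooling size {k} must divide spatial dims {H}x{W}")
        val = self.data.reshape(N, C, H // k, k, W // k, k).mean(axis=(3, 5))
        out = self._make(val, (self,), None)

        def backward(g):
            g_up = np.repeat(np.repeat(g, k, axis=2), k, axis=3) / (k * k)
            self._accum(g_up)

        out._backward = backward if out.requires_grad else None
        return out

    def upsample2d(self, k: int = 2):
        val = np.repeat(np.repeat(self.data, k, axis=2), k, axis=3)
        out = self._make(val, (self,), None)

        def backward(g):
            N, C, H, W = self.data.shape
            self._accum(g.reshape(N, C, H, k, W, k).sum(axis=(3, 5)))

        out._backward = backward if out.requires_grad else None
        return out

    def avg_pool3d(self, k: int = 2):
        N, C, D, H, W = self.data.shape
        if D % k or H % k or W % k:
            raise ValueError(f"pooling size {k} must divide dims {D}x{H}x{W}")
        val = self.data.reshape(N, C, D // k, k, H // k, k, W // k, k).mean(
            axis=(3, 5, 7))
        out = self._make(val, (self,), None)

        def backward(g):
            g_up = g
            for ax in (2, 3, 4):
                g_up = np.repeat(g_up, k, axis=ax)
            self._accum(g_up / (k**3))

        out._backward = backward if out.requires_grad else None
        return out

    def upsample3d(self, k: int = 2):
        val = self.data
        for ax in (2, 3, 4):
            val = np.repeat(val, k, axis=ax)
        out = self._make(val, (self,), None)

        def backward(g):
            N, C, D, H, W = self.data.shape
            self._accum(
                g.reshape(N, C, D, k, H, k, W, k).sum(axis=(3, 5, 7)))

        out._backward = backward if out.requires_grad else None
        return out


def concat(tensors: list, axis: int = 0) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    data = np.concatenate([t.data for t in tensors], axis=axis)
    out = tensors[0]._make(data, tuple(tensors), None)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        pieces = np.split(g, splits, axis=axis)
        for t, piece in zip(tensors, pieces):
            if t.requires_grad:
                t._accum(piece)

    out._backward = backward if out.requires_grad else None
    return out


def stack(tensors: list, axis: int = 0) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    data = np.stack([t.data for t in tensors], axis=axis)
    out = tensors[0]._make(data, tuple(tensors), None)

    def backward(g):
        pieces = np.split(g, len(tensors), axis=axis)
        for t, piece in zip(tensors, pieces):
            if t.requires_grad:
                t._accum(np.squeeze(piece, axis=axis))

    out._backward = backward if out.requires_grad else None
    return out
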