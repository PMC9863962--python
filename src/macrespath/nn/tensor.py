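"""Minimal reverse-mode autodiff on NumPy arrays.

A :class:`Tensor` wraps a float32 ndarray and records the operations applied
to it on a tape; :meth:`Tensor.backward` replays the tape in reverse
topological order.  Only the operations the model zoo needs are implemented —
elementwise arithmetic, matmul, reductions, reshaping/slicing/concatenation,
relu/sigmoid/exp/log, strided 2-D convolution, 2x2 max pooling, adaptive
average pooling and nearest-neighbour upsampling.  Spatial arrays are channels-last (NHWC).
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
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
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False, _prev: tuple = ()):
        # float64 ndarrays keep their precision (loss algebra); python
        # scalars and non-float arrays live in float32 (network path)
        arr = np.asarray(data)
        if arr.dtype != np.float64 or type(data) in (bool, int, float):
            arr = arr.astype(np.float32, copy=False)
        self.data = arr
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._prev = _prev

    # -- bookkeeping ------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        if self.data.size != 1:
            raise ValueError("item() requires a single-element tensor")
        return float(self.data.reshape(()))

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(g, copy=True)
        else:
            self.grad += g

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._prev:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- helpers ----------------------------------------------------------
    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def _make(self, data, backward, prev) -> "Tensor":
        req = any(p.requires_grad for p in prev)
        out = Tensor(data, requires_grad=req, _prev=tuple(p for p in prev if p.requires_grad))
        if req:
            out._backward = backward
        return out

    # -- arithmetic -------------------------------------------------------
    def __add__(self, other):
        if type(other) in (bool, int, float):
            # python scalars use weak promotion: the tensor dtype survives
            def backward_s(g):
                self._accum(g)

            return self._make(self.data + other, backward_s, (self,))
        o = self._lift(other)

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.shape))
            if o.requires_grad:
                o._accum(_unbroadcast(g, o.shape))

        return self._make(self.data + o.data, backward, (self, o))

    __radd__ = __add__

    def __mul__(self, other):
        if type(other) in (bool, int, float):
            def backward_s(g):
                self._accum(g * other)

            return self._make(self.data * other, backward_s, (self,))
        o = self._lift(other)

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * o.data, self.shape))
            if o.requires_grad:
                o._accum(_unbroadcast(g * self.data, o.shape))

        return self._make(self.data * o.data, backward, (self, o))

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        if type(other) in (bool, int, float):
            return self + (-other)
        return self + (-self._lift(other))

    def __rsub__(self, other):
        if type(other) in (bool, int, float):
            return (-self) + other
        return self._lift(other) + (-self)

    def __truediv__(self, other):
        o = self._lift(other)
        return self * o ** -1.0

    def __rtruediv__(self, other):
        return self._lift(other) * self ** -1.0

    def __pow__(self, p: float):
        assert np.isscalar(p)

        def backward(g):
            self._accum(_unbroadcast(g * p * self.data ** (p - 1.0), self.shape))

        return self._make(self.data ** p, backward, (self,))

    def __matmul__(self, other):
        o = self._lift(other)

        def backward(g):
            if self.requires_grad:
                self._accum(g @ o.data.T)
            if o.requires_grad:
                o._accum(self.data.T @ g)

        return self._make(self.data @ o.data, backward, (self, o))

    # -- elementwise nonlinear -------------------------------------------
    def exp(self):
        out_data = np.exp(self.data)

        def backward(g):
            self._accum(g * out_data)

        return self._make(out_data, backward, (self,))

    def log(self):
        def backward(g):
            self._accum(g / self.data)

        return self._make(np.log(self.data), backward, (self,))

    def relu(self):
        mask = self.data > 0

        def backward(g):
            self._accum(g * mask)

        return self._make(self.data * mask, backward, (self,))

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-self.data))

        def backward(g):
            self._accum(g * out_data * (1.0 - out_data))

        return self._make(out_data, backward, (self,))

    # -- reductions / shaping --------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        def backward(g):
            gg = g
            if axis is not None and not keepdims:
                gg = np.expand_dims(gg, axis)
            self._accum(np.ascontiguousarray(np.broadcast_to(gg, self.shape)))

        return self._make(np.asarray(self.data.sum(axis=axis, keepdims=keepdims)),
                          backward, (self,))

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        orig = self.shape

        def backward(g):
            self._accum(g.reshape(orig))

        return self._make(self.data.reshape(shape), backward, (self,))

    def transpose(self, *axes):
        inv = np.argsort(axes)

        def backward(g):
            self._accum(g.transpose(inv))

        return self._make(self.data.transpose(axes), backward, (self,))

    def __getitem__(self, idx):
        def backward(g):
            full = np.zeros(self.shape, dtype=np.float32)
            full[idx] = g
            self._accum(full)

        return self._make(self.data[idx], backward, (self,))

    # -- spatial ops (NHWC) ----------------------------------------------
    def conv2d(self, weight: "Tensor", bias: "Tensor | None" = None,
               stride: int = 1, padding: int = 0) -> "Tensor":
        """Cross-correlation of an NHWC input with an (O, C, kh, kw) kernel.

        Computed as kh*kw shifted GEMMs in channels-last layout, which keeps
        every copy a contiguous memcpy and every product a BLAS call.
        """
        x, w = self, weight
        N, H, W, C = x.shape
        O, Cw, kh, kw = w.shape
        assert C == Cw, f"channel mismatch {C} vs {Cw}"
        s, p = stride, padding
        xp = np.pad(x.data, ((0, 0), (p, p), (p, p), (0, 0))) if p else x.data
        Ho = (xp.shape[1] - kh) // s + 1
        Wo = (xp.shape[2] - kw) // s + 1
        wk = np.ascontiguousarray(w.data.transpose(2, 3, 1, 0))  # kh,kw,C,O
        acc = np.zeros((N * Ho * Wo, O), dtype=np.float32)
        for i in range(kh):
            for j in range(kw):
                xs = np.ascontiguousarray(
                    xp[:, i:i + s * Ho:s, j:j + s * Wo:s, :]).reshape(-1, C)
                acc += xs @ wk[i, j]
        if bias is not None:
            acc += bias.data
        out = acc.reshape(N, Ho, Wo, O)

        def backward(g):
            gmat = g.reshape(N * Ho * Wo, O)
            if w.requires_grad:
                dw = np.empty((kh, kw, C, O), dtype=np.float32)
                for i in range(kh):
                    for j in range(kw):
                        xs = np.ascontiguousarray(
                            xp[:, i:i + s * Ho:s, j:j + s * Wo:s, :]).reshape(-1, C)
                        dw[i, j] = xs.T @ gmat
                w._accum(dw.transpose(3, 2, 0, 1))
            if bias is not None and bias.requires_grad:
                bias._accum(gmat.sum(axis=0))
            if x.requires_grad:
                dxp = np.zeros_like(xp)
                for i in range(kh):
                    for j in range(kw):
                        dxp[:, i:i + s * Ho:s, j:j + s * Wo:s, :] += \
                            (gmat @ wk[i, j].T).reshape(N, Ho, Wo, C)
                x._accum(dxp[:, p:p + H, p:p + W, :] if p else dxp)

        prev = (x, w) if bias is None else (x, w, bias)
        return self._make(out, backward, prev)

    def maxpool2(self) -> "Tensor":
        """2x2 max pooling, stride 2; spatial dims must be even."""
        N, H, W, C = self.shape
        assert H % 2 == 0 and W % 2 == 0, "maxpool2 requires even spatial dims"
        r = self.data.reshape(N, H // 2, 2, W // 2, 2, C)
        out = r.max(axis=(2, 4))
        mask = (r == out[:, :, None, :, None, :])
        # break ties: keep only the first max per window
        flat = mask.transpose(0, 1, 3, 5, 2, 4).reshape(N, H // 2, W // 2, C, 4)
        first = np.cumsum(flat, axis=-1) == 1
        mask = ((flat & first)
                .reshape(N, H // 2, W // 2, C, 2, 2)
                .transpose(0, 1, 4, 2, 5, 3))

        def backward(g):
            gg = mask * g[:, :, None, :, None, :]
            self._accum(gg.reshape(N, H, W, C))

        return self._make(out, backward, (self,))

    def adaptive_avg_pool(self, grid: int) -> "Tensor":
        """Average-pool to a (grid x grid) output, torch-style bin edges."""
        N, H, W, C = self.shape
        if H < grid or W < grid:
            raise ValueError(f"input {H}x{W} smaller than pooling grid {grid}")
        hb = [(i * H // grid, -(-(i + 1) * H // grid)) for i in range(grid)]
        wb = [(j * W // grid, -(-(j + 1) * W // grid)) for j in range(grid)]
        out = np.empty((N, grid, grid, C), dtype=np.float32)
        for i, (h0, h1) in enumerate(hb):
            for j, (w0, w1) in enumerate(wb):
                out[:, i, j, :] = self.data[:, h0:h1, w0:w1, :].mean(axis=(1, 2))

        def backward(g):
            dx = np.zeros(self.shape, dtype=np.float32)
            for i, (h0, h1) in enumerate(hb):
                for j, (w0, w1) in enumerate(wb):
                    area = (h1 - h0) * (w1 - w0)
                    dx[:, h0:h1, w0:w1, :] += g[:, i:i + 1, j:j + 1, :] / area
            self._accum(dx)

        return self._make(out, backward, (self,))

    def upsample_nearest2(self) -> "Tensor":
        N, H, W, C = self.shape
        out = self.data.repeat(2, axis=1).repeat(2, axis=2)

        def backward(g):
            self._accum(g.reshape(N, H, 2, W, 2, C).sum(axis=(2, 4)))

        return self._make(out, backward, (self,))


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    sizes = [t.shape[axis] for t in tensors]
    data = np.concatenate([t.data for t in tensors], axis=axis)
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, o0, o1 in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(o0, o1)
                t._accum(g[tuple(sl)])

    req = any(t.requires_grad for t in tensors)
    out = Tensor(data, requires_grad=req,
                 _prev=tuple(t for t in tensors if t.requires_grad))
    if req:
        out._backward = backward
    return out
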