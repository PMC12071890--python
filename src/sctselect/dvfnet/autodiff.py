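"""Minimal reverse-mode automatic differentiation over numpy arrays.

Just enough machinery for a volumetric registration network: elementwise
arithmetic, 3D convolution, average pooling / nearest upsampling, channel
concatenation, batch normalization, PReLU, a differentiable backward-warp
(trilinear sampling, gradients with respect to the displacement), and the
valid-window box filter the SSIM loss is built from.

Tensors are float64 end-to-end: at the volume sizes this package trains on,
exact reproducibility across runs matters more than throughput.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.ndimage import uniform_filter

__all__ = ["Tensor", "conv3d", "avgpool2", "upsample2", "concat", "batchnorm",
           "prelu", "warp3d", "boxfilter_valid", "grad_penalty"]


class Tensor:
    """Array node in the autodiff graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "name")

    def __init__(self, data, requires_grad: bool = False, parents=(), name: str = ""):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        # parents: sequence of (parent_tensor, grad_fn) where grad_fn maps the
        # output gradient to this parent's gradient contribution
        self._parents = tuple(parents)
        self.name = name

    @property
    def shape(self):
        return self.data.shape

    # -- graph construction -------------------------------------------------

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float64))

    def _make(self, data, parents) -> "Tensor":
        needs = any(p.requires_grad or p._parents for p, _ in parents)
        return Tensor(data, parents=parents if needs else (), name="")

    def __add__(self, other):
        o = self._lift(other)
        return self._make(
            self.data + o.data,
            [(self, lambda g: _unbroadcast(g, self.shape)),
             (o, lambda g: _unbroadcast(g, o.shape))],
        )

    __radd__ = __add__

    def __neg__(self):
        return self._make(-self.data, [(self, lambda g: -g)])

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        o = self._lift(other)
        return self._make(
            self.data * o.data,
            [(self, lambda g: _unbroadcast(g * o.data, self.shape)),
             (o, lambda g: _unbroadcast(g * self.data, o.shape))],
        )

    __rmul__ = __mul__

    def __truediv__(self, other):
        o = self._lift(other)
        return self._make(
            self.data / o.data,
            [(self, lambda g: _unbroadcast(g / o.data, self.shape)),
             (o, lambda g: _unbroadcast(-g * self.data / (o.data**2), o.shape))],
        )

    def square(self):
        return self._make(self.data**2, [(self, lambda g: 2.0 * g * self.data)])

    def mean(self):
        n = self.data.size
        return self._make(
            np.asarray(self.data.mean()),
            [(self, lambda g: np.broadcast_to(g / n, self.shape).copy())],
        )

    def sum(self):
        return self._make(
            np.asarray(self.data.sum()),
            [(self, lambda g: np.broadcast_to(g, self.shape).copy())],
        )

    # -- backward pass ------------------------------------------------------

    def backward(self) -> None:
        """Accumulate gradients of this (scalar) tensor into the graph."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()

        def visit(t: Tensor) -> None:
            if id(t) in seen:
                return
            seen.add(id(t))
            for p, _ in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        grads: dict[int, np.ndarray] = {id(self): np.ones_like(self.data)}
        for t in reversed(topo):
            g = grads.pop(id(t), None)
            if g is None:
                continue
            if t.requires_grad:
                t.grad = g if t.grad is None else t.grad + g
            for p, fn in t._parents:
                contrib = fn(g)
                if id(p) in grads:
                    grads[id(p)] = grads[id(p)] + contrib
                else:
                    grads[id(p)] = contrib


def _unbroadcast(grad: np.ndarray, shape) -> np.ndarray:
    """Sum a gradient down to the shape the operand was broadcast from."""
    g = grad
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g.reshape(shape)


# ---------------------------------------------------------------------------
# neural-network operations on (N, C, D, H, W) tensors
# ---------------------------------------------------------------------------


def _corr_same(x: np.ndarray, w: np.ndarray):
    """Same-padded stride-1 correlation of (N,C,D,H,W) with (O,C,k,k,k).

    Returns the (N,O,D,H,W) output and the padded sliding-window view
    (reused for the weight gradient).
    """
    k = w.shape[2]
    p = k // 2
    xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p), (p, p)))
    win = sliding_window_view(xp, (k, k, k), axis=(2, 3, 4))  # N,C,D,H,W,k,k,k (view)
    out = np.tensordot(win, w, axes=([1, 5, 6, 7], [1, 2, 3, 4]))  # N,D,H,W,O
    return np.moveaxis(out, -1, 1), win


def conv3d(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """Same-padded stride-1 3D convolution; w has shape (O, C, k, k, k)."""
    O, C, k, _, _ = w.shape
    if x.shape[1] != C:
        raise ValueError(f"channel mismatch: input {x.shape[1]}, kernel {C}")
    out, win = _corr_same(x.data, w.data)
    out += b.data.reshape(1, -1, 1, 1, 1)

    def grad_x(g):
        # input grad = correlation with the flipped, channel-transposed kernel
        wf = w.data[:, :, ::-1, ::-1, ::-1].transpose(1, 0, 2, 3, 4)
        return _corr_same(g, wf)[0]

    def grad_w(g):
        gw = np.tensordot(win, g, axes=([0, 2, 3, 4], [0, 2, 3, 4]))  # C,k,k,k,O
        return np.moveaxis(gw, -1, 0)

    def grad_b(g):
        return g.sum(axis=(0, 2, 3, 4))

    return Tensor(out, parents=[(x, grad_x), (w, grad_w), (b, grad_b)])


def avgpool2(x: Tensor) -> Tensor:
    """2x2x2 average pooling (all spatial dims must be even)."""
    N, C, D, H, W = x.shape
    for ax, n in zip("DHW", (D, H, W)):
        if n % 2:
            raise ValueError(f"avgpool2 requires even spatial dims; axis {ax} has {n}")
    r = x.data.reshape(N, C, D // 2, 2, H // 2, 2, W // 2, 2)
    out = r.mean(axis=(3, 5, 7))

    def grad_x(g):
        g8 = np.repeat(np.repeat(np.repeat(g, 2, axis=2), 2, axis=3), 2, axis=4)
        return g8 / 8.0

    return Tensor(out, parents=[(x, grad_x)])


def upsample2(x: Tensor) -> Tensor:
    """Nearest-neighbour 2x upsampling of the spatial dims."""
    out = np.repeat(np.repeat(np.repeat(x.data, 2, axis=2), 2, axis=3), 2, axis=4)
    N, C, D, H, W = x.shape

    def grad_x(g):
        r = g.reshape(N, C, D, 2, H, 2, W, 2)
        return r.sum(axis=(3, 5, 7))

    return Tensor(out, parents=[(x, grad_x)])


def concat(a: Tensor, b: Tensor) -> Tensor:
    """Concatenate along the channel axis."""
    ca = a.shape[1]
    out = np.concatenate([a.data, b.data], axis=1)
    return Tensor(
        out,
        parents=[(a, lambda g: g[:, :ca]), (b, lambda g: g[:, ca:])],
    )


def batchnorm(
    x: Tensor,
    gamma: Tensor,
    beta: Tensor,
    running: dict,
    training: bool,
    momentum: float = 0.1,
    eps: float = 1e-5,
) -> Tensor:
    """Per-channel batch normalization over (N, D, H, W)."""
    axes = (0, 2, 3, 4)
    shape = (1, -1, 1, 1, 1)
    if training:
        mu = x.data.mean(axis=axes)
        var = x.data.var(axis=axes)
        running["mean"] = (1 - momentum) * running["mean"] + momentum * mu
        running["var"] = (1 - momentum) * running["var"] + momentum * var
    else:
        mu, var = running["mean"], running["var"]
    std = np.sqrt(var + eps)
    xhat = (x.data - mu.reshape(shape)) / std.reshape(shape)
    out = gamma.data.reshape(shape) * xhat + beta.data.reshape(shape)
    m = x.data.size / x.shape[1]

    def grad_x(g):
        dxhat = g * gamma.data.reshape(shape)
        if not training:
            return dxhat / std.reshape(shape)
        # gradient through the batch statistics
        s = std.reshape(shape)
        t1 = dxhat.sum(axis=axes, keepdims=True)
        t2 = (dxhat * xhat).sum(axis=axes, keepdims=True)
        return (dxhat - t1 / m - xhat * t2 / m) / s

    def grad_gamma(g):
        return (g * xhat).sum(axis=axes)

    def grad_beta(g):
        return g.sum(axis=axes)

    return Tensor(out, parents=[(x, grad_x), (gamma, grad_gamma), (beta, grad_beta)])


def prelu(x: Tensor, alpha: Tensor) -> Tensor:
    """Parametric ReLU with one learnable negative slope per channel."""
    a = alpha.data.reshape(1, -1, 1, 1, 1)
    pos = x.data > 0
    out = np.where(pos, x.data, a * x.data)

    def grad_x(g):
        return g * np.where(pos, 1.0, a)

    def grad_alpha(g):
        return (g * np.where(pos, 0.0, x.data)).sum(axis=(0, 2, 3, 4))

    return Tensor(out, parents=[(x, grad_x), (alpha, grad_alpha)])


def warp3d(image: np.ndarray, disp_vox: Tensor) -> Tensor:
    """Differentiable backward warp of a fixed image by a displacement tensor.

    ``image`` is a constant (N, C, D, H, W) array; ``disp_vox`` an
    (N, 3, D, H, W) displacement in voxel units.  The output voxel at x
    samples the image trilinearly at x + u(x); out-of-grid samples clamp to
    the border (border value, zero gradient).  Gradients are taken with
    respect to the displacement only.
    """
    N, C, D, H, W = image.shape
    if disp_vox.shape != (N, 3, D, H, W):
        raise ValueError(
            f"displacement shape {disp_vox.shape} does not match image {image.shape}"
        )
    sizes = (D, H, W)
    base = np.indices((D, H, W), dtype=np.float64)
    coords = disp_vox.data + base  # (N,3,D,H,W)
    inside = np.empty_like(coords, dtype=bool)
    cl = np.empty_like(coords)
    for a in range(3):
        inside[:, a] = (coords[:, a] > 0.0) & (coords[:, a] < sizes[a] - 1)
        cl[:, a] = np.clip(coords[:, a], 0.0, sizes[a] - 1)
    f = np.floor(cl).astype(np.int64)
    for a in range(3):
        np.minimum(f[:, a], sizes[a] - 2, out=f[:, a])
    t = cl - f  # fractional part, (N,3,D,H,W)

    out = np.zeros((N, C, D, H, W))
    # cache per-axis derivative accumulators
    dts = [np.zeros((N, C, D, H, W)) for _ in range(3)]
    corners = {}
    for n in range(N):
        fx, fy, fz = f[n]
        tx, ty, tz = t[n]
        wx = (1 - tx, tx)
        wy = (1 - ty, ty)
        wz = (1 - tz, tz)
        V = {}
        for i in (0, 1):
            for j in (0, 1):
                for l in (0, 1):
                    V[(i, j, l)] = image[n][:, fx + i, fy + j, fz + l]  # (C,D,H,W)
        corners[n] = V
        for i in (0, 1):
            for j in (0, 1):
                for l in (0, 1):
                    out[n] += V[(i, j, l)] * (wx[i] * wy[j] * wz[l])[None]
        # partial derivatives wrt tx, ty, tz
        for j in (0, 1):
            for l in (0, 1):
                dts[0][n] += (V[(1, j, l)] - V[(0, j, l)]) * (wy[j] * wz[l])[None]
        for i in (0, 1):
            for l in (0, 1):
                dts[1][n] += (V[(i, 1, l)] - V[(i, 0, l)]) * (wx[i] * wz[l])[None]
        for i in (0, 1):
            for j in (0, 1):
                dts[2][n] += (V[(i, j, 1)] - V[(i, j, 0)]) * (wx[i] * wy[j])[None]

    def grad_disp(g):
        gd = np.zeros((N, 3, D, H, W))
        for a in range(3):
            gd[:, a] = (g * dts[a]).sum(axis=1) * inside[:, a]
        return gd

    return Tensor(out, parents=[(disp_vox, grad_disp)])


def _box_mean_valid(arr: np.ndarray, k: int) -> np.ndarray:
    """Sliding-window mean over the last 3 axes, valid windows only."""
    size = (1,) * (arr.ndim - 3) + (k, k, k)
    full = uniform_filter(arr, size=size, mode="constant")
    h = k // 2
    sl = (Ellipsis,) + tuple(
        slice(h, h + n - k + 1) for n in arr.shape[-3:]
    )
    return full[sl]


def boxfilter_valid(x: Tensor, k: int) -> Tensor:
    """Mean over sliding k^3 windows (valid mode; output shrinks by k-1)."""
    if any(n < k for n in x.shape[-3:]):
        raise ValueError(f"window {k} larger than volume {x.shape[-3:]}")
    out = _box_mean_valid(x.data, k)

    def grad_x(g):
        pads = [(0, 0)] * (g.ndim - 3) + [(k - 1, k - 1)] * 3
        gp = np.pad(g, pads)
        return _box_mean_valid(gp, k)  # transpose of the mean is the mean

    return Tensor(out, parents=[(x, grad_x)])


def grad_penalty(disp_mm: Tensor, spacing) -> Tensor:
    """Diffusion regularizer: mean squared forward-difference gradient.

    ``disp_mm`` is (N, 3, D, H, W) in mm; differences are divided by the
    voxel spacing so the penalty is on dimensionless strain.
    """
    sp = np.asarray(spacing, dtype=np.float64)
    diffs = []
    total = 0.0
    for b in range(3):
        ax = 2 + b
        d = (np.diff(disp_mm.data, axis=ax)) / sp[b]
        diffs.append((ax, d))
        total += (d**2).mean()
    total /= 3.0

    def grad_disp(g):
        out = np.zeros_like(disp_mm.data)
        for ax, d in diffs:
            coeff = 2.0 * g / (3.0 * d.size) / sp[ax - 2]
            lo = [slice(None)] * 5
            hi = [slice(None)] * 5
            lo[ax] = slice(0, -1)
            hi[ax] = slice(1, None)
            out[tuple(hi)] += coeff * d
            out[tuple(lo)] -= coeff * d
        return out

    return Tensor(np.asarray(total), parents=[(disp_mm, grad_disp)])
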