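"""Minimal numpy neural-network core for 5-axis video tensors.

All feature maps use the fixed axis order ``(N, C, T, H, W)`` — batch,
channels, time (frames), height, width.  Layers implement explicit
``forward``/``backward`` passes (reverse-mode differentiation by hand), which
keeps the package dependency-free, fully deterministic under a seed, and fast
enough for the desk-scale sequence lengths this package targets (10 frames).

Convolutions are cross-correlations (the deep-learning convention) computed by
looping over kernel taps and accumulating BLAS mat-muls, which handles
arbitrary stride and dilation with one code path.
"""

from __future__ import annotations

from itertools import product

import numpy as np

from .errors import ShapeError

__all__ = [
    "Parameter",
    "Module",
    "Identity",
    "ReLU",
    "Conv3d",
    "BatchNorm3d",
    "MaxPool3d",
    "GlobalAvgPool",
    "Flatten",
    "Linear",
    "Sequential",
    "SGD",
    "softmax",
    "cross_entropy",
    "conv_output_length",
]


class Parameter:
    """A trainable array with an accumulated gradient."""

    __slots__ = ("data", "grad")

    def __init__(self, data: np.ndarray):
        self.data = np.ascontiguousarray(data, dtype=np.float32)
        self.grad = np.zeros_like(self.data)

    @property
    def size(self) -> int:
        return self.data.size


class Module:
    """Base layer: tracks parameters and non-trainable buffers by attribute walk."""

    def forward(self, x, train=False):  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, grad):  # pragma: no cover - abstract
        raise NotImplementedError

    def __call__(self, x, train=False):
        return self.forward(x, train=train)

    # -- parameter / buffer traversal ------------------------------------
    def _children(self):
        for name, val in vars(self).items():
            if isinstance(val, Module):
                yield name, val
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        yield f"{name}.{i}", item

    def named_parameters(self, prefix=""):
        for name, val in vars(self).items():
            if isinstance(val, Parameter):
                yield prefix + name, val
        for name, child in self._children():
            yield from child.named_parameters(f"{prefix}{name}.")

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def named_buffers(self, prefix=""):
        for name, val in getattr(self, "_buffers", {}).items():
            yield prefix + name, val
        for name, child in self._children():
            yield from child.named_buffers(f"{prefix}{name}.")

    def zero_grad(self):
        for p in self.parameters():
            p.grad[...] = 0.0

    def num_parameters(self) -> int:
        return sum(p.size for p in self.parameters())

    # -- (de)serialization -----------------------------------------------
    def state_dict(self):
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        for name, buf in self.named_buffers():
            state[name] = buf.copy()
        return state

    def load_state_dict(self, state):
        own = dict(self.named_parameters())
        bufs = dict(self.named_buffers())
        for name, arr in state.items():
            if name in own:
                if own[name].data.shape != arr.shape:
                    raise ShapeError(
                        f"parameter {name!r}: checkpoint shape {arr.shape} "
                        f"!= model shape {own[name].data.shape}"
                    )
                own[name].data[...] = arr
            elif name in bufs:
                bufs[name][...] = arr
            else:
                raise KeyError(f"unexpected entry {name!r} in state dict")
        missing = (set(own) | set(bufs)) - set(state)
        if missing:
            raise KeyError(f"state dict missing entries: {sorted(missing)}")


class Identity(Module):
    def forward(self, x, train=False):
        return x

    def backward(self, grad):
        return grad


class ReLU(Module):
    def forward(self, x, train=False):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, grad):
        return np.where(self._mask, grad, 0.0)


def conv_output_length(n: int, k: int, *, stride: int = 1, dilation: int = 1,
                       padding: int = 0) -> int:
    """Output extent of a conv/pool axis: floor((n + 2p - K)/s) + 1, K = d(k-1)+1."""
    eff = dilation * (k - 1) + 1
    out = (n + 2 * padding - eff) // stride + 1
    if out < 1:
        raise ShapeError(
            f"axis of extent {n} too small for kernel {k} (dilation {dilation}, "
            f"padding {padding}, stride {stride})"
        )
    return out


class Conv3d(Module):
    """3-D cross-correlation over (T,H,W) with per-axis stride/dilation/padding.

    Weight shape is ``(out_channels, in_channels, kt, kh, kw)``.  He-normal
    initialisation from the supplied generator; pass ``init="zeros"`` for
    functional use where weights are injected afterwards.
    """

    def __init__(self, in_channels, out_channels, kernel, *, stride=(1, 1, 1),
                 dilation=(1, 1, 1), padding=(0, 0, 0), bias=False,
                 rng: np.random.Generator | None = None, init="he"):
        self.in_channels = int(in_channels)
        self.out_channels = int(out_channels)
        self.kernel = tuple(int(k) for k in kernel)
        self.stride = tuple(int(s) for s in stride)
        self.dilation = tuple(int(d) for d in dilation)
        self.padding = tuple(int(p) for p in padding)
        shape = (self.out_channels, self.in_channels, *self.kernel)
        if init == "zeros" or rng is None:
            w = np.zeros(shape, dtype=np.float32)
        else:
            fan_in = self.in_channels * int(np.prod(self.kernel))
            w = rng.standard_normal(shape, dtype=np.float32)
            w *= np.float32(np.sqrt(2.0 / fan_in))
        self.weight = Parameter(w)
        self.bias = Parameter(np.zeros(self.out_channels)) if bias else None

    def output_shape(self, in_shape):
        """(C,T,H,W) -> (C',T',H',W') shape arithmetic without running data."""
        c, t, h, w = in_shape
        if c != self.in_channels:
            raise ShapeError(
                f"conv expects {self.in_channels} channels, got input shape {in_shape}"
            )
        dims = [
            conv_output_length(n, k, stride=s, dilation=d, padding=p)
            for n, k, s, d, p in zip(
                (t, h, w), self.kernel, self.stride, self.dilation, self.padding
            )
        ]
        return (self.out_channels, *dims)

    def forward(self, x, train=False):
        if x.ndim != 5 or x.shape[1] != self.in_channels:
            raise ShapeError(
                f"conv expects (N,{self.in_channels},T,H,W), got {x.shape}"
            )
        pt, ph, pw = self.padding
        xp = np.pad(x, ((0, 0), (0, 0), (pt, pt), (ph, ph), (pw, pw)))
        n = x.shape[0]
        _, to, ho, wo = self.output_shape(x.shape[1:])
        out = np.zeros((n, self.out_channels, to, ho, wo), dtype=np.float32)
        st, sh, sw = self.stride
        dt, dh, dw = self.dilation
        kt, kh, kw = self.kernel
        w = self.weight.data
        for it, ih, iw in product(range(kt), range(kh), range(kw)):
            xs = xp[:, :,
                    it * dt: it * dt + (to - 1) * st + 1: st,
                    ih * dh: ih * dh + (ho - 1) * sh + 1: sh,
                    iw * dw: iw * dw + (wo - 1) * sw + 1: sw]
            # (O,C) x (N,C,T,H,W) contracted over C -> (O,N,T,H,W)
            out += np.tensordot(w[:, :, it, ih, iw], xs,
                                axes=([1], [1])).transpose(1, 0, 2, 3, 4)
        if self.bias is not None:
            out += self.bias.data[None, :, None, None, None]
        self._cache = (xp, x.shape, (to, ho, wo))
        return out

    def backward(self, grad):
        xp, x_shape, (to, ho, wo) = self._cache
        st, sh, sw = self.stride
        dt, dh, dw = self.dilation
        kt, kh, kw = self.kernel
        pt, ph, pw = self.padding
        w = self.weight.data
        grad = np.ascontiguousarray(grad, dtype=np.float32)
        dxp = np.zeros_like(xp)
        for it, ih, iw in product(range(kt), range(kh), range(kw)):
            sl = (slice(None), slice(None),
                  slice(it * dt, it * dt + (to - 1) * st + 1, st),
                  slice(ih * dh, ih * dh + (ho - 1) * sh + 1, sh),
                  slice(iw * dw, iw * dw + (wo - 1) * sw + 1, sw))
            xs = xp[sl]
            self.weight.grad[:, :, it, ih, iw] += np.tensordot(
                grad, xs, axes=([0, 2, 3, 4], [0, 2, 3, 4]))
            dxp[sl] += np.tensordot(w[:, :, it, ih, iw], grad,
                                    axes=([0], [1])).transpose(1, 0, 2, 3, 4)
        if self.bias is not None:
            self.bias.grad += grad.sum(axis=(0, 2, 3, 4))
        _, _, t, h, wd = x_shape
        return dxp[:, :, pt:pt + t, ph:ph + h, pw:pw + wd]


class BatchNorm3d(Module):
    """Per-channel normalisation over (N,T,H,W) with learned scale/shift."""

    def __init__(self, num_features, *, eps=1e-5, momentum=0.1):
        self.num_features = int(num_features)
        self.eps = float(eps)
        self.momentum = float(momentum)
        self.gamma = Parameter(np.ones(num_features))
        self.beta = Parameter(np.zeros(num_features))
        self._buffers = {
            "running_mean": np.zeros(num_features, dtype=np.float32),
            "running_var": np.ones(num_features, dtype=np.float32),
        }

    def forward(self, x, train=False):
        axes = (0, 2, 3, 4)
        if train:
            mu = x.mean(axis=axes)
            var = x.var(axis=axes)
            n = x.size / x.shape[1]
            m = self.momentum
            self._buffers["running_mean"] *= 1 - m
            self._buffers["running_mean"] += m * mu
            unbiased = var * n / max(n - 1, 1)
            self._buffers["running_var"] *= 1 - m
            self._buffers["running_var"] += m * unbiased
        else:
            mu = self._buffers["running_mean"]
            var = self._buffers["running_var"]
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu[None, :, None, None, None]) * inv_std[None, :, None, None, None]
        self._cache = (xhat, inv_std, train)
        return (self.gamma.data[None, :, None, None, None] * xhat
                + self.beta.data[None, :, None, None, None])

    def backward(self, grad):
        xhat, inv_std, train = self._cache
        axes = (0, 2, 3, 4)
        self.gamma.grad += (grad * xhat).sum(axis=axes)
        self.beta.grad += grad.sum(axis=axes)
        g = self.gamma.data[None, :, None, None, None] * inv_std[None, :, None, None, None]
        if not train:
            return g * grad
        m = grad.shape[0] * grad.shape[2] * grad.shape[3] * grad.shape[4]
        mean_g = grad.mean(axis=axes, keepdims=True)
        mean_gx = (grad * xhat).sum(axis=axes, keepdims=True) / m
        return g * (grad - mean_g - xhat * mean_gx)


class MaxPool3d(Module):
    """Max pooling over (T,H,W); ties broken by the first tap (deterministic)."""

    def __init__(self, kernel, *, stride=None, padding=(0, 0, 0)):
        self.kernel = tuple(int(k) for k in kernel)
        self.stride = tuple(int(s) for s in (stride or kernel))
        self.padding = tuple(int(p) for p in padding)

    def output_shape(self, in_shape):
        c, t, h, w = in_shape
        dims = [
            conv_output_length(n, k, stride=s, padding=p)
            for n, k, s, p in zip((t, h, w), self.kernel, self.stride, self.padding)
        ]
        return (c, *dims)

    def forward(self, x, train=False):
        pt, ph, pw = self.padding
        xp = np.pad(x, ((0, 0), (0, 0), (pt, pt), (ph, ph), (pw, pw)),
                    constant_values=-np.inf)
        _, to, ho, wo = self.output_shape(x.shape[1:])
        st, sh, sw = self.stride
        kt, kh, kw = self.kernel
        best = np.full((x.shape[0], x.shape[1], to, ho, wo), -np.inf, dtype=np.float32)
        best_tap = np.zeros(best.shape, dtype=np.int16)
        for tap, (it, ih, iw) in enumerate(product(range(kt), range(kh), range(kw))):
            xs = xp[:, :,
                    it: it + (to - 1) * st + 1: st,
                    ih: ih + (ho - 1) * sh + 1: sh,
                    iw: iw + (wo - 1) * sw + 1: sw]
            better = xs > best
            best = np.where(better, xs, best)
            best_tap = np.where(better, tap, best_tap)
        self._cache = (best_tap, xp.shape, x.shape, (to, ho, wo))
        return best

    def backward(self, grad):
        best_tap, xp_shape, x_shape, (to, ho, wo) = self._cache
        st, sh, sw = self.stride
        kt, kh, kw = self.kernel
        pt, ph, pw = self.padding
        dxp = np.zeros(xp_shape, dtype=np.float32)
        for tap, (it, ih, iw) in enumerate(product(range(kt), range(kh), range(kw))):
            sl = (slice(None), slice(None),
                  slice(it, it + (to - 1) * st + 1, st),
                  slice(ih, ih + (ho - 1) * sh + 1, sh),
                  slice(iw, iw + (wo - 1) * sw + 1, sw))
            dxp[sl] += np.where(best_tap == tap, grad, 0.0)
        _, _, t, h, w = x_shape
        return dxp[:, :, pt:pt + t, ph:ph + h, pw:pw + w]


class GlobalAvgPool(Module):
    """Mean over (T,H,W): (N,C,T,H,W) -> (N,C)."""

    def forward(self, x, train=False):
        self._shape = x.shape
        return x.mean(axis=(2, 3, 4))

    def backward(self, grad):
        n, c, t, h, w = self._shape
        scale = 1.0 / (t * h * w)
        return np.broadcast_to(
            grad[:, :, None, None, None] * scale, self._shape
        ).astype(np.float32).copy()


class Flatten(Module):
    def forward(self, x, train=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class Linear(Module):
    def __init__(self, in_features, out_features, *, bias=True,
                 rng: np.random.Generator | None = None):
        self.in_features = int(in_features)
        self.out_features = int(out_features)
        if rng is None:
            w = np.zeros((out_features, in_features), dtype=np.float32)
        else:
            w = rng.standard_normal((out_features, in_features), dtype=np.float32)
            w *= np.float32(np.sqrt(2.0 / in_features))
        self.weight = Parameter(w)
        self.bias = Parameter(np.zeros(out_features)) if bias else None

    def forward(self, x, train=False):
        if x.shape[1] != self.in_features:
            raise ShapeError(
                f"linear expects {self.in_features} features, got {x.shape}"
            )
        self._x = x
        out = x @ self.weight.data.T
        if self.bias is not None:
            out = out + self.bias.data
        return out

    def backward(self, grad):
        self.weight.grad += grad.T @ self._x
        if self.bias is not None:
            self.bias.grad += grad.sum(axis=0)
        return grad @ self.weight.data


class Sequential(Module):
    def __init__(self, *modules):
        self.layers = list(modules)

    def forward(self, x, train=False):
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, grad):
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def cross_entropy(logits: np.ndarray, labels: np.ndarray):
    """Mean softmax cross-entropy; returns (loss, dloss/dlogits)."""
    n = logits.shape[0]
    p = softmax(logits.astype(np.float64))
    loss = -np.log(np.clip(p[np.arange(n), labels], 1e-12, None)).mean()
    grad = p
    grad[np.arange(n), labels] -= 1.0
    return float(loss), (grad / n).astype(np.float32)


class SGD:
    """Momentum SGD with optional L2 weight decay."""

    def __init__(self, params, lr, *, momentum=0.9, weight_decay=0.0):
        self.params = list(params)
        self.lr = float(lr)
        self.momentum = float(momentum)
        self.weight_decay = float(weight_decay)
        self._velocity = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        for p, v in zip(self.params, self._velocity):
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            v *= self.momentum
            v += g
            p.data -= self.lr * v
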