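"""Neural-network layers, parameter containers and the Adam optimizer.

Layers follow the NCHW convention.  Convolution is implemented as
pad -> patch gather (im2col) -> grouped matmul, so that its backward pass
is composed of differentiable engine primitives and second-order
gradients (required by the gradient penalty) come for free.
"""

from __future__ import annotations

import math
from typing import Iterator

import numpy as np

from .autodiff import Tensor, concat, no_grad

__all__ = [
    "Module", "Parameter", "Conv2d", "ConvTranspose2d", "Linear",
    "BatchNorm2d", "InstanceNorm2d", "MaxPool2d", "Dropout", "LeakyReLU",
    "Sigmoid", "Sequential", "Adam", "kaiming_normal_", "normal_",
    "global_grad_norm", "clip_grad_norm_",
]


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(np.asarray(data, dtype=np.float32), requires_grad=True)


class Module:
    """Minimal module container with named parameter traversal."""

    def __init__(self):
        self._modules: dict[str, Module] = {}
        self._params: dict[str, Parameter] = {}
        self.training = True

    def __setattr__(self, name, value):
        if isinstance(value, Parameter):
            self.__dict__.setdefault("_params", {})[name] = value
        elif isinstance(value, Module):
            self.__dict__.setdefault("_modules", {})[name] = value
        object.__setattr__(self, name, value)

    def modules(self) -> Iterator["Module"]:
        yield self
        for m in self._modules.values():
            yield from m.modules()

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Parameter]]:
        for n, p in self._params.items():
            yield (f"{prefix}{n}", p)
        for mn, m in self._modules.items():
            yield from m.named_parameters(prefix=f"{prefix}{mn}.")

    def parameters(self) -> list[Parameter]:
        return [p for _, p in self.named_parameters()]

    def num_parameters(self) -> int:
        return sum(p.size for p in self.parameters())

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def train(self, mode: bool = True):
        for m in self.modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {n: p.data.copy() for n, p in self.named_parameters()}
        for i, m in enumerate(self.modules()):
            if isinstance(m, BatchNorm2d):
                state[f"__bn{i}.running_mean"] = m.running_mean.copy()
                state[f"__bn{i}.running_var"] = m.running_var.copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]):
        for n, p in self.named_parameters():
            p.data = np.asarray(state[n], dtype=np.float32).reshape(p.shape)
        for i, m in enumerate(self.modules()):
            if isinstance(m, BatchNorm2d):
                m.running_mean = np.asarray(state[f"__bn{i}.running_mean"],
                                            dtype=np.float32)
                m.running_var = np.asarray(state[f"__bn{i}.running_var"],
                                           dtype=np.float32)

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Sequential(Module):
    def __init__(self, *layers: Module):
        super().__init__()
        self.layers = list(layers)
        for i, layer in enumerate(layers):
            setattr(self, f"l{i}", layer)

    def forward(self, x):
        for layer in self.layers:
            x = layer(x)
        return x


# ---------------------------------------------------------------------------
# convolution primitives
#
# im2col and col2im are exact adjoints of each other (for fixed kernel,
# stride, dilation and padding), so each can serve as the other's backward
# pass; both backwards are again engine ops, preserving double backprop.
# ---------------------------------------------------------------------------

def _conv_out(h, kh, stride, dilation, padding):
    return (h + 2 * padding - dilation * (kh - 1) - 1) // stride + 1


def _im2col_np(x, kh, kw, stride, dilation, padding):
    n, c, h, w = x.shape
    if padding:
        x = np.pad(x, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    hp, wp = x.shape[2], x.shape[3]
    oh = (hp - dilation * (kh - 1) - 1) // stride + 1
    ow = (wp - dilation * (kw - 1) - 1) // stride + 1
    cols = np.empty((n, c, kh, kw, oh, ow), x.dtype)
    for ki in range(kh):
        for kj in range(kw):
            cols[:, :, ki, kj] = x[:, :,
                                   ki * dilation: ki * dilation + (oh - 1) * stride + 1: stride,
                                   kj * dilation: kj * dilation + (ow - 1) * stride + 1: stride]
    return cols.reshape(n, c * kh * kw, oh * ow), (oh, ow)


def _col2im_np(cols, xshape, kh, kw, stride, dilation, padding, oh, ow):
    n, c, h, w = xshape
    hp, wp = h + 2 * padding, w + 2 * padding
    out = np.zeros((n, c, hp, wp), dtype=cols.dtype)
    cols = cols.reshape(n, c, kh, kw, oh, ow)
    for ki in range(kh):
        for kj in range(kw):
            out[:, :, ki * dilation: ki * dilation + (oh - 1) * stride + 1: stride,
                kj * dilation: kj * dilation + (ow - 1) * stride + 1: stride] \
                += cols[:, :, ki, kj]
    if padding:
        out = out[:, :, padding:-padding, padding:-padding]
    return out


def im2col(x: Tensor, kh, kw, stride=1, dilation=1, padding=0) -> Tensor:
    data, (oh, ow) = _im2col_np(x.data, kh, kw, stride, dilation, padding)
    xshape = x.shape

    def bw(g):
        return (col2im(g, xshape, kh, kw, stride, dilation, padding, oh, ow),)
    return Tensor._make(data, (x,), bw)


def col2im(cols: Tensor, xshape, kh, kw, stride, dilation, padding, oh, ow) -> Tensor:
    data = _col2im_np(cols.data, xshape, kh, kw, stride, dilation, padding, oh, ow)
    cshape = cols.shape

    def bw(g):
        return (im2col(g, kh, kw, stride, dilation, padding).reshape(cshape),)
    return Tensor._make(data, (cols,), bw)


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None = None, *,
           stride: int = 1, padding: int = 0, dilation: int = 1,
           groups: int = 1) -> Tensor:
    """Grouped/dilated/strided 2D convolution.

    Implemented as a single taped op: the forward pass runs im2col + GEMM in
    raw NumPy and discards the patch matrix; the backward closure recomputes
    it (checkpointing), which keeps the live graph at activation size.  The
    backward closure is built from engine ops, so the op remains
    twice-differentiable.
    """
    n, c, h, w = x.shape
    co, cig, kh, kw = weight.shape
    if c != cig * groups:
        raise ValueError(f"channel mismatch: input {c}, weight expects {cig * groups}")
    oh = _conv_out(h, kh, stride, dilation, padding)
    ow = _conv_out(w, kw, stride, dilation, padding)
    L = oh * ow
    ckk = cig * kh * kw

    cols_np, _ = _im2col_np(x.data, kh, kw, stride, dilation, padding)
    if groups == 1:
        out_np = weight.data.reshape(co, ckk) @ cols_np
    else:
        out_np = (weight.data.reshape(groups, co // groups, ckk)
                  @ cols_np.reshape(n, groups, ckk, L)).reshape(n, co, L)
    out_np = out_np.reshape(n, co, oh, ow)
    if bias is not None:
        out_np = out_np + bias.data.reshape(1, co, 1, 1)
    del cols_np

    parents = (x, weight) if bias is None else (x, weight, bias)

    def bw(g):
        gm = g.reshape(n, co, L)
        cols = im2col(x, kh, kw, stride, dilation, padding)
        if groups == 1:
            wmat = weight.reshape(co, ckk)
            dx_cols = wmat.transpose((1, 0)).matmul(gm)       # (n, ckk, L)
            dw = (gm.transpose((1, 0, 2)).reshape(co, n * L)
                  .matmul(cols.transpose((0, 2, 1)).reshape(n * L, ckk))
                  .reshape(co, cig, kh, kw))
        else:
            gg = gm.reshape(n, groups, co // groups, L)
            wmat = weight.reshape(groups, co // groups, ckk)
            colsg = cols.reshape(n, groups, ckk, L)
            dx_cols = wmat.transpose((0, 2, 1)).matmul(gg)    # (n,g,ckk,L)
            dx_cols = dx_cols.reshape(n, groups * ckk, L)
            dw = (gg.transpose((1, 2, 0, 3)).reshape(groups, co // groups, n * L)
                  .matmul(colsg.transpose((1, 0, 3, 2))
                          .reshape(groups, n * L, ckk))
                  .reshape(co, cig, kh, kw))
        dx = col2im(dx_cols, x.shape, kh, kw, stride, dilation, padding, oh, ow)
        if bias is None:
            return (dx, dw)
        return (dx, dw, g.sum(axis=(0, 2, 3)))

    return Tensor._make(out_np, parents, bw)


class Conv2d(Module):
    def __init__(self, in_ch, out_ch, kernel_size, stride=1, padding=0,
                 dilation=1, groups=1, bias=True):
        super().__init__()
        self.in_ch, self.out_ch = in_ch, out_ch
        self.kernel_size = kernel_size
        self.stride, self.padding = stride, padding
        self.dilation, self.groups = dilation, groups
        k = kernel_size
        fan_in = in_ch // groups * k * k
        bound = 1.0 / math.sqrt(fan_in)
        rng = np.random.default_rng((in_ch * 1000003 + out_ch * 9176 + k) % (2**31))
        self.weight = Parameter(rng.uniform(-bound, bound,
                                            (out_ch, in_ch // groups, k, k)))
        self.bias = Parameter(np.zeros(out_ch)) if bias else None

    def forward(self, x):
        return conv2d(x, self.weight, self.bias, stride=self.stride,
                      padding=self.padding, dilation=self.dilation,
                      groups=self.groups)


class ConvTranspose2d(Module):
    """Stride-2, kernel-2 transposed convolution (exact 2x upsampling).

    With no kernel overlap this is a per-pixel linear map followed by a
    pixel-shuffle rearrangement, which keeps the op composed of matmul and
    reshape primitives.
    """

    def __init__(self, in_ch, out_ch):
        super().__init__()
        self.in_ch, self.out_ch = in_ch, out_ch
        fan_in = in_ch
        bound = 1.0 / math.sqrt(fan_in)
        rng = np.random.default_rng((7 + in_ch * 1000003 + out_ch * 9176) % (2**31))
        self.weight = Parameter(rng.uniform(-bound, bound, (in_ch, out_ch, 2, 2)))
        self.bias = Parameter(np.zeros(out_ch))

    def forward(self, x):
        n, c, h, w = x.shape
        co = self.out_ch
        wmat = self.weight.reshape(c, co * 4)              # (c, co*4)
        xm = x.reshape(n, c, h * w).transpose((0, 2, 1))   # (n, hw, c)
        y = xm.matmul(wmat)                                # (n, hw, co*4)
        y = y.reshape(n, h, w, co, 2, 2)
        y = y.transpose((0, 3, 1, 4, 2, 5))                # (n, co, h, 2, w, 2)
        y = y.reshape(n, co, 2 * h, 2 * w)
        return y + self.bias.reshape(1, co, 1, 1)


class Linear(Module):
    def __init__(self, in_features, out_features, bias=True):
        super().__init__()
        bound = 1.0 / math.sqrt(in_features)
        rng = np.random.default_rng((13 + in_features * 1000003 + out_features * 9176) % (2**31))
        self.weight = Parameter(rng.uniform(-bound, bound, (in_features, out_features)))
        self.bias = Parameter(np.zeros(out_features)) if bias else None

    def forward(self, x):
        y = x.matmul(self.weight)
        if self.bias is not None:
            y = y + self.bias
        return y


def _norm_op(x: Tensor, gamma: Tensor | None, beta: Tensor | None,
             axes: tuple, eps: float) -> Tensor:
    """Fused normalization over ``axes`` with optional per-channel affine.

    Forward runs in raw NumPy and retains only ``x`` (and the affine
    parameters); the backward closure rebuilds the exact gradient — the
    textbook normalization backward, including the mean/variance terms —
    out of engine ops, so the op stays twice-differentiable.
    """
    mu = x.data.mean(axis=axes, keepdims=True)
    xc = x.data - mu
    var = (xc * xc).mean(axis=axes, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    out = xc * inv
    cshape = (1, x.shape[1], 1, 1)
    if gamma is not None:
        out = out * gamma.data.reshape(cshape) + beta.data.reshape(cshape)
    parents = (x,) if gamma is None else (x, gamma, beta)
    stats = (mu, var)

    def bw(g):
        mu_x = x.mean(axis=axes, keepdims=True)
        xc_t = x - mu_x
        var_t = (xc_t * xc_t).mean(axis=axes, keepdims=True)
        inv_t = (var_t + eps).pow(-0.5)
        xhat = xc_t * inv_t
        if gamma is not None:
            dxhat = g * gamma.reshape(cshape)
        else:
            dxhat = g
        dx = inv_t * (dxhat - dxhat.mean(axis=axes, keepdims=True)
                      - xhat * (dxhat * xhat).mean(axis=axes, keepdims=True))
        if gamma is None:
            return (dx,)
        red = tuple(i for i in range(x.ndim) if i != 1)
        dgamma = (g * xhat).sum(axis=red)
        dbeta = g.sum(axis=red)
        return (dx, dgamma, dbeta)

    return Tensor._make(out, parents, bw), stats


class BatchNorm2d(Module):
    def __init__(self, num_features, eps=1e-5, momentum=0.1):
        super().__init__()
        self.eps, self.momentum = eps, momentum
        self.gamma = Parameter(np.ones(num_features))
        self.beta = Parameter(np.zeros(num_features))
        self.running_mean = np.zeros(num_features, dtype=np.float32)
        self.running_var = np.ones(num_features, dtype=np.float32)

    def forward(self, x):
        c = x.shape[1]
        if self.training:
            out, (mu, var) = _norm_op(x, self.gamma, self.beta,
                                      (0, 2, 3), self.eps)
            m = self.momentum
            self.running_mean = ((1 - m) * self.running_mean
                                 + m * mu.reshape(c).astype(np.float32))
            self.running_var = ((1 - m) * self.running_var
                                + m * var.reshape(c).astype(np.float32))
            return out
        mu = Tensor(self.running_mean.reshape(1, c, 1, 1))
        var = Tensor(self.running_var.reshape(1, c, 1, 1))
        xhat = (x - mu) * (var + self.eps).pow(-0.5)
        return (xhat * self.gamma.reshape(1, c, 1, 1)
                + self.beta.reshape(1, c, 1, 1))


class InstanceNorm2d(Module):
    """Per-sample, per-channel normalization without affine parameters."""

    def __init__(self, num_features, eps=1e-5):
        super().__init__()
        self.eps = eps

    def forward(self, x):
        return _norm_op(x, None, None, (2, 3), self.eps)[0]


class MaxPool2d(Module):
    def __init__(self, kernel_size=2):
        super().__init__()
        assert kernel_size == 2

    def forward(self, x):
        n, c, h, w = x.shape
        y = x.reshape(n, c, h // 2, 2, w // 2, 2)
        return y.max(axis=3).max(axis=4)


class Dropout(Module):
    def __init__(self, p=0.1, seed=0):
        super().__init__()
        self.p = p
        self.rng = np.random.default_rng(seed)

    def forward(self, x):
        if not self.training or self.p <= 0:
            return x
        keep = 1.0 - self.p
        mask = Tensor((self.rng.random(x.shape) < keep).astype(np.float32) / keep)
        return x * mask


class LeakyReLU(Module):
    def __init__(self, negative_slope=0.2):
        super().__init__()
        self.negative_slope = negative_slope

    def forward(self, x):
        return x.leaky_relu(self.negative_slope)


class Sigmoid(Module):
    def forward(self, x):
        return x.sigmoid()


# ---------------------------------------------------------------------------
# init + optim
# ---------------------------------------------------------------------------

def kaiming_normal_(param: Parameter, rng: np.random.Generator,
                    negative_slope: float = 0.2):
    """He-normal init for the fan-in of a conv/linear weight."""
    shape = param.shape
    if len(shape) == 4:
        fan_in = shape[1] * shape[2] * shape[3]
    else:
        fan_in = shape[0]
    gain = math.sqrt(2.0 / (1 + negative_slope ** 2))
    std = gain / math.sqrt(fan_in)
    param.data = rng.normal(0.0, std, shape).astype(np.float32)


def normal_(param: Parameter, rng: np.random.Generator,
            mean: float = 0.0, std: float = 0.02):
    param.data = rng.normal(mean, std, param.shape).astype(np.float32)


def global_grad_norm(params) -> float:
    total = 0.0
    for p in params:
        if p.grad is not None:
            total += float((p.grad.data.astype(np.float64) ** 2).sum())
    return math.sqrt(total)


def clip_grad_norm_(params, max_norm: float) -> float:
    params = list(params)
    norm = global_grad_norm(params)
    if norm > max_norm and norm > 0:
        scale = max_norm / norm
        for p in params:
            if p.grad is not None:
                p.grad = Tensor(p.grad.data * scale)
    return norm


class Adam:
    def __init__(self, params, lr=1e-4, betas=(0.5, 0.999), eps=1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros(p.shape, dtype=np.float32) for p in self.params]
        self.v = [np.zeros(p.shape, dtype=np.float32) for p in self.params]
        self.step_count = 0

    def step(self):
        self.t += 1
        self.step_count += 1
        b1, b2 = self.b1, self.b2
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad.data
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None
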