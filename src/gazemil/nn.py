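"""Neural-network layers and the AMSGrad optimizer on the autodiff tape.

Layers follow NCHW layout. Convolution is implemented as a small loop
over kernel offsets with strided slicing (cheap for 3x3 kernels), batch
normalization as a fused op with the standard analytic backward, and
bilinear resizing with the half-pixel-center coordinate convention.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, custom_op


class Module:
    """Base class: parameter discovery, train/eval mode, state dicts."""

    def __init__(self):
        self.training = True

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for attr in vars(self).values():
            if isinstance(attr, Tensor) and attr.requires_grad:
                params.append(attr)
            elif isinstance(attr, Module):
                params.extend(attr.parameters())
            elif isinstance(attr, (list, tuple)):
                for item in attr:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
        return params

    def _modules(self):
        for name, attr in vars(self).items():
            if isinstance(attr, Module):
                yield name, attr
            elif isinstance(attr, (list, tuple)):
                for i, item in enumerate(attr):
                    if isinstance(item, Module):
                        yield f"{name}.{i}", item

    def train(self, mode: bool = True):
        self.training = mode
        for _, m in self._modules():
            m.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def state_dict(self, prefix: str = "") -> dict[str, np.ndarray]:
        state: dict[str, np.ndarray] = {}
        for name, attr in vars(self).items():
            if isinstance(attr, Tensor):
                state[prefix + name] = attr.value.copy()
            elif isinstance(attr, np.ndarray):
                state[prefix + name] = attr.copy()
        for name, m in self._modules():
            state.update(m.state_dict(prefix + name + "."))
        return state

    def load_state_dict(self, state: dict[str, np.ndarray], prefix: str = "") -> None:
        for name, attr in vars(self).items():
            key = prefix + name
            if isinstance(attr, Tensor) and key in state:
                attr.value = state[key].copy()
            elif isinstance(attr, np.ndarray) and key in state:
                setattr(self, name, state[key].copy())
        for name, m in self._modules():
            m.load_state_dict(state, prefix + name + ".")

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Conv2d(Module):
    """2-D convolution (cross-correlation) with zero padding."""

    def __init__(self, in_ch, out_ch, kernel, stride=1, pad=None, rng=None, bias=True):
        super().__init__()
        self.in_ch, self.out_ch = in_ch, out_ch
        self.kernel, self.stride = kernel, stride
        self.pad = (kernel - 1) // 2 if pad is None else pad
        rng = rng or np.random.default_rng()
        fan_in = in_ch * kernel * kernel
        scale = np.sqrt(2.0 / fan_in)  # He initialization for ReLU nets
        self.weight = Tensor(
            rng.normal(0.0, scale, (out_ch, in_ch, kernel, kernel)).astype(np.float32),
            requires_grad=True,
        )
        self.bias = (
            Tensor(np.zeros(out_ch, dtype=np.float32), requires_grad=True)
            if bias
            else None
        )

    def forward(self, x: Tensor) -> Tensor:
        w, b = self.weight, self.bias
        k, s, p = self.kernel, self.stride, self.pad
        xv = x.value
        n, c, h, wd = xv.shape
        if c != self.in_ch:
            raise ValueError(f"expected {self.in_ch} channels, got {c}")
        ho = (h + 2 * p - k) // s + 1
        wo = (wd + 2 * p - k) // s + 1
        xp = np.pad(xv, ((0, 0), (0, 0), (p, p), (p, p)))
        out = np.zeros((n, self.out_ch, ho, wo), dtype=xv.dtype)
        for i in range(k):
            for j in range(k):
                patch = xp[:, :, i : i + s * ho : s, j : j + s * wo : s]
                out += np.einsum("nchw,oc->nohw", patch, w.value[:, :, i, j], optimize=True)
        if b is not None:
            out += b.value[None, :, None, None]

        def bw(g, x=x, w=w, b=b, xp=xp, k=k, s=s, p=p, ho=ho, wo=wo, shape=xv.shape):
            gw = np.zeros_like(w.value)
            gx_pad = np.zeros_like(xp)
            for i in range(k):
                for j in range(k):
                    patch = xp[:, :, i : i + s * ho : s, j : j + s * wo : s]
                    gw[:, :, i, j] = np.einsum("nohw,nchw->oc", g, patch, optimize=True)
                    gx_pad[:, :, i : i + s * ho : s, j : j + s * wo : s] += np.einsum(
                        "nohw,oc->nchw", g, w.value[:, :, i, j], optimize=True
                    )
            w._accumulate(gw)
            if b is not None:
                b._accumulate(g.sum(axis=(0, 2, 3)))
            h, wd = shape[2], shape[3]
            x._accumulate(gx_pad[:, :, p : p + h, p : p + wd])

        parents = (x, w) if b is None else (x, w, b)
        return custom_op(out, parents, bw)


class BatchNorm2d(Module):
    """Per-channel batch normalization with running statistics."""

    def __init__(self, channels, eps=1e-5, momentum=0.1):
        super().__init__()
        self.eps, self.momentum = eps, momentum
        self.gamma = Tensor(np.ones(channels, dtype=np.float32), requires_grad=True)
        self.beta = Tensor(np.zeros(channels, dtype=np.float32), requires_grad=True)
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)

    def forward(self, x: Tensor) -> Tensor:
        gm, bt = self.gamma, self.beta
        xv = x.value
        if self.training:
            mu = xv.mean(axis=(0, 2, 3))
            var = xv.var(axis=(0, 2, 3))
            self.running_mean += self.momentum * (mu - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mu, var = self.running_mean, self.running_var
        std = np.sqrt(var + self.eps)
        xhat = (xv - mu[None, :, None, None]) / std[None, :, None, None]
        out = gm.value[None, :, None, None] * xhat + bt.value[None, :, None, None]
        training = self.training

        def bw(g, x=x, gm=gm, bt=bt, xhat=xhat, std=std, training=training):
            gm._accumulate((g * xhat).sum(axis=(0, 2, 3)))
            bt._accumulate(g.sum(axis=(0, 2, 3)))
            gsc = g * gm.value[None, :, None, None] / std[None, :, None, None]
            if not training:
                x._accumulate(gsc)
                return
            m = g.shape[0] * g.shape[2] * g.shape[3]
            mean_g = gsc.mean(axis=(0, 2, 3), keepdims=True)
            mean_gx = (gsc * xhat).mean(axis=(0, 2, 3), keepdims=True)
            x._accumulate(gsc - mean_g - xhat * mean_gx)

        return custom_op(out.astype(xv.dtype), (x, gm, bt), bw)


def _interp_matrix(n_out: int, n_in: int, dtype=np.float32) -> np.ndarray:
    """(n_out, n_in) linear-interpolation matrix, half-pixel centers."""
    coords = (np.arange(n_out) + 0.5) * (n_in / n_out) - 0.5
    coords = np.clip(coords, 0, n_in - 1)
    i0 = np.floor(coords).astype(int)
    i1 = np.minimum(i0 + 1, n_in - 1)
    w1 = coords - i0
    mat = np.zeros((n_out, n_in), dtype=dtype)
    mat[np.arange(n_out), i0] += 1.0 - w1
    mat[np.arange(n_out), i1] += w1
    return mat


def bilinear_resize(x: Tensor, out_hw: tuple[int, int]) -> Tensor:
    """Bilinear resize of an NCHW tensor to ``out_hw``.

    Expressed as two interpolation-matrix products, so the backward
    pass is the transposed products (no scatter).
    """
    oh, ow = out_hw
    n, c, h, w = x.value.shape
    wr = _interp_matrix(oh, h, dtype=x.value.dtype)
    wc = _interp_matrix(ow, w, dtype=x.value.dtype)
    flat = x.value.reshape(n * c, h, w)
    out = (wr @ flat @ wc.T).reshape(n, c, oh, ow)

    def bw(g, x=x, wr=wr, wc=wc, shape=(n, c, h, w)):
        n, c, h, w = shape
        gf = g.reshape(n * c, g.shape[2], g.shape[3]).astype(wr.dtype)
        x._accumulate((wr.T @ gf @ wc).reshape(n, c, h, w))

    return custom_op(out, (x,), bw)


def maxpool2d(x: Tensor, kernel: int = 3, stride: int = 2, pad: int = 1) -> Tensor:
    xv = x.value
    n, c, h, w = xv.shape
    ho = (h + 2 * pad - kernel) // stride + 1
    wo = (w + 2 * pad - kernel) // stride + 1
    xp = np.full((n, c, h + 2 * pad, w + 2 * pad), -np.inf, dtype=xv.dtype)
    xp[:, :, pad : pad + h, pad : pad + w] = xv
    win = np.lib.stride_tricks.sliding_window_view(xp, (kernel, kernel), axis=(2, 3))
    win = win[:, :, ::stride, ::stride].reshape(n, c, ho, wo, kernel * kernel)
    arg = win.argmax(axis=-1)
    out = np.take_along_axis(win, arg[..., None], axis=-1)[..., 0]

    def bw(g, x=x, arg=arg, geom=(kernel, stride, pad, h, w)):
        kernel, stride, pad, h, w = geom
        n, c, ho, wo = g.shape
        hh = np.arange(ho)[None, None, :, None] * stride + arg // kernel - pad
        ww = np.arange(wo)[None, None, None, :] * stride + arg % kernel - pad
        nn = np.arange(n)[:, None, None, None]
        cc = np.arange(c)[None, :, None, None]
        gx = np.zeros((n, c, h, w), dtype=g.dtype)
        np.add.at(
            gx,
            (
                np.broadcast_to(nn, arg.shape),
                np.broadcast_to(cc, arg.shape),
                np.clip(hh, 0, h - 1),
                np.clip(ww, 0, w - 1),
            ),
            g,
        )
        x._accumulate(gx)

    return custom_op(out, (x,), bw)


class AMSGrad:
    """Adam with the AMSGrad maximum-of-second-moment correction."""

    def __init__(self, params, lr=0.001, betas=(0.9, 0.999), eps=1e-8, weight_decay=0.0):
        self.params = list(params)
        self.lr, self.betas, self.eps = lr, betas, eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]
        self.vhat = [np.zeros_like(p.value) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        b1, b2 = self.betas
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.value
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            np.maximum(self.vhat[i], self.v[i], out=self.vhat[i])
            mhat = self.m[i] / (1 - b1**self.t)
            vhat_c = self.vhat[i] / (1 - b2**self.t)
            p.value = p.value - self.lr * mhat / (np.sqrt(vhat_c) + self.eps)
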