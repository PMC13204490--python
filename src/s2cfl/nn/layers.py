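"""Neural-network building blocks on top of the autograd engine.

Contains exactly the blocks the two model branches need: dense and
convolutional layers, an LSTM, windowed multi-head self-attention blocks,
the convolutional block attention module (CBAM), loss functions and Adam.
Initialization is driven by an explicit numpy Generator for reproducibility.
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, concat

# ---------------------------------------------------------------------------
# Module base


class Module:
    def parameters(self) -> list[Tensor]:
        return [p for _, p in self.named_parameters()]

    def named_parameters(self, prefix: str = "") -> list[tuple[str, Tensor]]:
        out: list[tuple[str, Tensor]] = []
        for name, value in vars(self).items():
            full = f"{prefix}{name}"
            if isinstance(value, Tensor) and value.requires_grad:
                out.append((full, value))
            elif isinstance(value, Module):
                out.extend(value.named_parameters(f"{full}."))
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        out.extend(item.named_parameters(f"{full}.{i}."))
                    elif isinstance(item, Tensor) and item.requires_grad:
                        out.append((f"{full}.{i}", item))
            elif isinstance(value, dict):
                for key, item in value.items():
                    if isinstance(item, Module):
                        out.extend(item.named_parameters(f"{full}.{key}."))
        return out

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    def state_dict(self) -> dict[str, np.ndarray]:
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        named = dict(self.named_parameters())
        for name, arr in state.items():
            arr = np.asarray(arr, dtype=np.float64)
            if named[name].data.shape != arr.shape:
                raise ValueError(
                    f"parameter {name}: checkpoint shape {arr.shape} does not match "
                    f"model shape {named[name].data.shape}"
                )
            named[name].data = arr.copy()

    def param_checksum(self) -> float:
        return float(sum(np.abs(p.data).sum() for p in self.parameters()))

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def _param(rng: np.random.Generator, shape, scale: float) -> Tensor:
    return Tensor(rng.normal(0.0, scale, size=shape), requires_grad=True)


class Linear(Module):
    def __init__(self, rng: np.random.Generator, in_dim: int, out_dim: int, bias: bool = True):
        self.weight = _param(rng, (in_dim, out_dim), np.sqrt(2.0 / in_dim))
        self.bias = Tensor(np.zeros(out_dim), requires_grad=True) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        out = x @ self.weight
        if self.bias is not None:
            out = out + self.bias
        return out


# ---------------------------------------------------------------------------
# Convolutions (im2col primitives with scatter-add backward)


def _im2col1d(xp: np.ndarray, K: int, stride: int) -> np.ndarray:
    Lo = (xp.shape[2] - K) // stride + 1
    idx = (np.arange(Lo) * stride)[:, None] + np.arange(K)[None, :]
    return xp[:, :, idx]  # (B, C, Lo, K)


def _conv1d_input_grad(g: np.ndarray, w: np.ndarray, stride: int, pad: int, L: int) -> np.ndarray:
    """Input gradient via transposed correlation (full conv of the
    zero-stuffed output gradient with the spatially flipped kernel)."""
    B, O, Lo = g.shape
    _, C, K = w.shape
    Lp = L + 2 * pad
    gz = g
    if stride > 1:
        gz = np.zeros((B, O, (Lo - 1) * stride + 1))
        gz[:, :, ::stride] = g
    gzp = np.pad(gz, ((0, 0), (0, 0), (K - 1, K - 1)))
    cols = _im2col1d(gzp, K, 1)  # (B, O, Ls, K)
    w_flip = w[:, :, ::-1]
    dxp_part = np.einsum("bolk,ock->bcl", cols, w_flip, optimize=True)
    dxp = np.zeros((B, C, Lp))
    dxp[:, :, : dxp_part.shape[2]] = dxp_part  # trailing samples never covered
    return dxp[:, :, pad : pad + L] if pad else dxp


def conv1d(x: Tensor, w: Tensor, b: Tensor | None, stride: int = 1, pad: int = 0) -> Tensor:
    """x: (B, C, L), w: (O, C, K) -> (B, O, Lo)."""
    B, C, L = x.data.shape
    xp = np.pad(x.data, ((0, 0), (0, 0), (pad, pad))) if pad else x.data
    cols = _im2col1d(xp, w.data.shape[2], stride)
    out = np.einsum("bclk,ock->bol", cols, w.data, optimize=True)
    if b is not None:
        out = out + b.data[None, :, None]

    def bwd(g):
        if w.requires_grad:
            w._accumulate(np.einsum("bol,bclk->ock", g, cols, optimize=True))
        if b is not None and b.requires_grad:
            b._accumulate(g.sum(axis=(0, 2)))
        if x.requires_grad:
            x._accumulate(_conv1d_input_grad(g, w.data, stride, pad, L))

    parents = (x, w) if b is None else (x, w, b)
    return Tensor._make(out, parents, bwd)


def _im2col2d(xp: np.ndarray, kh: int, kw: int, stride: int) -> np.ndarray:
    Ho = (xp.shape[2] - kh) // stride + 1
    Wo = (xp.shape[3] - kw) // stride + 1
    ih = (np.arange(Ho) * stride)[:, None] + np.arange(kh)[None, :]
    iw = (np.arange(Wo) * stride)[:, None] + np.arange(kw)[None, :]
    return xp[:, :, ih[:, None, :, None], iw[None, :, None, :]]  # (B,C,Ho,Wo,kh,kw)


def _conv2d_input_grad(
    g: np.ndarray, w: np.ndarray, stride: int, pad: int, H: int, W: int
) -> np.ndarray:
    B, O, Ho, Wo = g.shape
    _, C, kh, kw = w.shape
    Hp, Wp = H + 2 * pad, W + 2 * pad
    gz = g
    if stride > 1:
        gz = np.zeros((B, O, (Ho - 1) * stride + 1, (Wo - 1) * stride + 1))
        gz[:, :, ::stride, ::stride] = g
    gzp = np.pad(gz, ((0, 0), (0, 0), (kh - 1, kh - 1), (kw - 1, kw - 1)))
    cols = _im2col2d(gzp, kh, kw, 1)
    w_flip = w[:, :, ::-1, ::-1]
    part = np.einsum("bohwkl,ockl->bchw", cols, w_flip, optimize=True)
    dxp = np.zeros((B, C, Hp, Wp))
    dxp[:, :, : part.shape[2], : part.shape[3]] = part
    return dxp[:, :, pad : pad + H, pad : pad + W] if pad else dxp


def conv2d(x: Tensor, w: Tensor, b: Tensor | None, stride: int = 1, pad: int = 0) -> Tensor:
    """x: (B, C, H, W), w: (O, C, kh, kw) -> (B, O, Ho, Wo)."""
    B, C, H, W = x.data.shape
    O, _, kh, kw = w.data.shape
    xp = np.pad(x.data, ((0, 0), (0, 0), (pad, pad), (pad, pad))) if pad else x.data
    cols = _im2col2d(xp, kh, kw, stride)
    out = np.einsum("bchwkl,ockl->bohw", cols, w.data, optimize=True)
    if b is not None:
        out = out + b.data[None, :, None, None]

    def bwd(g):
        if w.requires_grad:
            w._accumulate(np.einsum("bohw,bchwkl->ockl", g, cols, optimize=True))
        if b is not None and b.requires_grad:
            b._accumulate(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            x._accumulate(_conv2d_input_grad(g, w.data, stride, pad, H, W))

    parents = (x, w) if b is None else (x, w, b)
    return Tensor._make(out, parents, bwd)


class Conv1d(Module):
    def __init__(self, rng, in_ch: int, out_ch: int, kernel: int, stride: int = 1, pad: int = 0):
        self.weight = _param(rng, (out_ch, in_ch, kernel), np.sqrt(2.0 / (in_ch * kernel)))
        self.bias = Tensor(np.zeros(out_ch), requires_grad=True)
        self.stride, self.pad = stride, pad

    def forward(self, x: Tensor) -> Tensor:
        return conv1d(x, self.weight, self.bias, self.stride, self.pad)


class Conv2d(Module):
    def __init__(self, rng, in_ch: int, out_ch: int, kernel: int, stride: int = 1, pad: int = 0):
        self.weight = _param(rng, (out_ch, in_ch, kernel, kernel), np.sqrt(2.0 / (in_ch * kernel * kernel)))
        self.bias = Tensor(np.zeros(out_ch), requires_grad=True)
        self.stride, self.pad = stride, pad

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, self.stride, self.pad)


def zero_stuff1d(x: Tensor, stride: int) -> Tensor:
    """Insert ``stride-1`` zeros between samples (transposed-conv upsampling)."""
    if stride == 1:
        return x
    B, C, L = x.data.shape
    out = np.zeros((B, C, L * stride))
    out[:, :, ::stride] = x.data

    def bwd(g):
        if x.requires_grad:
            x._accumulate(g[:, :, ::stride])

    return Tensor._make(out, (x,), bwd)


class ConvTranspose1d(Module):
    """Transposed 1-D convolution realized as zero-stuffing + convolution."""

    def __init__(self, rng, in_ch: int, out_ch: int, kernel: int, stride: int = 1):
        self.conv = Conv1d(rng, in_ch, out_ch, kernel, stride=1, pad=kernel // 2)
        self.stride = stride

    def forward(self, x: Tensor) -> Tensor:
        return self.conv(zero_stuff1d(x, self.stride))


# ---------------------------------------------------------------------------
# Recurrent layer


class LSTM(Module):
    """Single-layer LSTM.

    Returns (outputs (B, L, H) or None, final state (B, 2H)).  The final state
    is the full recurrent state [h; c/sqrt(L)]: the cell state carries
    unsquashed running integrals of the gated inputs (sequence-length
    normalized), which the output squashing h = o * tanh(c) would destroy.
    ``forget_bias`` > 0 starts the recurrence with long memory.
    """

    def __init__(self, rng, in_dim: int, hidden: int, forget_bias: float = 1.0):
        s = 1.0 / np.sqrt(hidden)
        self.wx = Tensor(rng.uniform(-s, s, size=(in_dim, 4 * hidden)), requires_grad=True)
        self.wh = Tensor(rng.uniform(-s, s, size=(hidden, 4 * hidden)), requires_grad=True)
        b = np.zeros(4 * hidden)
        b[hidden : 2 * hidden] = forget_bias
        self.b = Tensor(b, requires_grad=True)
        self.hidden = hidden

    def forward(self, x: Tensor, collect_outputs: bool = False):
        B, L, _ = x.data.shape
        H = self.hidden
        h = Tensor(np.zeros((B, H)))
        c = Tensor(np.zeros((B, H)))
        outs = []
        for t in range(L):
            xt = x[:, t, :]
            z = xt @ self.wx + h @ self.wh + self.b
            i = z[:, 0 * H : 1 * H].sigmoid()
            f = z[:, 1 * H : 2 * H].sigmoid()
            g = z[:, 2 * H : 3 * H].tanh()
            o = z[:, 3 * H : 4 * H].sigmoid()
            c = f * c + i * g
            h = o * c.tanh()
            if collect_outputs:
                outs.append(h)
        state = concat([h, c * (1.0 / np.sqrt(L))], axis=1)
        if collect_outputs:
            from .autograd import stack

            return stack(outs, axis=1), state
        return None, state


# ---------------------------------------------------------------------------
# Normalization, attention, CBAM


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        self.gamma = Tensor(np.ones(dim), requires_grad=True)
        self.beta = Tensor(np.zeros(dim), requires_grad=True)
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        return xc * (var + self.eps) ** -0.5 * self.gamma + self.beta


class WindowAttention(Module):
    """Multi-head self-attention within non-overlapping square windows."""

    def __init__(self, rng, dim: int, heads: int, window: int):
        self.q = Linear(rng, dim, dim)
        # no key bias: softmax cancels a constant shift of the logits row,
        # so a key bias would be a provably gradient-dead parameter
        self.k = Linear(rng, dim, dim, bias=False)
        self.v = Linear(rng, dim, dim)
        self.proj = Linear(rng, dim, dim)
        self.heads, self.window, self.dim = heads, window, dim

    def forward(self, tokens: Tensor) -> Tensor:
        # tokens: (nWindows*B, N, C)
        Bn, N, C = tokens.data.shape
        h = self.heads
        d = C // h
        scale = 1.0 / np.sqrt(d)

        def split_heads(t: Tensor) -> Tensor:
            return t.reshape(Bn, N, h, d).transpose(0, 2, 1, 3)

        q = split_heads(self.q(tokens))
        k = split_heads(self.k(tokens))
        v = split_heads(self.v(tokens))
        attn = (q @ k.transpose(0, 1, 3, 2) * scale).softmax(axis=-1)
        out = (attn @ v).transpose(0, 2, 1, 3).reshape(Bn, N, C)
        return self.proj(out)


def _partition_windows(x: Tensor, window: int) -> tuple[Tensor, tuple]:
    """(B, C, H, W) -> (B*nh*nw, window*window, C) token windows."""
    B, C, H, W = x.data.shape
    w = min(window, H, W)
    nh, nw = H // w, W // w
    t = x.transpose(0, 2, 3, 1)  # B,H,W,C
    t = t.reshape(B, nh, w, nw, w, C).transpose(0, 1, 3, 2, 4, 5)
    tokens = t.reshape(B * nh * nw, w * w, C)
    return tokens, (B, C, H, W, w, nh, nw)


def _merge_windows(tokens: Tensor, meta: tuple) -> Tensor:
    B, C, H, W, w, nh, nw = meta
    t = tokens.reshape(B, nh, nw, w, w, C).transpose(0, 1, 3, 2, 4, 5)
    return t.reshape(B, H, W, C).transpose(0, 3, 1, 2)


class SwinBlock(Module):
    """Pre-norm windowed-attention transformer block on (B, C, H, W) maps."""

    def __init__(self, rng, dim: int, heads: int = 2, window: int = 4, mlp_ratio: float = 2.0):
        self.norm1 = LayerNorm(dim)
        self.attn = WindowAttention(rng, dim, heads, window)
        self.norm2 = LayerNorm(dim)
        hidden = int(dim * mlp_ratio)
        self.fc1 = Linear(rng, dim, hidden)
        self.fc2 = Linear(rng, hidden, dim)
        self.window = window

    def forward(self, x: Tensor) -> Tensor:
        tokens, meta = _partition_windows(x, self.window)
        tokens = tokens + self.attn(self.norm1(tokens))
        tokens = tokens + self.fc2(self.fc1(self.norm2(tokens)).relu())
        return _merge_windows(tokens, meta)


class CBAM(Module):
    """Convolutional block attention: channel gating then spatial gating."""

    def __init__(self, rng, channels: int, reduction: int = 4, spatial_kernel: int = 7):
        hidden = max(1, channels // reduction)
        self.fc1 = Linear(rng, channels, hidden)
        self.fc2 = Linear(rng, hidden, channels)
        self.spatial = Conv2d(rng, 2, 1, spatial_kernel, pad=spatial_kernel // 2)
        # start near-uniform attention (gates ~ 0.5 everywhere): random gates
        # at init scramble the features they multiply and stall optimization
        self.fc2.weight.data *= 0.1
        self.spatial.weight.data *= 0.1
        self.last_channel_attention: np.ndarray | None = None
        self.last_spatial_attention: np.ndarray | None = None

    def forward(self, x: Tensor) -> Tensor:
        B, C, H, W = x.data.shape
        flat = x.reshape(B, C, H * W)
        avg = flat.mean(axis=2)
        mx = flat.max(axis=2)
        ca = (self.fc2(self.fc1(avg).relu()) + self.fc2(self.fc1(mx).relu())).sigmoid()
        self.last_channel_attention = ca.data.copy()
        x = x * ca.reshape(B, C, 1, 1)
        mean_plane = x.mean(axis=1, keepdims=True)
        max_plane = x.max(axis=1, keepdims=True)
        planes = concat([mean_plane, max_plane], axis=1)
        sa = self.spatial(planes).sigmoid()
        self.last_spatial_attention = sa.data.copy()
        return x * sa


# ---------------------------------------------------------------------------
# Losses and optimizer


def mse_loss(pred: Tensor, target: np.ndarray | Tensor) -> Tensor:
    target = target.data if isinstance(target, Tensor) else np.asarray(target)
    diff = pred - Tensor(target)
    return (diff * diff).mean()


def cross_entropy_logits(logits: Tensor, labels: np.ndarray) -> Tensor:
    labels = np.asarray(labels, dtype=int)
    lse = logits.logsumexp(axis=-1)
    picked = logits[(np.arange(labels.shape[0]), labels)]
    return (lse - picked).mean()


def bce_logits(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Binary cross-entropy on raw scores: softplus(z) - y*z, averaged."""
    y = Tensor(np.asarray(targets, dtype=float))
    return (logits.softplus() - y * logits).mean()


class Adam:
    def __init__(self, params: list[Tensor], lr: float = 1e-3, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.b1, self.b2, self.eps = lr, betas[0], betas[1], eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1.0 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1.0 - self.b2) * g * g
            mhat = self.m[i] / b1t
            vhat = self.v[i] / b2t
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()
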