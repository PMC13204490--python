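"""Image branch: densely connected convolution pyramidal transformer network.

Consumes per-episode stacks of time-frequency images (3 transforms x 3
modalities), conditioned on the raw-signal branch's task probabilities, and
produces three sigmoid depressive-state quantification (DSQ) scores.

Architecture (row index j in 1..5, column index i in 0..4, triangular
occupancy j <= 5 - i):

- a dense convolution stem over the image channels concatenated with
  broadcast task-probability planes produces DC[0][0] and feeds a windowed
  self-attention backbone emitting one map per row, Sw[j][0]', at spatial
  resolution H/2^j x W/2^j;
- a mixed feature pyramid refines rows 1-3 from all three of them (row 4 and
  5 pass through);
- grid cell (j, i) is a transformer block over the concatenation of all
  previous same-row features plus an upsampled projection Vq of the fusion
  output FF[j+1][i-1]; FF[j][i] fuses Sw[j][i] with pooled encoder taps of
  the raw-signal branch;
- a dense convolution column DC[0][k] consumes every earlier DC cell plus
  FF[1][k-1] (strict dense connectivity);
- the DSQ head concatenates DC[0][1..5], adds a projection of the task
  probabilities, applies CBAM, a 1x1 convolution to 3 channels, global
  average pooling and a sigmoid.

The forward pass records the exact wiring (which named cells feed which), so
the dense-connectivity pattern can be asserted rather than trusted.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import ConfigurationError, ShapeError
from .nn import CBAM, Adam, Conv2d, Linear, Module, SwinBlock, Tensor, concat
from .nn.layers import bce_logits

N_ROWS = 5
TASK_ORDER = ("depression", "valence", "arousal")


@dataclass
class GridConfig:
    n_rows: int = 5
    image_size: tuple[int, int] = (64, 64)
    in_channels: int = 9
    row_widths: tuple[int, ...] = (8, 8, 12, 12, 16)
    dc_channels: int = 8
    heads: int = 2
    window: int = 4
    mlp_ratio: float = 2.0
    cbam_reduction: int = 4
    tap_dims: tuple[int, int] = (48, 96)
    use_conditioning: bool = True  # task-probability planes + DSQ conditioning
    use_fusion: bool = True  # encoder-tap FF fusion
    use_cbam: bool = True
    lr: float = 1e-3
    batch_size: int = 32
    epochs: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_rows != N_ROWS:
            raise ConfigurationError("the grid is fixed at 5 rows by its occupancy pattern")
        if len(self.row_widths) != N_ROWS:
            raise ConfigurationError("row_widths must have 5 entries")
        if any(w <= 0 for w in self.row_widths) or self.dc_channels <= 0:
            raise ConfigurationError("widths must be positive")
        H, W = self.image_size
        if H % 2**N_ROWS or W % 2**N_ROWS:
            raise ConfigurationError("image size must be divisible by 2**5")
        for w in self.row_widths:
            if w % self.heads:
                raise ConfigurationError("row widths must be divisible by the head count")


@dataclass
class DSQOutput:
    """Sigmoid depressive-state quantification scores, one per task."""

    dep: float
    val: float
    aro: float

    def __post_init__(self) -> None:
        for name in ("dep", "val", "aro"):
            v = float(getattr(self, name))
            if not (0.0 < v < 1.0) or not np.isfinite(v):
                raise ShapeError(f"DSQ score {name} must lie in (0, 1)")


def triangular_cells() -> list[tuple[int, int]]:
    """The 15 populated (row j, column i) grid cells."""
    return [(j, i) for i in range(N_ROWS) for j in range(1, N_ROWS - i + 1)]


def _pool2d(x: Tensor, factor: int) -> Tensor:
    if factor == 1:
        return x
    B, C, H, W = x.shape
    return x.reshape(B, C, H // factor, factor, W // factor, factor).mean(axis=(3, 5))


def _resize_map(x: Tensor, target_hw: int) -> Tensor:
    h = x.shape[-1]
    if h == target_hw:
        return x
    if h < target_hw:
        return x.repeat2d(target_hw // h)
    return _pool2d(x, h // target_hw)


def _tile_vector(v: Tensor, hw: int) -> Tensor:
    B, C = v.shape
    return v.reshape(B, C, 1, 1) * Tensor(np.ones((1, 1, hw, hw)))


class DC2PTN(Module):
    """See module docstring.  Build via :func:`build_grid` or directly."""

    def __init__(self, config: GridConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        c = config
        w = c.row_widths
        in_ch = c.in_channels + (3 if c.use_conditioning else 0)
        self.stem = Conv2d(rng, in_ch, c.dc_channels, 3, stride=1, pad=1)
        self.stem2 = Conv2d(rng, c.dc_channels, c.dc_channels, 3, stride=2, pad=1)
        # backbone: one downsampling conv + transformer block per row
        self.down = [
            Conv2d(rng, c.dc_channels if j == 0 else w[j - 1], w[j], 3,
                   stride=1 if j == 0 else 2, pad=1)
            for j in range(N_ROWS)
        ]
        self.backbone_blocks = [
            SwinBlock(rng, w[j], heads=c.heads, window=c.window, mlp_ratio=c.mlp_ratio)
            for j in range(N_ROWS)
        ]
        # mixed feature pyramid 1x1 mixers for rows 1..3
        mix_in = w[0] + w[1] + w[2]
        self.mfp = [Conv2d(rng, mix_in, w[j], 1) for j in range(3)]
        # grid cells: per-cell input mixer, Vq projection and transformer block
        self.cell_mix: dict[str, Conv2d] = {}
        self.cell_vq: dict[str, Conv2d] = {}
        self.cell_block: dict[str, SwinBlock] = {}
        for j, i in triangular_cells():
            if i == 0:
                continue
            key = f"{j},{i}"
            in_width = (i + 1) * w[j - 1]  # i same-row maps + projected Vq
            self.cell_vq[key] = Conv2d(rng, w[j], w[j - 1], 1)
            self.cell_mix[key] = Conv2d(rng, in_width, w[j - 1], 1)
            self.cell_block[key] = SwinBlock(
                rng, w[j - 1], heads=c.heads, window=c.window, mlp_ratio=c.mlp_ratio
            )
        # fusion blocks, one per row (shared across columns of the row)
        self.ff_proj1 = {str(j): Linear(rng, c.tap_dims[0], w[j - 1]) for j in range(1, N_ROWS + 1)}
        self.ff_proj2 = {str(j): Linear(rng, c.tap_dims[1], w[j - 1]) for j in range(1, N_ROWS + 1)}
        ff_in = lambda j: w[j - 1] * (3 if c.use_fusion else 1)  # noqa: E731
        self.ff_conv = {str(j): Conv2d(rng, ff_in(j), w[j - 1], 3, pad=1) for j in range(1, N_ROWS + 1)}
        # dense convolution column
        self.dc_conv = [
            Conv2d(rng, k * c.dc_channels + w[0], c.dc_channels, 3, pad=1)
            for k in range(1, N_ROWS + 1)
        ]
        # DSQ head
        head_ch = N_ROWS * c.dc_channels
        # additive conditioning: a spatial embedding of the task probabilities
        # plus a direct skip into the logits (the image features then only
        # need to learn the residual correction)
        self.prob_proj = Linear(rng, 3, head_ch) if c.use_conditioning else None
        self.prob_skip = Linear(rng, 3, 3) if c.use_conditioning else None
        self.cbam = CBAM(rng, head_ch, reduction=c.cbam_reduction) if c.use_cbam else None
        self.head_conv = Conv2d(rng, head_ch, 3, 1)
        self.wiring: dict[str, list[str]] = {}

    # -- forward pieces -------------------------------------------------------

    def _row_res(self, j: int) -> int:
        return self.config.image_size[0] // 2**j

    def first_column_forward(self, images: Tensor, probs: Tensor):
        """Stem + backbone: returns (DC[0][0], {j: Sw[j][0]'})."""
        c = self.config
        B, C, H, W = images.shape
        if (H, W) != tuple(c.image_size) or C != c.in_channels:
            raise ShapeError(
                f"image stack {(C, H, W)} incompatible with configured "
                f"{(c.in_channels, *c.image_size)}"
            )
        if c.use_conditioning:
            planes = _tile_vector(probs, H)
            x = concat([images, planes], axis=1)
            self.wiring["stem"] = ["images", "probs"]
        else:
            x = images
            self.wiring["stem"] = ["images"]
        dc00 = self.stem(x).relu()
        h = self.stem2(dc00).relu()
        sw_prime = {}
        prev = "stem"
        for j in range(1, N_ROWS + 1):
            h = self.down[j - 1](h).relu()
            h = self.backbone_blocks[j - 1](h)
            sw_prime[j] = h
            self.wiring[f"Sw[{j}][0]'"] = [prev]
            prev = f"Sw[{j}][0]'"
        return dc00, sw_prime

    def mixed_feature_pyramid(self, sw_prime: dict[int, Tensor]) -> dict[int, Tensor]:
        """Rows 1-3 are refined from all three; rows 4-5 pass through."""
        sw0 = {}
        for j in (1, 2, 3):
            res = self._row_res(j)
            mixed = concat([_resize_map(sw_prime[k], res) for k in (1, 2, 3)], axis=1)
            sw0[j] = self.mfp[j - 1](mixed).relu()
            self.wiring[f"Sw[{j}][0]"] = ["Sw[1][0]'", "Sw[2][0]'", "Sw[3][0]'"]
        for j in (4, 5):
            sw0[j] = sw_prime[j]
            self.wiring[f"Sw[{j}][0]"] = [f"Sw[{j}][0]'"]
        return sw0

    def _ff(self, j: int, i: int, sw: Tensor, u1: Tensor | None, u2: Tensor | None) -> Tensor:
        hw = sw.shape[-1]
        if self.config.use_fusion:
            t1 = _tile_vector(self.ff_proj1[str(j)](u1).relu(), hw)
            t2 = _tile_vector(self.ff_proj2[str(j)](u2).relu(), hw)
            x = concat([sw, t1, t2], axis=1)
            self.wiring[f"FF[{j}][{i}]"] = [f"Sw[{j}][{i}]", "U1", "U2"]
        else:
            x = sw
            self.wiring[f"FF[{j}][{i}]"] = [f"Sw[{j}][{i}]"]
        return self.ff_conv[str(j)](x).relu()

    def grid_forward(self, sw0: dict[int, Tensor], u1: Tensor | None, u2: Tensor | None):
        """Column-order sweep filling Sw[j][i] and FF[j][i]."""
        sw: dict[tuple[int, int], Tensor] = {(j, 0): sw0[j] for j in range(1, N_ROWS + 1)}
        ff: dict[tuple[int, int], Tensor] = {}
        for j in range(1, N_ROWS + 1):
            ff[(j, 0)] = self._ff(j, 0, sw[(j, 0)], u1, u2)
        for i in range(1, N_ROWS):
            for j in range(1, N_ROWS - i + 1):
                key = f"{j},{i}"
                inputs = [sw[(j, p)] for p in range(i)]
                names = [f"Sw[{j}][{p}]" for p in range(i)]
                if (j + 1, i - 1) in ff:
                    vq = self.cell_vq[key](ff[(j + 1, i - 1)].repeat2d(2))
                    inputs.append(vq)
                    names.append(f"Vq(FF[{j + 1}][{i - 1}])")
                merged = self.cell_mix[key](concat(inputs, axis=1)).relu()
                cell = self.cell_block[key](merged)
                sw[(j, i)] = cell
                self.wiring[f"Sw[{j}][{i}]"] = names
                ff[(j, i)] = self._ff(j, i, cell, u1, u2)
        return sw, ff

    def dense_column_update(self, dc00: Tensor, ff: dict[tuple[int, int], Tensor]):
        """DC[0][k] = conv(concat(all DC[0][<k], FF[1][k-1])): strict density."""
        dc = [_pool2d(dc00, 2)]  # column runs at the row-1 resolution
        self.wiring["DC[0][0]"] = ["stem"]
        for k in range(1, N_ROWS + 1):
            inputs = list(dc) + [ff[(1, k - 1)]]
            names = [f"DC[0][{p}]" for p in range(k)] + [f"FF[1][{k - 1}]"]
            out = self.dc_conv[k - 1](concat(inputs, axis=1)).relu()
            dc.append(out)
            self.wiring[f"DC[0][{k}]"] = names
        return dc

    def dsq_head(self, dc: list[Tensor], probs: Tensor) -> Tensor:
        z = concat(dc[1:], axis=1)
        names = [f"DC[0][{k}]" for k in range(1, N_ROWS + 1)]
        if self.config.use_conditioning:
            cond = self.prob_proj(probs)
            z = z + cond.reshape(cond.shape[0], cond.shape[1], 1, 1)
            names.append("probs")
        if self.cbam is not None:
            z = self.cbam(z)
        logits = self.head_conv(z).mean(axis=(2, 3))
        if self.config.use_conditioning:
            logits = logits + self.prob_skip(probs)
        self.wiring["DSQ"] = names
        return logits

    def forward(self, images: np.ndarray | Tensor, probs: np.ndarray | Tensor,
                taps: tuple[np.ndarray, np.ndarray] | None = None) -> Tensor:
        """Full pass; returns per-task logits (B, 3) ordered (dep, val, aro)."""
        images = images if isinstance(images, Tensor) else Tensor(images)
        probs = probs if isinstance(probs, Tensor) else Tensor(probs)
        self.wiring = {}
        if self.config.use_fusion:
            if taps is None:
                raise ShapeError("encoder taps required when fusion is enabled")
            u1, u2 = (t if isinstance(t, Tensor) else Tensor(t) for t in taps)
        else:
            u1 = u2 = None
        dc00, sw_prime = self.first_column_forward(images, probs)
        sw0 = self.mixed_feature_pyramid(sw_prime)
        _, ff = self.grid_forward(sw0, u1, u2)
        dc = self.dense_column_update(dc00, ff)
        return self.dsq_head(dc, probs)

    def predict_scores(self, images, probs, taps=None) -> np.ndarray:
        """(N, 3) sigmoid DSQ scores, batched."""
        c = self.config
        out = []
        n = images.shape[0]
        for lo in range(0, n, c.batch_size):
            hi = min(n, lo + c.batch_size)
            logits = self.forward(
                images[lo:hi], probs[lo:hi],
                None if taps is None else (taps[0][lo:hi], taps[1][lo:hi]),
            )
            out.append(logits.sigmoid().data)
        return np.concatenate(out, axis=0)


def build_grid(config: GridConfig, seed: int | None = None) -> DC2PTN:
    """Allocate the triangular grid; seeded builds are bit-reproducible."""
    if seed is not None:
        config = GridConfig(**{**config.__dict__, "seed": seed})
    return DC2PTN(config)


def expected_wiring(use_conditioning: bool = True, use_fusion: bool = True) -> dict[str, list[str]]:
    """The argument lists the dense-grid wiring rules prescribe, enumerated
    independently of the model code (used to audit the recorded wiring)."""
    w: dict[str, list[str]] = {}
    w["stem"] = ["images", "probs"] if use_conditioning else ["images"]
    w["Sw[1][0]'"] = ["stem"]
    for j in range(2, N_ROWS + 1):
        w[f"Sw[{j}][0]'"] = [f"Sw[{j - 1}][0]'"]
    for j in (1, 2, 3):
        w[f"Sw[{j}][0]"] = ["Sw[1][0]'", "Sw[2][0]'", "Sw[3][0]'"]
    for j in (4, 5):
        w[f"Sw[{j}][0]"] = [f"Sw[{j}][0]'"]
    for j, i in triangular_cells():
        ff_in = [f"Sw[{j}][{i}]"] + (["U1", "U2"] if use_fusion else [])
        w[f"FF[{j}][{i}]"] = ff_in
        if i > 0:
            w[f"Sw[{j}][{i}]"] = [f"Sw[{j}][{p}]" for p in range(i)] + [
                f"Vq(FF[{j + 1}][{i - 1}])"
            ]
    w["DC[0][0]"] = ["stem"]
    for k in range(1, N_ROWS + 1):
        w[f"DC[0][{k}]"] = [f"DC[0][{p}]" for p in range(k)] + [f"FF[1][{k - 1}]"]
    w["DSQ"] = [f"DC[0][{k}]" for k in range(1, N_ROWS + 1)] + (
        ["probs"] if use_conditioning else []
    )
    return w


# ---------------------------------------------------------------------------
# Training


def train_dc2ptn(
    images: np.ndarray,
    probs: np.ndarray,
    taps: tuple[np.ndarray, np.ndarray] | None,
    labels: dict[str, np.ndarray],
    config: GridConfig,
    epochs: int | None = None,
) -> tuple[DC2PTN, list[dict]]:
    """Train with summed binary cross-entropy on the three DSQ logits.

    The raw-signal branch inputs (probabilities and encoder taps) are fixed
    arrays: its weights stay frozen during this stage.
    """
    model = DC2PTN(config)
    y = np.stack([labels[t] for t in TASK_ORDER], axis=1).astype(float)
    rng = np.random.default_rng(config.seed + 3)
    opt = Adam(model.parameters(), lr=config.lr)
    n = images.shape[0]
    history = []
    for epoch in range(epochs if epochs is not None else config.epochs):
        order = rng.permutation(n)
        losses = []
        for lo in range(0, n, config.batch_size):
            idx = order[lo : lo + config.batch_size]
            logits = model.forward(
                images[idx], probs[idx],
                None if taps is None else (taps[0][idx], taps[1][idx]),
            )
            loss = bce_logits(logits, y[idx])
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(loss.data.item())
        history.append({"epoch": epoch, "train_bce": float(np.mean(losses))})
    return model, history


def save_checkpoint(model: DC2PTN, path: str | Path, history=None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    cfg = {**model.config.__dict__}
    cfg["image_size"] = list(cfg["image_size"])
    cfg["row_widths"] = list(cfg["row_widths"])
    cfg["tap_dims"] = list(cfg["tap_dims"])
    np.savez_compressed(
        path, __meta__=json.dumps({"config": cfg, "history": history or []}), **model.state_dict()
    )


def load_checkpoint(path: str | Path) -> DC2PTN:
    with np.load(Path(path), allow_pickle=False) as data:
        cfg = json.loads(str(data["__meta__"]))["config"]
        for key in ("image_size", "row_widths", "tap_dims"):
            cfg[key] = tuple(cfg[key])
        model = DC2PTN(GridConfig(**cfg))
        model.load_state_dict({k: data[k] for k in data.files if k != "__meta__"})
    return model
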