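"""Raw-signal branch: triple-path encoder-decoder network.

One conv+LSTM encoder per modality (HR, GSR, ACC magnitude), concatenation
fusion to a shared latent for the classification stage, and two
interchangeable head sets:

- per-modality reconstruction decoders (dense -> recurrent unroll ->
  transposed convolutions, plus a latent-conditioned harmonic readout) used
  for the self-supervised pretraining stage, which minimizes the MSE between
  the input signals and their reconstructions from the modality latents;
- three softmax classification heads (depression / valence / arousal) on the
  fused latent, trained in the supervised fine-tuning stage on the
  transferred encoder weights.

Training uses Adam (default learning rate 1e-3, batch size 32) with early
stopping on a validation split.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import DataError, InvalidConfigError, LabelError, MissingModalityError, ShapeError
from .nn import LSTM, Adam, Conv1d, ConvTranspose1d, Linear, Module, Tensor, concat
from .nn.layers import cross_entropy_logits, mse_loss
from .types import Modality

TASKS = ("depression", "valence", "arousal")


@dataclass
class TPEDNConfig:
    """Architecture and optimization knobs of the raw-signal branch.

    ``lstm_width`` is the per-modality latent width: the full final recurrent
    state [h; c] of an LSTM with hidden size ``lstm_width // 2``.
    """

    conv_channels: tuple[int, ...] = (96, 96)
    kernel: int = 7
    stride: int = 4
    lstm_width: int = 128
    fused_width: int = 128
    input_length: int = 1800
    modalities: tuple[Modality, ...] = (Modality.HR, Modality.GSR, Modality.ACC)
    lr: float = 1e-3
    batch_size: int = 32
    epochs: int = 50
    patience: int = 5
    val_fraction: float = 0.1
    seed: int = 0
    #: feed sin/cos positional channels and signal-basis products to the convs
    #: (helps the reconstruction objective estimate drift phases; the label
    #: tasks do better without the extra phase-carrying channels)
    harmonic_features: bool = True
    #: latent = full final recurrent state [h; c] rather than h alone
    full_state_latent: bool = True

    def __post_init__(self) -> None:
        if self.lr <= 0:
            raise InvalidConfigError("learning rate must be positive")
        if any(c <= 0 for c in self.conv_channels) or self.lstm_width <= 0 or self.fused_width <= 0:
            raise InvalidConfigError("all widths must be positive")
        if self.full_state_latent and self.lstm_width % 2:
            raise InvalidConfigError("lstm_width must be even when the latent is [h; c]")
        if self.batch_size <= 0 or self.epochs <= 0:
            raise InvalidConfigError("batch size and epochs must be positive")

    @property
    def coarse_length(self) -> int:
        L = self.input_length
        for _ in self.conv_channels:
            L = (L + self.stride - 1) // self.stride  # conv with pad=k//2, stride s
        return L


@dataclass
class TaskProbabilities:
    """Per-episode 2-class probability vectors for the three affect tasks."""

    p_dep: np.ndarray
    p_val: np.ndarray
    p_aro: np.ndarray

    def __post_init__(self) -> None:
        for name in ("p_dep", "p_val", "p_aro"):
            v = np.asarray(getattr(self, name), dtype=float)
            setattr(self, name, v)
            if v.shape != (2,) or not np.isclose(v.sum(), 1.0, atol=1e-6) or (v < 0).any():
                raise ShapeError(f"{name} must be a 2-class probability vector")

    def positives(self) -> np.ndarray:
        """P(high) for (depression, valence, arousal)."""
        return np.array([self.p_dep[1], self.p_val[1], self.p_aro[1]])


class _Encoder(Module):
    """Conv stack + LSTM; the final recurrent state is the latent.

    The signal is presented together with sin/cos positional channels and the
    pointwise signal-basis products (a deterministic harmonic featurization,
    the 1-D analogue of feeding a spectrogram): integrating a product channel
    over time yields the signal's projection onto that basis function, which
    is the sufficient statistic of the slow drifts the decoder reconstructs.
    """

    def __init__(self, rng, cfg: TPEDNConfig):
        self.cfg = cfg
        in_ch = 1 + (4 * _N_POS_FREQS if cfg.harmonic_features else 0)
        chans = (in_ch,) + tuple(cfg.conv_channels)
        self.convs = [
            Conv1d(rng, chans[i], chans[i + 1], cfg.kernel, stride=cfg.stride, pad=cfg.kernel // 2)
            for i in range(len(cfg.conv_channels))
        ]
        hidden = cfg.lstm_width // 2 if cfg.full_state_latent else cfg.lstm_width
        self.lstm = LSTM(rng, cfg.conv_channels[-1], hidden, forget_bias=3.0)
        self._pos = np.ascontiguousarray(_positional_basis(cfg.input_length).transpose(0, 2, 1))

    def forward(self, x: Tensor):
        """x: (B, L) -> (latent (B, lstm_width), conv taps [(B, C_i, L_i), ...])."""
        B, L = x.shape
        h = x.reshape(B, 1, L)
        if self.cfg.harmonic_features:
            pos = Tensor(np.broadcast_to(self._pos, (B, self._pos.shape[1], L)).copy())
            h = concat([h, pos, h * pos], axis=1)
        taps = []
        for conv in self.convs:
            h = conv(h).relu()
            taps.append(h)
        seq = h.transpose(0, 2, 1)  # (B, L_c, C)
        _, state = self.lstm(seq)
        latent = state if self.cfg.full_state_latent else state[:, : self.lstm.hidden]
        return latent, taps


#: Fourier time-basis frequencies (cycles per episode) spanning the band of
#: the slow physiological drifts; dense at the low end where they live.
_POS_CYCLES = (
    0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 1.0, 1.1, 1.2,
    1.4, 1.6, 1.8, 2.0, 2.25, 2.5, 2.75, 3.0, 3.5, 4.0, 4.5, 5.0, 6.0, 8.0,
)
_N_POS_FREQS = len(_POS_CYCLES)


def _positional_basis(length: int) -> np.ndarray:
    """(1, length, 2 * _N_POS_FREQS) sin/cos time basis."""
    t = np.arange(length) / length
    cycles = np.array(_POS_CYCLES)
    phases = 2.0 * np.pi * t[:, None] * cycles[None, :]
    return np.concatenate([np.sin(phases), np.cos(phases)], axis=1)[None]


class _Decoder(Module):
    """Mirror decoder for one modality, fed by that modality's latent."""

    def __init__(self, rng, cfg: TPEDNConfig):
        hidden = cfg.lstm_width // 2
        self.expand = Linear(rng, cfg.lstm_width, hidden)
        self.lstm = LSTM(rng, hidden + 2 * _N_POS_FREQS, hidden)
        chans = (hidden,) + tuple(reversed(cfg.conv_channels[:-1])) + (1,)
        self.deconvs = [
            ConvTranspose1d(rng, chans[i], chans[i + 1], cfg.kernel, stride=cfg.stride)
            for i in range(len(chans) - 1)
        ]
        # latent-conditioned harmonic readout: the latent directly sets the
        # amplitude/phase of each slow Fourier component (additive skip around
        # the recurrent path, which models the non-harmonic residual)
        self.harmonic = Linear(rng, cfg.lstm_width, 2 * _N_POS_FREQS)
        self.harmonic.weight.data *= 0.1  # start near zero: no initial wiggle
        self.coarse_length = cfg.coarse_length
        self.out_length = cfg.input_length
        self._pos = _positional_basis(cfg.coarse_length)
        self._pos_full = _positional_basis(cfg.input_length)

    def forward(self, latent: Tensor) -> Tensor:
        B = latent.shape[0]
        z = self.expand(latent).tanh()
        rep = z.reshape(B, 1, z.shape[1]) * Tensor(np.ones((1, self.coarse_length, 1)))
        pos = Tensor(np.broadcast_to(self._pos, (B, self.coarse_length, self._pos.shape[2])).copy())
        rep = concat([rep, pos], axis=2)
        outs, _ = self.lstm(rep, collect_outputs=True)
        h = outs.transpose(0, 2, 1)  # (B, H, L_c)
        for i, deconv in enumerate(self.deconvs):
            h = deconv(h)
            if i < len(self.deconvs) - 1:
                h = h.relu()
        h = h.reshape(B, h.shape[2])
        if h.shape[1] != self.out_length:  # stride rounding
            h = h[:, : self.out_length]
        coef = self.harmonic(latent).reshape(B, 1, 2 * _N_POS_FREQS)
        basis = Tensor(np.broadcast_to(self._pos_full, (B, self.out_length, 2 * _N_POS_FREQS)).copy())
        return h + (basis * coef).sum(axis=2)


class TPEDN(Module):
    """Triple-path encoder-decoder with reconstruction and classification heads."""

    def __init__(self, config: TPEDNConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        self.encoders = {m.value: _Encoder(rng, config) for m in config.modalities}
        self.fusion = Linear(rng, len(config.modalities) * config.lstm_width, config.fused_width)
        self.decoders = {m.value: _Decoder(rng, config) for m in config.modalities}
        self.heads = {t: Linear(rng, config.fused_width, 2) for t in TASKS}

    # -- pieces ---------------------------------------------------------------

    def encode_modality(self, modality: Modality, x: Tensor):
        if x.ndim != 2 or x.shape[1] != self.config.input_length:
            raise ShapeError(
                f"expected (B, {self.config.input_length}) input, got {tuple(x.shape)}"
            )
        return self.encoders[Modality(modality).value](x)

    def fuse_latents(self, latents: dict[Modality, Tensor]) -> Tensor:
        parts = []
        for m in self.config.modalities:
            lat = latents.get(m)
            if lat is None:
                raise MissingModalityError(f"missing latent for modality {m.value}")
            parts.append(lat)
        return self.fusion(concat(parts, axis=1))

    def forward_trunk(self, xs: dict[Modality, Tensor]):
        """Encode every modality and fuse; returns (fused, latents, taps)."""
        latents, taps = {}, {}
        for m in self.config.modalities:
            if m not in xs:
                raise MissingModalityError(f"missing modality {m.value}")
            latents[m], taps[m] = self.encode_modality(m, xs[m])
        return self.fuse_latents(latents), latents, taps

    def reconstruct(self, latents: dict[Modality, Tensor]) -> dict[Modality, Tensor]:
        """Per-modality reconstructions from the per-modality latents."""
        out = {}
        for m in self.config.modalities:
            if m not in latents:
                raise MissingModalityError(f"missing latent for modality {m.value}")
            out[m] = self.decoders[m.value](latents[m])
        return out

    def head_logits(self, fused: Tensor) -> dict[str, Tensor]:
        return {t: self.heads[t](fused) for t in TASKS}

    def predict_proba(self, xs: dict[Modality, np.ndarray]) -> dict[str, np.ndarray]:
        fused, _, _ = self.forward_trunk({m: Tensor(v) for m, v in xs.items()})
        return {t: logit.softmax(axis=-1).data for t, logit in self.head_logits(fused).items()}

    def encoder_taps(self, xs: dict[Modality, np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
        """Time-pooled first/second conv-stage features, concatenated across
        modalities; the fusion conditioning consumed by the image branch."""
        _, _, taps = self.forward_trunk({m: Tensor(v) for m, v in xs.items()})
        u1 = np.concatenate([taps[m][0].data.mean(axis=2) for m in self.config.modalities], axis=1)
        u2 = np.concatenate([taps[m][-1].data.mean(axis=2) for m in self.config.modalities], axis=1)
        return u1, u2

    @property
    def tap_dims(self) -> tuple[int, int]:
        n = len(self.config.modalities)
        return n * self.config.conv_channels[0], n * self.config.conv_channels[-1]


# ---------------------------------------------------------------------------
# Data marshalling


def signals_to_arrays(records, config: TPEDNConfig) -> dict[Modality, np.ndarray]:
    """Stack preprocessed episode signals into (N, input_length) arrays."""
    if not records:
        raise DataError("no episodes provided")
    out: dict[Modality, np.ndarray] = {}
    for m in config.modalities:
        rows = []
        for rec in records:
            if m not in rec.signals:
                raise MissingModalityError(f"episode {rec.episode_id} lacks {m.value}")
            v = rec.signals[m].values
            if v.ndim != 1:
                v = np.sqrt((v**2).sum(axis=1))
            if v.shape[0] < config.input_length:
                raise ShapeError(
                    f"episode {rec.episode_id} {m.value} has {v.shape[0]} samples, "
                    f"expected >= {config.input_length}"
                )
            rows.append(v[: config.input_length])
        out[m] = np.stack(rows)
    return out


def task_labels(records) -> dict[str, np.ndarray]:
    labels = {}
    for t in TASKS:
        try:
            labels[t] = np.array([getattr(r.labels, t) for r in records], dtype=int)
        except AttributeError as exc:  # pragma: no cover
            raise LabelError(f"label table missing task {t}") from exc
    return labels


def _batches(n: int, batch_size: int, rng: np.random.Generator):
    order = rng.permutation(n)
    for i in range(0, n, batch_size):
        yield order[i : i + batch_size]


# ---------------------------------------------------------------------------
# Training stages


def pretrain_ssl(records, config: TPEDNConfig, model: TPEDN | None = None):
    """Self-supervised reconstruction pretraining.

    Returns (model, history) where history is a list of per-epoch dicts with
    train/validation MSE.  Early stopping restores the best validation state.
    """
    if len(records) < 2:
        raise DataError("need at least 2 episodes to pretrain")
    model = model or TPEDN(config)
    xs = signals_to_arrays(records, config)
    n = len(records)
    rng = np.random.default_rng(config.seed + 1)
    order = rng.permutation(n)
    n_val = max(1, int(round(config.val_fraction * n)))
    val_idx, train_idx = order[:n_val], order[n_val:]
    if train_idx.size == 0:
        raise DataError("training split is empty")
    opt = Adam(model.parameters(), lr=config.lr)
    history: list[dict] = []
    best_val, best_state, wait = np.inf, None, 0

    def recon_mse(idx) -> float:
        latents = {
            m: model.encode_modality(m, Tensor(v[idx]))[0] for m, v in xs.items()
        }
        recons = model.reconstruct(latents)
        losses = [mse_loss(recons[m], xs[m][idx]) for m in config.modalities]
        total = losses[0]
        for l in losses[1:]:
            total = total + l
        return total * (1.0 / len(losses))

    for epoch in range(config.epochs):
        train_losses = []
        for idx in _batches(train_idx.size, config.batch_size, rng):
            loss = recon_mse(train_idx[idx])
            opt.zero_grad()
            loss.backward()
            opt.step()
            train_losses.append(loss.data.item())
        val_loss = recon_mse(val_idx).data.item()
        history.append(
            {"epoch": epoch, "train_mse": float(np.mean(train_losses)), "val_mse": val_loss}
        )
        if val_loss < best_val - 1e-9:
            best_val, best_state, wait = val_loss, model.state_dict(), 0
        else:
            wait += 1
            if wait >= config.patience:
                break
    if best_state is not None:
        model.load_state_dict(best_state)
    return model, history


def reconstruction_mse(model: TPEDN, records) -> float:
    """Mean reconstruction MSE of ``model`` on ``records`` (no training)."""
    xs = signals_to_arrays(records, model.config)
    latents = {m: model.encode_modality(m, Tensor(v))[0] for m, v in xs.items()}
    recons = model.reconstruct(latents)
    return float(
        np.mean([np.mean((recons[m].data - xs[m]) ** 2) for m in model.config.modalities])
    )


def finetune_heads(
    records,
    config: TPEDNConfig,
    pretrained_state: dict | None = None,
    epochs: int | None = None,
    freeze_trunk: bool = False,
):
    """Supervised fine-tuning of the three affect heads (summed cross-entropy).

    Transfers ``pretrained_state`` encoder weights when given; otherwise trains
    from scratch.  Returns (model, history).
    """
    if not records:
        raise DataError("empty training set")
    model = TPEDN(config)
    if pretrained_state is not None:
        model.load_state_dict({k: v for k, v in pretrained_state.items() if k in dict(model.named_parameters())})
    xs = signals_to_arrays(records, config)
    ys = task_labels(records)
    rng = np.random.default_rng(config.seed + 2)
    head_params = [p for head in model.heads.values() for p in head.parameters()]
    trainable = head_params if freeze_trunk else model.parameters()
    opt = Adam(trainable, lr=config.lr)
    n_epochs = epochs if epochs is not None else config.epochs
    history = []
    for epoch in range(n_epochs):
        losses = []
        for idx in _batches(len(records), config.batch_size, rng):
            batch = {m: Tensor(v[idx]) for m, v in xs.items()}
            fused, _, _ = model.forward_trunk(batch)
            logits = model.head_logits(fused)
            loss = cross_entropy_logits(logits[TASKS[0]], ys[TASKS[0]][idx])
            for t in TASKS[1:]:
                loss = loss + cross_entropy_logits(logits[t], ys[t][idx])
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(loss.data.item())
        history.append({"epoch": epoch, "train_ce": float(np.mean(losses))})
    return model, history


def predict_records(model: TPEDN, records) -> list[TaskProbabilities]:
    xs = signals_to_arrays(records, model.config)
    probs = model.predict_proba(xs)
    return [
        TaskProbabilities(
            p_dep=probs["depression"][i], p_val=probs["valence"][i], p_aro=probs["arousal"][i]
        )
        for i in range(len(records))
    ]


# ---------------------------------------------------------------------------
# Checkpointing


def save_checkpoint(model: TPEDN, path: str | Path, history=None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    cfg = model.config
    meta = {
        "config": {
            "conv_channels": list(cfg.conv_channels),
            "kernel": cfg.kernel,
            "stride": cfg.stride,
            "lstm_width": cfg.lstm_width,
            "fused_width": cfg.fused_width,
            "input_length": cfg.input_length,
            "modalities": [m.value for m in cfg.modalities],
            "lr": cfg.lr,
            "batch_size": cfg.batch_size,
            "epochs": cfg.epochs,
            "patience": cfg.patience,
            "val_fraction": cfg.val_fraction,
            "seed": cfg.seed,
            "harmonic_features": cfg.harmonic_features,
            "full_state_latent": cfg.full_state_latent,
        },
        "history": history or [],
    }
    np.savez_compressed(path, __meta__=json.dumps(meta), **model.state_dict())


def load_checkpoint(path: str | Path) -> TPEDN:
    with np.load(Path(path), allow_pickle=False) as data:
        meta = json.loads(str(data["__meta__"]))
        cfg_d = meta["config"]
        cfg_d["conv_channels"] = tuple(cfg_d["conv_channels"])
        cfg_d["modalities"] = tuple(Modality(m) for m in cfg_d["modalities"])
        model = TPEDN(TPEDNConfig(**cfg_d))
        model.load_state_dict({k: data[k] for k in data.files if k != "__meta__"})
    return model
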