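"""Signal-to-image transforms: MR-STFT, wavelet packets, multiscale HHT.

Each transform renders one modality stream as a fixed-size nonnegative 2-D
energy map (rows = frequency/scale, columns = time) so the image branch can
treat physiological episodes as pictures:

- ``mr_stft``: short-time Fourier analysis whose Gaussian window length varies
  inversely with the analysis frequency (constant-Q behaviour), clamped to a
  usable range;
- ``wpt_image``: full wavelet-packet tree energies, leaves in natural
  frequency order;
- ``mhht_image``: empirical-mode decomposition of the signal at several dyadic
  smoothing scales, Hilbert instantaneous amplitude/frequency per mode, energy
  binned onto a shared time-frequency grid and summed over scales.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
import pywt
from scipy.interpolate import CubicSpline
from scipy.ndimage import zoom as ndi_zoom
from scipy.signal import hilbert

from .errors import ConfigurationError, DegenerateSignalError, InvalidArgumentError
from .types import Modality, ModalitySignal


class Transform(str, Enum):
    MRSTFT = "mrstft"
    WPT = "wpt"
    MHHT = "mhht"


@dataclass
class TimeFrequencyImage:
    transform: Transform
    modality: Modality | None
    grid: np.ndarray  # (F, T), nonnegative energy
    freq_axis: np.ndarray  # bin centre frequencies (or scale-band centres)
    time_axis: np.ndarray  # bin centre times in s

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        if self.grid.ndim != 2:
            raise ConfigurationError("grid must be 2-D")
        if not np.all(np.isfinite(self.grid)) or np.any(self.grid < 0):
            raise ConfigurationError("grid entries must be finite and nonnegative")


def _resize_grid(grid: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Bilinear resize preserving nonnegativity."""
    if grid.shape == shape:
        return grid
    factors = (shape[0] / grid.shape[0], shape[1] / grid.shape[1])
    out = ndi_zoom(grid, factors, order=1, grid_mode=True, mode="nearest")
    out = out[: shape[0], : shape[1]]
    return np.clip(out, 0.0, None)


# ---------------------------------------------------------------------------
# Multi-resolution STFT


def default_window_law(rate: float, cycles: float = 6.0, l_min_s: float = 4.0, l_max_s: float = 60.0):
    """Window length in samples for analysis frequency f: clamp(c*rate/f)."""

    def law(f: float) -> int:
        length = cycles * rate / max(f, 1e-12)
        length = min(max(length, l_min_s * rate), l_max_s * rate)
        return max(4, int(round(length)))

    return law


def constant_window_law(length_samples: int):
    """Fixed-length window law; reduces MR-STFT to a plain Gaussian-window STFT."""

    def law(_f: float) -> int:
        return int(length_samples)

    return law


def mr_stft(
    values: np.ndarray,
    rate: float,
    window_law=None,
    F: int = 64,
    T: int = 64,
    f_min: float | None = None,
    f_max: float | None = None,
    freq_spacing: str = "log",
) -> TimeFrequencyImage:
    """Squared-magnitude multi-resolution STFT on an (F, T) grid.

    For each analysis frequency, a Gaussian window of frequency-dependent
    length is centred at each time bin (truncated at the signal edges) and the
    squared modulus of the windowed Fourier integral is evaluated.  Rows are
    ordered low-to-high frequency.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1:
        raise ConfigurationError("mr_stft expects a single-channel signal")
    if not np.all(np.isfinite(x)):
        raise InvalidArgumentError("input contains non-finite samples")
    if F < 2 or T < 2:
        raise ConfigurationError("F and T must each be at least 2")
    n = x.shape[0]
    duration = n / rate
    if window_law is None:
        window_law = default_window_law(rate)
        if n < 4.0 * rate:
            raise DegenerateSignalError("signal shorter than the minimum analysis window")
    if f_min is None:
        f_min = max(2.0 / duration, 1e-4)
    if f_max is None:
        f_max = 0.45 * rate
    if freq_spacing == "log":
        freqs = np.geomspace(f_min, f_max, F)
    else:
        freqs = np.linspace(f_min, f_max, F)
    times = (np.arange(T) + 0.5) * duration / T
    centers = np.round(times * rate).astype(int)

    grid = np.empty((F, T))
    sample_idx = np.arange(n)
    for fi, f in enumerate(freqs):
        L = int(window_law(f))
        if L < 2:
            raise DegenerateSignalError("window law returned a degenerate window")
        half = L // 2
        offs = np.arange(-half, L - half)  # window support, centred
        sigma = L / 6.0
        w = np.exp(-0.5 * (offs / sigma) ** 2)
        phase = np.exp(-2j * np.pi * f * offs / rate)
        kern = w * phase
        # windows truncated at the edges: out-of-range samples contribute zero
        idx = centers[:, None] + offs[None, :]
        valid = (idx >= 0) & (idx < n)
        seg = np.where(valid, x[np.clip(idx, 0, n - 1)], 0.0)
        X = seg @ kern
        grid[fi] = np.abs(X) ** 2
    return TimeFrequencyImage(Transform.MRSTFT, None, grid, freqs, times)


# ---------------------------------------------------------------------------
# Wavelet packet transform


@dataclass
class PacketTree:
    """Full wavelet-packet decomposition to a fixed depth.

    ``leaves`` are the terminal-node coefficient arrays in natural frequency
    order.  Orthogonal wavelets with periodization give perfect reconstruction
    and exact energy conservation.
    """

    wavelet: str
    levels: int
    leaves: list[np.ndarray]
    n_samples: int

    def reconstruct(self) -> np.ndarray:
        if self.levels == 0:
            return self.leaves[0].copy()
        wp = pywt.WaveletPacket(
            data=None, wavelet=self.wavelet, mode="periodization", maxlevel=self.levels
        )
        for node, leaf in zip(
            pywt.WaveletPacket(
                data=np.zeros(self.n_samples), wavelet=self.wavelet, mode="periodization"
            ).get_level(self.levels, order="freq"),
            self.leaves,
        ):
            wp[node.path] = leaf
        return np.asarray(wp.reconstruct(update=False))[: self.n_samples]


def wpt_decompose(values: np.ndarray, wavelet_name: str = "db4", levels: int = 5) -> PacketTree:
    """Complete binary wavelet-packet tree via recursive filtering + decimation."""
    x = np.asarray(values, dtype=float)
    if wavelet_name not in pywt.wavelist(kind="discrete"):
        raise ConfigurationError(f"unsupported wavelet {wavelet_name!r}")
    if levels < 0:
        raise ConfigurationError("levels must be nonnegative")
    if x.shape[0] < 2**levels:
        raise ConfigurationError("signal shorter than 2**levels samples")
    if levels == 0:
        return PacketTree(wavelet_name, 0, [x.copy()], x.shape[0])
    wp = pywt.WaveletPacket(data=x, wavelet=wavelet_name, mode="periodization", maxlevel=levels)
    leaves = [np.asarray(node.data, dtype=float) for node in wp.get_level(levels, order="freq")]
    return PacketTree(wavelet_name, levels, leaves, x.shape[0])


def wpt_image(
    values: np.ndarray,
    wavelet_name: str = "db4",
    levels: int = 5,
    T: int = 64,
    rate: float = 1.0,
) -> TimeFrequencyImage:
    """Energy map of the packet tree: row j = squared coefficients of leaf j.

    Each leaf's coefficient sequence is linearly resampled to T time bins;
    F = 2**levels rows in natural frequency order.
    """
    tree = wpt_decompose(values, wavelet_name, levels)
    n = tree.n_samples
    duration = n / rate
    F = 2**levels
    grid = np.empty((F, T))
    t_out = (np.arange(T) + 0.5) / T
    for j, leaf in enumerate(tree.leaves):
        e = leaf**2
        m = e.shape[0]
        t_in = (np.arange(m) + 0.5) / m
        grid[j] = np.interp(t_out, t_in, e)
    nyq = rate / 2.0
    freqs = (np.arange(F) + 0.5) * nyq / F
    times = t_out * duration
    return TimeFrequencyImage(Transform.WPT, None, grid, freqs, times)


# ---------------------------------------------------------------------------
# Empirical mode decomposition and multiscale HHT


@dataclass
class EMDResult:
    imfs: list[np.ndarray]
    residue: np.ndarray

    def reconstruct(self) -> np.ndarray:
        out = self.residue.copy()
        for imf in self.imfs:
            out = out + imf
        return out


def _local_extrema(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    d = np.diff(x)
    maxima = np.where((np.hstack([d, -1.0]) < 0) & (np.hstack([1.0, d]) > 0))[0]
    minima = np.where((np.hstack([d, 1.0]) > 0) & (np.hstack([-1.0, d]) < 0))[0]
    return maxima, minima


def _envelope(t: np.ndarray, idx: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Cubic-spline envelope through extrema, with mirrored boundary extrema."""
    ti, xi = t[idx], x[idx]
    # mirror up to two extrema past each end to tame boundary swings
    k = min(2, len(idx) - 1)
    t_pre = 2 * t[0] - ti[1 : k + 1][::-1]
    x_pre = xi[1 : k + 1][::-1]
    t_post = 2 * t[-1] - ti[-k - 1 : -1][::-1]
    x_post = xi[-k - 1 : -1][::-1]
    tt = np.concatenate([t_pre, ti, t_post])
    xx = np.concatenate([x_pre, xi, x_post])
    order = np.argsort(tt)
    tt, xx = tt[order], xx[order]
    keep = np.concatenate([[True], np.diff(tt) > 0])
    return CubicSpline(tt[keep], xx[keep])(t)


def emd(
    values: np.ndarray,
    max_imfs: int = 8,
    sift_tol: float = 0.05,
    max_sift_iters: int = 50,
) -> EMDResult:
    """Standard EMD sifting; the identity sum(IMFs) + residue == input holds by
    construction.  Monotone inputs yield zero IMFs with residue == input."""
    x = np.asarray(values, dtype=float)
    if x.shape[0] < 8:
        raise InvalidArgumentError("EMD needs at least 8 samples")
    if not np.all(np.isfinite(x)):
        raise InvalidArgumentError("input contains non-finite samples")
    t = np.arange(x.shape[0], dtype=float)
    residue = x.copy()
    total_energy = float(np.sum(x * x))
    imfs: list[np.ndarray] = []
    while len(imfs) < max_imfs:
        # a negligible residue carries no more modes; further sifting only
        # amplifies boundary-spline artifacts
        if float(np.sum(residue * residue)) < 1e-12 * total_energy + 1e-30:
            break
        maxima, minima = _local_extrema(residue)
        if len(maxima) < 2 or len(minima) < 2:
            break  # monotone (or trend-only) residue
        h = residue.copy()
        h_energy0 = float(np.sum(h * h))
        for _ in range(max_sift_iters):
            mx, mn = _local_extrema(h)
            if len(mx) < 2 or len(mn) < 2:
                break
            mean_env = 0.5 * (_envelope(t, mx, h) + _envelope(t, mn, h))
            h_new = h - mean_env
            if float(np.sum(h_new * h_new)) > 3.0 * h_energy0 + 1e-30:
                break  # spline overshoot would amplify the mode; keep current h
            denom = float(np.sum(h * h)) + 1e-30
            sd = float(np.sum(mean_env * mean_env)) / denom
            h = h_new
            if sd < sift_tol:
                break
        imfs.append(h)
        residue = residue - h
    return EMDResult(imfs, residue)


def _hilbert_energy(imf: np.ndarray, rate: float) -> tuple[np.ndarray, np.ndarray]:
    """Instantaneous (frequency, squared amplitude) via the analytic signal."""
    analytic = hilbert(imf)
    amp = np.abs(analytic)
    phase = np.unwrap(np.angle(analytic))
    freq = np.gradient(phase) * rate / (2.0 * np.pi)  # centred differences
    freq = np.clip(freq, 0.0, rate / 2.0)
    return freq, amp**2


def mhht_image(
    values: np.ndarray,
    rate: float,
    n_scales: int = 3,
    F: int = 64,
    T: int = 64,
    max_imfs: int = 6,
    f_max: float | None = None,
) -> TimeFrequencyImage:
    """Multiscale Hilbert-Huang energy map.

    The signal is smoothed and decimated to ``n_scales`` dyadic scales; each
    scale is EMD-decomposed; each mode's Hilbert energy is binned onto the
    shared (F, T) grid; scales are summed.  ``n_scales=1`` is the plain HHT of
    the unsmoothed signal.
    """
    x = np.asarray(values, dtype=float)
    n = x.shape[0]
    if n_scales < 1 or n // 2 ** (n_scales - 1) < 8:
        raise ConfigurationError("n_scales too large for the signal length")
    duration = n / rate
    if f_max is None:
        f_max = rate / 2.0
    f_edges = np.linspace(0.0, f_max, F + 1)
    t_edges = np.linspace(0.0, duration, T + 1)
    grid = np.zeros((F, T))
    for s in range(n_scales):
        step = 2**s
        if step == 1:
            ys, rs = x, rate
        else:
            kern = np.full(step, 1.0 / step)
            sm = np.convolve(x, kern, mode="same")
            ys, rs = sm[::step], rate / step
        ts = np.arange(ys.shape[0]) / rs
        result = emd(ys, max_imfs=max_imfs)
        for imf in result.imfs:
            freq, energy = _hilbert_energy(imf, rs)
            h, _, _ = np.histogram2d(freq, ts, bins=[f_edges, t_edges], weights=energy)
            grid += h
    f_centers = 0.5 * (f_edges[:-1] + f_edges[1:])
    t_centers = 0.5 * (t_edges[:-1] + t_edges[1:])
    return TimeFrequencyImage(Transform.MHHT, None, grid, f_centers, t_centers)


# ---------------------------------------------------------------------------
# Normalization and episode stacking


def normalize_image(img: TimeFrequencyImage, mode: str = "log1p-minmax") -> TimeFrequencyImage:
    """Compress dynamic range and map to [0, 1]; all-zero grids pass through."""
    g = img.grid
    if mode == "log1p-minmax":
        g = np.log1p(g)
        lo, hi = g.min(), g.max()
        if hi > lo:
            g = (g - lo) / (hi - lo)
    elif mode == "none":
        pass
    else:
        raise ConfigurationError(f"unknown normalization mode {mode!r}")
    return TimeFrequencyImage(img.transform, img.modality, g, img.freq_axis, img.time_axis)


#: default channel layout of an episode image stack
STACK_TRANSFORMS = (Transform.MRSTFT, Transform.WPT, Transform.MHHT)
STACK_MODALITIES = (Modality.HR, Modality.GSR, Modality.ACC)


def episode_image_stack(
    record,
    size: tuple[int, int] = (64, 64),
    transforms=STACK_TRANSFORMS,
    modalities=STACK_MODALITIES,
    wavelet: str = "db4",
    levels: int = 5,
    n_scales: int = 3,
    band_fraction: float = 0.12,
) -> np.ndarray:
    """Render one preprocessed episode as a (len(transforms)*len(modalities), F, T)
    stack of normalized energy maps.  Channel order: transform-major.

    ``band_fraction`` restricts the imaged band to [0, band_fraction * rate]:
    for 1 Hz conditioned wearable streams the physiological structure (slow
    drifts, phasic responses, activity bouts) lives far below the Nyquist
    frequency, and imaging the full band would spend almost every row on
    noise.
    """
    F, T = size
    chans = []
    for tr in transforms:
        for mod in modalities:
            sig = record.signals[mod]
            x = sig.values if sig.values.ndim == 1 else np.sqrt((sig.values**2).sum(axis=1))
            duration = x.shape[0] / sig.rate
            if tr is Transform.MRSTFT:
                img = mr_stft(
                    x, sig.rate, F=F, T=T,
                    f_min=1.5 / duration, f_max=band_fraction * sig.rate,
                )
            elif tr is Transform.WPT:
                lv = min(levels, int(np.floor(np.log2(x.shape[0]))))
                img = wpt_image(x, wavelet, lv, T=T, rate=sig.rate)
                keep = max(2, int(np.ceil(2.0 * band_fraction * 2**lv)))
                img = TimeFrequencyImage(
                    img.transform, img.modality, img.grid[:keep],
                    img.freq_axis[:keep], img.time_axis,
                )
            elif tr is Transform.MHHT:
                img = mhht_image(
                    x, sig.rate, n_scales=n_scales, F=F, T=T,
                    f_max=band_fraction * sig.rate,
                )
            else:
                raise ConfigurationError(f"unknown transform {tr}")
            img = normalize_image(img)
            chans.append(_resize_grid(img.grid, (F, T)))
    return np.stack(chans, axis=0)


def stack_channel_names(transforms=STACK_TRANSFORMS, modalities=STACK_MODALITIES) -> list[str]:
    return [f"{tr.value}_{mod.value.lower()}" for tr in transforms for mod in modalities]


def write_image_stacks(stacks: dict[str, np.ndarray], path) -> None:
    """Persist per-episode stacks as one compressed array container."""
    np.savez_compressed(path, **stacks)


def read_image_stacks(path) -> dict[str, np.ndarray]:
    with np.load(path) as data:
        return {k: data[k] for k in data.files}
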