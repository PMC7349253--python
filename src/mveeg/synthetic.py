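"""Synthetic motor-imagery EEG generator.

Produces labelled multichannel trial sets whose class structure mimics
event-related desynchronization / synchronization (ERD/ERS): a shared
1/f-shaped background in the 0.5-100 Hz acquisition band, plus a
class-specific oscillatory signature confined to one mu/beta sub-band
(8-30 Hz) on a small set of contiguous channels.  The generator exists so
the full pipeline (CSP -> stacked RBM -> parametric t-SNE -> SVM) can be
exercised end to end without external recordings.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

__all__ = [
    "TrialSet",
    "SimConfig",
    "ANALYSIS_BANDS",
    "generate_trialset",
    "generate_confusion",
]

#: The five mu/beta analysis sub-bands tiling 8-30 Hz (Hz).
ANALYSIS_BANDS: tuple[tuple[float, float], ...] = (
    (8.0, 12.0),
    (12.0, 16.0),
    (16.0, 20.0),
    (20.0, 24.0),
    (24.0, 30.0),
)


@dataclass
class TrialSet:
    """Labelled multichannel EEG trials.

    Parameters
    ----------
    data
        Array of shape ``(n_trials, n_channels, n_samples)`` in
        microvolt-like units.
    labels
        Integer class label per trial, in ``1..n_classes``.
    fs
        Sampling rate in Hz.
    channel_names, class_names
        Optional human-readable names; auto-filled when empty.
    """

    data: np.ndarray
    labels: np.ndarray
    fs: float
    channel_names: list[str] = field(default_factory=list)
    class_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.data.ndim != 3:
            raise ValueError("data must be (n_trials, n_channels, n_samples)")
        if self.labels.shape != (self.data.shape[0],):
            raise ValueError("labels length must equal n_trials")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.data.shape[2] < 1:
            raise ValueError("n_samples must be positive")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("data contains non-finite values")
        if self.labels.size and self.labels.min() < 1:
            raise ValueError("labels must be 1-based positive integers")
        if not self.channel_names:
            self.channel_names = [f"ch{i + 1}" for i in range(self.n_channels)]
        if not self.class_names:
            self.class_names = [f"class{k}" for k in self.classes]

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def classes(self) -> np.ndarray:
        return np.unique(self.labels)

    def copy_with(self, data: np.ndarray) -> "TrialSet":
        """Return a TrialSet sharing metadata but holding new signal data."""
        return TrialSet(
            data=data,
            labels=self.labels.copy(),
            fs=self.fs,
            channel_names=list(self.channel_names),
            class_names=list(self.class_names),
        )


@dataclass
class SimConfig:
    """Configuration of the synthetic ERD/ERS generator.

    ``snr`` is the ratio of class-signature power to background power inside
    the signature's own sub-band on its own channels; 0 removes all class
    structure.
    """

    n_trials_per_class: int = 72
    n_channels: int = 22
    fs: float = 250.0
    trial_seconds: float = 3.0
    n_classes: int = 4
    snr: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_trials_per_class", "n_channels", "n_classes"):
            if int(getattr(self, name)) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.snr < 0:
            raise ValueError("snr must be non-negative")
        if self.fs <= 0 or self.trial_seconds <= 0:
            raise ValueError("fs and trial_seconds must be positive")
        if self.n_classes > len(ANALYSIS_BANDS):
            raise ValueError(
                f"at most {len(ANALYSIS_BANDS)} classes supported "
                "(one signature sub-band per class)"
            )

    @property
    def n_samples(self) -> int:
        return int(round(self.fs * self.trial_seconds))


def _pink_background(rng: np.random.Generator, shape: tuple[int, ...], fs: float) -> np.ndarray:
    """1/f-shaped Gaussian noise restricted to the 0.5-100 Hz acquisition band."""
    n = shape[-1]
    white = rng.standard_normal(shape)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    # 1/sqrt(f) amplitude shaping -> 1/f power; floor below 1 Hz to keep it finite
    shaping = 1.0 / np.sqrt(np.maximum(freqs, 1.0))
    shaping[0] = 0.0
    shaped = np.fft.irfft(np.fft.rfft(white, axis=-1) * shaping, n=n, axis=-1)
    high = min(100.0, 0.45 * fs)
    sos = sps.butter(4, [0.5, high], btype="bandpass", fs=fs, output="sos")
    shaped = sps.sosfiltfilt(sos, shaped, axis=-1)
    # unit variance per channel so snr has a fixed reference scale
    shaped /= shaped.std(axis=-1, keepdims=True)
    return shaped


def _band_power(x: np.ndarray, fs: float, band: tuple[float, float]) -> np.ndarray:
    """Mean power of ``x`` (last axis = time) inside ``band`` via the periodogram."""
    n = x.shape[-1]
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    spec = np.abs(np.fft.rfft(x, axis=-1)) ** 2
    mask = (freqs >= band[0]) & (freqs <= band[1])
    # Parseval: sum |X_k|^2 * 2 / n^2 over positive freqs ~ band variance
    return 2.0 * spec[..., mask].sum(axis=-1) / n**2


def _class_channels(k: int, n_channels: int) -> np.ndarray:
    """Four contiguous channels assigned to class ``k`` (0-based), wrapping."""
    width = min(4, n_channels)
    start = (k * width) % max(n_channels - width + 1, 1)
    return np.arange(start, start + width)


def generate_trialset(cfg: SimConfig) -> TrialSet:
    """Generate a labelled synthetic trial set. Deterministic given ``cfg.seed``.

    Background activity is shared across classes; class ``k`` adds a coherent
    sinusoidal burst (random frequency within its sub-band, random phase per
    trial) on its four designated channels, scaled so that burst power equals
    ``snr`` times the background power in that sub-band on those channels.
    """
    rng = np.random.default_rng(cfg.seed)
    n_total = cfg.n_trials_per_class * cfg.n_classes
    n = cfg.n_samples
    t = np.arange(n) / cfg.fs

    labels = np.repeat(np.arange(1, cfg.n_classes + 1), cfg.n_trials_per_class)
    data = _pink_background(rng, (n_total, cfg.n_channels, n), cfg.fs)

    if cfg.snr > 0:
        for i in range(n_total):
            k = labels[i] - 1
            band = ANALYSIS_BANDS[k]
            chans = _class_channels(k, cfg.n_channels)
            f0 = rng.uniform(band[0] + 0.5, band[1] - 0.5)
            phase = rng.uniform(0.0, 2.0 * np.pi)
            p_bg = _band_power(data[i, chans], cfg.fs, band).mean()
            amp = np.sqrt(2.0 * cfg.snr * p_bg)
            data[i, chans] += amp * np.sin(2.0 * np.pi * f0 * t + phase)
    else:
        # consume the same number of draws so trial-level structure stays
        # comparable across snr settings with a common seed
        for i in range(n_total):
            rng.uniform(size=2)

    data -= data.mean(axis=-1, keepdims=True)
    class_names = [f"imagery{k}" for k in range(1, cfg.n_classes + 1)]
    return TrialSet(data=data, labels=labels, fs=cfg.fs, class_names=class_names)


def generate_confusion(n_classes: int, style: str, n: int):
    """Deterministic confusion-matrix fixtures for metric testing.

    ``perfect`` puts all counts on the diagonal, ``uniform`` spreads them
    equally over every cell, ``degenerate`` predicts everything as class 1.
    ``n`` must be divisible by ``n_classes`` (and by ``n_classes**2`` for
    ``uniform``).
    """
    from .evaluate import ConfusionMatrix  # deferred: evaluate builds on this module

    if n_classes < 1 or n < 1:
        raise ValueError("n_classes and n must be positive")
    if n % n_classes:
        raise ValueError(f"n={n} not divisible by n_classes={n_classes}")
    per_class = n // n_classes
    counts = np.zeros((n_classes, n_classes), dtype=np.int64)
    if style == "perfect":
        np.fill_diagonal(counts, per_class)
    elif style == "uniform":
        if per_class % n_classes:
            raise ValueError("uniform style needs n divisible by n_classes**2")
        counts[:] = per_class // n_classes
    elif style == "degenerate":
        counts[:, 0] = per_class
    else:
        raise ValueError(f"unknown style {style!r}")
    names = [f"class{k}" for k in range(1, n_classes + 1)]
    return ConfusionMatrix(counts=counts, class_names=names)
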