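"""Multi-view feature construction for motor-imagery EEG.

Three views of each trial are built and spatially filtered with multi-class
common spatial patterns (CSP):

* F1 - the preprocessed time-domain signal;
* F2 - a five-band filter bank tiling 8-30 Hz (8-12, 12-16, 16-20, 20-24,
  24-30 Hz);
* F3 - wavelet-packet sub-band signals (depth-4 Daubechies tree, leaves
  whose nominal span intersects 8-30 Hz, reconstructed to the time domain).

Each view is passed through CSP banks fitted with one-versus-rest and
two-versus-two class dichotomies; per-component log-power features
``f_j = log(sum_t Z_j(t)^2)`` are concatenated, and the three view blocks
are 2-norm normalised per trial before concatenation into the multi-view
feature ``F = [F1'/||F1'||, F2'/||F2'||, F3'/||F3'||]``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pywt
from scipy import linalg as spl
from scipy import signal as sps

from .synthetic import ANALYSIS_BANDS, TrialSet

__all__ = [
    "BandSpec",
    "SpatialFilter",
    "CSPBank",
    "ViewFeatures",
    "MultiViewFeature",
    "DEFAULT_BANDS",
    "preprocess_trials",
    "bandpass_filter",
    "wpd_view",
    "fit_csp",
    "apply_csp",
    "fit_multiclass_csp",
    "build_view",
    "fit_view_banks",
    "apply_view_banks",
    "assemble_multiview",
]


@dataclass(frozen=True)
class BandSpec:
    """A frequency band in Hz, ``0 < low < high``."""

    low: float
    high: float

    def __post_init__(self) -> None:
        if not 0 < self.low < self.high:
            raise ValueError(f"invalid band {self.low}-{self.high} Hz")

    def validate_for(self, fs: float) -> None:
        if self.high >= fs / 2:
            raise ValueError(
                f"band {self.low}-{self.high} Hz exceeds Nyquist {fs / 2} Hz"
            )


#: Filter-bank partition of the 8-30 Hz mu/beta range.
DEFAULT_BANDS: tuple[BandSpec, ...] = tuple(BandSpec(*b) for b in ANALYSIS_BANDS)


@dataclass
class SpatialFilter:
    """A fitted CSP projection for one two-class dichotomy.

    ``W`` holds the first N and last N rows of the full CSP matrix (the most
    discriminative directions for each side); ``eigvals`` are the matching
    generalized eigenvalues (each pair sums to 1 with its complement).
    """

    W: np.ndarray
    n_pairs: int
    pairing_id: str
    eigvals: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=np.float64)
        if not np.all(np.isfinite(self.W)):
            raise ValueError("spatial filter contains non-finite values")
        if self.W.shape[0] > self.W.shape[1]:
            raise ValueError("2N must not exceed the channel count")


@dataclass
class CSPBank:
    """Ordered collection of SpatialFilters covering all class dichotomies."""

    filters: list[SpatialFilter]
    strategy: str


@dataclass
class ViewFeatures:
    """Per-trial CSP feature matrix for one view (F1', F2' or F3')."""

    values: np.ndarray
    view_id: str
    feature_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("view features contain non-finite values")


@dataclass
class MultiViewFeature:
    """Concatenation of the 2-norm-normalised view blocks."""

    values: np.ndarray
    block_slices: dict[str, slice]


# ---------------------------------------------------------------------------
# signal-level views
# ---------------------------------------------------------------------------

def preprocess_trials(
    raw: TrialSet,
    band: tuple[float, float] | None = (0.5, 100.0),
) -> TrialSet:
    """Per-channel mean removal per trial, plus an optional acquisition-band
    filter. The result is the time-domain view source F1."""
    data = raw.data - raw.data.mean(axis=-1, keepdims=True)
    out = raw.copy_with(data)
    if band is not None:
        high = min(band[1], 0.499 * raw.fs)
        if high <= band[0]:
            raise ValueError(f"fs={raw.fs} too low for band {band}")
        out = bandpass_filter(out, BandSpec(band[0], high))
    return out


def bandpass_filter(trials: TrialSet, band: BandSpec, order: int = 4) -> TrialSet:
    """Zero-phase Butterworth band-pass applied per channel per trial."""
    band.validate_for(trials.fs)
    sos = sps.butter(order, [band.low, band.high], btype="bandpass",
                     fs=trials.fs, output="sos")
    return trials.copy_with(sps.sosfiltfilt(sos, trials.data, axis=-1))


def wpd_leaf_bands(fs: float, levels: int) -> list[tuple[float, float]]:
    """Nominal frequency span of each depth-``levels`` leaf in natural
    frequency order: leaf k spans [k, k+1] * fs / 2**(levels+1)."""
    width = fs / 2 ** (levels + 1)
    return [(k * width, (k + 1) * width) for k in range(2**levels)]


def wpd_view(
    trials: TrialSet,
    levels: int = 4,
    wavelet: str = "db4",
    retain_band: tuple[float, float] | None = (8.0, 30.0),
) -> list[TrialSet]:
    """Wavelet-packet sub-band view: decompose to depth ``levels`` and
    reconstruct each retained leaf back to a time-domain signal set.

    Leaves are taken in natural frequency order; with ``retain_band`` set,
    only leaves whose nominal span intersects it (open overlap) are kept.
    ``retain_band=None`` keeps all ``2**levels`` leaves.  Zero-extension
    boundary handling keeps the analysis energy-preserving at any signal
    length, so the leaf signals sum back to the input.
    """
    n = trials.n_samples
    if n < 2**levels:
        raise ValueError(f"n_samples={n} too short for {levels} levels")
    spans = wpd_leaf_bands(trials.fs, levels)
    if retain_band is None:
        keep = list(range(len(spans)))
    else:
        lo, hi = retain_band
        keep = [k for k, (a, b) in enumerate(spans) if a < hi and b > lo]

    wp = pywt.WaveletPacket(trials.data, wavelet, mode="zero",
                            maxlevel=levels, axis=-1)
    paths = [node.path for node in wp.get_level(levels, order="freq")]
    out: list[TrialSet] = []
    for k in keep:
        solo = pywt.WaveletPacket(None, wavelet, mode="zero",
                                  maxlevel=levels, axis=-1)
        solo[paths[k]] = wp[paths[k]].data
        rec = solo.reconstruct(update=False)
        out.append(trials.copy_with(rec[..., :n]))
    return out


# ---------------------------------------------------------------------------
# CSP
# ---------------------------------------------------------------------------

def _class_covariance(data: np.ndarray, ridge: float) -> np.ndarray:
    """Trace-normalised spatial covariance averaged over trials, with a
    small ridge for conditioning."""
    covs = np.einsum("ncs,nds->ncd", data, data)
    traces = np.einsum("ncc->n", covs)
    if np.any(traces <= 0):
        raise ValueError("trial with zero total power; cannot normalise covariance")
    cov = (covs / traces[:, None, None]).mean(axis=0)
    return cov + ridge * np.trace(cov) * np.eye(cov.shape[0])


def fit_csp(
    class_a: np.ndarray,
    class_b: np.ndarray,
    n_pairs: int = 2,
    ridge: float = 1e-10,
    pairing_id: str = "a_vs_b",
) -> SpatialFilter:
    """Fit a two-class CSP filter by the generalized eigenproblem
    ``Sa w = lambda (Sa + Sb) w``.

    Rows of the returned ``W`` are the ``n_pairs`` most class-a-discriminative
    directions (largest lambda) followed by the ``n_pairs`` most
    class-b-discriminative ones (smallest lambda). Eigenvectors are scaled so
    ``W (Sa + Sb) W^T = I``, hence the per-component diagonal pair of
    ``W Sa W^T`` and ``W Sb W^T`` sums to 1.
    """
    class_a = np.asarray(class_a, dtype=np.float64)
    class_b = np.asarray(class_b, dtype=np.float64)
    if class_a.size == 0 or class_b.size == 0:
        raise ValueError("both classes must be non-empty")
    n_channels = class_a.shape[1]
    if 2 * n_pairs > n_channels:
        raise ValueError(f"2N={2 * n_pairs} exceeds n_channels={n_channels}")
    Sa = _class_covariance(class_a, ridge)
    Sb = _class_covariance(class_b, ridge)
    composite = Sa + Sb
    min_eig = spl.eigvalsh(composite)[0]
    if min_eig <= 0:
        raise ValueError(
            "composite covariance is rank deficient; increase the ridge "
            "regularization or supply more / longer trials"
        )
    evals, evecs = spl.eigh(Sa, composite)  # ascending; v^T (Sa+Sb) v = I
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    W_full = evecs.T
    rows = np.r_[0:n_pairs, n_channels - n_pairs:n_channels]
    return SpatialFilter(
        W=W_full[rows],
        n_pairs=n_pairs,
        pairing_id=pairing_id,
        eigvals=evals[rows],
    )


def apply_csp(
    filt: SpatialFilter,
    trial: np.ndarray,
    zero_power: str = "floor",
) -> np.ndarray:
    """Project trial(s) through a spatial filter and take log component power:
    ``Z = W X``, ``f_j = log(sum_t Z_j(t)^2)`` (no variance normalisation).

    Accepts a single ``(channels, samples)`` trial or a stacked
    ``(trials, channels, samples)`` array. ``zero_power`` controls handling
    of components with exactly zero power: ``"floor"`` clamps at machine
    epsilon with a warning, ``"error"`` raises.
    """
    trial = np.asarray(trial, dtype=np.float64)
    single = trial.ndim == 2
    X = trial[None] if single else trial
    if X.shape[1] != filt.W.shape[1]:
        raise ValueError(
            f"channel mismatch: filter expects {filt.W.shape[1]}, got {X.shape[1]}"
        )
    Z = np.einsum("jc,ncs->njs", filt.W, X)
    power = (Z**2).sum(axis=-1)
    if np.any(power == 0):
        if zero_power == "error":
            raise ValueError("zero-power CSP component (log undefined)")
        warnings.warn("zero-power CSP component floored at machine epsilon",
                      RuntimeWarning, stacklevel=2)
        power = np.maximum(power, np.finfo(np.float64).eps)
    f = np.log(power)
    return f[0] if single else f


def _dichotomies(classes: np.ndarray, strategy: str) -> list[tuple[str, np.ndarray, np.ndarray]]:
    classes = np.asarray(sorted(classes))
    out: list[tuple[str, np.ndarray, np.ndarray]] = []
    if strategy in ("ovr", "both"):
        for k in classes:
            rest = classes[classes != k]
            out.append((f"ovr:{k}", np.array([k]), rest))
    if strategy in ("two_vs_two", "both"):
        if len(classes) != 4:
            raise ValueError("two_vs_two strategy requires exactly 4 classes")
        seen = set()
        for pair in combinations(classes, 2):
            if classes[0] not in pair:
                continue  # fix the first class on one side to avoid duplicates
            rest = tuple(c for c in classes if c not in pair)
            key = frozenset((pair, rest))
            if key in seen:
                continue
            seen.add(key)
            out.append((
                f"tvt:{pair[0]}{pair[1]}_vs_{rest[0]}{rest[1]}",
                np.array(pair), np.array(rest),
            ))
    if strategy not in ("ovr", "two_vs_two", "both"):
        raise ValueError(f"unknown strategy {strategy!r}")
    return out


def fit_multiclass_csp(
    trials: TrialSet,
    strategy: str = "both",
    n_pairs: int = 2,
    ridge: float = 1e-10,
) -> CSPBank:
    """Fit a bank of CSP filters covering the multi-class dichotomies.

    ``ovr`` yields one filter per class (class vs pooled rest); for four
    classes ``two_vs_two`` yields the three balanced splits
    {1,2}v{3,4}, {1,3}v{2,4}, {1,4}v{2,3}; ``both`` concatenates them
    (7 filters for 4 classes).
    """
    classes = trials.classes
    if len(classes) < 2:
        raise ValueError("need at least 2 classes to fit CSP")
    filters = []
    for pairing_id, side_a, side_b in _dichotomies(classes, strategy):
        mask_a = np.isin(trials.labels, side_a)
        mask_b = np.isin(trials.labels, side_b)
        filters.append(fit_csp(trials.data[mask_a], trials.data[mask_b],
                               n_pairs=n_pairs, ridge=ridge, pairing_id=pairing_id))
    return CSPBank(filters=filters, strategy=strategy)


# ---------------------------------------------------------------------------
# view assembly
# ---------------------------------------------------------------------------

def fit_view_banks(
    sources: list[TrialSet],
    fit_indices: np.ndarray | None = None,
    strategy: str = "both",
    n_pairs: int = 2,
    ridge: float = 1e-10,
) -> list[CSPBank]:
    """Fit one CSP bank per source signal set, on ``fit_indices`` only
    (all trials when None). CSP fitting is the only supervised step, so
    restricting it to training trials keeps evaluation leakage-safe."""
    banks = []
    for src in sources:
        if fit_indices is not None:
            fit_set = TrialSet(src.data[fit_indices], src.labels[fit_indices],
                               src.fs, list(src.channel_names), list(src.class_names))
        else:
            fit_set = src
        banks.append(fit_multiclass_csp(fit_set, strategy=strategy,
                                        n_pairs=n_pairs, ridge=ridge))
    return banks


def apply_view_banks(
    banks: list[CSPBank],
    sources: list[TrialSet],
    view_id: str,
    source_names: list[str] | None = None,
) -> ViewFeatures:
    """Apply fitted banks to every trial of every source and concatenate the
    log-power features into one row per trial."""
    if len(banks) != len(sources):
        raise ValueError("one CSP bank per source required")
    n_trials = sources[0].n_trials
    cols, names = [], []
    for s_idx, (bank, src) in enumerate(zip(banks, sources)):
        if src.n_trials != n_trials:
            raise ValueError("mismatched trial counts across sources")
        sname = source_names[s_idx] if source_names else f"src{s_idx}"
        for filt in bank.filters:
            feats = apply_csp(filt, src.data)
            cols.append(feats)
            names += [f"{view_id}:{sname}:{filt.pairing_id}:w{j}"
                      for j in range(feats.shape[1])]
    return ViewFeatures(values=np.hstack(cols), view_id=view_id, feature_names=names)


def build_view(
    sources: TrialSet | list[TrialSet],
    view_id: str,
    strategy: str = "both",
    n_pairs: int = 2,
    fit_indices: np.ndarray | None = None,
    ridge: float = 1e-10,
    source_names: list[str] | None = None,
) -> ViewFeatures:
    """Fit CSP banks on the (training) trials of each source signal set and
    extract the view's feature matrix for all trials."""
    if isinstance(sources, TrialSet):
        sources = [sources]
    banks = fit_view_banks(sources, fit_indices=fit_indices, strategy=strategy,
                           n_pairs=n_pairs, ridge=ridge)
    return apply_view_banks(banks, sources, view_id, source_names=source_names)


def assemble_multiview(
    f1: ViewFeatures, f2: ViewFeatures, f3: ViewFeatures
) -> MultiViewFeature:
    """Concatenate the three views with per-trial, per-block 2-norm
    normalisation: ``F = [F1'/||F1'||, F2'/||F2'||, F3'/||F3'||]``."""
    views = [f1, f2, f3]
    n_trials = f1.values.shape[0]
    blocks, slices, start = [], {}, 0
    for v in views:
        if v.values.shape[0] != n_trials:
            raise ValueError("views disagree on the number of trials")
        norms = np.linalg.norm(v.values, axis=1, keepdims=True)
        if np.any(norms == 0):
            raise ValueError(f"all-zero feature block in view {v.view_id}")
        blocks.append(v.values / norms)
        slices[v.view_id] = slice(start, start + v.values.shape[1])
        start += v.values.shape[1]
    return MultiViewFeature(values=np.hstack(blocks), block_slices=slices)
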