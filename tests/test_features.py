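"""Multi-view feature construction: filters, wavelet packets, CSP and the
normalised assembly."""

import numpy as np
import pytest

from mveeg import (
    DEFAULT_BANDS,
    BandSpec,
    SimConfig,
    TrialSet,
    apply_csp,
    assemble_multiview,
    bandpass_filter,
    build_view,
    fit_csp,
    fit_multiclass_csp,
    generate_trialset,
    preprocess_trials,
    wpd_view,
)
from mveeg.features import SpatialFilter, ViewFeatures, wpd_leaf_bands


def make_trials(data, fs=250.0, labels=None):
    data = np.asarray(data, dtype=float)
    if labels is None:
        labels = np.ones(data.shape[0], dtype=int)
    return TrialSet(data=data, labels=labels, fs=fs)


def sine_trial(freq, fs=250.0, seconds=3.0, channels=2):
    t = np.arange(int(fs * seconds)) / fs
    return np.tile(np.sin(2 * np.pi * freq * t), (channels, 1))


# ---------------------------------------------------------------- preprocess

def test_preprocess_removes_constant_offset():
    ts = make_trials(5.0 * np.ones((1, 3, 500)))
    out = preprocess_trials(ts, band=None)
    assert np.allclose(out.data, 0.0)


def test_preprocess_identity_on_zero_mean_without_bandpass():
    rng = np.random.default_rng(0)
    data = rng.standard_normal((2, 3, 400))
    data -= data.mean(axis=-1, keepdims=True)
    out = preprocess_trials(make_trials(data), band=None)
    assert np.allclose(out.data, data, atol=1e-12)


def test_preprocess_attenuates_above_acquisition_band():
    rng = np.random.default_rng(1)
    ts = make_trials(rng.standard_normal((1, 1, 4096)), fs=500.0)
    out = preprocess_trials(ts, band=(0.5, 100.0))
    freqs = np.fft.rfftfreq(4096, 1 / 500.0)
    pin = np.abs(np.fft.rfft(ts.data[0, 0])) ** 2
    pout = np.abs(np.fft.rfft(out.data[0, 0])) ** 2
    passband = (freqs > 5) & (freqs < 80)
    stopband = freqs > 110
    gain_pass = pout[passband].sum() / pin[passband].sum()
    gain_stop = pout[stopband].sum() / pin[stopband].sum()
    assert 10 * np.log10(gain_pass / gain_stop) >= 20.0


# ------------------------------------------------------------------ bandpass

def test_bandpass_frequency_response():
    band = BandSpec(8.0, 12.0)
    inside = bandpass_filter(make_trials(sine_trial(10.0)[None]), band)
    outside = bandpass_filter(make_trials(sine_trial(25.0)[None]), band)
    rms_in = np.sqrt((inside.data**2).mean())
    rms_out = np.sqrt((outside.data**2).mean())
    ref = np.sqrt((sine_trial(10.0) ** 2).mean())
    assert rms_in >= 0.9 * ref
    assert rms_out <= 0.1 * ref


def test_bandpass_zero_input_and_nyquist_guard():
    ts = make_trials(np.zeros((1, 2, 300)))
    assert np.allclose(bandpass_filter(ts, BandSpec(8, 12)).data, 0.0)
    with pytest.raises(ValueError):
        bandpass_filter(ts, BandSpec(8, 130))


def test_default_bands_tile_mu_beta_range():
    assert DEFAULT_BANDS[0].low == 8.0 and DEFAULT_BANDS[-1].high == 30.0
    for a, b in zip(DEFAULT_BANDS, DEFAULT_BANDS[1:]):
        assert a.high == b.low


# ----------------------------------------------------------------------- WPD

def test_wpd_leaf_count_and_retention():
    ts = make_trials(np.random.default_rng(2).standard_normal((2, 3, 750)))
    all_leaves = wpd_view(ts, retain_band=None)
    assert len(all_leaves) == 16
    spans = wpd_leaf_bands(250.0, 4)
    assert spans[1] == (7.8125, 15.625)
    retained = wpd_view(ts)  # leaves intersecting 8-30 Hz
    assert len(retained) == 3


def test_wpd_perfect_reconstruction_and_energy():
    rng = np.random.default_rng(3)
    ts = make_trials(rng.standard_normal((2, 2, 768)))
    leaves = wpd_view(ts, retain_band=None)
    total = sum(leaf.data for leaf in leaves)
    assert np.abs(total - ts.data).max() <= 1e-8 * np.abs(ts.data).max()

    import pywt

    wp = pywt.WaveletPacket(ts.data[0, 0], "db4", mode="zero", maxlevel=4)
    coeff_energy = sum((node.data**2).sum() for node in wp.get_level(4))
    sig_energy = (ts.data[0, 0] ** 2).sum()
    assert abs(coeff_energy - sig_energy) <= 1e-8 * sig_energy


def test_wpd_too_short_signal_errors():
    with pytest.raises(ValueError):
        wpd_view(make_trials(np.ones((1, 1, 8))), levels=4)


# ----------------------------------------------------------------------- CSP

def orthogonal_two_channel_trials(amp1, amp2, n_trials=6, n=500, fs=250.0):
    """Trials whose sample covariance is exactly diagonal: full periods of
    cosine on channel 1 and sine on channel 2."""
    t = np.arange(n) / fs
    x = np.stack([amp1 * np.cos(2 * np.pi * 10 * t),
                  amp2 * np.sin(2 * np.pi * 10 * t)])
    return np.tile(x, (n_trials, 1, 1))


def test_csp_two_channel_closed_form():
    """Class variances (4,1) vs (1,4) give generalized eigenvalues
    (0.8, 0.2) and axis-aligned filters."""
    a = orthogonal_two_channel_trials(2.0, 1.0)
    b = orthogonal_two_channel_trials(1.0, 2.0)
    filt = fit_csp(a, b, n_pairs=1)
    assert np.allclose(filt.eigvals, [0.8, 0.2], atol=1e-6)
    # rows align with coordinate axes up to sign/scale
    for row, axis in zip(filt.W, np.eye(2)):
        cosine = abs(row @ axis) / np.linalg.norm(row)
        assert cosine > 1 - 1e-6


def test_csp_identical_covariances_non_discriminative():
    a = orthogonal_two_channel_trials(1.0, 1.0)
    filt = fit_csp(a, a.copy(), n_pairs=1)
    assert np.allclose(filt.eigvals, 0.5, atol=1e-9)


def test_csp_simultaneous_diagonalization(small_trials):
    """W diagonalizes both class covariances; diagonal pairs sum to 1."""
    from mveeg.features import _class_covariance

    a = small_trials.data[small_trials.labels == 1]
    b = small_trials.data[small_trials.labels == 2]
    filt = fit_csp(a, b, n_pairs=2)
    Sa = _class_covariance(a, 0.0)
    Sb = _class_covariance(b, 0.0)
    Da, Db = filt.W @ Sa @ filt.W.T, filt.W @ Sb @ filt.W.T
    for D in (Da, Db):
        off = D - np.diag(np.diag(D))
        assert np.abs(off).max() < 1e-8 * np.abs(np.diag(D)).max()
    assert np.allclose(np.diag(Da) + np.diag(Db), 1.0, atol=1e-8)


def test_csp_rank_deficient_errors():
    a = np.zeros((3, 4, 100))
    a[:, 0] = 1.0  # rank-1 data
    with pytest.raises(ValueError):
        fit_csp(a, a.copy(), n_pairs=2, ridge=0.0)


# ----------------------------------------------------------------- apply_csp

def test_apply_csp_log_power_exact_and_scaling():
    filt = SpatialFilter(W=np.eye(1), n_pairs=1, pairing_id="id")
    trial = np.ones((1, 10))
    assert np.isclose(apply_csp(filt, trial)[0], np.log(10.0), atol=1e-12)

    rng = np.random.default_rng(4)
    W = rng.standard_normal((2, 4))
    filt = SpatialFilter(W=W, n_pairs=1, pairing_id="rnd")
    X = rng.standard_normal((4, 200))
    c = 3.7
    assert np.allclose(apply_csp(filt, c * X) - apply_csp(filt, X),
                       2 * np.log(c), atol=1e-10)


def test_apply_csp_zero_power_handling():
    filt = SpatialFilter(W=np.eye(2), n_pairs=1, pairing_id="id")
    zero = np.zeros((2, 50))
    with pytest.raises(ValueError):
        apply_csp(filt, zero, zero_power="error")
    with pytest.warns(RuntimeWarning):
        f = apply_csp(filt, zero)  # floored at machine epsilon
    assert np.all(np.isfinite(f))


def test_apply_csp_channel_permutation_invariance(rng):
    W = rng.standard_normal((2, 5))
    X = rng.standard_normal((5, 100))
    perm = rng.permutation(5)
    f1 = apply_csp(SpatialFilter(W, 1, "p"), X)
    f2 = apply_csp(SpatialFilter(W[:, perm], 1, "p"), X[perm])
    assert np.allclose(f1, f2, atol=1e-12)


# ------------------------------------------------------------- multiclass CSP

def test_multiclass_bank_sizes(small_trials):
    assert len(fit_multiclass_csp(small_trials, "ovr").filters) == 4
    assert len(fit_multiclass_csp(small_trials, "two_vs_two").filters) == 3
    assert len(fit_multiclass_csp(small_trials, "both").filters) == 7


def test_two_vs_two_requires_four_classes(small_trials):
    three = TrialSet(
        data=small_trials.data[small_trials.labels <= 3],
        labels=small_trials.labels[small_trials.labels <= 3],
        fs=small_trials.fs)
    with pytest.raises(ValueError):
        fit_multiclass_csp(three, "two_vs_two")


def test_ovr_filters_respond_to_own_class(small_trials):
    """Each one-vs-rest filter's top component has higher mean log power for
    its own class than for the rest (training data, high snr)."""
    pre = preprocess_trials(small_trials)
    bank = fit_multiclass_csp(pre, "ovr", n_pairs=1)
    for filt, k in zip(bank.filters, sorted(pre.classes)):
        feats = apply_csp(filt, pre.data)[:, 0]  # most own-class direction
        own = feats[pre.labels == k].mean()
        rest = feats[pre.labels != k].mean()
        assert own > rest


# ------------------------------------------------------------------ assembly

def test_view_feature_dimensions(small_trials):
    pre = preprocess_trials(small_trials)
    f1 = build_view(pre, "F1p")
    assert f1.values.shape == (small_trials.n_trials, 28)
    f2_sources = [bandpass_filter(pre, b) for b in DEFAULT_BANDS]
    f2 = build_view(f2_sources, "F2p")
    assert f2.values.shape == (small_trials.n_trials, 140)
    f3 = build_view(wpd_view(pre), "F3p")
    assert f3.values.shape == (small_trials.n_trials, 84)
    F = assemble_multiview(f1, f2, f3)
    assert F.values.shape == (small_trials.n_trials, 252)
    for view_id, sl in F.block_slices.items():
        norms = np.linalg.norm(F.values[:, sl], axis=1)
        assert np.allclose(norms, 1.0, atol=1e-9), view_id


def test_assemble_normalizes_and_is_idempotent():
    f1 = ViewFeatures(np.array([[3.0, 4.0]]), "F1p")
    f2 = ViewFeatures(np.array([[1.0, 0.0]]), "F2p")
    f3 = ViewFeatures(np.array([[0.0, 2.0]]), "F3p")
    F = assemble_multiview(f1, f2, f3)
    assert np.allclose(F.values[0, :2], [0.6, 0.8])
    again = assemble_multiview(
        ViewFeatures(F.values[:, F.block_slices["F1p"]], "F1p"),
        ViewFeatures(F.values[:, F.block_slices["F2p"]], "F2p"),
        ViewFeatures(F.values[:, F.block_slices["F3p"]], "F3p"))
    assert np.allclose(again.values, F.values, atol=1e-12)


def test_assemble_rejects_zero_block():
    good = ViewFeatures(np.ones((2, 3)), "F1p")
    bad = ViewFeatures(np.zeros((2, 3)), "F2p")
    with pytest.raises(ValueError):
        assemble_multiview(good, bad, good)
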