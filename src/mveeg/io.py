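"""On-disk formats and run configuration.

* TrialSet container: a directory with ``manifest.csv`` (trial_id, label,
  file, fs, n_channels, n_samples), a ``meta.json`` carrying names, the
  seed and the config hash, and one CSV matrix (channels x samples) per
  trial.
* DeepNet container: a directory with ``manifest.json`` (layer dims,
  activations, training metadata) and per-layer weight/bias CSV arrays.
* RunConfig: a strict YAML schema mirroring the pipeline sections; unknown
  keys are rejected so typos fail fast.
* GDF/EDF: cue-locked epoch extraction through mne (optional import).
"""

from __future__ import annotations

import csv
import hashlib
import json
from pathlib import Path

import numpy as np
import yaml

from .rbm import DeepNet, LayerSchedule, PretrainSchedule
from .ptsne import TSNEConfig
from .synthetic import SimConfig, TrialSet

__all__ = [
    "read_trials",
    "write_trials",
    "save_net",
    "load_net",
    "load_config",
    "config_hash",
    "DEFAULT_CONFIG",
]


class FormatError(ValueError):
    """Malformed container or unsupported on-disk format."""


# ---------------------------------------------------------------------------
# TrialSet container
# ---------------------------------------------------------------------------

def write_trials(ts: TrialSet, path: str | Path, force: bool = False,
                 meta: dict | None = None) -> None:
    """Write a TrialSet to a directory container (see module docstring).

    Refuses to overwrite an existing container unless ``force``.
    """
    if ts.n_trials == 0:
        raise FormatError("refusing to write an empty TrialSet")
    path = Path(path)
    manifest = path / "manifest.csv"
    if manifest.exists() and not force:
        raise FileExistsError(
            f"{path} already holds a trial container (use force=True)")
    path.mkdir(parents=True, exist_ok=True)
    with open(manifest, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["trial_id", "label", "file", "fs",
                         "n_channels", "n_samples"])
        for i in range(ts.n_trials):
            fname = f"trial_{i:04d}.csv"
            np.savetxt(path / fname, ts.data[i], delimiter=",", fmt="%.10g")
            writer.writerow([i, int(ts.labels[i]), fname, ts.fs,
                             ts.n_channels, ts.n_samples])
    info = {"channel_names": ts.channel_names, "class_names": ts.class_names}
    info.update(meta or {})
    (path / "meta.json").write_text(json.dumps(info, indent=1))


def read_trials(path: str | Path, format: str = "container",
                epoch_window: tuple[float, float] = (0.5, 3.5)) -> TrialSet:
    """Load a TrialSet.

    ``format="container"`` reads the directory layout written by
    :func:`write_trials`; ``"gdf"``/``"edf"`` read a raw recording through
    mne and cut cue-locked epochs at ``epoch_window`` seconds relative to
    each annotation onset.
    """
    if format == "container":
        return _read_container(Path(path))
    if format in ("gdf", "edf"):
        return _read_raw_epochs(Path(path), format, epoch_window)
    raise FormatError(f"unsupported format {format!r}")


def _read_container(path: Path) -> TrialSet:
    manifest = path / "manifest.csv"
    if not manifest.exists():
        raise FormatError(f"no manifest.csv under {path}")
    rows = list(csv.DictReader(open(manifest)))
    if not rows:
        raise FormatError(f"empty manifest in {path}")
    data, labels = [], []
    fs = float(rows[0]["fs"])
    for row in rows:
        fpath = path / row["file"]
        if not fpath.exists():
            raise FormatError(f"manifest lists missing trial file {fpath}")
        mat = np.loadtxt(fpath, delimiter=",", ndmin=2)
        if mat.shape != (int(row["n_channels"]), int(row["n_samples"])):
            raise FormatError(
                f"{fpath}: shape {mat.shape} disagrees with manifest "
                f"({row['n_channels']} x {row['n_samples']})")
        data.append(mat)
        labels.append(int(row["label"]))
    names: dict = {}
    meta_path = path / "meta.json"
    if meta_path.exists():
        names = json.loads(meta_path.read_text())
    return TrialSet(
        data=np.stack(data), labels=np.array(labels), fs=fs,
        channel_names=names.get("channel_names", []),
        class_names=names.get("class_names", []),
    )


def _read_raw_epochs(path: Path, fmt: str,
                     window: tuple[float, float]) -> TrialSet:
    try:
        import mne
    except ImportError as exc:  # pragma: no cover
        raise FormatError("reading gdf/edf requires the mne package") from exc
    reader = mne.io.read_raw_gdf if fmt == "gdf" else mne.io.read_raw_edf
    raw = reader(str(path), preload=True, verbose="error")
    events, event_id = mne.events_from_annotations(raw, verbose="error")
    epochs = mne.Epochs(raw, events, event_id=event_id, tmin=window[0],
                        tmax=window[1], baseline=None, preload=True,
                        verbose="error")
    data = epochs.get_data() * 1e6  # volts -> microvolts
    labels = epochs.events[:, 2]
    # relabel to 1..K in sorted event-code order
    codes = {c: i + 1 for i, c in enumerate(sorted(np.unique(labels)))}
    labels = np.array([codes[c] for c in labels])
    return TrialSet(data=data, labels=labels, fs=float(raw.info["sfreq"]),
                    channel_names=list(epochs.ch_names))


# ---------------------------------------------------------------------------
# DeepNet container
# ---------------------------------------------------------------------------

def save_net(net: DeepNet, path: str | Path, force: bool = False) -> None:
    path = Path(path)
    if (path / "manifest.json").exists() and not force:
        raise FileExistsError(f"{path} already holds a network (use force=True)")
    path.mkdir(parents=True, exist_ok=True)
    layers = []
    for li, (W, b, kind) in enumerate(net.layers):
        np.savetxt(path / f"W{li}.csv", W, delimiter=",", fmt="%.17g")
        np.savetxt(path / f"b{li}.csv", b, delimiter=",", fmt="%.17g")
        layers.append({"index": li, "shape": list(W.shape), "activation": kind})
    (path / "manifest.json").write_text(json.dumps(
        {"layers": layers, "meta": net.meta}, indent=1))


def load_net(path: str | Path) -> DeepNet:
    path = Path(path)
    manifest = path / "manifest.json"
    if not manifest.exists():
        raise FormatError(f"no network manifest under {path}")
    manifest_data = json.loads(manifest.read_text())
    layers = []
    for entry in manifest_data["layers"]:
        li = entry["index"]
        W = np.loadtxt(path / f"W{li}.csv", delimiter=",", ndmin=2)
        b = np.atleast_1d(np.loadtxt(path / f"b{li}.csv", delimiter=","))
        if list(W.shape) != entry["shape"]:
            raise FormatError(f"layer {li}: array shape disagrees with manifest")
        layers.append((W, b, entry["activation"]))
    return DeepNet(layers=layers, meta=manifest_data.get("meta", {}))


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "output_dir": "mveeg_out",
    "simulate": {
        "n_trials_per_class": 72, "n_channels": 22, "fs": 250.0,
        "trial_seconds": 3.0, "n_classes": 4, "snr": 1.0,
    },
    "features": {
        "bands": [[8, 12], [12, 16], [16, 20], [20, 24], [24, 30]],
        "preprocess_band": [0.5, 100.0],
        "wavelet": "db4", "levels": 4, "n_pairs": 2, "strategy": "both",
    },
    "pretrain": {
        "hidden_widths": [500, 500, 2500],
        "sigmoid": {"learning_rate": 0.007, "weight_cost": 0.005,
                    "n_iterations": 70, "momentum_initial": 0.5,
                    "momentum_later": 0.7},
        "linear": {"learning_rate": 0.0002, "weight_cost": 0.003,
                   "n_iterations": 80, "momentum_initial": 0.6,
                   "momentum_later": 0.8},
        "weight_meaning": "weight_cost",
    },
    "finetune": {
        "d": 60, "alpha": 32.0, "perplexity": 25.0, "batch_size": 100,
        "n_iterations": 50, "cg_steps_per_batch": 3,
    },
    "evaluate": {
        "k": 10, "mode": "leakage_safe", "svm_kernel": "rbf",
        "svm_C": 1.0, "svm_gamma": "scale",
    },
    "sweep": {
        "d_values": list(range(5, 71, 5)),
        "alpha_values": list(range(4, 49, 4)),
    },
}


def _check_keys(user: dict, defaults: dict, prefix: str = "") -> None:
    for key, value in user.items():
        if key not in defaults:
            raise FormatError(f"unknown config key {prefix}{key!r}")
        if isinstance(defaults[key], dict):
            if not isinstance(value, dict):
                raise FormatError(f"config key {prefix}{key!r} must be a mapping")
            _check_keys(value, defaults[key], prefix=f"{prefix}{key}.")


def _deep_merge(defaults: dict, user: dict) -> dict:
    out = {}
    for key, dval in defaults.items():
        if key in user and isinstance(dval, dict):
            out[key] = _deep_merge(dval, user[key])
        elif key in user:
            out[key] = user[key]
        else:
            out[key] = dval
    return out


def load_config(path: str | Path | None = None) -> dict:
    """Load a YAML run configuration merged over the defaults; unknown keys
    are rejected."""
    if path is None:
        return json.loads(json.dumps(DEFAULT_CONFIG))
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"config file {path} not found")
    user = yaml.safe_load(path.read_text()) or {}
    if not isinstance(user, dict):
        raise FormatError("config must be a YAML mapping")
    _check_keys(user, DEFAULT_CONFIG)
    return _deep_merge(DEFAULT_CONFIG, user)


def config_hash(config: dict) -> str:
    """Stable short hash identifying a run configuration."""
    blob = json.dumps(config, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def pipeline_config_from(config: dict):
    """Build a PipelineConfig from a loaded RunConfig mapping."""
    from . import features as ftmod
    from .evaluate import PipelineConfig

    fsec, psec, tsec, esec = (config["features"], config["pretrain"],
                              config["finetune"], config["evaluate"])
    return PipelineConfig(
        bands=tuple(ftmod.BandSpec(*b) for b in fsec["bands"]),
        preprocess_band=(tuple(fsec["preprocess_band"])
                         if fsec["preprocess_band"] else None),
        wavelet=fsec["wavelet"],
        levels=int(fsec["levels"]),
        n_pairs=int(fsec["n_pairs"]),
        strategy=fsec["strategy"],
        hidden_widths=tuple(int(w) for w in psec["hidden_widths"]),
        pretrain=PretrainSchedule(
            sigmoid=LayerSchedule(**psec["sigmoid"]),
            linear=LayerSchedule(**psec["linear"]),
        ),
        weight_meaning=psec["weight_meaning"],
        tsne=TSNEConfig(
            alpha=float(tsec["alpha"]), d=int(tsec["d"]),
            perplexity=float(tsec["perplexity"]),
            batch_size=int(tsec["batch_size"]),
            n_iterations=int(tsec["n_iterations"]),
            cg_steps_per_batch=int(tsec["cg_steps_per_batch"]),
            seed=int(config["seed"]),
        ),
        svm_kernel=esec["svm_kernel"],
        svm_C=float(esec["svm_C"]),
        svm_gamma=(esec["svm_gamma"] if esec["svm_gamma"] == "scale"
                   else float(esec["svm_gamma"])),
    )


def sim_config_from(config: dict) -> SimConfig:
    sec = dict(config["simulate"])
    return SimConfig(seed=int(config["seed"]), **sec)
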