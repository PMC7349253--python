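"""Classification and evaluation of deep multi-view features.

An SVM (one-vs-one multiclass) is trained on the latent embedding;
performance is reported as accuracy, Acc = 100 * sum_i n_ii / N, and the
kappa score kappa = (po - pe) / (1 - pe).  Two chance terms pe are
available: the standard Cohen form using row x column marginals (default)
and a diagonal variant in which the per-class "predicted" count is the
number predicted correctly (the matrix diagonal).

Cross-validation is stratified k-fold after a seeded shuffle.  In the
default leakage-safe mode, every supervised stage (CSP banks, feature
scaling, RBM pretraining, parametric t-SNE fine-tuning, SVM) is refitted
on each training fold; signal-level transforms (band-pass bank, wavelet
packets) are per-trial and unsupervised, so they are computed once.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import MinMaxScaler
from sklearn.svm import SVC

from . import features as ft
from .ptsne import TSNEConfig, embed, finetune
from .rbm import DeepNet, PretrainSchedule, train_rbm_stack
from .synthetic import TrialSet

__all__ = [
    "ConfusionMatrix",
    "EvalReport",
    "PipelineConfig",
    "accuracy",
    "kappa",
    "confusion_from_predictions",
    "train_svm",
    "compute_sources",
    "DeepMultiViewPipeline",
    "cross_validate",
    "parameter_sweep",
]


@dataclass
class ConfusionMatrix:
    """Class-by-class prediction counts; rows = actual, columns = predicted."""

    counts: np.ndarray
    class_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 2 or self.counts.shape[0] != self.counts.shape[1]:
            raise ValueError("confusion matrix must be square")
        if np.any(self.counts < 0):
            raise ValueError("confusion counts must be non-negative")
        if not self.class_names:
            self.class_names = [f"class{k + 1}" for k in range(self.counts.shape[0])]

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def confusion_from_predictions(
    y_true: np.ndarray, y_pred: np.ndarray, classes: Sequence[int]
) -> ConfusionMatrix:
    classes = list(classes)
    index = {c: i for i, c in enumerate(classes)}
    counts = np.zeros((len(classes), len(classes)), dtype=np.int64)
    for t, p in zip(y_true, y_pred):
        counts[index[t], index[p]] += 1
    return ConfusionMatrix(counts, [str(c) for c in classes])


def accuracy(cm: ConfusionMatrix) -> float:
    """Percent accuracy: 100 * trace / N."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    return 100.0 * float(np.trace(cm.counts)) / cm.total


def kappa(cm: ConfusionMatrix, mode: str = "standard") -> float:
    """Chance-corrected agreement (po - pe) / (1 - pe).

    ``mode="standard"``: Cohen's pe = sum_i (row_i * col_i) / n^2.
    ``mode="diagonal"``: pe = sum_i (row_i * diag_i) / n^2, taking the
    per-class predicted count as the number predicted correctly.
    """
    n = cm.total
    if n == 0:
        raise ValueError("empty confusion matrix")
    po = float(np.trace(cm.counts)) / n
    rows = cm.counts.sum(axis=1).astype(np.float64)
    if mode == "standard":
        cols = cm.counts.sum(axis=0).astype(np.float64)
    elif mode == "diagonal":
        cols = np.diag(cm.counts).astype(np.float64)
    else:
        raise ValueError(f"unknown kappa mode {mode!r}")
    pe = float(rows @ cols) / n**2
    if pe >= 1.0:
        raise ValueError("pe = 1: kappa undefined")
    return (po - pe) / (1.0 - pe)


def train_svm(
    X: np.ndarray,
    y: np.ndarray,
    kernel: str = "rbf",
    C: float = 1.0,
    gamma: str | float = "scale",
) -> SVC:
    """Fit a deterministic multi-class SVM (one-vs-one decision shape)."""
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("need at least two classes to train the SVM")
    clf = SVC(kernel=kernel, C=C, gamma=gamma, decision_function_shape="ovo",
              random_state=0)
    clf.fit(np.asarray(X, dtype=np.float64), y)
    return clf


# ---------------------------------------------------------------------------
# end-to-end pipeline
# ---------------------------------------------------------------------------

#: Default traversal lattice for the d / alpha parameter sweep.
DEFAULT_D_VALUES: tuple[int, ...] = tuple(range(5, 71, 5))
DEFAULT_ALPHA_VALUES: tuple[int, ...] = tuple(range(4, 49, 4))


@dataclass(frozen=True)
class PipelineConfig:
    """Everything needed to run features -> pretraining -> fine-tuning -> SVM.

    Defaults follow the published configuration: five-band filter bank over
    8-30 Hz, depth-4 db4 wavelet packets, N = 2 CSP pairs with both
    one-vs-rest and two-vs-two dichotomies, hidden widths 500-500-2500,
    latent d = 60, alpha = 32, perplexity 25, batches of 100, 70/80 CD
    epochs and 50 fine-tuning epochs.
    """

    bands: tuple[ft.BandSpec, ...] = ft.DEFAULT_BANDS
    preprocess_band: tuple[float, float] | None = (0.5, 100.0)
    wavelet: str = "db4"
    levels: int = 4
    wpd_retain_band: tuple[float, float] | None = (8.0, 30.0)
    n_pairs: int = 2
    strategy: str = "both"
    csp_ridge: float = 1e-10
    hidden_widths: tuple[int, ...] = (500, 500, 2500)
    pretrain: PretrainSchedule = PretrainSchedule()
    weight_meaning: str = "weight_cost"
    tsne: TSNEConfig = TSNEConfig()
    svm_kernel: str = "rbf"
    svm_C: float = 1.0
    svm_gamma: str | float = "scale"

    def scaled_down(
        self,
        hidden_widths: tuple[int, ...] = (64, 64, 256),
        d: int = 10,
        rbm_epochs: int = 10,
        finetune_epochs: int = 10,
    ) -> "PipelineConfig":
        """A small-budget variant of the same pipeline for fixtures."""
        return replace(
            self,
            hidden_widths=hidden_widths,
            pretrain=self.pretrain.scaled(rbm_epochs),
            tsne=replace(self.tsne, d=d, n_iterations=finetune_epochs),
        )


def compute_sources(trials: TrialSet, cfg: PipelineConfig) -> dict[str, list[TrialSet]]:
    """Per-trial, label-free signal transforms feeding the three views:
    the preprocessed signal (F1), the five band-passed sets (F2) and the
    retained wavelet-packet leaf sets (F3)."""
    pre = ft.preprocess_trials(trials, band=cfg.preprocess_band)
    f2_sources = [ft.bandpass_filter(pre, band) for band in cfg.bands]
    f3_sources = ft.wpd_view(pre, levels=cfg.levels, wavelet=cfg.wavelet,
                             retain_band=cfg.wpd_retain_band)
    return {"F1p": [pre], "F2p": f2_sources, "F3p": f3_sources}


class DeepMultiViewPipeline:
    """Fit/transform wrapper over the full method.

    ``fit`` learns CSP banks, the [0,1] feature scaling, the RBM stack and
    the parametric t-SNE fine-tuning on training trials only; ``transform``
    maps any trials (given their precomputed sources) into the latent
    space; ``fit_classifier``/``predict`` add the SVM on top.
    """

    def __init__(self, cfg: PipelineConfig, seed: int = 0) -> None:
        self.cfg = cfg
        self.seed = int(seed)
        self.banks_: dict[str, list] | None = None
        self.scaler_: MinMaxScaler | None = None
        self.net_: DeepNet | None = None
        self.finetune_trace_: list[dict] | None = None
        self.svm_: SVC | None = None

    # -- feature side -------------------------------------------------
    def _view_features(
        self, sources: dict[str, list[TrialSet]]
    ) -> ft.MultiViewFeature:
        views = []
        for view_id in ("F1p", "F2p", "F3p"):
            views.append(ft.apply_view_banks(self.banks_[view_id],
                                             sources[view_id], view_id))
        return ft.assemble_multiview(*views)

    def fit(
        self,
        sources: dict[str, list[TrialSet]],
        labels: np.ndarray,
        train_idx: np.ndarray,
        pretrain_net: DeepNet | None = None,
    ) -> "DeepMultiViewPipeline":
        cfg = self.cfg
        self.banks_ = {
            view_id: ft.fit_view_banks(
                sources[view_id], fit_indices=train_idx,
                strategy=cfg.strategy, n_pairs=cfg.n_pairs, ridge=cfg.csp_ridge)
            for view_id in ("F1p", "F2p", "F3p")
        }
        F = self._view_features(sources)
        X_train = F.values[train_idx]
        self.scaler_ = MinMaxScaler(clip=True).fit(X_train)
        X01 = self.scaler_.transform(X_train)
        widths = list(cfg.hidden_widths) + [cfg.tsne.d]
        if pretrain_net is None:
            pretrain_net = train_rbm_stack(
                X01, widths=widths, schedule=cfg.pretrain, seed=self.seed,
                weight_meaning=cfg.weight_meaning)
        self.pretrain_net_ = pretrain_net
        self.net_, self.finetune_trace_ = finetune(
            pretrain_net, X01, replace(cfg.tsne, seed=self.seed))
        self._feature_cache = F  # reused by transform on the same sources
        return self

    def transform(
        self, sources: dict[str, list[TrialSet]], idx: np.ndarray | None = None,
        _reuse_cache: bool = True,
    ) -> np.ndarray:
        if self.net_ is None:
            raise RuntimeError("pipeline is not fitted")
        F = self._feature_cache if _reuse_cache and hasattr(self, "_feature_cache") \
            else self._view_features(sources)
        values = F.values if idx is None else F.values[idx]
        return embed(self.net_, self.scaler_.transform(values))

    # -- classifier side ----------------------------------------------
    def fit_classifier(self, Z_train: np.ndarray, y_train: np.ndarray) -> None:
        self.svm_ = train_svm(Z_train, y_train, kernel=self.cfg.svm_kernel,
                              C=self.cfg.svm_C, gamma=self.cfg.svm_gamma)

    def predict(self, Z: np.ndarray) -> np.ndarray:
        if self.svm_ is None:
            raise RuntimeError("classifier is not fitted")
        return self.svm_.predict(Z)


@dataclass
class EvalReport:
    """Cross-validation summary: percent accuracy, kappa scores, per-fold
    accuracies and the pooled confusion matrix."""

    accuracy: float
    kappa_standard: float
    kappa_diagonal: float
    fold_accuracies: list[float]
    confusion: ConfusionMatrix
    mode: str = "leakage_safe"

    def to_dict(self) -> dict:
        return {
            "accuracy_percent": self.accuracy,
            "kappa_standard": self.kappa_standard,
            "kappa_diagonal": self.kappa_diagonal,
            "fold_accuracies": self.fold_accuracies,
            "confusion_counts": self.counts_list(),
            "class_names": self.confusion.class_names,
            "mode": self.mode,
        }

    def counts_list(self) -> list[list[int]]:
        return [[int(c) for c in row] for row in self.confusion.counts]


def cross_validate(
    trials: TrialSet,
    cfg: PipelineConfig | None = None,
    k: int = 10,
    seed: int = 0,
    mode: str = "leakage_safe",
    classifier_factory=None,
    sources: dict[str, list[TrialSet]] | None = None,
) -> EvalReport:
    """Stratified k-fold evaluation of the full pipeline.

    ``mode="leakage_safe"`` (default) refits CSP banks, scaling, the RBM
    stack, fine-tuning and the SVM on each training fold.  ``mode="pooled"``
    fits the feature learning once on all trials (mirroring evaluation
    protocols that pool and re-split data) and cross-validates only the
    classifier.
    ``classifier_factory`` optionally replaces the SVM with any object
    exposing fit/predict (e.g. a dummy classifier for chance baselines).
    """
    if cfg is None:
        cfg = PipelineConfig()
    labels = trials.labels
    counts = np.bincount(labels)
    present = np.nonzero(counts)[0]
    if np.any(counts[present] < k):
        raise ValueError(f"every class needs at least k={k} trials")
    if mode not in ("leakage_safe", "pooled"):
        raise ValueError(f"unknown evaluation mode {mode!r}")

    if sources is None:
        sources = compute_sources(trials, cfg)
    classes = [int(c) for c in trials.classes]
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    pooled = np.zeros((len(classes), len(classes)), dtype=np.int64)
    fold_accs: list[float] = []

    shared: DeepMultiViewPipeline | None = None
    if mode == "pooled":
        shared = DeepMultiViewPipeline(cfg, seed=seed)
        shared.fit(sources, labels, np.arange(trials.n_trials))
        Z_all = shared.transform(sources)

    for fold, (train_idx, test_idx) in enumerate(
            skf.split(np.zeros(trials.n_trials), labels)):
        if mode == "leakage_safe":
            pipe = DeepMultiViewPipeline(cfg, seed=seed + fold)
            pipe.fit(sources, labels, train_idx)
            Z_train = pipe.transform(sources, train_idx)
            Z_test = pipe.transform(sources, test_idx)
        else:
            Z_train, Z_test = Z_all[train_idx], Z_all[test_idx]
        if classifier_factory is None:
            clf = train_svm(Z_train, labels[train_idx], kernel=cfg.svm_kernel,
                            C=cfg.svm_C, gamma=cfg.svm_gamma)
        else:
            clf = classifier_factory()
            clf.fit(Z_train, labels[train_idx])
        pred = clf.predict(Z_test)
        cm = confusion_from_predictions(labels[test_idx], pred, classes)
        pooled += cm.counts
        fold_accs.append(accuracy(cm))

    pooled_cm = ConfusionMatrix(pooled, [str(c) for c in classes])
    return EvalReport(
        accuracy=accuracy(pooled_cm),
        kappa_standard=kappa(pooled_cm, "standard"),
        kappa_diagonal=kappa(pooled_cm, "diagonal"),
        fold_accuracies=fold_accs,
        confusion=pooled_cm,
        mode=mode,
    )


def parameter_sweep(
    trials: TrialSet,
    d_values: Sequence[int] | None = None,
    alpha_values: Sequence[float] | None = None,
    cfg: PipelineConfig | None = None,
    k: int = 10,
    seed: int = 0,
    mode: str = "leakage_safe",
) -> dict:
    """Grid search over the latent dimension d and the Student-t degrees of
    freedom alpha; defaults reproduce the 14 x 12 lattice d = 5..70 step 5,
    alpha = 4..48 step 4.

    Returns ``{"d_values", "alpha_values", "grid"``
    (accuracy, d x alpha)``, "kappa_grid", "best"}`` where ``best`` holds
    the argmax cell.
    """
    if d_values is None:
        d_values = DEFAULT_D_VALUES
    if alpha_values is None:
        alpha_values = DEFAULT_ALPHA_VALUES
    d_values = list(d_values)
    alpha_values = list(alpha_values)
    if not d_values or not alpha_values:
        raise ValueError("empty sweep grid")
    if cfg is None:
        cfg = PipelineConfig()
    # the lattice varies only d and alpha, so the signal-level sources are shared
    sources = compute_sources(trials, cfg)
    grid = np.empty((len(d_values), len(alpha_values)))
    kgrid = np.empty_like(grid)
    for i, d in enumerate(d_values):
        for j, alpha in enumerate(alpha_values):
            cell_cfg = replace(cfg, tsne=replace(cfg.tsne, d=int(d),
                                                 alpha=float(alpha)))
            report = cross_validate(trials, cell_cfg, k=k, seed=seed, mode=mode,
                                    sources=sources)
            grid[i, j] = report.accuracy
            kgrid[i, j] = report.kappa_standard
    best_flat = int(np.argmax(grid))
    bi, bj = np.unravel_index(best_flat, grid.shape)
    return {
        "d_values": d_values,
        "alpha_values": alpha_values,
        "grid": grid,
        "kappa_grid": kgrid,
        "best": {"d": d_values[bi], "alpha": alpha_values[bj],
                 "accuracy": float(grid[bi, bj])},
    }
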