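"""Leave-one-run-out position decoding with RFE-SVM.

Eight-way decoding of stimulus position from multivoxel patterns with a
linear support vector machine (native one-vs-one multiclass), wrapped in a
recursive feature elimination (RFE) loop: at each iteration the classifier
is trained on the current voxel set, voxels are ranked by their average
absolute weight across the binary classifiers, and the lowest-ranked 20% are
removed.  Elimination stops when a nested leave-one-run-out validation
accuracy has not improved for 10 consecutive iterations (or a voxel floor is
reached), and the voxel set at the best recorded accuracy is kept.  The
outer leave-one-run-out split is never touched during selection, so the
held-out run measures generalization only.

Statistical reference points: a permutation null (training labels shuffled
within each fold, once per permutation) and a group-level binomial test on
the number of subjects individually beating their threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from sklearn.svm import SVC

from . import stats
from .synthetic import ROIDataset

__all__ = [
    "RFEConfig",
    "DecoderResult",
    "loro_splits",
    "auto_c",
    "rfe_select",
    "decode_timepoint",
    "pooled_window_decode",
    "permutation_null",
    "group_significance",
]


@dataclass(frozen=True)
class RFEConfig:
    """Recursive feature elimination settings.

    ``c_mode="auto"`` sets the SVM cost to 1 / mean squared sample norm
    (data-scaled cost, the toolbox convention "C = -1"); a float fixes C.
    Setting ``min_features`` to the full voxel count disables elimination.
    """

    elimination_fraction: float = 0.20
    patience: int = 10
    min_features: int = 8
    c_mode: float | str = "auto"

    def __post_init__(self) -> None:
        if not 0.0 < self.elimination_fraction < 1.0:
            raise ValueError("elimination_fraction must be in (0, 1)")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")


@dataclass
class DecoderResult:
    """Per-split decoding outcome at one timepoint (or pooled window)."""

    timepoint: float | tuple[float, ...]
    split_accuracies: np.ndarray
    surviving_voxels: list[np.ndarray]
    accuracy_traces: list[list[float]]

    @property
    def mean_accuracy(self) -> float:
        return float(self.split_accuracies.mean())


def loro_splits(run_labels) -> list[tuple[np.ndarray, object]]:
    """Leave-one-run-out splits: (train run ids, test run id) per run."""
    runs = np.unique(np.asarray(run_labels))
    if runs.size < 2:
        raise ValueError("need at least 2 runs for leave-one-run-out")
    return [(runs[runs != r], r) for r in runs]


def auto_c(x: np.ndarray) -> float:
    """Data-scaled SVM cost: 1 over the mean squared sample norm."""
    norms = np.einsum("ij,ij->i", x, x)
    m = float(norms.mean())
    if m <= 0:
        raise ValueError("degenerate data: zero mean squared norm")
    return 1.0 / m


def _fit_svm(x: np.ndarray, y: np.ndarray, cfg: RFEConfig) -> SVC:
    c = auto_c(x) if cfg.c_mode == "auto" else float(cfg.c_mode)
    clf = SVC(kernel="linear", C=c)
    clf.fit(x, y)
    return clf


def _rank_weights(clf: SVC) -> np.ndarray:
    """Average absolute weight of every feature across the one-vs-one
    binary classifiers."""
    return np.abs(clf.coef_).mean(axis=0)


def _inner_cv_accuracy(
    x: np.ndarray, y: np.ndarray, runs: np.ndarray, cfg: RFEConfig
) -> float:
    accs = []
    for train_runs, test_run in loro_splits(runs):
        tr = np.isin(runs, train_runs)
        te = runs == test_run
        if len(np.unique(y[tr])) < 2:
            raise ValueError("inner training fold has a single class")
        clf = _fit_svm(x[tr], y[tr], cfg)
        accs.append(float(np.mean(clf.predict(x[te]) == y[te])))
    return float(np.mean(accs))


def rfe_select(
    train_data: np.ndarray,
    train_labels: np.ndarray,
    train_runs: np.ndarray,
    cfg: RFEConfig = RFEConfig(),
) -> tuple[np.ndarray, list[float]]:
    """Select voxels by recursive elimination on training data only.

    Returns the voxel index set at the best nested-validation accuracy and
    the accuracy trace over iterations.  Feature counts follow
    ``n_k = n_{k-1} - ceil(f * n_{k-1})`` down to ``min_features``; the loop
    also stops once the best accuracy has not been exceeded for ``patience``
    consecutive iterations.  Ties in the elimination ranking are broken by
    voxel index (stable order).
    """
    if len(np.unique(train_labels)) < 2:
        raise ValueError("training labels contain a single class")
    n_total = train_data.shape[1]
    if n_total < cfg.min_features:
        raise ValueError("fewer features than min_features")
    current = np.arange(n_total)
    trace: list[float] = []
    best_acc = -np.inf
    best_set = current.copy()
    since_best = 0
    while True:
        acc = _inner_cv_accuracy(
            train_data[:, current], train_labels, train_runs, cfg
        )
        trace.append(acc)
        if acc > best_acc:
            best_acc = acc
            best_set = current.copy()
            since_best = 0
        else:
            since_best += 1
        if since_best >= cfg.patience or current.size <= cfg.min_features:
            break
        clf = _fit_svm(train_data[:, current], train_labels, cfg)
        ranks = _rank_weights(clf)
        n_drop = max(1, math.ceil(cfg.elimination_fraction * current.size))
        if current.size - n_drop < cfg.min_features:
            n_drop = current.size - cfg.min_features
        # stable argsort: ties resolved by voxel index
        drop = np.argsort(ranks, kind="stable")[:n_drop]
        current = np.delete(current, drop)
    return best_set, trace


def _select_trials(ds: ROIDataset, correct_only: bool = True) -> np.ndarray:
    mask = ds.correct if correct_only else np.ones(len(ds.correct), bool)
    return np.flatnonzero(mask)


def _decode_matrix(
    x: np.ndarray,
    y: np.ndarray,
    runs: np.ndarray,
    cfg: RFEConfig,
    timepoint,
    rfe: bool = True,
) -> DecoderResult:
    accs, survivors, traces = [], [], []
    for train_runs, test_run in loro_splits(runs):
        tr = np.isin(runs, train_runs)
        te = runs == test_run
        if rfe and x.shape[1] > cfg.min_features:
            feats, trace = rfe_select(x[tr], y[tr], runs[tr], cfg)
        else:
            feats, trace = np.arange(x.shape[1]), []
        clf = _fit_svm(x[tr][:, feats], y[tr], cfg)
        accs.append(float(np.mean(clf.predict(x[te][:, feats]) == y[te])))
        survivors.append(feats)
        traces.append(trace)
    return DecoderResult(timepoint, np.asarray(accs), survivors, traces)


def decode_timepoint(
    ds: ROIDataset,
    t: float,
    cfg: RFEConfig = RFEConfig(),
    correct_only: bool = True,
    rfe: bool = True,
) -> DecoderResult:
    """Leave-one-run-out decoding of position at a single timepoint."""
    ti = ds.time_index(t)
    sel = _select_trials(ds, correct_only)
    x = ds.data[sel, ti, :]
    y = ds.position_labels[sel]
    runs = ds.run_labels[sel]
    return _decode_matrix(x, y, runs, cfg, t, rfe)


def pooled_window_decode(
    ds: ROIDataset,
    window: tuple[float, float] = (6.0, 10.0),
    cfg: RFEConfig = RFEConfig(),
    correct_only: bool = True,
    rfe: bool = True,
) -> DecoderResult:
    """Decoding with voxel patterns concatenated across a time window
    (inclusive endpoints); a single-timepoint window reduces to
    :func:`decode_timepoint`."""
    lo, hi = window
    tidx = np.flatnonzero(
        (ds.time_labels >= lo - 1e-9) & (ds.time_labels <= hi + 1e-9)
    )
    if tidx.size == 0:
        raise ValueError("empty pooling window")
    sel = _select_trials(ds, correct_only)
    x = ds.data[sel][:, tidx, :].reshape(sel.size, -1)
    y = ds.position_labels[sel]
    runs = ds.run_labels[sel]
    return _decode_matrix(
        x, y, runs, cfg, tuple(float(ds.time_labels[i]) for i in tidx), rfe
    )


def permutation_null(
    ds: ROIDataset,
    t: float,
    cfg: RFEConfig = RFEConfig(),
    n_perm: int = 100,
    rng: np.random.Generator | None = None,
    correct_only: bool = True,
    rfe: bool = True,
) -> tuple[np.ndarray, float, float]:
    """Permutation null for single-timepoint decoding.

    Each permutation shuffles the training-set labels once within every
    cross-validation fold (test labels intact) and reruns the full decoding
    path.  Returns (null accuracies, p, observed accuracy) with
    ``p = (1 + #null >= observed) / (1 + n_perm)``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = rng or np.random.default_rng()
    ti = ds.time_index(t)
    sel = _select_trials(ds, correct_only)
    x = ds.data[sel, ti, :]
    y = ds.position_labels[sel]
    runs = ds.run_labels[sel]
    observed = _decode_matrix(x, y, runs, cfg, t, rfe).mean_accuracy
    null = np.empty(n_perm)
    for i in range(n_perm):
        accs = []
        for train_runs, test_run in loro_splits(runs):
            tr = np.isin(runs, train_runs)
            te = runs == test_run
            y_tr = rng.permutation(y[tr])
            if rfe and x.shape[1] > cfg.min_features:
                feats, _ = rfe_select(x[tr], y_tr, runs[tr], cfg)
            else:
                feats = np.arange(x.shape[1])
            clf = _fit_svm(x[tr][:, feats], y_tr, cfg)
            accs.append(float(np.mean(clf.predict(x[te][:, feats]) == y[te])))
        null[i] = np.mean(accs)
    p = (1.0 + np.sum(null >= observed - 1e-12)) / (1.0 + n_perm)
    return null, float(p), observed


def group_significance(
    above_threshold: int | np.ndarray,
    n_subjects: int | None = None,
    subject_alpha: float = 0.05,
) -> stats.TestResult:
    """Group-level binomial test: probability of seeing at least this many
    subjects individually significant when each clears the subject-level
    threshold with probability ``subject_alpha`` under the null."""
    if np.ndim(above_threshold) > 0:
        flags = np.asarray(above_threshold, bool)
        k, n = int(flags.sum()), flags.size
    else:
        if n_subjects is None:
            raise ValueError("n_subjects required when passing a count")
        k, n = int(above_threshold), int(n_subjects)
    p = stats.binomial_tail(k, n, subject_alpha)
    return stats.TestResult(float(k), p, df=n, sided="greater")
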