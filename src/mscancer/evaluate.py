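"""Evaluation protocol: confusion metrics, ROC/AUC, repeated 70/30 hold-out.

The protocol mirrors the standard repeated independent train/test design
for small clinical MS cohorts: per repeat, a stratified random 70/30
split; the dimensionality reducer (classical PCA or PPCA) is fitted on
the training partition; the latent dimension q is either fixed or chosen
so the cumulative variance fraction of the training eigenvalues reaches a
threshold (default 99.99%); an RBF-SVM is grid-searched and trained on
the training scores; the held-out 30% yields confusion counts,
accuracy/sensitivity/specificity in percent, and an ROC curve.  Per-method
averages over repeats give the familiar comparison-table shape.

By default the reducer sees only the training partition (no information
leakage).  ``pooled_reduction=True`` fits the reducer on all samples
before splitting, reproducing the protocol of studies that select q from
the pooled eigenspectrum; it is available for fidelity but leaks the test
distribution into the features and is off by default.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn import metrics as skmetrics

from . import classify, ppca
from .msio import SpectrumSet

__all__ = [
    "ConfusionCounts",
    "RunResult",
    "ExperimentReport",
    "metrics",
    "confusion_from_predictions",
    "roc_curve",
    "split_70_30",
    "run_experiment",
    "average_table",
]

log = logging.getLogger(__name__)

METHODS = ("pca-svm", "ppca-svm")


@dataclass
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


@dataclass
class RunResult:
    """One repeat of one method: counts, percent metrics, ROC."""

    run_index: int          # 1-based
    method: str
    counts: ConfusionCounts
    accuracy: float
    sensitivity: float      # nan flags an empty positive class
    specificity: float      # nan flags an empty negative class
    roc: list[tuple[float, float]]
    auc: float
    best_c: float = float("nan")
    best_g: float = float("nan")
    q: int = 0


@dataclass
class ExperimentReport:
    runs: list[RunResult]
    averages: dict[str, dict[str, float]]
    config: dict = field(default_factory=dict)
    seeds: list[int] = field(default_factory=list)

    def to_json(self, indent: int = 2) -> str:
        def default(o):
            if dataclasses.is_dataclass(o):
                return dataclasses.asdict(o)
            if isinstance(o, np.ndarray):
                return o.tolist()
            if isinstance(o, (np.integer,)):
                return int(o)
            if isinstance(o, (np.floating,)):
                return float(o)
            raise TypeError(f"not JSON-serializable: {type(o)}")
        return json.dumps(dataclasses.asdict(self), default=default,
                          indent=indent, sort_keys=True)


def metrics(counts: ConfusionCounts) -> tuple[float, float, float]:
    """Accuracy, sensitivity, specificity in percent.

    accuracy    = (TP + TN) / (TP + TN + FP + FN) * 100
    sensitivity = TP / (FN + TP) * 100
    specificity = TN / (FP + TN) * 100

    A metric whose denominator is 0 is returned as ``nan`` (undefined
    flag), never as a crash.
    """
    if counts.total == 0:
        raise ValueError("no evaluated samples")
    acc = 100.0 * (counts.TP + counts.TN) / counts.total
    pos = counts.FN + counts.TP
    neg = counts.FP + counts.TN
    sens = 100.0 * counts.TP / pos if pos > 0 else float("nan")
    spec = 100.0 * counts.TN / neg if neg > 0 else float("nan")
    return acc, sens, spec


def confusion_from_predictions(y_true: np.ndarray, y_pred: np.ndarray) -> ConfusionCounts:
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    return ConfusionCounts(
        TP=int(np.sum((y_true == 1) & (y_pred == 1))),
        TN=int(np.sum((y_true == 0) & (y_pred == 0))),
        FP=int(np.sum((y_true == 0) & (y_pred == 1))),
        FN=int(np.sum((y_true == 1) & (y_pred == 0))),
    )


def roc_curve(y: np.ndarray, scores: np.ndarray
              ) -> tuple[list[tuple[float, float]], float]:
    """ROC points (FPR, TPR) from a threshold sweep, and trapezoidal AUC.

    Ties in the decision values are grouped; the curve starts at (0, 0)
    and ends at (1, 1).
    """
    y = np.asarray(y, dtype=int)
    scores = np.asarray(scores, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    if not np.all(np.isfinite(scores)):
        raise ValueError("decision values must be finite")
    fpr, tpr, _ = skmetrics.roc_curve(y, scores, drop_intermediate=False)
    auc = float(skmetrics.auc(fpr, tpr))
    points = [(float(a), float(b)) for a, b in zip(fpr, tpr)]
    if points[0] != (0.0, 0.0):
        points.insert(0, (0.0, 0.0))
    if points[-1] != (1.0, 1.0):
        points.append((1.0, 1.0))
    return points, auc


def split_70_30(labels: np.ndarray, seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Stratified random 70/30 split, deterministic under ``seed``.

    The overall training size is round(0.7 N); per-class training counts
    are the floors of 0.7 n_c topped up by largest fractional remainder
    so the totals match (every class keeps at least one sample on each
    side).  Returns disjoint, exhaustive (train_idx, test_idx).
    """
    labels = np.asarray(labels, dtype=int)
    N = labels.size
    if N < 10:
        raise ValueError("need at least 10 samples to split")
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2:
        raise ValueError("both classes must be present")
    if counts.min() < 2:
        raise ValueError("every class needs at least 2 members")
    n_train = int(np.floor(0.7 * N + 0.5))
    exact = 0.7 * counts
    base = np.floor(exact).astype(int)
    base = np.clip(base, 1, counts - 1)
    remainder = n_train - int(base.sum())
    order = np.argsort(-(exact - np.floor(exact)), kind="stable")
    for k in order:
        if remainder <= 0:
            break
        if base[k] < counts[k] - 1:
            base[k] += 1
            remainder -= 1
    rng = np.random.default_rng(seed)
    train_parts, test_parts = [], []
    for cls, k in zip(classes, base):
        idx = np.where(labels == cls)[0]
        perm = rng.permutation(idx)
        train_parts.append(perm[:k])
        test_parts.append(perm[k:])
    train_idx = np.sort(np.concatenate(train_parts))
    test_idx = np.sort(np.concatenate(test_parts))
    return train_idx, test_idx


def _choose_q(eigenvalues: np.ndarray, q_policy: int | str,
              cumvar: float, n_train: int, d: int) -> int:
    if q_policy == "auto-cumvar":
        q = ppca.choose_q_by_cumvar(eigenvalues, cumvar)
    else:
        q = int(q_policy)
    # the sample covariance of n centered samples has rank <= n - 1, and
    # PPCA needs residual variance outside span(W), hence q <= n - 2
    return int(min(q, n_train - 2, d - 1))


def _fit_reduce(method: str, X_train: np.ndarray, X_test: np.ndarray,
                q: int, seed: int, ppca_fit: str, em_tol: float,
                em_max_iter: int) -> tuple[np.ndarray, np.ndarray]:
    if method == "pca-svm":
        model = ppca.fit_pca(X_train, q)
        return model.scores(X_train), model.scores(X_test)
    if method == "ppca-svm":
        # the closed-form eigendecomposition fit reaches the ML optimum
        # exactly; the EM route targets the same optimum iteratively and
        # is available for fidelity at small scale
        if ppca_fit == "closed-form":
            pm = ppca.fit_ppca_closed_form(X_train, q)
        elif ppca_fit == "em":
            pm = ppca.fit_ppca_em(X_train, q, tol=em_tol,
                                  max_iter=em_max_iter, seed=seed)
        else:
            raise ValueError(f"unknown ppca_fit {ppca_fit!r}")
        return (ppca.transform(pm, X_train).Z, ppca.transform(pm, X_test).Z)
    raise ValueError(f"unknown method {method!r}")


def run_experiment(sset: SpectrumSet, methods: tuple[str, ...] = METHODS,
                   n_repeats: int = 10, q_policy: int | str = "auto-cumvar",
                   cumvar: float = 0.9999, svm_cfg: classify.SVMConfig | None = None,
                   seed: int = 0, pooled_reduction: bool = False,
                   ppca_fit: str = "closed-form", em_tol: float = 1e-7,
                   em_max_iter: int = 500) -> ExperimentReport:
    """Repeated stratified 70/30 hold-out comparison of the reducer+SVM stacks.

    Repeat r uses split seed ``seed + r``; the reducer is fitted on the
    training partition (or the pooled set if ``pooled_reduction``), q
    chosen by ``q_policy``, the SVM grid-searched on training scores, and
    the test partition scored.
    """
    for m in methods:
        if m not in METHODS:
            raise ValueError(f"unknown method {m!r}")
    y = sset.require_labels()
    X = sset.X
    if svm_cfg is None:
        svm_cfg = classify.SVMConfig()
    runs: list[RunResult] = []
    seeds = []
    for r in range(n_repeats):
        split_seed = seed + r
        seeds.append(split_seed)
        train_idx, test_idx = split_70_30(y, split_seed)
        Xtr, Xte = X[train_idx], X[test_idx]
        ytr, yte = y[train_idx], y[test_idx]
        eig_source = X if pooled_reduction else Xtr
        eigenvalues = ppca.pca_eigenvalues(eig_source)
        q = _choose_q(eigenvalues, q_policy, cumvar, Xtr.shape[0], X.shape[1])
        for method in methods:
            fit_source = X if pooled_reduction else Xtr
            Ztr_full, Zte = _fit_reduce(method, fit_source, Xte, q,
                                        seed=split_seed, ppca_fit=ppca_fit,
                                        em_tol=em_tol,
                                        em_max_iter=em_max_iter)
            Ztr = Ztr_full[train_idx] if pooled_reduction else Ztr_full
            cfg_r = dataclasses.replace(svm_cfg, seed=split_seed)
            clf = classify.train_with_search(Ztr, ytr, cfg_r)
            y_pred, dec = classify.predict(clf, Zte)
            counts = confusion_from_predictions(yte, y_pred)
            acc, sens, spec = metrics(counts)
            roc_pts, auc = roc_curve(yte, dec)
            runs.append(RunResult(
                run_index=r + 1, method=method, counts=counts,
                accuracy=acc, sensitivity=sens, specificity=spec,
                roc=roc_pts, auc=auc, best_c=clf.best_c, best_g=clf.best_g, q=q,
            ))
            log.info("run %d %s: q=%d acc=%.2f sens=%.2f spec=%.2f auc=%.3f",
                     r + 1, method, q, acc, sens, spec, auc)
    averages = {
        m: average_table([r for r in runs if r.method == m]) for m in methods
    }
    config = dict(methods=list(methods), n_repeats=n_repeats,
                  q_policy=str(q_policy), cumvar=cumvar, seed=seed,
                  pooled_reduction=pooled_reduction, ppca_fit=ppca_fit,
                  svm=dict(c_grid=list(svm_cfg.c_grid), g_grid=list(svm_cfg.g_grid),
                           k_folds=svm_cfg.k_folds))
    return ExperimentReport(runs=runs, averages=averages, config=config, seeds=seeds)


def average_table(runs: list[RunResult] | list[dict] | np.ndarray
                  ) -> dict[str, float]:
    """Arithmetic mean of per-run accuracy/sensitivity/specificity.

    Accepts RunResults or plain per-run metric rows.  Means are computed
    on the unrounded values; display rounding is the caller's concern.
    """
    if runs is None or len(runs) == 0:
        raise ValueError("average_table needs at least one run")
    if isinstance(runs[0], RunResult):
        rows = [(r.accuracy, r.sensitivity, r.specificity) for r in runs]
    elif isinstance(runs[0], dict):
        rows = [(r["accuracy"], r["sensitivity"], r["specificity"]) for r in runs]
    else:
        rows = [tuple(r) for r in np.atleast_2d(np.asarray(runs, dtype=float))]
    arr = np.asarray(rows, dtype=float)
    return {
        "accuracy": float(np.mean(arr[:, 0])),
        "sensitivity": float(np.mean(arr[:, 1])),
        "specificity": float(np.mean(arr[:, 2])),
    }
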