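"""RBF-SVM classification over latent scores.

The soft-margin SVM (minimize (1/2)||w||^2 + c * sum(xi) subject to the
margin constraints) with an RBF kernel exp(-g ||x - x'||^2) is solved by
scikit-learn's libsvm binding; this module owns hyperparameter selection
and the feature scaling contract around it.

Hyperparameters (c, g) are chosen by stratified k-fold cross-validated
grid search on the training partition only, on the conventional
exponential grids (c in 2^-5..2^15, g in 2^-15..2^3).  Features are
standardized (mean 0, sd 1 on training data) before the kernel, since RBF
distances are scale-sensitive and latent-score scales vary by component;
the scaler parameters travel with the trained classifier so prediction
never touches test statistics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

__all__ = ["SVMConfig", "TrainedClassifier", "grid_search_cv", "train", "predict"]


def _log2_grid(lo: int, hi: int, step: int = 2) -> tuple[float, ...]:
    return tuple(float(2.0 ** e) for e in range(lo, hi + 1, step))


@dataclass
class SVMConfig:
    """Grid-search and cross-validation settings."""

    c_grid: tuple[float, ...] = field(default_factory=lambda: _log2_grid(-5, 15))
    g_grid: tuple[float, ...] = field(default_factory=lambda: _log2_grid(-15, 3))
    k_folds: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        self.c_grid = tuple(float(c) for c in self.c_grid)
        self.g_grid = tuple(float(g) for g in self.g_grid)
        if not self.c_grid or not self.g_grid:
            raise ValueError("c_grid and g_grid must be non-empty")
        if min(self.c_grid) <= 0 or min(self.g_grid) <= 0:
            raise ValueError("all grid values must be > 0")
        if self.k_folds < 2:
            raise ValueError("k_folds must be >= 2")


@dataclass
class TrainedClassifier:
    """Fitted RBF-SVM plus the standardization learned on training scores."""

    svm: SVC
    best_c: float
    best_g: float
    cv_accuracy: float
    folds_seed: int
    scaler_mean: np.ndarray
    scaler_scale: np.ndarray


def _standardize_fit(Z: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mean = Z.mean(axis=0)
    sd = Z.std(axis=0)
    zero = sd == 0
    if np.any(zero):
        warnings.warn(
            f"{int(np.sum(zero))} zero-variance feature(s); sd treated as 1",
            stacklevel=3,
        )
        sd = np.where(zero, 1.0, sd)
    return mean, sd


def _check_Zy(Z: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    y = np.asarray(y, dtype=int)
    if y.size != Z.shape[0]:
        raise ValueError("Z and y lengths differ")
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    return Z, y


def grid_search_cv(Z: np.ndarray, y: np.ndarray, cfg: SVMConfig
                   ) -> tuple[float, float, np.ndarray]:
    """Stratified k-fold CV accuracy over the (c, g) grid.

    Returns (best_c, best_g, cv_table) where ``cv_table[i, j]`` is the mean
    fold accuracy of ``(c_grid[i], g_grid[j])``.  Ties are broken toward
    smaller c, then smaller g.
    """
    Z, y = _check_Zy(Z, y)
    counts = np.bincount(y)
    min_class = int(counts[counts > 0].min())
    if cfg.k_folds > min_class:
        raise ValueError(
            f"k_folds = {cfg.k_folds} exceeds the minority class size {min_class}"
        )
    skf = StratifiedKFold(n_splits=cfg.k_folds, shuffle=True, random_state=cfg.seed)
    folds = list(skf.split(Z, y))

    # standardize within each fold from its training part only
    table = np.zeros((len(cfg.c_grid), len(cfg.g_grid)))
    fold_data = []
    for tr, te in folds:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            mean, sd = _standardize_fit(Z[tr])
        fold_data.append(((Z[tr] - mean) / sd, y[tr], (Z[te] - mean) / sd, y[te]))
    for i, c in enumerate(cfg.c_grid):
        for j, g in enumerate(cfg.g_grid):
            correct = 0
            for Ztr, ytr, Zte, yte in fold_data:
                clf = SVC(C=c, gamma=g, kernel="rbf")
                clf.fit(Ztr, ytr)
                correct += int(np.sum(clf.predict(Zte) == yte))
            table[i, j] = correct / y.size
    # argmax with smaller-c-then-smaller-g tie-break: first max in row-major order
    best_flat = int(np.argmax(table.ravel() > table.max() - 1e-12))
    bi, bj = divmod(best_flat, table.shape[1])
    return cfg.c_grid[bi], cfg.g_grid[bj], table


def train(Z: np.ndarray, y: np.ndarray, c: float, g: float,
          folds_seed: int = 0, cv_accuracy: float = float("nan")) -> TrainedClassifier:
    """Fit the RBF-SVM at (c, g) on standardized training scores."""
    Z, y = _check_Zy(Z, y)
    mean, sd = _standardize_fit(Z)
    svm = SVC(C=float(c), gamma=float(g), kernel="rbf")
    svm.fit((Z - mean) / sd, y)
    return TrainedClassifier(svm=svm, best_c=float(c), best_g=float(g),
                             cv_accuracy=cv_accuracy, folds_seed=folds_seed,
                             scaler_mean=mean, scaler_scale=sd)


def train_with_search(Z: np.ndarray, y: np.ndarray, cfg: SVMConfig) -> TrainedClassifier:
    """Grid search then fit at the selected (c, g)."""
    best_c, best_g, table = grid_search_cv(Z, y, cfg)
    bi = cfg.c_grid.index(best_c)
    bj = cfg.g_grid.index(best_g)
    return train(Z, y, best_c, best_g, folds_seed=cfg.seed,
                 cv_accuracy=float(table[bi, bj]))


def predict(model: TrainedClassifier, Z_new: np.ndarray
            ) -> tuple[np.ndarray, np.ndarray]:
    """Predicted labels and signed decision values for new scores.

    Scaling uses the stored training parameters only; the decision
    threshold is 0 and the decision-value sign always matches the label.
    """
    Z_new = np.atleast_2d(np.asarray(Z_new, dtype=float))
    if Z_new.shape[1] != model.scaler_mean.size:
        raise ValueError(
            f"scores have {Z_new.shape[1]} columns, model expects {model.scaler_mean.size}"
        )
    Zs = (Z_new - model.scaler_mean) / model.scaler_scale
    dec = model.svm.decision_function(Zs)
    labels = (dec > 0).astype(int)
    return labels, dec
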