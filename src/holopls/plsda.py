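"""PLS-DA: auto-scaled NIPALS latent-variable regression on a binary response.

The classifier regresses a 0/1 response on auto-scaled predictors with
PLS1 (NIPALS), selects the number of latent components by stratified
k-fold cross-validated accuracy, and assigns class 1 when the continuous
score is at or above the cutoff (default 0.5).
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold

logger = logging.getLogger(__name__)

__all__ = [
    "LabeledSet",
    "PLSDAModel",
    "autoscale_fit",
    "fit_pls_nipals",
    "select_components_cv",
    "fit_plsda",
    "predict",
    "save_model",
    "load_model",
]

_DEFLATION_TOL = 1e-12


@dataclass
class LabeledSet:
    """Predictor matrix, binary response, and sample identifiers."""

    X: np.ndarray
    y: np.ndarray
    ids: list[str]

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-D")
        if self.X.shape[0] != self.y.size or self.X.shape[0] != len(self.ids):
            raise ValueError("X, y, and ids must agree on the number of samples")
        if not set(np.unique(self.y).tolist()) <= {0, 1}:
            raise ValueError("y must be binary 0/1")
        if np.isnan(self.X).any():
            raise ValueError("X contains missing values")
        self.y = self.y.astype(int)


@dataclass
class PLSDAModel:
    """Fitted PLS-DA model (scaling + latent structure + coefficients).

    ``coefficients`` live on the auto-scaled kept columns;
    ``coefficients_original`` maps raw (unscaled) kept columns, with
    ``intercept`` completing the affine prediction on raw inputs.
    """

    n_features_in: int
    kept_columns: np.ndarray
    column_means: np.ndarray
    column_sds: np.ndarray
    y_mean: float
    W: np.ndarray  # (p_kept, k) weights
    P: np.ndarray  # (p_kept, k) X-loadings
    q: np.ndarray  # (k,) response loadings
    n_components: int
    coefficients: np.ndarray
    class_cutoff: float = 0.5
    cv_trace: list[float] = field(default_factory=list)
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_components < 1:
            raise ValueError("n_components must be >= 1")
        if not 0.0 < self.class_cutoff < 1.0:
            raise ValueError("class_cutoff must lie in (0, 1)")
        if len(self.coefficients) != len(self.kept_columns):
            raise ValueError("coefficients must align with kept_columns")

    @property
    def coefficients_original(self) -> np.ndarray:
        return self.coefficients / self.column_sds

    @property
    def intercept(self) -> float:
        return float(self.y_mean - self.column_means @ self.coefficients_original)

    def coefficient_for_column(self, j: int) -> float:
        """Original-scale coefficient of raw column ``j`` (0 if dropped)."""
        pos = np.where(self.kept_columns == j)[0]
        return float(self.coefficients_original[pos[0]]) if pos.size else 0.0


def autoscale_fit(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-column mean/SD (ddof=1) and the indices of non-constant columns.

    Zero-variance columns are dropped from the model (their indices are
    simply absent from ``kept_columns``); an all-constant matrix is an
    error.
    """
    X = np.asarray(X, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("auto-scaling requires n >= 2 samples")
    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=1)
    kept = np.where(sds > 0)[0]
    if kept.size == 0:
        raise ValueError("all columns have zero variance")
    if kept.size < X.shape[1]:
        logger.debug("dropping %d zero-variance columns", X.shape[1] - kept.size)
    return means[kept], sds[kept], kept


def _apply_scaling(X: np.ndarray, means: np.ndarray, sds: np.ndarray, kept: np.ndarray) -> np.ndarray:
    return (X[:, kept] - means) / sds


def fit_pls_nipals(
    X_scaled: np.ndarray, y_centered: np.ndarray, k: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """NIPALS PLS1 on pre-scaled data.

    Per component: w ∝ Xᵀy (unit norm), t = Xw, p = Xᵀt/tᵀt, q = yᵀt/tᵀt,
    then deflate X (and y).  Returns (W, P, q, coefficients) where
    coefficients b = W (PᵀW)⁻¹ q reconstruct ŷ = X·b on the scaled data.
    Degenerate deflation stops early with a warning, returning the
    achieved number of components.
    """
    X = np.array(X_scaled, dtype=float)
    y = np.array(y_centered, dtype=float)
    n, p = X.shape
    if k < 1:
        raise ValueError("k must be >= 1")
    W = np.zeros((p, k))
    P = np.zeros((p, k))
    q = np.zeros(k)
    achieved = 0
    for a in range(k):
        w = X.T @ y
        wn = np.linalg.norm(w)
        if wn < _DEFLATION_TOL:
            warnings.warn(
                f"NIPALS stopped early at {achieved} components (degenerate weight)",
                RuntimeWarning,
            )
            break
        w /= wn
        t = X @ w
        tt = float(t @ t)
        if tt < _DEFLATION_TOL:
            warnings.warn(
                f"NIPALS stopped early at {achieved} components (degenerate score)",
                RuntimeWarning,
            )
            break
        p_a = X.T @ t / tt
        q_a = float(y @ t) / tt
        X -= np.outer(t, p_a)
        y -= q_a * t
        W[:, a], P[:, a], q[a] = w, p_a, q_a
        achieved += 1
    if achieved == 0:
        raise ValueError("no PLS component could be extracted (X'y is zero)")
    W, P, q = W[:, :achieved], P[:, :achieved], q[:achieved]
    coef = W @ np.linalg.solve(P.T @ W, q)
    return W, P, q, coef


def _fit_fixed_k(X: np.ndarray, y: np.ndarray, k: int, cutoff: float) -> PLSDAModel:
    means, sds, kept = autoscale_fit(X)
    Xs = _apply_scaling(X, means, sds, kept)
    y_mean = float(np.mean(y))
    W, P, q, coef = fit_pls_nipals(Xs, y - y_mean, k)
    return PLSDAModel(
        n_features_in=X.shape[1],
        kept_columns=kept,
        column_means=means,
        column_sds=sds,
        y_mean=y_mean,
        W=W,
        P=P,
        q=q,
        n_components=W.shape[1],
        coefficients=coef,
        class_cutoff=cutoff,
    )


def predict(model: PLSDAModel, X_new: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Continuous scores and 0/1 labels for new samples.

    Label 1 is assigned when score >= cutoff (boundary goes to class 1).
    """
    X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
    if X_new.shape[1] != model.n_features_in:
        raise ValueError(
            f"column mismatch: model was trained on {model.n_features_in} columns, "
            f"got {X_new.shape[1]}"
        )
    Xs = _apply_scaling(X_new, model.column_means, model.column_sds, model.kept_columns)
    scores = model.y_mean + Xs @ model.coefficients
    labels = (scores >= model.class_cutoff).astype(int)
    return scores, labels


def select_components_cv(
    data: LabeledSet,
    k_max: int | None = None,
    folds: int = 10,
    seed: int = 0,
    class_cutoff: float = 0.5,
) -> tuple[int, list[float]]:
    """Choose the component count by stratified k-fold CV accuracy.

    Accuracy is pooled over folds at the class cutoff; ties are broken
    towards the smallest k.  ``k_max`` defaults to min(15, rank(X), n-1).
    """
    if folds < 2:
        raise ValueError("folds must be >= 2")
    n = data.X.shape[0]
    if n < folds:
        raise ValueError(f"need at least {folds} samples for {folds}-fold CV")
    counts = np.bincount(data.y, minlength=2)
    if counts.min() < folds:
        raise ValueError(
            f"minority class has {counts.min()} samples; cannot stratify into {folds} folds"
        )
    rank = int(np.linalg.matrix_rank(data.X - data.X.mean(axis=0)))
    cap = max(1, min(15, rank, n - 1))
    k_max = cap if k_max is None else max(1, min(k_max, cap))

    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(skf.split(data.X, data.y))
    correct = np.zeros(k_max)
    for train_idx, test_idx in splits:
        Xtr, ytr = data.X[train_idx], data.y[train_idx]
        Xte, yte = data.X[test_idx], data.y[test_idx]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            model = _fit_fixed_k(Xtr, ytr, k_max, class_cutoff)
        # reuse one k_max fit: the k-component coefficient vector is the
        # truncation of the same NIPALS sequence
        Xs = _apply_scaling(Xte, model.column_means, model.column_sds, model.kept_columns)
        for k in range(1, k_max + 1):
            kk = min(k, model.n_components)
            Wk, Pk, qk = model.W[:, :kk], model.P[:, :kk], model.q[:kk]
            coef_k = Wk @ np.linalg.solve(Pk.T @ Wk, qk)
            scores = model.y_mean + Xs @ coef_k
            pred = (scores >= class_cutoff).astype(int)
            correct[k - 1] += int(np.sum(pred == yte))
    cv_trace = (correct / n).tolist()
    best_k = int(np.argmax(correct)) + 1  # argmax returns the first (smallest) maximizer
    return best_k, cv_trace


def fit_plsda(
    data: LabeledSet,
    n_components: int | None = None,
    k_max: int | None = None,
    folds: int = 10,
    seed: int = 0,
    class_cutoff: float = 0.5,
) -> PLSDAModel:
    """Fit a PLS-DA model, selecting components by CV unless fixed."""
    if n_components is None:
        n_components, cv_trace = select_components_cv(
            data, k_max=k_max, folds=folds, seed=seed, class_cutoff=class_cutoff
        )
    else:
        cv_trace = []
    model = _fit_fixed_k(data.X, data.y, n_components, class_cutoff)
    model.cv_trace = cv_trace
    model.seed = seed
    return model


# ---------------------------------------------------------------------------
# JSON round-trip


def save_model(model: PLSDAModel, path: str | Path) -> None:
    payload = {
        "n_features_in": model.n_features_in,
        "kept_columns": model.kept_columns.tolist(),
        "column_means": model.column_means.tolist(),
        "column_sds": model.column_sds.tolist(),
        "y_mean": model.y_mean,
        "W": model.W.tolist(),
        "P": model.P.tolist(),
        "q": model.q.tolist(),
        "n_components": model.n_components,
        "coefficients": model.coefficients.tolist(),
        "class_cutoff": model.class_cutoff,
        "cv_trace": model.cv_trace,
        "seed": model.seed,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)
        fh.write("\n")


def load_model(path: str | Path) -> PLSDAModel:
    with open(path) as fh:
        d = json.load(fh)
    return PLSDAModel(
        n_features_in=int(d["n_features_in"]),
        kept_columns=np.asarray(d["kept_columns"], dtype=int),
        column_means=np.asarray(d["column_means"], dtype=float),
        column_sds=np.asarray(d["column_sds"], dtype=float),
        y_mean=float(d["y_mean"]),
        W=np.asarray(d["W"], dtype=float),
        P=np.asarray(d["P"], dtype=float),
        q=np.asarray(d["q"], dtype=float),
        n_components=int(d["n_components"]),
        coefficients=np.asarray(d["coefficients"], dtype=float),
        class_cutoff=float(d["class_cutoff"]),
        cv_trace=list(d["cv_trace"]),
        seed=d["seed"],
    )
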