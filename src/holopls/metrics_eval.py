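"""Confusion-matrix metrics and repeated random-split robustness evaluation.

The four classification measures are

    ACC = (TP + TN) / (TP + FP + TN + FN)
    SEN = TP / (TP + FN)
    SPE = TN / (TN + FP)
    MCC = (TP*TN - FN*FP) / sqrt((TN+FN)(FN+TP)(TP+FP)(FP+TN))

with the positive class being label 1.  Report display rounds half-up to
two decimal places; raw values are always retained in machine output.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Callable, Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "ConfusionCounts",
    "MetricSet",
    "confusion_counts",
    "compute_metrics",
    "round_half_up",
    "repeated_split_eval",
    "RepeatedSplitResult",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """TP/TN/FP/FN counts for a binary classifier (positive class = 1)."""

    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self) -> None:
        for name in ("TP", "TN", "FP", "FN"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")
        if self.n == 0:
            raise ValueError("confusion counts must cover at least one sample")

    @property
    def n(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


@dataclass(frozen=True)
class MetricSet:
    """ACC/SEN/SPE in [0,1] and MCC in [-1,1]; undefined ratios are NaN."""

    ACC: float
    SEN: float
    SPE: float
    MCC: float

    def rounded(self, ndigits: int = 2) -> dict[str, float]:
        """Half-up rounded copy as a plain dict (display convention)."""
        return {
            k: round_half_up(v, ndigits) if not math.isnan(v) else float("nan")
            for k, v in self.as_dict().items()
        }

    def as_dict(self) -> dict[str, float]:
        return {"ACC": self.ACC, "SEN": self.SEN, "SPE": self.SPE, "MCC": self.MCC}


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round with ties going away from zero (table display convention)."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def _as_binary(labels: Sequence[int], name: str) -> np.ndarray:
    arr = np.asarray(labels)
    if arr.ndim != 1 or arr.size == 0:
        raise ValueError(f"{name} must be a non-empty 1-D sequence")
    uniq = set(np.unique(arr).tolist())
    if not uniq <= {0, 1}:
        raise ValueError(f"{name} must contain only 0/1 labels, got {sorted(uniq)}")
    return arr.astype(int)


def confusion_counts(predicted: Sequence[int], truth: Sequence[int]) -> ConfusionCounts:
    """Count TP/TN/FP/FN with class 1 as the positive class."""
    p = _as_binary(predicted, "predicted")
    t = _as_binary(truth, "truth")
    if p.shape != t.shape:
        raise ValueError(f"length mismatch: {p.size} predictions vs {t.size} labels")
    return ConfusionCounts(
        TP=int(np.sum((p == 1) & (t == 1))),
        TN=int(np.sum((p == 0) & (t == 0))),
        FP=int(np.sum((p == 1) & (t == 0))),
        FN=int(np.sum((p == 0) & (t == 1))),
    )


def compute_metrics(c: ConfusionCounts) -> MetricSet:
    """Compute ACC, SEN, SPE, and MCC from confusion counts.

    SEN (resp. SPE) with an empty denominator is reported as NaN with a
    warning rather than silently coerced to 0 or 1.  A zero MCC
    denominator yields MCC = 0 by convention (logged).
    """
    tp, tn, fp, fn = float(c.TP), float(c.TN), float(c.FP), float(c.FN)
    acc = (tp + tn) / c.n

    if tp + fn == 0:
        logger.warning("SEN undefined: no positive samples (TP+FN=0); reporting NaN")
        sen = float("nan")
    else:
        sen = tp / (tp + fn)

    if tn + fp == 0:
        logger.warning("SPE undefined: no negative samples (TN+FP=0); reporting NaN")
        spe = float("nan")
    else:
        spe = tn / (tn + fp)

    denom = math.sqrt((tn + fn) * (fn + tp) * (tp + fp) * (fp + tn))
    if denom == 0.0:
        logger.info("MCC denominator is zero; reporting MCC = 0 by convention")
        mcc = 0.0
    else:
        mcc = (tp * tn - fn * fp) / denom

    return MetricSet(ACC=acc, SEN=sen, SPE=spe, MCC=mcc)


@dataclass
class RepeatedSplitResult:
    """Per-repeat accuracies plus their summary statistics (ddof=1 SD)."""

    train_acc: np.ndarray
    valid_acc: np.ndarray
    n_resampled: int

    @property
    def train_mean(self) -> float:
        return float(np.mean(self.train_acc))

    @property
    def train_sd(self) -> float:
        return float(np.std(self.train_acc, ddof=1))

    @property
    def valid_mean(self) -> float:
        return float(np.mean(self.valid_acc))

    @property
    def valid_sd(self) -> float:
        return float(np.std(self.valid_acc, ddof=1))

    def summary(self) -> dict[str, float]:
        return {
            "train_mean": self.train_mean,
            "train_sd": self.train_sd,
            "valid_mean": self.valid_mean,
            "valid_sd": self.valid_sd,
            "n_repeats": len(self.train_acc),
            "n_resampled": self.n_resampled,
        }


def repeated_split_eval(
    X: np.ndarray,
    y: Sequence[int],
    fit_predict: Callable[[np.ndarray, np.ndarray, np.ndarray], tuple[np.ndarray, np.ndarray]],
    n_repeats: int = 1000,
    train_fraction: float = 2.0 / 3.0,
    seed: int = 0,
    max_resample: int = 100,
) -> RepeatedSplitResult:
    """Repeated random-split model evaluation.

    For each repeat a seeded random train/validation split is drawn,
    ``fit_predict(X_train, y_train, X_valid)`` is called and must return
    ``(train_predictions, valid_predictions)``; training and validation
    accuracies are recorded.  Splits that leave a single class in the
    training portion are resampled (counted in ``n_resampled``).

    The default 2:1 train/validation proportion mirrors the source
    protocol's 736/368 division.
    """
    if n_repeats < 2:
        raise ValueError("n_repeats must be >= 2")
    y = _as_binary(y, "y")
    X = np.asarray(X, dtype=float)
    if X.shape[0] != y.size:
        raise ValueError("X and y row counts differ")
    n = y.size
    n_train = int(round(train_fraction * n))
    if not 1 <= n_train < n:
        raise ValueError(f"train_fraction {train_fraction} leaves no validation samples")

    rng = np.random.default_rng(seed)
    train_accs = np.empty(n_repeats)
    valid_accs = np.empty(n_repeats)
    n_resampled = 0
    for r in range(n_repeats):
        for _ in range(max_resample):
            perm = rng.permutation(n)
            tr, va = perm[:n_train], perm[n_train:]
            if len(set(y[tr].tolist())) == 2:
                break
            n_resampled += 1
        else:
            raise RuntimeError("could not draw a two-class training split")
        pred_tr, pred_va = fit_predict(X[tr], y[tr], X[va])
        train_accs[r] = float(np.mean(np.asarray(pred_tr) == y[tr]))
        valid_accs[r] = float(np.mean(np.asarray(pred_va) == y[va]))
    if n_resampled:
        logger.info("repeated_split_eval resampled %d degenerate splits", n_resampled)
    return RepeatedSplitResult(train_acc=train_accs, valid_acc=valid_accs, n_resampled=n_resampled)
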