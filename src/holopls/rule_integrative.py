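"""Single-descriptor threshold rule and the two-stage integrative classifier.

The rule classifies a compound as class 1 when a scalar descriptor lies
strictly beyond a threshold (default direction: greater-is-positive, as
in the BV12-DRY > -0.1 rule; equality goes to class 0).

The integrative classifier runs hologram PLS-DA first and the rule
second.  Two modes are provided:

* ``deploy`` — label-blind: compounds whose PLS-DA continuous score
  falls inside the ambiguity band [cutoff-δ, cutoff+δ] are re-assigned
  by the rule; everyone else keeps the PLS-DA label.
* ``oracle_eval`` — label-aware evaluation that mirrors the source
  procedure: compounds the PLS-DA misclassifies are re-evaluated by the
  rule.  This mode requires true labels and is for evaluation only.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .plsda import PLSDAModel, predict

__all__ = [
    "RuleModel",
    "IntegrativeModel",
    "IntegrationResult",
    "apply_rule",
    "calibrate_threshold",
    "integrate",
    "DEFAULT_RULE",
]

Direction = Literal["greater_is_positive", "less_is_positive"]


@dataclass(frozen=True)
class RuleModel:
    descriptor_name: str
    threshold: float
    direction: Direction = "greater_is_positive"

    def __post_init__(self) -> None:
        if not np.isfinite(self.threshold):
            raise ValueError("threshold must be finite")
        if self.direction not in ("greater_is_positive", "less_is_positive"):
            raise ValueError(f"unknown direction {self.direction!r}")


#: The published single-descriptor rule: BV12-DRY > -0.1 => inhibitor.
DEFAULT_RULE = RuleModel(descriptor_name="BV12-DRY", threshold=-0.1)


@dataclass
class IntegrativeModel:
    pls: PLSDAModel
    rule: RuleModel
    ambiguity_band: float = 0.15
    mode: Literal["deploy", "oracle_eval"] = "deploy"

    def __post_init__(self) -> None:
        if self.ambiguity_band < 0:
            raise ValueError("ambiguity band must be >= 0")
        if self.mode not in ("deploy", "oracle_eval"):
            raise ValueError(f"unknown mode {self.mode!r}")


@dataclass
class IntegrationResult:
    """Final labels plus, per compound, which stage decided ('pls' or 'rule')."""

    labels: np.ndarray
    provenance: list[str]
    pls_scores: np.ndarray
    pls_labels: np.ndarray


def apply_rule(rule: RuleModel, values: Sequence[float]) -> np.ndarray:
    """Apply the threshold rule (strict inequality; boundary is class 0)."""
    v = np.asarray(values, dtype=float)
    if np.isnan(v).any():
        raise ValueError("descriptor values contain missing entries")
    if rule.direction == "greater_is_positive":
        return (v > rule.threshold).astype(int)
    return (v < rule.threshold).astype(int)


def calibrate_threshold(
    values: Sequence[float], labels: Sequence[int], descriptor_name: str = "descriptor"
) -> RuleModel:
    """Fit a threshold rule maximizing balanced accuracy (mean of SEN, SPE).

    Candidate thresholds are the midpoints between adjacent sorted unique
    values; both rule directions are tried.  Ties go to the smallest
    threshold, with greater-is-positive preferred on exact direction ties.
    """
    v = np.asarray(values, dtype=float)
    y = np.asarray(labels, dtype=int)
    if v.size != y.size or v.size == 0:
        raise ValueError("values and labels must be equal-length and non-empty")
    if len(set(y.tolist())) < 2:
        raise ValueError("both classes must be present for calibration")

    uniq = np.unique(v)
    if uniq.size < 2:
        raise ValueError("descriptor is constant; no threshold separates the classes")
    midpoints = (uniq[:-1] + uniq[1:]) / 2.0

    n_pos = int(np.sum(y == 1))
    n_neg = y.size - n_pos
    best: tuple[float, float, str] | None = None  # (-bacc, threshold, direction)
    for thr in midpoints:
        for direction in ("greater_is_positive", "less_is_positive"):
            pred = apply_rule(RuleModel(descriptor_name, float(thr), direction), v)
            sen = float(np.sum((pred == 1) & (y == 1))) / n_pos
            spe = float(np.sum((pred == 0) & (y == 0))) / n_neg
            cand = (-(sen + spe) / 2.0, float(thr), direction)
            if best is None or cand < best:
                best = cand
    _, thr, direction = best
    return RuleModel(descriptor_name=descriptor_name, threshold=thr, direction=direction)


def integrate(
    imodel: IntegrativeModel,
    holograms: np.ndarray,
    descriptor_values: Sequence[float],
    labels: Sequence[int] | None = None,
) -> IntegrationResult:
    """Two-stage classification: PLS-DA first, threshold rule second.

    In ``deploy`` mode the rule overrides PLS-DA inside the score
    ambiguity band only, independent of any labels.  In ``oracle_eval``
    mode the rule re-evaluates exactly the PLS-DA errors against the
    supplied true labels (evaluation-only; flagged in provenance).
    """
    scores, pls_labels = predict(imodel.pls, holograms)
    desc = np.asarray(descriptor_values, dtype=float)
    if desc.size != scores.size:
        raise ValueError("descriptor values and hologram rows must align")
    rule_labels = apply_rule(imodel.rule, desc)

    if imodel.mode == "oracle_eval":
        if labels is None:
            raise ValueError("oracle_eval mode requires true labels")
        y = np.asarray(labels, dtype=int)
        if y.size != scores.size:
            raise ValueError("labels must align with samples")
        use_rule = pls_labels != y
    else:
        cutoff, delta = imodel.pls.class_cutoff, imodel.ambiguity_band
        if delta == 0:  # degenerate band: pure PLS-DA
            use_rule = np.zeros(scores.size, dtype=bool)
        else:
            use_rule = (scores >= cutoff - delta) & (scores <= cutoff + delta)

    final = np.where(use_rule, rule_labels, pls_labels)
    provenance = ["rule" if u else "pls" for u in use_rule]
    return IntegrationResult(
        labels=final.astype(int),
        provenance=provenance,
        pls_scores=scores,
        pls_labels=pls_labels,
    )
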