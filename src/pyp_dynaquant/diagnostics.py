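"""Quantitative classification rules and diagnostic/agreement statistics.

Two subject-level rules from the study:

* blood-pool grade — positive when myocardial SUVmean is equal to or greater
  than blood-pool SUVmean on the same image;
* %ID/mL threshold — positive when myocardial %ID/mL is at least 0.003%
  (the boundary itself counts as positive; the study states only strict
  inequalities on either side, so the convention is recorded in the output).

Plus confusion-matrix performance, Cohen's kappa, and a Welch t-test from
group summary statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .quantitation import DegenerateInputError

POSITIVE = "positive"
NEGATIVE = "negative"


@dataclass(frozen=True)
class DiagnosisRecord:
    """One rule application: the label and exactly what was compared."""

    subject_id: str
    window: tuple[float, float]
    rule: str  # "blood_pool_grade" or "pid_threshold"
    inputs_used: dict = field(default_factory=dict)
    label: str = NEGATIVE


@dataclass(frozen=True)
class PerformanceSummary:
    """Confusion counts and percent sensitivity/specificity/accuracy.

    Rates are ``None`` when the corresponding truth class is absent.
    """

    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: float | None
    specificity: float | None
    accuracy: float

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def classify_blood_pool_grade(suv_myo: float, suv_bp: float,
                              subject_id: str = "",
                              window: tuple[float, float] = (0.0, 0.0)
                              ) -> DiagnosisRecord:
    """Positive iff myocardial SUV >= blood-pool SUV."""
    if suv_myo <= 0 or suv_bp <= 0:
        raise DegenerateInputError("SUV inputs must be positive")
    return DiagnosisRecord(
        subject_id=subject_id, window=window, rule="blood_pool_grade",
        inputs_used={"suv_myo": float(suv_myo), "suv_bp": float(suv_bp)},
        label=POSITIVE if suv_myo >= suv_bp else NEGATIVE)


def classify_pid(pid_percent: float, threshold: float = 0.003,
                 subject_id: str = "",
                 window: tuple[float, float] = (0.0, 0.0)) -> DiagnosisRecord:
    """Positive iff %ID/mL >= threshold (boundary counts as positive)."""
    if pid_percent < 0:
        raise DegenerateInputError("%ID/mL must be non-negative")
    return DiagnosisRecord(
        subject_id=subject_id, window=window, rule="pid_threshold",
        inputs_used={"pid_percent": float(pid_percent),
                     "threshold": float(threshold),
                     "boundary_convention": ">= is positive"},
        label=POSITIVE if pid_percent >= threshold else NEGATIVE)


def _as_binary(labels) -> np.ndarray:
    arr = np.asarray(labels)
    if arr.size == 0:
        raise DegenerateInputError("empty label list")
    if arr.dtype.kind in "UOS":
        return arr == POSITIVE
    return arr.astype(bool)


def diagnostic_performance(predicted, truth) -> PerformanceSummary:
    """Confusion counts and percentages of predictions against truth.

    Accepts 'positive'/'negative' strings or booleans.
    """
    pred = _as_binary(predicted)
    true = _as_binary(truth)
    if pred.shape != true.shape:
        raise DegenerateInputError("prediction and truth lengths differ")
    tp = int(np.sum(pred & true))
    fp = int(np.sum(pred & ~true))
    tn = int(np.sum(~pred & ~true))
    fn = int(np.sum(~pred & true))
    n_pos, n_neg = tp + fn, tn + fp
    return PerformanceSummary(
        tp=tp, fp=fp, tn=tn, fn=fn,
        sensitivity=100.0 * tp / n_pos if n_pos else None,
        specificity=100.0 * tn / n_neg if n_neg else None,
        accuracy=100.0 * (tp + tn) / (tp + tn + fp + fn))


def cohen_kappa(labels_a, labels_b) -> float:
    """Cohen's kappa for two binary label vectors.

    kappa = (p_o - p_e) / (1 - p_e) with marginal-product expected agreement.
    Perfect agreement returns 1.0 even when a marginal is degenerate (all one
    class), so unanimous readers score kappa = 1 rather than 0/0.
    """
    a = _as_binary(labels_a)
    b = _as_binary(labels_b)
    if a.shape != b.shape:
        raise DegenerateInputError("label vectors must have equal length")
    n = a.size
    p_o = float(np.mean(a == b))
    p_a, p_b = float(a.mean()), float(b.mean())
    p_e = p_a * p_b + (1 - p_a) * (1 - p_b)
    if p_o == 1.0:
        return 1.0  # declared convention for degenerate-but-perfect agreement
    if p_e == 1.0:
        return 0.0
    return (p_o - p_e) / (1.0 - p_e)


def welch_t_from_summary(mean1: float, sd1: float, n1: int,
                         mean2: float, sd2: float, n2: int
                         ) -> tuple[float, float, float]:
    """Welch's unequal-variance t-test from group summaries.

    Returns (t, Welch-Satterthwaite df, two-sided p).
    """
    if n1 < 2 or n2 < 2:
        raise DegenerateInputError("each group needs n >= 2")
    if sd1 <= 0 or sd2 <= 0:
        raise DegenerateInputError("group SDs must be positive")
    v1, v2 = sd1**2 / n1, sd2**2 / n2
    t = (mean1 - mean2) / np.sqrt(v1 + v2)
    df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(df), float(p)
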