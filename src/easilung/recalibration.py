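"""Recalibrating the fixed score on a new platform or cohort.

A score developed on one sequencing platform keeps its discrimination on
another (affine maps with positive slope leave the ROC untouched) but its
probability mapping and decision threshold generally do not transfer.
The remedy is logistic recalibration: fit label ~ score on the new cohort
to obtain an intercept A and slope B — perfect transfer corresponds to
(A, B) = (0, 1) on the logit scale of an already-calibrated score — and
define the recalibrated logit as A + B·score.  A new Youden threshold is
then chosen; it is reported on the ORIGINAL score scale so that the
unmodified score terms remain directly usable with the new cut-off.

Low-burden samples (< 1 sub/Mb) never enter the recalibration fit; they
are handled by the gate as before.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .development import (
    ThresholdResult,
    auc,
    fit_logistic,
    hosmer_lemeshow,
    wald_ci,
    youden_threshold,
)
from .errors import ContractError, EstimationError
from .scoring import ScoreModel


@dataclass(frozen=True)
class CalibrationFit:
    """Single-predictor logistic fit of outcome on score."""

    intercept: float  # A
    slope: float  # B
    intercept_se: float
    slope_se: float

    @property
    def intercept_ci(self) -> tuple[float, float]:
        return (self.intercept - 1.96 * self.intercept_se, self.intercept + 1.96 * self.intercept_se)

    @property
    def slope_ci(self) -> tuple[float, float]:
        return (self.slope - 1.96 * self.slope_se, self.slope + 1.96 * self.slope_se)


def fit_recalibration(scores: Sequence[float], labels: Sequence[int]) -> CalibrationFit:
    """Maximum-likelihood fit of label ~ score; returns (A, B) with SEs."""
    s = np.asarray(scores, dtype=float)
    if np.all(s == s[0]):
        raise EstimationError("scores are constant; recalibration is not identifiable")
    fit = fit_logistic(pd.DataFrame({"score": s}), labels)
    term = fit.terms[0]
    return CalibrationFit(
        intercept=fit.intercept,
        slope=term.beta,
        intercept_se=fit.intercept_se,
        slope_se=term.se,
    )


def apply_recalibration(score: float | np.ndarray, A: float, B: float):
    """Recalibrated logit ``A + B·score`` (affine, order-preserving for B>0)."""
    return A + B * np.asarray(score, dtype=float) if isinstance(score, np.ndarray) else A + B * score


@dataclass
class RecalibrationResult:
    """Outcome of external-validation recalibration on one cohort."""

    intercept: float  # A
    slope: float  # B
    threshold: ThresholdResult  # new Youden threshold on the original score scale
    auc: float
    hosmer_lemeshow: tuple[float, int, float]
    pre: dict | None  # se/sp at the old threshold, if one was supplied
    post: dict

    def to_dict(self) -> dict:
        return {
            "intercept": self.intercept,
            "slope": self.slope,
            "threshold": self.threshold.threshold,
            "auc": self.auc,
            "hosmer_lemeshow": {
                "statistic": self.hosmer_lemeshow[0],
                "df": self.hosmer_lemeshow[1],
                "p_value": self.hosmer_lemeshow[2],
            },
            "pre": self.pre,
            "post": self.post,
        }


def _se_sp_at(scores: np.ndarray, labels: np.ndarray, threshold: float) -> dict:
    """Se/Sp (with Wald CIs) of the rule score > threshold."""
    y = np.asarray(labels, dtype=int)
    pred = scores > threshold
    n1 = int(y.sum())
    n0 = len(y) - n1
    se = float(np.sum(pred & (y == 1)) / n1)
    sp = float(np.sum(~pred & (y == 0)) / n0)
    return {
        "threshold": threshold,
        "sensitivity": se,
        "sensitivity_ci": list(wald_ci(se, n1)),
        "specificity": sp,
        "specificity_ci": list(wald_ci(sp, n0)),
    }


def validate(
    scores: Sequence[float],
    labels: Sequence[int],
    A: float | None = None,
    B: float | None = None,
    old_threshold: float | None = None,
    hl_groups: int = 10,
) -> RecalibrationResult:
    """Recalibrate and re-assess a fixed score on a validation cohort.

    If (A, B) are not supplied they are fitted from the data.  Reports
    the AUC (invariant under the affine recalibration, kept for audit),
    the Hosmer–Lemeshow test on the recalibrated probabilities, the new
    Youden threshold on the original score scale, and se/sp before (at
    ``old_threshold``, when given) and after (at the new threshold).
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    if len(np.unique(y)) < 2:
        raise ContractError("both label classes required for validation")
    if A is None or B is None:
        fit = fit_recalibration(s, y)
        A, B = fit.intercept, fit.slope
    if B <= 0:
        raise EstimationError("recalibration slope must be positive")
    probs = expit(apply_recalibration(s, A, B))
    thr = youden_threshold(s, y)
    return RecalibrationResult(
        intercept=float(A),
        slope=float(B),
        threshold=thr,
        auc=auc(s, y),
        hosmer_lemeshow=hosmer_lemeshow(probs, y, hl_groups),
        pre=_se_sp_at(s, y, old_threshold) if old_threshold is not None else None,
        post=_se_sp_at(s, y, thr.threshold),
    )


def recalibrated_model(base: ScoreModel, result: RecalibrationResult, name: str | None = None) -> ScoreModel:
    """A deployable ScoreModel: unmodified score terms + new calibration/threshold."""
    return base.with_calibration(
        result.intercept, result.slope, result.threshold.threshold, name=name
    )


__all__ = [
    "CalibrationFit",
    "RecalibrationResult",
    "fit_recalibration",
    "apply_recalibration",
    "validate",
    "recalibrated_model",
]
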