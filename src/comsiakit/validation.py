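"""Internal and external model-validation statistics.

Internal quality is the leave-one-out q²; external predictivity on a held-out
test set is r²pred = (SD − PRESS)/SD with SD taken about the *training* mean.
The external battery additionally applies the through-origin criteria of
Golbraikh & Tropsha: with y the observed and ŷ the predicted test
activities,

    k  = Σ y·ŷ / Σ ŷ²      (slope of y on ŷ through the origin)
    k' = Σ y·ŷ / Σ y²      (slope of ŷ on y through the origin)
    r0²  = 1 − Σ(y − k·ŷ)² / Σ(y − ȳ)²
    r0'² = 1 − Σ(ŷ − k'·y)² / Σ(ŷ − ŷ̄)²

and a model is considered externally predictive when q² > 0.5, r² > 0.6,
(r² − r0²)/r² < 0.1 or (r² − r0'²)/r² < 0.1, and 0.85 ≤ k ≤ 1.15 or
0.85 ≤ k' ≤ 1.15.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict

import numpy as np

from .pls import regression_summary


class ValidationError(ValueError):
    pass


def _pair(y, y_pred, min_len=2):
    y = np.asarray(y, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y.shape != y_pred.shape or y.ndim != 1 or len(y) < min_len:
        raise ValidationError(
            f"need matched 1-D arrays of length >= {min_len}, got {y.shape} vs {y_pred.shape}")
    return y, y_pred


def q2_score(y, y_loo_pred, y_mean=None) -> float:
    """Cross-validated determination coefficient 1 − Σ(y−ŷ)²/Σ(y−ȳ)²."""
    y, y_pred = _pair(y, y_loo_pred)
    y_mean = float(y.mean()) if y_mean is None else float(y_mean)
    ss = float(np.sum((y - y_mean) ** 2))
    if ss <= 0:
        raise ValidationError("constant activities: q^2 undefined")
    return 1.0 - float(np.sum((y - y_pred) ** 2)) / ss


def r2pred(y_test, y_pred_test, y_train_mean):
    """External predictive r² = (SD − PRESS)/SD about the training mean.

    Returns ``(r2pred, SD, PRESS)``.
    """
    y, y_pred = _pair(y_test, y_pred_test, min_len=1)
    if not math.isfinite(y_train_mean):
        raise ValidationError("training mean must be finite")
    sd = float(np.sum((y - y_train_mean) ** 2))
    press = float(np.sum((y - y_pred) ** 2))
    if sd <= 0:
        raise ValidationError("SD = 0: test activities equal the training mean")
    return (sd - press) / sd, sd, press


regression_stats = regression_summary


@dataclass(frozen=True)
class ValidationReport:
    """External-validation scalars and the four pass/fail criteria."""

    q2: float
    r2: float
    r0_sq: float
    r0p_sq: float
    k: float
    k_prime: float
    crit_q2: bool          # q2 > 0.5
    crit_r2: bool          # r2 > 0.6
    crit_r0: bool          # (r2−r0²)/r2 < 0.1 or (r2−r0'²)/r2 < 0.1
    crit_slope: bool       # 0.85 <= k <= 1.15 or same for k'

    @property
    def all_pass(self) -> bool:
        return self.crit_q2 and self.crit_r2 and self.crit_r0 and self.crit_slope

    def to_json(self, **kwargs) -> str:
        d = asdict(self)
        d["all_pass"] = self.all_pass
        return json.dumps(d, **kwargs)

    def __str__(self) -> str:
        lines = [
            f"q2      = {self.q2:.4f}   [{'pass' if self.crit_q2 else 'FAIL'}] (> 0.5)",
            f"r2      = {self.r2:.4f}   [{'pass' if self.crit_r2 else 'FAIL'}] (> 0.6)",
            f"r0^2    = {self.r0_sq:.4f}, r0'^2 = {self.r0p_sq:.4f}   "
            f"[{'pass' if self.crit_r0 else 'FAIL'}] ((r2-r0^2)/r2 < 0.1)",
            f"k       = {self.k:.4f}, k' = {self.k_prime:.4f}   "
            f"[{'pass' if self.crit_slope else 'FAIL'}] (0.85..1.15)",
            f"overall: {'PASS' if self.all_pass else 'FAIL'}",
        ]
        return "\n".join(lines)


def through_origin(y, x):
    """Slope and r² of the no-intercept regression y = k·x.

    r0² is computed about the mean of y (so it can be negative when the
    origin-constrained line fits worse than the mean).
    """
    y, x = _pair(y, x)
    sxx = float(np.sum(x * x))
    if sxx <= 0:
        raise ValidationError("zero-variance regressor in through-origin fit")
    k = float(np.sum(y * x)) / sxx
    ss = float(np.sum((y - y.mean()) ** 2))
    if ss <= 0:
        raise ValidationError("zero-variance response in through-origin fit")
    r0sq = 1.0 - float(np.sum((y - k * x) ** 2)) / ss
    return k, r0sq


def tropsha_report(y_test, y_pred_test, q2_train) -> ValidationReport:
    """Full external-validation battery on test-set predictions."""
    y, y_pred = _pair(y_test, y_pred_test, min_len=3)
    if np.std(y) <= 0 or np.std(y_pred) <= 0:
        raise ValidationError("zero-variance observed or predicted activities")
    r2 = float(np.corrcoef(y, y_pred)[0, 1] ** 2)
    k, r0_sq = through_origin(y, y_pred)
    k_prime, r0p_sq = through_origin(y_pred, y)
    crit_r0 = ((r2 - r0_sq) / r2 < 0.1) or ((r2 - r0p_sq) / r2 < 0.1)
    crit_slope = (0.85 <= k <= 1.15) or (0.85 <= k_prime <= 1.15)
    return ValidationReport(
        q2=float(q2_train), r2=r2, r0_sq=r0_sq, r0p_sq=r0p_sq,
        k=k, k_prime=k_prime,
        crit_q2=bool(q2_train > 0.5), crit_r2=bool(r2 > 0.6),
        crit_r0=bool(crit_r0), crit_slope=bool(crit_slope),
    )
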