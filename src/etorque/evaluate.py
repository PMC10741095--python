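"""Prediction-quality metrics and the performance criteria.

RMSE and the coefficient of determination R² are computed on the unscaled
torques in N·m.  A model is considered to perform well when the ratio of the
RMSE to the mean actual torque is below 15% and R² exceeds 0.9.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DomainError, IntegrityError

RATIO_LIMIT_PCT = 15.0
R2_LIMIT = 0.9


def rmse(y: np.ndarray, yhat: np.ndarray) -> float:
    """Root-mean-square error sqrt(mean((y − ŷ)²))."""
    y = np.asarray(y, dtype=float).reshape(-1)
    yhat = np.asarray(yhat, dtype=float).reshape(-1)
    if y.size == 0 or y.shape != yhat.shape:
        raise IntegrityError("rmse needs equal, non-empty inputs")
    return float(np.sqrt(np.mean((y - yhat) ** 2)))


def r2(y: np.ndarray, yhat: np.ndarray) -> float:
    """Coefficient of determination 1 − SS_res/SS_tot; may be negative."""
    y = np.asarray(y, dtype=float).reshape(-1)
    yhat = np.asarray(yhat, dtype=float).reshape(-1)
    if y.size == 0 or y.shape != yhat.shape:
        raise IntegrityError("r2 needs equal, non-empty inputs")
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        raise DomainError("r2 undefined for constant actual values")
    ss_res = float(np.sum((y - yhat) ** 2))
    return 1.0 - ss_res / ss_tot


def ratio_to_mean(rmse_val: float, y: np.ndarray) -> float:
    """100 × RMSE / mean(actual torque), in percent; requires a positive mean."""
    mean = float(np.mean(np.asarray(y, dtype=float)))
    if mean <= 0:
        raise DomainError(f"mean actual torque must be positive, got {mean:.4g}")
    return 100.0 * rmse_val / mean


@dataclass
class Metrics:
    """Summary of prediction accuracy on one evaluation set."""

    rmse: float
    r2: float
    mean_actual: float
    ratio_pct: float
    n: int

    def __str__(self) -> str:
        return (f"RMSE {self.rmse:.4f} N·m | mean actual {self.mean_actual:.4f} "
                f"N·m | ratio {self.ratio_pct:.2f}% | R² {self.r2:.4f} "
                f"(n={self.n})")


def compute_metrics(y: np.ndarray, yhat: np.ndarray) -> Metrics:
    """All metrics of one actual/predicted torque pair."""
    e = rmse(y, yhat)
    return Metrics(rmse=e, r2=r2(y, yhat),
                   mean_actual=float(np.mean(y)),
                   ratio_pct=ratio_to_mean(e, y),
                   n=int(np.asarray(y).reshape(-1).size))


def performance_ok(m: Metrics) -> tuple[bool, list[str]]:
    """Apply the performance criteria (ratio < 15%, R² > 0.9).

    Returns ``(passed, reasons)`` where ``reasons`` names each violated
    criterion; empty on a pass.
    """
    reasons = []
    if not m.ratio_pct < RATIO_LIMIT_PCT:
        reasons.append(
            f"RMSE/mean ratio {m.ratio_pct:.2f}% not below {RATIO_LIMIT_PCT}%"
        )
    if not m.r2 > R2_LIMIT:
        reasons.append(f"R² {m.r2:.4f} not above {R2_LIMIT}")
    return (not reasons), reasons
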