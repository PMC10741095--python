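"""Windowed EMG features and principal-component fusion.

Each 25 ms window yields an eight-dimensional feature vector in the fixed
order F1–F8:

====  ============================
F1    RMS, biceps
F2    RMS, triceps
F3    RMS, brachioradialis
F4    elbow joint angle (deg)
F5    elbow angular velocity (deg/s)
F6    iEMG, biceps
F7    iEMG, triceps
F8    iEMG, brachioradialis
====  ============================

Fusion standardizes the columns and eigendecomposes their 8×8 correlation
matrix; an eigenvalue's contribution rate is its share of the total variance
(λ/8 on standardized features, as a percentage).  The first five components
are retained by default.

iEMG is the windowed mean EMG value.  On zero-mean bandpassed EMG the plain
mean is ≈ 0, so the default mode rectifies first (mean |x|); ``mode="literal"``
computes the un-rectified mean for strict compatibility.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Mapping

import numpy as np

from .errors import DegenerateFeatureError, IntegrityError, StateError
from .preprocess import WindowGrid

FEATURE_NAMES = (
    "rms_biceps", "rms_triceps", "rms_brachioradialis",
    "elbow_angle", "angular_velocity",
    "iemg_biceps", "iemg_triceps", "iemg_brachioradialis",
)
_CHANNELS = ("biceps", "triceps", "brachioradialis")


def rms(window: np.ndarray, axis: int = -1) -> np.ndarray | float:
    """Root-mean-square of a window (or of each row of a window stack)."""
    window = np.asarray(window, dtype=float)
    if window.size == 0:
        raise IntegrityError("rms of an empty window")
    return np.sqrt(np.mean(np.square(window), axis=axis))


def iemg(window: np.ndarray, mode: Literal["rectified", "literal"] = "rectified",
         axis: int = -1) -> np.ndarray | float:
    """Integrated EMG: windowed mean of |x| (default) or of x (``literal``)."""
    window = np.asarray(window, dtype=float)
    if window.size == 0:
        raise IntegrityError("iemg of an empty window")
    if mode == "rectified":
        return np.mean(np.abs(window), axis=axis)
    if mode == "literal":
        return np.mean(window, axis=axis)
    raise ValueError(f"unknown iemg mode {mode!r}")


@dataclass
class FeatureMatrix:
    """``W × 8`` per-window feature values in the fixed F1–F8 column order."""

    values: np.ndarray
    grid: WindowGrid | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != len(FEATURE_NAMES):
            raise IntegrityError(
                f"feature matrix must have {len(FEATURE_NAMES)} columns, "
                f"got shape {self.values.shape}"
            )
        if not np.all(np.isfinite(self.values)):
            raise IntegrityError("feature matrix contains non-finite values")
        if np.any(self.values[:, [0, 1, 2]] < 0):
            raise IntegrityError("RMS columns must be non-negative")

    @property
    def n_windows(self) -> int:
        return self.values.shape[0]

    def save(self, path: str | Path) -> None:
        header = "\t".join(FEATURE_NAMES)
        np.savetxt(path, self.values, delimiter="\t", header=header)


def assemble_features(emg_windows: Mapping[str, np.ndarray],
                      angle: np.ndarray, velocity: np.ndarray,
                      grid: WindowGrid | None = None,
                      iemg_mode: Literal["rectified", "literal"] = "rectified",
                      ) -> FeatureMatrix:
    """Build the F1–F8 matrix from named per-channel window stacks.

    ``emg_windows`` maps channel names (exactly ``biceps``, ``triceps``,
    ``brachioradialis``) to ``(W, samples_per_window)`` arrays of filtered EMG;
    naming the channels makes an accidental channel permutation a loud error
    instead of silently mislabelled features.
    """
    if set(emg_windows) != set(_CHANNELS):
        raise IntegrityError(
            f"emg_windows keys {sorted(emg_windows)} != expected {sorted(_CHANNELS)}"
        )
    angle = np.asarray(angle, dtype=float)
    velocity = np.asarray(velocity, dtype=float)
    counts = {ch: np.asarray(w).shape[0] for ch, w in emg_windows.items()}
    w = angle.shape[0]
    if velocity.shape[0] != w or any(c != w for c in counts.values()):
        raise IntegrityError(
            f"window-count mismatch: angle {w}, velocity {velocity.shape[0]}, "
            f"emg {counts}"
        )
    cols = [rms(np.asarray(emg_windows[ch], dtype=float)) for ch in _CHANNELS]
    cols += [angle, velocity]
    cols += [iemg(np.asarray(emg_windows[ch], dtype=float), mode=iemg_mode)
             for ch in _CHANNELS]
    return FeatureMatrix(values=np.column_stack(cols), grid=grid)


# ---------------------------------------------------------------------------
# PCA fusion
# ---------------------------------------------------------------------------

@dataclass
class FusionModel:
    """Standardization statistics plus the PCA loadings of the 8 features."""

    mean: np.ndarray
    scale: np.ndarray
    loadings: np.ndarray          # 8 × 8, orthonormal columns, eigenvalue order
    eigenvalues: np.ndarray       # descending, sum = 8 on standardized data
    k: int = 5

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.scale = np.asarray(self.scale, dtype=float)
        self.loadings = np.asarray(self.loadings, dtype=float)
        self.eigenvalues = np.asarray(self.eigenvalues, dtype=float)
        p = len(FEATURE_NAMES)
        if self.loadings.shape != (p, p) or self.eigenvalues.shape != (p,):
            raise IntegrityError("fusion model has wrong shapes")
        if np.any(np.diff(self.eigenvalues) > 1e-9) or np.any(self.eigenvalues < -1e-9):
            raise IntegrityError("eigenvalues must be non-increasing and >= 0")
        if not 1 <= self.k <= p:
            raise IntegrityError(f"k must be in 1..{p}")

    @property
    def contribution_pct(self) -> np.ndarray:
        return contribution_rates(self.eigenvalues)

    @property
    def cumulative_pct(self) -> np.ndarray:
        return np.cumsum(self.contribution_pct)

    def to_dict(self) -> dict:
        return {"mean": self.mean.tolist(), "scale": self.scale.tolist(),
                "loadings": self.loadings.tolist(),
                "eigenvalues": self.eigenvalues.tolist(), "k": int(self.k)}

    @classmethod
    def from_dict(cls, d: dict) -> "FusionModel":
        return cls(mean=np.array(d["mean"], dtype=float),
                   scale=np.array(d["scale"], dtype=float),
                   loadings=np.array(d["loadings"], dtype=float),
                   eigenvalues=np.array(d["eigenvalues"], dtype=float),
                   k=int(d["k"]))


def contribution_rates(eigenvalues: np.ndarray) -> np.ndarray:
    """Per-component variance share, in %, for standardized features.

    On standardized data the eigenvalues of the correlation matrix sum to the
    number of features, so the rate is λ_i / p × 100.
    """
    eigenvalues = np.asarray(eigenvalues, dtype=float)
    return eigenvalues / eigenvalues.size * 100.0


def fit_fusion(features: FeatureMatrix | np.ndarray,
               k: int | float = 5) -> FusionModel:
    """Standardize the feature columns and eigendecompose their correlation.

    ``k`` is either the retained component count (int) or a cumulative
    contribution threshold in percent (float < number of features), in which
    case the smallest k reaching the threshold is chosen.  Loading signs are
    fixed by making each column's largest-magnitude entry positive.
    """
    X = features.values if isinstance(features, FeatureMatrix) else np.asarray(features, dtype=float)
    p = len(FEATURE_NAMES)
    if X.ndim != 2 or X.shape[1] != p:
        raise IntegrityError(f"need a W x {p} matrix, got {X.shape}")
    if X.shape[0] < p + 1:
        raise IntegrityError(f"need at least {p + 1} windows to fit fusion")
    mean = X.mean(axis=0)
    scale = X.std(axis=0, ddof=0)
    dead = np.flatnonzero(scale <= 0)
    if dead.size:
        names = ", ".join(FEATURE_NAMES[i] for i in dead)
        raise DegenerateFeatureError(f"constant feature column(s): {names}")
    Z = (X - mean) / scale
    corr = (Z.T @ Z) / Z.shape[0]
    eigval, eigvec = np.linalg.eigh(corr)
    order = np.argsort(eigval)[::-1]
    eigval = np.clip(eigval[order], 0.0, None)
    eigvec = eigvec[:, order]
    # deterministic sign: largest-|entry| of each loading made positive
    flips = np.sign(eigvec[np.argmax(np.abs(eigvec), axis=0), np.arange(p)])
    flips[flips == 0] = 1.0
    eigvec = eigvec * flips

    if isinstance(k, (int, np.integer)):
        k_sel = int(k)
    else:  # float: cumulative-contribution threshold in percent
        cum = np.cumsum(contribution_rates(eigval))
        k_sel = min(int(np.searchsorted(cum, k - 1e-9)) + 1, p)
    return FusionModel(mean=mean, scale=scale, loadings=eigvec,
                       eigenvalues=eigval, k=k_sel)


def apply_fusion(model: FusionModel, features: FeatureMatrix | np.ndarray,
                 k: int | None = None) -> np.ndarray:
    """Project standardized features onto the first ``k`` loadings (W × k)."""
    if model is None:
        raise StateError("fusion model not fitted")
    X = features.values if isinstance(features, FeatureMatrix) else np.asarray(features, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    if X.shape[1] != len(FEATURE_NAMES):
        raise IntegrityError(f"need {len(FEATURE_NAMES)} feature columns")
    k = model.k if k is None else k
    Z = (X - model.mean) / model.scale
    return Z @ model.loadings[:, :k]


def inverse_fusion(model: FusionModel, scores: np.ndarray) -> np.ndarray:
    """Map component scores back to the standardized feature space."""
    scores = np.asarray(scores, dtype=float)
    k = scores.shape[1]
    return scores @ model.loadings[:, :k].T
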