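"""EMG filtering, non-overlapping windowing and elbow-angle kinematics.

The conditioning chain is the standard surface-EMG one: a 20–500 Hz Butterworth
bandpass removes baseline drift and out-of-band noise, a 50 Hz notch removes
mains interference.  Both filters exist in two flavours:

* zero-phase (forward–backward, :func:`bandpass_emg` / :func:`notch_50`) for
  offline training, where preserving EMG–angle alignment matters;
* causal (:class:`CausalFilterBank`) for the streaming control emulator, where
  only past samples may be used.

Feature extraction operates on non-overlapping 25 ms windows
(:class:`WindowGrid`); at 1200 Hz each window holds 30 EMG samples.  The angle
streams (100 Hz) are interpolated to window centres rather than decimating the
EMG, since a 25 ms window spans only 2.5 angle samples.

Everything in this module is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .errors import IntegrityError, SamplingRateError

BAND_HZ = (20.0, 500.0)
NOTCH_HZ = 50.0
DEFAULT_ORDER = 4
DEFAULT_NOTCH_Q = 30.0
DEFAULT_WINDOW_S = 0.025


def _bandpass_sos(fs: float, order: int = DEFAULT_ORDER) -> np.ndarray:
    if fs <= 2 * BAND_HZ[1]:
        raise SamplingRateError(
            f"fs={fs} Hz too low for a {BAND_HZ[1]} Hz passband edge"
        )
    return signal.butter(order, BAND_HZ, btype="bandpass", fs=fs, output="sos")


def _notch_sos(fs: float, q: float = DEFAULT_NOTCH_Q) -> np.ndarray:
    if fs <= 2 * NOTCH_HZ:
        raise SamplingRateError(f"fs={fs} Hz too low for a {NOTCH_HZ} Hz notch")
    b, a = signal.iirnotch(NOTCH_HZ, q, fs=fs)
    return signal.tf2sos(b, a)


def bandpass_emg(x: np.ndarray, fs: float, order: int = DEFAULT_ORDER) -> np.ndarray:
    """Zero-phase 20–500 Hz Butterworth bandpass; preserves signal length."""
    x = np.asarray(x, dtype=float)
    return signal.sosfiltfilt(_bandpass_sos(fs, order), x)


def notch_50(x: np.ndarray, fs: float, q: float = DEFAULT_NOTCH_Q) -> np.ndarray:
    """Zero-phase 50 Hz notch (second-order IIR, quality factor ``q``)."""
    x = np.asarray(x, dtype=float)
    return signal.sosfiltfilt(_notch_sos(fs, q), x)


def filter_emg(x: np.ndarray, fs: float, order: int = DEFAULT_ORDER,
               q: float = DEFAULT_NOTCH_Q) -> np.ndarray:
    """Bandpass then notch — the full offline conditioning chain."""
    return notch_50(bandpass_emg(x, fs, order), fs, q)


class CausalFilterBank:
    """Stateful causal bandpass+notch for streaming use.

    ``process(chunk)`` filters an arbitrary-length chunk while carrying the
    IIR state forward, so feeding a signal in pieces produces exactly the same
    output as feeding it at once (truncation equivalence).
    """

    def __init__(self, fs: float, order: int = DEFAULT_ORDER,
                 q: float = DEFAULT_NOTCH_Q):
        self._sos = np.vstack([_bandpass_sos(fs, order), _notch_sos(fs, q)])
        self._zi = np.zeros((self._sos.shape[0], 2))

    def process(self, chunk: np.ndarray) -> np.ndarray:
        chunk = np.asarray(chunk, dtype=float)
        out, self._zi = signal.sosfilt(self._sos, chunk, zi=self._zi)
        return out


@dataclass(frozen=True)
class WindowGrid:
    """Non-overlapping analysis windows (step equals window length)."""

    window_length: float
    fs_emg: float
    n_windows: int

    @property
    def step(self) -> float:
        return self.window_length

    @property
    def samples_per_window(self) -> int:
        return int(round(self.window_length * self.fs_emg))

    @property
    def centers(self) -> np.ndarray:
        """Window-centre times in seconds."""
        return (np.arange(self.n_windows) + 0.5) * self.window_length


def make_windows(fs_emg: float, duration: float,
                 window_length: float = DEFAULT_WINDOW_S) -> WindowGrid:
    """Build the grid of ``floor(duration / window_length)`` windows."""
    if window_length <= 0 or fs_emg <= 0:
        raise IntegrityError("window_length and fs_emg must be positive")
    n = int(np.floor(duration / window_length + 1e-9))
    if n < 1:
        raise IntegrityError(
            f"duration {duration} s shorter than one {window_length} s window"
        )
    return WindowGrid(window_length=window_length, fs_emg=fs_emg, n_windows=n)


def window_signal(x: np.ndarray, grid: WindowGrid) -> np.ndarray:
    """Reshape a sample stream into a ``(n_windows, samples_per_window)`` array."""
    x = np.asarray(x, dtype=float)
    spw = grid.samples_per_window
    need = grid.n_windows * spw
    if x.size < need:
        raise IntegrityError(f"signal has {x.size} samples, grid needs {need}")
    return x[:need].reshape(grid.n_windows, spw)


def elbow_angle(angle_upper: np.ndarray, angle_fore: np.ndarray) -> np.ndarray:
    """Relative elbow angle: forearm minus upper-arm orientation, folded to [0, 180].

    The two attitude streams give absolute segment orientations; the elbow
    flexion angle is their difference, wrapped so that e.g. (−20°, 70°) → 90°.
    """
    angle_upper = np.asarray(angle_upper, dtype=float)
    angle_fore = np.asarray(angle_fore, dtype=float)
    if angle_upper.shape != angle_fore.shape:
        raise IntegrityError("orientation streams differ in length")
    d = np.mod(angle_fore - angle_upper, 360.0)
    return np.where(d > 180.0, 360.0 - d, d)


def angular_velocity(beta: np.ndarray, fs: float) -> np.ndarray:
    """Angular velocity in deg/s by central differences (one-sided at the ends)."""
    beta = np.asarray(beta, dtype=float)
    if beta.size < 3:
        raise IntegrityError("need at least 3 angle samples for differentiation")
    return np.gradient(beta) * fs


def causal_angular_velocity(beta: np.ndarray, fs: float) -> np.ndarray:
    """Backward-difference angular velocity for the streaming path.

    Each output sample depends only on the current and previous input sample,
    so extending the stream never changes already-computed values.
    """
    beta = np.asarray(beta, dtype=float)
    if beta.size < 2:
        return np.zeros_like(beta)
    v = np.empty_like(beta)
    v[1:] = np.diff(beta) * fs
    v[0] = v[1]
    return v


def angle_at_windows(beta: np.ndarray, fs_angle: float, grid: WindowGrid,
                     velocity: np.ndarray | None = None,
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Linear-interpolate angle and angular velocity at window centres.

    ``velocity`` defaults to the central-difference derivative of ``beta``.
    Window centres must be covered by the angle stream's support (the last
    sample sits at ``(len(beta)-1)/fs_angle``; a trailing centre within half a
    window of the end is tolerated and clamped to the final sample).
    """
    beta = np.asarray(beta, dtype=float)
    t = np.arange(beta.size) / fs_angle
    centers = grid.centers
    if centers[0] < t[0] - 1e-9 or centers[-1] > t[-1] + grid.window_length:
        raise IntegrityError("window centres extend beyond the angle stream")
    if velocity is None:
        velocity = angular_velocity(beta, fs_angle)
    return np.interp(centers, t, beta), np.interp(centers, t, velocity)
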