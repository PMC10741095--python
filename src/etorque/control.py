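"""Proportional myoelectric assist control and the streaming emulator.

The control law converts the predicted active elbow torque into an assist
command every 25 ms window:

1. assist magnitude = assist ratio × |predicted active torque|, clamped to
   the configured safety maximum;
2. direction follows the sign of the elbow angular velocity, with a small
   deadband to prevent sign chatter near zero velocity;
3. windows whose velocity magnitude exceeds the configured maximum have the
   assist suppressed entirely (over-speed guard);
4. the commanded motor current is assist torque / torque constant.

:func:`run_stream` emulates the on-device pipeline causally: per window it
advances stateful causal filters, extracts features, applies the fitted
fusion and network, and logs the command.  Only samples at or before each
window's end are ever used, so processing a truncated recording reproduces
the corresponding prefix of the full log exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import preprocess
from .bpnet import forward
from .dataio import CHANNELS, NetworkParams, SignalRecording
from .errors import ConfigError, StateError
from .features import FusionModel, apply_fusion, assemble_features


@dataclass
class ControlConfig:
    """Assist-law parameters."""

    assist_ratio: float = 0.8
    tau_max: float = 5.0              # N·m safety clamp
    velocity_deadband: float = 2.0    # deg/s
    torque_constant: float = 0.6      # N·m/A
    max_angular_velocity: float = 200.0  # deg/s over-speed guard

    def __post_init__(self) -> None:
        if self.assist_ratio < 0:
            raise ConfigError("assist_ratio must be >= 0")
        if self.tau_max <= 0:
            raise ConfigError("tau_max must be positive")
        if self.velocity_deadband < 0:
            raise ConfigError("velocity_deadband must be >= 0")
        if self.torque_constant <= 0:
            raise ConfigError("torque_constant must be positive")


def assist_torque(tau_active: float, cfg: ControlConfig) -> float:
    """Assist torque = ratio × active torque, clamped to ±tau_max."""
    return float(np.clip(cfg.assist_ratio * tau_active, -cfg.tau_max, cfg.tau_max))


def direction(omega: float, deadband: float) -> int:
    """Assist direction from angular velocity: +1 / −1 outside the deadband, else 0."""
    if omega > deadband:
        return 1
    if omega < -deadband:
        return -1
    return 0


def torque_to_current(tau: float, k_t: float) -> float:
    """Commanded current i = τ / k_t for a linear motor model."""
    if k_t <= 0:
        raise ConfigError("torque constant must be positive")
    return tau / k_t


@dataclass
class ControlLog:
    """Per-window record of the streaming controller."""

    times: list[float] = field(default_factory=list)
    tau_active: list[float] = field(default_factory=list)
    tau_assist: list[float] = field(default_factory=list)
    direction: list[int] = field(default_factory=list)
    current: list[float] = field(default_factory=list)
    clamped: list[bool] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.times)

    def save(self, path: str | Path) -> None:
        arr = np.column_stack([self.times, self.tau_active, self.tau_assist,
                               self.direction, self.current,
                               np.asarray(self.clamped, dtype=int)])
        np.savetxt(path, arr, delimiter="\t",
                   header="time_s\ttau_active\ttau_assist\tdirection\tcurrent_A\tclamped")


def run_stream(rec: SignalRecording, params: NetworkParams, fusion: FusionModel,
               cfg: ControlConfig, window_length: float = 0.025,
               iemg_mode: str = "rectified") -> ControlLog:
    """Causal per-window emulation of the real-time assist pipeline."""
    if params is None or fusion is None:
        raise StateError("run_stream needs a trained model and fitted fusion")
    grid = preprocess.make_windows(rec.fs_emg, rec.duration, window_length)
    spw = grid.samples_per_window
    banks = [preprocess.CausalFilterBank(rec.fs_emg) for _ in CHANNELS]
    flexion = preprocess.elbow_angle(rec.angle_upper, rec.angle_fore)
    t_angle = np.arange(flexion.size) / rec.fs_angle

    log = ControlLog()
    for j in range(grid.n_windows):
        t_end = (j + 1) * window_length
        center = t_end - window_length / 2.0
        chunk = {ch: banks[c].process(rec.emg[c, j * spw:(j + 1) * spw])
                 for c, ch in enumerate(CHANNELS)}
        # causal kinematics: only angle samples strictly before the window end
        n_avail = int(np.floor(t_end * rec.fs_angle - 1e-9)) + 1
        n_avail = min(n_avail, flexion.size)
        beta_pfx = flexion[:n_avail]
        t_pfx = t_angle[:n_avail]
        angle_c = float(np.interp(center, t_pfx, beta_pfx))
        vel_pfx = preprocess.causal_angular_velocity(beta_pfx, rec.fs_angle)
        omega_c = float(np.interp(center, t_pfx, vel_pfx))

        fm = assemble_features({ch: chunk[ch][None, :] for ch in CHANNELS},
                               np.array([angle_c]), np.array([omega_c]),
                               iemg_mode=iemg_mode)
        s = apply_fusion(fusion, fm)[0]
        _, tau_active = forward(params, s)

        mag = assist_torque(abs(tau_active), cfg)
        clamped = cfg.assist_ratio * abs(tau_active) > cfg.tau_max
        sign = direction(omega_c, cfg.velocity_deadband)
        if abs(omega_c) > cfg.max_angular_velocity:
            mag, sign = 0.0, 0   # over-speed: suppress assist
        tau_cmd = mag * sign
        log.times.append(center)
        log.tau_active.append(float(tau_active))
        log.tau_assist.append(tau_cmd)
        log.direction.append(sign)
        log.current.append(torque_to_current(tau_cmd, cfg.torque_constant))
        log.clamped.append(bool(clamped))
    return log
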