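"""Synthetic flexion–extension recordings with known ground-truth torque.

No elbow dataset ships with the tool, so every downstream stage is exercised
on generated data whose label-generating law is the package's own inverse
dynamics — a single source of truth shared with :mod:`etorque.biomech`.

The generator emulates the documented facts about surface EMG — amplitudes in
the 0.1–5 mV band, dominant spectral content between 50 and 150 Hz, 50 Hz
mains contamination — and elbow flexion–extension cycles spanning 0–120°:

* the trajectory is a raised cosine per cycle (smooth, periodic, C² — peak
  angular velocity π·range/period at mid-flexion);
* muscle excitation envelopes are derived from the required active torque:
  the flexor envelope is proportional to its positive part, the extensor to
  its negative part, and the brachioradialis follows the biceps at 70%
  synergy (plus small independent noise when an rng is supplied);
* EMG is a Gaussian carrier bandpassed to the dominant band, normalized to
  unit peak, amplitude-modulated by the envelope, with an additive 50 Hz
  mains tone and white sensor noise.  The mains tone is injected on purpose
  so the notch filter is exercised.

Everything is reproducible from ``SynthConfig.seed``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .biomech import TorqueSeries, required_active_torque, torque_labels
from .dataio import CHANNELS, SignalRecording, SubjectAnthropometry
from .errors import ConfigError, IntegrityError
from .preprocess import make_windows

#: brachioradialis envelope as a fraction of the biceps envelope
BRACHIORADIALIS_SYNERGY = 0.7
#: sd of the optional independent noise on the brachioradialis envelope
SYNERGY_NOISE_SD = 0.02


@dataclass
class SynthConfig:
    """Study conditions for the synthetic flexion–extension protocol."""

    n_cycles: int = 240
    cycle_period: float = 4.0
    angle_range: tuple[float, float] = (0.0, 120.0)
    emg_amplitude_range: tuple[float, float] = (1e-4, 5e-3)
    carrier_band: tuple[float, float] = (50.0, 150.0)
    mains_amplitude: float = 2e-4
    noise_sd: float = 2e-5
    fs_emg: float = 1200.0
    fs_angle: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.angle_range
        if not (0.0 <= lo <= hi <= 120.0):
            raise ConfigError("angle_range must satisfy 0 <= lo <= hi <= 120")
        a_lo, a_hi = self.emg_amplitude_range
        if not (0.0 <= a_lo <= a_hi):
            raise ConfigError("emg_amplitude_range must be ordered and >= 0")
        if self.cycle_period <= 0:
            raise ConfigError("cycle_period must be positive")
        if self.mains_amplitude < 0 or self.noise_sd < 0:
            raise ConfigError("mains_amplitude and noise_sd must be >= 0")
        if self.fs_emg <= 0 or self.fs_angle <= 0:
            raise ConfigError("sampling rates must be positive")


def make_trajectory(cfg: SynthConfig, n_cycles: int | None = None) -> np.ndarray:
    """Raised-cosine flexion angle β(t) in degrees at ``fs_angle``.

    Each cycle runs min → max → min over ``cycle_period`` seconds with
    continuous first and second derivatives across cycle boundaries.
    """
    n_cycles = cfg.n_cycles if n_cycles is None else n_cycles
    if n_cycles < 1:
        raise IntegrityError("n_cycles must be at least 1")
    n = int(round(n_cycles * cfg.cycle_period * cfg.fs_angle))
    t = np.arange(n) / cfg.fs_angle
    lo, hi = cfg.angle_range
    return lo + 0.5 * (hi - lo) * (1.0 - np.cos(2.0 * np.pi * t / cfg.cycle_period))


def make_activation(beta_deg: np.ndarray, anthro: SubjectAnthropometry,
                    fs: float = 100.0,
                    rng: np.random.Generator | None = None,
                    ) -> dict[str, np.ndarray]:
    """Excitation envelopes u(t) ∈ [0,1] for the three elbow muscles.

    The required active torque on the flexion trajectory is split by sign:
    flexors carry its positive part, the extensor its negative part, each
    normalized by the trial's peak |torque| and clipped to [0,1].
    """
    torque = required_active_torque(beta_deg, fs, anthro)
    peak = np.max(np.abs(torque))
    if peak <= 0:
        zero = np.zeros_like(torque)
        return {ch: zero.copy() for ch in CHANNELS}
    flexor = np.clip(torque, 0.0, None) / peak
    extensor = np.clip(-torque, 0.0, None) / peak
    brachio = BRACHIORADIALIS_SYNERGY * flexor
    if rng is not None:
        brachio = brachio + rng.normal(0.0, SYNERGY_NOISE_SD, brachio.shape)
    return {
        "biceps": np.clip(flexor, 0.0, 1.0),
        "triceps": np.clip(extensor, 0.0, 1.0),
        "brachioradialis": np.clip(brachio, 0.0, 1.0),
    }


def make_emg(envelope: np.ndarray, cfg: SynthConfig,
             rng: np.random.Generator | None = None) -> np.ndarray:
    """One EMG channel (volts, at ``fs_emg``) from an excitation envelope.

    A zero-mean Gaussian carrier is bandpassed to ``carrier_band``, scaled to
    unit peak, and amplitude-modulated so full excitation reaches the top of
    the configured amplitude range; the 50 Hz mains tone and white sensor
    noise are added afterwards.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    envelope = np.asarray(envelope, dtype=float)
    n_e = int(round(envelope.size * cfg.fs_emg / cfg.fs_angle))
    t_a = np.arange(envelope.size) / cfg.fs_angle
    t_e = np.arange(n_e) / cfg.fs_emg
    env_up = np.interp(t_e, t_a, envelope)

    carrier = rng.standard_normal(n_e)
    sos = signal.butter(4, cfg.carrier_band, btype="bandpass",
                        fs=cfg.fs_emg, output="sos")
    carrier = signal.sosfiltfilt(sos, carrier)
    peak = np.max(np.abs(carrier))
    if peak > 0:
        carrier = carrier / peak

    _, a_max = cfg.emg_amplitude_range
    x = env_up * a_max * carrier
    if cfg.mains_amplitude > 0:
        x = x + cfg.mains_amplitude * np.sin(2.0 * np.pi * 50.0 * t_e)
    if cfg.noise_sd > 0:
        x = x + rng.normal(0.0, cfg.noise_sd, n_e)
    return x


def make_dataset(cfg: SynthConfig, anthro: SubjectAnthropometry,
                 subject_id: str = "synthetic",
                 window_length: float = 0.025,
                 ) -> tuple[list[SignalRecording], TorqueSeries]:
    """Generate labelled flexion–extension cycles.

    Returns one :class:`SignalRecording` per cycle plus a single
    :class:`TorqueSeries` of per-window ground-truth labels, concatenated in
    recording order on a global time axis.  Labels are computed by the
    inverse-dynamics oracle on the noiseless trajectory at the window
    centres, using the sensor-convention bending angle (−flexion).
    """
    rng = np.random.default_rng(cfg.seed)
    beta_cycle = make_trajectory(cfg, n_cycles=1)
    envelopes = make_activation(beta_cycle, anthro, fs=cfg.fs_angle, rng=rng)

    grid = make_windows(cfg.fs_emg, cfg.cycle_period, window_length)
    t_a = np.arange(beta_cycle.size) / cfg.fs_angle
    beta_centers = np.interp(grid.centers, t_a, beta_cycle)
    labels_cycle = torque_labels(-beta_centers, anthro, dt=window_length)

    recordings: list[SignalRecording] = []
    all_times, all_torque = [], []
    for i in range(cfg.n_cycles):
        emg = np.vstack([make_emg(envelopes[ch], cfg, rng=rng) for ch in CHANNELS])
        rec = SignalRecording(
            emg=emg,
            angle_upper=np.zeros_like(beta_cycle),
            angle_fore=beta_cycle.copy(),
            fs_emg=cfg.fs_emg, fs_angle=cfg.fs_angle,
            subject_id=f"{subject_id}-{i:03d}",
        )
        recordings.append(rec)
        all_times.append(labels_cycle.times + i * cfg.cycle_period)
        all_torque.append(labels_cycle.torque)
    labels = TorqueSeries(times=np.concatenate(all_times),
                          torque=np.concatenate(all_torque), source="lagrange")
    return recordings, labels
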