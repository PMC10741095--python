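"""Domain types and on-disk formats.

Hosts the shared containers (:class:`SignalRecording`,
:class:`SubjectAnthropometry`, :class:`NetworkParams`) and the two file
formats the tool reads and writes:

* recordings — a delimited text file with a ``key: value`` header followed by
  an ``[emg]`` block (one row per 1200 Hz sample, three voltage columns in the
  fixed channel order biceps, triceps, brachioradialis) and an ``[angle]``
  block (one row per 100 Hz sample, upper-arm and forearm orientation in
  degrees);
* trained models — a single JSON document bundling the 5-3-1 network
  parameters, the target scaler and the fitted PCA fusion, so that a saved
  model reproduces its predictions without reassembling the pipeline.

Units are fixed at the module boundary: angles in degrees, torques in N·m,
EMG in volts.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import FormatError, IntegrityError

#: Fixed EMG channel order used everywhere in the package.
CHANNELS = ("biceps", "triceps", "brachioradialis")

_RECORDING_MAGIC = "# etorque recording v1"
_MODEL_MAGIC = "etorque-model"


@dataclass
class SignalRecording:
    """Synchronized raw EMG and segment-orientation streams for one trial.

    ``emg`` is a ``3 × N_e`` array in volts, channel order per :data:`CHANNELS`;
    ``angle_upper`` / ``angle_fore`` are the upper-arm and forearm orientation
    streams in degrees sampled at ``fs_angle``.
    """

    emg: np.ndarray
    angle_upper: np.ndarray
    angle_fore: np.ndarray
    fs_emg: float = 1200.0
    fs_angle: float = 100.0
    subject_id: str = "unknown"

    def __post_init__(self) -> None:
        self.emg = np.asarray(self.emg, dtype=float)
        self.angle_upper = np.asarray(self.angle_upper, dtype=float)
        self.angle_fore = np.asarray(self.angle_fore, dtype=float)
        if self.fs_emg <= 0 or self.fs_angle <= 0:
            raise IntegrityError("sampling rates must be positive")
        if self.emg.ndim != 2 or self.emg.shape[0] != len(CHANNELS):
            raise IntegrityError(
                f"emg must be {len(CHANNELS)} x N (channels {CHANNELS}), "
                f"got shape {self.emg.shape}"
            )
        if self.angle_upper.shape != self.angle_fore.shape or self.angle_upper.ndim != 1:
            raise IntegrityError("angle streams must be 1-D and equally long")
        # EMG and angle streams must describe the same time span (within one
        # coarse sample period).
        d_emg = self.emg.shape[1] / self.fs_emg
        d_ang = self.angle_upper.size / self.fs_angle
        tol = max(1.0 / self.fs_emg, 1.0 / self.fs_angle) + 1e-9
        if abs(d_emg - d_ang) > tol:
            raise IntegrityError(
                f"EMG span {d_emg:.4f} s and angle span {d_ang:.4f} s disagree "
                f"by more than one sample period"
            )

    @property
    def duration(self) -> float:
        """Recording length in seconds (EMG stream)."""
        return self.emg.shape[1] / self.fs_emg


@dataclass
class SubjectAnthropometry:
    """Segment parameters entering the elbow inverse dynamics.

    ``segment_mass`` is the mass moved about the elbow (forearm + hand); when
    omitted it defaults to the standard anthropometric coefficient
    0.022 × body mass.  ``forearm_length`` (l3) plus ``elbow_radius`` (r2)
    form the single lever arm used by the torque model.
    """

    body_mass: float
    forearm_length: float
    elbow_radius: float = 0.035
    upper_arm_length: float = 0.309
    hand_length: float = 0.187
    segment_mass: float | None = None
    gravity: float = 9.8

    #: forearm+hand mass as a fraction of body mass (standard coefficient)
    SEGMENT_MASS_COEF = 0.022

    def __post_init__(self) -> None:
        if self.segment_mass is None:
            self.segment_mass = self.SEGMENT_MASS_COEF * self.body_mass
        for name in ("body_mass", "forearm_length", "elbow_radius",
                     "upper_arm_length", "hand_length", "segment_mass"):
            if getattr(self, name) <= 0:
                raise IntegrityError(f"{name} must be positive")
        if self.gravity <= 0:
            raise IntegrityError("gravity must be positive")

    @property
    def lever_arm(self) -> float:
        """Distance l3 + r2 from the rotation centre to the moved mass (m)."""
        return self.forearm_length + self.elbow_radius

    @classmethod
    def reference(cls) -> "SubjectAnthropometry":
        """Mean adult-male subject used as the default synthetic subject.

        Body mass 66.5 kg, upper arm 30.9 cm, forearm 26.45 cm, hand 18.7 cm —
        the mean of a seven-subject able-bodied cohort.
        """
        return cls(body_mass=66.5, forearm_length=0.2645, elbow_radius=0.035,
                   upper_arm_length=0.309, hand_length=0.187)


@dataclass
class NetworkParams:
    """Weights/thresholds of the 5-3-1 network plus the torque target scaler.

    The hidden layer computes ``tansig(w_in @ s + b_in)`` (3×5 weights), the
    output layer ``tansig(w_out @ h + b_out)`` (1×3 weights).  ``target_scale``
    is the (t_min, t_max) torque range, in N·m, mapped linearly onto the
    bounded output range of the tansig.
    """

    w_in: np.ndarray
    b_in: np.ndarray
    w_out: np.ndarray
    b_out: np.ndarray
    target_scale: tuple[float, float] = (-1.0, 1.0)

    def __post_init__(self) -> None:
        self.w_in = np.asarray(self.w_in, dtype=float)
        self.b_in = np.asarray(self.b_in, dtype=float).reshape(-1)
        self.w_out = np.asarray(self.w_out, dtype=float).reshape(1, -1)
        self.b_out = np.asarray(self.b_out, dtype=float).reshape(-1)
        if self.w_in.shape != (3, 5):
            raise IntegrityError(f"w_in must be 3x5, got {self.w_in.shape}")
        if self.b_in.shape != (3,):
            raise IntegrityError(f"b_in must have length 3, got {self.b_in.shape}")
        if self.w_out.shape != (1, 3):
            raise IntegrityError(f"w_out must be 1x3, got {self.w_out.shape}")
        if self.b_out.shape != (1,):
            raise IntegrityError(f"b_out must have length 1, got {self.b_out.shape}")
        t_min, t_max = self.target_scale
        if not t_min < t_max:
            raise IntegrityError("target_scale requires t_min < t_max")

    def copy(self) -> "NetworkParams":
        return NetworkParams(self.w_in.copy(), self.b_in.copy(),
                             self.w_out.copy(), self.b_out.copy(),
                             tuple(self.target_scale))


# ---------------------------------------------------------------------------
# recording files
# ---------------------------------------------------------------------------

def save_recording(rec: SignalRecording, path: str | Path) -> None:
    """Write a recording in the documented text format."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(_RECORDING_MAGIC + "\n")
        fh.write(f"subject_id: {rec.subject_id}\n")
        fh.write(f"fs_emg: {rec.fs_emg!r}\n")
        fh.write(f"fs_angle: {rec.fs_angle!r}\n")
        fh.write("[emg]\n")
        np.savetxt(fh, rec.emg.T, fmt="%.9e")
        fh.write("[angle]\n")
        np.savetxt(fh, np.column_stack([rec.angle_upper, rec.angle_fore]),
                   fmt="%.9e")


def load_recording(path: str | Path) -> SignalRecording:
    """Read a recording written by :func:`save_recording`.

    Raises :class:`FormatError` for a malformed file (missing header keys,
    wrong column counts) and :class:`IntegrityError` when the parsed streams
    violate the recording invariants.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines or lines[0].strip() != _RECORDING_MAGIC:
        raise FormatError(f"{path}: not an etorque recording file")
    header: dict[str, str] = {}
    i = 1
    while i < len(lines) and lines[i].strip() != "[emg]":
        line = lines[i].strip()
        if line:
            if ":" not in line:
                raise FormatError(f"{path}: malformed header line {line!r}")
            key, val = line.split(":", 1)
            header[key.strip()] = val.strip()
        i += 1
    if i == len(lines):
        raise FormatError(f"{path}: missing [emg] block")
    try:
        fs_emg = float(header["fs_emg"])
        fs_angle = float(header["fs_angle"])
    except KeyError as exc:
        raise FormatError(f"{path}: missing header key {exc}") from exc
    subject_id = header.get("subject_id", "unknown")

    try:
        j = lines.index("[angle]", i)
    except ValueError:
        raise FormatError(f"{path}: missing [angle] block") from None
    emg = _read_block(lines[i + 1:j], 3, path, "emg")
    ang = _read_block(lines[j + 1:], 2, path, "angle")
    return SignalRecording(emg=emg.T, angle_upper=ang[:, 0], angle_fore=ang[:, 1],
                           fs_emg=fs_emg, fs_angle=fs_angle, subject_id=subject_id)


def _read_block(lines: list[str], ncols: int, path: Path, name: str) -> np.ndarray:
    text = "\n".join(l for l in lines if l.strip())
    try:
        arr = np.loadtxt(io.StringIO(text), ndmin=2)
    except ValueError as exc:
        raise FormatError(f"{path}: unparseable {name} block: {exc}") from exc
    if arr.size == 0:
        raise FormatError(f"{path}: empty {name} block")
    if arr.shape[1] != ncols:
        raise FormatError(
            f"{path}: {name} block has {arr.shape[1]} columns, expected {ncols}"
        )
    return arr


# ---------------------------------------------------------------------------
# model files
# ---------------------------------------------------------------------------

def save_model(params: NetworkParams, fusion, path: str | Path) -> None:
    """Persist network parameters and the fitted fusion model in one JSON file."""
    doc = {
        "format": _MODEL_MAGIC,
        "version": 1,
        "network": {
            "w_in": params.w_in.tolist(),
            "b_in": params.b_in.tolist(),
            "w_out": params.w_out.tolist(),
            "b_out": params.b_out.tolist(),
            "target_scale": list(params.target_scale),
        },
        "fusion": fusion.to_dict(),
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def load_model(path: str | Path):
    """Load ``(NetworkParams, FusionModel)`` from a model file.

    Any parse or validation failure raises :class:`IntegrityError`; no partial
    model is ever returned.
    """
    from .features import FusionModel  # deferred: features does not import dataio

    try:
        doc = json.loads(Path(path).read_text())
        if doc.get("format") != _MODEL_MAGIC:
            raise IntegrityError(f"{path}: not an etorque model file")
        net = doc["network"]
        params = NetworkParams(
            w_in=np.array(net["w_in"], dtype=float),
            b_in=np.array(net["b_in"], dtype=float),
            w_out=np.array(net["w_out"], dtype=float),
            b_out=np.array(net["b_out"], dtype=float),
            target_scale=tuple(net["target_scale"]),
        )
        fusion = FusionModel.from_dict(doc["fusion"])
    except IntegrityError:
        raise
    except (json.JSONDecodeError, KeyError, TypeError, ValueError) as exc:
        raise IntegrityError(f"{path}: corrupt model file: {exc}") from exc
    return params, fusion
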