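"""End-to-end orchestration: recordings → features → fusion → network → metrics.

Thin glue over the library modules; this is what the CLI and the
reproducibility script drive.  The canonical experiment
(:func:`run_study`) generates the default synthetic flexion–extension
protocol, labels it with the inverse-dynamics oracle, splits windows
6:2:2, fits the fusion and target scaler on the training split only,
PSO-initializes and trains the 5-3-1 network, and reports test-split metrics
in N·m.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import bpnet, preprocess, synth
from .biomech import TorqueSeries
from .dataio import CHANNELS, NetworkParams, SignalRecording, SubjectAnthropometry
from .errors import IntegrityError
from .evaluate import Metrics, compute_metrics
from .features import FeatureMatrix, FusionModel, apply_fusion, assemble_features, fit_fusion


def extract_features(rec: SignalRecording, window_length: float = 0.025,
                     iemg_mode: str = "rectified") -> FeatureMatrix:
    """Offline (zero-phase) feature extraction for one recording."""
    grid = preprocess.make_windows(rec.fs_emg, rec.duration, window_length)
    windows = {}
    for c, ch in enumerate(CHANNELS):
        filtered = preprocess.filter_emg(rec.emg[c], rec.fs_emg)
        windows[ch] = preprocess.window_signal(filtered, grid)
    flexion = preprocess.elbow_angle(rec.angle_upper, rec.angle_fore)
    angle_w, vel_w = preprocess.angle_at_windows(flexion, rec.fs_angle, grid)
    return assemble_features(windows, angle_w, vel_w, grid=grid,
                             iemg_mode=iemg_mode)


def build_design(recordings: list[SignalRecording], labels: TorqueSeries,
                 window_length: float = 0.025, iemg_mode: str = "rectified",
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Concatenate per-recording feature matrices and align them with labels."""
    mats = [extract_features(r, window_length, iemg_mode).values
            for r in recordings]
    X = np.vstack(mats)
    y = labels.torque
    if X.shape[0] != y.size:
        raise IntegrityError(
            f"{X.shape[0]} feature windows vs {y.size} labels"
        )
    return X, y


@dataclass
class StudyResult:
    """Everything produced by one synthetic training run."""

    params: NetworkParams
    fusion: FusionModel
    history: bpnet.TrainingHistory
    metrics_test: Metrics
    metrics_val: Metrics
    y_test: np.ndarray
    yhat_test: np.ndarray
    n_windows: int


def run_study(seed: int = 0,
              synth_cfg: synth.SynthConfig | None = None,
              anthro: SubjectAnthropometry | None = None,
              train_cfg: bpnet.TrainingConfig | None = None,
              pso_cfg: bpnet.PSOConfig | None = None,
              k: int = 5) -> StudyResult:
    """Run the full synthetic torque-prediction experiment.

    ``seed`` drives every random source (data generation, split, PSO,
    fallback init) unless explicit configs override it.
    """
    if synth_cfg is None:
        synth_cfg = synth.SynthConfig(seed=seed)
    if anthro is None:
        anthro = SubjectAnthropometry.reference()
    if train_cfg is None:
        train_cfg = bpnet.TrainingConfig(seed=seed)
    if pso_cfg is None:
        pso_cfg = bpnet.PSOConfig(seed=seed + 1)

    recordings, labels = synth.make_dataset(synth_cfg, anthro)
    X, y = build_design(recordings, labels)

    i_train, i_val, i_test = bpnet.split_622(X.shape[0], seed=train_cfg.seed,
                                             ratio=train_cfg.split_ratio)
    fusion = fit_fusion(X[i_train], k=k)
    S = apply_fusion(fusion, X)
    t_scale = (float(y[i_train].min()), float(y[i_train].max()))

    init = bpnet.pso_init(S[i_train], bpnet.scale_targets(y[i_train], t_scale),
                          pso_cfg, target_scale=t_scale)
    params, hist = bpnet.train(S[i_train], y[i_train], S[i_val], y[i_val],
                               train_cfg, init=init, target_scale=t_scale)
    yhat_test = bpnet.predict(params, S[i_test])
    yhat_val = bpnet.predict(params, S[i_val])
    return StudyResult(
        params=params, fusion=fusion, history=hist,
        metrics_test=compute_metrics(y[i_test], yhat_test),
        metrics_val=compute_metrics(y[i_val], yhat_val),
        y_test=y[i_test], yhat_test=yhat_test,
        n_windows=X.shape[0],
    )
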