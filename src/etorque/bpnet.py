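"""The 5-3-1 torque-prediction network and its training algorithm.

Architecture: five inputs (the retained principal components), one hidden
layer of three units, one output unit, tansig (``2/(1+e^{−2x}) − 1``, i.e.
tanh) on both layers::

    τ_scaled = tansig( w_out · tansig(w_in · s + b_in) + b_out )

Because the output is bounded in (−1, 1), torque targets are min–max mapped
into [−0.9, 0.9] (the margin avoids saturating the output unit); the scaler
is stored with the parameters so predictions are returned in N·m.

Training is full-batch gradient descent with a momentum blend of consecutive
gradients and a sign-driven adaptive learning rate::

    Δω(k) = η(k) · [(1−μ)·g(k) + μ·g(k−1)]
    η(k)  = 2^λ · η(k−1),   λ = sign⟨g(k), g(k−1)⟩

λ is the sign of the inner product of the flattened gradients — a scalar, so
η stays a scalar; λ=0 leaves η unchanged.  η is clamped to keep the doubling
stable.  Parameters move *against* the loss gradient (descent convention).

Early stopping follows the overfitting rule: training stops when the
validation MSE has not improved for ``patience`` consecutive epochs, and the
parameters from the best-validation epoch are returned.

Initial weights come from particle swarm optimization over all 22 free
parameters (15+3+3+1), standard global-best updates with inertia decaying
linearly from 0.9 to 0.4 across iterations; fitness is the training MSE of
the decoded network (estimated on a fixed random subsample for large
datasets).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dataio import NetworkParams
from .errors import DivergenceError, IntegrityError

N_IN, N_HID, N_OUT = 5, 3, 1
N_PARAMS = N_IN * N_HID + N_HID + N_HID * N_OUT + N_OUT  # 22
TARGET_MARGIN = 0.9


def tansig(x: np.ndarray | float) -> np.ndarray | float:
    """tansig(x) = 2 / (1 + e^{−2x}) − 1, evaluated as tanh(x).

    The two expressions are algebraically identical; tanh avoids the
    exponential overflow of the literal form for large |x|.
    """
    return np.tanh(np.asarray(x, dtype=float))


@dataclass
class TrainingConfig:
    """Training constants: 3000 epochs max, MSE goal 1e-3, initial rate 0.01."""

    max_epochs: int = 3000
    goal_mse: float = 1e-3
    lr0: float = 0.01
    momentum: float = 0.9
    lr_bounds: tuple[float, float] = (1e-5, 1.0)
    split_ratio: tuple[float, float, float] = (0.6, 0.2, 0.2)
    patience: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.split_ratio) - 1.0) > 1e-9:
            raise IntegrityError("split ratios must sum to 1")
        if not 0.0 <= self.momentum < 1.0:
            raise IntegrityError("momentum must lie in [0, 1)")
        lo, hi = self.lr_bounds
        if not 0 < lo < hi or not lo <= self.lr0 <= hi:
            raise IntegrityError("need 0 < eta_min < eta_max and lr0 within bounds")
        if self.goal_mse <= 0:
            raise IntegrityError("goal_mse must be positive")


@dataclass
class PSOConfig:
    """Swarm constants: 100 particles, c1=c2=2, 2000 iterations, ω 0.9→0.4."""

    n_particles: int = 100
    c1: float = 2.0
    c2: float = 2.0
    t_max: int = 2000
    w_initial: float = 0.9
    w_final: float = 0.4
    position_bound: float = 5.0
    velocity_clamp: float = 1.0
    fitness_subsample: int | None = 2048
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_particles < 2:
            raise IntegrityError("need at least 2 particles")
        if not 0 < self.w_final <= self.w_initial:
            raise IntegrityError("need 0 < w_final <= w_initial")


@dataclass
class TrainingHistory:
    """Per-epoch training diagnostics."""

    train_mse: list[float] = field(default_factory=list)
    val_mse: list[float] = field(default_factory=list)
    lr: list[float] = field(default_factory=list)
    lam: list[int] = field(default_factory=list)
    best_epoch: int = 0
    stop_reason: str = ""

    def save(self, path) -> None:
        arr = np.column_stack([self.train_mse, self.val_mse, self.lr, self.lam])
        np.savetxt(path, arr, delimiter="\t",
                   header="train_mse\tval_mse\tlr\tlambda")


# ---------------------------------------------------------------------------
# target scaling
# ---------------------------------------------------------------------------

def scale_targets(torque: np.ndarray, target_scale: tuple[float, float]
                  ) -> np.ndarray:
    """Map torque (N·m) linearly from [t_min, t_max] to [−0.9, 0.9]."""
    t_min, t_max = target_scale
    return -TARGET_MARGIN + 2 * TARGET_MARGIN * (np.asarray(torque, dtype=float)
                                                 - t_min) / (t_max - t_min)


def unscale_targets(scaled: np.ndarray, target_scale: tuple[float, float]
                    ) -> np.ndarray:
    """Inverse of :func:`scale_targets`."""
    t_min, t_max = target_scale
    return t_min + (np.asarray(scaled, dtype=float) + TARGET_MARGIN) \
        * (t_max - t_min) / (2 * TARGET_MARGIN)


# ---------------------------------------------------------------------------
# forward / gradient
# ---------------------------------------------------------------------------

def forward(params: NetworkParams, s: np.ndarray
            ) -> tuple[np.ndarray, np.ndarray]:
    """Network output for one 5-vector or an (N, 5) batch.

    Returns ``(τ_scaled, τ)`` — the raw bounded output and the torque in N·m
    after inverting the target scaling.  Shapes follow the input: scalars for
    a single vector, length-N arrays for a batch.
    """
    s = np.asarray(s, dtype=float)
    single = s.ndim == 1
    S = s[None, :] if single else s
    if S.shape[1] != N_IN:
        raise IntegrityError(f"input must have {N_IN} features, got {S.shape[1]}")
    h = tansig(S @ params.w_in.T + params.b_in)          # (N, 3)
    out = tansig(h @ params.w_out.T + params.b_out)      # (N, 1)
    tau_scaled = out[:, 0]
    tau = unscale_targets(tau_scaled, params.target_scale)
    if single:
        return float(tau_scaled[0]), float(tau[0])
    return tau_scaled, tau


@dataclass
class Gradients:
    """Loss gradients for the four parameter blocks; supports flattening."""

    w_in: np.ndarray
    b_in: np.ndarray
    w_out: np.ndarray
    b_out: np.ndarray

    def ravel(self) -> np.ndarray:
        return np.concatenate([self.w_in.ravel(), self.b_in.ravel(),
                               self.w_out.ravel(), self.b_out.ravel()])


def gradient(params: NetworkParams, S: np.ndarray, y_scaled: np.ndarray
             ) -> Gradients:
    """Analytic gradients of the batch MSE (on scaled targets).

    MSE = mean over the batch of (τ_scaled − target)²; gradients are exact
    and invariant to duplicating the batch.
    """
    S = np.asarray(S, dtype=float)
    y = np.asarray(y_scaled, dtype=float).reshape(-1)
    if S.shape[0] == 0:
        raise IntegrityError("empty batch")
    n = S.shape[0]
    z1 = S @ params.w_in.T + params.b_in
    h = tansig(z1)                                   # (n, 3)
    z2 = h @ params.w_out.T + params.b_out           # (n, 1)
    out = tansig(z2)[:, 0]

    d_out = 2.0 * (out - y) / n                      # dMSE/d out
    d_z2 = d_out * (1.0 - tansig(z2)[:, 0] ** 2)     # (n,)
    g_w_out = (d_z2[None, :] @ h)                    # (1, 3)
    g_b_out = np.array([d_z2.sum()])
    d_h = d_z2[:, None] * params.w_out               # (n, 3)
    d_z1 = d_h * (1.0 - h ** 2)                      # (n, 3)
    g_w_in = d_z1.T @ S                              # (3, 5)
    g_b_in = d_z1.sum(axis=0)
    return Gradients(w_in=g_w_in, b_in=g_b_in, w_out=g_w_out, b_out=g_b_out)


def batch_mse(params: NetworkParams, S: np.ndarray, y_scaled: np.ndarray
              ) -> float:
    out, _ = forward(params, S)
    return float(np.mean((out - np.asarray(y_scaled).reshape(-1)) ** 2))


# ---------------------------------------------------------------------------
# one update step
# ---------------------------------------------------------------------------

def update_step(params: NetworkParams, g: Gradients, g_prev: Gradients | None,
                eta_prev: float, cfg: TrainingConfig,
                ) -> tuple[NetworkParams, float, int]:
    """Apply one momentum + adaptive-learning-rate descent step.

    Returns ``(new_params, η_k, λ)``.  With no previous gradient the step is
    plain descent at the unchanged rate.
    """
    if g_prev is None:
        lam = 0
        blend = g
    else:
        inner = float(g.ravel() @ g_prev.ravel())
        lam = int(np.sign(inner))
        mu = cfg.momentum
        blend = Gradients(
            w_in=(1 - mu) * g.w_in + mu * g_prev.w_in,
            b_in=(1 - mu) * g.b_in + mu * g_prev.b_in,
            w_out=(1 - mu) * g.w_out + mu * g_prev.w_out,
            b_out=(1 - mu) * g.b_out + mu * g_prev.b_out,
        )
    lo, hi = cfg.lr_bounds
    eta = float(np.clip(2.0 ** lam * eta_prev, lo, hi))
    new = NetworkParams(
        w_in=params.w_in - eta * blend.w_in,
        b_in=params.b_in - eta * blend.b_in,
        w_out=params.w_out - eta * blend.w_out,
        b_out=params.b_out - eta * blend.b_out,
        target_scale=params.target_scale,
    )
    return new, eta, lam


# ---------------------------------------------------------------------------
# particle swarm initialization
# ---------------------------------------------------------------------------

def _decode(position: np.ndarray, target_scale: tuple[float, float]
            ) -> NetworkParams:
    p = np.asarray(position, dtype=float)
    i0 = N_IN * N_HID
    return NetworkParams(w_in=p[:i0].reshape(N_HID, N_IN),
                         b_in=p[i0:i0 + N_HID],
                         w_out=p[i0 + N_HID:i0 + 2 * N_HID].reshape(N_OUT, N_HID),
                         b_out=p[i0 + 2 * N_HID:],
                         target_scale=target_scale)


def _swarm_fitness(P: np.ndarray, S: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Training MSE of every particle, vectorized across the swarm."""
    n_p = P.shape[0]
    i0 = N_IN * N_HID
    w_in = P[:, :i0].reshape(n_p, N_HID, N_IN)
    b_in = P[:, i0:i0 + N_HID]
    w_out = P[:, i0 + N_HID:i0 + 2 * N_HID]
    b_out = P[:, i0 + 2 * N_HID]
    h = np.tanh(np.einsum("phi,ni->pnh", w_in, S) + b_in[:, None, :])
    out = np.tanh(np.einsum("pnh,ph->pn", h, w_out) + b_out[:, None])
    return np.mean((out - y[None, :]) ** 2, axis=1)


def pso_init(S: np.ndarray, y_scaled: np.ndarray, cfg: PSOConfig,
             target_scale: tuple[float, float] = (-1.0, 1.0),
             ) -> NetworkParams:
    """Choose initial network parameters by global-best PSO.

    Particles encode the 22 free parameters; fitness is the (sub-sampled)
    training MSE of the decoded network.  The global best is monotonically
    non-increasing by construction; ``t_max=0`` returns the best particle of
    the random initial swarm.
    """
    S = np.asarray(S, dtype=float)
    y = np.asarray(y_scaled, dtype=float).reshape(-1)
    if S.shape[0] == 0:
        raise IntegrityError("empty training set")
    rng = np.random.default_rng(cfg.seed)
    if cfg.fitness_subsample is not None and S.shape[0] > cfg.fitness_subsample:
        idx = rng.choice(S.shape[0], size=cfg.fitness_subsample, replace=False)
        S_fit, y_fit = S[idx], y[idx]
    else:
        S_fit, y_fit = S, y

    b = cfg.position_bound
    P = rng.uniform(-b, b, size=(cfg.n_particles, N_PARAMS))
    V = rng.uniform(-cfg.velocity_clamp, cfg.velocity_clamp, size=P.shape)
    fit = _swarm_fitness(P, S_fit, y_fit)
    pbest, pbest_fit = P.copy(), fit.copy()
    g_idx = int(np.argmin(fit))
    gbest, gbest_fit = P[g_idx].copy(), float(fit[g_idx])

    for t in range(cfg.t_max):
        frac = t / max(cfg.t_max - 1, 1)
        w = cfg.w_initial + (cfg.w_final - cfg.w_initial) * frac
        r1 = rng.uniform(size=P.shape)
        r2 = rng.uniform(size=P.shape)
        V = w * V + cfg.c1 * r1 * (pbest - P) + cfg.c2 * r2 * (gbest - P)
        np.clip(V, -cfg.velocity_clamp, cfg.velocity_clamp, out=V)
        P = np.clip(P + V, -b, b)
        fit = _swarm_fitness(P, S_fit, y_fit)
        improved = fit < pbest_fit
        pbest[improved] = P[improved]
        pbest_fit[improved] = fit[improved]
        g_idx = int(np.argmin(pbest_fit))
        if pbest_fit[g_idx] < gbest_fit:
            gbest, gbest_fit = pbest[g_idx].copy(), float(pbest_fit[g_idx])
    return _decode(gbest, target_scale)


# ---------------------------------------------------------------------------
# dataset split and training loop
# ---------------------------------------------------------------------------

def split_622(n: int, seed: int = 0,
              ratio: tuple[float, float, float] = (0.6, 0.2, 0.2),
              ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Shuffled disjoint train/validation/test index split.

    Sizes are ``floor(r_train·n)`` / ``floor(r_val·n)`` / remainder.
    """
    if n < 10:
        raise IntegrityError("need at least 10 samples to split 6:2:2")
    perm = np.random.default_rng(seed).permutation(n)
    n_train = int(np.floor(ratio[0] * n))
    n_val = int(np.floor(ratio[1] * n))
    return (perm[:n_train], perm[n_train:n_train + n_val],
            perm[n_train + n_val:])


def train(S_train: np.ndarray, y_train: np.ndarray,
          S_val: np.ndarray, y_val: np.ndarray,
          cfg: TrainingConfig, init: NetworkParams | None = None,
          target_scale: tuple[float, float] | None = None,
          ) -> tuple[NetworkParams, TrainingHistory]:
    """Full-batch training with momentum, adaptive rate and early stopping.

    Torque targets are given in N·m; the scaler is learned from the training
    targets unless supplied.  Losses are MSE on the scaled targets.  Returns
    the parameters of the best-validation epoch.
    """
    S_train = np.asarray(S_train, dtype=float)
    S_val = np.asarray(S_val, dtype=float)
    y_train = np.asarray(y_train, dtype=float).reshape(-1)
    y_val = np.asarray(y_val, dtype=float).reshape(-1)
    if target_scale is None:
        t_min, t_max = float(y_train.min()), float(y_train.max())
        if t_min == t_max:
            raise IntegrityError("constant training targets")
        target_scale = (t_min, t_max)
    yt = scale_targets(y_train, target_scale)
    yv = scale_targets(y_val, target_scale)

    if init is None:
        rng = np.random.default_rng(cfg.seed)
        params = _decode(rng.uniform(-0.5, 0.5, N_PARAMS), target_scale)
    else:
        params = init.copy()
        params.target_scale = target_scale

    hist = TrainingHistory()
    best_params, best_val, best_epoch = params.copy(), np.inf, 0
    eta = cfg.lr0
    g_prev: Gradients | None = None

    for epoch in range(1, cfg.max_epochs + 1):
        train_mse = batch_mse(params, S_train, yt)
        val_mse = batch_mse(params, S_val, yv)
        if not np.isfinite(train_mse):
            raise DivergenceError(
                f"non-finite training loss at epoch {epoch} (eta={eta:.3g})"
            )
        hist.train_mse.append(train_mse)
        hist.val_mse.append(val_mse)
        if val_mse < best_val:
            best_val, best_params, best_epoch = val_mse, params.copy(), epoch
        if train_mse <= cfg.goal_mse:
            hist.lr.append(eta)
            hist.lam.append(0)
            hist.stop_reason = "goal"
            break
        if epoch - best_epoch >= cfg.patience:
            hist.lr.append(eta)
            hist.lam.append(0)
            hist.stop_reason = "early-stop"
            break
        g = gradient(params, S_train, yt)
        params, eta, lam = update_step(params, g, g_prev, eta, cfg)
        g_prev = g
        hist.lr.append(eta)
        hist.lam.append(lam)
    else:
        hist.stop_reason = "max-epochs"

    hist.best_epoch = best_epoch
    return best_params, hist


def predict(params: NetworkParams, S: np.ndarray) -> np.ndarray:
    """Torque predictions in N·m for an (N, 5) component matrix."""
    _, tau = forward(params, np.atleast_2d(np.asarray(S, dtype=float)))
    return tau
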