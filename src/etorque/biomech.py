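"""Hill-type muscle torque and Lagrangian elbow inverse dynamics.

Two independent torque models live here:

* a Hill-type active-force model — static exponential activation
  ``a(u) = (e^{Au} − 1)/(e^{A} − 1)``, Thelen-parameterized force–length and
  force–velocity curves, ``F_CE = a·f1·fv·F0``, pennation projection
  ``F_M = (F_CE + F_PE)·cosφ`` and a signed moment-arm sum over the three
  elbow muscles (flexors positive, extensor negative).  Only the active
  contractile force is needed for assist control, so the passive term
  defaults to zero;
* rigid-body inverse dynamics of the forearm about the elbow,
  ``T = m·(l3+r2)²·β″ − m·g·(l3+r2)·sin β``, with the forearm+hand mass ``m``
  rotating at lever arm ``l3 + r2``.  This is the label oracle: its output is
  the expected network output during training.

The inverse-dynamics formula is implemented exactly as written, with the
bending angle β in the attitude-sensor convention in which flexion is
negative, so that the active torque demanded from the flexors comes out
positive (gravity term ``+mgl·sin(flexion)``).  :func:`torque_labels` applies
the convention; see docs/methods.md.

Thelen curve constants (Gaussian force–length width γ=0.45, eccentric
plateau 1.4, maximum shortening velocity 10 optimal fiber lengths/s) follow
the standard formulation and are exposed as arguments.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .dataio import SubjectAnthropometry
from .errors import DomainError, IntegrityError

GAMMA_FL = 0.45          # force-length Gaussian width
AF_FV = 0.25             # force-velocity curvature
ECC_CEILING = 1.4        # eccentric force plateau (× F0)
V_MAX_LOPT_S = 10.0      # max shortening velocity, optimal lengths / s


@dataclass
class MuscleParams:
    """Hill-model parameters for one muscle acting at the elbow."""

    f0: float                     # maximum isometric force, N
    optimal_fiber_length: float   # m
    moment_arm: float             # m, magnitude
    role: int                     # +1 flexor, -1 extensor
    pennation: float = 0.17       # rad
    tendon_length: float = 0.20   # m, l_t1 + l_t2 (fixed, rigid tendon)
    A: float = -2.0               # activation nonlinearity factor, < 0

    def __post_init__(self) -> None:
        if self.f0 <= 0 or self.optimal_fiber_length <= 0 or self.moment_arm <= 0:
            raise IntegrityError("F0, optimal fiber length and moment arm must be > 0")
        if not -5.0 <= self.A < 0.0:
            raise IntegrityError("A must lie in [-5, 0)")
        if self.role not in (+1, -1):
            raise IntegrityError("role must be +1 (flexor) or -1 (extensor)")


#: Default elbow muscle set.  The moment arms and Hill constants are
#: configuration values (generic adult-scale numbers), not subject claims.
DEFAULT_MUSCLES: dict[str, MuscleParams] = {
    "biceps": MuscleParams(f0=500.0, optimal_fiber_length=0.116,
                           moment_arm=0.030, role=+1),
    "brachioradialis": MuscleParams(f0=250.0, optimal_fiber_length=0.173,
                                    moment_arm=0.025, role=+1),
    "triceps": MuscleParams(f0=700.0, optimal_fiber_length=0.134,
                            moment_arm=0.021, role=-1),
}


def activation(u: np.ndarray | float, A: float) -> np.ndarray | float:
    """Static EMG-to-activation nonlinearity a = (e^{Au} − 1)/(e^{A} − 1).

    Monotone increasing, maps [0,1] onto [0,1] for any A ≠ 0.
    """
    u = np.asarray(u, dtype=float)
    if np.any(u < 0) or np.any(u > 1):
        raise DomainError("normalized EMG u must lie in [0, 1]")
    if A == 0:
        raise DomainError("A must be nonzero")
    a = np.expm1(A * u) / np.expm1(A)
    return float(a) if a.ndim == 0 else a


def force_length(l_norm: np.ndarray | float, gamma: float = GAMMA_FL
                 ) -> np.ndarray | float:
    """Active force–length factor f1 = exp(−(l_norm − 1)² / γ)."""
    l_norm = np.asarray(l_norm, dtype=float)
    if np.any(l_norm <= 0):
        raise DomainError("normalized fiber length must be positive")
    f1 = np.exp(-np.square(l_norm - 1.0) / gamma)
    return float(f1) if f1.ndim == 0 else f1


def force_velocity(v_norm: np.ndarray | float, a_f: float = AF_FV,
                   ecc_ceiling: float = ECC_CEILING) -> np.ndarray | float:
    """Force–velocity factor; ``v_norm`` is shortening velocity / v_max.

    Isometric (v=0) gives 1; force falls to 0 at maximal shortening (v=1)
    and plateaus at ``ecc_ceiling`` for fast lengthening (v<0).
    """
    v = np.asarray(v_norm, dtype=float)
    conc = np.clip(1.0 - v, 0.0, None) / (1.0 + np.clip(v, 0.0, None) / a_f)
    w = np.clip(-v, 0.0, None)  # lengthening speed
    ecc = ecc_ceiling - (ecc_ceiling - 1.0) / (1.0 + w / a_f)
    fv = np.where(v >= 0, conc, ecc)
    return float(fv) if fv.ndim == 0 else fv


def active_fiber_force(a, f1, fv, f0: float) -> np.ndarray | float:
    """Contractile-element force F_CE = a · f1 · fv · F0 (N)."""
    out = np.asarray(a, dtype=float) * np.asarray(f1, dtype=float) \
        * np.asarray(fv, dtype=float) * f0
    return float(out) if np.ndim(out) == 0 else out


def muscle_force(f_ce, phi: float, f_pe=0.0) -> np.ndarray | float:
    """Musculotendon force F_M = (F_CE + F_PE)·cos φ along the tendon line."""
    if not 0.0 <= phi < np.pi / 2:
        raise DomainError("pennation angle must lie in [0, π/2)")
    out = (np.asarray(f_ce, dtype=float) + np.asarray(f_pe, dtype=float)) * np.cos(phi)
    return float(out) if np.ndim(out) == 0 else out


def hill_elbow_torque(forces: Mapping[str, np.ndarray | float],
                      muscles: Mapping[str, MuscleParams] | None = None,
                      ) -> np.ndarray | float:
    """Signed moment sum Σ role · F_M · moment_arm over the named muscles."""
    muscles = DEFAULT_MUSCLES if muscles is None else muscles
    total = 0.0
    for name, f in forces.items():
        mp = muscles[name]
        total = total + mp.role * np.asarray(f, dtype=float) * mp.moment_arm
    return float(total) if np.ndim(total) == 0 else total


def fiber_state(beta_flex_rad: np.ndarray, omega_rad_s: np.ndarray,
                mp: MuscleParams, beta_ref: float = np.pi / 3,
                ) -> tuple[np.ndarray, np.ndarray]:
    """Normalized fiber length and shortening velocity from elbow kinematics.

    Rigid-tendon geometry: the musculotendon length changes linearly with the
    joint angle at the (constant) moment arm, referenced so the fiber sits at
    its optimum at ``beta_ref``.  Flexors shorten as flexion increases,
    the extensor lengthens (handled by ``role``).
    """
    beta_flex_rad = np.asarray(beta_flex_rad, dtype=float)
    omega_rad_s = np.asarray(omega_rad_s, dtype=float)
    dl_mt = -mp.role * mp.moment_arm * (beta_flex_rad - beta_ref)
    l_m = mp.optimal_fiber_length + dl_mt / np.cos(mp.pennation)
    l_norm = np.clip(l_m / mp.optimal_fiber_length, 1e-6, None)
    v_fiber = mp.role * mp.moment_arm * omega_rad_s / np.cos(mp.pennation)
    v_norm = v_fiber / (V_MAX_LOPT_S * mp.optimal_fiber_length)
    return l_norm, v_norm


def hill_torque_series(envelopes: Mapping[str, np.ndarray],
                       beta_flex_deg: np.ndarray, omega_deg_s: np.ndarray,
                       muscles: Mapping[str, MuscleParams] | None = None,
                       times: np.ndarray | None = None) -> "TorqueSeries":
    """Hill-model active elbow torque from per-muscle excitation envelopes.

    ``envelopes`` maps muscle names to normalized EMG envelopes u(t) ∈ [0,1]
    sampled together with the joint kinematics.
    """
    muscles = DEFAULT_MUSCLES if muscles is None else muscles
    beta = np.deg2rad(np.asarray(beta_flex_deg, dtype=float))
    omega = np.deg2rad(np.asarray(omega_deg_s, dtype=float))
    forces = {}
    for name, u in envelopes.items():
        mp = muscles[name]
        a = activation(np.clip(u, 0.0, 1.0), mp.A)
        l_norm, v_norm = fiber_state(beta, omega, mp)
        f_ce = active_fiber_force(a, force_length(l_norm), force_velocity(v_norm),
                                  mp.f0)
        forces[name] = muscle_force(f_ce, mp.pennation)
    torque = hill_elbow_torque(forces, muscles)
    if times is None:
        times = np.arange(beta.size, dtype=float)
    return TorqueSeries(times=np.asarray(times, dtype=float),
                        torque=np.atleast_1d(torque), source="hill")


# ---------------------------------------------------------------------------
# Lagrangian inverse dynamics
# ---------------------------------------------------------------------------

@dataclass
class TorqueSeries:
    """A time-aligned elbow torque trace in N·m with a provenance tag."""

    times: np.ndarray
    torque: np.ndarray
    source: str = "lagrange"   # lagrange | hill | predicted

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.torque = np.asarray(self.torque, dtype=float)
        if self.times.shape != self.torque.shape:
            raise IntegrityError("times and torque must have equal length")
        if not np.all(np.isfinite(self.torque)):
            raise IntegrityError("torque contains non-finite values")


def lagrange_torque(beta_rad: np.ndarray | float,
                    beta_ddot: np.ndarray | float,
                    anthro: SubjectAnthropometry) -> np.ndarray | float:
    """Elbow torque from the second-kind Lagrange equation.

    ``T = m·(l3+r2)²·β″ − m·g·(l3+r2)·sin β`` with the bending angle β in
    radians and β″ in rad/s².  Linear in the segment mass and in β″.
    """
    lever = anthro.lever_arm
    m = anthro.segment_mass
    out = m * lever ** 2 * np.asarray(beta_ddot, dtype=float) \
        - m * anthro.gravity * lever * np.sin(np.asarray(beta_rad, dtype=float))
    return float(out) if np.ndim(out) == 0 else out


def required_active_torque(flexion_deg: np.ndarray, fs: float,
                           anthro: SubjectAnthropometry) -> np.ndarray:
    """Active torque demanded by a flexion trajectory, muscle-demand sign.

    Evaluates the Lagrangian formula with the sensor-convention bending angle
    β = −flexion, so holding a flexed posture against gravity demands positive
    torque.  β″ is obtained by repeated central differences.
    """
    flexion = np.deg2rad(np.asarray(flexion_deg, dtype=float))
    if flexion.size < 3:
        raise IntegrityError("need at least 3 samples to differentiate")
    dt = 1.0 / fs
    beta = -flexion
    beta_ddot = np.gradient(np.gradient(beta, dt), dt)
    return lagrange_torque(beta, beta_ddot, anthro)


def torque_labels(beta_deg: np.ndarray, anthro: SubjectAnthropometry,
                  dt: float, times: np.ndarray | None = None,
                  ) -> TorqueSeries:
    """Per-window torque labels from a bending-angle sequence on a uniform grid.

    ``beta_deg`` is the sensor-convention bending angle (degrees) at the window
    centres, spaced ``dt`` seconds apart; β″ comes from central finite
    differences on that grid.  Pass the sensor-convention angle (−flexion) to
    obtain muscle-demand labels; see :func:`required_active_torque`.
    """
    beta = np.deg2rad(np.asarray(beta_deg, dtype=float))
    if beta.size < 3:
        raise IntegrityError("need at least 3 windows for torque labels")
    beta_ddot = np.gradient(np.gradient(beta, dt), dt)
    torque = lagrange_torque(beta, beta_ddot, anthro)
    if times is None:
        times = (np.arange(beta.size) + 0.5) * dt
    return TorqueSeries(times=np.asarray(times, dtype=float), torque=torque,
                        source="lagrange")
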