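"""Dopamine-dependent BCM rule for cortico-striatal plasticity.

The rule is a rate-coded reduction of triplet spike-timing-dependent
plasticity.  With pre-rate ``x``, post-rate ``y`` and sliding threshold
``theta``, the expected weight change is

    dw/dt = eta * y * (y - theta_bcm) * x,
    theta_bcm = <y^2> * C_bcm(d),
    C_bcm(d)  = -(A_minus(d) * tau_ratio + A_plus(d)) * c_gain,

where ``eta`` lumps the triplet factor and its time constants
(A3 * tau_plus * tau_y), ``c_gain`` = tau_plus / (A3 * tau_plus * tau_y), and
``tau_ratio`` = tau_minus / tau_plus (1 by default).  The pair coefficients
``A_plus``/``A_minus`` are signed, receptor-specific (D1 vs D2 MSNs), and
measured at low and high dopamine; at intermediate simulated dopamine ``d``
they are blended with the saturating mixing function

    alpha(d) = 4 d / (1 + 4 d),

so A(d) = alpha(d) A_hi + (1 - alpha(d)) A_lo.  The resulting sign structure:
C_bcm is positive for D1 and negative for D2 at low dopamine (dips favour
D1-LTD and D2-LTP), and reverses at high dopamine (bursts drive strong
D1-LTP) — the arrangement that lets dips weaken and bursts strengthen the GO
pathway of the active channel.

``<y^2>`` is tracked as an exponential moving average of the squared
post-synaptic rate.  Updates are gated to a window after each phasic
dopamine event; between events the trajectories are flat.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from actdisc.config import PlasticityConfig

RECEPTORS = ("D1", "D2")


@dataclass
class PlasticityCoefficients:
    """Eight signed pair coefficients (receptor x dopamine level x timing)."""

    a_plus_d1_hi: float = 1.0
    a_minus_d1_hi: float = -0.25
    a_plus_d1_lo: float = 0.25
    a_minus_d1_lo: float = -1.0
    a_plus_d2_hi: float = -1.0
    a_minus_d2_hi: float = -0.25
    a_plus_d2_lo: float = 1.0
    a_minus_d2_lo: float = 1.0

    @classmethod
    def from_config(cls, cfg: PlasticityConfig) -> "PlasticityCoefficients":
        return cls(**{f: getattr(cfg, f) for f in cls.__dataclass_fields__})

    def pair(self, receptor: str, level: str) -> tuple[float, float]:
        """(A_plus, A_minus) for a receptor at dopamine level 'hi' or 'lo'."""
        r = receptor.lower()
        return (
            getattr(self, f"a_plus_{r}_{level}"),
            getattr(self, f"a_minus_{r}_{level}"),
        )


@dataclass
class LearningRuleParams:
    """Lumped rate constants and bounds of the weight-update rule."""

    eta: float = 0.03
    c_gain: float = 25.0
    tau_ratio: float = 1.0
    ysq_tau: float = 5.0
    w_min: float = 0.05
    w_max: float = 2.0
    window: float = 1.0

    def __post_init__(self) -> None:
        if self.eta <= 0:
            raise ValueError("eta must be positive")
        if self.w_min < 0:
            raise ValueError("w_min must be non-negative")

    @classmethod
    def from_config(cls, cfg: PlasticityConfig) -> "LearningRuleParams":
        return cls(eta=cfg.eta, c_gain=cfg.c_gain, tau_ratio=cfg.tau_ratio,
                   ysq_tau=cfg.ysq_tau, w_min=cfg.w_min, w_max=cfg.w_max,
                   window=cfg.window)


@dataclass
class YsqTracker:
    """Running <y^2> per MSN population per channel (EMA, time constant
    ``ysq_tau``); equals y^2 at steady state for constant y."""

    n_channels: int = 3
    ysq: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.ysq = np.zeros((2, self.n_channels))  # rows: D1, D2

    def update(self, y: np.ndarray, dt: float, ysq_tau: float) -> None:
        self.ysq = update_ysq(self.ysq, np.asarray(y, float), dt, ysq_tau)


@njit
def alpha(d: float) -> float:
    """Saturating dopamine mixing function 4d / (1 + 4d)."""
    return 4.0 * d / (1.0 + 4.0 * d)


@njit
def blend_coefficient(a_hi: float, a_lo: float, d: float) -> float:
    """Dopamine-blended pair coefficient alpha(d) A_hi + (1 - alpha(d)) A_lo."""
    m = alpha(d)
    return m * a_hi + (1.0 - m) * a_lo


@njit
def _c_bcm_scalar(d, a_plus_hi, a_plus_lo, a_minus_hi, a_minus_lo,
                  tau_ratio, c_gain):
    a_plus = blend_coefficient(a_plus_hi, a_plus_lo, d)
    a_minus = blend_coefficient(a_minus_hi, a_minus_lo, d)
    return -(a_minus * tau_ratio + a_plus) * c_gain


def c_bcm(d: float, receptor: str, coeffs: PlasticityCoefficients,
          params: LearningRuleParams) -> float:
    """Dopamine-dependent BCM factor for one receptor class."""
    ph, mh = coeffs.pair(receptor, "hi")
    pl, ml = coeffs.pair(receptor, "lo")
    return _c_bcm_scalar(d, ph, pl, mh, ml, params.tau_ratio, params.c_gain)


def theta_bcm(ysq: float, c: float) -> float:
    """Sliding threshold theta = <y^2> * C_bcm(d)."""
    return ysq * c


@njit
def weight_update(w: float, x: float, y: float, theta: float, eta: float,
                  dt: float, w_min: float, w_max: float) -> float:
    """One Euler step of the BCM rule, clipped to the weight bounds."""
    w2 = w + dt * eta * y * (y - theta) * x
    if w2 < w_min:
        return w_min
    if w2 > w_max:
        return w_max
    return w2


@njit
def update_ysq(ysq: np.ndarray, y: np.ndarray, dt: float,
               ysq_tau: float) -> np.ndarray:
    """Exponential moving average of y^2 with time constant ysq_tau."""
    k = dt / ysq_tau
    return ysq + k * (y * y - ysq)
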