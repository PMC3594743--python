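"""Phasic dopamine as a sensory prediction error.

At each evaluated interaction with the target block the binary flash feature
``y_f`` is compared with its phasic prediction ``y*``.  The superior
colliculus responds to the unpredicted part of the flash,

    y_sc = [y_f - y*]+,

and a canceling signal (habenula-like) carries the unfulfilled part of the
prediction,

    y_cancel = [y* - y_f]+,

so the sensory prediction error e = y_sc - y_cancel = y_f - y* exactly.  Both
signals are short triangular pulses (width 0.2 s) forming the input to SNc
dopamine neurons with asymmetric gains,

    I_snc = a_plus * y_sc - a_minus * y_cancel,      a_plus = 2, a_minus = 1.

The SNc activation integrates I_snc with the standard leaky-integrator
dynamics; its output is deliberately *not* normalized so it can be read as a
simulated dopamine level:

    d = max(0, a_snc + 0.2),

giving a resting level d = 0.2, bursts above it, and dips rectified at zero.
"""

from __future__ import annotations

from dataclasses import dataclass

from numba import njit


@dataclass
class PhasicEventSignals:
    """Pulse amplitudes generated by one evaluated target interaction."""

    y_f: float
    y_sc: float
    y_cancel: float
    pulse_width: float = 0.2
    a_plus: float = 2.0
    a_minus: float = 1.0


@dataclass
class SNcState:
    """Leaky-integrator dopamine neuron: activation and output level d."""

    a_snc: float = 0.0
    tau: float = 0.04
    rest: float = 0.2

    @property
    def d(self) -> float:
        return snc_output(self.a_snc, self.rest)

    def step(self, I_snc: float, dt: float) -> float:
        self.a_snc += (dt / self.tau) * (-self.a_snc + I_snc)
        return self.d


@njit
def sc_response(y_f: float, y_star: float) -> float:
    """Collicular response to the flash: rectified positive prediction error."""
    x = y_f - y_star
    return x if x > 0.0 else 0.0


@njit
def cancel_signal(y_f: float, y_star: float) -> float:
    """Canceling signal: rectified unfulfilled prediction."""
    x = y_star - y_f
    return x if x > 0.0 else 0.0


def prediction_error(y_sc: float, y_cancel: float) -> float:
    """Sensory prediction error e = y_sc - y_cancel (= y_f - y*)."""
    return y_sc - y_cancel


@njit
def snc_input(y_sc: float, y_cancel: float, a_plus: float = 2.0,
              a_minus: float = 1.0) -> float:
    """Effective SNc drive with asymmetric burst/dip gains."""
    return a_plus * y_sc - a_minus * y_cancel


@njit
def snc_output(a_snc: float, rest: float = 0.2) -> float:
    """Unnormalized, below-rectified dopamine level d = max(0, a_snc + rest)."""
    x = a_snc + rest
    return x if x > 0.0 else 0.0


@njit
def triangular_pulse(t: float, t_event: float, width: float,
                     amplitude: float) -> float:
    """Symmetric triangular pulse on [t_event, t_event + width], peaking at
    the window centre with the given amplitude; zero outside."""
    x = t - t_event
    if x <= 0.0 or x >= width:
        return 0.0
    half = 0.5 * width
    if x <= half:
        return amplitude * x / half
    return amplitude * (width - x) / half
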