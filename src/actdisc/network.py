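"""Rate-coded basal-ganglia + thalamocortical selection network.

Three discrete action channels (explore, interact-red, interact-white) run
through a leaky-integrator network comprising sensory cortex, motor cortex,
D1- and D2-striatum, STN, GPe, GPi/SNr, ventrolateral thalamus (VL), the
thalamic reticular nucleus (TRN) and a brainstem population.  Each population
houses one leaky-integrator unit per channel,

    tau * da/dt = -a + I,

with a piecewise-linear squashing function ``y = clip(a - eps, 0, 1)`` mapping
activation to a normalized firing rate.  The D1-striatum -> GPi/SNr route with
diffuse STN excitation implements an off-centre/on-surround competition: the
channel with the largest salience suppresses its own GPi/SNr output, releasing
its thalamo-cortical loop and brainstem population.  A channel is selected for
behavioural expression when its brainstem output exceeds the threshold ``phi``.

Tonic dopamine ``lam`` scales cortico-striatal transmission multiplicatively:
D1 weights by ``1 + lam`` and D2 weights by ``1 - lam``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

N_CHANNELS = 3

# population indices
SCTX, MCTX, D1, D2, STN, GPE, GPI, VL, TRN, BS = range(10)
N_POP = 10

POPULATION_NAMES = (
    "sensory_cortex",
    "motor_cortex",
    "striatum_d1",
    "striatum_d2",
    "stn",
    "gpe",
    "gpi_snr",
    "vl_thalamus",
    "trn",
    "brainstem",
)

# gain-vector indices (inter-nucleus projection weights)
(
    G_SCTX_MCTX,
    G_VL_MCTX,
    G_MCTX_REC,
    G_MCTX_STN,
    G_GPE_STN,
    G_STN_GPE,
    G_D2_GPE,
    G_STN_GPI,
    G_D1_GPI,
    G_GPE_GPI,
    G_MCTX_VL,
    G_GPI_VL,
    G_TRN_VL_LOCAL,
    G_TRN_VL_DISTAL,
    G_MCTX_TRN,
    G_VL_TRN,
    G_GPI_TRN,
    G_MCTX_BS,
    G_GPI_BS,
) = range(19)
N_GAINS = 19


def default_gains() -> np.ndarray:
    """Inter-nucleus projection weights.

    The family follows the classic rate-coded selection architecture (diffuse
    cross-channel STN excitation onto both pallidal segments, strong focused
    D1 inhibition of GPi/SNr, a GPe control loop, weak within-channel but
    stronger cross-channel TRN -> VL inhibition, and sub-unity motor-cortex
    recurrence so maintained behaviour stays interruptible).  Magnitudes were
    tuned against the selection-competence battery: winner-take-all on a
    salience grid, a lone-channel expression threshold near salience 0.2,
    suppression of high-salience losers, and sensitivity of the expression
    threshold to the plastic cortico-striatal weights.
    """
    g = np.zeros(N_GAINS)
    g[G_SCTX_MCTX] = 1.0
    g[G_VL_MCTX] = 0.34
    g[G_MCTX_REC] = 0.35
    g[G_MCTX_STN] = 0.59
    g[G_GPE_STN] = 0.61
    g[G_STN_GPE] = 0.91
    g[G_D2_GPE] = 2.17
    g[G_STN_GPI] = 1.35
    g[G_D1_GPI] = 2.05
    g[G_GPE_GPI] = 0.44
    g[G_MCTX_VL] = 1.25
    g[G_GPI_VL] = 1.2
    g[G_TRN_VL_LOCAL] = 0.08
    g[G_TRN_VL_DISTAL] = 0.5
    g[G_MCTX_TRN] = 0.54
    g[G_VL_TRN] = 0.13
    g[G_GPI_TRN] = 0.45
    g[G_MCTX_BS] = 1.08
    g[G_GPI_BS] = 2.08
    return g


GAIN_NAMES = (
    "sctx_mctx", "vl_mctx", "mctx_rec", "mctx_stn", "gpe_stn", "stn_gpe",
    "d2_gpe", "stn_gpi", "d1_gpi", "gpe_gpi", "mctx_vl", "gpi_vl",
    "trn_vl_local", "trn_vl_distal", "mctx_trn", "vl_trn", "gpi_trn",
    "mctx_bs", "gpi_bs",
)


def gains_from_overrides(overrides: dict[str, float] | None = None) -> np.ndarray:
    """Default gain vector with named overrides applied (config interface)."""
    g = default_gains()
    for name, value in (overrides or {}).items():
        g[GAIN_NAMES.index(name)] = value
    return g


def eps_from_overrides(overrides: dict[str, float] | None = None) -> np.ndarray:
    """Default output thresholds with per-population overrides applied."""
    eps = default_eps()
    for name, value in (overrides or {}).items():
        eps[POPULATION_NAMES.index(name)] = value
    return eps


def default_eps() -> np.ndarray:
    """Output thresholds per population.

    Small positive eps for striatum (quiet at rest), negative eps for the
    tonically active nuclei STN, GPe and GPi/SNr (positive output at zero
    activation), zero elsewhere.
    """
    eps = np.zeros(N_POP)
    eps[D1] = 0.06
    eps[D2] = 0.06
    eps[STN] = -0.25
    eps[GPE] = -0.2
    eps[GPI] = -0.2
    return eps


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class UnitParams:
    """Membrane time constant tau (s) and output threshold eps of one unit."""

    tau: float = 0.04
    eps: float = 0.0

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError(f"tau must be positive, got {self.tau}")


@dataclass
class PopulationState:
    """Activation and normalized output of one population (one unit/channel)."""

    a: np.ndarray
    y: np.ndarray


@dataclass
class CorticoStriatalWeights:
    """Plastic cortico-striatal weights plus the tonic dopamine level.

    ``motor``/``sensory`` have shape (2, n_channels): row 0 targets
    D1-striatum, row 1 targets D2-striatum.  Sensory weights start at zero;
    positive increments acquired through learning act as stimulus-derived
    selection biases.
    """

    motor: np.ndarray
    sensory: np.ndarray
    lam: float = 0.2

    def __post_init__(self) -> None:
        self.motor = np.asarray(self.motor, dtype=float)
        self.sensory = np.asarray(self.sensory, dtype=float)
        if np.any(self.motor < 0) or np.any(self.sensory < 0):
            raise ValueError("cortico-striatal weights must be non-negative")
        if not 0 <= self.lam < 1:
            raise ValueError(f"tonic dopamine lam must be in [0, 1), got {self.lam}")

    @classmethod
    def initial(cls, motor_value: float = 0.55, lam: float = 0.2,
                n_channels: int = N_CHANNELS) -> "CorticoStriatalWeights":
        return cls(
            motor=np.full((2, n_channels), motor_value),
            sensory=np.zeros((2, n_channels)),
            lam=lam,
        )

    def copy(self) -> "CorticoStriatalWeights":
        return CorticoStriatalWeights(self.motor.copy(), self.sensory.copy(), self.lam)


@dataclass
class NetworkState:
    """Activations of all populations; shape (N_POP, n_channels)."""

    a: np.ndarray = field(default_factory=lambda: np.zeros((N_POP, N_CHANNELS)))
    eps: np.ndarray = field(default_factory=default_eps)
    tau: float = 0.04

    @property
    def n_channels(self) -> int:
        return self.a.shape[1]

    def outputs(self) -> np.ndarray:
        """Normalized rates y of every population, shape (N_POP, n_channels)."""
        return output_rates(self.a, self.eps)

    def population(self, name: str) -> PopulationState:
        idx = POPULATION_NAMES.index(name)
        return PopulationState(a=self.a[idx].copy(), y=self.outputs()[idx].copy())

    def copy(self) -> "NetworkState":
        return NetworkState(self.a.copy(), self.eps.copy(), self.tau)


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------


def integrate_unit(a: float, I: float, dt: float, tau: float) -> float:
    """One forward-Euler step of ``tau da/dt = -a + I``.

    ``dt`` must not exceed ``tau``; larger steps destabilize the explicit
    integration scheme.
    """
    if dt <= 0:
        raise ValueError(f"dt must be positive, got {dt}")
    if dt > tau:
        raise ValueError(
            f"integration step dt={dt} exceeds membrane time constant tau={tau}; "
            "forward Euler would be unstable"
        )
    return a + (dt / tau) * (-a + I)


@njit
def squash(a: float, eps: float) -> float:
    """Piecewise-linear squashing: 0 below eps, unit slope, saturation at 1."""
    if a <= eps:
        return 0.0
    if a >= 1.0 + eps:
        return 1.0
    return a - eps


@njit
def output_rates(a: np.ndarray, eps: np.ndarray) -> np.ndarray:
    """Apply the squashing function population-wise; a has shape (N_POP, nc)."""
    n_pop, nc = a.shape
    y = np.empty((n_pop, nc))
    for p in range(n_pop):
        for c in range(nc):
            y[p, c] = squash(a[p, c], eps[p])
    return y


def effective_cortico_striatal_weight(w: float, lam: float, receptor: str) -> float:
    """Tonic-dopamine-scaled weight: ``w (1 + lam)`` at D1, ``w (1 - lam)`` at D2."""
    if w < 0:
        raise ValueError("weight must be non-negative")
    if receptor == "D1":
        return w * (1.0 + lam)
    if receptor == "D2":
        return w * (1.0 - lam)
    raise ValueError(f"receptor must be 'D1' or 'D2', got {receptor!r}")


@njit
def step_kernel(a, sal, noise, w_mot, w_sen, lam, eps, gains, dt, tau):
    """Advance all populations by one Euler step (in place).

    a       : (N_POP, nc) activations
    sal     : (nc,) salience input to sensory cortex
    noise   : (nc,) additive input noise on sensory cortex
    w_mot   : (2, nc) plastic motor-cortex -> striatum weights (rows D1, D2)
    w_sen   : (2, nc) plastic sensory-cortex -> striatum weights
    """
    nc = a.shape[1]
    y = output_rates(a, eps)

    y_stn_sum = 0.0
    y_trn_sum = 0.0
    for c in range(nc):
        y_stn_sum += y[STN, c]
        y_trn_sum += y[TRN, c]

    I = np.empty((N_POP, nc))
    for c in range(nc):
        I[SCTX, c] = sal[c] + noise[c]
        I[MCTX, c] = (
            gains[G_SCTX_MCTX] * y[SCTX, c]
            + gains[G_VL_MCTX] * y[VL, c]
            + gains[G_MCTX_REC] * y[MCTX, c]
        )
        I[D1, c] = (1.0 + lam) * (w_mot[0, c] * y[MCTX, c] + w_sen[0, c] * y[SCTX, c])
        I[D2, c] = (1.0 - lam) * (w_mot[1, c] * y[MCTX, c] + w_sen[1, c] * y[SCTX, c])
        I[STN, c] = gains[G_MCTX_STN] * y[MCTX, c] - gains[G_GPE_STN] * y[GPE, c]
        I[GPE, c] = gains[G_STN_GPE] * y_stn_sum - gains[G_D2_GPE] * y[D2, c]
        I[GPI, c] = (
            gains[G_STN_GPI] * y_stn_sum
            - gains[G_D1_GPI] * y[D1, c]
            - gains[G_GPE_GPI] * y[GPE, c]
        )
        trn_other = y_trn_sum - y[TRN, c]
        I[VL, c] = (
            gains[G_MCTX_VL] * y[MCTX, c]
            - gains[G_GPI_VL] * y[GPI, c]
            - gains[G_TRN_VL_LOCAL] * y[TRN, c]
            - gains[G_TRN_VL_DISTAL] * trn_other
        )
        I[TRN, c] = (
            gains[G_MCTX_TRN] * y[MCTX, c]
            + gains[G_VL_TRN] * y[VL, c]
            - gains[G_GPI_TRN] * y[GPI, c]
        )
        I[BS, c] = gains[G_MCTX_BS] * y[MCTX, c] - gains[G_GPI_BS] * y[GPI, c]

    k = dt / tau
    for p in range(N_POP):
        for c in range(nc):
            a[p, c] += k * (I[p, c] - a[p, c])


def step_network(
    state: NetworkState,
    saliences: np.ndarray,
    weights: CorticoStriatalWeights,
    dt: float,
    gains: np.ndarray | None = None,
    noise: np.ndarray | None = None,
) -> NetworkState:
    """One integration step of the full network (returns the mutated state)."""
    if dt > state.tau:
        raise ValueError("dt must not exceed tau")
    if gains is None:
        gains = default_gains()
    sal = np.asarray(saliences, dtype=float)
    if noise is None:
        noise = np.zeros_like(sal)
    step_kernel(
        state.a, sal, noise, weights.motor, weights.sensory,
        weights.lam, state.eps, gains, dt, state.tau,
    )
    if not np.all(np.isfinite(state.a)):
        raise FloatingPointError("non-finite network activation: bad parameterization")
    return state


def select_actions(y_bs: np.ndarray, phi: float = 0.5) -> set[int]:
    """Channels whose brainstem output exceeds the selection threshold phi."""
    return {int(i) for i in np.flatnonzero(np.asarray(y_bs) > phi)}


def run_to_equilibrium(
    state: NetworkState,
    saliences: np.ndarray,
    weights: CorticoStriatalWeights,
    dt: float = 0.01,
    duration: float = 1.0,
    gains: np.ndarray | None = None,
) -> NetworkState:
    """Hold saliences constant and integrate for ``duration`` seconds."""
    n = int(round(duration / dt))
    for _ in range(n):
        step_network(state, saliences, weights, dt, gains=gains)
    return state


# ---------------------------------------------------------------------------
# calibration
# ---------------------------------------------------------------------------


class CalibrationError(RuntimeError):
    """Raised when no motor-weight value makes every action cleanly selectable."""


def selection_battery(
    weights: CorticoStriatalWeights,
    gains: np.ndarray | None = None,
    phi: float = 0.5,
    grid: np.ndarray | None = None,
    dt: float = 0.01,
    settle: float = 1.0,
) -> tuple[bool, list[str]]:
    """Static selection-competence test.

    For salience pairs (s1, s2) on a grid with the third channel at zero, the
    selected channel (if any) must carry the larger salience, every channel
    must be selectable on its own, and clearly distinct saliences must not
    yield sustained dual selection.  Returns (passed, failure descriptions).
    """
    if grid is None:
        grid = np.linspace(0.0, 1.0, 6)
    failures: list[str] = []

    # each channel selectable when its salience dominates
    for ch in range(N_CHANNELS):
        sal = np.full(N_CHANNELS, 0.1)
        sal[ch] = 0.8
        st = run_to_equilibrium(NetworkState(), sal, weights, dt, settle, gains)
        sel = select_actions(st.outputs()[BS], phi)
        if sel != {ch}:
            failures.append(f"channel {ch} not cleanly selectable: selected={sel}")

    # winner = larger salience on the grid
    for s1 in grid:
        for s2 in grid:
            sal = np.array([s1, s2, 0.0])
            st = run_to_equilibrium(NetworkState(), sal, weights, dt, settle, gains)
            sel = select_actions(st.outputs()[BS], phi)
            if sel:
                winner = max(sel)
                want = 0 if s1 >= s2 else 1
                if abs(s1 - s2) > 1e-9 and (0 if s1 > s2 else 1) not in sel:
                    failures.append(
                        f"saliences ({s1:.2f},{s2:.2f}): winner missing, selected={sel}"
                    )
                if abs(s1 - s2) >= 0.2 and len(sel) > 1:
                    failures.append(
                        f"saliences ({s1:.2f},{s2:.2f}): sustained dual selection {sel}"
                    )
                del winner, want

    # mid-run switching: raising the rival's salience well above the
    # incumbent's must hand over the selection (behavioural maintenance makes
    # an engaged channel sticky, so interruption needs a clearly higher
    # salience, as with a high exploration drive)
    st = run_to_equilibrium(NetworkState(), np.array([0.4, 0.1, 0.0]), weights,
                            dt, settle, gains)
    run_to_equilibrium(st, np.array([0.4, 0.8, 0.0]), weights, dt, 2.0, gains)
    if select_actions(st.outputs()[BS], phi) != {1}:
        failures.append("raising channel 2's salience mid-run did not switch selection")

    # rest state: nothing selected, GPi/SNr tonically positive
    st = run_to_equilibrium(NetworkState(), np.zeros(N_CHANNELS), weights, dt, settle, gains)
    if select_actions(st.outputs()[BS], phi):
        failures.append("rest state selects an action")
    if np.any(st.outputs()[GPI] <= 0):
        failures.append("GPi/SNr output not tonically positive at rest")

    return (not failures, failures)


def calibrate_motor_weights(
    lam: float = 0.2,
    gains: np.ndarray | None = None,
    phi: float = 0.5,
    candidates: np.ndarray | None = None,
) -> CorticoStriatalWeights:
    """Initial motor-weight calibration session.

    Sweeps a ladder of symmetric motor-weight values and returns the first
    that passes the selection battery AND makes every action selectable at a
    moderate lone salience (0.22, the middle of the explore/block operating
    range), emulating the pre-experiment learning session that endows the
    agent with the ability to perform (and have selected) each of its three
    actions.  Sensory weights are left at zero.
    """
    if candidates is None:
        candidates = np.arange(0.35, 0.95, 0.1)
    diagnostics = []
    for w in candidates:
        weights = CorticoStriatalWeights.initial(motor_value=float(w), lam=lam)
        ok, failures = selection_battery(weights, gains=gains, phi=phi)
        if ok:
            for ch in range(N_CHANNELS):
                sal = np.zeros(N_CHANNELS)
                sal[ch] = 0.22
                st = run_to_equilibrium(NetworkState(), sal, weights, gains=gains)
                if select_actions(st.outputs()[BS], phi) != {ch}:
                    ok = False
                    failures.append(f"channel {ch} not selectable at salience 0.45")
                    break
        if ok:
            return weights
        diagnostics.append(f"w={w:.2f}: {failures[:2]}")
    raise CalibrationError(
        "no motor-weight value passed the selection battery:\n" + "\n".join(diagnostics)
    )
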