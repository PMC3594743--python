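"""Phenomenological prediction of the phasic outcome, and salience generation.

The light flash delivered on interaction with the active block is represented
by a binary feature ``y_f``.  A latent prediction ``y`` in [0, 1] is stored
per block and updated recursively after each interaction with that block:
a delivered flash pulls the prediction up,

    y <- 1 - k (1 - y),        (first-ever flash sets y = 0.2)

while a flash omitted despite a non-zero prediction decays it,

    y <- k y,

with ``k = 0.95``.  Between interaction events the latent prediction is
constant; at an event the phasic prediction read-out ``y*`` equals the latent
value.

Novelty salience is a tent map of the phasic prediction — maximal (0.5) when
the outcome is completely uncertain (y* = 0.5) and zero for firm predictions
(y* = 0 or 1).  Intrinsic block salience habituates geometrically: within a
day by ``gamma_b`` per completed interaction, and across days the first-
interaction value of the previous day is multiplied by ``gamma_a``, which
typically recovers (dishabituates) salience relative to the end of the
previous day.  The exploratory action's salience is an internal motivation
drawn from Uniform(0, 0.8), i.e. mean 0.4 and standard deviation 0.8/sqrt(12)
~= 0.231.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

BLOCKS = ("red", "white")


@dataclass
class PredictionState:
    """Latent prediction per block plus the first-event bookkeeping."""

    k: float = 0.95
    first_flash_value: float = 0.2
    y_latent: dict[str, float] = field(
        default_factory=lambda: {b: 0.0 for b in BLOCKS}
    )
    seen_first_event: dict[str, bool] = field(
        default_factory=lambda: {b: False for b in BLOCKS}
    )

    def __post_init__(self) -> None:
        if not 0 < self.k < 1:
            raise ValueError(f"k must satisfy 0 < k < 1, got {self.k}")


@dataclass
class SalienceState:
    """Intrinsic and novelty salience per block, with habituation factors."""

    s_init: float = 0.45
    gamma_a: float = 0.95
    gamma_b: float = 0.95
    s_int: dict[str, float] = field(init=False)
    s_nov: dict[str, float] = field(init=False)
    s_day_start: dict[str, float] = field(init=False)

    def __post_init__(self) -> None:
        self.s_int = {b: self.s_init for b in BLOCKS}
        self.s_nov = {b: 0.0 for b in BLOCKS}
        self.s_day_start = {b: self.s_init for b in BLOCKS}


def update_prediction(
    y_latent: float,
    outcome: str,
    k: float = 0.95,
    seen_first_event: bool = True,
    first_flash_value: float = 0.2,
) -> float:
    """Recursive prediction update after an interaction with the block.

    ``outcome`` is ``"flash"`` or ``"omission"``.  The omission decay only
    applies when there is a non-zero prediction to disappoint.
    """
    if outcome == "flash":
        if not seen_first_event:
            return first_flash_value
        return 1.0 - k * (1.0 - y_latent)
    if outcome == "omission":
        return k * y_latent if y_latent > 0 else y_latent
    raise ValueError(f"outcome must be 'flash' or 'omission', got {outcome!r}")


def phasic_prediction(y_latent: float) -> float:
    """Phasic manifestation of the latent prediction at an interaction event."""
    return y_latent


def novelty_salience(y_star: float) -> float:
    """Tent map: 0.5 - |y* - 0.5|; maximal at total outcome uncertainty."""
    return 0.5 - abs(y_star - 0.5)


def habituate_within_day(s_int: float, gamma_b: float = 0.95) -> float:
    """Geometric decrement applied after each completed block interaction."""
    return gamma_b * s_int


def dishabituate_across_days(s_day_start_prev: float, gamma_a: float = 0.95) -> float:
    """Day-start re-initialization from the previous day's FIRST-interaction
    value (not its last), which yields overnight recovery of salience."""
    return gamma_a * s_day_start_prev


def total_salience(s_int: float, s_nov: float) -> float:
    """Total block salience: intrinsic plus novelty contribution."""
    return s_int + s_nov


def explore_salience(
    rng: np.random.Generator, low: float = 0.0, high: float = 0.8
) -> float:
    """One draw of the exploration salience (uniform; mean 0.4, sd ~0.231)."""
    return float(rng.uniform(low, high))
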