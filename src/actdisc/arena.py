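"""Kinematic 2D arena and the embedding action subsystems.

The arena is a bounded square (60 x 60 length units) with two static blocks
against opposite walls: a red (active) block carrying a flashable point light,
and a white (inactive) block.  The agent is a differential-drive disc robot
(radius 2.8) whose pose advances with standard two-wheel kinematics; walls and
blocks are impenetrable (positions are clamped, there is no physics).

Three action subsystems generate wheel commands z = (z_l, z_r):

* ``explore`` — wander with heading redraws and proximity steering away from
  walls and blocks; it never produces block interactions.
* ``interact_red`` / ``interact_white`` — a fixed interaction sequence run by
  a small finite-state machine: orient -> approach -> bump -> back off ->
  stop -> slow re-approach; the second contact completes the interaction.

When several subsystems are selected simultaneously their commands are
averaged (motor blending); when none is selected the agent halts.  A bump on
the red block queries the reinforcement schedule: FR1 flashes at every bump,
VI only when the availability timer (exponential intervals, mean 120 s) has
armed, and bumps on the white block never flash.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from actdisc.config import ArenaConfig

# FSM stages of the interaction subsystems
ORIENT, APPROACH, BACKOFF, STOP, REAPPROACH = 0, 1, 2, 3, 4
STAGE_TIMEOUT = (4.0, 12.0, 1e9, 1e9, 8.0)  # BACKOFF/STOP end by duration


@njit
def wrap_angle(a: float) -> float:
    """Wrap an angle to (-pi, pi]."""
    return (a + math.pi) % (2.0 * math.pi) - math.pi


@njit
def rect_distance(x: float, y: float, xmin: float, ymin: float,
                  xmax: float, ymax: float) -> float:
    """Euclidean distance from a point to an axis-aligned rectangle."""
    dx = max(xmin - x, 0.0, x - xmax)
    dy = max(ymin - y, 0.0, y - ymax)
    return math.hypot(dx, dy)


@njit
def diff_drive(x: float, y: float, th: float, zl: float, zr: float,
               dt: float, axle: float) -> tuple[float, float, float]:
    """One step of two-wheel kinematics (speeds in length units / s)."""
    v = 0.5 * (zl + zr)
    om = (zr - zl) / axle
    return (x + v * math.cos(th) * dt, y + v * math.sin(th) * dt,
            wrap_angle(th + om * dt))


@njit
def clamp_position(x: float, y: float, r: float, size: float,
                   rects: np.ndarray) -> tuple[float, float]:
    """Clamp the agent inside the walls and outside the block rectangles."""
    x = min(max(x, r), size - r)
    y = min(max(y, r), size - r)
    for i in range(rects.shape[0]):
        xmin, ymin, xmax, ymax = rects[i, 0], rects[i, 1], rects[i, 2], rects[i, 3]
        if rect_distance(x, y, xmin, ymin, xmax, ymax) < r:
            cx = min(max(x, xmin), xmax)
            cy = min(max(y, ymin), ymax)
            dx, dy = x - cx, y - cy
            n = math.hypot(dx, dy)
            if n > 1e-12:
                x = cx + dx / n * r
                y = cy + dy / n * r
            else:  # centre inside the block: push toward the arena centre
                x = cx
                y = ymin - r if cy > size * 0.5 else ymax + r
    return x, y


@njit
def visible(x: float, y: float, th: float, bx: float, by: float,
            fov_half: float, fov_range: float) -> bool:
    """Block visibility: within the forward field-of-view cone and range."""
    dx, dy = bx - x, by - y
    if math.hypot(dx, dy) > fov_range:
        return False
    return abs(wrap_angle(math.atan2(dy, dx) - th)) <= fov_half


@njit
def interact_fsm_step(stage: int, t_stage: float, x: float, y: float,
                      th: float, rect: np.ndarray, agent_r: float,
                      contact: float, v_approach: float, v_backoff: float,
                      v_reapproach: float, v_max: float, turn_gain: float,
                      backoff_time: float, stop_time: float, dt: float):
    """Advance one interaction FSM by dt.

    Returns (zl, zr, stage, t_stage, bump, complete); ``bump`` marks the
    first contact of the sequence, ``complete`` the end of the sequence.
    """
    bx = 0.5 * (rect[0] + rect[2])
    by = 0.5 * (rect[1] + rect[3])
    err = wrap_angle(math.atan2(by - y, bx - x) - th)
    dist = rect_distance(x, y, rect[0], rect[1], rect[2], rect[3])
    in_contact = dist < agent_r + contact
    zl = 0.0
    zr = 0.0
    bump = False
    complete = False
    t_stage += dt

    if stage == ORIENT:
        c = min(max(turn_gain * err, -v_max), v_max)
        zl, zr = -c, c
        if abs(err) < 0.15:
            stage, t_stage = APPROACH, 0.0
        elif t_stage > STAGE_TIMEOUT[ORIENT]:
            t_stage = 0.0
    elif stage == APPROACH:
        c = min(max(turn_gain * err, -0.5 * v_approach), 0.5 * v_approach)
        zl, zr = v_approach - c, v_approach + c
        if in_contact:
            bump = True
            stage, t_stage = BACKOFF, 0.0
        elif t_stage > STAGE_TIMEOUT[APPROACH]:
            stage, t_stage = ORIENT, 0.0
    elif stage == BACKOFF:
        zl = zr = -v_backoff
        if t_stage >= backoff_time:
            stage, t_stage = STOP, 0.0
    elif stage == STOP:
        if t_stage >= stop_time:
            stage, t_stage = REAPPROACH, 0.0
    else:  # REAPPROACH
        c = min(max(turn_gain * err, -0.5 * v_reapproach), 0.5 * v_reapproach)
        zl, zr = v_reapproach - c, v_reapproach + c
        if in_contact:
            complete = True
            stage, t_stage = ORIENT, 0.0
        elif t_stage > STAGE_TIMEOUT[REAPPROACH]:
            stage, t_stage = ORIENT, 0.0

    zl = min(max(zl, -v_max), v_max)
    zr = min(max(zr, -v_max), v_max)
    return zl, zr, stage, t_stage, bump, complete


@njit
def explore_command(psi: float, x: float, y: float, th: float,
                    v_explore: float, v_max: float,
                    turn_gain: float) -> tuple[float, float]:
    """Wheel speeds steering toward the current wander heading psi."""
    err = wrap_angle(psi - th)
    c = min(max(turn_gain * err, -v_explore), v_explore)
    zl = min(max(v_explore - c, -v_max), v_max)
    zr = min(max(v_explore + c, -v_max), v_max)
    return zl, zr


@njit
def near_obstacle(x: float, y: float, size: float, rects: np.ndarray,
                  avoid: float) -> bool:
    if x < avoid or x > size - avoid or y < avoid or y > size - avoid:
        return True
    for i in range(rects.shape[0]):
        if rect_distance(x, y, rects[i, 0], rects[i, 1], rects[i, 2],
                         rects[i, 3]) < avoid:
            return True
    return False


# ---------------------------------------------------------------------------
# python-level containers and spec operations
# ---------------------------------------------------------------------------


@dataclass
class ArenaState:
    """Static geometry plus agent pose and light state."""

    config: ArenaConfig = field(default_factory=ArenaConfig)
    x: float = 30.0
    y: float = 30.0
    heading: float = 0.0
    flash_remaining: float = 0.0

    @property
    def red_rect(self) -> np.ndarray:
        c = self.config
        half = c.block_half_width
        return np.array([c.size / 2 - half, c.size - c.block_depth,
                         c.size / 2 + half, c.size])

    @property
    def white_rect(self) -> np.ndarray:
        c = self.config
        half = c.block_half_width
        return np.array([c.size / 2 - half, 0.0, c.size / 2 + half,
                         c.block_depth])

    @property
    def rects(self) -> np.ndarray:
        return np.vstack((self.red_rect, self.white_rect))

    def block_center(self, block: str) -> tuple[float, float]:
        r = self.red_rect if block == "red" else self.white_rect
        return 0.5 * (r[0] + r[2]), 0.5 * (r[1] + r[3])


def step_kinematics(pose: tuple[float, float, float],
                    z: tuple[float, float], dt: float,
                    arena: ArenaState) -> tuple[float, float, float]:
    """Advance the agent pose, clamped at walls and blocks."""
    c = arena.config
    x, y, th = diff_drive(pose[0], pose[1], pose[2], z[0], z[1], dt,
                          c.axle_length)
    x, y = clamp_position(x, y, c.agent_radius, c.size, arena.rects)
    return x, y, th


def perceive(pose: tuple[float, float, float],
             arena: ArenaState) -> dict[str, bool | int]:
    """Per-block visibility plus the flash feature y_f.

    The flash is a bright point light and is perceived arena-wide regardless
    of heading; block visibility needs the field-of-view cone.
    """
    c = arena.config
    fov = math.radians(c.fov_half_angle_deg)
    out: dict[str, bool | int] = {}
    for block in ("red", "white"):
        bx, by = arena.block_center(block)
        out[block] = visible(pose[0], pose[1], pose[2], bx, by, fov,
                             c.fov_range)
    out["y_f"] = 1 if arena.flash_remaining > 0 else 0
    return out


def blend_motors(commands: list[tuple[float, float]]) -> tuple[float, float]:
    """Component-wise mean of the selected subsystems' commands; zero when
    nothing is selected."""
    if not commands:
        return (0.0, 0.0)
    zl = sum(c[0] for c in commands) / len(commands)
    zr = sum(c[1] for c in commands) / len(commands)
    return (zl, zr)


@dataclass
class ScheduleState:
    """Reinforcement schedule: FR1 (always armed) or VI (arms after an
    exponential interval, mean ``vi_mean`` seconds)."""

    kind: str = "vi"
    vi_mean: float = 120.0
    armed: bool = False
    next_arm_time: float = 0.0

    def start(self, t: float, rng: np.random.Generator) -> None:
        if self.kind == "vi":
            self.armed = False
            self.next_arm_time = t + rng.exponential(self.vi_mean)

    def tick(self, t: float) -> None:
        if self.kind == "vi" and not self.armed and t >= self.next_arm_time:
            self.armed = True


def schedule_gate(schedule: ScheduleState, block: str, t: float,
                  rng: np.random.Generator) -> bool:
    """Decide whether a bump event triggers the light flash."""
    if block != "red":
        return False
    if schedule.kind == "fr1":
        return True
    schedule.tick(t)
    if schedule.armed:
        schedule.armed = False
        schedule.next_arm_time = t + rng.exponential(schedule.vi_mean)
        return True
    return False


@dataclass
class ActionSubsystem:
    """One embedding-architecture behaviour with its FSM state and command."""

    id: str  # "explore" | "interact_red" | "interact_white"
    stage: int = ORIENT
    t_stage: float = 0.0
    psi: float = 0.0  # wander heading (explore only)
    z: tuple[float, float] = (0.0, 0.0)

    def reset(self) -> None:
        self.stage = ORIENT
        self.t_stage = 0.0

    def step(self, pose: tuple[float, float, float], arena: ArenaState,
             dt: float, rng: np.random.Generator | None = None) -> dict:
        """Advance the subsystem by dt; returns {'z', 'bump', 'complete'}."""
        c = arena.config
        if self.id == "explore":
            if rng is not None and near_obstacle(pose[0], pose[1], c.size,
                                                 arena.rects, c.avoid_dist):
                cx = c.size / 2 - pose[0]
                cy = c.size / 2 - pose[1]
                self.psi = math.atan2(cy, cx) + rng.uniform(-0.5, 0.5)
            self.z = explore_command(self.psi, pose[0], pose[1], pose[2],
                                     c.speed_explore, c.speed_max,
                                     c.turn_gain)
            return {"z": self.z, "bump": False, "complete": False}
        rect = arena.red_rect if self.id == "interact_red" else arena.white_rect
        zl, zr, self.stage, self.t_stage, bump, complete = interact_fsm_step(
            self.stage, self.t_stage, pose[0], pose[1], pose[2], rect,
            c.agent_radius, c.contact_dist, c.speed_approach,
            c.speed_backoff, c.speed_reapproach, c.speed_max, c.turn_gain,
            c.backoff_time, c.stop_time, dt)
        self.z = (zl, zr)
        return {"z": self.z, "bump": bump, "complete": complete}
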