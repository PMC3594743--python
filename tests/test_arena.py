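"""Arena kinematics, perception, subsystem FSMs, blending and schedules."""

import math

import numpy as np
import pytest

from actdisc import arena as ar
from actdisc.config import ArenaConfig


@pytest.fixture
def world():
    return ar.ArenaState()


class TestKinematics:
    def test_equal_speeds_straight_line(self, world):
        x, y, th = ar.step_kinematics((30.0, 30.0, 0.0), (5.0, 5.0), 0.1, world)
        assert y == pytest.approx(30.0)
        assert th == pytest.approx(0.0)
        assert x == pytest.approx(30.5)

    def test_opposite_speeds_pure_rotation(self, world):
        x, y, th = ar.step_kinematics((30.0, 30.0, 0.0), (-3.0, 3.0), 0.1, world)
        assert (x, y) == (30.0, 30.0)
        assert th > 0

    def test_wall_clamp(self, world):
        x, y, th = ar.step_kinematics((3.0, 30.0, math.pi), (10.0, 10.0), 1.0,
                                      world)
        assert x >= world.config.agent_radius
        assert 0 + world.config.agent_radius <= y <= 60 - world.config.agent_radius

    def test_block_is_impenetrable(self, world):
        # drive straight at the red block (top wall, centred)
        pose = (30.0, 50.0, math.pi / 2)
        for _ in range(200):
            pose = ar.step_kinematics(pose, (8.0, 8.0), 0.05, world)
        dist = ar.rect_distance(pose[0], pose[1], *world.red_rect)
        assert dist >= world.config.agent_radius - 1e-9


class TestPerception:
    def test_facing_block_within_range_visible(self, world):
        percept = ar.perceive((30.0, 45.0, math.pi / 2), world)
        assert percept["red"] is True
        assert percept["white"] is False

    def test_facing_away_sees_nothing(self, world):
        percept = ar.perceive((30.0, 45.0, -math.pi / 2), world)
        assert percept["red"] is False
        # white block is out of range (40) from y=45
        assert percept["white"] is False

    def test_flash_perceived_regardless_of_heading(self, world):
        world.flash_remaining = 0.1
        for heading in (0.0, math.pi, -math.pi / 2):
            assert ar.perceive((30.0, 30.0, heading), world)["y_f"] == 1
        world.flash_remaining = 0.0
        assert ar.perceive((30.0, 30.0, 0.0), world)["y_f"] == 0


class TestBlending:
    def test_single_command_unchanged(self):
        assert ar.blend_motors([(3.0, 4.0)]) == (3.0, 4.0)

    def test_opposite_commands_cancel(self):
        assert ar.blend_motors([(5.0, 5.0), (-5.0, -5.0)]) == (0.0, 0.0)

    def test_empty_selection_halts(self):
        assert ar.blend_motors([]) == (0.0, 0.0)

    def test_blend_respects_speed_bounds(self):
        cfg = ArenaConfig()
        z = ar.blend_motors([(cfg.speed_max, cfg.speed_max),
                             (cfg.speed_max, -cfg.speed_max)])
        assert abs(z[0]) <= cfg.speed_max and abs(z[1]) <= cfg.speed_max


class TestInteractionFSM:
    def test_bump_and_completion_within_bounded_time(self, world):
        """Facing the red block from nearby, the full sequence (bump,
        back-off, stop, re-approach) completes within a bounded time."""
        sub = ar.ActionSubsystem("interact_red")
        pose = (30.0, 50.0, math.pi / 2)
        bumped = completed = False
        t = 0.0
        while t < 30.0 and not completed:
            out = sub.step(pose, world, 0.01)
            pose = ar.step_kinematics(pose, out["z"], 0.01, world)
            bumped = bumped or out["bump"]
            completed = completed or out["complete"]
            t += 0.01
        assert bumped and completed
        assert t < 20.0

    def test_deselection_resets_sequence(self, world):
        sub = ar.ActionSubsystem("interact_red")
        sub.stage = ar.BACKOFF
        sub.t_stage = 0.3
        sub.reset()
        assert sub.stage == ar.ORIENT and sub.t_stage == 0.0

    def test_explore_emits_no_interactions(self, world, rng):
        """A minute of exploration steers off obstacles, never penetrates a
        block and never emits bump/interaction events."""
        sub = ar.ActionSubsystem("explore", psi=rng.uniform(-math.pi, math.pi))
        pose = (30.0, 30.0, 0.0)
        min_dist = np.inf
        for i in range(6000):
            if i % 300 == 0:
                sub.psi = rng.uniform(-math.pi, math.pi)
            out = sub.step(pose, world, 0.01, rng=rng)
            pose = ar.step_kinematics(pose, out["z"], 0.01, world)
            for rect in (world.red_rect, world.white_rect):
                min_dist = min(min_dist, ar.rect_distance(pose[0], pose[1],
                                                          *rect))
            assert not out["bump"] and not out["complete"]
        # collision clamping keeps the body outside the blocks throughout
        assert min_dist > world.config.agent_radius - 0.2


class TestSchedules:
    def test_fr1_always_flashes_on_red(self, rng):
        sched = ar.ScheduleState(kind="fr1")
        assert all(ar.schedule_gate(sched, "red", t, rng) for t in range(10))

    def test_white_never_flashes(self, rng):
        for kind in ("fr1", "vi"):
            sched = ar.ScheduleState(kind=kind)
            sched.armed = True
            assert not ar.schedule_gate(sched, "white", 0.0, rng)

    def test_vi_premature_bump_unreinforced(self, rng):
        sched = ar.ScheduleState(kind="vi", vi_mean=120.0)
        sched.start(0.0, rng)
        early = sched.next_arm_time / 2
        assert not ar.schedule_gate(sched, "red", early, rng)
        assert ar.schedule_gate(sched, "red", sched.next_arm_time + 1.0, rng)

    def test_vi_flash_rate_bounded_by_mean_interval(self, rng):
        """Bumping continuously, expected flashes <= duration / mean."""
        sched = ar.ScheduleState(kind="vi", vi_mean=120.0)
        sched.start(0.0, rng)
        duration = 360_000.0
        flashes = sum(ar.schedule_gate(sched, "red", t, rng)
                      for t in np.arange(0.0, duration, 1.0))
        assert flashes <= 1.1 * duration / 120.0
        assert flashes > 0.5 * duration / 120.0
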