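"""Simulated teleoperation tasks and their operational-quality rewards.

Two desk-scale tasks on a continuous 2-D plane (dimensionless units):

* trajectory tracking — drag the robot along a preset polyline
  (straight, slope or curve difficulty); quality combines accumulated
  trajectory deviation and completion time,
  R_t = 1 / (sum |Y_m - O_m| + eps) + g*t + offset.
* target positioning — keep the sight's frame fully enclosing a
  randomly placed bullseye for a continuous lock duration T; quality is
  time-based, R_p = g*t + offset once the lock succeeds.

The time-gain coefficient g defaults to a negative value so shorter
completion times score higher; the positive offset keeps rewards
positive for feasible rounds. The step clock equals the 2000 ms
feature-window cadence so a nominal round yields 50 decision steps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidInputError, InvalidStateError

#: Step duration (s): one mental-state feature window per control step.
DT = 2.0
#: Nominal decision steps per round.
STEPS_PER_ROUND = 50

DEVIATION_EPS = 1e-6
DEFAULT_G = -0.004
DEFAULT_OFFSET = 1.0

DIFFICULTIES = ("straight", "slope", "curve")


@dataclass
class ControlCommand:
    """Operator 2-D displacement intent for one step (mouse surrogate)."""

    dx: float
    dy: float

    def as_array(self) -> np.ndarray:
        return np.array([self.dx, self.dy])


def make_trajectory(
    difficulty: str = "straight", length: float = 50.0, n_points: int = 200
) -> np.ndarray:
    """Preset target polyline for the tracking task.

    straight: horizontal line; slope: an inclined ramp with entry and
    exit direction changes; curve: sine arc. Scaled so a unit-speed
    robot traverses it in ~STEPS_PER_ROUND steps.
    """
    if difficulty not in DIFFICULTIES:
        raise InvalidInputError(f"unknown difficulty {difficulty!r}")
    if difficulty == "slope":
        corners = np.array([[0.0, 0.0], [8.0, 0.0], [28.0, 20.0], [36.0, 20.0]])
        corners *= length / 50.0
        # densify so deviation sampling matches the other paths
        parts = []
        per = max(n_points // (len(corners) - 1), 2)
        for a, b in zip(corners[:-1], corners[1:]):
            parts.append(a + np.linspace(0, 1, per)[:, None] * (b - a))
        return np.vstack([p[:-1] for p in parts[:-1]] + [parts[-1]])
    x = np.linspace(0.0, length, n_points)
    if difficulty == "straight":
        y = np.zeros_like(x)
    else:  # curve
        y = 5.0 * np.sin(2.0 * np.pi * x / length * 2.0)
    return np.column_stack([x, y])


def _point_to_polyline(p: np.ndarray, poly: np.ndarray) -> tuple[float, float]:
    """(distance to nearest segment, arc-length of the projection).

    The final segment is treated as extending past the endpoint, so
    overrunning the finish line along the path direction counts as
    completed progress, not as tracking deviation.
    """
    a = poly[:-1]
    b = poly[1:]
    ab = b - a
    seg_len2 = np.einsum("ij,ij->i", ab, ab)
    tpar = np.einsum("ij,ij->i", p - a, ab) / np.maximum(seg_len2, 1e-12)
    hi = np.ones(len(tpar))
    hi[-1] = np.inf  # last segment extended beyond the endpoint
    tpar = np.clip(tpar, 0.0, hi)
    proj = a + tpar[:, None] * ab
    d = np.linalg.norm(p - proj, axis=1)
    k = int(np.argmin(d))
    seg_len = np.sqrt(seg_len2)
    arc = float(np.sum(seg_len[:k]) + tpar[k] * seg_len[k])
    return float(d[k]), arc


def reward_tracking(
    deviation_sum: float,
    t: float,
    g: float = DEFAULT_G,
    offset: float = DEFAULT_OFFSET,
    eps: float = DEVIATION_EPS,
) -> float:
    """R_t = 1/(sum deviation + eps) + g*t + offset."""
    if t <= 0:
        raise InvalidInputError(f"completion time must be positive, got {t}")
    if deviation_sum < 0:
        raise InvalidInputError("deviation sum must be nonnegative")
    return 1.0 / (deviation_sum + eps) + g * t + offset


def reward_positioning(
    t: float,
    g: float = DEFAULT_G,
    T: float = 4.0,
    offset: float = DEFAULT_OFFSET,
) -> float:
    """R_p = g*t + offset for a successful round (lock reached after t >= T)."""
    if t < T:
        raise InvalidStateError(
            f"positioning reward undefined before lock: t={t} < T={T}"
        )
    return g * t + offset


@dataclass
class RoundRecord:
    """Everything recorded about one completed round."""

    task: str
    reward: float
    quality: float
    completion_time: float
    deviation_sum: float
    actions: list[int]
    truncated: bool
    positions: np.ndarray = field(repr=False, default=None)


class TrackingEnv:
    """Trajectory-tracking task environment.

    The robot starts at the head of the polyline; each step it moves by
    the operator's intent scaled by the current speed multiplier
    (magnitude-capped), the perpendicular distance to the polyline is
    accumulated, and the round ends when the projected arc-length
    reaches the end of the path. Unfinished rounds at the step cap are
    scored on the projected completion time (elapsed * length/progress)
    and flagged truncated.
    """

    task_name = "tracking"

    def __init__(
        self,
        difficulty: str = "straight",
        g: float = DEFAULT_G,
        offset: float = DEFAULT_OFFSET,
        dt: float = DT,
        step_cap: int = STEPS_PER_ROUND,
        max_step_size: float = 3.0,
        path: np.ndarray | None = None,
    ) -> None:
        self.difficulty = difficulty
        self.path = make_trajectory(difficulty) if path is None else np.asarray(path)
        if self.path.shape[0] < 2:
            raise InvalidInputError("target polyline needs at least 2 points")
        seg = np.diff(self.path, axis=0)
        self.total_length = float(np.sum(np.linalg.norm(seg, axis=1)))
        self.g, self.offset, self.dt = g, offset, dt
        self.step_cap, self.max_step_size = step_cap, max_step_size
        self.reset()

    def reset(self, rng: np.random.Generator | None = None) -> None:
        self.pos = self.path[0].astype(float).copy()
        self.t = 0.0
        self.steps = 0
        self.deviation_sum = 0.0
        self.progress = 0.0
        self.done = False
        self.truncated = False
        self.positions: list[np.ndarray] = [self.pos.copy()]
        self.actions: list[int] = []

    def guidance(self) -> np.ndarray:
        """Unit vector from the robot toward the path ahead (operator's aim)."""
        target_arc = min(self.progress + 1.5, self.total_length)
        pt = self._point_at_arc(target_arc)
        d = pt - self.pos
        n = np.linalg.norm(d)
        return d / n if n > 1e-9 else np.zeros(2)

    def _point_at_arc(self, arc: float) -> np.ndarray:
        seg = np.diff(self.path, axis=0)
        lens = np.linalg.norm(seg, axis=1)
        cum = np.concatenate([[0.0], np.cumsum(lens)])
        k = int(np.searchsorted(cum, arc, side="right") - 1)
        k = min(k, len(lens) - 1)
        frac = (arc - cum[k]) / max(lens[k], 1e-12)
        return self.path[k] + frac * seg[k]

    def step(self, command: ControlCommand, speed_multiplier: float) -> None:
        if self.done:
            raise InvalidStateError("step after round end")
        disp = command.as_array() * speed_multiplier
        mag = np.linalg.norm(disp)
        if mag > self.max_step_size:
            disp *= self.max_step_size / mag
        self.pos = self.pos + disp
        dist, arc = _point_to_polyline(self.pos, self.path)
        self.deviation_sum += dist
        self.progress = max(self.progress, arc)
        self.t += self.dt
        self.steps += 1
        self.positions.append(self.pos.copy())
        if self.progress >= self.total_length - 1e-9:
            self.done = True
        elif self.steps >= self.step_cap:
            self.done = True
            self.truncated = True

    def truncate(self) -> None:
        """End the round at the step cap; reward uses elapsed state."""
        self.done = True
        self.truncated = True

    def completion_time(self) -> float:
        if not self.done:
            raise InvalidStateError("round still active")
        if self.truncated:
            frac = max(self.progress / self.total_length, 1e-3)
            return self.t / frac  # projected completion time
        return self.t

    def round_reward(self) -> float:
        return reward_tracking(
            self.deviation_sum, self.completion_time(), self.g, self.offset
        )

    def record(self) -> RoundRecord:
        r = self.round_reward()
        return RoundRecord(
            task=self.task_name,
            reward=r,
            quality=operational_quality(r),
            completion_time=self.completion_time(),
            deviation_sum=self.deviation_sum,
            actions=list(self.actions),
            truncated=self.truncated,
            positions=np.asarray(self.positions),
        )


class PositioningEnv:
    """Target-positioning task environment.

    The bullseye is re-randomized each round; the sight must stay
    within the enclosure radius continuously for T seconds. Breaking
    enclosure resets the lock timer. Unsuccessful rounds at the step
    cap are scored on a doubled elapsed time and flagged truncated.
    """

    task_name = "positioning"

    def __init__(
        self,
        g: float = DEFAULT_G,
        offset: float = DEFAULT_OFFSET,
        dt: float = DT,
        step_cap: int = STEPS_PER_ROUND,
        lock_duration: float = 4.0,
        enclosure_radius: float = 1.0,
        arena_radius: float = 25.0,
        max_step_size: float = 3.0,
    ) -> None:
        self.g, self.offset, self.dt = g, offset, dt
        self.step_cap = step_cap
        self.T = lock_duration
        self.enclosure_radius = enclosure_radius
        self.arena_radius = arena_radius
        self.max_step_size = max_step_size
        self.reset(np.random.default_rng(0))

    def reset(self, rng: np.random.Generator | None = None) -> None:
        rng = rng or np.random.default_rng(0)
        ang = rng.uniform(0, 2 * np.pi)
        rad = rng.uniform(0.5, 1.0) * self.arena_radius
        self.bullseye = np.array([rad * np.cos(ang), rad * np.sin(ang)])
        self.pos = np.zeros(2)
        self.t = 0.0
        self.steps = 0
        self.lock = 0.0
        self.success_time: float | None = None
        self.done = False
        self.truncated = False
        self.positions: list[np.ndarray] = [self.pos.copy()]
        self.actions: list[int] = []

    def guidance(self) -> np.ndarray:
        d = self.bullseye - self.pos
        n = np.linalg.norm(d)
        return d / n if n > 1e-9 else np.zeros(2)

    @property
    def enclosed(self) -> bool:
        return bool(np.linalg.norm(self.pos - self.bullseye) < self.enclosure_radius)

    def step(self, command: ControlCommand, speed_multiplier: float) -> None:
        if self.done:
            raise InvalidStateError("step after round end")
        disp = command.as_array() * speed_multiplier
        mag = np.linalg.norm(disp)
        if mag > self.max_step_size:
            disp *= self.max_step_size / mag
        self.pos = self.pos + disp
        self.t += self.dt
        self.steps += 1
        self.positions.append(self.pos.copy())
        if self.enclosed:
            self.lock += self.dt
        else:
            self.lock = 0.0
        if self.lock >= self.T:
            self.done = True
            self.success_time = self.t
        elif self.steps >= self.step_cap:
            self.done = True
            self.truncated = True

    def truncate(self) -> None:
        """End the round at the step cap; reward uses elapsed state."""
        self.done = True
        self.truncated = True

    def completion_time(self) -> float:
        if not self.done:
            raise InvalidStateError("round still active")
        if self.truncated:
            return 2.0 * self.t  # failure penalty: doubled elapsed time
        return float(self.success_time)

    def round_reward(self) -> float:
        t = self.completion_time()
        if self.truncated:
            return self.g * t + self.offset
        return reward_positioning(t, self.g, self.T, self.offset)

    def record(self) -> RoundRecord:
        r = self.round_reward()
        return RoundRecord(
            task=self.task_name,
            reward=r,
            quality=operational_quality(r),
            completion_time=self.completion_time(),
            deviation_sum=0.0,
            actions=list(self.actions),
            truncated=self.truncated,
            positions=np.asarray(self.positions),
        )


def operational_quality(reward: float) -> float:
    """Round reward mapped to the reporting scale.

    With the default negative g and positive offset the reward already
    lives on a positive quality scale, so the mapping is the identity.
    """
    return float(reward)


def make_env(task: str, difficulty: str = "straight", **kwargs):
    if task == "tracking":
        return TrackingEnv(difficulty=difficulty, **kwargs)
    if task == "positioning":
        return PositioningEnv(**kwargs)
    raise InvalidInputError(f"unknown task {task!r}")
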