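"""Three-session experimental protocol and the conventional baseline.

A protocol run mirrors the human study design at desk scale:

* training session — 18 rounds (3 practice + 15 formal) of closed-loop
  policy-gradient learning; the trained parameters are frozen.
* testing session — 15 rounds with the frozen policy, learning off.
* control session — 15 rounds under the conventional warning-threshold
  method: a scalar mental-state indicator (here the mean EOG low/high
  power ratio of the current window, a low-arousal proxy) is compared
  against a preset threshold; above it the speed is reduced to a fixed
  level, otherwise a fixed normal level is applied. Stateless and
  identical for every operator — the non-personalized contrast.

Testing and control face identically seeded operators so the
comparison of operational quality is like-for-like.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InvalidInputError
from .features import eog_power_ratio
from .policy import DEFAULT_MULTIPLIERS, PolicyParameters, SpeedAction
from .rl import TrainConfig, TrainerState, collect_episode, train_session
from .signals import preprocess
from .tasks import make_env, operational_quality


def conventional_controller(
    mental_indicator: float,
    threshold: float,
    normal_level: int = 1,
    reduced_level: int = 0,
) -> SpeedAction:
    """Warning-threshold speed rule: reduce above threshold, else normal.

    Strict inequality: an indicator exactly at the threshold keeps the
    normal level. Stateless — no hysteresis, no personalization.
    """
    if not np.isfinite(mental_indicator):
        raise InvalidInputError(f"indicator must be finite, got {mental_indicator}")
    level = reduced_level if mental_indicator > threshold else normal_level
    return SpeedAction.from_level(level)


@dataclass
class SessionReport:
    """Per-round records and summaries for one session."""

    kind: str  # training | testing | control
    rewards: list[float] = field(default_factory=list)
    qualities: list[float] = field(default_factory=list)
    times: list[float] = field(default_factory=list)
    action_hists: list[np.ndarray] = field(default_factory=list)
    phases: list[str] = field(default_factory=list)
    velocities: list[np.ndarray] = field(default_factory=list, repr=False)

    def add(self, reward, quality, time, action_hist, phase="formal",
            velocity=None) -> None:
        self.rewards.append(float(reward))
        self.qualities.append(float(quality))
        self.times.append(float(time))
        self.action_hists.append(np.asarray(action_hist))
        self.phases.append(phase)
        if velocity is not None:
            self.velocities.append(np.asarray(velocity))

    @property
    def n_rounds(self) -> int:
        return len(self.rewards)

    def formal_qualities(self) -> np.ndarray:
        return np.array(
            [q for q, p in zip(self.qualities, self.phases) if p == "formal"]
        )

    def early_late_contrast(self, n: int = 3) -> dict:
        """First-n vs last-n formal-round quality summary."""
        q = self.formal_qualities()
        if len(q) < 2 * n:
            raise InvalidInputError(f"need >= {2 * n} formal rounds, have {len(q)}")
        early, late = q[:n], q[-n:]
        return {
            "early_mean": float(early.mean()),
            "late_mean": float(late.mean()),
            "early_sd": float(early.std(ddof=1)),
            "late_sd": float(late.std(ddof=1)),
            "improved": bool(late.mean() > early.mean()),
        }

    def velocity_samples(self) -> np.ndarray:
        """Per-step robot velocity components (n, 2), pooled over rounds."""
        if not self.velocities:
            return np.empty((0, 2))
        return np.vstack(self.velocities)

    def velocity_spread(self) -> float:
        """Pooled standard deviation of the x/y velocity components."""
        v = self.velocity_samples()
        return float(v.std()) if v.size else 0.0

    def speed_samples(self) -> np.ndarray:
        """Applied speed multipliers, one per step, pooled over rounds."""
        mults = np.asarray(DEFAULT_MULTIPLIERS)
        out = []
        for h in self.action_hists:
            out.extend(np.repeat(mults, h.astype(int)))
        return np.asarray(out)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "round": np.arange(self.n_rounds),
                "phase": self.phases,
                "reward": self.rewards,
                "quality": self.qualities,
                "completion_time": self.times,
            }
        )


@dataclass
class ProtocolConfig:
    task: str = "tracking"
    difficulty: str = "straight"
    train: TrainConfig = field(default_factory=TrainConfig)
    testing_rounds: int = 15
    control_rounds: int = 15
    conventional_normal_level: int = 1  # multiplier 1.0 = unadjusted speed
    conventional_reduced_level: int = 0
    threshold_percentile: float = 80.0  # warning = unusually high indicator
    seed: int = 0


def _mean_pr(rec) -> float:
    """Mean EOG power ratio over the window's EOG channels."""
    _, eog = preprocess(rec)
    return float(
        np.mean([eog_power_ratio(eog.samples[:, j], fs=eog.fs) for j in range(2)])
    )


def run_conventional_round(
    env, operator, threshold: float, k: int = 50,
    normal_level: int = 1, reduced_level: int = 0,
) -> dict:
    """One round under the warning-threshold controller."""
    for _ in range(k):
        operator.step((), dt=2.0)
        rec = operator.emit_window(2.0)
        action = conventional_controller(
            _mean_pr(rec), threshold, normal_level, reduced_level
        )
        env.actions.append(action.level)
        cmd = operator.intent(env, action.level)
        env.step(cmd, action.multiplier)
        if env.done:
            break
    if not env.done:
        env.truncate()
    r = env.round_reward()
    return {
        "reward": r,
        "quality": operational_quality(r),
        "time": env.completion_time(),
        "action_hist": np.bincount(env.actions, minlength=4),
    }


@dataclass
class ProtocolResult:
    training: SessionReport
    testing: SessionReport
    control: SessionReport
    theta: PolicyParameters
    trainer: TrainerState
    threshold: float
    comparison: dict = field(default_factory=dict)


def run_protocol(
    profile,
    config: ProtocolConfig | None = None,
) -> ProtocolResult:
    """Run training, testing and control sessions for one operator."""
    from .operator import SyntheticOperator

    cfg = config or ProtocolConfig()
    ss = np.random.SeedSequence(cfg.seed)
    s_train_op, s_matched, s_sess, s_act = ss.spawn(4)
    train_cfg = TrainConfig(**{**asdict(cfg.train), "seed": int(ss.generate_state(1)[0] % (2**31))})

    # --- training session ------------------------------------------------
    op_train = SyntheticOperator(profile, seed=int(s_train_op.generate_state(1)[0] % (2**31)))
    trainer, metrics, normalizer = train_session(
        lambda rng: _fresh_env(cfg, rng), op_train, train_cfg
    )
    training = SessionReport(kind="training")
    pr_samples: list[float] = []
    for m in metrics:
        training.add(m.reward, m.quality, 0.0, m.action_hist, m.phase)

    # conventional warning threshold: a high percentile of the indicator
    # over practice-like rounds, so the alarm fires on unusual states only
    op_thr = SyntheticOperator(profile, seed=int(s_sess.generate_state(1)[0] % (2**31)))
    for _ in range(cfg.train.practice_rounds * 10):
        op_thr.step((), dt=2.0)
        pr_samples.append(_mean_pr(op_thr.emit_window(2.0)))
    threshold = float(np.percentile(pr_samples, cfg.threshold_percentile))

    # --- testing session (frozen theta, matched operator seed) -----------
    matched_seed = int(s_matched.generate_state(1)[0] % (2**31))
    env_rng_t = np.random.default_rng(ss.generate_state(2)[1] % (2**31))
    action_rng = np.random.default_rng(int(s_act.generate_state(1)[0] % (2**31)))
    op_test = SyntheticOperator(profile, seed=matched_seed)
    testing = SessionReport(kind="testing")
    for _ in range(cfg.testing_rounds):
        env = _fresh_env(cfg, env_rng_t)
        op_test.reset_round()
        traj = collect_episode(
            env, op_test, trainer.theta, action_rng,
            k=cfg.train.steps_per_round, normalizer=normalizer,
        )
        testing.add(
            traj.reward, traj.quality, env.completion_time(),
            np.bincount(traj.actions, minlength=4),
            velocity=np.diff(np.asarray(env.positions), axis=0) / env.dt,
        )

    # --- control session (conventional method, matched operator seed) ----
    env_rng_c = np.random.default_rng(ss.generate_state(2)[1] % (2**31))
    op_ctrl = SyntheticOperator(profile, seed=matched_seed)
    control = SessionReport(kind="control")
    for _ in range(cfg.control_rounds):
        env = _fresh_env(cfg, env_rng_c)
        op_ctrl.reset_round()
        rec = run_conventional_round(
            env, op_ctrl, threshold, k=cfg.train.steps_per_round,
            normal_level=cfg.conventional_normal_level,
            reduced_level=cfg.conventional_reduced_level,
        )
        control.add(rec["reward"], rec["quality"], rec["time"], rec["action_hist"])

    result = ProtocolResult(
        training=training,
        testing=testing,
        control=control,
        theta=trainer.theta,
        trainer=trainer,
        threshold=threshold,
    )
    result.comparison = compare_sessions(testing, control)
    if len(training.formal_qualities()) >= 6:
        result.comparison["training_contrast"] = training.early_late_contrast()
    return result


def _fresh_env(cfg: ProtocolConfig, rng: np.random.Generator):
    env = make_env(cfg.task, difficulty=cfg.difficulty)
    env.reset(rng)
    return env


def compare_sessions(testing: SessionReport, control: SessionReport) -> dict:
    """Descriptive means/sds and t statistics on operational quality."""
    a = np.asarray(testing.qualities, dtype=float)
    b = np.asarray(control.qualities, dtype=float)
    if len(a) != len(b):
        raise InvalidInputError(
            f"round counts differ: {len(a)} testing vs {len(b)} control"
        )
    if np.array_equal(a, b):
        two = type("T", (), {"statistic": 0.0, "pvalue": 1.0})
        paired = type("T", (), {"statistic": 0.0, "pvalue": 1.0})
    else:
        two = stats.ttest_ind(a, b)
        paired = stats.ttest_rel(a, b) if len(a) > 1 else None
    return {
        "testing_mean": float(a.mean()),
        "testing_sd": float(a.std(ddof=1)) if len(a) > 1 else 0.0,
        "control_mean": float(b.mean()),
        "control_sd": float(b.std(ddof=1)) if len(b) > 1 else 0.0,
        "mean_difference": float(a.mean() - b.mean()),
        "t_two_sample": float(two.statistic),
        "p_two_sample": float(two.pvalue),
        "t_paired": float(paired.statistic) if paired else float("nan"),
        "p_paired": float(paired.pvalue) if paired else float("nan"),
        "psa_better": bool(a.mean() > b.mean()),
    }
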