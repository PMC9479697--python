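"""Monte-Carlo policy-gradient training of the speed-adaptation policy.

One task round is one episode. At each of the (nominally 50) windowed
steps the operator's signals are preprocessed and turned into the
152-dim state, an action is sampled from the policy, and its speed
multiplier is applied to the environment. The episode's scalar reward
(the round's operational quality) is shared uniformly by all its steps;
the gradient estimator is the baseline-corrected score function

    grad ~ (1/N) sum_n sum_i (R(tau_n) - b) * grad ln p_theta(a_i | s_i)

with b the running mean of observed episode rewards, and parameters
ascend by ADAM (beta1=0.9, beta2=0.999, lr=0.001). The policy is
updated once per episode (N=1 by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidInputError
from .features import FeatureNormalizer, extract_state_vector
from .policy import (
    LEARNING_RATE,
    PARAM_KEYS,
    PolicyParameters,
    adam_update,
    grad_log_prob,
    policy_forward,
    pretrain,
    sample_action,
)
from .signals import preprocess


@dataclass
class EpisodeTrajectory:
    """One round's (state, action) sequence plus its scalar reward."""

    states: np.ndarray  # (k, state_dim)
    actions: list[int]
    reward: float
    episode: int = 0
    truncated: bool = False
    preferred_levels: list[int] = field(default_factory=list)
    quality: float = 0.0

    @property
    def k(self) -> int:
        return len(self.actions)

    def log_probability(self, theta: PolicyParameters) -> float:
        """Sum over steps of ln p_theta(a_i | s_i)."""
        probs = policy_forward(theta, self.states)
        return float(
            np.sum(np.log(probs[np.arange(self.k), np.asarray(self.actions)]))
        )


@dataclass
class TrainerState:
    """Mutable training state: parameters, baseline, reward history."""

    theta: PolicyParameters
    baseline: float | None = None
    reward_history: list[float] = field(default_factory=list)
    episode: int = 0
    lr: float = LEARNING_RATE

    def observe_reward(self, r: float) -> None:
        """Update the running-mean baseline with a new episode reward."""
        self.reward_history.append(float(r))
        self.baseline = float(np.mean(self.reward_history))
        self.episode += 1


def collect_episode(
    env,
    operator,
    theta: PolicyParameters,
    rng: np.random.Generator,
    k: int = 50,
    normalizer: FeatureNormalizer | None = None,
    update_normalizer: bool = False,
    events: dict[int, tuple[str, ...]] | None = None,
    window_s: float = 2.0,
    episode: int = 0,
    exploration_eps: float = 0.0,
) -> EpisodeTrajectory:
    """Run one closed-loop round and return its trajectory.

    Per step: advance the operator's latent state (with any scheduled
    stimulation events), emit a signal window, preprocess + extract the
    state vector, sample an action, and apply its multiplier together
    with the operator's control intent to the environment. Stops early
    if the round ends; otherwise the episode is truncated at ``k``
    steps and the reward is computed on the elapsed round state.

    ``exploration_eps`` mixes a uniform component into the sampling
    distribution (training-time exploration mechanism); the policy's
    own probabilities are what the gradient sees.
    """
    events = events or {}
    states: list[np.ndarray] = []
    actions: list[int] = []
    preferred: list[int] = []
    for i in range(k):
        operator.step(events.get(i, ()), dt=window_s)
        rec = operator.emit_window(window_s)
        eeg, eog = preprocess(rec)
        fv = extract_state_vector(eeg.samples, eog.samples)
        if normalizer is not None:
            if update_normalizer and not normalizer.frozen:
                normalizer.update(fv)
            fv = normalizer.transform(fv)
        probs = policy_forward(theta, fv.values)
        if exploration_eps > 0:
            n_a = probs.shape[0]
            behavior = (1 - exploration_eps) * probs + exploration_eps / n_a
        else:
            behavior = probs
        action = sample_action(behavior, rng)
        states.append(fv.values)
        actions.append(action.level)
        preferred.append(operator.preferred_level())
        env.actions.append(action.level)
        cmd = operator.intent(env, action.level)
        env.step(cmd, action.multiplier)
        if env.done:
            break
    if not env.done:
        env.truncate()
    reward = env.round_reward()
    from .tasks import operational_quality

    return EpisodeTrajectory(
        states=np.asarray(states),
        actions=actions,
        reward=float(reward),
        episode=episode,
        truncated=bool(getattr(env, "truncated", False)),
        preferred_levels=preferred,
        quality=operational_quality(reward),
    )


def policy_gradient(
    trajectories: list[EpisodeTrajectory],
    b: float,
    theta: PolicyParameters,
) -> dict[str, np.ndarray]:
    """Baseline-corrected score-function gradient averaged over episodes."""
    if not trajectories:
        raise InvalidInputError("need at least one trajectory")
    total = {k: np.zeros_like(getattr(theta, k)) for k in PARAM_KEYS}
    for traj in trajectories:
        adv = traj.reward - b
        if adv == 0.0:
            continue
        for s, a in zip(traj.states, traj.actions):
            g = grad_log_prob(theta, s, a)
            for key in PARAM_KEYS:
                total[key] += adv * g[key]
    n = len(trajectories)
    return {key: v / n for key, v in total.items()}


def update_parameters(
    state: TrainerState, gradient: dict[str, np.ndarray]
) -> TrainerState:
    """One ADAM ascent step on the policy parameters."""
    adam_update(state.theta, gradient, lr=state.lr, maximize=True)
    return state


@dataclass
class TrainConfig:
    """Knobs of a training session (desk-scale defaults)."""

    practice_rounds: int = 3
    formal_rounds: int = 15
    steps_per_round: int = 50
    lr: float = LEARNING_RATE
    pretrain_enabled: bool = True
    pretrain_epochs: int = 50
    pretrain_per_class: int = 25
    rest_every: int = 5  # 1-min rest in the middle of every 5 formal rounds
    stimulation_prob: float = 0.3  # per-round chance of a random prompt
    exploration_eps: float = 0.0  # optional uniform mix into training sampling
    seed: int = 0


@dataclass
class EpisodeMetrics:
    episode: int
    phase: str  # practice | formal
    reward: float
    quality: float
    k: int
    action_hist: np.ndarray
    preferred_mode: int
    truncated: bool


def _round_events(
    cfg: TrainConfig, formal_index: int, rng: np.random.Generator
) -> dict[int, tuple[str, ...]]:
    events: dict[int, tuple[str, ...]] = {}
    if formal_index > 0 and formal_index % cfg.rest_every == 0:
        events[0] = ("rest",)
    if rng.random() < cfg.stimulation_prob:
        step = int(rng.integers(0, cfg.steps_per_round))
        kind = str(rng.choice(["positive", "negative", "nervous"]))
        events.setdefault(step, ())
        events[step] = events[step] + (kind,)
    return events


def train_session(
    env_factory,
    operator,
    config: TrainConfig | None = None,
    theta: PolicyParameters | None = None,
    normalizer: FeatureNormalizer | None = None,
) -> tuple[TrainerState, list[EpisodeMetrics], FeatureNormalizer]:
    """Run a full training session: pretraining, practice, formal rounds.

    ``env_factory(rng)`` must return a freshly reset environment for one
    round. Practice rounds (default 3) accumulate feature-normalization
    statistics and update nothing; formal rounds (default 15) each
    perform one collect -> gradient -> ADAM update cycle.
    """
    cfg = config or TrainConfig()
    ss = np.random.SeedSequence(cfg.seed)
    s_init, s_pre, s_act, s_env, s_ev = ss.spawn(5)
    init_rng = np.random.default_rng(s_init)
    action_rng = np.random.default_rng(s_act)
    env_rng = np.random.default_rng(s_env)
    event_rng = np.random.default_rng(s_ev)

    if theta is None:
        theta = PolicyParameters.init(init_rng)
    if normalizer is None:
        normalizer = FeatureNormalizer()
    if cfg.pretrain_enabled:
        from .operator import make_deap_like_dataset

        pre_rng = np.random.default_rng(s_pre)
        X, y = make_deap_like_dataset(
            cfg.pretrain_per_class, pre_rng, profile=operator.profile
        )
        # pretraining and the closed loop share one normalization state:
        # the min-max stats seeded here keep accumulating through the session
        for row in X:
            normalizer.update(row)
        span = normalizer.hi - normalizer.lo
        Xn = np.clip((X - normalizer.lo) / np.where(span > 0, span, 1.0), 0, 1)
        pretrain(theta, Xn, y, epochs=cfg.pretrain_epochs, rng=pre_rng)

    trainer = TrainerState(theta=theta, lr=cfg.lr)
    metrics: list[EpisodeMetrics] = []

    def run_round(phase: str, idx: int, learn: bool) -> EpisodeTrajectory:
        env = env_factory(env_rng)
        operator.reset_round()
        events = _round_events(cfg, idx, event_rng) if phase == "formal" else {}
        traj = collect_episode(
            env,
            operator,
            trainer.theta,
            action_rng,
            k=cfg.steps_per_round,
            normalizer=normalizer,
            update_normalizer=True,
            events=events,
            episode=idx,
            exploration_eps=cfg.exploration_eps if learn else 0.0,
        )
        hist = np.bincount(traj.actions, minlength=trainer.theta.n_actions)
        metrics.append(
            EpisodeMetrics(
                episode=idx,
                phase=phase,
                reward=traj.reward,
                quality=traj.quality,
                k=traj.k,
                action_hist=hist,
                preferred_mode=int(np.bincount(traj.preferred_levels).argmax()),
                truncated=traj.truncated,
            )
        )
        if learn:
            trainer.observe_reward(traj.reward)
            if cfg.lr > 0:
                grad = policy_gradient([traj], trainer.baseline, trainer.theta)
                update_parameters(trainer, grad)
        return traj

    for i in range(cfg.practice_rounds):
        run_round("practice", i, learn=False)
    # normalization statistics freeze once practice ends: formal rounds,
    # testing and control all see one stable feature map (practice exists
    # to calibrate; a drifting map would move a fixed policy's actions)
    if not normalizer.frozen:
        normalizer.freeze()
    for i in range(cfg.formal_rounds):
        run_round("formal", i, learn=True)
    return trainer, metrics, normalizer


def convergence_check(
    reward_history: list[float],
    action_history: list[list[int]],
    operator_preference: list[list[int]] | list[int],
    window: int = 5,
    eps_r: float = 0.15,
    agreement: float = 0.8,
) -> tuple[bool, dict]:
    """Reward-stability + action/preference agreement convergence test.

    Converged iff (a) the coefficient of variation of the last
    ``window`` episode rewards is below ``eps_r`` and (b) in at least
    ``agreement`` of those episodes' steps the episode's modal action
    level lies within +/-1 of the operator's preferred level.
    """
    n = len(reward_history)
    if n < window:
        return False, {"reason": f"only {n} episodes observed, need {window}"}
    recent = np.asarray(reward_history[-window:], dtype=float)
    mean = float(np.mean(recent))
    cv = float(np.std(recent) / abs(mean)) if mean != 0 else float("inf")
    stable = cv < eps_r

    agree_steps = 0
    total_steps = 0
    for acts, prefs in list(zip(action_history, operator_preference))[-window:]:
        acts = np.atleast_1d(acts)
        modal = int(np.bincount(acts).argmax())
        prefs = np.atleast_1d(prefs)
        if prefs.size == 1:
            prefs = np.full(acts.size, int(prefs[0]))
        agree_steps += int(np.sum(np.abs(modal - prefs) <= 1))
        total_steps += prefs.size
    satisfied = total_steps > 0 and agree_steps / total_steps >= agreement
    report = {
        "cv": cv,
        "reward_stable": stable,
        "agreement": agree_steps / total_steps if total_steps else 0.0,
        "satisfaction": satisfied,
    }
    return bool(stable and satisfied), report
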