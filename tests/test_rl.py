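"""REINFORCE trainer: gradient estimator, ADAM updates, closed loop."""

import numpy as np
import pytest

from psa.errors import InvalidInputError
from psa.policy import PolicyParameters, adam_update, grad_log_prob, policy_forward
from psa.rl import (
    EpisodeTrajectory,
    TrainConfig,
    TrainerState,
    collect_episode,
    convergence_check,
    policy_gradient,
    train_session,
    update_parameters,
)

PARAM_KEYS = ("W1", "b1", "W2", "b2")


def make_traj(states, actions, reward):
    return EpisodeTrajectory(np.atleast_2d(states), list(actions), reward)


class TestPolicyGradient:
    def test_zero_advantage_gives_zero_gradient(self, tiny_theta, rng):
        traj = make_traj(rng.standard_normal((3, 6)), [0, 1, 2], reward=5.0)
        grad = policy_gradient([traj], b=5.0, theta=tiny_theta)
        for k in PARAM_KEYS:
            assert np.allclose(grad[k], 0.0)

    def test_single_step_unit_advantage_equals_score(self, tiny_theta, rng):
        s = rng.standard_normal(6)
        traj = make_traj(s, [2], reward=1.0)
        grad = policy_gradient([traj], b=0.0, theta=tiny_theta)
        score = grad_log_prob(tiny_theta, s, 2)
        for k in PARAM_KEYS:
            assert np.allclose(grad[k], score[k], atol=1e-12)

    def test_mirrored_advantages_cancel(self, tiny_theta, rng):
        s = rng.standard_normal((2, 6))
        t1 = make_traj(s, [1, 3], reward=1.0)
        t2 = make_traj(s, [1, 3], reward=-1.0)
        grad = policy_gradient([t1, t2], b=0.0, theta=tiny_theta)
        for k in PARAM_KEYS:
            assert np.allclose(grad[k], 0.0, atol=1e-12)

    def test_baseline_shift_invariance(self, tiny_theta, rng):
        trajs = [
            make_traj(rng.standard_normal((4, 6)), [0, 1, 2, 3], reward=r)
            for r in (2.0, 5.0)
        ]
        g1 = policy_gradient(trajs, b=1.0, theta=tiny_theta)
        shifted = [
            make_traj(t.states, t.actions, t.reward + 10.0) for t in trajs
        ]
        g2 = policy_gradient(shifted, b=11.0, theta=tiny_theta)
        for k in PARAM_KEYS:
            assert np.allclose(g1[k], g2[k], atol=1e-10)

    def test_matches_finite_difference_surrogate(self, rng):
        # gradient of (1/N) sum (R-b) ln p(tau) with R, b held constant
        theta = PolicyParameters.init(rng, input_dim=4, hidden_dim=5, n_actions=3)
        trajs = [
            make_traj(rng.standard_normal((3, 4)), list(rng.integers(0, 3, 3)), r)
            for r in (1.5, -0.5)
        ]
        b = 0.3
        grad = policy_gradient(trajs, b, theta)

        def surrogate():
            return sum(
                (t.reward - b) * t.log_probability(theta) for t in trajs
            ) / len(trajs)

        h = 1e-5
        for k in PARAM_KEYS:
            arr = getattr(theta, k)
            it = np.nditer(arr, flags=["multi_index"])
            for _ in it:
                idx = it.multi_index
                orig = arr[idx]
                arr[idx] = orig + h
                up = surrogate()
                arr[idx] = orig - h
                dn = surrogate()
                arr[idx] = orig
                num = (up - dn) / (2 * h)
                denom = max(abs(num), 1e-3)
                assert abs(grad[k][idx] - num) / denom < 1e-4

    def test_empty_list_raises(self, tiny_theta):
        with pytest.raises(InvalidInputError):
            policy_gradient([], b=0.0, theta=tiny_theta)


class TestAdamUpdate:
    def test_first_step_magnitude_is_lr(self, tiny_theta):
        before = tiny_theta.copy()
        grad = {k: np.ones_like(getattr(tiny_theta, k)) for k in PARAM_KEYS}
        adam_update(tiny_theta, grad, lr=1e-3)
        for k in PARAM_KEYS:
            delta = np.abs(getattr(tiny_theta, k) - getattr(before, k))
            assert np.allclose(delta, 1e-3, atol=1e-9)

    def test_zero_gradient_no_change(self, tiny_theta):
        before = tiny_theta.copy()
        grad = {k: np.zeros_like(getattr(tiny_theta, k)) for k in PARAM_KEYS}
        adam_update(tiny_theta, grad)
        assert tiny_theta.equals(before)

    def test_sign_flip_shrinks_second_step(self, tiny_theta):
        g = {k: np.ones_like(getattr(tiny_theta, k)) for k in PARAM_KEYS}
        before1 = tiny_theta.copy()
        adam_update(tiny_theta, g, lr=1e-3)
        step1 = np.abs(tiny_theta.b2 - before1.b2)
        before2 = tiny_theta.copy()
        adam_update(tiny_theta, {k: -v for k, v in g.items()}, lr=1e-3)
        step2 = np.abs(tiny_theta.b2 - before2.b2)
        assert np.all(step2 < step1)

    def test_nonfinite_gradient_rejected(self, tiny_theta):
        grad = {k: np.zeros_like(getattr(tiny_theta, k)) for k in PARAM_KEYS}
        grad["b2"][0] = np.nan
        before = tiny_theta.copy()
        with pytest.raises(InvalidInputError):
            update_parameters(TrainerState(theta=tiny_theta), grad)
        assert tiny_theta.equals(before)


class TestCollectEpisode:
    def _env(self):
        from psa.tasks import TrackingEnv, make_trajectory

        # long path so the episode always runs the full 50 windowed steps
        path = make_trajectory("straight", length=500.0)
        return TrackingEnv(path=path)

    def test_k_equals_windows_per_round(self, conservative_operator, full_theta):
        env = self._env()
        traj = collect_episode(
            env, conservative_operator, full_theta, np.random.default_rng(0)
        )
        assert traj.k == 50
        assert traj.states.shape == (50, 152)
        assert traj.truncated

    def test_deterministic_under_fixed_seeds(self, full_theta):
        from psa.operator import OperatorProfile, SyntheticOperator

        runs = []
        for _ in range(2):
            op = SyntheticOperator(OperatorProfile.conservative(), seed=3)
            traj = collect_episode(
                self._env(), op, full_theta, np.random.default_rng(1), k=10
            )
            runs.append(traj)
        assert np.array_equal(runs[0].states, runs[1].states)
        assert runs[0].actions == runs[1].actions
        assert runs[0].reward == runs[1].reward

    def test_log_probability_recomputation(self, conservative_operator, full_theta):
        traj = collect_episode(
            self._env(), conservative_operator, full_theta,
            np.random.default_rng(2), k=8,
        )
        manual = 0.0
        for s, a in zip(traj.states, traj.actions):
            manual += np.log(policy_forward(full_theta, s)[a])
        assert abs(traj.log_probability(full_theta) - manual) < 1e-10


class TestConvergenceCheck:
    def test_stable_and_matching_converges(self):
        ok, report = convergence_check(
            [1.0] * 6, [[2] * 10] * 6, [[2] * 10] * 6
        )
        assert ok and report["reward_stable"] and report["satisfaction"]

    def test_fluctuating_rewards_fail(self):
        ok, report = convergence_check(
            [0.0, 10.0] * 3, [[2] * 10] * 6, [[2] * 10] * 6
        )
        assert not ok and not report["reward_stable"]

    def test_action_preference_mismatch_fails(self):
        ok, report = convergence_check(
            [1.0] * 6, [[0] * 10] * 6, [[3] * 10] * 6
        )
        assert not ok and not report["satisfaction"]

    def test_within_one_level_counts_as_agreement(self):
        ok, _ = convergence_check([1.0] * 5, [[2] * 10] * 5, [[3] * 10] * 5)
        assert ok

    def test_short_history_reports_reason(self):
        ok, report = convergence_check([1.0, 1.0], [[1]] * 2, [[1]] * 2)
        assert not ok and "reason" in report


class TestTrainSession:
    def _cfg(self, **kw):
        base = dict(
            practice_rounds=1,
            formal_rounds=4,
            steps_per_round=8,
            pretrain_enabled=False,
            seed=11,
        )
        base.update(kw)
        return TrainConfig(**base)

    def _env_factory(self):
        from psa.tasks import make_env

        def factory(rng):
            env = make_env("tracking")
            env.reset(rng)
            return env

        return factory

    def test_round_counts_and_phases(self):
        from psa.operator import OperatorProfile, SyntheticOperator

        op = SyntheticOperator(OperatorProfile.conservative(), seed=1)
        trainer, metrics, norm = train_session(
            self._env_factory(), op, self._cfg()
        )
        phases = [m.phase for m in metrics]
        assert phases.count("practice") == 1
        assert phases.count("formal") == 4
        assert trainer.episode == 4
        assert norm.frozen

    def test_default_formal_round_count_is_15(self):
        assert TrainConfig().formal_rounds == 15
        assert TrainConfig().practice_rounds == 3

    def test_practice_rounds_do_not_update_parameters(self):
        from psa.operator import OperatorProfile, SyntheticOperator
        from psa.policy import PolicyParameters

        op = SyntheticOperator(OperatorProfile.conservative(), seed=2)
        theta = PolicyParameters.init(np.random.default_rng(0))
        snapshot = theta.copy()
        train_session(
            self._env_factory(), op, self._cfg(formal_rounds=0), theta=theta
        )
        assert theta.equals(snapshot)

    def test_reproducible_given_seed(self):
        from psa.operator import OperatorProfile, SyntheticOperator

        hist = []
        for _ in range(2):
            op = SyntheticOperator(OperatorProfile.conservative(), seed=5)
            trainer, *_ = train_session(self._env_factory(), op, self._cfg())
            hist.append(trainer.reward_history)
        assert hist[0] == hist[1]


class TestBanditDegenerateCase:
    """1-state 2-action bandit: REINFORCE with baseline must concentrate
    on the rewarded action, matching the exact solution of the
    degenerate MDP."""

    @staticmethod
    def run_bandit(seed, episodes=200):
        rng = np.random.default_rng(seed)
        theta = PolicyParameters.init(rng, input_dim=3, hidden_dim=8, n_actions=2)
        s = np.ones(3)
        state = TrainerState(theta=theta)
        for _ in range(episodes):
            probs = policy_forward(theta, s)
            a = int(rng.choice(2, p=probs))
            r = 1.0 if a == 0 else 0.0
            state.observe_reward(r)
            traj = EpisodeTrajectory(np.atleast_2d(s), [a], r)
            grad = policy_gradient([traj], state.baseline, theta)
            update_parameters(state, grad)
        return policy_forward(theta, s)[0]

    def test_best_action_probability_exceeds_090(self):
        wins = sum(self.run_bandit(seed) > 0.9 for seed in range(5))
        assert wins >= 3
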