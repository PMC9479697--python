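"""One full closed-loop training session on the trajectory-tracking task.

18 rounds (3 practice + 15 formal): per round the synthetic operator's
signals are windowed into 50 mental states, the policy samples a speed
level per state, and the round's operational quality becomes the
episodic reward for one baseline-corrected REINFORCE/ADAM update.
"""

import numpy as np

from psa.operator import OperatorProfile, SyntheticOperator
from psa.rl import TrainConfig, convergence_check, train_session
from psa.tasks import make_env

profile = OperatorProfile.conservative(seed=3)
operator = SyntheticOperator(profile, seed=3)


def env_factory(rng):
    env = make_env("tracking")
    env.reset(rng)
    return env


trainer, metrics, normalizer = train_session(env_factory, operator, TrainConfig(seed=3))

formal = [m for m in metrics if m.phase == "formal"]
print("episode quality:", " ".join(f"{m.quality:.2f}" for m in formal))
early = np.mean([m.quality for m in formal[:3]])
late = np.mean([m.quality for m in formal[-3:]])
print(f"early (first 3) {early:.3f} -> late (last 3) {late:.3f} "
      f"({'improved' if late > early else 'no improvement'})")
print(f"final-round action histogram (levels 0-3): {formal[-1].action_hist}, "
      f"operator's preferred level: {formal[-1].preferred_mode}")

ok, report = convergence_check(
    [m.reward for m in formal],
    [np.repeat(np.arange(4), m.action_hist) for m in formal],
    [[m.preferred_mode] for m in formal],
)
print(f"converged: {ok} (reward CV {report['cv']:.3f}, "
      f"action/preference agreement {report['agreement']:.2f})")
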