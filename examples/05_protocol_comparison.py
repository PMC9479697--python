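"""Three-session protocol: personalized adaptation vs warning threshold.

Runs training (18 rounds), testing (15 rounds, frozen policy) and
control (15 rounds, conventional threshold controller) for one
aggressive and one conservative operator, then compares operational
quality between the testing and control arms (which face identically
seeded operators).
"""

from psa.experiment import ProtocolConfig, run_protocol
from psa.operator import OperatorProfile

for profile in (OperatorProfile.aggressive(seed=1), OperatorProfile.conservative(seed=2)):
    res = run_protocol(profile, ProtocolConfig(task="tracking", seed=profile.seed))
    c = res.comparison
    print(f"{profile.style} operator (preferred level {profile.base_level}):")
    print(f"  PSA testing quality     {c['testing_mean']:.3f} +/- {c['testing_sd']:.3f}")
    print(f"  conventional control    {c['control_mean']:.3f} +/- {c['control_sd']:.3f}")
    print(f"  two-sample t = {c['t_two_sample']:.2f} (p = {c['p_two_sample']:.2g}); "
          f"{'PSA better' if c['psa_better'] else 'conventional better'}")
    tc = c["training_contrast"]
    print(f"  training early->late quality: {tc['early_mean']:.3f} -> {tc['late_mean']:.3f}")
    print(f"  testing-session velocity spread: {res.testing.velocity_spread():.3f}")
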