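"""Fine-tune the TCR generator and run a short PPO attack on a scorer.

The policy is rewarded with the scorer's raw logit; a rising mean reward
with increasingly odd sequences is the signature of reward hacking the
framework is designed to expose.
"""

import numpy as np

from tcrshield import (
    BAPConfig,
    GeneratorConfig,
    PolicyModel,
    PPOConfig,
    SyntheticConfig,
    build_bap,
    collect_candidates,
    make_benchmark,
    ppo_attack,
    sample,
    sft_train,
    train_bap,
)

bench = make_benchmark(SyntheticConfig(n_epitopes=2, tcrs_per_epitope=80,
                                       n_healthy=400, seed=42))
bap = train_bap(build_bap(BAPConfig(architecture="mlp", hidden=(32,),
                                    epochs=60, seed=0)), bench.train)
policy, reference = sft_train(PolicyModel(GeneratorConfig(seed=1)),
                              bench.train.positives(), epochs=40, seed=2)

e = bench.epitopes[0]
print(f"epitope {e}, planted motif {bench.rule.motif_for(e)}")
print("SFT samples:", [s.tcr for s in sample(policy, e, n=3, seed=3)])

attacked, trace = ppo_attack(
    policy, reference, bap, bench.epitopes,
    PPOConfig(steps=30, batch_per_step=12, kl_coef=0.003, seed=4),
)
mr = trace.mean_rewards()
print(f"mean reward logit: step 1 = {mr[0]:.2f}, final = {mr[-1]:.2f}")
print("late-step samples:", [t for t, _, _ in trace.steps[-1].records[:3]])
cands = collect_candidates(trace)
print(f"{len(cands)} candidate pairs harvested "
      f"({sum(r >= 0 for *_, r in cands)} scored as binders)")
# The reward climbs while samples drift away from authentic-looking CDR3s.
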