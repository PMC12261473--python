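"""Shared fixtures: a small noiseless benchmark and lightly trained models.

Session scope keeps the suite fast — the fixtures are read-only; tests that
mutate models clone them first.
"""

from __future__ import annotations

import numpy as np
import pytest

from tcrshield.bap import BAPConfig, build_bap, train_bap
from tcrshield.generator import GeneratorConfig, PolicyModel, sft_train, train_gptll
from tcrshield.synthetic import SyntheticConfig, make_benchmark


@pytest.fixture(scope="session")
def small_config() -> SyntheticConfig:
    return SyntheticConfig(
        n_epitopes=2, tcrs_per_epitope=80, n_healthy=400, motif_noise=0.0, seed=7
    )


@pytest.fixture(scope="session")
def bench(small_config):
    """320-pair noiseless benchmark: 160 positives, 80+80 negatives."""
    return make_benchmark(small_config)


@pytest.fixture(scope="session")
def trained_bap(bench):
    """A small trained MLP scorer over the benchmark train split."""
    cfg = BAPConfig(architecture="mlp", hidden=(64,), epochs=100, seed=3)
    return train_bap(build_bap(cfg), bench.train)


@pytest.fixture(scope="session")
def small_policy():
    """A small decoder for cheap structural tests (untrained)."""
    return PolicyModel(GeneratorConfig(n_layers=1, d_model=24, d_ff=48, seed=0))


@pytest.fixture(scope="session")
def sft_models(bench):
    """Policy fine-tuned on the benchmark positives, plus frozen reference."""
    policy, reference = sft_train(
        PolicyModel(GeneratorConfig(seed=1)), bench.train.positives(), epochs=50, seed=2
    )
    return policy, reference


@pytest.fixture(scope="session")
def gptll_model(bench):
    """Likelihood model trained on the healthy repertoire plus binder TCRs."""
    corpus = bench.healthy + [p.tcr for p in bench.train.positives()]
    model, report = train_gptll(corpus, epochs=12, seed=4)
    return model, report


@pytest.fixture(scope="session")
def micro_states(bench, sft_models, gptll_model, trained_bap):
    """A miniature two-iteration attack-and-defend run for bookkeeping tests."""
    from tcrshield.attack import PPOConfig
    from tcrshield.authenticity import FPThresholds, ReferenceDB
    from tcrshield.defend import IterationConfig, run_iterations

    policy, reference = sft_models
    gptll, _ = gptll_model
    refs = ReferenceDB.from_dataset(bench.train.positives())
    cfg = IterationConfig(
        max_iterations=2,
        ppo=PPOConfig(steps=8, batch_per_step=8, kl_coef=0.003, seed=41),
        thresholds=FPThresholds(reward_min=0.0, tcrmatch_min=0.35,
                                gptll_per_residue_min=-2.0),
        n_curated=80,
        finetune_epochs=20,
        stop_min=0,
        stop_fraction=0.0,
        seed=13,
    )
    return run_iterations(
        trained_bap, bench.pool, policy, reference, refs, gptll, cfg,
        epitopes=bench.epitopes, eval_dataset=bench.test,
    )
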