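import logging

import numpy as np
import pytest

from tcrshield.attack import PPOConfig
from tcrshield.authenticity import FPThresholds, ReferenceDB
from tcrshield.bap import BAPConfig, build_bap, predict_logits, train_bap
from tcrshield.defend import (
    BASE_LR,
    FINETUNE_LR,
    CurationRatios,
    IterationConfig,
    curate_finetune_set,
    finetune_bap,
    fp_records_to_dataset,
    run_iterations,
)
from tcrshield.seqio import BindingPair, PairDataset


def make_adversarial(n, epitope="GILGFVFTL", iteration=1):
    pairs = []
    for i in range(n):
        # distinct degenerate-ish but valid sequences
        filler = "ACDEFGHIKLMNPQRSTVWY"[i % 20]
        pairs.append(
            BindingPair(
                tcr=f"CASSW{filler * 3}W{'ACDEFGHIKLMNPQRSTVWY'[(i // 20) % 20]}DEQYF",
                epitope=epitope,
                label=0,
                group="adversarial",
                source_model="test",
                iteration=iteration,
            )
        )
    return PairDataset(list({(p.tcr, p.epitope): p for p in pairs}.values()))


class TestCuration:
    def test_largest_remainder_exact_counts(self, bench):
        adv = make_adversarial(150)
        train, val = curate_finetune_set(
            bench.pairs, adv, CurationRatios(2, 1, 1, 1), n_total=300,
            seed=0, val_fraction=0.0,
        )
        counts = train.group_counts()
        assert counts == {"positive": 120, "neg_shuffle": 60,
                          "neg_healthy": 60, "adversarial": 60}

    def test_ratios_2111_with_500_total(self, bench):
        """Weights (2,1,1,1) at n=500 -> 200/100/100/100 apportionment."""
        from tcrshield.defend import _largest_remainder

        counts = _largest_remainder(
            {"positive": 2, "neg_shuffle": 1, "neg_healthy": 1, "adversarial": 1}, 500
        )
        assert counts == {"positive": 200, "neg_shuffle": 100,
                          "neg_healthy": 100, "adversarial": 100}

    def test_positive_only_ratios(self, bench):
        adv = make_adversarial(10)
        train, val = curate_finetune_set(
            bench.pairs, adv, CurationRatios(1, 0, 0, 0), n_total=50,
            seed=0, val_fraction=0.0,
        )
        assert set(train.group_counts()) == {"positive"}

    def test_shortfall_redistribution_preserves_total(self, bench, caplog):
        """30 adversarial available but 60 requested: all 30 taken and the
        30-pair shortfall spread over the other groups at their ratios."""
        adv = make_adversarial(30)
        with caplog.at_level(logging.WARNING):
            train, val = curate_finetune_set(
                bench.pairs, adv, CurationRatios(2, 1, 1, 1), n_total=300,
                seed=0, val_fraction=0.0,
            )
        counts = train.group_counts()
        assert sum(counts.values()) == 300
        assert counts["adversarial"] == 30
        assert counts["positive"] == 135  # 120 + 2/4 of the 30-pair shortfall
        assert "redistributing" in caplog.text

    def test_requested_adversarial_but_empty_set_raises(self, bench):
        with pytest.raises(ValueError):
            curate_finetune_set(bench.pairs, PairDataset([]), CurationRatios(),
                                n_total=100, seed=0)

    def test_validation_carveout_is_stratified(self, bench):
        adv = make_adversarial(50)
        train, val = curate_finetune_set(
            bench.pairs, adv, CurationRatios(2, 1, 1, 1), n_total=200,
            seed=0, val_fraction=0.2,
        )
        assert set(val.group_counts()) == set(train.group_counts())
        assert len(train) + len(val) == 200


class TestFinetune:
    def test_default_rates_follow_the_100x_protocol(self):
        assert BASE_LR / FINETUNE_LR == pytest.approx(100.0)
        assert BAPConfig().learning_rate / FINETUNE_LR == pytest.approx(100.0)

    def test_zero_epochs_is_identity(self, trained_bap, bench):
        out = finetune_bap(trained_bap, bench.pool, bench.pool, epochs=0)
        for a, b in zip(out.parameters(), trained_bap.parameters()):
            assert np.array_equal(a.data, b.data)

    def test_history_is_appended_not_overwritten(self, trained_bap, bench):
        before = len(trained_bap.training_history["val_loss"])
        out = finetune_bap(trained_bap, bench.pool, bench.pool.by_group("positive")
                           .concat(bench.pool.by_group("neg_healthy")), epochs=3)
        assert len(out.training_history["val_loss"]) == before + 3

    def test_finetuning_reduces_misclassification_of_its_adversarial_set(
        self, trained_bap, bench
    ):
        adv = make_adversarial(40)
        train, val = curate_finetune_set(bench.pool, adv, CurationRatios(),
                                         n_total=120, seed=1, val_fraction=0.1)
        adv_train = [p for p in train if p.group == "adversarial"]
        before = int((predict_logits(trained_bap, adv_train) >= 0).sum())
        out = finetune_bap(trained_bap, train, val, lr=1e-4, epochs=60)
        after = int((predict_logits(out, adv_train) >= 0).sum())
        assert after < before

    def test_high_lr_warns_but_runs(self, trained_bap, bench, caplog):
        adv = make_adversarial(20)
        train, val = curate_finetune_set(bench.pool, adv, n_total=60, seed=2)
        with caplog.at_level(logging.WARNING):
            finetune_bap(trained_bap, train, val, lr=1e-2, epochs=1)
        assert "not below" in caplog.text


class TestIterations:
    def test_at_most_the_configured_number_of_iterations(self, micro_states):
        assert 1 <= len(micro_states) <= 2

    def test_cumulative_adversarial_is_monotone(self, micro_states):
        sizes = [len(s.cumulative_adversarial) for s in micro_states]
        assert sizes == sorted(sizes)

    def test_states_carry_attack_trajectories_and_metrics(self, micro_states):
        for s in micro_states:
            assert s.attack_mean_rewards and len(s.attack_mean_rewards) == 8
            assert s.metrics is not None
            assert s.fp_count_this_iter >= 0

    def test_iterations_are_reproducible(self, bench, sft_models, gptll_model,
                                         trained_bap, micro_states):
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
        again = run_iterations(trained_bap, bench.pool, policy, reference, refs,
                               gptll, cfg, epitopes=bench.epitopes,
                               eval_dataset=bench.test)
        assert [s.fp_count_this_iter for s in again] == [
            s.fp_count_this_iter for s in micro_states
        ]
        assert [len(s.cumulative_adversarial) for s in again] == [
            len(s.cumulative_adversarial) for s in micro_states
        ]


def test_fp_records_to_dataset_builds_adversarial_pairs():
    from tcrshield.authenticity import AuthenticityScore, FalsePositiveRecord

    rec = FalsePositiveRecord(
        tcr="CASSWWWWDEQYF",
        epitope="GILGFVFTL",
        reward_logit=2.5,
        scores=AuthenticityScore(0.1, -40.0, -3.0, True),
        iteration=2,
        source_model="cnn",
    )
    ds = fp_records_to_dataset([rec])
    assert len(ds) == 1
    p = ds.pairs[0]
    assert p.group == "adversarial" and p.label == 0
    assert p.source_model == "cnn" and p.iteration == 2
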