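import numpy as np
import pytest

from tcrshield.generator import (
    _EOS_OUT,
    N_OUT,
    GenerationSample,
    GeneratorConfig,
    PolicyModel,
    sample,
    sequence_loglik,
    sequence_loglik_per_token,
    sft_train,
    train_gptll,
)


def stepwise_loglik_oracle(model, tcr, epitope=None):
    """Chain-rule oracle: score one token at a time with fresh forwards."""
    ids, start = model.token_ids(tcr, epitope)
    a = model.alphabet
    targets = list(ids[start:]) + [_EOS_OUT]
    total = 0.0
    for j, tgt in enumerate(targets):
        prefix = ids[: start + j][None, :]
        logits = model.forward_logits(prefix).data[0, -1]
        logits = logits - logits.max()
        logp = logits - np.log(np.exp(logits).sum())
        total += logp[tgt if tgt < N_OUT else _EOS_OUT]
    return float(total)


class TestLikelihood:
    def test_uniform_untrained_model_closed_form(self, small_policy):
        """Zero-initialized head => exactly uniform over 20 residues + EOS."""
        model = small_policy.copy(role="likelihood")
        assert sequence_loglik(model, "AC") == pytest.approx(3 * np.log(1.0 / 21), abs=1e-9)

    def test_matches_stepwise_chain_rule_oracle(self, sft_models, bench):
        policy, _ = sft_models
        for p in bench.test.positives().pairs[:5]:
            fast = sequence_loglik(policy, p.tcr, p.epitope)
            slow = stepwise_loglik_oracle(policy, p.tcr, p.epitope)
            assert fast == pytest.approx(slow, abs=1e-5)

    def test_loglik_is_never_positive(self, gptll_model, bench):
        model, _ = gptll_model
        for s in bench.healthy[:20]:
            assert sequence_loglik(model, s) <= 0.0

    def test_conditioning_contract(self, sft_models, gptll_model):
        policy, _ = sft_models
        likelihood, _ = gptll_model
        with pytest.raises(ValueError):
            sequence_loglik(policy, "CASSF")  # conditioned model needs epitope
        with pytest.raises(ValueError):
            sequence_loglik(likelihood, "CASSF", "GILGFVFTL")


class TestSampling:
    def test_seeded_determinism(self, sft_models, bench):
        policy, _ = sft_models
        e = bench.epitopes[0]
        a = sample(policy, e, n=20, seed=9)
        b = sample(policy, e, n=20, seed=9)
        assert [s.tcr for s in a] == [s.tcr for s in b]

    def test_vocabulary_closure(self, sft_models, bench):
        from tcrshield.seqio import RESIDUES

        policy, _ = sft_models
        for s in sample(policy, bench.epitopes[0], n=30, seed=3):
            assert s.tcr and set(s.tcr) <= set(RESIDUES)
            assert len(s.tcr) <= policy.config.max_len

    def test_total_logprob_is_sum_of_tokens(self, sft_models, bench):
        policy, _ = sft_models
        for s in sample(policy, bench.epitopes[0], n=10, seed=4):
            assert s.total_logprob == pytest.approx(sum(s.token_logprobs), abs=1e-9)
            assert s.total_logprob <= 0

    def test_rescoring_reproduces_sampling_logprobs(self, sft_models, bench):
        """Terminated samples re-scored at temperature 1 match exactly."""
        policy, _ = sft_models
        for s in sample(policy, bench.epitopes[0], n=15, seed=5):
            if len(s.token_logprobs) == len(s.tcr) + 1:  # ended with EOS
                assert sequence_loglik(policy, s.tcr, s.epitope) == pytest.approx(
                    s.total_logprob, abs=1e-5
                )

    def test_low_temperature_limit_is_greedy_decoding(self, sft_models, bench):
        policy, _ = sft_models
        e = bench.epitopes[0]
        greedy = {s.tcr for s in sample(policy, e, n=5, temperature=1e-6, seed=1)}
        assert len(greedy) == 1
        # independent argmax decode
        a = policy.alphabet
        ids = [a.bos] + a.encode(e).tolist() + [a.sep]
        out = []
        for _ in range(policy.config.max_len):
            logits = policy.forward_logits(np.array([ids])).data[0, -1]
            c = int(np.argmax(logits))
            if c == _EOS_OUT:
                break
            out.append(c)
            ids.append(c)
        assert greedy == {"".join(a.residues[c] for c in out)}

    def test_normalization_of_next_token_distribution(self, sft_models):
        policy, _ = sft_models
        ids, _ = policy.token_ids("CASSF", "GILGFVFTL")
        logits = policy.forward_logits(ids[None, :]).data
        probs = np.exp(logits - logits.max(-1, keepdims=True))
        probs /= probs.sum(-1, keepdims=True)
        assert np.allclose(probs.sum(-1), 1.0, atol=1e-6)

    def test_invalid_arguments(self, sft_models):
        policy, _ = sft_models
        with pytest.raises(ValueError):
            sample(policy, "GILGFVFTL", n=0)
        with pytest.raises(ValueError):
            sample(policy, "GILGFVFTL", n=1, temperature=0.0)
        with pytest.raises(ValueError):
            sample(policy, "GILGFVFTL", n=1, max_len=0)


class TestSFT:
    def test_objective_improves_and_reference_is_frozen_copy(self, sft_models, bench):
        policy, reference = sft_models
        assert policy.sft_history[-1] < policy.sft_history[0]
        assert reference.role == "reference"
        for a, b in zip(policy.parameters(), reference.parameters()):
            assert np.array_equal(a.data, b.data)

    def test_sampled_tcrs_carry_the_epitope_motif(self, sft_models, bench):
        """After SFT on noiseless planted data, most samples contain the
        prompted epitope's motif."""
        policy, _ = sft_models
        e = bench.epitopes[0]
        motif = bench.rule.motif_for(e)
        hits = np.mean([motif in s.tcr for s in sample(policy, e, n=40, seed=6)])
        assert hits > 0.5

    def test_seeded_determinism(self, bench):
        cfg = GeneratorConfig(n_layers=1, d_model=24, d_ff=48, seed=3)
        a, _ = sft_train(PolicyModel(cfg), bench.train.positives(), epochs=2, seed=5)
        b, _ = sft_train(PolicyModel(cfg), bench.train.positives(), epochs=2, seed=5)
        for pa, pb in zip(a.parameters(), b.parameters()):
            assert np.array_equal(pa.data, pb.data)

    def test_rejects_wrong_inputs(self, bench, small_policy):
        with pytest.raises(ValueError):
            sft_train(small_policy, bench.train, epochs=1)  # contains negatives
        from tcrshield.seqio import PairDataset

        with pytest.raises(ValueError):
            sft_train(small_policy, PairDataset([]), epochs=1)


class TestGPTLL:
    def test_heldout_likelihood_improves_over_untrained(self, gptll_model):
        _, report = gptll_model
        assert report["holdout_loglik_after"] > report["holdout_loglik_before"]

    def test_ranks_authentic_above_degenerate(self, gptll_model, bench):
        model, _ = gptll_model
        authentic = np.mean(
            [sequence_loglik_per_token(model, s) for s in bench.healthy[-30:]]
        )
        repeats = np.mean(
            [sequence_loglik_per_token(model, r * 12) for r in "AEKW"]
        )
        assert authentic > repeats

    def test_empty_corpus_rejected(self):
        with pytest.raises(ValueError):
            train_gptll([], epochs=1)
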