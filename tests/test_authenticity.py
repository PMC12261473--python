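import itertools

import numpy as np
import pytest

from tcrshield.authenticity import (
    DEFAULT_BETA,
    FPThresholds,
    ReferenceDB,
    calibrate_fp_thresholds,
    calibrate_gptll_floor,
    degenerate_anchors,
    identify_false_positives,
    kmer_kernel,
    score_sequence,
    tcrmatch_score,
)
from tcrshield.seqio import RESIDUES, blosum62


def brute_force_kernel(a, b, sub, k_range=(1, 10), beta=DEFAULT_BETA):
    """Four-nested-loop evaluation of the k-mer kernel."""
    k_max = min(k_range[1], len(a), len(b))
    total = 0.0
    for k in range(min(k_range[0], k_max), k_max + 1):
        for i in range(len(a) - k + 1):
            for j in range(len(b) - k + 1):
                prod = 1.0
                for q in range(k):
                    prod *= np.exp(beta * sub.score(a[i + q], b[j + q]))
                total += prod
    return total


@pytest.fixture(scope="module")
def refs(bench):
    return ReferenceDB.from_dataset(bench.train.positives())


class TestKernel:
    def test_matches_brute_force_on_short_sequences(self):
        sub = blosum62()
        rng = np.random.default_rng(1)
        seqs = [
            "".join(RESIDUES[i] for i in rng.integers(0, 20, size=rng.integers(2, 7)))
            for _ in range(6)
        ]
        for a, b in itertools.product(seqs, repeat=2):
            assert kmer_kernel(a, b, sub) == pytest.approx(
                brute_force_kernel(a, b, sub), rel=1e-10
            )

    def test_symmetry(self):
        sub = blosum62()
        rng = np.random.default_rng(2)
        for _ in range(10):
            a = "".join(RESIDUES[i] for i in rng.integers(0, 20, size=8))
            b = "".join(RESIDUES[i] for i in rng.integers(0, 20, size=11))
            assert kmer_kernel(a, b, sub) == pytest.approx(kmer_kernel(b, a, sub))

    def test_self_kernel_is_positive(self):
        assert kmer_kernel("A", "A") > 0
        assert kmer_kernel("CASSF", "CASSF") > 0

    def test_invalid_k_range_rejected(self):
        with pytest.raises(ValueError):
            kmer_kernel("CASSF", "CASSF", k_range=(3, 2))


class TestSimilarityScore:
    def test_identical_query_scores_one(self, refs, bench):
        e = bench.epitopes[0]
        q = refs.by_epitope[e][0]
        assert tcrmatch_score(q, refs, e) == pytest.approx(1.0, abs=1e-9)

    def test_bounded_in_unit_interval(self, refs):
        rng = np.random.default_rng(3)
        for _ in range(50):
            q = "".join(RESIDUES[i] for i in rng.integers(0, 20, size=rng.integers(2, 20)))
            assert 0.0 <= tcrmatch_score(q, refs) <= 1.0

    def test_degenerate_sequence_scores_below_authentic(self, refs, bench):
        e = bench.epitopes[0]
        authentic = [p.tcr for p in bench.test.positives() if p.epitope == e][:10]
        auth_scores = [tcrmatch_score(t, refs, e) for t in authentic]
        assert tcrmatch_score("AYAYAYAY", refs, e) < np.mean(auth_scores)

    def test_empty_scope_rejected(self):
        with pytest.raises(ValueError):
            tcrmatch_score("CASSF", ReferenceDB(by_epitope={"GILGFVFTL": []}))


class TestFalsePositiveRule:
    def _stub_candidates(self):
        return [
            ("CASSLGDEQYF", "GILGFVFTL", 3.0),
            ("CASSPDRGAYF", "GILGFVFTL", -2.0),
        ]

    def test_disjunction_semantics(self, refs, gptll_model, trained_bap):
        """Low similarity alone flags a high-reward candidate (OR rule)."""
        gptll, _ = gptll_model
        thr = FPThresholds(
            reward_min=0.0, tcrmatch_min=2.0, gptll_per_residue_min=-np.inf
        )  # tcrmatch always below 2.0 -> every high-reward candidate flagged
        fps = identify_false_positives(
            self._stub_candidates(), trained_bap, refs, gptll, thr
        )
        assert [r.tcr for r in fps] == ["CASSLGDEQYF"]

    def test_reward_gate_excludes_low_scorers(self, refs, gptll_model, trained_bap):
        gptll, _ = gptll_model
        thr = FPThresholds(reward_min=0.0, tcrmatch_min=2.0, gptll_per_residue_min=0.0)
        fps = identify_false_positives(
            [("CASSPDRGAYF", "GILGFVFTL", -2.0)], trained_bap, refs, gptll, thr
        )
        assert fps == []

    def test_calibrated_thresholds_flag_exactly_the_degenerate_pool(
        self, refs, gptll_model, bench
    ):
        """10 plausible + 10 degenerate high-reward candidates: exactly the
        degenerate ones are flagged under calibrated thresholds."""
        gptll, _ = gptll_model
        e = bench.epitopes[0]
        held = [(p.tcr, p.epitope) for p in bench.pool.positives()][:40]
        thr = calibrate_fp_thresholds(refs, gptll, held)
        plausible = refs.by_epitope[e][:10]  # known binders of the epitope
        degenerate = ["W" * 12, "M" * 10, "E" * 10, "KWKWKWKWKWKW", "N" * 14,
                      "I" * 12, "A" * 20, "WAWAWAWAWAWA", "K" * 11, "H" * 13]
        cands = [(t, e, 5.0) for t in plausible + degenerate]
        fps = identify_false_positives(cands, None, refs, gptll, thr)
        assert sorted(r.tcr for r in fps) == sorted(degenerate)

    def test_threshold_lattice_monotonicity(self, refs, gptll_model, bench):
        """Raising the similarity floor grows the FP set; raising the reward
        gate shrinks it."""
        gptll, _ = gptll_model
        e = bench.epitopes[0]
        cands = [(p.tcr, e, float(i)) for i, p in enumerate(bench.test.pairs[:20])]
        base = FPThresholds(reward_min=2.0, tcrmatch_min=0.3,
                            gptll_per_residue_min=-np.inf)
        fp0 = {r.tcr for r in identify_false_positives(cands, None, refs, gptll, base)}
        looser_sim = FPThresholds(reward_min=2.0, tcrmatch_min=0.6,
                                  gptll_per_residue_min=-np.inf)
        fp1 = {r.tcr for r in identify_false_positives(cands, None, refs, gptll, looser_sim)}
        assert fp0 <= fp1
        higher_gate = FPThresholds(reward_min=10.0, tcrmatch_min=0.3,
                                   gptll_per_residue_min=-np.inf)
        fp2 = {r.tcr for r in identify_false_positives(cands, None, refs, gptll, higher_gate)}
        assert fp2 <= fp0

    def test_records_rescore_bitwise(self, refs, gptll_model, trained_bap, bench):
        gptll, _ = gptll_model
        e = bench.epitopes[0]
        thr = FPThresholds(reward_min=-np.inf, tcrmatch_min=1.1,
                           gptll_per_residue_min=-np.inf)
        fps = identify_false_positives(
            [("WWWWWWWW", e, 1.0)], trained_bap, refs, gptll, thr
        )
        assert len(fps) == 1
        r = fps[0]
        again = score_sequence(r.tcr, r.epitope, refs, gptll)
        assert again == r.scores

    def test_dedupe_keeps_max_reward(self, refs, gptll_model, trained_bap, bench):
        gptll, _ = gptll_model
        e = bench.epitopes[0]
        thr = FPThresholds(reward_min=0.0, tcrmatch_min=1.1, gptll_per_residue_min=-np.inf)
        fps = identify_false_positives(
            [("WWWWWWWW", e, 1.0), ("WWWWWWWW", e, 4.0)], trained_bap, refs, gptll, thr
        )
        assert len(fps) == 1 and fps[0].reward_logit == 4.0


class TestCalibration:
    def test_floor_is_a_low_percentile_of_authentic_scores(self, gptll_model, bench):
        gptll, _ = gptll_model
        seqs = bench.healthy[:40]
        floor = calibrate_gptll_floor(gptll, seqs, percentile=5.0)
        from tcrshield.generator import sequence_loglik_per_token

        scores = [sequence_loglik_per_token(gptll, s) for s in seqs]
        assert floor == pytest.approx(np.percentile(scores, 5.0))

    def test_anchored_thresholds_sit_below_authentic_tail(self, refs, gptll_model, bench):
        gptll, _ = gptll_model
        held = [(p.tcr, p.epitope) for p in bench.pool.positives()][:40]
        thr = calibrate_fp_thresholds(refs, gptll, held)
        from tcrshield.generator import sequence_loglik_per_token

        auth = [sequence_loglik_per_token(gptll, t) for t, _ in held]
        assert thr.gptll_per_residue_min <= np.percentile(auth, 5.0)
        assert 0.0 < thr.tcrmatch_min < thr.tcrmatch_exempt <= 1.0

    def test_degenerate_anchors_are_valid_and_low_complexity(self):
        from tcrshield.seqio import max_residue_run, validate_sequence

        anchors = degenerate_anchors()
        assert anchors
        for s in anchors:
            validate_sequence(s)
            assert max_residue_run(s) >= 2 or len(s) <= 2 or len(set(s)) == 2
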