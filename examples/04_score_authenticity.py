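"""Score sequences for biological plausibility.

Two independent measures: a k-mer string-kernel similarity to known binders
(1.0 = matches a reference exactly) and the per-residue log-likelihood under
an autoregressive model of authentic TCRs (higher = more typical).
"""

from tcrshield import (
    ReferenceDB,
    SyntheticConfig,
    make_benchmark,
    sequence_loglik_per_token,
    tcrmatch_score,
    train_gptll,
    heuristic_filter,
)

bench = make_benchmark(SyntheticConfig(n_epitopes=2, tcrs_per_epitope=60,
                                       n_healthy=500, seed=42))
refs = ReferenceDB.from_dataset(bench.train.positives())
gptll, report = train_gptll(
    bench.healthy + [p.tcr for p in bench.train.positives()], epochs=10, seed=0
)
print(f"held-out per-token log-likelihood after training: "
      f"{report['holdout_per_token_after']:.2f}")

e = bench.epitopes[0]
queries = {
    "held-out binder": bench.test.positives().pairs[0].tcr,
    "healthy TCR": bench.healthy[-1],
    "poly-tryptophan": "W" * 12,
    "ultra-short": "AY",
}
for name, q in queries.items():
    print(
        f"{name:16s} {q:20s} similarity={tcrmatch_score(q, refs, e):.3f} "
        f"loglik/token={sequence_loglik_per_token(gptll, q):6.2f} "
        f"heuristic={'pass' if heuristic_filter(q) else 'FAIL'}"
    )
# Degenerate sequences score low on both metrics; authentic ones score high.
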