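"""Build the synthetic TCR-epitope benchmark and inspect its composition.

The generator plants one private 4-residue motif per epitope into otherwise
background-like CDR3beta sequences, then assembles positives, shuffled
negatives and healthy negatives at 2:1:1 and splits them 64/16/20.
"""

from tcrshield import SyntheticConfig, make_benchmark

bench = make_benchmark(SyntheticConfig(seed=42))

print(f"epitopes and their planted motifs: {bench.rule.motifs}")
print(f"group counts: {bench.pairs.group_counts()}")
print(
    f"split sizes: train={len(bench.train)} pool={len(bench.pool)} "
    f"test={len(bench.test)} "
    f"({100 * len(bench.train) / len(bench.pairs):.0f}% train)"
)
print("example positive pair:", bench.train.positives().pairs[0])

# The pair counts follow the 2:1:1 positive:shuffled:healthy protocol and the
# train percentage is the 64% used to fit the base predictors.
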