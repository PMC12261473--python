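"""Synthetic CDR3beta/epitope benchmark with a planted, learnable binding rule.

Real TCR-epitope resources (VDJdb/IEDB/McPAS positives, multi-million healthy
repertoires) require downloads, so the whole framework trains and tests on a
generated stand-in instead.  The generator emulates the structural features
the pipeline actually exercises:

* CDR3beta-like TCRs — conserved ``CASS`` prefix, one of a small set of
  ``...F`` suffixes, lengths ~12-18, middle residues drawn from a skewed
  background distribution;
* short epitopes (8-11 aa);
* an epitope-specific binding rule: each epitope has a short private motif
  planted (with optional per-position corruption) in the central window of
  its binding TCRs, so classifiers have a genuine learnable signal and the
  per-epitope reference sets used for similarity scoring are meaningful;
* the three pair groups — positives, shuffled negatives (a binding TCR
  reassigned to a different epitope) and healthy negatives (epitopes paired
  with background repertoire TCRs) — at the 2:1:1 default composition;
* the 64/16/20 train/pool/test split.

Everything is a pure function of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .seqio import (
    ALPHABET,
    RESIDUES,
    BindingPair,
    PairDataset,
    validate_sequence,
)

__all__ = [
    "SyntheticConfig",
    "BindingRule",
    "generate_epitopes",
    "generate_repertoire",
    "make_binding_rule",
    "plant_positives",
    "make_negative_shuffle",
    "make_negative_healthy",
    "split_dataset",
    "make_benchmark",
    "Benchmark",
]

#: conserved CDR3beta ends used by the generator
DEFAULT_PREFIX = "CASS"
DEFAULT_SUFFIXES = ("EQYF", "EQFF", "YTF")

# Skewed residue background for the variable middle of the CDR3 loop: small
# and flexible residues (G, S, L, A, R, T) are favoured, as in real junctions.
_BG_WEIGHTS = {
    "G": 3.0, "S": 3.0, "L": 2.5, "A": 2.0, "R": 2.0, "T": 2.0,
    "D": 1.5, "E": 1.5, "N": 1.2, "Q": 1.2, "P": 1.2, "V": 1.2,
    "F": 1.0, "Y": 1.0, "I": 1.0, "K": 1.0, "H": 0.8, "M": 0.6,
    "W": 0.4, "C": 0.3,
}
_BG_P = np.array([_BG_WEIGHTS[r] for r in RESIDUES])
_BG_P = _BG_P / _BG_P.sum()


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for the synthetic benchmark.

    Defaults give 4 epitopes x 150 binders = 600 positives plus 300 shuffled
    and 300 healthy negatives (the 2:1:1 composition), with a 2000-sequence
    background repertoire for healthy sampling and likelihood-model training.
    """

    n_epitopes: int = 4
    tcrs_per_epitope: int = 150
    n_healthy: int = 2000
    length_range: Tuple[int, int] = (12, 18)
    epitope_length_range: Tuple[int, int] = (8, 11)
    motif_length: int = 4
    #: per-position motif corruption probability.  The default rule is exact
    #: containment: corrupted-motif positives are observationally identical
    #: to plausible non-binders, so any noise injects irreducible label
    #: ambiguity; set > 0 deliberately to study robustness under such noise.
    motif_noise: float = 0.0
    prefix: str = DEFAULT_PREFIX
    suffixes: Tuple[str, ...] = DEFAULT_SUFFIXES
    seed: int = 0

    def __post_init__(self):
        if min(self.n_epitopes, self.tcrs_per_epitope, self.n_healthy) <= 0:
            raise ValueError("all counts must be positive")
        for lo, hi in (self.length_range, self.epitope_length_range):
            if lo > hi:
                raise ValueError(f"length range ({lo},{hi}) not ordered")
        if not 0.0 <= self.motif_noise <= 1.0:
            raise ValueError("motif_noise must lie in [0,1]")
        min_len = self.length_range[0]
        ends = len(self.prefix) + max(len(s) for s in self.suffixes)
        if min_len < ends + 1:
            raise ValueError(
                f"length_range too short: minimum {min_len} cannot fit "
                f"prefix+suffix ({ends}) plus a variable middle"
            )


@dataclass(frozen=True)
class BindingRule:
    """The planted epitope-specific binding rule: epitope -> private motif.

    A TCR binds an epitope iff it carries that epitope's motif in the central
    window between the conserved ends (subject to corruption noise when
    positives are planted).
    """

    motifs: Dict[str, str]

    def __post_init__(self):
        vals = list(self.motifs.values())
        if len(set(vals)) != len(vals):
            raise ValueError("per-epitope motifs must be distinct")
        for m in vals:
            validate_sequence(m, "motif")

    def motif_for(self, epitope: str) -> str:
        return self.motifs[epitope]

    def matches(self, tcr: str, epitope: str) -> bool:
        """Noiseless containment check — the oracle classifier for the rule."""
        return self.motifs[epitope] in tcr


def _random_seq(rng: np.random.Generator, length: int, p: Optional[np.ndarray] = None) -> str:
    idx = rng.choice(20, size=length, p=p)
    return "".join(RESIDUES[i] for i in idx)


def generate_epitopes(cfg: SyntheticConfig, seed: int) -> List[str]:
    """Distinct uniform-random epitopes with lengths in the configured range."""
    rng = np.random.default_rng(seed)
    lo, hi = cfg.epitope_length_range
    out: List[str] = []
    seen = set()
    while len(out) < cfg.n_epitopes:
        e = _random_seq(rng, int(rng.integers(lo, hi + 1)))
        if e not in seen:
            seen.add(e)
            out.append(e)
    return out


def generate_repertoire(n: int, cfg: SyntheticConfig, seed: int) -> List[str]:
    """Background CDR3beta-like sequences with no planted motif.

    Each sequence is prefix + background middle + suffix, with total length
    drawn uniformly from ``cfg.length_range``.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    rng = np.random.default_rng(seed)
    lo, hi = cfg.length_range
    out = []
    for _ in range(n):
        suffix = cfg.suffixes[int(rng.integers(len(cfg.suffixes)))]
        length = int(rng.integers(lo, hi + 1))
        mid = length - len(cfg.prefix) - len(suffix)
        out.append(cfg.prefix + _random_seq(rng, mid, _BG_P) + suffix)
    return out


def make_binding_rule(epitopes: Sequence[str], cfg: SyntheticConfig, seed: int) -> BindingRule:
    """Draw one distinct private motif per epitope."""
    if cfg.motif_length >= cfg.length_range[0] - 4:
        raise ValueError("motif too long for the configured TCR lengths")
    rng = np.random.default_rng(seed)
    motifs: Dict[str, str] = {}
    used = set()
    for e in epitopes:
        while True:
            m = _random_seq(rng, cfg.motif_length)
            # binding motifs are specific contact patterns: require sequence
            # complexity so a motif is never itself a low-complexity repeat
            if m not in used and len(set(m)) >= min(3, cfg.motif_length):
                used.add(m)
                motifs[e] = m
                break
    return BindingRule(motifs=motifs)


def plant_positives(
    epitopes: Sequence[str], rule: BindingRule, cfg: SyntheticConfig, seed: int
) -> PairDataset:
    """Positive pairs: background TCRs with the epitope's motif written into
    the central window, each position corrupted independently with
    probability ``cfg.motif_noise``."""
    rng = np.random.default_rng(seed)
    pairs = []
    for e in epitopes:
        motif = rule.motif_for(e)
        backbones = generate_repertoire(
            cfg.tcrs_per_epitope, cfg, int(rng.integers(2**31))
        )
        for t in backbones:
            lo = len(cfg.prefix)
            hi = len(t) - 3 - len(motif)  # keep at least the last 3 suffix residues
            pos = int(rng.integers(lo, max(lo + 1, hi + 1)))
            planted = list(motif)
            for i in range(len(planted)):
                if rng.random() < cfg.motif_noise:
                    planted[i] = RESIDUES[int(rng.integers(20))]
            seq = t[:pos] + "".join(planted) + t[pos + len(motif):]
            pairs.append(BindingPair(tcr=seq, epitope=e, label=1, group="positive"))
    return PairDataset(pairs)


def make_negative_shuffle(
    positives: PairDataset, seed: int, n: Optional[int] = None
) -> PairDataset:
    """Shuffled negatives: a binding TCR reassigned to an epitope it is not
    known to bind.

    The constraint is pair-level: no emitted pair duplicates a known positive
    pair (a TCR may still appear with several epitopes).  Default size is
    half the positive count, giving the 2:1:1 overall composition when
    combined with an equal number of healthy negatives.
    """
    epitopes = positives.epitopes()
    if len(epitopes) < 2:
        raise ValueError("negative shuffling needs at least 2 distinct epitopes")
    if n is None:
        n = len(positives) // 2
    rng = np.random.default_rng(seed)
    pos_keys = {(p.tcr, p.epitope) for p in positives}
    tcr_to_eps: Dict[str, set] = {}
    for p in positives:
        tcr_to_eps.setdefault(p.tcr, set()).add(p.epitope)
    tcrs = sorted(tcr_to_eps)
    pairs = []
    emitted = set()
    attempts = 0
    max_attempts = 200 * n
    while len(pairs) < n and attempts < max_attempts:
        attempts += 1
        t = tcrs[int(rng.integers(len(tcrs)))]
        candidates = [e for e in epitopes if e not in tcr_to_eps[t]]
        if not candidates:
            continue
        e = candidates[int(rng.integers(len(candidates)))]
        if (t, e) in pos_keys or (t, e) in emitted:
            continue
        emitted.add((t, e))
        pairs.append(BindingPair(tcr=t, epitope=e, label=0, group="neg_shuffle"))
    if len(pairs) < n:
        raise ValueError(f"could only construct {len(pairs)} of {n} shuffled negatives")
    return PairDataset(pairs)


def make_negative_healthy(
    epitopes: Sequence[str], healthy: Sequence[str], n: int, seed: int
) -> PairDataset:
    """Healthy negatives: epitopes paired with background repertoire TCRs,
    drawn without replacement while the repertoire lasts."""
    if not healthy:
        raise ValueError("healthy repertoire is empty")
    if n <= 0:
        raise ValueError("n must be positive")
    rng = np.random.default_rng(seed)
    healthy = list(healthy)
    order: List[str] = []
    while len(order) < n:
        take = min(n - len(order), len(healthy))
        idx = rng.choice(len(healthy), size=take, replace=False)
        order.extend(healthy[i] for i in idx)
    pairs = [
        BindingPair(
            tcr=t,
            epitope=epitopes[int(rng.integers(len(epitopes)))],
            label=0,
            group="neg_healthy",
        )
        for t in order
    ]
    return PairDataset(pairs)


def split_dataset(
    ds: PairDataset,
    fractions: Tuple[float, float, float] = (0.64, 0.16, 0.20),
    seed: int = 0,
) -> Tuple[PairDataset, PairDataset, PairDataset]:
    """Stratified train/pool/test partition.

    Within each group, pool and test sizes are the rounded targets and the
    remainder goes to train; shuffling is seed-deterministic; the union of
    the three outputs is exactly the input.
    """
    if any(f < 0 for f in fractions):
        raise ValueError("fractions must be nonnegative")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1, got {fractions}")
    f_train, f_pool, f_test = fractions
    rng = np.random.default_rng(seed)
    train, pool, test = [], [], []
    groups = list(dict.fromkeys(p.group for p in ds))
    for g in groups:
        members = [p for p in ds if p.group == g]
        idx = rng.permutation(len(members))
        n = len(members)
        n_pool = int(round(n * f_pool))
        n_test = int(round(n * f_test))
        n_pool = min(n_pool, n)
        n_test = min(n_test, n - n_pool)
        pool.extend(members[i] for i in idx[:n_pool])
        test.extend(members[i] for i in idx[n_pool : n_pool + n_test])
        train.extend(members[i] for i in idx[n_pool + n_test :])
    return (
        PairDataset(train, split_tag="train"),
        PairDataset(pool, split_tag="pool"),
        PairDataset(test, split_tag="test"),
    )


@dataclass
class Benchmark:
    """A fully assembled synthetic study: pairs, splits, rule and repertoire."""

    config: SyntheticConfig
    epitopes: List[str]
    rule: BindingRule
    healthy: List[str]
    pairs: PairDataset
    train: PairDataset
    pool: PairDataset
    test: PairDataset


def make_benchmark(cfg: Optional[SyntheticConfig] = None, seed: Optional[int] = None) -> Benchmark:
    """Build the complete benchmark: positives + both negative groups at
    2:1:1, a healthy repertoire, and the 64/16/20 split."""
    cfg = cfg or SyntheticConfig()
    seed = cfg.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    sub = [int(rng.integers(2**31)) for _ in range(6)]
    epitopes = generate_epitopes(cfg, sub[0])
    rule = make_binding_rule(epitopes, cfg, sub[1])
    healthy = generate_repertoire(cfg.n_healthy, cfg, sub[2])
    positives = plant_positives(epitopes, rule, cfg, sub[3])
    n_neg_each = len(positives) // 2
    shuffled = make_negative_shuffle(positives, sub[4], n=n_neg_each)
    healthy_neg = make_negative_healthy(epitopes, healthy, n_neg_each, sub[5])
    pairs = PairDataset(list(positives) + list(shuffled) + list(healthy_neg))
    train, pool, test = split_dataset(pairs, seed=seed)
    return Benchmark(
        config=cfg,
        epitopes=epitopes,
        rule=rule,
        healthy=healthy,
        pairs=pairs,
        train=train,
        pool=pool,
        test=test,
    )
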