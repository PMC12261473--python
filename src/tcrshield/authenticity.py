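"""Authenticity scoring of generated TCRs and false-positive identification.

A generated pair is a false positive when the binding predictor scores it
high (reward logit above a threshold) while it fails an authenticity check:
either low k-mer string-kernel similarity to the known binders of its epitope
(a TCRMatch-style score in [0,1]) or low autoregressive log-likelihood under
the model trained on authentic repertoire sequences.

The kernel between sequences a, b is

    K(a,b) = sum_k sum_{i,j} prod_{p<k} s(a[i+p], b[j+p]),
    s(x,y) = exp(beta * BLOSUM62(x,y)),

summed over k-mer lengths in a configured range, and the similarity score is
the max over reference sequences of K(q,r)/sqrt(K(q,q) K(r,r)).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .bap import BAPModel
from .generator import PolicyModel, sequence_loglik, sequence_loglik_per_token
from .seqio import (
    ALPHABET,
    PairDataset,
    SubstitutionMatrix,
    blosum62,
    heuristic_filter,
    validate_sequence,
)

__all__ = [
    "DEFAULT_BETA",
    "ReferenceDB",
    "AuthenticityScore",
    "FPThresholds",
    "FalsePositiveRecord",
    "kmer_kernel",
    "tcrmatch_score",
    "calibrate_gptll_floor",
    "identify_false_positives",
]

logger = logging.getLogger(__name__)

#: exponential scaling of BLOSUM62 scores in the per-residue similarity
DEFAULT_BETA = 0.11387

#: default k-mer length range (clipped to the shorter sequence per pair)
DEFAULT_K_RANGE = (1, 10)


def kmer_kernel(
    a: str,
    b: str,
    sub: Optional[SubstitutionMatrix] = None,
    k_range: Tuple[int, int] = DEFAULT_K_RANGE,
    beta: float = DEFAULT_BETA,
) -> float:
    """Unnormalized k-mer string kernel between two sequences.

    The k range is clipped to the shorter sequence; an empty range after
    clipping is an error.  Symmetric in (a, b) by construction.
    """
    a = validate_sequence(a)
    b = validate_sequence(b)
    sub = sub if sub is not None else blosum62()
    k_min, k_max = k_range
    if k_min < 1 or k_min > k_max:
        raise ValueError(f"invalid k range {k_range}")
    k_max = min(k_max, len(a), len(b))
    # when the configured minimum exceeds the shorter sequence, fall back to
    # the k-mer lengths that are available
    k_min = min(k_min, k_max)
    ia = ALPHABET.encode(a)
    ib = ALPHABET.encode(b)
    S = np.exp(beta * sub.scores[np.ix_(ia, ib)])
    total = 0.0
    P = S.copy()  # P[i, j] = product over the k-mer starting at (i, j)
    if k_min == 1:
        total += P.sum()
    for k in range(2, k_max + 1):
        P = P[:-1, :-1] * S[k - 1 :, k - 1 :]
        if k >= k_min:
            total += P.sum()
    return float(total)


@dataclass
class ReferenceDB:
    """Known binding TCRs, per epitope and flattened, for similarity scoring."""

    by_epitope: Dict[str, List[str]]
    k_range: Tuple[int, int] = DEFAULT_K_RANGE
    beta: float = DEFAULT_BETA
    min_scope: int = 5  # fall back to the global set below this many refs
    sub: SubstitutionMatrix = field(default_factory=blosum62)

    def __post_init__(self):
        self.by_epitope = {
            e: [validate_sequence(t) for t in ts] for e, ts in self.by_epitope.items()
        }
        self._self_kernels: Dict[str, float] = {}

    @classmethod
    def from_dataset(cls, positives: PairDataset, **kwargs) -> "ReferenceDB":
        by_ep: Dict[str, List[str]] = {}
        for p in positives:
            if p.label == 1:
                by_ep.setdefault(p.epitope, []).append(p.tcr)
        if not by_ep:
            raise ValueError("no positive pairs to build a reference database from")
        return cls(by_epitope=by_ep, **kwargs)

    @property
    def global_set(self) -> List[str]:
        return [t for ts in self.by_epitope.values() for t in ts]

    def scope(self, epitope: Optional[str]) -> List[str]:
        if epitope is not None:
            refs = self.by_epitope.get(epitope, [])
            if len(refs) >= self.min_scope:
                return refs
        return self.global_set

    def self_kernel(self, seq: str) -> float:
        if seq not in self._self_kernels:
            self._self_kernels[seq] = kmer_kernel(
                seq, seq, self.sub, self.k_range, self.beta
            )
        return self._self_kernels[seq]


def tcrmatch_score(
    query: str, refs: ReferenceDB, epitope: Optional[str] = None
) -> float:
    """Normalized similarity of a query TCR to a reference set, in [0,1].

    Scope is the epitope's known binders when an epitope is given (falling
    back to the global set when that scope is too small), else the global
    set.  Score 1 means the query matches a reference exactly under the
    kernel.
    """
    query = validate_sequence(query, "query")
    scope = refs.scope(epitope)
    if not scope:
        raise ValueError("reference scope is empty")
    kq = kmer_kernel(query, query, refs.sub, refs.k_range, refs.beta)
    best = 0.0
    for r in scope:
        kr = refs.self_kernel(r)
        val = kmer_kernel(query, r, refs.sub, refs.k_range, refs.beta)
        best = max(best, val / np.sqrt(kq * kr))
    # the exponentiated-substitution similarity is not exactly PSD, so guard
    # the Cauchy-Schwarz bound against tiny overshoot
    return float(min(best, 1.0))


@dataclass(frozen=True)
class AuthenticityScore:
    tcrmatch: float
    gptll_total: float
    gptll_per_residue: float
    heuristic_pass: bool

    def __post_init__(self):
        if not 0.0 <= self.tcrmatch <= 1.0:
            raise ValueError("tcrmatch score must lie in [0,1]")
        if self.gptll_total > 1e-9:
            raise ValueError("log-likelihood cannot be positive")


@dataclass(frozen=True)
class FPThresholds:
    """Cutoffs defining a false positive.

    ``reward_min`` logit 0 corresponds to binding probability 0.5 — sequences
    the model calls binders.  The likelihood floor is usually calibrated as a
    low percentile of held-out authentic per-token scores.
    """

    reward_min: float = 0.0
    tcrmatch_min: float = 0.8
    gptll_per_residue_min: float = -3.0
    #: candidates at least this similar to known binders are never flagged
    #: (high similarity implies binding characteristics); None disables
    tcrmatch_exempt: Optional[float] = None


@dataclass(frozen=True)
class FalsePositiveRecord:
    tcr: str
    epitope: str
    reward_logit: float
    scores: AuthenticityScore
    iteration: int = 1
    source_model: str = "bap"


def calibrate_tcrmatch_floor(
    refs: ReferenceDB,
    authentic: Sequence[Tuple[str, str]],
    percentile: float = 5.0,
) -> float:
    """Similarity floor = a low percentile of the scores that held-out
    authentic (tcr, epitope) binders achieve against the reference database.

    The absolute scale of the normalized kernel depends on its k range and
    beta, so the cutoff separating "as similar as real binders" from
    "dissimilar" is estimated on authentic held-out pairs rather than fixed.
    """
    if not authentic:
        raise ValueError("need authentic pairs to calibrate against")
    scores = [tcrmatch_score(t, refs, e) for t, e in authentic]
    return float(np.percentile(scores, percentile))


def degenerate_anchors(lengths: Sequence[int] = (2, 6, 12, 18)) -> List[str]:
    """Constructed implausible sequences — single-residue repeats and
    dipeptide repeats at several lengths — used as the negative anchor when
    calibrating authenticity cutoffs."""
    out: List[str] = []
    for L in lengths:
        for r in "AEKWNG":
            out.append(r * L)
        out.append(("KW" * L)[:L])
        out.append(("NG" * L)[:L])
    return sorted(set(out))


def calibrate_fp_thresholds(
    refs: ReferenceDB,
    gptll: PolicyModel,
    authentic: Sequence[Tuple[str, str]],
    reward_min: float = 0.0,
    percentile: float = 5.0,
    anchor_weight: float = 0.25,
    tcrmatch_anchor_weight: float = 0.5,
) -> FPThresholds:
    """Anchor the authenticity cutoffs between authentic and degenerate scores.

    Each floor interpolates between a low percentile of held-out authentic
    binders' scores and the median score of constructed degenerate sequences
    (repeats, ultra-short), ``anchor_weight`` giving the degenerate side's
    share.  This flags gross implausibility — the regime the authenticity
    metrics are meant to police — rather than mild atypicality, which matters
    because RL-shifted generations are always somewhat atypical of the
    authentic distribution.
    """
    if not authentic:
        raise ValueError("need authentic pairs to calibrate against")
    if not 0.0 <= anchor_weight <= 1.0:
        raise ValueError("anchor_weight must lie in [0,1]")
    anchors = degenerate_anchors()
    auth_tm = [tcrmatch_score(t, refs, e) for t, e in authentic]
    auth_gl = [sequence_loglik_per_token(gptll, t) for t, _ in authentic]
    degen_tm = [tcrmatch_score(s, refs) for s in anchors]
    degen_gl = [sequence_loglik_per_token(gptll, s) for s in anchors]
    # the kernel-similarity floor gets a wider margin: at small reference-set
    # sizes the similarity of authentic binders is noisy near its lower tail,
    # so only confidently dissimilar sequences should fail this arm
    w_tm = tcrmatch_anchor_weight
    w_gl = anchor_weight
    tm_lo = np.percentile(auth_tm, percentile)
    gl_lo = np.percentile(auth_gl, percentile)
    tm_min = float((1 - w_tm) * tm_lo + w_tm * np.median(degen_tm))
    gl_min = float((1 - w_gl) * gl_lo + w_gl * np.median(degen_gl))
    return FPThresholds(
        reward_min=reward_min,
        tcrmatch_min=min(tm_min, tm_lo),
        gptll_per_residue_min=min(gl_min, gl_lo),
        tcrmatch_exempt=float(np.median(auth_tm)),
    )


def calibrate_gptll_floor(
    gptll: PolicyModel, authentic: Sequence[str], percentile: float = 5.0
) -> float:
    """Likelihood floor = a low percentile of per-token scores of authentic
    held-out sequences."""
    if not authentic:
        raise ValueError("need authentic sequences to calibrate against")
    scores = [sequence_loglik_per_token(gptll, s) for s in authentic]
    return float(np.percentile(scores, percentile))


def score_sequence(
    tcr: str,
    epitope: str,
    refs: ReferenceDB,
    gptll: PolicyModel,
) -> AuthenticityScore:
    total = sequence_loglik(gptll, tcr)
    return AuthenticityScore(
        tcrmatch=tcrmatch_score(tcr, refs, epitope),
        gptll_total=total,
        gptll_per_residue=total / (len(tcr) + 1),
        heuristic_pass=heuristic_filter(tcr),
    )


def identify_false_positives(
    candidates: Sequence[Tuple[str, str, float]],
    bap: BAPModel,
    refs: ReferenceDB,
    gptll: PolicyModel,
    thresholds: Optional[FPThresholds] = None,
    iteration: int = 1,
    source_model: str = "bap",
) -> List[FalsePositiveRecord]:
    """Flag candidates with high reward but low authenticity.

    A candidate is a false positive when ``reward >= reward_min`` and it
    fails *either* authenticity metric (similarity below ``tcrmatch_min`` OR
    per-token log-likelihood below the floor).  Candidates whose similarity
    reaches ``tcrmatch_exempt`` are presumed to carry real binding
    characteristics and are never flagged.  Deduplicated on (tcr, epitope),
    keeping the maximal reward.
    """
    thresholds = thresholds or FPThresholds()
    best: Dict[Tuple[str, str], float] = {}
    order: List[Tuple[str, str]] = []
    for t, e, r in candidates:
        key = (t, e)
        if key not in best:
            best[key] = r
            order.append(key)
        elif r > best[key]:
            best[key] = r
    out: List[FalsePositiveRecord] = []
    for t, e in order:
        r = best[(t, e)]
        if r < thresholds.reward_min:
            continue
        scores = score_sequence(t, e, refs, gptll)
        if (
            thresholds.tcrmatch_exempt is not None
            and scores.tcrmatch >= thresholds.tcrmatch_exempt
        ):
            continue
        if (
            scores.tcrmatch < thresholds.tcrmatch_min
            or scores.gptll_per_residue < thresholds.gptll_per_residue_min
        ):
            out.append(
                FalsePositiveRecord(
                    tcr=t,
                    epitope=e,
                    reward_logit=r,
                    scores=scores,
                    iteration=iteration,
                    source_model=source_model,
                )
            )
    return out
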