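"""Post-hoc characterization of adversarial negatives: CDR3 distances,
silhouette-selected medoid clustering, position-frequency motif matrices and
per-iteration reports.

The distance is the CDR3 term of the similarity-weighted Hamming family:
sequences are length-equalized by central gap insertion, mismatches cost
``min(cap, cap - substitution score)``, gaps a fixed penalty, and the central
loop positions are up-weighted.  Only symmetry, nonnegativity and zero
self-distance are guaranteed — the weighting does not satisfy the triangle
inequality in general.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.metrics import silhouette_samples, silhouette_score

from .bap import evaluate_groups, predict_logits
from .seqio import ALPHABET, RESIDUES, PairDataset, SubstitutionMatrix, blosum62, validate_sequence

__all__ = [
    "DistanceMatrix",
    "PositionFrequencyMatrix",
    "tcrdist",
    "distance_matrix",
    "cluster_by_silhouette",
    "position_frequency_matrix",
    "iteration_report",
]

#: substitution-cost cap and central up-weighting used by the CDR3 distance
DEFAULT_CAP = 4.0
DEFAULT_GAP_PENALTY = 4.0
DEFAULT_CENTER_WEIGHT = 3.0

_GAP = "-"


@dataclass
class DistanceMatrix:
    values: np.ndarray
    sequences: List[str]

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("distance matrix must be square")
        if not np.allclose(v, v.T):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(v) != 0):
            raise ValueError("distance matrix must have zero diagonal")
        if np.any(v < 0):
            raise ValueError("distances must be nonnegative")
        self.values = v

    def __len__(self) -> int:
        return len(self.sequences)


def _center_gapped(seq: str, target_len: int) -> str:
    """Insert gaps centrally to stretch `seq` to `target_len`."""
    n_gap = target_len - len(seq)
    if n_gap <= 0:
        return seq
    mid = len(seq) // 2
    return seq[:mid] + _GAP * n_gap + seq[mid:]


def tcrdist(
    a: str,
    b: str,
    sub: Optional[SubstitutionMatrix] = None,
    gap_penalty: float = DEFAULT_GAP_PENALTY,
    center_weight: float = DEFAULT_CENTER_WEIGHT,
    cap: float = DEFAULT_CAP,
) -> float:
    """Similarity-weighted Hamming-style distance between two CDR3 sequences.

    Per-position cost: 0 for identical residues, ``gap_penalty`` where a gap
    was inserted, else ``min(cap, cap - substitution_score)``; positions in
    the central third (the loop apex) are multiplied by ``center_weight``.
    Symmetric; zero iff the strings are equal.
    """
    a = validate_sequence(a)
    b = validate_sequence(b)
    sub = sub if sub is not None else blosum62()
    L = max(len(a), len(b))
    ga, gb = _center_gapped(a, L), _center_gapped(b, L)
    lo, hi = L // 3, L - L // 3  # central third
    total = 0.0
    for i, (x, y) in enumerate(zip(ga, gb)):
        if x == y:
            cost = 0.0
        elif x == _GAP or y == _GAP:
            cost = gap_penalty
        else:
            cost = min(cap, cap - sub.score(x, y))
        if lo <= i < hi:
            cost *= center_weight
        total += cost
    return float(total)


def distance_matrix(
    seqs: Sequence[str],
    sub: Optional[SubstitutionMatrix] = None,
    gap_penalty: float = DEFAULT_GAP_PENALTY,
    center_weight: float = DEFAULT_CENTER_WEIGHT,
) -> DistanceMatrix:
    sub = sub if sub is not None else blosum62()
    seqs = [validate_sequence(s) for s in seqs]
    n = len(seqs)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = tcrdist(seqs[i], seqs[j], sub, gap_penalty, center_weight)
    return DistanceMatrix(values=d, sequences=list(seqs))


def _kmedoids(d: np.ndarray, k: int, max_iter: int = 100) -> np.ndarray:
    """Deterministic k-medoids on a precomputed distance matrix.

    Initialization is farthest-first from the 1-medoid (the point minimizing
    total distance), which makes the result invariant to input order up to
    distance ties.
    """
    n = d.shape[0]
    medoids = [int(np.argmin(d.sum(axis=1)))]
    while len(medoids) < k:
        dist_to_nearest = d[:, medoids].min(axis=1)
        medoids.append(int(np.argmax(dist_to_nearest)))
    medoids = np.array(medoids)
    for _ in range(max_iter):
        assign = np.argmin(d[:, medoids], axis=1)
        new_medoids = medoids.copy()
        for c in range(k):
            members = np.where(assign == c)[0]
            if len(members) == 0:
                continue
            within = d[np.ix_(members, members)].sum(axis=1)
            new_medoids[c] = members[int(np.argmin(within))]
        if np.array_equal(new_medoids, medoids):
            break
        medoids = new_medoids
    return np.argmin(d[:, medoids], axis=1)


def cluster_by_silhouette(
    d: DistanceMatrix, k_range: Sequence[int] = (2, 3, 4, 5), seed: int = 0
) -> Tuple[Optional[np.ndarray], Optional[int], Dict[int, float]]:
    """Medoid clustering at each k; return the assignment maximizing the mean
    silhouette (ties broken toward smaller k).

    Returns ``(assignment, chosen_k, silhouette_per_k)``; for degenerate
    input (all pairwise distances zero) the assignment and k are None.
    """
    if any(k < 2 for k in k_range):
        raise ValueError("k_range values must be >= 2")
    n = len(d)
    if n < max(k_range) + 1:
        raise ValueError(f"need at least {max(k_range)+1} sequences")
    if np.allclose(d.values, 0):
        return None, None, {}
    scores: Dict[int, float] = {}
    assignments: Dict[int, np.ndarray] = {}
    for k in sorted(k_range):
        labels = _kmedoids(d.values, k)
        if len(np.unique(labels)) < 2:
            continue
        scores[k] = float(silhouette_score(d.values, labels, metric="precomputed"))
        assignments[k] = labels
    if not scores:
        return None, None, {}
    best_k = max(sorted(scores), key=lambda k: (scores[k], -k))
    return assignments[best_k], best_k, scores


@dataclass
class PositionFrequencyMatrix:
    """Per-position residue frequencies over an aligned set of sequences.

    Rows with zero coverage are all-zero and listed in ``empty_rows``; every
    covered row sums to 1.
    """

    values: np.ndarray  # L x 20
    mode: str
    coverage: np.ndarray  # per-position sequence counts

    @property
    def empty_rows(self) -> np.ndarray:
        return np.where(self.coverage == 0)[0]


def position_frequency_matrix(
    seqs: Sequence[str], mode: str = "left"
) -> PositionFrequencyMatrix:
    """Residue frequency matrix underlying a sequence-logo plot.

    ``mode='left'``: sequences anchored at position 0 (ragged right edge);
    ``mode='center-gapped'``: shorter sequences stretched by central gaps,
    as in the distance computation.
    """
    if not seqs:
        raise ValueError("need at least one sequence")
    if mode not in ("left", "center-gapped"):
        raise ValueError(f"unknown alignment mode {mode!r}")
    seqs = [validate_sequence(s) for s in seqs]
    L = max(len(s) for s in seqs)
    counts = np.zeros((L, 20))
    for s in seqs:
        aligned = s if mode == "left" else _center_gapped(s, L)
        for i, c in enumerate(aligned):
            if c != _GAP:
                counts[i, ALPHABET.index(c)] += 1
    coverage = counts.sum(axis=1)
    values = np.zeros_like(counts)
    covered = coverage > 0
    values[covered] = counts[covered] / coverage[covered, None]
    return PositionFrequencyMatrix(values=values, mode=mode, coverage=coverage)


def pfm_to_frame(pfm: PositionFrequencyMatrix) -> pd.DataFrame:
    return pd.DataFrame(pfm.values, columns=list(RESIDUES))


def iteration_report(states: Sequence, test: PairDataset) -> pd.DataFrame:
    """Per-iteration table: new-FP count, cumulative adversarial size, and
    the checkpoint's TPR/TNR per group on the evaluation set (including TNR
    on the cumulative adversarial negatives)."""
    if not states:
        raise ValueError("no iteration states")
    rows = []
    for s in states:
        rep = evaluate_groups(s.bap_checkpoint, test)
        row = {
            "iteration": s.iteration,
            "fp_count": s.fp_count_this_iter,
            "cumulative_adversarial": len(s.cumulative_adversarial),
            "tpr_positive": rep.metric("positive"),
            "tnr_neg_shuffle": rep.metric("neg_shuffle"),
            "tnr_neg_healthy": rep.metric("neg_healthy"),
            "accuracy": rep.accuracy,
        }
        if len(s.cumulative_adversarial):
            z = predict_logits(s.bap_checkpoint, s.cumulative_adversarial.pairs)
            row["tnr_adversarial"] = float((z < 0).mean())
        else:
            row["tnr_adversarial"] = float("nan")
        rows.append(row)
    return pd.DataFrame(rows)
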