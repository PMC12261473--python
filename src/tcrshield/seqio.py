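"""Alphabet, substitution matrix, sequence encodings, pair I/O and plausibility filters.

Sequences throughout the package are CDR3beta amino-acid strings over the 20
canonical residues; epitopes are short (8-11 aa) peptides over the same
alphabet.  This module owns the shared vocabulary (residues plus the special
tokens used by the autoregressive models), the BLOSUM62 encoding used by the
static-embedding classifiers, and the CSV/FASTA plumbing every other module
goes through.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO as _BioSeqIO
from Bio.Align import substitution_matrices as _submat

__all__ = [
    "RESIDUES",
    "AminoAcidAlphabet",
    "ALPHABET",
    "SubstitutionMatrix",
    "blosum62",
    "BindingPair",
    "PairDataset",
    "GROUPS",
    "validate_sequence",
    "encode_blosum",
    "encode_indices",
    "max_residue_run",
    "heuristic_filter",
    "read_pairs",
    "write_pairs",
    "read_repertoire",
    "write_repertoire",
]

#: the 20 canonical residues, in the fixed order used by every encoding
RESIDUES = "ACDEFGHIKLMNPQRSTVWY"

#: legal values of :attr:`BindingPair.group`
GROUPS = ("positive", "neg_shuffle", "neg_healthy", "adversarial")


class SequenceValidationError(ValueError):
    """A sequence contains characters outside the canonical residue alphabet."""


class PairParseError(ValueError):
    """A pairs file row could not be parsed."""


@dataclass(frozen=True)
class AminoAcidAlphabet:
    """Canonical residue alphabet plus the special tokens of the sequence models.

    Residues occupy token ids ``0..19`` (in :data:`RESIDUES` order); the
    special tokens (padding, begin/end of sequence, epitope/TCR separator)
    take the ids after them so the two ranges never overlap.
    """

    residues: str = RESIDUES
    pad: int = 20
    bos: int = 21
    eos: int = 22
    sep: int = 23

    @property
    def n_residues(self) -> int:
        return len(self.residues)

    @property
    def vocab_size(self) -> int:
        """Residues plus the four special tokens."""
        return self.n_residues + 4

    def index(self, residue: str) -> int:
        i = self.residues.find(residue)
        if i < 0:
            raise SequenceValidationError(f"residue {residue!r} is not canonical")
        return i

    def encode(self, seq: str) -> np.ndarray:
        """Token ids of a residue string (no specials appended)."""
        validate_sequence(seq, what="sequence")
        lut = {c: i for i, c in enumerate(self.residues)}
        return np.array([lut[c] for c in seq], dtype=np.int64)

    def decode(self, ids: Iterable[int]) -> str:
        out = []
        for i in ids:
            if 0 <= i < self.n_residues:
                out.append(self.residues[i])
            elif i == self.eos:
                break
            else:
                raise SequenceValidationError(f"token id {i} is not a residue")
        return "".join(out)


#: module-level default alphabet shared by all models
ALPHABET = AminoAcidAlphabet()


def validate_sequence(seq: str, what: str = "sequence") -> str:
    """Uppercase and validate a residue string; reject ambiguous codes.

    Ambiguous one-letter codes (B, J, O, U, X, Z) are rejected rather than
    silently dropped so the model vocabularies stay fixed.
    """
    if not isinstance(seq, str) or not seq:
        raise SequenceValidationError(f"{what} must be a nonempty string, got {seq!r}")
    up = seq.upper()
    bad = set(up) - set(RESIDUES)
    if bad:
        raise SequenceValidationError(
            f"{what} {seq!r} contains non-canonical residues {sorted(bad)}"
        )
    return up


@dataclass(frozen=True)
class SubstitutionMatrix:
    """A symmetric 20x20 integer residue-substitution score table."""

    scores: np.ndarray
    name: str = "BLOSUM62"

    def __post_init__(self):
        s = np.asarray(self.scores)
        if s.shape != (20, 20):
            raise ValueError(f"expected a 20x20 table, got shape {s.shape}")
        if not np.array_equal(s, s.T):
            raise ValueError("substitution matrix must be symmetric")
        object.__setattr__(self, "scores", s)

    def score(self, a: str, b: str) -> float:
        return float(self.scores[ALPHABET.index(a), ALPHABET.index(b)])


def blosum62() -> SubstitutionMatrix:
    """The standard BLOSUM62 table restricted to the 20 canonical residues."""
    m = _submat.load("BLOSUM62")
    idx = [m.alphabet.index(r) for r in RESIDUES]
    scores = np.asarray(m)[np.ix_(idx, idx)].astype(np.int64)
    return SubstitutionMatrix(scores=scores, name="BLOSUM62")


@dataclass(frozen=True)
class BindingPair:
    """One (TCR, epitope) record: the unit of every dataset in the package.

    ``group`` encodes the provenance class of the pair; positives carry
    label 1 and every negative group label 0.  Adversarial pairs always
    record which model produced them and in which attack iteration.
    """

    tcr: str
    epitope: str
    label: int
    group: str = "positive"
    source_model: Optional[str] = None
    iteration: Optional[int] = None

    def __post_init__(self):
        object.__setattr__(self, "tcr", validate_sequence(self.tcr, "tcr"))
        object.__setattr__(self, "epitope", validate_sequence(self.epitope, "epitope"))
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}; expected one of {GROUPS}")
        if self.label not in (0, 1):
            raise ValueError(f"label must be 0 or 1, got {self.label!r}")
        if (self.group == "positive") != (self.label == 1):
            raise ValueError(
                f"group {self.group!r} inconsistent with label {self.label}"
            )
        if self.group == "adversarial" and (
            self.source_model is None or self.iteration is None
        ):
            raise ValueError("adversarial pairs must carry source_model and iteration")


@dataclass
class PairDataset:
    """An ordered collection of :class:`BindingPair` with an optional split tag."""

    pairs: list = field(default_factory=list)
    split_tag: Optional[str] = None

    def __post_init__(self):
        self._check_consistency()

    def _check_consistency(self):
        seen: dict = {}
        for p in self.pairs:
            key = (p.tcr, p.epitope)
            if key in seen and seen[key] != p.label:
                raise ValueError(
                    f"conflicting labels for pair {key}: {seen[key]} vs {p.label}"
                )
            seen[key] = p.label

    def __len__(self) -> int:
        return len(self.pairs)

    def __iter__(self) -> Iterator[BindingPair]:
        return iter(self.pairs)

    def __getitem__(self, i):
        return self.pairs[i]

    def by_group(self, group: str) -> "PairDataset":
        return PairDataset([p for p in self.pairs if p.group == group],
                           split_tag=self.split_tag)

    def group_counts(self) -> dict:
        counts: dict = {}
        for p in self.pairs:
            counts[p.group] = counts.get(p.group, 0) + 1
        return counts

    def positives(self) -> "PairDataset":
        return self.by_group("positive")

    def epitopes(self) -> list:
        """Distinct epitopes in first-appearance order."""
        return list(dict.fromkeys(p.epitope for p in self.pairs))

    def labels(self) -> np.ndarray:
        return np.array([p.label for p in self.pairs], dtype=np.int64)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "tcr": [p.tcr for p in self.pairs],
                "epitope": [p.epitope for p in self.pairs],
                "label": [p.label for p in self.pairs],
                "group": [p.group for p in self.pairs],
                "source_model": [p.source_model or "" for p in self.pairs],
                "iteration": ["" if p.iteration is None else p.iteration
                              for p in self.pairs],
            }
        )

    def concat(self, other: "PairDataset") -> "PairDataset":
        return PairDataset(list(self.pairs) + list(other.pairs))

    def with_tag(self, tag: str) -> "PairDataset":
        return PairDataset(list(self.pairs), split_tag=tag)


def encode_blosum(
    seq: str,
    matrix: Optional[SubstitutionMatrix] = None,
    max_len: int = 30,
    pad_value: float = 0.0,
) -> np.ndarray:
    """Encode a sequence as a ``max_len x 20`` matrix of substitution-table rows.

    Row ``i`` is the matrix row of residue ``i``; rows past the sequence end
    are filled with ``pad_value``.  This is the classic static BLOSUM62
    featurization used by sequence classifiers.
    """
    matrix = matrix if matrix is not None else blosum62()
    seq = validate_sequence(seq)
    if len(seq) > max_len:
        raise ValueError(f"sequence length {len(seq)} exceeds max_len {max_len}")
    out = np.full((max_len, 20), float(pad_value))
    idx = ALPHABET.encode(seq)
    out[: len(seq)] = matrix.scores[idx]
    return out


def encode_indices(seq: str, max_len: int, alphabet: AminoAcidAlphabet = ALPHABET) -> np.ndarray:
    """Token ids right-padded with the pad token to ``max_len``."""
    seq = validate_sequence(seq)
    if len(seq) > max_len:
        raise ValueError(f"sequence length {len(seq)} exceeds max_len {max_len}")
    out = np.full(max_len, alphabet.pad, dtype=np.int64)
    out[: len(seq)] = alphabet.encode(seq)
    return out


def max_residue_run(seq: str) -> int:
    """Length of the longest run of one identical residue."""
    seq = validate_sequence(seq)
    return max(len(list(g)) for _, g in itertools.groupby(seq))


def heuristic_filter(
    seq: str, min_len: int = 5, max_len: int = 30, max_run: int = 6
) -> bool:
    """Simple plausibility screen: length in ``[min_len, max_len]`` and no
    residue repeated more than ``max_run`` times in a row.

    Catches the grossly implausible sequences (e.g. ``"AY"``, poly-E runs)
    that a degenerate generator tends to produce; returns True when the
    sequence is plausible.
    """
    if min_len > max_len:
        raise ValueError(f"min_len {min_len} > max_len {max_len}")
    seq = validate_sequence(seq)
    return min_len <= len(seq) <= max_len and max_residue_run(seq) <= max_run


# ---------------------------------------------------------------------------
# File I/O.  Pairs travel as CSV with the canonical header
# ``tcr,epitope,label,group,source_model,iteration``; unlabeled repertoires as
# FASTA or one-sequence-per-line text.
# ---------------------------------------------------------------------------

_PAIR_COLUMNS = ["tcr", "epitope", "label", "group", "source_model", "iteration"]


def read_pairs(path, fmt: str = "csv") -> PairDataset:
    """Read a labeled pairs CSV into a :class:`PairDataset`, preserving row order."""
    if fmt != "csv":
        raise ValueError(f"unsupported pairs format {fmt!r}")
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = {"tcr", "epitope", "label"} - set(df.columns)
    if missing:
        raise PairParseError(f"{path}: missing required columns {sorted(missing)}")
    pairs = []
    for row_no, row in enumerate(df.itertuples(index=False), start=2):
        try:
            label = int(float(getattr(row, "label")))
            group = getattr(row, "group", "") or ("positive" if label == 1 else "neg_shuffle")
            src = getattr(row, "source_model", "") or None
            it_raw = getattr(row, "iteration", "")
            iteration = int(it_raw) if it_raw not in ("", None) else None
            pairs.append(
                BindingPair(
                    tcr=getattr(row, "tcr"),
                    epitope=getattr(row, "epitope"),
                    label=label,
                    group=group,
                    source_model=src,
                    iteration=iteration,
                )
            )
        except SequenceValidationError:
            raise
        except (ValueError, TypeError) as exc:
            raise PairParseError(f"{path}: malformed row at line {row_no}: {exc}") from exc
    return PairDataset(pairs)


def write_pairs(ds: PairDataset, path) -> None:
    ds.to_frame().to_csv(path, index=False, columns=_PAIR_COLUMNS)


def read_repertoire(path) -> list:
    """Read unlabeled TCRs from FASTA (descriptions ignored) or plain text."""
    path = Path(path)
    text = path.read_text()
    if text.lstrip().startswith(">"):
        seqs = [str(rec.seq) for rec in _BioSeqIO.parse(path, "fasta")]
    else:
        seqs = [line.strip() for line in text.splitlines() if line.strip()]
    return [validate_sequence(s, "repertoire sequence") for s in seqs]


def write_repertoire(seqs: Sequence[str], path) -> None:
    Path(path).write_text("\n".join(seqs) + "\n")
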