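"""Autoregressive TCR sequence models: the epitope-conditioned policy used
for attack, its frozen reference copy, and the unconditioned likelihood
scorer used as an authenticity metric.

One small decoder-only transformer serves all three roles.  Conditioning is
implemented as a prefix — ``BOS, epitope, SEP, tcr..., EOS`` — with the loss
masked to the TCR tokens (the unconditioned model sees ``BOS, tcr..., EOS``).
The output head spans the 20 residues plus end-of-sequence, so generation can
only emit canonical residues; the head is zero-initialized, which makes an
untrained model exactly uniform over its output vocabulary.

The likelihood score of a sequence is the chain-rule total

    S(t) = sum_i log P(a_i | a_<i)  (+ the end-of-sequence term),

always <= 0; higher means more typical of the training distribution.  Both
the total and the per-token mean (total / (L+1)) are exposed: the total
penalizes long sequences simply for being long, so downstream false-positive
flagging uses the length-normalized form by default.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from . import nn
from .nn import Tensor
from .seqio import ALPHABET, AminoAcidAlphabet, PairDataset, validate_sequence

__all__ = [
    "GeneratorConfig",
    "PolicyModel",
    "GenerationSample",
    "sft_train",
    "sample",
    "sequence_loglik",
    "sequence_loglik_per_token",
    "train_gptll",
]

#: output head vocabulary: the 20 residues (ids 0..19) plus EOS at index 20
N_OUT = 21
_EOS_OUT = 20


@dataclass(frozen=True)
class GeneratorConfig:
    """A small decoder trained from scratch: 2 blocks, model width 48."""

    n_layers: int = 2
    d_model: int = 48
    d_ff: int = 96
    max_len: int = 30  # matches the heuristic-filter upper bound
    max_epitope_len: int = 15
    seed: int = 0


class PolicyModel(nn.Module):
    """Decoder-only autoregressive model over TCR tokens.

    ``role`` is one of ``policy`` (trainable, epitope-conditioned),
    ``reference`` (frozen SFT copy used for KL regularization) or
    ``likelihood`` (unconditioned authenticity scorer).
    """

    def __init__(self, config: Optional[GeneratorConfig] = None, role: str = "policy"):
        config = config or GeneratorConfig()
        if role not in ("policy", "reference", "likelihood"):
            raise ValueError(f"unknown role {role!r}")
        self.config = config
        self.role = role
        self.alphabet: AminoAcidAlphabet = ALPHABET
        rng = np.random.default_rng(config.seed)
        d = config.d_model
        ctx = config.max_len + config.max_epitope_len + 3
        self.tok = nn.Embedding(self.alphabet.vocab_size, d, rng)
        self.pos = nn.Embedding(ctx, d, rng)
        self.blocks = []
        for _ in range(config.n_layers):
            self.blocks.append(nn.SelfAttention(d, rng))
            self.blocks.append(nn.LayerNorm(d))
            self.blocks.append(nn.Linear(d, config.d_ff, rng))
            self.blocks.append(nn.Linear(config.d_ff, d, rng))
            self.blocks.append(nn.LayerNorm(d))
        # zero-init head: the untrained model is exactly uniform over outputs
        self.head = nn.Linear(d, N_OUT, rng, zero_init=True)

    @property
    def conditioned(self) -> bool:
        return self.role in ("policy", "reference")

    # -- core forward ------------------------------------------------------

    def forward_logits(self, tokens: np.ndarray) -> Tensor:
        """Next-token logits, shape (B, L, N_OUT), causal mask applied."""
        B, L = tokens.shape
        x = self.tok(tokens) + self.pos(np.arange(L))
        causal = np.triu(np.full((L, L), -1e9), k=1)
        mask = np.broadcast_to(causal, (B, L, L))
        for i in range(0, len(self.blocks), 5):
            att, ln1, up, down, ln2 = self.blocks[i : i + 5]
            x = ln1(x + att(x, mask))
            x = ln2(x + down(up(x).relu()))
        return self.head(x)

    def token_ids(self, tcr: str, epitope: Optional[str]) -> Tuple[np.ndarray, int]:
        """Input token sequence and the index where TCR prediction starts.

        Layout: ``BOS [epitope SEP] tcr`` — position i predicts token i+1;
        the first TCR prediction is made at index ``start-1``.
        """
        a = self.alphabet
        ids = [a.bos]
        if epitope is not None:
            ids.extend(a.encode(epitope).tolist())
            ids.append(a.sep)
        start = len(ids)
        ids.extend(a.encode(tcr).tolist())
        return np.array(ids, dtype=np.int64), start

    def copy(self, role: Optional[str] = None) -> "PolicyModel":
        out = PolicyModel(self.config, role=role or self.role)
        out.load_state_dict(self.state_dict())
        return out

    def save(self, path) -> None:
        path = Path(path)
        np.savez(path.with_suffix(".npz"), *self.state_dict())
        path.with_suffix(".json").write_text(
            json.dumps({"config": asdict(self.config), "role": self.role}, indent=2)
        )

    @classmethod
    def load(cls, path) -> "PolicyModel":
        path = Path(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        model = cls(GeneratorConfig(**meta["config"]), role=meta["role"])
        with np.load(path.with_suffix(".npz")) as z:
            model.load_state_dict([z[k] for k in z.files])
        return model


@dataclass(frozen=True)
class GenerationSample:
    """One sampled TCR with its sampling-time per-token log-probabilities."""

    tcr: str
    epitope: Optional[str]
    token_logprobs: Tuple[float, ...]
    total_logprob: float

    def __post_init__(self):
        if abs(self.total_logprob - sum(self.token_logprobs)) > 1e-6:
            raise ValueError("total_logprob must equal the sum of per-token terms")
        if self.total_logprob > 1e-12:
            raise ValueError("log-probabilities cannot be positive")


# ---------------------------------------------------------------------------
# Batched teacher-forced loss
# ---------------------------------------------------------------------------


def _batch_tokens(
    model: PolicyModel, tcrs: Sequence[str], epitopes: Optional[Sequence[Optional[str]]]
):
    """Pack a batch into padded token arrays plus target ids and loss mask.

    Targets are over the output vocabulary (residues + EOS); epitope prefix
    positions and padding are excluded from the loss.
    """
    a = model.alphabet
    rows, targets, mask = [], [], []
    for i, t in enumerate(tcrs):
        e = epitopes[i] if epitopes is not None else None
        ids, start = model.token_ids(t, e)
        tgt = np.full(len(ids), -1, dtype=np.int64)
        # position j predicts ids[j+1]; last position predicts EOS
        tgt[start - 1 : len(ids) - 1] = ids[start:]
        tgt[len(ids) - 1] = _EOS_OUT
        rows.append(ids)
        targets.append(tgt)
    L = max(len(r) for r in rows)
    tok = np.full((len(rows), L), a.pad, dtype=np.int64)
    tgt = np.full((len(rows), L), -1, dtype=np.int64)
    for i, (r, tg) in enumerate(zip(rows, targets)):
        tok[i, : len(r)] = r
        tgt[i, : len(tg)] = tg
    return tok, tgt


def _nll(model: PolicyModel, tok: np.ndarray, tgt: np.ndarray) -> Tensor:
    """Mean per-sequence negative log-likelihood of the masked targets."""
    logits = model.forward_logits(tok)
    logp = nn.log_softmax(logits, axis=-1)
    valid = tgt >= 0
    safe_tgt = np.where(valid, tgt, 0)
    B, L = tok.shape
    picked = logp[np.arange(B)[:, None], np.arange(L)[None, :], safe_tgt]
    picked = picked * Tensor(valid.astype(float))
    return -(picked.sum() / float(B))


def sft_train(
    model: PolicyModel,
    positives: PairDataset,
    epochs: int = 60,
    lr: float = 1e-3,
    seed: int = 0,
    batch_size: int = 32,
) -> Tuple[PolicyModel, PolicyModel]:
    """Supervised fine-tuning on binding pairs: maximize sum_i log p(t_i | e_i).

    Only the TCR tokens (and the end-of-sequence token) enter the loss; the
    epitope prefix is conditioning context.  Returns the trained policy and a
    frozen copy tagged ``reference``.
    """
    if model.role != "policy":
        raise ValueError("sft_train expects a model with role 'policy'")
    if len(positives) == 0:
        raise ValueError("empty SFT dataset")
    if any(p.label != 1 for p in positives):
        raise ValueError("SFT dataset must contain only positive pairs")
    model = model.copy()
    rng = np.random.default_rng(seed)
    opt = nn.Adam(model.parameters(), lr=lr)
    pairs = list(positives.pairs)
    history = []
    for _ in range(epochs):
        order = rng.permutation(len(pairs))
        ep = 0.0
        nb = 0
        for lo in range(0, len(pairs), batch_size):
            chunk = [pairs[i] for i in order[lo : lo + batch_size]]
            tok, tgt = _batch_tokens(
                model, [p.tcr for p in chunk], [p.epitope for p in chunk]
            )
            loss = _nll(model, tok, tgt)
            opt.zero_grad()
            loss.backward()
            opt.step()
            ep += float(loss.data)
            nb += 1
        history.append(ep / nb)
    model.sft_history = history
    reference = model.copy(role="reference")
    return model, reference


# ---------------------------------------------------------------------------
# Sampling and likelihood
# ---------------------------------------------------------------------------


def _np_forward_logits(model: PolicyModel, tokens: np.ndarray) -> np.ndarray:
    """Gradient-free forward pass (plain ndarray) for sampling/scoring."""
    return model.forward_logits(tokens).data


def sample(
    policy: PolicyModel,
    epitope: Optional[str],
    n: int,
    max_len: Optional[int] = None,
    temperature: float = 1.0,
    seed: int = 0,
) -> List[GenerationSample]:
    """Ancestral sampling of TCRs until EOS or ``max_len`` residues.

    Per-token log-probabilities are recorded under the sampling-time
    (temperature-scaled) distribution.  Empty draws (EOS first) are rejected
    and resampled, so recorded log-probabilities are the model's own —
    rescoring a sample at temperature 1 reproduces them exactly.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    max_len = policy.config.max_len if max_len is None else max_len
    if max_len < 1:
        raise ValueError("max_len must be at least 1")
    if policy.conditioned != (epitope is not None):
        raise ValueError(
            "epitope must be supplied iff the model is epitope-conditioned"
        )
    if epitope is not None:
        epitope = validate_sequence(epitope, "epitope")
    rng = np.random.default_rng(seed)
    out: List[GenerationSample] = []
    attempts = 0
    while len(out) < n and attempts < 20:
        attempts += 1
        need = n - len(out)
        out.extend(_sample_batch(policy, epitope, need, max_len, temperature, rng))
    if len(out) < n:
        raise RuntimeError("sampler repeatedly produced empty sequences")
    return out[:n]


def _sample_batch(policy, epitope, n, max_len, temperature, rng):
    a = policy.alphabet
    prefix = [a.bos]
    if epitope is not None:
        prefix += a.encode(epitope).tolist() + [a.sep]
    tokens = np.tile(np.array(prefix, dtype=np.int64), (n, 1))
    alive = np.ones(n, dtype=bool)
    logprobs: List[List[float]] = [[] for _ in range(n)]
    residues: List[List[int]] = [[] for _ in range(n)]
    # sequences that use the whole length budget end without an EOS term;
    # their recorded log-probabilities cover exactly the emitted residues
    for _ in range(max_len):
        logits = _np_forward_logits(policy, tokens)[:, -1, :] / temperature
        logits -= logits.max(axis=1, keepdims=True)
        logp = logits - np.log(np.exp(logits).sum(axis=1, keepdims=True))
        u = rng.random(n)
        cdf = np.cumsum(np.exp(logp), axis=1)
        cdf[:, -1] = 1.0
        choice = (u[:, None] > cdf).sum(axis=1)
        nxt = np.full(n, a.pad, dtype=np.int64)
        for i in range(n):
            if not alive[i]:
                continue
            c = int(choice[i])
            logprobs[i].append(float(logp[i, c]))
            if c == _EOS_OUT:
                alive[i] = False
            else:
                residues[i].append(c)
                nxt[i] = c
        if not alive.any():
            break
        tokens = np.concatenate([tokens, nxt[:, None]], axis=1)
    samples = []
    for i in range(n):
        if alive[i]:
            # hit max_len without EOS: drop the unterminated tail token count
            # by scoring exactly the residues emitted (no EOS term recorded)
            pass
        if not residues[i]:
            continue  # empty draw; caller resamples
        tcr = "".join(ALPHABET.residues[c] for c in residues[i])
        lp = tuple(logprobs[i])
        samples.append(
            GenerationSample(
                tcr=tcr, epitope=epitope, token_logprobs=lp, total_logprob=sum(lp)
            )
        )
    return samples


def sequence_loglik(model: PolicyModel, tcr: str, epitope: Optional[str] = None) -> float:
    """Exact chain-rule total log-likelihood of a TCR, including the EOS term."""
    tcr = validate_sequence(tcr, "tcr")
    if model.conditioned != (epitope is not None):
        raise ValueError("epitope must be supplied iff the model is conditioned")
    tok, tgt = _batch_tokens(model, [tcr], [epitope] if epitope else None)
    logits = _np_forward_logits(model, tok)[0]
    logits -= logits.max(axis=1, keepdims=True)
    logp = logits - np.log(np.exp(logits).sum(axis=1, keepdims=True))
    valid = tgt[0] >= 0
    return float(logp[np.arange(tok.shape[1])[valid], tgt[0][valid]].sum())


def sequence_loglik_per_token(
    model: PolicyModel, tcr: str, epitope: Optional[str] = None
) -> float:
    """Length-normalized log-likelihood: total / (len(tcr) + 1 EOS term)."""
    return sequence_loglik(model, tcr, epitope) / (len(tcr) + 1)


def train_gptll(
    corpus: Sequence[str],
    epochs: int = 10,
    lr: float = 1e-3,
    seed: int = 0,
    batch_size: int = 32,
    config: Optional[GeneratorConfig] = None,
    holdout_fraction: float = 0.2,
) -> Tuple[PolicyModel, Dict[str, float]]:
    """Train the unconditioned likelihood model on authentic TCR sequences.

    Returns the trained model (role ``likelihood``) and a report with the
    held-out mean total and per-token log-likelihood before and after
    training.
    """
    corpus = [validate_sequence(s, "corpus sequence") for s in corpus]
    if not corpus:
        raise ValueError("empty corpus")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(corpus))
    n_hold = max(1, int(len(corpus) * holdout_fraction))
    held = [corpus[i] for i in order[:n_hold]]
    train = [corpus[i] for i in order[n_hold:]] or held
    model = PolicyModel(config or GeneratorConfig(seed=seed), role="likelihood")

    def held_mean(m):
        tot = [sequence_loglik(m, s) for s in held]
        per = [t / (len(s) + 1) for t, s in zip(tot, held)]
        return float(np.mean(tot)), float(np.mean(per))

    before_tot, before_per = held_mean(model)
    opt = nn.Adam(model.parameters(), lr=lr)
    for _ in range(epochs):
        ep_order = rng.permutation(len(train))
        for lo in range(0, len(train), batch_size):
            chunk = [train[i] for i in ep_order[lo : lo + batch_size]]
            tok, tgt = _batch_tokens(model, chunk, None)
            loss = _nll(model, tok, tgt)
            opt.zero_grad()
            loss.backward()
            opt.step()
    after_tot, after_per = held_mean(model)
    report = {
        "holdout_loglik_before": before_tot,
        "holdout_loglik_after": after_tot,
        "holdout_per_token_before": before_per,
        "holdout_per_token_after": after_per,
        "n_train": len(train),
        "n_holdout": len(held),
    }
    return model, report
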