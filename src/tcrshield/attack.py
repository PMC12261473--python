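"""RLAIF attack: PPO drives the generator to maximize the target scorer's logit.

The reward for a generated TCR is exactly the raw logit of the binding
predictor for the (TCR, epitope) pair — no sigmoid, no clipping, no shaping —
so the policy is optimized over the unbounded pre-activation scale.  Updates
use clipped-ratio PPO with a running-mean baseline, per-batch advantage
whitening and a KL spring toward the frozen reference policy; every generated
sequence and its reward are traced so candidates can be harvested later.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from . import nn
from .nn import Tensor
from .bap import BAPModel, predict_logit
from .generator import (
    _EOS_OUT,
    GenerationSample,
    PolicyModel,
    _sample_batch,
)
from .seqio import ALPHABET

__all__ = [
    "PPOConfig",
    "StepRecord",
    "AttackTrace",
    "reward",
    "ppo_attack",
    "collect_candidates",
]


@dataclass(frozen=True)
class PPOConfig:
    steps: int = 60
    batch_per_step: int = 16
    clip_epsilon: float = 0.2
    kl_coef: float = 0.05
    ppo_epochs_per_batch: int = 2
    learning_rate: float = 3e-4
    temperature: float = 1.0
    max_len: int = 30
    seed: int = 0

    def __post_init__(self):
        if self.clip_epsilon <= 0:
            raise ValueError("clip_epsilon must be positive")
        if self.kl_coef < 0:
            raise ValueError("kl_coef must be nonnegative")


@dataclass
class StepRecord:
    """One PPO step: every sampled sequence with its raw reward logit."""

    step: int
    records: List[Tuple[str, str, float]]  # (tcr, epitope, reward logit)

    @property
    def mean_reward(self) -> float:
        return float(np.mean([r for _, _, r in self.records]))


@dataclass
class AttackTrace:
    steps: List[StepRecord] = field(default_factory=list)

    def mean_rewards(self) -> np.ndarray:
        return np.array([s.mean_reward for s in self.steps])

    def all_records(self) -> List[Tuple[str, str, float]]:
        return [r for s in self.steps for r in s.records]

    def __len__(self) -> int:
        return len(self.steps)


def reward(bap: BAPModel, tcr: str, epitope: str) -> float:
    """The RL reward: bitwise the predictor's raw logit for the pair."""
    return predict_logit(bap, tcr, epitope)


def _token_logprobs(
    policy: PolicyModel, samples: Sequence[GenerationSample]
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pack sampled sequences for re-scoring: tokens, target ids, loss mask."""
    a = policy.alphabet
    rows, tgts = [], []
    for s in samples:
        ids, start = policy.token_ids(s.tcr, s.epitope)
        tgt = np.full(len(ids), -1, dtype=np.int64)
        tgt[start - 1 : len(ids) - 1] = ids[start:]
        if len(s.token_logprobs) == len(s.tcr) + 1:  # terminated with EOS
            tgt[len(ids) - 1] = _EOS_OUT
        rows.append(ids)
        tgts.append(tgt)
    L = max(len(r) for r in rows)
    tok = np.full((len(rows), L), a.pad, dtype=np.int64)
    tgt = np.full((len(rows), L), -1, dtype=np.int64)
    for i, (r, t) in enumerate(zip(rows, tgts)):
        tok[i, : len(r)] = r
        tgt[i, : len(t)] = t
    return tok, tgt, tgt >= 0


def _gather_logp(logits: Tensor, tgt: np.ndarray, valid: np.ndarray) -> Tensor:
    logp = nn.log_softmax(logits, axis=-1)
    B, L = tgt.shape
    safe = np.where(valid, tgt, 0)
    picked = logp[np.arange(B)[:, None], np.arange(L)[None, :], safe]
    return picked * Tensor(valid.astype(float))


def ppo_attack(
    policy: PolicyModel,
    reference: PolicyModel,
    bap: BAPModel,
    epitopes: Sequence[str],
    cfg: Optional[PPOConfig] = None,
) -> Tuple[PolicyModel, AttackTrace]:
    """Run the PPO attack loop and trace every generated sequence.

    Per step: sample a batch (epitopes cycled uniformly), score each sequence
    with the raw BAP logit, form advantages (reward minus a running-mean
    baseline, whitened per batch with a no-variance fallback), and take
    clipped-ratio policy-gradient steps with a quadratic-around-zero KL
    penalty toward the frozen reference.
    """
    cfg = cfg or PPOConfig()
    if not epitopes:
        raise ValueError("epitopes must be nonempty")
    policy = policy.copy(role="policy")
    rng = np.random.default_rng(cfg.seed)
    opt = nn.Adam(policy.parameters(), lr=cfg.learning_rate)
    trace = AttackTrace()
    baseline = 0.0
    seen_batches = 0
    for step in range(cfg.steps):
        # -- rollout (epitopes cycled uniformly, batched per epitope) ------
        counts: Dict[str, int] = {}
        for i in range(cfg.batch_per_step):
            e = epitopes[(step * cfg.batch_per_step + i) % len(epitopes)]
            counts[e] = counts.get(e, 0) + 1
        samples: List[GenerationSample] = []
        for e, k in counts.items():
            got: List[GenerationSample] = []
            tries = 0
            while len(got) < k and tries < 20:
                tries += 1
                got.extend(
                    _sample_batch(
                        policy, e, k - len(got), cfg.max_len, cfg.temperature, rng
                    )
                )
            if len(got) < k:
                raise RuntimeError("policy produced only empty sequences")
            samples.extend(got[:k])
        rewards = np.array(
            [reward(bap, s.tcr, s.epitope) for s in samples], dtype=float
        )
        trace.steps.append(
            StepRecord(
                step=step,
                records=[(s.tcr, s.epitope, float(r)) for s, r in zip(samples, rewards)],
            )
        )
        # -- advantages ------------------------------------------------------
        adv = rewards - baseline
        seen_batches += 1
        baseline += (rewards.mean() - baseline) / seen_batches
        std = adv.std()
        if std > 1e-8:
            adv = (adv - adv.mean()) / std
        # degenerate batch (zero advantage variance): keep raw advantages
        tok, tgt, valid = _token_logprobs(policy, samples)
        old_lp = _gather_logp(policy.forward_logits(tok), tgt, valid).data
        ref_lp = _gather_logp(reference.forward_logits(tok), tgt, valid).data
        adv_tok = adv[:, None] * valid  # uniform credit over generated tokens
        n_tok = valid.sum()
        # -- clipped updates ------------------------------------------------
        for _ in range(cfg.ppo_epochs_per_batch):
            new_lp = _gather_logp(policy.forward_logits(tok), tgt, valid)
            ratio = (new_lp - Tensor(old_lp)).exp()
            lo, hi = 1.0 - cfg.clip_epsilon, 1.0 + cfg.clip_epsilon
            inside = ((ratio.data > lo) & (ratio.data < hi)).astype(float)
            clipped = ratio * Tensor(inside) + Tensor(
                np.clip(ratio.data, lo, hi) * (1.0 - inside)
            )
            t_raw = ratio * Tensor(adv_tok)
            t_clip = clipped * Tensor(adv_tok)
            take_raw = (t_raw.data <= t_clip.data).astype(float)
            obj = t_raw * Tensor(take_raw) + t_clip * Tensor(1.0 - take_raw)
            surrogate = obj.sum() / float(n_tok)
            # KL spring toward the reference (zero value & gradient at ref)
            delta = Tensor(ref_lp) - new_lp
            kl = (delta.exp() - 1.0 - delta) * Tensor(valid.astype(float))
            loss = -surrogate + cfg.kl_coef * (kl.sum() / float(n_tok))
            opt.zero_grad()
            loss.backward()
            opt.step()
    return policy, trace


def collect_candidates(
    trace: AttackTrace, dedupe: bool = True
) -> List[Tuple[str, str, float]]:
    """Union of all traced sequences; with dedupe, one record per (tcr,
    epitope) keeping the maximal reward."""
    if not trace.steps:
        raise ValueError("empty attack trace")
    records = trace.all_records()
    if not dedupe:
        return records
    best: Dict[Tuple[str, str], float] = {}
    order: List[Tuple[str, str]] = []
    for t, e, r in records:
        key = (t, e)
        if key not in best:
            best[key] = r
            order.append(key)
        elif r > best[key]:
            best[key] = r
    return [(t, e, best[(t, e)]) for t, e in order]
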