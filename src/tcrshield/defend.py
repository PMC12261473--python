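"""Defense phase: ratio-controlled curation, reduced-rate fine-tuning, and
the attack -> identify -> defend iteration loop.

Fine-tuning continues from the attacked model's parameters at a learning
rate 100x below base training (1e-5 vs 1e-3) on a curated set mixing the
reserved pool groups with the accumulated adversarial negatives at
configurable proportions (default 2:1:1:1 positive : shuffled : healthy :
adversarial).  Iterations stop when an attack yields a negligible number of
new false positives — at most max(5, 10% of the first iteration's count) by
default — or at the iteration cap (default 3).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .attack import PPOConfig, collect_candidates, ppo_attack
from .authenticity import (
    FalsePositiveRecord,
    FPThresholds,
    ReferenceDB,
    calibrate_gptll_floor,
    calibrate_tcrmatch_floor,
    identify_false_positives,
)
from .bap import BAPModel, EvalReport, evaluate_groups, train_bap
from .generator import PolicyModel
from .seqio import BindingPair, PairDataset

__all__ = [
    "CurationRatios",
    "IterationConfig",
    "IterationState",
    "curate_finetune_set",
    "finetune_bap",
    "run_iterations",
    "fp_records_to_dataset",
]

logger = logging.getLogger(__name__)

#: base-training learning rate (the fine-tune default is 100x lower)
BASE_LR = 1e-3
FINETUNE_LR = 1e-5


@dataclass(frozen=True)
class CurationRatios:
    """Relative group weights for the curated fine-tuning set (proportions,
    not necessarily summing to 1)."""

    positive: float = 2.0
    neg_shuffle: float = 1.0
    neg_healthy: float = 1.0
    adversarial: float = 1.0

    def __post_init__(self):
        w = (self.positive, self.neg_shuffle, self.neg_healthy, self.adversarial)
        if any(x < 0 for x in w):
            raise ValueError("ratio weights must be nonnegative")
        if sum(w) <= 0:
            raise ValueError("at least one ratio weight must be positive")

    def as_dict(self) -> Dict[str, float]:
        return {
            "positive": self.positive,
            "neg_shuffle": self.neg_shuffle,
            "neg_healthy": self.neg_healthy,
            "adversarial": self.adversarial,
        }


def _largest_remainder(weights: Dict[str, float], n_total: int) -> Dict[str, int]:
    total_w = sum(weights.values())
    quotas = {g: n_total * w / total_w for g, w in weights.items()}
    counts = {g: int(np.floor(q)) for g, q in quotas.items()}
    short = n_total - sum(counts.values())
    order = sorted(weights, key=lambda g: (-(quotas[g] - counts[g]), g))
    for g in order[:short]:
        counts[g] += 1
    return counts


def curate_finetune_set(
    pool: PairDataset,
    adversarial: PairDataset,
    ratios: Optional[CurationRatios] = None,
    n_total: int = 500,
    seed: int = 0,
    val_fraction: float = 0.1,
) -> Tuple[PairDataset, PairDataset]:
    """Sample the fine-tuning set at controlled group proportions.

    Group counts follow largest-remainder apportionment of ``n_total`` by the
    ratio weights; sampling is without replacement within each group.  When a
    group cannot supply its quota, everything it has is taken and the
    shortfall is redistributed proportionally across the remaining groups
    (with a logged warning).  A stratified ``val_fraction`` is held out for
    checkpoint selection.
    """
    ratios = ratios or CurationRatios()
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    weights = ratios.as_dict()
    supply = {
        g: [p for p in pool if p.group == g]
        for g in ("positive", "neg_shuffle", "neg_healthy")
    }
    supply["adversarial"] = [p for p in adversarial if p.group == "adversarial"]
    if weights["adversarial"] > 0 and not supply["adversarial"]:
        raise ValueError(
            "adversarial pairs requested but the adversarial set is empty"
        )
    rng = np.random.default_rng(seed)
    counts = _largest_remainder({g: w for g, w in weights.items() if w > 0}, n_total)
    chosen: Dict[str, List[BindingPair]] = {}
    # take capped groups first, then redistribute the shortfall
    remaining = dict(counts)
    while True:
        over = {g: c for g, c in remaining.items() if c > len(supply[g]) and g not in chosen}
        for g in over:
            chosen[g] = list(supply[g])
            logger.warning(
                "group %s can supply only %d of %d requested; redistributing",
                g, len(supply[g]), remaining[g],
            )
        shortfall = sum(remaining[g] - len(supply[g]) for g in over)
        open_groups = {g: remaining[g] for g in remaining if g not in chosen}
        if not over or not open_groups:
            break
        extra = _largest_remainder(
            {g: weights[g] for g in open_groups}, shortfall
        )
        remaining = {g: open_groups[g] + extra.get(g, 0) for g in open_groups}
    for g, c in remaining.items():
        if g in chosen:
            continue
        members = supply[g]
        take = min(c, len(members))
        idx = rng.choice(len(members), size=take, replace=False)
        chosen[g] = [members[i] for i in idx]
    # stratified validation carve-out
    train, val = [], []
    for g, members in chosen.items():
        if not members:
            continue
        idx = rng.permutation(len(members))
        if val_fraction <= 0 or len(members) < 2:
            n_val = 0
        else:
            n_val = max(1, int(round(len(members) * val_fraction)))
        val.extend(members[i] for i in idx[:n_val])
        train.extend(members[i] for i in idx[n_val:])
    return PairDataset(train, split_tag="train"), PairDataset(val, split_tag="val")


def finetune_bap(
    model: BAPModel,
    train: PairDataset,
    val: PairDataset,
    lr: float = FINETUNE_LR,
    epochs: int = 200,
) -> BAPModel:
    """Continue training at the reduced defense learning rate and return the
    minimum-validation-loss checkpoint; training history is appended."""
    if lr >= BASE_LR:
        logger.warning(
            "fine-tune lr %.2g is not below the base training rate %.2g", lr, BASE_LR
        )
    if epochs == 0:
        return model.clone()
    return train_bap(model, train, val, lr=lr, epochs=epochs, reset_history=False)


def fp_records_to_dataset(records: Sequence[FalsePositiveRecord]) -> PairDataset:
    """Adversarial label-0 pairs from false-positive records."""
    return PairDataset(
        [
            BindingPair(
                tcr=r.tcr,
                epitope=r.epitope,
                label=0,
                group="adversarial",
                source_model=r.source_model,
                iteration=r.iteration,
            )
            for r in records
        ]
    )


@dataclass(frozen=True)
class IterationConfig:
    max_iterations: int = 3
    stop_fraction: float = 0.1  # of the first iteration's FP count
    stop_min: int = 5
    ppo: PPOConfig = field(default_factory=PPOConfig)
    thresholds: Optional[FPThresholds] = None  # None -> calibrate at runtime
    calibration_percentile: float = 5.0
    ratios: CurationRatios = field(default_factory=CurationRatios)
    n_curated: int = 500
    finetune_lr: float = FINETUNE_LR
    finetune_epochs: int = 60
    source_model: str = "bap"
    seed: int = 0


@dataclass
class IterationState:
    """Snapshot of one attack-and-defend iteration (1-based)."""

    iteration: int
    bap_checkpoint: BAPModel
    checkpoint_id: str
    cumulative_adversarial: PairDataset
    fp_count_this_iter: int
    metrics: Optional[EvalReport] = None
    attack_mean_rewards: Optional[List[float]] = None


def run_iterations(
    base: BAPModel,
    pool: PairDataset,
    policy: PolicyModel,
    reference: PolicyModel,
    refs: ReferenceDB,
    gptll: PolicyModel,
    cfg: Optional[IterationConfig] = None,
    epitopes: Optional[Sequence[str]] = None,
    eval_dataset: Optional[PairDataset] = None,
) -> List[IterationState]:
    """Drive the attack -> identify -> defend loop to convergence.

    Each iteration re-initializes the attack policy from the supervised
    reference (a fresh attack against the current defended model), harvests
    false positives, appends them to the cumulative adversarial set, curates
    a ratio-controlled fine-tuning set from the reserved pool, and fine-tunes
    the current model; the best checkpoint becomes the next iteration's base.
    The loop stops when an iteration's new-FP count falls to at most
    ``max(stop_min, stop_fraction x iteration-1 count)`` or at the cap.
    """
    cfg = cfg or IterationConfig()
    epitopes = list(epitopes or pool.epitopes())
    thresholds = cfg.thresholds
    if thresholds is None:
        held = [(p.tcr, p.epitope) for p in pool.positives()]
        rng = np.random.default_rng(cfg.seed)
        idx = rng.choice(len(held), size=min(60, len(held)), replace=False)
        held = [held[i] for i in idx]
        thresholds = FPThresholds(
            reward_min=0.0,
            tcrmatch_min=calibrate_tcrmatch_floor(
                refs, held, cfg.calibration_percentile
            ),
            gptll_per_residue_min=calibrate_gptll_floor(
                gptll, [t for t, _ in held], cfg.calibration_percentile
            ),
        )
        logger.info("calibrated FP thresholds: %s", thresholds)
    states: List[IterationState] = []
    current = base
    cumulative = PairDataset([])
    stop_at: Optional[float] = None
    for it in range(1, cfg.max_iterations + 1):
        ppo_cfg = PPOConfig(
            **{
                **cfg.ppo.__dict__,
                "seed": cfg.ppo.seed + 1000 * it,
            }
        )
        fresh_policy = reference.copy(role="policy")
        _, trace = ppo_attack(fresh_policy, reference, current, epitopes, ppo_cfg)
        mean_rewards = [float(x) for x in trace.mean_rewards()]
        candidates = collect_candidates(trace)
        fps = identify_false_positives(
            candidates,
            current,
            refs,
            gptll,
            thresholds,
            iteration=it,
            source_model=cfg.source_model,
        )
        # keep only adversarial pairs not already accumulated
        known = {(p.tcr, p.epitope) for p in cumulative}
        new_fps = [r for r in fps if (r.tcr, r.epitope) not in known]
        fp_count = len(new_fps)
        cumulative = cumulative.concat(fp_records_to_dataset(new_fps))
        if it == 1:
            stop_at = max(cfg.stop_min, cfg.stop_fraction * fp_count)
        if fp_count == 0 and it == 1:
            logger.info("no false positives at iteration 1; nothing to defend")
            states.append(
                IterationState(
                    iteration=it,
                    bap_checkpoint=current,
                    checkpoint_id=f"iter{it}",
                    cumulative_adversarial=cumulative,
                    fp_count_this_iter=0,
                    metrics=evaluate_groups(current, eval_dataset)
                    if eval_dataset is not None
                    else None,
                    attack_mean_rewards=mean_rewards,
                )
            )
            break
        if fp_count > 0:
            train, val = curate_finetune_set(
                pool,
                cumulative,
                cfg.ratios,
                cfg.n_curated,
                seed=cfg.seed + it,
                val_fraction=0.2,
            )
            current = finetune_bap(
                current, train, val, lr=cfg.finetune_lr, epochs=cfg.finetune_epochs
            )
        states.append(
            IterationState(
                iteration=it,
                bap_checkpoint=current,
                checkpoint_id=f"iter{it}",
                cumulative_adversarial=cumulative,
                fp_count_this_iter=fp_count,
                metrics=evaluate_groups(current, eval_dataset)
                if eval_dataset is not None
                else None,
                attack_mean_rewards=mean_rewards,
            )
        )
        if fp_count <= stop_at:
            logger.info(
                "stopping after iteration %d: %d new false positives (<= %.1f)",
                it, fp_count, stop_at,
            )
            break
    return states
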