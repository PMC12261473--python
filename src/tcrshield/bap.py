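"""Binding-affinity prediction (BAP) model zoo: the attack targets.

Four architecture families — ``mlp``, ``cnn``, ``lstm`` and ``attention`` —
score a (TCR, epitope) pair with a single raw logit; the binding probability
is ``sigmoid(logit)``, so logit 0 is exactly probability 0.5.  Residues are
embedded either with static BLOSUM62 rows or a small learned table.  Training
minimizes binary cross-entropy at learning rate 0.001 for 200 epochs by
default, and the checkpoint with minimal validation loss is the one returned.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from . import nn
from .nn import Tensor
from .seqio import ALPHABET, PairDataset, SubstitutionMatrix, blosum62, validate_sequence

__all__ = [
    "ARCHITECTURES",
    "EMBEDDINGS",
    "BAPConfig",
    "BAPModel",
    "EvalReport",
    "build_bap",
    "train_bap",
    "predict_logit",
    "predict_probability",
    "logit_to_probability",
    "evaluate_groups",
]

ARCHITECTURES = ("mlp", "cnn", "lstm", "attention")
EMBEDDINGS = ("blosum62", "learned")

# BLOSUM62 entries span roughly [-4, 11]; scale rows down so all embeddings
# enter the networks at comparable magnitude.
_BLOSUM_SCALE = 0.25


@dataclass(frozen=True)
class BAPConfig:
    architecture: str = "mlp"
    embedding: str = "blosum62"
    embed_dim: int = 16
    hidden: Tuple[int, ...] = (32,)
    max_tcr_len: int = 30
    max_epi_len: int = 15
    learning_rate: float = 0.001
    epochs: int = 200
    batch_size: int = 32
    cnn_kernel: int = 3
    seed: int = 0
    val_fraction: float = 0.1

    def __post_init__(self):
        if self.architecture not in ARCHITECTURES:
            raise ValueError(
                f"unknown architecture {self.architecture!r}; expected {ARCHITECTURES}"
            )
        if self.embedding not in EMBEDDINGS:
            raise ValueError(
                f"unknown embedding {self.embedding!r}; expected {EMBEDDINGS}"
            )


class BAPModel(nn.Module):
    """A trainable binary scorer producing one raw logit per (TCR, epitope) pair."""

    def __init__(self, config: BAPConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        self._blosum = blosum62()
        d = 20 if config.embedding == "blosum62" else config.embed_dim
        if config.embedding == "learned":
            # 20 residues + pad row (kept at index 20)
            self.embed = nn.Embedding(21, config.embed_dim, rng)
        arch = config.architecture
        h = config.hidden[0] if config.hidden else 32
        if arch == "mlp":
            dims = [2 * d] + list(config.hidden) + [1]
            self.layers = [nn.Linear(a, b, rng) for a, b in zip(dims[:-1], dims[1:])]
        elif arch == "cnn":
            self.conv_t = nn.Conv1d(d, h, config.cnn_kernel, rng)
            self.conv_e = nn.Conv1d(d, h, min(config.cnn_kernel, 3), rng)
            # hidden layer lets the head model TCR-epitope interactions
            self.head_hidden = nn.Linear(2 * h, h, rng)
            self.head = nn.Linear(h, 1, rng)
        elif arch == "lstm":
            self.lstm_t = nn.LSTM(d, h, rng)
            self.lstm_e = nn.LSTM(d, h, rng)
            self.head_hidden = nn.Linear(2 * h, h, rng)
            self.head = nn.Linear(h, 1, rng)
        elif arch == "attention":
            self.proj = nn.Linear(d, h, rng)
            self.pos = nn.Embedding(config.max_tcr_len + config.max_epi_len, h, rng)
            self.att = nn.SelfAttention(h, rng)
            self.norm = nn.LayerNorm(h)
            self.head = nn.Linear(h, 1, rng)
        self.training_history: Dict[str, list] = {"train_loss": [], "val_loss": []}
        self.checkpoint_id: Optional[int] = None

    # -- featurization -----------------------------------------------------

    def _features(self, seqs: Sequence[str], max_cfg_len: int, what: str):
        """Return (features Tensor (B,L,d), lengths, pad mask (B,L) bool)."""
        lengths = np.array([len(s) for s in seqs])
        if lengths.max() > max_cfg_len:
            bad = seqs[int(lengths.argmax())]
            raise ValueError(
                f"{what} {bad!r} has length {lengths.max()} > configured "
                f"maximum {max_cfg_len} (no silent truncation)"
            )
        # pad to at least the CNN kernel width so very short generated
        # sequences (e.g. "AY") can still be scored by every architecture
        min_L = self.config.cnn_kernel if self.config.architecture == "cnn" else 3
        L = max(int(lengths.max()), min_L)
        mask = np.arange(L)[None, :] < lengths[:, None]
        if self.config.embedding == "blosum62":
            feats = np.zeros((len(seqs), L, 20))
            for i, s in enumerate(seqs):
                idx = ALPHABET.encode(s)
                feats[i, : len(s)] = self._blosum.scores[idx] * _BLOSUM_SCALE
            return Tensor(feats), lengths, mask
        idx = np.full((len(seqs), L), 20, dtype=np.int64)  # pad row
        for i, s in enumerate(seqs):
            idx[i, : len(s)] = ALPHABET.encode(s)
        return self.embed(idx), lengths, mask

    @staticmethod
    def _masked_mean(x: Tensor, mask: np.ndarray) -> Tensor:
        m = mask[:, :, None].astype(float)
        return (x * Tensor(m)).sum(axis=1) / Tensor(m.sum(axis=1))

    # -- architectures -----------------------------------------------------

    def forward_logits(self, tcrs: Sequence[str], epitopes: Sequence[str]) -> Tensor:
        """Raw logits for a batch of pairs, shape (B,)."""
        xt, lt, mt = self._features(tcrs, self.config.max_tcr_len, "tcr")
        xe, le, me = self._features(epitopes, self.config.max_epi_len, "epitope")
        arch = self.config.architecture
        if arch == "mlp":
            z = nn.cat([self._masked_mean(xt, mt), self._masked_mean(xe, me)], axis=1)
            for layer in self.layers[:-1]:
                z = layer(z).relu()
            return self.layers[-1](z)[:, 0]
        if arch == "cnn":
            return self._forward_cnn(xt, lt, xe, le)
        if arch == "lstm":
            B = len(tcrs)
            ht = self.lstm_t(xt)[np.arange(B), lt - 1, :]
            he = self.lstm_e(xe)[np.arange(B), le - 1, :]
            z = self.head_hidden(nn.cat([ht, he], axis=1)).relu()
            return self.head(z)[:, 0]
        # attention: joint sequence [tcr ; epitope], pads masked out of keys
        x = nn.cat([xt, xe], axis=1)
        mask = np.concatenate([mt, me], axis=1)
        L = x.shape[1]
        z = self.proj(x) + self.pos(np.arange(L))
        addmask = np.where(mask, 0.0, -1e9)[:, None, :]  # (B,1,L) on keys
        z = self.norm(z + self.att(z, np.broadcast_to(addmask, (len(tcrs), L, L))))
        return self.head(self._masked_mean(z, mask))[:, 0]

    def _forward_cnn(self, xt, lt, xe, le) -> Tensor:
        def branch(conv, x, lengths):
            k = conv.kernel
            L_out = x.shape[1] - k + 1
            h = conv(x).relu()
            # windows extending past the true sequence end are masked out;
            # sequences shorter than the kernel keep window 0 (padded rows)
            valid = np.arange(L_out)[None, :] <= (lengths[:, None] - k)
            valid[:, 0] |= lengths < k
            addmask = np.where(valid, 0.0, -1e9)[:, :, None]
            return (h + Tensor(addmask)).max(axis=1)

        # epitopes/TCRs shorter than the kernel are prevented by validation
        ht = branch(self.conv_t, xt, lt)
        he = branch(self.conv_e, xe, le)
        z = self.head_hidden(nn.cat([ht, he], axis=1)).relu()
        return self.head(z)[:, 0]

    def clone(self) -> "BAPModel":
        out = BAPModel(self.config)
        out.load_state_dict(self.state_dict())
        out.training_history = copy.deepcopy(self.training_history)
        out.checkpoint_id = self.checkpoint_id
        return out

    # -- persistence -------------------------------------------------------

    def save(self, path) -> None:
        path = Path(path)
        np.savez(path.with_suffix(".npz"), *self.state_dict())
        sidecar = {
            "config": asdict(self.config),
            "checkpoint_id": self.checkpoint_id,
            "training_history": self.training_history,
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def load(cls, path) -> "BAPModel":
        path = Path(path)
        sidecar = json.loads(path.with_suffix(".json").read_text())
        cfg = sidecar["config"]
        cfg["hidden"] = tuple(cfg["hidden"])
        model = cls(BAPConfig(**cfg))
        with np.load(path.with_suffix(".npz")) as z:
            model.load_state_dict([z[k] for k in z.files])
        model.checkpoint_id = sidecar["checkpoint_id"]
        model.training_history = sidecar["training_history"]
        return model


def build_bap(config: BAPConfig) -> BAPModel:
    """Construct an untrained scorer; same config and seed give identical
    initial parameters."""
    return BAPModel(config)


def _bce_loss(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Stable binary cross-entropy on raw logits: softplus(z) - z*y."""
    return (logits.softplus() - logits * Tensor(labels.astype(float))).mean()


def _dataset_loss(
    model: BAPModel, ds: PairDataset, batch: int = 256, balanced: bool = False
) -> float:
    """Mean BCE over a dataset; with ``balanced``, the unweighted mean of
    per-group mean losses (used for checkpoint selection on small curated
    sets so no group dominates by count)."""
    losses, groups = [], []
    for lo in range(0, len(ds), batch):
        chunk = ds.pairs[lo : lo + batch]
        logits = model.forward_logits([p.tcr for p in chunk], [p.epitope for p in chunk])
        labels = np.array([p.label for p in chunk], dtype=float)
        losses.append(np.logaddexp(0.0, logits.data) - logits.data * labels)
        groups.extend(p.group for p in chunk)
    loss = np.concatenate(losses)
    if not balanced:
        return float(loss.mean())
    groups = np.array(groups)
    return float(np.mean([loss[groups == g].mean() for g in dict.fromkeys(groups)]))


def train_bap(
    model: BAPModel,
    train: PairDataset,
    val: Optional[PairDataset] = None,
    lr: Optional[float] = None,
    epochs: Optional[int] = None,
    reset_history: bool = True,
    balanced_selection: bool = False,
) -> BAPModel:
    """Train with cross-entropy; return the epoch checkpoint with minimal
    validation loss.

    When no validation set is supplied, a stratified 10% of the training set
    is carved out for checkpoint selection.
    """
    cfg = model.config
    lr = cfg.learning_rate if lr is None else lr
    epochs = cfg.epochs if epochs is None else epochs
    labels = train.labels()
    if labels.min() == labels.max():
        raise ValueError("training set contains a single label class")
    rng = np.random.default_rng(cfg.seed + 1)
    if val is None:
        train, val = _carve_validation(train, cfg.val_fraction, rng)
    model = model.clone()
    if reset_history:
        model.training_history = {"train_loss": [], "val_loss": []}
    opt = nn.Adam(model.parameters(), lr=lr)
    best_state, best_val, best_epoch = model.state_dict(), np.inf, None
    pairs = list(train.pairs)
    for epoch in range(epochs):
        order = rng.permutation(len(pairs))
        ep_loss, n_batches = 0.0, 0
        for lo in range(0, len(pairs), cfg.batch_size):
            chunk = [pairs[i] for i in order[lo : lo + cfg.batch_size]]
            logits = model.forward_logits(
                [p.tcr for p in chunk], [p.epitope for p in chunk]
            )
            loss = _bce_loss(logits, np.array([p.label for p in chunk]))
            opt.zero_grad()
            loss.backward()
            opt.step()
            ep_loss += float(loss.data)
            n_batches += 1
        val_loss = _dataset_loss(model, val, balanced=balanced_selection)
        model.training_history["train_loss"].append(ep_loss / max(n_batches, 1))
        model.training_history["val_loss"].append(val_loss)
        if val_loss < best_val:
            best_val, best_epoch = val_loss, len(model.training_history["val_loss"]) - 1
            best_state = model.state_dict()
    model.load_state_dict(best_state)
    model.checkpoint_id = best_epoch
    return model


def _carve_validation(
    ds: PairDataset, fraction: float, rng: np.random.Generator
) -> Tuple[PairDataset, PairDataset]:
    train, val = [], []
    for g in dict.fromkeys(p.group for p in ds):
        members = [p for p in ds if p.group == g]
        idx = rng.permutation(len(members))
        n_val = max(1, int(round(len(members) * fraction)))
        val.extend(members[i] for i in idx[:n_val])
        train.extend(members[i] for i in idx[n_val:])
    return PairDataset(train, split_tag="train"), PairDataset(val, split_tag="val")


def predict_logit(model: BAPModel, tcr: str, epitope: str) -> float:
    """The raw pre-sigmoid score of one pair."""
    tcr = validate_sequence(tcr, "tcr")
    epitope = validate_sequence(epitope, "epitope")
    return float(model.forward_logits([tcr], [epitope]).data[0])


def predict_logits(model: BAPModel, pairs: Sequence, batch: int = 256) -> np.ndarray:
    out = []
    items = list(pairs)
    for lo in range(0, len(items), batch):
        chunk = items[lo : lo + batch]
        out.append(
            model.forward_logits(
                [p.tcr for p in chunk], [p.epitope for p in chunk]
            ).data
        )
    return np.concatenate(out) if out else np.array([])


def logit_to_probability(logit: float) -> float:
    """The sigmoid link: binding probability of a raw logit; 0 maps to 0.5."""
    return float(1.0 / (1.0 + np.exp(-logit)))


def predict_probability(model: BAPModel, tcr: str, epitope: str) -> float:
    """Binding probability = sigmoid(logit); logit 0 maps to exactly 0.5."""
    return logit_to_probability(predict_logit(model, tcr, epitope))


@dataclass
class EvalReport:
    """Per-group TPR/TNR plus overall accuracy and (two-class) AUC."""

    per_group: pd.DataFrame
    accuracy: float
    auc: float

    def metric(self, group: str) -> float:
        row = self.per_group[self.per_group.group == group]
        return float(row.value.iloc[0]) if len(row) else float("nan")


def evaluate_groups(
    model: BAPModel, ds: PairDataset, threshold: float = 0.5
) -> EvalReport:
    """Per-group metrics: TPR for positives, TNR for each negative group.

    A probability exactly at the threshold counts as predicted-binding.
    Since each group carries a single label class, only the matching rate is
    defined per group; accuracy and AUC are reported over the whole set.
    """
    if len(ds) == 0:
        raise ValueError("dataset is empty")
    logits = predict_logits(model, ds.pairs)
    probs = 1.0 / (1.0 + np.exp(-logits))
    pred = probs >= threshold
    labels = ds.labels().astype(bool)
    rows = []
    groups = np.array([p.group for p in ds.pairs])
    for g in dict.fromkeys(groups):
        sel = groups == g
        if not sel.any():
            rows.append({"group": g, "metric": "NA", "value": float("nan"), "n": 0})
            continue
        if g == "positive":
            rows.append({"group": g, "metric": "TPR",
                         "value": float(pred[sel].mean()), "n": int(sel.sum())})
        else:
            rows.append({"group": g, "metric": "TNR",
                         "value": float((~pred[sel]).mean()), "n": int(sel.sum())})
    accuracy = float((pred == labels).mean())
    auc = (
        float(roc_auc_score(labels.astype(int), probs))
        if labels.any() and not labels.all()
        else float("nan")
    )
    return EvalReport(per_group=pd.DataFrame(rows), accuracy=accuracy, auc=auc)
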