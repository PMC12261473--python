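# Methods

This note documents the models and procedures implemented in `tcrshield`,
the assumptions behind them, the parameters that matter, and what the
synthetic benchmark does and does not establish.

## The task and the threat model

A binding-affinity predictor (BAP) `M` maps a (TCR, epitope) pair of
amino-acid strings to one raw logit; binding probability is
`sigmoid(logit)`, and the classification threshold is probability 0.5
(logit 0) throughout. The threat is *reward hacking*: when `M` is used as a
reward function for sequence generation, the generator discovers inputs
that `M` scores as binders but that are not authentic TCRs. The framework
turns this failure mode into a data-curation tool: harvest those inputs,
label them negative, fine-tune, repeat.

## Synthetic benchmark

Real positives and repertoires require database downloads, so all
experiments run on a generated stand-in (`tcrshield.synthetic`).

* **TCRs** are CDR3β-like: conserved prefix `CASS`, suffix from
  {`EQYF`, `EQFF`, `YTF`}, total length uniform on 12–18, middle residues
  drawn from a background distribution skewed toward small/flexible
  residues (G, S, L, A, R, T high; W, C, M low), roughly imitating real
  junctional composition.
* **Epitopes** are 8–11-mers; each is assigned one private 4-residue motif
  with at least 3 distinct residues (a binding motif is a specific contact
  pattern, never itself a low-complexity repeat — this also keeps the
  planted rule orthogonal to the degeneracy the attack exploits).
* **Binding rule**: a TCR binds epitope *e* iff it is a plausible CDR3
  carrying *e*'s motif in its central window. `motif_noise` (default 0)
  optionally corrupts planted motif positions; any noise makes
  corrupted-motif positives observationally identical to plausible
  non-binders, i.e. injects irreducible label ambiguity, so the default
  regime is the exact-containment, perfectly separable one, and noise is a
  deliberate robustness knob.
* **Pair groups**: positives (motif planted); shuffled negatives (a binding
  TCR reassigned to an epitope it is not known to bind — the constraint is
  pair-level, nothing stronger); healthy negatives (epitopes paired with
  background TCRs, sampled without replacement while possible). Default
  composition 2:1:1 positives:shuffled:healthy — 4 epitopes × 150 binders
  = 600 positives plus 300 + 300 negatives, with a 2000-sequence healthy
  repertoire.
* **Split**: 64% train / 16% reserved pool (for defense curation) / 20%
  test, stratified by group, remainder-to-train rounding, pair-level random
  (an epitope-disjoint split is a config flag, not the default).

Everything is a pure function of (config, seed).

## Models

All networks run on the package's vectorized NumPy reverse-mode autodiff
core (`tcrshield.nn`): float64, Adam, explicit per-model RNGs, so every
training run is bitwise reproducible from its seed.

**Scorer zoo** (`tcrshield.bap`). Four families share one interface —
`mlp` (mean-pooled residue embeddings of TCR and epitope, concatenated,
through ReLU hidden layers), `cnn` (1-D convolutions, width `cnn_kernel`,
default 3, masked global max-pool per branch, interaction hidden layer),
`lstm` (final hidden states of per-branch LSTMs, interaction hidden
layer) and `attention` (single-head self-attention over the joint
`[tcr; epitope]` sequence with learned positions, masked mean-pool).
Embeddings are either static BLOSUM62 rows (scaled ×0.25 so they enter the
network at unit-ish magnitude) or a small learned table. Training: binary
cross-entropy on the raw logit (stable `softplus(z) − z·y` form), lr 0.001,
200 epochs, batch 32; the epoch with minimal validation loss is the
returned checkpoint (validation is a stratified 10% carve-out when no
explicit set is given). Short inputs are padded up to the convolution
width so even two-residue sequences are scorable — no silent truncation in
the other direction: over-length input raises.

**Generator / likelihood model** (`tcrshield.generator`). One small
decoder-only transformer (2 blocks, width 48, feed-forward 96, single
head, trained from scratch) serves three roles. Conditioning is a prefix:
`BOS, epitope, SEP, tcr…`, with the loss masked to TCR tokens plus the
end-of-sequence token; the unconditioned likelihood role sees `BOS, tcr…`.
The output head spans exactly the 20 residues + EOS and is
zero-initialized, so an untrained model is exactly uniform over its output
vocabulary (which gives the closed-form `(L+1)·log(1/21)` check). The
supervised fine-tuning objective is the summed conditional log-likelihood
of binder TCRs given their epitopes; the trained policy is copied and
frozen as the reference. Sampling is ancestral with a temperature, capped
at 30 residues (the plausibility filter's upper bound); empty draws are
rejected and resampled so recorded per-token log-probabilities are the
model's own and rescoring a terminated sample reproduces its total
exactly. The likelihood score is exposed both as the total and as the
per-token mean (total / (L+1)); false-positive flagging uses the
length-normalized form so long sequences are not penalized twice.

The likelihood model's corpus is the healthy repertoire *plus* the
training-split binder TCRs: the natural TCR distribution it is meant to
represent contains binders, and a corpus without motifs would score every
motif-carrying sequence as atypical.

## Attack

PPO (`tcrshield.attack`) with standard sequence-RL choices, every constant
in `PPOConfig`: clipped ratio (ε = 0.2), bandit-style credit (one reward
per sequence, spread uniformly over its generated tokens), advantage =
reward − running-mean baseline, whitened per batch with a raw-advantage
fallback when the batch has zero variance, and a quadratic-around-zero KL
spring toward the frozen reference (`exp(Δ) − 1 − Δ` on per-token
log-probability differences) whose coefficient sets how far the policy may
drift. The reward is bitwise the scorer's raw logit — no shaping, no
clipping — and every sampled sequence is traced with its reward, so the
candidate pool is exactly the union of step records (deduplicated keeping
the maximal reward). Epitope prompts cycle uniformly through the training
epitopes. Benchmark attack settings: 100 steps × 16 sequences,
kl_coef 0.003, lr 3e-4 — weak enough a leash that the policy can actually
reach the degenerate high-reward region the defense needs to see.

## False-positive identification

A candidate is a false positive when its reward clears `reward_min`
(default 0 — the model calls it a binder) AND it fails either authenticity
arm: kernel similarity below `tcrmatch_min` OR per-token log-likelihood
below `gptll_per_residue_min`.

The kernel is `K(a,b) = Σ_k Σ_{i,j} Π_p exp(β·BLOSUM62(a[i+p], b[j+p]))`
with β = 0.11387 and k from 1 up to 10 (clipped to the shorter sequence),
evaluated by a vectorized diagonal recursion and normalized per reference
by the geometric mean of self-kernels; the score against a reference set
is the max, scoped to the epitope's known binders (global fallback below 5
references). The exponentiated-substitution similarity is not exactly
positive semidefinite, so the normalized score is clamped to [0,1].

The cutoffs are calibrated at run time, because absolute kernel and
likelihood scales depend on reference-set size and corpus: each floor
interpolates between a low percentile (5th) of held-out authentic binder
scores and the median score of constructed degenerate anchors (residue and
dipeptide repeats at several lengths). The similarity arm gets a wider
margin toward the anchors (weight 0.5 vs 0.25) because at ~150 references
per epitope the similarity of genuine binders is noisy near its lower
tail. Finally, candidates scoring above the authentic *median* similarity
are exempt from flagging altogether — sequences at least as similar to
known binders as a typical real binder are presumed to carry binding
characteristics, which is the similarity metric's own rationale. A
heuristic plausibility bit (length 5–30, no residue repeated more than 6
times in a row) is recorded with every score but does not gate the rule.

## Defense and iteration

Curation draws from the reserved pool plus the cumulative adversarial set
at configurable weights (default 2:1:1:1) by largest-remainder
apportionment, without replacement; when a group cannot fill its quota the
shortfall is redistributed proportionally over the remaining groups with a
logged warning. A stratified 10% (20% inside the iteration loop) is held
out to select the fine-tuning checkpoint.

Fine-tuning continues from the current parameters at lr 1e-5 — 100× below
base training. `finetune_bap`'s own default is 200 epochs; the benchmark
iteration loop uses 2500, because at 1e-5 the total Adam displacement over
a few hundred epochs is too small to reshape a from-scratch desk-scale
network (large pretrained models get away with far fewer steps at this
rate). Epoch counts are ordinary config.

The loop re-initializes the attack policy from the SFT reference each
iteration (a fresh attack against the defended model), resamples the
curated set fresh, accumulates adversarial negatives across iterations
(deduplicated), and stops when an iteration's new-FP count is at most
max(5, 10% of iteration 1's count), or after 3 iterations. Zero false
positives at iteration 1 end the loop immediately — there is nothing to
defend.

The benchmark's attack target is the `cnn` scorer with kernel width 4,
width 64, 120 training epochs. The windowed representation is the one zoo
member that can hold "exact motif inside an authentic CDR3 frame" apart
from "motif fragments inside junk"; defending the mean-pooled `mlp` or the
single-block `attention` model necessarily drags the true-positive rate,
because in their nearly compositional feature spaces the adversarial
direction is not separable from the binding signal. All four
architectures remain first-class and run through the same attack/defend
code paths in the tests.

## Numerical and procedural choices

* Determinism: one integer seed drives every stage through SHA-256-derived
  per-stage seeds (all below 2³¹); reruns reproduce CSVs bitwise.
* Probability at the threshold counts as predicted-binding (`≥` rule).
* Silhouette-selected k-medoids clustering runs on the precomputed CDR3
  distance matrix (central-gap length equalization, per-position cost
  `min(4, 4 − BLOSUM62)`, gap penalty 4, central third up-weighted ×3);
  ties in silhouette break toward smaller k; farthest-first init from the
  1-medoid makes the result input-order invariant up to distance ties.
  The weighted scheme does not guarantee the triangle inequality and no
  claim of equivalence with any full multi-CDR distance is made.
* Degenerate inputs: all-identical sequences return an explicit
  "no clustering" status; a zero-variance PPO batch falls back to raw
  advantages; empty evaluation groups report NaN, never zero.

## What the benchmark does and does not show

The planted-motif world gives the scorers a genuinely learnable signal,
gives the similarity metric meaningful per-epitope reference sets, and
makes ground truth available for auditing the flagged false positives —
that is what the passing tests certify: the mechanics of the loop (reward
identity, harvesting, calibration, curation arithmetic, checkpointing) and
its qualitative dynamics (rising attack reward, shrinking FP counts,
adversarial TNR gained at small cost to the untouched test groups). It
does not emulate real CDR3 gene usage, epitope biology, cross-reactivity,
or database noise, and absolute numbers (FP counts, TNR/TPR levels) do not
transfer to real data. Per-seed variability at this scale is substantial:
attack yields and defense deltas fluctuate with the drawn motifs and
policy trajectories, which is why the headline quantities are reported per
run rather than claimed as constants.
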