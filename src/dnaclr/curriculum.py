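"""Two-phase curriculum contrastive training (C2LR).

Phase I trains with Weighted SimCLR on non-overlapping fragment pairs; phase II
switches to Manifold Instance Mixup, whose mixed anchors are the harder
contrastive targets.  Checkpoints are taken every ``checkpoint_every`` steps
(and at each phase end) with an evaluation-mode validation loss; the model
returned is the validation-loss argmin among the checkpoints of the final
phase (losses of different objectives are not comparable across phases).

Ablation variants are selected purely through ``TrainConfig.objective``:
``c2lr`` (default), ``wsimclr+imix``, and the single-objective runs
``wsimclr``, ``mimix``, ``imix``, ``supcon``.
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from autograd import value_and_grad
from autograd.misc.flatten import flatten

from .encoder import Encoder, tokenize
from .objectives import (
    MixConfig,
    i_mix_loss,
    mi_mix_loss,
    supcon_loss,
    weighted_simclr_loss,
)
from .records import PairBatch

logger = logging.getLogger(__name__)

__all__ = ["TrainConfig", "Checkpoint", "train_c2lr", "validate", "OBJECTIVES"]

OBJECTIVES = ("c2lr", "wsimclr+imix", "wsimclr", "mimix", "imix", "supcon")


@dataclass
class TrainConfig:
    """Training hyperparameters.

    Reference-scale values are temperature 0.05, Beta alpha 1.0, learning rate
    3e-6 and batch size 48 with one phase-I and two phase-II epochs; the
    defaults here are desk-scale (larger learning rate, smaller batch) and are
    logged with every run.
    """

    tau: float = 0.05
    beta_alpha: float = 1.0
    learning_rate: float = 1e-4
    batch_size: int = 16
    phase1_epochs: int = 1
    phase2_epochs: int = 2
    checkpoint_every: int = 100
    seed: int = 0
    objective: str = "c2lr"
    adam_betas: tuple[float, float] = (0.9, 0.999)
    adam_eps: float = 1e-8
    weight_decay: float = 0.0
    eligible_layers: frozenset[int] | None = None  # None: encoder config default
    differentiable_weights: bool = False
    # Sample each batch from distinct genomes where possible.  At reference
    # scale a uniformly shuffled batch almost never contains two pairs of the
    # same genome; with few genomes it nearly always does, and those collisions
    # are false negatives that the hard-negative weighting amplifies.
    # Stratified sampling restores the large-corpus batch statistics.
    stratify_by_genome: bool = True

    def __post_init__(self) -> None:
        if self.batch_size < 2:
            raise ValueError("batch_size must be >= 2 (losses need negatives)")
        if self.phase1_epochs < 0 or self.phase2_epochs < 0:
            raise ValueError("epoch counts must be non-negative")
        if self.learning_rate <= 0 or self.tau <= 0:
            raise ValueError("learning_rate and tau must be positive")
        if self.objective not in OBJECTIVES:
            raise ValueError(f"objective must be one of {OBJECTIVES}")


@dataclass
class Checkpoint:
    params: dict
    step: int
    phase: int
    validation_loss: float


def _phase_plan(cfg: TrainConfig) -> list[tuple[int, str, int]]:
    """[(phase_number, objective, epochs)]; single objectives run as phase 1."""
    if cfg.objective == "c2lr":
        return [(1, "wsimclr", cfg.phase1_epochs), (2, "mimix", cfg.phase2_epochs)]
    if cfg.objective == "wsimclr+imix":
        return [(1, "wsimclr", cfg.phase1_epochs), (2, "imix", cfg.phase2_epochs)]
    return [(1, cfg.objective, cfg.phase1_epochs + cfg.phase2_epochs)]


def _batch_loss(encoder, params, batch: PairBatch, objective: str,
                cfg: TrainConfig, mix_seed: int,
                train_rng: np.random.Generator | None):
    """Loss of one minibatch under the given objective; differentiable in params."""
    max_tokens = encoder.config.max_tokens
    if objective in ("wsimclr", "supcon"):
        # one forward pass over the 2B stacked views is ~2x cheaper to trace
        both = tokenize(batch.anchors + batch.positives, max_tokens)
        ZZ = encoder.encode_batch(both, params, train_rng)
        b = len(batch)
        if objective == "wsimclr":
            return weighted_simclr_loss(ZZ[:b], ZZ[b:], cfg.tau,
                                        cfg.differentiable_weights)
        labels = np.array(batch.genome_ids + batch.genome_ids)
        return supcon_loss(ZZ, labels, cfg.tau)
    anchors = tokenize(batch.anchors, max_tokens)
    positives = tokenize(batch.positives, max_tokens)
    if objective in ("mimix", "imix"):
        layers = cfg.eligible_layers or encoder.config.eligible_mix_layers
        mix_cfg = MixConfig(beta_alpha=cfg.beta_alpha, eligible_layers=layers,
                            seed=mix_seed)
        fn = mi_mix_loss if objective == "mimix" else i_mix_loss
        return fn(encoder, anchors, positives, mix_cfg, cfg.tau, params,
                  train_rng, differentiable_weights=cfg.differentiable_weights)
    raise ValueError(f"unknown objective {objective!r}")


def _minibatches(n: int, batch_size: int, rng: np.random.Generator):
    """Shuffled minibatch index lists; a trailing batch of size < 2 is dropped."""
    order = rng.permutation(n)
    for i in range(0, n, batch_size):
        idx = order[i : i + batch_size]
        if len(idx) >= 2:
            yield idx.tolist()


def _minibatches_stratified(genome_ids: list[str], batch_size: int,
                            rng: np.random.Generator):
    """Batches drawn from distinct genomes whenever enough genomes remain.

    Every epoch still visits each pair exactly once: pairs are pooled per
    genome, each batch greedily takes one pair from the ``batch_size`` genomes
    with most pairs left (random tie-breaking via pre-shuffled pools), and the
    epoch tail falls back to whatever genomes remain.
    """
    pools: dict[str, list[int]] = {}
    for i in rng.permutation(len(genome_ids)):
        pools.setdefault(genome_ids[i], []).append(int(i))
    names = list(pools)
    rng.shuffle(names)
    remaining = len(genome_ids)
    while remaining >= 2:
        order = sorted(names, key=lambda g: -len(pools[g]))
        batch = []
        for g in order:
            if len(batch) == batch_size:
                break
            if pools[g]:
                batch.append(pools[g].pop())
        while len(batch) < batch_size:  # tail: reuse genomes with spare pairs
            refill = [g for g in order if pools[g]]
            if not refill:
                break
            batch.append(pools[refill[0]].pop())
        remaining -= len(batch)
        if len(batch) >= 2:
            yield batch


def validate(encoder: Encoder, val_pairs: PairBatch, objective: str,
             cfg: TrainConfig, params: dict | None = None) -> float:
    """Mean per-batch validation loss, evaluation mode (no dropout).

    MI-Mix/i-Mix validation uses a mix seed fixed by ``cfg.seed`` and the batch
    position, so losses are comparable across checkpoints.
    """
    if len(val_pairs) == 0:
        raise ValueError("validation pair set is empty")
    p = params if params is not None else encoder.params
    losses = []
    n = len(val_pairs)
    for j, start in enumerate(range(0, n, cfg.batch_size)):
        idx = list(range(start, min(start + cfg.batch_size, n)))
        if len(idx) < 2 and n > 1:
            continue
        batch = val_pairs.subset(idx)
        loss = _batch_loss(encoder, p, batch, objective, cfg,
                           mix_seed=cfg.seed * 100_003 + j, train_rng=None)
        losses.append(float(loss))
    return float(np.mean(losses))


def train_c2lr(
    encoder: Encoder,
    train_pairs: PairBatch,
    val_pairs: PairBatch,
    cfg: TrainConfig,
) -> tuple[Checkpoint, pd.DataFrame]:
    """Run the curriculum (or an ablation objective) and return the best model.

    Returns the argmin-validation-loss checkpoint of the final phase together
    with the per-step training log (step, phase, objective, loss, mixing layer,
    mean lambda).  Fully deterministic given ``cfg.seed``.
    """
    if len(train_pairs) == 0:
        raise ValueError("training pair set is empty")
    if len(val_pairs) == 0:
        raise ValueError("validation pair set is empty")

    flat, unflatten = flatten(encoder.params)
    flat = flat.copy()
    m1 = np.zeros_like(flat)
    m2 = np.zeros_like(flat)
    b1, b2 = cfg.adam_betas

    data_rng = np.random.default_rng(cfg.seed + 1)
    drop_rng = np.random.default_rng(cfg.seed + 2)

    log_rows: list[dict] = []
    checkpoints: list[Checkpoint] = []
    step = 0
    plan = [(ph, obj, ep) for ph, obj, ep in _phase_plan(cfg) if ep > 0]
    if not plan:
        raise ValueError("no training epochs configured")

    def take_checkpoint(phase: int, objective: str) -> None:
        params = unflatten(flat)
        vloss = validate(encoder, val_pairs, objective, cfg, params)
        if not np.isfinite(vloss):
            raise RuntimeError(f"non-finite validation loss at step {step}")
        checkpoints.append(
            Checkpoint(params=copy.deepcopy(params), step=step, phase=phase,
                       validation_loss=vloss)
        )

    for phase, objective, epochs in plan:
        for epoch in range(epochs):
            if cfg.stratify_by_genome:
                batches = _minibatches_stratified(train_pairs.genome_ids,
                                                  cfg.batch_size, data_rng)
            else:
                batches = _minibatches(len(train_pairs), cfg.batch_size,
                                       data_rng)
            for idx in batches:
                batch = train_pairs.subset(idx)
                mix_seed = int(
                    np.random.default_rng((cfg.seed, step)).integers(2**31 - 1)
                )
                # one rng shared by all dropout draws of this step, re-seeded so
                # the traced loss is a pure function of the parameters
                step_drop_seed = int(drop_rng.integers(2**31 - 1))

                def loss_fn(f):
                    params = unflatten(f)
                    rng = np.random.default_rng(step_drop_seed)
                    return _batch_loss(encoder, params, batch, objective, cfg,
                                       mix_seed, rng)

                loss, grad_flat = value_and_grad(loss_fn)(flat)
                loss = float(loss)
                if not np.isfinite(loss):
                    raise RuntimeError(
                        f"non-finite training loss at step {step} "
                        f"(batch ids {[r.seq_id for r in batch.anchors][:4]}...)"
                    )
                if cfg.weight_decay > 0:
                    grad_flat = grad_flat + cfg.weight_decay * flat
                step += 1
                m1 = b1 * m1 + (1 - b1) * grad_flat
                m2 = b2 * m2 + (1 - b2) * grad_flat**2
                mhat = m1 / (1 - b1**step)
                vhat = m2 / (1 - b2**step)
                flat = flat - cfg.learning_rate * mhat / (np.sqrt(vhat) + cfg.adam_eps)

                row = {"step": step, "phase": phase, "objective": objective,
                       "epoch": epoch, "loss": loss, "mix_layer": np.nan,
                       "mean_lambda": np.nan}
                if objective in ("mimix", "imix"):
                    from .objectives import sample_mix

                    layers = (cfg.eligible_layers
                              or encoder.config.eligible_mix_layers)
                    if objective == "imix":
                        layers = frozenset({0})
                    mc = MixConfig(cfg.beta_alpha, frozenset(layers), mix_seed)
                    perm, lam, m = sample_mix(len(batch), mc)
                    row["mix_layer"] = m
                    row["mean_lambda"] = float(np.mean(lam))
                log_rows.append(row)

                if step % cfg.checkpoint_every == 0:
                    take_checkpoint(phase, objective)
        # phase boundary: always checkpoint so every phase is represented
        if not checkpoints or checkpoints[-1].step != step:
            take_checkpoint(phase, objective)

    final_phase = plan[-1][0]
    candidates = [c for c in checkpoints if c.phase == final_phase]
    best = min(candidates, key=lambda c: (c.validation_loss, c.step))
    log = pd.DataFrame(log_rows)
    logger.info(
        "training done: %d steps, best checkpoint step %d (val loss %.4f)",
        step, best.step, best.validation_loss,
    )
    return best, log
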