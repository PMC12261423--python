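"""Contrastive objectives: Weighted SimCLR, MI-Mix, i-Mix and SupCon.

All losses score cosine similarities at temperature ``tau`` (default 0.05).

* Weighted SimCLR: every other sample in the batch of ``2B`` views is a
  negative; negatives closer to the anchor receive larger weights
  ``a_ij = exp(s_ij / tau) / mean_k exp(s_ik / tau)`` (mean over the ``2B - 2``
  negatives, so the weights average to exactly 1), and the positive enters the
  denominator with weight 1.  Both views of each pair serve as anchors.

* Manifold Instance Mixup (MI-Mix): anchors' hidden states at a randomly chosen
  eligible layer ``m`` are convexly mixed with a shuffled copy of the batch
  (per-anchor weight ``lambda_i ~ Beta(alpha, alpha)``), pushed through the
  remaining layers and pooled; the one-hot virtual labels mix identically.  The
  mixed anchor is scored only against the ``B`` positive-view embeddings, with
  hard-negative weights normalized over the ``B - 1`` non-self positives.

* i-Mix is exactly MI-Mix with the eligible layer set fixed to ``{0}`` (mixing
  at the token-embedding output).

* SupCon is the standard supervised contrastive loss over labelled embeddings,
  kept as an ablation baseline.

Hard-negative weights are treated as constants under differentiation (standard
reweighting practice); pass ``differentiable_weights=True`` to let gradients
flow through them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import autograd.numpy as anp
import numpy as np
from autograd.extend import primitive, defvjp
from autograd.tracer import getval

from .encoder import Encoder, HiddenState, TokenizedBatch, tokenize

logger = logging.getLogger(__name__)

__all__ = [
    "MixConfig",
    "MixedBatch",
    "cosine_similarity_matrix",
    "negative_weights_full",
    "weighted_simclr_loss",
    "sample_mix",
    "mix_hidden",
    "mi_mix_loss",
    "i_mix_loss",
    "supcon_loss",
]


@primitive
def stop_gradient(x):
    """Identity with zero gradient."""
    return x


defvjp(stop_gradient, lambda ans, x: lambda g: np.zeros_like(x))


@dataclass
class MixConfig:
    """Mixing hyperparameters: Beta(alpha, alpha) weight, eligible layers, seed."""

    beta_alpha: float = 1.0
    eligible_layers: frozenset[int] = field(default_factory=lambda: frozenset({0}))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.beta_alpha <= 0:
            raise ValueError("beta_alpha must be positive")
        if not self.eligible_layers:
            raise ValueError("eligible_layers must be non-empty")
        self.eligible_layers = frozenset(int(m) for m in self.eligible_layers)


@dataclass
class MixedBatch:
    """Mixed hidden states with their soft virtual labels.

    ``v_mix`` row i equals ``lam_i * v_i + (1 - lam_i) * v_perm[i]`` where the
    virtual label ``v_i`` is the i-th one-hot indicator over the batch.
    """

    hidden: HiddenState
    v_mix: np.ndarray        # (B, B), rows sum to 1, <= 2 nonzeros
    lam: np.ndarray          # (B,)
    perm: np.ndarray         # (B,)


def _row_norms(X):
    return anp.sqrt(anp.sum(X * X, axis=1))


def cosine_similarity_matrix(A, B):
    """Pairwise cosine similarities; raises on zero-norm rows."""
    na, nb = _row_norms(A), _row_norms(B)
    if np.any(getval(na) < 1e-12) or np.any(getval(nb) < 1e-12):
        raise ValueError("cosine similarity undefined for zero-norm rows")
    return (A @ B.T) / na[:, None] / nb[None, :]


def negative_weights_full(Z, Zp, i: int, tau: float = 0.05) -> np.ndarray:
    """Hard-negative weights of anchor ``x_i`` over its ``2B - 2`` negatives.

    The stacked view order is ``[x_1..x_B, x_1+..x_B+]``; the returned vector
    follows that order with ``x_i`` and ``x_i+`` removed.  Weights are
    ``exp(s/tau)`` normalized by their mean, so they average to exactly 1.
    ``B = 1`` returns an empty vector (no negatives).
    """
    Z, Zp = np.asarray(Z, float), np.asarray(Zp, float)
    B = Z.shape[0]
    if B == 1:
        return np.zeros(0)
    S = np.vstack([Z, Zp])
    s = cosine_similarity_matrix(S[i : i + 1], S)[0]
    keep = np.ones(2 * B, dtype=bool)
    keep[i] = keep[(i + B) % (2 * B)] = False
    e = np.exp((s[keep] - s[keep].max()) / tau)
    return e / e.mean()


def _weighted_denominator_logits(logits, pos_idx, neg_mask, differentiable_weights):
    """log of ``exp(l_pos) + sum_j a_j exp(l_j)`` per row, max-stabilized.

    ``logits``: (n, k) similarity logits of each anchor against its comparison
    set; ``pos_idx``: positive column per row; ``neg_mask``: boolean (n, k)
    marking negative columns.  Weights a_j are exp-logit normalized by their
    row mean over negatives.
    """
    n, k = np.shape(logits)
    rows = np.arange(n)
    neg_counts = neg_mask.sum(axis=1)
    M = anp.max(logits, axis=1, keepdims=True)
    E = anp.exp(logits - M) * neg_mask  # stabilized exp over negatives only
    mean_neg = anp.sum(E, axis=1) / np.maximum(neg_counts, 1)
    # Hard-negative weights, constant under differentiation by default.
    alpha = E / anp.maximum(mean_neg, 1e-300)[:, None]
    if not differentiable_weights:
        alpha = stop_gradient(alpha)
    pos_term = anp.exp(logits[rows, pos_idx] - M[:, 0])
    denom = pos_term + anp.sum(alpha * anp.exp(logits - M) * neg_mask, axis=1)
    return M[:, 0] + anp.log(denom)


def weighted_simclr_loss(Z, Zp, tau: float = 0.05,
                         differentiable_weights: bool = False):
    """Batch Weighted SimCLR loss: mean per-anchor loss over all ``2B`` views."""
    B = np.shape(Z)[0]
    S = anp.concatenate([Z, Zp], axis=0)
    sim = cosine_similarity_matrix(S, S)
    logits = sim / tau
    n = 2 * B
    rows = np.arange(n)
    pos_idx = (rows + B) % n
    neg_mask = np.ones((n, n), dtype=bool)
    neg_mask[rows, rows] = False
    neg_mask[rows, pos_idx] = False
    if B == 1:
        # no negatives: numerator equals denominator, loss is exactly 0
        return anp.sum(Z * 0.0) + anp.sum(Zp * 0.0)
    log_denom = _weighted_denominator_logits(
        logits, pos_idx, neg_mask, differentiable_weights
    )
    losses = log_denom - logits[rows, pos_idx]
    return anp.mean(losses)


def sample_mix(B: int, cfg: MixConfig) -> tuple[np.ndarray, np.ndarray, int]:
    """Draw (permutation, per-anchor Beta weights, mixing layer) from cfg.seed."""
    if B < 1:
        raise ValueError("batch size must be >= 1")
    rng = np.random.default_rng(cfg.seed)
    layers = sorted(cfg.eligible_layers)
    m = int(layers[rng.integers(len(layers))])
    perm = rng.permutation(B)
    lam = rng.beta(cfg.beta_alpha, cfg.beta_alpha, size=B)
    return perm, lam, m


def mix_hidden(hidden: HiddenState, perm: np.ndarray, lam: np.ndarray) -> MixedBatch:
    """Convexly mix hidden states with their shuffled copy; OR the pad masks."""
    B = hidden.pad_mask.shape[0]
    perm = np.asarray(perm)
    lam = np.asarray(lam, dtype=float)
    if perm.shape != (B,) or lam.shape != (B,):
        raise ValueError("perm and lam must each have one entry per batch row")
    if np.any(lam < 0) or np.any(lam > 1):
        raise ValueError("mixing weights must lie in [0, 1]")
    w = lam[:, None, None]
    X = hidden.states
    mixed = w * X + (1.0 - w) * X[perm]
    mask = hidden.pad_mask | hidden.pad_mask[perm]
    eye = np.eye(B)
    v_mix = lam[:, None] * eye + (1.0 - lam)[:, None] * eye[perm]
    return MixedBatch(
        hidden=HiddenState(hidden.layer_index, mixed, mask),
        v_mix=v_mix, lam=lam, perm=perm,
    )


def _mimix_loss_from_embeddings(A, Zp, v_mix, tau, differentiable_weights):
    """Per-anchor v_mix-weighted softmax loss of mixed anchors against {f(x_j+)}."""
    B = np.shape(A)[0]
    logits = cosine_similarity_matrix(A, Zp) / tau
    rows = np.arange(B)
    neg_mask = np.ones((B, B), dtype=bool)
    neg_mask[rows, rows] = False
    if B == 1:
        log_denom = logits[:, 0]
    else:
        log_denom = _weighted_denominator_logits(
            logits, rows, neg_mask, differentiable_weights
        )
    per_anchor = log_denom - anp.sum(v_mix * logits, axis=1)
    return anp.mean(per_anchor)


def mi_mix_loss(
    encoder: Encoder,
    anchors: TokenizedBatch,
    positives: TokenizedBatch,
    cfg: MixConfig,
    tau: float = 0.05,
    params: dict | None = None,
    train_rng: np.random.Generator | None = None,
    mix_override: tuple[np.ndarray, np.ndarray, int] | None = None,
    differentiable_weights: bool = False,
):
    """Manifold Instance Mixup loss for one batch of positive pairs.

    Four steps: draw a layer ``m`` uniformly from the eligible set, run the
    anchors to ``m``, mix states and virtual labels against a shuffled copy,
    run the mixture through the remaining layers and pool.  Only the anchors
    are mixed; the comparison set is the ``B`` positive-view embeddings.
    ``mix_override = (perm, lam, m)`` bypasses sampling (used for the
    ``lambda = 1`` reduction checks).
    """
    B = anchors.batch_size
    if positives.batch_size != B:
        raise ValueError("anchors and positives must have equal batch size")
    perm, lam, m = mix_override if mix_override is not None else sample_mix(B, cfg)
    if not 0 <= m <= encoder.config.n_layers:
        raise ValueError(f"mixing layer {m} outside encoder range")
    hid = encoder.forward_prefix(anchors, m, params, train_rng)
    mixed = mix_hidden(hid, perm, lam)
    final = encoder.forward_suffix(mixed.hidden, params, train_rng)
    A = encoder.pool(final)
    Zp = encoder.encode_batch(positives, params, train_rng)
    return _mimix_loss_from_embeddings(A, Zp, mixed.v_mix, tau,
                                       differentiable_weights)


def i_mix_loss(
    encoder: Encoder,
    anchors: TokenizedBatch,
    positives: TokenizedBatch,
    cfg: MixConfig,
    tau: float = 0.05,
    params: dict | None = None,
    train_rng: np.random.Generator | None = None,
    differentiable_weights: bool = False,
):
    """Input-layer instance mixup: MI-Mix with the eligible set fixed to {0}."""
    cfg0 = MixConfig(beta_alpha=cfg.beta_alpha, eligible_layers=frozenset({0}),
                     seed=cfg.seed)
    return mi_mix_loss(encoder, anchors, positives, cfg0, tau, params,
                       train_rng, differentiable_weights=differentiable_weights)


def supcon_loss(X, labels, tau: float = 0.05):
    """Supervised contrastive loss over labelled embeddings.

    For each anchor with at least one same-label positive: mean over its
    positives of ``-log softmax`` against all other samples.  Anchors whose
    class is singleton are skipped (count logged); all-singleton input raises.
    """
    labels = np.asarray(labels)
    n = np.shape(X)[0]
    if labels.shape != (n,):
        raise ValueError("labels must align with embedding rows")
    logits = cosine_similarity_matrix(X, X) / tau
    same = labels[:, None] == labels[None, :]
    off_diag = ~np.eye(n, dtype=bool)
    pos_mask = same & off_diag
    has_pos = pos_mask.any(axis=1)
    if not has_pos.any():
        raise ValueError("supcon_loss needs at least one class with >= 2 members")
    skipped = int((~has_pos).sum())
    if skipped:
        logger.warning("supcon_loss: skipped %d singleton-class anchors", skipped)
    M = anp.max(anp.where(off_diag, logits, -np.inf), axis=1, keepdims=True)
    log_denom = M[:, 0] + anp.log(
        anp.sum(anp.exp(logits - M) * off_diag, axis=1)
    )
    per_pair = log_denom[:, None] - logits  # -log softmax per (anchor, other)
    per_anchor = anp.sum(anp.where(pos_mask, per_pair, 0.0), axis=1) / np.maximum(
        pos_mask.sum(axis=1), 1
    )
    return anp.sum(anp.where(has_pos, per_anchor, 0.0)) / has_pos.sum()
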