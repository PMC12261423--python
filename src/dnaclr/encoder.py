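"""A small transformer encoder with a layer-split forward contract.

The encoder maps character-tokenized DNA to per-token hidden states and, via
masked mean pooling, to a fixed-size embedding.  Its forward pass factors as
``f(x) = f_m(g_m(x))`` for every layer index ``m``: :func:`Encoder.forward_prefix`
computes the hidden states at layer ``m`` (``m = 0`` is the token embedding plus
positional encoding) and :func:`Encoder.forward_suffix` runs the remaining
blocks.  Manifold mixing interpolates two inputs' hidden states at a chosen
``m`` and pushes the mixture through the suffix.

All array math is written against ``autograd.numpy`` so losses built on top of
the forward pass are differentiable with respect to the parameter pytree; in
evaluation mode the same code runs as plain NumPy and is deterministic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import autograd.numpy as anp
import numpy as np

from .records import SequenceRecord

__all__ = ["EncoderConfig", "TokenizedBatch", "HiddenState", "Encoder", "tokenize"]

VOCAB = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4, "PAD": 5}
PAD_ID = VOCAB["PAD"]


@dataclass
class EncoderConfig:
    max_tokens: int = 512
    n_layers: int = 2
    hidden_dim: int = 64
    n_heads: int = 4
    dropout_rate: float = 0.1
    # Sinusoidal positions are scaled to the token-embedding magnitude so the
    # shared positional offset does not dominate cosine similarity of pooled
    # embeddings at initialization (unit-scale positions leave the contrastive
    # logits with almost no dynamic range).
    pos_scale: float = 0.02
    # Eligible manifold-mix layers; 0 = token-embedding output, n_layers = the
    # final hidden states.  Default: embedding output plus every non-final block.
    eligible_mix_layers: frozenset[int] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.n_layers < 1:
            raise ValueError("n_layers must be >= 1")
        if self.hidden_dim % self.n_heads != 0:
            raise ValueError("hidden_dim must be divisible by n_heads")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must lie in [0, 1)")
        if not self.eligible_mix_layers:
            self.eligible_mix_layers = frozenset(range(self.n_layers))
        else:
            self.eligible_mix_layers = frozenset(int(m) for m in self.eligible_mix_layers)
        if not all(0 <= m <= self.n_layers for m in self.eligible_mix_layers):
            raise ValueError(
                f"eligible_mix_layers must lie in 0..{self.n_layers}"
            )


@dataclass
class TokenizedBatch:
    token_ids: np.ndarray  # (B, L) int
    pad_mask: np.ndarray   # (B, L) bool, True = real token
    lengths: np.ndarray    # (B,) int

    @property
    def batch_size(self) -> int:
        return self.token_ids.shape[0]


@dataclass
class HiddenState:
    """Per-token states at a named layer; pad_mask carried through unchanged."""

    layer_index: int
    states: object        # (B, L, d) ndarray or autograd box
    pad_mask: np.ndarray  # (B, L) bool


def tokenize(records: list[SequenceRecord], max_tokens: int = 512) -> TokenizedBatch:
    """One token per base; truncation to ``max_tokens``; right padding."""
    if not records:
        raise ValueError("cannot tokenize an empty record list")
    seqs = [r.sequence[:max_tokens] for r in records]
    if any(len(s) == 0 for s in seqs):
        raise ValueError("empty sequence cannot be tokenized")
    L = max(len(s) for s in seqs)
    ids = np.full((len(seqs), L), PAD_ID, dtype=np.int64)
    mask = np.zeros((len(seqs), L), dtype=bool)
    lengths = np.zeros(len(seqs), dtype=np.int64)
    for i, s in enumerate(seqs):
        ids[i, : len(s)] = [VOCAB[c] for c in s]
        mask[i, : len(s)] = True
        lengths[i] = len(s)
    return TokenizedBatch(token_ids=ids, pad_mask=mask, lengths=lengths)


def _sinusoidal(L: int, d: int) -> np.ndarray:
    pos = np.arange(L)[:, None]
    i = np.arange(d // 2)[None, :]
    angle = pos / np.power(10000.0, 2 * i / d)
    enc = np.zeros((L, d))
    enc[:, 0::2] = np.sin(angle)
    enc[:, 1::2] = np.cos(angle)
    return enc


def _layer_norm(x, g, b, eps: float = 1e-5):
    mu = anp.mean(x, axis=-1, keepdims=True)
    var = anp.mean((x - mu) ** 2, axis=-1, keepdims=True)
    return g * (x - mu) / anp.sqrt(var + eps) + b


def _dropout(x, rate: float, rng: np.random.Generator | None):
    if rng is None or rate <= 0.0:
        return x
    keep = rng.random(np.shape(x)) >= rate
    return x * keep / (1.0 - rate)


def _softmax_last(x):
    m = anp.max(x, axis=-1, keepdims=True)
    e = anp.exp(x - m)
    return e / anp.sum(e, axis=-1, keepdims=True)


class Encoder:
    """Transformer encoder (pre-LayerNorm blocks, sinusoidal positions).

    Parameters live in a nested dict pytree so that losses can be
    differentiated with ``autograd`` by closing over the encoder and treating
    the pytree as the free variable.
    """

    def __init__(self, config: EncoderConfig, seed: int = 0,
                 params: dict | None = None) -> None:
        self.config = config
        self.params = params if params is not None else self.init_params(config, seed)

    # -- parameters ---------------------------------------------------------
    @staticmethod
    def init_params(config: EncoderConfig, seed: int) -> dict:
        rng = np.random.default_rng(seed)
        d = config.hidden_dim
        scale = 0.02

        def mat(*shape):
            return rng.normal(0.0, scale, size=shape)

        layers = []
        for _ in range(config.n_layers):
            layers.append(
                {
                    "Wq": mat(d, d), "bq": np.zeros(d),
                    "Wk": mat(d, d), "bk": np.zeros(d),
                    "Wv": mat(d, d), "bv": np.zeros(d),
                    "Wo": mat(d, d), "bo": np.zeros(d),
                    "ln1_g": np.ones(d), "ln1_b": np.zeros(d),
                    "ln2_g": np.ones(d), "ln2_b": np.zeros(d),
                    "W1": mat(d, 4 * d), "b1": np.zeros(4 * d),
                    "W2": mat(4 * d, d), "b2": np.zeros(d),
                }
            )
        return {"tok": mat(len(VOCAB), d), "layers": layers}

    # -- forward pieces -----------------------------------------------------
    def _block(self, x, p, pad_mask, train_rng):
        cfg = self.config
        B, L = pad_mask.shape
        d, nh = cfg.hidden_dim, cfg.n_heads
        dk = d // nh
        rate = cfg.dropout_rate if train_rng is not None else 0.0

        def heads(y):  # (B, L, d) -> (B, nh, L, dk)
            return anp.swapaxes(anp.reshape(y, (B, L, nh, dk)), 1, 2)

        h = _layer_norm(x, p["ln1_g"], p["ln1_b"])
        q = heads(h @ p["Wq"] + p["bq"])
        k = heads(h @ p["Wk"] + p["bk"])
        v = heads(h @ p["Wv"] + p["bv"])
        scores = anp.matmul(q, anp.swapaxes(k, -1, -2)) / np.sqrt(dk)
        neg = np.where(pad_mask, 0.0, -1e9)[:, None, None, :]  # mask pad keys
        attn = _softmax_last(scores + neg)
        attn = _dropout(attn, rate, train_rng)
        ctx = anp.swapaxes(anp.matmul(attn, v), 1, 2)  # back to (B, L, nh, dk)
        ctx = anp.reshape(ctx, (B, L, d)) @ p["Wo"] + p["bo"]
        x = x + _dropout(ctx, rate, train_rng)

        h2 = _layer_norm(x, p["ln2_g"], p["ln2_b"])
        ff = anp.maximum(h2 @ p["W1"] + p["b1"], 0.0) @ p["W2"] + p["b2"]
        return x + _dropout(ff, rate, train_rng)

    def forward_prefix(self, batch: TokenizedBatch, m: int,
                       params: dict | None = None,
                       train_rng: np.random.Generator | None = None) -> HiddenState:
        """Hidden states at layer ``m`` (0 = embedding + positional output)."""
        cfg = self.config
        if not 0 <= m <= cfg.n_layers:
            raise ValueError(f"layer index {m} outside 0..{cfg.n_layers}")
        p = self.params if params is None else params
        L = batch.token_ids.shape[1]
        x = p["tok"][batch.token_ids] + cfg.pos_scale * _sinusoidal(L, cfg.hidden_dim)
        for layer in p["layers"][:m]:
            x = self._block(x, layer, batch.pad_mask, train_rng)
        return HiddenState(layer_index=m, states=x, pad_mask=batch.pad_mask)

    def forward_suffix(self, hidden: HiddenState, params: dict | None = None,
                       train_rng: np.random.Generator | None = None) -> HiddenState:
        """Run remaining blocks; identity when ``hidden.layer_index == n_layers``."""
        cfg = self.config
        if not 0 <= hidden.layer_index <= cfg.n_layers:
            raise ValueError(f"layer index {hidden.layer_index} out of range")
        p = self.params if params is None else params
        x = hidden.states
        for layer in p["layers"][hidden.layer_index:]:
            x = self._block(x, layer, hidden.pad_mask, train_rng)
        return HiddenState(layer_index=cfg.n_layers, states=x, pad_mask=hidden.pad_mask)

    def forward(self, batch: TokenizedBatch, params: dict | None = None,
                train_rng: np.random.Generator | None = None) -> HiddenState:
        return self.forward_suffix(self.forward_prefix(batch, 0, params, train_rng),
                                   params, train_rng)

    def pool(self, final: HiddenState):
        """Masked mean over token positions of the final hidden states."""
        if final.layer_index != self.config.n_layers:
            raise ValueError("pool expects final-layer hidden states")
        mask = final.pad_mask
        counts = mask.sum(axis=1)
        if np.any(counts == 0):
            raise ValueError("cannot pool a row whose pad_mask is all False")
        w = mask.astype(float)[:, :, None]
        return anp.sum(final.states * w, axis=1) / counts[:, None]

    def encode_batch(self, batch: TokenizedBatch, params: dict | None = None,
                     train_rng: np.random.Generator | None = None):
        return self.pool(self.forward(batch, params, train_rng))

    def embed(self, records: list[SequenceRecord], batch_size: int = 128) -> np.ndarray:
        """Deterministic (evaluation-mode) embeddings, batched; (n, d) array."""
        out = []
        for i in range(0, len(records), batch_size):
            batch = tokenize(records[i : i + batch_size], self.config.max_tokens)
            out.append(np.asarray(self.encode_batch(batch)))
        return np.vstack(out)

    # -- checkpointing ------------------------------------------------------
    def save(self, path, metadata: dict | None = None) -> None:
        """Single-file checkpoint: weights + config + metadata (npz, version 1)."""
        flat = {"tok": self.params["tok"]}
        for i, layer in enumerate(self.params["layers"]):
            for k, v in layer.items():
                flat[f"layer{i}/{k}"] = v
        cfg = asdict(self.config)
        cfg["eligible_mix_layers"] = sorted(self.config.eligible_mix_layers)
        header = {"format_version": 1, "config": cfg, "metadata": metadata or {}}
        np.savez(path, __header__=np.frombuffer(
            json.dumps(header).encode(), dtype=np.uint8), **flat)

    @classmethod
    def load(cls, path) -> "Encoder":
        with np.load(path) as z:
            header = json.loads(bytes(z["__header__"]).decode())
            cfg_d = header["config"]
            cfg_d["eligible_mix_layers"] = frozenset(cfg_d["eligible_mix_layers"])
            config = EncoderConfig(**cfg_d)
            params = {"tok": z["tok"], "layers": []}
            for i in range(config.n_layers):
                params["layers"].append(
                    {k.split("/", 1)[1]: z[k] for k in z.files
                     if k.startswith(f"layer{i}/")}
                )
        return cls(config, params=params)
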