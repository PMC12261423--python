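"""Synthetic species genomes and contrastive training-pair construction.

Real species differ in genome-wide sequence composition; short-range base
dependencies (captured well by a low-order Markov chain) are exactly the signal
that tetranucleotide-frequency binning exploits.  This module emulates that
structure: each synthetic species is an order-``k`` Markov chain whose
transition rows are drawn from a symmetric Dirichlet.  A small concentration
parameter makes rows spiky and species compositionally divergent; a large one
pushes every species toward the uniform i.i.d. genome, removing the signal.

It also implements the positive-pair constructions used for contrastive
training: non-overlapping fragment pairs from one genome (the primary
strategy), random mutation, and reverse complement, plus a read-noise
corruption channel for evaluation sequences.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np

from .records import PairBatch, SequenceRecord
from .io import read_fasta, write_fasta, read_labels, write_labels  # noqa: F401
# FASTA/label I/O is re-exported here because generated datasets and their
# readers belong to the same workflow surface.

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_labels",
    "write_labels",
    "SpeciesModel",
    "sample_species_models",
    "synthesize_genome",
    "extract_pairs",
    "apply_read_noise",
    "make_positive_pair",
    "make_dropout_pairs",
    "reverse_complement",
    "make_training_pairs",
    "make_evaluation_mixture",
]

_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass
class SpeciesModel:
    """Generative parameters for one synthetic species.

    ``transition_probs`` maps every length-``order`` context over ACGT to a
    probability vector over the next base (A, C, G, T).  ``order == 0`` means a
    single context ``""`` (i.i.d. bases).
    """

    species_id: str
    order: int
    transition_probs: dict[str, np.ndarray]
    genome_length: int

    def __post_init__(self) -> None:
        if self.order < 0:
            raise ValueError("Markov order must be >= 0")
        if self.genome_length <= 0:
            raise ValueError("genome_length must be positive")
        n_ctx = 4**self.order
        if len(self.transition_probs) != n_ctx:
            raise ValueError(
                f"expected {n_ctx} contexts for order {self.order}, "
                f"got {len(self.transition_probs)}"
            )
        for ctx, p in self.transition_probs.items():
            p = np.asarray(p, dtype=float)
            if p.shape != (4,) or np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
                raise ValueError(
                    f"context {ctx!r}: probability vector must be length 4, "
                    "non-negative and sum to 1"
                )
            self.transition_probs[ctx] = p

    def transition_matrix(self) -> np.ndarray:
        """(4^order, 4) row-stochastic matrix, contexts in lexicographic order."""
        ctxs = contexts(self.order)
        return np.stack([self.transition_probs[c] for c in ctxs])


def contexts(order: int) -> list[str]:
    """All length-``order`` contexts over ACGT in lexicographic order."""
    return ["".join(t) for t in itertools.product(_BASES, repeat=order)]


def sample_species_models(
    n_species: int,
    order: int = 2,
    concentration: float = 0.5,
    genome_length: int = 100_000,
    seed: int = 0,
) -> list[SpeciesModel]:
    """Draw ``n_species`` Markov-chain species models.

    Every context's next-base distribution is an independent draw from a
    symmetric Dirichlet(``concentration``).  Smaller concentration gives more
    divergent compositions between species.
    """
    if n_species < 1:
        raise ValueError("n_species must be >= 1")
    if genome_length <= 0:
        raise ValueError("genome_length must be positive")
    if concentration <= 0:
        raise ValueError("concentration must be positive")
    if order < 0:
        raise ValueError("order must be >= 0")
    rng = np.random.default_rng(seed)
    ctxs = contexts(order)
    models = []
    for i in range(n_species):
        probs = rng.dirichlet([concentration] * 4, size=len(ctxs))
        models.append(
            SpeciesModel(
                species_id=f"species_{i:03d}",
                order=order,
                transition_probs=dict(zip(ctxs, probs)),
                genome_length=genome_length,
            )
        )
    return models


def synthesize_genome(model: SpeciesModel, seed: int = 0) -> SequenceRecord:
    """Sample one genome of ``model.genome_length`` bases from the chain.

    The start context is drawn uniformly over the 4^order contexts and forms
    the first ``order`` bases of the genome.
    """
    rng = np.random.default_rng(seed)
    k, length = model.order, model.genome_length
    n_ctx = 4**k
    cum = np.cumsum(model.transition_matrix(), axis=1)
    cum[:, -1] = 1.0  # guard against float round-off in searchsorted

    if k == 0:
        us = rng.random(length)
        idx = np.searchsorted(cum[0], us, side="right")
        seq = "".join(_BASES[i] for i in idx)
    else:
        start = int(rng.integers(n_ctx))
        prefix = contexts(k)[start] if length >= k else contexts(k)[start][:length]
        out = list(prefix)
        ctx = start
        us = rng.random(max(length - k, 0))
        mod = n_ctx // 4  # shifting the context window: drop oldest base
        for u in us:
            b = int(np.searchsorted(cum[ctx], u, side="right"))
            out.append(_BASES[b])
            ctx = (ctx % mod) * 4 + b if k > 1 else b
        seq = "".join(out)
    return SequenceRecord(
        seq_id=f"{model.species_id}|genome", sequence=seq, species_id=model.species_id
    )


def extract_pairs(
    genome: SequenceRecord,
    fragment_length: int,
    n_pairs: int,
    seed: int = 0,
) -> PairBatch:
    """Sample ``n_pairs`` positive pairs of non-overlapping fragments.

    Each pair is two length-``fragment_length`` fragments of ``genome`` whose
    half-open source intervals are disjoint.  Placements are drawn uniformly
    over all ordered disjoint placements (sorted-offsets construction), so the
    boundary case ``genome.length == 2 * fragment_length`` deterministically
    yields the two halves.  Across pairs, sampling is with replacement.
    """
    if fragment_length < 1 or n_pairs < 1:
        raise ValueError("fragment_length and n_pairs must be positive")
    L = genome.length
    if L < 2 * fragment_length:
        raise ValueError(
            f"genome {genome.seq_id!r} of length {L} cannot hold two disjoint "
            f"fragments of length {fragment_length}"
        )
    rng = np.random.default_rng(seed)
    anchors, positives, intervals = [], [], []
    M = L - 2 * fragment_length  # free slack
    for p in range(n_pairs):
        t = np.sort(rng.integers(0, M + 1, size=2))
        s1, s2 = int(t[0]), int(t[1]) + fragment_length
        if rng.random() < 0.5:
            s1, s2 = s2, s1
        iv1, iv2 = (s1, s1 + fragment_length), (s2, s2 + fragment_length)
        anchors.append(
            SequenceRecord(
                seq_id=f"{genome.seq_id}|p{p}|a",
                sequence=genome.sequence[iv1[0] : iv1[1]],
                species_id=genome.species_id,
            )
        )
        positives.append(
            SequenceRecord(
                seq_id=f"{genome.seq_id}|p{p}|b",
                sequence=genome.sequence[iv2[0] : iv2[1]],
                species_id=genome.species_id,
            )
        )
        intervals.append((iv1, iv2))
    return PairBatch(
        anchors=anchors,
        positives=positives,
        genome_ids=[genome.seq_id] * n_pairs,
        intervals=intervals,
    )


def apply_read_noise(
    record: SequenceRecord,
    sub_rate: float,
    indel_rate: float,
    seed: int = 0,
) -> SequenceRecord:
    """Corrupt a sequence with substitutions then indels, emulating read error.

    Each position is independently substituted to a uniformly random *different*
    base with probability ``sub_rate`` (N positions are left untouched by
    substitution), then independently deleted or duplicated with probability
    ``indel_rate / 2`` each.
    """
    for name, r in (("sub_rate", sub_rate), ("indel_rate", indel_rate)):
        if not 0.0 <= r <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1], got {r}")
    rng = np.random.default_rng(seed)
    idx = np.frombuffer(record.sequence.encode(), dtype=np.uint8)
    code = np.full(idx.shape, 4, dtype=np.int64)  # 4 = N
    for b, i in _BASE_INDEX.items():
        code[idx == ord(b)] = i

    sub = (rng.random(code.size) < sub_rate) & (code < 4)
    if sub.any():
        shift = rng.integers(1, 4, size=int(sub.sum()))
        code[sub] = (code[sub] + shift) % 4

    u = rng.random(code.size)
    reps = np.ones(code.size, dtype=np.int64)
    reps[u < indel_rate / 2] = 0
    reps[(u >= indel_rate / 2) & (u < indel_rate)] = 2
    out = np.repeat(code, reps)
    if out.size == 0:
        raise ValueError(
            f"read noise deleted every base of record {record.seq_id!r}"
        )
    alph = _BASES + "N"
    seq = "".join(alph[i] for i in out)
    return SequenceRecord(
        seq_id=f"{record.seq_id}|noisy", sequence=seq, species_id=record.species_id
    )


def reverse_complement(sequence: str) -> str:
    """Reverse complement over {A,C,G,T,N}: reversed string with A<->T, C<->G."""
    if not set(sequence) <= set("ACGTN"):
        bad = sorted(set(sequence) - set("ACGTN"))
        raise ValueError(f"cannot reverse-complement characters {bad}")
    return sequence.translate(_COMPLEMENT)[::-1]


def make_positive_pair(
    record: SequenceRecord,
    strategy: str,
    seed: int = 0,
    swap_frac: float = 0.05,
    del_frac: float = 0.05,
) -> tuple[SequenceRecord, SequenceRecord]:
    """Build a positive pair from one sequence by a view-construction strategy.

    ``double`` pairs the sequence with its reverse complement.  ``mutate``
    applies adjacent transpositions at ``swap_frac`` of positions and then
    deletes an independently chosen ``del_frac`` of positions (counts are
    ``round(frac * length)``, so the output length is deterministic).  The
    dropout strategy duplicates the input and relies on encoder dropout; see
    :func:`make_dropout_pairs`.
    """
    if strategy == "double":
        rc = SequenceRecord(
            seq_id=f"{record.seq_id}|rc",
            sequence=reverse_complement(record.sequence),
            species_id=record.species_id,
        )
        return record, rc
    if strategy != "mutate":
        raise ValueError(f"unknown strategy {strategy!r}; use 'mutate' or 'double'")

    rng = np.random.default_rng(seed)
    chars = list(record.sequence)
    L = len(chars)
    n_swap = int(round(swap_frac * L))
    if n_swap > 0 and L >= 2:
        pos = rng.choice(L - 1, size=min(n_swap, L - 1), replace=False)
        for p in pos:
            chars[p], chars[p + 1] = chars[p + 1], chars[p]
    n_del = int(round(del_frac * L))
    if n_del > 0:
        drop = set(rng.choice(L, size=min(n_del, L - 1), replace=False).tolist())
        chars = [c for i, c in enumerate(chars) if i not in drop]
    variant = SequenceRecord(
        seq_id=f"{record.seq_id}|mut",
        sequence="".join(chars),
        species_id=record.species_id,
    )
    return record, variant


def make_dropout_pairs(records: list[SequenceRecord]) -> PairBatch:
    """Duplicate each sequence into a pair; the two views differ only through
    encoder dropout at training time."""
    positives = [
        SequenceRecord(f"{r.seq_id}|dup", r.sequence, r.species_id) for r in records
    ]
    return PairBatch(
        anchors=list(records),
        positives=positives,
        genome_ids=[r.seq_id for r in records],
    )


# ---------------------------------------------------------------------------
# High-level dataset builders (the study conditions for training & evaluation)
# ---------------------------------------------------------------------------


def make_training_pairs(
    models: list[SpeciesModel],
    pairs_per_species: int,
    fragment_length: int,
    seed: int = 0,
) -> PairBatch:
    """One genome per species, ``pairs_per_species`` disjoint fragment pairs each."""
    rng = np.random.default_rng(seed)
    batches = []
    for model in models:
        g_seed, p_seed = (int(s) for s in rng.integers(0, 2**31 - 1, size=2))
        genome = synthesize_genome(model, seed=g_seed)
        batches.append(
            extract_pairs(genome, fragment_length, pairs_per_species, seed=p_seed)
        )
    return PairBatch.concatenate(batches)


def make_evaluation_mixture(
    models: list[SpeciesModel],
    fragment_length: int,
    fragments_per_species: int | None = None,
    size_range: tuple[int, int] = (15, 150),
    sub_rate: float = 0.0,
    indel_rate: float = 0.0,
    seed: int = 0,
) -> tuple[list[SequenceRecord], dict[str, str]]:
    """A labelled mixture of fragments emulating a multi-species sample.

    With ``fragments_per_species=None``, per-species counts are drawn
    log-uniformly over ``size_range``, giving the heavily skewed species sizes
    seen in real community samples; a fixed count gives a balanced mixture.
    Optional read noise corrupts every fragment.
    """
    rng = np.random.default_rng(seed)
    records: list[SequenceRecord] = []
    labels: dict[str, str] = {}
    for model in models:
        g_seed = int(rng.integers(0, 2**31 - 1))
        genome = synthesize_genome(model, seed=g_seed)
        if fragments_per_species is None:
            lo, hi = size_range
            n = int(round(math.exp(rng.uniform(math.log(lo), math.log(hi)))))
        else:
            n = fragments_per_species
        starts = rng.integers(0, genome.length - fragment_length + 1, size=n)
        for j, s in enumerate(starts):
            rec = SequenceRecord(
                seq_id=f"{model.species_id}|frag{j}",
                sequence=genome.sequence[s : s + fragment_length],
                species_id=model.species_id,
            )
            if sub_rate > 0 or indel_rate > 0:
                rec = apply_read_noise(
                    rec, sub_rate, indel_rate, seed=int(rng.integers(0, 2**31 - 1))
                )
                rec = SequenceRecord(
                    seq_id=f"{model.species_id}|frag{j}",
                    sequence=rec.sequence,
                    species_id=model.species_id,
                )
            records.append(rec)
            labels[rec.seq_id] = model.species_id
    return records, labels
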