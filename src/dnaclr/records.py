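"""Core sequence containers shared across the package.

A :class:`SequenceRecord` is one DNA sequence (a genome, a contig, or a
fragment) over the alphabet ``{A, C, G, T, N}``.  A :class:`PairBatch` holds B
positive pairs -- the unit of contrastive training, where each pair is two
non-overlapping fragments of the same genome.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

__all__ = ["SequenceRecord", "PairBatch", "VALID_BASES"]

VALID_BASES = frozenset("ACGTN")
_VALID_RE = re.compile(r"^[ACGTN]+$")


@dataclass(frozen=True)
class SequenceRecord:
    """One DNA sequence with an identifier and an optional species label."""

    seq_id: str
    sequence: str
    species_id: str | None = None

    def __post_init__(self) -> None:
        if not self.seq_id:
            raise ValueError("seq_id must be non-empty")
        if not self.sequence:
            raise ValueError(f"sequence of record {self.seq_id!r} is empty")
        if not _VALID_RE.match(self.sequence):
            bad = sorted(set(self.sequence) - VALID_BASES)
            raise ValueError(
                f"record {self.seq_id!r} contains invalid characters {bad}; "
                "allowed alphabet is A, C, G, T, N"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class PairBatch:
    """B positive pairs ``(x_i, x_i+)`` of fragments from the same genome.

    ``intervals`` records the half-open source intervals ``((s1, e1), (s2, e2))``
    of each pair within its genome when the batch was built by
    :func:`dnaclr.synthdata.extract_pairs`; it is ``None`` for pairs built by
    other strategies (mutation, reverse complement, duplication).
    """

    anchors: list[SequenceRecord]
    positives: list[SequenceRecord]
    genome_ids: list[str]
    intervals: list[tuple[tuple[int, int], tuple[int, int]] | None] = field(
        default_factory=list
    )

    def __post_init__(self) -> None:
        b = len(self.anchors)
        if b < 1:
            raise ValueError("a PairBatch needs at least one pair")
        if len(self.positives) != b or len(self.genome_ids) != b:
            raise ValueError("anchors, positives and genome_ids must align")
        if not self.intervals:
            self.intervals = [None] * b
        elif len(self.intervals) != b:
            raise ValueError("intervals must align with pairs")

    def __len__(self) -> int:
        return len(self.anchors)

    def subset(self, idx) -> "PairBatch":
        """Return the sub-batch at integer positions ``idx`` (order kept)."""
        return PairBatch(
            anchors=[self.anchors[i] for i in idx],
            positives=[self.positives[i] for i in idx],
            genome_ids=[self.genome_ids[i] for i in idx],
            intervals=[self.intervals[i] for i in idx],
        )

    @staticmethod
    def concatenate(batches: list["PairBatch"]) -> "PairBatch":
        if not batches:
            raise ValueError("cannot concatenate zero batches")
        return PairBatch(
            anchors=[r for b in batches for r in b.anchors],
            positives=[r for b in batches for r in b.positives],
            genome_ids=[g for b in batches for g in b.genome_ids],
            intervals=[iv for b in batches for iv in b.intervals],
        )
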