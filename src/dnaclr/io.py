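"""FASTA and label-table I/O.

FASTA parsing/writing is delegated to Biopython's ``SeqIO``; labels travel as a
two-column TSV ``seq_id<TAB>species_id`` with a header row.
"""

from __future__ import annotations

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as BioSeqRecord

from .records import SequenceRecord

__all__ = ["FormatError", "read_fasta", "write_fasta", "read_labels", "write_labels"]


class FormatError(ValueError):
    """A malformed input file (duplicate IDs, bad characters, wrong columns)."""


def read_fasta(path) -> list[SequenceRecord]:
    """Read a FASTA file into records, upper-casing bases.

    Wrapped and unwrapped line layouts are both accepted.  Duplicate IDs or
    characters outside ``{A,C,G,T,N}`` raise :class:`FormatError` naming the
    offending record.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"duplicate sequence ID {rec.id!r} in {path}")
        seen.add(rec.id)
        try:
            records.append(SequenceRecord(seq_id=rec.id, sequence=str(rec.seq).upper()))
        except ValueError as exc:
            raise FormatError(f"malformed record {rec.id!r} in {path}: {exc}") from exc
    if not records:
        raise FormatError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: list[SequenceRecord], path, width: int = 80) -> None:
    ids = [r.seq_id for r in records]
    if len(set(ids)) != len(ids):
        dup = sorted({i for i in ids if ids.count(i) > 1})
        raise FormatError(f"duplicate sequence IDs {dup} cannot be written")
    bio = [
        BioSeqRecord(Seq(r.sequence), id=r.seq_id, description="") for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(bio)


def read_labels(path) -> dict[str, str]:
    """Read a ``seq_id<TAB>species_id`` TSV (with header) into a dict."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise FormatError(f"label file {path} needs two tab-separated columns")
    ids, species = df.iloc[:, 0], df.iloc[:, 1]
    if ids.duplicated().any():
        dup = ids[ids.duplicated()].iloc[0]
        raise FormatError(f"duplicate seq_id {dup!r} in label file {path}")
    if ids.isna().any() or species.isna().any():
        raise FormatError(f"missing values in label file {path}")
    return dict(zip(ids, species))


def write_labels(labels: dict[str, str], path) -> None:
    df = pd.DataFrame(
        {"seq_id": list(labels.keys()), "species_id": list(labels.values())}
    )
    df.to_csv(path, sep="\t", index=False)
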