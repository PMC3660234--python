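"""Reading, merging and serializing amplicon sequence datasets.

A *dataset* is one sample's reads: an ordered multiset of nucleotide
strings plus a sample label.  Duplicate reads are meaningful — abundance
drives compressibility — so they are always preserved.

Before compression a dataset is flattened to a bare byte stream: labels
and FASTA headers are dropped (so that sequence names cannot affect the
distance) and, by default, the lines are sorted bytewise so that similar
sequences sit next to each other, which is what makes dictionary
compression effective on amplicon data.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio.SeqIO.FastaIO import SimpleFastaParser

__all__ = [
    "SequenceDataset",
    "SerializedDataset",
    "FastaParseError",
    "read_fasta",
    "read_sequence_lines",
    "write_fasta",
    "merge_datasets",
    "serialize",
]


class FastaParseError(ValueError):
    """Raised for malformed or empty FASTA input."""


@dataclass
class SequenceDataset:
    """One sample's reads.

    Parameters
    ----------
    label : str
        Sample identifier (defaults to the file stem when read from disk).
    sequences : list of str
        Ordered multiset of nucleotide strings, uppercase.  Duplicates are
        permitted and preserved.
    source : pathlib.Path, optional
        Provenance path, if the dataset was read from a file.
    """

    label: str
    sequences: list[str] = field(default_factory=list)
    source: Path | None = None

    def __len__(self) -> int:
        return len(self.sequences)

    def validate(self) -> None:
        """Check the invariants required before a distance computation."""
        if not self.sequences:
            raise ValueError(f"dataset {self.label!r} is empty")
        for i, seq in enumerate(self.sequences):
            if not seq:
                raise ValueError(f"dataset {self.label!r}: sequence {i} is empty")
            if any(c.isspace() for c in seq):
                raise ValueError(
                    f"dataset {self.label!r}: sequence {i} contains whitespace"
                )


@dataclass(frozen=True)
class SerializedDataset:
    """The exact byte stream handed to the compressor.

    ``payload`` is the sequences joined by single ``\\n`` characters with a
    trailing newline; no headers, labels or other metadata appear.  When
    ``sort_applied`` is set the lines are in bytewise lexicographic order.
    """

    payload: bytes
    record_count: int
    sort_applied: bool


def read_fasta(path: str | Path, label: str | None = None) -> SequenceDataset:
    """Read a FASTA file into a :class:`SequenceDataset`.

    Wrapped (multi-line) sequence bodies are joined; header text after
    ``>`` is discarded; residues are uppercased.  The sample label defaults
    to the file stem, never to anything in the headers.

    Raises
    ------
    FastaParseError
        If the file is empty, contains no records, contains a sequence
        line before any header, or contains a header with no body.
    """
    path = Path(path)
    text = path.read_text()
    _validate_fasta_layout(text, path)
    with io.StringIO(text) as handle:
        records = [(title, seq) for title, seq in SimpleFastaParser(handle)]
    if not records:
        raise FastaParseError(f"{path}: empty dataset (no FASTA records)")
    sequences = []
    for title, seq in records:
        if not seq:
            raise FastaParseError(f"{path}: empty sequence record {title!r}")
        sequences.append(seq.upper())
    return SequenceDataset(
        label=label if label is not None else path.stem,
        sequences=sequences,
        source=path,
    )


def _validate_fasta_layout(text: str, path: Path) -> None:
    for lineno, line in enumerate(text.splitlines(), start=1):
        stripped = line.strip()
        if not stripped:
            continue
        if not stripped.startswith(">"):
            raise FastaParseError(
                f"{path}: line {lineno}: sequence data before any '>' header"
            )
        return
    raise FastaParseError(f"{path}: empty dataset")


def read_sequence_lines(path: str | Path, label: str | None = None) -> SequenceDataset:
    """Read the plain-text alternative format: one sequence per line.

    Blank lines are ignored; residues are uppercased.
    """
    path = Path(path)
    sequences = [
        line.strip().upper() for line in path.read_text().splitlines() if line.strip()
    ]
    if not sequences:
        raise FastaParseError(f"{path}: empty dataset")
    return SequenceDataset(
        label=label if label is not None else path.stem,
        sequences=sequences,
        source=path,
    )


def write_fasta(ds: SequenceDataset, path: str | Path) -> Path:
    """Write a dataset as uncompressed FASTA, one record per read."""
    path = Path(path)
    with open(path, "w") as fh:
        for i, seq in enumerate(ds.sequences):
            fh.write(f">{ds.label}_{i}\n{seq}\n")
    return path


def merge_datasets(parts: Sequence[SequenceDataset], label: str) -> SequenceDataset:
    """Multiset union of several datasets under a new label.

    Mirrors pooling one subject's samples from several time points into a
    single per-subject dataset before pairwise comparison.
    """
    if not parts:
        raise ValueError("merge_datasets requires at least one part")
    for part in parts:
        part.validate()
    merged: list[str] = []
    for part in parts:
        merged.extend(part.sequences)
    return SequenceDataset(label=label, sequences=merged)


def serialize(ds: SequenceDataset, sort: bool = True) -> SerializedDataset:
    """Flatten a dataset to the byte stream the compressor consumes.

    Each sequence becomes one newline-terminated ASCII line.  With
    ``sort=True`` (the default, and the convention used for all distance
    computations) lines are sorted bytewise ascending, which places
    similar reads adjacently and improves the compression ratio.
    """
    ds.validate()
    lines = [seq.encode("ascii") for seq in ds.sequences]
    if sort:
        lines.sort()
    return SerializedDataset(
        payload=b"\n".join(lines) + b"\n",
        record_count=len(lines),
        sort_applied=sort,
    )


def serialize_lines(lines: Iterable[bytes], sort: bool = True) -> bytes:
    """Serialize raw byte lines with the same layout as :func:`serialize`."""
    lines = list(lines)
    if sort:
        lines.sort()
    return b"\n".join(lines) + b"\n"
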