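"""Sequence and collapsed-tag I/O.

All sequences are normalised to an uppercase DNA alphabet (U -> T) on input,
so every downstream comparison happens in a single alphabet even though small
RNAs are, biologically, RNA.  Collapsed tag libraries -- unique tag sequence
to read count, plus the library's clean-read total used as the normalisation
denominator -- are the container every pipeline stage exchanges.
"""

from __future__ import annotations

import gzip
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO

__all__ = [
    "SequenceRecord",
    "TagLibrary",
    "read_fasta",
    "read_fastq",
    "write_fasta",
    "collapse_reads",
    "write_tag_table",
    "read_tag_table",
    "revcomp",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_ALPHABET = frozenset("ACGTN")


def revcomp(seq: str) -> str:
    """Reverse complement in the DNA alphabet (N self-complementary)."""
    return seq.translate(_COMPLEMENT)[::-1]


def normalize_sequence(seq: str) -> str:
    """Uppercase and map U->T; reject residues outside {A,C,G,T,N}."""
    s = seq.upper().replace("U", "T")
    if not s:
        raise ValueError("empty sequence")
    bad = set(s) - _ALPHABET
    if bad:
        raise ValueError(f"non-nucleotide characters {sorted(bad)!r} in sequence")
    return s


@dataclass(frozen=True)
class SequenceRecord:
    """One FASTA/FASTQ entry after alphabet normalisation."""

    id: str
    sequence: str
    quality: tuple[int, ...] | None = None  # Phred scores, FASTQ only

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", normalize_sequence(self.sequence))
        if self.quality is not None and len(self.quality) != len(self.sequence):
            raise ValueError(f"record {self.id}: quality length != sequence length")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class TagLibrary:
    """One library's unique tags with counts.

    ``total_clean_reads`` is the clean-read denominator for per-million
    normalisation; it is at least the sum of retained tag counts (tags may be
    dropped after counting, the denominator is not recomputed).
    """

    library_id: str
    tags: dict[str, int] = field(default_factory=dict)
    total_clean_reads: int = 0

    def __post_init__(self) -> None:
        for tag, count in self.tags.items():
            if count < 1:
                raise ValueError(f"tag {tag}: count must be a positive integer")
        if self.total_clean_reads < 0:
            raise ValueError("total_clean_reads must be >= 0")

    @property
    def n_unique(self) -> int:
        return len(self.tags)

    @property
    def n_reads(self) -> int:
        return sum(self.tags.values())

    def count(self, tag: str) -> int:
        return self.tags.get(tag, 0)

    def __contains__(self, tag: str) -> bool:
        return tag in self.tags


def _open_text(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def _records_from_seqio(path: str | Path, fmt: str) -> Iterator[SequenceRecord]:
    seen: set[str] = set()
    with _open_text(path) as handle:
        for i, rec in enumerate(SeqIO.parse(handle, fmt)):
            if rec.id in seen:
                raise ValueError(f"{path}: duplicate record id {rec.id!r}")
            seen.add(rec.id)
            seq = str(rec.seq)
            if not seq:
                raise ValueError(f"{path}: record {rec.id!r} has an empty sequence")
            qual = None
            if fmt == "fastq":
                qual = tuple(rec.letter_annotations["phred_quality"])
            try:
                yield SequenceRecord(rec.id, seq, qual)
            except ValueError as exc:  # name the offending record
                raise ValueError(f"{path}: record {rec.id!r} (entry {i + 1}): {exc}") from exc


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a (optionally gzipped) FASTA file, order preserved."""
    return list(_records_from_seqio(path, "fasta"))


def read_fastq(path: str | Path) -> list[SequenceRecord]:
    """Read a (optionally gzipped) FASTQ file with Phred+33 qualities."""
    return list(_records_from_seqio(path, "fastq"))


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    with open(path, "w") as out:
        for rec in records:
            out.write(f">{rec.id}\n{rec.sequence}\n")


def collapse_reads(reads: Iterable[SequenceRecord | str], library_id: str) -> TagLibrary:
    """Collapse reads to unique tags with multiplicities.

    ``total_clean_reads`` is the number of input reads.  An empty input yields
    a valid empty library with total 0 (unusable as a normalisation
    denominator, which per-million conversion rejects).
    """
    counts: Counter[str] = Counter()
    total = 0
    for read in reads:
        seq = read if isinstance(read, str) else read.sequence
        counts[normalize_sequence(seq)] += 1
        total += 1
    return TagLibrary(library_id, dict(counts), total)


def _sorted_tags(lib: TagLibrary) -> list[tuple[str, int]]:
    # deterministic order: count descending, then lexicographic
    return sorted(lib.tags.items(), key=lambda kv: (-kv[1], kv[0]))


def write_tag_table(lib: TagLibrary, path: str | Path) -> None:
    """Write a TSV of (tag, count) sorted by count desc then tag."""
    with open(path, "w") as out:
        out.write(f"# library_id={lib.library_id}\ttotal_clean_reads={lib.total_clean_reads}\n")
        out.write("tag\tcount\n")
        for tag, count in _sorted_tags(lib):
            out.write(f"{tag}\t{count}\n")


def read_tag_table(path: str | Path) -> TagLibrary:
    """Inverse of :func:`write_tag_table`."""
    with _open_text(path) as handle:
        header = handle.readline().strip()
        if not header.startswith("#"):
            raise ValueError(f"{path}: missing tag-table header line")
        meta = dict(part.split("=", 1) for part in header[1:].strip().split("\t"))
        cols = handle.readline().strip().split("\t")
        if cols != ["tag", "count"]:
            raise ValueError(f"{path}: unexpected columns {cols}")
        tags: dict[str, int] = {}
        for line in handle:
            tag, count = line.split()
            if tag in tags:
                raise ValueError(f"{path}: duplicate tag {tag}")
            tags[tag] = int(count)
    return TagLibrary(meta["library_id"], tags, int(meta["total_clean_reads"]))
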