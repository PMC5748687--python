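"""Raw small-RNA read filtering and tag annotation.

The cascade mirrors the standard small-RNA pipeline for collapsed tag
libraries: quality filter, 3' adapter trimming (rejecting adapter-dimer and
adapterless reads), insert length filter to [15, 30] nt, collapse to unique
tags, then class annotation by exact substring match against reference
non-coding RNA sets in a fixed priority order (structural RNA classes before
sequence-database classes before the polyA rule), so every tag receives
exactly one class.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from .io import SequenceRecord, TagLibrary, collapse_reads, read_fasta

__all__ = [
    "CleanReadStats",
    "AnnotationSet",
    "AnnotatedTag",
    "trim_adapter",
    "filter_length",
    "quality_ok",
    "annotate_tag",
    "preprocess_reads",
    "library_stats",
]

MIN_INSERT = 15
MAX_INSERT = 30
MIN_ADAPTER_OVERLAP = 6
MAX_ADAPTER_MISMATCH = 1
ANNOTATION_CLASSES = ("rRNA", "tRNA", "snRNA", "snoRNA", "known_miRNA", "repeat")


@dataclass
class CleanReadStats:
    """Per-library cascade counts (monotone non-increasing)."""

    library_id: str
    total_reads: int
    high_quality: int
    clean_reads: int
    unique_tags: int

    def __post_init__(self) -> None:
        if not (self.total_reads >= self.high_quality >= self.clean_reads >= 0):
            raise ValueError("cascade counts must be monotone non-increasing")
        if self.unique_tags > self.clean_reads:
            raise ValueError("unique_tags cannot exceed clean_reads")


@dataclass(frozen=True)
class AnnotatedTag:
    tag: str
    annotation: str  # one of ANNOTATION_CLASSES, "polyA" or "unannotated"
    source_id: str | None = None


def quality_ok(read: SequenceRecord, min_q: int = 20, max_low_frac: float = 0.10) -> bool:
    """Low-quality rule: drop reads with any N or >10% bases under Q20.

    Reads without quality strings (FASTA input) pass unless they contain N.
    """
    if "N" in read.sequence:
        return False
    if read.quality is None:
        return True
    low = sum(1 for q in read.quality if q < min_q)
    return low / len(read.quality) <= max_low_frac


def trim_adapter(read: SequenceRecord, adapter3: str) -> SequenceRecord | None:
    """Trim the 3' adapter; None signals rejection.

    The insert is the read prefix before the left-most adapter match.  A
    match is >= 6 nt of the adapter's prefix with at most one mismatch.
    Reads whose adapter starts at position 0 are adapter-dimers; reads with
    no adapter match carry no recognisable insert.  Both are rejected.
    """
    if len(adapter3) < MIN_ADAPTER_OVERLAP:
        raise ValueError("adapter must be at least 6 nt")
    seq = read.sequence
    for i in range(0, len(seq) - MIN_ADAPTER_OVERLAP + 1):
        n = min(len(adapter3), len(seq) - i)
        mm = sum(1 for a, b in zip(seq[i : i + n], adapter3[:n]) if a != b)
        if mm <= MAX_ADAPTER_MISMATCH:
            if i == 0:
                return None  # adapter-dimer
            qual = read.quality[:i] if read.quality is not None else None
            return SequenceRecord(read.id, seq[:i], qual)
    return None


def filter_length(tag: str) -> bool:
    """Keep inserts of 15-30 nt inclusive."""
    return MIN_INSERT <= len(tag) <= MAX_INSERT


class AnnotationSet:
    """Reference non-coding RNA sets, one FASTA-derived pool per class.

    Classes are checked in the fixed priority order of
    :data:`ANNOTATION_CLASSES`; a tag matching several classes gets the
    first.  The polyA rule (3' A-run covering >= 80% of the tag) applies only
    when no reference class matched.
    """

    def __init__(self, references: dict[str, Sequence[SequenceRecord]]):
        if not references:
            raise ValueError("empty reference set")
        unknown = set(references) - set(ANNOTATION_CLASSES)
        if unknown:
            raise ValueError(f"unknown annotation classes: {sorted(unknown)}")
        self.classes = [c for c in ANNOTATION_CLASSES if c in references]
        self._records = {c: list(references[c]) for c in self.classes}
        # concatenated per-class text for fast substring probing
        self._pools = {
            c: "#" + "#".join(r.sequence for r in self._records[c]) + "#" for c in self.classes
        }

    @classmethod
    def from_directory(cls, path: str | Path) -> "AnnotationSet":
        """Load ``<class>.fasta`` files from a directory."""
        path = Path(path)
        refs = {}
        for cls_name in ANNOTATION_CLASSES:
            f = path / f"{cls_name}.fasta"
            if f.exists():
                refs[cls_name] = read_fasta(f)
        return cls(refs)

    def lookup(self, tag: str) -> tuple[str, str] | None:
        for cls_name in self.classes:
            if tag in self._pools[cls_name]:
                for rec in self._records[cls_name]:
                    if tag in rec.sequence:
                        return cls_name, rec.id
        return None


def is_polya(tag: str, min_frac: float = 0.80) -> bool:
    run = len(tag) - len(tag.rstrip("A"))
    return run >= min_frac * len(tag)


def annotate_tag(tag: str, refs: AnnotationSet | None) -> AnnotatedTag:
    """Assign exactly one annotation class to a tag."""
    if refs is not None:
        hit = refs.lookup(tag)
        if hit is not None:
            return AnnotatedTag(tag, hit[0], hit[1])
    if is_polya(tag):
        return AnnotatedTag(tag, "polyA")
    return AnnotatedTag(tag, "unannotated")


def preprocess_reads(
    reads: Iterable[SequenceRecord],
    adapter3: str,
    library_id: str,
    refs: AnnotationSet | None = None,
) -> tuple[TagLibrary, CleanReadStats, dict[str, AnnotatedTag]]:
    """Run the full cascade: quality -> adapter -> length -> collapse -> annotate.

    Returns the clean tag library (total_clean_reads = number of clean
    reads), the cascade statistics, and per-tag annotations.  The library
    keeps all clean tags; the annotation map lets downstream stages select
    the classes they need (e.g. unannotated tags for novel miRNA calling).
    """
    total = high_quality = clean = 0
    inserts: list[str] = []
    for read in reads:
        total += 1
        if not quality_ok(read):
            continue
        high_quality += 1
        trimmed = trim_adapter(read, adapter3)
        if trimmed is None or not filter_length(trimmed.sequence):
            continue
        clean += 1
        inserts.append(trimmed.sequence)
    lib = collapse_reads(inserts, library_id)
    stats = CleanReadStats(library_id, total, high_quality, clean, lib.n_unique)
    annotations = {tag: annotate_tag(tag, refs) for tag in lib.tags}
    return lib, stats, annotations


def library_stats(raw_reads: Sequence[SequenceRecord], processed: TagLibrary,
                  high_quality: int | None = None) -> CleanReadStats:
    """Cascade statistics from a raw read list and its processed library."""
    hq = high_quality if high_quality is not None else len(raw_reads)
    return CleanReadStats(
        processed.library_id,
        total_reads=len(raw_reads),
        high_quality=hq,
        clean_reads=processed.n_reads,
        unique_tags=processed.n_unique,
    )
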