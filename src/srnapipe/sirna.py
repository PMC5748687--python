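"""siRNA duplex detection and repeat-element mapping.

A Dicer-processed siRNA duplex is two 21-24 nt strands whose paired cores
are exact reverse complements, each strand carrying a 2-nt unpaired 3'
overhang.  With both overhangs fixed at 2 nt and exact core
complementarity, the defining relation between strands a and b is

    revcomp(a[:-2]) == b[:-2]

(which forces equal strand lengths and is symmetric in a and b).  The
search indexes 5' cores by their reverse complement so it runs linearly in
the number of tags instead of over all pairs.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Sequence

from .io import SequenceRecord, TagLibrary, revcomp

__all__ = [
    "DuplexPair",
    "RepeatMapping",
    "find_duplex_pairs",
    "map_duplexes_to_elements",
    "duplex_length_distribution",
]

MIN_SIRNA = 21
MAX_SIRNA = 24
OVERHANG = 2


@dataclass(frozen=True)
class DuplexPair:
    """One unordered duplex; tag_a <= tag_b lexicographically."""

    tag_a: str
    tag_b: str

    @property
    def paired_length(self) -> int:
        return len(self.tag_a) - OVERHANG

    @property
    def longer_length(self) -> int:
        return max(len(self.tag_a), len(self.tag_b))


def is_duplex(a: str, b: str) -> bool:
    """The 2-nt 3'-overhang rule for one candidate strand pair."""
    if not (MIN_SIRNA <= len(a) <= MAX_SIRNA and MIN_SIRNA <= len(b) <= MAX_SIRNA):
        return False
    return revcomp(a[:-OVERHANG]) == b[:-OVERHANG]


def find_duplex_pairs(tags: TagLibrary | Iterable[str]) -> list[DuplexPair]:
    """All unordered duplex pairs among 21-24 nt tags.

    A tag may participate in multiple pairs; self-complementary tags whose
    core satisfies the rule against themselves are reported once as a
    self-pair.  Output is sorted for determinism.
    """
    seqs = sorted(set(tags.tags) if isinstance(tags, TagLibrary) else set(tags))
    seqs = [s for s in seqs if MIN_SIRNA <= len(s) <= MAX_SIRNA]
    by_core: dict[str, list[str]] = defaultdict(list)
    for s in seqs:
        by_core[s[:-OVERHANG]].append(s)
    pairs: set[tuple[str, str]] = set()
    for s in seqs:
        for partner in by_core.get(revcomp(s[:-OVERHANG]), ()):
            pairs.add((min(s, partner), max(s, partner)))
    return [DuplexPair(a, b) for a, b in sorted(pairs)]


@dataclass
class RepeatMapping:
    """Per-position small-RNA duplex coverage along one repeat element."""

    element_id: str
    length: int
    coverage: list[int]  # 1-based positions stored at index pos-1
    mapped_duplexes: int


def map_duplexes_to_elements(
    pairs: Sequence[DuplexPair],
    elements: Sequence[SequenceRecord],
) -> tuple[dict[str, RepeatMapping], int]:
    """Map duplexes onto repeat elements requiring perfect strand matches.

    A duplex maps to an element iff one strand matches the element's sense
    strand exactly and the other matches its antisense strand (i.e. its
    reverse complement is a sense substring).  Coverage counts both strands'
    matched spans.  Returns the per-element mappings and the number of
    unmapped duplexes (mapped + unmapped = total).
    """
    mappings = {
        el.id: RepeatMapping(el.id, len(el.sequence), [0] * len(el.sequence), 0)
        for el in elements
    }
    unmapped = 0
    for pair in pairs:
        hit_any = False
        for el in elements:
            spans = None
            for sense, anti in ((pair.tag_a, pair.tag_b), (pair.tag_b, pair.tag_a)):
                i = el.sequence.find(sense)
                j = el.sequence.find(revcomp(anti))
                if i != -1 and j != -1:
                    spans = [(i, i + len(sense)), (j, j + len(anti))]
                    break
            if spans is not None:
                m = mappings[el.id]
                m.mapped_duplexes += 1
                for s, e in spans:
                    for k in range(s, e):
                        m.coverage[k] += 1
                hit_any = True
        if not hit_any:
            unmapped += 1
    return mappings, unmapped


def duplex_length_distribution(pairs: Sequence[DuplexPair]) -> dict[int, float]:
    """Fractions per duplex length class (longer strand), summing to 1."""
    if not pairs:
        raise ValueError("empty duplex set")
    counts: dict[int, int] = defaultdict(int)
    for p in pairs:
        counts[p.longer_length] += 1
    total = len(pairs)
    return {length: counts[length] / total for length in sorted(counts)}
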