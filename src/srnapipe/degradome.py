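"""Degradome (PARE) tag processing and miRNA cleavage-target calling.

Degradome tags are the 5' ends of uncapped cleavage fragments; a pile-up of
tag 5' ends at the position pairing nucleotide 10 of a complementary miRNA
is the classic evidence of miRNA-guided slicing.  Candidate miRNA:target
duplexes are scored as mismatches + 0.5 per G:U wobble + 1 per gap
position; the cleavage site of an alignment spanning [start, end] on the
transcript is end - 9.  Each called event is placed in the standard
five-category scheme ranking the site signal against the transcript's
degradome maximum and median.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from statistics import median
from typing import Iterable, Mapping, Sequence

import numpy as np

from .io import SequenceRecord, TagLibrary, revcomp
from .preprocess import AnnotationSet, annotate_tag, trim_adapter

__all__ = [
    "TranscriptDegradationProfile",
    "CleavageEvent",
    "prepare_degradome_tags",
    "build_profile",
    "score_alignment",
    "predict_cleavage",
    "find_target_sites",
    "call_targets",
    "assign_category",
    "tplot_data",
]

DEG_MIN, DEG_MAX = 20, 21
POLYN_FRAC = 0.70
DEFAULT_MAX_SCORE = 4.5
CLEAVAGE_OFFSET = 9  # site = alignment end - 9 (pairs miRNA nucleotide 10)

_ENC = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
_COMP_CODE = np.array([3, 2, 1, 0, 4], dtype=np.uint8)  # A<->T, C<->G, N->N(=4 never matches)


def is_polyn(tag: str) -> bool:
    """PolyN rule: one base strictly over 70% of positions."""
    return max(tag.count(b) for b in "ACGT") / len(tag) > POLYN_FRAC


def prepare_degradome_tags(
    reads: Iterable[SequenceRecord | str],
    adapter3: str | None = None,
    refs: AnnotationSet | None = None,
    library_id: str = "degradome",
) -> TagLibrary:
    """Trim, length-filter (20-21 nt), drop polyN, drop annotated tags.

    ``reads`` may be raw reads (then ``adapter3`` is trimmed) or already
    clipped fragments.  Only unannotated, non-polyN tags survive; these are
    the tags mapped to transcripts downstream.
    """
    kept: dict[str, int] = {}
    total = 0
    for read in reads:
        total += 1
        rec = read if isinstance(read, SequenceRecord) else SequenceRecord(f"r{total}", read)
        if adapter3 is not None:
            rec = trim_adapter(rec, adapter3)
            if rec is None:
                continue
        seq = rec.sequence
        if not (DEG_MIN <= len(seq) <= DEG_MAX):
            continue
        if is_polyn(seq):
            continue
        if annotate_tag(seq, refs).annotation != "unannotated":
            continue
        kept[seq] = kept.get(seq, 0) + 1
    return TagLibrary(library_id, kept, total)


@dataclass
class TranscriptDegradationProfile:
    """Summed degradome tag abundance by 5'-end position (1-based)."""

    transcript_id: str
    positions: dict[int, int] = field(default_factory=dict)

    @property
    def total(self) -> int:
        return sum(self.positions.values())

    def abundance(self, pos: int) -> int:
        return self.positions.get(pos, 0)


def build_profile(
    tags: TagLibrary,
    transcripts: Sequence[SequenceRecord],
) -> dict[str, TranscriptDegradationProfile]:
    """Map tags to transcripts by exact sense-strand substring match.

    A tag matching k transcripts contributes its full count to each; a tag
    matching one transcript at several positions contributes to every
    matched 5' position.  Antisense matches contribute nothing.
    """
    profiles = {t.id: TranscriptDegradationProfile(t.id) for t in transcripts}
    for tag, count in tags.tags.items():
        for t in transcripts:
            start = t.sequence.find(tag)
            while start != -1:
                pos = start + 1
                prof = profiles[t.id]
                prof.positions[pos] = prof.positions.get(pos, 0) + count
                start = t.sequence.find(tag, start + 1)
    return profiles


def _pair_cost(mirna_base: str, target_base: str) -> float:
    """Cost of pairing one miRNA base against one target (mRNA) base."""
    if "N" in (mirna_base, target_base):
        return 1.0
    if target_base == {"A": "T", "C": "G", "G": "C", "T": "A"}[mirna_base]:
        return 0.0
    if (mirna_base, target_base) in (("G", "T"), ("T", "G")):
        return 0.5  # G:U wobble
    return 1.0


def score_alignment(mirna: str, site: str) -> float:
    """Score the antisense miRNA:site duplex (mismatch + 0.5*G:U + gaps).

    The miRNA 5' end pairs toward the site's 3' end.  Equal lengths score
    the ungapped alignment; a length difference of up to 2 nt is absorbed by
    one gap (of that length, one unit of score per gap position) placed
    wherever it minimises the score.
    """
    lm, ls = len(mirna), len(site)
    d = abs(lm - ls)
    if d > 2:
        raise ValueError("site length must be within 2 nt of the miRNA length")
    site_rc_order = site[::-1]  # align mirna[i] against site[ls-1-i]

    def pairwise(m: str, s: str) -> float:
        return sum(_pair_cost(a, b) for a, b in zip(m, s) if a != "-" and b != "-") + sum(
            1.0 for a, b in zip(m, s) if a == "-" or b == "-"
        )

    if d == 0:
        return pairwise(mirna, site_rc_order)
    short, long_ = (mirna, site_rc_order) if lm < ls else (site_rc_order, mirna)
    best = None
    for g in range(len(short) + 1):
        gapped = short[:g] + "-" * d + short[g:]
        s = pairwise(gapped, long_) if lm < ls else pairwise(long_, gapped)
        if best is None or s < best:
            best = s
    return best


def predict_cleavage(alignment_range: tuple[int, int]) -> int:
    """Cleavage site (1-based) of an alignment span: end - 9."""
    start, end = alignment_range
    if end - start + 1 < 15:
        raise ValueError("alignment range shorter than 15 nt")
    return end - CLEAVAGE_OFFSET


def find_target_sites(
    mirna: str,
    transcript: SequenceRecord | str,
    max_score: float = DEFAULT_MAX_SCORE,
) -> list[tuple[int, int, float]]:
    """All ungapped antisense sites of a miRNA on one transcript.

    Scans every window of the miRNA's length with a vectorised scorer;
    returns 1-based inclusive ``(start, end, score)`` for windows with
    score <= max_score.
    """
    seq = transcript.sequence if isinstance(transcript, SequenceRecord) else transcript
    L = len(mirna)
    n = len(seq)
    if n < L:
        return []
    t = np.frombuffer(seq.encode(), dtype=np.uint8)
    codes = np.full(256, 4, dtype=np.uint8)
    for base, code in _ENC.items():
        codes[ord(base)] = code
    t = codes[t]
    q = _COMP_CODE[[_ENC[b] for b in mirna[::-1]]]  # expected window = revcomp(mirna)
    windows = np.lib.stride_tricks.sliding_window_view(t, L)
    eq = windows == q
    # wobble in window space: miRNA G vs target T -> (q=C, window=T);
    # miRNA T vs target G -> (q=A, window=G)
    wob = ((q == _ENC["C"]) & (windows == _ENC["T"])) | ((q == _ENC["A"]) & (windows == _ENC["G"]))
    valid = (windows != 4) & (q != 4)
    cost = np.where(eq & valid, 0.0, np.where(wob & valid, 0.5, 1.0)).sum(axis=1)
    hits = np.flatnonzero(cost <= max_score)
    return [(int(i) + 1, int(i) + L, float(cost[i])) for i in hits]


@dataclass
class CleavageEvent:
    """One miRNA -> transcript degradome-supported cleavage call."""

    mirna_id: str
    transcript_id: str
    alignment_score: float
    alignment_range: tuple[int, int]  # 1-based inclusive
    cleavage_site: int
    category: int | None = None
    abundance: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        lo, hi = self.alignment_range
        if not (lo <= self.cleavage_site <= hi):
            raise ValueError("cleavage site outside alignment range")


def assign_category(
    site_abundance: int,
    profile: TranscriptDegradationProfile,
) -> int:
    """Five-category degradome convention.

    0: site equals the transcript maximum, > 1 read, maximum unique;
    1: equals a shared maximum, > 1 read;
    2: below the maximum but above the median of non-zero positions;
    3: at or below that median, > 1 read;
    4: exactly one read.
    """
    if site_abundance <= 0:
        raise ValueError("site has no degradome signal")
    if site_abundance == 1:
        return 4
    values = list(profile.positions.values())
    mx = max(values)
    if site_abundance == mx:
        return 0 if values.count(mx) == 1 else 1
    med = median(values)
    return 2 if site_abundance > med else 3


def call_targets(
    mirnas: Mapping[str, str],
    transcripts: Sequence[SequenceRecord],
    profiles_by_library: Mapping[str, Mapping[str, TranscriptDegradationProfile]],
    max_score: float = DEFAULT_MAX_SCORE,
) -> list[CleavageEvent]:
    """Call degradome-supported cleavage events for a set of miRNAs.

    For every miRNA x transcript candidate site scoring <= max_score an
    event is emitted iff the summed degradome abundance at the predicted
    cleavage site is >= 1.  Different miRNAs cleaving the same site yield
    distinct events.  The category is assigned on the library-summed
    profile; per-library site abundances are recorded.
    """
    # combined profile across libraries
    combined: dict[str, TranscriptDegradationProfile] = {}
    for lib_profiles in profiles_by_library.values():
        for tid, prof in lib_profiles.items():
            agg = combined.setdefault(tid, TranscriptDegradationProfile(tid))
            for pos, cnt in prof.positions.items():
                agg.positions[pos] = agg.positions.get(pos, 0) + cnt

    events: list[CleavageEvent] = []
    for mirna_id in sorted(mirnas):
        seq = mirnas[mirna_id]
        for t in transcripts:
            for start, end, score in find_target_sites(seq, t, max_score):
                site = predict_cleavage((start, end))
                agg = combined.get(t.id)
                total_ab = agg.abundance(site) if agg else 0
                if total_ab < 1:
                    continue
                per_lib = {
                    lib: (lp[t.id].abundance(site) if t.id in lp else 0)
                    for lib, lp in profiles_by_library.items()
                }
                events.append(
                    CleavageEvent(
                        mirna_id,
                        t.id,
                        score,
                        (start, end),
                        site,
                        assign_category(total_ab, agg),
                        per_lib,
                    )
                )
    return events


def tplot_data(
    event: CleavageEvent,
    profile: TranscriptDegradationProfile,
) -> list[tuple[int, int, bool]]:
    """T-plot rows ``(position, abundance, is_cleavage_site)`` sorted by position."""
    return [
        (pos, ab, pos == event.cleavage_site)
        for pos, ab in sorted(profile.positions.items())
    ]
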