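"""Two-hit trigger loci, 21-nt phase registers and tasiRNA targets.

A TAS3-style locus carries two recognition sites for a 21-nt trigger miRNA
(miR390); cleavage at one site fixes a 21-nt register from which phased
small RNAs D1(+), D2(+), ... are diced toward the other site.  The phase
count of a locus is round(spacing / 21), where spacing is the nucleotides
strictly between the two site spans -- the only rule reproducing the
published 174 nt -> 8 phases and 261 nt -> 12 phases examples, neither
spacing being an exact multiple of 21.  tasiRNA target genes are found by
the same wobble-aware antisense scoring used for degradome alignments.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .degradome import (
    DEFAULT_MAX_SCORE,
    TranscriptDegradationProfile,
    find_target_sites,
    predict_cleavage,
)
from .io import SequenceRecord, TagLibrary

__all__ = [
    "TargetSite",
    "TasiLocus",
    "PhasedSmallRNA",
    "TasiTargetGene",
    "CorrelationResult",
    "find_trigger_sites",
    "detect_two_hit_locus",
    "extract_phases",
    "predict_tasi_targets",
    "correlate_series",
]

PHASE = 21


@dataclass(frozen=True)
class TargetSite:
    transcript_id: str
    span: tuple[int, int]  # 1-based inclusive
    score: float
    cleaved: bool = False  # degradome-supported


@dataclass
class TasiLocus:
    """A two-hit trigger locus with its phase register."""

    transcript_id: str
    site5: TargetSite  # 5'-proximal
    site3: TargetSite  # 3'-proximal

    def __post_init__(self) -> None:
        if self.site5.span[1] >= self.site3.span[0]:
            raise ValueError("site5 must end before site3 starts")

    @property
    def spacing_nt(self) -> int:
        return self.site3.span[0] - self.site5.span[1] - 1

    @property
    def phase_count(self) -> int:
        return round(self.spacing_nt / PHASE)

    @property
    def validated(self) -> bool:
        """Exactly one site degradome-cleaved (the canonical two-hit pattern)."""
        return self.site5.cleaved != self.site3.cleaved


@dataclass
class PhasedSmallRNA:
    name: str  # Dk(+) / Dk(-)
    k: int
    sequence: str
    span: tuple[int, int]
    abundance: dict[str, int] = field(default_factory=dict)
    truncated: bool = False


def find_trigger_sites(
    trigger: str,
    transcripts: Sequence[SequenceRecord],
    max_score: float = DEFAULT_MAX_SCORE,
    profiles: Mapping[str, TranscriptDegradationProfile] | None = None,
) -> dict[str, list[TargetSite]]:
    """All antisense trigger sites per transcript, degradome-flagged.

    A site is flagged ``cleaved`` when a degradome profile shows signal at
    its predicted cleavage position (site end - 9).
    """
    if len(trigger) != PHASE:
        raise ValueError("trigger must be 21 nt")
    out: dict[str, list[TargetSite]] = {}
    for t in transcripts:
        sites = []
        for start, end, score in find_target_sites(trigger, t, max_score):
            cleaved = False
            if profiles is not None and t.id in profiles:
                cleaved = profiles[t.id].abundance(predict_cleavage((start, end))) >= 1
            sites.append(TargetSite(t.id, (start, end), score, cleaved))
        if sites:
            out[t.id] = sites
    return out


def _prune_overlaps(sites: list[TargetSite]) -> list[TargetSite]:
    """Discard the higher-scoring site of an overlapping pair (tie: keep 5'-most)."""
    kept: list[TargetSite] = []
    for site in sorted(sites, key=lambda s: (s.score, s.span[0])):
        if all(site.span[1] < k.span[0] or site.span[0] > k.span[1] for k in kept):
            kept.append(site)
    return sorted(kept, key=lambda s: s.span[0])


def detect_two_hit_locus(sites_by_transcript: Mapping[str, Sequence[TargetSite]]) -> list[TasiLocus]:
    """Form loci from transcripts bearing two or more non-overlapping sites.

    The closest compliant pair (smallest spacing with at least one phase)
    defines the locus; one locus per transcript.
    """
    loci = []
    for tid in sorted(sites_by_transcript):
        sites = _prune_overlaps(list(sites_by_transcript[tid]))
        if len(sites) < 2:
            continue
        best: TasiLocus | None = None
        for i in range(len(sites) - 1):
            for j in range(i + 1, len(sites)):
                locus = TasiLocus(tid, sites[i], sites[j])
                if locus.phase_count < 1:
                    continue
                if best is None or locus.spacing_nt < best.spacing_nt:
                    best = locus
        if best is not None:
            loci.append(best)
    return loci


def extract_phases(
    locus: TasiLocus,
    transcript: SequenceRecord | str,
    tag_libraries: Sequence[TagLibrary] = (),
    anchor: str = "site3_cleavage",
    max_k: int | None = None,
) -> list[PhasedSmallRNA]:
    """Extract Dk(+) 21-nt phased windows from a two-hit locus.

    With the default ``site3_cleavage`` anchor, the register starts at the
    3'-proximal site's predicted cleavage position and windows are counted
    toward the 5' site (Dk spans ``[c - 21k, c - 1 - 21(k-1)]``).  The
    ``site5_end`` anchor counts downstream from the 5'-proximal site's end
    instead.  Windows are reported whether or not any tag supports them;
    windows running off the register are truncated and flagged.
    """
    seq = transcript.sequence if isinstance(transcript, SequenceRecord) else transcript
    if max_k is None:
        max_k = locus.phase_count
    phases = []
    for k in range(1, max_k + 1):
        if anchor == "site3_cleavage":
            c = predict_cleavage(locus.site3.span)
            start, end = c - PHASE * k, c - 1 - PHASE * (k - 1)
        elif anchor == "site5_end":
            e = locus.site5.span[1]
            start, end = e + 1 + PHASE * (k - 1), e + PHASE * k
        else:
            raise ValueError(f"unknown anchor {anchor!r}")
        truncated = start < 1 or end > len(seq)
        s, e_ = max(1, start), min(len(seq), end)
        window = seq[s - 1 : e_]
        abundance = {lib.library_id: lib.count(window) for lib in tag_libraries}
        phases.append(PhasedSmallRNA(f"D{k}(+)", k, window, (s, e_), abundance, truncated))
    return phases


@dataclass
class TasiTargetGene:
    gene_id: str
    sites: list[TargetSite]
    annotation: str | None = None

    def __post_init__(self) -> None:
        if not (1 <= len(self.sites) <= 2):
            raise ValueError("a tasiRNA target gene carries one or two sites")


def predict_tasi_targets(
    tasi: str,
    genes: Sequence[SequenceRecord],
    max_mismatch: float = 2.0,
) -> list[TasiTargetGene]:
    """Genes with 1-2 antisense tasiRNA sites at score <= max_mismatch.

    Near-perfect complementarity: the same mismatch scoring as degradome
    alignment (G:U = 0.5).  Genes with more than two qualifying sites are
    reported with their best two (lowest score, then 5'-most).
    """
    if len(tasi) != PHASE:
        raise ValueError("tasiRNA must be 21 nt")
    out = []
    for gene in genes:
        sites = [
            TargetSite(gene.id, (s, e), sc)
            for s, e, sc in find_target_sites(tasi, gene, max_mismatch)
        ]
        if sites:
            sites = sorted(sites, key=lambda s: (s.score, s.span[0]))[:2]
            out.append(TasiTargetGene(gene.id, sorted(sites, key=lambda s: s.span[0])))
    return out


@dataclass(frozen=True)
class CorrelationResult:
    pair: tuple[str, str]
    r: float
    corr_class: str  # negative | positive | flat


def correlate_series(
    a: Sequence[float],
    b: Sequence[float],
    pair: tuple[str, str] = ("a", "b"),
    threshold: float = 0.5,
) -> CorrelationResult:
    """Pearson correlation over a condition series with a sign class.

    ``negative`` if r < -threshold, ``positive`` if r > threshold, else
    ``flat``.  Constant series have no defined correlation and raise.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) != len(b) or len(a) < 3:
        raise ValueError("series must have equal length >= 3")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("correlation undefined for a constant series")
    r = float(np.corrcoef(a, b)[0, 1])
    cls = "negative" if r < -threshold else "positive" if r > threshold else "flat"
    return CorrelationResult(pair, r, cls)
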