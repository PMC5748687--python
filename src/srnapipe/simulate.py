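"""Synthetic transcriptome, small-RNA and degradome libraries with ground truth.

The generator emulates the statistical structure of a three-condition salt
time-course small-RNA experiment (an untreated control plus an early-shock
and a late-stress library):

* transcripts hosting planted miRNA hairpins -- a mature strand, a linker
  loop, and a near-reverse-complement star strand arranged so the
  mature/star duplex has the canonical 2-nt 3' overhang on each strand;
* TAS3-like loci with two 21-nt trigger recognition sites spaced a whole
  number of 21-nt phases apart, phased D7/D8 tasiRNA content, and degradome
  support at the 3'-proximal site only;
* repeat elements present in multiple transcript copies that shed siRNA
  duplex pairs obeying the 2-nt overhang rule, with the 24-nt class enriched;
* miRNA target transcripts carrying antisense target sites whose degradome
  tags pile up exactly at the predicted cleavage position;
* log-normally skewed tag abundances, condition-dependent fold changes for a
  configurable fraction of miRNAs, library-specific miRNAs, and
  substitution-only sequencing error.

Every planted structure is recorded in :class:`GroundTruth` so downstream
detectors can be scored for sensitivity and precision without external data.
One RNG stream per output library is derived from the master seed, so adding
a library never perturbs an earlier one.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .degradome import predict_cleavage, score_alignment
from .io import SequenceRecord, TagLibrary, revcomp

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "PlantedMiRNA",
    "PlantedDuplex",
    "PlantedTas3",
    "PlantedCleavage",
    "simulate_transcriptome",
    "simulate_small_rna_libraries",
    "simulate_degradome",
    "reads_from_library",
]

BASES = np.array(list("ACGT"))
CONDITIONS = ("CK", "T4h", "T5d")

# miR390 (conserved trigger) and a TAS3 D7(+) tasiRNA-ARF, DNA alphabet
DEFAULT_TRIGGER = "AAGCTCAGGAGGGATAGCGCC"
DEFAULT_TASI_ARF = "TTCTTGACCTTGTAAGACCCA"


@dataclass
class SimulationConfig:
    """Knobs of the synthetic experiment (defaults are the study conditions)."""

    seed: int = 0
    n_transcripts: int = 250  # background transcripts
    n_mirna: int = 30  # planted hairpins
    n_conserved: int = 8  # tags drawn from the bundled known-miRNA reference
    n_tas3: int = 2  # planted two-hit loci
    n_repeat: int = 4  # repeat elements (each in >= 2 transcript copies)
    n_targets: int = 20  # planted miRNA cleavage targets
    n_arf: int = 3  # ARF-like tasiRNA target genes
    n_specific: int = 4  # library-specific miRNAs (absent from control)
    depth: int = 120_000  # reads per small-RNA library
    degradome_depth: int = 40_000
    de_fraction: float = 0.4  # fraction of planted miRNAs differentially expressed
    de_log2fc: float = 2.0
    adapter3: str = "TGGAATTCTCGGGTGCCAAGG"
    error_rate: float = 0.001  # per-base substitution probability
    # mixture over read lengths for background tags
    length_mode_weights: dict = field(
        default_factory=lambda: {21: 0.50, 24: 0.30, "other": 0.20}
    )
    duplex_pairs: int = 60
    duplex_len24_weight: float = 0.6
    n_background_tags: int = 1500  # random-sequence background tags
    n_fragment_tags: int = 150  # transcript-derived background tags
    tas3_jitter: int = 0  # +/- nt applied to inter-site spacing
    star_dropout: float = 0.0  # fraction of hairpins whose star is never emitted
    loop_len: int = 12
    trigger: str = DEFAULT_TRIGGER
    tasi_arf: str = DEFAULT_TASI_ARF
    adapter_dimer_frac: float = 0.02
    low_quality_frac: float = 0.02

    def validate(self) -> None:
        for name in ("de_fraction", "error_rate", "star_dropout", "duplex_len24_weight",
                     "adapter_dimer_frac", "low_quality_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.depth < 1 or self.degradome_depth < 1:
            raise ValueError("library depth must be >= 1")
        if self.de_log2fc < 1.0:
            raise ValueError("de_log2fc below 1 cannot clear the |log2 ratio| > 1 call threshold")
        if len(self.adapter3) < 6:
            raise ValueError("adapter must be at least 6 nt")
        planted_tags = 2 * self.n_mirna + self.n_conserved + 2 * self.duplex_pairs + 3 * self.n_tas3
        if planted_tags > self.depth:
            raise ValueError("config plants more unique tags than the library depth")


@dataclass
class PlantedMiRNA:
    name: str
    mature: str
    star: str
    transcript_id: str
    precursor_span: tuple[int, int]  # 1-based inclusive in the transcript
    mature_span: tuple[int, int]
    arm: str  # "5'" | "3'"
    de_label: str | None  # None | up | down | specific_treatment
    base_weight: float
    star_emitted: bool


@dataclass
class PlantedDuplex:
    tag_a: str
    tag_b: str
    repeat_id: str  # repeat element name
    element_transcripts: tuple[str, ...]


@dataclass
class PlantedTas3:
    transcript_id: str
    site5_span: tuple[int, int]
    site3_span: tuple[int, int]
    spacing_nt: int
    phase_count: int
    cleavage_site: int  # at the 3'-proximal site
    d7: str
    d8: str


@dataclass
class PlantedArf:
    """An ARF-like tasiRNA target gene with one or two recognition sites."""

    gene_id: str
    site_spans: tuple[tuple[int, int], ...]  # 1-based inclusive


@dataclass
class PlantedCleavage:
    mirna_name: str
    mirna_seq: str
    transcript_id: str
    alignment_span: tuple[int, int]
    site: int
    score: float


@dataclass
class GroundTruth:
    """Everything the generator planted, with per-condition expected weights."""

    mirnas: list[PlantedMiRNA] = field(default_factory=list)
    conserved: list[tuple[str, str]] = field(default_factory=list)  # (tag, family)
    duplexes: list[PlantedDuplex] = field(default_factory=list)
    tas3_loci: list[PlantedTas3] = field(default_factory=list)
    cleavages: list[PlantedCleavage] = field(default_factory=list)
    arf_genes: list[PlantedArf] = field(default_factory=list)
    trigger: str = DEFAULT_TRIGGER
    tasi_arf: str = DEFAULT_TASI_ARF
    # expected relative abundance per condition: {condition: {tag: weight}}
    weights: dict[str, dict[str, float]] = field(default_factory=dict)
    transcripts: list[tuple[str, str]] = field(default_factory=list)  # (id, seq) -- regenerable

    def to_json(self, path: str | Path) -> None:
        doc = asdict(self)
        with open(path, "w") as out:
            json.dump(doc, out, indent=1)

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        with open(path) as handle:
            doc = json.load(handle)
        truth = cls(
            mirnas=[PlantedMiRNA(**{**m, "precursor_span": tuple(m["precursor_span"]),
                                    "mature_span": tuple(m["mature_span"])}) for m in doc["mirnas"]],
            conserved=[tuple(c) for c in doc["conserved"]],
            duplexes=[PlantedDuplex(**{**d, "element_transcripts": tuple(d["element_transcripts"])})
                      for d in doc["duplexes"]],
            tas3_loci=[PlantedTas3(**{**t, "site5_span": tuple(t["site5_span"]),
                                      "site3_span": tuple(t["site3_span"])}) for t in doc["tas3_loci"]],
            cleavages=[PlantedCleavage(**{**c, "alignment_span": tuple(c["alignment_span"])})
                       for c in doc["cleavages"]],
            arf_genes=[PlantedArf(a["gene_id"], tuple(tuple(s) for s in a["site_spans"]))
                       for a in doc.get("arf_genes", [])],
            trigger=doc["trigger"],
            tasi_arf=doc["tasi_arf"],
            weights=doc["weights"],
            transcripts=[tuple(t) for t in doc["transcripts"]],
        )
        return truth


def _rng(cfg: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([cfg.seed, stream])


def _random_seq(rng: np.random.Generator, n: int, gc: float = 0.45) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(BASES, size=n, p=p))


def _mutate(rng: np.random.Generator, seq: str, positions: Sequence[int]) -> str:
    out = list(seq)
    for pos in positions:
        choices = [b for b in "ACGT" if b != out[pos]]
        out[pos] = choices[rng.integers(len(choices))]
    return "".join(out)


def _lognormal_weight(rng: np.random.Generator, median: float, sigma: float,
                      lo: float, hi: float) -> float:
    return float(np.clip(rng.lognormal(np.log(median), sigma), lo, hi))


# ---------------------------------------------------------------------------


def simulate_transcriptome(cfg: SimulationConfig) -> tuple[list[SequenceRecord], GroundTruth]:
    """Generate the transcript set and all planted structures.

    Deterministic under a fixed seed: the same config yields byte-identical
    transcripts and ground truth.
    """
    cfg.validate()
    rng = _rng(cfg, 0)
    truth = GroundTruth(trigger=cfg.trigger, tasi_arf=cfg.tasi_arf)
    records: list[SequenceRecord] = []

    # background transcripts
    for i in range(cfg.n_transcripts):
        records.append(SequenceRecord(f"TR{i + 1:04d}", _random_seq(rng, int(rng.integers(400, 1500)))))

    # planted miRNA hairpins, one per host transcript
    n_de = int(round(cfg.de_fraction * cfg.n_mirna))
    de_slots = list(rng.permutation(cfg.n_mirna))
    de_set = set(de_slots[:n_de])
    specific_set = set(de_slots[n_de : n_de + cfg.n_specific])
    for i in range(cfg.n_mirna):
        mature = _random_seq(rng, 21, gc=float(rng.uniform(0.3, 0.6)))
        star_core = revcomp(mature[:19])
        n_mm = int(rng.integers(0, 3))
        if n_mm:
            pos = rng.choice(np.arange(3, 16), size=n_mm, replace=False)
            star_core = _mutate(rng, star_core, [int(p) for p in pos])
        star = star_core + _random_seq(rng, 2)
        loop = _random_seq(rng, cfg.loop_len)
        arm = "5'" if rng.random() < 0.5 else "3'"
        hairpin = mature + loop + star if arm == "5'" else star + loop + mature
        left = _random_seq(rng, int(rng.integers(60, 160)))
        right = _random_seq(rng, int(rng.integers(60, 160)))
        seq = left + hairpin + right
        tid = f"MIRTR{i + 1:03d}"
        records.append(SequenceRecord(tid, seq))
        p0 = len(left) + 1
        m_off = 0 if arm == "5'" else len(star) + len(loop)
        if i in specific_set:
            de_label = "specific_treatment"
        elif i in de_set:
            de_label = "up" if rng.random() < 0.5 else "down"
        else:
            de_label = None
        truth.mirnas.append(
            PlantedMiRNA(
                name=f"planted-miR-{i + 1}",
                mature=mature,
                star=star,
                transcript_id=tid,
                precursor_span=(p0, p0 + len(hairpin) - 1),
                mature_span=(p0 + m_off, p0 + m_off + 20),
                arm=arm,
                de_label=de_label,
                base_weight=_lognormal_weight(rng, 300, 1.0, 60, 30_000),
                star_emitted=bool(rng.random() >= cfg.star_dropout),
            )
        )

    # conserved miRNA tags (no hairpin needed; matched against the reference)
    from .hairpin import load_known_mirnas

    known = load_known_mirnas()
    for i in range(cfg.n_conserved):
        ref = known[int(rng.integers(len(known)))]
        tag = ref.sequence
        n_mm = int(rng.integers(0, 3))
        if n_mm:
            pos = rng.choice(np.arange(len(tag)), size=n_mm, replace=False)
            tag = _mutate(rng, tag, [int(p) for p in pos])
        truth.conserved.append((tag, ref.id))

    # TAS3-like two-hit loci
    site3_seq = revcomp(cfg.trigger)  # perfect-complement 3' site (cleaved)
    for i in range(cfg.n_tas3):
        site5_seq = _mutate(
            rng, site3_seq, [int(p) for p in rng.choice(np.arange(2, 19), size=2, replace=False)]
        )
        phases = int(rng.integers(8, 13))
        jitter = int(rng.integers(-cfg.tas3_jitter, cfg.tas3_jitter + 1)) if cfg.tas3_jitter else 0
        spacing = phases * 21 + jitter
        left = _random_seq(rng, int(rng.integers(60, 120)))
        spacer = _random_seq(rng, spacing)
        right = _random_seq(rng, int(rng.integers(60, 120)))
        seq = left + site5_seq + spacer + site3_seq + right
        tid = f"TASTR{i + 1:02d}"
        s5 = (len(left) + 1, len(left) + 21)
        s3 = (s5[1] + spacing + 1, s5[1] + spacing + 21)
        c = predict_cleavage(s3)
        # overwrite the D7/D8 phase windows with tasiRNA-ARF content
        d7 = cfg.tasi_arf
        d8 = _mutate(rng, cfg.tasi_arf, [1, 19])
        seq = seq[: c - 21 * 7 - 1] + d7 + seq[c - 21 * 6 - 1 :]
        seq = seq[: c - 21 * 8 - 1] + d8 + seq[c - 21 * 7 - 1 :]
        records.append(SequenceRecord(tid, seq))
        truth.tas3_loci.append(
            PlantedTas3(tid, s5, s3, spacing, round(spacing / 21), c, d7, d8)
        )

    # repeat elements in >= 2 transcript copies, shedding duplex pairs
    pair_lengths = _duplex_lengths(rng, cfg)
    pairs_per_repeat = np.array_split(pair_lengths, cfg.n_repeat)
    for i in range(cfg.n_repeat):
        element = _random_seq(rng, int(rng.integers(400, 800)))
        copies = []
        for copy in range(2):
            tid = f"REPTR{i + 1:02d}_{copy + 1}"
            copies.append(tid)
            flank_l = _random_seq(rng, int(rng.integers(30, 120)))
            flank_r = _random_seq(rng, int(rng.integers(30, 120)))
            records.append(SequenceRecord(tid, flank_l + element + flank_r))
        for L in pairs_per_repeat[i]:
            p = int(rng.integers(2, len(element) - int(L)))
            a = element[p : p + int(L)]
            b = revcomp(element[p - 2 : p + int(L) - 2])
            truth.duplexes.append(PlantedDuplex(a, b, f"repeat-{i + 1}", tuple(copies)))

    # miRNA cleavage targets with planted degradome sites
    for i in range(cfg.n_targets):
        mir = truth.mirnas[i % len(truth.mirnas)]
        site = revcomp(mir.mature)
        n_mm = int(rng.integers(0, 3))
        if n_mm:
            pos = rng.choice(np.arange(2, 19), size=n_mm, replace=False)
            site = _mutate(rng, site, [int(p) for p in pos])
        left = _random_seq(rng, int(rng.integers(100, 600)))
        right = _random_seq(rng, int(rng.integers(100, 400)))
        tid = f"TGTR{i + 1:03d}"
        records.append(SequenceRecord(tid, left + site + right))
        span = (len(left) + 1, len(left) + 21)
        truth.cleavages.append(
            PlantedCleavage(
                mir.name, mir.mature, tid, span, predict_cleavage(span),
                score_alignment(mir.mature, site),
            )
        )

    # ARF-like tasiRNA target genes: one or two antisense tasiRNA-ARF sites
    tasi_site = revcomp(cfg.tasi_arf)
    for i in range(cfg.n_arf):
        n_sites = 2 if i % 3 != 2 else 1
        segs = [_random_seq(rng, int(rng.integers(200, 500)))]
        spans = []
        pos = len(segs[0])
        for _ in range(n_sites):
            site = tasi_site
            if rng.random() < 0.5:
                site = _mutate(rng, site, [int(rng.integers(2, 19))])
            segs.append(site)
            spans.append((pos + 1, pos + 21))
            pos += 21
            filler = _random_seq(rng, int(rng.integers(120, 300)))
            segs.append(filler)
            pos += len(filler)
        tid = f"ARFG{i + 1:02d}"
        records.append(SequenceRecord(tid, "".join(segs)))
        truth.arf_genes.append(PlantedArf(tid, tuple(spans)))

    truth.transcripts = [(r.id, r.sequence) for r in records]
    _assign_weights(cfg, rng, truth)
    return records, truth


def _duplex_lengths(rng: np.random.Generator, cfg: SimulationConfig) -> np.ndarray:
    w24 = cfg.duplex_len24_weight
    other = (1 - w24) / 3
    return rng.choice([21, 22, 23, 24], size=cfg.duplex_pairs, p=[other, other, other, w24])


def _assign_weights(cfg: SimulationConfig, rng: np.random.Generator, truth: GroundTruth) -> None:
    """Per-condition expected relative abundances for every emitted tag."""
    weights: dict[str, dict[str, float]] = {c: {} for c in CONDITIONS}

    def put(tag: str, per_cond: dict[str, float]) -> None:
        for cond in CONDITIONS:
            w = per_cond.get(cond, 0.0)
            if w > 0:
                weights[cond][tag] = weights[cond].get(tag, 0.0) + w

    fc = 2.0 ** cfg.de_log2fc
    for mir in truth.mirnas:
        w = mir.base_weight
        if mir.de_label == "up":
            per = {"CK": w, "T4h": w * fc, "T5d": w * fc}
        elif mir.de_label == "down":
            per = {"CK": w, "T4h": w / fc, "T5d": w / fc}
        elif mir.de_label == "specific_treatment":
            per = {"CK": 0.0, "T4h": w, "T5d": w * 0.5}
        else:
            per = {c: w for c in CONDITIONS}
        put(mir.mature, per)
        if mir.star_emitted:
            sw = max(25.0, 0.08 * w)
            put(mir.star, {c: sw * per[c] / w for c in CONDITIONS})
    for tag, _family in truth.conserved:
        w = _lognormal_weight(rng, 400, 1.0, 80, 50_000)
        put(tag, {c: w for c in CONDITIONS})
    for dup in truth.duplexes:
        for strand in (dup.tag_a, dup.tag_b):
            w = _lognormal_weight(rng, 40, 0.7, 8, 2_000)
            put(strand, {c: w for c in CONDITIONS})
    # tasiRNAs decline with stress duration; the trigger declines faster
    for locus in truth.tas3_loci:
        w7 = _lognormal_weight(rng, 500, 0.4, 200, 5_000)
        w8 = _lognormal_weight(rng, 60, 0.4, 25, 500)
        put(locus.d7, {"CK": w7, "T4h": 0.8 * w7, "T5d": 0.5 * w7})
        put(locus.d8, {"CK": w8, "T4h": 0.8 * w8, "T5d": 0.5 * w8})
    put(truth.trigger, {"CK": 300.0, "T4h": 180.0, "T5d": 90.0})

    # background: random tags with a 21/24-nt length mixture, log-skewed
    lmw = cfg.length_mode_weights
    other_lens = [l for l in range(15, 31) if l not in (21, 24)]
    for _ in range(cfg.n_background_tags):
        u = rng.random()
        if u < lmw[21]:
            L = 21
        elif u < lmw[21] + lmw[24]:
            L = 24
        else:
            L = int(other_lens[rng.integers(len(other_lens))])
        tag = _random_seq(rng, L)
        put(tag, {c: _lognormal_weight(rng, 2, 1.0, 0.2, 500) for c in CONDITIONS})
    # transcript-derived fragments (map to transcripts, exercise specificity);
    # drawn from background transcripts only, so they never sit on a planted tag
    seqs = truth.transcripts[: cfg.n_transcripts]
    for _ in range(cfg.n_fragment_tags):
        tid, seq = seqs[int(rng.integers(len(seqs)))]
        if len(seq) < 60:
            continue
        p = int(rng.integers(0, len(seq) - 21))
        put(seq[p : p + 21], {c: _lognormal_weight(rng, 3, 1.0, 0.2, 300) for c in CONDITIONS})

    truth.weights = weights


# ---------------------------------------------------------------------------


def _apply_sequencing_error(
    rng: np.random.Generator, counts: dict[str, int], error_rate: float
) -> dict[str, int]:
    """Substitution-only error: each erroneous read carries one random change."""
    if error_rate <= 0:
        return counts
    out: dict[str, int] = {}
    for tag, c in counts.items():
        p_err = 1.0 - (1.0 - error_rate) ** len(tag)
        k = int(rng.binomial(c, p_err))
        if c - k > 0:
            out[tag] = out.get(tag, 0) + (c - k)
        for _ in range(k):
            variant = _mutate(rng, tag, [int(rng.integers(len(tag)))])
            out[variant] = out.get(variant, 0) + 1
    return out


def simulate_small_rna_libraries(
    truth: GroundTruth, cfg: SimulationConfig
) -> list[TagLibrary]:
    """Sample the three condition libraries from the planted weights.

    Counts are multinomial over tag weights, so each library's total equals
    ``cfg.depth`` exactly; sequencing error then redistributes single-read
    substitutions without changing the total.
    """
    if cfg.depth < 1:
        raise ValueError("depth must be >= 1")
    libs = []
    for idx, cond in enumerate(CONDITIONS):
        rng = _rng(cfg, 1 + idx)
        tags = sorted(truth.weights[cond])
        w = np.array([truth.weights[cond][t] for t in tags], dtype=float)
        counts = rng.multinomial(cfg.depth, w / w.sum())
        raw = {t: int(c) for t, c in zip(tags, counts) if c > 0}
        raw = _apply_sequencing_error(rng, raw, cfg.error_rate)
        libs.append(TagLibrary(cond, raw, cfg.depth))
    return libs


def simulate_degradome(truth: GroundTruth, cfg: SimulationConfig) -> dict[str, TagLibrary]:
    """Degradome tag libraries: 20-21 nt fragments piling up at planted sites.

    For each planted cleavage event (miRNA targets and the cleaved
    3'-proximal TAS3 sites) the tags starting exactly at the site carry ~85%
    of that transcript's degradome weight; the rest is low-level background
    at random positions, plus diffuse background on unrelated transcripts.
    """
    seq_by_id = dict(truth.transcripts)
    planted: list[tuple[str, int]] = [(c.transcript_id, c.site) for c in truth.cleavages]
    planted += [(t.transcript_id, t.cleavage_site) for t in truth.tas3_loci]

    out: dict[str, TagLibrary] = {}
    for idx, cond in enumerate(CONDITIONS):
        rng = _rng(cfg, 10 + idx)
        weights: dict[str, float] = {}
        for tid, site in planted:
            seq = seq_by_id[tid]
            site_w = _lognormal_weight(rng, 120, 0.5, 40, 2_000)
            for L, frac in ((20, 0.5), (21, 0.5)):
                frag = seq[site - 1 : site - 1 + L]
                if len(frag) == L:
                    weights[frag] = weights.get(frag, 0.0) + site_w * frac
            # low-level background degradation on the same transcript
            for _ in range(5):
                p = int(rng.integers(1, max(2, len(seq) - 21)))
                frag = seq[p - 1 : p - 1 + 20]
                if len(frag) == 20 and p != site:
                    weights[frag] = weights.get(frag, 0.0) + 0.03 * site_w
        # diffuse background on random transcripts
        for _ in range(400):
            tid, seq = truth.transcripts[int(rng.integers(len(truth.transcripts)))]
            if len(seq) < 60:
                continue
            p = int(rng.integers(0, len(seq) - 21))
            frag = seq[p : p + 20]
            weights[frag] = weights.get(frag, 0.0) + 1.0
        tags = sorted(weights)
        w = np.array([weights[t] for t in tags], dtype=float)
        counts = rng.multinomial(cfg.degradome_depth, w / w.sum())
        lib = {t: int(c) for t, c in zip(tags, counts) if c > 0}
        out[cond] = TagLibrary(cond, lib, cfg.degradome_depth)
    return out


def reads_from_library(
    lib: TagLibrary, cfg: SimulationConfig, read_length: int = 49
) -> list[SequenceRecord]:
    """Expand a tag library into adapter-carrying raw reads (FASTQ model).

    Each read is the tag plus the 3' adapter, padded/truncated to
    ``read_length``.  A small fraction of reads are replaced by
    adapter-dimers or low-quality reads so the preprocessing cascade has
    realistic rejections; the fractions are configured, hence the expected
    clean-read rate is known.
    """
    stream = {c: i for i, c in enumerate(CONDITIONS)}.get(lib.library_id, 7)
    rng = _rng(cfg, 20 + stream)
    reads: list[SequenceRecord] = []
    i = 0
    hi_q = tuple([40] * read_length)
    for tag, count in sorted(lib.tags.items(), key=lambda kv: (-kv[1], kv[0])):
        for _ in range(count):
            i += 1
            u = rng.random()
            if u < cfg.adapter_dimer_frac:
                seq = (cfg.adapter3 + "A" * read_length)[:read_length]
                reads.append(SequenceRecord(f"{lib.library_id}_r{i}", seq, hi_q))
            elif u < cfg.adapter_dimer_frac + cfg.low_quality_frac:
                seq = (tag + cfg.adapter3 + "A" * read_length)[:read_length]
                low_q = tuple([2] * read_length)
                reads.append(SequenceRecord(f"{lib.library_id}_r{i}", seq, low_q))
            else:
                seq = (tag + cfg.adapter3 + "A" * read_length)[:read_length]
                reads.append(SequenceRecord(f"{lib.library_id}_r{i}", seq, hi_q))
    return reads


def write_fastq(reads: Sequence[SequenceRecord], path: str | Path) -> None:
    with open(path, "w") as out:
        for rec in reads:
            qual = "".join(chr(q + 33) for q in (rec.quality or [40] * len(rec)))
            out.write(f"@{rec.id}\n{rec.sequence}\n+\n{qual}\n")
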