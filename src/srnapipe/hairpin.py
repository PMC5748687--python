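"""Conserved and novel miRNA identification from collapsed tag libraries.

Novel miRNAs are called transcript-wise: an unannotated tag that maps
perfectly to a transcript nominates candidate precursor windows around it;
each window is folded to its minimum-free-energy secondary structure and the
mature/miRNA* duplex is evaluated against the classic plant criteria --
fewer than six mature positions unpaired in the duplex, the mature kept off
the terminal loop, a 2-nt 3' overhang geometry, and the star strand actually
observed in the sequencing data.  Passing precursors are summarised by the
standard hairpin statistics: mature length (LM), precursor length (LP), arm,
G+C%, folding energy dG, AMFE = 100*|dG|/LP and MFEI = AMFE / GC%.

Conserved miRNAs are matched against a bundled miniature reference of plant
mature miRNAs, allowing up to two substitutions and up to 2 nt of terminal
length variation.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .io import SequenceRecord, TagLibrary, revcomp

__all__ = [
    "FoldResult",
    "HairpinEvaluation",
    "MiRNARecord",
    "gc_percent",
    "compute_amfe",
    "compute_mfei",
    "round2",
    "fold_hairpin",
    "evaluate_duplex",
    "match_conserved",
    "call_novel_mirnas",
    "load_novel_mirna_table",
    "load_known_mirnas",
    "INCONSISTENT_MFEI_ROWS",
]

# Rows of the bundled cotton novel-miRNA table whose printed MFEI cannot be
# reproduced from their own printed dG/LP/GC values (recomputation gives 0.57
# and 0.58 against a printed 0.65).  They are flagged, never silently fixed.
INCONSISTENT_MFEI_ROWS = frozenset({"miR1348", "miR1356"})

MIN_PRECURSOR = 50
MAX_PRECURSOR = 400
EXCISION_OFFSETS = (20, 60, 100, 150)


def round2(x: float) -> float:
    """Round half-up to 2 decimal places (table presentation convention)."""
    return float(Decimal(repr(float(x))).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def gc_percent(seq: str) -> float:
    """G+C content of a sequence as a percentage."""
    if not seq:
        raise ValueError("gc_percent of an empty sequence")
    return 100.0 * (seq.count("G") + seq.count("C")) / len(seq)


def compute_amfe(delta_g: float, length: int) -> float:
    """Adjusted MFE: folding energy per 100 nt, reported positive (kcal/mol)."""
    if length <= 0:
        raise ValueError("length must be positive")
    if delta_g > 0:
        raise ValueError("delta_g must be <= 0 (minimum free energy)")
    return (-delta_g / length) * 100.0


def compute_mfei(delta_g: float, length: int, gc: float) -> float:
    """Minimal folding free energy index: AMFE divided by G+C percentage.

    High MFEI separates miRNA precursors from tRNA/rRNA/mRNA folds.
    """
    if gc <= 0:
        raise ValueError("MFEI undefined for GC <= 0")
    return compute_amfe(delta_g, length) / gc


# ---------------------------------------------------------------------------
# folding backends


@dataclass(frozen=True)
class FoldResult:
    """Secondary structure in dot-bracket notation with its energy."""

    structure: str
    delta_g: float  # kcal/mol, <= 0
    backend: str = "vienna"

    def __post_init__(self) -> None:
        if self.structure.count("(") != self.structure.count(")"):
            raise ValueError("unbalanced dot-bracket structure")

    def pair_table(self) -> list[int]:
        """1-based pair table: pt[i] = j if i pairs j, 0 if unpaired."""
        n = len(self.structure)
        pt = [0] * (n + 1)
        stack: list[int] = []
        for i, c in enumerate(self.structure, start=1):
            if c == "(":
                stack.append(i)
            elif c == ")":
                j = stack.pop()
                pt[i], pt[j] = j, i
        return pt


def _fold_vienna(seq: str) -> FoldResult:
    import RNA

    structure, mfe = RNA.fold(seq.replace("T", "U"))
    return FoldResult(structure, float(mfe), "vienna")


def _fold_nussinov(seq: str) -> FoldResult:
    """Base-pair maximisation with a simplified stacking-free energy model.

    Pairs are weighted GC=3, AT=2, GT=1 (a Nussinov recursion on pair
    weights); the reported energy is -1.0 kcal/mol per weight unit.  This is
    a deliberately simple, dependency-free fold used only when a
    thermodynamic folder is not requested.
    """
    weight = {("A", "T"): 2, ("T", "A"): 2, ("G", "C"): 3, ("C", "G"): 3,
              ("G", "T"): 1, ("T", "G"): 1}
    n = len(seq)
    minloop = 3
    dp = [[0] * n for _ in range(n)]
    for span in range(minloop + 1, n):
        for i in range(n - span):
            j = i + span
            best = dp[i][j - 1]
            for k in range(i, j - minloop):
                w = weight.get((seq[k], seq[j]))
                if w is None:
                    continue
                left = dp[i][k - 1] if k > i else 0
                inner = dp[k + 1][j - 1] if k + 1 <= j - 1 else 0
                cand = left + inner + w
                if cand > best:
                    best = cand
            dp[i][j] = best
    # traceback
    struct = ["."] * n

    def trace(i: int, j: int) -> None:
        while i < j:
            if dp[i][j] == (dp[i][j - 1] if j - 1 >= i else 0):
                j -= 1
                continue
            for k in range(i, j - minloop):
                w = weight.get((seq[k], seq[j]))
                if w is None:
                    continue
                left = dp[i][k - 1] if k > i else 0
                inner = dp[k + 1][j - 1] if k + 1 <= j - 1 else 0
                if dp[i][j] == left + inner + w:
                    struct[k], struct[j] = "(", ")"
                    if k > i:
                        trace(i, k - 1)
                    i, j = k + 1, j - 1
                    break
            else:  # pragma: no cover - defensive
                break

    trace(0, n - 1)
    return FoldResult("".join(struct), -1.0 * dp[0][n - 1], "nussinov")


_BACKENDS = {"vienna": _fold_vienna, "nussinov": _fold_nussinov}


def fold_hairpin(seq: str, backend: str = "vienna") -> FoldResult:
    """Fold one candidate precursor (50-400 nt) to its MFE structure."""
    if not (MIN_PRECURSOR <= len(seq) <= MAX_PRECURSOR):
        raise ValueError(f"precursor length {len(seq)} outside [{MIN_PRECURSOR}, {MAX_PRECURSOR}]")
    if seq.count("N") / len(seq) > 0.10:
        raise ValueError("sequence rejected: >10% N")
    return _BACKENDS[backend](seq)


# ---------------------------------------------------------------------------
# duplex evaluation


@dataclass
class HairpinEvaluation:
    """Duplex checks and hairpin statistics for one candidate precursor."""

    precursor: str
    structure: str
    delta_g: float
    mature_span: tuple[int, int]  # 1-based inclusive
    star_span: tuple[int, int] | None
    star_sequence: str | None
    arm: str | None  # "5'" or "3'"
    duplex_mismatches: int | None
    in_terminal_loop: bool
    overhang_ok: bool
    star_in_tags: bool
    passed: bool
    reason: str | None

    @property
    def lm(self) -> int:
        return self.mature_span[1] - self.mature_span[0] + 1

    @property
    def lp(self) -> int:
        return len(self.precursor)

    @property
    def gc_percent(self) -> float:
        return gc_percent(self.precursor)

    @property
    def amfe(self) -> float:
        return compute_amfe(self.delta_g, self.lp)

    @property
    def mfei(self) -> float:
        return compute_mfei(self.delta_g, self.lp, self.gc_percent)

    @property
    def mature(self) -> str:
        return self.precursor[self.mature_span[0] - 1 : self.mature_span[1]]


def _hairpin_loops(structure: str) -> list[tuple[int, int]]:
    """1-based inclusive spans of hairpin loops (dot runs closed by a pair)."""
    loops = []
    n = len(structure)
    i = 0
    while i < n:
        if structure[i] == ".":
            j = i
            while j < n and structure[j] == ".":
                j += 1
            if i > 0 and j < n and structure[i - 1] == "(" and structure[j] == ")":
                loops.append((i + 1, j))
            i = j
        else:
            i += 1
    return loops


def _fail(ev_kwargs: dict, reason: str) -> HairpinEvaluation:
    return HairpinEvaluation(passed=False, reason=reason, **ev_kwargs)


def _star_evidence(
    precursor: str,
    nominal: tuple[int, int],
    tag_index,
    max_shift: int = 3,
    max_len_diff: int = 2,
) -> tuple[tuple[int, int], str] | None:
    """Find a sequenced tag consistent with the star arm.

    MFE folds may absorb a duplex mismatch as a 1-nt bulge, shifting the
    apparent star register; evidence therefore admits tags starting within
    ``max_shift`` nt of the nominal star span with up to ``max_len_diff`` nt
    length difference, preferring the smallest shift then length difference.
    """
    s0, e0 = nominal
    L0 = e0 - s0 + 1
    best = None
    for shift in range(-max_shift, max_shift + 1):
        for dl in range(-max_len_diff, max_len_diff + 1):
            s = s0 + shift
            e = s + L0 + dl - 1
            if s < 1 or e > len(precursor):
                continue
            cand = precursor[s - 1 : e]
            if cand in tag_index:
                key = (abs(shift), abs(dl))
                if best is None or key < best[0]:
                    best = (key, (s, e), cand)
    if best is None:
        return None
    return best[1], best[2]


def evaluate_duplex(
    precursor: str,
    fold: FoldResult,
    mature_span: tuple[int, int],
    tag_index: TagLibrary | Mapping[str, int] | set[str] | None = None,
    max_duplex_mismatches: int = 6,
) -> HairpinEvaluation:
    """Evaluate the mature/miRNA* duplex implied by a fold.

    The duplex region is the mature minus its own 2-nt 3' overhang.
    ``duplex_mismatches`` counts duplex-region positions left unpaired in the
    fold (bulges count one each; G:U wobbles are paired by the fold and
    therefore not mismatches).  The star span is the region pairing with the
    duplex region -- extrapolated through frayed helix ends so terminal
    breathing does not shift it -- plus the canonical 2-nt 3' offset on the
    star strand.  A pass requires strictly fewer than
    ``max_duplex_mismatches`` mismatches, a mature span disjoint from the
    terminal loop, the overhang geometry to fit inside the precursor, and --
    when a tag index is supplied -- the star sequence to be present in the
    sequencing data (miRNA* evidence).
    """
    m1, m2 = mature_span
    if not (1 <= m1 <= m2 <= len(precursor)):
        raise ValueError("mature span outside precursor")
    base = dict(
        precursor=precursor,
        structure=fold.structure,
        delta_g=fold.delta_g,
        mature_span=mature_span,
        star_span=None,
        star_sequence=None,
        arm=None,
        duplex_mismatches=None,
        in_terminal_loop=False,
        overhang_ok=False,
        star_in_tags=False,
    )
    pt = fold.pair_table()
    d2 = m2 - 2  # duplex region [m1, d2]: mature 3' overhang excluded
    paired = [i for i in range(m1, d2 + 1) if pt[i] != 0 and not (m1 <= pt[i] <= m2)]
    if not paired:
        return _fail(base, "mature entirely unpaired")
    # keep only the dominant duplex register: in an antiparallel duplex
    # i + pt[i] is (nearly) constant; pairs far off register -- e.g. mature
    # bases captured by a spurious loop hairpin -- are structural mismatches
    regs = sorted(i + pt[i] for i in paired)
    med = regs[len(regs) // 2]
    paired = [i for i in paired if abs(i + pt[i] - med) <= 2]
    if not paired:
        return _fail(base, "mature entirely unpaired")
    mismatches = (d2 - m1 + 1) - len(paired)
    base["duplex_mismatches"] = mismatches

    first_p, last_p = paired[0], paired[-1]
    arm = "5'" if pt[first_p] > first_p else "3'"
    base["arm"] = arm

    # terminal loop of the helix the mature sits on: the single hairpin loop
    # enclosed by the mature's innermost pair
    inner = last_p if arm == "5'" else first_p
    lo, hi = sorted((inner, pt[inner]))
    loops_inside = [lp for lp in _hairpin_loops(fold.structure) if lo < lp[0] and lp[1] <= hi]
    if not loops_inside:
        return _fail(base, "no terminal loop (not a hairpin)")
    if len(loops_inside) > 1:
        return _fail(base, "branched structure between mature and star")
    loop = loops_inside[0]
    # the duplex region must stay off the loop; the mature's own 2-nt 3'
    # overhang canonically abuts it and is not counted as loop residency
    overlaps_loop = not (d2 < loop[0] or m1 > loop[1])
    base["in_terminal_loop"] = overlaps_loop

    # star span from the dominant register (star position = med - i for a
    # mature position i), extrapolated through frayed/bulged ends; the
    # star's 3' end -- which pairs the mature's 5' end on either arm --
    # gets the 2-nt offset
    star_start = med - d2
    star_end = med - m1 + 2
    overhang_ok = 1 <= star_start < star_end <= len(precursor)
    base["overhang_ok"] = overhang_ok
    if overhang_ok:
        base["star_span"] = (star_start, star_end)
        base["star_sequence"] = precursor[star_start - 1 : star_end]
        if tag_index is not None:
            hit = _star_evidence(precursor, (star_start, star_end), tag_index)
            if hit is not None:
                base["star_span"], base["star_sequence"] = hit

    if overlaps_loop:
        return _fail(base, "mature overlaps terminal loop")
    if mismatches >= max_duplex_mismatches:
        return _fail(base, f"{mismatches} duplex mismatches (>= {max_duplex_mismatches})")
    if not overhang_ok:
        return _fail(base, "star 3' overhang outside precursor")

    star_seq = base["star_sequence"]
    if tag_index is not None:
        present = star_seq in tag_index
        base["star_in_tags"] = present
        if not present:
            return _fail(base, "no miRNA* evidence")
    return HairpinEvaluation(passed=True, reason=None, **base)


# ---------------------------------------------------------------------------
# conserved matching


def _end_to_end_mismatches(tag: str, ref: str, max_len_diff: int = 2) -> int | None:
    """Minimum substitution count aligning tag to ref end-to-end.

    Length differences up to ``max_len_diff`` are absorbed at the termini
    (the shorter sequence may start/end inside the longer one); overhanging
    bases are the length-variant allowance, not mismatches.
    """
    short, long_ = (tag, ref) if len(tag) <= len(ref) else (ref, tag)
    diff = len(long_) - len(short)
    if diff > max_len_diff:
        return None
    best = None
    for off in range(diff + 1):
        mm = sum(1 for a, b in zip(short, long_[off : off + len(short)]) if a != b)
        if best is None or mm < best:
            best = mm
    return best


def match_conserved(
    tag: str,
    reference: Sequence[SequenceRecord],
    max_mismatches: int = 2,
) -> tuple[str, int] | None:
    """Match a tag against known mature miRNAs.

    Returns ``(family, mismatches)`` for the best (fewest-mismatch) match with
    at most ``max_mismatches`` substitutions and <= 2 nt terminal length
    difference; ties break lexicographically by family name.
    """
    if not reference:
        raise ValueError("empty known-miRNA reference")
    best: tuple[int, str] | None = None
    for rec in reference:
        mm = _end_to_end_mismatches(tag, rec.sequence)
        if mm is None or mm > max_mismatches:
            continue
        key = (mm, rec.id)
        if best is None or key < best:
            best = key
    if best is None:
        return None
    return best[1], best[0]


# ---------------------------------------------------------------------------
# novel miRNA calling


@dataclass
class MiRNARecord:
    """One identified miRNA (conserved or novel)."""

    name: str
    mature: str
    source_id: str  # transcript (novel) or family (conserved)
    status: str  # "conserved" | "novel"
    star: str | None = None
    family: str | None = None
    evaluation: HairpinEvaluation | None = None
    counts: dict[str, int] | None = None  # per library


def _has_star_candidate(window: str, core_rc: str, max_mm: int = 5, seed_len: int = 6) -> bool:
    """Cheap pre-fold screen: does the window hold a plausible star region?

    Looks for any placement of the reverse-complemented mature core with at
    most ``max_mm`` substitutions, located via exact ``seed_len``-mers (a
    19-nt core with <= 2 substitutions always retains an exact 6-mer run).
    Windows failing the screen cannot yield a passing duplex and are not
    folded.
    """
    n, k = len(window), len(core_rc)
    tried: set[int] = set()
    for s in range(0, k - seed_len + 1):
        seed = core_rc[s : s + seed_len]
        p = window.find(seed)
        while p != -1:
            start = p - s
            if 0 <= start <= n - k and start not in tried:
                tried.add(start)
                mm = sum(1 for a, b in zip(core_rc, window[start : start + k]) if a != b)
                if mm <= max_mm:
                    return True
            p = window.find(seed, p + 1)
    return False


def _tag_positions(tag: str, transcripts: Sequence[SequenceRecord]) -> list[tuple[str, int, str]]:
    """All perfect sense matches of tag in transcripts: (id, 0-based pos, seq)."""
    hits = []
    for rec in transcripts:
        start = rec.sequence.find(tag)
        while start != -1:
            hits.append((rec.id, start, rec.sequence))
            start = rec.sequence.find(tag, start + 1)
    return hits


def call_novel_mirnas(
    tag_libraries: Sequence[TagLibrary],
    transcripts: Sequence[SequenceRecord],
    *,
    min_count: int = 2,
    backend: str = "vienna",
    offsets: Sequence[int] = EXCISION_OFFSETS,
    max_candidates_per_tag: int = 2,
) -> list[MiRNARecord]:
    """Call novel miRNAs from tags that map perfectly onto transcripts.

    For each candidate tag, precursor windows ``[pos-L, tag_end+R]`` for
    L, R in ``offsets`` are tried smallest-first; a window is folded only if
    it passes a cheap star-region screen, and the first passing window (the
    tightest precursor call) is kept.  Candidate loci sharing a transcript
    region keep only the most abundant mature (this collapses the star
    strand, which would otherwise nominate the same hairpin).  Records are
    named novel-miR-1, novel-miR-2, ... in transcript order and returned
    sorted by name.
    """
    union: dict[str, int] = {}
    for lib in tag_libraries:
        for tag, cnt in lib.tags.items():
            union[tag] = union.get(tag, 0) + cnt
    tag_index = set(union)

    window_order = sorted(
        ((l, r) for l in offsets for r in offsets), key=lambda lr: (lr[0] + lr[1], lr)
    )
    candidates = [t for t, c in union.items() if c >= min_count and 18 <= len(t) <= 25]
    passing: list[tuple[str, int, int, str, HairpinEvaluation, int]] = []
    for tag in candidates:
        hits = _tag_positions(tag, transcripts)[:max_candidates_per_tag]
        core_rc = revcomp(tag[: len(tag) - 2])
        best: tuple[float, str, int, HairpinEvaluation] | None = None
        for tid, pos, tseq in hits:
            seen_windows: set[tuple[int, int]] = set()
            for left, right in window_order:
                w1 = max(0, pos - left)
                w2 = min(len(tseq), pos + len(tag) + right)
                if (w1, w2) in seen_windows:
                    continue
                seen_windows.add((w1, w2))
                window = tseq[w1:w2]
                if not (MIN_PRECURSOR <= len(window) <= MAX_PRECURSOR):
                    continue
                if window.count("N") / len(window) > 0.10:
                    continue
                if not _has_star_candidate(window, core_rc):
                    continue
                fold = fold_hairpin(window, backend=backend)
                span = (pos - w1 + 1, pos - w1 + len(tag))
                ev = evaluate_duplex(window, fold, span, tag_index)
                if ev.passed:
                    if best is None or fold.delta_g < best[0]:
                        best = (fold.delta_g, tid, w1, ev)
                    break  # first (tightest) passing window for this hit
        if best is not None:
            _, tid, w1, ev = best
            passing.append((tag, union[tag], w1, tid, ev, w1 + len(ev.precursor)))

    # collapse overlapping loci on the same transcript: keep the most abundant
    passing.sort(key=lambda p: (-p[1], p[0]))
    kept: list[tuple[str, int, int, str, HairpinEvaluation, int]] = []
    for cand in passing:
        tag, cnt, w1, tid, ev, w2 = cand
        clash = any(k[3] == tid and not (w2 <= k[2] or w1 >= k[5]) for k in kept)
        if not clash:
            kept.append(cand)

    kept.sort(key=lambda p: (p[3], p[2]))
    records = []
    for i, (tag, cnt, w1, tid, ev, _) in enumerate(kept, start=1):
        counts = {lib.library_id: lib.count(tag) for lib in tag_libraries}
        records.append(
            MiRNARecord(
                name=f"novel-miR-{i}",
                mature=tag,
                source_id=tid,
                status="novel",
                star=ev.star_sequence,
                evaluation=ev,
                counts=counts,
            )
        )
    return records


def novel_mirna_table(records: Sequence[MiRNARecord]) -> pd.DataFrame:
    """Summary frame with the canonical hairpin-statistics columns."""
    rows = []
    for rec in records:
        ev = rec.evaluation
        rows.append(
            {
                "name": rec.name,
                "mature": rec.mature,
                "gene_id": rec.source_id,
                "lm": ev.lm,
                "arm": ev.arm,
                "lp": ev.lp,
                "gc_percent": round2(ev.gc_percent),
                "star": rec.star,
                "delta_g": ev.delta_g,
                "amfe": round2(ev.amfe),
                "mfei": round2(ev.mfei),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["name", "mature", "gene_id", "lm", "arm", "lp", "gc_percent",
                 "star", "delta_g", "amfe", "mfei"],
    )


# ---------------------------------------------------------------------------
# bundled reference data


def _data_path(name: str):
    return importlib.resources.files("srnapipe.data").joinpath(name)


def load_novel_mirna_table() -> pd.DataFrame:
    """The bundled table of 24 novel cotton miRNAs with precursor statistics.

    Columns: name, mature, gene_id, lm, arm, lp, gc_percent, star, delta_g,
    mfei -- the published presentation of the salt-stress novel miRNA set.
    ``mfei_recomputed`` and ``mfei_consistent`` are added on load; the two
    rows whose printed MFEI disagrees with their own printed inputs
    (:data:`INCONSISTENT_MFEI_ROWS`) are flagged, not corrected.
    """
    with importlib.resources.as_file(_data_path("cotton_novel_mirnas.tsv")) as p:
        df = pd.read_csv(p, sep="\t")
    df["mfei_recomputed"] = [
        round2(compute_mfei(dg, lp, gc))
        for dg, lp, gc in zip(df["delta_g"], df["lp"], df["gc_percent"])
    ]
    df["mfei_consistent"] = df["mfei_recomputed"] == df["mfei"]
    return df


def load_known_mirnas() -> list[SequenceRecord]:
    """Bundled miniature reference of conserved plant mature miRNAs."""
    from .io import read_fasta

    with importlib.resources.as_file(_data_path("plant_mature_mirnas.fasta")) as p:
        return read_fasta(p)
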