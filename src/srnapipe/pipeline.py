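"""End-to-end orchestration of the analysis stages.

Stages run in dependency order -- simulate (optional), preprocess, miRNA
identification, differential expression, siRNA duplexes, degradome target
calling, tasiRNA phasing -- writing deterministic TSV outputs, a combined
markdown report and a JSON run manifest with content digests.  Identical
configuration and seed give byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import sys
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .degradome import build_profile, call_targets, tplot_data
from .diffexpr import de_table
from .hairpin import call_novel_mirnas, load_known_mirnas, match_conserved, novel_mirna_table
from .io import SequenceRecord, TagLibrary, read_tag_table, write_fasta, write_tag_table
from .simulate import (
    CONDITIONS,
    GroundTruth,
    SimulationConfig,
    reads_from_library,
    simulate_degradome,
    simulate_small_rna_libraries,
    simulate_transcriptome,
    write_fastq,
)
from .sirna import duplex_length_distribution, find_duplex_pairs, map_duplexes_to_elements
from .tasirna import detect_two_hit_locus, extract_phases, find_trigger_sites, predict_tasi_targets

STAGES = ("simulate", "preprocess", "mirna", "de", "sirna", "degradome", "tasi", "report")


@dataclass
class PipelineConfig:
    """Paths, thresholds and stage toggles for one run."""

    out_dir: Path
    seed: int = 0
    alpha: float = 0.01
    min_log2: float = 1.0
    max_score: float = 4.5
    tasi_max_mismatch: float = 2.0
    stages: tuple[str, ...] = STAGES
    simulation: SimulationConfig | None = None
    write_reads: bool = False  # expand simulated tags to FASTQ as well

    def __post_init__(self) -> None:
        self.out_dir = Path(self.out_dir)
        if self.alpha <= 0 or self.min_log2 < 0 or self.max_score < 0:
            raise ValueError("thresholds must be positive")
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")


@dataclass
class PipelineState:
    """In-memory hand-off between stages."""

    transcripts: list[SequenceRecord] = field(default_factory=list)
    truth: GroundTruth | None = None
    libraries: list[TagLibrary] = field(default_factory=list)
    degradome_libs: dict[str, TagLibrary] = field(default_factory=dict)
    novel: list = field(default_factory=list)
    de_tables: dict[str, pd.DataFrame] = field(default_factory=dict)
    outputs: list[Path] = field(default_factory=list)
    counts: dict[str, int] = field(default_factory=dict)


def _log(stage: str, msg: str) -> None:
    print(f"[{stage}] {msg}", file=sys.stderr)


def _write_tsv(df: pd.DataFrame, path: Path, state: PipelineState) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")
    state.outputs.append(path)


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the configured stages; returns the run manifest."""
    out = cfg.out_dir
    out.mkdir(parents=True, exist_ok=True)
    state = PipelineState()
    sim = cfg.simulation or SimulationConfig(seed=cfg.seed)

    for stage in STAGES:
        if stage not in cfg.stages:
            continue
        try:
            _STAGE_FNS[stage](cfg, sim, state, out)
        except Exception as exc:
            _log(stage, f"FAILED: {exc}")
            raise PipelineError(stage, str(exc)) from exc

    manifest = {
        "version": __version__,
        "seed": cfg.seed,
        "thresholds": {
            "alpha": cfg.alpha,
            "min_log2": cfg.min_log2,
            "max_score": cfg.max_score,
            "tasi_max_mismatch": cfg.tasi_max_mismatch,
        },
        "stages": [s for s in STAGES if s in cfg.stages],
        "record_counts": state.counts,
        "outputs": {
            str(p.relative_to(out)): hashlib.sha256(p.read_bytes()).hexdigest()
            for p in state.outputs
        },
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


# ---------------------------------------------------------------------------
# stages


def _stage_simulate(cfg, sim, state, out: Path) -> None:
    recs, truth = simulate_transcriptome(sim)
    state.transcripts, state.truth = recs, truth
    state.libraries = simulate_small_rna_libraries(truth, sim)
    state.degradome_libs = simulate_degradome(truth, sim)
    write_fasta(recs, out / "transcripts.fasta")
    state.outputs.append(out / "transcripts.fasta")
    truth.to_json(out / "truth.json")
    state.outputs.append(out / "truth.json")
    for lib in state.libraries:
        write_tag_table(lib, out / f"tags_{lib.library_id}.tsv")
        state.outputs.append(out / f"tags_{lib.library_id}.tsv")
        if cfg.write_reads:
            write_fastq(reads_from_library(lib, sim), out / f"reads_{lib.library_id}.fastq")
    for cond, lib in state.degradome_libs.items():
        write_tag_table(lib, out / f"degradome_{cond}.tsv")
        state.outputs.append(out / f"degradome_{cond}.tsv")
    state.counts["transcripts"] = len(recs)
    state.counts["planted_mirnas"] = len(truth.mirnas)
    _log("simulate", f"{len(recs)} transcripts, {len(state.libraries)} libraries")


def _stage_preprocess(cfg, sim, state, out: Path) -> None:
    # when simulation ran in-process the libraries are already clean tags;
    # otherwise load collapsed tag tables from the output directory
    if not state.libraries:
        paths = sorted(out.glob("tags_*.tsv"))
        if not paths:
            raise FileNotFoundError("no tag libraries found (run simulate or provide tags_*.tsv)")
        state.libraries = [read_tag_table(p) for p in paths]
    rows = [
        {
            "library": lib.library_id,
            "clean_reads": lib.total_clean_reads,
            "unique_tags": lib.n_unique,
        }
        for lib in state.libraries
    ]
    _write_tsv(pd.DataFrame(rows), out / "library_stats.tsv", state)
    state.counts["libraries"] = len(state.libraries)
    _log("preprocess", f"{len(state.libraries)} libraries ready")


def _stage_mirna(cfg, sim, state, out: Path) -> None:
    known = load_known_mirnas()
    conserved_rows = []
    union: dict[str, int] = {}
    for lib in state.libraries:
        for tag, cnt in lib.tags.items():
            union[tag] = union.get(tag, 0) + cnt
    for tag, total in sorted(union.items()):
        if len(tag) >= 24 or total <= 1:
            continue
        hit = match_conserved(tag, known)
        if hit is not None:
            conserved_rows.append({"tag": tag, "family": hit[0], "mismatches": hit[1]})
    _write_tsv(pd.DataFrame(conserved_rows, columns=["tag", "family", "mismatches"]),
               out / "conserved_mirnas.tsv", state)

    state.novel = call_novel_mirnas(state.libraries, state.transcripts)
    _write_tsv(novel_mirna_table(state.novel), out / "novel_mirnas.tsv", state)
    state.counts["conserved_mirnas"] = len(conserved_rows)
    state.counts["novel_mirnas"] = len(state.novel)
    _log("mirna", f"{len(conserved_rows)} conserved tags, {len(state.novel)} novel miRNAs")


def _stage_de(cfg, sim, state, out: Path) -> None:
    libs = {lib.library_id: lib for lib in state.libraries}
    control = state.libraries[0].library_id
    for treat in [l.library_id for l in state.libraries[1:]]:
        df = de_table(libs[control], libs[treat], alpha=cfg.alpha, min_log2=cfg.min_log2)
        state.de_tables[f"{control}_vs_{treat}"] = df
        _write_tsv(df, out / f"de_{control}_vs_{treat}.tsv", state)
        counts = df["class"].value_counts().to_dict()
        state.counts[f"de_{control}_vs_{treat}"] = int(
            sum(v for k, v in counts.items() if k != "ns")
        )
        _log("de", f"{control} vs {treat}: " + ", ".join(f"{k}={v}" for k, v in sorted(counts.items())))


def _stage_sirna(cfg, sim, state, out: Path) -> None:
    union: set[str] = set()
    for lib in state.libraries:
        union |= set(lib.tags)
    pairs = find_duplex_pairs(union)
    rows = [{"tag_a": p.tag_a, "tag_b": p.tag_b, "paired_length": p.paired_length,
             "duplex_length": p.longer_length} for p in pairs]
    _write_tsv(pd.DataFrame(rows, columns=["tag_a", "tag_b", "paired_length", "duplex_length"]),
               out / "duplexes.tsv", state)
    if pairs:
        dist = duplex_length_distribution(pairs)
        _write_tsv(
            pd.DataFrame({"length": list(dist), "fraction": list(dist.values())}),
            out / "duplex_length_distribution.tsv", state,
        )
    repeats = [r for r in state.transcripts if r.id.startswith("REPTR")]
    if repeats and pairs:
        mappings, unmapped = map_duplexes_to_elements(pairs, repeats)
        cov_rows = []
        for m in mappings.values():
            for pos, depth in enumerate(m.coverage, start=1):
                if depth:
                    cov_rows.append({"element": m.element_id, "position": pos, "depth": depth})
        _write_tsv(pd.DataFrame(cov_rows, columns=["element", "position", "depth"]),
                   out / "element_coverage.tsv", state)
        state.counts["mapped_duplexes"] = sum(m.mapped_duplexes for m in mappings.values())
    state.counts["duplex_pairs"] = len(pairs)
    state.counts["duplex_tags"] = len({t for p in pairs for t in (p.tag_a, p.tag_b)})
    _log("sirna", f"{len(pairs)} duplex pairs")


def _stage_degradome(cfg, sim, state, out: Path) -> None:
    if not state.degradome_libs:
        paths = sorted(out.glob("degradome_*.tsv"))
        state.degradome_libs = {p.stem.split("_", 1)[1]: read_tag_table(p) for p in paths}
    if not state.degradome_libs:
        _log("degradome", "no degradome libraries; stage skipped")
        return
    profiles = {
        cond: build_profile(lib, state.transcripts)
        for cond, lib in state.degradome_libs.items()
    }
    state.profiles = profiles
    mirnas = {rec.name: rec.mature for rec in state.novel}
    for rec in load_known_mirnas():
        mirnas[rec.id] = rec.sequence
    events = call_targets(mirnas, state.transcripts, profiles, cfg.max_score)
    lib_ids = sorted(state.degradome_libs)
    rows = [
        {
            "mirna": e.mirna_id,
            "transcript": e.transcript_id,
            "alignment_score": e.alignment_score,
            "alignment_range": f"{e.alignment_range[0]}-{e.alignment_range[1]}",
            "cleavage_site": e.cleavage_site,
            "category": e.category,
            **{f"abundance_{lib}": e.abundance.get(lib, 0) for lib in lib_ids},
        }
        for e in events
    ]
    _write_tsv(pd.DataFrame(rows, columns=["mirna", "transcript", "alignment_score",
                                           "alignment_range", "cleavage_site", "category"]
                            + [f"abundance_{lib}" for lib in lib_ids]),
               out / "targets.tsv", state)
    # one t-plot table per event, on the library-summed profile
    combined: dict[str, dict[int, int]] = {}
    for prof_map in profiles.values():
        for tid, prof in prof_map.items():
            agg = combined.setdefault(tid, {})
            for pos, cnt in prof.positions.items():
                agg[pos] = agg.get(pos, 0) + cnt
    tdir = out / "tplots"
    tdir.mkdir(exist_ok=True)
    from .degradome import TranscriptDegradationProfile

    for e in events:
        prof = TranscriptDegradationProfile(e.transcript_id, combined.get(e.transcript_id, {}))
        rows = tplot_data(e, prof)
        df = pd.DataFrame(rows, columns=["position", "abundance", "is_site"])
        _write_tsv(df, tdir / f"{e.mirna_id}_{e.transcript_id}_{e.cleavage_site}.tsv", state)
    state.events = events
    state.counts["cleavage_events"] = len(events)
    _log("degradome", f"{len(events)} cleavage events")


def _stage_tasi(cfg, sim, state, out: Path) -> None:
    trigger = (state.truth.trigger if state.truth else None) or "AAGCTCAGGAGGGATAGCGCC"
    profiles = getattr(state, "profiles", None)
    combined = None
    if profiles:
        from .degradome import TranscriptDegradationProfile

        combined = {}
        for prof_map in profiles.values():
            for tid, prof in prof_map.items():
                agg = combined.setdefault(tid, TranscriptDegradationProfile(tid))
                for pos, cnt in prof.positions.items():
                    agg.positions[pos] = agg.positions.get(pos, 0) + cnt
    sites = find_trigger_sites(trigger, state.transcripts, cfg.max_score, combined)
    loci = detect_two_hit_locus(sites)
    seq_by_id = {r.id: r.sequence for r in state.transcripts}
    loci_rows = []
    phase_rows = []
    tasi_target_rows = []
    for locus in loci:
        loci_rows.append(
            {
                "transcript": locus.transcript_id,
                "site5": f"{locus.site5.span[0]}-{locus.site5.span[1]}",
                "site3": f"{locus.site3.span[0]}-{locus.site3.span[1]}",
                "spacing_nt": locus.spacing_nt,
                "phase_count": locus.phase_count,
                "validated": locus.validated,
            }
        )
        phases = extract_phases(locus, seq_by_id[locus.transcript_id], state.libraries)
        for ph in phases:
            phase_rows.append(
                {
                    "locus": locus.transcript_id,
                    "name": ph.name,
                    "sequence": ph.sequence,
                    **{lib.library_id: ph.abundance.get(lib.library_id, 0)
                       for lib in state.libraries},
                }
            )
            if ph.k in (7, 8) and len(ph.sequence) == 21:
                genes = [r for r in state.transcripts if not r.id.startswith(("TASTR",))]
                for tg in predict_tasi_targets(ph.sequence, genes, cfg.tasi_max_mismatch):
                    tasi_target_rows.append(
                        {
                            "tasi": f"{locus.transcript_id}:{ph.name}",
                            "gene": tg.gene_id,
                            "sites": ";".join(f"{s.span[0]}-{s.span[1]}" for s in tg.sites),
                        }
                    )
    _write_tsv(pd.DataFrame(loci_rows, columns=["transcript", "site5", "site3", "spacing_nt",
                                                "phase_count", "validated"]),
               out / "loci.tsv", state)
    lib_cols = [lib.library_id for lib in state.libraries]
    _write_tsv(pd.DataFrame(phase_rows, columns=["locus", "name", "sequence"] + lib_cols),
               out / "phases.tsv", state)
    _write_tsv(pd.DataFrame(tasi_target_rows, columns=["tasi", "gene", "sites"]).drop_duplicates(),
               out / "tasi_targets.tsv", state)
    state.counts["tas3_loci"] = len(loci)
    _log("tasi", f"{len(loci)} two-hit loci")


def _stage_report(cfg, sim, state, out: Path) -> None:
    lines = ["# srnapipe run report", ""]
    lines.append("## Libraries")
    for lib in state.libraries:
        lines.append(f"- {lib.library_id}: {lib.total_clean_reads} clean reads, "
                     f"{lib.n_unique} unique tags")
    lines.append("")
    lines.append("## Record counts")
    for key in sorted(state.counts):
        lines.append(f"- {key}: {state.counts[key]}")
    lines.append("")
    for name in ("novel_mirnas.tsv", "targets.tsv", "loci.tsv"):
        p = out / name
        if p.exists():
            n = max(0, sum(1 for _ in open(p)) - 1)
            lines.append(f"- {name}: {n} rows")
    report = out / "report.md"
    report.write_text("\n".join(lines) + "\n")
    state.outputs.append(report)
    _log("report", f"written to {report}")


_STAGE_FNS = {
    "simulate": _stage_simulate,
    "preprocess": _stage_preprocess,
    "mirna": _stage_mirna,
    "de": _stage_de,
    "sirna": _stage_sirna,
    "degradome": _stage_degradome,
    "tasi": _stage_tasi,
    "report": _stage_report,
}
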