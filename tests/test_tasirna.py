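"""Two-hit loci, phase registers, tasiRNA targets and expression correlation."""

import numpy as np
import pytest

from srnapipe.io import SequenceRecord, TagLibrary, collapse_reads, revcomp
from srnapipe.simulate import DEFAULT_TRIGGER
from srnapipe.tasirna import (
    TargetSite,
    TasiLocus,
    correlate_series,
    detect_two_hit_locus,
    extract_phases,
    find_trigger_sites,
    predict_tasi_targets,
)


def _locus(spacing, start5=100):
    s5 = TargetSite("T", (start5, start5 + 20), 2.0)
    s3_start = start5 + 21 + spacing
    s3 = TargetSite("T", (s3_start, s3_start + 20), 0.0, cleaved=True)
    return TasiLocus("T", s5, s3)


class TestTriggerSites:
    def test_planted_perfect_site_scores_zero(self):
        rng = np.random.default_rng(0)
        flank = "".join(rng.choice(list("ACGT"), 200))
        t = SequenceRecord("T", flank + revcomp(DEFAULT_TRIGGER) + flank)
        sites = find_trigger_sites(DEFAULT_TRIGGER, [t])["T"]
        assert any(s.span == (201, 221) and s.score == 0.0 for s in sites)

    def test_single_wobble_site_scores_half(self):
        site = list(revcomp(DEFAULT_TRIGGER))
        # trigger 5' A..: pair a trigger G with a T instead of C
        gpos = DEFAULT_TRIGGER.index("G")
        site[20 - gpos] = "T"
        t = SequenceRecord("T", "CATCAT" * 20 + "".join(site) + "CATCAT" * 20)
        sites = find_trigger_sites(DEFAULT_TRIGGER, [t])["T"]
        assert min(s.score for s in sites) == 0.5

    def test_matches_sliding_window_oracle(self, bench):
        from srnapipe.degradome import score_alignment

        trigger = bench["truth"].trigger
        transcripts = bench["records"][:20]
        got = find_trigger_sites(trigger, transcripts, max_score=4.5)
        for t in transcripts:
            expected = []
            for i in range(len(t.sequence) - 20):
                sc = score_alignment(trigger, t.sequence[i : i + 21])
                if sc <= 4.5:
                    expected.append(((i + 1, i + 21), sc))
            assert [(s.span, s.score) for s in got.get(t.id, [])] == expected

    def test_non21nt_trigger_rejected(self):
        with pytest.raises(ValueError):
            find_trigger_sites("ACGT", [])


class TestTwoHitLoci:
    @pytest.mark.parametrize("spacing,phases", [(174, 8), (261, 12), (168, 8)])
    def test_phase_count_rule(self, spacing, phases):
        assert _locus(spacing).phase_count == phases

    def test_spacing_excludes_site_spans(self):
        loc = _locus(174)
        assert loc.spacing_nt == 174
        assert loc.site5.span[1] < loc.site3.span[0]

    def test_closest_pair_forms_locus_and_matches_bruteforce(self):
        rng = np.random.default_rng(6)
        for _ in range(40):
            n = int(rng.integers(2, 7))
            starts = sorted(rng.choice(np.arange(1, 2000, 30), size=n, replace=False))
            sites = [TargetSite("T", (int(s), int(s) + 20), float(rng.integers(0, 5)))
                     for s in starts]
            loci = detect_two_hit_locus({"T": sites})
            # brute-force oracle over non-overlapping prunes
            kept = []
            for s in sorted(sites, key=lambda x: (x.score, x.span[0])):
                if all(s.span[1] < k.span[0] or s.span[0] > k.span[1] for k in kept):
                    kept.append(s)
            kept.sort(key=lambda s: s.span[0])
            best = None
            for i in range(len(kept) - 1):
                for j in range(i + 1, len(kept)):
                    spacing = kept[j].span[0] - kept[i].span[1] - 1
                    if round(spacing / 21) >= 1 and (best is None or spacing < best[0]):
                        best = (spacing, kept[i], kept[j])
            if best is None:
                assert loci == []
            else:
                assert len(loci) == 1
                assert loci[0].site5.span == best[1].span
                assert loci[0].site3.span == best[2].span

    def test_validated_requires_exactly_one_cleaved_site(self):
        loc = _locus(174)
        assert loc.validated
        both = TasiLocus(
            "T",
            TargetSite("T", (100, 120), 0.0, cleaved=True),
            TargetSite("T", (300, 320), 0.0, cleaved=True),
        )
        assert not both.validated


class TestPhaseExtraction:
    def test_planted_d7_d8_recovered(self, bench):
        truth = bench["truth"]
        sites = find_trigger_sites(truth.trigger, bench["records"])
        loci = {l.transcript_id: l for l in detect_two_hit_locus(sites)}
        for planted in truth.tas3_loci:
            locus = loci[planted.transcript_id]
            phases = extract_phases(locus, bench["seq_by_id"][planted.transcript_id],
                                    bench["libraries"])
            assert phases[6].sequence == planted.d7
            assert phases[7].sequence == planted.d8
            assert sum(phases[6].abundance.values()) > 0

    def test_windows_tile_register(self):
        rng = np.random.default_rng(2)
        seq = "".join(rng.choice(list("ACGT"), 600))
        locus = _locus(210, start5=100)
        phases = extract_phases(locus, seq)
        starts = [p.span[0] for p in phases]
        assert all(len(p.sequence) == 21 for p in phases)
        assert all(a - b == 21 for a, b in zip(starts, starts[1:]))
        spans = sorted(p.span for p in phases)
        assert all(s2[0] == s1[1] + 1 for s1, s2 in zip(spans, spans[1:]))  # no overlap

    def test_truncated_windows_flagged(self):
        locus = _locus(210, start5=10)
        phases = extract_phases(locus, "ACGT" * 120, max_k=12)
        assert any(p.truncated for p in phases)


class TestTasiTargets:
    def test_two_sites_and_threshold(self):
        tasi = "TTCTTGACCTTGTAAGACCCA"
        rng = np.random.default_rng(3)
        pad = "".join(rng.choice(list("ACGT"), 150))
        site = revcomp(tasi)
        mm3 = "CCC" + site[3:]
        gene2 = SequenceRecord("G2", pad + site + pad + site + pad)
        gene_bad = SequenceRecord("GB", pad + mm3 + pad)
        out = predict_tasi_targets(tasi, [gene2, gene_bad], max_mismatch=2.0)
        assert [g.gene_id for g in out] == ["G2"]
        assert len(out[0].sites) == 2

    def test_spans_match_bruteforce_scan(self, bench):
        from srnapipe.degradome import score_alignment

        tasi = bench["truth"].tasi_arf
        genes = [r for r in bench["records"] if r.id.startswith("ARFG")]
        out = {g.gene_id: g for g in predict_tasi_targets(tasi, genes)}
        for g in genes:
            expected = []
            for i in range(len(g.sequence) - 20):
                sc = score_alignment(tasi, g.sequence[i : i + 21])
                if sc <= 2.0:
                    expected.append((i + 1, i + 21))
            if expected:
                assert [s.span for s in out[g.id].sites] == expected[:2]
            else:
                assert g.id not in out

    def test_planted_arf_genes_recovered(self, bench):
        truth = bench["truth"]
        genes = [r for r in bench["records"] if r.id.startswith("ARFG")]
        out = {g.gene_id: g for g in predict_tasi_targets(truth.tasi_arf, genes)}
        for planted in truth.arf_genes:
            assert planted.gene_id in out
            assert [s.span for s in out[planted.gene_id].sites] == list(planted.site_spans)


class TestCorrelation:
    def test_negative_pair(self):
        res = correlate_series([1, 0.5, 0.2], [1, 2, 4], ("miR", "target"))
        a = np.array([1, 0.5, 0.2])
        b = np.array([1, 2, 4])
        manual = ((a - a.mean()) * (b - b.mean())).sum() / (
            np.sqrt(((a - a.mean()) ** 2).sum()) * np.sqrt(((b - b.mean()) ** 2).sum())
        )
        assert res.r == pytest.approx(manual)
        assert res.corr_class == "negative"

    def test_identical_series_positive(self):
        res = correlate_series([1, 2, 3], [1, 2, 3])
        assert res.r == pytest.approx(1.0)
        assert res.corr_class == "positive"

    def test_constant_series_is_error(self):
        with pytest.raises(ValueError):
            correlate_series([1, 1, 1], [1, 2, 3])
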