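"""Hairpin statistics, duplex evaluation and miRNA matching."""

import numpy as np
import pytest

from srnapipe.hairpin import (
    INCONSISTENT_MFEI_ROWS,
    FoldResult,
    compute_amfe,
    compute_mfei,
    evaluate_duplex,
    fold_hairpin,
    gc_percent,
    load_known_mirnas,
    load_novel_mirna_table,
    match_conserved,
    call_novel_mirnas,
    round2,
)
from srnapipe.io import SequenceRecord, TagLibrary, collapse_reads, revcomp


class TestFormulas:
    def test_gc_percent_extremes(self):
        assert gc_percent("GCGC") == 100.0
        assert gc_percent("ATAT") == 0.0

    def test_gc_percent_of_a_mature_differs_from_its_precursor(self):
        # 4 G + 0 C over 21 nt; the table's 27.87% is the precursor's GC
        assert round2(gc_percent("TGAATATTGTTAAAGTAGAAA")) == 19.05

    def test_amfe(self):
        assert round2(compute_amfe(-43.30, 122)) == 35.49
        assert compute_amfe(0, 100) == 0.0
        assert compute_amfe(-21.0, 100) == 21.0
        with pytest.raises(ValueError):
            compute_amfe(5.0, 100)

    def test_mfei_undefined_for_zero_gc(self):
        with pytest.raises(ValueError):
            compute_mfei(-10.0, 100, 0.0)

    def test_mfei_scales_linearly_in_energy_and_ignores_orientation(self):
        base = compute_mfei(-30.0, 120, 40.0)
        assert compute_mfei(-60.0, 120, 40.0) == pytest.approx(2 * base)
        # pure formula: reversing a sequence changes neither length nor GC
        seq = "ACGGTTACGGATCC"
        assert gc_percent(seq) == gc_percent(seq[::-1])


class TestBundledTable:
    def test_inconsistent_rows_flagged_not_corrected(self):
        df = load_novel_mirna_table()
        flagged = set(df.loc[~df.mfei_consistent, "name"])
        assert flagged == set(INCONSISTENT_MFEI_ROWS)
        for _, row in df[~df.mfei_consistent].iterrows():
            assert row.mfei_recomputed != row.mfei  # printed value left as printed

    def test_consistent_rows_reproduce_printed_mfei(self):
        df = load_novel_mirna_table()
        ok = df[df.mfei_consistent]
        assert len(ok) == 22
        assert df.mfei.min() == 0.64 and df.mfei.max() == 1.74


class TestFold:
    def test_perfect_inverted_repeat_folds_to_hairpin(self):
        stem = "GCGCAAGGCCTTGGACGGTTCAACGGTAGC"
        seq = stem + "AAACAAAA" + revcomp(stem)
        fold = fold_hairpin(seq)
        assert fold.delta_g < 0
        assert "(" in fold.structure and ")" in fold.structure

    def test_homopolymer_has_no_structure(self):
        fold = fold_hairpin("A" * 80)
        assert fold.structure.count("(") == 0
        assert fold.delta_g == 0.0

    def test_length_bounds_enforced(self):
        with pytest.raises(ValueError):
            fold_hairpin("ACGT" * 10)  # 40 nt < 50
        with pytest.raises(ValueError):
            fold_hairpin("ACGT" * 101)

    def test_n_rich_sequence_rejected(self):
        with pytest.raises(ValueError, match="N"):
            fold_hairpin("N" * 20 + "A" * 60)

    def test_nussinov_backend_contract(self):
        stem = "GCGCAAGGCCTTGGACGGTTCAACGGTAGC"
        seq = stem + "AAACAAAA" + revcomp(stem)
        fold = fold_hairpin(seq, backend="nussinov")
        assert fold.backend == "nussinov"
        assert fold.structure.count("(") == fold.structure.count(")")
        assert fold.delta_g < 0
        pt = fold.pair_table()
        for i, j in enumerate(pt[1:], start=1):
            if j:
                assert pt[j] == i


def _planted_hairpin(seed=0, arm="5'", star_mm=0):
    """Construct a mature/star hairpin with the canonical overhang geometry."""
    rng = np.random.default_rng(seed)
    mature = "".join(rng.choice(list("ACGT"), 21))
    core = revcomp(mature[:19])
    if star_mm:
        pos = rng.choice(np.arange(3, 16), size=star_mm, replace=False)
        core = list(core)
        for p in pos:
            core[p] = {"A": "C", "C": "A", "G": "T", "T": "G"}[core[p]]
        core = "".join(core)
    star = core + "".join(rng.choice(list("ACGT"), 2))
    loop = "".join(rng.choice(list("ACGT"), 12))
    precursor = mature + loop + star if arm == "5'" else star + loop + mature
    m0 = 1 if arm == "5'" else len(star) + len(loop) + 1
    return precursor, (m0, m0 + 20), mature, star


class TestDuplexEvaluation:
    @pytest.mark.parametrize("arm", ["5'", "3'"])
    def test_planted_perfect_hairpin_passes(self, arm):
        precursor, span, mature, star = _planted_hairpin(seed=4, arm=arm)
        ev = evaluate_duplex(precursor, fold_hairpin(precursor), span, {mature, star})
        assert ev.passed
        assert ev.duplex_mismatches == 0
        assert ev.arm == arm
        assert ev.star_sequence == star
        assert ev.lm == 21 and ev.lp == len(precursor)

    def test_star_absent_from_tags_fails(self):
        precursor, span, mature, star = _planted_hairpin(seed=4)
        ev = evaluate_duplex(precursor, fold_hairpin(precursor), span, {mature})
        assert not ev.passed
        assert ev.reason == "no miRNA* evidence"

    def test_six_mismatches_is_a_strict_failure(self):
        # hand-built fold: mature 1-19 paired except six engineered bulges
        mature_len = 21
        struct = list("(" * 19 + ".." + "." * 12 + ")" * 19 + "..")
        for pos in (2, 5, 8, 11, 14, 17):  # six unpaired mature positions
            struct[pos] = "."
        # rebalance: drop the matching closing brackets (innermost pairing)
        closes = [i for i, c in enumerate(struct) if c == ")"]
        for k in range(6):
            struct[closes[k]] = "."
        fold = FoldResult("".join(struct), -20.0, backend="synthetic")
        precursor = "A" * (19 + 2 + 12 + 19 + 2)
        ev = evaluate_duplex(precursor, fold, (1, mature_len), None)
        assert not ev.passed
        assert ev.duplex_mismatches >= 6

    def test_no_hairpin_structure_rejected(self):
        fold = FoldResult("." * 60, 0.0)
        ev = evaluate_duplex("A" * 60, fold, (1, 21), None)
        assert not ev.passed

    def test_pass_never_overlaps_terminal_loop(self, bench, bench_tag_union):
        tags = set(bench_tag_union)
        for m in bench["truth"].mirnas:
            p1, p2 = m.precursor_span
            prec = bench["seq_by_id"][m.transcript_id][p1 - 1 : p2]
            span = (m.mature_span[0] - p1 + 1, m.mature_span[1] - p1 + 1)
            ev = evaluate_duplex(prec, fold_hairpin(prec), span, tags)
            if ev.passed:
                assert not ev.in_terminal_loop


@pytest.fixture(scope="module")
def known():
    return load_known_mirnas()


class TestConservedMatching:

    def test_identical_match(self, known):
        ref = known[0]
        assert match_conserved(ref.sequence, known) == (ref.id, 0)

    def test_two_mismatches_match_three_do_not(self, known):
        ref = known[0].sequence
        swap = {"A": "C", "C": "A", "G": "T", "T": "G"}
        two = ref[:-2] + "".join(swap[b] for b in ref[-2:])
        m2 = match_conserved(two, known)
        assert m2 is not None and m2[1] <= 2
        three = ref[:-3] + "".join(swap[b] for b in ref[-3:])
        assert match_conserved(three, known) is None

    def test_terminal_length_variant_matches(self, known):
        ref = known[3].sequence
        assert match_conserved(ref[:-2], known) == (known[3].id, 0)

    def test_empty_reference_is_an_error(self):
        with pytest.raises(ValueError):
            match_conserved("ACGT" * 5, [])


class TestNovelCalling:
    def test_single_planted_hairpin_recovered(self):
        precursor, span, mature, star = _planted_hairpin(seed=8)
        flank = "".join(np.random.default_rng(9).choice(list("ACGT"), 80))
        transcript = SequenceRecord("T1", flank + precursor + flank[::-1])
        lib = collapse_reads([mature] * 50 + [star] * 5, "CK")
        records = call_novel_mirnas([lib], [transcript])
        assert [r.mature for r in records] == [mature]
        assert records[0].star == star
        assert records[0].evaluation.passed

    def test_hairpin_without_star_evidence_excluded(self):
        precursor, span, mature, star = _planted_hairpin(seed=8)
        flank = "".join(np.random.default_rng(9).choice(list("ACGT"), 80))
        transcript = SequenceRecord("T1", flank + precursor + flank[::-1])
        lib = collapse_reads([mature] * 50, "CK")  # star never cloned
        assert call_novel_mirnas([lib], [transcript]) == []
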