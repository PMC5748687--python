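"""Degradome tag preparation, alignment scoring and category assignment."""

import itertools

import numpy as np
import pytest

from srnapipe.degradome import (
    TranscriptDegradationProfile,
    assign_category,
    build_profile,
    call_targets,
    find_target_sites,
    is_polyn,
    predict_cleavage,
    prepare_degradome_tags,
    score_alignment,
    tplot_data,
)
from srnapipe.io import SequenceRecord, TagLibrary, revcomp


def _pair_cost_oracle(m, t):
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    if t == comp[m]:
        return 0.0
    if (m, t) in (("G", "T"), ("T", "G")):
        return 0.5
    return 1.0


def _score_oracle(mirna, site):
    """Exhaustive enumeration over all single contiguous gap placements."""
    rev = site[::-1]
    lm, ls = len(mirna), len(rev)
    d = abs(lm - ls)
    if d == 0:
        candidates = [(mirna, rev)]
    else:
        short, long_ = (mirna, rev) if lm < ls else (rev, mirna)
        candidates = []
        for g in range(len(short) + 1):
            gapped = short[:g] + "-" * d + short[g:]
            candidates.append((gapped, long_) if lm < ls else (long_, gapped))
    best = None
    for m, t in candidates:
        s = 0.0
        for a, b in zip(m, t):
            s += 1.0 if "-" in (a, b) else _pair_cost_oracle(a, b)
        best = s if best is None else min(best, s)
    return best


class TestPreparation:
    def test_polyn_boundary(self):
        assert is_polyn("A" * 20 + "C")  # 20/21 > 70%
        assert not is_polyn("A" * 14 + "CGTCGT")  # exactly 70% is kept

    def test_length_window(self):
        kept20 = "ACGT" * 5
        kept21 = "C" + "ACGT" * 5
        dropped22 = "ACGT" * 5 + "CG"
        dropped19 = "ACGT" * 4 + "CGT"
        lib = prepare_degradome_tags([kept20, kept21, dropped22, dropped19])
        assert set(lib.tags) == {kept20, kept21}

    def test_planted_fragments_survive(self, bench):
        lib = bench["degradome"]["CK"]
        kept = prepare_degradome_tags(list(lib.tags))
        assert len(kept.tags) / lib.n_unique >= 0.99


class TestProfiles:
    def test_single_tag_position_and_count(self):
        t = SequenceRecord("T1", "G" * 99 + "ACGTACGTACGTACGTACGT" + "G" * 40)
        tags = TagLibrary("d", {"ACGTACGTACGTACGTACGT": 7}, 7)
        prof = build_profile(tags, [t])["T1"]
        assert prof.positions == {100: 7}

    def test_antisense_match_contributes_nothing(self):
        frag = "ACGTTGCAACGGATCCGGTA"
        t = SequenceRecord("T1", "G" * 50 + revcomp(frag) + "G" * 50)
        prof = build_profile(TagLibrary("d", {frag: 5}, 5), [t])["T1"]
        assert prof.positions == {}

    def test_matches_bruteforce_scan(self, bench):
        transcripts = bench["records"][:50]
        lib = bench["degradome"]["CK"]
        sub = dict(itertools.islice(lib.tags.items(), 120))
        profs = build_profile(TagLibrary("d", sub, sum(sub.values())), transcripts)
        for t in transcripts:
            expected: dict[int, int] = {}
            for tag, cnt in sub.items():
                for i in range(len(t.sequence) - len(tag) + 1):
                    if t.sequence[i : i + len(tag)] == tag:
                        expected[i + 1] = expected.get(i + 1, 0) + cnt
            assert profs[t.id].positions == expected


class TestScoring:
    def test_perfect_complement_scores_zero(self):
        m = "TGCCTGGCTCCCTGTATGCCA"
        assert score_alignment(m, revcomp(m)) == 0.0

    def test_single_gu_wobble_is_half(self):
        m = "TGCCTGGCTCCCTGTATGCCA"
        site = list(revcomp(m))
        # miRNA position 2 is a G pairing site position 20 (antisense);
        # replacing that C with T turns the Watson-Crick pair into G:U
        site[19] = "T"
        assert score_alignment(m, "".join(site)) == 0.5

    def test_additivity_three_mismatch_two_wobble(self):
        m = "TTAAAAAAAACCCCCCCCCCC"
        site = list(revcomp(m))
        site[20] = "G"  # miRNA 5' T : G wobble
        site[19] = "G"  # second T : G wobble
        for i in (0, 1, 2):
            site[i] = "C"  # C:C mispairs against the miRNA 3' end
        assert score_alignment(m, "".join(site)) == 3.0 + 2 * 0.5

    @pytest.mark.parametrize("ld", [-2, -1, 0, 1, 2])
    def test_matches_enumeration_oracle(self, ld):
        rng = np.random.default_rng(40 + ld)
        for _ in range(60):
            m = "".join(rng.choice(list("ACGT"), 21))
            site = "".join(rng.choice(list("ACGT"), 21 + ld))
            assert score_alignment(m, site) == _score_oracle(m, site)

    def test_length_gap_over_two_rejected(self):
        with pytest.raises(ValueError):
            score_alignment("A" * 21, "T" * 25)


class TestCleavagePrediction:
    @pytest.mark.parametrize(
        "rng_,site", [((378, 398), 389), ((19, 39), 30), ((101, 120), 111)]
    )
    def test_site_is_end_minus_nine(self, rng_, site):
        assert predict_cleavage(rng_) == site

    def test_short_range_rejected(self):
        with pytest.raises(ValueError):
            predict_cleavage((10, 20))


class TestCategories:
    def test_unique_maximum_is_category_zero(self):
        prof = TranscriptDegradationProfile("T", {10: 12, 50: 2, 80: 1})
        assert assign_category(12, prof) == 0

    def test_single_read_is_category_four(self):
        prof = TranscriptDegradationProfile("T", {10: 12, 50: 1})
        assert assign_category(1, prof) == 4

    def test_matches_clausewise_oracle_on_random_profiles(self):
        def oracle(ab, values):
            mx = max(values)
            med = sorted(values)[len(values) // 2] if len(values) % 2 else (
                sum(sorted(values)[len(values) // 2 - 1 : len(values) // 2 + 1]) / 2
            )
            if ab == 1:
                return 4
            if ab == mx:
                return 0 if values.count(mx) == 1 else 1
            if ab > med:
                return 2
            return 3

        rng = np.random.default_rng(9)
        for _ in range(300):
            n = int(rng.integers(1, 12))
            values = [int(v) for v in rng.integers(1, 30, size=n)]
            prof = TranscriptDegradationProfile("T", dict(enumerate(values, start=1)))
            site_ab = values[int(rng.integers(n))]
            assert assign_category(site_ab, prof) == oracle(site_ab, values)

    def test_events_partition_into_categories(self, bench):
        profiles = {
            cond: build_profile(lib, bench["records"])
            for cond, lib in bench["degradome"].items()
        }
        mirnas = {m.name: m.mature for m in bench["truth"].mirnas}
        events = call_targets(mirnas, bench["records"], profiles)
        assert events
        assert all(e.category in (0, 1, 2, 3, 4) for e in events)


class TestTargetCalling:
    def test_two_mirnas_same_site_two_events(self):
        site = revcomp("TGCCTGGCTCCCTGTATGCCA")
        t = SequenceRecord("T1", "G" * 100 + site + "G" * 100)
        frag = t.sequence[111 : 111 + 20]  # 5' fragment from predicted site 112
        profiles = {"CK": build_profile(TagLibrary("d", {frag: 9}, 9), [t])}
        mirnas = {"mirA": "TGCCTGGCTCCCTGTATGCCA", "mirB": "TGCCTGGCTCCCTGTATGCTA"}
        events = call_targets(mirnas, [t], profiles, max_score=4.5)
        assert {e.mirna_id for e in events} == {"mirA", "mirB"}
        assert all(e.cleavage_site == 112 for e in events)

    def test_site_without_degradome_signal_not_called(self):
        site = revcomp("TGCCTGGCTCCCTGTATGCCA")
        t = SequenceRecord("T1", "G" * 100 + site + "G" * 100)
        profiles = {"CK": build_profile(TagLibrary("d", {"ACGT" * 5: 3}, 3), [t])}
        assert call_targets({"mirA": "TGCCTGGCTCCCTGTATGCCA"}, [t], profiles) == []


class TestTplot:
    def test_rows_sorted_and_conserving(self, bench):
        profiles = {
            cond: build_profile(lib, bench["records"])
            for cond, lib in bench["degradome"].items()
        }
        mirnas = {m.name: m.mature for m in bench["truth"].mirnas}
        events = call_targets(mirnas, bench["records"], profiles)
        e = events[0]
        prof = profiles["CK"][e.transcript_id]
        rows = tplot_data(e, prof)
        positions = [r[0] for r in rows]
        assert positions == sorted(positions)
        assert sum(r[1] for r in rows) == prof.total
        assert sum(1 for r in rows if r[2]) <= 1
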