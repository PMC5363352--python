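"""Switch detection, breakpoint/conversion classification, IBD comparison."""

import numpy as np
import pytest

from segdupcnv import (
    Contig,
    GeneConversion,
    GenomicInterval,
    NahrDeletion,
    assign_hotspot,
    build_allele,
    classify_events,
    compare_alleles,
    detect_switches,
    divergence_separation,
    interval_length,
    psv_profile,
    realize_sequence,
    simulate_paralog_pair,
)
from segdupcnv.assign import PSVProfile
from segdupcnv.breakpoints import BreakpointInterval


def profile_from(positions, states):
    return PSVProfile(states=tuple(zip(positions, states)))


class TestIntervalLength:
    @pytest.mark.parametrize(
        "start,end,kb",
        [
            (159806619, 159815757, 9.1),
            (159888461, 159897571, 9.1),
            (159888397, 159890836, 2.4),
            (159824223, 159830623, 6.4),
        ],
    )
    def test_printed_tract_sizes(self, start, end, kb):
        assert round(interval_length((start, end)) / 1000, 1) == kb

    def test_single_base_and_translation_invariance(self):
        assert interval_length((5, 5)) == 1
        assert interval_length((100, 350)) == interval_length((10_100, 10_350))

    def test_inverted_interval_rejected(self):
        with pytest.raises(ValueError):
            interval_length((10, 9))


class TestDetectSwitches:
    def test_uniform_profile_no_switch(self):
        prof = profile_from(range(100, 600, 100), "AAAAA")
        switches, masked = detect_switches(prof, min_run=2)
        assert switches == [] and masked == []

    def test_simple_switch_interval(self):
        prof = profile_from([100, 200, 300, 400, 500, 600], "AAABBB")
        switches, _ = detect_switches(prof, min_run=2)
        assert len(switches) == 1
        sw = switches[0]
        assert (sw.from_state, sw.to_state) == ("A", "B")
        assert (sw.interval.start, sw.interval.end) == (300, 400)
        assert sw.n_support == (3, 3)

    def test_isolated_discordant_state_masked(self):
        positions = [100, 200, 300, 400, 500, 600, 700, 800]
        prof = profile_from(positions, "AABAABBB")
        switches, masked = detect_switches(prof, min_run=2)
        assert masked == [300]
        assert len(switches) == 1
        assert (switches[0].interval.start, switches[0].interval.end) == (500, 600)

    def test_min_run_one_keeps_every_boundary(self):
        prof = profile_from([10, 20, 30, 40], "ABAB")
        switches, masked = detect_switches(prof, min_run=1)
        assert masked == []
        assert [(s.from_state, s.to_state) for s in switches] == [
            ("A", "B"),
            ("B", "A"),
            ("A", "B"),
        ]

    def test_other_states_ignored(self):
        prof = profile_from([10, 20, 30, 40, 50], ("A", "A", "other", "B", "B"))
        switches, _ = detect_switches(prof, min_run=2)
        assert (switches[0].interval.start, switches[0].interval.end) == (20, 40)

    def test_uninformative_profile_warns(self):
        prof = profile_from([10, 20], ("other", "other"))
        with pytest.warns(UserWarning, match="no informative"):
            switches, masked = detect_switches(prof)
        assert switches == []

    def test_exhaustive_eight_state_patterns(self):
        """Against a brute-force reference on every A/B pattern of length 8:
        after removing runs shorter than min_run, each boundary between the
        surviving (merged) runs must be reported exactly once."""
        positions = list(range(100, 900, 100))
        for bits in range(256):
            states = ["A" if (bits >> i) & 1 else "B" for i in range(8)]
            prof = profile_from(positions, states)
            switches, masked = detect_switches(prof, min_run=2)
            # oracle: independent run-length computation
            runs = []
            for pos, s in zip(positions, states):
                if runs and runs[-1][0] == s:
                    runs[-1][1].append(pos)
                else:
                    runs.append([s, [pos]])
            surviving = [r for r in runs if len(r[1]) >= 2]
            merged = []
            for s, ps in surviving:
                if merged and merged[-1][0] == s:
                    merged[-1][1].extend(ps)
                else:
                    merged.append([s, list(ps)])
            expected = [
                (r1[1][-1], r2[1][0]) for r1, r2 in zip(merged, merged[1:])
            ]
            got = [(s.interval.start, s.interval.end) for s in switches]
            assert got == expected, f"pattern {''.join(states)}"
            assert sorted(masked) == sorted(
                p for s, ps in runs if len(ps) < 2 for p in ps
            )


class TestClassifyEvents:
    def test_interior_tract_called_conversion(self):
        prof = profile_from(
            [100, 200, 300, 400, 500, 600, 700, 800], "AAABBAAA"
        )
        switches, _ = detect_switches(prof, min_run=2)
        bps, convs = classify_events(switches, prof)
        assert bps == []
        assert len(convs) == 1
        conv = convs[0]
        assert (conv.donor, conv.acceptor) == ("B", "A")
        assert (conv.tract.start, conv.tract.end) == (400, 500)
        assert (conv.outer.start, conv.outer.end) == (300, 600)
        assert conv.n_psvs == 2

    def test_single_switch_is_breakpoint(self):
        prof = profile_from([100, 200, 300, 400], "AABB")
        switches, _ = detect_switches(prof, min_run=2)
        bps, convs = classify_events(switches, prof)
        assert convs == []
        assert len(bps) == 1
        assert (bps[0].interval.start, bps[0].interval.end) == (200, 300)

    def test_empty_switch_list(self):
        prof = profile_from([100], "A")
        assert classify_events([], prof) == ([], [])

    def test_parsimony_breakpoint_before_conversion(self):
        """Chimera with a short conversion on its B side: the parse keeping
        the conversion tract short wins, so the first switch is the
        breakpoint."""
        positions = list(range(100, 1600, 100))
        states = "AAAA" + "BBBBB" + "AA" + "BBBB"  # bp, then short A tract
        prof = profile_from(positions, states)
        switches, _ = detect_switches(prof, min_run=2)
        bps, convs = classify_events(switches, prof)
        assert len(bps) == 1 and len(convs) == 1
        assert (bps[0].interval.start, bps[0].interval.end) == (400, 500)
        assert convs[0].donor == "A"
        assert (convs[0].tract.start, convs[0].tract.end) == (1000, 1100)

    def test_parsimony_conversion_before_breakpoint(self):
        positions = list(range(100, 1600, 100))
        states = "AAAA" + "BB" + "AAAAA" + "BBBB"  # short B tract, then bp
        prof = profile_from(positions, states)
        switches, _ = detect_switches(prof, min_run=2)
        bps, convs = classify_events(switches, prof)
        assert len(bps) == 1 and len(convs) == 1
        assert convs[0].donor == "B"
        assert (convs[0].tract.start, convs[0].tract.end) == (500, 600)
        assert (bps[0].interval.start, bps[0].interval.end) == (1100, 1200)

    def test_known_conversion_overlap_marks_ambiguous(self):
        prof = profile_from([100, 200, 300, 400], "AABB")
        switches, _ = detect_switches(prof, min_run=2)
        bps, _ = classify_events(
            switches, prof, known_conversions=[GenomicInterval(250, 320)]
        )
        assert bps[0].ambiguous_psvs == (300,)


class TestAssignHotspot:
    CATALOG = {
        "proximal": GenomicInterval(2800, 4000, "proximal"),
        "distal": GenomicInterval(12200, 13400, "distal"),
    }

    def test_contained_interval_gets_label(self):
        bp = BreakpointInterval(GenomicInterval(12500, 12600))
        assert assign_hotspot(bp, self.CATALOG).hotspot_label == "distal"

    def test_no_overlap_unassigned(self):
        bp = BreakpointInterval(GenomicInterval(7000, 7100))
        assert assign_hotspot(bp, self.CATALOG).hotspot_label == "unassigned"

    def test_random_catalog_matches_overlap_oracle(self, rng):
        catalog = {}
        for i in range(5):
            s = int(rng.integers(1, 9000))
            catalog[f"r{i}"] = GenomicInterval(s, s + int(rng.integers(50, 2000)))
        for _ in range(20):
            s = int(rng.integers(1, 10_000))
            bp = BreakpointInterval(GenomicInterval(s, s + int(rng.integers(1, 1500))))
            labelled = assign_hotspot(bp, catalog)
            overlaps = {
                name: bp.interval.overlap_bp(region)
                for name, region in catalog.items()
            }
            best = max(overlaps.values())
            if best == 0:
                assert labelled.hotspot_label == "unassigned"
            else:
                assert overlaps[labelled.hotspot_label] == best


class TestCompareAlleles:
    def test_self_comparison_is_ibd(self):
        iv = GenomicInterval(300, 400)
        flank = {100: "A", 200: "A", 500: "B"}
        assert compare_alleles(iv, flank, iv, dict(flank)) == "consistent_IBD"

    def test_different_intervals_distinct(self):
        flank = {100: "A", 500: "B"}
        assert (
            compare_alleles(
                GenomicInterval(300, 400), flank, GenomicInterval(300, 450), flank
            )
            == "distinct"
        )

    def test_flanking_state_difference_distinct(self):
        iv = GenomicInterval(300, 400)
        assert (
            compare_alleles(iv, {100: "A", 500: "B"}, iv, {100: "B", 500: "B"})
            == "distinct"
        )

    def test_simulated_pairs_match_generation_truth(self):
        """Over 100 replicate pairs of error-free deletion alleles, shared
        generating breakpoints are called IBD-consistent and breakpoints in
        different inter-PSV gaps are called distinct."""
        pair = simulate_paralog_pair(2000, 0.02, seed=13)
        psvs = pair.psv_positions
        rng = np.random.default_rng(99)

        def call(b):
            allele = build_allele(pair, [NahrDeletion(int(b))])
            seq = realize_sequence(allele, pair)[0]
            prof = psv_profile(Contig("c", seq, 0, 1), pair)
            switches, _ = detect_switches(prof, min_run=1)
            (bp,), _ = classify_events(switches, prof, min_tract_psvs=1)
            return bp.interval, dict(prof.states)

        gaps = np.searchsorted(psvs, np.arange(2, 2000))
        for _ in range(100):
            b1 = int(rng.integers(psvs[2], psvs[-3]))
            same = bool(rng.random() < 0.5)
            if same:
                b2 = b1
            else:
                b2 = int(rng.integers(psvs[2], psvs[-3]))
                if gaps[b2 - 2] == gaps[b1 - 2]:
                    continue  # same inter-PSV gap: indistinguishable, skip
            iv1, f1 = call(b1)
            iv2, f2 = call(b2)
            expected = "consistent_IBD" if same else "distinct"
            assert compare_alleles(iv1, f1, iv2, f2) == expected


class TestDivergenceSeparation:
    def test_identical_sequences_not_separable(self):
        res = divergence_separation(["ACGT"] * 4, ["A", "A", "B", "B"])
        assert not res.separable
        assert np.all(res.differences == 0)

    def test_matrix_symmetric_zero_diagonal(self, rng):
        seqs = ["".join(rng.choice(list("ACGT"), size=50)) for _ in range(6)]
        res = divergence_separation(seqs, ["A"] * 3 + ["B"] * 3)
        assert np.array_equal(res.differences, res.differences.T)
        assert np.all(np.diag(res.differences) == 0)

    def test_two_paralog_groups_separate(self, rng):
        """10 A-derived and 10 B-derived units with private noise: statistic
        equals brute-force pairwise counting and exceeds 1."""
        pair = simulate_paralog_pair(1500, 0.015, seed=21)
        seqs, labels = [], []
        for label, ref in (("A", pair.seq_a), ("B", pair.seq_b)):
            for _ in range(10):
                s = list(ref)
                for pos in rng.integers(0, 1500, size=3):
                    s[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[s[pos]]
                seqs.append("".join(s))
                labels.append(label)
        res = divergence_separation(seqs, labels)
        # brute-force oracle for one entry
        i, j = 0, 15
        hand_count = sum(1 for x, y in zip(seqs[i], seqs[j]) if x != y)
        assert res.differences[i, j] == hand_count
        assert res.statistic > 1 and res.separable

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError):
            divergence_separation(["ACGT", "ACG"], ["A", "B"])


class TestBreakpointProperties:
    def test_breakpoint_interval_contains_generating_breakpoint(self):
        """100 simulated single-NAHR alleles, error-free, min_run=1: the
        called interval always brackets the generating breakpoint."""
        pair = simulate_paralog_pair(2000, 0.02, seed=5)
        psvs = pair.psv_positions
        rng = np.random.default_rng(17)
        for _ in range(100):
            b = int(rng.integers(psvs[0], psvs[-1]))
            allele = build_allele(pair, [NahrDeletion(b)])
            seq = realize_sequence(allele, pair)[0]
            prof = psv_profile(Contig("c", seq, 0, 1), pair)
            switches, _ = detect_switches(prof, min_run=1)
            bps, _ = classify_events(switches, prof, min_tract_psvs=1)
            assert len(bps) == 1
            assert bps[0].interval.start <= b <= bps[0].interval.end

    def test_adding_interior_psv_never_widens_interval(self, rng):
        positions = [100, 200, 300, 700, 800, 900]
        prof = profile_from(positions, "AAABBB")
        (sw,), _ = detect_switches(prof, min_run=2)
        base = (sw.interval.start, sw.interval.end)
        for new_pos in (350, 500, 650):
            for state in "AB":
                states = list(prof.states)
                states.append((new_pos, state))
                states.sort()
                refined = PSVProfile(states=tuple(states))
                switches, _ = detect_switches(refined, min_run=1)
                widths = [
                    s.interval.end - s.interval.start for s in switches
                ]
                assert max(widths) <= base[1] - base[0]

    def test_conversion_tract_recovery(self):
        """Generated tracts covering >= 2 PSVs are recovered: the inner call
        sits inside the true tract and the outer interval contains it."""
        pair = simulate_paralog_pair(2000, 0.02, seed=31)
        psvs = pair.psv_positions
        rng = np.random.default_rng(71)
        recovered = 0
        for _ in range(50):
            start = int(rng.integers(50, 1400))
            end = start + int(rng.integers(100, 500))
            covered = [p for p in psvs if start <= p <= end]
            allele = build_allele(
                pair, [GeneConversion(unit=0, donor="B", start=start, end=end)]
            )
            seq = realize_sequence(allele, pair)[0]
            prof = psv_profile(Contig("c", seq, 0, 1), pair)
            switches, _ = detect_switches(prof, min_run=2)
            _, convs = classify_events(switches, prof, min_tract_psvs=2)
            if len(covered) < 2:
                continue  # tract invisible to the PSV grid by construction
            flank_ok = covered[0] > psvs[1] and covered[-1] < psvs[-2]
            if not flank_ok:
                continue  # too close to the unit edge for min_run support
            assert len(convs) == 1
            conv = convs[0]
            assert start <= conv.tract.start <= conv.tract.end <= end
            assert conv.outer.start <= start and end <= conv.outer.end
            recovered += 1
        assert recovered >= 30  # the property was actually exercised
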