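"""Repeat counting, outcome classification and repair signatures."""

import re
from collections import Counter

import numpy as np
import pytest

from cagrepair.locus import RepeatLocus
from cagrepair.outcomes import (
    IndelEvent,
    classify_read,
    count_repeats,
    detect_microhomology,
    detect_staggered_ins,
    detect_templated_insertion,
    estimate_stutter,
    summarize,
)
from cagrepair.reads import align_to_amplicon, normalize_indels


def brute_longest_run(seq, motif="CAG"):
    """Independent oracle: regex enumeration of maximal tandem runs."""
    best = (0, (0, 0))
    for m in re.finditer("(?:%s)+" % motif, seq):
        units = (m.end() - m.start()) // len(motif)
        units_span = (m.start(), m.start() + units * len(motif))
        if units > best[0]:
            best = (units, units_span)
    return best


class TestCountRepeats:
    @pytest.mark.parametrize(
        "seq,units,interval",
        [
            ("TTT" + "CAG" * 41 + "GGT", 41, (3, 126)),
            ("TTTT", 0, (0, 0)),
            # the CAA interrupts the run; leftmost 2-unit run wins the tie
            ("CAGCAGCAACAGCAG", 2, (0, 6)),
        ],
    )
    def test_examples(self, seq, units, interval):
        assert count_repeats(seq) == (units, interval)

    @pytest.mark.parametrize("seed", range(5))
    def test_agrees_with_regex_oracle_on_random_sequences(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(200):
            seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 300))
            assert count_repeats(seq) == brute_longest_run(seq)

    def test_repeat_rich_random_sequences(self):
        # biased alphabet makes long accidental runs much more likely
        rng = np.random.default_rng(99)
        for _ in range(200):
            seq = "".join(rng.choice(["C", "A", "G", "CAG"], 120))
            assert count_repeats(seq) == brute_longest_run(seq)


def _aln(read, locus):
    return normalize_indels(align_to_amplicon(read, locus), locus)


class TestClassifyRead:
    def test_unedited(self, locus, guides):
        rec = classify_read(_aln(locus.amplicon, locus), locus, guides)
        assert rec.category == "UNEDITED"
        assert rec.cag_units == 41
        assert rec.net_delta == 0 and not rec.frameshift

    def test_two_unit_tract_deletion(self, locus, guides):
        s = locus.repeat_start
        read = locus.amplicon[:s] + locus.amplicon[s + 6 :]
        rec = classify_read(_aln(read, locus), locus, guides)
        assert rec.category == "DEL_CAG"
        assert rec.cag_units == 39
        assert not rec.flank_changed and not rec.frameshift

    def test_single_a_insertion_at_upstream_cut(self, locus, guides):
        cut = guides["g_upstream"].blunt_cut
        read = locus.amplicon[:cut] + "A" + locus.amplicon[cut:]
        rec = classify_read(_aln(read, locus), locus, guides)
        assert rec.category == "INS"
        assert rec.frameshift and rec.staggered_ins

    def test_whole_tract_deletion_with_flanks(self, locus, guides):
        s, e = locus.repeat_interval
        read = locus.amplicon[: s - 1] + locus.amplicon[e + 1 :]  # net -125
        rec = classify_read(_aln(read, locus), locus, guides)
        assert rec.category == "DEL"
        assert rec.frameshift and rec.flank_changed and rec.whole_tract_excised
        assert rec.net_delta == -125

    def test_category_frameshift_invariants(self, locus, guides):
        """Frameshift <=> net not divisible by 3; frameshift categories and
        in-frame categories are mutually exclusive."""
        from cagrepair.pipeline import classify_reads
        from cagrepair.simulate import OutcomeSpec, SimConfig, simulate_reads

        spec = OutcomeSpec.from_dict(
            {"WHOLE_TRACT_MH_DEL": 0.3, "STAGGERED_INS": 0.2, "COMPLEX": 0.2,
             "INS_CAG": 0.15, "STUTTER": 0.15}
        )
        reads, _ = simulate_reads(locus, guides, spec, SimConfig(n_reads=300, seed=5))
        recs, _, _ = classify_reads(reads, locus, guides)
        for r in recs:
            assert r.frameshift == (r.net_delta % 3 != 0)
            if r.category in ("INS", "DEL", "INDEL"):
                assert r.frameshift
            if r.category in ("UNEDITED", "INS_CAG", "DEL_CAG"):
                assert not r.frameshift
            if r.category == "UNEDITED":
                assert r.net_delta == 0 and r.cag_units == locus.expected_units


class TestDetectMicrohomology:
    def test_cc_junction_repeat(self):
        amp = "AAACCGGGTTTCCTTT"
        ev = IndelEvent("DEL", 5, 13, amp[5:13])
        assert detect_microhomology(ev, amp) == ("CC", 2)

    def test_unique_junction(self):
        amp = "AAAATTTTGGGGCCCC"
        ev = IndelEvent("DEL", 2, 10, amp[2:10])
        assert detect_microhomology(ev, amp) == ("", 0)

    def test_deletion_inside_repeat_run(self, locus):
        s = locus.repeat_start
        ev = IndelEvent("DEL", s + 3, s + 12, locus.amplicon[s + 3 : s + 12])
        word, k = detect_microhomology(ev, locus.amplicon)
        assert k >= 3
        assert set(word) <= set("CAG")

    @pytest.mark.parametrize("seed", range(3))
    def test_agrees_with_placement_enumeration(self, locus, seed):
        """MH length = max contiguous left/right shift over all equivalent
        deletion placements (brute-force string rebuild)."""
        rng = np.random.default_rng(seed)
        amp = locus.amplicon
        for _ in range(150):
            L = int(rng.integers(1, 20))
            s = int(rng.integers(1, len(amp) - L - 1))
            ev = IndelEvent("DEL", s, s + L, amp[s : s + L])
            edited = amp[:s] + amp[s + L :]
            left = 0
            while s - left - 1 >= 0 and amp[: s - left - 1] + amp[s + L - left - 1 :] == edited:
                left += 1
            right = 0
            while s + right + 1 + L <= len(amp) and amp[: s + right + 1] + amp[s + right + 1 + L :] == edited:
                right += 1
            expected = min(10, max(left, right))
            assert detect_microhomology(ev, amp)[1] == expected


class TestDetectTemplatedInsertion:
    def test_upstream_copy_found(self, locus):
        amp = locus.amplicon
        donor = amp[10:16]  # 6-nt word 10 nt upstream of insertion point 20
        ev = IndelEvent("INS", 20, 20, donor)
        hit = detect_templated_insertion(ev, amp)
        assert hit is not None
        assert amp[hit[0] : hit[1]] == donor

    def test_single_base_not_reported(self, locus):
        ev = IndelEvent("INS", 38, 38, "A")
        assert detect_templated_insertion(ev, locus.amplicon) is None

    def test_no_neighborhood_match(self, locus):
        # the upstream flank contains no TTTT run
        ev = IndelEvent("INS", 20, 20, "TTTTT")
        assert detect_templated_insertion(ev, locus.amplicon) is None


class TestDetectStaggeredIns:
    def test_donor_base_at_cut(self, locus, guides):
        g = guides["g_upstream"]
        ev = IndelEvent("INS", g.blunt_cut, g.blunt_cut, "A")
        assert detect_staggered_ins(ev, g, locus.amplicon)

    def test_wrong_base(self, locus, guides):
        g = guides["g_upstream"]
        ev = IndelEvent("INS", g.blunt_cut, g.blunt_cut, "T")
        assert not detect_staggered_ins(ev, g, locus.amplicon)

    def test_two_base_insertion(self, locus, guides):
        g = guides["g_upstream"]
        ev = IndelEvent("INS", g.blunt_cut, g.blunt_cut, "AA")
        assert not detect_staggered_ins(ev, g, locus.amplicon)


def _simulate_records(locus, guides, mix, n, seed, error=0.0):
    from cagrepair.pipeline import classify_reads
    from cagrepair.simulate import OutcomeSpec, SimConfig, simulate_reads

    spec = OutcomeSpec.from_dict(mix)
    reads, truth = simulate_reads(
        locus, guides, spec, SimConfig(n_reads=n, seed=seed, sub_error_rate=error)
    )
    recs, _, _ = classify_reads(reads, locus, guides)
    return recs, truth


class TestEstimateStutter:
    def test_pure_unedited_is_point_mass(self, locus, guides):
        recs, _ = _simulate_records(locus, guides, {"UNEDITED": 1.0}, 200, 0)
        assert estimate_stutter(recs) == {0: 1.0}

    def test_slip_rate_recovered(self, locus, guides):
        recs, _ = _simulate_records(locus, guides, {"STUTTER": 1.0}, 20_000, 1)
        dist = estimate_stutter(recs)
        p_slip = 1.0 - dist.get(0, 0.0)
        sigma = np.sqrt(0.1 * 0.9 / 20_000)
        assert abs(p_slip - 0.1) < 3 * sigma

    def test_flank_only_control_errors(self, locus, guides):
        recs, _ = _simulate_records(locus, guides, {"STAGGERED_INS": 1.0}, 50, 2)
        with pytest.raises(ValueError, match="no usable reads"):
            estimate_stutter(recs)

    def test_empty_control_errors(self):
        with pytest.raises(ValueError, match="empty control"):
            estimate_stutter([])


class TestSummarize:
    def test_pure_unedited(self, locus, guides):
        recs, _ = _simulate_records(locus, guides, {"UNEDITED": 1.0}, 50, 0)
        s = summarize(recs, locus)
        assert s.category_fractions["UNEDITED"] == 1.0
        assert s.length_histogram == {(41, False): 1.0}

    def test_fractions_sum_to_one(self, locus, guides):
        mix = {"UNEDITED": 0.2, "WHOLE_TRACT_MH_DEL": 0.3, "STAGGERED_INS": 0.2,
               "INFRAME_DEL_CAG": 0.2, "COMPLEX": 0.1}
        recs, _ = _simulate_records(locus, guides, mix, 2000, 3)
        s = summarize(recs, locus)
        assert sum(s.category_fractions.values()) == pytest.approx(1.0, abs=1e-9)
        assert sum(s.length_histogram.values()) == pytest.approx(1.0, abs=1e-9)
        # frameshift fraction agrees when computed from categories vs net_delta
        fs_cat = sum(
            f for c, f in s.category_fractions.items() if c in ("INS", "DEL", "INDEL")
        )
        fs_net = sum(r.net_delta % 3 != 0 for r in recs) / len(recs)
        assert fs_cat == pytest.approx(fs_net, abs=1e-12)

    def test_flank_fraction_uses_edited_denominator(self, locus, guides):
        mix = {"UNEDITED": 0.5, "FLANK_DEL": 0.5}
        recs, _ = _simulate_records(locus, guides, mix, 1000, 4)
        s = summarize(recs, locus)
        # every edited read changes the flank here, unedited reads dilute
        # the all-reads fraction but not the edited-reads fraction
        assert s.flank_fraction == 1.0

    def test_stutter_self_deconvolution(self, locus, guides):
        recs, _ = _simulate_records(locus, guides, {"STUTTER": 1.0}, 5000, 5)
        s = summarize(recs, locus, control_records=recs)
        corrected_nonzero = s.stutter_corrected["DEL_CAG"] + s.stutter_corrected["INS_CAG"]
        assert corrected_nonzero == pytest.approx(0.0, abs=1e-9)

    def test_top_variant_is_dominant_template(self, locus, guides):
        mix = {"UNEDITED": 0.8, "STAGGERED_INS": 0.2}
        recs, _ = _simulate_records(locus, guides, mix, 500, 6)
        s = summarize(recs, locus)
        sig, frac = s.top_variants[0]
        assert sig == (0, ())  # the unedited signature dominates
        assert frac > 0.5
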