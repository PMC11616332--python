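"""Synthetic-data generators: determinism, truth labels, stated laws."""

from collections import Counter

import numpy as np
import pandas as pd
import pytest

from cagrepair.pipeline import classify_reads
from cagrepair.qpcr import resection_table
from cagrepair.simulate import (
    SIM_CLASSES,
    OutcomeSpec,
    SimConfig,
    sample_stutter,
    simulate_ce_peaks,
    simulate_lfq,
    simulate_reads,
    simulate_resection_cq,
)


class TestOutcomeSpec:
    def test_probabilities_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            OutcomeSpec.from_dict({"UNEDITED": 0.5, "STUTTER": 0.4})

    def test_unknown_class_rejected(self):
        with pytest.raises(ValueError, match="unknown outcome class"):
            OutcomeSpec.from_dict({"NOT_A_CLASS": 1.0})


class TestSimulateReads:
    def test_pure_unedited_reads_equal_amplicon(self, locus, guides):
        spec = OutcomeSpec.from_dict({"UNEDITED": 1.0})
        reads, truth = simulate_reads(locus, guides, spec, SimConfig(n_reads=20, seed=0))
        assert all(r.seq == locus.amplicon for r in reads)
        assert (truth["category"] == "UNEDITED").all()

    def test_staggered_reads_carry_single_donor_base(self, locus, guides):
        g = guides["g_upstream"]
        spec = OutcomeSpec.from_dict({"STAGGERED_INS": 1.0})
        reads, _ = simulate_reads(locus, guides, spec, SimConfig(n_reads=20, seed=0))
        cut, donor = g.blunt_cut, locus.amplicon[g.staggered_donor]
        expected = locus.amplicon[:cut] + donor + locus.amplicon[cut:]
        assert donor == "A"
        assert all(r.seq == expected for r in reads)

    def test_mixture_counts_within_binomial_bounds(self, locus, guides):
        spec = OutcomeSpec.from_dict({"UNEDITED": 0.5, "WHOLE_TRACT_MH_DEL": 0.5})
        _, truth = simulate_reads(locus, guides, spec, SimConfig(n_reads=20_000, seed=7))
        n_un = (truth["class"] == "UNEDITED").sum()
        sigma = np.sqrt(20_000 * 0.25)
        assert abs(n_un - 10_000) < 3 * sigma

    def test_seed_determinism_byte_identical(self, locus, guides, tmp_path):
        spec = OutcomeSpec.from_dict({"UNEDITED": 0.4, "WHOLE_TRACT_MH_DEL": 0.6})
        cfg = SimConfig(n_reads=100, seed=42, sub_error_rate=0.01)
        for d in ("a", "b"):
            simulate_reads(locus, guides, spec, cfg, out_dir=tmp_path / d)
        assert (tmp_path / "a/sim.fastq").read_bytes() == (tmp_path / "b/sim.fastq").read_bytes()
        assert (tmp_path / "a/sim_truth.tsv").read_bytes() == (tmp_path / "b/sim_truth.tsv").read_bytes()

    def test_guide_required_error(self, locus):
        spec = OutcomeSpec.from_dict({"STAGGERED_INS": 1.0})
        with pytest.raises(ValueError, match="guide required"):
            simulate_reads(locus, {}, spec, SimConfig(n_reads=5, seed=0))

    @pytest.mark.parametrize("cls", SIM_CLASSES)
    def test_generator_classifier_closure(self, locus, guides, cls):
        """At zero error, classification recovers each class's intended
        category and signature flags for every read."""
        spec = OutcomeSpec.from_dict({cls: 1.0})
        reads, truth = simulate_reads(locus, guides, spec, SimConfig(n_reads=40, seed=9))
        recs, qc, _ = classify_reads(reads, locus, guides)
        assert qc["rejected"] == 0
        for rec, t in zip(recs, truth.itertuples()):
            assert rec.category == t.category
            assert rec.cag_units == t.cag_units
            assert rec.net_delta == t.net_delta
            assert rec.flank_changed == bool(t.flank_changed)
            assert rec.whole_tract_excised == bool(t.whole_tract_excised)
            assert rec.staggered_ins == bool(t.staggered_ins)

    def test_paired_layout_merges_back_to_template(self, locus, guides):
        from cagrepair.reads import merge_pair

        spec = OutcomeSpec.from_dict({"UNEDITED": 0.5, "INFRAME_DEL_CAG": 0.5})
        pairs, truth = simulate_reads(
            locus, guides, spec,
            SimConfig(n_reads=50, seed=3, layout="paired"),
        )
        for (r1, r2), t in zip(pairs, truth.itertuples()):
            merged = merge_pair(r1, r2)
            assert merged is not None
            assert len(merged.seq) == len(locus.amplicon) + t.net_delta


class TestSampleStutter:
    def test_no_slip_returns_units(self):
        rng = np.random.default_rng(0)
        assert all(sample_stutter(41, 0.0, rng) == 41 for _ in range(100))

    def test_zero_units_clamped(self):
        rng = np.random.default_rng(0)
        assert all(sample_stutter(0, 0.4, rng) == 0 for _ in range(100))

    def test_monte_carlo_matches_stated_law(self):
        rng = np.random.default_rng(1)
        draws = np.array([sample_stutter(41, 0.1, rng) for _ in range(100_000)])
        delta = draws - 41
        p_slip = np.mean(delta != 0)
        sigma = np.sqrt(0.1 * 0.9 / 100_000)
        assert abs(p_slip - 0.1) < 3 * sigma
        assert delta.mean() < 0  # contraction-biased


class TestSimulateResectionCq:
    def test_full_resection_gives_zero_delta_cq(self):
        truth = pd.DataFrame([{"site": "D", "timepoint_h": 6, "ssdna_pct": 100.0}])
        cq = simulate_resection_cq(truth, noise_sd=0.0)
        by_cond = cq.groupby("condition")["cq"].mean()
        assert by_cond["digested"] == pytest.approx(by_cond["mock"], abs=1e-12)

    def test_two_thirds_gives_delta_cq_one(self):
        truth = pd.DataFrame([{"site": "D", "timepoint_h": 6, "ssdna_pct": 200 / 3}])
        cq = simulate_resection_cq(truth, noise_sd=0.0)
        by_cond = cq.groupby("condition")["cq"].mean()
        assert by_cond["digested"] - by_cond["mock"] == pytest.approx(1.0, abs=1e-12)

    def test_round_trip_exact_at_zero_noise(self):
        truth = pd.DataFrame(
            [
                {"site": s, "timepoint_h": t, "ssdna_pct": p}
                for s, t, p in [("A", 1, 3.5), ("D", 6, 35.0), ("E", 24, 80.0)]
            ]
        )
        cq = simulate_resection_cq(truth, noise_sd=0.0, n_bio=3)
        table = resection_table(cq)
        merged = table.merge(truth, on=["site", "timepoint_h"])
        assert np.allclose(merged["ssdna_mean"], merged["ssdna_pct"], atol=1e-9)

    def test_invalid_percentage(self):
        truth = pd.DataFrame([{"site": "A", "timepoint_h": 1, "ssdna_pct": 0.0}])
        with pytest.raises(ValueError):
            simulate_resection_cq(truth)


class TestSimulateLfq:
    def test_zero_effect_has_no_shifted_truth(self):
        _, _, truth = simulate_lfq(100, 0, 0.0, seed=0)
        assert not truth.shifted.any()

    def test_mnar_missingness_decreases_with_intensity(self):
        mat, _, _ = simulate_lfq(2000, 0, 0.0, missing_mechanism="MNAR", seed=1)
        # decile by underlying intensity is unobservable for missing values;
        # use protein-mean intensity deciles instead
        prot_mean = np.log10(mat).mean(axis=1, skipna=True).values
        deciles = pd.qcut(prot_mean, 10, labels=False)
        rates = [
            np.isnan(mat.values[deciles == d]).mean() for d in range(10)
        ]
        assert all(a > b for a, b in zip(rates, rates[1:]))

    def test_invalid_mechanism(self):
        with pytest.raises(ValueError):
            simulate_lfq(10, 0, 0.0, missing_mechanism="MCAR")


class TestSimulateCePeaks:
    def test_single_product_single_peak(self):
        df = simulate_ce_peaks({242.0: 1.0})
        assert len(df) == 1 and df["size_bp"].iloc[0] == 242.0

    def test_area_ratio_follows_fractions(self):
        df = simulate_ce_peaks({120.0: 0.4, 242.0: 0.6})
        a = df.set_index("size_bp")["area_bp"]
        assert a[120.0] / a[242.0] == pytest.approx(2 / 3)

    def test_noise_peaks_removed_by_height_filter(self):
        from cagrepair.ce import filter_peaks, percent_shortened

        clean = simulate_ce_peaks({120.0: 0.4, 242.0: 0.6})
        noisy = simulate_ce_peaks({120.0: 0.4, 242.0: 0.6}, n_noise_peaks=5, seed=2)
        assert len(noisy) == 7
        p_clean = percent_shortened(filter_peaks(clean))
        p_noisy = percent_shortened(filter_peaks(noisy))
        assert p_noisy == pytest.approx(p_clean)

    def test_fractions_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            simulate_ce_peaks({120.0: 0.5, 242.0: 0.6})
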