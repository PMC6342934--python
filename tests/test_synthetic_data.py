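"""Generator behaviour: determinism, conservation, truth consistency."""

import numpy as np
import pytest
from scipy import stats

from pamscreen import (
    AmpliconSimConfig,
    GelSimConfig,
    LibrarySimConfig,
    NucleasePamModel,
    count_pams,
    default_amplicon_reference,
    make_donor,
    simulate_amplicon_reads,
    simulate_gel_lanes,
    simulate_pam_library,
    validate_donor,
)


class TestNucleasePamModel:
    def test_activity_is_product_of_weights(self):
        model = NucleasePamModel.from_iupac("NNNNTTTN")
        assert model.activity("ACGTTTTA") == 1.0
        assert model.activity("ACGTTTAA") == 0.0

    def test_all_ones_gives_unit_activity(self):
        model = NucleasePamModel(weights=np.ones((8, 4)))
        assert model.activity("ACGTACGT") == 1.0

    def test_partial_activity_multiplies(self):
        model = NucleasePamModel.from_iupac("TT", off_target_activity=0.5)
        assert model.activity("TT") == 1.0
        assert model.activity("TA") == 0.5
        assert model.activity("AA") == 0.25

    def test_invalid_weights_rejected(self):
        with pytest.raises(ValueError):
            NucleasePamModel(weights=np.full((8, 4), 1.5))


class TestPamLibrary:
    def test_no_selection_leaves_sample_and_control_homogeneous(self):
        """With zero activity, sample and control base compositions differ
        only by sampling noise: the pooled per-position chi-square
        homogeneity statistic is not rejected at alpha=0.01."""
        model = NucleasePamModel(weights=np.zeros((8, 4)), depletion_strength=1.0)
        cfg = LibrarySimConfig(
            n_plasmids=10_000, reads_per_sample=10_000, seq_error_rate=0.0, seed=21
        )
        sample, control, truth = simulate_pam_library(model, cfg)
        assert truth.records["survived"].all()

        def base_matrix(reads):
            table = count_pams(reads, tol=0, k=8)
            mat = np.array([list(p) for p in table.counts])
            counts = np.array(list(table.counts.values()))
            return np.array(
                [[counts[mat[:, pos] == b].sum() for b in "ACGT"] for pos in range(8)]
            )

        s_counts = base_matrix(sample)
        c_counts = base_matrix(control)
        total_stat, total_df = 0.0, 0
        for pos in range(8):
            stat, _, df, _ = stats.chi2_contingency([s_counts[pos], c_counts[pos]])
            total_stat += stat
            total_df += df
        pvalue = stats.chi2.sf(total_stat, total_df)
        assert pvalue > 0.01

    def test_deterministic_elimination_removes_all_active(self):
        model = NucleasePamModel.from_iupac("NNNNTTTN", depletion_strength=1.0)
        cfg = LibrarySimConfig(
            n_plasmids=20_000, reads_per_sample=5_000, seq_error_rate=0.0, seed=2
        )
        sample, control, truth = simulate_pam_library(model, cfg)
        table = count_pams(sample, tol=0, k=8)
        assert table.valid_reads == 5_000
        assert all(p[4:7] != "TTT" for p in table.counts)
        # while the control keeps active PAMs
        ctrl = count_pams(control, tol=0, k=8)
        assert any(p[4:7] == "TTT" for p in ctrl.counts)

    def test_seed_determinism_byte_identical(self):
        model = NucleasePamModel.from_iupac("NNNNTTTN", depletion_strength=0.5)
        cfg = LibrarySimConfig(
            n_plasmids=100, reads_per_sample=100, seq_error_rate=0.0, seed=9
        )
        run1 = simulate_pam_library(model, cfg)
        run2 = simulate_pam_library(model, cfg)
        assert [r.seq for r in run1[0]] == [r.seq for r in run2[0]]
        assert [r.seq for r in run1[1]] == [r.seq for r in run2[1]]
        assert run1[2].records.equals(run2[2].records)

    def test_truth_record_conservation(self):
        model = NucleasePamModel.null()
        cfg = LibrarySimConfig(n_plasmids=777, reads_per_sample=100, seed=1)
        _, _, truth = simulate_pam_library(model, cfg)
        assert len(truth) == 777

    def test_read_layout(self):
        model = NucleasePamModel.null()
        cfg = LibrarySimConfig(
            n_plasmids=50, reads_per_sample=10, seq_error_rate=0.0, seed=4
        )
        sample, _, truth = simulate_pam_library(model, cfg)
        pams = set(truth.records["pam"])
        for read in sample:
            assert read.seq.startswith(cfg.upstream_pad)
            assert read.seq.endswith(cfg.downstream_pad)
            pam = read.seq[len(cfg.upstream_pad) : len(cfg.upstream_pad) + 8]
            assert pam in pams
            assert cfg.anchor in read.seq

    def test_model_width_mismatch_rejected(self):
        model = NucleasePamModel.from_iupac("TTTT")
        with pytest.raises(ValueError):
            simulate_pam_library(model, LibrarySimConfig(random_len=8, n_plasmids=10))


class TestAmpliconSim:
    def test_null_rates_reproduce_reference(self, amplicon_ref):
        cfg = AmpliconSimConfig(
            reference=amplicon_ref, indel_rate=0.0, hdr_rate=0.0,
            seq_error_rate=0.0, n_reads=50, seed=5,
        )
        reads, truth = simulate_amplicon_reads(cfg)
        assert all(r.seq == amplicon_ref.sequence for r in reads)
        assert (truth.records["outcome"] == "WT").all()

    def test_forced_deletion_length(self, amplicon_ref):
        cfg = AmpliconSimConfig(
            reference=amplicon_ref, indel_rate=1.0,
            indel_length_distribution={-7: 1.0},
            seq_error_rate=0.0, n_reads=50, seed=5,
        )
        reads, truth = simulate_amplicon_reads(cfg)
        wt = len(amplicon_ref.sequence)
        assert all(len(r.seq) == wt - 7 for r in reads)
        assert (truth.records["net_indel_length"] == -7).all()

    def test_indel_fraction_within_binomial_bound(self, amplicon_ref):
        cfg = AmpliconSimConfig(
            reference=amplicon_ref, indel_rate=0.3, n_reads=2000, seed=12
        )
        _, truth = simulate_amplicon_reads(cfg)
        frac = (truth.records["outcome"] == "INDEL").mean()
        sd = np.sqrt(0.3 * 0.7 / 2000)
        assert abs(frac - 0.3) <= 3 * sd

    def test_truth_conservation(self, amplicon_ref):
        cfg = AmpliconSimConfig(reference=amplicon_ref, n_reads=123, seed=0)
        reads, truth = simulate_amplicon_reads(cfg)
        assert len(reads) == len(truth) == 123

    def test_rate_validation(self, amplicon_ref):
        with pytest.raises(ValueError):
            AmpliconSimConfig(reference=amplicon_ref, indel_rate=0.7, hdr_rate=0.5)


class TestDonor:
    def test_default_donor_is_120nt(self, amplicon_ref):
        donor = make_donor(amplicon_ref)
        assert len(donor) == 120
        validate_donor(amplicon_ref, donor)

    def test_donor_carries_tg_to_ca(self, amplicon_ref):
        donor = make_donor(amplicon_ref)
        edited = amplicon_ref.edited_sequence()
        assert donor in edited
        assert donor not in amplicon_ref.sequence  # edits present

    def test_inconsistent_donor_rejected(self, amplicon_ref):
        donor = make_donor(amplicon_ref)
        bad = "A" + donor[1:] if donor[0] != "A" else "C" + donor[1:]
        with pytest.raises(ValueError):
            validate_donor(amplicon_ref, bad)

    def test_hdr_window_is_36nt(self, amplicon_ref):
        assert len(amplicon_ref.hdr_window) == 36


class TestGelSim:
    def test_no_cutting_single_band(self):
        lane, truth = simulate_gel_lanes(GelSimConfig(0.0, 0.0, total_signal=100.0))
        assert (lane.a, lane.b, lane.c) == (100.0, 0.0, 0.0)
        assert truth.records.loc[0, "expected_percent"] == 0.0

    def test_ten_percent_cutting_splits_mass(self):
        lane, _ = simulate_gel_lanes(GelSimConfig(0.1, 0.1, total_signal=100.0))
        assert lane.a == pytest.approx(81.0)
        assert lane.b + lane.c == pytest.approx(19.0)

    def test_complete_cutting_empties_uncut_band(self):
        lane, _ = simulate_gel_lanes(GelSimConfig(1.0, 1.0))
        assert lane.a == 0.0

    def test_noise_is_truncated_at_zero(self):
        for seed in range(10):
            lane, _ = simulate_gel_lanes(
                GelSimConfig(0.05, 0.05, total_signal=10.0, noise_sd=5.0, seed=seed)
            )
            assert min(lane.a, lane.b, lane.c) >= 0.0
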