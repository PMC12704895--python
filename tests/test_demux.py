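"""Demultiplexing: extraction, whitelist matching, frameshift recovery,
per-base composition diagnostics."""

import numpy as np
import pytest
from scipy import stats

import splitpool as sp
from splitpool import demux, synth
from splitpool.scheme import (
    FRAMESHIFT_DELETION_LEN,
    RoundSpec,
    WellPath,
    random_whitelist,
    truncation_window,
)


def _construct(scheme, path=(1, 2, 3), umi="ACGTACGT", insert=None):
    insert = insert or "ACGT" * 30
    return sp.assemble_construct(scheme, WellPath(path), umi, insert)


class TestExtractSegments:
    def test_round_trip(self, scheme):
        layout = sp.read_layout(scheme)
        read = _construct(scheme)[: layout.span]
        segs = sp.extract_segments(read, layout)
        assert segs["umi"] == "ACGTACGT"
        assert segs["constant"] == scheme.constant_prefix
        for rs, well in zip(scheme.rounds, (1, 2, 3)):
            assert segs[f"bc_{rs.round_index}"] == rs.whitelist[well]

    def test_short_read_signals_truncation(self, scheme):
        layout = sp.read_layout(scheme)
        read = _construct(scheme)[: layout.span - 8]
        with pytest.raises(demux.TruncatedReadError):
            sp.extract_segments(read, layout)

    def test_zero_length_umi_segment(self):
        rounds = tuple(
            RoundSpec(round_index=r, whitelist=("AAAA", "CCCC"), linker="TTTT")
            for r in range(2)
        )
        scheme = sp.BarcodeScheme(rounds=rounds, umi_len=0, constant_prefix="GG")
        layout = sp.read_layout(scheme)
        segs = sp.extract_segments("GG" + "AAAA" + "TTTT" + "CCCC", layout)
        assert "umi" not in segs


class TestMatchWell:
    WL = ("AAAA", "CCCC", "GGGG", "TTTT", "ACGT")

    def test_exact_member(self):
        assert sp.match_well("GGGG", self.WL, max_hamming=0) == 2

    def test_one_mismatch_rejected_at_zero(self):
        assert sp.match_well("GGGA", self.WL, max_hamming=0) is None

    def test_one_mismatch_corrected_at_one(self):
        assert sp.match_well("GGGA", self.WL, max_hamming=1) == 2

    def test_ambiguity_rejected(self):
        # AAGT is distance 1 from both ACGT... construct a true tie:
        # "ACGA" is 1 from ACGT and 3 from AAAA; use ("AAAA","AATT") with "AATA"
        wl = ("AAAA", "AATT")
        seg = "AATA"  # distance 1 from both — brute-force verified
        assert all(sum(a != b for a, b in zip(seg, w)) == 1 for w in wl)
        assert sp.match_well(seg, wl, max_hamming=1) is None

    def test_single_errors_always_corrected_at_min_distance_three(self):
        # brute force over every barcode and every single substitution
        wl = random_whitelist(8, 6, seed=5, min_hamming=3)
        for idx, bc in enumerate(wl):
            for pos in range(6):
                for base in "ACGT":
                    if base == bc[pos]:
                        continue
                    mutant = bc[:pos] + base + bc[pos + 1 :]
                    assert sp.match_well(mutant, wl, max_hamming=1) == idx


class TestDemuxRead:
    def test_in_frame_read_ok(self, scheme):
        layout = sp.read_layout(scheme)
        read = _construct(scheme, path=(5, 6, 7))[: layout.span]
        call = sp.demux_read(read, scheme)
        assert call.status == "ok"
        assert call.wells == (5, 6, 7)
        assert call.shift_applied == 0
        assert call.umi == "ACGTACGT"

    def test_linker_deletion_recovered(self, scheme):
        layout = sp.read_layout(scheme)
        win_start, _ = truncation_window(scheme)
        full = _construct(scheme, path=(8, 9, 10))
        shifted = full[:win_start] + full[win_start + FRAMESHIFT_DELETION_LEN :]
        call = sp.demux_read(shifted[: layout.span], scheme)
        assert call.status == "frameshift_recovered"
        assert call.wells == (8, 9, 10)
        assert call.shift_applied == 8

    def test_seven_nt_deletion_unassigned(self):
        # min-distance-3 whitelists so neither frame can match by accident
        rounds = tuple(
            RoundSpec(round_index=r, whitelist=random_whitelist(6, 6, seed=30 + r, min_hamming=3))
            for r in range(3)
        )
        scheme = sp.BarcodeScheme(rounds=rounds)
        layout = sp.read_layout(scheme)
        win_start, _ = truncation_window(scheme)
        full = _construct(scheme, path=(1, 2, 3))
        seven = full[:win_start] + full[win_start + 7 :]
        call = sp.demux_read(seven[: layout.span], scheme)
        assert call.status == "unassigned"
        assert not call.assigned

    def test_order_independence(self, scheme, transcriptome):
        cells = synth.draw_cells(10, 0.5, scheme, seed=40, genes=transcriptome,
                                 reads_per_cell_mean=20)
        sim = synth.simulate_reads(cells, transcriptome, scheme,
                                   frameshift_rate=0.2, seed=41)
        fwd, _ = demux.demux_reads(sim.read2, scheme)
        rev, _ = demux.demux_reads(sim.read2[::-1], scheme)
        fwd = fwd.sort_values("read_id").reset_index(drop=True)
        rev = rev.sort_values("read_id").reset_index(drop=True)
        assert fwd.equals(rev)

    def test_rejects_streamed_not_dropped(self, scheme):
        reads = [("good", _construct(scheme)[:64]), ("bad", "N" * 64)]
        calls, rejects = demux.demux_reads(reads, scheme)
        assert len(calls) == 2
        assert [rid for rid, _ in rejects] == ["bad"]


class TestComposition:
    def test_identical_reads_are_one_hot(self):
        prof = sp.per_base_composition(["ACGT"] * 10)
        assert prof.matrix.shape == (4, 5)
        expected = np.zeros((4, 5))
        for i, b in enumerate("ACGT"):
            expected[i, "ACGTN".index(b)] = 1.0
        np.testing.assert_allclose(prof.matrix, expected)

    def test_rows_sum_to_one_with_ragged_lengths(self):
        rng = np.random.default_rng(0)
        reads = [
            "".join("ACGT"[i] for i in rng.integers(0, 4, rng.integers(5, 30)))
            for _ in range(200)
        ]
        prof = sp.per_base_composition(reads)
        np.testing.assert_allclose(prof.matrix.sum(axis=1), 1.0, atol=1e-9)

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            sp.per_base_composition([])

    def test_fifty_fifty_mixture_is_average_of_pure_frames(self, scheme, transcriptome):
        cells = synth.draw_cells(20, 0.5, scheme, seed=50, genes=transcriptome,
                                 reads_per_cell_mean=25)
        in_frame = synth.simulate_reads(cells, transcriptome, scheme,
                                        frameshift_rate=0.0, seed=51)
        shifted = synth.simulate_reads(cells, transcriptome, scheme,
                                       frameshift_rate=1.0, seed=51)
        n = min(len(in_frame.read2), len(shifted.read2))
        pure_a = sp.per_base_composition(s for _i, s in in_frame.read2[:n])
        pure_b = sp.per_base_composition(s for _i, s in shifted.read2[:n])
        mix = sp.per_base_composition(
            [s for _i, s in in_frame.read2[:n]] + [s for _i, s in shifted.read2[:n]]
        )
        np.testing.assert_allclose(mix.matrix, (pure_a.matrix + pure_b.matrix) / 2,
                                   atol=1e-12)


class TestFrameshiftReport:
    def test_no_frameshift_means_zero_shifted(self, clean_sim, scheme):
        rep = sp.frameshift_report(clean_sim.read2, scheme)
        assert rep.n_shifted == 0
        assert rep.n_in_frame == rep.n_total
        assert rep.assigned_fraction == 1.0

    def test_counts_partition_total(self, scheme, transcriptome):
        cells = synth.draw_cells(30, 0.5, scheme, seed=60, genes=transcriptome,
                                 reads_per_cell_mean=30)
        sim = synth.simulate_reads(cells, transcriptome, scheme,
                                   frameshift_rate=0.3, error_rate=0.02, seed=61)
        rep = sp.frameshift_report(sim.read2, scheme)
        assert rep.n_in_frame + rep.n_shifted + rep.n_unassigned == rep.n_total

    def test_shifted_fraction_estimates_rate(self, scheme, transcriptome):
        # ~10,000 reads, frameshift rate 0.1, no errors
        cells = synth.draw_cells(100, 0.5, scheme, seed=62, genes=transcriptome,
                                 reads_per_cell_mean=100)
        sim = synth.simulate_reads(cells, transcriptome, scheme,
                                   frameshift_rate=0.1, seed=63)
        rep = sp.frameshift_report(sim.read2, scheme)
        assert rep.assigned_fraction == 1.0
        lo, hi = stats.binom.interval(0.99, rep.n_total, 0.1)
        assert lo <= rep.n_shifted <= hi
        # tallies agree with the generator's truth exactly
        assert rep.n_shifted == int(sim.truth.reads["frameshifted"].sum())
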