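"""Reduced-alphabet alignment, pair merging and read-level methylation calls."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from widcfoc.align_call import (
    AlignmentResult,
    align_fragment,
    align_fragment_bruteforce,
    call_read_methylation,
    compute_mapping_rate,
    merge_pair,
    process_sample,
    reduce_alphabet,
    summarize_region,
)
from widcfoc.simulate import ReadSimParams, revcomp, simulate_reads

dna = st.text(alphabet="ACGTN", min_size=0, max_size=60)


class TestReduceAlphabet:
    def test_c2t(self):
        assert reduce_alphabet("ACGT", "C2T") == "ATGT"

    def test_g2a(self):
        assert reduce_alphabet("ACGT", "G2A") == "ACAT"

    @settings(max_examples=50, deadline=None)
    @given(dna)
    def test_idempotent(self, seq):
        once = reduce_alphabet(seq, "C2T")
        assert reduce_alphabet(once, "C2T") == once

    def test_unknown_mode(self):
        with pytest.raises(ValueError):
            reduce_alphabet("ACGT", "X2Y")


class TestMergePair:
    def test_identical_fully_overlapping_mates(self):
        frag = "ACGTACGTACGTACGT"
        merged, overlapped = merge_pair(frag, revcomp(frag), min_overlap=4)
        assert overlapped and merged == frag

    # aperiodic fragment so no shorter overlap can outscore the true one
    FRAG = "ATTGCCAGGATCACGAGTTC"

    def test_quality_tie_disagreement_becomes_n(self):
        r2 = list(self.FRAG)
        r2[5] = "A" if self.FRAG[5] != "A" else "G"
        merged, overlapped = merge_pair(
            self.FRAG, revcomp("".join(r2)), min_overlap=4
        )
        assert overlapped
        assert merged[5] == "N"
        assert merged[:5] + merged[6:] == self.FRAG[:5] + self.FRAG[6:]

    def test_higher_quality_base_wins(self):
        r2 = list(self.FRAG)
        r2[5] = "A" if self.FRAG[5] != "A" else "G"
        merged, _ = merge_pair(
            self.FRAG, revcomp("".join(r2)),
            r1_qual="I" * 20, r2_qual="#" * 20, min_overlap=4,
        )
        assert merged == self.FRAG  # forward mate had the higher quality

    def test_simulator_amplicon_round_trip(self, panel_short):
        """150 bp amplicon with 150 bp mates merges to the amplicon itself."""
        params = ReadSimParams(
            depth_per_region=5, tumor_fraction=1.0, conversion_rate=1.0,
            overconversion_rate=0.0, seq_error_rate=0.0, seed=1,
        )
        region = panel_short[0]
        # fully methylated + perfect conversion: only non-CpG Cs become T
        expected = "".join(
            "T" if b == "C" and i not in region.cpg_positions else b
            for i, b in enumerate(region.ref_seq)
        )
        pairs, _ = simulate_reads("S", panel_short, params)
        for p in pairs:
            merged, overlapped = merge_pair(p.r1_seq, p.r2_seq)
            assert overlapped and len(merged) == 150
            assert merged == expected

    def test_empty_mate_rejected(self):
        with pytest.raises(ValueError):
            merge_pair("", "ACGT")


class TestAlignFragment:
    def test_converted_reference_copy_maps_at_origin(self, panel3):
        region = panel3[0]
        fragment = region.ref_seq.replace("C", "T")  # all Cs converted
        aln = align_fragment(fragment, panel3)
        assert aln.mapped
        assert aln.region_id == region.region_id
        assert aln.offset == 0
        assert aln.mismatches == 0

    def test_random_fragment_unmapped(self, panel3):
        rng = np.random.default_rng(5)
        for _ in range(20):
            frag = "".join("ACGT"[i] for i in rng.integers(0, 4, 150))
            assert not align_fragment(frag, panel3).mapped

    def test_matches_bruteforce_oracle_on_simulated_fragments(self, panel3):
        params = ReadSimParams(depth_per_region=30, tumor_fraction=0.3, seed=6,
                               offtarget_gdna_read_fraction=0.1)
        pairs, _ = simulate_reads("S", panel3, params)
        for p in pairs:
            merged, _ = merge_pair(p.r1_seq, p.r2_seq)
            fast = align_fragment(merged, panel3, read_id=p.read_id)
            slow = align_fragment_bruteforce(merged, panel3, read_id=p.read_id)
            assert fast == slow

    def test_overlong_fragment_is_unmapped(self, panel3):
        assert not align_fragment("A" * 1000, panel3).mapped


class TestMappingRateQC:
    @staticmethod
    def _alignments(n_mapped, n_total):
        mapped = [AlignmentResult(f"r{i}", "R", 0, 0, True) for i in range(n_mapped)]
        un = [AlignmentResult(f"u{i}", None, 0, 0, False) for i in range(n_total - n_mapped)]
        return mapped + un

    def test_just_below_two_percent_fails(self):
        qc = compute_mapping_rate(self._alignments(19, 1000), 1000, "S")
        assert qc.mapping_rate == pytest.approx(0.019)
        assert not qc.passed

    def test_exactly_two_percent_passes(self):
        qc = compute_mapping_rate(self._alignments(20, 1000), 1000, "S")
        assert qc.mapping_rate == pytest.approx(0.02)
        assert qc.passed

    def test_all_mapped_passes(self):
        qc = compute_mapping_rate(self._alignments(10, 10), 10, "S")
        assert qc.mapping_rate == 1.0 and qc.passed

    def test_zero_pairs_invalid(self):
        with pytest.raises(ValueError):
            compute_mapping_rate([], 0, "S")


class TestCallReadMethylation:
    def _aligned(self, region, fragment, offset=0):
        aln = AlignmentResult("r", region.region_id, offset, 0, True)
        return call_read_methylation(aln, fragment, region)

    def test_all_cpgs_methylated(self, panel3):
        region = panel3[0]
        call = self._aligned(region, region.ref_seq)  # unconverted = all C
        assert call.cpg_states == ("methylated",) * region.n_cpgs
        assert call.fully_methylated

    def test_one_unmethylated_cpg_blocks_full_call(self, panel3):
        region = panel3[0]
        frag = list(region.ref_seq)
        frag[region.cpg_positions[2]] = "T"
        call = self._aligned(region, "".join(frag))
        assert call.cpg_states[2] == "unmethylated"
        assert not call.fully_methylated

    def test_ambiguous_base_counts_as_not_methylated(self, panel3):
        region = panel3[0]
        frag = list(region.ref_seq)
        frag[region.cpg_positions[0]] = "N"
        call = self._aligned(region, "".join(frag))
        assert call.cpg_states[0] == "ambiguous"
        assert not call.fully_methylated

    def test_partial_coverage_cannot_be_fully_methylated(self, panel3):
        region = panel3[0]
        last_cpg = region.cpg_positions[-1]
        frag = region.ref_seq[:last_cpg]  # drops the final CpG
        call = self._aligned(region, frag)
        assert call.cpg_states[-1] == "uncovered"
        assert call.partial and not call.fully_methylated

    def test_unmapped_input_is_contract_violation(self, panel3):
        aln = AlignmentResult("r", None, 0, 0, False)
        with pytest.raises(ValueError):
            call_read_methylation(aln, "ACGT", panel3[0])


class TestSummarizeRegion:
    @staticmethod
    def _calls(region, n_full, n_total):
        full = ("methylated",) * region.n_cpgs
        notf = ("unmethylated",) + ("methylated",) * (region.n_cpgs - 1)
        from widcfoc.align_call import ReadMethylationCall

        return [
            ReadMethylationCall(f"r{i}", region.region_id,
                                full if i < n_full else notf)
            for i in range(n_total)
        ]

    def test_two_percent(self, panel3):
        s = summarize_region(self._calls(panel3[0], 2, 100), "S", panel3[0].region_id)
        assert s.pct_fully_methylated == pytest.approx(2.0)

    def test_zero_of_hundred(self, panel3):
        s = summarize_region(self._calls(panel3[0], 0, 100), "S", panel3[0].region_id)
        assert s.pct_fully_methylated == 0.0
        assert not s.no_amplification

    def test_no_reads_flagged_no_amplification(self, panel3):
        s = summarize_region([], "S", panel3[0].region_id)
        assert s.no_amplification
        assert s.pct_fully_methylated is None


class TestProcessSample:
    def test_counts_partition_and_exact_truth_recovery(self, panel3, clean_params):
        """Error-free chemistry: pipeline pct equals truth fraction exactly."""
        pairs, truth = simulate_reads("S", panel3, clean_params)
        summaries, qc, alignments = process_sample("S", pairs, panel3)
        # partition: every pair mapped to exactly one region or unmapped
        assert sum(s.n_reads_mapped for s in summaries.values()) == qc.n_pairs_mapped
        assert qc.n_pairs_total == len(pairs)
        for rid, summary in summaries.items():
            region_truth = [t for t in truth if t.region_id == rid]
            truth_pct = 100 * sum(t.fully_methylated for t in region_truth) / len(
                region_truth
            )
            assert summary.pct_fully_methylated == pytest.approx(truth_pct, abs=0)

    def test_offtarget_reads_lower_mapping_rate(self, panel3):
        params = ReadSimParams(
            depth_per_region=40, offtarget_gdna_read_fraction=0.5, seed=4
        )
        pairs, _ = simulate_reads("S", panel3, params)
        _, qc, _ = process_sample("S", pairs, panel3)
        assert 0.4 < qc.mapping_rate < 0.6
        assert qc.passed
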