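"""Paralog merge and depth-table construction against independent oracles."""

import numpy as np
import pytest

import c4quant as cq
from c4quant.depth import (build_depth_table, build_depth_table_fast,
                           merge_blocks, merge_paralog_alignments)

from conftest import naive_pileup


def _write_sam(path, ref, records):
    lines = ["@HD\tVN:1.6\tSO:unsorted"]
    for name, seq in ref.sequences.items():
        lines.append(f"@SQ\tSN:{name}\tLN:{len(seq)}")
    for rec in records:
        lines.append("\t".join(str(x) for x in rec))
    path.write_text("\n".join(lines) + "\n")
    return path


def _pair(name, contig, pos1, cigar1, seq1, pos2, cigar2, seq2,
          qual="I", flag_extra=0, tags=("AS:i:100",)):
    q1 = qual * len(seq1)
    q2 = qual * len(seq2)
    r1 = [name, 99 | flag_extra, contig, pos1, 60, cigar1, "=", pos2, 500,
          seq1, q1, *tags]
    r2 = [name, 147 | flag_extra, contig, pos2, 60, cigar2, "=", pos1, -500,
          seq2, q2, *tags]
    return [r1, r2]


class TestMergeContract:
    def test_read_aligned_to_both_paralogs_counted_once(self, model, reference,
                                                        tmp_path):
        c4a = reference.sequences["C4A"]
        seq = c4a[999:1019]
        recs = _pair("frag1", "C4A", 1000, "20M", seq, 1400, "20M",
                     c4a[1399:1419])
        # secondary placement of the same fragment on C4B (identical coords
        # pre-HERV)
        for r in _pair("frag1", "C4B", 1000, "20M", seq, 1400, "20M",
                       c4a[1399:1419], flag_extra=0x100, tags=("AS:i:90",)):
            recs.append(r)
        sam = _write_sam(tmp_path / "m.sam", reference, recs)
        merged = merge_paralog_alignments(sam, reference, model)
        assert merged.stats["c4_reads"] == 2
        table = build_depth_table(merged, model)
        assert table.total[999:1019].tolist() == [1] * 20

    def test_tie_breaks_resolve_to_the_c4a_frame(self, model, reference, tmp_path):
        c4a = reference.sequences["C4A"]
        recs = _pair("f", "C4B", 1000, "20M", c4a[999:1019], 1400, "20M",
                     c4a[1399:1419])
        recs += _pair("f", "C4A", 1000, "20M", c4a[999:1019], 1400, "20M",
                      c4a[1399:1419])
        sam = _write_sam(tmp_path / "t.sam", reference, recs)
        merged = merge_paralog_alignments(sam, reference, model)
        assert all(not r.from_short for r in merged.reads)

    def test_tnxb_reads_stay_out_of_the_c4_frame(self, model, reference, tmp_path):
        tnxb = reference.sequences["TNXB"]
        recs = _pair("t1", "TNXB", 501, "20M", tnxb[500:520], 901, "20M",
                     tnxb[900:920])
        sam = _write_sam(tmp_path / "t.sam", reference, recs)
        table = build_depth_table(
            merge_paralog_alignments(sam, reference, model), model)
        assert table.c4.sum() == 0
        assert table.tnxb[:, :4].sum() == 40
        assert table.tnxb_total[500:520].tolist() == [1] * 20

    def test_unknown_contig_counted_and_skipped(self, model, reference, tmp_path):
        recs = [["x", 0, "chr6", 100, 60, "10M", "*", 0, 0, "A" * 10, "I" * 10]]
        sam = _write_sam(tmp_path / "u.sam", reference, recs)
        # pysam requires the contig in the header for parsing; add it
        text = sam.read_text().splitlines()
        text.insert(1, "@SQ\tSN:chr6\tLN:100000")
        sam.write_text("\n".join(text) + "\n")
        merged = merge_paralog_alignments(sam, reference, model)
        assert merged.stats["unknown_contig"] == 1
        assert not merged.reads

    def test_duplicate_flagged_reads_excluded(self, model, reference, tmp_path):
        c4a = reference.sequences["C4A"]
        recs = _pair("d", "C4A", 1000, "20M", c4a[999:1019], 1400, "20M",
                     c4a[1399:1419], flag_extra=0x400)
        sam = _write_sam(tmp_path / "d.sam", reference, recs)
        merged = merge_paralog_alignments(sam, reference, model)
        assert merged.stats["duplicate"] == 2
        assert not merged.reads

    def test_merging_is_idempotent(self, model, reference, standard_sam):
        merged = merge_paralog_alignments(standard_sam, reference, model)
        again = merge_paralog_alignments(merged, reference, model)
        assert again is merged

    def test_short_frame_read_crossing_the_herv_junction_is_split(
            self, model, reference, tmp_path):
        """A C4B read across the HERV junction must contribute to both
        flanks of the HERV gap in the overall frame."""
        c4b = reference.sequences["C4B"]
        j = reference.herv_start - 1  # 1-based short position of last pre-HERV base... 0-based junction
        start1 = j - 9  # 1-based: covers 10 bases before and 10 after
        seq = c4b[start1 - 1:start1 + 19]
        recs = _pair("x", "C4B", start1, "20M", seq, start1 + 300, "20M",
                     c4b[start1 + 299:start1 + 319])
        sam = _write_sam(tmp_path / "j.sam", reference, recs)
        table = build_depth_table(
            merge_paralog_alignments(sam, reference, model), model)
        h0, h1 = model.herv_span
        assert table.total[h0 - 11:h0 - 1].sum() == 10   # last 10 pre-HERV
        assert table.total[h1:h1 + 10].sum() == 10       # first 10 post-HERV
        assert table.total[h0 - 1:h1].sum() == 0         # nothing inside the gap


class TestPileupRules:
    def test_single_clean_read_gives_unit_depth(self, model, reference, tmp_path):
        c4a = reference.sequences["C4A"]
        recs = _pair("r", "C4A", 2001, "30M", c4a[2000:2030], 2401, "30M",
                     c4a[2400:2430])
        sam = _write_sam(tmp_path / "s.sam", reference, recs)
        table = build_depth_table(
            merge_paralog_alignments(sam, reference, model), model)
        for i in range(2000, 2030):
            base = c4a[i]
            counts = table.counts_at(i + 1)
            assert counts[base] == 1 and sum(counts.values()) == 1

    def test_one_base_deletion_counts_at_the_deleted_position(
            self, model, reference, tmp_path):
        c4a = reference.sequences["C4A"]
        seq = c4a[2000:2010] + c4a[2011:2021]  # skips position 2012 (1-based)
        recs = _pair("r", "C4A", 2001, "10M1D10M", seq, 2401, "20M",
                     c4a[2400:2420])
        sam = _write_sam(tmp_path / "del.sam", reference, recs)
        table = build_depth_table(
            merge_paralog_alignments(sam, reference, model), model)
        assert table.counts_at(2011)["del"] == 1
        assert table.counts_at(2012)["del"] == 0
        assert table.total[2010] == 1  # deletion still counts as spanning depth

    def test_insertion_anchors_after_the_preceding_base(self, model, reference,
                                                        tmp_path):
        c4a = reference.sequences["C4A"]
        seq = c4a[2000:2010] + "TC" + c4a[2010:2018]
        recs = _pair("r", "C4A", 2001, "10M2I8M", seq, 2401, "20M",
                     c4a[2400:2420])
        sam = _write_sam(tmp_path / "ins.sam", reference, recs)
        table = build_depth_table(
            merge_paralog_alignments(sam, reference, model), model)
        assert table.counts_at(2010)["ins"] == 1
        assert table.c4[:, 5].sum() == 1

    def test_soft_clips_and_low_quality_bases_excluded(self, model, reference,
                                                       tmp_path):
        c4a = reference.sequences["C4A"]
        seq = "ACGT" + c4a[2000:2016]
        qual = "I" * 20
        lowq = "I" * 10 + "#" * 6 + "I" * 4  # Q2 bases in the middle
        recs = [["r", 99, "C4A", 2001, 60, "4S16M", "=", 2401, 500, seq, qual],
                ["r", 147, "C4A", 2401, 60, "20M", "=", 2001, -500,
                 c4a[2400:2420], lowq]]
        sam = _write_sam(tmp_path / "sq.sam", reference, recs)
        table = build_depth_table(
            merge_paralog_alignments(sam, reference, model), model)
        assert table.total[1996:2000].sum() == 0          # soft-clip ignored
        assert table.total[2000:2016].sum() == 16
        assert table.total[2410:2416].sum() == 0          # low-quality ignored
        assert table.total[2400:2410].sum() == 10

    def test_overlapping_mates_count_once_per_position(self, model, reference,
                                                       tmp_path):
        c4a = reference.sequences["C4A"]
        # mates overlap at positions 2011-2020 (1-based)
        recs = _pair("ov", "C4A", 2001, "20M", c4a[2000:2020], 2011, "20M",
                     c4a[2010:2030])
        sam = _write_sam(tmp_path / "ov.sam", reference, recs)
        table = build_depth_table(
            merge_paralog_alignments(sam, reference, model), model)
        assert table.total[2000:2030].max() == 1

    def test_allele_sums_conserve_spanning_reads(self, model, reference,
                                                 standard_sam, standard_bundle):
        """At any position, the six-way counts sum to the number of merged
        reads spanning it (checked against the independent oracle)."""
        merged = merge_paralog_alignments(standard_sam, reference, model)
        table = build_depth_table(merged, model)
        oc4, otn = naive_pileup(standard_sam, reference, model)
        assert np.array_equal(table.total, oc4[:, :5].sum(axis=1))
        assert np.array_equal(table.tnxb_total, otn[:, :5].sum(axis=1))


class TestOracleEquivalence:
    @pytest.mark.parametrize("genotype,error", [
        ((4, 2, 2, None), 0.0),
        ((4, 2, 2, "auto"), 0.01),
        ((3, 0, 1, "auto"), 0.01),
        ((1, 1, 0, "auto"), 0.0),
        ((2, 2, 2, None), 0.02),
    ])
    def test_depth_table_equals_naive_pileup(self, model, reference, tmp_path,
                                             genotype, error):
        n, a, l, lof = genotype
        h1, h2 = cq.genotype_from_counts(n, a, l, lof=lof)
        cfg = cq.SimConfig(hap1=h1, hap2=h2, coverage=10, error_rate=error,
                           seed=n * 100 + a * 10 + l)
        bundle = cq.simulate_sample(cfg, model, reference)
        sam = tmp_path / "x.sam"
        bundle.write_sam(sam)
        table = build_depth_table(
            merge_paralog_alignments(sam, reference, model), model)
        oc4, otn = naive_pileup(sam, reference, model)
        assert np.array_equal(table.c4, oc4)
        assert np.array_equal(table.tnxb, otn)

    def test_fast_path_equals_sam_path(self, model, reference, standard_bundle,
                                       standard_sam):
        t_sam = build_depth_table(
            merge_paralog_alignments(standard_sam, reference, model), model)
        t_fast = build_depth_table_fast(
            merge_blocks(standard_bundle.blocks, reference), model)
        assert np.array_equal(t_sam.c4, t_fast.c4)
        assert np.array_equal(t_sam.tnxb, t_fast.tnxb)

    def test_zero_error_sample_has_no_spurious_alleles(self, model, reference):
        """With error rate 0, non-reference counts appear only at the
        diagnostic-site alleles of B/Ch copies and injected variants."""
        h1, h2 = cq.genotype_from_counts(2, 1, 2)
        pos, alt = 5000, "A"
        ref_base = reference.sequences["C4A"][pos - 1]
        if ref_base == "A":
            alt = "C"
        h1.copies[0].snvs = [(pos, alt)]
        cfg = cq.SimConfig(hap1=h1, hap2=h2, coverage=10, error_rate=0.0, seed=4)
        bundle = cq.simulate_sample(cfg, model, reference)
        table = build_depth_table_fast(
            merge_blocks(bundle.blocks, reference), model)
        c4a = np.frombuffer(reference.sequences["C4A"].encode(), np.uint8)
        col = {65: 0, 67: 1, 71: 2, 84: 3}
        expected_nonref = {pos - 1} | {
            model.site_absolute(s) - 1
            for s in model.isotype_sites + model.epitope_sites}
        nonref = set()
        for i in range(model.total_length):
            for code, c in col.items():
                if code != c4a[i] and table.c4[i, c] > 0:
                    nonref.add(i)
        assert nonref <= expected_nonref
        assert pos - 1 in nonref

    def test_depth_table_tsv_round_trip(self, model, standard_bundle, reference,
                                        tmp_path):
        table = build_depth_table_fast(
            merge_blocks(standard_bundle.blocks, reference), model)
        table.to_tsv(tmp_path / "d.tsv", tmp_path / "t.tsv")
        loaded = cq.DepthTable.from_tsv(tmp_path / "d.tsv", tmp_path / "t.tsv",
                                        model)
        assert np.array_equal(loaded.c4, table.c4)
        assert np.array_equal(loaded.tnxb, table.tnxb)
        frame = table.to_frame()
        assert list(frame.columns[:2]) == ["pos", "feature_coord"]
        assert frame.iloc[0]["feature_coord"] == "U5.-285"
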