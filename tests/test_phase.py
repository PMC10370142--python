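"""Read-backed phasing, recombinant detection and the E26 window analysis."""

import numpy as np
import pytest

import c4quant as cq
from c4quant.copynum import CopyNumberProfile
from c4quant.depth import merge_blocks, merge_paralog_alignments
from c4quant.model import C4Model
from c4quant.phase import (CLASSES, PhaseEvidence, call_recombinants,
                           classify_e26_extended_variants,
                           collect_phase_evidence, phasing_completeness)

from test_depth import _pair, _write_sam


def _profile(overall=4, a=2, rg=2, l=2):
    return CopyNumberProfile(overall=overall, a=a, b=overall - a, rg=rg,
                             ch=overall - rg, l=l, s=overall - l,
                             functional_a=a, functional_b=overall - a)


def _simulate_blocks(model, reference, seed, recombinant=None, coverage=30,
                     error=0.0, **kw):
    h1, h2 = cq.genotype_from_counts(4, 2, 2, recombinant=recombinant, **kw)
    cfg = cq.SimConfig(hap1=h1, hap2=h2, coverage=coverage, error_rate=error,
                       seed=seed)
    bundle = cq.simulate_sample(cfg, model, reference)
    return merge_blocks(bundle.blocks, reference)


class TestEvidenceCollection:
    def test_pair_bridging_both_groups_reads_out_directly(self, model,
                                                          reference, tmp_path):
        """R1 over the E26 isotype sites (A alleles) + R2 over the E28
        epitope sites (Ch alleles) -> one A-Ch evidence pair."""
        c4a = reference.sequences["C4A"]
        iso = model.site_absolute(model.isotype_sites[-1])  # E26.145
        epi = model.site_absolute(model.epitope_sites[0])   # E28.111
        s1 = iso - 10  # 1-based start covering E26.145
        seq1 = c4a[s1 - 1:s1 + 19]
        s2 = epi - 5
        seq2 = list(c4a[s2 - 1:s2 + 19])
        for site in model.epitope_sites:  # flip all covered epitope sites to Ch
            p = model.site_absolute(site)
            if s2 <= p < s2 + 20:
                seq2[p - s2] = site.alleles["Ch"]
        recs = _pair("pair1", "C4A", s1, "20M", seq1, s2, "20M", "".join(seq2))
        sam = _write_sam(tmp_path / "p.sam", reference, recs)
        merged = merge_paralog_alignments(sam, reference, model)
        ev = collect_phase_evidence(merged, model)
        assert len(ev) == 1
        assert (ev[0].isotype, ev[0].epitope) == ("A", "Ch")
        assert ev[0].informative

    def test_pair_covering_only_one_group_is_excluded(self, model, reference,
                                                      tmp_path):
        c4a = reference.sequences["C4A"]
        iso = model.site_absolute(model.isotype_sites[0])
        recs = _pair("only26", "C4A", iso - 5, "20M", c4a[iso - 6:iso + 14],
                     iso + 300, "20M", c4a[iso + 299:iso + 319])
        sam = _write_sam(tmp_path / "o.sam", reference, recs)
        ev = collect_phase_evidence(
            merge_paralog_alignments(sam, reference, model), model)
        assert ev == []

    def test_conflicting_sites_within_a_group_are_ambiguous(self, model,
                                                            reference,
                                                            tmp_path):
        c4a = reference.sequences["C4A"]
        sites = model.isotype_sites
        # a 10-base read covering exactly the first two isotype sites,
        # one with the A allele and one with the B allele -> tie
        s1 = model.site_absolute(sites[0]) - 1
        seq1 = list(c4a[s1 - 1:s1 + 9])
        seq1[model.site_absolute(sites[0]) - s1] = sites[0].alleles["A"]
        seq1[model.site_absolute(sites[1]) - s1] = sites[1].alleles["B"]
        epi = model.site_absolute(model.epitope_sites[0])
        recs = _pair("conf", "C4A", s1, "10M", "".join(seq1), epi - 5, "20M",
                     c4a[epi - 6:epi + 14])
        sam = _write_sam(tmp_path / "c.sam", reference, recs)
        ev = collect_phase_evidence(
            merge_paralog_alignments(sam, reference, model), model)
        assert len(ev) == 1
        assert ev[0].isotype == "ambiguous"
        assert not ev[0].informative

    def test_evidence_counts_conserved_across_classes(self, model, reference):
        blocks = _simulate_blocks(model, reference, seed=21, error=0.01)
        ev = collect_phase_evidence(blocks, model)
        call = call_recombinants(ev, _profile())
        informative = sum(1 for e in ev if e.informative)
        assert sum(call.counts.values()) == informative == call.informative_pairs

    def test_sam_and_fast_paths_agree(self, model, reference, standard_bundle,
                                      standard_sam):
        from collections import Counter

        merged = merge_paralog_alignments(standard_sam, reference, model)
        blocks = merge_blocks(standard_bundle.blocks, reference)
        c_sam = Counter((e.isotype, e.epitope)
                        for e in collect_phase_evidence(merged, model))
        c_fast = Counter((e.isotype, e.epitope)
                         for e in collect_phase_evidence(blocks, model))
        assert c_sam == c_fast


class TestRecombinantCalls:
    def test_no_evidence_means_no_recombinant(self):
        call = call_recombinants([], _profile())
        assert not any(call.flags.values())
        assert call.informative_pairs == 0

    def test_support_rules_require_pairs_and_fraction(self):
        ev = [PhaseEvidence(f"f{i}", "A", "Rg") for i in range(50)]
        ev += [PhaseEvidence("x1", "A", "Ch"), PhaseEvidence("x2", "A", "Ch")]
        call = call_recombinants(ev, _profile(), min_pairs=3, min_fraction=0.01)
        assert not call.flags["A-Ch"]  # only 2 pairs < min_pairs
        ev.append(PhaseEvidence("x3", "A", "Ch"))
        call = call_recombinants(ev, _profile(), min_pairs=3, min_fraction=0.1)
        assert not call.flags["A-Ch"]  # 3/53 < 10% of informative pairs
        call = call_recombinants(ev, _profile(), min_pairs=3, min_fraction=0.05)
        assert call.flags["A-Ch"]

    def test_impossible_class_suppressed_with_warning(self):
        ev = [PhaseEvidence(f"f{i}", "A", "Ch") for i in range(10)]
        profile = _profile(a=0, rg=0)  # no A copies: A-Ch impossible
        call = call_recombinants(ev, profile)
        assert not call.flags["A-Ch"]
        assert "A-Ch" in call.suppressed
        assert call.warnings

    def test_simulated_recombinant_detected(self, model, reference):
        blocks = _simulate_blocks(model, reference, seed=31,
                                  recombinant="A-Ch", error=0.01)
        ev = collect_phase_evidence(blocks, model)
        call = call_recombinants(ev, _profile(rg=1))
        assert call.flags["A-Ch"]
        assert not call.flags["B-Rg"]

    def test_no_false_flags_on_non_recombinants(self, model, reference):
        for seed in range(41, 46):
            blocks = _simulate_blocks(model, reference, seed=seed, error=0.01)
            ev = collect_phase_evidence(blocks, model)
            call = call_recombinants(ev, _profile())
            assert not call.flags["A-Ch"] and not call.flags["B-Rg"]

    def test_support_grows_with_coverage(self, model, reference):
        """Mean recombinant support pairs rise monotonically over a
        coverage ladder for a fixed A-Ch genotype."""
        means = []
        for coverage in (5, 15, 45):
            pairs = []
            for seed in range(3):
                blocks = _simulate_blocks(model, reference, seed=51 + seed,
                                          recombinant="A-Ch",
                                          coverage=coverage)
                ev = collect_phase_evidence(blocks, model)
                pairs.append(call_recombinants(ev, _profile(rg=1)).counts["A-Ch"])
            means.append(np.mean(pairs))
        assert means[0] < means[1] < means[2]


class TestE26Window:
    def test_all_canonical_reads_give_no_extended_variants(self, model,
                                                           reference):
        blocks = _simulate_blocks(model, reference, seed=61)
        df = classify_e26_extended_variants(blocks, model, 4)
        assert df.attrs["status"] == "ok"
        noncanon = df[(df["canonical"].isna()) & (df["copy"] >= 1)]
        assert len(noncanon) == 0
        canon = set(df[df["canonical"].notna()]["canonical"])
        assert canon == {"A", "B"}

    def test_hybrid_string_on_one_of_four_copies_reported_at_copy_one(
            self, model, reference):
        # copy 0 (an A copy) carries B alleles at the last three isotype
        # sites: an in-phase hybrid string
        snvs = {0: [(model.site_absolute(s), s.alleles["B"])
                    for s in model.isotype_sites[2:]]}
        h1, h2 = cq.genotype_from_counts(4, 2, 2, snvs=snvs)
        cfg = cq.SimConfig(hap1=h1, hap2=h2, coverage=60, error_rate=0.0,
                           seed=62)
        bundle = cq.simulate_sample(cfg, model, reference)
        blocks = merge_blocks(bundle.blocks, reference)
        df = classify_e26_extended_variants(blocks, model, 4)
        hybrid = "".join([model.isotype_sites[0].alleles["A"],
                          model.isotype_sites[1].alleles["A"]]
                         + [s.alleles["B"] for s in model.isotype_sites[2:]])
        row = df[df["alleles"] == hybrid]
        assert len(row) == 1
        assert row.iloc[0]["copy"] == 1
        assert pd.isna(row.iloc[0]["canonical"])

    def test_uncovered_window_is_an_explicit_no_call(self, model, reference):
        cfg = cq.SimConfig(coverage=10, seed=63)  # zero C4 copies
        bundle = cq.simulate_sample(cfg, model, reference)
        df = classify_e26_extended_variants(
            merge_blocks(bundle.blocks, reference), model, 0)
        assert df.attrs["status"] == "no_coverage"
        assert len(df) == 0


class TestCompleteness:
    def _call(self, phased):
        return cq.RecombinantCall(
            counts={c: 0 for c in CLASSES}, informative_pairs=0,
            flags={"A-Ch": False, "B-Rg": False},
            phased={c: phased for c in CLASSES})

    def test_all_carriers_phased_gives_one(self):
        calls = [self._call(True)] * 4
        profiles = [_profile()] * 4
        out = phasing_completeness(calls, profiles)
        assert out["completeness_A_Rg"] == 1.0
        assert out["completeness_B_Ch"] == 1.0

    def test_no_informative_pairs_gives_zero_with_warning(self):
        calls = [self._call(False)] * 3
        profiles = [_profile()] * 3
        out = phasing_completeness(calls, profiles)
        assert out["completeness_A_Rg"] == 0.0
        assert out["warnings"]

    def test_non_carriers_excluded_from_the_denominator(self):
        calls = [self._call(True), self._call(False)]
        profiles = [_profile(), _profile(a=4, rg=4)]  # second has no B/Ch
        out = phasing_completeness(calls, profiles)
        assert out["carriers_B_Ch"] == 1
        assert out["completeness_B_Ch"] == 1.0
        assert out["completeness_A_Rg"] == 0.5

    def test_simulated_cohort_fully_phased_at_high_coverage(self, model,
                                                            reference):
        from c4quant.validation import phasing_completeness_panel

        out = phasing_completeness_panel(seed=2, n_samples=6, coverage=30,
                                         error_rate=0.01)
        assert out["completeness_A_Rg"] == 1.0
        assert out["completeness_B_Ch"] == 1.0


import pandas as pd  # noqa: E402  (used in TestE26Window)
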