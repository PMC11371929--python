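"""Point/CNA/fusion driver criteria and germline screening."""

import pytest

from oncointerp import (CNSegment, GermlineVariant, SVRecord, TumorProfile,
                        VariantRecord, call_amplification,
                        call_biallelic_deletion, classify_point_driver,
                        detect_gene_fusion, detect_second_hit, gene_copy_number,
                        screen_germline)
from oncointerp.drivers import detect_somatic_biallelic_inactivation


def _variant(gene, pc, vclass="missense", **kw):
    base = dict(chrom="7", pos=10_100_000, ref="C", alt="T", gene=gene,
                protein_change=pc, variant_class=vclass, tumor_depth=40,
                tumor_alt=10, normal_depth=20, normal_alt=0,
                trinucleotide_context="ACA")
    base.update(kw)
    return VariantRecord(**base)


def _profile(segments, ploidy=2.0):
    return TumorProfile("s", 0.6, ploidy, segments=segments)


def _flat_profile(kb, ploidy=2.0, total=2.0, minor=1.0):
    return _profile([CNSegment(c, 1, kb.chromosome_length, total, minor)
                     for c in kb.chromosomes], ploidy)


class TestPointDrivers:
    def test_oncogene_hotspot_and_drug_linked(self, kb):
        call = classify_point_driver(_variant("EGFR", "L858R"), kb.entry("EGFR"))
        assert call is not None and call.driver_class == "oncogene_point"
        assert any("cosmic_recurrent" in e for e in call.evidence)
        assert any("drug_linked" in e for e in call.evidence)

    def test_oncogene_non_recurrent_non_drugged_not_driver(self, kb):
        call = classify_point_driver(_variant("EGFR", "A123B"), kb.entry("EGFR"))
        assert call is None

    def test_synonymous_in_hotspot_not_driver(self, kb):
        call = classify_point_driver(_variant("EGFR", "L858R", "synonymous"),
                                     kb.entry("EGFR"))
        assert call is None

    def test_tsg_truncating_always_driver(self, kb):
        call = classify_point_driver(_variant("APC", "p.X", "frameshift"),
                                     kb.entry("APC"))
        assert call is not None and call.driver_class == "tsg_inactivating"

    def test_tsg_missense_requires_deleterious_prediction(self, kb):
        benign = classify_point_driver(_variant("PTEN", "T167A"), kb.entry("PTEN"))
        assert benign is None
        deleterious = classify_point_driver(_variant("PTEN", "R130Q"),
                                            kb.entry("PTEN"))
        assert deleterious is not None
        assert "sift_deleterious" in deleterious.evidence

    def test_gene_absent_from_kb(self, kb):
        assert classify_point_driver(_variant("NOSUCH", "X1Y"), None) is None

    def test_tert_promoter_hotspot(self, kb):
        call = classify_point_driver(_variant("TERT", "C228T", "promoter"),
                                     kb.entry("TERT"))
        assert call is not None and call.driver_class == "oncogene_point"


class TestCopyNumberDrivers:
    def test_gene_cn_length_weighted_mean(self, kb):
        entry = kb.entry("EML4")  # 2:20,000,000-20,200,000
        mid = entry.start + entry.length // 2
        segs = [CNSegment("2", 1, mid - 1, 2.0, 1.0),
                CNSegment("2", mid, 60_000_000, 6.0, 1.0)]
        cn = gene_copy_number(entry, _profile(segs))
        assert cn == pytest.approx(4.0, abs=0.01)
        assert gene_copy_number(entry, _profile(segs), "max") == 6.0

    def test_amplification_boundary_inclusive_non_drugged(self, kb):
        entry = kb.entry("EML4")   # no drug links in the fixture
        for cn, expected in ((6.9, False), (7.0, True)):
            segs = [CNSegment("2", 1, 60_000_000, cn, 1.0)]
            call = call_amplification("EML4", _profile(segs), entry)
            assert (call is not None) is expected

    def test_drugged_gene_lower_cutoff(self, kb):
        entry = kb.entry("FGFR2")
        segs = [CNSegment("10", 1, 60_000_000, 3.0, 1.0)]
        call = call_amplification("FGFR2", _profile(segs), entry)
        assert call is not None and not call.hyperamplified

    def test_hyperamplification_flag(self, kb):
        for gene, cn in (("FGFR2", 185.0), ("EGFR", 80.5)):
            entry = kb.entry(gene)
            segs = [CNSegment(entry.chrom, 1, 60_000_000, cn, 1.0)]
            call = call_amplification(gene, _profile(segs), entry)
            assert call.hyperamplified and call.driver_class == "amplification"

    def test_amplification_monotone_in_cn(self, kb):
        entry = kb.entry("EML4")
        called = False
        for cn in (5.0, 7.0, 9.0, 50.0, 200.0):
            segs = [CNSegment("2", 1, 60_000_000, cn, 1.0)]
            call = call_amplification("EML4", _profile(segs), entry)
            if called:
                assert call is not None   # increasing CN never removes the call
            called = called or call is not None

    def test_no_overlapping_segment(self, kb):
        profile = _profile([CNSegment("22", 1, 100, 2.0, 1.0)])
        assert call_amplification("EGFR", profile, kb.entry("EGFR")) is None

    @pytest.mark.parametrize("cn,zero_seg,expected", [
        (0.5, False, True),    # inclusive boundary
        (0.51, False, False),
        (0.9, True, True),     # CN < 1 over a zero-copy segment
        (0.9, False, False),
        (1.05, True, False),   # zero-copy segment but gene CN >= 1
    ])
    def test_biallelic_deletion_criteria(self, kb, cn, zero_seg, expected):
        entry = kb.entry("PTEN")   # 10:5,000,000-5,110,000
        if zero_seg:
            mid = entry.start + entry.length // 2
            lo = 2 * cn - 0.0      # segment CN making the weighted mean = cn
            segs = [CNSegment("10", 1, mid - 1, lo, 0.0),
                    CNSegment("10", mid, 60_000_000, 0.0, 0.0)]
        else:
            segs = [CNSegment("10", 1, 60_000_000, cn, 0.0)]
        call = call_biallelic_deletion("PTEN", _profile(segs), entry)
        assert (call is not None) is expected


class TestFusions:
    def _sv(self, ca, pa, oa, cb, pb, ob, svt):
        return SVRecord(ca, pa, oa, cb, pb, ob, svt, tumor_support=10,
                        normal_support=0)

    def test_eml4_alk_detected(self, kb):
        alk, eml4 = kb.entry("ALK"), kb.entry("EML4")
        sv = self._sv("2", alk.start + 300_000, "+", "2", eml4.start + 50_000,
                      "+", "INV")
        calls = detect_gene_fusion([sv], kb)
        assert [c.alteration for c in calls] == ["EML4-ALK"]

    def test_hip1_alk_translocation(self, kb):
        alk, hip1 = kb.entry("ALK"), kb.entry("HIP1")
        sv = self._sv("7", hip1.start + 50_000, "-", "2", alk.start + 300_000,
                      "+", "TRA")
        calls = detect_gene_fusion([sv], kb)
        assert [c.alteration for c in calls] == ["HIP1-ALK"]

    def test_incompatible_orientation_rejected(self, kb):
        alk, eml4 = kb.entry("ALK"), kb.entry("EML4")
        # ALK breakend retains its 5' portion instead of its 3' portion
        sv = self._sv("2", alk.start + 300_000, "-", "2", eml4.start + 50_000,
                      "+", "INV")
        assert detect_gene_fusion([sv], kb) == []

    def test_intergenic_breakpoints_no_call(self, kb):
        sv = self._sv("3", 1_000_000, "+", "9", 2_000_000, "-", "TRA")
        assert detect_gene_fusion([sv], kb) == []

    def test_non_allowlisted_pair_no_call(self, kb):
        # both breakpoints inside genes, but KRAS is not an allow-listed partner
        kras, egfr = kb.entry("KRAS"), kb.entry("EGFR")
        sv = self._sv("12", kras.start + 10_000, "-", "7", egfr.start + 10_000,
                      "-", "TRA")
        assert detect_gene_fusion([sv], kb) == []


class TestGermline:
    def test_screen_boundaries(self, kb):
        keep = GermlineVariant("BRCA1", "p.L1780P", 0.0001, "pathogenic", True)
        at_limit = GermlineVariant("BRCA1", "p.X", 0.005, "pathogenic", True)
        vus = GermlineVariant("BRCA2", "p.Y", 0.0001, "vus", True)
        not_predisposition = GermlineVariant("EGFR", "p.Z", 0.0001, "pathogenic",
                                             False)
        out = screen_germline([keep, at_limit, vus, not_predisposition],
                              kb.predisposition_genes())
        assert out == [keep]

    def test_second_hit_loh(self, kb):
        entry = kb.entry("BRCA1")
        segs = [CNSegment("17", 1, 60_000_000, 2.0, 0.0)]
        hit = GermlineVariant("BRCA1", "p.L1780P", 0.0001, "pathogenic", True)
        ev = detect_second_hit(hit, [], [], _profile(segs), kb)
        assert ev == ["loh_minor_cn_0"]

    def test_no_second_hit(self, kb):
        segs = [CNSegment("17", 1, 60_000_000, 2.0, 1.0)]
        hit = GermlineVariant("BRCA1", "p.L1780P", 0.0001, "pathogenic", True)
        assert detect_second_hit(hit, [], [], _profile(segs), kb) is None

    def test_somatic_biallelic_inactivation_brip1(self, kb):
        """Intragenic disruptive SV plus LOH reported without a germline hit."""
        entry = kb.entry("BRIP1")
        segs = [CNSegment("17", 1, 60_000_000, 2.0, 0.0)]
        sv = SVRecord("17", entry.start + 50_000, "+", "17",
                      entry.start + 71_100, "-", "DEL", 10, 0)
        calls = detect_somatic_biallelic_inactivation([], [sv], _profile(segs), kb)
        brip1 = [c for c in calls if c.gene == "BRIP1"]
        assert len(brip1) == 1
        assert brip1[0].driver_class == "tsg_inactivating"
        assert "intragenic_sv" in brip1[0].evidence


def test_no_spurious_drivers_on_clean_samples(kb, references):
    """Across a seed sweep, samples without injected drivers yield none."""
    from oncointerp import SimulationConfig, run_sample, simulate_callset
    for seed in range(5):
        cfg = SimulationConfig(seed=seed, n_sbs=400, n_indel=150, n_sv=100)
        rep = run_sample(*simulate_callset(cfg, kb=kb, references=references)[:5],
                         kb=kb, references=references)
        assert rep.drivers == []
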