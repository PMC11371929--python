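"""Domain-type invariants and format round-trips."""

import numpy as np
import pytest

import oncointerp.io as fio
from oncointerp import (CNSegment, DriverCall, GermlineVariant, IndelFeatures,
                        InterpretationReport, MicrosatelliteSite, SVRecord,
                        SimulationConfig, TumorProfile, ValidationError,
                        VariantRecord, read_report, simulate_callset,
                        write_report)
from oncointerp.io import ParseError, read_signature_reference, write_signature_reference


def _snv(**kw):
    base = dict(chrom="1", pos=100, ref="C", alt="T", tumor_depth=40, tumor_alt=5,
                normal_depth=20, normal_alt=0, trinucleotide_context="ACA")
    base.update(kw)
    return VariantRecord(**base)


class TestRecordInvariants:
    def test_alt_reads_bounded_by_depth(self):
        with pytest.raises(ValidationError):
            _snv(tumor_alt=41)
        with pytest.raises(ValidationError):
            _snv(normal_alt=21)

    def test_pon_af_bounds(self):
        with pytest.raises(ValidationError):
            _snv(pon_af=1.2)

    def test_context_xor_indel_features(self):
        with pytest.raises(ValidationError):
            _snv(trinucleotide_context=None)
        with pytest.raises(ValidationError):
            _snv(indel_features=IndelFeatures(1, 1, 0))

    def test_intra_chromosomal_sv_ordering(self):
        with pytest.raises(ValidationError):
            SVRecord("1", 500, "+", "1", 100, "-", "DEL", 5, 0)
        sv = SVRecord("1", 100, "+", "1", 500, "-", "DEL", 5, 0)
        assert sv.size == 400
        tra = SVRecord("1", 100, "+", "2", 500, "-", "TRA", 5, 0)
        assert tra.size is None

    def test_segment_and_profile_invariants(self):
        with pytest.raises(ValidationError):
            CNSegment("1", 100, 50, 2.0, 1.0)
        with pytest.raises(ValidationError):
            CNSegment("1", 1, 100, 1.0, 2.0)   # minor > total
        with pytest.raises(ValidationError):
            TumorProfile("s", 0.5, 2.0, segments=[
                CNSegment("1", 1, 150, 2, 1), CNSegment("1", 100, 200, 2, 1)])
        # adjacent segments are fine
        TumorProfile("s", 0.5, 2.0, segments=[
            CNSegment("1", 1, 100, 2, 1), CNSegment("1", 101, 200, 2, 1)])


@pytest.fixture(scope="module")
def callset():
    cfg = SimulationConfig(seed=11, n_sbs=150, n_indel=60, n_sv=40,
                           drivers=[], n_microsat_sites=20)
    return simulate_callset(cfg)


class TestVariantTableIO:
    @pytest.mark.parametrize("dialect", ["vcf", "tsv"])
    def test_round_trip_exact(self, tmp_path, callset, dialect):
        variants = callset[0]
        path = tmp_path / f"v.{dialect}"
        fio.write_variant_table(variants, path, dialect)
        back = fio.read_variant_table(path, dialect)
        assert back == variants

    def test_empty_file_with_header(self, tmp_path):
        path = tmp_path / "empty.vcf"
        fio.write_variant_table([], path, "vcf")
        assert fio.read_variant_table(path, "vcf") == []
        path2 = tmp_path / "empty.tsv"
        fio.write_variant_table([], path2, "tsv")
        assert fio.read_variant_table(path2, "tsv") == []

    def test_vaf_derivable_downstream(self, tmp_path):
        rec = _snv(tumor_depth=40, tumor_alt=5)
        path = tmp_path / "one.tsv"
        fio.write_variant_table([rec], path, "tsv")
        (back,) = fio.read_variant_table(path, "tsv")
        assert back.tumor_vaf == pytest.approx(0.125)

    def test_out_of_range_pon_af_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        fio.write_variant_table([_snv()], path, "tsv")
        text = path.read_text().replace("0.0\t", "1.2\t", 1)
        # rewrite pon_af column directly
        lines = text.splitlines()
        cols = lines[0].split("\t")
        vals = lines[1].split("\t")
        vals[cols.index("pon_af")] = "1.2"
        path.write_text(lines[0] + "\n" + "\t".join(vals) + "\n")
        with pytest.raises(ValidationError):
            fio.read_variant_table(path, "tsv")

    def test_malformed_row_names_line(self, tmp_path):
        path = tmp_path / "bad.tsv"
        fio.write_variant_table([_snv()], path, "tsv")
        lines = path.read_text().splitlines()
        cols = lines[0].split("\t")
        vals = lines[1].split("\t")
        vals[cols.index("pos")] = "not_a_number"
        path.write_text(lines[0] + "\n" + "\t".join(vals) + "\n")
        with pytest.raises(ParseError, match="line 2"):
            fio.read_variant_table(path, "tsv")

    def test_missing_file(self):
        with pytest.raises(FileNotFoundError):
            fio.read_variant_table("/nonexistent/x.vcf", "vcf")


class TestSVAndSegmentIO:
    def test_bedpe_round_trip_and_half_open_conversion(self, tmp_path, callset):
        svs = callset[1]
        path = tmp_path / "svs.bedpe"
        fio.write_sv_bedpe(svs, path)
        back = fio.read_sv_bedpe(path)
        assert back == svs
        # BEDPE on disk is 0-based half-open
        line = path.read_text().splitlines()[1].split("\t")
        assert int(line[2]) - int(line[1]) == 1
        assert int(line[1]) == svs[0].pos_a - 1

    def test_segments_round_trip(self, tmp_path, callset):
        profile = callset[2]
        path = tmp_path / "segs.tsv"
        fio.write_segments(profile.segments, path)
        assert fio.read_segments(path) == profile.segments

    def test_overlapping_segments_rejected(self, tmp_path):
        path = tmp_path / "overlap.tsv"
        fio.write_segments([CNSegment("1", 1, 150, 2, 1)], path)
        with open(path, "a") as fh:
            fh.write("1\t100\t200\t2.0\t1.0\n")
        with pytest.raises(ValidationError, match="overlap"):
            fio.read_segments(path)

    def test_minor_above_total_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("chrom\tstart\tend\ttotal_cn\tminor_cn\n1\t1\t100\t1.0\t2.0\n")
        with pytest.raises(ValidationError):
            fio.read_segments(path)

    def test_profile_round_trip(self, tmp_path, callset):
        profile = callset[2]
        path = tmp_path / "profile.json"
        fio.write_profile(profile, path)
        assert fio.read_profile(path) == profile


class TestSignatureReferenceIO:
    def test_round_trip(self, tmp_path, references):
        for sig_class, ref in references.items():
            path = tmp_path / f"{sig_class}.tsv"
            write_signature_reference(ref, path)
            back = read_signature_reference(path, sig_class)
            assert back.names == ref.names
            np.testing.assert_allclose(back.matrix, ref.matrix, atol=1e-9)

    def test_column_sum_tolerance(self, tmp_path, references):
        ref = references["SV32"]
        path = tmp_path / "drift.tsv"
        write_signature_reference(ref, path)
        # perturb one column to sum 0.999: renormalized, not an error
        import pandas as pd
        df = pd.read_csv(path, sep="\t", index_col=0)
        df.iloc[:, 0] *= 0.999
        df.to_csv(path, sep="\t")
        back = read_signature_reference(path, "SV32")
        assert back.matrix.sum(axis=0) == pytest.approx(1.0, abs=1e-9)
        # sum 0.9 is out of tolerance
        df.iloc[:, 0] *= 0.9
        df.to_csv(path, sep="\t")
        with pytest.raises(ValidationError):
            read_signature_reference(path, "SV32")

    def test_wrong_channel_count_rejected(self, tmp_path, references):
        path = tmp_path / "short.tsv"
        write_signature_reference(references["SBS96"], path)
        lines = path.read_text().splitlines()
        path.write_text("\n".join(lines[:-1]) + "\n")  # 95 channel rows
        with pytest.raises(ValidationError, match="channel"):
            read_signature_reference(path, "SBS96")


class TestOtherTablesAndReports:
    def test_microsatellite_and_germline_round_trips(self, tmp_path, callset):
        sites, germ = callset[4], callset[3]
        p1, p2 = tmp_path / "ms.tsv", tmp_path / "germ.tsv"
        fio.write_microsatellite_table(sites, p1)
        assert fio.read_microsatellite_table(p1) == sites
        fio.write_germline_table(germ, p2)
        assert fio.read_germline_table(p2) == germ

    def test_empty_report_round_trip(self, tmp_path):
        rep = InterpretationReport(sample_id="S1", cancer_type="lung",
                                   question="actionability", tcf=0.5, ploidy=2.0,
                                   interpretable=True)
        path = tmp_path / "r.json"
        write_report(rep, path, "json")
        back = read_report(path)
        assert back == rep
        assert back.drivers == []

    def test_report_with_driver_and_unicode_gene(self, tmp_path):
        driver = DriverCall(gene="GÈNE‐β", alteration="L858R",
                            driver_class="oncogene_point",
                            evidence=["cosmic_recurrent:L858R"], vaf=0.25)
        rep = InterpretationReport(sample_id="S2", cancer_type="lung",
                                   question="actionability", tcf=0.4, ploidy=2.0,
                                   interpretable=True, drivers=[driver])
        path = tmp_path / "r.json"
        write_report(rep, path, "json")
        back = read_report(path)
        assert back == rep
        assert back.drivers[0].gene == "GÈNE‐β"

    def test_markdown_contains_key_sections(self, tmp_path, callset):
        from oncointerp import run_sample
        rep = run_sample(*callset[:5])
        path = tmp_path / "r.md"
        write_report(rep, path, "markdown")
        text = path.read_text()
        for token in ("Phenotypes", "Drivers", "Germline", "TMB", "HRD"):
            assert token in text
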