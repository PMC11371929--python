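"""Readers and writers for the external representations.

Dialects: a VCF v4.2 subset for SNV/indel calls (INFO keys for mapping quality,
panel-of-normals frequency and annotations; AD/DP FORMAT fields for TUMOR and
NORMAL), a flat TSV alternative, BEDPE for SVs, a SEG-style TSV for copy-number
segments, COSMIC-layout TSV signature matrices, TSV microsatellite and germline
tables, and JSON/Markdown interpretation reports.

Coordinates are 1-based inclusive in memory everywhere; BEDPE conversion to
0-based half-open happens here and only here.  Fractional fields are written at
6 decimals and rounded to 6 decimals on read, so write-then-read round-trips
reproduce records exactly.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import pandas as pd
import pysam

from .records import (CNSegment, GermlineVariant, IndelFeatures,
                      MicrosatelliteSite, SVRecord, TumorProfile,
                      ValidationError, VariantRecord, chrom_sort_key)
from .signatures import SignatureReference
from .channels import CHANNELS_BY_CLASS

logger = logging.getLogger(__name__)


class ParseError(ValueError):
    """A malformed row in an input file (message names the line)."""


def _r6(x: float) -> float:
    return round(float(x), 6)


# --- variant tables -----------------------------------------------------------

_VCF_INFO_HEADER = [
    '##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">',
    '##INFO=<ID=VC,Number=1,Type=String,Description="Variant class">',
    '##INFO=<ID=PC,Number=1,Type=String,Description="Protein change">',
    '##INFO=<ID=MQ,Number=1,Type=Float,Description="Mapping quality">',
    '##INFO=<ID=PON_AF,Number=1,Type=Float,Description="Panel-of-normals allele frequency">',
    '##INFO=<ID=TNC,Number=1,Type=String,Description="Trinucleotide context (SNVs)">',
    '##INFO=<ID=RUS,Number=1,Type=Integer,Description="Indel repeat unit size">',
    '##INFO=<ID=RC,Number=1,Type=Integer,Description="Indel repeat count in reference">',
    '##INFO=<ID=MH,Number=1,Type=Integer,Description="Indel microhomology length">',
    '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">',
    '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
]

_TSV_COLUMNS = ["chrom", "pos", "ref", "alt", "variant_class", "gene",
                "protein_change", "tumor_depth", "tumor_alt", "normal_depth",
                "normal_alt", "mapping_quality", "pon_af",
                "trinucleotide_context", "repeat_unit_size", "repeat_count",
                "mh_len"]


def write_variant_table(records: list[VariantRecord], path: str | Path,
                        dialect: str = "vcf") -> None:
    path = Path(path)
    if dialect == "tsv":
        rows = []
        for r in records:
            feats = r.indel_features
            rows.append({
                "chrom": r.chrom, "pos": r.pos, "ref": r.ref, "alt": r.alt,
                "variant_class": r.variant_class, "gene": r.gene,
                "protein_change": r.protein_change,
                "tumor_depth": r.tumor_depth, "tumor_alt": r.tumor_alt,
                "normal_depth": r.normal_depth, "normal_alt": r.normal_alt,
                "mapping_quality": _r6(r.mapping_quality), "pon_af": _r6(r.pon_af),
                "trinucleotide_context": r.trinucleotide_context or "",
                "repeat_unit_size": feats.repeat_unit_size if feats else "",
                "repeat_count": feats.repeat_count if feats else "",
                "mh_len": feats.mh_len if feats else "",
            })
        pd.DataFrame(rows, columns=_TSV_COLUMNS).to_csv(path, sep="\t", index=False)
        return
    if dialect != "vcf":
        raise ValidationError(f"unknown dialect {dialect!r}")

    chroms = sorted({r.chrom for r in records}, key=chrom_sort_key)
    lines = ["##fileformat=VCFv4.2"]
    lines += [f"##contig=<ID={c}>" for c in chroms]
    lines += _VCF_INFO_HEADER
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tTUMOR\tNORMAL")
    for r in records:
        info = [f"MQ={_r6(r.mapping_quality):g}", f"PON_AF={_r6(r.pon_af):.6f}"]
        if r.gene:
            info.append(f"GENE={r.gene}")
        if r.protein_change:
            info.append(f"PC={r.protein_change}")
        info.append(f"VC={r.variant_class}")
        if r.trinucleotide_context is not None:
            info.append(f"TNC={r.trinucleotide_context}")
        else:
            f = r.indel_features
            info.append(f"RUS={f.repeat_unit_size};RC={f.repeat_count};MH={f.mh_len}")
        tumor = f"{r.tumor_depth - r.tumor_alt},{r.tumor_alt}:{r.tumor_depth}"
        normal = f"{r.normal_depth - r.normal_alt},{r.normal_alt}:{r.normal_depth}"
        lines.append("\t".join([r.chrom, str(r.pos), ".", r.ref, r.alt, ".", "PASS",
                                ";".join(info), "AD:DP", tumor, normal]))
    path.write_text("\n".join(lines) + "\n")


_KNOWN_INFO = {"GENE", "VC", "PC", "MQ", "PON_AF", "TNC", "RUS", "RC", "MH"}


def _record_from_vcf(rec) -> VariantRecord:
    info = dict(rec.info)
    unknown = set(info) - _KNOWN_INFO
    if unknown:
        logger.warning("ignoring unknown INFO fields %s at %s:%s",
                       sorted(unknown), rec.chrom, rec.pos)
    tumor, normal = rec.samples["TUMOR"], rec.samples["NORMAL"]
    t_ad, n_ad = tumor["AD"], normal["AD"]
    tnc = info.get("TNC")
    feats = None
    if tnc is None:
        feats = IndelFeatures(int(info.get("RUS", 1)), int(info.get("RC", 0)),
                              int(info.get("MH", 0)))
    return VariantRecord(
        chrom=rec.chrom, pos=rec.pos, ref=rec.ref, alt=rec.alts[0],
        variant_class=info.get("VC", "other"), gene=info.get("GENE", "") or "",
        protein_change=info.get("PC", "") or "",
        tumor_depth=int(tumor["DP"]), tumor_alt=int(t_ad[1]),
        normal_depth=int(normal["DP"]), normal_alt=int(n_ad[1]),
        mapping_quality=_r6(info.get("MQ", 60.0)),
        pon_af=_r6(info.get("PON_AF", 0.0)),
        trinucleotide_context=tnc, indel_features=feats)


def read_variant_table(path: str | Path, dialect: str = "vcf") -> list[VariantRecord]:
    """Read SNV/indel calls from a VCF subset or flat TSV."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "vcf":
        out = []
        with pysam.VariantFile(str(path)) as vf:
            for i, rec in enumerate(vf, start=1):
                try:
                    out.append(_record_from_vcf(rec))
                except (KeyError, TypeError, IndexError) as exc:
                    raise ParseError(f"record {i} ({rec.chrom}:{rec.pos}): "
                                     f"malformed fields ({exc})") from exc
        return out
    if dialect != "tsv":
        raise ValidationError(f"unknown dialect {dialect!r}")
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    unknown = set(df.columns) - set(_TSV_COLUMNS)
    if unknown:
        logger.warning("ignoring unknown columns %s in %s", sorted(unknown), path)
    out = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # 1 header line
        try:
            tnc = row.trinucleotide_context or None
            feats = None
            if tnc is None:
                feats = IndelFeatures(int(row.repeat_unit_size),
                                      int(row.repeat_count), int(row.mh_len))
            out.append(VariantRecord(
                chrom=row.chrom, pos=int(row.pos), ref=row.ref, alt=row.alt,
                variant_class=row.variant_class, gene=row.gene,
                protein_change=row.protein_change,
                tumor_depth=int(row.tumor_depth), tumor_alt=int(row.tumor_alt),
                normal_depth=int(row.normal_depth), normal_alt=int(row.normal_alt),
                mapping_quality=_r6(row.mapping_quality), pon_af=_r6(row.pon_af),
                trinucleotide_context=tnc, indel_features=feats))
        except (TypeError, ValueError) as exc:
            if isinstance(exc, ValidationError):
                raise
            raise ParseError(f"line {i}: {exc}") from exc
    return out


# --- SV BEDPE -----------------------------------------------------------------

_BEDPE_COLUMNS = ["chrom1", "start1", "end1", "chrom2", "start2", "end2", "name",
                  "score", "strand1", "strand2", "sv_type", "tumor_support",
                  "normal_support", "mapping_quality", "pon_freq", "homology_len"]


def write_sv_bedpe(svs: list[SVRecord], path: str | Path) -> None:
    rows = []
    for i, sv in enumerate(svs):
        rows.append({
            "chrom1": sv.chrom_a, "start1": sv.pos_a - 1, "end1": sv.pos_a,
            "chrom2": sv.chrom_b, "start2": sv.pos_b - 1, "end2": sv.pos_b,
            "name": f"sv{i}", "score": ".", "strand1": sv.orient_a,
            "strand2": sv.orient_b, "sv_type": sv.sv_type,
            "tumor_support": sv.tumor_support, "normal_support": sv.normal_support,
            "mapping_quality": _r6(sv.mapping_quality),
            "pon_freq": _r6(sv.pon_freq), "homology_len": sv.homology_len,
        })
    pd.DataFrame(rows, columns=_BEDPE_COLUMNS).to_csv(path, sep="\t", index=False)


def read_sv_bedpe(path: str | Path) -> list[SVRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    out = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            out.append(SVRecord(
                chrom_a=row.chrom1, pos_a=int(row.end1), orient_a=row.strand1,
                chrom_b=row.chrom2, pos_b=int(row.end2), orient_b=row.strand2,
                sv_type=row.sv_type, tumor_support=int(row.tumor_support),
                normal_support=int(row.normal_support),
                mapping_quality=_r6(row.mapping_quality),
                pon_freq=_r6(row.pon_freq), homology_len=int(row.homology_len)))
        except (TypeError, ValueError) as exc:
            if isinstance(exc, ValidationError):
                raise
            raise ParseError(f"line {i}: {exc}") from exc
    return out


# --- copy-number segments -----------------------------------------------------

def write_segments(segments: list[CNSegment], path: str | Path) -> None:
    rows = [{"chrom": s.chrom, "start": s.start, "end": s.end,
             "total_cn": _r6(s.total_cn), "minor_cn": _r6(s.minor_cn)}
            for s in segments]
    pd.DataFrame(rows, columns=["chrom", "start", "end", "total_cn", "minor_cn"]
                 ).to_csv(path, sep="\t", index=False)


def read_segments(path: str | Path) -> list[CNSegment]:
    """Read a SEG-style TSV; segments are sorted and non-overlap is enforced."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    segs = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            segs.append(CNSegment(row.chrom, int(row.start), int(row.end),
                                  _r6(row.total_cn), _r6(row.minor_cn)))
        except (TypeError, ValueError) as exc:
            if isinstance(exc, ValidationError):
                raise
            raise ParseError(f"line {i}: {exc}") from exc
    segs.sort(key=lambda s: (chrom_sort_key(s.chrom), s.start))
    prev = None
    for s in segs:
        if prev is not None and s.chrom == prev.chrom and s.start <= prev.end:
            raise ValidationError(
                f"overlapping segments on {s.chrom}: [{prev.start},{prev.end}] "
                f"and [{s.start},{s.end}]")
        prev = s
    return segs


def write_profile(profile: TumorProfile, path: str | Path) -> None:
    doc = {"sample_id": profile.sample_id, "tcf": _r6(profile.tcf),
           "ploidy": _r6(profile.ploidy), "sample_type": profile.sample_type,
           "acquisition": profile.acquisition, "cancer_type": profile.cancer_type,
           "segments": [{"chrom": s.chrom, "start": s.start, "end": s.end,
                         "total_cn": _r6(s.total_cn), "minor_cn": _r6(s.minor_cn)}
                        for s in profile.segments]}
    Path(path).write_text(json.dumps(doc, indent=1))


def read_profile(path: str | Path) -> TumorProfile:
    doc = json.loads(Path(path).read_text())
    return TumorProfile(
        sample_id=doc["sample_id"], tcf=doc["tcf"], ploidy=doc["ploidy"],
        sample_type=doc["sample_type"], acquisition=doc["acquisition"],
        cancer_type=doc.get("cancer_type", "unknown"),
        segments=[CNSegment(s["chrom"], s["start"], s["end"], s["total_cn"],
                            s["minor_cn"]) for s in doc["segments"]])


# --- signature matrices -------------------------------------------------------

def write_signature_reference(ref: SignatureReference, path: str | Path) -> None:
    df = pd.DataFrame(ref.matrix, index=list(CHANNELS_BY_CLASS[ref.sig_class]),
                      columns=ref.names)
    df.index.name = "MutationType"
    df.to_csv(path, sep="\t", float_format="%.10g")


def read_signature_reference(path: str | Path, sig_class: str) -> SignatureReference:
    """Read a COSMIC-layout TSV (rows channels, columns signatures); channels are
    reordered to the canonical order and columns renormalized within 1e-3."""
    channels = CHANNELS_BY_CLASS.get(sig_class)
    if channels is None:
        raise ValidationError(f"unknown signature class {sig_class!r}")
    df = pd.read_csv(path, sep="\t", index_col=0)
    if set(df.index) != set(channels):
        raise ValidationError(
            f"channel set does not match {sig_class}: {len(df.index)} rows")
    df = df.reindex(list(channels))
    sums = df.sum(axis=0)
    drifted = [c for c in df.columns if 1e-6 < abs(sums[c] - 1.0) <= 1e-3]
    if drifted:
        logger.warning("renormalizing signature columns %s", drifted)
    return SignatureReference(sig_class=sig_class, names=list(df.columns),
                              matrix=df.to_numpy())


# --- microsatellite and germline tables --------------------------------------

def _encode_hist(h: dict[int, int]) -> str:
    return ",".join(f"{l}:{c}" for l, c in sorted(h.items()))


def _decode_hist(s: str) -> dict[int, int]:
    out = {}
    for part in s.split(","):
        l, c = part.split(":")
        out[int(l)] = int(c)
    return out


def write_microsatellite_table(sites: list[MicrosatelliteSite],
                               path: str | Path) -> None:
    rows = [{"locus_id": s.locus_id, "repeat_unit": s.repeat_unit,
             "tumor_hist": _encode_hist(s.tumor_hist),
             "normal_hist": _encode_hist(s.normal_hist)} for s in sites]
    pd.DataFrame(rows, columns=["locus_id", "repeat_unit", "tumor_hist",
                                "normal_hist"]).to_csv(path, sep="\t", index=False)


def read_microsatellite_table(path: str | Path) -> list[MicrosatelliteSite]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    out = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            out.append(MicrosatelliteSite(row.locus_id, row.repeat_unit,
                                          _decode_hist(row.tumor_hist),
                                          _decode_hist(row.normal_hist)))
        except (TypeError, ValueError) as exc:
            if isinstance(exc, ValidationError):
                raise
            raise ParseError(f"line {i}: {exc}") from exc
    return out


def write_germline_table(variants: list[GermlineVariant], path: str | Path) -> None:
    rows = [{"gene": g.gene, "hgvs_p": g.hgvs_p,
             "population_af": _r6(g.population_af),
             "clinvar_class": g.clinvar_class,
             "predisposition_gene": int(g.predisposition_gene)} for g in variants]
    pd.DataFrame(rows, columns=["gene", "hgvs_p", "population_af", "clinvar_class",
                                "predisposition_gene"]
                 ).to_csv(path, sep="\t", index=False)


def read_germline_table(path: str | Path) -> list[GermlineVariant]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    out = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            out.append(GermlineVariant(row.gene, row.hgvs_p,
                                       _r6(row.population_af), row.clinvar_class,
                                       bool(int(row.predisposition_gene))))
        except (TypeError, ValueError) as exc:
            if isinstance(exc, ValidationError):
                raise
            raise ParseError(f"line {i}: {exc}") from exc
    return out
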