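"""Patient report assembly and the end-to-end interpretation pipeline.

A sample flows filter -> catalogs/refitting -> phenotypes -> drivers ->
category -> report.  Samples with tumor cell fraction below 15% are marked
noninterpretable and downstream sections are suppressed.  The report carries a
provenance block recording every threshold actually applied.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from .categories import CategoryAssignment, assign_category
from .drivers import DriverCall, GermlineFinding, interpret_drivers
from .filters import FilterThresholds, filter_snv_indel, filter_sv
from .kb import Knowledgebase, load_knowledgebase
from .phenotypes import (DEFAULT_CALLABLE_MB, PhenotypeReport,
                         compute_phenotypes)
from .records import (GermlineVariant, MicrosatelliteSite, SVRecord,
                      TumorProfile, ValidationError, VariantRecord)
from .refsigs import build_reference, default_signature_set
from .signatures import (SignatureExposure, SignatureReference,
                         build_id83_catalog, build_sbs96_catalog,
                         build_sv32_catalog, refine_signature_set)

logger = logging.getLogger(__name__)

MIN_INTERPRETABLE_TCF = 0.15   # strict: TCF < 15% is noninterpretable


@dataclass
class InterpretationReport:
    sample_id: str
    cancer_type: str
    question: str
    tcf: float
    ploidy: float
    interpretable: bool
    drivers: list[DriverCall] = field(default_factory=list)
    phenotypes: PhenotypeReport | None = None
    germline_findings: list[GermlineFinding] = field(default_factory=list)
    category: CategoryAssignment | None = None
    exposures: dict[str, SignatureExposure] = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)


def run_sample(variants: list[VariantRecord], svs: list[SVRecord],
               profile: TumorProfile, germline: list[GermlineVariant],
               sites: list[MicrosatelliteSite], question: str = "actionability",
               kb: Knowledgebase | None = None,
               references: dict[str, SignatureReference] | None = None,
               thresholds: FilterThresholds | None = None,
               callable_mb: float = DEFAULT_CALLABLE_MB) -> InterpretationReport:
    """Run the full interpretation pipeline for one sample."""
    kb = kb or load_knowledgebase()
    references = references or {c: build_reference(c)
                                for c in ("SBS96", "ID83", "SV32")}
    thresholds = thresholds or FilterThresholds()
    cancer_type = profile.cancer_type

    provenance = {"thresholds": dataclasses.asdict(thresholds),
                  "callable_mb": callable_mb,
                  "min_interpretable_tcf": MIN_INTERPRETABLE_TCF}

    if profile.tcf < MIN_INTERPRETABLE_TCF:
        logger.info("sample %s noninterpretable: TCF %.3f < %.2f",
                    profile.sample_id, profile.tcf, MIN_INTERPRETABLE_TCF)
        return InterpretationReport(
            sample_id=profile.sample_id, cancer_type=cancer_type,
            question=question, tcf=profile.tcf, ploidy=profile.ploidy,
            interpretable=False, provenance=provenance)

    passing, _ = filter_snv_indel(variants, thresholds)
    passing_svs, _ = filter_sv(svs, thresholds)

    snvs = [v for v in passing if v.is_snv]
    indels = [v for v in passing if not v.is_snv]
    sbs_catalog = build_sbs96_catalog(snvs)
    id_catalog = build_id83_catalog(indels)
    sv_catalog = build_sv32_catalog(passing_svs)

    exposures = {}
    for sig_class, catalog in (("SBS96", sbs_catalog), ("ID83", id_catalog),
                               ("SV32", sv_catalog)):
        initial = default_signature_set(cancer_type, sig_class)
        exposures[sig_class] = refine_signature_set(catalog, references[sig_class],
                                                    initial)
    provenance["refinement_traces"] = {
        c: e.refinement_trace for c, e in exposures.items()}

    phenotypes = compute_phenotypes(
        filtered_variant_count=len(passing), profile=profile,
        sbs_exposure=exposures["SBS96"], id_exposure=exposures["ID83"],
        sv_exposure=exposures["SV32"], id_catalog=id_catalog, sites=sites,
        callable_mb=callable_mb,
        chromosome_length=kb.chromosome_length)

    drivers, findings = interpret_drivers(passing, passing_svs, profile, kb,
                                          germline)

    category = assign_category(drivers, phenotypes, findings, kb, cancer_type,
                               question, purity=profile.tcf,
                               sbs_exposure=exposures["SBS96"],
                               id_exposure=exposures["ID83"])

    return InterpretationReport(
        sample_id=profile.sample_id, cancer_type=cancer_type, question=question,
        tcf=profile.tcf, ploidy=profile.ploidy, interpretable=True,
        drivers=drivers, phenotypes=phenotypes, germline_findings=findings,
        category=category, exposures=exposures, provenance=provenance)


# --- serialization ------------------------------------------------------------

def report_to_dict(report: InterpretationReport) -> dict:
    return {
        "sample_id": report.sample_id,
        "cancer_type": report.cancer_type,
        "question": report.question,
        "tcf": report.tcf,
        "ploidy": report.ploidy,
        "interpretable": report.interpretable,
        "drivers": [dataclasses.asdict(d) for d in report.drivers],
        "phenotypes": dataclasses.asdict(report.phenotypes)
        if report.phenotypes else None,
        "germline_findings": [
            {"variant": dataclasses.asdict(f.variant), "second_hit": f.second_hit}
            for f in report.germline_findings],
        "category": {
            "primary_question": report.category.primary_question,
            "category": report.category.category,
            "evidence": [list(e) for e in report.category.evidence],
        } if report.category else None,
        "exposures": {
            c: {"sig_class": e.sig_class, "exposures": e.exposures,
                "cosine": e.cosine, "active_set": e.active_set,
                "refinement_trace": e.refinement_trace,
                "degenerate": e.degenerate, "best_effort": e.best_effort}
            for c, e in report.exposures.items()},
        "provenance": report.provenance,
    }


def report_from_dict(doc: dict) -> InterpretationReport:
    return InterpretationReport(
        sample_id=doc["sample_id"], cancer_type=doc["cancer_type"],
        question=doc["question"], tcf=doc["tcf"], ploidy=doc["ploidy"],
        interpretable=doc["interpretable"],
        drivers=[DriverCall(**d) for d in doc["drivers"]],
        phenotypes=PhenotypeReport(**doc["phenotypes"])
        if doc["phenotypes"] else None,
        germline_findings=[
            GermlineFinding(variant=GermlineVariant(**f["variant"]),
                            second_hit=f["second_hit"])
            for f in doc["germline_findings"]],
        category=CategoryAssignment(
            primary_question=doc["category"]["primary_question"],
            category=doc["category"]["category"],
            evidence=[tuple(e) for e in doc["category"]["evidence"]])
        if doc["category"] else None,
        exposures={c: SignatureExposure(**e)
                   for c, e in doc["exposures"].items()},
        provenance=doc["provenance"])


def _render_markdown(report: InterpretationReport) -> str:
    lines = [f"# Interpretation report: {report.sample_id}", "",
             f"- Cancer type: {report.cancer_type}",
             f"- Primary question: {report.question}",
             f"- Tumor cell fraction: {report.tcf:.1%}; ploidy: {report.ploidy:.2f}"]
    if not report.interpretable:
        lines += ["", "**Noninterpretable genome (tumor cell fraction < 15%); "
                      "downstream sections suppressed.**", ""]
        return "\n".join(lines)
    cat = report.category
    lines += [f"- Category: **{cat.category if cat else 'none'}**", "", "## Drivers", ""]
    if report.drivers:
        for d in report.drivers:
            lines.append(f"- {d.gene} {d.alteration} ({d.driver_class}); "
                         f"evidence: {', '.join(d.evidence)}")
    else:
        lines.append("- none")
    p = report.phenotypes
    lines += ["", "## Phenotypes", "",
              f"- TMB: {p.tmb:.2f} mutations/Mb",
              f"- Whole-genome duplication: {p.wgd}",
              f"- HRD probability: {p.hrd_probability:.3f} "
              f"({'positive' if p.hrd_positive else 'negative'})",
              f"- MSI score: {p.msisensor_like_score:.1f}; MSI signature "
              f"proportion: {p.msi_signature_proportion:.3f}; call: {p.msi_call}",
              "", "## Germline findings", ""]
    if report.germline_findings:
        for f in report.germline_findings:
            hit = ", ".join(f.second_hit) if f.second_hit else "no second hit"
            lines.append(f"- {f.variant.gene} {f.variant.hgvs_p} "
                         f"({f.variant.clinvar_class}); {hit}")
    else:
        lines.append("- none")
    if cat and cat.evidence:
        lines += ["", "## Category evidence", ""]
        for subject, match in cat.evidence:
            lines.append(f"- {subject} -> {match}")
    lines.append("")
    return "\n".join(lines)


def write_report(report: InterpretationReport, path: str | Path,
                 format: str = "json") -> None:
    """Write an interpretation report as lossless JSON or readable Markdown."""
    path = Path(path)
    if format == "json":
        path.write_text(json.dumps(report_to_dict(report), indent=1,
                                   ensure_ascii=False))
    elif format == "markdown":
        path.write_text(_render_markdown(report))
    else:
        raise ValidationError(f"unknown report format {format!r}")


def read_report(path: str | Path) -> InterpretationReport:
    return report_from_dict(json.loads(Path(path).read_text()))


# --- pipeline driver ----------------------------------------------------------

def run_pipeline(config, outdir: str | Path | None = None,
                 kb: Knowledgebase | None = None,
                 references: dict[str, SignatureReference] | None = None,
                 thresholds: FilterThresholds | None = None,
                 ) -> InterpretationReport:
    """Simulate a call set from a config and interpret it end to end.

    When ``outdir`` is given, all intermediates (VCF, BEDPE, profile JSON,
    germline and microsatellite tables, ground-truth manifest, JSON and
    Markdown reports) are written there.
    """
    from .simulate import ground_truth_manifest, simulate_callset

    kb = kb or load_knowledgebase()
    references = references or {c: build_reference(c)
                                for c in ("SBS96", "ID83", "SV32")}
    variants, svs, profile, germline, sites, truth = simulate_callset(
        config, kb=kb, references=references)
    report = run_sample(variants, svs, profile, germline, sites,
                        question=config.question, kb=kb, references=references,
                        thresholds=thresholds)
    if outdir is not None:
        from . import io as fio
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        fio.write_variant_table(variants, outdir / "variants.vcf", "vcf")
        fio.write_sv_bedpe(svs, outdir / "svs.bedpe")
        fio.write_profile(profile, outdir / "profile.json")
        fio.write_germline_table(germline, outdir / "germline.tsv")
        fio.write_microsatellite_table(sites, outdir / "microsatellites.tsv")
        ground_truth_manifest(truth).to_csv(outdir / "manifest.tsv", sep="\t",
                                            index=False)
        write_report(report, outdir / "report.json", "json")
        write_report(report, outdir / "report.md", "markdown")
    return report
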