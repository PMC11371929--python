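"""Driver interpretation: point drivers, copy-number drivers, fusions, germline.

Oncogene point variants are drivers when they are oncogene-class alterations
(missense, in-frame indel, promoter) that are either recurrent in COSMIC or
drug-linked; TSG variants when truncating, or missense with a deleterious
prediction or ClinVar pathogenic assertion.  Copy-number drivers are called
relative to tumor ploidy: amplification at gene CN >= ploidy + 5 (ploidy + 1
for drug-targetable genes), biallelic deletion at gene CN <= 0.5 or CN < 1 over
a zero-copy segment.  Fusions are reported from breakpoint pairs landing in an
allow-listed 5'/3' gene pair with orientations compatible with a head-to-tail
transcript.  Germline screening retains rare (<0.5%) pathogenic variants in
predisposition genes and looks for somatic second hits (LOH, truncating
mutation, or disruptive SV/deletion).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .kb import GeneKBEntry, Knowledgebase
from .records import (GermlineVariant, SVRecord, TumorProfile,
                      TRUNCATING_CLASSES, VariantRecord, chrom_sort_key)

logger = logging.getLogger(__name__)

COSMIC_RECURRENCE_THRESHOLD = 10
HYPERAMPLIFICATION_CN = 50.0       # ecDNA-scale annotation flag; does not gate amplification
ONCOGENE_CLASSES = ("missense", "inframe_indel", "promoter")

DRIVER_CLASSES = ("oncogene_point", "tsg_inactivating", "amplification",
                  "hyperamplification", "biallelic_deletion", "fusion",
                  "germline_with_second_hit")


@dataclass
class DriverCall:
    gene: str
    alteration: str
    driver_class: str
    evidence: list[str] = field(default_factory=list)
    copy_number: float | None = None
    hyperamplified: bool = False
    vaf: float | None = None
    chrom: str = ""
    pos: int = 0

    def __post_init__(self):
        if self.driver_class not in DRIVER_CLASSES:
            raise ValueError(f"unknown driver_class {self.driver_class!r}")
        if not self.evidence:
            raise ValueError("driver calls require at least one evidence item")


def classify_point_driver(variant: VariantRecord, kb_entry: GeneKBEntry | None,
                          cosmic_threshold: int = COSMIC_RECURRENCE_THRESHOLD,
                          ) -> DriverCall | None:
    """Apply the oncogene/TSG point-driver criteria to one passing variant."""
    if kb_entry is None:
        logger.info("gene %s absent from knowledgebase; skipped", variant.gene)
        return None
    desc = variant.protein_change
    evidence: list[str] = []

    if kb_entry.role in ("oncogene", "both") and variant.variant_class in ONCOGENE_CLASSES:
        if kb_entry.hotspots.get(desc, 0) >= cosmic_threshold:
            evidence.append(f"cosmic_recurrent:{desc}")
        if kb_entry.drug_links_for(desc, None):
            evidence.append(f"drug_linked:{desc}")
        if evidence:
            return DriverCall(gene=variant.gene, alteration=desc or variant.variant_class,
                              driver_class="oncogene_point", evidence=evidence,
                              vaf=variant.tumor_vaf, chrom=variant.chrom,
                              pos=variant.pos)

    if kb_entry.role in ("tsg", "both"):
        if variant.variant_class in TRUNCATING_CLASSES:
            evidence = [f"truncating:{variant.variant_class}"]
        elif variant.variant_class == "missense":
            preds = kb_entry.deleterious.get(desc, {})
            for key, label in (("sift", "sift_deleterious"),
                               ("polyphen", "polyphen_deleterious"),
                               ("clinvar", "clinvar_pathogenic")):
                if preds.get(key):
                    evidence.append(label)
        if evidence:
            return DriverCall(gene=variant.gene, alteration=desc or variant.variant_class,
                              driver_class="tsg_inactivating", evidence=evidence,
                              vaf=variant.tumor_vaf, chrom=variant.chrom,
                              pos=variant.pos)
    return None


def gene_copy_number(entry: GeneKBEntry, profile: TumorProfile,
                     method: str = "weighted_mean") -> float | None:
    """Gene copy number over its interval: length-weighted mean of overlapping
    segments' total CN (or the maximum segment CN with method='max')."""
    segs = profile.segments_overlapping(entry.chrom, entry.start, entry.end)
    if not segs:
        return None
    if method == "max":
        return max(s.total_cn for s in segs)
    total_len = 0
    acc = 0.0
    for s in segs:
        ov = min(s.end, entry.end) - max(s.start, entry.start) + 1
        acc += ov * s.total_cn
        total_len += ov
    return acc / total_len


def call_amplification(gene: str, profile: TumorProfile, kb_entry: GeneKBEntry,
                       cn_method: str = "weighted_mean") -> DriverCall | None:
    """Oncogenic amplification relative to ploidy.

    Threshold is ploidy + 5; ploidy + 1 when the gene carries any drug/trial
    link ("targeted drugs available").  CN >= 50 additionally flags
    ecDNA-scale hyperamplification without changing amplification status.
    """
    cn = gene_copy_number(kb_entry, profile, cn_method)
    if cn is None:
        logger.info("no segment overlaps %s; amplification not evaluated", gene)
        return None
    drugged = bool(kb_entry.drugs)
    threshold = profile.ploidy + (1.0 if drugged else 5.0)
    if cn < threshold:
        return None
    evidence = [f"cn_{cn:.1f}_ge_ploidy_plus_{1 if drugged else 5}"]
    hyper = cn >= HYPERAMPLIFICATION_CN
    if hyper:
        evidence.append("hyperamplification_cn_ge_50")
    return DriverCall(gene=gene, alteration="amplification",
                      driver_class="amplification", evidence=evidence,
                      copy_number=cn, hyperamplified=hyper, chrom=kb_entry.chrom,
                      pos=kb_entry.start)


def call_biallelic_deletion(gene: str, profile: TumorProfile,
                            kb_entry: GeneKBEntry,
                            cn_method: str = "weighted_mean") -> DriverCall | None:
    """TSG biallelic deletion: gene CN <= 0.5, or CN < 1 over a zero-copy segment."""
    cn = gene_copy_number(kb_entry, profile, cn_method)
    if cn is None:
        return None
    segs = profile.segments_overlapping(kb_entry.chrom, kb_entry.start, kb_entry.end)
    zero_segment = any(s.total_cn == 0 for s in segs)
    if cn <= 0.5:
        evidence = [f"gene_cn_{cn:.2f}_le_0.5"]
    elif cn < 1.0 and zero_segment:
        evidence = [f"gene_cn_{cn:.2f}_lt_1_with_zero_copy_segment"]
    else:
        return None
    return DriverCall(gene=gene, alteration="biallelic deletion",
                      driver_class="biallelic_deletion", evidence=evidence,
                      copy_number=cn, chrom=kb_entry.chrom, pos=kb_entry.start)


def _retains_five_prime(entry: GeneKBEntry, orient: str) -> bool:
    # '+' retains sequence left of the breakpoint; a plus-strand gene's 5' end
    # is at lower coordinates
    return orient == ("+" if entry.strand == "+" else "-")


def _retains_three_prime(entry: GeneKBEntry, orient: str) -> bool:
    return orient == ("-" if entry.strand == "+" else "+")


def detect_gene_fusion(svs: list[SVRecord], kb: Knowledgebase) -> list[DriverCall]:
    """Report allow-listed in-frame-compatible gene fusions from breakpoint pairs."""
    calls: list[DriverCall] = []
    seen: set[tuple[str, str]] = set()
    for sv in svs:
        genes_a = kb.genes_at(sv.chrom_a, sv.pos_a)
        genes_b = kb.genes_at(sv.chrom_b, sv.pos_b)
        for ga in genes_a:
            for gb in genes_b:
                if ga.gene == gb.gene:
                    continue
                for five, f_or, three, t_or in (
                        (ga, sv.orient_a, gb, sv.orient_b),
                        (gb, sv.orient_b, ga, sv.orient_a)):
                    if not kb.is_allowed_fusion(five.gene, three.gene):
                        continue
                    if not (_retains_five_prime(five, f_or)
                            and _retains_three_prime(three, t_or)):
                        continue
                    name = f"{five.gene}-{three.gene}"
                    if (name, sv.sv_type) in seen:
                        continue
                    seen.add((name, sv.sv_type))
                    calls.append(DriverCall(
                        gene=three.gene, alteration=name, driver_class="fusion",
                        evidence=[f"breakpoints_in_{five.gene}_and_{three.gene}",
                                  f"sv_type:{sv.sv_type}",
                                  "orientation_head_to_tail"],
                        chrom=sv.chrom_a, pos=sv.pos_a))
    return calls


def screen_germline(germline_variants: list[GermlineVariant],
                    predisposition_genes: list[str],
                    max_population_af: float = 0.005) -> list[GermlineVariant]:
    """Rare (<0.5%, strict) pathogenic/likely-pathogenic variants in predisposition genes."""
    return [g for g in germline_variants
            if g.population_af < max_population_af
            and g.clinvar_class in ("pathogenic", "likely_pathogenic")
            and g.gene in predisposition_genes]


def _gene_has_loh(entry: GeneKBEntry, profile: TumorProfile) -> bool:
    segs = profile.segments_overlapping(entry.chrom, entry.start, entry.end)
    return any(s.minor_cn <= 1e-9 for s in segs)


def _disruptive_sv_in_gene(entry: GeneKBEntry, svs: list[SVRecord]) -> bool:
    for sv in svs:
        if sv.sv_type in ("DEL", "INV", "DUP", "TRA") and (
                entry.contains(sv.chrom_a, sv.pos_a)
                or entry.contains(sv.chrom_b, sv.pos_b)):
            return True
    return False


def detect_second_hit(germline_hit: GermlineVariant,
                      somatic_variants: list[VariantRecord],
                      svs: list[SVRecord],
                      profile: TumorProfile,
                      kb: Knowledgebase) -> list[str] | None:
    """Somatic second hit for a retained germline variant: LOH at the locus,
    a somatic truncating variant, or a disruptive SV/deletion in the gene."""
    entry = kb.entry(germline_hit.gene)
    if entry is None:
        return None
    evidence = []
    if _gene_has_loh(entry, profile):
        evidence.append("loh_minor_cn_0")
    if any(v.gene == germline_hit.gene and v.variant_class in TRUNCATING_CLASSES
           for v in somatic_variants):
        evidence.append("somatic_truncating_variant")
    if call_biallelic_deletion(germline_hit.gene, profile, entry) is not None:
        evidence.append("biallelic_deletion")
    if _disruptive_sv_in_gene(entry, svs):
        evidence.append("disruptive_sv")
    return evidence or None


def detect_somatic_biallelic_inactivation(somatic_variants: list[VariantRecord],
                                          svs: list[SVRecord],
                                          profile: TumorProfile,
                                          kb: Knowledgebase) -> list[DriverCall]:
    """TSGs completely inactivated by two somatic events (no germline hit):
    a truncating variant or intragenic disruptive SV combined with LOH, or a
    biallelic deletion."""
    calls = []
    for entry in kb.genes.values():
        if entry.role not in ("tsg", "both"):
            continue
        loh = _gene_has_loh(entry, profile)
        truncating = any(v.gene == entry.gene and v.variant_class in TRUNCATING_CLASSES
                         for v in somatic_variants)
        disruptive = _disruptive_sv_in_gene(entry, svs)
        deletion = call_biallelic_deletion(entry.gene, profile, entry)
        if deletion is not None:
            calls.append(deletion)
        elif loh and (truncating or disruptive):
            mech = "somatic_truncating" if truncating else "intragenic_sv"
            calls.append(DriverCall(
                gene=entry.gene, alteration="biallelic inactivation",
                driver_class="tsg_inactivating",
                evidence=[mech, "loh_minor_cn_0"],
                chrom=entry.chrom, pos=entry.start))
    return calls


@dataclass
class GermlineFinding:
    variant: GermlineVariant
    second_hit: list[str] | None

    @property
    def has_second_hit(self) -> bool:
        return bool(self.second_hit)


def interpret_drivers(variants: list[VariantRecord], svs: list[SVRecord],
                      profile: TumorProfile, kb: Knowledgebase,
                      germline_variants: list[GermlineVariant] | None = None,
                      cosmic_threshold: int = COSMIC_RECURRENCE_THRESHOLD,
                      ) -> tuple[list[DriverCall], list[GermlineFinding]]:
    """Run every driver caller for one sample; driver list is order-canonicalized
    by (chrom, pos, gene)."""
    calls: list[DriverCall] = []
    for v in variants:
        if not v.gene:
            continue
        call = classify_point_driver(v, kb.entry(v.gene), cosmic_threshold)
        if call is not None:
            calls.append(call)

    for entry in kb.genes.values():
        if entry.role in ("oncogene", "both"):
            amp = call_amplification(entry.gene, profile, entry)
            if amp is not None:
                calls.append(amp)

    calls.extend(detect_somatic_biallelic_inactivation(variants, svs, profile, kb))
    calls.extend(detect_gene_fusion(svs, kb))

    findings: list[GermlineFinding] = []
    for hit in screen_germline(germline_variants or [], kb.predisposition_genes()):
        second = detect_second_hit(hit, variants, svs, profile, kb)
        findings.append(GermlineFinding(variant=hit, second_hit=second))
        if second:
            calls.append(DriverCall(
                gene=hit.gene, alteration=f"germline {hit.hgvs_p} + second hit",
                driver_class="germline_with_second_hit",
                evidence=[f"germline_{hit.clinvar_class}"] + second,
                chrom=kb.entry(hit.gene).chrom if kb.entry(hit.gene) else "",
                pos=kb.entry(hit.gene).start if kb.entry(hit.gene) else 0))

    calls.sort(key=lambda c: (chrom_sort_key(c.chrom), c.pos, c.gene, c.driver_class))
    findings.sort(key=lambda f: (f.variant.gene, f.variant.hgvs_p))
    return calls, findings
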