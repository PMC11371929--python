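"""Driver calling: point drivers, copy-number drivers relative to ploidy,
gene fusions from breakpoint orientation, and germline second hits."""

from oncointerp import (CNSegment, GermlineVariant, SVRecord, TumorProfile,
                        VariantRecord, call_amplification, classify_point_driver,
                        detect_gene_fusion, detect_second_hit, load_knowledgebase,
                        screen_germline)

kb = load_knowledgebase()

# point driver: recurrent, drug-linked oncogene hotspot
variant = VariantRecord(chrom="7", pos=10_100_000, ref="C", alt="T", gene="EGFR",
                        protein_change="L858R", variant_class="missense",
                        tumor_depth=60, tumor_alt=20, normal_depth=25,
                        normal_alt=0, trinucleotide_context="ACA")
call = classify_point_driver(variant, kb.entry("EGFR"))
print(f"EGFR L858R -> {call.driver_class}, evidence {call.evidence}")

# amplification relative to ploidy: FGFR2 at ~185 copies (ecDNA scale)
profile = TumorProfile("S", 0.6, 2.0, segments=[
    CNSegment("10", 1, 19_999_999, 2.0, 1.0),
    CNSegment("10", 20_000_000, 20_120_000, 185.0, 1.0),
    CNSegment("10", 20_120_001, 60_000_000, 2.0, 1.0)])
amp = call_amplification("FGFR2", profile, kb.entry("FGFR2"))
print(f"FGFR2 CN {amp.copy_number:.0f} -> {amp.driver_class}, "
      f"hyperamplified={amp.hyperamplified}")

# fusion: breakpoints inside EML4 and ALK with head-to-tail orientations
alk, eml4 = kb.entry("ALK"), kb.entry("EML4")
sv = SVRecord("2", alk.start + 300_000, "+", "2", eml4.start + 50_000, "+",
              "INV", tumor_support=14, normal_support=0)
for fusion in detect_gene_fusion([sv], kb):
    print(f"fusion {fusion.alteration} ({sv.sv_type}), evidence {fusion.evidence}")

# germline screening and second hit: rare pathogenic BRCA1 variant + tumor LOH
germ = GermlineVariant("BRCA1", "p.L1780P", 0.0001, "pathogenic", True)
kept = screen_germline([germ], kb.predisposition_genes())
loh_profile = TumorProfile("S", 0.6, 2.0, segments=[
    CNSegment("17", 1, 60_000_000, 2.0, 0.0)])
second = detect_second_hit(kept[0], [], [], loh_profile, kb)
print(f"germline {germ.gene} {germ.hgvs_p}: retained by screen, "
      f"second hit: {second}")
# A biallelic-inactivation pattern (germline hit + somatic LOH) is what links a
# pathogenic germline variant causally to the tumor's phenotype.
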