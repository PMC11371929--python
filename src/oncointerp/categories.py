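"""Actionability (I-1/I-2/I-3) and clarity (II-1/II-2/II-3) categorization.

Actionability precedence is I-1 (approved therapy match) > I-2 (trial match) >
I-3 (resistance rule excludes a therapy) > none.  Phenotype rules participate:
MSI-H maps to immune-checkpoint therapy, HRD-positive to PARP inhibitors
(approved in the indicated cancer types, trial-level elsewhere).  The clarity
arm resolves, in precedence order, II-1 (resistance/response mechanism, e.g.
wild-type-allele hyperamplification of the targeted gene), II-2 (tumor-origin
evidence from etiologic signatures: SBS4 and ID3 fractions both >= 0.20 implies
tobacco exposure, hence lung origin) and II-3 (germline evaluation: a positive
screen, or a confident negative with low HRD).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .drivers import DriverCall, GermlineFinding
from .kb import Knowledgebase
from .phenotypes import HRD_PROBABILITY_CUTOFF, PhenotypeReport
from .records import ValidationError
from .reporting_utils import percent
from .signatures import SignatureExposure
from .simulate import expected_vaf

logger = logging.getLogger(__name__)

ACTIONABILITY_CATEGORIES = ("I-1", "I-2", "I-3")
CLARITY_CATEGORIES = ("II-1", "II-2", "II-3")

TOBACCO_SBS4_MIN = 0.20
TOBACCO_ID3_MIN = 0.20
WT_AMP_VAF_FACTOR = 0.5    # observed VAF < 0.5 x expected implies wild-type-allele amp


@dataclass
class CategoryAssignment:
    primary_question: str                      # actionability | clarity
    category: str                              # I-1..I-3, II-1..II-3, none
    evidence: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self):
        if self.category.startswith("I-") and self.primary_question != "actionability":
            raise ValidationError("I-* categories require the actionability question")
        if self.category.startswith("II-") and self.primary_question != "clarity":
            raise ValidationError("II-* categories require the clarity question")
        if self.category != "none" and not self.evidence:
            raise ValidationError("non-none category requires evidence")


def _driver_drug_matches(driver: DriverCall, kb: Knowledgebase, cancer_type: str,
                         evidence_level: str) -> list[tuple[str, str]]:
    entry = kb.entry(driver.gene)
    if entry is None:
        return []
    if driver.driver_class == "oncogene_point":
        alteration = driver.alteration
    elif driver.driver_class == "amplification":
        alteration = "amplification"
    elif driver.driver_class == "fusion":
        alteration = "fusion"
    elif driver.driver_class in ("tsg_inactivating", "biallelic_deletion"):
        alteration = "inactivation"
    else:
        return []
    out = []
    for link in entry.drug_links_for(alteration, cancer_type, evidence_level):
        label = link.drug if link.trial_id is None else f"{link.drug} ({link.trial_id})"
        out.append((f"{driver.gene} {driver.alteration}", label))
    return out


def _phenotype_matches(phenotypes: PhenotypeReport, kb: Knowledgebase,
                       cancer_type: str, evidence_level: str) -> list[tuple[str, str]]:
    rules = kb.phenotype_rules
    out = []
    if phenotypes.msi_call == "MSI-H" and evidence_level == "approved":
        rule = rules.get("msi_h")
        if rule and ("any" in rule["cancer_types"] or cancer_type in rule["cancer_types"]):
            out.append(("MSI-H", rule["drug"]))
    if phenotypes.hrd_positive:
        hrd = rules.get("hrd", {})
        if evidence_level == "approved":
            approved = hrd.get("approved", {})
            if cancer_type in approved.get("cancer_types", []):
                out.append(("HRD-positive", "/".join(approved["drugs"])))
        else:
            trial = hrd.get("trial", {})
            types = trial.get("cancer_types", [])
            if "any" in types or cancer_type in types:
                out.append(("HRD-positive",
                            f"{'/'.join(trial['drugs'])} ({trial.get('trial_id', '')})"))
    return out


def _resistance_matches(drivers: list[DriverCall], kb: Knowledgebase,
                        cancer_type: str) -> list[tuple[str, str]]:
    out = []
    for driver in drivers:
        if driver.driver_class != "oncogene_point":
            continue
        entry = kb.entry(driver.gene)
        if entry is None:
            continue
        for rule in entry.resistance_rules:
            if not rule.matches_cancer_type(cancer_type):
                continue
            fires = (rule.alteration == driver.alteration
                     or (rule.alteration == "any_hotspot"
                         and driver.alteration in entry.hotspots))
            if fires:
                out.append((f"{driver.gene} {driver.alteration}",
                            f"excluded: {rule.excluded_therapy}"))
    return out


def detect_wild_type_allele_amplification(drivers: list[DriverCall],
                                          kb: Knowledgebase,
                                          purity: float) -> list[tuple[str, str]]:
    """Hyperamplified drug-target gene whose co-occurring point mutation sits at a
    VAF far below what a mutant-allele amplification would produce."""
    out = []
    amps = {d.gene: d for d in drivers
            if d.driver_class == "amplification" and d.hyperamplified}
    for point in drivers:
        if point.driver_class != "oncogene_point" or point.vaf is None:
            continue
        amp = amps.get(point.gene)
        if amp is None or amp.copy_number is None:
            continue
        entry = kb.entry(point.gene)
        if entry is None or not entry.drugs:
            continue
        exp = expected_vaf(purity, amp.copy_number / 2.0, amp.copy_number)
        if exp > 0 and point.vaf < WT_AMP_VAF_FACTOR * exp:
            out.append((f"{point.gene} {point.alteration} + CN {amp.copy_number:.0f}",
                        "wild-type allele amplification"))
    return out


def assign_category(drivers: list[DriverCall], phenotypes: PhenotypeReport,
                    germline_findings: list[GermlineFinding], kb: Knowledgebase,
                    cancer_type: str, question: str, purity: float = 0.5,
                    sbs_exposure: SignatureExposure | None = None,
                    id_exposure: SignatureExposure | None = None,
                    ) -> CategoryAssignment:
    """Assign the sample's category for its primary clinical question."""
    known_types = {"lung", "breast", "colorectal", "stomach", "prostate", "ovarian",
                   "urothelial", "cholangiocarcinoma", "melanoma", "pancreatic"}
    if cancer_type not in known_types:
        logger.info("cancer type %r not recognized; type-agnostic rules only",
                    cancer_type)

    drivers = sorted(drivers, key=lambda d: (d.gene, d.driver_class, d.alteration))

    if question == "actionability":
        approved: list[tuple[str, str]] = []
        for d in drivers:
            approved += _driver_drug_matches(d, kb, cancer_type, "approved")
        approved += _phenotype_matches(phenotypes, kb, cancer_type, "approved")
        if approved:
            return CategoryAssignment("actionability", "I-1", approved)

        trials: list[tuple[str, str]] = []
        for d in drivers:
            trials += _driver_drug_matches(d, kb, cancer_type, "trial")
        trials += _phenotype_matches(phenotypes, kb, cancer_type, "trial")
        if trials:
            return CategoryAssignment("actionability", "I-2", trials)

        resistance = _resistance_matches(drivers, kb, cancer_type)
        if resistance:
            return CategoryAssignment("actionability", "I-3", resistance)
        return CategoryAssignment("actionability", "none", [])

    if question != "clarity":
        raise ValidationError(f"unknown question {question!r}")

    mechanism = detect_wild_type_allele_amplification(drivers, kb, purity)
    if mechanism:
        return CategoryAssignment("clarity", "II-1", mechanism)

    if sbs_exposure is not None and id_exposure is not None:
        sbs4 = sbs_exposure.fraction("SBS4")
        id3 = id_exposure.fraction("ID3")
        if sbs4 >= TOBACCO_SBS4_MIN and id3 >= TOBACCO_ID3_MIN:
            return CategoryAssignment(
                "clarity", "II-2",
                [(f"SBS4 {sbs4:.1%} / ID3 {id3:.1%}",
                  "tobacco-exposure signature: lung origin")])

    if germline_findings:
        ev = [(f"{f.variant.gene} {f.variant.hgvs_p}",
               "germline pathogenic" + (" + second hit" if f.has_second_hit else ""))
              for f in germline_findings]
        return CategoryAssignment("clarity", "II-3", ev)
    if phenotypes.hrd_probability < HRD_PROBABILITY_CUTOFF:
        return CategoryAssignment(
            "clarity", "II-3",
            [("no pathogenic germline variant; HRD low",
              "familial cancer confidently excluded")])
    return CategoryAssignment("clarity", "none", [])


@dataclass
class CohortSummary:
    counts: dict[str, int]
    denominators: dict[str, int]       # per arm

    def percentage(self, category: str, decimals: int = 1) -> float:
        arm = "actionability" if category.startswith("I-") else "clarity"
        return percent(self.counts.get(category, 0), self.denominators[arm], decimals)

    def supportive_count(self, arm: str) -> int:
        cats = ACTIONABILITY_CATEGORIES if arm == "actionability" else CLARITY_CATEGORIES
        return sum(self.counts.get(c, 0) for c in cats)

    def supportive_percentage(self, arm: str, decimals: int = 1) -> float:
        return percent(self.supportive_count(arm), self.denominators[arm], decimals)

    def overall_supportive_percentage(self, decimals: int = 0) -> float:
        total = sum(self.denominators.values())
        supportive = (self.supportive_count("actionability")
                      + self.supportive_count("clarity"))
        return percent(supportive, total, decimals)


def summarize_cohort(assignments: list[CategoryAssignment]) -> CohortSummary:
    """Per-category counts and denominators over the two question arms."""
    if not assignments:
        raise ValidationError("cohort summary requires at least one assignment")
    counts: dict[str, int] = {}
    denoms = {"actionability": 0, "clarity": 0}
    for a in assignments:
        denoms[a.primary_question] += 1
        if a.category != "none":
            counts[a.category] = counts.get(a.category, 0) + 1
    denoms = {k: v for k, v in denoms.items() if v}
    return CohortSummary(counts=counts, denominators=denoms)
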