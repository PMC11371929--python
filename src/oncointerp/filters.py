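"""High-confidence somatic variant and SV selection.

A small-variant call is retained when it has at least 2 supporting reads in the
tumor, at most 1 in the normal, mapping quality >= 15, normal-sample VAF <= 5%
and panel-of-normals allele frequency <= 1%.  SVs are retained under the
analogous support/quality criteria with a 5% panel-of-normals ceiling.  All
boundaries are inclusive on the passing side.

The 5% VAF ceiling is applied to the NORMAL sample by default (a contamination
guard); a tumor-side reading of the rule is available via
``vaf_ceiling_applies_to="tumor"``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .records import SVRecord, ValidationError, VariantRecord

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FilterThresholds:
    min_tumor_alt: int = 2
    max_normal_alt: int = 1
    min_mapping_quality: float = 15.0
    max_normal_vaf: float = 0.05
    max_pon_af: float = 0.01
    sv_min_tumor_support: int = 2
    sv_max_normal_support: int = 1
    sv_min_mq: float = 15.0
    sv_max_pon_freq: float = 0.05
    vaf_ceiling_applies_to: str = "normal"

    def __post_init__(self):
        for name in ("min_tumor_alt", "max_normal_alt", "min_mapping_quality",
                     "sv_min_tumor_support", "sv_max_normal_support", "sv_min_mq"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        for name in ("max_normal_vaf", "max_pon_af", "sv_max_pon_freq"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValidationError(f"{name} must be in [0, 1]")
        if self.vaf_ceiling_applies_to not in ("normal", "tumor"):
            raise ValidationError("vaf_ceiling_applies_to must be 'normal' or 'tumor'")


@dataclass
class FilterVerdict:
    passed: bool
    failed_criteria: list[str] = field(default_factory=list)


def _evaluate_snv(rec: VariantRecord, t: FilterThresholds) -> FilterVerdict:
    failed = []
    if rec.tumor_alt < t.min_tumor_alt:
        failed.append("min_tumor_alt")
    if rec.normal_alt > t.max_normal_alt:
        failed.append("max_normal_alt")
    if rec.mapping_quality < t.min_mapping_quality:
        failed.append("min_mapping_quality")
    if t.vaf_ceiling_applies_to == "normal":
        if rec.normal_depth == 0:
            # no normal coverage: VAF treated as 0, noted once per call site
            vaf = 0.0
        else:
            vaf = rec.normal_vaf
        if vaf > t.max_normal_vaf:
            failed.append("max_normal_vaf")
    else:
        if rec.tumor_vaf > t.max_normal_vaf:
            failed.append("max_tumor_vaf")
    if rec.pon_af > t.max_pon_af:
        failed.append("max_pon_af")
    return FilterVerdict(passed=not failed, failed_criteria=failed)


def filter_snv_indel(records: list[VariantRecord],
                     thresholds: FilterThresholds | None = None,
                     ) -> tuple[list[VariantRecord], list[FilterVerdict]]:
    """Apply the high-confidence criteria; returns (passing records, all verdicts).

    Verdicts are positional (one per input record) and carry every failed
    criterion by name for records that do not pass.
    """
    t = thresholds or FilterThresholds()
    if any(r.normal_depth == 0 for r in records):
        logger.info("records with zero normal depth: normal VAF treated as 0")
    verdicts = [_evaluate_snv(r, t) for r in records]
    passing = [r for r, v in zip(records, verdicts) if v.passed]
    return passing, verdicts


def _evaluate_sv(sv: SVRecord, t: FilterThresholds) -> FilterVerdict:
    failed = []
    if sv.tumor_support < t.sv_min_tumor_support:
        failed.append("sv_min_tumor_support")
    if sv.normal_support > t.sv_max_normal_support:
        failed.append("sv_max_normal_support")
    if sv.mapping_quality < t.sv_min_mq:
        failed.append("sv_min_mq")
    if sv.pon_freq > t.sv_max_pon_freq:
        failed.append("sv_max_pon_freq")
    return FilterVerdict(passed=not failed, failed_criteria=failed)


def filter_sv(svs: list[SVRecord], thresholds: FilterThresholds | None = None,
              ) -> tuple[list[SVRecord], list[FilterVerdict]]:
    """Apply the SV selection criteria; returns (passing SVs, all verdicts)."""
    t = thresholds or FilterThresholds()
    verdicts = [_evaluate_sv(s, t) for s in svs]
    passing = [s for s, v in zip(svs, verdicts) if v.passed]
    return passing, verdicts
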