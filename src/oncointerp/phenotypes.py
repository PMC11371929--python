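"""Sample-level genome phenotypes: TMB, whole-genome duplication, HRD, MSI.

HRD is scored as a logistic model over six feature groups — SBS3/SBS8 exposure
fractions, the ID6 fraction, the RS3+RS5 rearrangement fraction, the proportion
of deletions at microhomology, and the count of long LOH segments — positive at
probability >= 0.7.  MSI is called from two independent evidence sources: a
microsatellite-site instability score (fraction of loci whose tumor repeat-length
histogram differs from the normal) and the summed exposure fraction of the seven
MSI-associated SBS signatures.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from importlib.resources import files
from pathlib import Path

import numpy as np
from scipy.stats import chi2_contingency, false_discovery_control

from .records import MicrosatelliteSite, TumorProfile, ValidationError
from .signatures import (MutationalCatalog, SignatureExposure,
                         mh_deletion_proportion, msi_signature_proportion)

HRD_PROBABILITY_CUTOFF = 0.7       # inclusive: score >= 0.7 is HRD positive
WGD_PLOIDY_CUTOFF = 3.5            # strict: ploidy > 3.5 is a whole-genome duplication
DEFAULT_CALLABLE_MB = 2800.0
MSI_SCORE_THRESHOLD = 3.5
MSI_PROPORTION_THRESHOLD = 0.20
LOH_MIN_SEGMENT_BP = 15_000_000
_WHOLE_CHROM_FRACTION = 0.99


@dataclass
class HRDFeatures:
    sbs3_count: float
    sbs3_fraction: float
    sbs8_count: float
    sbs8_fraction: float
    id6_count: float
    id6_fraction: float
    rs3_count: float
    rs5_count: float
    rs_fraction: float
    mh_del_proportion: float
    loh_segment_count: int
    degenerate_indels: bool = False

    def as_feature_dict(self) -> dict[str, float]:
        return {
            "sbs3_fraction": self.sbs3_fraction,
            "sbs8_fraction": self.sbs8_fraction,
            "id6_fraction": self.id6_fraction,
            "rs_fraction": self.rs_fraction,
            "mh_del_proportion": self.mh_del_proportion,
            "loh_segment_count": float(self.loh_segment_count),
        }


@dataclass
class PhenotypeReport:
    tmb: float
    wgd: bool
    hrd_probability: float
    hrd_positive: bool
    msisensor_like_score: float
    msi_signature_proportion: float
    msi_call: str

    def __post_init__(self):
        if self.hrd_positive != (self.hrd_probability >= HRD_PROBABILITY_CUTOFF):
            raise ValidationError("hrd_positive inconsistent with hrd_probability")


def compute_tmb(filtered_variant_count: int,
                callable_mb: float = DEFAULT_CALLABLE_MB) -> float:
    """Somatic mutations per megabase of callable genome."""
    if callable_mb <= 0:
        raise ValidationError("callable_mb must be positive")
    return filtered_variant_count / callable_mb


def call_wgd(ploidy: float) -> bool:
    """Whole-genome duplication: ploidy strictly above 3.5."""
    if ploidy <= 0:
        raise ValidationError("ploidy must be positive")
    return ploidy > WGD_PLOIDY_CUTOFF


def count_loh_segments(profile: TumorProfile,
                       min_length: int = LOH_MIN_SEGMENT_BP,
                       chromosome_length: int | None = None) -> int:
    """Segments with minor copy number 0 and length >= 15 Mb, excluding
    whole-chromosome LOH (a segment spanning >= 99% of its chromosome)."""
    n = 0
    for seg in profile.segments:
        if seg.minor_cn > 1e-9 or seg.length < min_length:
            continue
        if chromosome_length is not None and \
                seg.length >= _WHOLE_CHROM_FRACTION * chromosome_length:
            continue
        n += 1
    return n


def extract_hrd_features(sbs_exposure: SignatureExposure,
                         id_exposure: SignatureExposure,
                         sv_exposure: SignatureExposure,
                         id_catalog: MutationalCatalog,
                         profile: TumorProfile,
                         chromosome_length: int | None = None) -> HRDFeatures:
    """Assemble the six HRD-associated feature groups for one sample."""
    if sbs_exposure.sig_class != "SBS96" or id_exposure.sig_class != "ID83" \
            or sv_exposure.sig_class != "SV32" or id_catalog.sig_class != "ID83":
        raise ValidationError("exposure/catalog classes do not match their roles")
    degenerate = id_catalog.total == 0
    return HRDFeatures(
        sbs3_count=sbs_exposure.exposures.get("SBS3", 0.0),
        sbs3_fraction=sbs_exposure.fraction("SBS3"),
        sbs8_count=sbs_exposure.exposures.get("SBS8", 0.0),
        sbs8_fraction=sbs_exposure.fraction("SBS8"),
        id6_count=id_exposure.exposures.get("ID6", 0.0),
        id6_fraction=id_exposure.fraction("ID6"),
        rs3_count=sv_exposure.exposures.get("RS3", 0.0),
        rs5_count=sv_exposure.exposures.get("RS5", 0.0),
        rs_fraction=sv_exposure.fraction("RS3", "RS5"),
        mh_del_proportion=mh_deletion_proportion(id_catalog),
        loh_segment_count=count_loh_segments(
            profile, chromosome_length=chromosome_length),
        degenerate_indels=degenerate,
    )


def load_hrd_coefficients(path: str | Path | None = None) -> dict:
    if path is None:
        raw = files("oncointerp.data").joinpath("hrd_coefficients.json").read_text()
    else:
        raw = Path(path).read_text()
    return json.loads(raw)


def hrd_probability(features: HRDFeatures, coefficients: dict | None = None) -> float:
    """Logistic HRD probability over standardized features; positive at >= 0.7."""
    coef = coefficients or load_hrd_coefficients()
    values = features.as_feature_dict()
    z = float(coef["intercept"])
    for name, spec in coef["features"].items():
        if name not in values:
            raise ValidationError(f"feature {name!r} missing from HRD feature vector")
        z += spec["weight"] * (values[name] - spec["mean"]) / spec["scale"]
    return 1.0 / (1.0 + math.exp(-z))


def is_hrd_positive(probability: float) -> bool:
    return probability >= HRD_PROBABILITY_CUTOFF


def _site_pvalue(site: MicrosatelliteSite) -> float:
    lengths = sorted(set(site.tumor_hist) | set(site.normal_hist))
    tumor = np.array([site.tumor_hist.get(l, 0) for l in lengths], dtype=float)
    normal = np.array([site.normal_hist.get(l, 0) for l in lengths], dtype=float)
    keep = (tumor + normal) > 0
    tumor, normal = tumor[keep], normal[keep]
    if len(tumor) < 2:
        return 1.0
    if np.array_equal(tumor / tumor.sum(), normal / normal.sum()):
        return 1.0
    _, p, _, _ = chi2_contingency(np.vstack([tumor, normal]))
    return float(p)


def msisensor_like_score(sites: list[MicrosatelliteSite], alpha: float = 0.05,
                         min_reads: int = 20) -> float:
    """Percentage of evaluable microsatellite loci with a somatic length-histogram
    shift (tumor vs normal chi-square, Benjamini-Hochberg adjusted p < alpha).

    A locus is evaluable when both samples have >= ``min_reads`` supporting reads.
    """
    evaluable = [s for s in sites
                 if sum(s.tumor_hist.values()) >= min_reads
                 and sum(s.normal_hist.values()) >= min_reads]
    if not evaluable:
        raise ValidationError("no evaluable microsatellite sites")
    pvals = np.array([_site_pvalue(s) for s in evaluable])
    adjusted = false_discovery_control(pvals, method="bh")
    return 100.0 * float((adjusted < alpha).sum()) / len(evaluable)


def msi_call(score: float, msi_sig_proportion: float,
             score_threshold: float = MSI_SCORE_THRESHOLD,
             proportion_threshold: float = MSI_PROPORTION_THRESHOLD) -> str:
    """MSI-H when either evidence source crosses its threshold (both inclusive)."""
    if score >= score_threshold or msi_sig_proportion >= proportion_threshold:
        return "MSI-H"
    return "MSS"


def compute_phenotypes(filtered_variant_count: int,
                       profile: TumorProfile,
                       sbs_exposure: SignatureExposure,
                       id_exposure: SignatureExposure,
                       sv_exposure: SignatureExposure,
                       id_catalog: MutationalCatalog,
                       sites: list[MicrosatelliteSite],
                       callable_mb: float = DEFAULT_CALLABLE_MB,
                       chromosome_length: int | None = None,
                       hrd_coefficients: dict | None = None) -> PhenotypeReport:
    """Run every phenotype caller for one sample and assemble the report."""
    features = extract_hrd_features(sbs_exposure, id_exposure, sv_exposure,
                                    id_catalog, profile,
                                    chromosome_length=chromosome_length)
    prob = hrd_probability(features, hrd_coefficients)
    score = msisensor_like_score(sites) if sites else 0.0
    proportion = msi_signature_proportion(sbs_exposure)
    return PhenotypeReport(
        tmb=compute_tmb(filtered_variant_count, callable_mb),
        wgd=call_wgd(profile.ploidy),
        hrd_probability=prob,
        hrd_positive=is_hrd_positive(prob),
        msisensor_like_score=score,
        msi_signature_proportion=proportion,
        msi_call=msi_call(score, proportion),
    )
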