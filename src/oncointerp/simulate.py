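"""Synthetic tumor/normal call-set generator with known ground truth.

Emulates the *outputs* of a somatic calling stage (SNV/indel records with read
evidence, SV breakpoint pairs, a purity/ploidy-annotated copy-number profile,
germline variants and a microsatellite site table) on a miniature genome of
23 chromosomes x 60 Mb, so that every interpretation stage has a deterministic,
no-download test surface.

Mutation channels are drawn multinomially from the configured signature mixture;
read support is binomial around the expected variant allele fraction
purity x mutated_copies / (purity x total_CN + 2(1 - purity)), with local tumor
depth scaled by copy number around a 40x diploid average (20x for the normal).
Injected artifact records each violate exactly one named filter criterion.
Identical configs (including seed) produce identical output, byte for byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .channels import (ID83_CHANNELS, SBS96_CHANNELS, SV32_CHANNELS,
                       reverse_complement, sbs96_channel)
from .kb import Knowledgebase, load_knowledgebase
from .records import (CNSegment, GermlineVariant, IndelFeatures,
                      MicrosatelliteSite, SVRecord, TumorProfile,
                      ValidationError, VariantRecord)
from .refsigs import build_reference
from .signatures import MutationalCatalog, SignatureReference

TUMOR_DEPTH_MEAN = 40.0    # diploid-equivalent tumor coverage
NORMAL_DEPTH_MEAN = 20.0
_CLUSTER_HOTSPOT = ("1", 5_000_000, 6_000_000)   # clustered SVs accumulate here
_NONCLUSTERED_KEEPOUT = ("1", 3_000_000, 9_000_000)

_SV_BIN_RANGES = {"<10kb": (1_000, 10_000), "10-100kb": (10_000, 100_000),
                  "100kb-1Mb": (100_000, 1_000_000), "1-10Mb": (1_000_000, 10_000_000),
                  ">10Mb": (10_000_000, 20_000_000)}

SNV_ARTIFACT_CRITERIA = ("min_tumor_alt", "max_normal_alt", "min_mapping_quality",
                         "max_normal_vaf", "max_pon_af")
SV_ARTIFACT_CRITERIA = ("sv_min_tumor_support", "sv_max_normal_support",
                        "sv_min_mq", "sv_max_pon_freq")


@dataclass(frozen=True)
class DriverSpec:
    """One injected driver: a point mutation, CNA, or fusion instruction."""
    gene: str
    kind: str                      # point | amplification | deletion | fusion
    descriptor: str = ""           # protein change for point drivers
    variant_class: str = "missense"
    copy_number: float = 20.0
    partner: str = ""              # 5' partner gene for fusions
    vaf: float | None = None       # override observed tumor VAF (e.g. wild-type amp)


@dataclass(frozen=True)
class GermlinePayload:
    variant: GermlineVariant
    second_hit: str = "none"       # loh | somatic_truncating | none


@dataclass
class SimulationConfig:
    seed: int = 0
    sample_id: str = "SIM-001"
    cancer_type: str = "unknown"
    question: str = "actionability"        # actionability | clarity
    n_sbs: int = 3000
    n_indel: int = 800
    n_sv: int = 200
    signature_mixture: dict[str, dict[str, float]] | None = None
    drivers: list[DriverSpec] = field(default_factory=list)
    purity: float = 0.6
    ploidy: float = 2.0
    msi_status: str = "MSS"
    hrd_status: bool = False
    germline_payload: list[GermlinePayload] = field(default_factory=list)
    artifact_fraction: float = 0.10
    n_microsat_sites: int = 200
    msi_site_fraction: float = 0.30
    n_loh_segments: int | None = None      # default: 12 if HRD else 2
    sample_type: str = "fresh"
    acquisition: str = "surgery"
    intended_category: str = ""

    def __post_init__(self):
        if self.n_sbs < 0 or self.n_indel < 0 or self.n_sv < 0:
            raise ValidationError("mutation counts must be >= 0")
        if not 0 <= self.purity <= 1:
            raise ValidationError("purity must be in [0, 1]")
        if self.msi_status not in ("MSS", "MSI-H"):
            raise ValidationError(f"unknown msi_status {self.msi_status!r}")
        if self.question not in ("actionability", "clarity"):
            raise ValidationError(f"unknown question {self.question!r}")


def default_mixture(hrd_status: bool, msi_status: str) -> dict[str, dict[str, float]]:
    """Study-condition signature mixtures for the three phenotype archetypes."""
    if msi_status == "MSI-H":
        sbs = {"SBS1": 0.20, "SBS5": 0.20, "SBS6": 0.15, "SBS15": 0.09,
               "SBS20": 0.09, "SBS21": 0.09, "SBS26": 0.09, "SBS44": 0.09}
        idm = {"ID1": 0.5, "ID2": 0.5}
        sv = {"RS1": 0.5, "RS2": 0.5}
    elif hrd_status:
        sbs = {"SBS1": 0.20, "SBS3": 0.35, "SBS5": 0.35, "SBS8": 0.10}
        idm = {"ID1": 0.30, "ID2": 0.25, "ID6": 0.45}
        sv = {"RS1": 0.20, "RS2": 0.20, "RS3": 0.30, "RS5": 0.30}
    else:
        sbs = {"SBS1": 0.40, "SBS5": 0.60}
        idm = {"ID1": 0.60, "ID2": 0.40}
        sv = {"RS1": 0.50, "RS2": 0.50}
    return {"SBS96": sbs, "ID83": idm, "SV32": sv}


@dataclass
class GroundTruth:
    """Intended labels for every emitted record plus sample-level phenotypes."""
    sample_id: str
    variant_labels: list[dict]
    sv_labels: list[dict]
    germline_labels: list[dict]
    phenotype: dict
    expected_catalogs: dict[str, MutationalCatalog]
    intended_category: str


def ground_truth_manifest(truth: GroundTruth) -> pd.DataFrame:
    """One row per injected element with its intended downstream classification."""
    rows = []
    for i, lab in enumerate(truth.variant_labels):
        rows.append({"record_type": lab["kind"], "index": i, "label": lab["label"],
                     "detail": lab.get("detail", "")})
    for i, lab in enumerate(truth.sv_labels):
        rows.append({"record_type": "sv", "index": i, "label": lab["label"],
                     "detail": lab.get("detail", "")})
    for i, lab in enumerate(truth.germline_labels):
        rows.append({"record_type": "germline", "index": i, "label": lab["label"],
                     "detail": lab.get("detail", "")})
    for key, value in truth.phenotype.items():
        rows.append({"record_type": "phenotype", "index": -1, "label": key,
                     "detail": str(value)})
    return pd.DataFrame(rows, columns=["record_type", "index", "label", "detail"])


# --- copy-number scaffolding --------------------------------------------------

def _apply_override(segments: list[CNSegment], chrom: str, start: int, end: int,
                    total: float, minor: float) -> list[CNSegment]:
    """Overlay one interval onto a non-overlapping segment list (override wins)."""
    out = []
    for seg in segments:
        if seg.chrom != chrom or seg.end < start or seg.start > end:
            out.append(seg)
            continue
        if seg.start < start:
            out.append(CNSegment(chrom, seg.start, start - 1, seg.total_cn, seg.minor_cn))
        if seg.end > end:
            out.append(CNSegment(chrom, end + 1, seg.end, seg.total_cn, seg.minor_cn))
    out.append(CNSegment(chrom, start, end, total, minor))
    return out


def _build_profile(config: SimulationConfig, kb: Knowledgebase) -> TumorProfile:
    L = kb.chromosome_length
    base_total = float(round(config.ploidy))
    base_minor = float(max(1, round(config.ploidy / 2))) if base_total >= 2 else 0.0
    segments: list[CNSegment] = [CNSegment(c, 1, L, base_total, base_minor)
                                 for c in kb.chromosomes]

    n_loh = config.n_loh_segments
    if n_loh is None:
        n_loh = 12 if config.hrd_status else 2
    # LOH segments on a fixed chromosome rotation, 20 Mb each, copy-neutral
    loh_chroms = [c for c in kb.chromosomes
                  if c not in ("1",)][:max(n_loh, 0)]
    germline_loh_genes = {p.variant.gene for p in config.germline_payload
                          if p.second_hit == "loh"}
    reserved = {kb.entry(g).chrom for g in germline_loh_genes if kb.entry(g)}
    placed = 0
    for chrom in loh_chroms:
        if placed >= n_loh:
            break
        if chrom in reserved:
            continue
        # copy-neutral LOH: total CN kept, minor allele lost
        segments = _apply_override(segments, chrom, 20_000_001, 40_000_000,
                                   base_total, 0.0)
        placed += 1

    for gene in sorted(germline_loh_genes):
        entry = kb.entry(gene)
        if entry is None:
            raise ValidationError(f"germline payload gene {gene!r} not in knowledgebase")
        start = max(1, entry.start - 2_000_000)
        end = min(L, start + 20_000_000 - 1)
        segments = _apply_override(segments, entry.chrom, start, end,
                                   base_total, 0.0)

    for spec in config.drivers:
        entry = kb.entry(spec.gene)
        if entry is None:
            raise ValidationError(f"driver gene {spec.gene!r} not in knowledgebase")
        if spec.kind == "amplification":
            segments = _apply_override(segments, entry.chrom, entry.start, entry.end,
                                       float(spec.copy_number), base_minor)
        elif spec.kind == "deletion":
            segments = _apply_override(segments, entry.chrom, entry.start, entry.end,
                                       0.0, 0.0)

    return TumorProfile(sample_id=config.sample_id, tcf=config.purity,
                        ploidy=config.ploidy, segments=segments,
                        sample_type=config.sample_type,
                        acquisition=config.acquisition,
                        cancer_type=config.cancer_type)


# --- read evidence ------------------------------------------------------------

def _total_cn_at(profile: TumorProfile, chrom: str, pos: int, default: float) -> float:
    for seg in profile.segments_overlapping(chrom, pos, pos):
        return seg.total_cn
    return default


def expected_vaf(purity: float, mutated_copies: float, total_cn: float) -> float:
    denom = purity * total_cn + 2.0 * (1.0 - purity)
    if denom <= 0:
        return 0.0
    return purity * mutated_copies / denom


def _tumor_evidence(rng: np.random.Generator, purity: float, total_cn: float,
                    vaf_override: float | None = None) -> tuple[int, int]:
    depth_scale = (purity * total_cn + 2.0 * (1.0 - purity)) / 2.0
    depth = max(int(rng.poisson(TUMOR_DEPTH_MEAN * depth_scale)), 8)
    vaf = vaf_override if vaf_override is not None else expected_vaf(purity, 1.0, total_cn)
    alt = int(rng.binomial(depth, min(max(vaf, 0.0), 1.0)))
    return depth, min(max(alt, 2), depth)   # intended-pass records keep >= 2 alt reads


def _normal_evidence(rng: np.random.Generator) -> tuple[int, int]:
    return max(int(rng.poisson(NORMAL_DEPTH_MEAN)), 1), 0


# --- channel -> record materialization ----------------------------------------

def _random_position(rng: np.random.Generator, kb: Knowledgebase) -> tuple[str, int]:
    chrom = kb.chromosomes[int(rng.integers(len(kb.chromosomes)))]
    pos = int(rng.integers(1, kb.chromosome_length))
    return chrom, pos


def _snv_from_channel(channel: str, rng: np.random.Generator, kb: Knowledgebase,
                      profile: TumorProfile, config: SimulationConfig) -> VariantRecord:
    five, sub, three = channel[0], channel[2:5], channel[6]
    ref, alt = sub[0], sub[2]
    context = five + ref + three
    if rng.random() < 0.3:      # present some records on the purine strand
        ref, alt = {"C": "G", "T": "A"}[ref], reverse_complement(alt)
        context = reverse_complement(context)
    chrom, pos = _random_position(rng, kb)
    cn = _total_cn_at(profile, chrom, pos, 2.0)
    tdepth, talt = _tumor_evidence(rng, config.purity, cn)
    ndepth, nalt = _normal_evidence(rng)
    return VariantRecord(chrom=chrom, pos=pos, ref=ref, alt=alt,
                         variant_class="other", tumor_depth=tdepth, tumor_alt=talt,
                         normal_depth=ndepth, normal_alt=nalt,
                         mapping_quality=60.0, pon_af=0.0,
                         trinucleotide_context=context)


def _indel_from_channel(channel: str, rng: np.random.Generator, kb: Knowledgebase,
                        profile: TumorProfile, config: SimulationConfig,
                        ) -> VariantRecord:
    parts = channel.split(".")
    kind, sub = parts[0], parts[1]
    chrom, pos = _random_position(rng, kb)
    if sub in ("C", "T"):
        base = sub
        count = int(parts[3].rstrip("+"))
        seq = base
        features = IndelFeatures(1, count, 0)
    elif sub == "repeats":
        size = int(parts[2].rstrip("+"))
        count = int(parts[3].rstrip("+"))
        seq = ("ACGT" * ((size // 4) + 1))[:size]
        features = IndelFeatures(size, count, 0)
    else:  # MH
        size = int(parts[2].rstrip("+"))
        mh = int(parts[3].rstrip("+"))
        seq = ("ACGT" * ((size // 4) + 1))[:size]
        features = IndelFeatures(size, 1, mh)
    if kind == "DEL":
        ref, alt = "A" + seq, "A"
    else:
        ref, alt = "A", "A" + seq
    cn = _total_cn_at(profile, chrom, pos, 2.0)
    tdepth, talt = _tumor_evidence(rng, config.purity, cn)
    ndepth, nalt = _normal_evidence(rng)
    return VariantRecord(chrom=chrom, pos=pos, ref=ref, alt=alt,
                         variant_class="other", tumor_depth=tdepth, tumor_alt=talt,
                         normal_depth=ndepth, normal_alt=nalt,
                         mapping_quality=60.0, pon_af=0.0, indel_features=features)


def _sv_from_channel(channel: str, rng: np.random.Generator, kb: Knowledgebase,
                     ) -> SVRecord:
    parts = channel.split(".")
    clustered = parts[0] == "clustered"
    sv_type = parts[1]
    hot_chrom, hot_lo, hot_hi = _CLUSTER_HOTSPOT
    if sv_type == "TRA":
        if clustered:
            chrom_a = hot_chrom
            pos_a = int(rng.integers(hot_lo, hot_hi))
        else:
            chrom_a, pos_a = _nonclustered_position(rng, kb)
        others = [c for c in kb.chromosomes if c != chrom_a]
        chrom_b = others[int(rng.integers(len(others)))]
        pos_b = int(rng.integers(1, kb.chromosome_length))
        orient_a, orient_b = "+", "-"
        size_args = {}
    else:
        lo, hi = _SV_BIN_RANGES[parts[2]]
        size = int(rng.integers(lo, hi))
        if clustered:
            # breakpoint A always inside the hotspot so density flags it
            chrom_a = hot_chrom
            pos_a = int(rng.integers(hot_lo, hot_hi))
        else:
            chrom_a, pos_a = _nonclustered_position(rng, kb, margin=size)
        pos_b = pos_a + size
        chrom_b = chrom_a
        orient_a, orient_b = {"DEL": ("+", "-"), "DUP": ("-", "+"),
                              "INV": ("+", "+")}[sv_type]
        size_args = {}
    support = max(int(rng.poisson(15)), 2)
    return SVRecord(chrom_a=chrom_a, pos_a=pos_a, orient_a=orient_a,
                    chrom_b=chrom_b, pos_b=pos_b, orient_b=orient_b,
                    sv_type=sv_type, tumor_support=support, normal_support=0,
                    mapping_quality=60.0, pon_freq=0.0,
                    homology_len=int(rng.integers(0, 6)), **size_args)


def _nonclustered_position(rng: np.random.Generator, kb: Knowledgebase,
                           margin: int = 0) -> tuple[str, int]:
    ko_chrom, ko_lo, ko_hi = _NONCLUSTERED_KEEPOUT
    while True:
        chrom = kb.chromosomes[int(rng.integers(len(kb.chromosomes)))]
        hi = kb.chromosome_length - margin
        if hi <= 1:
            continue
        pos = int(rng.integers(1, hi))
        if chrom == ko_chrom and (ko_lo <= pos <= ko_hi
                                  or ko_lo <= pos + margin <= ko_hi
                                  or (pos < ko_lo and pos + margin > ko_hi)):
            continue
        return chrom, pos


# --- artifact injection -------------------------------------------------------

def _snv_artifact(base: VariantRecord, criterion: str) -> VariantRecord:
    if criterion == "min_tumor_alt":
        return replace(base, tumor_alt=1)
    if criterion == "max_normal_alt":
        return replace(base, normal_depth=60, normal_alt=2)
    if criterion == "min_mapping_quality":
        return replace(base, mapping_quality=10.0)
    if criterion == "max_normal_vaf":
        return replace(base, normal_depth=10, normal_alt=1)
    if criterion == "max_pon_af":
        return replace(base, pon_af=0.05)
    raise ValidationError(f"unknown artifact criterion {criterion!r}")


def _sv_artifact(base: SVRecord, criterion: str) -> SVRecord:
    if criterion == "sv_min_tumor_support":
        return replace(base, tumor_support=1)
    if criterion == "sv_max_normal_support":
        return replace(base, normal_support=2)
    if criterion == "sv_min_mq":
        return replace(base, mapping_quality=10.0)
    if criterion == "sv_max_pon_freq":
        return replace(base, pon_freq=0.10)
    raise ValidationError(f"unknown artifact criterion {criterion!r}")


# --- driver materialization ---------------------------------------------------

def _point_driver_record(spec: DriverSpec, rng: np.random.Generator,
                         kb: Knowledgebase, profile: TumorProfile,
                         config: SimulationConfig) -> VariantRecord:
    entry = kb.entry(spec.gene)
    pos = entry.start + entry.length // 2
    cn = _total_cn_at(profile, entry.chrom, pos, 2.0)
    tdepth, talt = _tumor_evidence(rng, config.purity, cn, vaf_override=spec.vaf)
    ndepth, nalt = _normal_evidence(rng)
    if spec.variant_class in ("missense", "promoter", "synonymous", "nonsense"):
        kwargs = {"ref": "C", "alt": "T", "trinucleotide_context": "ACA"}
    else:  # frameshift / inframe indels
        kwargs = {"ref": "AC", "alt": "A",
                  "indel_features": IndelFeatures(1, 1, 0)}
    return VariantRecord(chrom=entry.chrom, pos=pos, gene=spec.gene,
                         protein_change=spec.descriptor,
                         variant_class=spec.variant_class,
                         tumor_depth=tdepth, tumor_alt=talt,
                         normal_depth=ndepth, normal_alt=nalt,
                         mapping_quality=60.0, pon_af=0.0, **kwargs)


def _fusion_sv(spec: DriverSpec, rng: np.random.Generator, kb: Knowledgebase,
               ) -> SVRecord:
    three = kb.entry(spec.gene)
    five = kb.entry(spec.partner)
    if three is None or five is None:
        raise ValidationError(
            f"fusion partners {spec.partner!r}/{spec.gene!r} must be in knowledgebase")

    def pick_intron(entry):
        introns = entry.intron_intervals()
        s, e = introns[len(introns) // 2]
        return int(rng.integers(s, e + 1))

    pos5, pos3 = pick_intron(five), pick_intron(three)
    orient5 = "+" if five.strand == "+" else "-"
    orient3 = "-" if three.strand == "+" else "+"
    if five.chrom == three.chrom:
        sv_type = "INV" if orient5 == orient3 else ("DEL" if orient5 == "+" else "DUP")
        if pos5 <= pos3:
            a = (five.chrom, pos5, orient5)
            b = (three.chrom, pos3, orient3)
        else:
            a = (three.chrom, pos3, orient3)
            b = (five.chrom, pos5, orient5)
    else:
        sv_type = "TRA"
        a = (five.chrom, pos5, orient5)
        b = (three.chrom, pos3, orient3)
    return SVRecord(chrom_a=a[0], pos_a=a[1], orient_a=a[2],
                    chrom_b=b[0], pos_b=b[1], orient_b=b[2],
                    sv_type=sv_type, tumor_support=max(int(rng.poisson(15)), 2),
                    normal_support=0, mapping_quality=60.0, pon_freq=0.0,
                    homology_len=int(rng.integers(0, 6)))


# --- microsatellites ----------------------------------------------------------

def _microsat_sites(config: SimulationConfig, rng: np.random.Generator,
                    ) -> tuple[list[MicrosatelliteSite], list[bool]]:
    n = config.n_microsat_sites
    n_unstable = round(config.msi_site_fraction * n) if config.msi_status == "MSI-H" else 0
    sites, unstable_flags = [], []
    stable_p = np.array([0.15, 0.70, 0.15])
    shifted_p = np.array([0.70, 0.20, 0.10])
    for i in range(n):
        center = 12 + int(rng.integers(0, 8))
        lengths = [center - 1, center, center + 1]
        normal_counts = rng.multinomial(60, stable_p)
        unstable = i < n_unstable
        if unstable:
            tumor_lengths = [center - 3, center - 2, center - 1]
            tumor_counts = rng.multinomial(60, shifted_p)
        else:
            tumor_lengths = lengths
            tumor_counts = rng.multinomial(60, stable_p)
        sites.append(MicrosatelliteSite(
            locus_id=f"MS{i:04d}", repeat_unit="A",
            tumor_hist={l: int(c) for l, c in zip(tumor_lengths, tumor_counts) if c > 0},
            normal_hist={l: int(c) for l, c in zip(lengths, normal_counts) if c > 0}))
        unstable_flags.append(unstable)
    return sites, unstable_flags


# --- main entry ---------------------------------------------------------------

def simulate_callset(config: SimulationConfig,
                     kb: Knowledgebase | None = None,
                     references: dict[str, SignatureReference] | None = None,
                     ) -> tuple[list[VariantRecord], list[SVRecord], TumorProfile,
                                list[GermlineVariant], list[MicrosatelliteSite],
                                GroundTruth]:
    """Generate one tumor/normal call set with its ground-truth manifest."""
    kb = kb or load_knowledgebase()
    if references is None:
        references = {c: build_reference(c) for c in ("SBS96", "ID83", "SV32")}
    rng = np.random.default_rng(config.seed)
    mixtures = config.signature_mixture or default_mixture(
        config.hrd_status, config.msi_status)
    for sig_class in ("SBS96", "ID83", "SV32"):
        if sig_class not in mixtures:
            raise ValidationError(f"signature mixture missing class {sig_class}")

    profile = _build_profile(config, kb)

    variants: list[VariantRecord] = []
    variant_labels: list[dict] = []
    expected = {"SBS96": np.zeros(96), "ID83": np.zeros(83), "SV32": np.zeros(32)}

    # passing SBS records, channel counts drawn multinomially from the mixture
    p_sbs = references["SBS96"].mixture_distribution(mixtures["SBS96"])
    sbs_counts = rng.multinomial(config.n_sbs, p_sbs) if config.n_sbs else \
        np.zeros(96, dtype=int)
    for ci, count in enumerate(sbs_counts):
        for _ in range(int(count)):
            variants.append(_snv_from_channel(SBS96_CHANNELS[ci], rng, kb,
                                              profile, config))
            variant_labels.append({"kind": "snv", "label": "pass",
                                   "detail": SBS96_CHANNELS[ci]})
            expected["SBS96"][ci] += 1

    p_id = references["ID83"].mixture_distribution(mixtures["ID83"])
    id_counts = rng.multinomial(config.n_indel, p_id) if config.n_indel else \
        np.zeros(83, dtype=int)
    for ci, count in enumerate(id_counts):
        for _ in range(int(count)):
            variants.append(_indel_from_channel(ID83_CHANNELS[ci], rng, kb,
                                                profile, config))
            variant_labels.append({"kind": "indel", "label": "pass",
                                   "detail": ID83_CHANNELS[ci]})
            expected["ID83"][ci] += 1

    # point drivers (always intended-pass)
    for spec in config.drivers:
        if spec.kind != "point":
            continue
        rec = _point_driver_record(spec, rng, kb, profile, config)
        variants.append(rec)
        entry = kb.entry(spec.gene)
        label = "oncogene point driver" if entry.role == "oncogene" \
            else "tsg inactivating driver"
        variant_labels.append({"kind": "snv" if rec.is_snv else "indel",
                               "label": label,
                               "detail": f"{spec.gene} {spec.descriptor}"})
        # driver records also land in a catalog channel
        if rec.is_snv:
            expected["SBS96"][SBS96_CHANNELS.index(
                sbs96_channel(rec.ref, rec.alt, rec.trinucleotide_context))] += 1
        else:
            expected["ID83"][ID83_CHANNELS.index("DEL.C.1.1")] += 1

    # germline second hits realized as somatic truncating variants
    for payload in config.germline_payload:
        if payload.second_hit != "somatic_truncating":
            continue
        entry = kb.entry(payload.variant.gene)
        if entry is None:
            raise ValidationError(
                f"germline payload gene {payload.variant.gene!r} not in knowledgebase")
        pos = entry.start + entry.length // 3
        cn = _total_cn_at(profile, entry.chrom, pos, 2.0)
        tdepth, talt = _tumor_evidence(rng, config.purity, cn)
        ndepth, nalt = _normal_evidence(rng)
        variants.append(VariantRecord(
            chrom=entry.chrom, pos=pos, ref="C", alt="T", gene=payload.variant.gene,
            variant_class="nonsense", tumor_depth=tdepth, tumor_alt=talt,
            normal_depth=ndepth, normal_alt=nalt, mapping_quality=60.0,
            pon_af=0.0, trinucleotide_context="ACA"))
        variant_labels.append({"kind": "snv", "label": "somatic second hit",
                               "detail": payload.variant.gene})
        expected["SBS96"][SBS96_CHANNELS.index(sbs96_channel("C", "T", "ACA"))] += 1

    # artifact records: each violates exactly one named criterion
    n_artifacts = round(config.artifact_fraction * (config.n_sbs + config.n_indel))
    for i in range(n_artifacts):
        base = _snv_from_channel(SBS96_CHANNELS[int(rng.integers(96))], rng, kb,
                                 profile, config)
        criterion = SNV_ARTIFACT_CRITERIA[i % len(SNV_ARTIFACT_CRITERIA)]
        variants.append(_snv_artifact(base, criterion))
        variant_labels.append({"kind": "snv", "label": "artifact",
                               "detail": f"fails {criterion}"})

    # SVs
    svs: list[SVRecord] = []
    sv_labels: list[dict] = []
    p_sv = references["SV32"].mixture_distribution(mixtures["SV32"])
    sv_counts = rng.multinomial(config.n_sv, p_sv) if config.n_sv else \
        np.zeros(32, dtype=int)
    for ci, count in enumerate(sv_counts):
        for _ in range(int(count)):
            svs.append(_sv_from_channel(SV32_CHANNELS[ci], rng, kb))
            sv_labels.append({"label": "pass", "detail": SV32_CHANNELS[ci]})
            expected["SV32"][ci] += 1

    for spec in config.drivers:
        if spec.kind != "fusion":
            continue
        svs.append(_fusion_sv(spec, rng, kb))
        sv_labels.append({"label": "fusion driver",
                          "detail": f"{spec.partner}-{spec.gene}"})

    n_sv_artifacts = round(config.artifact_fraction * config.n_sv)
    for i in range(n_sv_artifacts):
        base = _sv_from_channel(SV32_CHANNELS[
            int(rng.integers(16, 32))], rng, kb)   # non-clustered base channels
        criterion = SV_ARTIFACT_CRITERIA[i % len(SV_ARTIFACT_CRITERIA)]
        svs.append(_sv_artifact(base, criterion))
        sv_labels.append({"label": "artifact", "detail": f"fails {criterion}"})

    # germline variants: payload plus fixed decoys exercising the screen
    germline: list[GermlineVariant] = [p.variant for p in config.germline_payload]
    germline_labels: list[dict] = [
        {"label": "screen keep" if (p.variant.population_af < 0.005 and
                                    p.variant.clinvar_class in ("pathogenic",
                                                                "likely_pathogenic"))
         else "screen drop",
         "detail": f"{p.variant.gene} {p.variant.hgvs_p} second_hit={p.second_hit}"}
        for p in config.germline_payload]
    decoys = [GermlineVariant("BRCA2", "p.V2109I", 0.0001, "vus", True),
              GermlineVariant("APC", "p.E1317Q", 0.0200, "pathogenic", True)]
    for d in decoys:
        germline.append(d)
        germline_labels.append({"label": "screen drop",
                                "detail": f"{d.gene} {d.hgvs_p} decoy"})

    sites, unstable_flags = _microsat_sites(config, rng)

    truth = GroundTruth(
        sample_id=config.sample_id,
        variant_labels=variant_labels,
        sv_labels=sv_labels,
        germline_labels=germline_labels,
        phenotype={"hrd": config.hrd_status, "msi": config.msi_status,
                   "wgd": config.ploidy > 3.5,
                   "n_unstable_sites": int(sum(unstable_flags))},
        expected_catalogs={
            "SBS96": MutationalCatalog("SBS96", expected["SBS96"]),
            "ID83": MutationalCatalog("ID83", expected["ID83"]),
            "SV32": MutationalCatalog("SV32", expected["SV32"]),
        },
        intended_category=config.intended_category,
    )
    return variants, svs, profile, germline, sites, truth


def demo_cohort_configs(seed: int = 0, n: int = 20) -> list[SimulationConfig]:
    """Twenty-sample demonstration cohort with known intended categories.

    Covers every category: approved-therapy matches (point, fusion, phenotype),
    trial matches (amplification, HRD outside approved indications), resistance
    exclusions, and the three clarity outcomes.
    """
    gv = GermlineVariant
    archetypes = [
        dict(cancer_type="lung", drivers=[DriverSpec("EGFR", "point", "L858R")],
             intended_category="I-1"),
        dict(cancer_type="stomach", msi_status="MSI-H", intended_category="I-1"),
        dict(cancer_type="prostate", hrd_status=True, intended_category="I-1"),
        dict(cancer_type="colorectal", drivers=[DriverSpec("KRAS", "point", "G12V")],
             intended_category="I-3"),
        dict(cancer_type="cholangiocarcinoma",
             drivers=[DriverSpec("FGFR2", "amplification", copy_number=185)],
             intended_category="I-2"),
        dict(cancer_type="breast", drivers=[DriverSpec("PIK3CA", "point", "H1047R")],
             intended_category="I-1"),
        dict(cancer_type="lung", drivers=[DriverSpec("ALK", "fusion", partner="EML4")],
             intended_category="I-1"),
        dict(cancer_type="colorectal", drivers=[DriverSpec("NRAS", "point", "G61K")],
             intended_category="I-3"),
        dict(cancer_type="stomach",
             drivers=[DriverSpec("CCND1", "amplification", copy_number=20)],
             intended_category="I-2"),
        dict(cancer_type="lung", drivers=[DriverSpec("ALK", "fusion", partner="HIP1")],
             intended_category="I-1"),
        dict(cancer_type="lung", question="clarity",
             drivers=[DriverSpec("EGFR", "amplification", copy_number=80),
                      DriverSpec("EGFR", "point", "L858R")],
             intended_category="II-1"),
        dict(cancer_type="unknown", question="clarity",
             signature_mixture={
                 "SBS96": {"SBS4": 0.40, "SBS1": 0.20, "SBS5": 0.40},
                 "ID83": {"ID3": 0.45, "ID1": 0.30, "ID2": 0.25},
                 "SV32": {"RS1": 0.50, "RS2": 0.50}},
             intended_category="II-2"),
        dict(cancer_type="colorectal", question="clarity",
             germline_payload=[GermlinePayload(
                 gv("APC", "p.R1114*", 0.0001, "pathogenic", True), "loh")],
             intended_category="II-3"),
        dict(cancer_type="breast", question="clarity", intended_category="II-3"),
        dict(cancer_type="urothelial", drivers=[DriverSpec("FGFR3", "point", "S249C")],
             intended_category="I-1"),
        dict(cancer_type="breast", hrd_status=True, intended_category="I-2"),
        dict(cancer_type="colorectal", drivers=[DriverSpec("KRAS", "point", "Q61L")],
             intended_category="I-3"),
        dict(cancer_type="stomach", hrd_status=True,
             germline_payload=[GermlinePayload(
                 gv("BRCA1", "p.L1780P", 0.0001, "pathogenic", True), "loh")],
             intended_category="I-2"),
        dict(cancer_type="lung",
             drivers=[DriverSpec("MET", "amplification", copy_number=25)],
             intended_category="I-2"),
        dict(cancer_type="colorectal", intended_category="none"),
    ]
    configs = []
    for i, arch in enumerate(archetypes[:n]):
        configs.append(SimulationConfig(
            seed=(seed * 10_007 + i * 101) % (2**31 - 1),
            sample_id=f"COHORT-{i:02d}", **arch))
    return configs
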