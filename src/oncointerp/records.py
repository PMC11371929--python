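"""Domain types for somatic interpretation.

All genomic coordinates are 1-based inclusive in memory (VCF convention); BEDPE
emission converts to 0-based half-open at the I/O boundary only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

VARIANT_CLASSES = ("missense", "nonsense", "frameshift", "inframe_indel",
                   "splice", "synonymous", "promoter", "other")
TRUNCATING_CLASSES = ("frameshift", "nonsense", "splice")

# canonical ordering of chromosomes 1..22, X, Y; unknown names sort after, verbatim
_CHROM_ORDER = {c: i for i, c in enumerate([str(n) for n in range(1, 23)] + ["X", "Y"])}


def chrom_sort_key(chrom: str) -> tuple[int, str]:
    return (_CHROM_ORDER.get(chrom, len(_CHROM_ORDER)), chrom)


class ValidationError(ValueError):
    """An input record violates a type invariant."""


@dataclass(frozen=True)
class IndelFeatures:
    """Repeat/microhomology context of one indel.

    ``repeat_count`` counts copies of the indel sequence in the reference
    (>=1 for deletions, >=0 for insertions); ``mh_len`` is the length of flanking
    microhomology in bp (deletions only, 0 if none).
    """
    repeat_unit_size: int
    repeat_count: int
    mh_len: int = 0

    def __post_init__(self):
        if self.repeat_unit_size < 1 or self.repeat_count < 0 or self.mh_len < 0:
            raise ValidationError(f"invalid indel features: {self}")


@dataclass(frozen=True)
class VariantRecord:
    """One somatic SNV/indel call with tumor/normal read evidence."""
    chrom: str
    pos: int
    ref: str
    alt: str
    variant_class: str = "other"
    gene: str = ""
    protein_change: str = ""
    tumor_depth: int = 0
    tumor_alt: int = 0
    normal_depth: int = 0
    normal_alt: int = 0
    mapping_quality: float = 60.0
    pon_af: float = 0.0
    trinucleotide_context: str | None = None
    indel_features: IndelFeatures | None = None

    def __post_init__(self):
        if self.pos < 1:
            raise ValidationError(f"pos must be >= 1 ({self.chrom}:{self.pos})")
        if self.variant_class not in VARIANT_CLASSES:
            raise ValidationError(f"unknown variant_class {self.variant_class!r}")
        for name in ("tumor_depth", "tumor_alt", "normal_depth", "normal_alt"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be non-negative")
        if self.tumor_alt > self.tumor_depth:
            raise ValidationError(
                f"tumor_alt {self.tumor_alt} > tumor_depth {self.tumor_depth} "
                f"at {self.chrom}:{self.pos}")
        if self.normal_alt > self.normal_depth:
            raise ValidationError(
                f"normal_alt {self.normal_alt} > normal_depth {self.normal_depth} "
                f"at {self.chrom}:{self.pos}")
        if self.mapping_quality < 0:
            raise ValidationError("mapping_quality must be non-negative")
        if not 0.0 <= self.pon_af <= 1.0:
            raise ValidationError(f"pon_af {self.pon_af} outside [0, 1]")
        if (self.trinucleotide_context is None) == (self.indel_features is None):
            raise ValidationError(
                "exactly one of trinucleotide_context / indel_features must be set")

    @property
    def is_snv(self) -> bool:
        return self.trinucleotide_context is not None

    @property
    def is_deletion(self) -> bool:
        return len(self.ref) > len(self.alt)

    @property
    def indel_size(self) -> int:
        return abs(len(self.ref) - len(self.alt))

    @property
    def tumor_vaf(self) -> float:
        return self.tumor_alt / self.tumor_depth if self.tumor_depth else 0.0

    @property
    def normal_vaf(self) -> float:
        return self.normal_alt / self.normal_depth if self.normal_depth else 0.0


@dataclass(frozen=True)
class SVRecord:
    """One somatic structural variant as an oriented breakpoint pair.

    Orientation '+' means the derivative retains sequence to the *left* of
    (at lower coordinates than) the breakpoint; '-' retains sequence to the right.
    """
    chrom_a: str
    pos_a: int
    orient_a: str
    chrom_b: str
    pos_b: int
    orient_b: str
    sv_type: str
    tumor_support: int = 0
    normal_support: int = 0
    mapping_quality: float = 60.0
    pon_freq: float = 0.0
    homology_len: int = 0

    def __post_init__(self):
        if self.sv_type not in ("DEL", "DUP", "INV", "TRA"):
            raise ValidationError(f"unknown sv_type {self.sv_type!r}")
        if self.orient_a not in "+-" or self.orient_b not in "+-":
            raise ValidationError("orientations must be '+' or '-'")
        if self.pos_a < 1 or self.pos_b < 1:
            raise ValidationError("breakpoint positions must be >= 1")
        if self.sv_type != "TRA":
            if self.chrom_a != self.chrom_b:
                raise ValidationError(f"{self.sv_type} must be intra-chromosomal")
            if self.pos_a > self.pos_b:
                raise ValidationError("intra-chromosomal SV requires pos_a <= pos_b")
        if self.tumor_support < 0 or self.normal_support < 0:
            raise ValidationError("supports must be >= 0")
        if not 0.0 <= self.pon_freq <= 1.0:
            raise ValidationError(f"pon_freq {self.pon_freq} outside [0, 1]")
        if self.homology_len < 0:
            raise ValidationError("homology_len must be >= 0")

    @property
    def size(self) -> int | None:
        """Event size in bp; undefined (None) for translocations."""
        return None if self.sv_type == "TRA" else self.pos_b - self.pos_a


@dataclass(frozen=True)
class CNSegment:
    """One copy-number segment (1-based inclusive coordinates)."""
    chrom: str
    start: int
    end: int
    total_cn: float
    minor_cn: float

    def __post_init__(self):
        if self.start > self.end:
            raise ValidationError(f"segment start {self.start} > end {self.end}")
        if self.minor_cn < 0 or self.total_cn < 0:
            raise ValidationError("copy numbers must be non-negative")
        if self.minor_cn > self.total_cn + 1e-9:
            raise ValidationError(
                f"minor_cn {self.minor_cn} > total_cn {self.total_cn}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class TumorProfile:
    """Purity/ploidy and segmented copy number for one tumor."""
    sample_id: str
    tcf: float
    ploidy: float
    segments: list[CNSegment] = field(default_factory=list)
    sample_type: str = "fresh"
    acquisition: str = "surgery"
    cancer_type: str = "unknown"

    def __post_init__(self):
        if not 0.0 <= self.tcf <= 1.0:
            raise ValidationError(f"tcf {self.tcf} outside [0, 1]")
        if self.ploidy <= 0:
            raise ValidationError("ploidy must be positive")
        if self.sample_type not in ("fresh", "FFPE"):
            raise ValidationError(f"unknown sample_type {self.sample_type!r}")
        if self.acquisition not in ("surgery", "biopsy"):
            raise ValidationError(f"unknown acquisition {self.acquisition!r}")
        self.segments = sorted(
            self.segments, key=lambda s: (chrom_sort_key(s.chrom), s.start))
        prev: CNSegment | None = None
        for seg in self.segments:
            if prev is not None and seg.chrom == prev.chrom and seg.start <= prev.end:
                raise ValidationError(
                    f"overlapping segments on {seg.chrom}: "
                    f"[{prev.start},{prev.end}] and [{seg.start},{seg.end}]")
            prev = seg

    def segments_overlapping(self, chrom: str, start: int, end: int) -> list[CNSegment]:
        return [s for s in self.segments
                if s.chrom == chrom and s.start <= end and s.end >= start]


@dataclass(frozen=True)
class GermlineVariant:
    gene: str
    hgvs_p: str
    population_af: float
    clinvar_class: str = "none"
    predisposition_gene: bool = False

    def __post_init__(self):
        if not 0.0 <= self.population_af <= 1.0:
            raise ValidationError(f"population_af {self.population_af} outside [0, 1]")
        if self.clinvar_class not in ("pathogenic", "likely_pathogenic", "vus",
                                      "benign", "none"):
            raise ValidationError(f"unknown clinvar_class {self.clinvar_class!r}")


@dataclass(frozen=True)
class MicrosatelliteSite:
    """Tumor vs normal repeat-length read histograms at one microsatellite locus."""
    locus_id: str
    repeat_unit: str
    tumor_hist: dict[int, int]
    normal_hist: dict[int, int]

    def __post_init__(self):
        for name in ("tumor_hist", "normal_hist"):
            h = getattr(self, name)
            if not h:
                raise ValidationError(f"{name} must be non-empty at {self.locus_id}")
            if any(c < 0 for c in h.values()):
                raise ValidationError(f"negative count in {name} at {self.locus_id}")
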