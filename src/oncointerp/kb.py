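"""Gene knowledgebase: roles, hotspots, drug/trial links, gene models.

The shipped knowledgebase is a versioned JSON fixture on a miniature genome
(23 chromosomes of 60 Mb, fictitious but fixed gene coordinates); it covers the
genes this package's rules reference and is fully replaceable by the caller.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib.resources import files
from pathlib import Path

from .records import ValidationError


@dataclass(frozen=True)
class DrugLink:
    drug: str
    alteration: str            # descriptor, or one of amplification/fusion/inactivation/any_hotspot
    cancer_types: tuple[str, ...]
    evidence: str              # approved | trial
    trial_id: str | None = None

    def matches_cancer_type(self, cancer_type: str) -> bool:
        return "any" in self.cancer_types or cancer_type in self.cancer_types


@dataclass(frozen=True)
class ResistanceRule:
    gene: str
    alteration: str
    cancer_types: tuple[str, ...]
    excluded_therapy: str

    def matches_cancer_type(self, cancer_type: str) -> bool:
        return "any" in self.cancer_types or cancer_type in self.cancer_types


@dataclass
class GeneKBEntry:
    gene: str
    chrom: str
    start: int
    end: int
    strand: str
    exons: int
    role: str
    predisposition: bool
    hotspots: dict[str, int]
    drugs: list[DrugLink]
    resistance_rules: list[ResistanceRule]
    deleterious: dict[str, dict[str, bool]]

    def __post_init__(self):
        if self.start > self.end:
            raise ValidationError(f"{self.gene}: malformed interval")
        if self.role not in ("oncogene", "tsg", "both"):
            raise ValidationError(f"{self.gene}: unknown role {self.role!r}")
        if any(c < 0 for c in self.hotspots.values()):
            raise ValidationError(f"{self.gene}: negative COSMIC count")
        if self.strand not in "+-":
            raise ValidationError(f"{self.gene}: unknown strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos <= self.end

    def intron_intervals(self) -> list[tuple[int, int]]:
        """Intron intervals of the even-split gene model (for fusion placement)."""
        n = self.exons
        if n < 2:
            return []
        # exons occupy the first tenth of each of n even slices; introns the rest
        slice_len = self.length // n
        exon_len = max(slice_len // 10, 1)
        introns = []
        for i in range(n - 1):
            s = self.start + i * slice_len + exon_len
            e = self.start + (i + 1) * slice_len - 1
            if s <= e:
                introns.append((s, e))
        return introns

    def drug_links_for(self, alteration: str, cancer_type: str | None,
                       evidence: str | None = None) -> list[DrugLink]:
        """Drug/trial links whose alteration pattern matches the given alteration.

        ``cancer_type=None`` skips the type filter (drug association regardless
        of indication)."""
        out = []
        for link in self.drugs:
            if cancer_type is not None and not link.matches_cancer_type(cancer_type):
                continue
            if evidence is not None and link.evidence != evidence:
                continue
            if link.alteration == alteration:
                out.append(link)
            elif link.alteration == "any_hotspot" and alteration in self.hotspots:
                out.append(link)
        return out


@dataclass
class Knowledgebase:
    version: str
    chromosomes: list[str]
    chromosome_length: int
    genes: dict[str, GeneKBEntry]
    fusion_pairs: list[tuple[str, str]]
    phenotype_rules: dict = field(default_factory=dict)

    def entry(self, gene: str) -> GeneKBEntry | None:
        return self.genes.get(gene)

    def genes_at(self, chrom: str, pos: int) -> list[GeneKBEntry]:
        return [g for g in self.genes.values() if g.contains(chrom, pos)]

    def predisposition_genes(self) -> list[str]:
        return sorted(g.gene for g in self.genes.values() if g.predisposition)

    def is_allowed_fusion(self, five_prime: str, three_prime: str) -> bool:
        for fp, tp in self.fusion_pairs:
            if tp == three_prime and fp in ("*", five_prime):
                return True
        return False


def _parse_entry(gene: str, d: dict) -> GeneKBEntry:
    return GeneKBEntry(
        gene=gene, chrom=str(d["chrom"]), start=int(d["start"]), end=int(d["end"]),
        strand=d["strand"], exons=int(d["exons"]), role=d["role"],
        predisposition=bool(d["predisposition"]),
        hotspots={k: int(v) for k, v in d.get("hotspots", {}).items()},
        drugs=[DrugLink(x["drug"], x["alteration"], tuple(x["cancer_types"]),
                        x["evidence"], x.get("trial_id"))
               for x in d.get("drugs", [])],
        resistance_rules=[ResistanceRule(gene, x["alteration"],
                                         tuple(x["cancer_types"]),
                                         x["excluded_therapy"])
                          for x in d.get("resistance_rules", [])],
        deleterious=d.get("deleterious", {}),
    )


def load_knowledgebase(path: str | Path | None = None) -> Knowledgebase:
    """Load a knowledgebase JSON; the bundled fixture when no path is given."""
    if path is None:
        raw = files("oncointerp.data").joinpath("knowledgebase.json").read_text()
    else:
        raw = Path(path).read_text()
    doc = json.loads(raw)
    for key in ("version", "genome", "genes", "fusion_pairs"):
        if key not in doc:
            raise ValidationError(f"knowledgebase missing required key {key!r}")
    genes = {g: _parse_entry(g, d) for g, d in doc["genes"].items()}
    return Knowledgebase(
        version=str(doc["version"]),
        chromosomes=[str(c) for c in doc["genome"]["chromosomes"]],
        chromosome_length=int(doc["genome"]["chromosome_length"]),
        genes=genes,
        fusion_pairs=[(p["five_prime"], p["three_prime"]) for p in doc["fusion_pairs"]],
        phenotype_rules=doc.get("phenotype_rules", {}),
    )
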