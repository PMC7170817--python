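"""Domain types for population-scale transporter variability analysis.

The central objects are :class:`VariantRecord` (one alternate allele at one
site, with per-population allele counts from a gnomAD-style cohort),
:class:`GeneModel` (gene-level annotation: subfamily, coding length,
inheritance mode, protein-domain intervals), :class:`CNVRecord` and
:class:`ClinicalVariant` (per-population minor-allele frequencies of
clinically characterized variants, transcribed in percent).

Coordinates are 1-based and fully closed (VCF convention); protein residues
are 1-based inclusive. Multi-allelic sites are decomposed into one record per
alternate allele and regrouped on (chrom, pos, ref) where needed.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Mapping, Optional

from .errors import UndefinedFrequencyError

#: gnomAD-style population panels, in canonical column order.
POPULATIONS: tuple[str, ...] = ("AFR", "AMR", "ASJ", "EAS", "SAS", "FIN", "NFE", "OTH")

#: The seven named panels used for the population-specificity partition
#: (the heterogeneous "other" panel is excluded).
SPECIFICITY_POPULATIONS: tuple[str, ...] = ("AFR", "AMR", "ASJ", "EAS", "SAS", "FIN", "NFE")

#: Number of sequenced individuals per panel in the 138,632-individual cohort.
GNOMAD_PANEL_SIZES: dict[str, int] = {
    "AFR": 12020,
    "AMR": 17210,
    "ASJ": 5076,
    "EAS": 9435,
    "SAS": 15391,
    "FIN": 12897,
    "NFE": 63369,
    "OTH": 3234,
}

#: Populations of the clinical frequency tables (a 1000G-style panel set).
CLINICAL_POPULATIONS: tuple[str, ...] = ("EUR", "AFR", "EAS", "SAS", "AMR", "AJ")

#: Missense effect predictors whose binarized calls are consumed as annotations.
PREDICTORS: tuple[str, ...] = ("sift", "polyphen2", "mutation_assessor", "vest3", "eigen")


class Consequence(str, enum.Enum):
    """Functional consequence class of a variant on its transcript."""

    MISSENSE = "missense"
    SYNONYMOUS = "synonymous"
    UTR = "utr"
    FRAMESHIFT = "frameshift"
    INFRAME_INDEL = "inframe_indel"
    START_LOST = "start_lost"
    STOP_GAINED = "stop_gained"
    SPLICE_SITE = "splice_site"
    OTHER = "other"


class PredictorCall(str, enum.Enum):
    DELETERIOUS = "D"
    NEUTRAL = "N"
    MISSING = "."


class ClinVarSignificance(str, enum.Enum):
    BENIGN = "benign"
    LIKELY_BENIGN = "likely_benign"
    OTHER = "other"


class Inheritance(str, enum.Enum):
    """Mendelian mode of inheritance of the disease linked to a gene."""

    AR = "AR"
    AD = "AD"
    XL = "XL"
    NONE = "none"


@dataclass(frozen=True)
class PopulationPanel:
    """A sequenced population panel: identifier plus cohort size."""

    code: str
    n_individuals: int

    def __post_init__(self) -> None:
        if self.n_individuals <= 0:
            raise ValueError(f"panel {self.code}: n_individuals must be > 0")

    @property
    def n_alleles(self) -> int:
        """Diploid allele number 2N."""
        return 2 * self.n_individuals


def default_panels() -> tuple[PopulationPanel, ...]:
    """The eight gnomAD panels with their published cohort sizes."""
    return tuple(PopulationPanel(code, n) for code, n in GNOMAD_PANEL_SIZES.items())


def validate_panels(panels: tuple[PopulationPanel, ...]) -> None:
    codes = [p.code for p in panels]
    if len(set(codes)) != len(codes):
        raise ValueError("population codes must be unique within a panel set")


@dataclass
class AminoAcidChange:
    """A protein-level change: 1-based residue position, reference and alternate."""

    position: int
    ref: str
    alt: str


@dataclass
class VariantRecord:
    """One alternate allele at one genomic site with per-population counts."""

    gene: str
    chrom: str
    pos: int
    ref: str
    alt: str
    consequence: Consequence
    per_pop_ac: dict[str, int]
    per_pop_an: dict[str, int]
    rsid: Optional[str] = None
    predictor_calls: dict[str, PredictorCall] = field(default_factory=dict)
    clinvar_significance: Optional[ClinVarSignificance] = None
    amino_acid_change: Optional[AminoAcidChange] = None

    def __post_init__(self) -> None:
        if isinstance(self.consequence, str):
            self.consequence = Consequence(self.consequence)
        for pop, ac in self.per_pop_ac.items():
            an = self.per_pop_an.get(pop, 0)
            if ac < 0 or an < 0:
                raise ValueError(f"{self.variant_id}: negative allele count in {pop}")
            if ac > an:
                raise ValueError(
                    f"{self.variant_id}: allele count {ac} exceeds allele number {an} in {pop}"
                )
        for name in self.predictor_calls:
            if name not in PREDICTORS:
                raise ValueError(f"unknown predictor {name!r}")

    @property
    def variant_id(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}>{self.alt}"

    def af(self, population: str) -> float:
        """Alternate-allele frequency in one panel; NaN where AN = 0."""
        an = self.per_pop_an.get(population, 0)
        if an == 0:
            return math.nan
        return self.per_pop_ac.get(population, 0) / an

    def pooled_af(self) -> float:
        return pooled_af(self)

    def folded_maf(self) -> float:
        """Minor-allele frequency pooled over all panels: min(af, 1 - af)."""
        af = self.pooled_af()
        return min(af, 1.0 - af)


def pooled_af(record: VariantRecord) -> float:
    """Allele-number-weighted pooled alternate-allele frequency.

    Equals (total alternate alleles) / (total alleles) over every panel, i.e.
    the whole-cohort frequency.

    Raises
    ------
    UndefinedFrequencyError
        If every panel has allele number zero.
    """
    total_an = sum(record.per_pop_an.values())
    if total_an == 0:
        raise UndefinedFrequencyError(f"{record.variant_id}: all allele numbers are zero")
    total_ac = sum(record.per_pop_ac.values())
    return total_ac / total_an


@dataclass(frozen=True)
class DomainInterval:
    """A named protein domain spanning a 1-based inclusive residue interval."""

    name: str
    start_residue: int
    end_residue: int

    def __post_init__(self) -> None:
        if self.start_residue < 1 or self.end_residue < self.start_residue:
            raise ValueError(f"invalid domain interval {self}")

    @property
    def length_aa(self) -> int:
        return self.end_residue - self.start_residue + 1

    def contains(self, residue: int) -> bool:
        return self.start_residue <= residue <= self.end_residue


DOMAIN_NAMES = ("TMD0", "TMD1", "TMD2", "NBD1", "NBD2", "ECD1", "ECD2", "other")


@dataclass(frozen=True)
class ConstraintScores:
    """Published constraint annotations (consumed, never computed here)."""

    oe_missense: Optional[float] = None
    oe_lof: Optional[float] = None
    z_missense: Optional[float] = None
    pli: Optional[float] = None


@dataclass
class GeneModel:
    """Gene-level annotation for one transporter gene."""

    gene: str
    subfamily: str
    cds_length_bp: int
    protein_length_aa: int
    inheritance: Inheritance = Inheritance.NONE
    domains: tuple[DomainInterval, ...] = ()
    constraint: Optional[ConstraintScores] = None

    def __post_init__(self) -> None:
        if isinstance(self.inheritance, str):
            self.inheritance = Inheritance(self.inheritance)
        if self.cds_length_bp <= 0:
            raise ValueError(f"{self.gene}: cds_length_bp must be positive")
        if self.protein_length_aa <= 0:
            raise ValueError(f"{self.gene}: protein_length_aa must be positive")
        spans = sorted(self.domains, key=lambda d: d.start_residue)
        for d in spans:
            if d.end_residue > self.protein_length_aa:
                raise ValueError(f"{self.gene}: domain {d.name} exceeds protein length")
        for a, b in zip(spans, spans[1:]):
            if b.start_residue <= a.end_residue:
                raise ValueError(f"{self.gene}: domains {a.name} and {b.name} overlap")

    def domain_of(self, residue: int) -> str:
        """Name of the annotated domain containing ``residue``, else ``"other"``."""
        for d in self.domains:
            if d.contains(residue):
                return d.name
        return "other"


class CNVKind(str, enum.Enum):
    DELETION = "deletion"
    DUPLICATION = "duplication"


@dataclass
class CNVRecord:
    """A deletion or duplication spanning at least one exon of a gene."""

    gene: str
    kind: CNVKind
    first_exon: int
    last_exon: int
    frequency: float

    def __post_init__(self) -> None:
        if isinstance(self.kind, str):
            self.kind = CNVKind(self.kind)
        if self.first_exon > self.last_exon:
            raise ValueError(f"{self.gene}: first_exon > last_exon")
        if not 0.0 <= self.frequency <= 1.0:
            raise ValueError(f"{self.gene}: CNV frequency outside [0, 1]")


@dataclass
class ClinicalVariant:
    """A clinically characterized variant with per-population MAFs in percent.

    Frequencies are stored exactly as printed in the source tables (named-allele
    frequency, percent scale, no folding). ``per_pop_maf`` holds biallelic
    entries; multi-allelic entries populate ``alleles`` (allele label →
    population → percent). Cells printed "N.A." are ``None``. Cells printed as
    an upper bound ("< 0.1") carry the bound as value and are listed in
    ``censored`` as (allele_label, population) pairs, with label "." for
    biallelic records.
    """

    rsid: str
    gene: str
    variant_type: str
    per_pop_maf: dict[str, Optional[float]] = field(default_factory=dict)
    alleles: dict[str, dict[str, Optional[float]]] = field(default_factory=dict)
    censored: frozenset[tuple[str, str]] = frozenset()

    @property
    def is_multiallelic(self) -> bool:
        return bool(self.alleles)

    def populations(self) -> tuple[str, ...]:
        if self.is_multiallelic:
            pops: list[str] = []
            for freqs in self.alleles.values():
                for p in freqs:
                    if p not in pops:
                        pops.append(p)
            return tuple(pops)
        return tuple(self.per_pop_maf)

    def allele_sum(self, population: str) -> Optional[float]:
        """Sum of named-allele frequencies in one population (multi-allelic only)."""
        if not self.is_multiallelic:
            return None
        vals = [f.get(population) for f in self.alleles.values()]
        if any(v is None for v in vals):
            return None
        return float(sum(v for v in vals if v is not None))


def frequencies_sum_ok(variant: ClinicalVariant, tolerance: float = 0.3) -> bool:
    """Check the multi-allelic transcription invariant: sums are 100 ± tolerance."""
    if not variant.is_multiallelic:
        return True
    for pop in variant.populations():
        s = variant.allele_sum(pop)
        if s is not None and abs(s - 100.0) > tolerance:
            return False
    return True
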