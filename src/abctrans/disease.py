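"""Recessive-disease risk from aggregated loss-of-function frequencies.

For a gene implicated in an autosomal-recessive Mendelian disorder, the
aggregated frequency of its loss-of-function alleles in a population,

    q = sum over LoF variants of af_pop   (clipped at 1),

yields under Hardy-Weinberg equilibrium a biallelic-affected frequency q**2
(compound heterozygotes count as affected, since frequencies are aggregated
across variants before squaring), a carrier frequency 2q(1-q), and the
conventional "1 in N" display with N = round(1 / q**2).

The approach assumes heterozygous loss of function is phenotypically silent
and therefore refuses genes with autosomal-dominant or X-linked inheritance.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

from .classify import is_lof
from .errors import ModeOfInheritanceError
from .model import GeneModel, Inheritance, VariantRecord


@dataclass
class DiseaseRiskEstimate:
    """Aggregated LoF frequency and derived Hardy-Weinberg quantities."""

    gene: Optional[str]
    population: Optional[str]
    q_agg: float
    n_lof_variants: int = 0
    empty: bool = False  # gene absent from the record set

    @property
    def carrier_freq(self) -> float:
        return 2.0 * self.q_agg * (1.0 - self.q_agg)

    @property
    def prevalence(self) -> float:
        return self.q_agg**2

    @property
    def one_in_n(self) -> Optional[int]:
        """Nearest-integer N of "1 in N"; None when the prevalence is zero."""
        if self.prevalence == 0.0:
            return None
        return int(round(1.0 / self.prevalence))


def aggregate_lof_frequency(
    records: Sequence[VariantRecord], gene: str, population: str
) -> DiseaseRiskEstimate:
    """Sum of per-population LoF allele frequencies for one gene, clipped at 1.

    Records should already have passed the ClinVar-benign filter for disease
    genes. A gene absent from the record set yields a zero estimate flagged
    ``empty``.
    """
    in_gene = [r for r in records if r.gene == gene]
    lof = [r for r in in_gene if is_lof(r.consequence)]
    q = 0.0
    n = 0
    for r in lof:
        af = r.af(population)
        if af == af:  # not NaN
            q += af
            n += 1
    return DiseaseRiskEstimate(
        gene=gene,
        population=population,
        q_agg=min(1.0, q),
        n_lof_variants=n,
        empty=not in_gene,
    )


def recessive_prevalence(q_agg: float) -> DiseaseRiskEstimate:
    """Hardy-Weinberg recessive quantities from an aggregated LoF frequency."""
    if not 0.0 <= q_agg <= 1.0:
        raise ValueError(f"aggregated frequency {q_agg} outside [0, 1]")
    return DiseaseRiskEstimate(gene=None, population=None, q_agg=q_agg)


def estimate_disease_risk(
    records: Sequence[VariantRecord],
    gene_model: GeneModel,
    population: str,
) -> DiseaseRiskEstimate:
    """Aggregated-LoF recessive risk for one AR gene and population.

    Raises
    ------
    ModeOfInheritanceError
        For genes whose inheritance mode is not autosomal recessive:
        heterozygous loss must be phenotypically silent for the q**2
        prevalence argument to hold.
    """
    if gene_model.inheritance is not Inheritance.AR:
        raise ModeOfInheritanceError(
            f"{gene_model.gene}: recessive prevalence requires autosomal-recessive "
            f"inheritance, not {gene_model.inheritance.value}"
        )
    return aggregate_lof_frequency(records, gene_model.gene, population)


def disease_risk_table(
    records: Sequence[VariantRecord],
    gene_models: Mapping[str, GeneModel],
    populations: Sequence[str],
) -> list[DiseaseRiskEstimate]:
    """Risk estimates for every AR gene in the model set, per population."""
    out = []
    for model in gene_models.values():
        if model.inheritance is not Inheritance.AR:
            continue
        for pop in populations:
            out.append(estimate_disease_risk(records, model, pop))
    return out
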