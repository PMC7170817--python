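"""Per-individual diploid burden of deleterious variants and population
specificity of the deleterious variant pool.

The headline statistic is the *expected* number of deleterious alternate
alleles carried by a diploid individual of a population,

    burden = sum over deleterious variants of 2 * af_pop ,

with a rare-variant component restricted to variants whose folded pooled MAF
is below 1%. A genotype simulator under Hardy-Weinberg equilibrium serves as
the Monte-Carlo validation oracle for the closed form.

A deleterious variant is "observed" in a panel when it has at least one
alternate allele there; a variant observed in exactly one of the seven named
panels is population-specific (the heterogeneous "other" panel is excluded).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .classify import RARE_MAF, Verdict, ensemble_call
from .errors import UndefinedFrequencyError
from .model import SPECIFICITY_POPULATIONS, VariantRecord


@dataclass
class BurdenSummary:
    """Expected deleterious alleles per diploid individual of a population."""

    gene: Optional[str]
    population: str
    burden: float
    burden_rare: float
    n_deleterious: int

    @property
    def rare_fraction(self) -> Optional[float]:
        """Share of the burden carried by rare variants; None when burden = 0."""
        if self.burden == 0.0:
            return None
        return self.burden_rare / self.burden


def _deleterious(records: Iterable[VariantRecord]) -> list[VariantRecord]:
    return [r for r in records if ensemble_call(r).value is Verdict.DELETERIOUS]


def per_individual_burden(
    records: Sequence[VariantRecord],
    population: str,
    gene: Optional[str] = None,
    rare_maf: float = RARE_MAF,
) -> BurdenSummary:
    """Closed-form diploid burden, optionally restricted to one gene.

    Uses the unfolded alternate-allele frequency (a deleterious variant at
    87% contributes 1.74 expected alleles); the rare component folds the
    pooled frequency before comparing against ``rare_maf``.
    """
    pool = [r for r in records if gene is None or r.gene == gene]
    deleterious = _deleterious(pool)
    if deleterious and all(r.per_pop_an.get(population, 0) == 0 for r in deleterious):
        raise UndefinedFrequencyError(
            f"allele number is zero in {population} for every deleterious record"
        )
    burden = 0.0
    burden_rare = 0.0
    for r in deleterious:
        af = r.af(population)
        if math.isnan(af):
            continue
        contribution = 2.0 * af
        burden += contribution
        if r.folded_maf() < rare_maf:
            burden_rare += contribution
    return BurdenSummary(
        gene=gene,
        population=population,
        burden=burden,
        burden_rare=burden_rare,
        n_deleterious=len(deleterious),
    )


def simulate_burden_check(
    records: Sequence[VariantRecord],
    population: str,
    n_individuals: int,
    seed: int,
    gene: Optional[str] = None,
) -> float:
    """Mean deleterious alternate alleles per simulated individual.

    Draws genotypes independently per variant under Hardy-Weinberg
    equilibrium at the panel frequency; converges to the closed-form burden.
    """
    from .simulate import simulate_genotypes

    if n_individuals <= 0:
        raise ValueError("n_individuals must be positive")
    pool = [r for r in records if gene is None or r.gene == gene]
    total = np.zeros(n_individuals, dtype=np.int64)
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    for r in _deleterious(pool):
        af = r.af(population)
        if math.isnan(af):
            continue
        total += simulate_genotypes(af, n_individuals, rng)
    return float(total.mean())


@dataclass
class SpecificityPartition:
    """Partition of deleterious variants into population-specific vs shared."""

    n_specific: int
    n_shared: int
    per_population: dict[str, int] = field(default_factory=dict)
    per_gene_fraction: dict[str, Optional[float]] = field(default_factory=dict)

    @property
    def total(self) -> int:
        return self.n_specific + self.n_shared

    @property
    def fraction_specific(self) -> Optional[float]:
        if self.total == 0:
            return None
        return self.n_specific / self.total


def specificity_partition(
    records: Sequence[VariantRecord],
    populations: Sequence[str] = SPECIFICITY_POPULATIONS,
) -> SpecificityPartition:
    """Count deleterious variants observed in exactly one vs several panels.

    Only variants with at least one observed allele in some named panel enter
    the partition. Also reports per-panel counts of panel-specific variants
    and the per-gene specific fraction.
    """
    n_specific = 0
    n_shared = 0
    per_population = {p: 0 for p in populations}
    gene_specific: dict[str, int] = {}
    gene_total: dict[str, int] = {}
    for r in _deleterious(records):
        observed = [p for p in populations if r.per_pop_ac.get(p, 0) >= 1]
        if not observed:
            continue
        gene_total[r.gene] = gene_total.get(r.gene, 0) + 1
        if len(observed) == 1:
            n_specific += 1
            per_population[observed[0]] += 1
            gene_specific[r.gene] = gene_specific.get(r.gene, 0) + 1
        else:
            n_shared += 1
    per_gene_fraction = {
        g: (gene_specific.get(g, 0) / t if t else None) for g, t in gene_total.items()
    }
    return SpecificityPartition(
        n_specific=n_specific,
        n_shared=n_shared,
        per_population=per_population,
        per_gene_fraction=per_gene_fraction,
    )
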