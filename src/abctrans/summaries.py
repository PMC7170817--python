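"""Per-gene and per-domain variability summaries.

Covers length-normalized variant density (variants per kb of coding
sequence), protein-domain variant density (variants per amino acid),
CNV event counts, subfamily comparisons (one-way ANOVA plus fold
difference of means), observed/expected constraint ratios with exact
Poisson 90% intervals, and the burden-constraint correlation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .classify import Verdict, affects_protein, ensemble_call
from .model import CNVRecord, GeneModel, VariantRecord


def consequence_counts(records: Sequence[VariantRecord]) -> pd.DataFrame:
    """Per-gene counts by consequence class plus a total column."""
    df = pd.DataFrame(
        {"gene": [r.gene for r in records], "consequence": [r.consequence.value for r in records]}
    )
    if df.empty:
        return pd.DataFrame(columns=["gene", "total"]).set_index("gene")
    table = pd.crosstab(df["gene"], df["consequence"])
    table["total"] = table.sum(axis=1)
    return table


def variants_per_kb(records: Sequence[VariantRecord], gene_model: GeneModel) -> float:
    """Exonic variants per kilobase of coding sequence for one gene."""
    if gene_model.cds_length_bp <= 0:
        raise ValueError(f"{gene_model.gene}: non-positive CDS length")
    n = sum(1 for r in records if r.gene == gene_model.gene)
    return n / (gene_model.cds_length_bp / 1000.0)


@dataclass
class DomainVariability:
    gene: str
    domain_name: str
    n_variants: int
    length_aa: int

    @property
    def density(self) -> float:
        """Variants per amino acid of the domain."""
        return self.n_variants / self.length_aa


def domain_density(
    records: Sequence[VariantRecord],
    gene_model: GeneModel,
    deleterious_only: bool = False,
) -> list[DomainVariability]:
    """Assign protein-affecting variants to domains and compute densities.

    Each variant with a residue annotation is attributed to the unique domain
    containing it, or to a synthetic "other" segment covering the residues
    outside any annotated domain. ``deleterious_only`` restricts the count to
    ensemble-deleterious variants. Residues beyond the protein length are
    skipped (flagged via the returned counts only).
    """
    counts: dict[str, int] = {d.name: 0 for d in gene_model.domains}
    counts["other"] = counts.get("other", 0)
    for r in records:
        if r.gene != gene_model.gene or not affects_protein(r.consequence):
            continue
        if r.amino_acid_change is None:
            continue
        if deleterious_only and ensemble_call(r).value is not Verdict.DELETERIOUS:
            continue
        residue = r.amino_acid_change.position
        if residue < 1 or residue > gene_model.protein_length_aa:
            continue  # out-of-range annotation: skip
        counts[gene_model.domain_of(residue)] += 1
    annotated = sum(d.length_aa for d in gene_model.domains)
    other_len = max(gene_model.protein_length_aa - annotated, 0)
    out = [
        DomainVariability(gene_model.gene, d.name, counts[d.name], d.length_aa)
        for d in gene_model.domains
    ]
    if other_len > 0 or counts["other"] > 0:
        out.append(
            DomainVariability(gene_model.gene, "other", counts["other"], max(other_len, 1))
        )
    return out


@dataclass
class CNVSummary:
    per_gene: dict[str, dict[str, int]]  # gene -> {deletion, duplication, total}

    @property
    def n_genes_with_cnv(self) -> int:
        return sum(1 for c in self.per_gene.values() if c["total"] > 0)

    @property
    def total_events(self) -> int:
        return sum(c["total"] for c in self.per_gene.values())


def cnv_summary(
    cnv_records: Iterable[CNVRecord], genes: Optional[Iterable[str]] = None
) -> CNVSummary:
    """Count CNV events per gene regardless of frequency.

    ``genes`` optionally seeds the table so CNV-free genes report zero.
    """
    per_gene: dict[str, dict[str, int]] = {
        g: {"deletion": 0, "duplication": 0, "total": 0} for g in (genes or ())
    }
    for r in cnv_records:
        entry = per_gene.setdefault(r.gene, {"deletion": 0, "duplication": 0, "total": 0})
        entry[r.kind.value] += 1
        entry["total"] += 1
    return CNVSummary(per_gene=per_gene)


@dataclass
class SubfamilyComparison:
    target: str
    fold_difference: float  # mean(target) / mean(all other subfamilies)
    f_statistic: float
    p_value: float
    group_means: dict[str, float]


def subfamily_comparison(
    per_gene_counts: Mapping[str, float],
    subfamily_map: Mapping[str, str],
    target: str,
) -> SubfamilyComparison:
    """Compare per-gene variant counts across subfamilies.

    Fold difference is mean(target subfamily) / mean(all remaining genes);
    the F and p come from a standard one-way ANOVA across subfamilies.
    Subfamilies without genes in the count table are excluded.
    """
    groups: dict[str, list[float]] = {}
    for gene, count in per_gene_counts.items():
        sf = subfamily_map.get(gene)
        if sf is None:
            continue
        groups.setdefault(sf, []).append(float(count))
    groups = {sf: v for sf, v in groups.items() if v}
    if len(groups) < 2:
        raise ValueError("need at least two non-empty subfamilies")
    if target not in groups:
        raise ValueError(f"target subfamily {target!r} has no genes")
    rest = [x for sf, v in groups.items() if sf != target for x in v]
    fold = float(np.mean(groups[target]) / np.mean(rest))
    f_stat, p = stats.f_oneway(*groups.values())
    # all-identical groups: scipy returns NaN with a warning; report F = 0
    if np.isnan(f_stat):
        f_stat, p = 0.0, 1.0
    return SubfamilyComparison(
        target=target,
        fold_difference=fold,
        f_statistic=float(f_stat),
        p_value=float(p),
        group_means={sf: float(np.mean(v)) for sf, v in groups.items()},
    )


@dataclass
class OERatio:
    observed: int
    expected: float
    ratio: float
    lower90: float
    upper90: float


def oe_ratio(observed: int, expected: float) -> OERatio:
    """Observed/expected variant-count ratio with an exact Poisson 90% interval.

    The interval is the exact (garwood) Poisson interval on the observed
    count, divided by the expected count: lower = chi2(0.05, 2k)/2,
    upper = chi2(0.95, 2k+2)/2.
    """
    if expected <= 0:
        raise ValueError("expected count must be positive")
    if observed < 0:
        raise ValueError("observed count must be non-negative")
    lower = 0.0 if observed == 0 else stats.chi2.ppf(0.05, 2 * observed) / 2.0
    upper = stats.chi2.ppf(0.95, 2 * (observed + 1)) / 2.0
    return OERatio(
        observed=observed,
        expected=expected,
        ratio=observed / expected,
        lower90=lower / expected,
        upper90=upper / expected,
    )


def burden_constraint_correlation(
    rare_fractions: Sequence[float], constraint_scores: Sequence[float]
) -> tuple[float, float]:
    """Pearson r (with two-sided t-based p) between burden composition and
    constraint annotations across genes."""
    x = np.asarray(rare_fractions, dtype=float)
    y = np.asarray(constraint_scores, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need paired vectors of length >= 3")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance: correlation undefined")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)
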