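"""Pipeline orchestration and tabular report assembly.

``run_pipeline`` executes read (or simulate) → ClinVar-benign filter →
classification → burden/population-specificity → disease risk → gene and
domain summaries, and writes a deterministic TSV bundle plus a
machine-readable run manifest (seed, config hash, package version).
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import pandas as pd

from . import __version__
from .burden import per_individual_burden, specificity_partition
from .classify import classify_records, clinvar_benign_filter
from .disease import disease_risk_table
from .errors import AbctransError
from .io import (
    load_packaged_clinical_variants,
    read_cnv_table,
    read_frequency_table,
    read_gene_models,
)
from .model import POPULATIONS, ClinicalVariant, GeneModel, VariantRecord
from .simulate import SimulationConfig, simulate_dataset, write_dataset
from .summaries import (
    cnv_summary,
    consequence_counts,
    domain_density,
    subfamily_comparison,
    variants_per_kb,
)

logger = logging.getLogger(__name__)


def format_percent(numerator: float, denominator: float, decimals: int = 1) -> float:
    """Percentage of ``numerator / denominator`` rounded for display.

    The summary formatter used in report prose, e.g. 15152/33137 -> 45.7.
    """
    if denominator == 0:
        raise ZeroDivisionError("denominator is zero")
    return round(100.0 * numerator / denominator, decimals)


def clinical_query(
    table: Sequence[ClinicalVariant],
    rsid: str,
    statistic: str,
    population: Optional[str] = None,
    allele: Optional[str] = None,
):
    """Summary statistics over the per-population MAFs of one clinical variant.

    ``max``/``min`` return the extreme non-missing frequency (percent);
    ``fold_range`` the max/min ratio over strictly positive entries (zeros
    are excluded with a logged warning); ``modal_allele`` the most frequent
    named allele of a multi-allelic record in ``population`` as a
    (label, percent) pair.
    """
    by_rsid = {v.rsid: v for v in table}
    if rsid not in by_rsid:
        raise KeyError(f"rsid {rsid!r} not in table")
    record = by_rsid[rsid]

    if statistic == "modal_allele":
        if not record.is_multiallelic:
            raise ValueError(f"{rsid} is biallelic: modal_allele undefined")
        if population is None:
            raise ValueError("modal_allele requires a population")
        best_label, best = None, -1.0
        for label, freqs in record.alleles.items():
            value = freqs.get(population)
            if value is not None and value > best:
                best_label, best = label, value
        if best_label is None:
            raise ValueError(f"{rsid}: no frequencies for population {population}")
        return best_label, best

    if record.is_multiallelic:
        if allele is None:
            raise ValueError(f"{rsid} is multi-allelic: specify an allele label")
        freqs = record.alleles[allele]
    else:
        freqs = record.per_pop_maf
    values = [v for v in freqs.values() if v is not None]
    if not values:
        raise ValueError(f"{rsid}: all population frequencies missing")
    if statistic == "max":
        return max(values)
    if statistic == "min":
        return min(values)
    if statistic == "fold_range":
        positive = [v for v in values if v > 0]
        if len(positive) < len(values):
            logger.warning("%s: zero frequencies excluded from fold_range", rsid)
        if not positive:
            raise ValueError(f"{rsid}: no strictly positive frequencies")
        return max(positive) / min(positive)
    raise ValueError(f"unknown statistic {statistic!r}")


@dataclass
class ReportBundle:
    """The assembled tables of one pipeline run."""

    manifest: dict
    per_gene_counts: pd.DataFrame
    calls: pd.DataFrame
    deleterious_per_gene: pd.DataFrame
    burden_table: pd.DataFrame
    specificity_overall: pd.DataFrame
    specificity_per_population: pd.DataFrame
    specificity_per_gene: pd.DataFrame
    domain_density_table: pd.DataFrame
    per_gene_summary: pd.DataFrame
    cnv_table: pd.DataFrame
    disease_risk: pd.DataFrame
    clinical_queries: pd.DataFrame

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        tables = {
            "per_gene_counts.tsv": self.per_gene_counts.reset_index(),
            "calls.tsv": self.calls,
            "deleterious_per_gene.tsv": self.deleterious_per_gene,
            "burden.tsv": self.burden_table,
            "popspec_overall.tsv": self.specificity_overall,
            "popspec_per_population.tsv": self.specificity_per_population,
            "popspec_per_gene.tsv": self.specificity_per_gene,
            "domain_density.tsv": self.domain_density_table,
            "per_gene_summary.tsv": self.per_gene_summary,
            "cnv_summary.tsv": self.cnv_table,
            "disease_risk.tsv": self.disease_risk,
            "clinical_queries.tsv": self.clinical_queries,
        }
        for name, frame in tables.items():
            frame.to_csv(
                outdir / name,
                sep="\t",
                index=False,
                float_format="%.8g",
                lineterminator="\n",
            )
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(self.manifest, fh, indent=2, sort_keys=True)
            fh.write("\n")


def config_hash(config: Mapping) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()


def _burden_frame(
    records: Sequence[VariantRecord], genes: Sequence[str], populations: Sequence[str]
) -> pd.DataFrame:
    rows = []
    for pop in populations:
        for gene in list(genes) + [None]:
            try:
                s = per_individual_burden(records, pop, gene=gene)
            except AbctransError:
                continue
            rf = s.rare_fraction
            rows.append(
                {
                    "gene": gene if gene is not None else "ALL",
                    "population": pop,
                    "burden": s.burden,
                    "burden_rare": s.burden_rare,
                    "rare_fraction": rf if rf is not None else math.nan,
                    "n_deleterious": s.n_deleterious,
                }
            )
    return pd.DataFrame(rows, columns=["gene", "population", "burden", "burden_rare", "rare_fraction", "n_deleterious"])


def run_pipeline(config: Mapping, outdir: str | Path) -> ReportBundle:
    """Execute the full analysis described by a configuration mapping.

    The configuration carries a ``seed`` plus either a ``simulate`` section
    (forwarded to :class:`SimulationConfig`) or an ``io`` section naming
    ``variants``/``genes``/``domains``/``cnv`` files. Writes the TSV bundle
    and manifest into ``outdir`` and returns the in-memory bundle.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))

    if "simulate" in config:
        sim_kwargs = dict(config["simulate"])
        sim_kwargs.setdefault("seed", seed)
        sim_config = SimulationConfig(**sim_kwargs)
        dataset = simulate_dataset(sim_config)
        write_dataset(dataset, outdir / "inputs")
        records = dataset.variants
        gene_models = dataset.gene_models
        cnvs = dataset.cnvs
    elif "io" in config:
        io_cfg = config["io"]
        records = read_frequency_table(io_cfg["variants"])
        gene_models = read_gene_models(io_cfg["genes"], io_cfg.get("domains"))
        cnvs = read_cnv_table(io_cfg["cnv"]) if io_cfg.get("cnv") else []
    else:
        raise ValueError("config needs a 'simulate' or 'io' section")

    if not records:
        logger.warning("empty variant table: emitting empty report bundle")

    populations = list(config.get("report", {}).get("populations", POPULATIONS))

    filtered = clinvar_benign_filter(records, gene_models)
    calls = classify_records(filtered)
    counts = consequence_counts(filtered)

    if not calls.empty:
        protein = calls[calls["protein_affecting"]]
        deleterious_per_gene = (
            protein.groupby("gene")["deleterious_call"]
            .value_counts()
            .unstack(fill_value=0)
            .reindex(columns=["deleterious", "neutral", "unscored"], fill_value=0)
            .reset_index()
        )
    else:
        deleterious_per_gene = pd.DataFrame(columns=["gene", "deleterious", "neutral", "unscored"])

    genes = sorted(gene_models)
    burden_table = _burden_frame(filtered, genes, populations)

    part = specificity_partition(filtered)
    specificity_overall = pd.DataFrame(
        [
            {
                "n_specific": part.n_specific,
                "n_shared": part.n_shared,
                "fraction_specific": part.fraction_specific if part.fraction_specific is not None else math.nan,
            }
        ]
    )
    specificity_per_population = pd.DataFrame(
        [{"population": p, "n_specific": n} for p, n in part.per_population.items()]
    )
    specificity_per_gene = pd.DataFrame(
        [
            {"gene": g, "fraction_specific": f if f is not None else math.nan}
            for g, f in sorted(part.per_gene_fraction.items())
        ],
        columns=["gene", "fraction_specific"],
    )

    density_rows = []
    for model in gene_models.values():
        for deleterious_only in (False, True):
            for d in domain_density(filtered, model, deleterious_only=deleterious_only):
                density_rows.append(
                    {
                        "gene": d.gene,
                        "domain": d.domain_name,
                        "mode": "deleterious" if deleterious_only else "protein_affecting",
                        "n_variants": d.n_variants,
                        "length_aa": d.length_aa,
                        "density_per_aa": d.density,
                    }
                )
    domain_table = pd.DataFrame(
        density_rows, columns=["gene", "domain", "mode", "n_variants", "length_aa", "density_per_aa"]
    )

    summary_rows = []
    for model in gene_models.values():
        c = model.constraint
        summary_rows.append(
            {
                "gene": model.gene,
                "subfamily": model.subfamily,
                "cds_length_bp": model.cds_length_bp,
                "n_variants": int(counts["total"].get(model.gene, 0)) if "total" in counts else 0,
                "variants_per_kb": variants_per_kb(filtered, model),
                "inheritance": model.inheritance.value,
                "oe_missense": c.oe_missense if c else math.nan,
                "oe_lof": c.oe_lof if c else math.nan,
            }
        )
    per_gene_summary = pd.DataFrame(summary_rows).sort_values("gene").reset_index(drop=True)

    try:
        comparison = subfamily_comparison(
            dict(zip(per_gene_summary["gene"], per_gene_summary["n_variants"])),
            {g: m.subfamily for g, m in gene_models.items()},
            target="A",
        )
        manifest_anova = {
            "target_subfamily": "A",
            "fold_difference": comparison.fold_difference,
            "anova_F": comparison.f_statistic,
            "anova_p": comparison.p_value,
        }
    except ValueError:
        manifest_anova = {}

    cs = cnv_summary(cnvs, genes=genes)
    cnv_table = pd.DataFrame(
        [
            {"gene": g, **counts_}
            for g, counts_ in sorted(cs.per_gene.items())
        ],
        columns=["gene", "deletion", "duplication", "total"],
    )

    risk = disease_risk_table(filtered, gene_models, populations)
    disease_frame = pd.DataFrame(
        [
            {
                "gene": r.gene,
                "population": r.population,
                "q_agg": r.q_agg,
                "carrier_freq": r.carrier_freq,
                "prevalence": r.prevalence,
                "one_in_n": r.one_in_n if r.one_in_n is not None else "",
            }
            for r in risk
        ],
        columns=["gene", "population", "q_agg", "carrier_freq", "prevalence", "one_in_n"],
    )

    clinical = load_packaged_clinical_variants()
    modal = clinical_query(clinical, "rs2032582", "modal_allele", population="SAS")
    clinical_frame = pd.DataFrame(
        [
            {"rsid": "rs17822931", "statistic": "fold_range", "value": clinical_query(clinical, "rs17822931", "fold_range")},
            {"rsid": "rs2032582", "statistic": "modal_allele_SAS", "value": modal[1]},
            {"rsid": "rs246221", "statistic": "max", "value": clinical_query(clinical, "rs246221", "max")},
            {"rsid": "rs2231142", "statistic": "max", "value": clinical_query(clinical, "rs2231142", "max")},
        ]
    )

    manifest = {
        "package": "abctrans",
        "version": __version__,
        "seed": seed,
        "config_sha256": config_hash(config),
        "n_variants": len(records),
        "n_variants_after_clinvar_filter": len(filtered),
        "n_genes": len(gene_models),
        "n_cnv_events": cs.total_events,
        **manifest_anova,
    }

    bundle = ReportBundle(
        manifest=manifest,
        per_gene_counts=counts,
        calls=calls,
        deleterious_per_gene=deleterious_per_gene,
        burden_table=burden_table,
        specificity_overall=specificity_overall,
        specificity_per_population=specificity_per_population,
        specificity_per_gene=specificity_per_gene,
        domain_density_table=domain_table,
        per_gene_summary=per_gene_summary,
        cnv_table=cnv_table,
        disease_risk=disease_frame,
        clinical_queries=clinical_frame,
    )
    bundle.write(outdir)
    return bundle
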