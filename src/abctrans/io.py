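"""Readers and writers for the package's tab-separated interchange formats.

Frequency table (header required)::

    gene chrom pos ref alt rsid consequence
    ac_afr ... ac_oth  an_afr ... an_oth
    sift polyphen2 mutation_assessor vest3 eigen   (D / N / .)
    clinvar                                        (benign / likely_benign / other / .)
    aa_pos aa_ref aa_alt                           ('.' where not applicable)

Clinical fixture table::

    rsid gene variant_type allele_label maf_eur maf_afr maf_eas maf_sas maf_amr maf_aj

with percentages as printed ('.' for N.A., '<x' for censored cells) and one
row per named allele of a multi-allelic entry (allele_label '.' for biallelic).

An optional VCF dialect mirrors the frequency TSV through INFO keys
``AC_<pop>``/``AN_<pop>`` and ``SIFT_CALL`` etc.; it requires cyvcf2.
"""

from __future__ import annotations

import csv
import logging
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

from .errors import MalformedInputError
from .model import (
    CLINICAL_POPULATIONS,
    POPULATIONS,
    PREDICTORS,
    AminoAcidChange,
    ClinVarSignificance,
    ClinicalVariant,
    CNVRecord,
    Consequence,
    ConstraintScores,
    DomainInterval,
    GeneModel,
    PopulationPanel,
    PredictorCall,
    VariantRecord,
    default_panels,
    frequencies_sum_ok,
    validate_panels,
)

logger = logging.getLogger(__name__)

_FIXED_COLUMNS = ("gene", "chrom", "pos", "ref", "alt", "rsid", "consequence")
_TAIL_COLUMNS = PREDICTORS + ("clinvar", "aa_pos", "aa_ref", "aa_alt")


def frequency_table_columns(panels: Sequence[PopulationPanel] | None = None) -> list[str]:
    panels = list(panels) if panels is not None else list(default_panels())
    cols = list(_FIXED_COLUMNS)
    cols += [f"ac_{p.code.lower()}" for p in panels]
    cols += [f"an_{p.code.lower()}" for p in panels]
    cols += list(_TAIL_COLUMNS)
    return cols


def _parse_int(value: str, what: str, path: str, line: int) -> int:
    try:
        return int(value)
    except ValueError:
        raise MalformedInputError(f"{what}: not an integer ({value!r})", path, line) from None


def read_frequency_table(
    path: str | Path, panels: Sequence[PopulationPanel] | None = None
) -> list[VariantRecord]:
    """Parse a per-population frequency TSV into one record per (site, alt).

    Rows violating the allele-count invariant (ac > an) or carrying
    non-numeric counts are rejected with a line-numbered
    :class:`MalformedInputError`; unknown population columns are rejected at
    the header.
    """
    panels = tuple(panels) if panels is not None else default_panels()
    validate_panels(panels)
    codes = [p.code for p in panels]
    expected = set(frequency_table_columns(panels))
    path = Path(path)

    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        header = reader.fieldnames or []
        for col in header:
            if (col.startswith("ac_") or col.startswith("an_")) and col not in expected:
                raise MalformedInputError(
                    f"unknown population column {col!r}", str(path), line=1
                )
        missing = expected - set(header)
        if missing:
            raise MalformedInputError(
                f"missing columns: {sorted(missing)}", str(path), line=1
            )

        records: list[VariantRecord] = []
        for idx, row in enumerate(reader):
            line = idx + 2  # header is line 1
            if any(v is None for v in row.values()):
                raise MalformedInputError("wrong number of fields", str(path), line)
            ac = {c: _parse_int(row[f"ac_{c.lower()}"], f"ac_{c.lower()}", str(path), line) for c in codes}
            an = {c: _parse_int(row[f"an_{c.lower()}"], f"an_{c.lower()}", str(path), line) for c in codes}
            for c in codes:
                if ac[c] > an[c]:
                    raise MalformedInputError(
                        f"allele count {ac[c]} exceeds allele number {an[c]} in {c}",
                        str(path),
                        line,
                    )
                if ac[c] < 0:
                    raise MalformedInputError(f"negative allele count in {c}", str(path), line)
            try:
                consequence = Consequence(row["consequence"])
            except ValueError:
                raise MalformedInputError(
                    f"unknown consequence {row['consequence']!r}", str(path), line
                ) from None
            calls = {}
            for alg in PREDICTORS:
                cell = row[alg]
                try:
                    calls[alg] = PredictorCall(cell)
                except ValueError:
                    raise MalformedInputError(
                        f"bad predictor call {cell!r} for {alg}", str(path), line
                    ) from None
            clinvar_cell = row["clinvar"]
            clinvar = None if clinvar_cell == "." else ClinVarSignificance(clinvar_cell)
            aa = None
            if row["aa_pos"] != ".":
                aa = AminoAcidChange(
                    position=_parse_int(row["aa_pos"], "aa_pos", str(path), line),
                    ref=row["aa_ref"],
                    alt=row["aa_alt"],
                )
            records.append(
                VariantRecord(
                    gene=row["gene"],
                    chrom=row["chrom"],
                    pos=_parse_int(row["pos"], "pos", str(path), line),
                    ref=row["ref"],
                    alt=row["alt"],
                    rsid=None if row["rsid"] == "." else row["rsid"],
                    consequence=consequence,
                    per_pop_ac=ac,
                    per_pop_an=an,
                    predictor_calls=calls,
                    clinvar_significance=clinvar,
                    amino_acid_change=aa,
                )
            )
    return records


def write_frequency_table(
    records: Iterable[VariantRecord],
    path: str | Path,
    panels: Sequence[PopulationPanel] | None = None,
) -> None:
    """Write records in the frequency-TSV dialect (inverse of the reader)."""
    panels = tuple(panels) if panels is not None else default_panels()
    codes = [p.code for p in panels]
    cols = frequency_table_columns(panels)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(cols)
        for r in records:
            row = [
                r.gene,
                r.chrom,
                str(r.pos),
                r.ref,
                r.alt,
                r.rsid if r.rsid is not None else ".",
                r.consequence.value,
            ]
            row += [str(r.per_pop_ac.get(c, 0)) for c in codes]
            row += [str(r.per_pop_an.get(c, 0)) for c in codes]
            row += [r.predictor_calls.get(alg, PredictorCall.MISSING).value for alg in PREDICTORS]
            row.append(r.clinvar_significance.value if r.clinvar_significance else ".")
            if r.amino_acid_change is not None:
                row += [str(r.amino_acid_change.position), r.amino_acid_change.ref, r.amino_acid_change.alt]
            else:
                row += [".", ".", "."]
            writer.writerow(row)


def read_frequency_vcf(
    path: str | Path, panels: Sequence[PopulationPanel] | None = None
) -> list[VariantRecord]:
    """Read the optional biallelic-decomposed VCF dialect (requires cyvcf2).

    INFO keys ``AC_<pop>``/``AN_<pop>`` mirror the TSV count columns;
    ``SIFT_CALL`` etc. carry predictor calls, ``CSQ_CLASS`` the consequence,
    ``GENE`` the gene symbol, ``CLNSIG`` the ClinVar class and
    ``AA_POS``/``AA_REF``/``AA_ALT`` the protein change.
    """
    from cyvcf2 import VCF  # heavy import kept optional

    panels = tuple(panels) if panels is not None else default_panels()
    codes = [p.code for p in panels]
    records = []
    for v in VCF(str(path)):
        info = dict(v.INFO)
        ac = {c: int(info.get(f"AC_{c.lower()}", 0)) for c in codes}
        an = {c: int(info.get(f"AN_{c.lower()}", 0)) for c in codes}
        calls = {
            alg: PredictorCall(str(info.get(f"{alg.upper()}_CALL", ".")))
            for alg in PREDICTORS
        }
        clnsig = str(info.get("CLNSIG", "."))
        aa = None
        if "AA_POS" in info:
            aa = AminoAcidChange(int(info["AA_POS"]), str(info.get("AA_REF", "?")), str(info.get("AA_ALT", "?")))
        records.append(
            VariantRecord(
                gene=str(info.get("GENE", "?")),
                chrom=v.CHROM,
                pos=v.POS,
                ref=v.REF,
                alt=v.ALT[0],
                rsid=v.ID if v.ID not in (None, ".") else None,
                consequence=Consequence(str(info.get("CSQ_CLASS", "other"))),
                per_pop_ac=ac,
                per_pop_an=an,
                predictor_calls=calls,
                clinvar_significance=None if clnsig == "." else ClinVarSignificance(clnsig),
                amino_acid_change=aa,
            )
        )
    return records


# ---------------------------------------------------------------------------
# clinical fixture tables


def _parse_maf_cell(cell: str) -> tuple[Optional[float], bool]:
    """Return (value-in-percent or None, censored flag) for one table cell."""
    cell = cell.strip()
    if cell in (".", "", "N.A", "N.A."):
        return None, False
    censored = cell.startswith("<")
    if censored:
        cell = cell[1:].strip()
    value = float(cell)
    if not 0.0 <= value <= 100.0:
        raise ValueError(f"frequency {value} outside [0, 100]")
    return value, censored


def read_clinical_table(path: str | Path) -> list[ClinicalVariant]:
    """Parse a clinical-variant fixture TSV into grouped records.

    Rows sharing an rsid with named allele labels are assembled into one
    multi-allelic record. A multi-allelic record whose allele frequencies sum
    outside 100 ± 0.3 in some population is kept but logged as a warning
    (transcription-rounding tolerance).
    """
    path = Path(path)
    pop_cols = [f"maf_{p.lower()}" for p in CLINICAL_POPULATIONS]
    grouped: dict[str, ClinicalVariant] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for idx, row in enumerate(reader):
            line = idx + 2
            if any(row.get(c) is None for c in ("rsid", "gene", "variant_type", "allele_label", *pop_cols)):
                raise MalformedInputError("missing required column/field", str(path), line)
            freqs: dict[str, Optional[float]] = {}
            censored_pops = []
            for pop, col in zip(CLINICAL_POPULATIONS, pop_cols):
                try:
                    value, censored = _parse_maf_cell(row[col])
                except ValueError as exc:
                    raise MalformedInputError(str(exc), str(path), line) from None
                freqs[pop] = value
                if censored:
                    censored_pops.append(pop)
            label = row["allele_label"]
            rec = grouped.get(row["rsid"])
            if rec is None:
                rec = ClinicalVariant(rsid=row["rsid"], gene=row["gene"], variant_type=row["variant_type"])
                grouped[row["rsid"]] = rec
            if label == ".":
                rec.per_pop_maf = freqs
            else:
                rec.alleles[label] = freqs
            rec.censored = rec.censored | {(label, p) for p in censored_pops}

    records = list(grouped.values())
    for rec in records:
        if not frequencies_sum_ok(rec):
            logger.warning(
                "%s: multi-allelic frequencies sum outside 100 +/- 0.3 in some population",
                rec.rsid,
            )
    return records


def load_packaged_clinical_variants() -> list[ClinicalVariant]:
    """The packaged transcription of the clinically characterized variants
    of ABCB1, the ABCC subfamily, and ABCG2 (per-population MAFs in percent)."""
    with resources.as_file(
        resources.files("abctrans").joinpath("data/clinical_variants.tsv")
    ) as p:
        return read_clinical_table(p)


# ---------------------------------------------------------------------------
# gene models, domains, CNVs, genotypes


def read_gene_models(
    genes_path: str | Path, domains_path: str | Path | None = None
) -> dict[str, GeneModel]:
    """Read the gene-model TSV (plus optional domain TSV) keyed by symbol."""
    genes = pd.read_csv(genes_path, sep="\t", dtype=str, keep_default_na=False)
    domains: dict[str, list[DomainInterval]] = {}
    if domains_path is not None:
        dom = pd.read_csv(domains_path, sep="\t", dtype=str, keep_default_na=False)
        for _, row in dom.iterrows():
            domains.setdefault(row["gene"], []).append(
                DomainInterval(row["domain"], int(row["start_res"]), int(row["end_res"]))
            )
    models: dict[str, GeneModel] = {}
    for i, row in genes.iterrows():
        constraint = None
        opt = {k: row.get(k, "") for k in ("oe_missense", "oe_lof", "z_missense", "pli")}
        if any(v not in ("", ".") for v in opt.values()):
            constraint = ConstraintScores(
                **{k: (float(v) if v not in ("", ".") else None) for k, v in opt.items()}
            )
        try:
            models[row["gene"]] = GeneModel(
                gene=row["gene"],
                subfamily=row["subfamily"],
                cds_length_bp=int(row["cds_length_bp"]),
                protein_length_aa=int(row["protein_length_aa"]),
                inheritance=row["inheritance"],
                domains=tuple(domains.get(row["gene"], ())),
                constraint=constraint,
            )
        except ValueError as exc:
            raise MalformedInputError(str(exc), str(genes_path), line=i + 2) from None
    return models


def write_gene_models(models: dict[str, GeneModel], genes_path: str | Path, domains_path: str | Path) -> None:
    with open(genes_path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["gene", "subfamily", "cds_length_bp", "protein_length_aa", "inheritance",
                    "oe_missense", "oe_lof", "z_missense", "pli"])
        for m in models.values():
            c = m.constraint or ConstraintScores()
            fmt = lambda v: "." if v is None else f"{v:.4g}"
            w.writerow([m.gene, m.subfamily, m.cds_length_bp, m.protein_length_aa,
                        m.inheritance.value, fmt(c.oe_missense), fmt(c.oe_lof),
                        fmt(c.z_missense), fmt(c.pli)])
    with open(domains_path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["gene", "domain", "start_res", "end_res"])
        for m in models.values():
            for d in m.domains:
                w.writerow([m.gene, d.name, d.start_residue, d.end_residue])


def read_cnv_table(path: str | Path) -> list[CNVRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    records = []
    for i, row in df.iterrows():
        try:
            records.append(
                CNVRecord(
                    gene=row["gene"],
                    kind=row["kind"],
                    first_exon=int(row["first_exon"]),
                    last_exon=int(row["last_exon"]),
                    frequency=float(row["frequency"]),
                )
            )
        except (ValueError, KeyError) as exc:
            raise MalformedInputError(str(exc), str(path), line=i + 2) from None
    return records


def write_cnv_table(records: Iterable[CNVRecord], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["gene", "kind", "first_exon", "last_exon", "frequency"])
        for r in records:
            w.writerow([r.gene, r.kind.value, r.first_exon, r.last_exon, f"{r.frequency:.3g}"])


def read_genotype_table(path: str | Path) -> dict[str, "pd.Series"]:
    """Read a long genotype TSV (sample, variant, dosage) into per-variant series."""
    df = pd.read_csv(path, sep="\t", dtype={"sample": str, "variant": str, "dosage": int})
    bad = ~df["dosage"].isin([0, 1, 2])
    if bad.any():
        line = int(df.index[bad][0]) + 2
        raise MalformedInputError("dosage outside {0,1,2}", str(path), line)
    return {v: g.set_index("sample")["dosage"] for v, g in df.groupby("variant")}
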