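"""Seeded generator of gnomAD-like transporter variant data.

The generator emulates the statistical structure of a population-scale
exome/genome aggregation cohort over an ABC-transporter-like gene family:

* eight population panels with unequal cohort sizes (the published panel
  sizes are the defaults, 138,632 individuals in total);
* a rare-skewed site-frequency spectrum: ancestral frequencies follow a
  truncated power law x**(-shape), so the pooled cohort is dominated by
  variants with folded MAF < 1% and a large singleton share;
* population differentiation under the Balding-Nichols model: each panel
  frequency is a Beta draw with mean equal to the ancestral frequency and
  variance F_ST * p * (1 - p), followed by binomial allele-count sampling;
* consequence classes drawn from fixed proportions (missense-dominated),
  a latent deleterious/neutral truth state per protein-affecting variant,
  and five predictor calls with configurable sensitivity/specificity and
  per-algorithm missing rates;
* Hardy-Weinberg genotype sampling for burden and prevalence oracles;
* rare CNV events per gene.

All randomness flows from a single integer seed through per-gene
sub-streams, so identical configurations produce byte-identical output
tables regardless of evaluation order.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .model import (
    POPULATIONS,
    PREDICTORS,
    AminoAcidChange,
    ClinVarSignificance,
    CNVKind,
    CNVRecord,
    Consequence,
    ConstraintScores,
    DomainInterval,
    GeneModel,
    Inheritance,
    PopulationPanel,
    PredictorCall,
    VariantRecord,
    default_panels,
)
from . import io as _io

#: Gene roster of the emulated family: subfamily -> member count (48 genes).
SUBFAMILY_SIZES: dict[str, int] = {"A": 12, "B": 11, "C": 12, "D": 4, "E": 1, "F": 3, "G": 5}

#: Consequence-class proportions of the emulated exonic variant pool.
DEFAULT_CONSEQUENCE_PROBS: dict[str, float] = {
    "missense": 0.531,
    "synonymous": 0.231,
    "utr": 0.167,
    "frameshift": 0.030,
    "stop_gained": 0.018,
    "splice_site": 0.011,
    "start_lost": 0.002,
    "inframe_indel": 0.004,
    "other": 0.006,
}

_DEFAULT_SENS = {alg: 0.8 for alg in PREDICTORS}
_DEFAULT_SPEC = {alg: 0.8 for alg in PREDICTORS}
_DEFAULT_MISSING = {
    "sift": 0.03,
    "polyphen2": 0.03,
    "mutation_assessor": 0.08,
    "vest3": 0.15,
    "eigen": 0.15,
}


@dataclass(frozen=True)
class SimulationConfig:
    """Conditions of one synthetic cohort; the defaults are the study scale."""

    seed: int
    panels: tuple[PopulationPanel, ...] = field(default_factory=default_panels)
    n_genes: int = 48
    gene_length_range_bp: tuple[int, int] = (2100, 6900)
    variants_per_kb: float = 290.0
    sfs_shape: float = 2.2
    sfs_support: tuple[float, float] = (1.0 / 277264, 0.5)
    fst: float = 0.05
    p_deleterious_true: float = 0.46
    predictor_sensitivity: Mapping[str, float] = field(default_factory=lambda: dict(_DEFAULT_SENS))
    predictor_specificity: Mapping[str, float] = field(default_factory=lambda: dict(_DEFAULT_SPEC))
    predictor_missing_rate: Mapping[str, float] = field(default_factory=lambda: dict(_DEFAULT_MISSING))
    consequence_probs: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CONSEQUENCE_PROBS)
    )
    cnv_rate: float = 20.9
    clinvar_benign_rate: float = 0.02

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        lo, hi = self.sfs_support
        if not (0.0 < lo <= hi <= 1.0):
            raise ValueError(f"degenerate SFS support {self.sfs_support}")
        if not 0.0 < self.fst < 1.0:
            raise ValueError("fst must lie in (0, 1)")
        for mapping in (
            self.predictor_sensitivity,
            self.predictor_specificity,
            self.predictor_missing_rate,
        ):
            for alg, p in mapping.items():
                if not 0.0 <= p <= 1.0:
                    raise ValueError(f"probability {p} for {alg} outside [0, 1]")
        if not 0.0 <= self.p_deleterious_true <= 1.0:
            raise ValueError("p_deleterious_true outside [0, 1]")

    @property
    def lof_fraction(self) -> float:
        """Fraction of variants in loss-of-function consequence classes."""
        lof = ("frameshift", "stop_gained", "splice_site", "start_lost")
        total = sum(self.consequence_probs.values())
        return sum(self.consequence_probs.get(c, 0.0) for c in lof) / total


def _rng(seed: int, *key: int) -> np.random.Generator:
    """Deterministic sub-stream generator for a (seed, stage, index...) key."""
    return np.random.default_rng(np.random.SeedSequence((int(seed), *map(int, key))))


def simulate_ancestral_frequencies(
    config: SimulationConfig, n_variants: int, rng: Optional[np.random.Generator] = None
) -> np.ndarray:
    """Draw ancestral frequencies from the truncated power law x**(-shape).

    Inverse-CDF sampling on [lo, hi]; shape 0 is the uniform law and a
    degenerate support lo == hi returns that constant.
    """
    rng = rng if rng is not None else _rng(config.seed, 0)
    lo, hi = config.sfs_support
    if lo == hi:
        return np.full(n_variants, lo)
    u = rng.random(n_variants)
    a = config.sfs_shape
    if abs(a - 1.0) < 1e-12:
        return lo * (hi / lo) ** u
    e = 1.0 - a
    return (lo**e + u * (hi**e - lo**e)) ** (1.0 / e)


def simulate_population_frequencies(
    ancestral_p: np.ndarray | float,
    fst: float,
    panels: Sequence[PopulationPanel],
    seed: int | np.random.Generator,
) -> tuple[dict[str, np.ndarray], dict[str, np.ndarray], dict[str, int]]:
    """Balding-Nichols panel frequencies and sampled allele counts.

    Each panel frequency is Beta with mean p and variance fst * p * (1 - p)
    (shape parameters p(1-F)/F and (1-p)(1-F)/F); allele counts are binomial
    at 2 * n_individuals. Returns (latent frequencies, allele counts, allele
    numbers), each keyed by panel code.
    """
    rng = seed if isinstance(seed, np.random.Generator) else _rng(int(seed), 10)
    p = np.atleast_1d(np.asarray(ancestral_p, dtype=float))
    if ((p <= 0) | (p >= 1)).any():
        raise ValueError("ancestral frequencies must lie strictly in (0, 1)")
    if not 0.0 < fst < 1.0:
        raise ValueError("fst must lie in (0, 1)")
    scale = (1.0 - fst) / fst
    freqs: dict[str, np.ndarray] = {}
    acs: dict[str, np.ndarray] = {}
    ans: dict[str, int] = {}
    for panel in panels:
        q = rng.beta(p * scale, (1.0 - p) * scale)
        ac = rng.binomial(panel.n_alleles, q)
        freqs[panel.code] = q
        acs[panel.code] = ac
        ans[panel.code] = panel.n_alleles
    return freqs, acs, ans


def simulate_genotypes(
    af: float, n_individuals: int, seed: int | np.random.Generator
) -> np.ndarray:
    """Independent Hardy-Weinberg diploid dosages: Binomial(2, af) per individual."""
    if not 0.0 <= af <= 1.0:
        raise ValueError(f"allele frequency {af} outside [0, 1]")
    if n_individuals <= 0:
        raise ValueError("n_individuals must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else _rng(int(seed), 20)
    return rng.binomial(2, af, size=n_individuals).astype(np.int8)


def simulate_annotations(
    records: Sequence[VariantRecord],
    config: SimulationConfig,
    rng: np.random.Generator,
    gene_models: Optional[Mapping[str, GeneModel]] = None,
    truth: Optional[Mapping[str, bool]] = None,
) -> dict[str, bool]:
    """Draw consequences, latent truth, predictor calls and ClinVar labels.

    Mutates ``records`` in place and returns the latent deleterious state per
    variant id. A supplied ``truth`` mapping pins the latent state of missense
    variants; loss-of-function classes and in-frame indels are always truly
    deleterious, non-protein-affecting classes never.
    """
    classes = list(config.consequence_probs)
    probs = np.array([config.consequence_probs[c] for c in classes], dtype=float)
    probs = probs / probs.sum()
    drawn = rng.choice(len(classes), size=len(records), p=probs)
    out: dict[str, bool] = {}
    lof_like = {"frameshift", "stop_gained", "splice_site", "start_lost", "inframe_indel"}
    for r, ci in zip(records, drawn):
        csq = classes[ci]
        r.consequence = Consequence(csq)
        protein_affecting = csq in lof_like or csq == "missense"
        if csq in lof_like:
            is_del = True
        elif csq == "missense":
            if truth is not None and r.variant_id in truth:
                is_del = bool(truth[r.variant_id])
            else:
                is_del = bool(rng.random() < config.p_deleterious_true)
        else:
            is_del = False
        out[r.variant_id] = is_del

        if protein_affecting:
            length = 500
            if gene_models is not None and r.gene in gene_models:
                length = gene_models[r.gene].protein_length_aa
            aas = "ACDEFGHIKLMNPQRSTVWY"
            pos = int(rng.integers(1, length + 1))
            ref_aa, alt_aa = (aas[i] for i in rng.choice(20, size=2, replace=False))
            r.amino_acid_change = AminoAcidChange(pos, ref_aa, alt_aa)
        else:
            r.amino_acid_change = None

        calls: dict[str, PredictorCall] = {}
        if csq == "missense":
            for alg in PREDICTORS:
                if rng.random() < config.predictor_missing_rate.get(alg, 0.0):
                    calls[alg] = PredictorCall.MISSING
                    continue
                p_call_del = (
                    config.predictor_sensitivity.get(alg, 1.0)
                    if is_del
                    else 1.0 - config.predictor_specificity.get(alg, 1.0)
                )
                calls[alg] = (
                    PredictorCall.DELETERIOUS
                    if rng.random() < p_call_del
                    else PredictorCall.NEUTRAL
                )
        else:
            calls = {alg: PredictorCall.MISSING for alg in PREDICTORS}
        r.predictor_calls = calls

        r.clinvar_significance = None
        if gene_models is not None:
            model = gene_models.get(r.gene)
            if (
                model is not None
                and model.inheritance is not Inheritance.NONE
                and not is_del
                and rng.random() < config.clinvar_benign_rate
            ):
                r.clinvar_significance = (
                    ClinVarSignificance.BENIGN
                    if rng.random() < 0.5
                    else ClinVarSignificance.LIKELY_BENIGN
                )
    return out


def _gene_roster(n_genes: int) -> list[tuple[str, str]]:
    """(symbol, subfamily) pairs; the first 48 follow the family layout."""
    roster = [
        (f"ABC{sf}{i}", sf)
        for sf in SUBFAMILY_SIZES
        for i in range(1, SUBFAMILY_SIZES[sf] + 1)
    ]
    extra = 0
    while len(roster) < n_genes:
        sf = "ABCDEFG"[extra % 7]
        roster.append((f"ABC{sf}{SUBFAMILY_SIZES[sf] + 1 + extra // 7}", sf))
        extra += 1
    return roster[:n_genes]


def _make_domains(sf: str, length: int, rng: np.random.Generator) -> tuple[DomainInterval, ...]:
    """Disjoint domain intervals with the family's typical topology."""

    def span(a: float, b: float) -> tuple[int, int]:
        return max(1, int(a * length)), min(length, int(b * length))

    domains: list[DomainInterval] = []
    if sf == "A":  # full transporter with two large extracellular domains
        layout = [
            ("TMD1", 0.02, 0.08), ("ECD1", 0.10, 0.30), ("NBD1", 0.36, 0.50),
            ("TMD2", 0.52, 0.58), ("ECD2", 0.60, 0.78), ("NBD2", 0.84, 0.97),
        ]
    elif sf in ("B", "C") and rng.random() < 0.5:  # TMD0-carrying member
        layout = [
            ("TMD0", 0.01, 0.12), ("TMD1", 0.16, 0.36), ("NBD1", 0.40, 0.55),
            ("TMD2", 0.58, 0.80), ("NBD2", 0.84, 0.97),
        ]
    else:
        layout = [
            ("TMD1", 0.06, 0.33), ("NBD1", 0.38, 0.55),
            ("TMD2", 0.60, 0.85), ("NBD2", 0.88, 0.98),
        ]
    for name, a, b in layout:
        s, e = span(a, b)
        if s <= e:
            domains.append(DomainInterval(name, s, e))
    return tuple(domains)


@dataclass
class SimulatedDataset:
    config: SimulationConfig
    variants: list[VariantRecord]
    gene_models: dict[str, GeneModel]
    cnvs: list[CNVRecord]
    truth: pd.DataFrame  # variant_id, gene, deleterious_true, p_true_<pop>...


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Generate a full cohort: gene models, variant table, CNVs, latent truth."""
    roster = _gene_roster(config.n_genes)
    panels = tuple(config.panels)
    gene_models: dict[str, GeneModel] = {}
    variants: list[VariantRecord] = []
    cnvs: list[CNVRecord] = []
    truth_rows: list[dict] = []

    for gi, (symbol, sf) in enumerate(roster):
        grng = _rng(config.seed, 1, gi)
        lo, hi = config.gene_length_range_bp
        cds = int(grng.integers(lo, hi + 1)) // 3 * 3
        length_aa = cds // 3
        modes = (Inheritance.AR, Inheritance.AD, Inheritance.XL, Inheritance.NONE)
        inheritance = modes[int(grng.choice(4, p=[0.35, 0.06, 0.02, 0.57]))]
        constraint = ConstraintScores(
            oe_missense=float(np.round(grng.uniform(0.6, 1.3), 3)),
            oe_lof=float(np.round(grng.uniform(0.2, 1.2), 3)),
            z_missense=float(np.round(grng.normal(1.0, 1.5), 3)),
            pli=float(np.round(grng.beta(0.2, 0.5), 4)),
        )
        gene_models[symbol] = GeneModel(
            gene=symbol,
            subfamily=sf,
            cds_length_bp=cds,
            protein_length_aa=length_aa,
            inheritance=inheritance,
            domains=_make_domains(sf, length_aa, grng),
            constraint=constraint,
        )

        # Draw candidate sites until the gene's emitted quota of variants
        # segregating in the sampled cohort is met (ascertainment keeps only
        # sites with 1 <= total alternate count < total allele number).
        target = min(int(grng.poisson(cds / 1000.0 * config.variants_per_kb)), cds)
        if target == 0:
            continue
        kept_freqs = {p.code: [] for p in panels}
        kept_acs = {p.code: [] for p in panels}
        ans: dict[str, int] = {p.code: p.n_alleles for p in panels}
        total_an = sum(ans.values())
        kept = 0
        drawn = 0
        max_draws = 2000 * target + 100_000  # safety ceiling for odd configs
        batch = max(2048, 4 * target)
        while kept < target and drawn < max_draws:
            ancestral = simulate_ancestral_frequencies(config, batch, grng)
            freqs, acs, _ = simulate_population_frequencies(
                ancestral, config.fst, panels, grng
            )
            total_ac = np.sum([acs[p.code] for p in panels], axis=0)
            keep = (total_ac >= 1) & (total_ac < total_an)
            for p in panels:
                kept_freqs[p.code].append(freqs[p.code][keep])
                kept_acs[p.code].append(acs[p.code][keep])
            kept += int(keep.sum())
            drawn += batch
            rate = max(kept / drawn, 1e-4)
            batch = int(min(max((target - kept) / rate * 1.3, 2048), 2_000_000))
        freqs = {c: np.concatenate(v)[:target] for c, v in kept_freqs.items()}
        acs = {c: np.concatenate(v)[:target] for c, v in kept_acs.items()}
        n_emitted = min(target, kept)
        if n_emitted == 0:
            continue

        chrom = str(gi % 22 + 1)
        start = 1_000_000 + gi * 1_000_000
        offsets = np.sort(grng.choice(cds, size=n_emitted, replace=False))
        bases = np.array(list("ACGT"))
        ref_i = grng.integers(0, 4, size=n_emitted)
        alt_i = (ref_i + grng.integers(1, 4, size=n_emitted)) % 4

        gene_records = []
        for k in range(n_emitted):
            gene_records.append(
                VariantRecord(
                    gene=symbol,
                    chrom=chrom,
                    pos=int(start + offsets[k]),
                    ref=str(bases[ref_i[k]]),
                    alt=str(bases[alt_i[k]]),
                    rsid=f"sim{gi:02d}_{k:05d}",
                    consequence=Consequence.OTHER,
                    per_pop_ac={p.code: int(acs[p.code][k]) for p in panels},
                    per_pop_an={p.code: int(ans[p.code]) for p in panels},
                )
            )
        truth_map = simulate_annotations(gene_records, config, grng, gene_models)
        variants.extend(gene_records)
        for k, rec in enumerate(gene_records):
            row = {
                "variant_id": rec.variant_id,
                "rsid": rec.rsid,
                "gene": symbol,
                "consequence": rec.consequence.value,
                "deleterious_true": truth_map[rec.variant_id],
            }
            for p in panels:
                row[f"p_true_{p.code.lower()}"] = float(freqs[p.code][k])
            truth_rows.append(row)

        crng = _rng(config.seed, 2, gi)
        n_cnv = int(crng.poisson(config.cnv_rate))
        n_exons = max(2, cds // 170)
        for _ in range(n_cnv):
            first = int(crng.integers(1, n_exons + 1))
            last = int(crng.integers(first, n_exons + 1))
            cnvs.append(
                CNVRecord(
                    gene=symbol,
                    kind=CNVKind.DELETION if crng.random() < 0.6 else CNVKind.DUPLICATION,
                    first_exon=first,
                    last_exon=last,
                    frequency=float(10 ** crng.uniform(-6, -3)),
                )
            )

    truth_cols = ["variant_id", "rsid", "gene", "consequence", "deleterious_true"] + [
        f"p_true_{p.code.lower()}" for p in panels
    ]
    truth = pd.DataFrame(truth_rows, columns=truth_cols)
    return SimulatedDataset(
        config=config, variants=variants, gene_models=gene_models, cnvs=cnvs, truth=truth
    )


def write_dataset(
    dataset: SimulatedDataset,
    outdir: str | Path,
    genotype_panel: str = "NFE",
    genotype_individuals: int = 500,
    max_genotyped_variants: int = 20,
) -> dict[str, Path]:
    """Write the dataset as the package's TSV dialects.

    genotypes.tsv holds Hardy-Weinberg dosages for the most common variants
    (pooled frequency >= 1%) at the ``genotype_panel`` frequency, for LD
    exercises on unphased data.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "variants": outdir / "variants.tsv",
        "genes": outdir / "genes.tsv",
        "domains": outdir / "domains.tsv",
        "cnv": outdir / "cnv.tsv",
        "truth": outdir / "truth.tsv",
        "genotypes": outdir / "genotypes.tsv",
    }
    _io.write_frequency_table(dataset.variants, paths["variants"], dataset.config.panels)
    _io.write_gene_models(dataset.gene_models, paths["genes"], paths["domains"])
    _io.write_cnv_table(dataset.cnvs, paths["cnv"])
    truth = dataset.truth.copy()
    for col in truth.columns:
        if col.startswith("p_true_"):
            truth[col] = truth[col].map(lambda x: f"{x:.8g}")
    truth.to_csv(paths["truth"], sep="\t", index=False, lineterminator="\n")

    common = [r for r in dataset.variants if r.pooled_af() >= 0.01][:max_genotyped_variants]
    rng = _rng(dataset.config.seed, 3)
    with open(paths["genotypes"], "w", newline="") as fh:
        fh.write("sample\tvariant\tdosage\n")
        for r in common:
            af = r.af(genotype_panel)
            dosages = simulate_genotypes(0.0 if af != af else af, genotype_individuals, rng)
            for si, d in enumerate(dosages):
                fh.write(f"s{si:04d}\t{r.variant_id}\t{int(d)}\n")
    return paths
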