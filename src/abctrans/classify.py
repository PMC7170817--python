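"""Variant classification: rarity, protein impact, and deleteriousness.

A variant is "putatively deleterious" if it belongs to a loss-of-function-like
consequence class (frameshift, in-frame indel, start-lost, stop-gained,
canonical splice site) or if it is a missense variant that at least half of
the available effect predictors (SIFT, PolyPhen2, MutationAssessor, VEST3,
Eigen) call damaging. Missense variants with no available predictor call are
"unscored" and excluded from both tallies. Non-protein-affecting classes
(synonymous, UTR, other) are neutral by class.

Rarity is defined on the folded (minor-allele) pooled frequency:
MAF < 1% is rare, MAF < 0.1% very rare, the rest common.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable, Mapping

from .model import (
    ClinVarSignificance,
    Consequence,
    GeneModel,
    Inheritance,
    PredictorCall,
    VariantRecord,
)

#: Default rarity thresholds (folded pooled MAF).
RARE_MAF = 0.01
VERY_RARE_MAF = 0.001

#: Ensemble majority threshold: deleterious when calls/available >= this.
ENSEMBLE_THRESHOLD = 0.5

_PROTEIN_AFFECTING = frozenset(
    {
        Consequence.MISSENSE,
        Consequence.FRAMESHIFT,
        Consequence.INFRAME_INDEL,
        Consequence.START_LOST,
        Consequence.STOP_GAINED,
        Consequence.SPLICE_SITE,
    }
)

#: Loss-of-function classes (the disease-risk aggregation set).
_LOF = frozenset(
    {
        Consequence.FRAMESHIFT,
        Consequence.START_LOST,
        Consequence.STOP_GAINED,
        Consequence.SPLICE_SITE,
    }
)

#: Classes deleterious by consequence alone (LoF plus in-frame indels).
_DELETERIOUS_BY_CLASS = _LOF | {Consequence.INFRAME_INDEL}


class Rarity(str, enum.Enum):
    COMMON = "common"
    RARE = "rare"
    VERY_RARE = "very_rare"


class Verdict(str, enum.Enum):
    DELETERIOUS = "deleterious"
    NEUTRAL = "neutral"
    UNSCORED = "unscored"


class CallBasis(str, enum.Enum):
    LOF_CLASS = "lof_class"
    ENSEMBLE = "ensemble"
    NO_CALLS = "no_calls"
    NOT_PROTEIN_AFFECTING = "not_protein_affecting"


@dataclass(frozen=True)
class DeleteriousnessCall:
    value: Verdict
    basis: CallBasis

    def __post_init__(self) -> None:
        if self.basis is CallBasis.LOF_CLASS and self.value is not Verdict.DELETERIOUS:
            raise ValueError("lof_class basis implies a deleterious verdict")
        if self.basis is CallBasis.NOT_PROTEIN_AFFECTING and self.value is not Verdict.NEUTRAL:
            raise ValueError("not_protein_affecting basis implies a neutral verdict")


def classify_rarity(maf: float, rare: float = RARE_MAF, very_rare: float = VERY_RARE_MAF) -> Rarity:
    """Classify a folded minor-allele frequency at the finest applicable level.

    Thresholds are strict: exactly 1% is common, exactly 0.1% is rare.
    """
    if not 0.0 <= maf <= 1.0:
        raise ValueError(f"MAF {maf} outside [0, 1]")
    if maf < very_rare:
        return Rarity.VERY_RARE
    if maf < rare:
        return Rarity.RARE
    return Rarity.COMMON


def affects_protein(consequence: Consequence) -> bool:
    """True for classes that alter the encoded amino-acid sequence or splicing."""
    return Consequence(consequence) in _PROTEIN_AFFECTING


def is_lof(consequence: Consequence) -> bool:
    """True exactly for frameshift, start-lost, stop-gained and splice-site."""
    return Consequence(consequence) in _LOF


def ensemble_call(
    record: VariantRecord, threshold: float = ENSEMBLE_THRESHOLD
) -> DeleteriousnessCall:
    """Deleteriousness verdict for one record.

    Missense verdicts use a majority vote over the *available* (non-missing)
    predictor calls, with ties (exactly ``threshold``) going to deleterious.
    """
    if not affects_protein(record.consequence):
        return DeleteriousnessCall(Verdict.NEUTRAL, CallBasis.NOT_PROTEIN_AFFECTING)
    if record.consequence in _DELETERIOUS_BY_CLASS:
        return DeleteriousnessCall(Verdict.DELETERIOUS, CallBasis.LOF_CLASS)
    calls = [c for c in record.predictor_calls.values() if c is not PredictorCall.MISSING]
    if not calls:
        return DeleteriousnessCall(Verdict.UNSCORED, CallBasis.NO_CALLS)
    k = sum(1 for c in calls if c is PredictorCall.DELETERIOUS)
    if k / len(calls) >= threshold:
        return DeleteriousnessCall(Verdict.DELETERIOUS, CallBasis.ENSEMBLE)
    return DeleteriousnessCall(Verdict.NEUTRAL, CallBasis.ENSEMBLE)


def clinvar_benign_filter(
    records: Iterable[VariantRecord], gene_models: Mapping[str, GeneModel]
) -> list[VariantRecord]:
    """Drop (likely) benign ClinVar variants from disease-associated genes.

    The filter is scoped to genes with a Mendelian inheritance mode; records
    without a ClinVar annotation, or in non-disease genes, always pass.
    """
    kept = []
    for r in records:
        model = gene_models.get(r.gene)
        disease_gene = model is not None and model.inheritance is not Inheritance.NONE
        benign = r.clinvar_significance in (
            ClinVarSignificance.BENIGN,
            ClinVarSignificance.LIKELY_BENIGN,
        )
        if disease_gene and benign:
            continue
        kept.append(r)
    return kept


def classify_records(records: Iterable[VariantRecord]) -> "pd.DataFrame":
    """Tabulate rarity, protein impact, LoF status and the ensemble verdict.

    One row per record, in input order; the frame is the interchange format of
    the ``classify`` CLI subcommand.
    """
    import pandas as pd

    rows = []
    for r in records:
        call = ensemble_call(r)
        rows.append(
            {
                "gene": r.gene,
                "chrom": r.chrom,
                "pos": r.pos,
                "ref": r.ref,
                "alt": r.alt,
                "rsid": r.rsid or ".",
                "consequence": r.consequence.value,
                "pooled_af": r.pooled_af(),
                "folded_maf": r.folded_maf(),
                "rarity": classify_rarity(r.folded_maf()).value,
                "protein_affecting": affects_protein(r.consequence),
                "lof": is_lof(r.consequence),
                "deleterious_call": call.value.value,
                "call_basis": call.basis.value,
            }
        )
    return pd.DataFrame(rows)
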