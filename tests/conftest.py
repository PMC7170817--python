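"""Shared fixtures: compact record builders and a small simulated dataset."""

from __future__ import annotations

import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # _oracles helper module

from abctrans.model import (
    POPULATIONS,
    AminoAcidChange,
    Consequence,
    GeneModel,
    PredictorCall,
    VariantRecord,
)


def make_record(
    gene: str = "ABCB1",
    consequence: str = "missense",
    ac: dict | int | None = None,
    an: dict | int = 1000,
    calls: str | dict | None = None,
    pos: int = 1000,
    ref: str = "A",
    alt: str = "T",
    clinvar=None,
    aa_pos: int | None = None,
    rsid: str | None = None,
) -> VariantRecord:
    """Terse VariantRecord constructor for tests.

    ``ac``/``an`` given as ints apply to every panel; ``calls`` given as a
    string like "DDN.." assigns the five predictors in canonical order.
    """
    if isinstance(an, int):
        an = {p: an for p in POPULATIONS}
    if ac is None:
        ac = 10
    if isinstance(ac, int):
        ac = {p: min(ac, an.get(p, 0)) for p in an}
    else:
        ac = {p: ac.get(p, 0) for p in an}
    predictor_calls = {}
    if isinstance(calls, str):
        from abctrans.model import PREDICTORS

        predictor_calls = {alg: PredictorCall(c) for alg, c in zip(PREDICTORS, calls)}
    elif isinstance(calls, dict):
        predictor_calls = {k: PredictorCall(v) for k, v in calls.items()}
    return VariantRecord(
        gene=gene,
        chrom="7",
        pos=pos,
        ref=ref,
        alt=alt,
        rsid=rsid,
        consequence=Consequence(consequence),
        per_pop_ac=ac,
        per_pop_an=an,
        predictor_calls=predictor_calls,
        clinvar_significance=clinvar,
        amino_acid_change=AminoAcidChange(aa_pos, "A", "V") if aa_pos else None,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture(scope="session")
def small_dataset():
    """A small but fully featured simulated cohort, shared across tests."""
    from abctrans.simulate import SimulationConfig, simulate_dataset

    config = SimulationConfig(
        seed=11,
        n_genes=6,
        gene_length_range_bp=(1500, 3000),
        variants_per_kb=60.0,
    )
    return simulate_dataset(config)
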