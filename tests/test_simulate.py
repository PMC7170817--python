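"""The synthetic-cohort generator: spectrum, differentiation, annotations,
genotypes, and determinism."""

from __future__ import annotations

import math

import numpy as np
import pytest

from abctrans.classify import Verdict, ensemble_call
from abctrans.model import PopulationPanel, default_panels
from abctrans.simulate import (
    SimulationConfig,
    simulate_ancestral_frequencies,
    simulate_annotations,
    simulate_dataset,
    simulate_genotypes,
    simulate_population_frequencies,
    write_dataset,
)
from _oracles import fst_moment_estimate
from conftest import make_record


class TestConfig:
    def test_degenerate_support_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(seed=1, sfs_support=(0.5, 0.1))

    def test_fst_bounds(self):
        with pytest.raises(ValueError):
            SimulationConfig(seed=1, fst=0.0)

    def test_lof_fraction_derived(self):
        cfg = SimulationConfig(seed=1)
        assert 0.0 < cfg.lof_fraction < 0.1


class TestAncestralFrequencies:
    def test_determinism(self):
        cfg = SimulationConfig(seed=7)
        a = simulate_ancestral_frequencies(cfg, 1000)
        b = simulate_ancestral_frequencies(cfg, 1000)
        assert np.array_equal(a, b)

    def test_support_respected(self):
        cfg = SimulationConfig(seed=7, sfs_support=(1e-4, 0.3))
        p = simulate_ancestral_frequencies(cfg, 5000)
        assert p.min() >= 1e-4 and p.max() <= 0.3

    def test_point_support_all_common(self):
        # shape 0 with support fixed at {0.5}: every variant is common
        cfg = SimulationConfig(seed=7, sfs_shape=0.0, sfs_support=(0.5, 0.5),
                               n_genes=1, gene_length_range_bp=(1500, 1500),
                               variants_per_kb=30.0)
        dataset = simulate_dataset(cfg)
        assert dataset.variants
        for r in dataset.variants:
            assert r.folded_maf() >= 0.01

    def test_rare_skew_increases_with_shape(self):
        lo = SimulationConfig(seed=7, sfs_shape=1.0)
        hi = SimulationConfig(seed=7, sfs_shape=2.5)
        frac_lo = (simulate_ancestral_frequencies(lo, 20000) < 0.01).mean()
        frac_hi = (simulate_ancestral_frequencies(hi, 20000) < 0.01).mean()
        assert frac_hi > frac_lo


class TestBaldingNichols:
    def test_variance_matches_model(self):
        # 10^4 replicate panels at p = 0.3: Var(q) ~ F p (1 - p) within 5%
        panels = tuple(PopulationPanel(f"P{i}", 5000) for i in range(1))
        fst = 0.1
        p = 0.3
        rng = np.random.default_rng(123)
        freqs, _, _ = simulate_population_frequencies(
            np.full(10_000, p), fst, panels, rng
        )
        var = freqs["P0"].var()
        assert var == pytest.approx(fst * p * (1 - p), rel=0.05)

    def test_small_fst_concentrates_at_ancestral(self):
        panels = default_panels()
        rng = np.random.default_rng(5)
        freqs, _, _ = simulate_population_frequencies(
            np.full(1000, 0.4), 1e-5, panels, rng
        )
        for q in freqs.values():
            assert np.abs(q - 0.4).max() < 0.02

    def test_fst_recovery_within_ten_percent(self):
        rng = np.random.default_rng(77)
        panels = default_panels()
        p = rng.uniform(0.1, 0.9, size=10_000)
        fst = 0.1
        freqs, _, _ = simulate_population_frequencies(p, fst, panels, rng)
        stacked = np.column_stack([freqs[pan.code] for pan in panels])
        est = fst_moment_estimate(stacked)
        assert abs(est - fst) / fst <= 0.10

    def test_counts_bounded_by_allele_numbers(self):
        rng = np.random.default_rng(6)
        panels = default_panels()
        _, acs, ans = simulate_population_frequencies(
            np.array([0.01, 0.2, 0.9]), 0.05, panels, rng
        )
        for pan in panels:
            assert (acs[pan.code] >= 0).all()
            assert (acs[pan.code] <= ans[pan.code]).all()


class TestAnnotations:
    def _records(self, n):
        return [make_record(pos=i, ref="A", alt="G") for i in range(n)]

    def test_noiseless_predictors_recover_truth(self):
        cfg = SimulationConfig(
            seed=1,
            predictor_sensitivity={a: 1.0 for a in ("sift", "polyphen2", "mutation_assessor", "vest3", "eigen")},
            predictor_specificity={a: 1.0 for a in ("sift", "polyphen2", "mutation_assessor", "vest3", "eigen")},
            predictor_missing_rate={a: 0.0 for a in ("sift", "polyphen2", "mutation_assessor", "vest3", "eigen")},
        )
        records = self._records(2000)
        rng = np.random.default_rng(2)
        truth = simulate_annotations(records, cfg, rng)
        for r in records:
            if r.consequence.value == "missense":
                verdict = ensemble_call(r).value
                assert (verdict is Verdict.DELETERIOUS) == truth[r.variant_id]

    def test_all_missing_gives_unscored(self):
        cfg = SimulationConfig(
            seed=1,
            predictor_missing_rate={a: 1.0 for a in ("sift", "polyphen2", "mutation_assessor", "vest3", "eigen")},
        )
        records = self._records(500)
        simulate_annotations(records, cfg, np.random.default_rng(3))
        for r in records:
            if r.consequence.value == "missense":
                assert ensemble_call(r).value is Verdict.UNSCORED

    def test_ensemble_beats_single_algorithm(self):
        # five independent 80/80 predictors: the majority vote is more accurate
        cfg = SimulationConfig(
            seed=1,
            predictor_missing_rate={a: 0.0 for a in ("sift", "polyphen2", "mutation_assessor", "vest3", "eigen")},
        )
        records = self._records(10_000)
        truth = simulate_annotations(records, cfg, np.random.default_rng(4))
        missense = [r for r in records if r.consequence.value == "missense"]
        ensemble_hits = single_hits = total = 0
        for r in missense:
            t = truth[r.variant_id]
            total += 1
            ensemble_hits += (ensemble_call(r).value is Verdict.DELETERIOUS) == t
            single_hits += (r.predictor_calls["sift"].value == "D") == t
        assert ensemble_hits / total > single_hits / total

    def test_consequence_mix_near_configured(self):
        cfg = SimulationConfig(seed=1)
        records = self._records(20_000)
        simulate_annotations(records, cfg, np.random.default_rng(5))
        frac_missense = np.mean([r.consequence.value == "missense" for r in records])
        assert frac_missense == pytest.approx(0.531, abs=0.02)


class TestGenotypes:
    def test_fixed_frequencies(self):
        assert (simulate_genotypes(0.0, 100, seed=1) == 0).all()
        assert (simulate_genotypes(1.0, 100, seed=1) == 2).all()

    def test_homozygote_fraction(self):
        dosages = simulate_genotypes(0.3, 100_000, seed=2)
        frac = (dosages == 2).mean()
        se = math.sqrt(0.09 * 0.91 / 100_000)
        assert abs(frac - 0.09) <= 3 * se

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            simulate_genotypes(1.5, 10, seed=1)
        with pytest.raises(ValueError):
            simulate_genotypes(0.5, 0, seed=1)


class TestDataset:
    def test_emitted_spectrum_is_rare_dominated(self, small_dataset):
        mafs = np.array([r.folded_maf() for r in small_dataset.variants])
        assert len(mafs) > 500
        assert (mafs < 0.01).mean() >= 0.95

    def test_records_satisfy_reader_invariants(self, small_dataset, tmp_path):
        from abctrans.io import read_frequency_table, write_frequency_table

        for r in small_dataset.variants[:200]:
            for pop, ac in r.per_pop_ac.items():
                assert 0 <= ac <= r.per_pop_an[pop]
        path = tmp_path / "v.tsv"
        write_frequency_table(small_dataset.variants, path)
        back = read_frequency_table(path)
        assert len(back) == len(small_dataset.variants)

    def test_truth_table_aligned(self, small_dataset):
        assert len(small_dataset.truth) == len(small_dataset.variants)
        ids = {r.variant_id for r in small_dataset.variants}
        assert set(small_dataset.truth["variant_id"]) == ids

    def test_byte_identical_outputs(self, tmp_path):
        cfg = dict(seed=13, n_genes=2, gene_length_range_bp=(1500, 2100), variants_per_kb=40.0)
        for d in ("a", "b"):
            write_dataset(simulate_dataset(SimulationConfig(**cfg)), tmp_path / d)
        for name in ("variants.tsv", "genes.tsv", "domains.tsv", "cnv.tsv", "truth.tsv", "genotypes.tsv"):
            assert (tmp_path / "a" / name).read_bytes() == (tmp_path / "b" / name).read_bytes()

    def test_gene_roster_subfamilies(self, small_dataset):
        subfamilies = {m.subfamily for m in small_dataset.gene_models.values()}
        assert subfamilies <= set("ABCDEFG")
        for m in small_dataset.gene_models.values():
            spans = sorted(m.domains, key=lambda d: d.start_residue)
            for a, b in zip(spans, spans[1:]):
                assert b.start_residue > a.end_residue
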