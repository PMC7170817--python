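"""Gene- and domain-level summaries: densities, CNVs, ANOVA, o/e, correlation."""

from __future__ import annotations

import numpy as np
import pytest
from scipy import stats

from abctrans.model import CNVRecord, DomainInterval, GeneModel
from abctrans.summaries import (
    burden_constraint_correlation,
    cnv_summary,
    consequence_counts,
    domain_density,
    oe_ratio,
    subfamily_comparison,
    variants_per_kb,
)
from conftest import make_record
from _oracles import anova_oracle, pearson_oracle


def _gene(name="ABCB1", length_aa=1280, domains=()):
    return GeneModel(gene=name, subfamily="B", cds_length_bp=3 * length_aa,
                     protein_length_aa=length_aa, domains=domains)


class TestVariantsPerKb:
    def test_simple_density(self):
        model = _gene(length_aa=2000 // 3 + 1)
        model.cds_length_bp = 2000
        records = [make_record(pos=i) for i in range(10)]
        assert variants_per_kb(records, model) == pytest.approx(5.0)

    def test_zero_variants(self):
        assert variants_per_kb([], _gene()) == 0.0

    def test_randomized_recount(self, rng):
        genes = [f"G{i}" for i in range(4)]
        records = [make_record(gene=str(rng.choice(genes)), pos=i) for i in range(100)]
        for g in genes:
            model = _gene(name=g + "X", length_aa=500)
            model.gene = g
            expected = sum(r.gene == g for r in records) / (model.cds_length_bp / 1000)
            assert variants_per_kb(records, model) == pytest.approx(expected)


class TestDomainDensity:
    def test_printed_magnitude(self):
        # 21 protein-affecting variants in a 100-residue accessory TMD0
        model = _gene(domains=(DomainInterval("TMD0", 1, 100),))
        records = [make_record(pos=i, aa_pos=1 + (i % 100)) for i in range(21)]
        densities = {d.domain_name: d for d in domain_density(records, model)}
        assert densities["TMD0"].density == pytest.approx(0.21)

    def test_unannotated_residue_counts_as_other(self):
        model = _gene(domains=(DomainInterval("NBD1", 1, 100),))
        records = [make_record(aa_pos=500)]
        densities = {d.domain_name: d for d in domain_density(records, model)}
        assert densities["other"].n_variants == 1

    def test_out_of_range_residue_skipped(self):
        model = _gene(length_aa=100, domains=(DomainInterval("NBD1", 1, 100),))
        records = [make_record(aa_pos=5000)]
        densities = {d.domain_name: d for d in domain_density(records, model)}
        assert sum(d.n_variants for d in densities.values()) == 0

    def test_synonymous_not_counted(self):
        model = _gene(domains=(DomainInterval("NBD1", 1, 100),))
        records = [make_record(consequence="synonymous", aa_pos=50)]
        densities = {d.domain_name: d for d in domain_density(records, model)}
        assert densities["NBD1"].n_variants == 0

    def test_random_placement_matches_interval_oracle(self, rng):
        domains = (
            DomainInterval("TMD1", 20, 300),
            DomainInterval("NBD1", 350, 600),
            DomainInterval("TMD2", 640, 900),
            DomainInterval("NBD2", 950, 1200),
        )
        model = _gene(domains=domains)
        residues = rng.integers(1, 1281, size=200)
        records = [make_record(pos=i, aa_pos=int(p)) for i, p in enumerate(residues)]
        densities = {d.domain_name: d for d in domain_density(records, model)}
        for d in domains:
            expected = int(((residues >= d.start_residue) & (residues <= d.end_residue)).sum())
            assert densities[d.name].n_variants == expected
        # domain and record order do not matter
        model2 = _gene(domains=domains[::-1])
        densities2 = {d.domain_name: d for d in domain_density(records[::-1], model2)}
        assert {k: v.n_variants for k, v in densities.items()} == {
            k: v.n_variants for k, v in densities2.items()
        }

    def test_deleterious_only_mode_is_subset(self):
        model = _gene(domains=(DomainInterval("NBD1", 1, 100),))
        records = [
            make_record(pos=1, aa_pos=10, calls="DDDDD"),
            make_record(pos=2, aa_pos=20, calls="NNNNN"),
        ]
        all_mode = {d.domain_name: d.n_variants for d in domain_density(records, model)}
        del_mode = {d.domain_name: d.n_variants
                    for d in domain_density(records, model, deleterious_only=True)}
        assert all_mode["NBD1"] == 2 and del_mode["NBD1"] == 1


class TestCNVSummary:
    def test_counts_events(self):
        cnvs = [CNVRecord("ABCC6", "deletion", 1, 3, 1e-4) for _ in range(3)]
        cnvs += [CNVRecord("ABCC6", "duplication", 2, 2, 5e-5) for _ in range(2)]
        s = cnv_summary(cnvs)
        assert s.per_gene["ABCC6"]["total"] == 5
        assert s.per_gene["ABCC6"]["deletion"] == 3

    def test_empty_input(self):
        s = cnv_summary([], genes=["ABCB7", "ABCD1"])
        assert s.total_events == 0
        assert s.n_genes_with_cnv == 0

    def test_cnv_free_genes_report_zero(self):
        cnvs = [CNVRecord("ABCC6", "deletion", 1, 2, 1e-4)]
        s = cnv_summary(cnvs, genes=["ABCB7", "ABCD1", "ABCC6"])
        assert s.per_gene["ABCB7"]["total"] == 0
        assert s.per_gene["ABCD1"]["total"] == 0
        assert s.n_genes_with_cnv == 1


class TestSubfamilyComparison:
    def test_fold_difference(self):
        counts = {"g1": 10, "g2": 10, "g3": 5, "g4": 5}
        sf = {"g1": "A", "g2": "A", "g3": "B", "g4": "B"}
        res = subfamily_comparison(counts, sf, target="A")
        assert res.fold_difference == pytest.approx(2.0)

    def test_identical_groups_f_zero(self):
        counts = {"g1": 7, "g2": 7, "g3": 7, "g4": 7}
        sf = {"g1": "A", "g2": "A", "g3": "B", "g4": "B"}
        res = subfamily_comparison(counts, sf, target="A")
        assert res.f_statistic == 0.0

    def test_three_groups_against_sum_of_squares_oracle(self, rng):
        groups = {sf: list(rng.poisson(30, size=4) + 1.0) for sf in "ABC"}
        counts, sf_map = {}, {}
        for sf, values in groups.items():
            for i, v in enumerate(values):
                counts[f"{sf}{i}"] = v
                sf_map[f"{sf}{i}"] = sf
        res = subfamily_comparison(counts, sf_map, target="A")
        f_expected, p_expected = anova_oracle(list(groups.values()))
        assert res.f_statistic == pytest.approx(f_expected)
        assert res.p_value == pytest.approx(p_expected)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            subfamily_comparison({"g": 1}, {"g": "A"}, target="A")


class TestOERatio:
    def test_excess_missense(self):
        res = oe_ratio(130, 100.0)
        assert res.ratio == pytest.approx(1.3)
        assert res.lower90 < 1.3 < res.upper90

    def test_equality(self):
        assert oe_ratio(100, 100.0).ratio == pytest.approx(1.0)

    def test_domain_error(self):
        with pytest.raises(ValueError):
            oe_ratio(10, 0.0)

    def test_interval_coverage_near_nominal(self, rng):
        lam = 20.0
        draws = rng.poisson(lam, size=2000)
        covered = 0
        for k in np.unique(draws):
            res = oe_ratio(int(k), 1.0)
            if res.lower90 <= lam <= res.upper90:
                covered += int((draws == k).sum())
        coverage = covered / draws.size
        # exact Poisson intervals are conservative: at or slightly above 90%
        assert 0.89 <= coverage <= 1.0


class TestCorrelation:
    def test_perfect_correlations(self):
        x = [0.1, 0.2, 0.5, 0.7, 0.9]
        r, _ = burden_constraint_correlation(x, x)
        assert r == pytest.approx(1.0)
        r, _ = burden_constraint_correlation(x, [-v for v in x])
        assert r == pytest.approx(-1.0)

    def test_against_covariance_oracle(self, rng):
        x = rng.normal(size=5)
        y = 0.4 * x + rng.normal(size=5)
        r, p = burden_constraint_correlation(x, y)
        assert r == pytest.approx(pearson_oracle(x, y))
        # p from the t transform with n - 2 df
        t = r * np.sqrt(3 / (1 - r**2))
        assert p == pytest.approx(2 * stats.t.sf(abs(t), 3), rel=1e-6)

    def test_zero_variance_flagged(self):
        with pytest.raises(ValueError):
            burden_constraint_correlation([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestConsequenceCounts:
    def test_counts_sum_to_total(self, rng):
        csqs = ["missense", "synonymous", "utr", "frameshift"]
        records = [
            make_record(gene=f"G{rng.integers(3)}", consequence=str(rng.choice(csqs)), pos=i)
            for i in range(80)
        ]
        table = consequence_counts(records)
        class_cols = [c for c in table.columns if c != "total"]
        assert (table[class_cols].sum(axis=1) == table["total"]).all()
        assert int(table["total"].sum()) == 80
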