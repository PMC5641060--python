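"""Promoter mapping, beta aggregation, differential methylation, correlation."""

import numpy as np
import pandas as pd
import pytest

from lncscna.io import Biotype, GeneRecord, OmicsMatrix
from lncscna.methylation import (
    compare_expression_groups,
    differential_methylation,
    gene_beta,
    map_probes,
    meth_expr_correlation,
    promoter_regions,
)


def gene(gid, tss, strand="+", chrom="chr1"):
    if strand == "+":
        return GeneRecord(gid, gid, Biotype.LNCRNA, chrom, tss, tss + 5000, "+")
    return GeneRecord(gid, gid, Biotype.LNCRNA, chrom, tss - 5000, tss, "-")


class TestPromoters:
    def test_plus_strand(self):
        (p,) = promoter_regions([gene("A", 5000)])
        assert (p.start, p.end) == (3000, 5000)

    def test_minus_strand(self):
        (p,) = promoter_regions([gene("A", 5000, strand="-")])
        assert (p.start, p.end) == (5000, 7000)

    def test_clipped_at_zero(self):
        (p,) = promoter_regions([gene("A", 1000)])
        assert (p.start, p.end) == (0, 1000)

    def test_strand_agnostic_mode(self):
        (p,) = promoter_regions([gene("A", 5000, strand="-")], strand_aware=False)
        assert (p.start, p.end) == (3000, 5000)


class TestProbeMapping:
    def _probes(self, positions):
        return pd.DataFrame(
            {"probe_id": [f"cg{i}" for i in range(len(positions))],
             "chrom": "chr1", "position": positions}
        )

    def test_unique_mapping_kept_ambiguous_dropped(self):
        promoters = promoter_regions([gene("A", 5000), gene("B", 6000)])
        # A: [3000,5000); B: [4000,6000) -> overlap [4000,5000)
        mapped = map_probes(self._probes([3500, 4500, 9999]), promoters)
        assert mapped.to_dict("records") == [{"probe_id": "cg0", "gene_id": "A"}]


class TestGeneBeta:
    def _beta(self, rows, probes):
        samples = [f"s{i}" for i in range(len(rows[0]))]
        cls = pd.Series(["tumor", "tumor", "normal"][: len(samples)], index=samples)
        return OmicsMatrix(
            pd.DataFrame(rows, index=probes, columns=samples), cls, "beta"
        )

    def test_single_probe_identity(self):
        beta = self._beta([[0.1, 0.2, 0.3]], ["cg0"])
        pm = pd.DataFrame({"probe_id": ["cg0"], "gene_id": ["A"]})
        out = gene_beta(beta, pm)
        assert np.allclose(out.values.loc["A"], [0.1, 0.2, 0.3])

    def test_multi_probe_mean(self):
        beta = self._beta([[0.2, 0.2, 0.2], [0.4, 0.4, 0.4]], ["cg0", "cg1"])
        pm = pd.DataFrame({"probe_id": ["cg0", "cg1"], "gene_id": ["A", "A"]})
        assert np.allclose(gene_beta(beta, pm).values.loc["A"], 0.3)

    def test_missing_imputed_with_probe_mean_first(self):
        beta = self._beta([[0.5, np.nan, 0.5]], ["cg0"])
        pm = pd.DataFrame({"probe_id": ["cg0"], "gene_id": ["A"]})
        assert gene_beta(beta, pm).values.loc["A", "s1"] == pytest.approx(0.5)

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        vals = rng.uniform(0, 1, size=(4, 3))
        vals[0, 1] = np.nan
        beta = self._beta(vals.tolist(), [f"cg{i}" for i in range(4)])
        pm = pd.DataFrame(
            {"probe_id": [f"cg{i}" for i in range(4)],
             "gene_id": ["A", "A", "B", "B"]}
        )
        once = gene_beta(beta, pm)
        pm2 = pd.DataFrame({"probe_id": ["A", "B"], "gene_id": ["A", "B"]})
        twice = gene_beta(once, pm2)
        assert np.allclose(once.values, twice.values)
        assert (once.values.to_numpy() >= 0).all() and (
            once.values.to_numpy() <= 1
        ).all()


def _two_class_beta(rng, n_genes=20, n_tumor=15, n_normal=10, hyper=()):
    vals = np.clip(rng.normal(0.2, 0.04, size=(n_genes, n_tumor + n_normal)), 0, 1)
    for g in hyper:
        vals[g, :n_tumor] = np.clip(rng.normal(0.55, 0.05, n_tumor), 0, 1)
        vals[g, n_tumor:] = np.clip(rng.normal(0.15, 0.03, n_normal), 0, 1)
    samples = [f"s{i}" for i in range(n_tumor + n_normal)]
    cls = pd.Series(["tumor"] * n_tumor + ["normal"] * n_normal, index=samples)
    return OmicsMatrix(
        pd.DataFrame(vals, index=[f"g{i}" for i in range(n_genes)], columns=samples),
        cls, "beta",
    )


class TestDifferentialMethylation:
    def test_fold_change_is_ratio_of_means(self):
        gb = _two_class_beta(np.random.default_rng(0))
        vals = gb.values.copy()
        vals.loc["g0", gb.samples_of("tumor")] = 0.6
        vals.loc["g0", gb.samples_of("normal")] = 0.2
        gb2 = OmicsMatrix(vals, gb.sample_class, "beta")
        row = differential_methylation(gb2).set_index("gene_id").loc["g0"]
        assert row.beta_fc == pytest.approx(3.0)
        assert row.state == "hyper"

    def test_identical_means_not_called(self):
        gb = _two_class_beta(np.random.default_rng(1))
        res = differential_methylation(gb)
        assert not res["called"].any()

    def test_planted_hyper_recovered(self):
        gb = _two_class_beta(np.random.default_rng(2), hyper=(0, 1, 2))
        res = differential_methylation(gb).set_index("gene_id")
        assert res.loc[["g0", "g1", "g2"], "called"].all()
        assert (res.loc[["g0", "g1", "g2"], "state"] == "hyper").all()

    def test_welch_p_close_to_permutation(self):
        from scipy import stats as sps

        rng = np.random.default_rng(3)
        gb = _two_class_beta(rng, n_genes=1, n_tumor=12, n_normal=8)
        vals = gb.values.copy()
        classes = (gb.sample_class == "tumor").to_numpy()
        vals.iloc[0, :12] += 0.05  # moderate planted shift
        gb = OmicsMatrix(vals, gb.sample_class, "beta")
        x = gb.values.iloc[0].to_numpy()

        def welch_t(mask):
            return abs(sps.ttest_ind(x[mask], x[~mask], equal_var=False).statistic)

        obs = welch_t(classes)
        n_perm = 4000
        count = sum(
            welch_t(rng.permutation(classes)) >= obs for _ in range(n_perm)
        )
        p_perm = (count + 1) / (n_perm + 1)
        p_welch = differential_methylation(gb)["p"].iloc[0]
        assert p_welch == pytest.approx(p_perm, abs=0.02)

    def test_small_class_errors(self):
        gb = _two_class_beta(np.random.default_rng(4), n_normal=1)
        with pytest.raises(ValueError):
            differential_methylation(gb)


class TestExpressionComparison:
    def _expr(self, rows, genes):
        samples = [f"s{i}" for i in range(len(rows[0]))]
        cls = pd.Series("tumor", index=samples)
        return OmicsMatrix(
            pd.DataFrame(rows, index=genes, columns=samples), cls, "expression"
        )

    def test_identical_groups_not_significant(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(5, 1, size=(10, 8))
        expr = self._expr(np.vstack([vals, vals]),
                          [f"a{i}" for i in range(10)] + [f"b{i}" for i in range(10)])
        res = compare_expression_groups(
            expr, {f"a{i}" for i in range(10)}, {f"b{i}" for i in range(10)}
        )
        assert res["p"] > 0.5

    def test_lower_group_detected(self):
        rng = np.random.default_rng(1)
        low = rng.normal(2, 0.3, size=(8, 10))
        high = rng.normal(5, 0.3, size=(20, 10))
        expr = self._expr(np.vstack([low, high]),
                          [f"l{i}" for i in range(8)] + [f"h{i}" for i in range(20)])
        res = compare_expression_groups(
            expr, {f"l{i}" for i in range(8)}, {f"h{i}" for i in range(20)}
        )
        assert res["p"] < 0.05 and res["direction"] == "a_lower"

    def test_singletons_defined(self):
        expr = self._expr([[1, 1, 1], [5, 5, 5]], ["a", "b"])
        res = compare_expression_groups(expr, {"a"}, {"b"})
        assert 0 < res["p"] <= 1

    def test_empty_group_rejected(self):
        expr = self._expr([[1, 1]], ["a"])
        with pytest.raises(ValueError):
            compare_expression_groups(expr, set(), {"a"})


class TestMethExprCorrelation:
    def test_exact_negative(self):
        rng = np.random.default_rng(0)
        b = np.clip(rng.uniform(0.2, 0.8, 30), 0, 1)
        samples = [f"s{i}" for i in range(30)]
        cls = pd.Series("tumor", index=samples)
        gb = OmicsMatrix(pd.DataFrame([b], index=["A"], columns=samples), cls, "beta")
        expr = OmicsMatrix(
            pd.DataFrame([10 - b], index=["A"], columns=samples), cls, "expression"
        )
        res = meth_expr_correlation(gb, expr)
        assert res.iloc[0]["r"] == pytest.approx(-1.0)
        assert bool(res.iloc[0]["negative"])

    def test_null_rate_near_nominal(self):
        rng = np.random.default_rng(1)
        flagged = 0
        n_rep = 300
        samples = [f"s{i}" for i in range(40)]
        cls = pd.Series("tumor", index=samples)
        for _ in range(n_rep):
            b = np.clip(rng.uniform(0.1, 0.9, 40), 0, 1)
            e = rng.normal(5, 1, 40)
            gb = OmicsMatrix(
                pd.DataFrame([b], index=["A"], columns=samples), cls, "beta"
            )
            expr = OmicsMatrix(
                pd.DataFrame([e], index=["A"], columns=samples), cls, "expression"
            )
            flagged += bool(meth_expr_correlation(gb, expr).iloc[0]["negative"])
        # two-sided 5% test, negative side only -> ~2.5% flagged
        assert flagged / n_rep < 0.07


def test_planted_hypermethylation_recovered(cohort, results):
    """The cohort's hypermethylated lncRNAs are called and negatively
    correlated with their own expression."""
    assert set(cohort.truth.hypermeth) <= set(results["hyper_lncs"])
    corr = results["meth_corr"].set_index("gene_id")
    planted = [g for g in cohort.truth.hypermeth if g in corr.index]
    assert corr.loc[planted, "negative"].mean() >= 0.9
    assert results["hyper_vs_rest"]["p"] < 0.05
    assert results["hyper_vs_rest"]["direction"] == "a_lower"
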