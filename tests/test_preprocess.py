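"""Normalisation, filters, SAM differential expression, Pearson screening."""

import numpy as np
import pandas as pd
import pytest

from lncscna.io import OmicsMatrix
from lncscna.preprocess import (
    filter_low_lncrna,
    filter_missing_genes,
    log_transform,
    pearson_screen,
    sam_differential_expression,
    upper_quartile_normalize,
)
from lncscna.synthetic import CohortConfig, generate_cohort


def make_matrix(values, genes=None, n_tumor=None, role="expression"):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = [f"s{i}" for i in range(values.shape[1])]
    n_tumor = values.shape[1] // 2 if n_tumor is None else n_tumor
    classes = pd.Series(
        ["tumor"] * n_tumor + ["normal"] * (values.shape[1] - n_tumor), index=samples
    )
    return OmicsMatrix(pd.DataFrame(values, index=genes, columns=samples), classes, role)


class TestUpperQuartile:
    def test_sample_already_at_target_unchanged(self):
        m = make_matrix([[1, 1], [2, 2], [3, 3], [4, 4]])
        q75 = np.percentile([1, 2, 3, 4], 75)
        out = upper_quartile_normalize(m, target=q75)
        assert np.allclose(out.values, m.values)

    def test_scale_invariance(self):
        m = make_matrix([[1, 2], [2, 4], [3, 6], [4, 8]])
        out = upper_quartile_normalize(m, target=1000)
        doubled = make_matrix([[2, 2], [4, 4], [6, 6], [8, 8]])
        # doubling one sample's raw values must not change its output
        assert np.allclose(
            upper_quartile_normalize(doubled, target=1000).values["s0"],
            out.values["s0"],
        )

    def test_matches_independent_percentile(self):
        m = make_matrix([[1], [2], [3], [4]], n_tumor=1)
        out = upper_quartile_normalize(m, target=1000)
        scale = 1000 / np.percentile([1, 2, 3, 4], 75, method="linear")
        assert np.allclose(out.values["s0"], np.array([1, 2, 3, 4]) * scale)

    def test_zeros_stay_zero_and_all_zero_sample_errors(self):
        m = make_matrix([[0, 0], [2, 0], [3, 0], [4, 0]])
        with pytest.raises(ValueError, match="s1"):
            upper_quartile_normalize(m)
        out = upper_quartile_normalize(make_matrix([[0, 1], [2, 2], [3, 3], [4, 4]]))
        assert out.values.loc["g0", "s0"] == 0.0


class TestFilters:
    def test_missing_fraction_boundary_is_strict(self):
        vals = np.ones((3, 100))
        vals[0, :31] = np.nan  # 31% -> removed
        vals[1, :30] = np.nan  # 30% -> retained
        m = make_matrix(vals)
        out = filter_missing_genes(m, 0.3)
        assert out.gene_ids == ["g1", "g2"]
        assert out.values.loc["g1"].isna().sum() == 30  # missing cells intact

    def test_fully_observed_unchanged(self):
        m = make_matrix(np.ones((3, 10)))
        assert filter_missing_genes(m).values.equals(m.values)

    def test_low_lncrna_rules(self):
        vals = np.zeros((3, 10))
        vals[1] = 5.0  # constant 5 -> retained
        vals[2, 6:] = 1.0  # 60% zeros -> median 0 -> removed
        m = make_matrix(vals)
        assert filter_low_lncrna(m).gene_ids == ["g1"]

    def test_q90_rule(self):
        vals = np.full((1, 10), 0.05)  # q90 = 0.05 <= 0.1 -> removed
        assert filter_low_lncrna(make_matrix(vals)).gene_ids == []


class TestLogTransform:
    @pytest.mark.parametrize(
        "v,pc,expected", [(0.0, 2.0, 1.0), (2.0, 2.0, 2.0), (0.0, 0.05, np.log2(0.05))]
    )
    def test_values(self, v, pc, expected):
        m = make_matrix([[v, v]])
        out = log_transform(m, pc)
        assert out.values.iloc[0, 0] == pytest.approx(expected, abs=1e-12)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            log_transform(make_matrix([[-1.0, 0.0]]), 2.0)


def _sam_fixture(seed=0, n_genes=60, n_tumor=30, n_normal=15, shift_genes=()):
    rng = np.random.default_rng(seed)
    log_vals = rng.normal(5, 0.3, size=(n_genes, n_tumor + n_normal))
    for g, delta in shift_genes:
        log_vals[g, :n_tumor] += delta
    linear = 2.0 ** log_vals
    genes = [f"g{i}" for i in range(n_genes)]
    return (
        make_matrix(log_vals, genes=genes, n_tumor=n_tumor),
        make_matrix(linear, genes=genes, n_tumor=n_tumor),
    )


class TestSAM:
    def test_equal_means_not_called(self):
        log_m, lin_m = _sam_fixture(seed=1)
        base = log_m.values.to_numpy().copy()
        base[0] = 5.0  # identical in both classes, zero spread handled by s0
        log_m.values.iloc[:, :] = base
        res = sam_differential_expression(log_m, lin_m, n_perm=100, seed=0)
        assert res.loc[res.gene_id == "g0", "statistic"].abs().iloc[0] < 1e-9
        assert not res.loc[res.gene_id == "g0", "called"].iloc[0]

    def test_statistic_invariant_to_gene_offset(self):
        log_m, lin_m = _sam_fixture(seed=2)
        res1 = sam_differential_expression(log_m, lin_m, n_perm=100, seed=0)
        shifted = log_m.values.copy()
        shifted.loc["g3"] += 7.0
        log_m2 = OmicsMatrix(shifted, log_m.sample_class, "expression")
        res2 = sam_differential_expression(log_m2, lin_m, n_perm=100, seed=0)
        assert res1.loc[res1.gene_id == "g3", "statistic"].iloc[0] == pytest.approx(
            res2.loc[res2.gene_id == "g3", "statistic"].iloc[0], abs=1e-9
        )

    def test_statistic_antisymmetric_under_class_swap(self):
        log_m, lin_m = _sam_fixture(seed=3)
        res = sam_differential_expression(log_m, lin_m, n_perm=100, seed=0)
        swapped_cls = log_m.sample_class.map(
            {"tumor": "normal", "normal": "tumor"}
        )
        log_sw = OmicsMatrix(log_m.values, swapped_cls, "expression")
        lin_sw = OmicsMatrix(lin_m.values, swapped_cls, "expression")
        res_sw = sam_differential_expression(log_sw, lin_sw, n_perm=100, seed=0)
        assert np.allclose(res["statistic"], -res_sw["statistic"], atol=1e-9)

    def test_planted_fourfold_genes_recovered(self):
        shift = [(g, 2.0 if g % 2 else -2.0) for g in range(8)]
        log_m, lin_m = _sam_fixture(seed=4, shift_genes=shift)
        res = sam_differential_expression(log_m, lin_m, n_perm=200, seed=0)
        called = set(res.loc[res.called, "gene_id"])
        planted = {f"g{g}" for g, _ in shift}
        assert planted <= called
        assert len(called - planted) / max(1, len(called)) <= 0.1

    def test_null_call_fraction_controlled(self):
        # global null over 20 seeds: average DE fraction stays below 10%
        fracs = []
        for seed in range(20):
            log_m, lin_m = _sam_fixture(seed=100 + seed, n_genes=40)
            res = sam_differential_expression(log_m, lin_m, n_perm=100, seed=seed)
            fracs.append(res["called"].mean())
        assert np.mean(fracs) <= 0.1

    def test_single_class_errors(self):
        log_m, lin_m = _sam_fixture()
        tumor_only_cls = pd.Series("tumor", index=log_m.sample_ids)
        m = OmicsMatrix(log_m.values, tumor_only_cls, "expression")
        with pytest.raises(ValueError):
            sam_differential_expression(m, lin_m, n_perm=100, seed=0)


class TestPearsonScreen:
    def test_perfect_and_anti_correlation(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=20)
        a = make_matrix(np.vstack([x, -x]), genes=["x", "negx"], n_tumor=10)
        edges = pearson_screen(a, a, r_min=0.5, fdr_max=0.05, sign="any")
        pair = edges[(edges.gene_a == "x") & (edges.gene_b == "negx")]
        assert pair["r"].iloc[0] == pytest.approx(-1.0)
        # self-pairs excluded when screening a matrix against itself
        assert not ((edges.gene_a == "x") & (edges.gene_b == "x")).any()

    def test_symmetric_edge_set(self):
        rng = np.random.default_rng(1)
        a = make_matrix(rng.normal(size=(4, 30)), genes=list("abcd"), n_tumor=15)
        b = make_matrix(rng.normal(size=(3, 30)), genes=list("xyz"), n_tumor=15)
        e_ab = pearson_screen(a, b, r_min=0.0, fdr_max=1.1, sign="any")
        e_ba = pearson_screen(b, a, r_min=0.0, fdr_max=1.1, sign="any")
        s_ab = {frozenset((r.gene_a, r.gene_b)) for r in e_ab.itertuples()}
        s_ba = {frozenset((r.gene_a, r.gene_b)) for r in e_ba.itertuples()}
        assert s_ab == s_ba

    def test_strict_threshold_and_sign(self):
        n = 20
        x = np.linspace(-1, 1, n)
        a = make_matrix(x[None, :], genes=["a"], n_tumor=10)
        b = make_matrix((-x)[None, :], genes=["b"], n_tumor=10)
        assert len(pearson_screen(a, b, r_min=0.5, sign="positive")) == 0
        assert len(pearson_screen(a, b, r_min=0.5, sign="negative")) == 1

    def test_too_few_samples_error(self):
        a = make_matrix(np.ones((1, 2)), n_tumor=1)
        with pytest.raises(ValueError):
            pearson_screen(a, a, r_min=0.5)


def test_planted_cerna_pairs_pass_screen(cohort, results):
    """Planted ceRNA lncRNA-PCG pairs survive the r > 0.5 screen."""
    edges = {(e.gene_a, e.gene_b) for e in results["coexpr"].itertuples()}
    for t in cohort.truth.cerna_triples:
        assert (t["lncrna"], t["pcg"]) in edges
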