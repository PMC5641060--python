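"""Promoter-level DNA-methylation analysis.

Promoters are the 2 kb upstream of each TSS (strand-aware by default).
Array probes are kept only when they fall in exactly one promoter; probe
beta values are mean-imputed across samples, averaged per gene, compared
between tumor and normal with a Welch t-test (fold change = ratio of class
mean betas), and correlated with expression.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io import NORMAL, TUMOR, GeneRecord, OmicsMatrix
from .stats import benjamini_hochberg, pearson_pvalue

logger = logging.getLogger("lncscna")


@dataclass(frozen=True)
class PromoterRegion:
    gene_id: str
    chrom: str
    start: int
    end: int


def promoter_regions(
    annotation: list[GeneRecord],
    length: int = 2000,
    strand_aware: bool = True,
) -> list[PromoterRegion]:
    """2 kb (by default) upstream of each TSS; [tss-L, tss) on +,
    [tss, tss+L) on -; clipped at position 0."""
    regions = []
    for g in annotation:
        if not strand_aware or g.strand == "+":
            start, end = max(0, g.tss - length), g.tss
        else:
            start, end = g.tss, g.tss + length
        if end > start:
            regions.append(PromoterRegion(g.gene_id, g.chrom, start, end))
    return regions


def map_probes(
    probes: pd.DataFrame, promoters: list[PromoterRegion]
) -> pd.DataFrame:
    """Keep each probe iff its position falls in exactly one promoter.

    *probes* needs columns probe_id, chrom, position.  Returns a DataFrame
    with columns probe_id, gene_id.
    """
    rows = []
    for p in probes.itertuples():
        owners = [
            pr.gene_id
            for pr in promoters
            if pr.chrom == p.chrom and pr.start <= p.position < pr.end
        ]
        if len(owners) == 1:
            rows.append({"probe_id": p.probe_id, "gene_id": owners[0]})
    return pd.DataFrame(rows, columns=["probe_id", "gene_id"])


def gene_beta(beta: OmicsMatrix, probe_map: pd.DataFrame) -> OmicsMatrix:
    """Aggregate probe-level beta to gene level.

    Missing probe values are first imputed with the probe's across-sample
    mean; a gene's value is then the mean over its probes per sample.
    Genes without probes are absent from the output.
    """
    if beta.role != "beta":
        raise ValueError("gene_beta requires a beta matrix")
    vals = beta.values.copy()
    probe_means = vals.mean(axis=1)
    vals = vals.apply(lambda row: row.fillna(probe_means[row.name]), axis=1)
    mapped = probe_map[probe_map["probe_id"].isin(vals.index)]
    grouped = vals.loc[mapped["probe_id"]].groupby(
        mapped.set_index("probe_id")["gene_id"]
    )
    gene_vals = grouped.mean()
    gene_vals.index.name = None
    return OmicsMatrix(gene_vals, beta.sample_class, "beta")


def differential_methylation(
    gb: OmicsMatrix, fc_min: float = 2.0, fdr_max: float = 0.01
) -> pd.DataFrame:
    """Welch t-test per gene between tumor and normal beta values; BH
    correction; hyper call iff beta_fc > fc_min and q < fdr_max, hypo iff
    beta_fc < 1/fc_min and q < fdr_max."""
    tumor = gb.values[gb.samples_of(TUMOR)].to_numpy()
    normal = gb.values[gb.samples_of(NORMAL)].to_numpy()
    if tumor.shape[1] < 2 or normal.shape[1] < 2:
        raise ValueError("need at least 2 samples per class")
    stat, p = sps.ttest_ind(tumor, normal, axis=1, equal_var=False)
    p = np.where(np.isnan(p), 1.0, p)
    q = benjamini_hochberg(p)
    mean_t = np.nanmean(tumor, axis=1)
    mean_n = np.nanmean(normal, axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        fc = mean_t / mean_n
    state = np.where(fc > 1.0, "hyper", "hypo")
    called = (q < fdr_max) & ((fc > fc_min) | (fc < 1.0 / fc_min))
    return pd.DataFrame(
        {
            "gene_id": gb.gene_ids,
            "beta_fc": fc,
            "t": stat,
            "p": p,
            "q": q,
            "state": state,
            "called": called,
        }
    )


def compare_expression_groups(
    expr: OmicsMatrix, group_a: set[str], group_b: set[str]
) -> dict:
    """Two-sided Wilcoxon rank-sum test comparing per-gene mean tumor
    expression between two gene sets, with a one-sided direction report."""
    if not group_a or not group_b:
        raise ValueError("both gene sets must be non-empty")
    tumor = expr.values[expr.samples_of(TUMOR)]
    means = tumor.mean(axis=1)
    a = means.loc[[g for g in expr.gene_ids if g in group_a]].to_numpy()
    b = means.loc[[g for g in expr.gene_ids if g in group_b]].to_numpy()
    if a.size == 0 or b.size == 0:
        raise ValueError("gene sets absent from the expression matrix")
    if a.size == 1 and b.size == 1:
        logger.warning("singleton groups: the rank-sum test has minimal power")
    res = sps.mannwhitneyu(a, b, alternative="two-sided")
    res_less = sps.mannwhitneyu(a, b, alternative="less")
    direction = "a_lower" if res_less.pvalue < 0.5 else "a_higher"
    return {
        "statistic": float(res.statistic),
        "p": float(res.pvalue),
        "direction": direction,
        "p_one_sided": float(min(res_less.pvalue, 1.0 - res_less.pvalue)),
        "n_a": int(a.size),
        "n_b": int(b.size),
    }


def meth_expr_correlation(
    gb: OmicsMatrix, expr: OmicsMatrix, p_max: float = 0.05
) -> pd.DataFrame:
    """Per-gene Pearson correlation between promoter beta and expression
    across shared tumor samples; flagged negative iff r < 0 and raw
    p < p_max (no FDR correction at this step)."""
    shared = [s for s in gb.samples_of(TUMOR) if s in set(expr.sample_ids)]
    if len(shared) < 3:
        raise ValueError("need at least 3 shared samples")
    genes = [g for g in gb.gene_ids if g in set(expr.gene_ids)]
    rows = []
    for g in genes:
        x = gb.values.loc[g, shared].to_numpy(dtype=float)
        y = expr.values.loc[g, shared].to_numpy(dtype=float)
        if x.std() == 0 or y.std() == 0:
            continue
        r = float(np.corrcoef(x, y)[0, 1])
        p = float(pearson_pvalue(np.array([r]), len(shared))[0])
        rows.append(
            {"gene_id": g, "r": r, "p": p, "negative": bool(r < 0 and p < p_max)}
        )
    return pd.DataFrame(rows, columns=["gene_id", "r", "p", "negative"])
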