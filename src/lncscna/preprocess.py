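"""Expression normalisation and filtering, SAM-style permutation differential
expression with fold-change gating, BH correction, and Pearson co-expression
screening.

The differential-expression statistic follows the SAM design: a moderated
t-like score d = (mean_tumor - mean_normal) / (s + s0), where s is the
gene-wise pooled standard error and s0 an exchangeability constant (here the
median of all gene-wise s).  Significance comes from a label-permutation
null pooled across genes, followed by Benjamini-Hochberg FDR control, and a
linear-scale fold-change gate (ratio of class averages).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .io import NORMAL, TUMOR, OmicsMatrix
from .stats import benjamini_hochberg, pearson_pvalue, pearson_rows

logger = logging.getLogger("lncscna")


def upper_quartile_normalize(m: OmicsMatrix, target: float = 1000.0) -> OmicsMatrix:
    """Scale each sample so the 75th percentile of its nonzero values equals
    *target*.  Zeros stay zero; missing cells stay missing."""
    if m.role != "expression":
        raise ValueError("upper-quartile normalisation applies to expression")
    values = m.values.copy()
    for sample in values.columns:
        col = values[sample].to_numpy()
        nonzero = col[np.isfinite(col) & (col != 0)]
        if nonzero.size == 0:
            raise ValueError(f"sample {sample!r} has no nonzero expression")
        q75 = np.percentile(nonzero, 75)  # linear interpolation convention
        values[sample] = col * (target / q75)
    return OmicsMatrix(values, m.sample_class, m.role)


def filter_missing_genes(
    m: OmicsMatrix, max_missing_fraction: float = 0.3
) -> OmicsMatrix:
    """Drop genes missing in strictly more than *max_missing_fraction* of
    samples; retained genes keep their missing cells intact."""
    frac = m.values.isna().mean(axis=1)
    keep = frac <= max_missing_fraction
    return OmicsMatrix(m.values.loc[keep], m.sample_class, m.role)


def log_transform(m: OmicsMatrix, pseudocount: float) -> OmicsMatrix:
    """v -> log2(v + pseudocount); input values must be non-negative."""
    vals = m.values.to_numpy()
    if np.nanmin(vals) < 0:
        raise ValueError("log transform requires non-negative values")
    return OmicsMatrix(np.log2(m.values + pseudocount), m.sample_class, m.role)


def filter_low_lncrna(m: OmicsMatrix) -> OmicsMatrix:
    """Drop lncRNAs whose median is 0 or whose 90th percentile is <= 0.1
    (linear scale)."""
    med = m.values.quantile(0.5, axis=1)
    q90 = m.values.quantile(0.9, axis=1)
    keep = ~((med == 0) | (q90 <= 0.1))
    return OmicsMatrix(m.values.loc[keep], m.sample_class, m.role)


def _sam_d(
    log_vals: np.ndarray, tumor_mask: np.ndarray, s0: float | None = None
) -> tuple[np.ndarray, float]:
    t = log_vals[:, tumor_mask]
    n = log_vals[:, ~tumor_mask]
    n1, n2 = t.shape[1], n.shape[1]
    diff = t.mean(axis=1) - n.mean(axis=1)
    ss = ((t - t.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) + (
        (n - n.mean(axis=1, keepdims=True)) ** 2
    ).sum(axis=1)
    s = np.sqrt((1.0 / n1 + 1.0 / n2) * ss / (n1 + n2 - 2))
    if s0 is None:
        s0 = float(np.median(s))
    return diff / (s + s0), s0


def sam_differential_expression(
    log_m: OmicsMatrix,
    linear_m: OmicsMatrix,
    n_perm: int = 300,
    fc_min: float = 2.0,
    fdr_max: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """SAM-style differential expression between tumor and normal samples.

    The d statistic is computed on the log-scale matrix; the fold change is
    the ratio of linear-scale class means.  Two-sided p-values come from the
    permutation null of class labels pooled across genes.  A gene is called
    iff q < fdr_max and fold change > fc_min or < 1/fc_min.

    Returns a DataFrame with columns gene_id, statistic, fold_change, p, q,
    direction, called.
    """
    classes = log_m.sample_class.to_numpy()
    tumor_mask = classes == TUMOR
    if tumor_mask.sum() < 2 or (~tumor_mask).sum() < 2:
        raise ValueError("need at least 2 samples per class")
    if n_perm < 100:
        logger.warning("n_perm=%d is low; permutation p-values will be coarse", n_perm)
    if list(log_m.gene_ids) != list(linear_m.gene_ids):
        raise ValueError("log and linear matrices must share gene order")

    log_vals = log_m.values.to_numpy()
    d, s0 = _sam_d(log_vals, tumor_mask)

    rng = np.random.default_rng(seed)
    null: list[np.ndarray] = []
    for _ in range(n_perm):
        perm = rng.permutation(tumor_mask)
        d_perm, _ = _sam_d(log_vals, perm, s0=s0)
        null.append(np.abs(d_perm))
    null_sorted = np.sort(np.concatenate(null))
    n_null = null_sorted.size
    exceed = n_null - np.searchsorted(null_sorted, np.abs(d), side="left")
    p = (1.0 + exceed) / (1.0 + n_null)
    q = benjamini_hochberg(p)

    lin = linear_m.values
    mean_t = lin.loc[:, tumor_mask].mean(axis=1).to_numpy()
    mean_n = lin.loc[:, ~tumor_mask].mean(axis=1).to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        fc = mean_t / mean_n
    direction = np.where(fc > 1.0, "up", "down")
    called = (q < fdr_max) & ((fc > fc_min) | (fc < 1.0 / fc_min))
    return pd.DataFrame(
        {
            "gene_id": log_m.gene_ids,
            "statistic": d,
            "fold_change": fc,
            "p": p,
            "q": q,
            "direction": direction,
            "called": called,
        }
    )


def pearson_screen(
    a: OmicsMatrix,
    b: OmicsMatrix,
    r_min: float,
    fdr_max: float = 0.05,
    sign: str = "positive",
) -> pd.DataFrame:
    """Score all cross pairs between the genes of *a* and *b* with Pearson r
    and a t-distribution p-value; BH-correct over all tested pairs; retain
    per the sign rule (strict inequalities).

    When both matrices carry the same gene set, each unordered pair is
    tested once and self-pairs are excluded.  Zero-variance genes are
    skipped (counted in a warning).
    """
    if sign not in ("positive", "negative", "any"):
        raise ValueError("sign must be positive/negative/any")
    if a.sample_ids != b.sample_ids:
        raise ValueError("matrices must share an identical ordered sample set")
    n = len(a.sample_ids)
    if n < 3:
        raise ValueError("need at least 3 shared samples")

    r = pearson_rows(a.values.to_numpy(), b.values.to_numpy())
    genes_a = np.asarray(a.gene_ids)
    genes_b = np.asarray(b.gene_ids)
    same = a.gene_ids == b.gene_ids
    if same:
        ii, jj = np.triu_indices(len(genes_a), k=1)
    else:
        ii, jj = np.meshgrid(
            np.arange(len(genes_a)), np.arange(len(genes_b)), indexing="ij"
        )
        ii, jj = ii.ravel(), jj.ravel()
    rv = r[ii, jj]
    valid = np.isfinite(rv)
    n_skipped = int((~valid).sum())
    if n_skipped:
        logger.warning("pearson_screen: skipped %d zero-variance pairs", n_skipped)
    ii, jj, rv = ii[valid], jj[valid], rv[valid]
    p = pearson_pvalue(rv, n)
    q = benjamini_hochberg(p) if p.size else p
    edges = pd.DataFrame(
        {"gene_a": genes_a[ii], "gene_b": genes_b[jj], "r": rv, "p": p, "q": q}
    )
    if sign == "positive":
        keep = edges["r"] > r_min
    elif sign == "negative":
        keep = edges["r"] < -r_min
    else:
        keep = edges["r"].abs() > r_min
    keep &= edges["q"] < fdr_max
    return edges.loc[keep].reset_index(drop=True)
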