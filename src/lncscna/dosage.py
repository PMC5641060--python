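"""Copy-number dosage analysis of lncRNAs.

Maps lncRNAs onto focal gain/loss fragments, computes per-gene alteration
frequencies from a discretised copy-number matrix, and scores dosage
sensitivity.  The dosage-sensitivity score (DSS) combines

* a linear component: Pearson correlation between per-sample copy number
  and expression, and
* a monotonicity component: samples are sorted by copy number, split into
  n equal-size bins, and the Kendall-type concordance of the bin mean
  expressions is computed: (concordant - discordant ordered bin pairs) /
  C(n, 2).

DSS = w * linear + (1 - w) * monotonicity, bounded in [-1, 1].  The score is
defined only for genes altered (copy number outside the normal window
[-0.3, 0.3]) in more than 20% of samples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io import FocalFragment, GeneRecord, OmicsMatrix, TUMOR

logger = logging.getLogger("lncscna")


@dataclass(frozen=True)
class FragmentHit:
    gene_id: str
    fragment_id: str
    direction: str
    overlap_bp: int


@dataclass(frozen=True)
class DssRecord:
    gene_id: str
    dss: float  # NaN when undefined (altered fraction <= gate)
    n_param: int
    altered_fraction: float
    n_used_samples: int
    linear_component: float
    monotonicity_component: float

    @property
    def defined(self) -> bool:
        return not np.isnan(self.dss)


def map_to_fragments(
    annotation: list[GeneRecord], fragments: list[FocalFragment]
) -> list[FragmentHit]:
    """Overlap genes with focal fragments (>= 1 bp, half-open intervals)."""
    frag_chroms = {f.chrom for f in fragments}
    gene_chroms = {g.chrom for g in annotation}
    for chrom in sorted(frag_chroms - gene_chroms):
        logger.warning("fragment chromosome %s absent from annotation", chrom)
    hits: list[FragmentHit] = []
    for g in annotation:
        for f in fragments:
            if g.chrom != f.chrom:
                continue
            overlap = min(g.end, f.end) - max(g.start, f.start)
            if overlap >= 1:
                hits.append(
                    FragmentHit(
                        gene_id=g.gene_id,
                        fragment_id=f.fragment_id,
                        direction=f.direction,
                        overlap_bp=overlap,
                    )
                )
    return hits


def alteration_frequency(
    dcn: OmicsMatrix, min_fraction: float = 0.2
) -> pd.DataFrame:
    """Per-gene gain/loss frequencies over tumor samples.

    high_frequency iff max(gain_freq, loss_freq) >= min_fraction ("at least
    20% of samples"); the dominant direction is the larger frequency, with
    ties resolved to gain.
    """
    if dcn.role != "discrete_cn":
        raise ValueError("alteration_frequency requires a discrete CN matrix")
    tumor = dcn.values[dcn.samples_of(TUMOR)]
    vals = tumor.to_numpy()
    observed = np.isfinite(vals)
    n_obs = observed.sum(axis=1)
    gain = ((vals > 0) & observed).sum(axis=1) / n_obs
    loss = ((vals < 0) & observed).sum(axis=1) / n_obs
    high = np.maximum(gain, loss) >= min_fraction
    direction = np.where(loss > gain, "loss", "gain")  # tie -> gain
    return pd.DataFrame(
        {
            "gene_id": dcn.gene_ids,
            "gain_freq": gain,
            "loss_freq": loss,
            "high_frequency": high,
            "direction": direction,
        }
    )


def _bin_sizes(m: int, n: int) -> list[int]:
    # equal-size bins; the last (m mod n) bins receive one extra sample
    base, extra = divmod(m, n)
    return [base] * (n - extra) + [base + 1] * extra


def dosage_sensitivity_score(
    cn: np.ndarray | pd.Series,
    expr: np.ndarray | pd.Series,
    gene_id: str = "",
    n: int = 6,
    normal_window: tuple[float, float] = (-0.3, 0.3),
    w: float = 0.5,
    min_altered_fraction: float = 0.2,
) -> DssRecord:
    """Score the coupling between copy number and expression for one gene.

    Returns a flagged (NaN) record when the gene is altered in <= 20% of
    samples ("more than 20%" gate, strict).  Raises when n exceeds the
    sample count.
    """
    cn = np.asarray(cn, dtype=float)
    expr = np.asarray(expr, dtype=float)
    if cn.shape != expr.shape or cn.ndim != 1:
        raise ValueError("cn and expr must be paired 1-d vectors")
    ok = np.isfinite(cn) & np.isfinite(expr)
    cn, expr = cn[ok], expr[ok]
    m = cn.size
    if n > m:
        raise ValueError(f"n={n} exceeds the number of samples ({m})")
    lo, hi = normal_window
    altered = float(np.mean((cn < lo) | (cn > hi)))
    if altered <= min_altered_fraction:
        return DssRecord(gene_id, np.nan, n, altered, m, np.nan, np.nan)

    if cn.std() == 0 or expr.std() == 0:
        linear = 0.0
    else:
        linear = float(np.corrcoef(cn, expr)[0, 1])

    # stable sort by (cn, position) so ties are reproducible
    order = np.lexsort((np.arange(m), cn))
    sorted_expr = expr[order]
    means = []
    pos = 0
    for size in _bin_sizes(m, n):
        means.append(sorted_expr[pos : pos + size].mean())
        pos += size
    conc = 0
    for k, l in combinations(range(n), 2):
        if means[l] > means[k]:
            conc += 1
        elif means[l] < means[k]:
            conc -= 1
    mono = conc / (n * (n - 1) / 2)

    dss = w * linear + (1.0 - w) * mono
    return DssRecord(gene_id, dss, n, altered, m, linear, mono)


def dss_table(
    cn: OmicsMatrix,
    expr: OmicsMatrix,
    gene_ids: list[str] | None = None,
    n: int = 6,
    normal_window: tuple[float, float] = (-0.3, 0.3),
    w: float = 0.5,
    min_altered_fraction: float = 0.2,
) -> pd.DataFrame:
    """Per-gene DSS over tumor samples shared by the CN and expression
    matrices, for the genes present in both."""
    tumor = [s for s in cn.samples_of(TUMOR) if s in set(expr.sample_ids)]
    if len(tumor) < n:
        raise ValueError("fewer shared tumor samples than bins")
    genes = gene_ids if gene_ids is not None else cn.gene_ids
    genes = [g for g in genes if g in set(cn.gene_ids) and g in set(expr.gene_ids)]
    records = [
        dosage_sensitivity_score(
            cn.values.loc[g, tumor],
            expr.values.loc[g, tumor],
            gene_id=g,
            n=n,
            normal_window=normal_window,
            w=w,
            min_altered_fraction=min_altered_fraction,
        )
        for g in genes
    ]
    return pd.DataFrame(
        {
            "gene_id": [r.gene_id for r in records],
            "dss": [r.dss for r in records],
            "n_param": [r.n_param for r in records],
            "altered_fraction": [r.altered_fraction for r in records],
            "n_used_samples": [r.n_used_samples for r in records],
            "linear_component": [r.linear_component for r in records],
            "monotonicity_component": [r.monotonicity_component for r in records],
        }
    )


def dss_robustness(
    cn: OmicsMatrix,
    expr: OmicsMatrix,
    gene_ids: list[str] | None = None,
    n_values: list[int] = [5, 6, 7, 15],
    **kwargs,
) -> pd.DataFrame:
    """Spearman rank correlation between DSS vectors computed at each pair
    of monotonicity parameters n, over genes defined for all n."""
    if len(n_values) < 2:
        raise ValueError("need at least two values of n")
    tables = {
        n: dss_table(cn, expr, gene_ids=gene_ids, n=n, **kwargs).set_index("gene_id")
        for n in n_values
    }
    common = None
    for t in tables.values():
        defined = set(t.index[t["dss"].notna()])
        common = defined if common is None else common & defined
    common = sorted(common)
    if not common:
        raise ValueError("no genes with defined DSS under every n")
    out = pd.DataFrame(index=n_values, columns=n_values, dtype=float)
    for n1 in n_values:
        for n2 in n_values:
            v1 = tables[n1].loc[common, "dss"]
            v2 = tables[n2].loc[common, "dss"]
            if n1 == n2:
                rho = 1.0
            else:
                rho = sps.spearmanr(v1, v2).statistic
                if np.isnan(rho):  # constant vectors: identical by construction
                    rho = 1.0 if np.allclose(v1, v2) else np.nan
            out.loc[n1, n2] = rho
    return out


def assign_dss_groups(dss: pd.Series, k: int = 7) -> pd.Series:
    """Assign defined DSS values to k equal-width groups spanning
    [min, max]; the last interval is right-closed.  Labels are 1..k ordered
    low to high."""
    vals = dss.dropna()
    if len(vals) < k:
        raise ValueError(f"need at least {k} defined scores")
    lo, hi = float(vals.min()), float(vals.max())
    if lo == hi:
        logger.warning("all DSS identical; a single group is returned")
        return pd.Series(1, index=vals.index)
    edges = np.linspace(lo, hi, k + 1)
    labels = np.minimum(np.searchsorted(edges, vals, side="right"), k)
    return pd.Series(labels, index=vals.index)
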