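"""Cis- and trans-acting regulatory network construction.

Cis: a co-expressed lncRNA-PCG pair is a cis edge when both genes sit on
the same chromosome with a gene-body gap of at most 300 kb (overlap = 0).

Trans: lncRNA-TF links come from a positive co-expression screen
(r > 0.6, FDR < 0.05); for each link the overlap between the lncRNA's
co-expressed PCGs and the TF's targets (both intersected with a universe of
eligible differentially expressed PCGs) is tested with an upper-tail
hypergeometric p-value, BH-corrected across all tested links; significant
links are expanded to one lncRNA-TF-PCG triple per overlap gene.
"""

from __future__ import annotations

import logging
from typing import Mapping

import numpy as np
import pandas as pd

from .io import GeneRecord, OmicsMatrix
from .preprocess import pearson_screen
from .stats import benjamini_hochberg, hypergeom_upper_tail

logger = logging.getLogger("lncscna")


def cis_pairs(
    coexpr: pd.DataFrame,
    annotation: list[GeneRecord],
    window_bp: int = 300_000,
) -> pd.DataFrame:
    """Filter co-expression edges (gene_a = lncRNA, gene_b = PCG) down to
    same-chromosome pairs whose gene-body gap is <= window_bp."""
    loci = {g.gene_id: g for g in annotation}
    rows = []
    skipped = 0
    for e in coexpr.itertuples():
        ga, gb = loci.get(e.gene_a), loci.get(e.gene_b)
        if ga is None or gb is None:
            skipped += 1
            continue
        if ga.chrom != gb.chrom:
            continue
        gap = max(ga.start, gb.start) - min(ga.end, gb.end)
        distance = max(0, gap)
        if distance <= window_bp:
            rows.append(
                {
                    "lncrna_id": e.gene_a,
                    "pcg_id": e.gene_b,
                    "distance_bp": distance,
                    "r": e.r,
                    "p": e.p,
                    "q": e.q,
                }
            )
    if skipped:
        logger.warning("cis_pairs: %d edges skipped (gene absent from annotation)", skipped)
    return pd.DataFrame(
        rows, columns=["lncrna_id", "pcg_id", "distance_bp", "r", "p", "q"]
    )


def tf_coexpression(
    lnc_expr: OmicsMatrix,
    tf_expr: OmicsMatrix,
    r_min: float = 0.6,
    fdr_max: float = 0.05,
) -> pd.DataFrame:
    """Positive co-expression screen between lncRNAs and TFs (strict
    r > r_min, BH q < fdr_max).  Columns: gene_a (lncRNA), gene_b (TF)."""
    return pearson_screen(lnc_expr, tf_expr, r_min=r_min, fdr_max=fdr_max, sign="positive")


def trans_triples(
    lnc_coexpr_pcgs: Mapping[str, set[str]],
    tf_targets: Mapping[str, set[str]],
    tf_links: pd.DataFrame,
    universe: set[str],
    fdr_max: float = 0.05,
) -> pd.DataFrame:
    """Hypergeometric overlap test per co-expressed (lncRNA, TF) link,
    expanded to per-gene triples when q < fdr_max.

    Columns of the result: lncrna_id, tf_id, pcg_id, tf_lnc_r, overlap_k,
    lnc_coexpr_M, tf_targets_L, universe_N, p, q.
    """
    if not universe:
        raise ValueError("empty universe")
    N = len(universe)
    tests = []
    for link in tf_links.itertuples():
        lnc, tf = link.gene_a, link.gene_b
        M_set = lnc_coexpr_pcgs.get(lnc, set()) & universe
        L_set = tf_targets.get(tf, set()) & universe
        overlap = sorted(M_set & L_set)
        k, M, L = len(overlap), len(M_set), len(L_set)
        p = hypergeom_upper_tail(N, M, L, k) if min(M, L) else 1.0
        tests.append((lnc, tf, link.r, overlap, k, M, L, p))
    if not tests:
        return pd.DataFrame(
            columns=[
                "lncrna_id", "tf_id", "pcg_id", "tf_lnc_r", "overlap_k",
                "lnc_coexpr_M", "tf_targets_L", "universe_N", "p", "q",
            ]
        )
    q = benjamini_hochberg([t[7] for t in tests])
    rows = []
    for (lnc, tf, r, overlap, k, M, L, p), qv in zip(tests, q):
        if qv >= fdr_max:
            continue
        for pcg in overlap:
            rows.append(
                {
                    "lncrna_id": lnc,
                    "tf_id": tf,
                    "pcg_id": pcg,
                    "tf_lnc_r": r,
                    "overlap_k": k,
                    "lnc_coexpr_M": M,
                    "tf_targets_L": L,
                    "universe_N": N,
                    "p": p,
                    "q": qv,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "lncrna_id", "tf_id", "pcg_id", "tf_lnc_r", "overlap_k",
            "lnc_coexpr_M", "tf_targets_L", "universe_N", "p", "q",
        ],
    )
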