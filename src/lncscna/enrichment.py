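"""Hypergeometric GO over-representation analysis, DSS-group functional
profiles, and the lncRNA-function bipartite network.

Terms are tested only when they hit the query set (k >= 1) and annotate at
least 3 universe genes; the upper-tail hypergeometric p is BH-corrected
across the tested terms of each query.
"""

from __future__ import annotations

import logging
from typing import Mapping

import numpy as np
import pandas as pd

from .stats import benjamini_hochberg, hypergeom_upper_tail

logger = logging.getLogger("lncscna")


def go_enrichment(
    gene_set: set[str],
    go_table: pd.DataFrame,
    universe: set[str],
    fdr_max: float = 0.05,
    min_term_size: int = 3,
) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of *gene_set* against GO terms.

    *go_table* has columns gene_id, term_id, term_name.  Returns every
    tested term with columns term_id, term_name, k, K, L_t, N_u, p, q,
    significant (q < fdr_max).
    """
    if not universe:
        raise ValueError("empty universe")
    gene_set = set(gene_set) & universe
    if not gene_set:
        return pd.DataFrame(
            columns=["term_id", "term_name", "k", "K", "L_t", "N_u", "p", "q", "significant"]
        )
    table = go_table[go_table["gene_id"].isin(universe)]
    N_u, K = len(universe), len(gene_set)
    rows = []
    for (term_id, term_name), sub in table.groupby(["term_id", "term_name"], sort=True):
        term_genes = set(sub["gene_id"])
        L_t = len(term_genes)
        k = len(term_genes & gene_set)
        if k < 1 or L_t < min_term_size:
            continue
        p = hypergeom_upper_tail(N_u, K, L_t, k)
        rows.append(
            {"term_id": term_id, "term_name": term_name, "k": k, "K": K,
             "L_t": L_t, "N_u": N_u, "p": p}
        )
    if not rows:
        return pd.DataFrame(
            columns=["term_id", "term_name", "k", "K", "L_t", "N_u", "p", "q", "significant"]
        )
    out = pd.DataFrame(rows)
    out["q"] = benjamini_hochberg(out["p"].to_numpy())
    out["significant"] = out["q"] < fdr_max
    return out


def dss_group_profiles(
    groups: pd.Series,
    coexpr: pd.DataFrame,
    go_table: pd.DataFrame,
    universe: set[str],
    fdr_max: float = 0.05,
) -> tuple[dict[int, pd.DataFrame], pd.DataFrame]:
    """Per-DSS-group enrichment of the union of co-expressed PCGs.

    *groups* maps lncRNA -> group label; *coexpr* has columns gene_a
    (lncRNA), gene_b (PCG).  Returns the per-group enrichment tables and a
    groups x terms matrix of -log10(q) for significant terms.
    """
    partners: dict[str, set[str]] = {}
    for e in coexpr.itertuples():
        partners.setdefault(e.gene_a, set()).add(e.gene_b)
    tables: dict[int, pd.DataFrame] = {}
    for label in sorted(groups.unique()):
        lncs = groups.index[groups == label]
        pcgs = set().union(*(partners.get(l, set()) for l in lncs)) if len(lncs) else set()
        if not pcgs:
            logger.info("DSS group %s has no co-expressed PCGs; skipped", label)
            continue
        tables[int(label)] = go_enrichment(pcgs, go_table, universe, fdr_max=fdr_max)
    terms = sorted(
        {t for tab in tables.values() for t in tab.loc[tab["significant"], "term_id"]}
    )
    profile = pd.DataFrame(0.0, index=sorted(tables), columns=terms)
    for label, tab in tables.items():
        sig = tab[tab["significant"]]
        for r in sig.itertuples():
            profile.loc[label, r.term_id] = -np.log10(max(r.q, 1e-300))
    return tables, profile


def lncrna_function_network(
    lnc_targets: Mapping[str, set[str]],
    go_table: pd.DataFrame,
    universe: set[str],
    dss: Mapping[str, float] | None = None,
    fdr_max: float = 0.05,
) -> pd.DataFrame:
    """Per-lncRNA enrichment of its (cis + trans) target set; one edge per
    (lncRNA, term) with q < fdr_max, annotated with the lncRNA's DSS."""
    dss = dict(dss or {})
    rows = []
    for lnc in sorted(lnc_targets):
        targets = lnc_targets[lnc]
        if not targets:
            continue
        tab = go_enrichment(targets, go_table, universe, fdr_max=fdr_max)
        for r in tab[tab["significant"]].itertuples():
            rows.append(
                {
                    "lncrna_id": lnc,
                    "term_id": r.term_id,
                    "term_name": r.term_name,
                    "p": r.p,
                    "q": r.q,
                    "dss": dss.get(lnc, np.nan),
                }
            )
    return pd.DataFrame(
        rows, columns=["lncrna_id", "term_id", "term_name", "p", "q", "dss"]
    )
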