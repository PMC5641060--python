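"""Competing-endogenous-RNA (ceRNA) network inference.

Positively co-expressed lncRNA-PCG pairs are candidate ceRNAs.  A pair is
retained when (1) at least one miRNA in the interaction tables targets both
partners and is negatively co-expressed with each of them (r < 0,
BH q < 0.05 within the family of all miRNA-gene tests performed), and
(2) the number of shared miRNAs x is significant under the hypergeometric
test

    P = 1 - sum_{i=0}^{x-1} C(L, i) C(N-L, M-i) / C(N, M)

where N is the number of miRNAs interacting with any lncRNA or PCG in the
run, M and L the miRNA counts of the lncRNA and the PCG, and x the shared
count — all taken from the interaction tables.  Both raw p < 0.05 and BH
q < 0.05 are required.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import InteractionTable, OmicsMatrix
from .stats import benjamini_hochberg, hypergeom_upper_tail, pearson_pvalue, pearson_rows

logger = logging.getLogger("lncscna")


def shared_mirna_pvalue(N: int, M: int, L: int, x: int) -> float:
    """Upper-tail hypergeometric p-value for x shared miRNAs between a
    lncRNA with M miRNAs and a PCG with L miRNAs out of N total."""
    if not (0 <= x <= min(M, L)):
        raise ValueError("x must lie in [0, min(M, L)]")
    if M > N or L > N:
        raise ValueError("M and L must not exceed N")
    return hypergeom_upper_tail(N, M, L, x)


@dataclass
class CeRNACandidate:
    lncrna_id: str
    pcg_id: str
    pair_r: float
    shared_mirnas: tuple[str, ...]  # all table-shared miRNAs (defines x)
    surviving_mirnas: tuple[str, ...]  # subset passing the negative screen


def _mirna_sets(
    mirna_lnc: InteractionTable, mirna_pcg: InteractionTable
) -> tuple[dict[str, set[str]], dict[str, set[str]]]:
    lnc_sets: dict[str, set[str]] = {}
    for r in mirna_lnc.pairs.itertuples():
        lnc_sets.setdefault(r.target_id, set()).add(r.source_id)
    pcg_sets: dict[str, set[str]] = {}
    for r in mirna_pcg.pairs.itertuples():
        pcg_sets.setdefault(r.target_id, set()).add(r.source_id)
    return lnc_sets, pcg_sets


def negative_mirna_filter(
    pairs: pd.DataFrame,
    mirna_expr: OmicsMatrix,
    lnc_expr: OmicsMatrix,
    pcg_expr: OmicsMatrix,
    mirna_lnc: InteractionTable,
    mirna_pcg: InteractionTable,
    fdr_max: float = 0.05,
) -> list[CeRNACandidate]:
    """Retain co-expressed pairs with >= 1 shared miRNA negatively
    co-expressed (r < 0, BH q < fdr_max) with both partners.

    BH is applied within the family of all miRNA-gene correlation tests
    performed in this step.  miRNAs present in the interaction tables but
    absent from the expression matrix are skipped (counted).
    """
    if mirna_expr.sample_ids != lnc_expr.sample_ids or (
        mirna_expr.sample_ids != pcg_expr.sample_ids
    ):
        raise ValueError("expression matrices must share an ordered sample set")
    n_samples = len(mirna_expr.sample_ids)
    lnc_sets, pcg_sets = _mirna_sets(mirna_lnc, mirna_pcg)
    known_mirnas = set(mirna_expr.gene_ids)

    # collect every miRNA-gene test needed, then BH once over all of them
    tests: list[tuple[str, str, str]] = []  # (mirna, gene, which_matrix)
    pair_shared: list[tuple[int, tuple[str, ...]]] = []
    n_missing = 0
    for idx, e in enumerate(pairs.itertuples()):
        shared = sorted(lnc_sets.get(e.gene_a, set()) & pcg_sets.get(e.gene_b, set()))
        usable = []
        for m in shared:
            if m not in known_mirnas:
                n_missing += 1
                continue
            usable.append(m)
            tests.append((m, e.gene_a, "lnc"))
            tests.append((m, e.gene_b, "pcg"))
        pair_shared.append((idx, tuple(shared)))
    if n_missing:
        logger.warning(
            "negative_mirna_filter: %d shared miRNAs lack expression", n_missing
        )
    uniq = sorted(set(tests))
    rq: dict[tuple[str, str, str], tuple[float, float]] = {}
    if uniq:
        mat = {"lnc": lnc_expr, "pcg": pcg_expr}
        rs = np.empty(len(uniq))
        for i, (m, g, which) in enumerate(uniq):
            x = mirna_expr.values.loc[m].to_numpy(dtype=float)
            y = mat[which].values.loc[g].to_numpy(dtype=float)
            rs[i] = pearson_rows(x[None, :], y[None, :])[0, 0]
        ps = pearson_pvalue(rs, n_samples)
        ps = np.where(np.isnan(ps), 1.0, ps)
        qs = benjamini_hochberg(ps)
        rq = {key: (rs[i], qs[i]) for i, key in enumerate(uniq)}

    candidates: list[CeRNACandidate] = []
    for (idx, shared) in pair_shared:
        e = pairs.iloc[idx]
        surviving = []
        for m in shared:
            kl = rq.get((m, e["gene_a"], "lnc"))
            kp = rq.get((m, e["gene_b"], "pcg"))
            if kl is None or kp is None:
                continue
            if kl[0] < 0 and kl[1] < fdr_max and kp[0] < 0 and kp[1] < fdr_max:
                surviving.append(m)
        if surviving:
            candidates.append(
                CeRNACandidate(
                    lncrna_id=e["gene_a"],
                    pcg_id=e["gene_b"],
                    pair_r=float(e["r"]),
                    shared_mirnas=shared,
                    surviving_mirnas=tuple(surviving),
                )
            )
    return candidates


def build_cerna_network(
    candidates: list[CeRNACandidate],
    mirna_lnc: InteractionTable,
    mirna_pcg: InteractionTable,
    fdr_max: float = 0.05,
    p_max: float = 0.05,
) -> pd.DataFrame:
    """Hypergeometric shared-miRNA test per candidate pair; retained iff
    raw p < p_max and BH q < fdr_max.  x, M, L, N are interaction-table
    counts; the negative-correlation filter only gates eligibility."""
    lnc_sets, pcg_sets = _mirna_sets(mirna_lnc, mirna_pcg)
    universe = set()
    for s in lnc_sets.values():
        universe |= s
    for s in pcg_sets.values():
        universe |= s
    N = len(universe)
    if not candidates:
        logger.warning("build_cerna_network: no candidate pairs")
        return pd.DataFrame(
            columns=[
                "lncrna_id", "pcg_id", "x", "M", "L", "N",
                "pair_r", "p", "q", "shared_mirnas",
            ]
        )
    rows = []
    for c in sorted(candidates, key=lambda c: (c.lncrna_id, c.pcg_id)):
        M = len(lnc_sets.get(c.lncrna_id, set()))
        L = len(pcg_sets.get(c.pcg_id, set()))
        x = len(c.shared_mirnas)
        p = shared_mirna_pvalue(N, M, L, x)
        rows.append(
            {
                "lncrna_id": c.lncrna_id,
                "pcg_id": c.pcg_id,
                "x": x,
                "M": M,
                "L": L,
                "N": N,
                "pair_r": c.pair_r,
                "p": p,
                "shared_mirnas": ",".join(c.shared_mirnas),
            }
        )
    edges = pd.DataFrame(rows)
    edges["q"] = benjamini_hochberg(edges["p"].to_numpy())
    keep = (edges["p"] < p_max) & (edges["q"] < fdr_max)
    edges = edges.loc[keep].reset_index(drop=True)
    return edges[
        ["lncrna_id", "pcg_id", "x", "M", "L", "N", "pair_r", "p", "q", "shared_mirnas"]
    ]


def degree_summary(edges: pd.DataFrame) -> pd.DataFrame:
    """Node degree table of the ceRNA network (lncRNAs and PCGs)."""
    counts: dict[tuple[str, str], int] = {}
    for e in edges.itertuples():
        counts[(e.lncrna_id, "lncRNA")] = counts.get((e.lncrna_id, "lncRNA"), 0) + 1
        counts[(e.pcg_id, "PCG")] = counts.get((e.pcg_id, "PCG"), 0) + 1
    return pd.DataFrame(
        [
            {"node": node, "node_type": t, "degree": d}
            for (node, t), d in sorted(counts.items())
        ],
        columns=["node", "node_type", "degree"],
    )
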