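"""End-to-end orchestration of the SCNA-lncRNA analysis.

``analyze_cohort`` runs every stage in order on an in-memory cohort and
returns all intermediate and final results; ``run_pipeline`` wraps it with
disk I/O (reads a cohort directory, writes one TSV/JSON per artifact plus a
run manifest with per-stage record counts and input checksums).  All
randomness (the SAM permutation null) is governed by ``config.seed``.

Stage order: preprocess -> SCNA mapping / DSS -> differential expression ->
methylation -> co-expression -> cis -> trans -> ceRNA -> enrichment /
function network -> prognosis -> drugs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cerna import build_cerna_network, degree_summary, negative_mirna_filter
from .dosage import (
    alteration_frequency,
    assign_dss_groups,
    dss_robustness,
    dss_table,
    map_to_fragments,
)
from .enrichment import dss_group_profiles, lncrna_function_network
from .io import Biotype, OmicsMatrix, TUMOR, write_edges
from .methylation import (
    compare_expression_groups,
    differential_methylation,
    gene_beta,
    map_probes,
    meth_expr_correlation,
    promoter_regions,
)
from .preprocess import (
    filter_low_lncrna,
    filter_missing_genes,
    log_transform,
    sam_differential_expression,
    upper_quartile_normalize,
)
from .preprocess import pearson_screen
from .prognosis import drug_candidates, km_coordinates, triple_risk
from .regulatory import cis_pairs, tf_coexpression, trans_triples
from .synthetic import Cohort, read_cohort

logger = logging.getLogger("lncscna")

STAGES = [
    "preprocess", "dss", "de", "meth", "coexpr", "cis", "trans",
    "cerna", "enrich", "prognosis", "drugs",
]


@dataclass
class PipelineConfig:
    """Every tunable threshold of the pipeline, at its standard default."""

    normal_window: tuple[float, float] = (-0.3, 0.3)
    min_altered_fraction: float = 0.2  # strict > gate for the DSS
    min_frequency: float = 0.2  # >= gate for high-frequency alteration
    dss_n: int = 6
    dss_w: float = 0.5
    dss_n_robustness: tuple[int, ...] = (5, 6, 7, 15)
    dss_groups_k: int = 7
    uq_target: float = 1000.0
    max_missing_fraction: float = 0.3
    pcg_pseudocount: float = 2.0
    lnc_pseudocount: float = 0.05
    de_fc_min: float = 2.0
    de_fdr_max: float = 0.05
    de_n_perm: int = 300
    meth_fc_min: float = 2.0
    meth_fdr_max: float = 0.01
    meth_corr_p_max: float = 0.05
    promoter_length: int = 2000
    coexpr_r_min: float = 0.5
    coexpr_fdr_max: float = 0.05
    tf_r_min: float = 0.6
    cis_window_bp: int = 300_000
    trans_fdr_max: float = 0.05
    cerna_fdr_max: float = 0.05
    cerna_p_max: float = 0.05
    go_fdr_max: float = 0.05
    survival_p_max: float = 0.05
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("normal_window", "dss_n_robustness"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def analyze_cohort(cohort: Cohort, config: PipelineConfig | None = None) -> dict:
    """Run every analysis stage on an in-memory cohort; returns a dict of
    intermediate and final artifacts keyed by name."""
    cfg = config or PipelineConfig()
    res: dict = {"config": cfg}

    # -- preprocess ---------------------------------------------------------
    pcg_lin = upper_quartile_normalize(
        filter_missing_genes(cohort.expr_pcg, cfg.max_missing_fraction),
        target=cfg.uq_target,
    )
    pcg_log = log_transform(pcg_lin, cfg.pcg_pseudocount)
    tf_lin = upper_quartile_normalize(cohort.expr_tf, target=cfg.uq_target)
    tf_log = log_transform(tf_lin, cfg.pcg_pseudocount)
    lnc_lin = filter_low_lncrna(cohort.expr_lncrna)
    lnc_log = log_transform(lnc_lin, cfg.lnc_pseudocount)
    mir_log = log_transform(cohort.expr_mirna, cfg.lnc_pseudocount)
    res.update(
        pcg_linear=pcg_lin, pcg_log=pcg_log, tf_log=tf_log,
        lnc_linear=lnc_lin, lnc_log=lnc_log, mir_log=mir_log,
    )

    # -- SCNA mapping and dosage sensitivity -------------------------------
    lnc_records = [g for g in cohort.annotation if g.biotype == Biotype.LNCRNA]
    hits = map_to_fragments(lnc_records, cohort.fragments)
    hits_df = pd.DataFrame(
        [
            {"gene_id": h.gene_id, "fragment_id": h.fragment_id,
             "direction": h.direction, "overlap_bp": h.overlap_bp}
            for h in hits
        ],
        columns=["gene_id", "fragment_id", "direction", "overlap_bp"],
    )
    freq = alteration_frequency(cohort.dcn_lncrna, min_fraction=cfg.min_frequency)
    mapped = set(hits_df["gene_id"])
    high = set(freq.loc[freq["high_frequency"], "gene_id"])
    scna_lncs = sorted((mapped & high) & set(lnc_log.gene_ids))
    dss = dss_table(
        cohort.cn_lncrna, lnc_log, gene_ids=scna_lncs,
        n=cfg.dss_n, normal_window=cfg.normal_window, w=cfg.dss_w,
        min_altered_fraction=cfg.min_altered_fraction,
    )
    robustness = dss_robustness(
        cohort.cn_lncrna, lnc_log, gene_ids=scna_lncs,
        n_values=list(cfg.dss_n_robustness),
        normal_window=cfg.normal_window, w=cfg.dss_w,
        min_altered_fraction=cfg.min_altered_fraction,
    )
    dss_series = dss.set_index("gene_id")["dss"]
    groups = assign_dss_groups(dss_series, k=cfg.dss_groups_k)
    res.update(
        fragment_hits=hits_df, alteration_freq=freq, scna_lncs=scna_lncs,
        dss=dss, dss_robustness=robustness, dss_groups=groups,
    )

    # -- differential expression -------------------------------------------
    de_pcg = sam_differential_expression(
        pcg_log, pcg_lin, n_perm=cfg.de_n_perm, fc_min=cfg.de_fc_min,
        fdr_max=cfg.de_fdr_max, seed=cfg.seed,
    )
    de_lnc = sam_differential_expression(
        lnc_log, lnc_lin, n_perm=cfg.de_n_perm, fc_min=cfg.de_fc_min,
        fdr_max=cfg.de_fdr_max, seed=cfg.seed + 1,
    )
    de_pcg_set = sorted(de_pcg.loc[de_pcg["called"], "gene_id"])
    res.update(de_pcg=de_pcg, de_lncrna=de_lnc, de_pcg_set=de_pcg_set)

    # -- methylation ---------------------------------------------------------
    promoters = promoter_regions(lnc_records, length=cfg.promoter_length)
    probe_map = map_probes(cohort.probe_positions, promoters)
    gb = gene_beta(cohort.beta_probes, probe_map)
    dm = differential_methylation(gb, fc_min=cfg.meth_fc_min, fdr_max=cfg.meth_fdr_max)
    hyper = set(dm.loc[dm["called"] & (dm["state"] == "hyper"), "gene_id"])
    hyper_in_expr = hyper & set(lnc_log.gene_ids)
    others = set(lnc_log.gene_ids) - hyper_in_expr
    if hyper_in_expr and others:
        hyper_vs_rest = compare_expression_groups(lnc_log, hyper_in_expr, others)
    else:
        hyper_vs_rest = {"statistic": float("nan"), "p": float("nan"),
                         "direction": "undefined", "p_one_sided": float("nan"),
                         "n_a": len(hyper_in_expr), "n_b": len(others)}
    if hyper_in_expr:
        meth_corr = meth_expr_correlation(
            gb.subset_genes(sorted(hyper_in_expr)), lnc_log, p_max=cfg.meth_corr_p_max
        )
    else:
        meth_corr = pd.DataFrame(columns=["gene_id", "r", "p", "negative"])
    res.update(
        probe_map=probe_map, gene_beta=gb, diff_meth=dm,
        hyper_lncs=sorted(hyper), hyper_vs_rest=hyper_vs_rest, meth_corr=meth_corr,
    )

    # -- co-expression (SCNA lncRNAs x DE PCGs, tumor samples) --------------
    tumor = lnc_log.samples_of(TUMOR)
    lnc_t = lnc_log.subset_samples(tumor)
    pcg_t = pcg_log.subset_samples(tumor)
    tf_t = tf_log.subset_samples(tumor)
    mir_t = mir_log.subset_samples(tumor)
    coexpr = pearson_screen(
        lnc_t.subset_genes(scna_lncs),
        pcg_t.subset_genes(de_pcg_set) if de_pcg_set else pcg_t.subset_genes([]),
        r_min=cfg.coexpr_r_min, fdr_max=cfg.coexpr_fdr_max, sign="positive",
    ) if scna_lncs and de_pcg_set else pd.DataFrame(
        columns=["gene_a", "gene_b", "r", "p", "q"]
    )
    res["coexpr"] = coexpr

    # -- cis ------------------------------------------------------------------
    cis = cis_pairs(coexpr, cohort.annotation, window_bp=cfg.cis_window_bp)
    res["cis_pairs"] = cis

    # -- trans ----------------------------------------------------------------
    tf_links = tf_coexpression(
        lnc_t.subset_genes(scna_lncs), tf_t,
        r_min=cfg.tf_r_min, fdr_max=cfg.coexpr_fdr_max,
    ) if scna_lncs else pd.DataFrame(columns=["gene_a", "gene_b", "r", "p", "q"])
    lnc_partner_sets: dict[str, set[str]] = {}
    for e in coexpr.itertuples():
        lnc_partner_sets.setdefault(e.gene_a, set()).add(e.gene_b)
    tf_target_sets = {
        tf: cohort.tf_gene.targets_of(tf)
        for tf in cohort.tf_gene.pairs["source_id"].unique()
    }
    universe = set(de_pcg_set)
    trans = (
        trans_triples(
            lnc_partner_sets, tf_target_sets, tf_links, universe,
            fdr_max=cfg.trans_fdr_max,
        )
        if len(tf_links) and universe
        else pd.DataFrame(
            columns=["lncrna_id", "tf_id", "pcg_id", "tf_lnc_r", "overlap_k",
                     "lnc_coexpr_M", "tf_targets_L", "universe_N", "p", "q"]
        )
    )
    res.update(tf_links=tf_links, trans_triples=trans)

    # -- ceRNA ----------------------------------------------------------------
    candidates = negative_mirna_filter(
        coexpr, mir_t, lnc_t, pcg_t, cohort.mirna_lnc, cohort.mirna_pcg,
        fdr_max=cfg.cerna_fdr_max,
    ) if len(coexpr) else []
    cerna_edges = build_cerna_network(
        candidates, cohort.mirna_lnc, cohort.mirna_pcg,
        fdr_max=cfg.cerna_fdr_max, p_max=cfg.cerna_p_max,
    )
    res.update(
        cerna_candidates=candidates, cerna=cerna_edges,
        cerna_degree=degree_summary(cerna_edges),
    )

    # -- enrichment and the lncRNA-function network --------------------------
    go_universe = set(pcg_log.gene_ids)
    group_tables, profile = dss_group_profiles(
        groups, coexpr, cohort.go_table, go_universe, fdr_max=cfg.go_fdr_max
    )
    lnc_targets: dict[str, set[str]] = {}
    for e in cis.itertuples():
        lnc_targets.setdefault(e.lncrna_id, set()).add(e.pcg_id)
    for e in trans.itertuples():
        lnc_targets.setdefault(e.lncrna_id, set()).add(e.pcg_id)
    function_net = lncrna_function_network(
        lnc_targets, cohort.go_table, go_universe,
        dss=dss_series.to_dict(), fdr_max=cfg.go_fdr_max,
    )
    res.update(
        group_enrichment=group_tables, group_profile=profile,
        function_network=function_net,
    )

    # -- prognosis -------------------------------------------------------------
    clinical_ids = set(cohort.clinical.data["sample_id"])
    expr_of: dict[str, pd.Series] = {}
    for m in (lnc_t, pcg_t, mir_t):
        for g in m.gene_ids:
            expr_of[g] = m.values.loc[g]
    risk_rows, risk_models = [], {}
    for e in cerna_edges.itertuples():
        mirnas = tuple(e.shared_mirnas.split(","))
        nodes = {e.lncrna_id: expr_of[e.lncrna_id], e.pcg_id: expr_of[e.pcg_id]}
        nodes.update({m: expr_of[m] for m in mirnas if m in expr_of})
        try:
            model = triple_risk(
                nodes, cohort.clinical, triple=(e.lncrna_id, mirnas, e.pcg_id)
            )
        except ValueError as exc:
            logger.warning("prognosis skipped for %s-%s: %s", e.lncrna_id, e.pcg_id, exc)
            continue
        risk_models[(e.lncrna_id, e.pcg_id)] = model
        risk_rows.append(
            {
                "lncrna_id": e.lncrna_id,
                "pcg_id": e.pcg_id,
                "mirnas": e.shared_mirnas,
                "beta_lncrna": model.betas[e.lncrna_id],
                "beta_pcg": model.betas[e.pcg_id],
                "beta_mirna_mean": float(
                    np.mean([model.betas[m] for m in mirnas if m in model.betas])
                ) if any(m in model.betas for m in mirnas) else float("nan"),
                "logrank_chi2": model.logrank_chi2,
                "logrank_p": model.logrank_p,
                "significant": bool(model.logrank_p < cfg.survival_p_max),
            }
        )
    risk = pd.DataFrame(
        risk_rows,
        columns=["lncrna_id", "pcg_id", "mirnas", "beta_lncrna", "beta_pcg",
                 "beta_mirna_mean", "logrank_chi2", "logrank_p", "significant"],
    )
    if len(risk):
        from .stats import benjamini_hochberg

        risk["logrank_q"] = benjamini_hochberg(risk["logrank_p"].fillna(1.0))
    else:
        risk["logrank_q"] = pd.Series(dtype=float)
    km = (
        pd.concat(
            [
                km_coordinates(m, cohort.clinical).assign(
                    lncrna_id=k[0], pcg_id=k[1]
                )
                for k, m in risk_models.items()
            ],
            ignore_index=True,
        )
        if risk_models
        else pd.DataFrame(columns=["time", "survival", "group", "lncrna_id", "pcg_id"])
    )
    res.update(risk=risk, risk_models=risk_models, km=km)

    # -- drugs -------------------------------------------------------------------
    de_lnc_dir = de_lnc.set_index("gene_id")["direction"].to_dict()
    de_pcg_dir = de_pcg.set_index("gene_id")["direction"].to_dict()
    module_rows = []
    for e in cerna_edges.itertuples():
        for m in e.shared_mirnas.split(","):
            module_rows.append(
                {
                    "mirna_id": m,
                    "lncrna_id": e.lncrna_id,
                    "pcg_id": e.pcg_id,
                    "lncrna_direction": de_lnc_dir.get(e.lncrna_id, "unknown"),
                    "pcg_direction": de_pcg_dir.get(e.pcg_id, "unknown"),
                }
            )
    module = pd.DataFrame(
        module_rows,
        columns=["mirna_id", "lncrna_id", "pcg_id", "lncrna_direction", "pcg_direction"],
    )
    drugs = drug_candidates(module, cohort.drug_mirna)
    res.update(cerna_module=module, drugs=drugs)
    return res


# ---------------------------------------------------------------------------
# disk orchestration
# ---------------------------------------------------------------------------

def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_matrix_like(m: OmicsMatrix, path: Path) -> None:
    m.values.to_csv(path, sep="\t", index_label="gene_id", float_format="%.10g")


def run_pipeline(
    input_dir: str | Path,
    out_dir: str | Path,
    config: PipelineConfig | None = None,
    stages: list[str] | None = None,
) -> dict:
    """Read a cohort directory, run the requested stages (default: all, in
    order) and write every artifact plus ``run_manifest.json``."""
    cfg = config or PipelineConfig()
    wanted = STAGES if stages is None else [s for s in STAGES if s in set(stages)]
    src, out = Path(input_dir), Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort = read_cohort(src)
    res = analyze_cohort(cohort, cfg)

    counts: dict[str, dict[str, int]] = {}

    def emit(stage: str, artifacts: dict[str, object]) -> None:
        if stage not in wanted:
            return
        counts[stage] = {}
        for name, obj in artifacts.items():
            path = out / f"{name}.tsv"
            if isinstance(obj, OmicsMatrix):
                _write_matrix_like(obj, path)
                counts[stage][name] = len(obj.gene_ids)
            elif isinstance(obj, pd.DataFrame):
                write_edges(obj, path)
                counts[stage][name] = len(obj)
            elif isinstance(obj, pd.Series):
                obj.rename("value").to_csv(path, sep="\t", index_label="gene_id")
                counts[stage][name] = len(obj)
            elif isinstance(obj, dict):
                with open(out / f"{name}.json", "w") as fh:
                    json.dump(obj, fh, indent=2, sort_keys=True)
                counts[stage][name] = len(obj)

    emit("preprocess", {
        "pcg_log": res["pcg_log"], "pcg_linear": res["pcg_linear"],
        "lnc_log": res["lnc_log"], "lnc_linear": res["lnc_linear"],
        "tf_log": res["tf_log"], "mir_log": res["mir_log"],
    })
    emit("dss", {
        "fragment_hits": res["fragment_hits"],
        "alteration_frequency": res["alteration_freq"],
        "dss": res["dss"],
        "dss_robustness": res["dss_robustness"].reset_index(names="n"),
        "dss_groups": res["dss_groups"],
    })
    emit("de", {"de_pcg": res["de_pcg"], "de_lncrna": res["de_lncrna"]})
    emit("meth", {
        "probe_map": res["probe_map"], "gene_beta": res["gene_beta"],
        "diff_methylation": res["diff_meth"], "meth_expr_corr": res["meth_corr"],
        "hypermeth_expression_test": res["hyper_vs_rest"],
    })
    emit("coexpr", {"coexpr_edges": res["coexpr"]})
    emit("cis", {"cis_pairs": res["cis_pairs"]})
    emit("trans", {"tf_coexpr": res["tf_links"], "trans_triples": res["trans_triples"]})
    emit("cerna", {"cerna_edges": res["cerna"], "cerna_degree": res["cerna_degree"]})
    emit("enrich", {
        "group_profile": res["group_profile"].reset_index(names="group"),
        "function_network": res["function_network"],
    })
    emit("prognosis", {"risk_models": res["risk"], "km_coordinates": res["km"]})
    emit("drugs", {"drug_candidates": res["drugs"]})

    manifest = {
        "software": {"name": "lncscna", "version": __version__},
        "seed": cfg.seed,
        "config_hash": hashlib.sha256(
            json.dumps(asdict(cfg), sort_keys=True, default=list).encode()
        ).hexdigest(),
        "inputs": {
            p.name: _sha256(p) for p in sorted(src.iterdir()) if p.is_file()
        },
        "stage_counts": counts,
    }
    with open(out / "run_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    res["manifest"] = manifest
    return res
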