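"""Synthetic tumor-cohort generator with planted ground truth.

Generates a complete miniature multi-omics cohort — gene annotation, focal
copy-number fragments, continuous and discretised copy number, expression
matrices (lncRNA, protein-coding, TF, miRNA), promoter-probe methylation,
interaction tables (miRNA-lncRNA, miRNA-mRNA, TF-gene, drug-miRNA), GO
annotation, and clinical follow-up — together with a manifest of every
planted signal, so that every downstream stage of the pipeline has a known
truth to recover:

* dosage-sensitive lncRNAs whose log2 expression is a linear function of
  copy number (slope drawn from ``dosage_slope_range``);
* differentially expressed PCGs (4-fold, both directions);
* ceRNA triples: a lncRNA-PCG pair driven by a shared per-tumor-sample
  latent factor, with a common set of miRNAs anti-coupled to that factor
  and listed for both partners in the interaction tables;
* promoter-hypermethylated lncRNAs (tumor beta ~3x normal) whose
  expression is negatively coupled to the per-sample beta level;
* cis pairs (lncRNA and a DE PCG within 50 kb on the same chromosome,
  co-expressed) and one trans unit (TF + lncRNA + coupled target PCGs);
* a prognostic ceRNA triple whose nodes drive an exponential survival
  hazard with configurable coefficient signs.

Copy-number background stays inside the no-alteration window [-0.3, 0.3];
within each fragment a fixed fraction of tumor samples receives shifts of
magnitude in (0.3, 1.5] whose sign follows the fragment direction, and the
discrete matrix is the thresholded continuous one.  Expression noise is
Gaussian on the log2 scale; matrices are emitted on the linear scale so the
pipeline's own pseudocount/log2 preprocessing is exercised.  Each data
layer draws from its own RNG stream spawned from the master seed, so
identical seeds give bit-identical cohorts.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .io import (
    Biotype,
    ClinicalTable,
    FocalFragment,
    GeneRecord,
    InteractionTable,
    NORMAL,
    OmicsMatrix,
    TUMOR,
    write_annotation,
    write_clinical,
    write_fragments,
    write_interactions,
    write_matrix,
)


class ConfigError(ValueError):
    """Infeasible cohort configuration."""


@dataclass
class CohortConfig:
    """Study conditions of the synthetic cohort (defaults are the package's
    standard conditions, documented in the methods note)."""

    n_tumor: int = 100
    n_normal: int = 30
    n_lncrna: int = 100
    n_pcg: int = 200
    n_tf: int = 8
    n_mirna: int = 30
    n_fragments: int = 10
    alteration_fraction: float = 0.5
    dosage_slope_range: tuple[float, float] = (0.2, 1.5)
    noise_sd: float = 0.3
    n_planted_dss: int = 40
    n_planted_de: int = 20  # dedicated DE PCGs; other planted PCGs are also DE
    n_planted_cerna: int = 5
    n_planted_hypermeth: int = 6
    n_planted_cis: int = 3
    n_trans_targets: int = 20
    n_trans_coupled: int = 15
    mirnas_shared_per_triple: int = 4
    de_log2_shift: float = 2.0  # 4-fold
    hazard_coefs: tuple[float, float, float] = (0.8, -0.8, 0.8)  # lnc, miRNA, PCG
    baseline_scale: float = 500.0  # days; exponential survival scale at eta=0
    censor_time: float = 255.0  # administrative censoring, ~40% events
    seed: int = 0

    def validate(self) -> None:
        populations = [
            self.n_tumor, self.n_normal, self.n_lncrna, self.n_pcg, self.n_tf,
            self.n_mirna, self.n_fragments,
        ]
        if any(c <= 0 for c in populations):
            raise ConfigError("population counts must be positive")
        planted = [
            self.n_planted_dss, self.n_planted_de, self.n_planted_cerna,
            self.n_planted_hypermeth, self.n_planted_cis,
            self.n_trans_targets, self.n_trans_coupled,
        ]
        if any(c < 0 for c in planted):
            raise ConfigError("planted counts must be non-negative")
        if not 0 < self.alteration_fraction <= 1:
            raise ConfigError("alteration_fraction must lie in (0, 1]")
        frag_planted = (
            self.n_planted_dss + self.n_planted_cerna + self.n_planted_cis
            + (1 if self.n_trans_coupled else 0)
        )
        if frag_planted + self.n_planted_hypermeth > self.n_lncrna:
            raise ConfigError("planted lncRNA roles exceed n_lncrna")
        if self.n_planted_cerna * (self.mirnas_shared_per_triple + 2) > self.n_mirna:
            raise ConfigError("ceRNA triples need more miRNAs than exist")
        if self.n_trans_coupled > self.n_trans_targets:
            raise ConfigError("n_trans_coupled must not exceed n_trans_targets")
        deds = self.n_planted_de
        if self.n_trans_targets - self.n_trans_coupled > deds:
            raise ConfigError("uncoupled trans targets exceed dedicated DE genes")
        planted_pcgs = (
            deds + self.n_planted_cerna + self.n_planted_cis + self.n_trans_coupled
        )
        if planted_pcgs > self.n_pcg:
            raise ConfigError("planted PCG roles exceed n_pcg")
        if self.dosage_slope_range[0] > self.dosage_slope_range[1]:
            raise ConfigError("invalid dosage_slope_range")


@dataclass
class GroundTruth:
    dss: dict[str, float]  # lncRNA -> true slope
    de: dict[str, str]  # gene -> direction
    cerna_triples: list[dict]  # {lncrna, pcg, mirnas}
    hypermeth: list[str]
    cis_pairs: list[dict]  # {lncrna, pcg}
    trans_triples: list[dict]  # {lncrna, tf, pcgs}
    prognostic: dict  # {lncrna, mirnas, pcg, coef_signs}


@dataclass
class Cohort:
    config: CohortConfig
    annotation: list[GeneRecord]
    fragments: list[FocalFragment]
    expr_lncrna: OmicsMatrix  # linear scale
    expr_pcg: OmicsMatrix
    expr_tf: OmicsMatrix
    expr_mirna: OmicsMatrix
    cn_lncrna: OmicsMatrix  # tumor samples only
    dcn_lncrna: OmicsMatrix
    beta_probes: OmicsMatrix
    probe_positions: pd.DataFrame  # probe_id, chrom, position
    mirna_lnc: InteractionTable
    mirna_pcg: InteractionTable
    tf_gene: InteractionTable
    drug_mirna: InteractionTable
    go_table: pd.DataFrame  # gene_id, term_id, term_name
    clinical: ClinicalTable
    truth: GroundTruth

    @property
    def sample_class(self) -> pd.Series:
        return self.expr_lncrna.sample_class


GENE_LEN = 10_000
SPACING = 1_000_000


def _linear(log2_vals: np.ndarray) -> np.ndarray:
    return np.power(2.0, log2_vals)


def generate_cohort(config: CohortConfig) -> Cohort:
    """Generate the full synthetic cohort for *config* (deterministic per seed)."""
    config.validate()
    cfg = config
    master = np.random.SeedSequence(cfg.seed)
    rng_cn, rng_expr, rng_meth, rng_inter, rng_surv, rng_go = (
        np.random.default_rng(s) for s in master.spawn(6)
    )

    tumor = [f"T{i + 1:03d}" for i in range(cfg.n_tumor)]
    normal = [f"N{i + 1:03d}" for i in range(cfg.n_normal)]
    samples = tumor + normal
    classes = pd.Series(
        [TUMOR] * cfg.n_tumor + [NORMAL] * cfg.n_normal, index=samples
    )
    tumor_classes = classes[tumor]
    is_tumor = np.array([1.0] * cfg.n_tumor + [0.0] * cfg.n_normal)

    lnc_ids = [f"LNC{i + 1:04d}" for i in range(cfg.n_lncrna)]
    pcg_ids = [f"PCG{i + 1:04d}" for i in range(cfg.n_pcg)]
    tf_ids = [f"TF{i + 1:02d}" for i in range(cfg.n_tf)]
    mir_ids = [f"miR-{i + 1:03d}" for i in range(cfg.n_mirna)]

    # ---- planted role assignment (deterministic by position) -------------
    pos = 0
    dss_lncs = lnc_ids[pos : pos + cfg.n_planted_dss]; pos += cfg.n_planted_dss
    cerna_lncs = lnc_ids[pos : pos + cfg.n_planted_cerna]; pos += cfg.n_planted_cerna
    cis_lncs = lnc_ids[pos : pos + cfg.n_planted_cis]; pos += cfg.n_planted_cis
    has_trans = cfg.n_trans_coupled > 0
    trans_lnc = None
    if has_trans:
        trans_lnc = lnc_ids[pos]; pos += 1
    hm_lncs = lnc_ids[pos : pos + cfg.n_planted_hypermeth]
    pos += cfg.n_planted_hypermeth
    neutral_lncs = lnc_ids[pos:]
    # fragment members: the planted SCNA roles plus a few dosage-insensitive
    # lncRNAs (slope 0); hypermethylated and remaining neutral lncRNAs sit
    # outside every fragment.  Latent-role lncRNAs (ceRNA/cis/trans) also
    # carry a dosage slope: SCNA-resident genes track their copy number.
    n_frag_neutral = min(4, len(neutral_lncs))
    frag_members_all = (
        dss_lncs + cerna_lncs + cis_lncs
        + ([trans_lnc] if has_trans else [])
        + neutral_lncs[:n_frag_neutral]
    )
    offfrag_lncs = hm_lncs + neutral_lncs[n_frag_neutral:]

    ppos = 0
    de_pcgs = pcg_ids[ppos : ppos + cfg.n_planted_de]; ppos += cfg.n_planted_de
    cerna_pcgs = pcg_ids[ppos : ppos + cfg.n_planted_cerna]; ppos += cfg.n_planted_cerna
    cis_pcgs = pcg_ids[ppos : ppos + cfg.n_planted_cis]; ppos += cfg.n_planted_cis
    trans_pcgs = pcg_ids[ppos : ppos + cfg.n_trans_coupled]
    ppos += cfg.n_trans_coupled
    trans_tf = tf_ids[0]
    n_uncoupled = cfg.n_trans_targets - cfg.n_trans_coupled
    trans_targets = trans_pcgs + de_pcgs[:n_uncoupled]

    # ---- annotation and fragments ----------------------------------------
    annotation: list[GeneRecord] = []
    fragments: list[FocalFragment] = []
    frag_of: dict[str, int] = {}
    per_frag: list[list[str]] = [[] for _ in range(cfg.n_fragments)]
    for i, lnc in enumerate(frag_members_all):
        f = i % cfg.n_fragments
        per_frag[f].append(lnc)
        frag_of[lnc] = f
    cis_pcg_of = dict(zip(cis_lncs, cis_pcgs))
    for f in range(cfg.n_fragments):
        chrom = f"chrF{f + 1}"
        members = per_frag[f]
        for j, lnc in enumerate(members):
            start = SPACING * (j + 1)
            strand = "+" if j % 2 == 0 else "-"
            annotation.append(
                GeneRecord(lnc, lnc, Biotype.LNCRNA, chrom, start, start + GENE_LEN, strand)
            )
            if lnc in cis_pcg_of:
                pstart = start + 60_000  # 50 kb body gap, well inside 300 kb
                annotation.append(
                    GeneRecord(
                        cis_pcg_of[lnc], cis_pcg_of[lnc], Biotype.PCG,
                        chrom, pstart, pstart + GENE_LEN, "+",
                    )
                )
        if members:
            lo = SPACING - 5_000
            hi = SPACING * len(members) + GENE_LEN + 5_000
            direction = "gain" if f % 2 == 0 else "loss"
            fragments.append(FocalFragment(f"FRAG{f + 1:02d}", chrom, lo, hi, direction))
    for j, lnc in enumerate(offfrag_lncs):
        start = SPACING * (j + 1)
        strand = "+" if j % 2 == 0 else "-"
        annotation.append(
            GeneRecord(lnc, lnc, Biotype.LNCRNA, "chrE", start, start + GENE_LEN, strand)
        )
    placed_pcgs = set(cis_pcgs)
    j = 0
    for pcg in pcg_ids:
        if pcg in placed_pcgs:
            continue
        start = SPACING * (j + 1)
        annotation.append(
            GeneRecord(pcg, pcg, Biotype.PCG, "chrP", start, start + GENE_LEN,
                       "+" if j % 2 == 0 else "-")
        )
        j += 1
    for j, tf in enumerate(tf_ids):
        start = SPACING * (j + 1)
        annotation.append(
            GeneRecord(tf, tf, Biotype.TF, "chrT", start, start + GENE_LEN, "+")
        )
    for j, mir in enumerate(mir_ids):
        start = 100_000 * (j + 1)
        annotation.append(
            GeneRecord(mir, mir, Biotype.MIRNA, "chrM", start, start + 100, "+")
        )

    # ---- copy number ------------------------------------------------------
    n_alt = int(round(cfg.alteration_fraction * cfg.n_tumor))
    # background scatter fills most of the no-alteration window, as
    # gene-level copy-number estimates do in diploid regions
    cn = rng_cn.uniform(-0.28, 0.28, size=(cfg.n_lncrna, cfg.n_tumor))
    lnc_index = {g: i for i, g in enumerate(lnc_ids)}
    for f, frag in enumerate(fragments):
        altered = rng_cn.choice(cfg.n_tumor, size=n_alt, replace=False)
        mags = rng_cn.uniform(0.301, 1.5, size=n_alt)
        sign = 1.0 if frag.direction == "gain" else -1.0
        for lnc in per_frag[f]:
            cn[lnc_index[lnc], altered] = sign * mags
    dcn = np.where(np.abs(cn) <= 0.3, 0.0, np.sign(cn))
    cn_m = OmicsMatrix(
        pd.DataFrame(cn, index=lnc_ids, columns=tumor), tumor_classes, "copy_number"
    )
    dcn_m = OmicsMatrix(
        pd.DataFrame(dcn, index=lnc_ids, columns=tumor), tumor_classes, "discrete_cn"
    )

    # ---- methylation latent levels (needed before expression coupling) ----
    hm_level = {}  # hypermeth lncRNA -> per-tumor-sample latent beta level
    for lnc in hm_lncs:
        hm_level[lnc] = np.clip(rng_meth.normal(0.5, 0.08, size=cfg.n_tumor), 0.02, 0.98)

    # ---- expression --------------------------------------------------------
    ns = len(samples)
    noise = lambda size: rng_expr.normal(0.0, cfg.noise_sd, size=size)
    # unit-variance latent co-expression factors keep the planted pair
    # correlations far above the 0.5 screen threshold at the default noise
    f_cerna = rng_expr.normal(0.0, 1.0, size=(cfg.n_planted_cerna, cfg.n_tumor))
    g_cis = rng_expr.normal(0.0, 1.0, size=(cfg.n_planted_cis, cfg.n_tumor))
    h_trans = rng_expr.normal(0.0, 1.0, size=cfg.n_tumor)
    slopes = rng_expr.uniform(*cfg.dosage_slope_range, size=cfg.n_planted_dss)

    def tumor_pad(x: np.ndarray) -> np.ndarray:
        out = np.zeros(ns)
        out[: cfg.n_tumor] = x
        return out

    lnc_log = np.empty((cfg.n_lncrna, ns))
    mu_lnc = rng_expr.uniform(3.0, 6.0, size=cfg.n_lncrna)
    for lnc in hm_lncs:
        mu_lnc[lnc_index[lnc]] = rng_expr.uniform(2.0, 3.0)
    for i, lnc in enumerate(lnc_ids):
        base = mu_lnc[i] + noise(ns)
        if lnc in dss_lncs:
            s = slopes[dss_lncs.index(lnc)]
            base += tumor_pad(s * cn[i])
        elif lnc in cerna_lncs:
            k = cerna_lncs.index(lnc)
            base += cfg.de_log2_shift * is_tumor + tumor_pad(f_cerna[k])
        elif lnc in cis_lncs:
            k = cis_lncs.index(lnc)
            base += tumor_pad(g_cis[k])
        elif lnc == trans_lnc:
            base += tumor_pad(h_trans)
        elif lnc in hm_lncs:
            base += tumor_pad(-3.0 * (hm_level[lnc] - 0.5))
        lnc_log[i] = base

    pcg_log = np.empty((cfg.n_pcg, ns))
    mu_pcg = rng_expr.uniform(3.0, 6.0, size=cfg.n_pcg)
    de_direction: dict[str, str] = {}
    for i, pcg in enumerate(pcg_ids):
        base = mu_pcg[i] + noise(ns)
        if pcg in de_pcgs:
            d = 1.0 if de_pcgs.index(pcg) % 2 == 0 else -1.0
            base += d * cfg.de_log2_shift * is_tumor
            de_direction[pcg] = "up" if d > 0 else "down"
        elif pcg in cerna_pcgs:
            k = cerna_pcgs.index(pcg)
            base += cfg.de_log2_shift * is_tumor + tumor_pad(f_cerna[k])
            de_direction[pcg] = "up"
        elif pcg in cis_pcgs:
            k = cis_pcgs.index(pcg)
            base += cfg.de_log2_shift * is_tumor + tumor_pad(g_cis[k])
            de_direction[pcg] = "up"
        elif pcg in trans_pcgs:
            base += cfg.de_log2_shift * is_tumor + tumor_pad(0.8 * h_trans)
            de_direction[pcg] = "up"
        pcg_log[i] = base

    tf_log = np.empty((cfg.n_tf, ns))
    mu_tf = rng_expr.uniform(3.0, 6.0, size=cfg.n_tf)
    for i, tf in enumerate(tf_ids):
        base = mu_tf[i] + noise(ns)
        if has_trans and tf == trans_tf:
            base += tumor_pad(h_trans)
        tf_log[i] = base

    # shared miRNA assignment per ceRNA triple (disjoint blocks), plus one
    # extra non-shared miRNA for each partner
    shared_sets: list[list[str]] = []
    used = 0
    for k in range(cfg.n_planted_cerna):
        shared_sets.append(mir_ids[used : used + cfg.mirnas_shared_per_triple])
        used += cfg.mirnas_shared_per_triple
    extra_pool = mir_ids[used:]
    lnc_extra: dict[str, str] = {}
    pcg_extra: dict[str, str] = {}
    for k in range(cfg.n_planted_cerna):
        pick = rng_inter.choice(len(extra_pool), size=2, replace=False)
        lnc_extra[cerna_lncs[k]] = extra_pool[pick[0]]
        pcg_extra[cerna_pcgs[k]] = extra_pool[pick[1]]

    mir_log = np.empty((cfg.n_mirna, ns))
    mu_mir = rng_expr.uniform(3.0, 6.0, size=cfg.n_mirna)
    mir_index = {m: i for i, m in enumerate(mir_ids)}
    for k, mirnas in enumerate(shared_sets):
        for m in mirnas:
            mir_log[mir_index[m]] = (
                mu_mir[mir_index[m]]
                - 1.0 * is_tumor
                + tumor_pad(-0.9 * f_cerna[k])
                + noise(ns)
            )
    planted_mirs = {m for s in shared_sets for m in s}
    for m in mir_ids:
        if m not in planted_mirs:
            mir_log[mir_index[m]] = mu_mir[mir_index[m]] + noise(ns)

    def make_expr(ids: list[str], log_vals: np.ndarray) -> OmicsMatrix:
        return OmicsMatrix(
            pd.DataFrame(_linear(log_vals), index=ids, columns=samples),
            classes, "expression",
        )

    expr_lnc = make_expr(lnc_ids, lnc_log)
    expr_pcg = make_expr(pcg_ids, pcg_log)
    expr_tf = make_expr(tf_ids, tf_log)
    expr_mir = make_expr(mir_ids, mir_log)

    # ---- methylation probes -----------------------------------------------
    gene_by_id = {g.gene_id: g for g in annotation}
    probe_rows, beta_rows, probe_ids = [], [], []
    for lnc in lnc_ids:
        rec = gene_by_id[lnc]
        if rec.strand == "+":
            pstart, pend = max(0, rec.tss - 2000), rec.tss
        else:
            pstart, pend = rec.tss, rec.tss + 2000
        offsets = (400, 1400)
        if lnc in hm_lncs:
            tum = np.stack(
                [np.clip(hm_level[lnc] + rng_meth.normal(0, 0.03, cfg.n_tumor), 0, 1)
                 for _ in offsets]
            )
            nor = np.clip(
                rng_meth.normal(0.15, 0.04, size=(len(offsets), cfg.n_normal)), 0, 1
            )
        else:
            center = rng_meth.uniform(0.1, 0.3)
            tum = np.clip(
                rng_meth.normal(center, 0.05, size=(len(offsets), cfg.n_tumor)), 0, 1
            )
            nor = np.clip(
                rng_meth.normal(center, 0.05, size=(len(offsets), cfg.n_normal)), 0, 1
            )
        for pi, off in enumerate(offsets):
            pid = f"cg_{lnc}_{pi + 1}"
            probe_ids.append(pid)
            probe_rows.append(
                {"probe_id": pid, "chrom": rec.chrom, "position": pstart + off}
            )
            beta_rows.append(np.concatenate([tum[pi], nor[pi]]))
    beta = np.asarray(beta_rows)
    # sprinkle a little missingness to exercise mean imputation
    n_miss = max(1, beta.size // 200)
    miss_i = rng_meth.integers(0, beta.shape[0], size=n_miss)
    miss_j = rng_meth.integers(0, beta.shape[1], size=n_miss)
    beta[miss_i, miss_j] = np.nan
    beta_m = OmicsMatrix(
        pd.DataFrame(beta, index=probe_ids, columns=samples), classes, "beta"
    )
    probe_positions = pd.DataFrame(probe_rows, columns=["probe_id", "chrom", "position"])

    # ---- interaction tables -----------------------------------------------
    ml_rows, mp_rows = [], []
    for k in range(cfg.n_planted_cerna):
        for m in shared_sets[k]:
            ml_rows.append((m, cerna_lncs[k]))
            mp_rows.append((m, cerna_pcgs[k]))
        ml_rows.append((lnc_extra[cerna_lncs[k]], cerna_lncs[k]))
        mp_rows.append((pcg_extra[cerna_pcgs[k]], cerna_pcgs[k]))
    background_lncs = [l for l in lnc_ids if l not in cerna_lncs]
    for lnc in background_lncs:
        for m in rng_inter.choice(mir_ids, size=3, replace=False):
            ml_rows.append((m, lnc))
    background_pcgs = [p for p in pcg_ids if p not in cerna_pcgs][:40]
    for pcg in background_pcgs:
        for m in rng_inter.choice(mir_ids, size=3, replace=False):
            mp_rows.append((m, pcg))
    mirna_lnc = InteractionTable(
        pd.DataFrame(ml_rows, columns=["source_id", "target_id"]).assign(
            kind="miRNA-lncRNA"
        ),
        "miRNA-lncRNA",
    )
    mirna_pcg = InteractionTable(
        pd.DataFrame(mp_rows, columns=["source_id", "target_id"]).assign(
            kind="miRNA-mRNA"
        ),
        "miRNA-mRNA",
    )
    tg_rows = [(trans_tf, t) for t in trans_targets] if has_trans else []
    for tf in tf_ids[1:]:
        for t in rng_inter.choice(pcg_ids, size=8, replace=False):
            tg_rows.append((tf, t))
    tf_gene = InteractionTable(
        pd.DataFrame(tg_rows, columns=["source_id", "target_id"]).assign(kind="TF-gene"),
        "TF-gene",
    )
    drug_rows = []
    module_mirs = shared_sets[0] if shared_sets else []
    if module_mirs:
        for i, drug in enumerate(["drug_A", "drug_B", "drug_C"]):
            drug_rows.append((drug, module_mirs[i % len(module_mirs)], "up"))
        drug_rows.append(("drug_D", module_mirs[0], "down"))
    other_mirs = [m for m in mir_ids if m not in module_mirs]
    for i, drug in enumerate(["drug_E", "drug_F"]):
        drug_rows.append((drug, other_mirs[i], "up"))
    drug_mirna = InteractionTable(
        pd.DataFrame(drug_rows, columns=["source_id", "target_id", "effect"]).assign(
            kind="drug-miRNA"
        ),
        "drug-miRNA",
    )

    # ---- GO annotation -----------------------------------------------------
    go_rows = [
        {"gene_id": g, "term_id": "GO:0000001", "term_name": "cell cycle process"}
        for g in trans_pcgs
    ]
    go_rows += [
        {"gene_id": g, "term_id": "GO:0000002", "term_name": "immune response"}
        for g in cerna_pcgs + cis_pcgs
    ]
    for t in range(8):
        for g in rng_go.choice(pcg_ids, size=12, replace=False):
            go_rows.append(
                {"gene_id": g, "term_id": f"GO:10000{t + 1:02d}",
                 "term_name": f"background process {t + 1}"}
            )
    go_table = pd.DataFrame(go_rows, columns=["gene_id", "term_id", "term_name"])

    # ---- survival ----------------------------------------------------------
    z = lambda v: (v - v.mean()) / v.std()
    prognostic: dict = {}
    if cerna_lncs:
        prog_lnc, prog_pcg = cerna_lncs[0], cerna_pcgs[0]
        prog_mirs = shared_sets[0]
        lnc_t = lnc_log[lnc_index[prog_lnc], : cfg.n_tumor]
        pcg_t = pcg_log[pcg_ids.index(prog_pcg), : cfg.n_tumor]
        mir_t = np.mean(
            [z(mir_log[mir_index[m], : cfg.n_tumor]) for m in prog_mirs], axis=0
        )
        cl, cm, cp = cfg.hazard_coefs
        eta = cl * z(lnc_t) + cm * z(mir_t) + cp * z(pcg_t)
        prognostic = {
            "lncrna": prog_lnc,
            "mirnas": prog_mirs,
            "pcg": prog_pcg,
            "coef_signs": [int(np.sign(c)) for c in cfg.hazard_coefs],
        }
    else:
        eta = np.zeros(cfg.n_tumor)
    time, event = simulate_survival(
        eta, rng_surv, baseline_scale=cfg.baseline_scale, censor_time=cfg.censor_time
    )
    clinical = ClinicalTable(
        pd.DataFrame({"sample_id": tumor, "time": time, "event": event.astype(int)})
    )

    truth = GroundTruth(
        dss={lnc: float(slopes[i]) for i, lnc in enumerate(dss_lncs)},
        de={
            **{g: de_direction[g] for g in de_pcgs},
            **{g: "up" for g in cerna_pcgs + cis_pcgs + trans_pcgs},
        },
        cerna_triples=[
            {"lncrna": cerna_lncs[k], "pcg": cerna_pcgs[k], "mirnas": shared_sets[k]}
            for k in range(cfg.n_planted_cerna)
        ],
        hypermeth=list(hm_lncs),
        cis_pairs=[{"lncrna": l, "pcg": cis_pcg_of[l]} for l in cis_lncs],
        trans_triples=(
            [{"lncrna": trans_lnc, "tf": trans_tf, "pcgs": trans_pcgs}]
            if has_trans else []
        ),
        prognostic=prognostic,
    )
    return Cohort(
        config=cfg,
        annotation=annotation,
        fragments=fragments,
        expr_lncrna=expr_lnc,
        expr_pcg=expr_pcg,
        expr_tf=expr_tf,
        expr_mirna=expr_mir,
        cn_lncrna=cn_m,
        dcn_lncrna=dcn_m,
        beta_probes=beta_m,
        probe_positions=probe_positions,
        mirna_lnc=mirna_lnc,
        mirna_pcg=mirna_pcg,
        tf_gene=tf_gene,
        drug_mirna=drug_mirna,
        go_table=go_table,
        clinical=clinical,
        truth=truth,
    )


def simulate_survival(
    eta: np.ndarray,
    rng: np.random.Generator,
    baseline_scale: float = 500.0,
    censor_time: float = 255.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Exponential event times with hazard proportional to exp(eta), under
    fixed administrative censoring.  Returns (observed time, event flag)."""
    eta = np.asarray(eta, dtype=float)
    latent = rng.exponential(baseline_scale * np.exp(-eta))
    event = latent <= censor_time
    time = np.where(event, latent, censor_time)
    time = np.maximum(time, 1e-6)
    return time, event


# ---------------------------------------------------------------------------
# cohort I/O
# ---------------------------------------------------------------------------

_MATRIX_FILES = {
    "expr_lncrna": ("expr_lncrna.tsv", "expression"),
    "expr_pcg": ("expr_pcg.tsv", "expression"),
    "expr_tf": ("expr_tf.tsv", "expression"),
    "expr_mirna": ("expr_mirna.tsv", "expression"),
    "cn_lncrna": ("cn_lncrna.tsv", "copy_number"),
    "dcn_lncrna": ("dcn_lncrna.tsv", "discrete_cn"),
    "beta_probes": ("beta_probes.tsv", "beta"),
}


def write_cohort(cohort: Cohort, out_dir: str | Path) -> None:
    """Write every cohort layer in the pipeline's input formats, plus the
    ground-truth manifest (JSON) and the generating config (YAML)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_annotation(cohort.annotation, out / "annotation.bed", dialect="BED")
    write_fragments(cohort.fragments, out / "fragments.tsv")
    for attr, (fname, _role) in _MATRIX_FILES.items():
        write_matrix(getattr(cohort, attr), out / fname)
    cohort.probe_positions.to_csv(out / "probe_positions.tsv", sep="\t", index=False)
    write_interactions(cohort.mirna_lnc, out / "mirna_lncrna.tsv")
    write_interactions(cohort.mirna_pcg, out / "mirna_mrna.tsv")
    write_interactions(cohort.tf_gene, out / "tf_targets.tsv")
    write_interactions(cohort.drug_mirna, out / "drug_mirna.tsv")
    cohort.go_table.to_csv(out / "go_annotations.tsv", sep="\t", index=False)
    write_clinical(cohort.clinical, out / "clinical.tsv")
    cohort.sample_class.rename("class").to_csv(
        out / "sample_classes.tsv", sep="\t", index_label="sample_id"
    )
    manifest = asdict(cohort.truth)
    with open(out / "ground_truth.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str, sort_keys=True)
    cfg = asdict(cohort.config)
    cfg["dosage_slope_range"] = list(cfg["dosage_slope_range"])
    cfg["hazard_coefs"] = list(cfg["hazard_coefs"])
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)


def read_cohort(in_dir: str | Path) -> Cohort:
    """Load a cohort written by :func:`write_cohort` (inverse round trip)."""
    from .io import (
        read_annotation, read_clinical, read_fragments, read_interactions,
        read_matrix,
    )

    src = Path(in_dir)
    with open(src / "config.yaml") as fh:
        raw = yaml.safe_load(fh)
    raw["dosage_slope_range"] = tuple(raw["dosage_slope_range"])
    raw["hazard_coefs"] = tuple(raw["hazard_coefs"])
    cfg = CohortConfig(**raw)
    class_map = (
        pd.read_csv(src / "sample_classes.tsv", sep="\t")
        .set_index("sample_id")["class"]
        .to_dict()
    )
    matrices = {
        attr: read_matrix(src / fname, role, class_map)
        for attr, (fname, role) in _MATRIX_FILES.items()
    }
    with open(src / "ground_truth.json") as fh:
        t = json.load(fh)
    truth = GroundTruth(
        dss=t["dss"], de=t["de"], cerna_triples=t["cerna_triples"],
        hypermeth=t["hypermeth"], cis_pairs=t["cis_pairs"],
        trans_triples=t["trans_triples"], prognostic=t["prognostic"],
    )
    return Cohort(
        config=cfg,
        annotation=read_annotation(src / "annotation.bed", dialect="BED"),
        fragments=read_fragments(src / "fragments.tsv"),
        probe_positions=pd.read_csv(src / "probe_positions.tsv", sep="\t"),
        mirna_lnc=read_interactions(src / "mirna_lncrna.tsv", "miRNA-lncRNA"),
        mirna_pcg=read_interactions(src / "mirna_mrna.tsv", "miRNA-mRNA"),
        tf_gene=read_interactions(src / "tf_targets.tsv", "TF-gene"),
        drug_mirna=read_interactions(src / "drug_mirna.tsv", "drug-miRNA"),
        go_table=pd.read_csv(src / "go_annotations.tsv", sep="\t"),
        clinical=read_clinical(src / "clinical.tsv"),
        truth=truth,
        **matrices,
    )
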