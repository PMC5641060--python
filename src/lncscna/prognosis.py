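"""Prognostic risk scoring of ceRNA triples and drug-miRNA nomination.

Each node (lncRNA, every shared miRNA, PCG) of a triple gets a univariate
Cox proportional-hazards coefficient on its z-scored expression; the
per-sample risk score is the coefficient-weighted sum of z-scores; patients
are split at the median risk (ties to low) and compared with a log-rank
test.  Cox fitting, the log-rank test and Kaplan-Meier curves are delegated
to lifelines; the triple-level combination is implemented here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import logrank_test

from .io import ClinicalTable, InteractionTable

logger = logging.getLogger("lncscna")


@dataclass
class RiskModel:
    triple: tuple[str, tuple[str, ...], str]  # (lncRNA, miRNAs, PCG)
    betas: dict[str, float]
    cox_p: dict[str, float]
    risk: pd.Series
    cut: float
    group: pd.Series  # "high" | "low"
    logrank_chi2: float
    logrank_p: float
    degenerate: bool = False
    converged: bool = True


def _zscore(x: pd.Series) -> pd.Series:
    sd = x.std(ddof=0)
    if sd == 0 or np.isnan(sd):
        return x * 0.0
    return (x - x.mean()) / sd


def univariate_cox(expr: pd.Series, clinical: ClinicalTable) -> tuple[float, float, bool]:
    """Univariate Cox PH fit of survival on z-scored expression.

    Returns (beta, Wald p, converged).  Constant expression gives beta = 0
    exactly (no variation to fit).
    """
    clin = clinical.data.set_index("sample_id")
    shared = [s for s in clin.index if s in expr.index]
    if len(shared) < 10:
        raise ValueError("need at least 10 samples with clinical follow-up")
    clin = clin.loc[shared]
    if int(clin["event"].sum()) < 3:
        raise ValueError("need at least 3 observed events")
    z = _zscore(expr.loc[shared].astype(float))
    if (z == 0).all():
        return 0.0, 1.0, True
    df = pd.DataFrame({"time": clin["time"], "event": clin["event"], "z": z})
    cph = CoxPHFitter()
    try:
        cph.fit(df, duration_col="time", event_col="event")
    except ConvergenceError:
        logger.warning("Cox fit did not converge")
        return float("nan"), float("nan"), False
    return float(cph.params_["z"]), float(cph.summary.loc["z", "p"]), True


def triple_risk(
    nodes: dict[str, pd.Series],
    clinical: ClinicalTable,
    triple: tuple[str, tuple[str, ...], str] | None = None,
) -> RiskModel:
    """Risk model for one lncRNA-miRNA(s)-PCG triple.

    *nodes* maps node id -> expression over the clinical samples.  The risk
    score is sum_node beta_node * z_node per sample; the median splits
    high/low (ties to low); groups are compared by log-rank.
    """
    clin = clinical.data.set_index("sample_id")
    betas: dict[str, float] = {}
    cox_p: dict[str, float] = {}
    converged = True
    for node, expr in nodes.items():
        missing = [s for s in clin.index if s not in expr.index]
        if missing:
            raise ValueError(f"node {node} lacks expression for samples {missing[:3]}")
        b, p, ok = univariate_cox(expr, clinical)
        betas[node], cox_p[node] = b, p
        converged &= ok
    shared = [s for s in clin.index]
    risk = pd.Series(0.0, index=shared)
    for node, expr in nodes.items():
        if np.isnan(betas[node]):
            continue
        risk += betas[node] * _zscore(expr.loc[shared].astype(float))
    cut = float(risk.median())
    group = pd.Series(np.where(risk > cut, "high", "low"), index=risk.index)
    if group.nunique() < 2:
        logger.warning("triple_risk: constant risk score; no log-rank test")
        return RiskModel(
            triple or ("", tuple(), ""), betas, cox_p, risk, cut, group,
            float("nan"), float("nan"), degenerate=True, converged=converged,
        )
    hi, lo = group == "high", group == "low"
    res = logrank_test(
        clin.loc[risk.index[hi], "time"],
        clin.loc[risk.index[lo], "time"],
        event_observed_A=clin.loc[risk.index[hi], "event"],
        event_observed_B=clin.loc[risk.index[lo], "event"],
    )
    return RiskModel(
        triple or ("", tuple(), ""), betas, cox_p, risk, cut, group,
        float(res.test_statistic), float(res.p_value), converged=converged,
    )


def km_coordinates(model: RiskModel, clinical: ClinicalTable) -> pd.DataFrame:
    """Kaplan-Meier survival-curve coordinates per risk group, for plotting."""
    clin = clinical.data.set_index("sample_id").loc[model.risk.index]
    frames = []
    for label in ("high", "low"):
        mask = model.group == label
        if mask.sum() == 0:
            continue
        km = KaplanMeierFitter()
        km.fit(clin.loc[mask.values, "time"], clin.loc[mask.values, "event"])
        sf = km.survival_function_.reset_index()
        sf.columns = ["time", "survival"]
        sf["group"] = label
        frames.append(sf)
    return pd.concat(frames, ignore_index=True)


def drug_candidates(
    module: pd.DataFrame,
    drug_table: InteractionTable,
) -> pd.DataFrame:
    """Nominate drugs acting on a ceRNA module through its miRNAs.

    *module* rows describe module membership with columns mirna_id,
    lncrna_id, pcg_id, lncrna_direction, pcg_direction (DE directions,
    "up"/"down").  A drug is a candidate when it up-regulates a module
    miRNA while both the lncRNA and the PCG are up-regulated in tumors
    (boosting the miRNA plausibly represses both); every other matching
    drug-miRNA row is reported with rationale "other".
    """
    if drug_table.kind != "drug-miRNA":
        raise ValueError("drug_table must be a drug-miRNA interaction table")
    module_mirnas = {}
    for r in module.itertuples():
        module_mirnas.setdefault(r.mirna_id, []).append(r)
    rows = []
    for d in drug_table.pairs.itertuples():
        if d.target_id not in module_mirnas:
            continue
        for m in module_mirnas[d.target_id]:
            both_up = m.lncrna_direction == "up" and m.pcg_direction == "up"
            rationale = (
                "suppresses overexpressed ceRNA partners"
                if d.effect == "up" and both_up
                else "other"
            )
            rows.append(
                {
                    "drug": d.source_id,
                    "mirna_id": d.target_id,
                    "effect": d.effect,
                    "lncrna_id": m.lncrna_id,
                    "pcg_id": m.pcg_id,
                    "rationale": rationale,
                }
            )
    return pd.DataFrame(
        rows, columns=["drug", "mirna_id", "effect", "lncrna_id", "pcg_id", "rationale"]
    )
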