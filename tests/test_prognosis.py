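"""Univariate Cox, triple risk score, median split, log-rank, drug rules."""

import numpy as np
import pandas as pd
import pytest

from lncscna.io import ClinicalTable, InteractionTable
from lncscna.prognosis import (
    drug_candidates,
    km_coordinates,
    triple_risk,
    univariate_cox,
)
from lncscna.synthetic import simulate_survival


def clinical(times, events, ids=None):
    ids = ids or [f"s{i}" for i in range(len(times))]
    return ClinicalTable(
        pd.DataFrame({"sample_id": ids, "time": times, "event": events})
    )


def series(values, ids=None):
    ids = ids or [f"s{i}" for i in range(len(values))]
    return pd.Series(np.asarray(values, dtype=float), index=ids)


def _simulated(seed, n=100, beta=0.0):
    rng = np.random.default_rng(seed)
    z = rng.normal(size=n)
    time, event = simulate_survival(beta * z, rng)
    return series(z), clinical(time, event.astype(int))


class TestUnivariateCox:
    def test_constant_expression_gives_zero(self):
        expr, clin = _simulated(0)
        beta, p, ok = univariate_cox(series(np.ones(100)), clin)
        assert beta == 0.0 and ok

    def test_recovers_simulated_coefficient(self):
        hits = 0
        for seed in range(25):
            expr, clin = _simulated(seed, n=300, beta=0.8)
            beta, _, ok = univariate_cox(expr, clin)
            hits += ok and abs(beta - 0.8) <= 0.2
        assert hits >= 23

    def test_null_betas_center_on_zero(self):
        betas = []
        for seed in range(20):
            expr, clin = _simulated(100 + seed, n=200, beta=0.0)
            b, _, _ = univariate_cox(expr, clin)
            betas.append(b)
        assert abs(np.mean(betas)) < 0.1

    def test_requires_events(self):
        expr = series(np.arange(20))
        clin = clinical(np.arange(1, 21), [0] * 20)
        with pytest.raises(ValueError):
            univariate_cox(expr, clin)


def logrank_oracle(times, events, group):
    """Hand-computable two-group log-rank chi-square."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    group = np.asarray(group)
    o_minus_e, var = 0.0, 0.0
    for t in sorted(set(times[events == 1])):
        at_risk = times >= t
        n, na = at_risk.sum(), (at_risk & (group == "a")).sum()
        d = ((times == t) & (events == 1)).sum()
        da = ((times == t) & (events == 1) & (group == "a")).sum()
        o_minus_e += da - d * na / n
        if n > 1:
            var += d * (na / n) * (1 - na / n) * (n - d) / (n - 1)
    return o_minus_e**2 / var


class TestTripleRisk:
    def test_logrank_matches_hand_oracle(self):
        # two interleaved groups with known event pattern, fully hand-computable
        times = [1, 3, 5, 7, 9, 11, 2, 4, 6, 8, 10, 12]
        events = [1, 1, 0, 1, 1, 0, 1, 1, 0, 1, 0, 0]
        clin = clinical(times, events)
        # binary expression forces the median split into the two groups
        nodes = {"node": series([0] * 6 + [1] * 6)}
        model = triple_risk(nodes, clin)
        expected = logrank_oracle(times, events, ["a"] * 6 + ["b"] * 6)
        assert model.logrank_chi2 == pytest.approx(expected, rel=1e-6)
        assert (model.group == "high").sum() == 6

    def test_median_split_sizes_balanced(self):
        for n in (11, 20, 25):
            rng = np.random.default_rng(n)
            z = rng.normal(size=n)
            time, event = simulate_survival(0.5 * z, rng)
            event[0] = True  # ensure events exist
            model = triple_risk(
                {"x": series(z)}, clinical(time, event.astype(int))
            )
            sizes = model.group.value_counts()
            assert abs(sizes.get("high", 0) - sizes.get("low", 0)) <= 1

    def test_constant_risk_flagged_degenerate(self):
        _, clin = _simulated(0)
        model = triple_risk({"x": series(np.ones(100))}, clin)
        assert model.degenerate and np.isnan(model.logrank_p)

    def test_risk_score_order_invariant(self):
        rng = np.random.default_rng(1)
        z1, z2, z3 = (series(rng.normal(size=60)) for _ in range(3))
        time, event = simulate_survival(0.8 * (z1 - z2 + z3).to_numpy(), rng)
        clin = clinical(time, event.astype(int), ids=list(z1.index))
        m1 = triple_risk({"a": z1, "b": z2, "c": z3}, clin)
        m2 = triple_risk({"c": z3, "a": z1, "b": z2}, clin)
        assert np.allclose(m1.risk, m2.risk)
        assert m1.logrank_p == pytest.approx(m2.logrank_p)

    def test_missing_node_expression_names_node(self):
        _, clin = _simulated(0)
        short = series(np.arange(10), ids=[f"s{i}" for i in range(10)])
        with pytest.raises(ValueError, match="x"):
            triple_risk({"x": short}, clin)

    def test_null_detection_rate_controlled(self):
        # a detection requires the planted sign pattern (+,-,+) AND a
        # significant median split; under the null this joint event is rare.
        # (The log-rank alone is anti-conservative here because the risk
        # weights are fitted on the same samples; see the methods note.)
        detected = 0
        n_triples = 60
        for seed in range(n_triples):
            rng = np.random.default_rng(2000 + seed)
            nodes = {k: series(rng.normal(size=80)) for k in ("l", "m", "p")}
            time, event = simulate_survival(np.zeros(80), rng)
            clin = clinical(time, event.astype(int))
            model = triple_risk(nodes, clin)
            signs_match = (
                model.betas["l"] > 0 and model.betas["m"] < 0 and model.betas["p"] > 0
            )
            detected += (
                signs_match
                and (not model.degenerate)
                and model.logrank_p < 0.05
            )
        assert detected / n_triples <= 0.1

    def test_null_single_node_split_is_nominal(self):
        # with one node the median split is the median of its expression
        # (independent of the fitted weight), so the log-rank is a valid test
        significant = 0
        n_reps = 60
        for seed in range(n_reps):
            rng = np.random.default_rng(4000 + seed)
            node = series(rng.normal(size=80))
            time, event = simulate_survival(np.zeros(80), rng)
            clin = clinical(time, event.astype(int))
            model = triple_risk({"x": node}, clin)
            significant += (not model.degenerate) and model.logrank_p < 0.05
        assert significant / n_reps <= 0.1


def test_km_coordinates_cover_both_groups():
    rng = np.random.default_rng(5)
    z = series(rng.normal(size=80))
    time, event = simulate_survival(1.0 * z.to_numpy(), rng)
    clin = clinical(time, event.astype(int))
    model = triple_risk({"x": z}, clin)
    km = km_coordinates(model, clin)
    assert set(km["group"]) == {"high", "low"}
    assert ((km["survival"] >= 0) & (km["survival"] <= 1)).all()


class TestDrugCandidates:
    def _module(self, lnc_dir="up", pcg_dir="up"):
        return pd.DataFrame(
            [{"mirna_id": "m1", "lncrna_id": "L", "pcg_id": "P",
              "lncrna_direction": lnc_dir, "pcg_direction": pcg_dir}]
        )

    def _drugs(self, rows):
        df = pd.DataFrame(rows, columns=["source_id", "target_id", "effect"])
        return InteractionTable(df.assign(kind="drug-miRNA"), "drug-miRNA")

    def test_up_drug_on_up_module_is_candidate(self):
        out = drug_candidates(self._module(), self._drugs([("d1", "m1", "up")]))
        assert out.iloc[0]["rationale"] == "suppresses overexpressed ceRNA partners"

    def test_down_drug_reported_as_other(self):
        out = drug_candidates(self._module(), self._drugs([("d1", "m1", "down")]))
        assert out.iloc[0]["rationale"] == "other"

    def test_down_regulated_module_not_candidate(self):
        out = drug_candidates(
            self._module(pcg_dir="down"), self._drugs([("d1", "m1", "up")])
        )
        assert out.iloc[0]["rationale"] == "other"

    def test_outside_mirna_excluded_and_empty_table(self):
        out = drug_candidates(self._module(), self._drugs([("d1", "m9", "up")]))
        assert len(out) == 0
        empty = self._drugs([])
        assert len(drug_candidates(self._module(), empty)) == 0


def test_planted_prognostic_triple_recovered(cohort, results):
    """The cohort's hazard-planted ceRNA triple yields the planted
    coefficient signs and a significant median-split separation."""
    truth = cohort.truth.prognostic
    risk = results["risk"].set_index(["lncrna_id", "pcg_id"])
    row = risk.loc[(truth["lncrna"], truth["pcg"])]
    assert row["beta_lncrna"] > 0 and row["beta_pcg"] > 0
    assert row["beta_mirna_mean"] < 0
    assert row["logrank_p"] < 0.05
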