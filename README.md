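# lncscna

Integrated analysis of **somatic-copy-number-altered (SCNA) lncRNAs** in a
tumor cohort: dosage-sensitivity scoring, tumor-vs-normal differential
expression and promoter methylation, cis- and trans-acting regulatory
networks, competing-endogenous-RNA (ceRNA) inference via a shared-miRNA
hypergeometric test, prognostic risk scoring of lncRNA–miRNA–mRNA triples,
and drug–miRNA candidate nomination.  It is aimed at computational
cancer-genomics researchers who want each of these steps as a tested,
seedable library function rather than a one-off script, together with a
synthetic-cohort generator that plants every signal the analysis assumes —
so the whole pipeline can be validated end to end against known ground
truth.

## The core quantities

**Dosage-sensitivity score.** For each lncRNA with copy number outside the
no-alteration window [−0.3, 0.3] in more than 20 % of tumor samples,

    DSS = w · r(c, e) + (1 − w) · M_n(c, e),          w = 0.5

where r is the Pearson correlation of copy number *c* and expression *e*
across tumor samples, and M_n is a bin-level concordance: samples sorted by
*c* are split into *n* equal-size bins (default n = 6) with mean
expressions m₁…m_n, and

    M_n = (#{k<l : m_l > m_k} − #{k<l : m_l < m_k}) / C(n, 2).

DSS ∈ [−1, 1]; +1 means expression rises monotonically and linearly with
copy number.  Rank stability across n ∈ {5, 6, 7, 15} is checked by
Spearman correlation.

**Shared-miRNA test.** A positively co-expressed lncRNA–PCG pair (Pearson
r > 0.5, BH FDR < 0.05) whose partners are both negatively co-expressed
with at least one common miRNA is scored with the hypergeometric upper
tail

    P = 1 − Σ_{i=0}^{x−1} C(L, i) C(N−L, M−i) / C(N, M)

with N the number of miRNAs interacting with any lncRNA or PCG in the run,
M and L the miRNA counts of the lncRNA and the PCG, and x the shared
count; edges require p < 0.05 and BH q < 0.05.

**Risk score.** Each node of a ceRNA triple receives a univariate Cox
coefficient β on z-scored expression; per-sample risk is Σ β·z; patients
are split at the median risk and compared by log-rank.

## Worked example

```python
from lncscna import CohortConfig, PipelineConfig, analyze_cohort, generate_cohort

cohort = generate_cohort(CohortConfig(seed=1))
res = analyze_cohort(cohort, PipelineConfig(seed=1))

dss = res["dss"].set_index("gene_id")["dss"]
print(f"SCNA lncRNAs scored: {dss.notna().sum()}")
print(f"mean DSS of dosage-planted lncRNAs: "
      f"{dss.loc[[g for g in cohort.truth.dss if g in dss.index]].mean():.3f}")
print(f"DE PCGs called: {int(res['de_pcg']['called'].sum())}")
print(f"hypermethylated lncRNAs called: {len(res['hyper_lncs'])}")
print(f"ceRNA edges: {len(res['cerna'])}")
print(res["cerna"][["lncrna_id", "pcg_id", "x", "M", "L", "N", "p", "q"]]
      .head(3).to_string(index=False))
row = res["risk"].iloc[0]
print(f"prognostic triple {row.lncrna_id}-{row.pcg_id}: "
      f"log-rank p = {row.logrank_p:.2e}")
```

prints

```
SCNA lncRNAs scored: 53
mean DSS of dosage-planted lncRNAs: 0.864
DE PCGs called: 43
hypermethylated lncRNAs called: 6
ceRNA edges: 5
lncrna_id  pcg_id  x  M  L  N        p        q
  LNC0041 PCG0021  4  5  5 30 0.000884 0.000884
  LNC0042 PCG0022  4  5  5 30 0.000884 0.000884
  LNC0043 PCG0023  4  5  5 30 0.000884 0.000884
prognostic triple LNC0041-PCG0021: log-rank p = 3.37e-11
```

All 53 fragment-resident lncRNAs clear the >20 % alteration gate; the 40
dosage-planted ones average DSS ≈ 0.86.  The 43 DE calls are exactly the
4-fold planted PCGs; the 5 ceRNA edges are exactly the planted triples
(x = 4 shared miRNAs of M = L = 5 listed per partner, N = 30), and the
hazard-planted triple separates the median-split risk groups decisively.

The same analysis runs from the shell on a written cohort directory:

```bash
lncscna synth --seed 42 --out cohort/
lncscna all --input cohort/ --out results/      # or per stage: dss, cerna, ...
```

Every stage writes TSV artifacts plus `run_manifest.json` (input checksums,
config hash, per-stage record counts); reruns with the same seed are
byte-identical.

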