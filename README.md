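# ruleout

Stratified error accounting and threshold selection for AI **rule-out
triage** in screening programs.

When a screening program lets an AI model exclude its lowest-risk exams
from radiologist review, the operative question is not the model's AUC
but a trade-off: how much reading workload disappears, how many cancers
are ruled out with it, and how those omissions net out against cancers a
radiologist might *additionally* catch while reading a smaller, enriched
pool. `ruleout` computes that trade-off from exam-level data — one row
per screening exam with a continuous AI risk score in [0, 1], the
radiologist's recall decision under standard practice, and the cancer
outcome within the follow-up window.

## The metrics

At a rule-out threshold *t* (score ≤ *t* is excluded from review), every
exam falls in one of eight cells by (ruled-out, recalled, cancer):

|            | ¬recall, ¬cancer | ¬recall, cancer | recall, ¬cancer | recall, cancer |
|------------|------|------|------|------|
| ruled out  | B    | C    | D    | E    |
| retained   | G    | H    | I    | J    |

with F = B+C+D+E ruled out, K = G+H+I+J retained, N = F+K. From these:

- **CRR** = F/N — caseload reduction rate;
- **G-FOR** = (C+E)/F = 1 − NPV — probability a ruled-out exam harbors cancer;
- **N-FOR** = E/F — G-FOR restricted to cancers the radiologist would
  have recalled under standard practice (C are interval cancers missed
  either way);
- **AN-FOR(f)** = (E − f·H)/F — N-FOR credited with a fraction *f* of
  the retained cancers the radiologist would otherwise have missed; can
  be negative, meaning triage nets out *ahead* of standard practice;
- **FDR** = (G+I)/K = 1 − PPV among retained exams;
- sensitivity (H+J)/(C+E+H+J), specificity (B+D)/(B+D+G+I), Youden's
  J = se + sp − 1, and Bayes-theorem predictive values.

Two selection policies are built in: the Youden optimum, and the
**AN-FOR-zero** policy — the largest grid threshold whose AN-FOR(f) is
still ≤ 0, i.e. the maximal caseload reduction with no net increase in
missed cancers under scenario *f*. Percentile-bootstrap confidence bands
(exam-level resampling) quantify uncertainty, and a synthetic-cohort
generator with closed-form expected metrics makes everything testable
without patient data.

## Worked example

The package bundles a reference dataset: the complete stratified counts
of a 114,229-exam retrospective screening-mammography cohort (864
cancers, prevalence 0.76%) at thresholds 0.01–0.85.

```python
from ruleout import compute_metrics, as_percent, net_missed_count, datasets

counts = datasets.counts_at(0.20)      # B=79194, C=82, D=5803, E=141, ...
m = compute_metrics(counts)
print(as_percent(m.crr), as_percent(m.g_for), as_percent(m.n_for),
      as_percent(m.an_for[0.30]), as_percent(m.fdr))
# 74.6 0.26 0.17 0.14 97.79
print(net_missed_count(counts, 0.30))  # 121
```

At threshold 0.20, 74.60% of the caseload is ruled out; 0.26% of
ruled-out exams harbor cancer (223 exams), 0.17% would have been caught
by the radiologist (141), and under the 30%-extra-detection scenario the
net burden is 0.14% (121 cancers). The outcome-based policy instead
picks the threshold where that burden reaches zero:

```python
from ruleout import run_sweep, select_anfor_zero
sweep = run_sweep(datasets.load_cohort(), datasets.tabulated_grid())
print(select_anfor_zero(sweep, 0.30).threshold)  # 0.05  (CRR 36.00%)
print(select_anfor_zero(sweep, 0.70).threshold)  # 0.09  (CRR 52.96%)
```

The `examples/` directory has one narrative script per capability
(metrics, selection, simulation, bootstrap bands, avoidable biopsies).

## Command line

```
ruleout simulate --n 100000 --seed 7 --out cohort.csv
ruleout sweep    --input cohort.csv --grid 0.01:0.99:0.01 --out out/
ruleout select   --input cohort.csv --policy anfor-zero --f 0.30 --out report.json
ruleout bootstrap --input cohort.csv --replicates 1000 --seed 1 --out bands.csv
ruleout report   --input cohort.csv --f 0.30 --out out/
```

JSON/CSV artifacts are the contract; plots (FOR-vs-CRR, FDR-vs-CRR) are
presentation.

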