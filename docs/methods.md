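# Methods

## The counterfactual accounting model

The package treats AI rule-out triage as a re-partition of a fixed
historical cohort. Each exam carries three observed binary facts at a
candidate threshold *t*: ruled out (AI score ≤ *t*), recalled by the
radiologist under standard practice, and cancer within the follow-up
window. The central idea is that raw AI error rates overstate the harm
of triage: some ruled-out cancers (cell C) were interval cancers the
radiologist missed anyway, so only cell E — ruled-out cancers the
radiologist *would* have recalled — is a true loss attributable to
triage. Conversely, retained cancers the radiologist missed (cell H) are
an opportunity: with a smaller and prevalence-enriched reading pool,
radiologists plausibly detect a fraction *f* of them, crediting the
ledger. Hence the family

    G-FOR  = (C+E)/F        gross omission
    N-FOR  = E/F            net of mutually missed cancers
    AN-FOR(f) = (E − f·H)/F adjusted for extra retained detections

AN-FOR can be negative: at low thresholds, few cancers are ruled out
while many radiologist-missed cancers remain retained, so triage can net
out ahead of standard practice. The signed value flows through tables
and curves; only the headline "additional missed cancers" count
(`net_missed_count(..., clamp=True)`) floors at zero, since "−9
additional missed cancers" is reported as none.

Key assumptions, inherited from the retrospective design:

- the radiologist recall flag is a faithful counterfactual for what
  would have happened without triage (no behavioral feedback in the
  historical data);
- *f* is a scenario parameter, not an estimate — the true uplift in the
  retained pool is unknown and would require a multi-reader prospective
  study; results are therefore reported across f ∈ {10, 30, 50, 70}%;
- *f* is treated as constant across thresholds, although in reality it
  likely varies with the retained pool's size and prevalence;
- exams are exchangeable (no per-patient clustering across rounds).

## Conventions and numerical choices

- **Rule-out comparison**: score ≤ threshold is ruled out; a score
  exactly on a grid threshold belongs to the ruled-out side.
- **Undefined metrics**: FOR-family rates at F = 0 and FDR/PPV at K = 0
  are a NaN sentinel rendered blank in tables — never zero and never an
  exception inside a sweep. Downstream consumers must test
  `is_defined`.
- **Rounding**: reported percentages round half-away-from-zero to two
  decimals (`round_half_away`), the convention of the classic
  statistical packages these tables are usually produced with; Python's
  builtin banker's rounding would disagree on exact halves. Internal
  computation is full double precision; golden-table tests check the
  rounded values, identity tests (Bayes vs count ratios) run in exact
  rational arithmetic.
- **Threshold grid**: default 0.01–0.99 step 0.01. Sweeps exploit the
  cumulative structure (one sort, then `searchsorted` per grid point),
  so dense grids are cheap.
- **Youden candidates**: by default all distinct observed scores, as in
  an ROC analysis on full-resolution data; a grid-restricted mode exists
  for tabulated fixtures. Ties break toward the smaller threshold —
  the conservative side, ruling out fewer exams.
- **AN-FOR-zero selection** returns the *largest* grid threshold with
  AN-FOR(f) ≤ target, maximizing caseload reduction subject to no net
  increase in missed cancers; if no row qualifies the result is a typed
  "no crossing" outcome rather than an error. The bracket (last
  qualifying row, first non-qualifying row) is reported as a
  diagnostic.

## Bundled reference dataset

`ruleout.datasets` ships the complete stratified counts of a 114,229-exam
retrospective screening-mammography cohort (864 cancers; radiologist
recall rate 8.66%, radiologist sensitivity 716/864 ≈ 82.9%) at
thresholds 0.01–0.85. Because only cumulative counts are available, the
exam-level `load_cohort()` is a *pseudo-cohort reconstruction*: cell
increments between consecutive thresholds become exams with scores
exactly at the bin's upper threshold, and the retained residual of the
last row is placed above the grid. Stratification at any tabulated
threshold then reproduces the source cells bit-for-bit. Two properties
follow:

- analyses on the pseudo-cohort are exact *at tabulated thresholds* and
  meaningless between them;
- the Youden optimum of the underlying full-resolution scores is not
  recoverable: on the 0.01-grid counts J peaks at 0.21 (J = 0.493),
  adjacent to the 0.20 operating point the full-resolution data support.
  The package therefore exposes the J profile as a diagnostic and does
  not treat grid-level Youden output as a reproduction of any particular
  published operating point.

## Synthetic cohort generator

`simulate_cohort` draws, per exam and independently:
cancer ~ Bernoulli(prevalence); score ~ Beta(a, b) conditional on class;
recall ~ Bernoulli(p) with class-specific p, optionally score-dependent.

Defaults are calibrated to the reference cohort, so the generator's
default output *is* the study condition:

| parameter | default | source of calibration |
|---|---|---|
| n | 114,229 | cohort size |
| prevalence | 0.0076 | 864/114,229 |
| recall_noncancer | 0.081 | 9,176/113,365 recalled non-cancers |
| detect_cancer | 0.829 | 716/864 screen-detected cancers |
| Beta non-cancer (a, b) | (0.659, 4.199) | class CDF 0.362 at 0.05 and 0.750 at 0.20 |
| Beta cancer (a, b) | (1.133, 1.644) | class CDF 0.057 at 0.05 and 0.258 at 0.20 |

Beta distributions are used for their [0, 1] support and two-parameter
flexibility; they are a modeling choice, not a claim about any specific
AI model's score distribution. The two-quantile fit pins the
class-conditional rule-out fractions at the two reference operating
points, which makes CRR, sensitivity and specificity match the reference
cohort closely across the 0.05–0.20 range and qualitatively elsewhere.

**Score–recall coupling.** Real reading data show radiologists miss
low-AI-score cancers disproportionately (among ruled-out cancers at the
0.20 threshold, 82/223 were radiologist-missed versus 148/864 overall).
The generator models this with one parameter per class: logit(p_recall)
= c + slope·score, with the intercept *c* solved by quadrature +
`brentq` so the class *marginal* recall probability stays at its
configured value regardless of slope. Slopes reproducing the reference
coupling are ≈ 4.7 (cancer) and ≈ 2.2 (non-cancer). The default slopes
are 0 (recall independent of score given class) because that is the
regime with closed-form expectations; tests that need the coupling set
the slopes explicitly.

**Closed-form oracle.** With zero slopes, writing p = prevalence,
q_c = P(score ≤ t | cancer), q_n = P(score ≤ t | ¬cancer),
d = detect_cancer:

    CRR = p·q_c + (1−p)·q_n          G-FOR = p·q_c / CRR
    N-FOR = d·G-FOR                  AN-FOR(f) = (p·q_c·d − f·p·(1−q_c)(1−d)) / CRR
    FDR = (1−p)(1−q_n) / (1 − CRR)

`expected_metrics` implements these and anchors the parameter-recovery
tests (empirical sweep on 10⁵–10⁶ simulated exams within 3 Monte-Carlo
standard errors of the analytic values).

**Biopsy outcomes** (for the avoidable-biopsy tally) are a simple
conditional model: recalled cancers biopsy malignant; recalled
non-cancers biopsy benign with probability 0.15 and high-risk with 0.03
(remainder resolve without biopsy) — plausible screening-recall
work-up rates chosen once for testability, with no external calibration
target.

**What the generator does not emulate**: per-patient correlation across
screening rounds, breast-density or age structure, drift in technology
or prevalence over the retrospective window, and any dependence of the
detection-uplift fraction *f* on threshold. Passing tests on synthetic
cohorts therefore validate the *accounting machinery and its sampling
behavior*, not the clinical transportability of any particular
threshold.

## Bootstrap

`bootstrap_bands` resamples exam records with replacement at full cohort
size (the exam is the exchangeable unit; no stratification), recomputes
the sweep per replicate, and forms percentile intervals — simple
2.5/97.5 quantiles with inclusive linear interpolation between order
statistics, so bands are bit-reproducible for a fixed seed. Replicates
at which a metric is undefined are excluded from that cell's quantiles
and the surviving count is reported (`n_defined_replicates`). Percentile
intervals were chosen over BCa for transparency and because the rates
involved are smooth functionals of multinomial counts; the construction
is stated in the output metadata. Empirical check: over 200 independent
synthetic cohorts (n = 5,000, default parameters, 200 replicates each),
the 95% band for G-FOR at threshold 0.20 covered the generative value
94% of the time — within binomial noise of nominal. At this cohort size
the band rests on only ~10 ruled-out cancers per replicate set, so
mild undercoverage at smaller n is expected behavior of percentile
intervals on rare-event proportions.

## Invasive-only analyses

`invasive_only(cohort, mode)` supports restricting the outcome to
invasive cancers. Default mode `recode` relabels in-situ cancers as
negative, keeping every denominator identical to the all-cancers
analysis so curves remain comparable at the same caseload axis; mode
`drop` removes the exams instead. Both require `cancer_type` on every
cancer record and fail fast otherwise.

## Problem sizes in the test suite

Unit and property tests run on toy cohorts (4–500 exams), the bundled
114k-exam pseudo-cohort, and synthetic cohorts of 2×10⁴–10⁶ exams;
bootstrap tests use 25–500 replicates and the coverage study uses
200 cohorts × 200 replicates at n = 5,000. These sizes were chosen so
the Monte-Carlo assertions have 3σ headroom while the full suite stays
fast enough to run on every change.

## Known limitations

- The framework evaluates *historical* counterfactuals; it cannot
  anticipate behavioral feedback (automation bias, prevalence effects)
  once triage is actually deployed.
- AN-FOR's credit term assumes the extra detections are drawn from cell
  H only; it does not model extra *false-positive* recalls in the
  retained pool, which the same behavioral mechanisms would also
  produce.
- The pseudo-cohort reconstruction quantizes scores to the tabulated
  grid; any analysis requiring sub-grid resolution needs the original
  exam-level scores.
- Metrics are point estimates of direct rates; the bootstrap quantifies
  sampling noise but not single-site selection effects.
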