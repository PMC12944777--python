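"""Potentially avoidable benign and high-risk biopsies per threshold.

Among recalled exams, biopsies with benign or high-risk pathology that
fall below the rule-out threshold would never be triggered under triage
— a downstream benefit that grows with caseload reduction.
"""

from ruleout import SimulationConfig, biopsies_avoided, simulate_cohort, stratify

cohort = simulate_cohort(SimulationConfig(n=100_000, seed=5))
print(f"{'threshold':>9} {'CRR%':>7} {'benign avoided':>15} {'high-risk avoided':>18}")
for t in (0.02, 0.05, 0.10, 0.20, 0.40):
    tab = biopsies_avoided(cohort, t)
    crr = 100 * stratify(cohort, t).f / len(cohort)
    print(f"{t:9.2f} {crr:7.2f} {tab.loc['benign', 'ruled_out']:15d} "
          f"{tab.loc['high_risk', 'ruled_out']:18d}")

print("\nAvoided-biopsy counts rise monotonically with the threshold: more rule-out")
print("means fewer recalls of exams that would have biopsied benign.")
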