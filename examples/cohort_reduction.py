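"""Recover known swelling reductions from a synthetic longitudinal cohort.

A cohort is simulated at the study group sizes with true peak reductions of
57 % (Flash9) and 40 % (Flash930) relative to the conventional group's
155 µm peak, then analysed exactly like real data: sham-referenced swelling,
per-group mean +- SEM curves, each group's maximum reaction, percent
reduction with propagated uncertainty, and a pooled two-sample t-test.
"""

from flashear import SyntheticScenario, generate_cohort, reduction_analysis

scenario = SyntheticScenario()
records = generate_cohort(scenario, seed=1)
truth = scenario.true_reductions()

for res in reduction_analysis(records):
    print(
        f"{res.test:>8} vs {res.reference}: peak {res.peak_test:6.1f} +- "
        f"{res.peak_test_sem:4.1f} um on day {res.peak_day_test:3.0f}  ->  "
        f"reduction ({res.reduction_percent:.0f} +- {res.reduction_sem:.0f}) %   "
        f"[truth {truth[res.test]:.0f} %]   p = {res.p_value:.2f}"
    )

print(
    "\nEach line compares a FLASH group's maximum ear swelling against the "
    "conventional group's; the injected truth should lie within ~2 SEM of "
    "the estimate. p-values are raw (no multiplicity correction)."
)
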