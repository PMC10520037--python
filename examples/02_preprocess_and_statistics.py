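"""Reproduce the paired statistical comparison of expression movements.

For every participant the combined (left+right) cheek and brow movement is
averaged per expression over the controlled task's high-intensity events; the
four expressions are then compared all-pairs with the two-sided Wilcoxon
signed-rank test, Bonferroni-corrected (m = 6 per sensor region).
"""

from omgpipe import (
    generate_cohort,
    preprocess_for_statistics,
    run_expression_comparison,
)

cohort = generate_cohort(n_participants=27, seed=42)
traces = [preprocess_for_statistics(r) for r in cohort]
events = [r.events for r in cohort]

res = run_expression_comparison(traces, events, intensity="high")
for signal in ("cheek", "brow"):
    meds = res.medians[signal]
    print(f"\n{signal} cohort medians of per-participant mean movement (mm):")
    for expr, value in sorted(meds.items(), key=lambda kv: -kv[1]):
        print(f"  {expr:<14} {value:6.2f}")
    print(f"{signal} pairwise Wilcoxon tests (Bonferroni m=6):")
    for t in res.for_signal(signal):
        print(f"  {t.pair[0]:<14} vs {t.pair[1]:<14} p_adj={t.p_adjusted:9.2e}  {t.annotation}")

print(
    "\nLarge cheek movement separates smile/squeezed-eyes from frown/eyebrow-raise;"
    "\nthe brow moves most for the eyebrow raise and least for the smile."
    "\n'ns' marks pairs whose movements are statistically indistinguishable."
)
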