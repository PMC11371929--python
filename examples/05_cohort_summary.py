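"""Interpret a 20-sample synthetic cohort and summarize category counts.

Each sample in the demonstration cohort encodes one clinical archetype
(approved-therapy match, trial match, resistance exclusion, or a clarity
outcome); the summary reports per-category counts and half-up rounded
percentages per question arm.
"""

from oncointerp import run_pipeline, summarize_cohort
from oncointerp.simulate import demo_cohort_configs

configs = demo_cohort_configs(seed=5)
reports = [run_pipeline(c) for c in configs]
assignments = [r.category for r in reports if r.category is not None]
summary = summarize_cohort(assignments)

print("category counts:")
for cat in sorted(summary.counts):
    print(f"  {cat}: {summary.counts[cat]}  ({summary.percentage(cat)}%)")
for arm, denom in summary.denominators.items():
    print(f"{arm}: {summary.supportive_count(arm)}/{denom} supportive "
          f"({summary.supportive_percentage(arm, decimals=0)}%)")
print(f"overall supportive: {summary.overall_supportive_percentage()}%")

mismatches = [(c.sample_id, c.intended_category, r.category.category)
              for c, r in zip(configs, reports)
              if (r.category.category if r.category else "none")
              != c.intended_category]
print(f"intended-category mismatches: {len(mismatches)}")
# Percentages use half-up rounding to one decimal (zero decimals for the arm
# totals), the convention used when reporting cohort fractions.
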