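"""Aggregate a simulated pregnancy cohort's adherence by phase and week.

Simulates 28 participants with realistic wear-time, questionnaire and
blood-pressure self-measurement behaviour, then prints the per-phase
summary and the first weeks of the gestational-week-aligned wear curve.
"""

import perimon as pm
from perimon.adherence import CohortTimeline, phase_summary, weekly_curves

rec, meta, truth = pm.simulate_cohort(pm.CohortSimConfig(n_participants=28, seed=4))
tl = CohortTimeline(rec, meta)

for phase, s in phase_summary(tl).items():
    print(
        f"{phase:10s}: wear {s.mean_wear_h:5.2f} ± {s.sd_wear_h:4.2f} h/day, "
        f"answered {s.answer_rate_pct:4.1f}% of days, BP {s.bp_per_week:4.2f}/week "
        f"({s.answered_days} answered days, n={s.n_participants})"
    )

print("\ngestational week : mean wear h/day (n)")
for w in weekly_curves(tl)[:6]:
    print(f"  gw {w.week:2d}         : {w.mean_wear_h:5.2f} ({w.n_contributing})")
# Phase summaries weight participants equally; weekly curves show who
# contributes as enrollment staggers across gestational ages.
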