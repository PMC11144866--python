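"""Estimate baseline-anchored transition tables from follow-up counts.

Reconstructs the routine-care longitudinal cohort from its packaged
follow-up count table (884/236/93 women per baseline category) and runs
the anchored estimator: P(state at period | baseline state), with women
lost to follow-up deflating the row mass.
"""

import periscreen as ps
from periscreen.states import HealthState, PerinatalPeriod

cohort = ps.reference_trajectories()
result = ps.estimate_anchored_transitions(cohort)

print(f"cohort size: {len(cohort)}; baseline groups: "
      f"{ {s.value: n for s, n in result.denominators.items()} }")
for m in result.schedule.matrices:
    row = m.row(HealthState.NORMAL)
    print(f"{m.period.value:17s} normal -> (N, S, H) = "
          f"({row[0]:.3f}, {row[1]:.3f}, {row[2]:.3f})  row mass {row.sum():.3f}")

cell = result.schedule.matrix(PerinatalPeriod.SECOND_TRIMESTER).row(HealthState.NORMAL)[0]
print(f"\nnormal->normal, second trimester: {100 * cell:.1f}% (826 of 884)")

dist, counts = ps.baseline_distribution(cohort)
print(f"baseline distribution: normal {dist.normal:.3f}, "
      f"suspicious {dist.suspicious:.3f}, high risk {dist.high_risk:.3f}")

# Row masses below 1 are women missing that period's screening visit; the
# Markov engine propagates that deficit rather than renormalizing it away.
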