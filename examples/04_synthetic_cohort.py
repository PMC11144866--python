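"""Generate a synthetic screening cohort and recover its parameters.

Subjects evolve as individual Markov chains from the routine-care tables
(row-normalized), with 10% of visits missing and integer EPDS scores drawn
within each state's band.  The chained estimator applied to the generated
data recovers the generating matrices up to sampling error.
"""

import numpy as np

import periscreen as ps

params = ps.reference_parameters()
config = ps.SimulationConfig(
    baseline=params.routine_initial,
    schedule=params.routine_schedule,
    n_subjects=5000,
    seed=7,
    missing_rate=0.10,
    emit_scores=True,
)
trajectories, truth = ps.simulate_trajectories(config)
print(f"simulated {len(trajectories)} women; "
      f"complete trajectories: {sum(t.complete for t in trajectories)}")

est = ps.estimate_chained_transitions(trajectories)
for m_true, m_est in zip(truth.normalized_schedule.matrices, est.schedule.matrices):
    err = np.abs(m_true.rows - m_est.rows).max()
    print(f"{m_true.period.value:17s} max |estimated - true| = {err:.4f}")

summary = ps.outcome_statistics(trajectories)
print(f"\never positive: {summary.ever_positive:.1%}; "
      f"always normal: {summary.always_normal:.1%}; "
      f"first positive postpartum: {summary.first_positive_postpartum:.1%}")

# Estimation error shrinks as 1/sqrt(row count). Rows conditioning on the
# rare high-risk state (~1-2% occupancy by late pregnancy) keep the largest
# errors; the well-populated normal rows agree to a few thousandths.
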