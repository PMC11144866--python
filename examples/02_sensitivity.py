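"""One-way (tornado) and probabilistic sensitivity analysis.

Sweeps each uncertain parameter over its surveyed range, then draws 1,000
joint Monte Carlo samples from the fitted Beta/Gamma distributions and
pushes each through the full two-arm model.
"""

import periscreen as ps

params = ps.reference_parameters()
builder = ps.model_builder_for(params)
specs = ps.reference_param_specs()

# Tornado on the incremental net monetary benefit of screening (yuan):
# a positive outcome means screening beats routine care at the threshold.
outcome = lambda c: -(params.wtp * c.delta_qalys - c.delta_cost)  # noqa: E731
records = ps.one_way_dsa(builder, specs, outcome)
print("tornado (incremental NMB of screening, widest first):")
for r in records[:6]:
    print(f"  {r.name:28s} spread {r.spread:10.2f}  [{r.outcome_at_low:.2f}, {r.outcome_at_high:.2f}]")

psa = ps.run_psa(builder, specs, n=1000, seed=42, wtp=params.wtp)
print()
print(f"PSA (n={psa.n}, seed={psa.seed}):")
print(f"  screening mean cost {psa.mean_reference_cost:8.2f} yuan, "
      f"mean QALYs {psa.mean_reference_qalys:.3f}")
print(f"  routine   mean cost {psa.mean_comparator_cost:8.2f} yuan, "
      f"mean QALYs {psa.mean_comparator_qalys:.3f}")
print(f"  fraction of draws where screening is cost-effective at "
      f"WTP {params.wtp:,.0f}: {psa.fraction_cost_effective():.1%}")

print()
print("acceptability curve (probability screening is preferred):")
for wtp, frac in ps.ceac(psa, [0, 20_000, 40_000, 80_976, 160_000]):
    print(f"  WTP {wtp:>9,.0f} -> {frac:.1%}")
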