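"""Two-step mediation MR: how much of an exposure's effect runs through a
mediator?

The generator's truth: exposure -> mediator b1 = 0.3, mediator -> outcome
b2 = 0.4, direct effect 0.08, so the total effect is 0.2 and the true
mediated proportion is 100*0.12/0.2 = 60%. The pipeline estimates the
three legs by IVW (the mediator's instruments exclude the exposure's, so
the second step is not contaminated by the direct path) and decomposes
the product.
"""

from medimr import MrConfig, SimTruth, run_mediation, simulate_triplet

truth = SimTruth(seed=4)
trip = simulate_triplet(truth)

med = run_mediation(
    [trip.exposure], [trip.mediator], trip.outcome, ld=trip.ld,
    config=MrConfig(n_boot=100, seed=4),
)

[pair] = med.pairs
print(f"true:      b1={truth.b1}  b2={truth.b2}  total={truth.theta_total}  "
      f"MP={truth.mediated_proportion_pct:.1f}%")
print(f"estimated: b1={pair.beta1:.3f}+-{pair.se1:.3f}  "
      f"b2={pair.beta2:.3f}+-{pair.se2:.3f}  total={pair.total:.3f}+-{pair.se_total:.3f}")
print(f"mediated effect  ME = b1*b2 = {pair.me:.4f} +- {pair.se_me:.4f}")
print(f"mediated proportion MP = {pair.mp_pct:.1f}% +- {pair.se_mp_pct:.1f}%")
print(f"direct effect = total - ME = {pair.direct:.4f}")
print(f"meaningful pair (both paths significant): {pair.meaningful}")
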