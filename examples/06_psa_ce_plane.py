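"""Probabilistic sensitivity analysis and the cost-effectiveness plane.

100 Monte Carlo batches: each draws a yearly caseload (uniform 250-400) and
every uncertain parameter from its assigned family (beta for probabilities
and disability weights, gamma for costs), re-evaluates both arms and records
the incremental (cost, DALYs averted) pair. The headline mean ICER is the
ratio of means with a percentile-bootstrap 95% uncertainty interval; the
scatter of draws against the ICER and willingness-to-pay rays is the
cost-effectiveness plane.
"""

from peds_or_cea import CEAModel, ce_plane, run_psa
from peds_or_cea.sensitivity import plot_ce_plane

model = CEAModel.default(seed=0)
res = run_psa(model, n_batches=100, seed=0)

print(f"batches: {len(res.samples)} (failed: {res.n_failed})")
print(f"mean incremental cost: ${res.mean_delta_cost:,.0f}")
print(f"mean DALYs averted:    {res.mean_dalys_averted:,.1f}")
print(f"mean ICER (ratio of means): ${res.mean_icer:,.0f} per DALY averted")
print(f"  95% UI: ${res.ui95[0]:,.0f} - ${res.ui95[1]:,.0f}")
print(f"mean of per-batch ICERs:    ${res.mean_of_sample_icers:,.0f}")
print(f"P(cost-effective at ${res.threshold:,.0f}/DALY): {res.prob_cost_effective:.2f}")

plane = ce_plane(res.samples, res.threshold)
plot_ce_plane(plane, "ce_plane.png")
print("wrote ce_plane.png")
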