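"""Generate a synthetic perioperative registry and summarize it.

The generator reproduces the statistical structure of the hospital's
database: 1,068 operated children over 3.2 years, right-skewed ages
(mean 3.84 y, SD 4.61), ~79% male, ~77% elective, and in-hospital mortality
of 0.2% (elective) vs 6.6% (emergency).
"""

from peds_or_cea import default_registry_params, generate_registry, summarize_registry

params = default_registry_params(seed=7)
records = generate_registry(params)
s = summarize_registry(records, params.months_span)

print(f"cases: {s.n_cases}  ({s.cases_per_month:.1f}/month)")
print(f"age: mean {s.mean_age:.2f} y, SD {s.sd_age:.2f} y")
print(f"male: {s.pct_male:.1f}%   elective: {s.pct_elective:.1f}%")
print(f"in-hospital mortality: {s.mortality_overall:.1f}% overall; "
      + ", ".join(f"{k} {v:.1f}%" for k, v in s.mortality_by_urgency.items()))
print("case mix (%):", {k: round(v, 1) for k, v in s.case_mix_observed.items()})
# Each line should sit near the registry marginals quoted above; deviations
# are binomial sampling noise at n=1,068.
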