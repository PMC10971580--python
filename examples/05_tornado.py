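"""One-way sensitivity analysis (tornado diagram).

Each parameter is swept alone across its plausible range while everything
else stays at base case. The ICER is most sensitive to the comparator's
volume share (how much surgery already happened without the dedicated ORs)
and to the discount rate; the individual cost components barely move it.
"""

from peds_or_cea import CEAModel, default_tornado_specs, tornado
from peds_or_cea.sensitivity import plot_tornado

model = CEAModel.default(seed=0)
entries = tornado(default_tornado_specs(model), model)

base = model.icer_at()
print(f"base-case ICER: ${base:,.0f} per DALY averted\n")
print(f"{'parameter':22s} {'ICER @ low':>10s} {'ICER @ high':>11s} {'span':>8s}")
for e in entries:
    print(f"{e.name:22s} {e.icer_at_low:10,.0f} {e.icer_at_high:11,.0f} {e.span:8,.0f}")

plot_tornado(entries, base, "tornado.png")
print("\nwrote tornado.png")
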