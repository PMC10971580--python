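"""The annual incremental cost ledger of the two-OR installation.

Six components, tagged by payor: annualized durable equipment, shipping and
installation, and administrative overhead (charity); incremental personnel
salaries and perioperative variable costs (Ministry of Health); and family
out-of-pocket spending (patient). The total is ~$177,526/year, of which the
MoH carries $72,980.
"""

from peds_or_cea import default_incremental_ledger

ledger = default_incremental_ledger()
print(ledger.to_frame().to_string(index=False, float_format=lambda v: f"{v:,.0f}"))
print(f"\ntotal: ${ledger.total:,.0f}/year")
for payor, amount in ledger.by_payor.items():
    print(f"  {payor:8s} ${amount:,.0f}  ({100 * amount / ledger.total:.0f}%)")
print(f"installation capital (equipment + shipping): ${ledger.installation_capital:,.0f}")
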