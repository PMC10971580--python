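# peds-or-cea

Cost-effectiveness analysis of installing **two dedicated pediatric
operating rooms** in a national referral hospital in Nigeria, implemented as
a tested, reusable Python pipeline: a two-arm decision-tree model with
discounted DALY outcomes, annualized multi-payor costing, the incremental
cost-effectiveness ratio (ICER) against a willingness-to-pay threshold,
one-way (tornado) sensitivity analysis, and a Monte Carlo probabilistic
sensitivity analysis (PSA) with bootstrap uncertainty intervals.

The package is aimed at health economists and global-surgery researchers
who want to reproduce, stress or adapt this kind of
infrastructure-investment evaluation. Because the underlying perioperative
patient registry is not public, the pipeline ships a **synthetic registry
generator** that reproduces its printed statistical structure (1,068
operated children over 3.2 years; mean age 3.84 y, SD 4.61; 79.2% male;
elective vs emergency in-hospital mortality 0.2% vs 6.6%; ~65% general
pediatric surgery, ~14% congenital anomalies), so every stage runs
end-to-end without any patient data.

## The model

A decision node compares two scenarios for one year of service: the
*standard of care* (226 cases/year operated, the pre-installation volume)
and the *dedicated pediatric OR* scenario (343 cases/year). Each of the 343
demand cases faces a chance node: with probability `pNoOR` it goes untreated
in that scenario and suffers the natural course of the disease; an operated
case dies before discharge with probability `pDBD`, otherwise treatment
succeeds with probability `pST` (with optional residual disability) or fails
back to the natural course.

Health outcomes are disability-adjusted life years. A stream of `L`
remaining life-years (national life expectancy 54 y minus age at surgery)
discounted continuously at rate `r` is worth

```
D(L) = (1 − e^(−rL)) / r        (→ L as r → 0),   r = 3% by default
```

so an untreated case accrues `[p_death + (1 − p_death)·DW] · D(L)` DALYs,
with `DW` the disease's disability weight. Costs take the all-payor
perspective — charity installation capital (annualized equipment, shipping,
overhead), Ministry of Health (incremental personnel, perioperative
variable costs) and patient out-of-pocket spending. The headline statistic
is

```
ICER = (Cost_OR − Cost_SoC) / (DALYs_SoC − DALYs_OR)   [$ per DALY averted]
```

judged against a threshold of half GDP per capita ($1,043). Because the
per-diagnosis natural-history parameters live in a non-public supplement,
the catalog's untreated-burden and residual/failure parameters are
**calibrated** so the two arms reproduce the published annual totals (840
and 302 DALYs); the calibration also reports the implied per-case burdens
(0.880 treated, 5.479 untreated DALYs/case).

## Worked example

```python
from peds_or_cea import CEAModel

model = CEAModel.default(seed=0)   # synthetic registry + calibrated catalog
res = model.base_case()
```

Running `python examples/04_base_case_icer.py` prints:

```
standard_of_care   cost $     117,514  DALYs   840.0  lives saved  21.4
pediatric_or       cost $     295,040  DALYs   302.0  lives saved  32.4

incremental: $177,526 for 538 DALYs averted
ICER: $330 per DALY averted  ($16,044 per life saved)
vs threshold $1,043/DALY: cost_effective
calibrated per-case burdens: treated 0.880, untreated 5.479 DALYs/case
```

Installing and running the two ORs costs ~$177.5k per year and averts 538
DALYs — about $330 per healthy life-year bought, roughly a third of the
cost-effectiveness threshold. The other scripts in `examples/` walk through
each capability: registry generation, per-case DALY arithmetic, the payor
ledger, the tornado diagram, and the PSA with its cost-effectiveness plane.

A full reproducible run (report bundle with JSON/CSV/figures and a Markdown
summary) is also available from the shell:

```
peds-or-cea run --seed 0 --out results/
```

## Layout

- `src/peds_or_cea/registry.py` — synthetic registry: generator, summaries, CSV I/O
- `src/peds_or_cea/burden.py` — discounting, per-case DALYs, catalog calibration
- `src/peds_or_cea/costing.py` — annualization, payor-tagged cost ledger
- `src/peds_or_cea/tree.py` — arm evaluation, ICER, threshold classification
- `src/peds_or_cea/sensitivity.py` — tornado, distribution fitting, PSA, bootstrap, CE plane
- `src/peds_or_cea/model.py`, `config.py`, `report.py`, `cli.py` — assembled model, run configuration, report bundle, CLI
- `docs/methods.md` — modelling assumptions, parameter provenance, limitations
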