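# Methods

## Decision problem and model structure

The package evaluates, over one year of service, whether adding two
dedicated pediatric operating rooms to a referral hospital with an existing
pediatric surgical service is cost-effective compared with the
pre-installation standard of care. The model is a two-arm decision tree
evaluated per patient. Annual demand is the post-installation volume
(343 cases/year); in the comparator arm only a fraction (226/343 ≈ 66%) is
operated and the remainder experiences the natural course of the disease —
in this setting there is no non-surgical alternative for the congenital and
acquired anatomical conditions involved.

Per-case outcomes:

- **Untreated**: death with the diagnosis-specific probability
  `p_death_untreated`, otherwise life at the untreated disability weight
  `dw_untreated`.
- **Treated**: death before discharge with probability `pDBD`; otherwise
  success with probability `pST` — fully cured, or with probability
  `p_residual_after_success` left with a residual burden — or failure,
  which reverts to the natural course. Residual burden follows one of two
  per-diagnosis conventions: `lifelong_disability` (years lived at
  `dw_residual`, the default) or `death_within_year` (full remaining-life
  loss).

Arm evaluation uses the tree's exact expectation by default: each demand
case is treated with probability `volume / demand` (the complement of
`pNoOR`). This is deterministic and equals the exhaustive
probability-weighted leaf sum, which the test suite checks against an
independent leaf-enumeration oracle. Explicit treated-subset semantics
(seeded random draw, or first-come order) are available via
`selection="random" / "by_order"` for experiments where the treated subset
matters.

## DALYs and discounting

Remaining life expectancy is `L = 54 − age` years (national life expectancy
at birth minus age at surgery, computed per record rather than at the
cohort mean). Future healthy years are discounted continuously at annual
rate `r` (default 3%, swept 0–6% in sensitivity analyses):

    D(L) = (1 − e^(−rL)) / r,   D(L) → L as r → 0.

No age weighting is applied, and disability is constant over the remaining
lifetime, so YLL and YLD streams are both disability-weight multiples of
`D(L)`; YLD streams are discounted identically to YLL streams. One DALY
equals one lost year of healthy life.

## Catalog calibration

The per-diagnosis natural-history parameters (untreated death
probabilities, disability weights) come from a supplement that is not
public; the shipped catalog carries placeholder magnitudes in [0.1, 0.6].
Before any headline number is produced, the catalog is calibrated against
the two published annual DALY totals (comparator 840, intervention 302).
The implied per-case burdens have a closed form,

    d_t = 302 / 343 = 0.880,
    d_u = (840 − 226 · d_t) / 117 = 5.479  DALYs/case,

and two scalar factors are then fitted by bracketed root finding on the
registry's case mix and ages: one multiplying every entry's natural-course
parameters until the mean untreated burden equals `d_u`, and one
multiplying the treatment-failure and residual probabilities until the mean
treated burden equals `d_t` (perioperative mortality stays at its observed
value). Because the same evaluator is used for calibration and for arm
evaluation, re-evaluating the arms reproduces the targets to solver
tolerance. Calibration fails loudly when targets would require
probabilities above one, or when the comparator target implies less burden
per untreated than per treated case.

## Costing

All values are 2021 USD; published USD figures are taken as authoritative
(the two underlying GBP→USD conversions imply slightly different factors,
which the source does not reconcile, so no conversion is recomputed).
Durable equipment is annualized straight-line over lifespan without
interest or salvage value; the equipment bundle is carried at its published
annualized total because per-item price sheets are not public. Components
and payors:

| component | payor | annual USD |
|---|---|---|
| durable equipment (annualized) | charity | 57,435 |
| shipping and installation | charity | 30,293 |
| administrative overhead | charity | 7,018 |
| incremental personnel salaries | MoH | 21,943 |
| perioperative variable costs | MoH | 51,037 |
| out-of-pocket | patient | 9,800 |

Per-case variable rates are back-computed from the annual totals over the
117 incremental cases (perioperative 436.21/case, split into
representative disposables/medications/utilities/bed-day components with
the bed-day rate ~$31/day at a 5-day mean stay, the WHO-CHOICE magnitude;
out-of-pocket 83.76/case). The personnel roster carries representative
public-scale salaries with per-case presence weights; a uniform incremental
share is back-computed so the roster reproduces the published aggregate.

The comparator arm carries the per-case variable costs of its own 226
cases and nothing else — this reconstruction is exact: (51,037 + 9,800)
× 226 / 117 = $117,514, the published comparator total, and the same rate
at 343 cases plus the fixed components gives $295,040 ≈ the published
intervention total. The component sum is $177,526 against a published
rounded total of $177,527. The overhead line is grouped under charity in
the payor partition ($94,746) while `installation_capital` reports the
equipment+shipping grouping ($87,728); both published groupings are thus
available.

## One-way sensitivity

Each parameter is set alone to the ends of its plausible range: the
comparator volume fraction over [0, 0.90], the discount rate over
[0, 0.06], perioperative mortality over the elective–emergency span
[0.002, 0.066], and ±20% for life expectancy and the cost components. The
ICER rises monotonically in the comparator volume fraction (the same
installation cost buys fewer incremental cases) and in the discount rate
(future healthy years count for less). With the calibrated defaults the
sweeps give roughly $187–853 (volume share) and $171–538 (discounting)
per DALY averted around the base case of $330; exact endpoint values
depend on the non-public supplementary inputs, so only the directions and
the bracketing of the base case are treated as reproducible.

## Probabilistic sensitivity analysis

100 Monte Carlo batches. Each batch draws a yearly caseload uniform on
[250, 400] and every uncertain parameter from its assigned family:

- beta for probabilities and disability weights (perioperative mortality
  over the empirical [0.002, 0.066] range; ±0.2 absolute, clipped to
  [0, 1], elsewhere),
- gamma for costs (±20% relative range),
- an empirical resampler for the perioperative medication rate, over a
  mean-preserving five-point grid spanning ±20% (no per-case medication
  data exists to resample from),

all moment-matched so the sampling mean equals the calibrated base value
and the variance is `((high − low)/3.92)²` (the range read as a central
95% interval). Infeasible moment combinations raise rather than silently
truncate.

The drawn caseload scales both arms' costs and effects linearly
(`caseload_mode="per_case"`): the tree is a per-patient model, so fixed
annual costs are amortized per case at the base volume of 343 and a
batch's totals are caseload multiples of its per-case expectations. This
makes each batch's ICER independent of the drawn caseload (a property the
tests pin down) and concentrates ICER uncertainty where it belongs, in the
parameter draws. The alternative `"fixed_annual"` mode holds the
installation cost constant while the caseload varies, which pushes the
mean ICER up by roughly 3–4% at the mean caseload of 325.

The headline PSA ICER is the **ratio of means** (mean incremental cost
over mean DALYs averted), the standard summary for decision purposes; the
mean of per-batch ratios is reported alongside and is systematically
higher (Jensen's inequality at ~30% coefficient of variation in per-batch
DALYs averted). Uncertainty intervals are percentile bootstrap: batches
are resampled with replacement 100 times and the summary statistic
recomputed per resample. With the shipped conditions the 100-batch ratio
of means is ≈330 $/DALY with a bootstrap 95% UI about ±25 wide; because
only 100 batches are drawn, the realized mean at any particular seed
scatters around the converged value (≈329.7 at 2,000 batches) with a
standard error near 8 $/DALY. Draws are fully seeded (one seed sequence,
spawned child streams for draws and bootstrap); failed batches are
excluded and counted, never silently retried.

## Synthetic registry

The generator emulates the printed registry structure: case count and span
(1,068 over 38.4 months, or any volume), sex (Bernoulli, 79.2% male),
urgency (Bernoulli; the ~1.5% of cases labelled neither elective nor
emergency are folded into elective, since the model has no third class),
urgency-specific in-hospital mortality (0.2% / 6.6%), an eight-group case
mix (~65% general pediatric, ~14% congenital anomalies, remainder split
over observed service lines), gamma out-of-pocket spending (mean $83.76 =
the annual OOP total over the incremental cases, shape 2), and ages from a
gamma law **moment-matched after truncation** to [0, 18): the truncated
distribution's first two moments are solved numerically so the sampled
mean/SD hit 3.84/4.61 despite the cut at 18 (a naive pre-truncation match
would bias the mean low by ~0.5 y). SD > mean forces a right-skewed law; a
normal cannot produce these moments on a nonnegative support.

What the generator does **not** emulate: within-diagnosis severity
gradients, correlation between age, urgency, diagnosis and mortality
(all margins are drawn independently), seasonal throughput variation, and
the pre/post-installation case-complexity shift. Tests passing on
synthetic registries therefore validate the pipeline's arithmetic and its
statistical contracts, not clinical properties of any real registry.

## Numerical choices and degenerate inputs

- Root finding uses bracketed Brent iterations (`xtol=1e-12`); truncated
  gamma moments use regularized incomplete-gamma identities rather than
  numerical integration.
- Ages are sampled by inverse CDF restricted to the truncation mass, so
  the truncated law is exact, not rejection-approximate.
- ICERs are never rounded internally; presentation rounds to the dollar.
  Negative ICERs are never reported: cheaper-and-more-effective is
  `dominant`, costlier-and-no-better is `dominated`, and a zero-benefit
  denominator yields NaN with a classification rather than a division
  crash. The threshold comparison is strict (`ICER < threshold`).
- Zero-variance PSA draws collapse to the base case exactly; equal arm
  specifications give exactly zero incremental cost and effect.
- `discounted_years` uses `expm1` for small-rate stability and returns `L`
  exactly at `r = 0`.

## Known limitations

- Calibration absorbs whatever is missing from the non-public supplement
  (per-diagnosis disability weights, untreated mortalities, price sheets)
  into two scale factors; the arms' totals are faithful but per-diagnosis
  attributions are not identifiable from published aggregates.
- The published $18,831 per life saved implies ~9.4 lives saved/year; the
  calibrated model yields ~11 lives/year (~$16,000 per life saved). The
  lives-saved count depends on the untreated death probabilities, which
  are exactly the parameters calibration cannot pin down, so this figure
  is reported as a consistency indicator, not a target.
- One-year horizon, no Markov extension, no waiting-list dynamics, no
  indirect costs (transport, lost wages), no preoperative diagnostics, and
  the same case mix before and after installation.
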