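# Methods

## Model structure

`ssbtax` simulates an ad valorem excise on sugar-sweetened beverages (SSBs)
for a closed adult cohort, in four deterministic steps, then propagates
parameter uncertainty around them.

**Step 1 — price.** The excise τ applies to the pre-excise retail price *p*
(default ZMW 3.77 per 300 mL serving). The consumer price rises by
*p·τ·ρ*, with ρ the pass-on rate (default 1.0). The excise base is not
affected by ρ: pass-through changes what consumers pay, not what the tax
authority collects per serving.

**Step 2 — demand.** The relative price change *x = τρ* moves quantities
through a linear (arc) elasticity approximation, Δq = q₀·ε·x, with
ε = −1.30 for SSBs and cross-price elasticities +0.32 (fruit juice) and
+0.18 (milk) applied to the *SSB* price change; juice and milk prices are
unchanged by an SSB-only excise. A constant-elasticity (power) form
q₁ = q₀(1+x)^ε is available behind `elasticities.functional_form`; the
linear form is the default because the modelled price change (25%) is
moderate and the linear form is the convention in this class of tax
simulations. Post-change quantities are floored at zero (binding only in
extreme sensitivity draws); a zero tax or zero pass-on is an exact fixed
point of the whole pipeline.

**Step 3 — energy and BMI.** Weekly serving changes convert to a daily
energy change ΔE = Σ_b Δq_b·E_b/7, with default energy densities per 300 mL
serving of 590 kJ (SSB), 675 kJ (juice) and 810 kJ (milk). These are
calibration constants in the plausible nutritional range (a sugared soft
drink at ~40–50 kcal/100 mL, juice and whole milk somewhat higher per
serving), chosen once so that the default scenario's mean daily energy
reduction lands inside the published interval; they are config values, not
measurements. A sustained ΔE maps to a steady-state weight change
Δkg = ΔE/94 (the 94 kJ/day-per-kg energy-balance rule), applied in full at
cycle 0 and held for the whole horizon — no weight dynamics. Each simulated
individual's BMI then moves by Δkg/height², using individual heights, so the
within-stratum BMI distribution deforms realistically near the obesity
boundary rather than translating as a block of stratum means.

**Step 4 — mortality and revenue.** BMI is classified into eight classes
(<18.5, 18.5–20.9, 21–22.9, 23–24.9, 25–26.9, 27–29.9, 30–34.9, ≥35 kg/m²,
half-open intervals, 30 belonging to the obese side) with all-cause
mortality relative risks (1.16, 1.03, 1.00, 1.00, 1.06, 1.13, 1.13, 1.59).
The potential impact fraction per stratum is the discrete
comparative-risk-assessment formula

    PIF = (Σ_c RR_c P_c − Σ_c RR_c P′_c) / Σ_c RR_c P_c,

computed from the sampled class distributions before (P) and after (P′) the
shift. Intervention mortality is m′ = m(1−PIF), clamped to [0, 1) with any
clamp logged. Sex-stratified closed-cohort life tables run 40 annual
cycles at the stratum PIF held constant (static-shift design, matching the
single applied BMI shift): deaths_t = alive_t·m′, person-years credit
decedents half a year (half-cycle correction, configurable off),
person-years are discounted at 6%/yr. Deaths averted (DA) compare
undiscounted deaths; life-years gained (LYG) compare discounted
person-years. Annual revenue is excise τ·p·Q′ on post-tax servings plus the
VAT change v·Σ_b p_b(Q′_b − Q_b) at v = 0.16 (the statutory VAT rate, not
published with the scenario; therefore revenue checks are interval-based).
The SSB VAT base is the pre-excise price so the excise is not VAT-cascaded
(a cascading option exists); juice and milk enter at their unchanged prices
(ZMW 4.93 and 3.64). Revenue is annualised at the post-tax steady state
over the consumer base: the 13% of adults who consume SSBs at all
(switchable to the total population).

## Synthetic population

The survey microdata behind the scenario are not published, so the baseline
is synthesised from printed summaries and is exact where summaries exist:

- **Counts.** 4,271,631 women and 4,072,855 men (adults 15+), split across
  six age groups by a young-skewed share vector
  (0.35, 0.25, 0.16, 0.11, 0.07, 0.06) typical of a high-fertility age
  pyramid. The within-sex age composition is an assumption; it matters
  mainly through the consumption weighting.
- **Consumption.** Weekly 300 mL servings per stratum are fixed at the
  published sex × age table for all three beverages. The package also
  provides `allocate_consumption` to spread any per-capita mean over strata
  by arbitrary non-negative shares with exact conservation of the
  population-weighted mean.
- **BMI.** Per sex, a two-parameter log-normal exactly identified by the
  published mean BMI (24.3 women, 22.5 men) and obesity prevalence (13.5%,
  3.99%): σ solves σ²/2 − zσ + ln(30/mean) = 0 with z = Φ⁻¹(1−prev) (smaller
  root), μ = ln 30 − zσ. Infeasible targets raise a calibration error that
  reports the achieved moments; a zero prevalence degenerates to a point
  mass. Individuals (default 17,000 per stratum, ≈10⁵ per sex) are drawn
  with per-stratum substreams spawned from the run seed, so samples are
  bit-reproducible. Heights are normal (means 1.59 f / 1.68 m, sd 0.07 m,
  assumptions — not published), truncated to (1.2, 2.2) m.
- **Mortality.** Age-group rates follow a Gompertz curve exp(0.09·age) at
  group midpoints, rescaled so the population-weighted mean annual rate is
  0.0085 (8.5 per 1000, a realistic adult all-cause level for the setting;
  the scenario's published figure of 30.1 per 100,000 is not plausible as
  an adult all-cause average and is treated as a configurable option, not a
  default). Cohorts age annually, adopting the next group's rate at each
  boundary; ages past the last bound keep the 65+ rate. The 65+ group is
  seeded over ages 65–84.

What the generator does **not** emulate: within-stratum consumption
heterogeneity (all individuals in a stratum share the stratum mean, and the
BMI shift is uniform in Δkg within a stratum), age structure within the BMI
distribution (both sexes use one distribution across their age groups,
whereas real BMI peaks in middle age), secular trends in consumption,
income or prices, and any correlation between consumption and BMI. Passing
tests therefore validate the arithmetic and calibration of the model, not
the empirical accuracy of the unpublished microdata.

## Uncertainty propagation

The probabilistic analysis redraws ε_SSB, ε_juice, ε_milk and ρ per
iteration from normal distributions via inverse-CDF sampling (the
spreadsheet NORM.INV idiom), with standard errors derived from published
95% intervals as width/3.92 (ε_SSB: 0.105; juice: 0.194; milk: 0.112;
ρ: 0.102 from the 80–120% range). Parameters without published intervals —
prices, energy densities, heights, mortality — are held fixed. Relative
risks can receive mean-one log-normal multipliers with configurable CV
(default 0). Each of the default 500 draws re-runs the full pipeline
against the *same* baseline BMI sample and baseline life table (common
random numbers), so per-draw DA/LYG are pure parameter contrasts.
Summaries are the arithmetic mean and percentile band, default 5th/95th
(the convention of the modelled study, which is a 90% interval;
2.5/97.5 is available by config). Draws are indexed substreams of the run
seed: any iteration is reproducible in isolation, and (config, seed)
determines every output byte. Deterministic one-way and two-way grids
re-run the pipeline at mean parameters over tax × pass-on values.

## Numerical choices and edge cases

- Probability vectors passed to `pif` must sum to 1 within 1e-6; the
  before/after class histograms come from the same individuals, so the
  null scenario yields PIF = 0 exactly (identical arrays short-circuit).
- m′ is clamped to [0, 1); PIF ≥ 1 is an error.
- BMI draws are clipped to (10, 70) kg/m² (negligible mass at calibrated
  parameters); heights to (1.2, 2.2) m.
- The default microsample (17,000 per stratum) puts a Monte Carlo standard
  error of ≈0.02 pp on the obesity-prevalence change, an order of magnitude
  below the effects of interest; two independent samples agree within
  0.1 pp (tested).
- Problem sizes were chosen for desk-scale work: one deterministic
  evaluation ≈0.1 s, the 500-draw Monte Carlo ≈8 s, the full test suite
  ≈20 s on one CPU.

## Known limitations and model behaviour worth flagging

- **Obesity-prevalence magnitude.** With per-sex two-parameter log-normals
  pinned to the published means and prevalences, the probability density at
  BMI 30 is ≈0.034/unit (women) and ≈0.017/unit (men), so a ≈0.13-unit BMI
  shift moves prevalence by ≈0.31 pp. Empirical BMI distributions with the
  same two moments can carry more mass just below 30 and hence larger
  prevalence responses; the published interval for this outcome (0.41–0.57
  pp) is not reachable from the two printed moments under any two-parameter
  family, and the package reports what its calibrated distribution implies
  rather than tuning extra distributional structure to the outcome.
- **Sign of the male health effect.** Under the printed relative-risk
  schedule, risk is flat (1.00) across 21–24.9, *higher* below 18.5 (1.16)
  and at 18.5–20.9 (1.03) than in the reference band. A population with
  mean BMI 22.5 has most mass where a downward shift is neutral or harmful
  (men: ≈15% below 18.5 at the calibrated log-normal), so the male
  per-capita PIF is slightly negative and male DA/LYG are slightly
  negative; totals across sexes are then small and *decrease* with the tax
  even though female DA/LYG (and revenue) increase monotonically. This is a
  structural property of the RR curve combined with the male BMI moments,
  not a numerical artefact; any unimodal male distribution with those
  moments behaves the same way. The female health gains — the equity
  finding — are robust: female per-capita PIF > 0 > male in all default
  runs, and the female DA percentile band excludes zero.
- **Revenue base.** The excise figure uses the population-weighted
  consumption table (1.745 servings/wk baseline), which is also what makes
  the consumption outcome land on its published value; a flat per-capita
  baseline of 1.55 would lower annual excise by ≈10%. The two published
  figures are not mutually consistent on this point; the package uses one
  self-consistent (weighted) baseline everywhere.
- No cause-specific mortality, morbidity or DALYs; no new cohort entrants;
  no income effects, firm pricing strategy, or behavioural responses beyond
  the constant elasticities.
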