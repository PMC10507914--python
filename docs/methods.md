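# Methods

## Scope and model

The package implements a within-trial economic evaluation of two surgical
strategies (VATS, the evaluated strategy, versus open thoracotomy, the
comparator) at two horizons: 30 days and 3 months after surgery.  Costs are
hospital production costs in 2018 euros; effects are EQ-5D-3L-derived QALYs.
No discounting is applied (horizon < 12 months).  Survival enters only as
binary 30/90-day mortality contrasts; because deaths are rare and not
different between arms, the all-patient cost comparison is labelled a
cost-minimisation analysis (a labelling rule — the computation never gates on
the mortality test).

## Costing

* **Adjusted-DRG method (initial stays).**  All index stays share one surgical
  DRG root; a severity digit 1–4 is added as
  `1 + major complication + re-intervention + prolonged stay`, capped at 4
  (packaged as a rule, not hard-coded).  The stay cost is
  `theatre_cost(arm) + (total − OR)/national_mean_LOS × LOS`, substituting the
  micro-costed theatre costs (VATS €3,870.49, thoracotomy €2,455.58 — the
  Methods-section values; a €3,876.49 variant appears elsewhere in the source
  and is not used) for the catalog's operating-room component.
* **Gross costing (follow-up stays).**  Re-hospitalisations map through a
  reason→DRG rule table and take the catalog total; LOS-prorating by the same
  per-diem rule is available behind a flag (default off, since the source
  describes per-diem weighting only for the index-stay remainder).
  A reason with no rule is an *uncostable stay*: excluded from sums with a
  warning rather than failing the pipeline.  Every rehabilitation admission
  maps to one DRG with flat cost €6,222.20.
* **Windows.**  Day offsets are integers with surgery = day 0; the 30-day
  cumulative cost covers (initial discharge, d30 visit], the 3-month figure
  adds (d30 visit, m3 visit], so m3 ≥ d30 by construction.  Undated visits
  fall back to nominal days 30/91 for window membership.
* **Arithmetic.**  Monetary amounts are exact decimal cents internally;
  rounding to whole euros happens only at reporting, so printed integers are
  reproduced without float drift.
* **Price updating.**  A CPI helper rescales amounts between years with a
  harmonised index (base 100 in 2015).  The bundled series is a synthetic
  stand-in (labelled so in its filename); the surgery defaults are already
  expressed in €2018.
* **Bundled catalog.**  The rehabilitation DRG cost is the published value;
  the surgical and re-hospitalisation catalog entries are synthetic, with the
  level-1 per-diem chosen so that mean initial-stay costs at the configured
  LOS land near €9,200 (thoracotomy) and €10,700 (VATS) — realistic
  magnitudes for this surgery.

## Utilities and QALYs

A tariff is an additive map `u = 1 − c − Σ decrement(dim, level) − n3·[any
level 3]`, anchored at 1 for full health.  The bundled default is the UK
MVH time-trade-off value set (floor −0.594); the trial's own tariff is not
public knowledge, so the tariff is a plain CSV and fully swappable — all
utility-scale results are tariff-dependent calibration targets, not exact
reproduction targets.

The *final QALY* at a horizon is the trapezoidal area under utility versus
day from day 0 to the nominal horizon day (30 or 91), divided by the horizon
length.  This time-weighted-average-utility scale matches the magnitude of
the published per-horizon QALYs (~0.7 at 30 days), which are incompatible
with year-denominated areas (≤ 0.085 over 30 days); a year-scaled variant is
available behind a flag.  The pre-operative observation is anchored at day 0;
beyond the last observation the curve extends flat, and an observation past
the horizon is truncated by linear interpolation.  A missing required
utility makes the outcome incomplete (no value) — completeness drives the
exclusion cascade.

## Complete-case selection

Exclusions are applied in a fixed order, each charged to the first failing
criterion: (i) death before the visit; (ii) visit more than ±14 days from
nominal (the source states the criterion without a tolerance; 14 days is the
package default and configurable); (iii) undated visit; (iv) missing EQ-5D
items.  The 3-month cascade starts from the 30-day included set and adds
deaths between the visits.  The cascade is idempotent on its included set.

## Uncertainty

The non-parametric bootstrap resamples patients with replacement *within each
arm*, preserving the original arm sizes — the standard design-respecting
scheme for a two-arm trial.  Each replicate records the paired mean
differentials.  Replicate r draws from a counter-based Philox substream of
the root seed, so results are independent of execution order and exactly
reproducible.  The ICER interval is the percentile CI of the per-replicate
ratios (undefined ratios at ΔE = 0 are dropped and counted; negative ratios
are kept and ordered numerically — a known caveat of ratio-scale
percentiles).  Quadrant shares classify replicates by the signs of (ΔE, ΔC),
boundary points counting toward the non-negative side.

The acceptability curve defaults to the net-monetary-benefit rule
P(λ·ΔE − ΔC > 0), which orders all quadrants correctly; the literal
ratio-threshold rule (ICER < λ among defined ratios) is provided as an
option because it is how acceptability curves are often captioned, but it
misorders NW/SW replicates.  Both agree when the cloud is entirely NE.
Replicates with ΔE exactly 0 are never acceptable under either rule.  The
default WTP grid is €0–100,000 in €1,000 steps (including the €25,000
reference threshold).

## Multiple imputation

The chained-equation engine is implemented in-repo: continuous cost
components by predictive mean matching (k = 5 donors, type-0 matching on
least-squares predictions), ordinal EQ-5D items by multinomial-logit draws on
{1,2,3} (fitted with scikit-learn on a z-scored design matrix; coarse solver
tolerance, since coefficients only feed a stochastic draw).  Each of the m
imputations is an independent chain: initialisation by resampling observed
values, then a fixed number of cycles (default 10) over the variables in
order of increasing missingness.  Observed cells are asserted unchanged.
Imputed items are rescored to utilities and QALYs rebuilt — utilities are
never imputed directly.  Patients who died or left follow-up are excluded
before imputation.  The predictor set is age, gender, performance status,
smoking status, BMI, all 20 item responses and the three hospital cost
components.  One imputation model serves both horizons.

Pooling: point differentials are arithmetic means across imputations
(Rubin's rule for point estimates), the pooled ICER relates the pooled
differentials, and between/within-imputation variance components are
reported.  The bootstrap default nests *within* imputations (⌈B/m⌉
replicates per completed dataset, pooled replicate cloud for the percentile
CI); re-imputing inside each bootstrap resample is available behind a flag
but is far costlier.  How pooled bootstrap CIs should be formed is a
genuinely open methodological point; the within-imputation default is
standard practice.

## Synthetic trial generator

The generator defines the study conditions the tests and the acceptance run
operate under: 130 patients per arm across 10 centres; 1:1 allocation in
shuffled blocks of 12 stratified by centre (every completed block exactly
balanced; per-centre imbalance ≤ half a block); per-arm/per-timepoint mean
utilities (VATS 0.83/0.66/0.80/0.79, thoracotomy 0.78/0.58/0.74/0.76,
SD 0.25); initial LOS gamma with mean 7.2/SD 3.3 days, rounded up, min 1;
per-window event probabilities (re-hospitalisation 4.58%/8.39% VATS,
3.13%/2.34% thoracotomy; rehabilitation 6.87%/3.82% and 6.25%/0%); 30-day
death ≈ 0.8% per arm, and 2.3% in the later window (the later-window rate is
not published; it was fixed once as "rare, not different"); per-timepoint
missingness 10/17/15/27%; visit jitter SD 4 days with rare grossly-off
(2%) and undated (1%) visits to exercise the exclusion cascade.

Utility trajectories sample a latent normal truncated to the tariff range and
snap to the nearest EQ-5D-3L state (ties → lexicographically smallest).  The
latent mean is calibrated by root-finding so the expected
truncated-and-discretised draw equals the target mean; centring the latent
normal on the target itself would undershoot it by up to ~0.1 near the
ceiling of the scale.  With SD = 0 the latent is the target itself (full
health maps exactly).

What the generator does **not** emulate: within-patient correlation of
missingness across timepoints (deletions are independent per timepoint, so
joint completeness is lower than in real questionnaire data), correlation
between utility trajectories and clinical events, operative detail (duration,
conversion), or any tumour characteristics.  Passing tests therefore
demonstrate correctness of the analysis machinery under the configured
marginal structure, not fidelity of any particular cohort.

A MAR missingness variant (deletion logistic in arm and centred pre-operative
utility; pre-op itself stays MCAR) exercises the imputation stage
non-trivially; the real trial's mechanism is unknown and neither variant
claims fidelity.

## Numerical and reproducibility choices

* One root seed per run; every operation draws from a named substream
  (`SeedSequence((seed, label))`), so datasets are identical across runs and
  independent of call order; bootstrap replicates use Philox counter jumps.
* Two pipeline runs with the same seed write byte-identical `summary.json`
  (floats rounded to 6 decimals at serialisation).
* Problem sizes in the test and acceptance runs: full-size cohorts (n = 260),
  B = 10,000 bootstrap replicates, m = 10 imputations with 10 cycles for the
  pipeline; the 50-seed imputation-recovery experiment uses m = 5 with 3
  cycles per chain, which is ample for a recovery check of the point
  estimate.
* Degenerate inputs: zero-variance groups give p = 1 and a zero-width CI at
  zero difference; ΔE = 0 gives an undefined ICER (quadrant "axis"); empty
  arms, 100%-missing variables and unachievable target means raise errors.

## Known limitations

* The bundled DRG catalog and CPI series are synthetic stand-ins except for
  the published rehabilitation cost; absolute synthetic cost levels are
  calibrated magnitudes, not estimates.
* Percentile-only bootstrap intervals (no Fieller or BCa), as implied by the
  source analysis.
* The ratio-rule CEAC is provided for fidelity but is statistically inferior
  to the NMB rule outside the NE quadrant.
* MICE uses multinomial draws rather than proportional-odds models for the
  ordinal items; at three levels the difference is negligible and the
  multinomial is simpler and faster.
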