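# Methods

This note documents the statistical model implemented by `waitcea`, the
choices made where the design was genuinely open, what the synthetic-data
generator does and does not emulate, and the package's known limitations.

## Design and identification

The package targets a two-arm waitlist RCT: participants are randomized
to immediate access to an app-guided self-management intervention
(n = 89) or delayed access at 3 months (n = 90), and surveyed at months
0, 3, 6 and 9 after randomization on functional disability (mapped to an
HRQoL index in [0, 1]) and health-care consumption (13 TiC-P use items
with mixed 1-month/3-month recall, plus drug consumption).

Randomization identifies the 3-month treatment effect directly. Beyond
that the control arm is itself exposed (from month 3), so later effects
are identified by *chaining*: the assumption is that the intervention's
short-term effects are the same in both arms, so the waitlist arm's mean
at month 6 — which reflects 3 months of exposure — can be corrected by
subtracting the estimated 3-month effect to construct an unexposed
comparator:

```
δ3 = E(3) − W(3)
δ6 = E(6) − [W(6) − δ3]
δ9 = E(9) − [W(9) − δ6]
```

Statistical uncertainty in δ3 propagates into δ6 and δ9 — the chained
estimates are strictly less precise than a parallel-control design would
give. Because the map from arm-by-wave cell means to (δ3, δ6, δ9) is
linear, the covariance propagation is exact (no delta method).

## Estimation

Each of the 16 outcomes (HRQoL, 13 use counts, 2 drug-cost classes) is
regressed on saturated arm×wave indicators. Point estimates are cell
sample means; the joint covariance of all 128 coefficients — across
outcomes as well as cells — is a participant-clustered sandwich (CR1,
scores summed within participant across equations, scaled by G/(G−1)).
Per-outcome observation counts may differ across cells because item-level
missingness is handled before estimation (below). An empty arm-wave cell
for any outcome is an error naming the cell.

The joint null test is a Wald chi-square that all 16 cumulative effects
are simultaneously zero, with degrees of freedom equal to the rank of the
joint covariance (pseudo-inverse with a logged warning if deficient).
With 16 restrictions and ~179 clusters the chi-square reference slightly
over-rejects in simulation (about 8% at the nominal 5% level); an F-type
small-sample reference would shrink this but the chi-square form is kept
for its simplicity and transparency.

### Alternative estimators (sensitivity grid)

- **Difference in differences** — arm means replaced by changes from
  baseline before chaining; removes additive baseline imbalance exactly.
- **Baseline adjustment (ANCOVA)** — each outcome's month-3/6/9 equation
  includes its baseline value; chaining applies to the adjusted arm
  contrasts (δ3 = c3, δ6 = c3 + c6, δ9 = c3 + c6 + c9). Same stacked
  cluster sandwich.
- **Pre-post** — single-arm change from baseline in the intervention
  group; flagged `single_arm` because it assumes no secular trend.

All variants coincide on noiseless, baseline-balanced data (tested).

## Missing data

Three mechanisms are distinguished:

1. **Item-level skips** in responded waves (≈0.55% of item cells): last
   observation carried forward, next observation carried backward at
   baseline. The carry chains across consecutive missing waves (the
   one-step variant is available via `chain=False`). An item missing at
   every responded wave is left absent with a logged warning.
2. **Wave non-response** is handled by the estimator's observed-data cell
   means under a missing-at-random assumption, and stress-tested by:
   complete-case analysis; best/worst-case imputation of missing outcomes
   with the 5th/95th percentile (HRQoL) and 95th/5th percentile (use,
   costs), percentiles pooled across arms and waves within outcome (the
   stratification was an open choice; pooling is the most conservative
   about wave trends and is switchable);
3. **Multiple imputation** by predictive mean matching: per outcome,
   linear prediction from arm, wave and baseline value; each missing cell
   draws uniformly from the k = 5 nearest observed donors by predicted
   value; m = 20 imputations pooled by Rubin's rules (within + (1+1/m)·
   between covariance) at the chained-effect level. m and k follow common
   practice for imputation software defaults; the original analysis did
   not state its values.

## Costing

Unit costs (SEK, 2023 price level) attach to use counts per item;
the main analysis costs only the publicly funded items
{1, 2, 4, 6, 7, 8, 9, 12, 13}; a sensitivity scenario adds the private
items {3, 5, 10, 11}. Inpatient care (item 13) is costed per day.
1-month-recall and 3-month-recall sums are never added directly — they
enter aggregation with different weights. Drug costs are units × price
with a related/unrelated classification carried in the price table, fully
attributed to the payer (no out-of-pocket staircase). Unit costs are
assumed already inflated to the analysis price level; CPI inflation is a
pre-processing step outside the package. The per-user app cost is total
maintenance cost over downloads (24,000/1,976 ≈ SEK 12; upper bound
including development (194,855+24,000)/1,976 ≈ SEK 111).

## Cumulative effects (discounted AUC)

Per-wave effects are aggregated over the 9-month horizon with each wave's
term discounted by (1+r)^(−m/12) at its follow-up month m (r = 0.03/year
by default; annual-step discounting would differ by <1% at this horizon).

- **HRQoL → QALYs**: trapezoid over (0, δ3, δ6, δ9) at months 0/3/6/9,
  i.e. 0.125(δ3+δ6)d3 ... — anchored at zero effect at randomization,
  which randomization guarantees. A `constant` option instead holds each
  quarter at its endpoint effect (0.25·Σ δm·dm); the ramp is the default
  because the effect cannot jump at randomization.
- **3-month-recall outcomes** (items 6–13, drug costs): Σ δm·dm — each
  wave's report covers its preceding quarter.
- **1-month-recall outcomes** (items 1–5): Σ 3·δm·dm — the reported
  month is taken as representative of its quarter. This is the simplest
  convention consistent with treating the two recall windows differently
  and is isolated behind the aggregation layer.

Incremental cost ΔC = Σ(unit cost × count AUC over the costing scope) +
related and unrelated drug-cost AUCs + app cost per user; incremental
effectiveness ΔE = the QALY AUC. Both are linear in the chained effects,
so their joint normal summary (SEs and correlation) is exact given the
sandwich covariance. 95% CIs are normal-theory (±1.96·SE).

## CE plane and value of information

(ΔE, ΔC) is summarized as a bivariate normal — justified asymptotically
because both are linear combinations of regression coefficients. All
downstream quantities are closed-form:

- P(cost-effective at λ) = Φ(μ_NB/σ_NB), μ_NB = λΔE − ΔC,
  σ_NB² = λ²se_e² + se_c² − 2λρ·se_e·se_c. A degenerate σ_NB returns the
  indicator of the sign of μ_NB (0.5 at a tie, for continuity).
- P(dominance) = P(ΔE>0, ΔC<0), a bivariate-normal orthant probability
  evaluated on standardized margins.
- EVPI per user = σ_NB·L(|μ_NB|/σ_NB), L(z) = φ(z) − z(1 − Φ(z)),
  assuming the current decision maximizes expected net benefit.
- EVPPI on one component X uses the linearity of E[NB | X]: slope
  s = λ − ρ·se_c/se_e (effect) or λρ·se_e/se_c − 1 (cost); value
  |s|·sd(X)·L(|μ_NB|/(|s|·sd(X))).
- Population totals multiply by Σ_{t=1..H} users/(1+r)^t (end-of-year
  cohorts; H = 5 years, 988 users/year by default). End-of-year timing
  was chosen because it reproduces the break-even development figure
  implied by the reported inputs; start-of-year timing is available via
  `timing="start"`.
- The break-even one-off development cost is μ_NB × discounted users.

When reconstructing from published summaries the effect-cost correlation
ρ is not reported; ρ = 0 is the documented default. The reconstruction
then gives a 92.7% probability of cost-effectiveness at SEK 500,000/QALY
(reported: 92%) and an acceptability curve moving from 91.8% to 92.7%
over λ ∈ [1, 10⁶]; a modest negative correlation (ρ ≈ −0.09 to −0.15)
reproduces the reported 92% exactly, flattens the curve to within half a
point, and brings the total EVPI to the reported SEK 5.4 million
(ρ = 0 gives 5.0 million). The rho-sweep acceptance test quantifies this.

## Synthetic-trial generator

The generator emulates the study conditions so the whole pipeline is
testable without microdata:

- **Allocation and waves**: 89/90 split, waves 0/3/6/9, waitlist exposure
  at month 3 (an unexposed-control mode exists for estimator validation).
- **HRQoL**: participant random effect (SD 0.070) plus within-wave noise
  (SD 0.053) around mean 0.564, clipped to [0, 1] — matching the baseline
  mean and total SD (≈0.088) of the trial sample; additive treatment
  effects per months-after-exposure.
- **Use counts**: hurdle models — probit any-use with participant
  heterogeneity (probit SD 0.7, marginal any-use probability calibrated
  to the baseline table, e.g. 33.5% for GP visits) times a shifted
  negative binomial positive part. The positive-part means and
  dispersions are calibration choices: the baseline table reports only
  any-use proportions and heavy-tailed cost summaries. Treatment effects
  on counts are multiplicative, implemented by binomial thinning
  (factor < 1) or Poisson superposition (factor > 1) so the expected
  count scales exactly — this is what makes injected cost effects exactly
  recoverable in parameter-recovery tests.
- **Drugs**: per-class Bernoulli use with lognormal positive costs,
  priced at 1 SEK/unit so simulated units read as SEK.
- **Non-response**: deterministic response-pattern allocation hits the
  per-wave counts 179/149/134/118 exactly *and* the 104 all-wave
  responders — the real response pattern was not monotone (fewer complete
  cases than month-9 responders), so intermittent patterns are introduced
  greedily only as needed. A strictly monotone-dropout mode
  (`complete_case_target=None`) is available.
- **Item missingness**: independent at 0.55% per item cell in responded
  waves.
- Default treatment effects are zero, consistent with the jointly
  non-significant trial result; effect-injection helpers compute the
  per-wave shifts that produce requested cumulative (ΔE, ΔC).

What the generator does **not** emulate: the disability-instrument item
stage (HRQoL is generated directly on the index scale because the
published mapping function is external), outcome-dependent dropout
(non-response is assigned at random given the pattern counts), serial
correlation in counts beyond the participant random effect, seasonal or
secular trends, and real unit-cost or drug-price levels (the bundled
tables are synthetic). Passing tests therefore demonstrate the
correctness and calibration of the *procedures* under these conditions,
not the clinical or economic conclusions for any real dataset.

## Numerical conventions

- Seeds: everything stochastic flows from one integer seed via
  numpy `default_rng`/`SeedSequence`; identical seeds give byte-identical
  datasets and outputs.
- Sandwich covariance uses pinv for the bread (saturated designs are
  never singular when no cell is empty); ties in PMM donor ranking break
  by stable sort order.
- Percentile imputation uses linear-interpolation percentiles.
- CSV round-trips write %.17g floats and read with round-trip parsing.
- Simulation sizes in tests: calibration checks use 200 replicate trials
  (recovery/coverage) and 500 (null rejection rate) at the study's own
  N = 179, and Monte-Carlo oracles use 10⁶ draws (nested 2,000×4,000 for
  partial information), chosen to make Monte-Carlo error small relative
  to the tolerances being checked.

## Limitations

- The chaining identification leans on equal short-term effects across
  arms; the package propagates — but cannot remove — the resulting
  precision loss at 6 and 9 months.
- Normal-theory CIs and the bivariate-normal plane are asymptotic; with
  N = 179 and heavy-tailed costs the joint Wald test over-rejects
  slightly (documented above) and cost CIs can be optimistic.
- EVPI/EVPPI capture statistical uncertainty only, conditional on the
  model, costing tables and population assumptions.
- An incremental cost-effectiveness ratio is deliberately not reported:
  under dominance its sign is uninformative; the plane probabilities and
  net-benefit quantities carry the decision-relevant content.
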