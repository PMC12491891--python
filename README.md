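# waitcea

Trial-based cost-effectiveness and value-of-information analysis for
**waitlist randomized trials**, built around the economic evaluation of an
app-guided self-management intervention for posttraumatic stress from a
Swedish public health-care perspective.

In a waitlist design the control arm receives the intervention after a
delay, so beyond the randomized horizon there is no unexposed comparator.
`waitcea` implements the full analysis chain for this setting:

1. **Waitlist chaining.** With E(m)/W(m) the intervention/waitlist arm
   means at follow-up month m (waitlist exposed at month 3):

   ```
   δ3 = E(3) − W(3)
   δ6 = E(6) − [W(6) − δ3]
   δ9 = E(9) − [W(9) − δ6]
   ```

   Effects are estimated per outcome (HRQoL index, 13 TiC-P
   health-care-use counts, 2 drug-cost classes) from a saturated
   arm-by-wave cell-means system, all outcomes jointly, with a
   participant-clustered sandwich covariance. The chained effects are
   exactly linear in cell means, so covariance propagation is exact.
2. **Discounted AUC aggregation.** QALYs from a trapezoid of the HRQoL
   effects anchored at zero at randomization; counts/costs summed per
   wave (×3 for 1-month-recall items, whose reported month proxies its
   quarter), each wave discounted at 3%/year. Costs apply unit costs to
   publicly funded items plus drug costs plus the per-user app cost.
3. **CE plane.** (ΔE, ΔC) as a bivariate normal. The probability of
   cost-effectiveness at threshold λ is Φ(μ_NB/σ_NB) with
   NB = λ·ΔE − ΔC; the probability of dominance is an orthant
   probability — no Monte-Carlo needed.
4. **Value of information.** EVPI per user = σ_NB·L(|μ_NB|/σ_NB) with the
   unit normal loss integral L(z) = φ(z) − z(1 − Φ(z)); EVPPI per
   component via the conditional-linear slope; totals scale by the
   discounted user population (988/year, 5 years, 3%).
5. **Sensitivity grid.** Difference-in-differences, baseline adjustment,
   single-arm pre-post, complete cases, best/worst-case percentile
   attrition imputation, multiple imputation by predictive mean matching,
   private-care costing, more users, higher app cost.

A fully parameterized synthetic-trial generator (`synthetic_trial`)
reproduces the study's structure — 89/90 allocation, 179/149/134/118
responses per wave with 104 all-wave responders, zero-heavy skewed use
counts, 0.55% item-level missingness — so every stage is testable without
any microdata.

## Worked example

Published trial summaries can be fed directly to the CEA/VOI layers
("summaries mode") — here the reported incremental effectiveness
0.0065 QALYs (95% CI −0.0219 to 0.0349) and incremental cost SEK −46,359
(95% CI −111,696 to 18,977) per user:

```python
import waitcea as w

inc = w.IncrementalResult.from_confidence_intervals(
    0.0065, (-0.0219, 0.0349), -46_359.0, (-111_696.0, 18_977.0)
)
pop = w.PopulationModel()  # 988 users/year, 5 years, 3% discount
print(f"P(cost-effective at SEK 500k/QALY) = {w.prob_cost_effective(inc, 5e5):.3f}")
print(f"P(dominant)                       = {w.prob_dominant(inc):.3f}")
print(f"EVPI per user                     = SEK {w.evpi_per_user(inc, 5e5):,.0f}")
print(f"Total EVPI                        = SEK {w.evpi_per_user(inc, 5e5)*w.discounted_users(pop):,.0f}")
print(f"Break-even development cost       = SEK {w.breakeven_dev_cost(inc, 5e5, pop)/1e6:,.1f} million")
```

prints

```
P(cost-effective at SEK 500k/QALY) = 0.927
P(dominant)                       = 0.618
EVPI per user                     = SEK 1,109
Total EVPI                        = SEK 5,017,194
Break-even development cost       = SEK 224.5 million
```

So under this reconstruction (zero effect-cost correlation) the
intervention has a 93% probability of being cost-effective at the
base-case threshold, a 62% probability of both gaining QALYs and saving
costs, and adoption would remain worthwhile up to a one-off development
cost of about SEK 224 million. The expected value of removing all
decision uncertainty for the 5-year user population is about SEK 5
million — an upper bound on what further research could be worth.

The full simulated pipeline runs from a YAML config:

```bash
waitcea run --config examples/demo.yaml --out out/
```

producing `table1.csv` (baseline summary), `table2.csv` (cumulative
effects with CIs), `table3.csv` (sensitivity grid), `ceac.csv`, `voi.csv`
and SVG figures (CE plane with 90/50/10% ellipses, acceptability curve,
EVPI/EVPPI curves), all deterministic given the seed. Subcommands
`simulate`, `cost`, `estimate`, `cea`, `voi` and `scenarios` expose the
individual stages.

## File formats

- `trial.csv` — one row per participant-wave: `participant_id`, `arm`
  (`intervention`/`waitlist`), `wave` (0/3/6/9 months), `responded`,
  `hrqol` (index in [0, 1]), `item_1`…`item_13` (use counts; items 1–5
  past month, items 6–13 past 3 months, item 13 = inpatient days).
  Missing outcomes are empty fields, never sentinel zeros.
- `drugs.csv` — `participant_id`, `wave`, `drug_code`, `units` consumed
  in the past 3 months.
- `unit_costs.csv` — `item`, `sek_per_unit`, `funding`
  (`public`/`private`), `recall` (`1mo`/`3mo`). The bundled defaults are
  synthetic calibration values; swap in a real cost-per-patient table for
  applied work.
- `drug_prices.csv` — `drug_code`, `sek_per_unit`, `drug_class`
  (`related`/`unrelated` to the indication).

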