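# dcepref

Discrete-choice conjoint analysis of patient preferences for
gadolinium-based contrast media (GBCM), built for researchers running
stated-preference studies in radiology and health economics.

Patients undergoing contrast-enhanced MRI trade off five product
attributes: cancer detection sensitivity (80–95%), intracranial gadolinium
retention (1–100 molecules per 100M administered), severe allergic-like
reaction rate (1–19/100k), mild reaction rate (10–1000/100k), and
out-of-pocket cost ($25–$100). `dcepref` covers the full analysis chain:

- **Design**: balanced, near-orthogonal paired choice sets
  (`generate_design`, `diagnose_design`).
- **Estimation**: hierarchical Bayes multinomial logit,
  P(a|t,i) = exp(x'β_i)/Σ exp(x'β_b) with β_i ~ N(α, Σ), fit by
  Metropolis-within-Gibbs (`HierarchicalBayesMNL`, an sklearn-style
  estimator), yielding zero-centered per-respondent part-worth utilities.
- **Importance**: per respondent, importance_a = 100 · range_a / Σ_b range_b,
  with t-interval summaries and univariable subgroup regressions
  (`importance_per_respondent`, `summarize_importance`,
  `subgroup_regression`, `sample_size_for_ci`).
- **Market simulation**: logit share-of-preference, first choice, and
  randomized first choice over arbitrary product profiles, with
  linear/log-axis interpolation between design levels
  (`share_of_preference`, `run_scenarios`).
- **Synthetic respondents** with known ground truth for validation
  (`default_population_spec`, `sample_population`, `simulate_choices`).

See `docs/methods.md` for the model, priors, calibration, and limitations.

## Worked example

```python
import dcepref as d

# simulate a study: 50 respondents, 15 paired tasks each
spec = d.default_population_spec(n_respondents=50, seed=3)
truth = d.sample_population(spec)
designs = d.personalized_designs(list(spec.attribute_space), 50, base_seed=3)
responses = d.simulate_choices(truth, designs, scale=1.0, seed=4)

# fit the hierarchical Bayes MNL (short chain for the example)
model = d.HierarchicalBayesMNL(n_iterations=5000, random_state=0)
model.fit(responses, list(spec.attribute_space))

table = d.importance_per_respondent(model.partworths_)
print(d.summarize_importance(table).round(1))
```

```
                 mean  ci_low  ci_high   n
sensitivity      40.9    39.7     42.0  50
retention        11.7    10.3     13.0  50
severe_reaction  14.4    13.1     15.7  50
mild_reaction    20.4    19.4     21.5  50
cost             12.7    11.8     13.5  50
```

Sensitivity dominates (~41% of decision weight), the reaction rates
follow, and retention and cost matter least — close to the generating
population's analytic importances (44.1 / 11.5 / 17.2 / 19.6 / 7.5); the
short 5,000-iteration chain and the small panel inflate the weakest
attributes a little (cost reads 12.7 vs a true 7.5). Shares for a
three-product market:

```python
res = d.run_scenarios(model.partworths_, list(spec.attribute_space))[0]
print({p: round(s, 1) for p, s in res.overall.items()})
```

```
{'Existing product A': 6.4, 'Existing product B': 22.4, 'Existing product C': 71.2}
```

Product C (high sensitivity, lowest retention, mid cost) captures most of
the preference share; A loses on sensitivity, B on cost and reaction rates.

The same steps are available from the shell:

```bash
dce simulate-data --n 50 --seed 3 --out resp.csv --covariates-out cov.csv
dce fit --responses resp.csv --iters 5000 --seed 0 --out utilities.csv
dce importance --utilities utilities.csv --out report/
dce simulate-market --utilities utilities.csv --out shares.csv
dce run --out full_run  # end-to-end pipeline with manifest
```

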