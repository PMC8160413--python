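# Methods

## Problem and model

`dcepref` analyses discrete-choice (choice-based conjoint) data on
gadolinium-based contrast media (GBCM): respondents repeatedly choose
between two hypothetical contrast agents described by five attributes —
cancer detection sensitivity (80–95%), intracranial gadolinium retention
(1–100 molecules per 100 million administered), severe allergic-like
reaction rate (1–19 per 100k), mild reaction rate (10–1000 per 100k), and
out-of-pocket cost ($25–$100). Choices are modeled with random-utility
theory: alternative *a* in task *t* is chosen by respondent *i* with
probability

    P(a | t, i) = exp(x_ta' β_i) / Σ_b exp(x_tb' β_i),

where *x* is the effects-coded attribute profile and β_i the respondent's
part-worth vector. Individual vectors follow a population multivariate
normal, β_i ~ N(α, Σ), with a diffuse normal prior on α (precision 0.01·I)
and an inverse-Wishart prior on Σ (df = p + 5, scale I, p = number of coded
parameters). These priors are standard weakly-informative defaults for
hierarchical-Bayes conjoint; the commercial packages used in applied work
do not publish theirs, so no draw-level equivalence is claimed.

Estimation is Metropolis-within-Gibbs: conjugate draws for α and Σ, and a
random-walk Metropolis step for each β_i with proposal covariance
proportional to the current Σ. Per-respondent step sizes adapt every 100
burn-in sweeps toward an acceptance rate of ~0.3 (multiplicative update,
clipped; adaptation stops at burn-in end so the retained chain is a valid
Markov chain). Defaults: 50,000 iterations, 25,000 burn-in, thinning 10 —
all configurable. The sampler is vectorised across respondents, so a sweep
costs a few dense linear-algebra calls regardless of panel size; 20,000
iterations for 200 respondents × 15 paired tasks run in about half a
minute on one CPU, which is the problem size used throughout the test
suite and the acceptance script.

Point estimates are posterior means of β_i, expanded from effects coding to
one utility per level and re-centered within attribute to sum to zero
exactly (the zero-centering convention: positive part-worths raise
selection probability). Confidence intervals for mean utilities and
importances are t-intervals across respondents; posterior draws are
retained so credible intervals can be formed instead.

## Attribute importance and subgroup contrasts

For each respondent, an attribute's importance is the range of their
part-worth utilities for that attribute divided by the sum of ranges over
all attributes, ×100; importances sum to 100 per respondent by
construction and are invariant to rescaling a respondent's utilities.
Subgroup differences are univariable OLS of importance on one covariate; a
binary contrast's coefficient equals the group mean difference. Following
the convention of a stricter secondary alpha, subgroup intervals default
to 99% and significance to p < 0.01 (both configurable). The sample-size
helper inverts the normal-theory CI: n = ceil((z·sd/half-width)²); with
sd = 66 it returns 168 at half-width 10 and 670 at half-width 5.

## Choice-design generation

Designs aim at level balance, near-orthogonality, and minimal within-task
level overlap. The generator starts from balanced shuffled level columns
(each level's count deviates from uniform by at most one) and greedily
accepts within-column slot swaps that lower a weighted score: duplicate
alternatives (weight 1000), within-task overlap (10), and the L1 deviation
of pairwise level co-occurrence counts from uniform (1). Swaps within a
column preserve level counts, so balance is never lost; a repair pass
guarantees no task shows two identical alternatives and an infeasibility
error is raised when the level space cannot hold the requested number of
distinct alternatives. Full-profile (all five attributes per task) is the
default; partial profiles are supported by cycling attribute subsets
across tasks. Per-respondent survey versions are approximated by
independently seeded designs.

## Market simulator

A product profile fixes one numeric value per attribute. Utilities at
arbitrary values are piecewise-linear interpolations between adjacent level
utilities on the attribute's axis — raw values for sensitivity and cost,
log10 for retention and the two reaction rates, which span one to three
orders of magnitude (a linear metric there would let a 0.1→100 retention
change dwarf everything else). Values outside the level range are linearly
extrapolated from the two boundary levels on the same axis; several
simulation products (retention 0.2 and 0.1, sensitivity 78) need this.
Both choices are config-switchable for sensitivity analysis.

Shares are computed three ways: `logit` share of preference (exponentiated
total product utility normalised to 100% per respondent, averaged —
the formula the applied literature describes), `first_choice` (argmax
indicator), and `rfc` (randomized first choice: first choices tallied over
Monte-Carlo Gumbel perturbations of product utilities; converges to
`first_choice` as the noise scale shrinks). `logit` is the default because
it is the formula actually written down in the applied description; RFC is
provided because it is the method usually named.

## Synthetic population

The generator emulates the data-generating process the model assumes:
per-respondent part-worths = subgroup mean + iid N(0, cell_sd²) per level
cell, re-centered per attribute (diagonal population covariance,
cell_sd = 0.25 by default); MNL choices at consistency `scale` (default 1;
0 gives uniform choices, large values argmax). Population means are linear
in level rank, monotone in each attribute's preferred direction, with
ranges set from base importance proportions (0.460, 0.062, 0.114, 0.170,
0.194) for (sensitivity, cost, retention, severe, mild) and a total
utility range of 6.0 — a consistency level at which paired choices are
informative but stochastic. A low-income subgroup (household income
< $50k, 13% prevalence mirroring published screening-cohort marginals)
has its cost range multiplied by 2.4 and sensitivity range by 0.62.
Mixing these profiles analytically gives expected importances of about
44.1 / 7.5 / 11.5 / 17.2 / 19.6 percent with the ordering
sensitivity > mild > severe > retention > cost, matching the magnitudes
and ordering reported for real screening populations, and an injected
low-vs-high-income contrast of roughly +6 points on cost and −13 on
sensitivity importance. `analytic_importances` computes this expectation
exactly for the noiseless population; with the default spread it is
accurate to well under a point at n = 2,000.

What the generator does **not** emulate: adaptive (utility-balance)
questioning, non-response and attention failures, correlated population
covariance structure, non-monotone or interaction preferences, and scale
heterogeneity across respondents. Passing recovery tests therefore show
the estimator and metrics are correct under the model's own assumptions,
not that real respondents satisfy them.

## Numerical choices and degenerate inputs

Log-sum-exp is used everywhere probabilities are formed, so huge utilities
do not overflow. Respondents whose utility ranges are all zero have
undefined importances and are dropped with a warning. Respondents with
fewer completed tasks than the configurable minimum (default: all tasks
observed) are excluded before fitting, mirroring complete-case analysis;
a permissive mode admits prior-only fits with no tasks. Interpolation at a
design level returns that level's utility exactly; log-scale interpolation
rejects non-positive values. RFC requires an explicit seed; all other
stochastic components are seeded through configuration, and identical
inputs plus seed reproduce byte-identical outputs.

## Known limitations

- Posterior-mean part-worths are shrunk toward the population mean, so
  subgroup importance contrasts estimated from a fitted model are
  attenuated relative to the generating truth (most visibly for weak
  attributes such as cost). Covariate-aware upper-level priors, which
  would remove this, are out of scope; subgroup power is therefore
  assessed on ground-truth importances.
- Noise in individual estimates inflates the estimated utility ranges of
  unimportant attributes slightly (cost importance reads ~1–2 points high
  at 15 tasks per respondent).
- The design search is greedy with a fixed budget; it reliably achieves
  balance ≤ 1 and zero overlap at the default 15×2×5 size but makes no
  optimality claim (Bayesian D-optimal search is a non-goal).
- Exact reproduction of published share tables would require the original
  per-respondent utilities and the exact interpolation/RFC conventions of
  the commercial simulator, neither of which is public; the workbook
  reader (`read_supplementary_utilities`) exists so such utilities can be
  loaded if available.
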