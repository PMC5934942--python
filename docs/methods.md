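# Methods

## Scope and data model

The package analyses *sister pairs*: two languages forming a two-tip
clade (cherry) on a dated phylogeny.  Inputs are (a) cognate-coded
basic-vocabulary wordlists, read either from long-format tables
(language, concept, cognate class, loan flag, status flag) or from binary
NEXUS presence/absence matrices with `concept_class` character labels;
(b) a Newick tree with node supports; (c) per-language metadata (speaker
population "in area", creole/extinct flags).  Cognate-class identifiers
are scoped per concept: the same label under two concepts denotes two
unrelated classes, and a class that recurs under two concepts (semantic
shift) is treated as two independent classes.

Exclusion rules, applied at ingestion: loan words and forms flagged
`doubtful`/`exclude` are dropped (unknown status values are an error —
fail loud rather than silently discard).  A (language, concept) cell is
*attested* if the source recorded any form there (even one that the
exclusion rules then dropped) or carries an explicit empty-marker row;
cells with no rows at all are missing data.  Classes whose concept is
unattested in either pair member are excluded from the informative tally
but kept in the comparison denominator, since a bare absence cannot be
distinguished from a gap in the database.

## Counting

For each cognate class of each concept, presence in member 1, member 2,
and anywhere else in the family determines its label (gain/loss localized
to one member, non-informative, or excluded); see `rate_counter`.  The
classification is total: every class of every concept receives exactly
one label, and the six tallies always sum to the number of comparisons.
"Elsewhere" means any language of the same family matrix after
exclusions, including members of other analysis pairs.  Standardized
rates divide each tally by the total comparisons.

## Poisson rate engine

Counts are modelled per pair as X_ji ~ Poisson(mu_j * N_ji^beta), i = 1,2.
The pair-level nuisance mu_j (divergence time x data quantity x baseline
rate) is eliminated by conditioning on the pair total:
X_j1 | (X_j1 + X_j2 = n_j) ~ Binomial(n_j, p_j) with
p_j = N_j1^beta / (N_j1^beta + N_j2^beta), computed in log space.  The
conditional likelihood depends only on beta and the population ratios, so
the fit is invariant to rescaling all populations, needs no divergence
dates, and treats each pair as one independent comparison.  Pairs with
zero totals contribute nothing but are retained in n.

Estimation: 1-D bounded maximization of the conditional log-likelihood
(beta in [-5, 5], tolerance 1e-10; `scipy.optimize.minimize_scalar`,
deterministic).  Test: likelihood-ratio statistic 2*(lnL(beta_hat) -
lnL(0)) against chi-square with 1 df; the conditional LRT is identical to
the LRT of the full Poisson model with per-pair nuisance rates profiled.
Standard error: Wald, from a central-difference observed information of
the conditional likelihood.  Note that a posterior standard deviation
from a Bayesian fit of the same model can be substantially larger than
this profile-likelihood SE; the SE column is the least comparable
quantity across implementations of this model, and the LRT and exponent
are the quantities to compare.

Pseudo-R^2 (default `r2_method="deviance"`): 1 - D(beta_hat)/D(0), where
D is the deviance of the full Poisson model against the saturated model,
with mu_j at its conditional MLE (fitted member means split the pair
total as n_j * p_j).  This measures the share of count deviance explained
by the population effect.  A McFadden variant on the conditional
likelihood (1 - lnL_full/lnL_null, binomial coefficients included) is
available; it is systematically smaller because the conditional
likelihood carries the combinatorial constants.

## Contrast engine and the Welch & Waxman filter

Contrasts per pair: d = (c1 - c2) / ((c1 + c2)/2) / sqrt(t) and
x = (ln N1 - ln N2) / sqrt(t), natural logs, t the height of the pair's
ancestral node.  Dividing by the mean count standardizes for data
quantity; dividing by sqrt(t) standardizes for divergence time, because
the variance of a count difference grows linearly in t under Poisson
accumulation.  Both contrasts use the orientation in which the pair is
supplied, applied uniformly to d and x; flipping all pairs' orientation
together leaves the slope inference unchanged.  The packaged family
tables are analysed in their published row order.

Undefined contrasts (t = 0 or c1 + c2 = 0) are flagged and removed before
filtering.  The Welch & Waxman filter then iterates: regress |d| on
sqrt(t) by OLS; while the slope is negative and significantly so
(one-sided p < 0.05), remove the pair with the smallest t (ties broken by
input order) and refit.  The rationale: if shallow pairs were as reliable
as deep ones, |d| would be flat in sqrt(t); a significant negative trend
marks the shallow end as noise-dominated.  The strict variant that
iterates while the slope is merely negative (`rule="slope"`) is available
but not the default: because |d| is mechanically bounded by 2/sqrt(t),
the point estimate of the slope is almost always negative in finite
samples and the strict rule strips most of the data.  At least three
pairs must survive or the filter errors out.

After filtering, d is regressed on x by OLS with an intercept
(statsmodels).  Reported: slope, its SE, the slope F statistic
(= t-squared), its p-value, and adjusted R^2 (which is negative when the
predictor explains less than one parameter's worth of variance — small-n
null results routinely produce this).

## Synthetic families

`synthetic_data.simulate_family` generates data under exactly the
assumptions the counting rules and the Poisson engine make, so end-to-end
recovery is a sharp test of the implementation rather than of model
misspecification:

* Each pair j has branch length t_j ~ Uniform(bl_range) and member
  populations drawn log-uniformly over `pop_log_range` (default
  10^2..10^7 persons, the span between the smallest and largest speech
  communities in the packaged tables).
* Each pair carries a private ancestral inventory: per concept,
  Poisson(`ancestral_classes_per_concept`) classes.  Each member loses
  each ancestral class independently with probability
  1 - exp(-a_loss * (N/N0)^beta_loss * t_j), and gains
  Poisson(a_gain * (N/N0)^beta_gain * t_j) brand-new family-unique
  classes assigned to random concepts.  N0 is the geometric centre of the
  population range; anchoring rates there is a pure reparameterization
  (the estimators are population-scale invariant) that keeps count
  magnitudes comparable across beta values.
* Each ancestral class is attested in one random outgroup language with
  probability `outgroup_retention`; a lost class attested nowhere else is
  invisible as a loss, and the surviving member's copy then (correctly,
  per the counting rules) looks like a gain.

Defaults (n_pairs=80, n_outgroups=5, n_concepts=210,
ancestral_classes_per_concept=1.0, a_gain=0.05, a_loss=1.5e-4,
bl_range=(50, 2000), outgroup_retention=0.9) are sized to the
Austronesian dataset: a 210-item wordlist, roughly one cognate class per
concept per language, and per-language gain/loss counts in the tens.

What the generator does *not* emulate: borrowing and contact, parallel
gains, loss of recently gained classes on the same branch, founder
effects, population growth, shared ancestral vocabulary across pairs
(outgroups stand in for the rest of the family), and missing data.
Passing recovery tests therefore demonstrates the correctness of the
counting and estimation machinery under the model's own assumptions, not
robustness to the realities of lexical databases.

`SimTruth` distinguishes all generated loss events from *detectable*
losses (sister retains the class — the only ones any sister-pair
comparison can in principle see) and *recognizable* losses (additionally
attested outside the pair).  With outgroup_retention=1 the pipeline's
counts equal the detectable truth exactly, integer for integer; this is
asserted on multiple seeds in the test suite.

`recovery_experiment` repeats simulate -> count -> fit and reports the
estimate distribution and rejection rates.  With the default design the
Poisson likelihood-ratio test's type-I error at alpha=0.05 sits inside
[0.02, 0.09] over 200 null replicates, and the median estimated exponent
is within 0.05 of the truth for beta in {-0.3, 0, 0.3} (200 replicates;
problem sizes chosen so the full suite runs in minutes on one CPU).

## Numerical and design choices

* Node supports: unannotated internal nodes count as fully supported
  (published summary trees fix their topology); supports > 1 are read as
  percentages.
* Non-ultrametric cherries: pair branch length is the mean of the two
  tip-to-ancestor paths, with a warning.  The packaged tables carry their
  published branch lengths verbatim.
* Fixture integrity: the three family tables are SHA-256 pinned; any edit
  raises before analysis.
* Degenerate inputs fail loudly: all-zero counts, fewer than two
  informative pairs, constant population contrasts, fewer than three
  pairs after filtering, non-positive populations.
* The Welch & Waxman stopping rule (significance, one-sided alpha=0.05)
  and the deviance pseudo-R^2 are the package defaults because they are
  the operationalizations that exactly reproduce the published per-family
  regression tables recomputed from the packaged fixtures; both
  alternatives remain available as options.

## Known limitations

* The counting method conflates semantic shift with gain/loss and cannot
  see losses of classes unattested elsewhere in the family; datasets
  coded with a single variant per concept (Swadesh-style) understate
  losses and may record frequency shifts as gains.
* Speaker census counts are a noisy proxy for the linguistically relevant
  community size, and current populations are applied to changes that
  accumulated over centuries.
* The Poisson engine assumes a constant population-size ratio over the
  pair's history and no founder effects; the contrast engine loses power
  quickly below ~15 pairs.
* With very asymmetric data quantities between members the
  equal-denominator standardization is only approximate.
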