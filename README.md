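# sisterates

Do languages with more speakers gain and lose words faster?  `sisterates`
is a toolkit for answering that question with the sister-pairs
comparative method: it counts gains and losses of cognate classes in the
basic vocabulary of pairs of closely related languages, and regresses
those rates on speaker population size with two complementary engines —
a phylogenetically controlled Poisson rate regression and a
Welch & Waxman–filtered standardized-contrast regression.  It is aimed at
quantitative historical linguists and cultural-evolution researchers
working with cognate-coded wordlists (ABVD/IELex-style exports or binary
NEXUS matrices) and dated phylogenies.

The per-pair data for three language families — Austronesian (81 pairs),
Indo-European (14 pairs) and Bantu (58 pairs) — ship with the package, so
all headline analyses run offline in seconds.  A synthetic-family
generator with known gain/loss dynamics lets you validate the entire
pipeline end to end and measure parameter recovery.

## Method

**Sister pairs.**  Two languages joined directly at their most recent
common ancestor (a *cherry* on the phylogeny) constitute one independent
natural experiment: one ancestral language split in two, and any
difference between the daughters arose independently of every other
pair.  Cherries are accepted when the ancestral node has ≥ 80% posterior
support and both members are extant, non-creole languages with known
speaker populations.

**Counting gains and losses.**  For each cognate class within a semantic
category, presence in the two members plus presence anywhere else in the
family classifies the class:

| pattern | interpretation |
|---|---|
| in both members | inherited, non-informative |
| in one member *and* elsewhere in the family | ancestral — **lost** by the other member |
| in one member only, nowhere else | **gained** by that member |
| in neither member | assumed absent from the ancestor, excluded |

Loans and forms flagged doubtful/exclude are dropped first; categories
without data for both members are excluded (absence of evidence, not
evidence of absence).  Counts are standardized by the total number of
comparisons.

**Poisson rate regression.**  Member counts are modelled as
X_ji ~ Poisson(μ_j · N_ji^β): rates are power functions of population
size (linear on a log-log scale), and μ_j absorbs the pair's shared
divergence time and data quantity.  Conditioning on the pair total turns
each pair into a binomial split with
p_j = N_j1^β / (N_j1^β + N_j2^β), which eliminates μ_j — no divergence
dates needed, and phylogeny is controlled at the pair level.  β is
estimated by maximum likelihood; the null β = 0 is tested by a
likelihood-ratio statistic against χ²(1 df), with a deviance-based
pseudo-R² as the effect size.

**Contrast regression.**  Per pair, d = (c₁ − c₂)/((c₁ + c₂)/2)/√t and
x = (ln N₁ − ln N₂)/√t standardize the count and population differences
by data quantity and divergence time t.  Because very shallow pairs have
noisy contrasts, the Welch & Waxman filter removes the shallowest pair
while |d| declines significantly in √t, then d is regressed on x by
ordinary least squares.

## Worked example

Re-run the Indo-European loss analysis on the packaged 14-pair table:

```bash
$ sisterates reproduce indo_european --analysis poisson --response loss
{
  "method": "poisson",
  "response": "loss",
  "n_pairs": 14,
  "beta_hat": -0.09500538912955528,
  "se": 0.026901752166248585,
  "statistic": 12.824288534888737,
  "p_value": 0.0003421485862618566,
  "r2": 0.2163074168347917,
  "family": "indo_european"
}
```

The population exponent on the loss rate is β ≈ −0.095: halving a
language's speaker population multiplies its rate of word loss by about
2^0.095 ≈ 1.07.  The likelihood-ratio statistic 12.82 (p ≈ 0.0003)
rejects the no-effect null — among these Indo-European pairs, the smaller
language of each pair loses basic-vocabulary words faster.  The same
command with `--analysis contrast` applies the Welch & Waxman filter
(removing exactly one very shallow pair, Upper/Lower Sorbian) and the
significance disappears (F = 2.52, p = 0.14) — the contrast engine has
less power at n = 13, so the Poisson result rests on a small sample.

The same interface works on your own data:

```bash
sisterates count -w wordlist.csv -t tree.nwk -m meta.csv -o counts.csv
sisterates fit-poisson counts.csv --response loss
sisterates fit-contrasts counts.csv --response loss --ww-rule significance
sisterates simulate --seed 1 --beta-loss -0.3 -o simfam/
```

or from Python via `sisterates.read_wordlist`, `extract_cherries`,
`count_pair`, `fit_poisson`, `ww_filter`, `contrast_regression`,
`simulate_family`, `recovery_experiment`.

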