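# Methods

This note records the statistical model behind `comorbnet`, the knobs
that matter, what the synthetic generator does and does not emulate, and
the numerical choices made where the design was genuinely open.

## 1. Data model

The atomic observation is an engagement event: (user, community,
timestamp in integer Unix epoch seconds, post/reply kind). Posts and
replies are treated identically; the kind is carried but never used —
there is no evidence-based weighting to apply between them. Malformed
rows in input files (unparseable timestamp, empty token) are skipped and
counted, never silently dropped and never fatal: real log extracts are
dirty, and the skip count is part of the run report.

Two derived structures drive everything:

* the **binary incidence** B (user × community, engaged at least once),
  whose row sums (user degrees) and column sums (community degrees) are
  the null model's invariant;
* the **first-engagement index** min-timestamp per (user, community),
  which is the only temporal information the TPD statistic uses.

Pair keys are always the lexicographically sorted community pair; every
symmetric table stores each unordered pair once. Output tables are
ordered by descending weight with lexicographic tie-breaks so reruns are
byte-identical.

## 2. Link significance

The co-engagement weight W_ij counts distinct users engaged in both i
and j. The incidence is deliberately binary: a user posting a hundred
times in one community is the same membership as a user posting once,
and instance counts enter only the temporal statistic. The open question
of a directed weight variant is resolved symmetrically — shared-user
counts are symmetric by definition, and no directed weight is exposed.

**Null ensemble.** Uniform sampling of binary matrices with both margins
fixed, via curveball trades: pick two users, pool the communities held
by exactly one of them, and deal the pool back at random keeping each
user's count. One replicate applies 5 × |edges| trades starting fresh
from the observed matrix — comfortably past the mixing times reported
for curveball — and every replicate's degree sequences are asserted
against the original (hard failure otherwise). The trade kernel is
numba-compiled over the dense boolean matrix with an inline splitmix64
counter PRNG; one replicate on a 3000-user, 12-community incidence costs
about 3 ms. PRNG adequacy is tested statistically: on an instance whose
fixed-margin space has exactly two members, 2000 shuffles hit each
member at 0.5 ± 0.03, and Monte-Carlo expected weights agree with
exhaustive fixed-margin enumeration within Monte-Carlo error on every
enumerable test instance.

**Retention rule.** The default is the bare strict inequality
W_ij > W̃_ij (with W̃ the replicate mean), plus a floor
`min_co_engaged_users` (default 5) that guards pairs whose W̃ ≈ 0 from
being trivially "significant". An empirical p-value
(exceedances + 1)/(replicates + 1) is always computed; an optional
threshold on it (default off) tightens retention to a proper test. The
default replicate count is 1000; the bare rule stabilizes far earlier,
and the p-value resolution is what drives the choice.

**Projection.** Retained links form an undirected graph weighted by the
*observed* W_ij (strength centrality then measures raw overlap, which is
what node sizing should convey); the null expectation is retained as an
edge attribute. Louvain modularity maximization (resolution 1.0, via
networkx) is run with 10 seeded restarts, keeping the best-modularity
partition, first found on ties; with a fixed master seed the partition
is deterministic, and on every ≤ 8-node graph in the test suite the
result attains the exhaustively enumerated modularity optimum. Partition
labels are contiguous integers ordered by each block's smallest
community token.

## 3. Temporal Probability Difference

For focal i and candidate j, over users co-engaged with both,
P_ij = mean per-user score s_u with s_u = 1 if first(j) > first(i),
0 if earlier, and `tie_weight` (default 0.5) on equal timestamps — the
convention that preserves P_ij + P_ji = 1 exactly.

**Reassignment null.** The bootstrap permutes the community labels of
the restricted events (those in {i, j} belonging to co-engaged users)
while every event keeps its user and timestamp. This is the minimal
scheme that preserves both each community's total instance count and
each user's instance count simultaneously; permuting timestamps as well
would preserve neither more nor less but would break the per-user
activity profile's alignment with real time. Events are put into a
canonical (user, timestamp, community) order before permuting, which
makes the iteration stream identical for the (i, j) and (j, i)
directions under a shared seed — TPD_ij = −TPD_ji then holds per
iteration on tie-free data, and the test suite asserts it.

Iterations whose reassignment leaves no co-engaged user are discarded
(P′ is undefined on them), counted, and reported; losing more than half
of the iterations marks the pair degenerate and is fatal. The per-pair
result records the observed P_ij, the bootstrap mean P′, the TPD mean,
and a percentile confidence interval at `ci_level` (default 0.95).

**CI convention.** The interval uses order statistics rounded outward
(`lower`/`higher`) rather than interpolated quantiles: with 200
iterations, linear interpolation makes the one-sided exclusion level
measurably anti-conservative (≈3.2% observed against a nominal 2.5%
over 400 exchangeable cohorts), while the outward convention restores
the nominal level (≈2.3% measured).

**Significance.** `significant_early` is `ci_high < 0`: the entire
interval below zero, i.e. the candidate preceded the focal community
more consistently than the reassignment null allows. Screens rank
candidates ascending by TPD mean, list ineligible candidates (below the
co-engagement floor) with the reason, and under the pooled cohort rule
merge all focal communities into one pseudo-community whose first
engagement is the earliest across them; the per-focal rule runs one
screen per focal community instead. Which rule matches a given study's
cohort definition is the caller's decision — both are exposed.

## 4. Synthetic cohorts

The generator emulates the statistical structure the analysis assumes:

* **Memberships** are independent Bernoulli draws with per-community
  baseline popularity. Probability depends on the community alone; user
  activity affects only instance counts. This is a deliberate design
  constraint: a Bernoulli matrix whose cell probabilities depend only on
  the column is, conditional on both degree sequences, exactly uniform
  over the fixed-margin space — precisely the ensemble the curveball
  null samples — so independence cohorts are an exact calibration
  harness for the retention rule.
* **Planted comorbid pairs** redraw the two communities jointly from the
  2×2 distribution with the configured marginals and odds ratio (the
  joint cell solves the standard quadratic), so the effect size is exact
  and the marginals are untouched. Pairs must be community-disjoint to
  keep this construction exact.
* **Activity** is a per-user multiplier from a truncated Zipf
  distribution (shape 2.2, cap 20 by default); each membership gets
  1 + Poisson instances with mean scaled by the multiplier, so
  per-membership instance counts average `instances_per_membership`
  (default 3) while being heavy-tailed across users.
* **Timestamps** are i.i.d. uniform integers on the window (defaults
  span roughly 2011–2023 in epoch seconds). For a planted precursor
  pair, each co-engaged user adheres with the configured probability;
  an adherent user's early-community instances are translated so the
  earliest lands 1 + Exp(lag_mean) seconds before their first focal
  instance — a one-parameter lag that makes min(early) < min(focal)
  strict and almost surely tie-free.
* **Seeding** uses one master seed with per-user Philox counter
  substreams, so growing the population never perturbs earlier users,
  and the exchangeable variant (precursors ignored, timestamps i.i.d.)
  shares the membership machinery.

What the generator does **not** emulate: posting cadence and
seasonality, user churn, community growth over time, content, or
correlated membership beyond pairwise planted odds. Passing tests
therefore demonstrate that the estimators recover the structure they
define under degree heterogeneity and exchangeable noise — not that any
particular real-world dataset satisfies those assumptions.

## 5. Problem sizes and defaults

The validation suite runs at sizes a laptop handles in minutes: planted
and independence cohorts of 3000 users × 12 communities over 20 seeds
with 200 null replicates; TPD calibration over 100 exchangeable cohorts
at 200 bootstrap iterations; a power grid over adherence
{0, 0.25, 0.5, 1} × cohort size {50, 200, 500} at 24 seeds per cell;
exhaustive oracles (fixed-margin enumeration, label-assignment
enumeration, set partitions) confined to instances small enough to
enumerate. Production defaults are higher (1000 replicates, 1000
bootstrap iterations) because the marginal cost is small at single-run
scale.

## 6. Known limitations

* The bare W > W̃ retention rule retains roughly half of all null pairs
  by construction (a fair coin beats its mean half the time); it is
  reproduced as the default because it is the method's stated rule, but
  the p-value threshold is the statistically meaningful variant and the
  pipeline reports both.
* Co-engagement is association, and TPD is temporal precedence within a
  platform's logs; neither supports causal or diagnostic claims.
* The empirical p-values are per-pair; no multiplicity correction is
  applied across pairs or candidates (the calibration tests quantify
  the per-pair rates).
* Curveball sampling is approximately uniform at finite trade counts;
  the 5 × |edges| schedule is validated on enumerable instances, not
  proven for all margins.
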