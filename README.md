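# comorbnet

Multimorbidity network inference and temporal early-signal detection from
online-community engagement logs.

## The problem

People managing a chronic condition often participate in several
disease-focused online communities at once, and the communities they share
trace the multimorbidity structure of the condition — which diseases tend
to co-occur in the same people. Engagement logs (one row per post or
reply: user, community, timestamp) therefore carry two signals worth
extracting carefully:

1. **Which community pairs share more users than chance allows.** Raw
   overlap counts are misleading: very active users and very popular
   communities produce large overlaps with no medical meaning. The
   overlap must be judged against a null model that preserves exactly how
   active each user is and how popular each community is.
2. **Which communities people join systematically *before* a focal
   community.** If first engagement in community *j* reliably precedes
   first engagement in the focal community *i*, activity in *j* is a
   candidate early signal of the focal condition.

`comorbnet` implements both procedures as a tested pipeline, driven by a
synthetic-cohort generator that plants known comorbid pairs and known
temporal precursors so every stage can be validated against ground truth.

## Methods in brief

**Link significance.** From the engagement log we build the binary
user × community incidence **B** (user *u* engaged community *c* at least
once). The co-engagement weight of a community pair is

&nbsp;&nbsp;&nbsp;&nbsp;*W*<sub>ij</sub> = #{users engaged in both *i* and *j*}.

The null ensemble holds both degree sequences of **B** fixed — each
user's number of distinct communities, each community's number of
distinct users — and samples binary matrices with those margins uniformly
via curveball trades. Averaging over replicates gives the expected weight
*W̃*<sub>ij</sub>; a link is retained when *W*<sub>ij</sub> >
*W̃*<sub>ij</sub> (an empirical p-value
(1 + #{replicates with null *W* ≥ observed *W*}) / (1 + replicates) is
also reported, with an optional threshold). Retained links form a
weighted undirected multimorbidity network; nodes are sized by strength
centrality (weighted degree) and partitioned by Louvain modularity
maximization.

**Temporal Probability Difference (TPD).** For focal community *i* and
candidate *j*, over users co-engaged with both, *P*<sub>ij</sub> is the
probability that the user's first engagement in *j* came after their
first engagement in *i*. The baseline *P′*<sub>ij</sub> comes from a
bootstrap that reassigns engagement instances at random: each event keeps
its user and timestamp while the community labels are permuted, which
preserves every community's instance total and every user's instance
count exactly. Per iteration,

&nbsp;&nbsp;&nbsp;&nbsp;TPD<sub>ij</sub> = *P*<sub>ij</sub> − *P′*<sub>ij</sub>,

and the mean of the bootstrap distribution is the TPD estimate with a
95% percentile confidence interval. A significantly **negative** TPD
(interval entirely below zero) means *j* systematically preceded *i* —
an early signal.

## Worked example

```python
from comorbnet import (SyntheticConfig, generate_cohort, RunConfig,
                       MultimorbidityModel, EarlySignalModel)

synth = SyntheticConfig(
    n_users=2000,
    communities=["diabetes", "depression", "loseit", "Anxiety", "ibs", "cancer"],
    baseline_popularity=0.2,
    comorbid_pairs=[("depression", "loseit", 4.0)],          # planted link, odds x4
    precursor_pairs=[("depression", "diabetes", 31_536_000.0, 0.8)],  # ~1y lead, 80% adherence
    seed=42,
)
events, truth = generate_cohort(synth)
cfg = RunConfig(n_null_replicates=500, n_bootstrap=500, master_seed=7)

print(MultimorbidityModel(events, config=cfg).fit().summary())
print(EarlySignalModel(events, focal="diabetes",
                       candidates=["depression", "loseit", "Anxiety", "ibs", "cancer"],
                       config=cfg).fit().summary())
```

prints

```
Multimorbidity link significance
========================================================
users: 1452   communities: 6
observed pairs: 15   retained links: 2
null replicates: 500   modularity: 0.0000   blocks: 1
--------------------------------------------------------
pair                               W       W~       p
depression--loseit               172    84.41  0.0020
Anxiety--loseit                   81    79.04  0.4012

Early-signal screen for focal community 'diabetes'
========================================================================
candidates tested: 5   ineligible: 0   significant early signals: 1
------------------------------------------------------------------------
candidate              n    P_ij      TPD              95% CI  early
depression            78   0.064   -0.424    [-0.545, -0.313]    yes
ibs                   89   0.393   -0.093    [-0.196, +0.007]
loseit                79   0.468   -0.025    [-0.144, +0.099]
cancer                73   0.521   +0.019    [-0.095, +0.137]
Anxiety               75   0.600   +0.115    [+0.006, +0.229]
```

The planted comorbid pair (depression, loseit) shows W = 172 against a
chance expectation of 84.4 and is the only strongly significant link
(p = 0.002); the borderline Anxiety–loseit pair (81 vs 79.0) illustrates
why the bare W > W̃ rule benefits from the optional p-value threshold.
In the screen, the planted precursor (depression) has P_ij = 0.064 — only
6% of co-engaged users reached depression *after* diabetes — giving
TPD = −0.42 with the whole interval below zero; the unplanted candidates'
intervals all cover zero on the negative side.

The same pipeline runs from the shell:

```bash
comorbnet simulate --config synth.yaml --out sim/
comorbnet network --events sim/events.csv --catalogue catalogue.csv --out net/ --seed 7
comorbnet early-signals --events sim/events.csv --catalogue catalogue.csv --out sig/ --seed 7
```

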