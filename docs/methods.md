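# Methods

## Data model

A swipe market is a directed bipartite network stored as two binary
incidence matrices, `M_F` (women→men) and `M_M` (men→women).  Repeated
identical swipes are collapsed to a single binary tie (the collapse count is
logged): only the first swipe and the response to it carry information, and
an accepted swipe is represented as the reverse tie, so a match is exactly a
mutual pair.  Isolates are retained in the node registries and enter every
degree vector as zeros — published medians of 1–3 imply many near-zero-degree
users belong in the node set.  Node order inside a registry is input order
and is never exposed: vector-valued results are keyed by node id.

## Measures

* **Degrees.**  Indegree of women = column sums of `M_M`; outdegree of women
  = row sums of `M_F`; analogously for men.  Standardized degree divides by
  the opposite-mode size, the maximum attainable, so the two genders are
  comparable.  Summary moments use the sample SD (n−1) and the moment-based
  Fisher–Pearson skewness g1 = m3/m2^{3/2}, reported as 0 for zero-variance
  vectors (the natural convention for a "no dispersion" vector; g1 is
  otherwise undefined there).
* **Density** = (ΣM_F + ΣM_M)/(2 n_w n_m): each of the n_w·n_m cross-mode
  pairs supports two directed ties.
* **Indegree centralization** (Freeman-style, per mode): observed dispersion
  Σ_i (c_max − c_i) over the mode, divided by the dispersion of the
  *bipartite in-star* in which one node receives a tie from every
  opposite-mode user and the rest receive none: (n_mode − 1)·n_opp.  A
  tie-count-preserving denominator (central node takes min(T, n_opp), the
  overflow packed onto as few nodes as possible) is available via
  `denominator="tie_preserving"`.  The bipartite-star normalization is the
  default because it is the maximum the bipartite constraint allows for the
  given mode sizes and it reproduces published centralization values from
  published inputs; the two variants coincide whenever T ≤ n_opp.
* **Reciprocity** = 2·ΣM_R/(ΣM_F + ΣM_M), the fraction of swipes that belong
  to a match.
* **Gender gap.**  Cohen's d on standardized indegrees, (women − men)/pooled
  SD with (n−1)-weighted pooling.  The attached two-sample randomization test
  permutes gender labels over the pooled standardized-indegree vector
  (standardization happens once, with the true group sizes, before any
  relabelling) and reports the two-sided proportion of permutations with
  |mean difference| ≥ observed; default 10,000 permutations, explicit seed
  required.  Zero pooled SD raises rather than reporting an arbitrary d.

## Tie-level desirability gaps

The all-ties gap in a direction is the mean over that direction's swipes of
(sender's standardized indegree − receiver's).  The weighted variant gives
each tie weight 1/outdegree(sender) and normalizes by total weight, so every
active sender contributes exactly weight one — swipes from indiscriminate
senders count less.  The reciprocated-pair gap averages (man − woman)
standardized indegree over matched pairs; matches are mutual, so only the
magnitude is interpretable and the male orientation is a sign convention.
The observed reciprocal gap uses standardized indegrees computed from the
full network (the matched subgraph inherits the market-wide desirability
scores); this is the adopted reading where the convention is ambiguous.

## CUG inference

The null model conditions on network size and the complete outdegree
sequence (hence density): every replicate applies an independent uniform
permutation to the entries of each row of *both* matrices — equivalent to
each sender re-choosing their receivers uniformly without replacement.  Both
matrices are always permuted, and all standardized indegrees entering a
statistic are recomputed from the permuted matrices.  Outdegree preservation
is asserted on every replicate.

Empirical p-values are Pr(sim ≤ obs) and Pr(sim ≥ obs) with ties counted on
both sides and **no** (n+1) correction, so a statistic outside the simulated
range reports exactly 0.00/1.00.  Replicates on which a statistic is
undefined (e.g. a permutation with no reciprocated pair) are recorded as
missing and excluded from the denominator, preserving the proportion
interpretation; their count is reported.  Default 1,000 replicates; a seed
is mandatory and identical seeds give bit-identical results.

## Preprocessing

* *Active filter*: drop zero-degree users (inclusion required at least one
  sent or received swipe).
* *Bot filter*: remove target-mode users (default: women) with indegree ≥ 30
  who reciprocated ≥ 100% of their in-neighbours — "accepted all, given at
  least 30 received", the boundary case qualifying.  Both thresholds are
  parameters.  Reciprocation is evaluated on the constructed binary network.
* *Market split*: one sub-network per city; cross-city ties are dropped with
  a logged count.  The pipeline order is city split → bot filter → active
  filter, recorded in the run manifest.

All filters are idempotent and report removed ids and tie counts.

## Synthetic market generator

The generator exists to exercise the machinery under realistic market
structure and to validate mechanism recovery; it is deliberately minimal:

1. latent desirability per node: normal, or lognormal for heavy-tailed
   modes; centred within mode (scores are relative standing);
2. intended outdegree per sender: negative binomial (mean, dispersion k;
   k = 0 gives a fixed count), truncated to the opposite-mode size — the
   count law matches the strong right skew of observed outdegrees;
3. receiver choice: k distinct receivers sampled with probability ∝
   exp(aspiration · z_receiver) (Gumbel-top-k, i.e. Plackett–Luce without
   replacement).  Aspiration 0 reduces *exactly* to the row-permutation
   null, which is what makes the calibration tests meaningful;
4. reciprocation: each first swipe is returned with probability
   sigmoid(intercept + slope·(z_initiator − z_receiver)); slope > 0 makes
   more desirable receivers choosier — the non-reciprocity mechanism.  Both
   response layers are driven by first swipes only.

Preset `brno_like` (497 men, 127 women; male/female mean activity 9/6.2 with
dispersions 1.5/1.2; lognormal σ=1 female desirability, normal σ=0.5 male;
male aspiration 1.0, female 0; reciprocation intercept −1.0, slope 1.5) was
chosen to emulate the published market's scale: ~20% women, ~5–6k swipes,
reciprocity near one quarter, strongly right-skewed female indegree.  The
aspiration and reciprocation coefficients express the two mechanisms the
preset is meant to carry — aspirational male pursuit and gap-dependent
rejection — at magnitudes that make them clearly visible at this market
size.  `prague_like` scales the same mechanism to 1,743/578 users;
`null` switches aspiration and reciprocation off entirely.

What the generator does *not* emulate: geography and app presentation order,
temporal dynamics (swipes are exchangeable within a collection window),
profile content, paid membership, and bots.  Passing tests therefore show
the *measures and tests* behave correctly under realistic marginal
structure, not that the generative mechanism is the true data-generating
process of any real market.

## Numerical and design choices

* Matrices are dense int8; all tie-level statistics use closed-form matrix
  expressions (no edge loops), so a 1,000-replicate CUG test on a 624-user
  market takes ~2 s on one CPU.
* Row permutation uses per-row random-key argsort (uniform by symmetry).
* p-value comparisons are exact float comparisons; gap statistics on binary
  matrices are ratios of small integers, so ties are matched reliably after
  rounding to 9 decimals in enumeration tests.
* Test problem sizes: exhaustive-enumeration oracles run on 3×4 networks
  (≤ 648 joint row arrangements); calibration and mechanism-recovery checks
  use 40–50 replicate markets at the 497×127 preset scale with 200–1,000 CUG
  replicates — chosen so the full suite completes in well under a minute per
  property while keeping Monte-Carlo bands tight enough to be informative.
* Reconstruction helpers (`random_fixed_tie_network`,
  `network_from_female_indegrees`) rebuild markets from published aggregate
  counts; measures depending only on those aggregates (mean degree, density,
  centralization from a max/total pair) are then exact by construction.

## Limitations

* The CUG null conditions on outdegrees only; no null preserving both degree
  sequences (bipartite configuration model) is provided, and no analytic
  null distributions — Monte Carlo only.
* No ERGM/relational-event modelling; no fitting of the generative model to
  data (qualitative reproduction only).
* Binary ties discard swipe multiplicity and timing.
* The bot rule is behavioural (accept-all with ≥ 30 received); it cannot
  detect bots that mimic selectivity.
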