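# Methods

## The question and the two estimators

Given a rooted phylogeny of a specialist clade and a species-level niche
table, we estimate what fraction of speciation events coincided with an
ecological niche shift.  A niche is a feeding habit crossed with a set
of host taxa; host labels are opaque strings, so the caller decides
whether they are families, genera, or species — mixing levels across
clades is permitted but changes what counts as "distinct", and the shift
counts are sensitive to that resolution.

**Shift counting (parsimony).**  Each distinct ingroup niche is a state
of one multistate character.  The minimum number of state changes on the
tree is computed by Sankoff's dynamic program: for node *v* and state
*s*, C_v(s) = Σ_children min_t [cost(s→t) + C_child(t)], with tip cost 0
on the tip's admissible states and +∞ elsewhere; the tree cost is
min_s C_root(s).  Polytomies are handled by the sum over children;
outgroups are coded unknown (full state set at zero cost).  Because *n*
extant species imply *n* − 1 splits, count / (*n* − 1) bounds the
ecological-speciation fraction from above: parsimony gives the *minimum*
number of shifts, but a shift need not coincide with a split.
Optimizing over every tree in a posterior sample (min/mean/max of the
per-tree counts) quantifies robustness to phylogenetic uncertainty.

**Step matrices.**  Under `all_one` every change costs 1.  Under
`generalist_zero`, cost(i→j) = 0 when state *j* is a generalist with the
same feeding habit whose host range contains all of state *i*'s hosts;
everything else costs 1.  The zero applies only *into* the subsuming
generalist: re-specializing out of it is still a change of realized
niche, so it costs 1.  A `symmetric_generalist_zero` switch zeroes the
reverse direction for sensitivity analysis.  Generalist pairs with
partial host overlap but no containment cost 1 — containment is the only
relation under which the narrower niche is unambiguously a sub-niche of
the wider one.  A habit change always costs 1, even with identical
hosts, because the niche is habit × hosts.  Since the `generalist_zero`
matrix is elementwise ≤ the `all_one` matrix, its tree cost can never
exceed the `all_one` cost (monotonicity of the DP in the costs, which
the tests assert).

**Ancestral states.**  A top-down pass reports, per node, the full set
of states attainable in at least one minimum-cost reconstruction (the
MPR set).  Ambiguity is exposed as a set rather than broken arbitrarily;
any single painted history would overstate certainty.  Host use can also
be optimized as its own unordered character with polymorphic tips
(multi-host species admit all of their hosts), via
`niche.host_character`.

**Sister-pair regression.**  Terminal sister pairs are internal nodes
whose two children are both tips; the pair's split age is the node
height divided by the root height (relative time).  Pairs are labeled
1 when the two species have different habits and/or disjoint host sets,
0 otherwise; pairs involving an unknown-niche species are dropped.  A
binary logistic regression of the label on split age is fitted by
maximum likelihood, and the fitted probability at age 0 estimates the
fraction of splits that were ecological *at the moment of splitting* —
the raw niche-different proportion confounds cladogenetic shifts with
post-speciational ones, which accumulate with age.  Pairs are treated as
independent observations; with one data point per cherry there is no
shared branch between observations, but deeper phylogenetic
pseudo-replication of the pair ages is not modeled.

## Numerical choices

- **Logistic fitter**: Newton/IRLS from β = 0 (intercept-only fits warm
  start at the closed-form logit of the sample proportion, which is the
  exact MLE).  Convergence when max |score| < 1e-8 or max |step| <
  1e-10, cap 100 iterations.  Wald standard errors come from the
  inverse observed information; a likelihood-ratio p-value for the age
  effect is reported alongside because the two can disagree at n ≈ 35.
  Complete separation (every observation on its own side of the
  boundary) or divergence (|β| > 10³ without score convergence) is
  flagged `separated`/non-converged instead of returning huge
  coefficients.
- **Sankoff infinities** are IEEE `inf` in a float DP table; they
  propagate correctly through `min` and `+` and need no overflow guard.
- **Node heights on non-ultrametric trees** use the mean distance from
  the node to its descendant tips, with a warning once the relative
  tip-depth spread exceeds 1e-6.  The intended input is a chronogram
  (effectively ultrametric), where the mean coincides with every path;
  the averaging rule merely keeps the function total.
- **Zero root height** (a star tree of zero branch lengths) makes
  relative ages undefined and raises.
- **Polytomies at a would-be cherry** (≥ 3 tip children) are skipped
  with a warning rather than decomposed into pairs: any enumeration of
  tip pairs from a polytomy would replicate one split age several times
  and bias the regression.
- **Ties and determinism**: the niche catalog is sorted by (habit,
  hosts), pairs are sorted by age then labels, and reports are
  serialized with sorted keys, so identical inputs give byte-identical
  outputs.
- **χ² test**: Pearson statistic without continuity correction (the
  intended tables have large margins); zero margins raise.
- **Host tallies** count a species once per host genus it uses, so
  clade totals are inflated by design; proportions are normalized by the
  inflated total.

## The simulator

`simulate` generates the statistical structure the analysis assumes:

- a constant-rate birth–death tree conditioned on the number of extant
  tips (extinct lineages pruned), rescaled to root height exactly 1 —
  defaults: 125 ingroup tips, pure birth (birth rate 1, death rate 0);
- niche evolution with two processes: at each split, with probability
  `p_eco` (default 0.2, matching the corrected estimate scale for the
  motivating clade) one daughter draws a new niche guaranteed
  non-overlapping with its sister's at that moment — this
  operationalizes ecological speciation as divergence into distinct,
  non-overlapping niches; along every branch, anagenetic shifts arrive
  as a Poisson process (`ana_rate` = 1 per unit relative time) and
  replace the current niche;
- niches drawn from 6 habits × 20 boreal host genera, two-host
  generalists with probability 0.15, yielding ~40–60 realized niches at
  125 tips, in line with a sparsely sampled specialist radiation;
- 5 outgroup species with unknown niche grafted as a basal grade
  (each stem 25% of the current height; the tree is rescaled back to
  unit height);
- a "posterior" sample emulated by random NNI moves (default 2 per
  tree) applied to the true topology.  This exercises
  counting-over-samples without an MCMC; it does not mimic the
  correlation structure or branch-length posteriors of a real chain.

All randomness flows from one seeded `random.Random`; the seed is
recorded in the dataset metadata and fixed seeds give identical Newick
strings.

What the simulator does *not* emulate: real host-taxonomy structure
(host labels are exchangeable), rate variation among lineages or clades,
niche-dependent diversification, biogeography, and sequence-level
uncertainty.  Passing tests therefore show that the estimators recover
the truth *under the generating model's assumptions* — notably that
anagenetic shifts are homogeneous in time — not that those assumptions
hold for any particular empirical clade.

A deliberate subtlety of the `p_eco = 1, ana_rate = 0` limit: each niche
is carried by exactly one lineage (at every split one daughter keeps the
parental niche), so the uniform-cost parsimony length equals *n* − 1
only when no two cladogenetic draws collide in the finite niche pool;
the test of that limit widens the pool so the no-collision precondition
holds and asserts it explicitly.

## Recovery of the ecological-speciation fraction

With 400-tip trees, `ana_rate` = 1 and `p_eco` ∈ {0.1, 0.2, 0.5} (20
replicates each), the mean fitted probability at age 0 tracks `p_eco`
within ±0.07 while the raw niche-different proportion overestimates it
in ≥ 15/20 replicates — the raw-versus-corrected gap the age correction
exists to remove.  The replicate count and tree size keep the check well
inside a normal test run (a few seconds per replicate); they are large
enough that the logistic fit converges in essentially every replicate.

## Known limitations

- Parsimony undercounts shifts in fast-evolving characters; the
  shift/speciation ratio is a lower bound on shifts but is used only as
  an upper bound on *ecological speciation*, where the directions agree.
- The logistic model is a convenience form; the true
  P(different | age) under the simulator is 1 − (1 − p_eco)·e^(−2·ana_rate·age·(1−ε))
  for small overlap probability ε, which the logistic only
  approximates.  Extrapolation to age 0 is nevertheless consistent in
  the small-age regime where cherries concentrate.
- Only strictly binary cherries enter the regression; taxon sampling
  that breaks up cherries (or duplicate exemplars of one species, which
  are dropped as self-pairs) changes the pair set.
- No likelihood/Bayesian character model and no phylogenetic logistic
  regression are provided; both are out of scope by design.
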