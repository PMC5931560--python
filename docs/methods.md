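# Methods

This note documents the models and numerical procedures implemented in
`endogem`, the choices behind them, and what the synthetic test bed does and
does not establish about real data.

## Constraint-based model and LP analyses

A metabolic network is a stoichiometric matrix S (metabolites × reactions)
with per-reaction flux bounds lb ≤ v ≤ ub, boolean gene–protein–reaction
(GPR) rules, and a biomass objective.  All analyses operate on the
steady-state polytope {v : S·v = 0, lb ≤ v ≤ ub}.  Flux units are
dimensionless in tests; for real endothelial data they carry
nmol·h⁻¹·(10⁶ cells)⁻¹ semantics.  Exchange reactions consume exactly one
metabolite with coefficient −1, so positive exchange flux is secretion and
negative flux is uptake; this convention is stated in every output.

* **FBA** maximises biomass flux by LP (HiGHS via `scipy.optimize.linprog`,
  primal feasibility tightened to 1e−10 so optimal solutions satisfy
  |S·v|∞ ≤ 1e−9 at the model sizes used here).
* **FVA** reports per-reaction min/max flux, optionally at ≥ a fraction of
  the FBA optimum.  The default fraction is 0.0 — the full polytope — because
  patient-model bounds in this pipeline derive from *sampling* of that space,
  not from growth-constrained variability.
* **Flux consistency** uses ε = 1e−4: a reaction is consistent if some
  feasible steady state gives it |v| ≥ ε (reversibles tested in both senses).
* **Essentiality**: a gene knockout sets the gene absent and closes every
  reaction whose GPR then evaluates false (all other genes present); a
  reaction knockout pins its bounds to zero.  An entity is essential when the
  knockout optimum falls below 1% of wild type.  The 1% threshold
  operationalises "biomass can no longer be active" while tolerating solver
  round-off; it is configurable.
* **Minimal exchange relaxation**: when measured exchange bounds make a model
  infeasible, the smallest set of candidate exchanges is reopened to wide
  default bounds (±1000).  Up to 12 candidates the minimum-cardinality set is
  found exactly by incremental subset enumeration; beyond that an elastic LP
  minimises total bound violation and relaxes the exchanges with nonzero
  slack.  The exact/heuristic crossover is a runtime trade-off; the heuristic
  can overcount by grouping violations but agrees with the exact search on
  all test fixtures.
* **Source preference** (`max_product_from_source`) closes uptake of every
  carbon-containing exchange except the named source, adds a temporary demand
  for the product, and maximises it — used to compare palmitate and glucose
  as acetyl-CoA sources.

## Context-specific extraction (FASTCORE scheme)

Given a flux-consistent model and a core set that must stay active,
extraction alternates two LPs: LP7 maximises the number of core reactions
reaching flux ≥ ε (auxiliary z ≤ v, z ∈ [0, ε]); LP10 finds a minimal-L1
support over the non-core penalty set while holding the reachable core at
≥ ε.  Reversible core reactions that cannot be activated forwards are retried
with flipped bounds, with a singleton fallback; iterations are capped at 1000
with a convergence check.  Determinism comes from processing reactions in
lexicographic id order.  The support threshold (1e−8) can leave stray
near-zero reactions in the kept set, so the result is verified and blocked
non-core stragglers dropped; every kept reaction is flux-consistent in the
returned submodel, which the tests assert.  The kept set is near-minimal, not
provably minimal — on all ≤14-reaction fixtures it is within +1 of the
brute-force minimum.  The biomass objective is force-included in every core:
all models here optimise biomass, and without forcing, extraction can drop
it.  The transcript-driven core is {reactions whose GPR is satisfied by
non-absent transcripts} ∩ {flux-consistent reactions}; genes a profile does
not cover are treated as absent (conservative) and counted in a log warning.
Present/absent calls only — no discretisation of continuous expression is
attempted, matching the calls-based data this pipeline targets.

## Flux sampling

Artificially-centered hit-and-run: warmup points are the 2·n FVA extreme
solutions; each step draws a direction from a random warmup point minus the
running centre, and a uniform step on the feasible chord.  Directions are
differences of steady-state points, so the chain never leaves the null space
of S (samples satisfy |S·v| ≤ 1e−6, re-checked in tests).  Defaults:
2000 samples, thinning 100 (the analysis scripts use 200–500 samples with
thinning 15–20, which the mixing smoke tests support at toy-network size);
the seed is a required argument and fully determines the output.  Exchange
summaries classify direction by the sample mean against a 1e−6 tolerance.
No uniformity guarantee is claimed; a variance smoke test on a box polytope
bounds gross mixing failure.

## Constraint-integration rules

* **Regulation**: gene-wise case/reference expression ratio; up if ratio
  ≥ 1.5, down if ≤ 1/1.5.  A cutoff above 1 makes the up and down sets
  disjoint by construction.  A reaction is up-regulated when its GPR contains
  at least one up gene and no down gene (symmetrically for down; conflicts
  leave it untouched) — the gene-to-reaction aggregation is this package's
  choice, as is scaling *both* bounds by 2 (up) or 0.5 (down); upper-bound
  only scaling is available via a flag.  Positive factors preserve bound
  order and reversibility class.
* **Exchange metabolomics**: measured mean rates m become bounds
  [m − 0.1|m|, m + 0.1|m|]; using |m| keeps intervals valid for negative
  (uptake) means.  A zero mean pins the exchange and is logged.
* **Glycolysis/PPP split**: the coupling (1−f)·v_gly − f·v_ppp = 0 is added
  as a pseudo-metabolite row, forcing v_gly/(v_gly+v_ppp) = f at any steady
  state with positive flux through the pair; f comes from the isotope
  estimator.  Which lumped reactions represent the two pathways is a
  configuration choice (GLYC and OXPPP in the toy network).
* **Patient models**: survivor exchange bounds are the sampled min/max of the
  inflamed base model, with (0, 100) where the sampled range is degenerate at
  zero.  Non-survivor bounds multiply the survivor bounds by the plasma
  fold change — magnitudes scale, signs are preserved, and the interval is
  reordered if needed so lb ≤ ub; (1, 2) with fold change 5 becomes (5, 10).
  Extending the rule to negative (uptake) intervals sign-preservingly is this
  package's documented choice.  Metabolites without a fold change keep
  survivor bounds.

## ¹³C lactate labelling

With 1,2-¹³C glucose, glycolysis cleaves fructose-1,6-bisphosphate so the two
labels stay on one triose: lactate is 50% M2, 50% M0.  The oxidative PPP
decarboxylates C1, and a single-pass model (3 glucose → 3 CO₂ + 3 pentose-P,
recombined by transketolase/transaldolase into 2 F6P + 1 GAP which enter
lower glycolysis, no F6P re-entry) yields lactate (M0, M1, M2, M3) =
(0.6, 0.2, 0.2, 0).  Both vectors are produced by atom-mapped propagation in
code, and the test suite reproduces them with an independent carbon-name
enumeration.  The atom-map rules are documented here and swappable; a
recursive-PPP model would shift the M1/M2 balance and is out of scope.

Natural-abundance correction solves the binomial convolution system
raw = C·true (C lower-triangular with entries B(n−j, p) at p = 0.0107,
carbon only) by non-negative least squares with renormalisation;
correct(convolve(x)) = x to 1e−9 for every simplex vector tested.  The
glycolysis fraction is the least-squares projection of the corrected lactate
vector onto the segment between the two theoretical bases (equivalent to
simplex-constrained mixing of two basis vectors); it recovers a planted 0.70
exactly noise-free and with mean absolute error below 0.02 under 1% relative
intensity noise.  A ratio formula such as M1/(M1+M2) would also identify the
mixture but uses less of the vector; the projection estimator is the
package's choice.

The metabolomics normalisation chain is: per-batch, per-variable division by
the root-sum-of-squares; per-sample constant-sum; natural log; per-variable
mean-centring and unit-variance scaling (ddof = 1).  Inputs must be positive
(missing values replaced by per-variable minimum positives upstream);
all-zero and constant variables are rejected by name.

## Model comparison

Fold change between two sampled models is (max|mean| + δ)/(min|mean| + δ)
with pseudocount δ = 1e−9 to tame near-zero fluxes; means with opposite signs
are flagged as sign flips and always selected, since a ratio cannot express a
direction change.  Selection uses fold ≥ 2 (with a 1e−9 relative tolerance so
an exact two-fold pair is not excluded by the pseudocount).  Two-sample
equal-variance t-tests run on the sampled flux columns with Bonferroni
correction over the tested reactions; because flux samples are
pseudo-replicates of a model's solution space rather than biological
replicates, outputs label these "sampling-based significance" — they order
separations between flux distributions and must not be read as experimental
p-values.  Changed reactions are clustered by average linkage under the
1 − Spearman rank correlation distance between row profiles (invariant to
monotone per-model transformations); labels are deterministic (renumbered by
first appearance in lexicographic reaction order), and the cluster count is a
configurable cut rather than a fixed constant.  Cluster composition tables
normalise each (cluster, super-subsystem) count by the total reactions of
that super subsystem.

## Synthetic test bed

The toy network (60 reactions, 41 metabolites, 29 genes) stands in for a
genome-scale endothelial reconstruction with lumped pathways: glycolysis
(glc → 2 pyr), single-pass oxidative PPP (3 glc → 3 CO₂ + 5 pyr), pyruvate
dehydrogenase, a lumped TCA/O₂ sink, β-oxidation (palmitate → 8 acetyl-CoA),
glutaminolysis and a GABA shunt, and synthesis plus exchange of six
endothelial-injury biomarkers (NO, L-kynurenine, 5-methoxy-tryptophan,
sphingosine-1-phosphate, prostaglandin D2, GABA).  Biomass drains acetyl-CoA,
a nucleotide precursor (made from acetyl-CoA + glutamine, so nucleotides can
come from fatty acids), an amino-acid pool, and a lipid pool, giving
fatty-acid and amino-acid essentiality structure.  Default uptake bounds
(glucose 10, palmitate 2, glutamine 5, O₂ 20, minor substrates 1) make the
network flux-consistent and biomass-feasible (optimum 3.0) by construction.
Lumping keeps brute-force oracles (vertex enumeration, exhaustive knockouts,
subset search) tractable; atom-level detail exists only where the isotope
module needs it.

Generators plant known truth: log-normal baseline expression with chosen
genes multiplied/divided by the effect size (2.0, above the 1.5 cutoff; an
effect of 1.0 plants nothing); multiplicative Gaussian noise on exchange
rates (cv 2–5%, triplicates — a small-replicate MS-like error model);
fold-change tables with designated planted entries.  All generators are
deterministic under their seed.

What passing the synthetic study shows — and does not.  It shows the
*rules* are implemented faithfully: planted regulation, exchange means,
pathway fractions, cluster partitions and biomarker direction changes are
recovered exactly or within stated noise envelopes.  It does not validate
the biology of any real reconstruction: the toy network has no isoenzyme
complexity, no compartmentalised cofactor balancing, no thermodynamic
constraints, and its noise models are idealised.  Conclusions about real
endothelial or patient data require the corresponding genome-scale model and
measured inputs, which this package accepts through the same interfaces.

## Known limitations

* FASTCORE results are near-minimal, not minimal; the +1 slack is asserted
  only on small fixtures.
* The sampler has no multi-chain convergence diagnostics; long thin polytopes
  may mix slowly.
* The elastic relaxation heuristic does not guarantee minimum cardinality
  above the exact-search threshold.
* The single-pass oxidative-PPP atom map ignores F6P re-entry; heavily
  recursive PPP flux would bias the estimated glycolysis fraction upward.
* t-tests on flux samples quantify separation of sampled distributions, not
  biological significance.
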