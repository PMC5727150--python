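# Methods

This note documents the models and procedures implemented in
`cooccurevo`, the parameter choices that matter, and what the synthetic
data can and cannot establish.

## Correlated evolution of two binary traits

### Model

Two binary traits evolve jointly along a rooted, bifurcating tree with
branch lengths, as a continuous-time Markov chain over the four joint
states, ordered (00, 01, 10, 11) with state index `2x + y`.  Transitions
change exactly one trait; simultaneous double transitions have rate zero.

* **Independent model (4 rates)** — trait X has gain/loss rates
  `ax`/`bx`, trait Y `ay`/`by`, regardless of the other trait's state.
  Embedded in the joint space: `q(00→10) = q(01→11) = ax`, etc.  The
  embedding is exact, so the independent model is nested in the dependent
  one; the test suite verifies the likelihood identity to 1e-10.
* **Dependent model (8 rates)** — each trait's gain and loss rates may
  differ according to the other trait's current state.

The likelihood of the observed tip states is computed by Felsenstein
pruning over the 4-state space: tip partial vectors are indicators (a
missing trait contributes an all-ones factor, i.e. is marginalized),
internal partials combine children through `P(t) = exp(Qt)`, and each
internal node is rescaled by its maximum partial to avoid underflow.  The
root is summed against a prior that defaults to uniform (¼ each) and can
be set to the chain's stationary distribution or any explicit vector; the
uniform default was chosen because the upstream tooling this emulates
does not document its choice.

`P(t)` for all branches is computed from one eigendecomposition of `Q`
(with a per-branch Padé `expm` fallback when the eigenvector matrix is
ill-conditioned, condition number ≥ 1e10); rows are clipped to [0, ∞) and
renormalized to absorb round-off.

### Fitting

* **Maximum likelihood** — L-BFGS-B on log-rates with bounds
  [1e-8, 1e3] on the natural scale, multi-start (a fixed start at rate
  0.5 plus unit-mean exponential draws).  The dependent fit is
  additionally polished from the embedded independent optimum, which
  enforces the nesting inequality in practice.  The LRT statistic
  `2(logL_dep − logL_ind)` is referred to χ²(df = 4) as a quick
  frequentist companion to the Bayes factor; it is an extra output, not a
  replacement.
* **MCMC** — random-walk Metropolis on log-rates (jointly perturbed),
  with independent Exponential(mean `prior_mean`, default 10) priors on
  the natural-scale rates (the log-scale Jacobian is included).  The step
  size adapts toward ~30% acceptance during burn-in only, so the recorded
  chain has a fixed kernel.  Acceptance rate and autocorrelation-based
  effective sample sizes are reported.
* **Marginal likelihood** — stepping-stone sampling.  Inverse
  temperatures follow `β_k = (k/K)^(1/0.3)` (quantiles of Beta(0.3, 1)),
  which concentrates rungs near the prior where the power-posterior
  integrand changes fastest.  The β = 0 rung is sampled i.i.d. from the
  prior (no MCMC error); subsequent rungs are warm-started.  Each rung's
  log-ratio uses a log-mean-exp estimator with a delta-method standard
  error scaled by the effective sample size of the rung's log-likelihood
  series; rung variances add to give the reported MC standard error.
  Stepping-stone was chosen over the harmonic-mean estimator for its
  stability; the test suite validates it against direct quadrature on a
  one-free-rate problem and against itself across rung counts.  Rates can
  be pinned (`fixed_rates`), in which case they carry no prior; with all
  rates pinned the marginal likelihood equals the likelihood exactly.
* **Bayes factor** — `BF = 2 (logZ_dep − logZ_ind)`, with bands
  `< 2` weak, `2–5` positive, `5–10` strong, `> 10` very strong
  (boundaries: 5 and 10 belong to "strong").

Default chain settings in the packaged pipeline (600 iterations per rung,
200 burn-in, 8 rungs) are sized for ~100-tip trees, where the two
regimes' Bayes factors differ by tens of log-units and an MC standard
error of ~0.5 is ample; for marginal decisions near BF ≈ 2, raise
`chain_length` and `n_stones` until the reported standard errors are
small against the margin.

## System detection

A system model declares mandatory, accessory and forbidden components, a
mandatory quorum (`min_mandatory`), and a co-localization window.  Hits
for model components on one replicon are clustered: consecutive hits stay
together when at most `colocalization_window` genes intervene (rank
difference ≤ window + 1); the default window of 5 intervening genes
mirrors the common default of quorum-based detection tools and is
configurable.  A cluster calls the system present when it contains at
least `min_mandatory` distinct mandatory components and no forbidden
component; `components_found` is the union of model components over all
valid clusters.  Hit scores are carried through but not thresholded —
profile scanning quality control is upstream of this package.

The shipped NHEJ model requires Ku (LigD accessory — Ku can recruit
other ligases, and Ku-only systems count).  The shipped type II model
requires the three core genes cas1, cas2, cas9 co-localized, with csn2
and cas4 accessory; subtype classification is csn2 → II-A, cas4 → II-B,
neither → II-C, and a system carrying both markers raises an error
rather than guessing.  This model encodes only the core-gene/marker
logic; published detection models are richer (exchangeable components,
per-gene weights) and their calls may differ on real data.

Multiple systems of one type in a genome collapse to a single boolean:
the downstream statistics are presence/absence.

## Orthology and the persistent genome

Pairwise alignment is end-gap-free (semi-global) global alignment:
terminal gaps in either sequence are free; internal gaps of length k cost
`gap_open + (k−1)·gap_extend` with BLOSUM62, −11/−1 defaults.  The
substitution matrix is configurable; BLOSUM62 is the field default and
the original procedure names none.

Two conventions needed pinning down, both configurable and recorded in
the run manifest:

* **similarity** = (core columns whose residue pair scores > 0) / (core
  column count), where the core excludes terminal-gap columns and
  internal-gap columns count as dissimilar.  "Similarity" (not identity)
  matches the positive-score reading of the underlying alignment scores.
  When the optimal alignment has an empty core (no residues aligned),
  similarity is 0 by convention at the RBH level, while the standalone
  `similarity()` operation treats it as undefined and raises.
* **relative length difference** = `|La − Lb| / max(La, Lb)` (longer
  sequence as denominator).  Pairs with similarity < 0.37 or length
  difference > 0.20 are discarded, with reasons recorded.

Reciprocal best hits demand that each protein be the other's *unique*
best-scoring partner; score ties make orthology ambiguous and the pair is
skipped and logged rather than broken arbitrarily.  Families are keyed by
pivot protein; the persistent genome keeps families with members in at
least `ceil(quorum · n_genomes)` genomes (90% default; 221 of 245, 9 of
10).

Multiple alignment is **pivot-anchored**: every member is aligned
pairwise to the pivot and merged on pivot coordinates, member insertions
stacked in gap-padded slots.  This is an approximation to a progressive
MSA — justified here because every persistent family contains the pivot —
and externally computed alignments can be supplied instead.  Columns with
more than `max_gap_fraction_per_column` gaps (default 0.5) are removed in
place of entropy-based trimming.  Concatenation joins family blocks in a
fixed order, filling genomes that lack a family with gap stretches;
block spans are 0-based half-open.

## Trees

The package builds trees only as a convenience: p-distances on the
concatenated alignment (gapped columns excluded pairwise; a pair with no
comparable columns is an error) and standard neighbor joining, with
negative NJ branch lengths clamped to zero (warned) and the result
midpoint-rooted.  Maximum-likelihood inference, model selection and
bootstrap support are deliberately out of scope: the correlated-evolution
machinery is tree-agnostic, and published analyses of this kind use ML
trees, which users can import as Newick.  Imported multifurcations are
resolved into zero-length bifurcations (warned) because pruning assumes
bifurcating topologies.

## Co-occurrence statistics

* Fisher exact test: two-sided by the point-probability method (the sum
  of hypergeometric probabilities no larger than the observed table's).
  Verified against rational-arithmetic enumeration on every table with
  N ≤ 30.
* Expected co-occurrence: product of marginal presence counts over N.
* Genome-size test: likelihood ratio between logistic models
  `presence ~ 1 + size` and `presence ~ 1`, referred to χ²(1).  The
  covariate is standardized internally, making the p-value exactly
  invariant to affine rescaling (bp vs Mb).  Perfect separation is
  flagged (with a ridge-stabilized likelihood bound) rather than raised.
* Rank-sum size comparison: exact for tie-free groups of ≤ 10 each,
  normal approximation with tie correction otherwise.
* Size filter: strict (`size < max_size_bp`), with 1 Mb = 10⁶ bp.
* Species aggregation: present iff strictly more than half of the
  species' genomes carry the system; ties count as absent.
* p-values are raw; a Benjamini–Hochberg helper exists as a labeled
  extension and is never applied implicitly.

## Synthetic data

The generator replaces a genome corpus with data whose generating truth
is known.  All randomness flows from one seed through
`numpy.random.SeedSequence` stream splitting (tree, traits, sizes,
proteomes, hit table each get a child stream), so identical configs give
byte-identical datasets and any stage can be regenerated in isolation.

* **Trees** — Yule (pure birth), default birth rate 1; after the n-th
  tip appears the process runs one further exponential waiting time so
  pendant edges are strictly positive.  Branch lengths are in arbitrary
  time units; only topology and lengths matter downstream.
* **Traits** — event-driven (Gillespie) simulation of the joint 4-state
  chain along each branch, rather than endpoint sampling from `exp(Qt)`:
  marginals are identical, but event counts become available to tests.
  The default dependent regime (gains 2.0 from the empty state, gains
  0.02 when the partner is present, losses 1.0, decay 4.0 out of the
  doubly-present state) produces the avoidance pattern with both traits
  segregating across clades — tip frequencies around 40%/40%/20% for
  (1,0)/(0,1)/(0,0) and co-occurrence near zero.  The default
  independent regime is symmetric gain = loss = 1.
* **Genome sizes** — lognormal per trait combination; defaults put
  NHEJ-carrying genomes at ~4.0 Mb vs ~3.0 Mb (sd 0.15 log-units),
  planting the size confounder the logistic test is meant to find, and
  II-A genomes slightly smaller — mirroring the real-data tendency of
  repair systems toward larger and these immune systems toward smaller
  genomes.
* **Proteomes** — per family a random founder (120–300 aa); each genome
  carries a copy with i.i.d. per-site substitution probability
  `sub_rate` (a star-shaped family: divergence from the founder, not
  along the tree), with optional per-genome family dropout.  Unrelated
  families are random sequences, hence ~5% background similarity.
* **Hit tables** — genomes carry co-localized component hits exactly
  for the systems their traits encode; optional decoys plant lone
  sub-quorum components from absent systems.

What passing tests on these data show — and what they do not: the
pipeline's inference machinery is internally correct (oracle-validated
likelihoods, estimators, filters) and recovers planted signals of
realistic strength at 30–100 genomes.  Real data differ in ways the
generator does not emulate: horizontal transfer (traits moving between
clades), detection error from profile scanning, paralogy and gene
fusions in proteomes, rate heterogeneity across lineages, and uneven
taxon sampling.  Results on real genomes inherit those caveats; the
synthetic results do not certify against them.

## Numerical choices and degenerate inputs

* Rate bounds [1e-8, 1e3] everywhere; log-scale proposals and
  optimization.
* Zero-length branches are legal (`P(0) = I`); an all-zero generator is
  legal (traits frozen at the root state).
* Alignment traceback ties are resolved by the underlying aligner's
  deterministic first-alignment order; score-level results are
  tie-independent.
* Trimming can empty an alignment block (warning, empty block — not an
  error).
* An empty genome filter result warns rather than raises.
* Species-aggregation ties, subtype marker conflicts and RBH score ties
  are all surfaced (absent / error / skip-and-log respectively), never
  silently resolved.

## Problem sizes

The packaged demonstration study uses 30 genomes; the model-recovery
study uses 100-tip trees with 12–20 replicates per regime and 8
stepping-stone rungs of 450 iterations — sizes at which the dependent and
independent regimes separate by orders of magnitude in Bayes factor while
a full run stays in the minutes range on a single core.
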