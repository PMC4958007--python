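# Methods

## Data model

The unit of replication is the **well**: one population founded from a
known ancestral background (the wild-type genome plus one first-step
mutation) and passaged for many transfers. Sequencing a handful of
endpoint isolates per well yields, per isolate, a set of **de novo
mutation keys** (`<position><from><TO>`, 1-based, e.g. `1910aG`). A
**reversion** — loss of the background mutation — is stored as the
ordinary back-mutation key at the background site (`1910aG`'s reversion is
`1910gA`), so each analysis can include or exclude reversions by flag
rather than by special-casing. A well's mutation complement is the union
over its sequenced isolates: analyses compare wells, not isolates, and the
union is the set of changes the well's population explored.

Quality control drops wells with fewer than four sequenced isolates
(configurable); with roughly five isolates per well, smaller samples make
the union too unstable to compare. A light contamination screen flags
isolates that simultaneously lack their own background mutation and carry
another background's first-step mutation; criteria that require cross-well
sequence forensics are out of scope.

Functional classification works from a feature table (genes with frame
offsets, promoters, terminators) plus the ancestral genome sequence, with
precedence regulatory > nonsynonymous > silent. Overlapping reading
frames are common in these genomes (genes D and E share sequence), so a
coding change is nonsynonymous if it alters the protein in *any* frame
containing it. The "cluster" identity level maps a mutation to its
regulatory feature, else to (gene, codon) — for overlapping genes, the
first-annotated containing gene, a deterministic tie-break — else to its
own nucleotide key. "Silent" covers synonymous coding changes *and*
intergenic non-regulatory changes; the per-class tables let a user count
either subset.

## Parallelism

P_ij = ½(|S_i∩S_j|/|S_i| + |S_i∩S_j|/|S_j|). Conventions that matter:

- A well whose identity set is empty after exclusions yields *missing*
  P_ij, not 0 — "nothing to compare" is different from "nothing shared".
- The headline summary is the **unweighted mean of per-background means**,
  not the pooled pair mean: backgrounds keep unequal numbers of wells
  after QC, and the design question ("how parallel is a typical
  background?") weights backgrounds equally.
- The background-effect statistic R = SS_between/SS_total is computed over
  within-background P_ij values. Because every well enters many pairs, the
  values are non-independent; significance therefore comes from permuting
  well-to-background labels (group sizes preserved) and recomputing R,
  with the add-one estimator p = (1 + #{R_perm ≥ R_obs})/(n_perm + 1) so
  p is never zero. Default n_perm = 9,999. If all within-group values are
  equal, R is defined as 0.

The per-pair ordering "cluster-level P_ij ≥ nucleotide-level P_ij" is
**not** a theorem, and the generator below produces counterexamples: when
two same-cluster mutations co-occur in one well's union, coarsening can
shrink that well's contribution faster than the intersection (S_i = {h1,
h2, x} vs S_j = {h1, h2}: 0.833 at the nucleotide level, 0.75 after
merging h1, h2). What does hold, and what summary comparisons rest on, is
the dataset-mean ordering; the test suite asserts the mean form green and
documents the per-pair form's failure honestly.

## Epistasis tests

**Within/between ratio.** P̄_within/P̄_between over all pairs, null by
label permutation, one-tailed (ratio ≥ observed). If P̄_between = 0 the
ratio is undefined and only the means are reported.

**Mutation × background LRT.** Presence is well-level (≥1 isolate).
Null: mutation k arises with one probability p̂_k = n_k/N in every well;
alternative: background-specific p̂_kb. Both are product-Bernoulli models
with plug-in MLEs, so Λ = Σ_k ΔlnL_k exactly, each ΔlnL_k ≥ 0, and
mutations present in zero or all wells contribute exactly 0 (flagged —
both models saturate). The global p-value comes from permuting well
labels; χ² asymptotics are avoided because most mutations are rare.
Stepwise identification removes the largest-ΔlnL mutation (ties broken by
lexicographic key), reruns the full test, and stops at p ≥ α; the removal
order with the p-value after each removal is returned. Reversions are
excluded by default: their opportunity is background-specific by
construction, which would trivially mimic epistasis.

**Reversion LRT.** Per-background binomial counts of reverted wells out of
available wells (totals may differ after QC); 2Λ referred to χ² with
B − 1 degrees of freedom. The statistic is the standard log-likelihood
difference; the χ² reference applies to twice that difference.

**Co-occurrence.** Unit of co-occurrence is the isolate; counts are
"wells where the pair shares ≥1 isolate". Singletons (one well) and
reversions are removed first. The null must preserve both margins the
observed count depends on — how many wells a mutation occupies and how
many isolates it fills within them — so a replicate re-places each
mutation independently onto a uniformly chosen set of wells of the same
size, permutes its per-well isolate counts across those wells, and picks
that many distinct isolates per well (a plain isolate-level shuffle is
available behind `isolate_level_null=True` for sensitivity analysis).
Expected counts are null means; p-values are two-tailed empirical with the
add-one estimator, capped at 1. Pairs with p < 0.05 but a single observed
co-occurrence are dropped from the main table as the most obvious false
positives; the full table keeps them with a `dropped` flag. No
multiple-testing correction is applied to `p` — the test is exploratory —
but a Benjamini–Hochberg column `p_bh` is emitted as a labelled
extension. Blocks (default: all catalog mutations inside the D-promoter
feature) are scored as "any member", and the block-vs-itself row counts
wells where two *distinct* members share an isolate — the signature of
mutual exclusivity within a functional element.

## Within-well trees

Isolate genotypes are binary characters rooted at the well ancestor. If
every mutation pair avoids the (1,0)/(0,1)/(1,1) pattern triple
(four-gamete condition with an all-zero root), the perfect phylogeny
exists, is unique, and is produced by sorting mutations by decreasing
isolate count (ties lexicographic) and threading genotypes into a prefix
tree. The same construction runs on incompatible matrices as a greedy
minimal-homoplasy heuristic — mutations may then label several edges, and
the homoplasy count (edges minus distinct mutations) is reported. The
greedy attains the true minimum on the toy fixtures verified against an
exhaustive Steiner-tree search, but is not optimal on all inputs (it is
bounded below by the optimum, which the suite also checks on random
inputs). Unsampled intermediates appear as zero-multiplicity nodes;
reversions are ordinary derived characters (a back-mutation edge).

Dynamics classes are assigned in order: **fixed** (one observed
genotype), **interference star** (every observed genotype is the shared
base — the intersection of all observed genotypes — or that base plus one
mutation), **sequential chain** (observed genotypes totally ordered by
inclusion), **branching multi-step** (everything else). The checks are
ordered, so the classes partition all wells.

A mutation is **adaptive** when it (1) occurs in ≥2 wells independently,
or (2) in some well is carried by at least `min_isolates_for_rise`
isolates (default 2 of ~5, i.e. ≥40% sampled frequency) *and* labels a
step where it is the sole difference from the nearest sampled ancestor
genotype — rising together with a linked driver does not count. The
default threshold is deliberately config-exposed: it operationalises
"rose above low frequency unaccompanied", for which no universal cutoff
exists.

## Selection coefficients and lysis curves

s is the per-replicate OLS slope of ln(mutant frequency) against
generation (generations = passages × 2 by default), averaged over
replicates, with the SE taken across replicate slopes rather than from a
pooled fit — replicates are the independent unit. Replicates touching 0
or 1 are excluded with a warning (the log transform is undefined;
boundary handling beyond exclusion is out of scope).

Lysis curves are per-genotype mean ± SE burst counts per time point (SE
requires ≥2 replicates). "When titer begins to rise" is operationalised
as the first time point whose mean burst exceeds `rise_multiple`
(default 2×) of the baseline, the mean over the first `baseline_points`
(default 5) time points; delays are differences of these lysis times, and
every delay is reported together with the threshold that produced it.

## The synthetic generator

`simulate_dataset` emulates the statistical structure the analyses
consume, not the biology that produced it:

- Per-well de novo mutation counts m ~ Poisson(λ) truncated to
  [m_min, m_max] (defaults 4.5 on [2, 9], matching the emulated
  experiment's per-well load).
- Mutation identities are drawn without replacement with probability
  ∝ expit(logit(p_k) + δ_kb): p_k is the catalog's base incidence and
  δ_kb an additive background effect on the log-odds scale — the lever
  for planting mutation–background epistasis.
- Within-well structure comes from a uniform-attachment genotype tree:
  each successive mutation attaches to a uniformly chosen existing
  genotype node, and isolates are sampled uniformly with replacement from
  non-root nodes. This reproduces all four dynamics archetypes with
  tunable frequencies while staying far simpler than a Wright–Fisher
  simulation, which the downstream analyses (which only see sampled
  genotypes) cannot distinguish anyway.
- Exclusivity groups are enforced per root-to-leaf path: two members may
  arise in one well, but never on one lineage — attachment is drawn
  uniformly over the nodes whose root path is free of other members.
- With probability r_b the background mutation reverts: the reversion key
  joins the tree like any mutation, and one sampled isolate is forced
  onto the reverted lineage, so r_b is the per-well incidence of an
  *observed* reversion (a reversion that persisted a hundred passages is
  not at trace frequency).
- Randomness is a hierarchical stream seeded per (background, well), so
  extending the design never perturbs already-generated wells.

`study_preset()` fixes the study conditions: 9 backgrounds × 8 wells
× 5 isolates, a 110-mutation catalog over a synthetic 5,577-nt
Microviridae-like annotation (real D-promoter coordinates 1909–1935;
gene coordinates and the ancestral sequence are fixed synthetic
stand-ins), two promoter hotspots (incidence 0.78 and 0.40) sharing one
exclusivity group with five rarer gene-D/E members, a long tail of
incidences (6 × 0.08, 12 × 0.04, 85 × 0.015) set by a one-off pilot so
that ~88% of wells generate at least one group member and most tail
mutations land in ≤4 wells, and heterogeneous reversion probabilities
(0.875, 0.375, 0.25, 3 × 0.125, 3 × 0) averaging ~15 reverted wells per
dataset.

What the generator does **not** emulate: selection within wells (isolate
sampling is uniform over genotypes, so hotspot *observed* frequencies sit
below their incidence parameters, unlike real sweeps), sequence-level
mutation processes, measurement error in mutation calling, or
contamination. Passing tests therefore demonstrate the statistics behave
correctly on data with this structure — calibrated null rejection rates,
recovery of planted effects — not that any biological conclusion about
real wells is reproduced.

## Numerical and design choices

- All permutation/bootstrap p-values use the add-one estimator; every
  randomized procedure takes an explicit seed and reproduces exactly.
- 0·log 0 = 0 throughout the binomial likelihoods; per-mutation ΔlnL is
  clipped at 0 against floating-point dust.
- Problem sizes in the test suite and acceptance script (200-dataset
  calibration runs at n_perm = 199 with 4 backgrounds × 4 wells;
  100-dataset recovery runs; 1,000–2,000 co-occurrence replicates) were
  chosen as the smallest designs whose Monte-Carlo error is comfortably
  inside the asserted bands.
- The planted-effect recovery experiment uses δ = +8 on a base incidence
  of 0.02 in one of four backgrounds — fixed by a pilot power run at
  which the planted mutation tops the ΔlnL ranking in ~98% of datasets.
- Degenerate inputs: wells with empty identity sets give missing P_ij
  (error only if *all* are empty); mutations present in no or all wells
  contribute ΔlnL = 0 and are flagged; a single background makes the LRT
  models coincide (Λ = 0, p = 1); fewer than two usable backgrounds is an
  error for the reversion LRT and ratio tests.

## Known limitations

- The co-occurrence null's two-stage re-placement is one reasonable
  scheme preserving both margins; other nulls (e.g. degree-preserving
  swaps) would differ in the tails. The isolate-level shuffle is provided
  for sensitivity checks.
- The greedy homoplasy tree is a heuristic on incompatible matrices; its
  count is an upper bound on the true minimum.
- Cluster assignment for overlapping genes uses the first-annotated gene;
  mutations in the same codon of the *second* gene but different codons
  of the first are not merged.
- The adaptive-evidence "rise" criterion depends on the sampled-frequency
  threshold; with ~5 isolates per well the distinction between "low" and
  "moderate" frequency is necessarily coarse.
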