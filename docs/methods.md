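# Methods

This note documents the models, estimators and design choices behind
`stokeshift`, in the spirit of the methods documentation of mature
phylogenetics packages: what is computed, under which assumptions, with
which defaults, and what the synthetic benchmarks do and do not establish.

## Substitution model

All likelihood computations assume a homogeneous general time-reversible
(GTR) amino-acid process: symmetric exchangeabilities `s_ab ≥ 0` and
equilibrium frequencies `π`, generator `q_ab = π_b s_ab` (off-diagonal),
rescaled so the expected rate at equilibrium is one substitution per site
per unit branch length. Detailed balance `π_a q_ab = π_b q_ba` holds by
construction and is validated to 1e-12 for the built-in JTT model.
Transition probabilities are computed by symmetric eigendecomposition of
`diag(√π) Q diag(1/√π)`, which is exact for reversible generators and
cheap enough to re-evaluate per branch and rate category.

### Protein-specific rate estimation

The protein-specific matrix is estimated directly from the alignment:

1. `π` from residue counts with one pseudocount per amino acid (keeps
   never-observed residues at small positive frequency so the generator
   stays irreducible in practice);
2. replacement counts pooled over all sequence pairs whose pairwise
   identity (over mutually resolved sites) lies in a window, default
   [0.20, 0.95] — near-identical pairs carry no information and highly
   diverged pairs are mutation-saturated;
3. multiple-hit correction by the matrix logarithm of the pooled
   row-conditional replacement-probability matrix. The real part of the
   log is projected to the nearest valid generator: negative off-diagonal
   entries (sampling noise) are clamped to zero and the diagonal
   recomputed;
4. exchangeabilities `s_ab = q̂_ab / π_b`, symmetrized by averaging with
   the transpose, then renormalized to unit expected rate.

The estimator is consistent in the regime that matters here (hundreds to
thousands of sites, tens of sequences): re-estimating from data simulated
under JTT (32 taxa, 5000 sites) recovers the 190 exchangeabilities with
Pearson r ≈ 0.99, and the estimator reproduces its own output at r ≥ 0.95
from 10,000-site resimulations. Degenerate inputs raise explicit errors
(identical sequences; an identity window containing no pairs).

### Rate heterogeneity

Among-site rate variation uses the standard discrete-gamma approximation:
`ncat` equal-probability categories, each category rate the *mean* of its
gamma quantile bin (the mean-of-bin form preserves the unit mean without a
renormalization step beyond floating-point cleanup). Defaults: 6
categories for reconstruction; the shape `α` is taken from configuration
or, when absent, chosen by maximizing tree likelihood over a fixed grid
from 0.1 to 10 — a deliberately coarse but deterministic substitute for a
full shape optimization. One category is simulated per site and held fixed
across the whole tree, matching the inference model's assumption.

## Ancestral reconstruction

Marginal empirical-Bayes posteriors are computed per inner node and site:
an inside (pruning) pass from the leaves, an outside pass from the root,
and `PP(n, s, a) ∝ Σ_c w_c · inside_c(n, s, a) · outside_c(n, s, a)`
normalized over amino acids, with rate categories integrated out rather
than assigned. Per-node per-site rescaling keeps the recursion finite for
alignments of at least ten thousand sites. Gaps and `X` are missing data
(all-ones partial likelihoods), so a data-free column's posterior equals
`π`. Polytomies are handled natively by the recursion.

This is a deliberate methodological substitution for profile-mixture MCMC
sampling of ancestors: it preserves the downstream contract — per-node,
per-site posterior vectors — while being deterministic and fast, at the
cost of ignoring across-site compositional heterogeneity and
reconstruction-model uncertainty. The posteriors agree with brute-force
enumeration over all ancestral state assignments to 1e-10 on small trees,
and are invariant under leaf reordering and re-rooting along a branch
(reversibility), to 1e-8.

Sampled ("full") libraries draw sequences site-independently from the
marginal posteriors under a seeded generator; this ignores the joint
dependence between sites that a true joint sample would carry, which is
acceptable for the d-measure (a function of marginals only).

## AltAll\*N libraries

Per site, the *plausible* states are those with posterior strictly above a
threshold (default 0.1), ranked by posterior with exact ties broken
alphabetically; the maximum-posterior state is always plausible, so every
site has at least one. The library holds `N = max_s n_s` sequences, and
sequence `k` carries the rank-`min(k, n_s)` state at site `s`. Sequence 1
is therefore the MAP ancestor and the last sequence combines each site's
deepest plausible alternative. Raising the threshold can only shrink the
library. This rank-clamped construction — rather than the single-sequence
"AltAll" of the resurrection literature — is the procedure the branch
scores consume.

## Branch scores

**Epistasis (rare-substitution) score.** For a branch from parent `u` to
child `v`, `L(u→v) = ln Σ_s Σ_{a≠b} PP_u(s,a) · PP_v(s,b) · 2 · NC(RF_ab)`
with `NC(r) = 1/(1+e^{200 r})` and `RF_ab = q_ab` of the unit-scaled
matrix, direction `a→b` as computed. The steepness 200 places the logistic
crossover near `q ≈ 0.01`: replacements an order of magnitude above that
contribute essentially nothing, replacements the matrix never makes
contribute up to `d = 1` when both posteriors are confident. The printed
formula is read as the four-factor product `PP_a·PP_b·2·NC` (keeping
`d ≤ 1` and `a, b` symmetric); the alternative reading `PP_a·PP_b²·NC` is
available as a configuration variant. By default only branches whose child
is an inner node are scored; leaf-terminated branches can be included, the
leaf contributing point-mass posteriors (gap sites contribute nothing).

**Structural change.** Library sequences are annotated per residue on four
tracks through a pluggable predictor; per branch and track the score is
the mean mismatch fraction over all parent×child sequence pairs (an
`O(L·|alphabet|)` counting identity avoids materializing the pairs).
Averaging over *cross* pairs is the default reading of "between all the
alternative ancestral sequences of neighboring nodes"; best-vs-best
comparison is available as `pairing="map"`. Annotations are computed on
the gap-free library sequences, which share the profile's site
coordinates, so positions correspond across nodes by construction.

The bundled **mock predictor** assigns each residue's class on each track
by a deterministic 64-bit hash (splitmix64 finalizer) of the residue and
its ±2 neighbours: translation-invariant, total, and local (a point
substitution perturbs at most five positions per track). It emulates the
*determinism and locality* of a real per-residue predictor, not its
biology: mock annotation changes are equally likely for conservative and
radical replacements, so synthetic structural-change scores track the
substitution count on a branch, not substitution rarity. The TSV adapter
serves precomputed annotations from any external predictor, matched by
sequence content, for real analyses.

**Classification.** Per metric, branches receive Hazen percentile ranks
`(rank − ½)/n · 100` with midpoint (average) ranks for ties; quartiles cut
at 25/50/75 (`Q1: ≤ 25` … `Q4: > 75`); a branch is flagged when its
percentile reaches the flag threshold (default 95). With all scores tied,
every branch sits at the 50th percentile (Q2) and none is flagged. Note a
consequence of the Hazen definition: with `n` branches the largest
attainable percentile is `100(n−½)/n`, so a 99th-percentile flag is
unattainable below ~50 scored branches — on small trees the 95th
percentile is the operative flag.

## The synthetic benchmark

The simulator emulates the study conditions end to end: pure-birth (Yule)
trees rescaled to height 1.0 substitutions/site (16 taxa for the branch
benchmarks), site-independent GTR evolution under JTT with gamma
heterogeneity (α = 1, 6 categories), 300-site sequences, and an optional
*conversion event*: one designated internal branch evolved under the same
frequencies but with the 190 exchangeabilities permuted by the fixed
rank-reversing derangement (largest↔smallest), rescaled to unit rate. The
reversal makes the replacements the global model considers rarest the
most frequent on that branch while leaving the expected substitution
count unchanged — a pure "which substitutions" deviation, which is the
signal the d-measure targets; a rate scaling would instead be a branch
length artifact.

The designated branch is drawn (seeded) uniformly among internal branches
spanning at least 30 % of the tree height, falling back to the longest
internal branch. A conversion event exists only through the substitutions
that express it; an event placed on a near-zero-length branch would be an
empty label that no statistic could recover, and the structural change
frequency in particular is intrinsically length-confounded, so the
synthetic event is defined as a major episode (≥ 0.3 expected
substitutions per site on the branch).

Under these conditions (50 replicates): the event branch reaches the top
epistasis quartile in ≈ 100 % of replicates and is the single
highest-scoring branch in ≈ 90–98 %; it reaches Q4 on at least three of
the four structural tracks in ≈ 86 %. Under the null (no event, 100
replicates) a pre-chosen branch is never flagged at the 99th percentile
(see the classification note above) and quartile assignments are uniform.
Gap injection is Bernoulli per cell from per-column and per-row
probability profiles, for exercising the hygiene filters' boundaries.

What passing these benchmarks does *not* show: robustness to alignment
error, to model misspecification beyond the simulated shift, to
compositional heterogeneity across sites or lineages, or that structural
Q4 calls on real data reflect structure rather than branch length — on
real proteins the predictor's biology (absent from the mock) carries that
burden. Problem sizes in the test suite (16–32 taxa, 300–5000 sites,
50–100 replicates) were chosen as the smallest at which the estimators'
asymptotics visibly hold.

## Numerical and interface choices

- Amino acids are indexed in PAML order `ARNDCQEGHILKMFPSTWYV`; rate
  matrices read/write the PAML `.dat` layout (190 lower-triangular
  exchangeabilities, then 20 frequencies).
- Unlabeled inner nodes are named `N<post-order index>` deterministically
  at parse time (root highest), so branch identifiers are stable across
  runs and serializations; labeled inner nodes keep their labels.
- Negative branch lengths are a parse error, never silently clamped.
- `X` counts as a residue (not a gap) in the hygiene filters; both filters
  use strict inequalities and are idempotent; filtering order is fixed
  sites-then-sequences and not iterated.
- Exact posterior ties anywhere (MAP calls, plausibility ranking) break
  alphabetically.
- The pipeline writes a manifest (resolved configuration, seed, input
  checksums); re-running a manifest's configuration reproduces every
  output byte-identically. All randomness flows from a single integer
  seed per run.

## Known limitations

- The reconstruction model is homogeneous GTR+Γ; lineage- or site-specific
  composition shifts are not modelled, and branches violating them may
  attract epistasis signal for the wrong reason.
- The epistasis log-sum is not length-normalized (by design, matching the
  percentile-comparison protocol), so long branches have elevated
  baselines; the percentile comparison is within-tree and nonparametric
  but not a significance test.
- `RF_ab` uses the directed generator entry; for very asymmetric
  frequencies the `a→b` and `b→a` weights differ, and no symmetrization
  is applied.
- The gamma-shape grid search trades resolution for determinism; supply
  `α` explicitly for final analyses.
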