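# Methods

`hgtscreen` decides whether a gene family in a recipient lineage was
horizontally acquired from bacteria.  The decision combines two independent
lines of evidence: a phylogenetic model-selection test (does the data prefer a
tree in which the recipient nests inside a bacterial donor clade over any tree
in which taxonomy is monophyletic?) and compositional amelioration tests (has
the gene's base composition and codon usage drifted toward the recipient
genome?).  This note records the models, the numerical choices, and what the
synthetic test-bed does and does not demonstrate.

## Homolog screening

Hits from a protein homology search (BLAST outfmt-6 tables) are retained when
the E-value is strictly below 0.001 and the hit overlaps the query's annotated
protein domain by strictly more than 50 aligned residues.  Both thresholds are
strict inequalities — boundary values are dropped — and both are configurable
(`ScreenConfig`).  Domain overlap is the intersection of the hit's query range
with a 1-based inclusive domain span supplied by the caller.  Each taxonomic
group then contributes its top ten subjects by bitscore (ties broken
lexicographically by subject id so runs are reproducible); groups named in
`unlimited_groups` — normally the recipient lineage itself — are exempt from
the cap.

## Alignment culling

Manual curation of an MSA ("remove sequences that are mostly gap against the
well-aligned core") is made reproducible with two knobs: core columns are
those with non-gap occupancy ≥ 0.8, and a sequence is culled when its gap
fraction over core columns exceeds 0.5.  Culling returns a
`recompute_needed` flag because removing sequences changes the optimal
alignment of the remainder; alignment computation itself (e.g. MUSCLE/MAFFT)
is deliberately external to the package.  All-gap columns are dropped after
culling.  Fewer than three surviving sequences is an error, since no unrooted
tree exists below that.

## Likelihood model

Protein evolution follows a general time-reversible empirical model: a
symmetric exchangeability matrix S (Poisson, Dayhoff, JTT, WAG or LG; the
matrices are embedded as text data files of the published constants) and
equilibrium frequencies π, giving Q_ij = S_ij·π_j with rows summing to zero,
rescaled to one expected substitution per site at equilibrium.  Transition
matrices come from the π-symmetrised eigendecomposition, which is computed
once per model and reused for every branch length and rate — this is the main
performance lever of the engine.  Tiny negative entries from eigen round-off
are clipped to zero.

Rate variation across sites uses the discrete-gamma construction: K
equal-probability categories (default K = 5, configurable 1–16) whose rates
are the in-category means of a mean-1 gamma(α, α), computed via the
incomplete-gamma identity rather than quadrature.  An optional invariant
class of rate 0 and weight p_inv is prepended, and the variable-class rates
are rescaled by 1/(1 − p_inv) so the mixture mean stays exactly 1; branch
lengths therefore keep their substitutions-per-site meaning across model
variants.  Gaps and `X` are missing data (partial likelihood one in every
state); columns missing in every sequence are dropped with a warning.

Site patterns are compressed before any computation.  Felsenstein pruning
runs per category with per-pattern scaling tracked in log space, and the
mixture is assembled with a log-sum-exp over categories, so invariant-class
mass reaches only constant patterns automatically.

### Optimisation

Branch lengths are optimised coordinate-wise.  One sweep computes inside
("down") partials post-order and outside partials pre-order; for an edge the
site likelihood factorises through the eigenbasis as
Σ_k (O·U)_k e^{λ_k t r} (D·U')_k, so each 1-D objective evaluation costs
O(patterns × states) per category and Brent's bounded method (branch lengths
in [0, 20] substitutions/site) is cheap.  Sweeps repeat until the lnL gain
falls below `tol` (default 1e-4) or 50 sweeps, with a warning on
non-convergence.  Gamma shape (bounded to [0.02, 100], searched in log space)
and p_inv (bounded to [0, 0.99]) are fitted by L-BFGS-B, alternating with
branch sweeps; because α and p_inv only change category rates, the cached
eigensystem survives these moves.

## Model selection

Scores are BIC = −2lnL + K·ln(n) and AICc = −2lnL + 2K + 2K(K+1)/(n−K−1)
with n the number of alignment columns — the standard convention in
phylogenetic model selection.  K counts 2·taxa − 3 branch lengths plus one
per free rate parameter (+G, +I).  Empirical frequencies (+F) add zero to K
by default (observed-frequency convention) with a documented switch to +19;
published K values from other programs are ambiguous on this point, so the
convention is explicit rather than asserted.  The default candidate set is
the 5 × 4 grid of model families × {plain, +G, +I, +G+I}, every candidate
refitted on the same topology and ranked ascending by BIC with AICc then
label as tie-breaks.

## Tree search and the transfer test

The ML search is neighbor joining on Poisson-corrected distances
(d = −ln(1 − p), saturated pairs at p ≥ 0.95 capped at 10 with a warning,
negative NJ branch lengths clamped to zero) followed by
nearest-neighbor-interchange hill-climbing.  Each candidate swap is scored
by re-optimising only the central edge against cached partials; the first
strictly improving move is applied and followed by a full branch-length
re-optimisation.  An exhaustive enumerator over all (2n−5)!! topologies
(practical to seven taxa) anchors the search's correctness in tests, rather
than trusting the heuristic.

A constrained search forces named taxon groups to be monophyletic: the start
tree is the plain NJ tree when it already satisfies the constraints (so
within-group structure stays data-driven); otherwise per-group NJ subtrees
are grafted onto an NJ backbone over group-average distances, with an
arbitrary within-group rooting.  NNI moves that would break any group are
rejected by a split-set check before evaluation.  Within-group arrangements
are re-optimised, not frozen.

The transfer test fits the unconstrained ML tree (the HGT-compatible model)
and one ladder of taxonomy-constrained alternatives (vertical descent),
refits the free model parameters on every topology, and reports Δ scores as
constrained − unconstrained (positive = worse).  Both ΔBIC ≥ 5 and
ΔAICc ≥ 5 counts as very strong evidence for the unconstrained model; the
threshold is the `evidence_threshold` configuration constant.  The operation
takes one substitution model and refits its free parameters per topology;
passing an explicit candidate list instead re-selects the whole model family
per topology (lowest BIC), which reproduces the common situation where
constrained alternatives carry slightly different best models (for instance
+I appearing only on a constrained row).

Bootstrap support is the standard column-resampling construction: replicate
alignments of the original length, a full search per replicate, and supports
(percent of replicates containing each split, rounded to integers) mapped
onto the best ML tree from the original alignment — not onto a consensus
tree.  Supports are bit-reproducible for a fixed seed.

## Compositional amelioration

%GC is 100·(G+C)/(G+C+A+T) with ambiguity codes excluded from numerator and
denominator.  Recipient and donor reference distributions are empirical, and
their two-tailed 95 % intervals are the 2.5th/97.5th percentiles with linear
interpolation — percentile bounds rather than normal theory, because real
genomic %GC distributions are skewed.  Sets smaller than 40 sequences get
an "unreliable" flag on the bounds.  A query %GC inside exactly one interval
is classified recipient-like or donor-like; inside both, ambiguous; inside
neither, neither.

CAI follows the classical relative-adaptiveness construction: zero counts
replaced by 0.5, w_c = count_c / family maximum, CAI the geometric mean of w
over informative codons (ATG, TGG and stops excluded as single-codon
families).  The expected CAI (E-CAI) is the 95th percentile of the CAI
distribution of `n_random` (default 500) sequences encoding the same protein
with codons drawn uniformly among synonyms — a no-adaptation null; `CAI >
E-CAI` is reported as "adapted".  Both the null and the percentile are
configurable; this is the conventional E-CAI construction, chosen here as
the package's own definition.

## Synthetic test-bed

The generator produces datasets whose transfer history is known, at the
scale used throughout validation: 16 taxa in four clades of four (recipient
clade, donor clade and two outgroup clades), 300-site alignments under LG+G
(α = 1).  Clades are independent Yule subtrees (birth rate 8, giving
within-clade depths of roughly 0.2–0.3 substitutions/site) joined by a fixed
backbone of 0.25-length stems — realistic interdomain divergence without
saturation.  A transfer is a single subtree-prune-regraft of the recipient
taxon onto the donor clade's stem with a pendant "stalk" of 0.05,
representing divergence since transfer; the recipient's taxonomy label stays
with its original clade, so the vertical-descent constraint is violated
exactly when a transfer happened.  Gene-duplication histories, indels,
covarion-style rate drift and multiple transfers are out of scope.

Codon provenance uses one mechanism for both compositional signals: a
recipient-like usage table preferring AT-rich codons and a donor-like table
preferring GC-rich codons (counts proportional to g^{#GC} with g = 0.25 and
4 respectively), mixed within synonymous families by a weight λ ∈ [0, 1]
(0 = fully ameliorated to the recipient, 1 = fully donor-like).  The focal
gene is back-translated at λ (default 0.8, a recent transfer); background
genes at λ = 0 and λ = 1 define the reference distributions.  %GC separation
between the two tables is wide (roughly 37 % vs 57 %), so GC classification
on synthetic data is easier than on real genomes with overlapping
distributions — passing tests demonstrate calibration and correctness of the
machinery, not field sensitivity.

What the simulations do not emulate: alignment error and gap patterns (the
simulator is indel-free, so culling is exercised on constructed fixtures),
compositional heterogeneity across lineages, codon-usage variation across
genes within a genome, and the deep, unbalanced taxon sampling of real
screens with hundreds of sequences.

## Problem sizes used in validation

Exactness checks (pruning vs enumeration) run on 4–5 taxa and ≤ 10 sites,
where full state enumeration is feasible.  Recovery studies use 12 taxa with
400 sites (model selection over the 20-candidate grid) or 1000 sites (gamma
shape), 20 replicates each.  Transfer-test power and calibration use the
16-taxon/300-site benchmark, 20 transfer and 20 vertical replicates; search
correctness and the constrained-likelihood bound use ≤ 6 taxa where
exhaustive search is exact.  Compositional calibration uses 1000 reference
and 1000 held-out coding sequences.  These sizes were chosen as the smallest
at which each property is statistically meaningful.

## Known limitations

- NNI (not SPR/TBR) search: adequate at benchmark scale and verified against
  exhaustive search on small instances, but real screens with hundreds of
  taxa would want a stronger search and starting-tree diversity.
- The constrained start tree's within-group rooting is arbitrary when the
  plain NJ tree violates the constraints; constrained optima can in
  principle be missed, which biases the test conservatively *against* the
  unconstrained model only when the constrained fit is undersold — on the
  null (vertical) benchmarks the constrained search reaches the
  unconstrained optimum, so the effect is not visible at validation scale.
- Branch lengths share one global rate mixture; no partitioning, no codon or
  nucleotide models, no ancestral-state reconstruction.
- E-CAI here is a uniform-synonym null; published E-CAI variants differ in
  the null and in significance interpretation, so absolute values are
  comparable only within this package.
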