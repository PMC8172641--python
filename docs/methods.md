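# Methods

This note documents the models behind `wgdkit`, the defaults that matter,
what the synthetic-data generator does and does not emulate, and the
numerical choices a maintainer would otherwise have to reverse-engineer.

## Gene-family birth–death simulation

Gene trees are simulated inside a rooted, ultrametric species tree.  One
gene lineage enters the root; along every branch each extant lineage
duplicates at rate λ and dies at rate μ (a linear birth–death process,
simulated by per-lineage exponential waiting times).  At an episodic WGD —
specified by a branch, a time on that branch, and a retention probability —
every lineage alive on the branch duplicates, and each *new* copy
immediately survives with independent probability `retention`; this
implements "at least 20% of genes retained" as a per-gene Bernoulli.
Extinct subtrees are pruned and unifurcations suppressed, so returned trees
are time-ultrametric with leaves labelled `SPECIES|gene`.

Defaults: λ = μ = 0.002 events per gene per My, a typical magnitude for
plant nuclear gene turnover on trees ~100–150 My deep; the root condition
is a single gene (no root family-size distribution).  Coverage filtering
("at least one tip per species") is plain rejection sampling and the
acceptance rate is reported; simulation aborts with a diagnostic if the
acceptance rate falls below 10⁻³, since that indicates rates incompatible
with the coverage requirement.  How lineages born and dying within a single
branch are conditioned differs between guest-tree simulators; we implement
the unconditioned linear process.

## The Ks clock and its noise

Pairwise synonymous divergence is assigned from the simulated tree as
`ks = 2 · r_s · t_MRCA`, with r_s = 0.01 Ks per My by default, multiplied
by gamma noise with mean 1 and coefficient of variation 0.15.  The gamma
form keeps Ks non-negative and produces approximately lognormal peak
shapes of realistic width; real Ks estimates have divergence-dependent
error that this constant-CV model does not attempt to capture.

## NG86 Ks estimation

For real codon alignments, Ks/Ka are estimated by Nei–Gojobori (1986)
counting with Jukes–Cantor correction: per codon, synonymous site content
is three times the synonymous fraction of its nine single-base changes
(mutations to stop codons excluded from the denominator); differences
between codons are averaged over all mutational orderings, discarding
orderings that pass through a stop codon; `ks = −(3/4)·ln(1 − (4/3)·p_s)`,
with p_s ≥ 3/4 reported as a saturation error.  Gap-containing codons are
dropped pairwise.  NG86 assumes equal base frequencies and no
transition/transversion bias, and therefore systematically underestimates
Ks at high divergence relative to codon-model ML (e.g. F3X4); the Ks-table
reader exists precisely so users can substitute ML estimates.  The test
suite validates the estimator against a brute-force enumeration oracle over
all sense-codon pairs.

## Node-weighted age distributions

When pairs carry duplication-node tags, each node's pairs share total
weight 1 equally (after windowing), so a family of 2ᵏ descendants does not
contribute O(4ᵏ) pairs of mass; untagged pairs weigh 1 each.  The default
fitting window is Ks ∈ [0.01, 3]: below 0.01 allelic noise and identical
pairs dominate; 3 comfortably covers peaks up to Ks ≈ 1.1 while excluding
the saturated tail.  Both node-weighted and raw-pair modes are available;
node-weighted is the default.

## Mixture model and component selection

Peaks are modelled as a k-component Gaussian mixture on ln Ks fitted by EM
with per-observation weights.  Numerical choices: 10 restarts (weighted
quantile-split initialisation, jittered after the first), relative
log-likelihood tolerance 10⁻⁸, at most 500 iterations, a σ floor of 10⁻³
on the ln scale, and a monotonicity assertion on the log-likelihood every
iteration.  The inner loop is JIT-compiled (numba) because the bootstrap
below refits the model thousands of times.

k is selected by a sequential parametric-bootstrap likelihood-ratio test
(k vs k+1, k = 1, 2, …), stopping at the first p > α (default 0.05) or at
k_max (default 4), with 200 bootstrap replicates per test.  Bootstrap
refits use 3 restarts, tolerance 10⁻⁶ and 200 iterations — parameter
precision is irrelevant there, only the null spread of the statistic — and
the observed statistic is computed with those same settings so that
optimisation quality cancels between numerator and null.  Sampling is
curtailed once enough exceedances have accumulated that the test can no
longer reach significance; the reported p then uses the replicates actually
drawn, which only makes the stopping decision earlier, never different.
Bootstrap samples are unweighted at the rounded effective sample size.
A peak's "median Ks" is e^μ of its component (the lognormal median).

## Ortholog divergence and peak placement

Cross-genome ortholog pairs are chosen by reciprocal best pairing with
minimum Ks as the similarity proxy (how ortholog pairs are selected for
divergence estimates varies between studies; syntenic orthologs are a
stricter alternative not implemented here).  The reported statistic is the
median Ks with a 1000-replicate bootstrap percentile CI.  A designated
mixture peak is called `shared-ancestral` when its bootstrap CI lies
entirely above the ortholog CI, `lineage-specific` when entirely below,
`ambiguous` otherwise.

## Anchors, chaining, syntenic depth

Anchors are Cartesian gene pairs within shared families; families with
more than 10 members in either genome are skipped as tandem-array/repeat
guards (the cap is a design choice).  Chaining works per chromosome pair
and orientation: a maximal-cardinality collinear chain (rank_a strictly
increasing, rank_b strictly monotone, at most 10 intervening genes between
consecutive anchors on *both* genomes — the stricter two-sided reading of
a "ten gene" cut-off) is found by O(n²) dynamic programming, extracted, its
anchors consumed, and the search repeated; chains under 5 pairs are
discarded.  Ties break toward larger combined span, then input-order
determinism.  Strand is reported per block (same/inverted) but never gates
chaining eligibility.

Depth is gene-rank coverage: for each gene, the number of block spans from
the opposite genome covering its rank.  The multiplicity ratio uses the
modal *nonzero* depth on each side — uncovered genes say nothing about
multiplicity, but the full histogram (including bin 0) is always reported —
and is printed unreduced (2:4, not 1:2), since the unreduced form carries
the absolute round count.  Whether published depth ratios are modal depths
or percentile summaries of the depth histogram is tool-dependent; modal is
implemented here with the histogram exposed.

## MAPS-style placement tests

The species tree must be strictly ladderized; ladder node N_i is the
ancestor of the first i+1 ingroup taxa (tip-to-root order).  Each gene tree
is rooted at its first outgroup tip (sorted by label; trees with no
outgroup are skipped and counted).  Every internal node maps to the
species-tree node that is the LCA of its leaf-species set and is a
duplication when two children's species sets intersect (species-overlap
reconciliation — the standard criterion, chosen here as the interpretation
of "duplications shared by descendant taxa").

The counting unit is the **maximal subtree**: a gene-tree node mapping to
N whose parent maps elsewhere; connected same-node regions count once, and
a subtree is "duplicated" if any node of its region is a duplication.
This choice matters: a retained WGD copy adds both extra duplications *and*
extra subtrees at nodes below the event, so per-subtree percentages stay
comparable between null and positive simulations, whereas per-tree binary
counting would let a WGD at one node inflate apparent duplication rates at
every descendant node.

Null simulations use 3000 coverage-filtered birth–death trees;
positive simulations add one WGD (retention ≥ 0.2 enforced, overridable
with a warning) halfway along the stated branch.  Uncertainty comes from
resampling 1000 trees without replacement 100 times (2.5–97.5 percentile
intervals).  Enrichment over the null is tested per node with a one-sided
(greater) Fisher's exact test on [(shared, not-shared) × (observed, null)];
no cross-node multiple-testing correction is applied, matching the
described protocol, so with four tested nodes roughly one run in five
shows a nominal false flag somewhere.  "Consistent with positive" means
Fisher-significant *and* observed percentage at or above the positive
simulation's lower resampling bound.

## Birth–death rate estimation from gene counts

Global (λ, μ) are estimated by maximum likelihood from family × species
count tables: Felsenstein pruning over copy-number space (truncated at 100
copies, tightened to max observed + 5), per-branch transition matrices
computed as the matrix exponential of the truncated birth–death generator
(uniform in λ = μ, where the closed forms degenerate), root count 1, and
conditioning on at least one surviving gene; all-zero families are dropped.
Optimisation is L-BFGS-B on (ln λ, ln μ) from three starts with bounds
[e⁻¹⁴, e]; estimates at the boundary (e.g. all-single-copy data driving
λ̂ → 0) are flagged in the diagnostics.  Identical count patterns are
collapsed with multiplicities for speed.

## What the generator does and does not emulate

It reproduces the statistical structure the analyses assume: birth–death
topology and timing, WGD retention, clock-with-noise Ks, and fractionated
polyploid gene orders with inversions.  It does not simulate sequences,
alignment or Ks-estimation error structure, gene conversion, tandem
duplication clustering, transfer, or incomplete lineage sorting.  Passing
tests therefore demonstrate that the inference machinery recovers the
truth *under its own model assumptions* — they do not certify performance
on real genomes, where anchor noise, assembly artefacts and rate variation
add error modes the generator omits.

## Problem sizes used in the checks

The bundled acceptance checks run at the protocol's stated scales where
one exists (3000 gene trees per MAPS simulation, 1000×100 resampling,
3500-pair mixture samples, 3000 families for rate estimation, 1000
ortholog pairs) and at 1000-gene base genomes for the depth-ratio
recoveries, where chaining statistics are already stable.
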