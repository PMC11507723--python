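# Methods

This note documents the models implemented in `complexkit`, the
parameters that matter, what the synthetic fixtures do and do not
emulate, and the numerical choices made where the design was open.

## Co-occurrence model (WMM)

Each experiment in a compendium is reduced to its set of detected
proteins; a protein counts as detected iff its abundance score is
*strictly* greater than the filter threshold (default 2.0 on a Z-score
scale; 4.0 gives a stricter second feature group). For a pair co-detected
`k` times, with marginal detection counts `n` and `m` over `N`
experiments, the feature is the upper hypergeometric tail
P(#shared ≥ k), evaluated in log space via log-gamma and log-sum-exp so
that compendia with tens of thousands of experiments neither overflow nor
underflow. Pairs never co-detected carry no row: absence of evidence is
encoded as missing and imputed (default 0, configurable) only when the
classifier input is assembled. Feature groups are computed per dataset
tag; a protein appearing in several tagged compendia contributes to each
separately.

## Gold standard

Redundancy reduction measures overlap by Jaccard on member sets and, at
or above the merge threshold (default 0.6), removes the larger complex
(ties drop the lexicographically later id, making the procedure
deterministic); complexes above the size threshold (default 30) are
removed first. An optional rule additionally removes complexes fully
contained in a larger one (off by default). The random split assigns each
complex to train or test with equal probability; whenever a train and a
test complex share a protein pair, the larger is removed, and after pair
expansion any pair labeled on both sides is deleted from both maps —
the test set therefore shares no pair with training, which the test suite
asserts exhaustively. Isoform suffixes are stripped on load.

## Classifier

A single gradient-boosted learner (XGBoost; scikit-learn's
GradientBoostingClassifier behind the same interface via
`learner="sklearn"`) is trained on all labeled positives plus up to
10,000 negatives subsampled without replacement. No further class
weighting is applied; balancing is by subsampling only. The feature
schema is frozen at fit time and scoring rejects mismatched schemas.
Precision-recall uses step-wise (rectangular) integration over recall;
linear interpolation in PR space is deliberately avoided as optimistic.
The curve agrees point-for-point with scikit-learn's
`precision_recall_curve` on shared thresholds (tested), but the AUPRC is
the step integral, not average precision over samples.

## Two-stage clustering

The network keeps edges with score ≥ the threshold. Dense regions grow
greedily from high-weighted-degree seeds, maximizing the cohesiveness
f(C) = w_in / (w_in + w_bound + p·|C|) with penalty p = 2, accepting the
best single-node add or remove move until none improves; grown clusters
are therefore locally optimal under single-node moves (asserted against a
brute-force oracle). Grown clusters merge while their match coefficient
|A∩B|²/(|A||B|) is ≥ the max-overlap parameter, and clusters smaller than
3 or below the density floor are discarded; note the merge and filter
steps may produce unions that are themselves no longer single-move
optimal — local optimality is a property of the growth stage.

MCL runs on each region's induced subgraph: self-loops at each node's
maximum incident weight, column normalization, then alternating expansion
(matrix squaring) and inflation (elementwise power, renormalization,
pruning below 1e-8) until the maximum column change is below 1e-6 or 100
iterations. Clusters are connected components of the attractor
structure, so flow never joins disconnected components.

Post-filters mirror the published pipeline semantics: a member survives
only if some within-cluster edge weight is *strictly greater* than the
score threshold (the build step's ≥ vs the post-filter's > is a
deliberate, documented asymmetry); clusters reduced below 2 members or
larger than 100 are dropped; exact duplicates collapse. The parameter
sweep enumerates whatever grid it is given (the reference grid of
14 thresholds × 2 overlaps × 4 densities × 9 inflations yields 1008
combinations) and records weighted k-clique precision/recall against the
training complexes. Tier selection supports manual choice or a Pareto
helper that keeps non-dominated (P, R) rows, thins them to at most six
spread along the frontier, and orders them by precision; the union
assigns each unique member-set the best tier in which it occurs.

## k-clique metric

For each k from 2 upward, the k-subsets of predicted clusters are
compared against gold complexes: precision_k is the fraction of distinct
predicted k-subsets contained in some gold complex, recall_k the
symmetric quantity. Subsets are counted as distinct sets across
overlapping clusters (no multiplicity), preventing shared cores from
being counted twice; per-size values are averaged with weights equal to
the number of same-side sets of size ≥ k. When the number of k-subsets on
a side exceeds the sampling limit (default 10,000), clusters are drawn
proportional to C(|c|, k), a uniform k-subset is taken from each draw,
and draws are deduplicated; this is uniform over distinct subsets exactly
when clusters do not overlap, and agrees with exact enumeration within
0.02 on the tested fixtures.

## Annotation enrichment and transfer

Enrichment reuses the hypergeometric tail kernel: for a complex of size
n overlapping a term in k proteins, with m term members inside the
background of N proteins, p = P(overlap ≥ k | n, m, N). BH correction is
applied within each complex across its tested terms (a global family is
available via configuration). The shuffled baseline permutes membership
slots across complexes and repairs duplicates by swapping, preserving the
complex-size multiset exactly. Transfer requires: ≥ 50 % of members carry
the term (the candidate protein counts in the denominator; switchable),
adjusted p ≤ 0.01, candidate annotation score ≤ 3, term not root-flagged,
and the candidate not already a term member. Ontology-graph propagation
is out of scope; term sets are taken as given.

## Structural mutual exclusivity

Models are retained iff pDockQ > 0.23, interface pLDDT > 70 (both
strict) and fewer than 5 residues (strict) across both chains have a
heavy atom within the clash distance of the other chain. The clash
distance is not fixed by the published workflow; the default here is
2.0 Å, configurable and recorded. When quality metadata is absent, pDockQ
is computed from coordinates with the published logistic (0.724, 0.052,
152.611, 0.018) on mean interface pLDDT × log10(interface residue
count); metadata always wins when present.

Superposition globally aligns the two common-chain sequences
(Biopython's pairwise aligner) and fits matched Cα atoms by Kabsch SVD
with a guaranteed proper rotation; at least 20 matched residues are
required, and no outlier-rejection cycles are run — determinism and
testability were preferred over emulating a specific viewer's heuristics.
Interfaces are residues with any heavy atom within 4.0 Å (inclusive) of
the model's own common chain; hydrogens are ignored. Overlap counts
distinct interface residues of either unique chain within 4.0 Å of the
other unique chain's interface residues, summed over both chains
(a per-chain maximum is available). Labels: overlap > 10 → mutually
exclusive; overlap = 0 → structurally consistent unless the unique chains
overlap anywhere in > 100 residues (model-clash exclusion); otherwise
inconclusive. Classification is symmetric in model order and invariant
to rigid pre-transforms (tested). Allosteric, non-steric exclusivity is
out of scope.

## ALL-IN score

Log abundances are z-scored per protein across its observed cell lines.
The robust correlation is the biweight midcorrelation with the standard
9-MAD tuning; it returns missing when either MAD is zero or fewer than
`min_overlap` pairwise-complete observations exist. `min_overlap` is 10
for correlations across cell lines (sub-score 1 and the within-lineage
correlations of sub-score 4); correlations across *lineages* (sub-score 2
and the outer correlation of sub-score 4) instead require at least 3
shared lineages, because lineage counts are an order of magnitude smaller
than cell-line counts.

Sub-score 3 restricts to proteins detected in ≥ 50 cell lines, imputes
missing values from N(−4, 0.3) — far below the observed z-range,
representing below-detection abundance — and, for each pair, averages the
two top-50-minus-bottom-50 mean differences (ties in selecting the top
and bottom cell lines break by cell-line id). Sub-score 4's per-lineage
protein-to-complex correlations are computed **on the same imputed
matrix**. This is a deliberate design choice on a point the procedure
leaves open: without imputation the sub-score is undefined for exactly
the never-co-detected pairs it is meant to flag, while with it an absent
subunit correlates near zero with its complex in lineages where it is not
expressed — precisely the lineage-specific signature the sub-score looks
for.

All four sub-scores measure co-expression, so all are negated before
combination (for sub-score 3, exclusive pairs drive the top-vs-bottom
difference toward the −4 imputation floor, making it strongly negative);
the orientation is recorded in `SUBSCORE_ORIENTATION`. Oriented
sub-scores are z-scored across all scored co-complex pairs (the default
family; the alternative of z-scoring only structurally called pairs is a
caller-side filter) and averaged; pairs with fewer than two sub-scores
are omitted. Homomultimer stratification groups pairs by whether their
common subunit homomultimerizes and compares the ALL-IN distributions by
Mann-Whitney U. The per-complex covariation summary takes the median of
intra-complex pair scores over complexes with ≥ 4 subunits, ≥ 50 %
subunit coverage, and (when tiers are present) an adequate tier.

## Synthetic fixtures: what they emulate, and what they do not

All generators are pure functions of their spec (seed included); each
uses its own seed stream, so changing one section's parameters does not
perturb another's draws.

**Compendium.** Each experiment samples one planted complex as bait
context, detects its members with probability 0.8, and adds background
preys at rate 0.05 from a 60-protein background pool; sub-threshold
observations exercise the abundance filter. A second complex co-purifies
with probability 0.3 — as unrelated assemblies routinely do in pulldowns
— which matters for the classifier: without it, every labeled negative
(cross-complex) pair would have an all-zero feature vector, the negative
class would collapse to a single point, and the classifier would learn
that *any* co-occurrence implies co-complex membership. With
co-purification, negatives carry weak but real evidence the model must
learn to discount. The generator does not model peptide-level MS noise,
batch structure, or abundance-dependent detection; passing tests show the
pipeline recovers planted structure under idealized independent
detection, not that it reproduces any published map.

**Dimers.** The common subunit is a gently helical Cα trace (a straight
trace would leave the Kabsch rotation degenerate about the chain axis),
with one CB dummy atom per residue to exercise any-atom distance logic;
unique chains dock over the same central segment (planted exclusive,
offset 1 Å so interfaces collide after superposition) or on the opposite
face (planted consistent, > 7 Å separation). The second model of each
instance is emitted under a random rigid transform so superposition is
always exercised. Quality metadata is written so planted models pass the
filters. Real structure-model pathologies — disorder, wrong-fold models,
partial interfaces — are not represented.

**Expression.** Four lineages × 40 cell lines per lineage; each planted
pair sits in its own 5-subunit complex whose extra subunits follow the
complex's lineage-mean profile (sd 1) plus noise (sd 0.2). Consistent
pairs follow the profile everywhere; exclusive pairs split the lineages
in half and are entirely unobserved outside their half — so they are
never co-detected, and their ALL-IN eligibility rests on sub-scores 3 and
4, which is exactly why those sub-scores use imputation. An optional
fraction of exclusive pairs is planted with only mild anti-correlation
(both proteins broadly detected) to emulate a homomultimeric common
subunit offering multiple equivalent binding sites; note that *strong*
global anti-correlation would be a stronger combined signal than hard
disjointness, so attenuation, not reversal, is the right model here.
Additional missingness is applied at rate 0.1.

**Annotations.** One coherent term per planted complex covering all
members except the planted uncharacterized proteins (annotation score 3),
plus background-only padding members and a root-flagged decoy. By
construction the qualifying transfer set is known exactly and the
enrichment p-values are orders of magnitude below the 0.01 threshold.

## Problem sizes and numerical tolerances

The test and acceptance workloads use 20 planted complexes (sizes 3–10)
over 200 experiments, 50 + 50 dimer instances, 30 + 30 expression pairs
over 160 cell lines, and 8 annotated complexes — sizes at which exact
enumeration oracles (hypergeometric tails at N ≤ 12, all k-subsets,
single-move cohesiveness checks) remain feasible and the full suite runs
in minutes on one core. Oracle agreement is asserted at 1e-12 for the
hypergeometric tail, 1e-6 Å RMSD for superposition of transformed
copies, 0.02 for sampled-vs-exact k-clique values and bicor-vs-Pearson
on clean Gaussian data. Degenerate inputs are defined throughout:
constant expression rows are dropped with a warning, zero-MAD vectors
yield missing correlations, empty predicted cluster sets report zero
precision with an explicit flag, and MCL non-convergence returns the
current state with a warning rather than failing.

## Known limitations

- The classifier consumes whatever feature columns it is given;
  externally computed features (co-fractionation correlations, spectral
  counts, socioaffinity and the like) enter as pass-through columns and
  are not recomputed here.
- k-clique sampling is approximately uniform over distinct subsets only
  when predicted clusters overlap little.
- The enrichment engine is a plain hypergeometric/BH test; it will not
  numerically match web services that use custom multiple-testing
  corrections.
- Mutual-exclusivity calls are purely steric; allosteric exclusivity and
  conformational heterogeneity are invisible to the overlap rule.
- The ALL-IN orientation assumes anti-correlation and large expression
  differences indicate exclusivity; co-regulated paralog pairs that are
  exclusive yet positively co-expressed will be missed.
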