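# Methods

`barcurate` implements an iterative curation workflow for DNA-barcode
reference libraries: delimit OTUs in the reference with several methods,
assign unknown specimens against the consensus OTUs, pool the queries
into the library, delimit again, and use the second delimitation both to
score the first round's assignments and to promote representatives of
newly discovered OTUs before a second assignment round.  This note
documents the models, the conventions chosen where the design was open,
and what the synthetic data generator does and does not emulate.

## Distances and the barcode gap

Pairwise distances use the Kimura two-parameter model,

    d = -1/2 ln((1 - 2P - Q) sqrt(1 - 2Q)),

with P and Q the transition and transversion proportions over the
pairwise-comparable sites (sites with gaps or ambiguity codes are
excluded pair by pair, so an `N` never forces a record out of the
analysis).  When the log argument is non-positive (saturation) the pair
gets an infinite sentinel distance, is excluded from median statistics,
and is counted in a logged warning; the clean data this workflow targets
never reach saturation, but a convention is required.

For a partition into OTUs, the gap table reports per OTU the maximum
intraspecific distance (0 for singletons) and the nearest-neighbor (NN)
distance — the smallest distance from any member to any member of
another OTU, ties broken toward the lexicographically smallest neighbor
id.  An OTU *has a barcode gap* when NN strictly exceeds max-intra.
Global medians are taken over OTU rows (singletons included), and the
fold ratio is median-NN / median-max-intra.  Distances are unit
fractions internally; reports may render them x100.

## Surrogate trees

The tree-based delimiters accept user-supplied newick trees (an
externally inferred ML tree or Bayesian chronogram); when none is given,
desk-scale surrogates are built from the K2P matrix:

* **Neighbor joining** (Saitou–Nei Q criterion) for the PTP input,
  midpoint-rooted.  Negative branch lengths are clamped to zero with the
  deficit moved to the sister branch, preserving the joined pair's
  distance; additive matrices are reproduced exactly.
* **UPGMA chronogram** for the GMYC input.  A strict clock converts
  distance to time: 1.2% *pairwise* divergence per My by default (i.e.
  0.6% per lineage — the clock convention is pairwise, stated here
  because the rate is often quoted ambiguously), so a merge at average
  distance d sits at age d / 0.012 My.

Identical sequences are pruned to one representative (first by input
order) before delimitation and the resulting labels are re-expanded to
the duplicates afterwards.

## Delimitation methods

**RSL** — single linkage at a 2.2% seed threshold, then refinement: for
each cluster, the 2-way split obtained by cutting its deepest
single-linkage merge is accepted when it raises the mean silhouette
(computed on the distance matrix; a one-cluster partition scores 0 by
convention, an all-singleton partition is never preferred).  This is a
documented approximation of registry-style refined single linkage and is
explicitly not BIN-compatible.

**ABGD** — for each prior p on a geometric grid (0.001–0.1, 10 steps),
scan the ranked pairwise distances for the first significant gap ending
above p; a gap is significant when its width exceeds 1.5x the local
slope, estimated as the mean of up to 10 neighboring gaps on each side.
Records are clustered by connectivity at the gap's lower edge and the
scan recurses within groups until stable.  The reported partition is
selected among *self-consistent* priors — those whose partition's
realized maximum within-group distance does not exceed the prior, since
the prior is by definition the assumed maximum intraspecific divergence.
Among self-consistent priors the group count with the widest plateau
across the whole grid wins, at the largest qualifying prior.  (A plain
modal-count rule is dominated by the degenerate low-prior oversplit
plateau, where every tiny prior yields the same noise-driven partition.)

**PTP** — species are subtrees under a cut set of nodes; branch lengths
within species and between species are modelled as exponential (one rate
per class in single mode; one rate per species subtree plus a
between-species rate in multi mode, the default).  Branch lengths are
floored at 1e-8 for the likelihood; a tree in which more than 80% of
branches are effectively zero carries no rate signal and returns the
one-species partition with a warning.  The maximum-likelihood cut set is
found by greedy hill climbing over split/merge moves from *both* extreme
states — all-one-species and all-singletons — plus seeded random
restarts; on small trees the search provably matches exhaustive
enumeration (tested), and the two-ended start matters: the one-species
start alone can stall in merge-heavy local optima.

**GMYC** — on an ultrametric chronogram, branching events older than a
threshold are Yule speciations, younger ones are coalescences within the
entities below the threshold.  Between successive branching events the
total rate is

    b = lambda_div * n_div^p_div + lambda_coal * sum_k (n_k(n_k-1)/2)^p_coal,

and each interval of length x contributes b exp(-b x) (the final
interval to the present contributes only the survival term).  The
threshold is realized as a cut set of entity-root nodes: an entity's
stem edge stays on the diversification side, so each lineage's effective
threshold is its entity's root age.  Rates and powers are optimized
numerically (L-BFGS-B, multiple starts) per candidate threshold (one
candidate between each pair of adjacent branching times, plus one below
all of them).  A likelihood-ratio test against the single-coalescent
null (chi-square, df = 2 by default — a debated choice, exposed as a
knob) gates the result: non-significant means one OTU.  Multi-threshold
mode (the default) refines the best single-threshold cut set by greedy
split/merge moves; the single-threshold model spends 5 parameters (4
rates/powers + 1 threshold) and each accepted move adds one "deviation"
parameter, compared by small-sample AICc over the n-2 waiting intervals.
AICc rather than AIC matters here: the sample is tiny and plain AIC
accepts knife-edge splits of near-identical haplotype pairs.

**Consensus** — two records share a consensus OTU when at least 2 of the
4 methods co-cluster them; consensus OTUs are the connected components
of that co-membership graph, so agreement is transitive.  Methods are
weighted equally.  The same >= 2 rule mirrors the 2-of-3 convention used
for assignment.

## Specimen assignment

One representative per consensus OTU is drawn uniformly at random
(seeded).  Two per-OTU anchors come from the *full* library distances,
before the reduction to representatives: theta1 = the OTU's maximum
intraspecific distance (singletons fall back to the global median of
multi-member values, 0.005 if there is none) and theta2 = the OTU's NN
distance.

* **FZ**: nearest representative by K2P; the probability is a Z-shaped
  fuzzy membership function of the distance x with a = theta1 and b =
  theta2 of the selected OTU — 1 for x <= a, 0 for x >= b, quadratic
  shoulders meeting at 0.5 at the midpoint; degenerate b <= a collapses
  to a step at a.  Because FZ selects by minimum distance, its ratio
  diagnostic never exceeds 1.
* **FZKMER**: alignment-free; normalized k-mer frequency vectors with k
  chosen as the smallest value (up to 5) maximizing leave-one-out
  self-assignment accuracy on the full library; assignment by nearest
  representative in k-mer space (Euclidean); FMF anchors are the 95th
  percentile of intra-OTU and 5th percentile of inter-OTU k-mer
  distances.
* **BP**: a one-hidden-layer backpropagation network (10 logistic
  hidden units, softmax output, 3-mer features) trained on every library
  member labelled by its OTU; the probability is the winning softmax
  output.  Training is deterministic under the seed.

The consensus verdict requires >= 2 of the 3 methods to agree (3/3 or
2/3), otherwise "ambiguous"; the mean probability always averages the
three method probabilities.  The ratio diagnostic — distance to the
selected OTU over distance to the nearest *other* OTU, both in K2P space
for all three methods so the figures share one axis — flags candidate
false positives when it exceeds 1.  (The alternative reading of the
ratio's denominator, the selected OTU's own NN distance, is available
via `theta2`; the query-relative form is the one whose values span 0–1
with >1 pathologies.)

## The two-round workflow and its accounting

Round 1 delimits the reference, builds the consensus and the assignment
reference, and assigns every query.  Round 2 delimits the pooled set
(reference + queries): consensus OTUs containing only queries are *new
OTUs*, each contributing one seeded-random promoted representative to
the updated reference; merges and splits are honored by rebuilding the
assignment reference from the pooled consensus restricted to the updated
reference records; the remaining (non-promoted) queries are reassigned.

A query's truth is its pooled-consensus OTU, mapped onto the round's
reference OTUs by maximum overlap (ties to the smallest OTU id).  A
consensus assignment matching the mapped truth is a true positive; a
query whose pooled OTU contains no reference member is a false positive
in round-1 accounting (it could not have been assigned correctly);
ambiguous verdicts are excluded from the percent-correct numerator but
kept in its denominator.  Percentages are reported to 1 decimal;
`pct_consensus_total` is the *sum of the rounded* 3/3 and 2/3
percentages, which is the only definition under which the two published
conventions (77.1 + 18.8 = 95.9 and 97.0 + 2.5 = 99.5) are both exact.
The cryptic-diversity excess is 100 x (n_OTUs - n_nominal) / n_nominal
over distinct non-empty nominal labels.

## The synthetic generator

The generator emulates the statistical structure the workflow assumes —
species-level clusters separated by a barcode gap — with the curation
scenarios layered on top: cryptic pairs (two true OTUs under one
nominal name), query-only OTUs absent from the reference, and mislabeled
records (label changed, truth unchanged).

* **Species tree**: a Yule tree whose node ages are affinely remapped so
  the youngest split sits at the gap floor (gap_factor x intra_depth of
  pairwise divergence) and the root at `max_inter_depth` (default 0.3,
  the scale of family-level COI divergence).  This keeps the topology
  and the order of splits while guaranteeing the gap and keeping the
  K2P estimator away from saturation.
* **Sequences** evolve along the tree under the K2P process itself
  (kappa = 2), deliberately matching the distance estimator rather than
  a richer model — the workflow under test is distance- and
  branch-length-based, not model-selection-based.  Substitutions that
  would create a stop codon in the reading frame are reverted (purifying
  selection on a protein-coding marker), so generated libraries pass the
  length/stop-codon QC screen exactly like curated real data.
* **Intraspecific variation**: a star radiation from the species
  ancestor with tip depths uniform on [0, intra_depth/4].  The
  calibration target is the *definition* of `intra_depth` as the
  expected realized maximum intraspecific K2P distance: at 538 sites the
  estimator's binomial noise (sd ~ sqrt(d(1-d)/L)) contributes about as
  much to the realized maximum as the true divergences do, and with this
  cap the realized maximum concentrates at ~intra_depth (measured mean
  0.0099 at the 0.01 default).  A Kingman-coalescent genealogy is
  available behind `coalescent_intra`.
* Everything is driven by one integer seed; identical configurations are
  byte-identical.

What the generator does **not** emulate: rate heterogeneity across sites
and lineages (GTR+Gamma-style), indels and alignment error, sequencing
error, incomplete lineage sorting and introgression (every species is
monophyletic in truth), geographic structure, and the deposited data's
actual sizes (the desk default is 15 species x 5 sequences; a
100 x 8 preset exists behind `--paper-scale`).  Tests passing on these
libraries therefore show that the pipeline's logic and bookkeeping are
correct and that each method recovers clean, gap-separated structure;
they do not show that the methods agree on real data — the published
experience is that they do not, which is precisely why the consensus and
the iterative design exist.  Published OTU counts are not reproducible
without the deposited dataset and cluster-scale ML/Bayesian tree
inference, and are out of scope.

## Numerical conventions and degenerate inputs

* Coordinates 0-based half-open; metadata TSV with required header.
* QC: ungapped length >= 500 and at least one forward frame free of stop
  codons (vertebrate mitochondrial code, frame chosen to minimize the
  stop count); failures are flagged, never dropped.
* Ties: NN ties and assignment-distance ties resolve to the smallest id;
  NJ Q-matrix ties to the smallest index pair; greedy searches break
  score ties by keeping the current (lumpier) state, with a 1e-9
  improvement threshold so float noise cannot drive a move.
* Singleton OTUs: theta1 falls back as described; a single-OTU reference
  makes FZ/FZKMER uninformative (probability 1, flagged) and is an error
  for BP and the ratio diagnostic.
* GMYC on < 4 tips returns one OTU flagged "test not applicable";
  non-ultrametric chronograms are rejected (1e-6 relative tolerance).
* Stochastic components (representative draws, PTP restarts, BP
  training, promotions) take explicit seeds; the default is 1 and the
  end-to-end run is reproducible bit for bit under a fixed master seed.

## Problem sizes

The test-suite and acceptance scenarios use 15 species x 5 sequences
(plus 3 unsampled query OTUs and 2 queries per OTU where the workflow is
exercised), 538 bp, 20 independent seeds — comfortably within a desk
run.  The same code paths drive arbitrary sizes; complexity is dominated
by the O(n^2 L) distance matrix and the O(n^2) GMYC threshold scan.

## Known limitations

* RSL is an approximation; BIN identity is disclaimed.
* The GMYC likelihood uses the combined-rate interval formulation and a
  per-lineage-threshold reading of the cut set; classic single-threshold
  GMYC is recovered up to the entity-stem convention documented above.
* The BP network is a documented stand-in architecture; published
  neural-network assigners differ in encoding and training details.
* ABGD's published windowing heuristics are approximated by the local
  mean-gap slope estimate; behavior is pinned by oracle tests rather
  than by bit-compatibility with the reference implementation.
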