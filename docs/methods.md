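# Methods

## Model overview and assumptions

`splicewalk` treats single-cell PSI estimation as a missing-data problem on
two similarity manifolds.  The central assumptions are (i) cells with
similar splicing-machinery activity — proxied by RNA-binding-protein (RBP)
expression, or directly by junction counts or PSI — share splicing
patterns, and (ii) events with similar regulatory features and sequence
context have comparable splicing outcomes.  Information is propagated over
the cell and event k-nearest-neighbor graphs by a random walk with
restart, and three imputation strategies are blended per event-cell pair
according to the predicted dropout scenario of that pair.

Raw PSI is the ratio of the mean inclusion-junction count to the sum of the
mean inclusion and mean exclusion counts, on library-size-normalized
counts.  Averaging within each junction class makes events with different
junction multiplicities (e.g. two inclusion junctions for a cassette exon
against one exclusion junction) comparable: every junction of a class is an
independent read-out of the same isoform at the same rate, so the class
mean estimates that rate.  Pairs with no reads in either class carry the
conventional value 0 and an explicit `support = False` flag; all
consumers that would be misled by the convention (RBP-PSI correlation,
scenario rules) honor the flag.

## Tunable parameters

| parameter | default | meaning and rationale |
|---|---|---|
| PCA variance threshold | 0.9 | components kept for cell features before distances |
| restart probability λ | 0.2 | weight of the restart term in the diffusion walk |
| convergence tolerance | 0.05 | SSE/SST relative change stopping both diffusion and the imputation fixed points |
| max iterations | 100 | hard cap with a warning; the tolerance normally stops far earlier |
| k_event | 10 | fixed neighbor count of the event graph |
| kernel bandwidth index | ⌈k/3⌉+1 | σ is that-ranked smallest distance of the row |
| normalization scale | 1e4 | counts per library-size unit; any fixed scale cancels in the PSI ratio |
| ω constants | a=−2·ln 9999, b=ln 9999 | pin ω(0)=1e-4, ω(0.5)=0.5, ω(1)=0.9999 |
| flank length | 300 nt | sequence context around the alternative region for k-mer/motif features |
| scenario thresholds | 0.05 / 0.8 / 0.5 | reference-extreme tolerance, BD same-side neighbor fraction, TD+Info neighbor-support fraction |

The cell neighbor count is not a parameter: the dynamic-K detector scans
the sorted distance profile of each cell for the first jump exceeding the
mean positive deviation between the difference vector and its running
means.  The search necessarily starts at k = 2 (the rule compares df(k)
with cdf(k−1)); when no jump qualifies — e.g. a perfectly linear profile —
k falls back to M−1 and the choice is logged.  The detector is
scale-invariant by construction.

## Numerical choices

- **SSE/SST.**  The stopping statistic divides the squared change between
  consecutive iterates by the total sum of squares of the previous iterate
  around its grand mean, the regression idiom.  Any fixed normalization
  only rescales the stopping rule; this one makes the statistic
  scale-free.  A constant previous matrix yields +inf with a warning.
- **Sparsification.**  After diffusion, each row keeps its k largest
  entries — the diagonal competes like any entry, since the restart
  guarantees genuine self-mass — and is renormalized to sum 1.
  Renormalization makes every downstream product a convex combination, so
  imputed PSI cannot leave [0, 1] and imputed counts stay nonnegative.
  Ties at the k-th value break by node order for reproducibility.
- **Event smoothing (strategy 3).**  The event operator is applied to the
  transposed PSI matrix and transposed back, i.e. out = (Ŝ_event · PSIᵀ)ᵀ,
  so each pair's update is the row-stochastic convex combination over
  similar events.
- **Zero bandwidth.**  When the ranked bandwidth distance is 0 (duplicate
  profiles), the smallest nonzero distance of the row substitutes, or 1
  for an all-zero row: duplicates receive maximal similarity, never NaN.
- **Degenerate denominators.**  Event-cell pairs whose entire neighborhood
  lacks reads after count smoothing keep PSI 0 and the unsupported flag.
- **Embedding.**  The sequence-feature embedding is a truncated singular
  decomposition of the column-standardized feature matrix with a
  deterministic sign convention (largest-magnitude loading positive).  Any
  user-trained events × L embedding can be supplied instead; only the
  embedded coordinates enter the similarity math.
- **Min-max normalization.**  Scenario-feature bounds are frozen at
  training time; test-time values are clipped to [0, 1]; constant features
  map to 0.  Class imbalance is handled by inverse-frequency weights.

## The synthetic-data generator

The generator emulates the statistical structure the method assumes, with
ground truth for every intermediate quantity:

- **Groups and truth.**  Cells belong to G groups (uniform mixture by
  default); each (group, event) has a true PSI drawn Beta(2, 2) — a broad,
  realistic spread of intermediate splicing levels.
- **Counts.**  Per event-cell pair a depth is drawn negative-binomially
  (mean 20 junction reads, size 2, modulated by log-normal library factors
  with σ = 0.3 and per-event depth factors with σ = 0.5).  Each inclusion
  junction then draws Binomial(depth, PSI) and the exclusion junction
  Binomial(depth, 1−PSI), independently — each junction is crossed by its
  own reads, matching the class-mean PSI estimator.
- **Regulation.**  Half the events are regulated; each of 30 RBPs reads
  out the mean true PSI of two regulated events with slope 1 plus Gaussian
  noise of 0.1 — roughly 10% of the PSI dynamic range, a regime in which
  distinct cell types are clearly separable by splicing-factor expression,
  which is the method's working premise.
- **Scenarios.**  Biological dropout (rate 0.20) acts on whole
  (group, event) blocks: the group's PSI is forced to 0 or 1 with
  probability equal to its PSI, so only one junction class receives reads.
  Technical dropout without information (0.10) also acts block-wise,
  zeroing depth for the whole group so the neighborhood is uninformative;
  technical dropout with information (0.20) zeroes depth of individual
  pairs while neighbors keep reads.  The remaining ~50% of pairs are
  non-dropout.
- **Event features.**  A synthetic stand-in for sequence-feature
  embeddings: 50 linear read-outs of the event's group-PSI profile plus
  Gaussian noise (σ = 0.3), so events with similar splicing behavior have
  nearby features.  This encodes the assumption that sequence determines
  regulation; it does not model real sequence composition.

What the generator does *not* emulate: read-level artifacts (mapping
bias, positional coverage, overlapping junctions), doublets and ambient
contamination, continuous trajectories rather than discrete groups, and
RBP-expression structure unrelated to splicing.  Passing the recovery
tests therefore demonstrates that the algorithm inverts its own generative
assumptions at realistic noise levels — not that it resolves every failure
mode of real scRNA-seq.

## Scenario cascade conventions

The published feature lists for the two logistic stages are not public, so
the package defines a documented 17-feature convention with the stated
semantics — distributional summaries of junction reads and PSI in the
target cell and its network neighbors: host-gene expression; target
total/inclusion/exclusion normalized reads; target raw PSI; neighborhood
size; neighbor means and variances of inclusion reads, exclusion reads and
PSI; fractions of neighbors with inclusion and with exclusion support;
fraction of single-isoform neighbors; neighbor mean host-gene expression;
and library size.  The second stage appends two features reflecting the
effect of count smoothing: |strategy-2 PSI − raw PSI| and the strategy-2
total reads.  Neighbor summaries are unweighted over the nonzero
off-diagonal entries of the diffused network row.

Reference-based labeling (used for fine-tuning on conserved events and for
pre-training on simulations) partitions dropout pairs: BD when the
reference PSI is within 0.05 of 0 or 1 and ≥ 80% of neighbors are
single-isoform on the same side; otherwise TD, with ≥ 50% neighbor read
support separating TD+Info from TD−Info.  All thresholds are
configurable.

## Problem sizes

The packaged study runs 200 cells × 300 events with three groups and the
default scenario rates — large enough for stable network estimation and
scenario training (≈30k labeled dropout pairs) while keeping the full
pipeline under a few seconds on one CPU.  Unit fixtures use 15–80 cells.

## Known limitations

- The fusion weight ω increases with the *p-value* of the profile
  correlation, i.e. the regulatory distance receives more weight when the
  profile correlation is *insignificant*; the printed constants force this
  behavior and it is implemented exactly as printed.
- Iterating strategy smoothing to its fixed point can over-smooth when the
  similarity graph mixes across genuinely distinct populations; the
  tolerance of 0.05 stops early in practice, but strongly connected event
  graphs (fixed k_event = 10) drift toward event-profile means.
- Intron-retention inclusion evidence is encoded as boundary
  pseudo-junction counters, one per exon-intron boundary, not intron-body
  coverage; both conventions fit the data model, and the boundary one
  keeps a single counting code path.
- The autoencoder originally proposed for sequence embeddings is replaced
  by the deterministic linear reducer; the hook accepts any externally
  trained embedding.
- Conservation features are accepted as a precomputed column only; no
  conservation-track ingestion.
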