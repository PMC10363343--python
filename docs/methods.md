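# Methods

This note documents the models, conventions and numerical choices behind
`megmapper`, and what the synthetic studies do and do not establish.

## Data model and preprocessing

All containers are time-major: a session is a (time × channels) matrix
with one paradigm label and one phase label (stimulus / fixation /
baseline / missing) per row. Real recordings described by the pipeline's
target regime are channel-major on disk and transposed before analysis;
fixing a single in-memory convention removes a whole class of transpose
bugs.

Preprocessing steps, in order:

- **Resampling** to a target rate (default 256 Hz) with polyphase
  anti-alias filtering (`scipy.signal.resample_poly`). Labels are
  piecewise-constant over trials, so each output row takes the label of
  the nearest original time point. Upsampling is refused.
- **Stimulus selection**: only rows in the stimulus phase whose values are
  all finite survive; rows with missing values are dropped, never imputed.
- **Pairwise concatenation**: the two paradigms' rows are stacked
  (first-named paradigm first, boundary index recorded) over the
  lexicographically ordered intersection of their channel ids.

## Mapper construction

- **Filter**: t-SNE (perplexity 30, capped at (n−1)/3 for tiny inputs,
  fixed `random_state`, PCA initialization) is the production filter; PCA
  is the deterministic filter used throughout the tests and synthetic
  studies. Both produce 2-D embeddings.
- **Cover**: per filter dimension, the coordinate range R is covered by n
  equal-length closed intervals of length `L = R/(n − (n−1)o)`, interval k
  starting at `min + k·L·(1−o)`; the identity `L(n − (n−1)o) = R` holds to
  machine precision and the last interval's end is pinned to the exact
  maximum so no point escapes by floating-point rounding. The 2-D bins are
  all n² interval cross-products; `n_intervals` is per-dimension. Points
  on shared boundaries belong to every touching bin; for overlap < 50% a
  point lies in at most 4 bins. A dimension with zero range collapses to a
  single interval with a logged warning. Empty bins produce no nodes.
- **Clustering**: single linkage under the Euclidean metric in the
  *original channel space* (Mapper clusters the preimage of the filter),
  cut at `min(n_clusters, bin size)` leaves. The fixed-count cut is what
  makes a "number of clusters" sweep meaningful for an otherwise
  parameter-free linkage. Clustering in the 2-D embedding instead would
  also be defensible; channel space is fixed here and recorded.
- **Nerve**: one node per cluster, an unweighted edge for every pair of
  clusters sharing a time index, organized per time index so the
  construction is linear in total membership rather than quadratic in
  nodes. Tested against the brute-force all-pairs oracle.

## Graph invariants

Node dominance is the strict majority paradigm of a node's members; exact
ties get a TIE sentinel and are excluded from every paradigm mean (they
are counted and reported instead — arbitrary assignment would bias the
paired comparison).

Centralities use the standard normalized definitions: degree `deg/(n−1)`;
betweenness pair-normalized; closeness `(n−1)/Σd`; eigenvector centrality
by power iteration (tolerance 1e−10, max 1000 iterations) rescaled to
unit maximum entry. Edges are unweighted. On a disconnected graph the
analysis restricts to the largest connected component with a warning (the
original analysis chose parameters so graphs come out connected; at desk
scale forced cluster cuts shave outlier singletons off); a strict mode
raises instead.

Communities come from deterministic greedy (CNM) modularity maximization
with communities renumbered by smallest node id; the `seed` argument is
accepted for interface stability but the optimizer is deterministic.
Modularity Q is evaluated directly from Newman's formula in the
aggregated per-community form `Σ_c (L_c/m − (d_c/2m)²)`, which equals the
pairwise double sum; an edgeless graph has Q = 0 by convention (logged).
The implementation is cross-checked in the tests against a brute-force
double-sum oracle and against networkx.

## Statistics

The paired comparison consumes per-subject pairs of paradigm mean
centralities:

- **Normality gate**: Shapiro–Wilk on the vector of paired differences
  (not the raw score columns) at α = 0.05; non-normal (or constant, where
  normality is undefined, or n < 3) routes to the permutation test.
- **Paired sign-flip permutation test**: statistic = mean of differences;
  the null makes each subject's pair exchangeable, so the null
  distribution is all sign patterns of the differences. Exact enumeration
  of all 2ⁿ patterns whenever n ≤ 20 (plain inclusive tail proportions;
  the identity pattern guarantees p > 0); otherwise seeded Monte Carlo
  with add-one smoothing `(count+1)/(B+1)`. Two-sided p is
  `min(1, 2·min(p_l, p_g))`; one-sided alternatives report the
  corresponding tail. Tail comparisons use a relative 1e−12 tolerance so
  sign patterns reproducing the observed statistic are counted inclusively.
- **Bonferroni**: `min(1, m·p)` with family size defaulting to the number
  of parameter triples in the sweep.
- **Hypothesis evaluation**: a triple supports a directional hypothesis
  when the corrected two-sided p is below α *and* the sample means are
  ordered as hypothesized; the hypothesis is "satisfied" when at least
  95% (configurable) of triples support it.
- **Correlation**: Pearson by default (Spearman available), two-sided p.

## The synthetic generator

Each paradigm block is a hidden-state process: S state centroids drawn
from an isotropic normal with scale σ_c; a state sequence with geometric
(memoryless) dwell times of mean d (the simplest law giving contiguous
state blocks); each time point = current centroid + isotropic noise σ_p.
Per-subject seeds derive deterministically from the cohort seed via
`SeedSequence`, so cohorts are reproducible and subjects independent.

Cognitive demand is encoded as *compactness*: the default demanding
paradigm has 3 states at centroid scale 0.5 versus the relaxed paradigm's
12 states at centroid scale 1.5, at equal within-state noise 0.7 and mean
dwell 20. Fewer states alone (at equal scales) would *not* make the
demanding time points mutually more similar — the mean pairwise distance
is dominated by the centroid scale and is independent of the state count
— and without the compactness the centrality ordering the mechanism
predicts does not emerge. Smaller centroid spread is the direct encoding
of "mutually more similar activation patterns".

What the generator does **not** emulate: sensor geometry and forward
models, 1/f and physiological noise spectra, trial structure beyond
phase labels, inter-subject topography differences. Passing synthetic
tests therefore establishes that the pipeline recovers the qualitative
orderings its mechanism predicts under a state-recurrence regime — not
that real recordings would show them.

## Desk-scale study sizes

All studies run on one CPU in minutes; sizes are the package's defaults:

- Hypothesis analog (demanding > relaxed): 20 cohort seeds × 10 subjects,
  32 channels, 1,000 time points per paradigm block, Mapper 10-50-5, PCA
  filter, closeness centrality.
- Matched-demand null control: 200 cohort seeds × 10 subjects, 16
  channels, 150 time points per block, identical paradigm configs, Mapper
  5-50-5; rejection rate at α = 0.05 stays near the nominal level.
- Full sweep: 8 triples {4,6}×{40,50}×{3,5}, 10 subjects, 32 channels,
  2×1,000 time points. Interval counts scale with point count: a cover
  that gives thousands of points per bin at full scale corresponds to
  single-digit interval counts at 2,000 points; running the full-scale
  interval counts {10,15,20} on 2,000 points leaves ~20 points per bin
  and shreds the graph into singletons.
- Modularity–response-time recovery: response times generated with slope
  −0.5 and noise set to half the signal spread (signal-to-noise 2:1),
  100 seeds.

## Known limitations and observed divergences

- Median modularity increases with the interval parameter (more nodes and
  edges), as expected. The decrease of median modularity with the cluster
  parameter reported for full-scale MEG graphs does **not** reproduce at
  desk scale under the state-recurrence generator: raising the cluster
  cut shaves outliers into extra well-separated fragments, and both the
  edge count and median Q *increase* with the cluster parameter in every
  regime probed. That observation appears tied to the ~350k-point regime
  where bins hold thousands of points and a deeper cut splits genuine
  sub-blobs. The tests assert the trends that reproduce (node count and
  median Q non-decreasing in intervals, node count non-decreasing in the
  cluster cut) and leave the cluster-direction trend undocumented as a
  guarantee.
- t-SNE hyperparameters of full-scale runs are not identifiable from
  graph summaries alone, so node/edge counts of any particular full-scale
  graph are not bit-reproducible; the PCA filter is provided for exact
  reproducibility.
- Exact permutation enumeration is capped at n = 20 pairs (2²⁰ patterns);
  larger cohorts use Monte Carlo with a reported B.
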