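# Methods

## Data model

A peak table is a samples-by-compounds matrix of nonnegative LC-MS peak
areas with two per-sample attributes: the processing-stage sample type
(unfermented, fermented, liquor) and the country of origin. Before any
analysis the table is row-normalized so each sample's peak areas sum to
100 (each entry then reads as the relative percentage of that compound in
the sample's profile), and columns are kept sorted by descending mean
peak area across samples, so "keep the top n compounds" is a column
prefix. Missing cells in compound columns are interpreted as
"not detected" and set to 0 (logged with a count); negative entries are
rejected with coordinates. Normalization is idempotent and preserves each
sample's within-profile rank order, so it cannot change Spearman
correlations — this invariance is tested end-to-end.

## Correlation

Sample-sample similarity is Pearson correlation of profiles, or Spearman
(Pearson on within-sample average ranks; mid-ranks for the many tied
zeros a sparse peak table carries). Spearman is the default throughout:
peak intensities are heavy-tailed and the rank correlation is invariant
under monotone distortions of the intensity scale, e.g. detector
response. The sample-vs-population covariance convention cancels in the
correlation ratio. Constant profiles have no defined correlation and
raise an error naming the offending sample. Computed values are clipped
to [−1, 1] to absorb last-ulp float overshoot.

## Thresholded networks

For threshold t ∈ [0, 1] an edge joins samples a, b iff r_ab ≥ t **and**
r_ab > 0. The strict-positivity clause makes the threshold-0 network the
graph of all positive correlations rather than the complete graph, and
negative correlations never form edges. Edge sets are therefore nested
along any increasing threshold sequence, which the sweep checks by
construction and the tests verify. Samples are never dropped from the
node set; isolation is a per-node flag, and the "isolated nodes dropped"
convention applies only to reported connected-node counts. Threshold
comparison is exact ≥ on stored values, no epsilon: thresholds are
user-supplied round numbers, and an epsilon would silently move the edge
rule. Networks export as SIF or edge-list CSV with a node-attribute CSV
alongside (Cytoscape-importable); layout and rendering are out of scope.

## Edge similarity and the null ensemble

Edge similarity of a labeled network is |{edges with equal endpoint
labels}| / |edges| — an edge-level quantity, never a cluster-level one.
An edgeless network yields an explicit undefined value (NaN in curve
output), never 0, since 0 would assert perfect dissimilarity.

The control ensemble permutes the multiset of positive correlations
uniformly at random over the pairs that carry positive correlation, then
re-thresholds. This preserves the correlation distribution exactly, and
because the number of weights ≥ t is permutation-invariant, the
thresholded null network at any t is a uniformly random k-subset of the
positive pairs. Hence the expected null similarity at every threshold
equals the full-network similarity s₀ — the analytic flat line the tests
check against Monte-Carlo means. The ensemble default is 100 replicates
(mean and population sd reported per threshold, per attribute), driven by
one generator seeded once with replicates advancing the stream. Whether
the published control permuted weights over positive pairs only or over
all pairs is ambiguous; the positive-pairs reading is the default because
it is the one that preserves "the same correlation distribution", and
`permute_all_pairs=True` exposes the alternative for sensitivity
analysis.

## Ideal networks and accuracy

The ideal network of an attribute has an edge exactly between same-label
pairs (Σ_c n_c(n_c−1)/2 edges for class sizes n_c). Against it, every
one of the n(n−1)/2 unordered sample pairs at a given threshold is a
true positive (edge present in both), true negative (absent in both),
false positive or false negative, and accuracy is α = (TP + TN) /
(n(n−1)/2). The counts are computed from the same-label pair total and
the edge list, and are cross-checked in tests against brute-force pair
enumeration.

## Majority-vote inference

A node's attribute is predicted leave-one-out as the most frequent label
among its voters: neighbors at radius 1, or nodes at graph distance 1 or
2 (each counted once) at radius 2, the wider net being useful when
neighborhoods are sparse. The queried node's own label is never
consulted, so relabeling a node cannot change its prediction, only its
correctness — a property test. Zero voters or a tied top count yield an
explicit undefined outcome: the reference analysis never specifies a tie
rule, and coin-flip resolution would inject nondeterminism into an
otherwise deterministic pipeline. An optional weighted-vote variant (off
by default) weights each voter by its edge correlation — for a distance-2
voter, the maximum over intermediates of the product of the two edge
weights — which resolves most count ties deterministically. The mean
prediction score at a threshold is #correct / #defined; undefined cells
are excluded from the denominator, and a threshold with no defined cell
reports an explicit null.

## Synthetic data generator

The generator emulates the study conditions the analysis assumes: 140
samples in 3 stages and 8 origins with uneven origin counts (defaults
2:2:3:1:2:4:2:2, largest ≈ 4× smallest, Ivory Coast most and Ghana
least), 1000 compound features, per-sample sums normalized to 100.
Latent log-profiles are

    z_a = mu + stage_effect · u_s + origin_effect · v_{s,o} + noise_sd · eps_a

with all factors standard spherical Gaussians over compounds, drawn once
per label (so profiles are label-consistent) and the origin factor nested
within stage; peak areas are exp(z_a). The log-normal form guarantees
nonnegative, heavy-tailed intensities, and since exp is monotone the
Spearman analysis sees exactly the latent Gaussian correlation structure,
where the algebra is closed-form: two samples' latent correlation is
(shared variance)/(total variance). The defaults baseline_sd = 1.0,
stage_effect = 1.3, origin_effect = 0.7, noise_sd = 0.5 (all in latent
log units) give expected correlations ≈ 0.29 for cross-stage pairs,
≈ 0.78 for same-stage/cross-origin, ≈ 0.93 for same-origin — chosen from
this algebra so that stage structure saturates near threshold 0.4 and
origin structure emerges above ≈ 0.8, the qualitative nested ordering the
analysis is designed to expose. Real effect sizes are not published, so
these defaults reproduce the ordering and rough crossing regions, not any
exact curve shape.

Samples are apportioned to origins by largest remainder and cycled
through stages deterministically; only the factor draws and noise consume
randomness, so a fixed seed gives a bit-identical table.

What the generator does *not* emulate: chromatography artifacts,
m/z/retention-time structure, compound identities, batch effects,
censoring at the detection limit, or correlated compound blocks
(compounds are exchangeable here). Passing tests therefore demonstrate
that the pipeline recovers nested group structure of this latent-factor
form, not that any particular real dataset has that structure.

## Pipeline and reproducibility

A run is a pure function of (input bytes, config, seed). The single run
seed feeds a SeedSequence whose spawned substreams seed the generator and
the null ensemble; manifests record the derived seeds and a SHA-256 hash
of every artifact, and repeated runs are hash-identical. One wrinkle: a
run config that embeds a generator config with the default seed 0 has
that seed replaced by the run-level substream (one number reproduces the
whole run); an explicitly nonzero generator seed is honored so a fixed
dataset can be reused across pipeline seeds.

## Numerical and format notes

- CSV round-trips are bit-exact (floats written as shortest round-trip
  repr, read with round-trip parsing). XLSX stores 15 significant digits
  (the Excel convention), so round-trip identity there holds for values
  representable at that precision.
- Compound-order ties in top-n selection keep original column order
  (stable sort on descending means).
- Undefined statistics (similarity of an edgeless network, score with no
  defined votes) propagate as NaN/null in outputs, never as 0.

## Problem sizes used in the test suite

Unit tests run on toy matrices (4–20 nodes) with enumeration or
transitive-closure oracles. The oracle-equivalence check uses 1000 random
5×8 tables against Pearson-on-ranks at 1e-12. The null closed form is
checked at 10,000 replicates on a 6-node toy (3-standard-error band) and
at the 100-replicate default (sd band). Nested-structure recovery runs 20
seeds at the full default conditions (140 samples × 1000 compounds, 10
thresholds), comparing the thresholds where the stage and origin
similarity and prediction-score curves first reach 0.9.

## Known limitations

- Similarity and accuracy treat attributes independently; no joint
  stage×origin statistic is computed.
- The null family is weight permutation only; degree-preserving rewiring
  nulls are out of scope.
- Majority voting is transductive (the query sample participates in the
  correlation matrix); there is no train/validation split or
  probabilistic calibration.
- Edge weights play no role in similarity/accuracy beyond thresholding;
  only the optional weighted vote uses them.
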