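# Methods

## Scope

`telesna` infers a proximity-based association network from GPS relocations
and quantifies how robust its metrics are to sampling effort, using four
resampling devices: datastream permutation, node subsampling, a node
bootstrap, and partial-vs-full node-metric comparison. It does not fit
movement models, clean GPS error, infer interactions in continuous time,
detect communities, or impute unobserved individuals.

## Association networks

Two fixes of different animals form a *joint observation* when their
timestamps differ by at most the temporal threshold *t* (default 7 min,
chosen to absorb scheduled-fix reception jitter: a fix at 09:57 is compared
with the partner's fixes up to 10:04). Candidate pairs are matched
**one-to-one per dyad**, greedily by ascending |Δt| with deterministic
tie-breaks (earlier first-animal fix, then earlier second-animal fix), so a
fix never enters two joint observations of the same dyad — important when
the fix interval is shorter than *t*, where many-to-many counting would
inflate the index denominator. The window is symmetric (|Δt| ≤ t) because
the dyad is unordered; a forward-only variant (`window="forward"`) and an
unmatched variant (`matching="all_pairs"`) are provided for sensitivity
analysis and for emulating pipelines that count every temporally close pair.

The edge weight is the Simple Ratio Index restricted to simultaneous
availability, SRI = x/(x+y), with x the joint observations within the
spatial threshold *s* (default 15 m; 10 m is a common choice for less
cohesive species) and y the rest. Dyads with no joint observations carry no
information and produce no edge; isolated animals remain as nodes, so the
network order always equals the number of tagged animals. No minimum-
denominator filter is applied by default (configurable), since dropping
sparse dyads is a study-specific decision.

`suggest_spatial_threshold` histograms joint-observation distances
(default 5-m bins up to 500 m) and returns the centre of the first local
maximum — the first mode plausibly reflects socially associating pairs,
while larger modes reflect shared habitat. For a monotonically decreasing
histogram the global maximum bin is returned. `sweep_thresholds` tabulates
edge count, density and mean strength over an (s, t) grid; edge count is
non-decreasing in s at fixed t by construction.

Distances are Euclidean for projected coordinates and haversine (sphere of
radius 6 371 000 m) for geographic ones; coordinates are never reprojected.
At the sub-100 m scales of association thresholds, sphere error is orders
of magnitude below GPS error.

## Network metrics

Node-level: degree, strength (sum of incident SRI weights), betweenness,
eigenvector centrality, local clustering. Global: edge density,
transitivity (3·triangles / connected triples, NA when no triples exist),
diameter, mean degree, mean strength, and scaled variants of mean strength
and diameter (divided by the node count N) used in the CI-width analysis.

Path- and triangle-based metrics use the **binary** topology: with SRI
weights, a "weighted shortest path" would treat strong associations as long
distances unless weights are inverted, an ambiguity we avoid by default. A
`weighted_paths` flag (using 1/weight as length) exists for sensitivity.
The diameter of a disconnected network is the maximum over component
diameters, so partitioned populations still yield a finite value. Mean
degree and mean strength average over all N nodes including isolates, hence
mean degree / (N−1) = density.

Eigenvector centrality is computed by power iteration on the weighted
adjacency (tolerance 1e-10, at most 10 000 iterations, uniform start
vector), **per connected component**, each component's vector scaled to
unit maximum; isolates get 0. Two numerical notes: the iteration runs on
A + (1 + max row sum)·I, which has the same eigenvectors but a unique
dominant eigenvalue, so bipartite components (whose ±λ pair makes plain
power iteration oscillate) converge; and the per-component unit-max
normalisation makes values comparable within, not across, components.

## Step 1 — datastream permutation

Each animal's stream is segmented into calendar-day tracks in an explicit
`day_timezone` (default UTC; timestamps themselves are stored in UTC). A
permutation shuffles, independently per animal, the dates of its own
observed date set; each fix keeps its time of day and coordinates. This
preserves every animal's home range, fix count, monitoring window and
within-day movement autocorrelation exactly, while randomising whom it
meets. p-values use the add-one correction, p_upper =
(1 + #{null ≥ observed})/(n_valid + 1), so they are never zero; metrics
undefined in a permutation (e.g. transitivity of a triple-free null
network) are excluded from the count and tallied. Per-permutation RNG
streams are spawned from one master generator, making runs reproducible
and order-independent. Dates are shuffled over the whole study period; no
seasonal blocking is implemented.

## Steps 2–3 — subsampling and bootstrap

Subsampling draws m = max(1, round(level·N)) nodes uniformly without
replacement and keeps the induced subgraph. Two exact laws anchor the
bias analysis and are verified by exhaustive enumeration in the tests:
E[induced density] equals the full density (each edge survives with
probability m(m−1)/(N(N−1)), which cancels against the pair count), and
E[induced mean strength] = (m−1)/(N−1) × full mean strength. Diameter and
transitivity have no such closed form and are studied empirically.

The node bootstrap resamples N node ids with replacement; each draw is a
distinct node-copy. Copies of different originals are adjacent iff the
originals were, with the original weight. A pair of copies of the same
original is always connected, with weight drawn uniformly from the original
edge list (`dup_edge_rule="always_draw"`); an alternative
(`"density_bernoulli"`) connects such pairs with probability equal to the
original density. Confidence intervals are percentile intervals with
type-7 (linear) interpolation; BCa is deliberately not used, keeping the
procedure simple and deterministic. Because never-observed dyads are zeros
in every replicate, bootstrap intervals can understate uncertainty on very
sparse networks; a warning is logged when density < 0.05 rather than any
correction applied.

CI width versus sample size repeats, for each size, an induced subsample
followed by a full bootstrap, averaging the CI width over `n_outer`
(default 10) outer draws; mean strength and diameter are replaced by their
scaled versions so widths are comparable across sizes. The split-half
calibration partitions the nodes into two disjoint random halves,
bootstraps each, and reports the proportion of trials whose CIs overlap —
near 1 on homogeneous networks if the intervals are not spuriously narrow.

Defaults follow common practice for this family of analyses: levels
0.1–0.9 in steps of 0.1, 100 subsample replicates, B = 1000 bootstrap
replicates, 95% intervals.

## Steps 4–5 — node-level stability and CIs

Step 4 correlates node metrics of induced subnetworks (levels 0.1, 0.3,
0.5, 0.7, 0.9; 10 repeats) against the same nodes' full-network values.
Pearson is the default (Spearman available); NA clustering values
(degree < 2) are removed pairwise; repeats with a constant metric vector
have undefined correlation and are excluded with a tally. A mean r > 0.7
is flagged as "stable" — a reporting guideline, not a filter. The
companion regression (subsample value on full value) quantifies
attenuation; for degree and strength the expected slope is (m−1)/(N−1),
the edge-survival probability.

Step 5 computes node metrics on each bootstrap replicate (copies are
distinct nodes), assigns each original node the mean over its copies,
and forms percentile CIs over the replicates containing the node —
on average a fraction 1−(1−1/N)^N ≈ 0.63 of them; `n_effective` reports
the realised count. Output is sorted by decreasing observed value for
caterpillar plotting.

## Synthetic herds

The generator produces discrete-time relocation streams at the fix
interval (default 2 h) over a multi-day campaign (default 30 days,
15 animals in 3 groups). Each group has a home-range centre (2 km ring
spacing by default). Each day, a group's attendees split among
`n_subgroups_per_day` (default 3) parties; each party's centroid starts at
a dispersed point in the group range and performs a random walk with
`step_sd` = 200 m travel steps. An attending member tracks its party's
centroid with attraction `cohesion` = 0.8 and `within_group_sd` = 10 m
spread — herds are tight relative to how far they travel, which is what
makes co-location informative about sociality rather than about shared
space. Per-animal daily attendance probabilities are drawn once from a
Beta distribution with mean `sociality` = 0.6 (concentration 2), giving
the between-individual gregariousness variation that produces
heterogeneous degrees and strengths; with probability
`group_switch_prob` = 0.05 an attendee joins another group's party for the
day, yielding a connected but modular network. Non-attending animals walk
independently around their own home centre with mild homing. Gaussian GPS
noise (5 m) is added to every emitted fix. Everything is deterministic
given the seed.

What the simulation does *not* emulate: habitat/landscape structure,
behavioural state switching, missed fixes and irregular schedules, GPS
error heavier than Gaussian, births/deaths/collar failures. Passing tests
therefore demonstrate correctness of the statistical machinery and the
qualitative sampling-effort patterns, not performance on any particular
field system.

## Problem sizes in tests and the acceptance script

The test and acceptance runs use scaled-down but structurally faithful
settings chosen for quick desk verification: 200 datastream permutations
(null p-values then bottom out at 1/201 ≈ 0.005), bootstrap B between 200
and 500, 50 split-half trials at B = 300, 50 correlation repeats, herds of
15 and 60 animals over 20–30 days, and random-graph fixtures G(40, 0.2),
G(50, 0.15), G(60, 0.15). Exact properties (oracle agreement, subsampling
bias laws, permutation conservation) do not depend on these sizes; the
stochastic assertions hold with wide margins at them.

## Known limitations

- The one-to-one greedy matching is one defensible convention; pipelines
  using many-to-many counting will report larger SRI denominators.
  Both are available, but results are only comparable within a convention.
- Eigenvector centrality across separated components is normalised per
  component; cross-component comparisons of its values are not meaningful.
- The bootstrap's duplicate-copy edge rule is a modelling choice with two
  implemented readings; node-level CIs for sparse networks inherit the
  zero-edge caveat above.
- Day segmentation assumes the `day_timezone` is meaningful for the study
  animals; for datasets spanning time zones choose the zone of the study
  area, not UTC.
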