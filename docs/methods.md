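# Methods

This note documents the models and conventions behind `repmap`: what each
stage computes, the parameters that matter, what the synthetic generator
does and does not emulate, and the numerical choices at the edges.

## 1. Data model and condensation

An individual cognitive map (ICM) is a signed directed graph: nodes are
SES components a respondent cited, edges carry a single sign in {+1, −1}
(Mental-Modeler convention: matrix row = cause, column = effect).  Isolated
nodes are legitimate data — citing a component is the datum, linked or not
— and they count in component totals and category proportions.
Self-loops are rejected on input by default (causal maps of this kind have
none); a `drop_self_loops` flag exists for dirty exports and logs a
warning, never a silent repair.

Labels live at three nested levels: `raw` (verbatim) → `component`
(canonical) → `type` (thematic, 32 in the emulated study), each type in
exactly one of six closed categories.  Matching of raw labels is by
normalized key (trimmed, internal whitespace collapsed, case-folded);
original spellings are preserved.

**Condensation** maps every node to its image at the coarser level and
re-tallies the raw edges between each ordered pair of images.  The merged
sign is the majority sign, `sign(pos − neg)`.  Two deliberate policies:

* exact ties (`pos == neg > 0`) become sign-0 *conflict edges*, excluded
  from link counts but retained and reported — a silent sign choice would
  bias every downstream metric;
* edges whose endpoints merge into the same node are dropped and counted
  in the condensation report: they are artifacts of the merge, not
  respondent intent.

Condensation is idempotent at a fixed level, never increases node counts,
and satisfies `|edges_after| + |conflicts| ≤ |edges_before|`; the test
suite checks equivalence against a brute-force regroup-and-retally oracle.

## 2. Per-map metrics and centrality

The nine *active* metrics per map are: component count *N*, link count *L*
(signed links only; conflicts excluded), density *D* = *L*/(*N*(*N*−1))
(directed, no self-loops; 0 when *N* < 2), and the six category
proportions (summing to 1).  Centrality is degree centrality on absolute
weights — for ±1 edges, in-degree + out-degree — the convention of
fuzzy-cognitive-map practice.  Within-map ranks descend from the most
central node (rank 1); ties get average ranks so input order cannot leak
into results.  The sampling saturation diagnostic is a component
accumulation curve: mean unique components cited by the first *k*
respondents over random orderings.

## 3. Social cognitive map

Aggregation is matrix addition over the union node set.  Each ordered pair
keeps `(pos, neg)` counts of maps holding a +1/−1 edge there; `weight_sum
= pos − neg` is the matrix-addition entry and `occurrence = pos + neg` the
number of maps citing the link.  Keeping both tallies makes *ambivalent*
links (positive for some respondents, negative for others) first-class;
exports emit one record per pair with both tallies and leave rendering to
the consumer.  A condensed map's conflict edges contribute nothing here:
that respondent's net judgement on the pair was sign 0.

Display filters use **strict** inequalities, matching how the cut-offs are
stated in the emulated study's figure captions: components kept when
frequency > 10 %, interactions when occurrence > 10 (full SCM) or > 2
(focal subgraphs).  Focal subgraphs are 1-hop and direction-agnostic:
focal nodes, plus the nodes reached by surviving incident edges.

## 4. Centrality–frequency zoning

Each component gets (i) its citation frequency across respondents and
(ii) the median of its within-map centrality ranks **over exactly the maps
citing it** (a component cited once is classified like any other; its
median is that single rank).  The quadrant rule with both cuts at the
median of the observed distributions yields the four zones (core / first
periphery / contrasting / second periphery).  Choices worth making
explicit:

* cuts default to medians — the standard structural-approach split — and
  the resolved numeric cuts are stored in the output for audit;
* ties at a cut go to the frequent / central side;
* ranking mode is the raw within-map rank by default; a `relative` mode
  (rank / map size) is exposed because map sizes in the emulated study
  vary from 20 to 97, and a raw median rank conflates importance with map
  size to some degree.  Both modes are reported by the pipeline
  configuration in use.
* zoning operates at component level; the type level is used for display.

## 5. PCA and clustering

The nine metrics mix counts and proportions, so the PCA is run on the
correlation matrix (columns centered, scaled by the population SD); total
inertia equals 9 and the eigenvalues match the eigendecomposition of the
correlation matrix (tested to 1e-8).  Axis signs are made deterministic by
forcing the largest-|loading| variable on each axis to load positively.
The stakeholder group never enters axis construction; it is projected
afterwards as category centroids in score space.  A zero-variance column
is an error naming the column — it cannot be standardized, and silently
dropping it would change the model.

Clustering is Ward linkage on Euclidean distances in the retained score
space (default: smallest axis set reaching 80 % cumulative variance).
`k="auto"` minimizes W(k)/W(k−1) over k ∈ [2, min(10, R−1)] — the largest
relative drop of within-inertia, the rule the reference HCPC
implementation uses to suggest a partition.  An earlier variant that
maximized the ratio of successive inertia gains proved degenerate near the
upper k bound (vanishing late gains inflate the ratio) and was discarded.
Optional k-means consolidation from the hierarchical centroids is off by
default so a result is always reproducible from the linkage alone.

Cluster comparison reports per-metric means ± SD (n−1) and a two-sided
two-sample *t* (pooled variance by default, Welch as an option).  No
multiple-testing correction is applied by default — mirroring the practice
being emulated — but a Holm flag exists.

## 6. The synthetic generator

The generator stands in for an undeposited interview campaign; its
defaults are the campaign's published statistics, fixed before any test
was run:

| parameter | default | source/rationale |
|---|---|---|
| respondents R | 32, two clusters of 16 | reported sample |
| universe | 162 components, 32 types, 6 categories | reported condensation |
| category counts | 48/64/33/2/6/9 | proportional to the mean of the two clusters' reported category proportions |
| planted zones | core 31, contrasting 20, first periphery 49, second periphery 62 | reported zone sizes cover the 100 displayed components; the second periphery absorbs the 62 never-displayed (rarely cited) ones |
| citation-probability intervals | core (.80,.95), first periphery (.55,.80), contrasting and second periphery (.05,.30) | frequent vs rare zones; act as relative sampling weights |
| centrality boost | ×4 for core and contrasting | central vs peripheral zones |
| map sizes | truncated normal, 29.1±7.6 / 45.8±10.1, bounds [20, 97] | reported cluster means/SDs; bounds are the reported size range |
| edge model | links = size × out-degree; degree ~ 1.44±0.29 / 1.77±0.36 | degree means = reported links/size; spreads calibrated to the reported density dispersion (±0.018/±0.012) |
| category mix | reported per-cluster proportions, as weight multipliers | cluster contrast in content |
| sign model | per-pair ground truth, P(+1)=0.7, flip prob 0.05 | simplest mechanism yielding ambivalent links |
| salience | log-normal type-pair backbone (σ=2.0) × component noise (σ=0.5) | a shared thematic backbone; without it no interaction recurs often enough to survive the ">10 respondents" display filter that the emulated study's social map visibly satisfies |

Respondents are allocated to clusters exactly (largest remainder, 16+16)
rather than multinomially, because the published comparison is at n=16+16;
stakeholder groups within clusters follow the reported composition the
same way.  Components are drawn per respondent without replacement with
weight citation-probability × category-mix multiplier; pairs with weight
boost×boost×salience; zone assignment is stratified across categories
(2-D apportionment) so content and structure stay unconfounded.

**What a green test does and does not establish.**  The generator
reproduces first-order statistics (sizes, link counts, density, category
mixes, zone frequency ordering, shared-link concentration) and planted
memberships.  It does not reproduce: the semantic identity of components,
respondent-level correlation between content and expertise, or — 
importantly — the full covariance geometry of clusters that were
themselves *derived* by clustering in the emulated study.  Matching a
derived partition's marginal statistics with a Gaussian mixture
understates its separation: at these effect sizes even a supervised
in-sample linear discriminant reaches only ≈95 % accuracy, so unsupervised
HCPC recovers the planted clusters only partially (mean adjusted Rand
index ≈ 0.4 over seeds).  Zone recovery, by contrast, is nearly exact
(≈99 % of planted-core components classified core), because the planted
frequency and centrality separations translate directly into the zoning
statistics.  Recovery numbers are therefore statements about the
generator's world, not about any empirical dataset.

Two further quirks of the stated statistics, recorded here because the
generator cannot satisfy them simultaneously: the overall mean map size
(41.5) is inconsistent with the two cluster means (29.1/45.8 → 37.45); and
for the larger cluster, the reported link SD (36.4), size SD (10.1) and
density SD (0.012) cannot co-exist under any model where degree is
independent of size.  The generator follows the cluster-level values and
the density dispersion.

## 7. Determinism and numerical choices

Every stochastic step flows from one integer seed through
`numpy.random.SeedSequence` spawning; the pipeline is a pure function of
(inputs, config, seed), and repeated runs produce byte-identical artifacts
(sorted node/edge orders, fixed float formatting, sorted JSON keys, no
timestamps).  Medians of even-length lists are midpoint averages;
rank ties are average ranks; apportionments (types per category, zones per
category, cluster sizes, groups per cluster) use largest-remainder with a
stable tie-break.  Degenerate inputs either have a defined value (density
of a 1-node map is 0) or raise a named error (empty collection, constant
PCA column, unresolvable label); nothing is repaired silently.

## 8. Known limitations

* No dynamic (scenario) simulation of the fuzzy cognitive maps — out of
  scope of the analysis chain this package implements.
* Centrality alternatives (betweenness, eigenvector) are not implemented;
  degree centrality is the convention the method is defined on.
* The generator's labels are synthetic identifiers; nothing lexical can be
  tested (no NLP condensation, by design).
* Focal subgraphs are strictly 1-hop; k-hop neighborhoods are not offered.
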