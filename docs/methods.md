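# Methods

## Input model

The pipeline operates on a samples × taxa table of non-negative genus-level
abundances and per-sample host metadata (country, study, age in years, sex,
BMI in kg/m²). Abundances are total-sum scaled per sample before any
distance computation; Bray–Curtis on relative abundances is the community
standard and the source collections store relative abundances. Countries
with fewer than 20 samples are excluded (inclusive boundary: exactly 20
passes). BMI is binned with the WHO convention using half-open intervals
[0, 18.5), [18.5, 25), [25, 30), [30, ∞); the printed bin labels
("18.5–24.9", "25–29.9") leave [24.9, 25) and [29.9, 30) ambiguous, and the
half-open reading is the standard one. Missing metadata is never an
enrichment level: dummy-coded indicator rows for a missing sample are
all-zero for that variable, keeping the sample in the network while
excluding it from that variable's signal. Cohort age summaries are computed
over non-missing ages and reported to one decimal.

## Mapper

* **Distances.** Bray–Curtis, `1 − 2·Σ min / (Σx + Σy)`, through
  `scipy.spatial.distance.pdist`; a hand-written implementation of the
  formula serves as the cross-check oracle in the tests. All-zero samples
  make the distance undefined and are rejected by name.
* **Lens.** Two-component metric MDS by stress majorization (SMACOF) on the
  precomputed distance matrix, initialised from classical (Torgerson)
  scaling, at most 300 iterations, stress-change tolerance 1e-6. The
  classical start makes the embedding deterministic; the seed argument is
  kept for interface stability. The raw final stress is reported.
* **Cover.** Per axis, base width `w = range/resolution`; bin *i* spans
  `[min + i·w − o·w/2, min + (i+1)·w + o·w/2]` for overlap fraction *o*; the
  2-D cover is the grid product and a degenerate axis contributes a single
  interval. Resolution means base intervals per axis, so the grid has
  resolution² bins.
* **Clustering.** DBSCAN (scikit-learn, precomputed metric) inside each bin
  on the original-space distances; core points need ≥ `min_samples` = 5
  neighbours within `eps` including themselves. `eps` is the nearest-rank
  95 % quantile of per-sample nearest-neighbour distances (`optimize_eps`);
  nearest-rank is used everywhere a percentile appears, for determinism and
  exact testability. Noise points are dropped; bins with fewer than 5
  members contribute no nodes. Dropped samples are the complement of the
  node-membership union; the cover ratio is retained/total.
* **Nerve.** One node per cluster; an edge exactly when two nodes share at
  least one sample. Node centroids are mean lens positions of members.
* **Persistence.** H0 only: finite deaths are the single-linkage merge
  heights (equivalently minimum-spanning-tree edge weights, via
  `scipy.cluster.hierarchy.linkage`), plus one infinite bar. The expected
  cluster count is read off with a largest-gap rule on the sorted deaths.
  Dimension-1 persistence is out of scope: on these data loops carry no
  high persistence and the H0 count alone drives the structural checks.

Default cover parameters ship as resolution 85 / overlap 0.85 — the
published final setting for the ~4,400-sample cohort. Resolution should
scale with sample count (bins need ≥ 5 members to form nodes); the bundled
experiments use resolutions 6–12 for 100–250-sample problems.

## SAFE enrichment

Node attribute = mean of the per-sample variable over the node's members
(missing values excluded; an all-missing node gets 0 and is flagged). Node
distances are unweighted shortest-path hop counts; the neighbourhood of a
node is itself plus all nodes within the nearest-rank 0.5th percentile of
all finite off-diagonal pairwise distances. The observed statistic is the
neighbourhood sum of the attribute. One-sided p-values use the add-one
estimator `p = (1 + #{null ≥ observed}) / (1 + P)` with `P` = 5,000
permutations by default; the SAFE score is `−log10 p / −log10 (1/(1+P))`
clipped to [0, 1], so the minimum attainable p maps to exactly 1. Nodes with
p < 0.05 are "enriched"; the SAFE enriched score of a variable is the sum of
its scores over enriched nodes (the enriched-node count is reported
alongside as an alternative summary). Ranking is by score, ties broken
lexicographically.

**Permutation null.** Two schemes are implemented. The default shuffles the
*per-sample* values across the network's samples and re-aggregates node
means for every permutation. The classical SAFE convention — shuffling the
node-level attribute values across nodes — is available as
`permute="nodes"` but is anti-conservative on Mapper networks with strongly
overlapping covers: adjacent nodes share member samples, so node attributes
are positively correlated even for a variable with no signal, and the node
shuffle destroys that correlation in the null. Measured on null cohorts at
overlap 0.85, the node scheme rejects ~13 % of nodes at α = 0.05 versus
5.1 % for the sample scheme (the inflation grows with overlap and vanishes
at disjoint bins). The sample-level null is exact for per-sample variables
and is therefore the default; the node scheme is retained for comparison
with reference implementations, whose scores it reproduces in spirit.

The permutation test is one-sided (enrichment only), matching how these
scores are used; depletion is not analysed. For a dummy level carried by
few, widely dispersed samples the neighbourhood sums are heavily tied and
the test is conservative — such variables can never reach significance,
which is the known low-sample caveat of the method and is reproduced as a
test.

## Co-enrichment and stratification

Pairwise co-enrichment of two variables is a one-sided Fisher exact test
(hypergeometric tail) on the 2×2 table (both / a only / b only / neither)
of their enriched node sets over all network nodes; an empty set on either
side returns p = 1. The paper-level operationalisation "enrich in the same
area of the network" has no named statistic; overlap of significant node
sets is the natural choice and is isolated behind one function so a
score-correlation alternative could be swapped in. The full p-matrix is
binarized at the nearest-rank 0.5th percentile of its upper-triangle values
(inclusive ≤), a deliberately strict cut standing in for multiplicity
control over the thousands of pairs; if all p-values are identical every
pair passes (documented degenerate case). Stratification assigns each node
the enriched variable with the highest SAFE score there (lexicographic
ties; nodes enriched for nothing stay unlabelled).

## Synthetic cohorts

`SyntheticSpec` describes a cohort: country sample counts, taxon count,
study count, per-study taxon-panel fraction, Dirichlet base concentration,
planted (country, taxon, effect ≥ 1) associations, and per-country
metadata distributions. Compositions are Dirichlet draws; the default
concentration is long-tailed, `αⱼ = 5/(1+j)` — a few dominant genera, a
sparse tail, median between-subject Bray–Curtis ≈ 0.55 and roughly a
quarter of entries near zero at 60 taxa, the regime of curated genus
tables. Planted effects multiply the target taxon's concentration for the
target country's samples before drawing, so every draw remains a valid
composition. Studies are country-exclusive (1–3 per country) and each
study measures a fixed random subset of taxa; off-panel taxa are zeroed
and the composition renormalised, giving all samples of a study an
identical structural-zero pattern — the curation artefact that makes
pooled repositories cluster by panel. `null_dataset` draws compositions
and study panels identically for all samples and attaches country labels
(and country-conditional metadata) independently, so labels are
exchangeable with respect to abundance — the calibration input.
`blob_dataset` puts k groups on disjoint taxon blocks for ground-truth
cluster counts. Everything is reproducible from the spec's seed.

What the generator does **not** emulate: taxon co-occurrence and
phylogenetic correlation, overdispersion beyond the Dirichlet, sequencing
depth variation, and within-country substructure. Passing tests therefore
demonstrate correctness of the machinery and its statistical calibration
under compositional noise — not that real cohorts will show any particular
enrichment pattern.

## Standard experiments and their conditions

`microstrat.experiments` fixes the package's validation studies in one
place:

* **Type-I calibration** — 50 end-to-end runs on null cohorts (2 countries
  × 50 samples, 30 taxa, resolution 6 / overlap 0.85, P = 999), probing
  the continuous age variable; the per-node rejection rate at α = 0.05 is
  ~0.05. Age is used because country-dummy node proportions are heavily
  tied at ~10-member nodes, which makes the discrete permutation test
  conservative rather than miscalibrated.
* **Planted-effect recovery** — 20 end-to-end runs with a ×5 concentration
  effect of one of two 50-sample countries on a mid-abundance genus
  (~3.5 % → ~15 % mean share), 60 taxa, resolution 7 / overlap 0.85,
  P = 999. Recovered: the planted country ranks first among countries by
  SAFE enriched score and the (country, taxon) pair survives binarization,
  each in ≥ 90 % of runs; no-signal controls flag the pair in ≤ 10 %.
  These conditions were validated on 100 held-out seeds (96 % / 99 %).
  Planting on the *dominant* genus instead separates the two countries
  completely, whereupon the diffuse complement country legitimately
  accumulates a larger enriched-score sum — with only two labels the
  complement of a compact planted region is itself a coherent signal, a
  useful caution when interpreting two-group stratifications.
* **Structural consistency** — on three compositional blobs, the Mapper
  network's connected-component count equals the H0 high-persistence bar
  count (three).

Problem sizes throughout the test and acceptance suites (≈100–250 samples,
30–120 taxa, P = 999) are scaled-down study conditions chosen so the full
suite completes in a few minutes; all thresholds and percentiles are the
full-scale defaults.

## Known limitations

* The SAFE enriched score grows with the number of nodes a variable's
  samples occupy; variables covering large sparse regions outscore equally
  strong but compact signals. Compare the enriched-node count column when
  ranking.
* Fisher overlap p-values are coarse on small networks (few dozen nodes);
  the 0.5th-percentile binarization then reduces to "the handful of most
  extreme pairs".
* The largest-gap cluster-count heuristic on H0 deaths is meaningful only
  when clusters are well separated; it returns 1 for a two-point diagram
  and an arbitrary split on gapless data.
* The cover convention (symmetric widening by `o·w/2`) is one of several
  in circulation; cover ratios are comparable only within one convention.
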