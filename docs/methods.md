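# Methods

## Connectome construction

A streamline contributes to the connectivity matrix only through its two
endpoints.  Each endpoint (world mm) is mapped through the inverse affine
of the parcellation label volume to continuous voxel coordinates, rounded
half-away-from-zero to the nearest 0-based voxel index (NIfTI convention),
and looked up in the label grid; out-of-bounds points map to background
(label 0).  A record is kept only when both endpoints land on labels of the
requested node set and the labels differ; each kept record increments both
a_ij and a_ji, so matrices are symmetric with zero diagonal by
construction.  Discards are tallied by reason (background, outside the
node subset, traversal-filtered, same-structure pair) and reported in the
provenance JSON — total weight always equals twice the kept count.

Same-structure streamlines are discarded rather than accumulated on the
diagonal: all downstream measures (degree, eigenvector, betweenness,
modularity, reaching centrality) are defined here on loop-free weighted
graphs, and a nonzero diagonal would contaminate degree and the Perron
vector with self-weight.

Per subject, run-level count matrices are averaged elementwise (no
rounding); subject-level matrices are averaged into an overarching mean
with elementwise inter-subject sample SDs (ddof = 1; SD is reported as
undefined for a single subject).

### Restriction modes

Removing structures from the node set can be done three ways, which differ
on real tractography and are all exposed:

- `submatrix` — drop rows/columns of an existing matrix;
- `endpoint_filter` — rebuild, discarding records with an endpoint in a
  removed structure;
- `traversal_filter` (default of `restrict`) — additionally discard
  records whose traversed-label set intersects the removed set.  This
  emulates re-running tractography with an altered white-matter mask: a
  streamline that *passes over* a removed relay structure is never
  produced, even though neither endpoint touches it.  On synthetic data
  this reproduces the qualitative drop of cortico-cortical connectivity
  when subcortical relays are removed.

Degenerate-input note: when the removed set carries *all* between-community
routes (the synthetic generator's default traversal design), the
traversal-filtered network splits into near-complete uniform blocks whose
betweenness is identically zero; ranking such a measure is then undefined
and `rank_structures` raises.  The end-to-end pipeline therefore defaults
to `endpoint_filter`; analyses that specifically target the severing
effect (the topology-contrast experiment) request `traversal_filter`
explicitly.

### Volume normalization

a'_ij = a_ij / (vol_i + vol_j), with volumes in mm³ taken from the
parcellation table (ensemble-mean volumes; per-subject volumes are not
modeled).  Scaling all volumes by c scales all normalized weights by 1/c,
so max-normalized rankings are invariant to the volume unit.

## Centrality

- Degree: row sums.
- Eigenvector: power iteration on A + sI (s = max row sum); the diagonal
  shift preserves the Perron vector while breaking the ±λ spectral
  symmetry of bipartite graphs that stalls plain power iteration.
  Convergence tolerance 1e-12 on the iterate change, max 10,000
  iterations; components are non-negative and rescaled to max 1 (only
  relative values matter for ranking).  On a disconnected matrix the
  vector is computed on the largest component with a warning and zeros
  elsewhere.
- Betweenness: edge length is the reciprocal of the weight; distances by
  Dijkstra from every source; shortest paths are counted over the DAG of
  "tight" edges, where an edge u→v is tight if d(s,u) + l(u,v) ≤
  d(s,v)·(1 + 1e-9) — the relative tolerance counts floating-point-tied
  geodesics as bona fide ties.  Through-counts use the decomposition
  σ_jk(i) = σ_ji·σ_ik when d(j,i) + d(i,k) matches d(j,k) within the same
  tolerance.  The prefactor 2/((N−1)(N−2)) with unordered pairs and
  endpoints excluded puts b_i in [0, 1]; a star center scores exactly 1.
  Unreachable pairs contribute 0.

Hub tables follow the per-subject-then-average protocol: centralities are
computed on each subject's run-averaged matrix, averaged per structure
across subjects with sample SDs, max-normalized (top structure exactly 1),
and sorted descending with lexicographic name tie-breaks.  SDs are emitted
both raw and on the normalized scale.  The centrality-of-the-averaged-
matrix variant is also available (it differs in general for the nonlinear
measures — the test suite constructs an explicit counterexample) and is
used for top-k exports of the overarching connectome.

## Global topology

- Global efficiency: mean inverse geodesic distance over ordered pairs;
  disconnected pairs contribute 0.
- Modularity: Newman's weighted Q.  Maximization uses the Louvain
  heuristic (networkx implementation, resolution 1) with seeded restarts
  (default 10), keeping the best partition; the single-community partition
  (Q = 0) is always a candidate, so the reported "ultimate modularity" is
  never negative.  The returned Q is recomputed from the returned
  partition with our own Q implementation, guaranteeing internal
  consistency to 1e-12; on graphs of ≤ 7 nodes the test suite checks
  Louvain against exhaustive enumeration of all partitions.
- Reaching centrality: the weighted local reaching centrality averages,
  over reachable targets, the mean edge weight along one selected geodesic
  per target.  Which geodesic is underdetermined for weighted graphs; the
  package selects by inverse-weight distance, breaking ties by fewest
  links and then lexicographic next-hop, making the selection
  deterministic.  This is the main metric ambiguity in the measure's
  definition for weighted undirected graphs; each undirected edge is
  treated as two directed links.  Raw weights are used as the link weights
  (no pre-normalization), so GRC scales with the weight scale; GRC ∈
  [0, 1] holds when weights are ≤ 1.  An alternative reading treats the
  weights themselves as distances in the geodesic selection; the
  inverse-weight reading is the default because it matches the distance
  convention used by betweenness and efficiency.

## Synthetic generator

The generator emulates the *output* statistics of probabilistic
tractography, not the tracking process: no diffusion signal, fibre
orientations, or curved geometry.

- **Parcellation**: two "hemisphere" community blocks plus a "subcortical"
  block holding the hubs (three communities; small parcellations without
  spare regions collapse to two).  Volumes are lognormal, median 3000 mm³
  and log-SD 0.4 by default (≈ ±50% spread, typical of same-scale brain
  structures); hubs get exactly `hub_multiplier × median` (default 3×,
  a brainstem-like outsized structure that is the largest in the table
  whenever the multiplier exceeds the dispersion-adjusted sample maximum).
- **Label volume**: a brain-like ellipsoid partitioned by nearest-seed
  Voronoi assignment, with per-region seed-point counts proportional to
  volume (budget 16 points/region), so voxel counts track volumes;
  background only outside the ellipsoid.
- **Ground truth**: pair weight w_in within a community, w_out between
  (defaults 2 and 1), times hub_boost (default 3) for pairs touching a
  hub, normalized to unit mass over unordered pairs.  Every
  between-community pair's traversal set holds one hub id — the
  deliberate, maximally simple abstraction of white-matter-mask effects
  (cortico-cortical streamlines passing over subcortical relays).  With
  hub_boost ≥ 3 and w_in/w_out = 2 the hub provably has the largest
  expected row mass.
- **Endpoints**: each record samples an unordered pair from the
  probability matrix, then an endpoint voxel uniformly within each
  region (no cortical-surface bias — the simplest defensible choice);
  orientation and record order are randomized.
- **Subjects/runs**: per subject, pair weights are perturbed by
  multiplicative lognormal noise (log-SD `subject_noise_sd`, default 0.2 —
  a free parameter, not calibrated to real cohorts, since no published
  inter-subject variance for matrix entries is available) and
  renormalized; runs resample endpoints independently.  Per-subject volume
  jitter is not modeled; volume normalization uses the parcellation's
  ensemble-mean volumes.

All randomness flows from `numpy.random.SeedSequence` spawns of one seed;
identical seeds give bit-identical ensembles, and a pipeline rerun with
the same config reproduces every output file byte for byte.

What passing on this generator shows — and what it does not: the synthetic
model reproduces the qualitative structure the analysis targets (a
dominant hub, community blocks, inter-community routes through the hub,
inter-subject variability) but not real tractography's biases (distance
and size dependence of streamline counts, gyral bias, false-positive
bundles), so test results validate the analysis machinery, not claims
about real brains.

## Study conditions and reference experiments

The packaged experiments fix the study conditions at 30 regions / 1 hub /
hub_boost 3 / w_in:w_out = 2 / subject noise 0.2:

- hub recovery: 100 independent ensembles of 20 subjects × 3 runs × 5,000
  streamlines; rates at which the hub ranks first per measure, and stays
  in the top 10 of all measures after volume normalization.
- topology contrast: 50 ensembles of 5 subjects × 2 runs × 5,000
  streamlines (a desk-scale choice; the contrast is stable at this size),
  restriction = hub removal with the traversal filter, Louvain with 3
  restarts; rates at which restricted variants have higher mean ultimate
  modularity and extended-raw the highest mean GRC.
- sampling recovery: fraction of pairs within the 4σ multinomial band at
  50,000 streamlines.

Known limitation: after volume normalization the hub's *eigenvector* rank
fluctuates — when one community's volumes sample small, its inflated
normalized mutual weights can capture the Perron vector and push the hub
just past rank 10 (of 30) in a minority of worlds.  The raw-centrality hub
dominance is unaffected.  `scripts/acceptance.py` computes and reports all
of these rates.

## Packaged atlas lists

The 104/84/20-structure tables in `structconn/data/` are synthetic
stand-ins (flagged in their filenames): FreeSurfer aseg/aparc naming with
plausible average volumes, constructed so the node-set arithmetic
(104 − 20 = 84) is exact and the brainstem is the flagged hub.  They are
not transcriptions of any cohort's measurements.
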