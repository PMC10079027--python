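# structconn

Structural connectome construction and hub analysis, with a synthetic
multi-subject streamline-endpoint generator.

## The problem

Diffusion-MRI tractography reconstructs white-matter streamlines; a
structural connectome summarizes them as a weighted network whose nodes are
parcellated brain structures and whose edge weight a_ij counts the
streamlines with one endpoint in structure i and the other in structure j.
Whether subcortical structures — above all the brainstem — are included in
the parcellation changes the network profoundly: an *extended* node set
(104 structures, brainstem included) and a *restricted* Desikan-Killiany
style set (84 structures, 20 subcortical structures removed) can disagree
about which structures are hubs and how integrated, segregated, and
hierarchical the network is.

`structconn` implements that analysis end to end for network
neuroscientists: building symmetric streamline-count matrices from endpoint
records, averaging over runs and subjects, restricting node sets three
different ways, normalizing by structure volume, and quantifying hubs and
global topology.  Because subject-level diffusion data is not
redistributable, the package ships a first-class synthetic generator — a
planted-hub stochastic block model over region pairs, sampled into
per-streamline endpoint coordinates inside a voxel label volume — so every
stage runs and is tested at desk scale.

## The measures

For the weighted adjacency A = (a_ij) with node set of size N:

- **Degree centrality (node strength)**: d_i = Σ_j a_ij.
- **Eigenvector centrality**: the components of the Perron eigenvector v of
  A (largest eigenvalue λ, Av = λv), rescaled so max_i v_i = 1.
- **Betweenness centrality**:
  b_i = 2/((N−1)(N−2)) · Σ_{j<k, j≠i≠k} σ_jk(i)/σ_jk, where σ_jk counts
  weighted shortest paths (edge length = 1/weight, Dijkstra) and σ_jk(i)
  those passing through i.
- **Global efficiency** (integration):
  E_glob = 1/(N(N−1)) · Σ_{i≠j} 1/s_ij with s_ij the geodesic distance.
- **Ultimate modularity** (segregation):
  Q = 1/(2m) Σ_ij [a_ij − d_i d_j/2m] δ(c_i, c_j), maximized over
  partitions with seeded Louvain restarts.
- **Global reaching centrality** (hierarchy):
  GRC = Σ_i [C_R^max − C_R(i)]/(N−1), where the local reaching centrality
  C_R(i) averages the mean edge weight along the selected geodesic from i
  to each reachable node.

Hub tables are built per subject, then averaged per structure with
inter-subject SDs and max-normalized so the top structure scores exactly 1.

## Worked example

```python
import structconn as sc

parc = sc.make_parcellation(n_regions=30, n_hubs=1, seed=7)
vol = sc.make_label_volume(parc, grid_shape=(16, 16, 16), seed=8)
gt = sc.make_ground_truth_matrix(parc, w_in=2.0, w_out=1.0, hub_boost=3.0)
records = sc.generate_ensemble(gt, vol, n_subjects=5, n_runs=3,
                               n_streamlines=5000, subject_noise_sd=0.2, seed=9)

by_subject = {}
for rs in records:
    by_subject.setdefault(rs.subject_id, []).append(rs)
subject_mats = [sc.average_runs([sc.build_matrix(r, vol, parc).matrix for r in runs])
                for _, runs in sorted(by_subject.items())]

table = sc.rank_structures(sc.per_subject_centralities(subject_mats, "degree"))
print(table.rows.head(5)[["name", "mean", "sd", "normalized_mean"]].to_string(index=False))

mean = sc.average_subjects(subject_mats).mean_matrix
part, q = sc.louvain_partition(mean, seed=0, n_restarts=10)
grc, _ = sc.global_reaching_centrality(mean)
print(f"E_glob = {sc.global_efficiency(mean):.1f}   Q* = {q:.3f} "
      f"({part.n_communities} communities)   GRC = {grc:.1f}")
```

prints

```
      name       mean        sd  normalized_mean
    hub-01 749.200000 23.092327         1.000000
ctx-lh-001 350.000000  9.840393         0.467165
ctx-rh-003 343.533333  9.269424         0.458534
ctx-lh-004 341.800000 11.199206         0.456220
ctx-lh-007 340.000000 18.351506         0.453817
E_glob = 14.6   Q* = 0.125 (3 communities)   GRC = 13.4
```

The planted hub tops the degree ranking by a wide margin (normalized 1.0
vs 0.47 for the runner-up), with inter-subject SDs far smaller than that
gap; the global summary shows a weakly modular (Q* = 0.125), strongly
hub-dominated network.

The same analysis is available from the shell:

```sh
structconn simulate --regions 30 --subjects 5 --runs 3 --seed 7 --out-dir data/
structconn build --endpoints data/endpoints.tsv --labels data/labels.nii \
    --parcellation data/parcellation.csv --out matrix.tsv
structconn centrality --matrices matrix.tsv --measure all --top 10 --out ranking.csv
structconn run --seed 7 --out-dir out/     # full pipeline, all four variants
```

Endpoint TSVs produced by any external tractography tool can be fed to
`structconn build` directly; the packaged 104/84/20-structure atlas lists
(synthetic volumes, FreeSurfer-style names) are in
`structconn.fixtures`.

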