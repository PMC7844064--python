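# posespace

Score-weighted analysis of ensemble docking pose spaces, built for
structure–activity work on congeneric ligand series — the motivating case
being pyrazoloquinolinone modulators docked into extracellular α+/β−
subunit interfaces of GABA_A receptors, where a single scaffold can adopt
several distinct binding modes and substituent changes can switch a
compound between them.

Given per-pose ligand–receptor complexes (PDB) and docking scores
(chemscore, higher = better), the package:

1. expresses ligand **core atoms in a binding-site-anchored frame** built
   from four Cα anchors (origin + three axes, Gram–Schmidt orthonormalized,
   rebuilt per pose complex) — no structural superposition needed;
2. **clusters poses by core-atom RMSD** (pooled over all compounds, Ward
   linkage, cut at K) and discards clusters in which no compound has more
   than `min_count` poses;
3. summarizes each compound as a **distribution of summed chemscores over
   retained pose clusters** and measures pairwise compound dissimilarity by
   **earth mover's distance**, with distances between cluster centroids in
   the first three principal components of the (sin/cos-encoded) spherical
   coordinates as the ground metric;
4. embeds compounds in a deterministic 3D **diffusion map** that exposes
   compound groups and branch points of the structure–activity landscape;
5. provides a **synthetic pose generator** with planted binding modes and
   ground truth, so every stage is testable without docking software; and
6. includes a small **efficacy meta-analysis** module (fold changes across
   receptor variants, γ2/δ impact summaries, NAM/silent/PAM classification,
   similarity-ordered heatmap layouts) for aggregated modulation data
   expressed as % of control GABA current.

For compound profiles p, q over retained clusters with centroid distances
d(i, j), the compound dissimilarity is the optimal-transport cost

    EMD(p, q) = min_f Σ_ij f_ij d(i,j)   s.t.  Σ_j f_ij = p_i, Σ_i f_ij = q_j, f ≥ 0,

solved exactly as a transportation LP; with d a metric, EMD is a metric.

## Worked example

```python
import numpy as np
from sklearn.metrics import adjusted_rand_score, silhouette_score
import posespace as ps

spec = ps.paper_scale_fixture(seed=1)          # 30 compounds x 200 poses, 4 planted modes
ensemble, truth = ps.generate_ensemble(spec)
result = ps.analyze_ensemble(ensemble, n_clusters=4)

cl = result.clustering
planted = truth.mode_array(result.features.keys)
groups = [truth.compound_groups[c] for c in result.embedding.compound_ids]
print("poses:", len(ensemble), "retained:", cl.retained_pose_count,
      "clusters:", cl.n_retained_clusters)
print("mode recovery ARI:", round(adjusted_rand_score(planted, cl.labels), 3))
print("group silhouette:", round(silhouette_score(result.embedding.coordinates, groups), 3))
```

prints

```
poses: 6000 retained: 6000 clusters: 4
mode recovery ARI: 1.0
group silhouette: 0.991
```

i.e. the canonical fixture's 6000 poses all survive the population filter
(every compound exceeds 10 poses in each of the four well-separated planted
modes), RMSD clustering recovers the planted modes exactly (adjusted Rand
index 1.0), and the EMD → diffusion-map embedding separates the three
planted compound groups almost perfectly (silhouette 0.99 on the 3D
coordinates).

The same workflow runs from the shell on exported files:

```bash
posespace simulate --out run/                 # synthetic run (PDBs + CSVs + truth)
posespace extract  --poses run/poses --scores run/scores.csv \
                   --core run/core_map.csv --anchors run/anchors.yaml \
                   --out coords.csv
posespace cluster  --coords coords.csv --K 4 --min-count 10 --out clusters.csv
posespace embed    --clusters clusters.csv --scores run/scores.csv \
                   --geometry clusters.geometry.json --out embedding.json
posespace efficacy --table eff.csv --report report/
```

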