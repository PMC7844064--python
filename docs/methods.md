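# Methods

## Problem and approach

Ensemble docking of a congeneric ligand series into a receptor pocket
produces, per compound, a few hundred scored poses. The question this
package addresses is not "which pose is best" but "how is each compound's
score mass distributed over the recurrent spatial arrangements (binding
modes) of the shared core, and which compounds switch modes as substituents
change". The workflow:

1. **Anchored frame.** Each pose complex is expressed in a local coordinate
   system built from four receptor Cα atoms: an origin residue and three
   axis residues (for the α1-subunit extracellular α+/β− pocket these are
   Gly208 as origin with Ser205, Tyr210 and the complementary-chain Met115
   as axes; homologous residues serve for other subunits and are supplied
   by configuration, never hard-coded). The basis is built by modified
   Gram–Schmidt over the axis directions in their listed order, with the
   third axis replaced by x̂ × ŷ signed along the orthogonalized third
   direction, so it is always orthonormal and right-handed. The frame is
   rebuilt from each pose's own complex, which absorbs receptor-side
   flexibility and makes superposition unnecessary: features are invariant
   to any rigid transform of a complex (verified to 1e-6 Å).

2. **Features.** The compound's core atoms (a configured subset shared
   across the series, ≥ 3 atoms, canonical label order) are expressed in
   the frame both as Cartesian coordinates and as spherical coordinates
   (r ≥ 0; polar θ ∈ [0, π] from +z; azimuth φ ∈ [−π, π) from +x toward +y;
   θ := 0 and φ := 0 at the degenerate origin/axis cases).

3. **Pose clustering.** Poses from *all* compounds are pooled and clustered
   agglomeratively with core-atom RMSD as the distance, cut at a fixed K.
   RMSD over fixed-order coordinates equals the Euclidean distance of the
   flattened coordinates divided by √m, so Ward linkage on the scaled
   coordinates is an exact RMSD hierarchy (average linkage is available by
   configuration). Clusters in which no single compound has strictly more
   than `min_count` poses (default 10, i.e. ≥ 11) are discarded together
   with their poses; retained clusters are renumbered 1..K′ preserving
   original order so ids are stable across reruns.

4. **Cluster geometry.** The spherical coordinates are encoded for PCA:
   each angle as its (sin, cos) pair and each radius scaled to unit
   variance. The encoding removes the wrap-around discontinuity at ±π that
   raw angles would inject into a linear method; raw radians remain
   available (`encoding="radians"`), and the choice is echoed in output
   metadata. Coordinates of covalently connected atoms are strongly
   cross-correlated; PCA decorrelates them, and distances between retained
   cluster centroids in the first three components serve as the
   between-mode ("ground") dissimilarity.

5. **Score profiles and EMD.** Per compound, pose chemscores are floored at
   zero (transport mass must be nonnegative; the count of floored poses is
   recorded), summed per retained cluster and normalized to unit mass.
   Compound dissimilarity is the exact earth mover's distance between
   profiles under the centroid ground metric, solved as a transportation
   linear program (HiGHS). With a metric ground distance EMD is itself a
   metric; the suite property-tests the axioms and checks the LP against
   an exhaustive enumeration of the transportation polytope's vertices on
   small instances (|Δ| ≤ 1e-9).

6. **Diffusion-map embedding.** The EMD matrix is embedded in 3D with a
   deterministic diffusion map: adaptive-bandwidth α-decay kernel
   K_ij = ½·(exp(−(d_ij/σ_i)^α) + exp(−(d_ij/σ_j)^α)) with σ_i the distance
   to the k-th nearest neighbor (k = 5, α = 10), rows normalized to a
   stochastic matrix, powered t = 3 steps, −log potential, classical MDS.
   No seeds are involved: dense eigendecomposition with the sign of each
   axis fixed so its largest-magnitude coordinate is positive. t is fixed
   rather than entropy-selected — determinism is valued over adaptivity
   here, and all kernel parameters are exposed and echoed in diagnostics.
   When groups of compounds are strongly separated the kernel graph
   disconnects; the embedding remains well-defined (the log-potential is
   finite across components), so this is reported as a warning by default,
   with `on_disconnect="error"` available for strict use.

7. **Subset score test.** Whether two subsets of the retained clusters
   (e.g. the two overall orientations of the core in the pocket) differ in
   mean per-pose chemscore is assessed by a two-sided Welch two-sample
   t-test; a seeded permutation test (10⁴ resamples) is available by
   configuration. The test treats poses as independent draws, which
   overstates the effective sample size for correlated poses of one
   compound — p-values should be read as descriptive of the score
   separation, not as confirmatory inference.

## Key parameters

| parameter | default | meaning |
|---|---|---|
| `n_clusters` (K) | 80 | hierarchy cut; 80/40 are the reference values for the two pockets analysed in the source workflow |
| `min_count` | 10 | cluster retained iff some compound has > 10 poses in it |
| `linkage` | ward | exact for RMSD (scaled Euclidean); `average` available |
| `encoding` | sincos | angle encoding for PCA; `radians` available |
| `n_components` | 3 | PCs used for centroid geometry |
| `knn`, `decay`, `t` | 5, 10, 3 | diffusion-map kernel bandwidth index, decay exponent α, diffusion time |
| `thresholds` | (80, 120) % | NAM / silent / PAM bands around the 100 % no-modulation point (a convention, configurable) |

## Synthetic generator

`synth.generate_ensemble` emulates a docking run at the level the pipeline
consumes. Each planted binding mode is a rigid placement (Euler rotation +
translation) of a hard-coded planar 8-atom fused-ring mock core; a pose is
the placement plus isotropic Gaussian jitter (σ = 0.35 Å by default), and
its chemscore is base + mode offset + Gaussian noise (σ = 1). Complexes
carry the four anchor Cα pseudo-residues (numbered 205/208/210 on the
principal chain and 115 on the complementary chain) so the real
anchor-resolution code path is exercised; one pose per PDB file. Each
compound draws from a child RNG stream spawned in compound order, so
extending a spec never perturbs existing compounds.

`paper_scale_fixture()` is the canonical full-scale run: 30 compounds ×
200 poses from 4 modes whose placements are ≥ 10 × jitter σ apart, with
high score offsets on modes 1–2 and low on modes 3–4 (subset gap ≈ 9 ×
noise σ), and three compound groups of ten (mode-1 loyal, mode-2 loyal,
ambivalent, with mixture weights 0.85/0.05/0.05/0.05 and 0.30/0.30/0.20/0.20).
Sample sizes mirror a realistic exhaustive docking campaign; separations
and offsets are chosen well clear of the noise floor so that failure to
recover them indicts the pipeline, not the draw.

What the generator does **not** emulate: pose-level energetics, receptor
flexibility (anchors are fixed), chemistry-dependent core geometry,
anisotropic or mode-dependent pose spread, and score–geometry correlation
within a mode. Passing recovery tests therefore demonstrates that the
pipeline's machinery is correct and well-conditioned, not that real docking
ensembles cluster this cleanly: real pose spaces have overlapping modes,
heavier filter attrition and weaker group structure.

## Numerical choices

- Strict "> min_count" filter (the retention rule counts ≥ 11 as passing at
  the default threshold).
- Degenerate spherical conventions: θ := 0 at the origin, φ := 0 on the
  z-axis; φ is half-open at +π.
- Anchor axis independence is guarded by a condition-number bound (1e6);
  left-handed anchor geometry is an error rather than silently flipped.
- PCA uses full SVD with a fixed sign convention (largest-|loading|
  positive); zero-variance input is rejected as a degenerate ensemble.
- EMD mass mismatch beyond 1e-6 is an error; profiles are validated to sum
  to 1 ± 1e-9.
- Log-potential offset 1e-7 and kernel-connectivity threshold 1e-8 in the
  diffusion map.
- Cluster labels are renumbered by first appearance in (sorted-key) row
  order, making the partition labeling independent of scipy internals.

## Design choices that were genuinely open

- Whether clustering operates on Cartesian or spherical RMSD: Cartesian
  in-frame coordinates are the default ("RMSD of the compound atoms"
  reads most naturally as real-space deviation), spherical features feed
  the PCA/centroid branch; both derive from the same frame.
- The identity of the statistical test behind the subset comparison:
  Welch's t by default, permutation as an option.
- The diffusion-map internals (kernel form, k, α, t) follow the
  phenotypic-EMD lineage of embedding score distributions; the specific
  defaults are this package's own and are all configurable.
- Orthonormalization of the anchor axes (rather than an oblique raw-vector
  frame) is a deliberate choice for numerical stability and rigid
  invariance.

## Problem sizes

The default test suite runs small ensembles (3 compounds × 20 poses) for
unit-level checks and one full-scale canonical run (30 × 200 = 6000 poses,
Ward over all poses, 435 EMD LPs) for recovery checks; the whole suite and
the acceptance script each complete in well under a minute on one CPU.

## Known limitations

- Pose clustering is O(N²) memory in the pooled pose count (condensed
  distance matrix); runs of ~10⁴ poses are routine, ~10⁵ are not.
- K is fixed by the user; no automatic model selection is offered.
- The efficacy module reproduces aggregation arithmetic only — no
  dose–response fitting, no error propagation from the source studies.
- PDB is the only complex format read; coordinates round-trip at PDB's
  1e-3 Å precision.
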