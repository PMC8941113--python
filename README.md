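# hypercore

Hyperbolic disc embedding and *k*-core percolation of voxel-wise
functional-connectivity networks from resting-state fMRI.

## The problem

Resting-state BOLD fluctuations define, for every pair of voxels, a
functional connectivity ρ̂(X, Y) — the sample Pearson correlation of their
time series. Thresholding the correlation matrix at a value chosen for
scale-freeness of the degree distribution (and retention of ≥ 80% of voxels
in the largest connected component) yields an unweighted, undirected brain
graph per subject. Two complementary analyses then expose its hierarchy:

1. **S1/H2 embedding.** Each voxel gets polar coordinates (r, θ) on a
   hyperbolic disc such that the Fermi connection probability

   p_ij = 1 / (1 + exp((β/2)(d_ij − R̂)))

   with d_ij the hyperbolic distance (law of cosines,
   cosh d = cosh r_i cosh r_j (1 − tanh r_i tanh r_j cos Δθ_ij), curvature 1)
   maximally explains the observed adjacency. Angles encode similarity —
   functionally cooperating voxel groups aggregate into angular sectors,
   quantified by the angular coherence ξ e^{iφ} = (1/N) Σ_k e^{iθ_k} — and
   radii encode popularity: hubs sit near the disc center.

2. ***k*-core percolation.** Iteratively peeling voxels of degree < k for
   growing k yields each voxel's coreness, the S(k) core-size curve with its
   abrupt drops, and finally the k_max-core — the innermost subgraph that
   disintegrates one step later. Profiling k_max-core membership against
   functional subnetwork labels (15 ICA components, collapsed to 7
   categories) classifies subjects as DMN-dominant, VN-dominant or
   distributed (> 40% of core voxels in one category), and the voxels shared
   by ≥ 60% of subjects' cores form the cohort's common core.

Real imaging cohorts are not bundled; the package ships
synthetic generators with planted ground truth — S1 networks with known
coordinates, block-correlated BOLD with known modules, planted dense cores,
and cohorts with prescribed dominance patterns — so every stage is testable
end to end.

## Worked example

Embedding recovery on S1-model networks with known coordinates
(`python analysis/01_benchmark_embedding.py`):

```
 seed  n_lcc  lcc_fraction  beta_true  beta_est  angle_similarity  kappa_pearson
    1    493         0.986        2.5     2.555            0.9909         0.9880
    2    497         0.994        2.5     2.555            0.9956         0.9768
    3    498         0.996        2.5     2.696            0.9909         0.9926
    4    496         0.992        2.5     2.555            0.9899         0.9842
    5    499         0.998        2.5     2.555            0.9918         0.9917

median aligned angle similarity: 0.991
```

`angle_similarity` is the mean cosine between inferred and planted angles
after resolving the disc's rotation/reflection gauge: 0.99 means the
embedding reproduces the planted geometry almost exactly, and `beta_est`
recovers the planted clustering parameter 2.5 within ~0.2.

Cohort analysis (`python analysis/04_core_composition.py`) on 9 synthetic
subjects — 3 per pattern:

```
 subject     intended   classified  core_size  k_max  frac_DMN  frac_VN
       0 DMN-dominant DMN-dominant         42     41       1.0     0.000
       3  VN-dominant  VN-dominant         70     69       0.0     1.000
       6  distributed  distributed        210     13       0.2     0.333
classification accuracy: 100%
common core at 60% share: 112 voxels
```

Dominant subjects' k_max-cores are exactly their planted dense module (DMN:
42 voxels at k_max = 41; VN: 70 at 69); distributed subjects keep all 210
voxels to a shallow k_max = 13, and no category exceeds the 40% dominance
rule. The 112 common-core voxels are the union of both dominant modules,
each present in 6/9 subjects' cores.

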