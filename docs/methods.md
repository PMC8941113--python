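# Methods

## Network construction

Functional connectivity is the sample Pearson correlation (unbiased
normalization, 1/(N−1)) between voxel BOLD series. Edges require ρ̂ > t
strictly, positive correlations only; negative correlations never form
edges. The working threshold is selected from a candidate grid (default
{0.30, 0.35, 0.40, 0.45, 0.50}, with 0.40 the reference operating point) as
the smallest candidate satisfying both admission criteria:

* **Scale-freeness.** "Straight line on a log–log plot" is operationalized
  as: log-binned degree PDF (bin ratio 2, empty bins dropped), ordinary
  least squares on the log–log points, pass iff R² ≥ 0.90 and slope < −1.
  The R² cutoff is a package decision — no numeric linearity criterion
  exists for the visual judgment it replaces — and is reported in every
  `ScaleFreeReport` so downstream users can audit it. Distributions
  producing fewer than 3 nonempty bins (e.g. regular graphs) are rejected
  as degenerate rather than scored; strongly humped distributions
  (Poisson/ER) score low R² and fail.
* **Inclusion.** The largest connected component must hold ≥ 80% of the
  voxels (the embedding substrate must cover most of the brain). Ties
  between equal components break toward the one containing the smallest
  voxel id.

When no candidate passes both, selection fails loudly with the per-candidate
audit trail (near-miss R², slope, LCC fraction) rather than silently
degrading.

## S1/H2 embedding

Model: node i has an angular (similarity) coordinate θ_i on a circle and a
radial (popularity) coordinate r_i on the hyperbolic plane of curvature −1
(the curvature parameter is fixed to 1; the model family is invariant to
rescaling it jointly with the radii). Pairs connect with the Fermi law
p_ij = 1/(1 + exp((β/2)(d_ij − R̂))), β > 1, where d_ij follows the
hyperbolic law of cosines. Numerically the law of cosines is evaluated as
cosh d = cosh(r₁−r₂) + 2 sinh r₁ sinh r₂ sin²(Δθ/2) — algebraically
identical, but immune to the catastrophic cancellation of the
cosh·cosh·(1 − tanh·tanh·cos) form at small separations.

The asymptotic form d ≈ r₁ + r₂ + 2 ln(Δθ/2) is provided with its validity
bound Δθ > √(e^(−2r₁) + e^(−2r₂)) enforced. Its Δθ/2 term stands in for
sin(Δθ/2), so the error grows with the angle: below Δθ ≈ 1 rad (r ≥ 5) the
relative error stays under 1%, but at Δθ = π it overshoots by exactly
2 ln(π/2) ≈ 0.90 (e.g. 4.5% at r₁ = r₂ = 10). The exact form is therefore
used everywhere accuracy matters; the asymptote exists for speed and
cross-checks.

Fitting pipeline (`embed`):

1. **β** by bisection on (1, 10]: for each candidate β, S1 graphs with the
   observed degree sequence as hidden degrees are sampled and their mean
   local clustering — computed over nodes of degree ≥ 2, since the triangle
   fraction of lower-degree nodes is undefined and counting them as zero
   ties the statistic to the sample's low-degree tail rather than to β —
   is matched to the observed value. Clustering is monotone in β, so
   bisection converges; bracket tolerance 0.01.
2. **Hidden degrees κ** by fixed point: under uniform angles the
   model-expected degree of node i is ≈ κ_i Σκ_j/Σκ (per-pair probabilities
   capped at 1); each κ_i is nudged multiplicatively (square-root damping)
   until expected degrees match observed degrees within 0.1 sup-norm
   (max 1000 iterations; non-convergence raises with the residual).
3. **Initial angles** from the two leading nontrivial eigenvectors of the
   normalized adjacency D^(−1/2) A D^(−1/2) (a Laplacian eigenmap). The raw
   atan2 projection preserves circular order well but compresses angular
   spans, which traps the subsequent coordinate ascent in poor local optima
   (measured recovery ~0.65 vs ~0.99 on S1 benchmarks); by default nodes
   are therefore redistributed uniformly around the circle in their
   eigenmap circular order. `equal_spacing=False` restores the raw
   projection.
4. **Likelihood ascent**: radii from κ via r_i = R̂ − 2 ln(κ_i/κ_0),
   κ_0 = min κ, R̂ = 2 ln(n/(π μ κ_0²)) with μ = β sin(π/β)/(2π⟨k⟩) — the
   standard S1↔H2 correspondence placing the strongest hub innermost and
   making R̂ the outermost radius. Angles are then refined by
   coordinate-wise sweeps: each node evaluates 20 candidate angles (its
   current angle, the κ-weighted circular mean of its neighbours, and
   jitters around that mean whose spread decays geometrically from π/2 per
   sweep, floored at 0.05 rad) against the full Bernoulli log-likelihood of
   its incident pairs, moving only on improvement — the total likelihood
   trace is non-decreasing by construction. Stops at sweep improvement
   < 1e-4 or 30 sweeps. The Fermi exponent is clamped to ±27.6
   (equivalently p ∈ [1e-12, 1−1e-12]) against saturation. The likelihood
   is dense over all pairs: O(n²) per sweep, intended for n ≤ ~6000.

Embeddings are identified only up to rotation and reflection of the disc.
`align_embeddings` maximizes the mean cosine of aligned angular differences
— analytically over rotations (the argument of the mean relative phasor)
and by enumeration over the two reflection states — and reports the
achieved similarity. Independent uniform angle sets score ≈ √(π/4n) ≈ 0.04
at n = 500, so similarities ≥ 0.8 are far outside the null.

## Angular coherence

ξ e^{iφ} = (1/N) Σ e^{iθ_k}: the mean resultant vector of the group's
angles. ξ is permutation- and rotation-invariant; labels with no embedded
member are reported absent rather than 0; multi-membership voxels count in
every label they carry. Cohort summaries report per-label mean, median, SD
and availability. The left/right comparison is a paired two-sided Wilcoxon
signed-rank across subjects (α = 0.05, no multiplicity correction, ≥ 6
pairs required; identical sides give p = 1 by convention) — the test choice
is a package decision and is stated in the output.

## k-core percolation

Coreness by the linear-time bucket algorithm (networkx `core_number`),
contract-verified in the tests against a brute-force repeated-deletion
oracle — coreness is independent of pruning order, so the two must agree
exactly. k_max is the largest k with a non-empty k-core (the (k_max+1)-core
is empty; component counts of the core are available for audit, since at
k_max the structure may also fragment). S(k) is reported for k = 1…k_max+1;
"abrupt decreases" — never quantified in the source analyses — are flagged
where a single step loses ≥ max(1, ⌈0.05·S(1)⌉) nodes by default, with the
absolute drop size exposed as a parameter.

## Core composition and dominance

The fifteen ICA subnetworks collapse to seven categories ({DMN, aDMN,
PCN}→DMN, {L/R CEN}→CEN, {SMN1,2}→SMN, {VN1–4, VAN}→VN, SN/DAN/AN
unchanged). A voxel in several constituents of one category counts once in
that category; a voxel in several categories counts once in each, so
category fractions may sum above 1. Dominance: VN- or DMN-dominant iff the
respective fraction of k_max-core voxels strictly exceeds 0.40; if both
exceed it the larger wins and an exact tie is distributed; otherwise
distributed. Anatomical schemes get composition profiles but no dominance
class. The common core takes voxels present in ≥ share·n_subjects cores
(inclusive threshold, default share 0.6, so 18 of 30 qualifies); common
cores are nested across thresholds by construction. Degree histograms of
core voxels read degrees off the full original graph, never the
core-induced subgraph.

## Synthetic data

The generators define the conditions under which the pipeline is validated:

* **S1 networks** (`sample_s1_network`): angles uniform; hidden degrees
  Pareto with exponent γ (κ_0 = ⟨k⟩(γ−2)/(γ−1) so the mean is ⟨k⟩); pairs
  connect with p = 1/(1+( RΔθ/(μκκ'))^β), R = n/2π. The closed-form density
  constant μ = β sin(π/β)/(2π⟨k⟩) is exact only in the thermodynamic limit
  — at n = 500 it leaves realized mean degree ~20% short (angular
  separations cap at π, probabilities at 1) — so μ is corrected by a scalar
  root find on the finite-sample expected mean degree. Benchmarks use
  n = 500, γ = 2.5, β = 2.5, ⟨k⟩ = 10: small enough to embed in seconds,
  heavy-tailed enough to exercise the radial map.
* **Block BOLD** (`simulate_bold`): zero-mean Gaussian series under an
  equicorrelation-block covariance (within_r inside a label block,
  between_r across, unit variance), PSD-verified before sampling via
  eigendecomposition.
* **Cohorts** (`make_cohort`): 210 voxels in fifteen equal label blocks,
  T = 1200 at TR = 0.72 s (both configurable). Distributed subjects put
  every block at within_r = 0.55; dominant subjects fuse their category's
  blocks into one module at 0.55 and suppress all other blocks to the
  midpoint (within_r+between_r)/2 = 0.325, below the 0.4 edge threshold, so
  after thresholding the dominant module is the unique dense structure. At
  T = 1200 the Pearson sampling SD is ≈ 0.027, making the 0.55/0.4/0.325
  separations ≥ 4.6 SDs — block edges essentially certain, suppressed edges
  essentially absent — which is what makes 9/9 classification the expected
  outcome rather than a coin flip. Thresholded cohort graphs fragment into
  modules by design, so the subject pipeline runs k-core percolation on the
  full thresholded graph; largest-component restriction applies to the
  embedding stages, which need a connected substrate.

What the generators deliberately omit: hemodynamic response shape, spatial
autocorrelation of fMRI noise, head motion, global signal, and any spatial
embedding of the blocks. Passing tests therefore demonstrate correctness of
the graph-theoretic and geometric machinery under the stated statistical
structure, not robustness to imaging artifacts.

## Problem sizes and determinism

Benchmarks run at n = 500 nodes (embedding), 210 voxels × 1200 timepoints
(cohorts), 200 random graphs of n ≤ 50 (oracle checks) and n = 1000
(planted cores) — sizes chosen so the full validation runs in minutes on a
single CPU while keeping each effect far from its detection floor. Every
stochastic component is a pure function of an explicit integer seed;
repeated calls with one seed are bit-identical.

## Known limitations

* The embedding refines angles only; radii stay at their hidden-degree map.
  Full joint (r, θ) likelihood maximization à la Mercator is out of scope.
* β and the clustering statistic are matched through sampled model graphs,
  so the estimate carries Monte-Carlo noise of a few percent.
* The dense-likelihood embedding is O(n²) per sweep; voxel counts beyond
  ~6000 need a different engine.
* Dominance classification is defined for the functional-7 scheme only.
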