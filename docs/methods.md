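# Methods

## Overview

`softparc` implements soft parcellation of resting-state functional
connectivity by fuzzy c-means (FCM) clustering of voxelwise correlation
profiles, together with the surrounding pipeline: temporal cleaning of
BOLD time series, motion-spike censoring, validity-based selection of the
number of clusters, comparison of parcellations across cluster counts,
and voxelwise classification uncertainty. Because no suitable public
dataset accompanies the problem, the package ships a synthetic-data
generator with planted hierarchical network structure; all quantitative
claims in the test suite and the acceptance script are made on that
generator's output.

## Preprocessing model

The input is a masked voxel-by-frame matrix on the mode-1000 intensity
scale (whole-brain mode normalized to 1000). The temporal pipeline is
fixed in this order:

1. **Detrending** — per voxel and per acquisition run, the least-squares
   line (intercept + slope) is removed.
2. **Low-pass filtering** — zero-phase (forward–backward) 2nd-order
   Butterworth with a 0.1 Hz cutoff. Zero-phase filtering is chosen
   because any phase lag would distort voxel-pair correlations; the
   effective magnitude response is the squared Butterworth magnitude and
   DC gain is exactly 1.
3. **Nuisance regression** — voxelwise OLS residual against an intercept,
   motion parameters and their backward-difference temporal derivatives,
   and the global (mask-mean) signal. The global signal enters without a
   derivative.
4. **DVARS censoring** — DVARS(t) is the RMS across voxels of the
   backward frame difference, divided by 10 so it reads as percent of the
   mode-1000 signal; the first frame of each run is defined as 0. Frames
   with DVARS strictly greater than 0.5% are censored, so a single spike
   removes both frames of each super-threshold transition. DVARS is
   computed once, before any censoring.
5. **Correlation features** — Pearson correlation between every voxel
   pair over kept frames. Row k of the resulting n×n matrix is voxel k's
   feature vector. Per-subject maps may be averaged entrywise before
   clustering. No Fisher z-transform is applied at any point: maps are
   averaged and clustered on the r scale.

Spatial smoothing of real volumes is a pass-through concern of the
caller; the synthetic path does not model it.

## Fuzzy c-means

Memberships and centroids follow the standard alternating updates

    u_ik = [ Σ_j ( ||X_k − V_i|| / ||X_k − V_j|| )^(2/(M−1)) ]^(−1)
    V_i  = Σ_k u_ik^M X_k / Σ_k u_ik^M

with Euclidean distance in correlation-profile space and fuzzifier
M = 1.2 by default — crisp enough to give essentially hard cores while
leaving graded membership at network boundaries. A voxel coincident with
a centroid receives full membership in the first such cluster (the
standard resolution of the zero-distance singularity; a measure-zero
event). Distances are normalized by the per-voxel minimum before
exponentiation so the d^(−2/(M−1)) powers stay in floating-point range
even at small M.

Convergence is monitored with the Xie–Beni index
XB = Σ u^M d² / (n · min separation²); iteration stops when XB changes by
less than 1e−4 over five consecutive iterations, with a hard cap of 1000
iterations (the cap is a safety net; typical runs converge in 10–100).
The FCM objective J_M is tracked alongside and is non-increasing across
iterations, which the tests assert.

All feature and membership arithmetic is double precision; at the
problem sizes this package targets (up to a few thousand voxels) memory
is not a constraint and several unit contracts are asserted at 1e−12.

### Initialization

Two schemes are provided.

**Seeded.** One centroid per named ROI: the mean feature row over in-mask
voxels within a 5 mm (default) sphere around a stereotaxic coordinate.
A seven-network seed table (precuneus/DMN, right DLPFC/FPC, left
STG/LAN, right MFG/VAN, left parietal operculum/SMN, superior
occipital/VIS, right FEF/DAN) ships with the package.

**Random cubes with subsample refinement (default).** Candidate
centroids are averages of feature rows within a 3-voxel cube centered on
a uniformly drawn in-mask voxel. Drawing exactly c such cubes
independently is unusable in practice: on data with K well-separated
networks the probability that c = K draws cover all networks is K!/K^K
(≈ 0.6% at K = 7), and with a crisp fuzzifier the membership updates
cannot migrate a duplicated centroid out of a covered network, so most
runs end in split/merge local optima. Instrumentation on planted data
showed that initial coverage fully determines run quality. The default
therefore draws a pool of candidate cubes (max(100, 10c)), groups the
pool into c clusters (k-means, two starts), and uses each group's medoid
cube as the starting centroid — a subsample-refinement in the spirit of
Bradley & Fayyad's refined initial points. Every starting centroid is
still an actual random-cube average; run-to-run variability comes from
the pool draw. The literal one-cube-per-centroid scheme remains
available as `refine="none"`.

### Consensus over runs

Results with random initialization are reported as the average of 20
runs. Runs that fail to converge are excluded and counted. Clusters of
each run are aligned to the lowest-objective run by optimal one-to-one
assignment (Hungarian algorithm) on the cosine similarity of membership
vectors; aligned membership matrices are averaged entrywise (column sums
remain exactly 1) and the centroids are recomputed from the averaged
memberships. Averaging without alignment would be meaningless; aligning
to the best-fitting run rather than an arbitrary one prevents a deviant
first run from diffusing the whole average.

## Model selection

The cluster dispersion measure

    CD = Σ_i Σ_k u_ik^M ||X_k − V_i||² / Σ_k ||X_k − x̄||²

compares fuzzy within-cluster scatter to total scatter about the grand
mean; CD(c=1) = 1 by construction and CD is invariant to global feature
scaling. The sweep clusters every c in a range (default 2–20, consensus
per c) and reports interior strict local minima of the curve; ties and
endpoints are never reported, and when several minima exist all are
reported rather than adjudicated.

At the global optimum the FCM objective — and hence CD — is
non-increasing in c, so interior minima necessarily reflect the behavior
of the *procedure* (consensus averaging of runs that disagree), not of
the objective itself. On planted data this is exactly what produces
them: at the planted count the runs agree and the consensus is as tight
as any single run, while past it different runs split different
networks, the aligned average becomes diffuse, and CD ticks upward.

## Similarity and matching

Spatial similarity between two membership vectors and temporal
similarity between two centroid vectors are both normalized inner
products (cosine), so self-similarity is 1 and both are symmetric and
invariant to positive rescaling. Membership vectors are nonnegative, so
raw spatial similarity cannot be negative; a "centered" mode removes
each vector's mean first and is used where anti-association matters
(system-association analyses, uncertainty association). Raw mode is
used for matching and stability. Every similarity artifact records the
mode and centering used.

"Temporal" similarity operates on centroids in the clustering feature
space (correlation profiles). When clustering was performed on
correlation maps, centroid time courses are not recoverable, but the
cosine of two correlation-profile centroids carries the same sign
structure: anticorrelated systems give values near −1.

Across solutions with equal cluster counts, identities are carried by
optimal one-to-one assignment; with unequal counts, each cluster of the
finer solution inherits the label of its most similar reference cluster,
and clusters sharing a reference get numeric suffixes in order of
decreasing similarity (FPC → FPC1, FPC2).

## Classification uncertainty

CU_k = (Π_i u_ik)^(1/c), computed as exp of the mean log with a
zero-weight short-circuit to 0. By AM–GM, CU ≤ 1/c with equality exactly
at uniform membership. The CU map is associated with each cluster's
membership map by centered spatial similarity; a constant CU map is
defined to score 0 (it has no spatial structure), a reachable degenerate
case on toy inputs.

With M = 1.2 and c = 7 the product of seven weights is dominated by the
five near-zero memberships of any voxel, so CU values on well-separated
data are small everywhere (order 1e−3) and the boundary–core contrast,
while strictly positive, is small. The uncertainty-localization
experiment therefore measures CU where the planted boundary actually
lives: strongly shared fuzzy voxels (primary weight U(0.5, 0.7))
bridging the two systems, scored on the two-cluster solution, where the
boundary–core gap is large (≈ 0.2).

## Synthetic data generator

A linear factor model with closed-form covariance:

    x_v(t) = Σ_i w_vi s_i(t) + σ ε_v(t),
    s_i(t) = λ_w η_i(t) + λ_s sgn_i g(t)

with iid standard normal g (system signal), η_i (network signals), ε_v
(voxel noise); sgn_i = +1 for task-positive and −1 for task-negative
networks; per-voxel weights w_v summing to 1. Voxels are offset to a
temporal mean of exactly 1000. The implied correlation matrix is exact
and exposed (`analytic_correlation`) for use as a test oracle. Networks
occupy contiguous blocks on a 5×5-cross-section grid stacked along z, so
cube initialization is meaningful.

Defaults (the study conditions for all planted-structure experiments):
7 networks × 100 voxels, the first 3 task-negative and the rest
task-positive (mirroring the 3/4 split of canonical parcellations);
λ_w = 1.0, λ_s = 0.5, σ = 1.15; 300 frames at TR 2.16 s; 10% fuzzy
voxels whose primary weight is drawn U(0.7, 0.9) with the complement on
a partner network. These values were calibrated so the generated data
exhibit the qualitative structure real group-averaged connectivity
shows: within-network correlation ≈ 0.5, clearly anticorrelated systems
(two-cluster centroid cosine ≈ −0.6 to −0.8), recoverable networks
(best-match accuracy ≥ 0.99), and reproducible random-init runs
(matched similarity ≥ 0.9 in ≥ 95% of runs).

Partner assignment defaults to "balanced": each network's fuzzy voxels
cycle round-robin over all other networks, so every network carries an
identical shared-membership load and no network is systematically wider
than another — the distributed (not merely spatially adjacent) character
of real shared-membership territory. "random", "adjacent",
"within-system" and "between-system" pairings are available; the
uncertainty-localization experiment uses "between-system".

What the generator does **not** emulate: hemodynamic response dynamics,
1/f noise spectra, physiological confounds, spatial smoothness beyond
block structure, susceptibility artifacts, and between-subject
variability. Passing tests therefore demonstrate correctness of the
algorithms and the recoverability of planted hierarchical structure
under realistic correlation levels — not performance on real fMRI data.

## Experiment sizes

The acceptance experiments use: 700 voxels × 300 frames for recovery,
hierarchy, stability, and uncertainty; 4 networks × 60 voxels × 250
frames plus the 7×100 default for the model-selection sweep (c = 2–10,
20 runs per c, 10 dataset seeds); 200 voxels × 200 frames for the
hard-k-means limit. These sizes keep every experiment comfortably
reproducible on a single CPU while preserving the qualitative regime of
the full-scale problem (the original analyses used ~18,600 voxels).

## Known limitations

- Consensus averaging assumes runs are mostly alignable; on data without
  clear cluster structure the averaged memberships can be diffuse, and
  cluster dispersion then reflects procedure variance as much as fit.
- Local minima of the dispersion curve are a property of consensus
  variability (see above); on data where every c yields consistent runs
  the curve is monotone and no interior minimum exists.
- The DVARS formula is the standard RMS-of-differences definition; other
  conventions (median-based, standardized DVARS) are not implemented.
- Seeded initialization requires the volume affine to map voxel indices
  to the same stereotaxic space as the ROI table; no registration is
  performed.
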