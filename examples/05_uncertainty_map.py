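"""Voxelwise classification uncertainty and its localization.

Plants voxels genuinely shared between the two anticorrelated systems,
computes the geometric-mean uncertainty of the two-cluster solution, and
shows that uncertainty concentrates on the planted boundary.
"""

import softparc as sp

spec = sp.HierarchySpec(
    fuzzy_partner="between-system",
    fuzzy_primary_range=(0.5, 0.7),  # strongly shared boundary voxels
    seed=4,
)
ts, truth = sp.simulate_bold(spec)
features = sp.correlation_map(ts)
sol = sp.consensus_runs(features, 2, n_runs=10, rng_seed=6)
sol.labels = ["TN", "TP"]

cu = sp.classification_uncertainty(sol.membership)
boundary = cu.cu[truth.boundary_mask].mean()
core = cu.cu[~truth.boundary_mask].mean()
print(f"mean uncertainty: boundary voxels {boundary:.3f}, core voxels {core:.3f} "
      f"(theoretical maximum 1/c = {1 / sol.c:.3f})")

assoc = sp.uncertainty_cluster_association(cu, sol)
print("association of the uncertainty map with each cluster:")
print(assoc.round(3).to_string())
# Boundary voxels carry an order of magnitude more uncertainty than
# committed ones. The centered association with the two system clusters is
# near zero on both sides: the shared territory sits between the systems
# and favors neither — exactly what a soft boundary should look like.
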