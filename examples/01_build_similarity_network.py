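"""Build one subject's morphological similarity network.

Generates a small synthetic subject (12 cortical regions, cortical
thickness), estimates each region's vertex-value distribution on a
28-point grid, links region pairs by 1 - Jensen-Shannon divergence, and
thresholds the matrix over the sparsity range with a spanning-tree
backbone.
"""

import numpy as np

import morphnet as mn

design = mn.CohortDesign(groups=(("HA", 2), ("HC", 2)), n_roi=12,
                         vertices_per_roi=(80, 150), features=("CT",), seed=1)
subject = mn.generate_cohort(design)[0]

dens = mn.estimate_density(subject.maps["CT"].roi_values(1), grid_size=28)
print(f"ROI 1 density: {dens.mass.size} grid points, mass sums to "
      f"{dens.mass.sum():.12f}")

S = mn.subject_similarity(subject, "CT")
off = S.weights[~np.eye(12, dtype=bool)]
print(f"similarity matrix: {S.weights.shape}, edge weights in "
      f"[{off.min():.3f}, {off.max():.3f}]  (1 = identical distributions)")

ens = mn.subject_ensemble(subject, "CT")
print(f"thresholded at {ens.sparsities.size} sparsity levels "
      f"({ens.sparsities[0]:.2f}..{ens.sparsities[-1]:.2f})")
for s, A in list(zip(ens.sparsities, ens.adjacencies))[::9]:
    print(f"  sparsity {s:.2f}: {int(A.sum()) // 2} edges (connected, "
          f"spanning tree always included)")
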