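"""Meta-analytic contrast and conjunction between two experiment sets.

Set A converges on a left-hemisphere location, set B on a right-hemisphere
location; both share a midline site.  The permutation contrast finds the
set-specific convergence, and the conjunction of the two thresholded maps
finds the shared site.
"""

import numpy as np

from alenet import (FociGenConfig, cluster_fwe, conjunction,
                    contrast_permutation, gen_foci_corpus, mni_like_grid)

grid = mni_like_grid(shape=(30, 36, 30), voxel_mm=2.0)


def corpus(centers, seed):
    return gen_foci_corpus(FociGenConfig(
        mask=grid, n_experiments=12, cluster_centers=centers,
        foci_per_cluster_per_experiment=2, noise_foci_per_experiment=1,
        jitter_sd_mm=4.0, seed=seed))


set_a = corpus(((-14.0, 0.0, 0.0), (0.0, 14.0, 0.0)), seed=1)
set_b = corpus(((14.0, 0.0, 0.0), (0.0, 14.0, 0.0)), seed=2)

res = contrast_permutation(set_a, set_b, grid, n_perm=2000, p=0.05,
                           min_extent=5, seed=7)
print("contrast A > B clusters:")
print(res.clusters_a_gt_b.to_string(index=False))
print("\ncontrast B > A clusters:")
print(res.clusters_b_gt_a.to_string(index=False))

# conjunction of the cluster-FWE-thresholded single-set results
_, lab_a, *_ = cluster_fwe(set_a, grid, n_iter=200, seed=11)
_, lab_b, *_ = cluster_fwe(set_b, grid, n_iter=200, seed=12)
conj = conjunction(lab_a, lab_b, min_extent=5)
print("\nconjunction clusters (significant in both analyses):")
print(conj.clusters[["label", "extent"]].to_string(index=False))
for lab in conj.clusters["label"]:
    vox = np.argwhere(conj.label_map.data == lab)
    centroid = grid.vox_to_mm(vox).mean(axis=0)
    print(f"  cluster {int(lab)} centroid (mm): {np.round(centroid, 1)}")
print("\nThe contrast isolates each set's lateralized site (a cluster peak "
      "at x ~ -14 for A>B and ~ +14 for B>A); the conjunction's centroid "
      "should sit near the shared site at (0, 14, 0).")
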