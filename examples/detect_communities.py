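"""Community detection and node roles on synthetic resting-state BOLD.

Generates 4D BOLD for 10 subjects whose 21 node spheres carry a planted
4-community covariance, extracts sphere-averaged time series, builds the
group Fisher-z FC matrix, runs consensus Louvain (200 repetitions), and
reports the recovered communities, each node's participation coefficient P
and within-module degree z-score, and the leading connectivity gradients.
"""

import numpy as np

from alenet import (BoldGenConfig, consensus_communities, fc_matrix, gen_bold,
                    gradient_decomposition, lattice_nodes,
                    participation_coefficient, sphere_timeseries,
                    within_module_zscore)
from alenet.calibration import planted_partition

nodes, grid = lattice_nodes(21, spacing_mm=12.0)
plant = planted_partition(21, 4)
cfg = BoldGenConfig(nodes=nodes, grid=grid, partition=tuple(plant),
                    within_r=0.5, between_r=0.05, n_timepoints=500,
                    n_subjects=10, seed=3)
ds = gen_bold(cfg)

ts = [sphere_timeseries(ds.subject(s)[0], grid, nodes, radius_mm=5.0)
      for s in range(cfg.n_subjects)]
fc = fc_matrix(ts)

part, agreement, freq = consensus_communities(fc, n_reps=200, seed=9)
print(f"planted communities:   {plant.tolist()}")
print(f"recovered communities: {part.labels.tolist()}")
print(f"modularity Q = {part.q:.3f}; modal solution frequency = {freq:.2f}")

P = participation_coefficient(fc, part.labels)
z = within_module_zscore(fc, part.labels)
print("\nnode roles (P: cross-community integration, z: within-community hub):")
for i in range(len(nodes)):
    print(f"  node {i:2d}  community {part.labels[i]}  P = {P[i]:.3f}  z = {z[i]:+.2f}")

grads = gradient_decomposition(np.corrcoef(fc), retain_fraction=0.2, k=3)
print("\ngradient explained-variance fractions:",
      np.round(grads.explained_variance, 3))
print("High modal frequency and a label-permutation match between planted "
      "and recovered communities show the planted block structure is "
      "recovered; the first gradients should align with the communities.")
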