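# Methods

This note documents the models, defaults, numerical choices, and open design
decisions behind `alenet`, and what the synthetic validation studies do and
do not establish.

## Grid and coordinate conventions

All volumetric work happens on a `VolumeGrid`: a voxel lattice with a
voxel→world affine (world coordinates in MNI-style mm) and a boolean
analysis mask. Defaults are 2 mm isotropic RAS grids with the world origin
at the grid centre. Voxel indices are 0-based; every distance (kernel
widths, sphere radii, peak spacing, pairwise node distances) is computed in
mm through the affine, so anisotropic grids are handled correctly.

## ALE

**Kernel.** A focus from an experiment with *n* subjects is modelled as an
isotropic 3D Gaussian with per-axis sd σ(n) = √(σ²_template + σ²_subject/n).
The defaults σ_template = 5.7/(2√(2/π)) ≈ 3.57 mm and σ_subject =
11.6/(2√(2/π)) ≈ 7.27 mm convert the empirical between-template and
between-subject Euclidean displacement calibrations (5.7 mm and 11.6 mm)
into Gaussian widths; both are exposed on `KernelSpec` because different
literatures may warrant different calibrations. Kernels are evaluated
discretely on the voxel lattice, spherically truncated at 4σ (configurable),
normalized to unit total mass per focus, and placed at the focus's nearest
voxel centre. Within an experiment, foci combine by voxel-wise maximum, so
several nearby foci reported by one experiment cannot inflate convergence —
the non-additive combination rule.

**Analytic null.** The null of ALE under independent random voxel
association is computed exactly (up to binning) by histogramming each
experiment's MA values over masked voxels (zeros included) and combining the
histograms sequentially under s = 1 − (1−a)(1−b), re-binning probability
mass at width 10⁻⁵. The bin width trades accuracy against the cost of the
pairwise-mass convolution; at 10⁻⁵ the survival function agrees with a
10⁶-draw Monte-Carlo voxel-pairing oracle to < 10⁻³ in the validation study
(tolerance asserted: 5×10⁻³).

**Voxel threshold and cFWE.** Voxels are retained when their null survival
probability is < p_voxel (default .001); the voxel p map and its
inverse-normal z map are returned for downstream peak extraction. The
degenerate setting p_voxel = 1 retains every masked voxel. Cluster-level
family-wise error control simulates `n_iter` (default 1,000; the validation
studies use 200) ALE analyses with every experiment's foci redrawn uniformly
over masked voxel centres — same foci counts, same sample sizes — applying
the observed analysis's ALE cutoff and recording the maximum
connected-component size (26-connectivity by default, 6/18 available).
Observed clusters survive if their extent exceeds the (1−p_cluster) quantile
of that null; reported cluster p values use the add-one estimator.

**Calibration study design.** The analytic null assumes each voxel sees the
same marginal MA distribution. Near a mask boundary this is not true —
boundary voxels have less kernel-covered neighbourhood, so the pooled
histogram mixes heterogeneous marginals and a voxel-wise calibration check
against it would confound boundary geometry with miscalibration. The
voxel-threshold calibration study therefore draws foci uniformly over the
analysis box padded by the kernel truncation radius, which makes every
analysis voxel geometrically equivalent; foci outside the mask are
explicitly legal inputs (they are retained with a warning in ordinary
analyses). Under this design the passing fraction at p < .001 is asserted to
be 0.001 ± 3 Monte-Carlo SEs over 200 replicate corpora of 20 experiments.
The cFWE simulation itself redraws foci strictly within the mask, as in
ordinary use.

## Foci tables and pooling

The TSV dialect has one focus per row (`study_id, experiment_id, contrast,
n, x, y, z, pooling_group`). Rows sharing an `experiment_id` are one
experiment's foci; experiments sharing a non-empty `pooling_group`
(overlapping samples) are merged into a single experiment whose foci are
concatenated and whose sample size is the **minimum** of the merged
experiments — the conservative choice for partially overlapping samples.
Malformed values are reported with their line number; node tables are
rejected by schema.

## Contrasts, conjunctions, subsampling

The contrast statistic is voxel-wise ALE_A − ALE_B with a label-permutation
null (pool, redraw groups at original sizes). p values use the add-one
estimator (b+1)/(n+1), avoiding zero p; voxels pass at p < .05 with a ≥
5-voxel cluster-extent threshold. Evaluation is restricted to a caller-
supplied mask; standard practice passes the union of the two cFWE-
significant masks, and the calibration study passes the kernel-coverage mask
(voxels never touched by any kernel have an all-zero permutation
distribution and p = 1 by construction, which would only dilute a
false-positive-rate estimate). Under same-generator inputs the voxel-wise
false-positive rate is asserted at 0.05 ± 3 SE across replicate dataset
pairs.

The subsampling balancer draws `n_subsamples` (default 25) size-matched
random subsets of the larger set, reruns the contrast per subset, and keeps
voxels significant in ≥ `agreement_fraction` (default 0.5) of subsamples.
These two defaults are this package's own reconstruction of a balancing
procedure whose published description is not fully specified; they are fully
configurable and the agreement rule is monotone (raising the fraction can
only shrink the result).

## Peaks and nodes

Peaks are local maxima (≥ all 26 neighbours) of a thresholded z map,
restricted to grey matter, selected greedily in descending z with a 15 mm
minimum spacing. Plateau ties resolve to the lexicographically first voxel;
cross-map merging keeps the higher-z peak, with z ties resolved by map order
then lexicographic coordinates — all deterministic and documented. The
packaged 21-node impulsivity-network table (regions, hemispheres, MNI
coordinates) ships as reference data; its minimum inter-node distance is
15.36 mm, consistent with the 15 mm extraction rule (the closest pair being
the bilateral ventral striatum at √332 ≈ 18.2 mm is a useful check that the
rule keeps genuine bilateral homologues separate).

## Connectivity

Mean framewise displacement (Power convention: summed absolute frame
differences of six rigid-body parameters, rotations mapped to arc length on
a 50 mm sphere) gates subject inclusion with an inclusive ≤ threshold
(0.5 mm for the discovery regime, 0.2 mm for the stricter replication
regime). Denoising follows the order: confound regression (WM/CSF/global
with intercept; collinear columns dropped with a warning), linear
detrending, zero-phase Butterworth order-2 bandpass at 0.01–0.1 Hz, then
spatial Gaussian smoothing at FWHM 5 mm. Long reflect padding is used in the
zero-phase filtering because the 0.01 Hz edge has a slow impulse response;
out-of-band attenuation is verified spectrally (a 0.2 Hz component passes at
< 5% amplitude), while finite-window edge transients remain a known property
of any causal-filter pair applied forward-backward. Node series average
grey-matter voxels whose centres lie within a 5 mm **radius** of the node;
FC is Pearson → Fisher z (|r| clipped at 1−10⁻⁷ before atanh) → element-wise
mean over subjects, with the diagonal set to 0 by convention. Seed-to-voxel
maps are per-subject Fisher-z correlation maps over grey matter, averaged
across subjects.

## Communities, node roles, gradients

Community detection maximizes signed modularity Q\* = Q⁺ − s⁻/(s⁺+s⁻)·Q⁻
(the asymmetric negative-weight extension: negative weights penalize
within-community placement, scaled by their share of total strength), which
reduces to Newman–Girvan Q on non-negative matrices. The Louvain
implementation does greedy local moves plus hierarchical aggregation, then
fine-tunes by re-running with the current partition as initialization until
Q stops increasing (tolerance 10⁻¹⁰). Resolution γ = 1. Fisher-z FC can be
negative, hence the signed default; a positive-only mode exists. Consensus
repeats the fine-tuned run (default 1,000×), accumulates the agreement
matrix (fraction of runs pairing two nodes), and reports the **modal**
label-invariant partition with its frequency — the modal rule is this
package's choice where an explicit consensus algorithm was not specified; on
21-node matrices with clear structure the modal frequency is ~1.0, making
the choice immaterial. Participation coefficients use positive weights by
default; isolated nodes get P = 0 with a warning. Within-module degree
z-scores set z = 0 when a module's strength sd is 0 (including singletons).

Gradient decomposition row-sparsifies the node-similarity matrix (retain the
top 20% of each row's similarities by default; 30/40% used for robustness
checks), then either takes principal components (SVD of the column-centred
sparsified matrix; explained-variance fractions from the squared singular
values) or a diffusion-map embedding: symmetrize and clip the sparsified
affinity, normalize anisotropically with α (default 0.05), form the
row-stochastic operator via its symmetric conjugate, and embed by the
leading non-trivial eigenvectors scaled by their eigenvalues. Components are
sign-aligned so the first node's loading is non-negative. At strong sparsity
the diffusion affinity can disconnect, duplicating unit eigenvalues — PCA is
the primary method; diffusion embedding is provided for robustness
comparisons.

## Annotation/receptor association

Maps are resampled to the analysis grid by trilinear interpolation
(nearest-neighbour available for label maps; non-overlapping fields of view
are an error), rescaled linearly to min 0 / max 100 over the mask
(idempotent; constant maps are an error), and sampled as mean density within
5 mm **diameter** (radius 2.5 mm) spheres around each node. The two sphere
sizes in the package — radius 5 mm for time series, radius 2.5 mm here —
mirror the two conventions in circulation for "5-mm sphere"; both are
configurable and the inconsistency is deliberate and flagged.

The screen requires |Spearman ρ| > 0.3 with matching sign in both a
discovery and a replication dataset. Survivors are tested against a
spatial null: node sets of the empirical size rejection-sampled from
grey-matter voxel centres, accepted iff their minimum, mean and maximum
pairwise distances each lie within one standard deviation of the empirical
network's corresponding value. "One standard deviation" is interpreted as
the sd of the empirical network's own pairwise-distance distribution — the
natural scale available from the empirical network; an explicit mm band is
accepted as an alternative. Sampling granularity is voxel centres. If the
acceptance rate collapses the sampler aborts and reports which constraint
binds.

`null_test` defaults to the literal one-sided rule: the association is
significant iff the empirical ρ exceeds the 95th percentile of the null
correlations (p is the add-one fraction of null ρ ≥ empirical). A
sign-directed one-sided test would double the null rejection rate to ~10%
and break the 5% calibration this package asserts, so 'greater' is the
default and 'less'/'two-sided' are explicit options.

## Synthetic data: what it emulates, what it does not

*Foci corpora*: experiments hit each planted cluster independently with a
configurable probability, contributing foci jittered isotropically (sd 5 mm
default — the scale of ALE spatial uncertainty) plus uniform noise foci;
sample sizes are uniform on a configurable interval (default 15–30,
typical of task-fMRI group studies). *BOLD*: node signals follow an exact
block covariance (within_r/between_r; the generator factorizes arbitrary
admissible covariances and rejects non-PSD ones), voxels in a node's sphere
share the node signal plus white noise (sd 1.0 — sphere averaging over ~81
voxels then attenuates target correlations by < 2%, inside the ±0.05
recovery tolerance), and motion traces are i.i.d. half-normal FD values.
*Annotation maps*: node-sphere values are drawn from a Gaussian copula
against the metric's normal scores (Pearson 2·sin(πρ_s/6) for target
Spearman ρ_s), embedded in a unit-variance background noise field, smoothed
to a requested FWHM; the generator redraws until the realized sphere-mean
Spearman ρ is within ±0.15 of the target.

None of the generators model haemodynamics, spatial autocorrelation of real
BOLD, scanner drift/physiological noise structure, or the anatomical
inhomogeneity of real grey matter. Passing validation therefore establishes
the *statistical machinery* — calibration of nulls, recovery of planted
structure, correctness of the combinatorial rules — not robustness to the
artefact structure of real data.

## Validation problem sizes

The studies in `alenet.calibration` (run by both the acceptance tests and
`scripts/acceptance.py`) use: a 30×36×30 toy grid with 5 experiments and
10⁶ Monte-Carlo draws for the analytic-null check; 200 replicate corpora of
20 experiments for voxel-threshold calibration; a 40×48×40 grid, 200 cFWE
iterations, and 20 plant-free seeds for cluster recovery; 8 replicate pairs
of 15+15 experiments with 500 permutations for contrast calibration; one
planted 4-community dataset (21 nodes, 20 subjects, 2,000 timepoints,
within_r = 0.5, between_r = 0.05) with 20 detection seeds × 100 consensus
repetitions for community recovery; and 100 zero-coupling simulations (199
null networks each), 20 planted-coupling seeds (499 null networks each), and
one 1,000-network ensemble for the receptor null. These sizes keep each
study's Monte-Carlo error comfortably below the asserted tolerances while
the full suite remains desk-runnable.

## Known limitations

- Foci snap to voxel centres for kernel placement; sub-voxel kernel
  placement would change MA values by less than the binning error of the
  null but is not implemented.
- The analytic-null convolution cost grows with the product of occupied
  bins; very large corpora (hundreds of experiments) would benefit from FFT
  convolution, not needed at validation scale.
- The balanced-contrast aggregation reports agreement fractions, not
  combined p values; its `p_map` fields hold 1 − agreement as a ranking
  surface, not calibrated probabilities.
- Community detection on matrices with many near-degenerate optima can
  return different modal partitions under different seeds; the agreement
  matrix and modal frequency are the diagnostic.
- The diffusion-map embedding drops a single trivial eigenvector; on
  disconnected sparsified affinities additional unit eigenvalues are kept,
  matching the behaviour of standard embedding toolboxes.
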