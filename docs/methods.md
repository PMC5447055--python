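# Methods

## Overview

`cbparc` implements connectivity-based parcellation of a seed region from
probabilistic-tractography count profiles.  The processing chain is:
per-voxel profile conditioning → native connectivity matrix →
cross-correlation matrix → normalized-cut spectral clustering per subject
and per k → group-consistent relabeling → probabilistic and maximum
probability maps → validity indices → suggested number of subregions.
Registration and tractography themselves are out of scope: the package
ingests count matrices already resampled to one common voxel grid (the
grid of the seed-mask image), or simulates them.

## Profile conditioning

Each seed voxel's profile holds the number of sampled streamlines
(default `n_samples` = 5,000) visiting each target voxel.  Three steps are
applied, in this fixed order:

1. **Threshold** — entries with visitation probability
   count/`n_samples` ≤ `threshold_p` (default 0.0004, i.e. 0.04%, which
   removes counts of 2 or fewer out of 5,000) are zeroed.  The inequality
   is strict: a count of 3 survives.  Thresholding is applied to *raw*
   counts, before distance correction, because the cutoff is defined in
   raw samples; applying it after rescaling would make "2 of 5,000"
   meaningless.  This ordering is a deliberate design choice of this
   package.
2. **Distance correction** — each retained entry is multiplied by the
   Euclidean distance (mm) between seed- and target-voxel centers,
   compensating the distance-dependent decay of streamline visitation.
   Without streamline geometry the straight-line distance stands in for
   pathway length; the seed's own voxel (distance 0) is zeroed, which
   also removes the trivially dominant self-count.
3. **Downsampling** — the target grid is partitioned into axis-aligned
   blocks of `block_mm` (default 5 mm) and entries are *summed* within
   blocks.  Summation (not averaging) conserves total corrected mass
   exactly.  `block_mm` must be an integer multiple of the voxel size;
   trailing partial blocks are kept.

The cross-correlation matrix is the Pearson correlation between all pairs
of native-matrix rows.  Zero-variance rows (a seed voxel with no
surviving connections) get correlation 0 with every other row and 1 with
themselves, keeping the matrix well-defined.

## Spectral clustering

The Ng–Jordan–Weiss symmetric variant is used, matching the normalized-cut
objective:

* affinity `W = max(C, 0)` with zero diagonal — negative correlations are
  clipped, not shifted, so anti-correlated profiles keep zero affinity;
* `L = D^(-1/2) W D^(-1/2)` with zero degrees replaced by 1e-12;
* top-k eigenvectors, rows normalized to unit length (all-zero rows kept);
* k-means with k-means++ initialization, `n_restarts` = 100 and a fixed
  seed.  An empty-cluster outcome triggers a restart with a derived seed
  (at most 10 attempts) before erroring; in practice scikit-learn's
  k-means never returns empty clusters.

Labels are canonicalized to 1..k by decreasing cluster size, ties broken
by the smallest contained voxel index.  This makes runs reproducible
across platforms: eigen-solver sign flips reflect the embedding, which
preserves all pairwise distances and therefore the partition.  No spatial
constraint is applied — spatial coherence is measured afterwards (by the
continuity index), not imposed.

## Group labeling

The group similarity matrix entry (i, j) is the fraction of subjects in
which voxels i and j share a label, thresholded at `group_threshold`
(default 0.5, a majority criterion).  Same-label co-occurrence was chosen
as the concrete definition of "connectional similarity" at the group
level; it is bounded, symmetric and directly reflects the agreement the
relabeling step needs.  Clustering this matrix (diagonal zeroed) yields
the group scheme; each subject's labels are then permuted by the
assignment that maximizes total cluster overlap with the scheme
(Hungarian algorithm on the k×k overlap-count matrix).  Among equally
optimal assignments the lexicographically smallest mapping is chosen, so
relabeling is deterministic.  Relabeling never changes a partition, only
its label names.

For bilateral analyses the right hemisphere is mirrored by flipping the
first voxel axis about the grid midplane (the common template is assumed
mid-sagittally symmetric) and matched to the left parcellation the same
way before any group pooling; non-overlapping mirrored supports fall back
to the identity permutation with a warning.

## Probability maps and MPM

Probabilistic maps divide by the *total* number of subjects, not the
number covering a voxel, so values reflect both disagreement and partial
coverage.  The MPM takes the per-voxel argmax; voxels with all-zero
probability stay background, and no minimum-probability floor is applied.
Exact ties are resolved by the average probability of each tied cluster
over the 26 adjacent voxels; the average always divides by 26, with
out-of-volume neighbors contributing 0 (a boundary penalty accepted for
simplicity and determinism).  Residual ties go to the smallest label;
tie-broken voxels are recorded.  Noise correction then flips any labeled
voxel that disagrees with the strict majority of its labeled 6-neighbors,
sweeping until convergence or 10 sweeps (a 3D checkerboard oscillates
forever, hence the cap).  Background voxels never gain labels, and the
operation cannot create new label values, so it is idempotent once
converged.

## Validity indices

All entropies use the natural logarithm: NMI is normalization-invariant
and VI is reported in nats.  Conventions for degenerate inputs:

* Cramér's V skips cells with zero expected count; two single-cluster
  labelings on the same domain get V = 1, a single-cluster labeling
  against a multi-cluster one raises (inside the resampling drivers such
  a replicate contributes CV = 0, as "no measurable association").
* Dice: a cluster empty in both parcellations contributes 1, empty in
  exactly one contributes 0.  Dice and the hierarchy index are
  label-sensitive by design; CV, NMI and VI are permutation-invariant.
* Silhouette uses cosine distance on native-matrix rows; distances
  involving an all-zero row are 1, singleton-cluster voxels score 0.
* Contact matrices exclude the diagonal; rows that touch nothing stay
  all-zero, and a topological distance against an empty contact pattern
  is 1.

Resampling: split-half (default `n_reps` = 100) compares MPMs of random
half-cohorts, with the extra subject joining the first half when n is
odd and the second MPM's labels aligned to the first by assignment before
comparison; pairwise compares all n(n−1)/2 subject pairs directly;
leave-one-out compares each subject with the MPM of the rest.

The VI stability rule flags k as stable when VI(k+1) − VI(k) exceeds the
mean + `vi_sd_factor`·sd (default factor 1, sample sd) of all increments
while VI(k) − VI(k−1) does not exceed the mean.  "Considerable increase"
is not quantified in the literature this follows; the mean+1·sd rule is
this package's explicit operationalization and both the flags and the
increment series are reported.

`suggest_k` collects, per index, the favorable *interior* local extrema
of the mean curve (maxima for CV/Dice/NMI/silhouette/continuity/HI,
minima for TpD, the stability flags for VI).  Endpoints are excluded — a
k with an unobserved neighbor cannot be called a peak, and including
endpoints would systematically favor k_min for monotone reproducibility
curves.  Only the 26-connectivity continuity curve votes, to avoid
triple-counting one index.  The suggestion is the mode of all votes
(smallest k on ties) and is advisory output; nothing downstream applies
it silently.

## Synthetic cohorts

The phantom generator emulates what the pipeline consumes, not raw MRI:
each planted subregion has a prototype target pattern (disjoint slab
supports with gamma-distributed weights, pairwise cosine similarity 0),
and a subject's profile at a seed voxel is a multinomial draw of
`n_samples` streamlines from
(1 − `noise_mix`)·prototype + `noise_mix`·uniform, modulated by a mild
1/(1 + d/d₀) distance decay (d₀ = half the target-grid extent) that
mimics tractography's distance bias.  Per-subject label permutations
reproduce the arbitrary numbering of clustering outputs; optional jitter
reassigns voxels within a Chebyshev radius of a planted boundary to a
neighboring cluster with probability 0.5.  Defaults: a 6×6×8 seed block
(288 voxels) centered in a 20³ target grid at 2.5 mm isotropic voxels,
k_true = 4, 20 subjects, `noise_mix` = 0.15, no jitter.  The 2.5 mm voxel
size keeps the default 5 mm analysis blocks an integer multiple of the
voxel size.

What the phantom does *not* emulate: spatially smooth individual anatomy
(prototypes are shared exactly across subjects), registration error,
partial-volume effects, distance-dependent *false-positive* structure, or
correlated noise between neighboring seed voxels.  Passing recovery tests
therefore demonstrates the correctness of the machinery under the stated
generative model, not performance on real diffusion MRI.

Determinism: per-subject RNG substreams are derived from
(master_seed, subject index), so cohorts are bit-identical across runs
and independent of execution order.

## Pipeline

Work units (per subject in steps 4–5, per k in steps 7–10) are
independent; joblib fans them out and the parent writes all outputs in a
fixed order.  Label and probability images are written as uncompressed
NIfTI-1 (compressed gzip containers embed metadata that can break
byte-identity), matrices as plain text with repr-precision floats, so
outputs are byte-identical for any worker count under a fixed master
seed.  Steps validate their inputs and are skipped on rerun when their
outputs still parse, giving cheap resumability; steps 1, 3 and 6
(registration, tractography, inverse warping) are logged as external
stages and satisfied by ingested inputs.

Voxel coordinates are 0-based array indices throughout (the text sidecar
format says so explicitly); world coordinates enter only through the
affine when distances in mm are needed.

## Test problem sizes

The test suite exercises the full chain on phantoms chosen to keep the
suite fast while preserving the study conditions that matter: unit and
property tests use a 4×4×4-seed, 6-subject cohort; the recovery tests use
the default 288-voxel, 20-subject, k_true = 4, noise 0.15 phantom over
k = 2…8 with 25 split-half repetitions per k, repeated over 10 master
seeds; worker-count determinism is checked by byte-comparing two complete
pipeline runs.  Split-half repetitions beyond ~25 change the mean curves
negligibly on these phantoms; the config default remains 100.

## Known limitations

* Straight-line distance is a proxy for pathway length; true path-length
  correction requires streamline geometry the ingested matrices lack.
* The group similarity matrix definition (same-label co-occurrence) is
  one reasonable reading of group-level "connectional similarity";
  alternatives (e.g. averaging subject correlation matrices) are not
  implemented.
* Cross-k cluster matching exists only implicitly inside the hierarchy
  index; MPM colors are not matched across k.
* The 26-neighbor tie-break divides by 26 at volume boundaries rather
  than by the in-volume neighbor count.
* No statistical testing of index differences across k; means and
  standard deviations only.
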