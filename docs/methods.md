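# Methods

This note documents the models, parameters and design choices behind
`lesionbench`: what the synthetic generator emulates, how each pipeline
stage is defined, and what the benchmark's results do and do not say about
real MRI.

## The phantom model

A phantom "head" is a set of nested ellipsoid shells on an isotropic grid
(default 64³ voxels at 1 mm): a CSF rim under the head surface
(normalised ellipsoidal radius ρ ∈ (0.90, 1]), a grey-matter ribbon
(ρ ∈ (0.72, 0.90]), a white-matter interior, and a central CSF "ventricle"
(ρ ≤ 0.18). Intensities follow T1-weighted contrast with tissue means
background 0 < CSF 30 < GM 70 < WM 100 (arbitrary units) and additive
Gaussian noise (default SD 5, i.e. SNR ≈ 14 against the GM–WM midpoint —
a clean research-quality scan).

The GM ribbon is partitioned into `n_roi_pairs` (default 31, 62 regions)
mirror-symmetric sectors by polar/azimuthal angle of the voxel direction
measured with |x − c_x|, so a left-right flip of the grid maps left ROI *k*
exactly onto right ROI *k* + `n_roi_pairs` (the documented pair offset).
The left-right grid axis must be even so the midplane falls between voxel
columns. Tissue probability maps are the one-hot tissue indicators
smoothed with a 1-voxel Gaussian and renormalised to sum to 1 inside the
head.

**What this does not emulate:** cortical folding, partial-volume
microstructure, bias fields, multi-site contrast differences, skull and
extracranial tissue. Every property the benchmark measures — tissue
contrast, bilateral label bookkeeping, mask-restricted identity — is
independent of those; conclusions about *real* parcellation tools on real
anatomy are out of reach of the phantoms by design.

### Subjects and deformations

Inter-subject anatomy is emulated by smooth random displacement fields:
white noise per component, Gaussian-smoothed (σ = 4 voxels), rescaled to a
peak norm of `warp_max_magnitude_mm` (default 3 mm — small enough that the
warp is locally one-to-one, which is verified by a positive-Jacobian check
before any image is produced). Intensities are pulled back with linear
interpolation, labels and masks with nearest-neighbour; masks are always
warped *before* smoothing.

### Lesions

A lesion profile specifies cluster count (1–14), total target volume
(tens of mm³ up to the hemisphere's capacity), laterality
(unilateral-left/right or bilateral) and a hypointense intensity model
(default: the CSF level, SD 3 — encephalomalacia-like on T1). Clusters are
grown by seeded stochastic dilation from random in-head seeds to an exact
voxel count, kept one voxel apart so the 26-connected component count
equals the cluster count exactly; placement retries a bounded number of
times and then fails explicitly. Bilateral profiles alternate hemispheres
across clusters. 26-connectivity is this package's convention for
"cluster"; clinical reports rarely state one.

## Simulated sets

For each (patient profile, control) pair:

1. the control phantom, resampled by its known deformation, is the
   **lesion-free** ground truth (with real data this resampling is a
   registration; here the true field is known, so no optimisation is run);
2. the patient image is intensity-matched to it by a single global factor —
   the ratio of head-masked medians. This linear model is exactly
   reproducible and scale-equivariant; for genuinely gain-mismatched pairs
   it provably reduces the binned histogram RMSE (verified against a
   brute-force scan over factors), though for already-matched pairs the
   median ratio can perturb alignment by a sub-bin amount;
3. the matched lesion patch is blended in under the repair mask smoothed
   with a 2-mm-FWHM Gaussian (σ = FWHM / (2√(2 ln 2)) ≈ 0.85 mm, kernel
   truncated at 4σ, weights clipped to [0, 1]):
   `lesioned = (1 − w)·lesion_free + w·patient`, with voxels at w = 0
   copied bit-exactly. The **outside-mask identity** — lesion-free and
   lesioned agree bit-for-bit wherever w = 0 — is the invariant every
   downstream comparison relies on.

Simulation QC fails a set (excluding it entirely) when the identity is
violated, when the in-mask contrast between lesioned and ground truth
falls below a threshold (default 10 intensity units), or when non-finite
voxels appear. An empty repair mask is degenerate but legal: the triple
collapses to three identical images.

## Lesion filling

The fill reproduces the skeleton of bilateral enantiomorphic grafting:

- **Brain extraction**: threshold at half the Otsu level (Otsu separates
  tissue from background; halving keeps the CSF rim), largest 26-connected
  component, hole filling, one closing pass. Deterministic.
- **Donor**: inside the smoothed-mask support, the left-right flipped
  image where the flipped mask weight is < 0.01 (contralateral homolog
  healthy), otherwise the tissue-probability synthesis Σ_t p_t(v)·μ_t with
  μ_t the mean of the 10–90 percentile band of outside-mask intensities in
  each tissue's TPM ≥ 0.5 region (robust to lesion-adjacent outliers;
  falls back to the template's level for a tissue fully hidden by the
  mask). A per-voxel source map records which rule fired.
- **Graft**: `filled = (1 − w)·lesioned + w·donor` under the same smoothed
  mask, **without dilation** — voxels with w = 0 keep their recipient
  value bit-exactly (the no-dilation guarantee).
- **Intensity match**: a final global factor (head-masked median ratio to
  the ground truth) applied *weighted by w*, so the guarantee survives;
  the factor is reverted to 1 if it worsens the head-masked histogram
  RMSE. Scale, RMSE before/after and source counts land in the set's
  provenance.

## Parcellation stand-in

Template labels are warped into the subject by its known field
(nearest-neighbour), retained only where the image intensity falls in a GM
band (default [50, 85], ≈ ±4 noise SD around the GM mean), and a bounded
nearest-labelled-neighbour pass (radius 3 voxels; distance ties broken by
a seeded label-priority permutation, then smallest id) relabels in-band
voxels carrying no label — the mechanism by which lesion intensities
produce local misclassification, as they do in real pipelines. Coverage is
the in-band fraction of warped cortex; below a floor (default 0.5, so only
the largest lesions fail) the attempt fails, and each image gets two
attempts, re-seeding only the tie-break order. The tie-break seed is fixed
per set, so parcellation is a pure function of image content: bit-identical
images yield bit-identical parcellations. A failed image excludes its
whole set from group comparison.

In-mask portions of all three parcellations are removed with the *binary*
repair mask before any comparison (the smoothed support would also remove
blended-but-labelled boundary voxels; the binary mask is the region
actually replaced).

## Metrics and statistics

DSC and PVD are computed per ROI on the mask-excluded maps; ROIs empty in
both maps carry no information (both lost the same in-mask portion) and
are excluded from the unweighted per-image means, as are ROIs absent from
the reference. Histogram RMSE uses 128 density bins over the pooled
head-masked min–max range — one of several defensible definitions, so
RMSE-based correlations are directional statements, not calibrated values.

The 1.5×IQR fence (linear-interpolation quartiles) is applied jointly to
mean DSC and mean PVD of both image types; a set flagged on any series is
removed from all comparisons. Paired *t*-tests use the textbook closed
form with Cohen's d = mean(diff)/SD(diff) and a 95% CI for the mean
difference; Spearman's ρ is Pearson on average ranks with a two-sided
*t*-approximation for *p*. No multiple-testing correction is applied
(α = 0.05). SciPy's implementations serve as independent cross-checks in
the test suite, not as the implementation.

## Problem sizes and determinism

The shipped study configuration (6 profiles × 4 controls at 64³) runs in
well under a minute; the property suites in the tests use 48³ grids with 8
ROI pairs, which preserve every invariant under test at a fraction of the
cost. One master seed drives everything: each stochastic operation derives
a CRC32-based per-purpose subseed, and a run's CSV outputs are
byte-identical across repetitions. Degenerate inputs (empty masks,
constant images, whole-head masks, oblique affines, folding warps) fail
explicitly with named errors rather than propagating silently.

## Known limitations

- Ellipsoid-shell anatomy cannot exhibit global (distant-from-lesion)
  parcellation errors, surface-reconstruction failures, or the
  topology-driven behaviour of CNN/surface pipelines; the stand-in
  parcellation's errors are purely local and intensity-driven.
- The enantiomorphic donor is exact on mirror-symmetric phantoms, which
  flatters flip-based filling relative to real asymmetric brains.
- The histogram-RMSE definition and the GM band are package conventions;
  absolute metric levels (e.g. mean DSC ≈ 0.996 on the shipped
  configuration) reflect the phantom's difficulty, not any real dataset's.
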