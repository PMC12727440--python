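# lesionbench

A desk-scale benchmark for **lesion filling (inpainting) and cortical
parcellation accuracy** on synthetic 3-D head phantoms.

Focal lesions in T1-weighted MRI of moderate-to-severe traumatic brain
injury — often bilateral, varying from tens of mm³ to >150,000 mm³ and from
1 to 14 clusters — violate the "normal anatomy" assumption of automated
parcellation tools. Lesion filling replaces abnormal voxel intensities with
plausible healthy-tissue values before parcellation; whether it *helps* can
only be measured against a ground truth, which real patient data never
provides. `lesionbench` builds that ground truth synthetically: for each
simulated patient it constructs a **(lesion-free, lesioned, filled)** image
triple that is *bit-identical outside the lesion's repair mask*, parcellates
all three, and scores the lesioned and filled parcellations against the
lesion-free one. It is aimed at neuroimaging-methods researchers who want a
fully controlled, seconds-fast, deterministic test bed for lesion-filling
pipelines and their evaluation statistics.

## What it computes

Per cortical region of interest (ROI; 31 bilateral pairs, 62 regions by
default), with the repair-mask portion removed from all parcellations:

- **Dice similarity coefficient** — spatial overlap of the test ROI *T*
  with the ground-truth ROI *R*:

  DSC = 2 |R ∩ T| / (|R| + |T|), 0 = disjoint, 1 = identical;

- **Percent volume difference** —

  PVD = 100 · (V_test − V_ref) / V_ref, negative = smaller than truth;

- **Histogram RMSE** — root-mean-square difference between the two images'
  binned head-masked intensity densities (global intensity alignment).

Per-image ROI means are screened with a 1.5×IQR outlier fence, compared
with paired *t*-tests (Cohen's *d* = mean difference / SD of differences),
and probed with Spearman correlations of lesion volume and histogram RMSE
against accuracy. An exclusion ledger tracks every simulated set from
simulation QC through parcellation retries to the final analysis.

The filling stage is a simplified bilateral grafting workflow: threshold
brain extraction, an enantiomorphic donor (contralateral left-right flip
where the homologous tissue is healthy, tissue-probability-map synthesis
where it is not), grafting under a 2-mm-FWHM-smoothed repair mask *without
dilation* (so voxels outside the smoothed-mask support are untouched,
bit-exactly), and a mask-weighted global intensity match to the ground
truth.

## Worked example

The numbered scripts under `analysis/` run the study end to end and write
their tables to `results/`:

```bash
python analysis/01_simulate_cohort.py      # phantoms, lesions, QC
python analysis/02_fill_lesions.py         # grafting + fill provenance
python analysis/03_run_study.py            # parcellation, metrics, statistics
python analysis/04_exclusion_worked_example.py
```

`analysis/03_run_study.py` (6 lesion profiles × 4 matched controls, 64³
voxels at 1 mm, master seed 42) prints:

```
exclusion ledger: {'n_sets_initial': 24, ..., 'n_sets_included': 19, 'paired_test_df': 18}

per-image means over included sets:
            mean_dsc  mean_pvd
filled      0.996397 -0.146895
lesioned    0.997352 -0.200916

paired tests (lesioned vs filled):
  metric         t  df        p         d
mean_dsc  3.950336  18 0.000938  0.906269
mean_pvd -1.439561  18 0.167157 -0.330258
```

Reading: on these phantoms the *lesioned* images parcellate slightly (but
significantly, for DSC) **more** accurately than the *filled* ones — the
fill's smoothed-boundary blending perturbs more cortex than the lesions
themselves destroy, since the stand-in parcellation only loses voxels whose
intensity leaves the grey-matter band. The Spearman table shows the
expected structure: accuracy falls as lesion volume and histogram RMSE grow
(e.g. lesion volume vs lesioned-image mean DSC: ρ = −0.97, p < 10⁻¹⁰), and
lesion volume drives histogram misalignment (ρ = 0.98).

`analysis/02_fill_lesions.py` confirms the fill itself is doing its job at
the intensity level: in-mask mean absolute error against the ground truth
drops for the filled image in 100% of the 24 sets (e.g. 29.4 → 15.5
intensity units for the smallest-lesion profile).

`analysis/04_exclusion_worked_example.py` runs the ledger arithmetic at
full study scale — 140 sets, two profiles failing simulation, six sets
failing parcellation twice, two outlier sets — ending at 112 analysed pairs
(111 degrees of freedom).

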