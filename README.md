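# hemidti

Interhemispheric DTI asymmetry analysis: a tested pipeline from
diffusion-weighted volumes to the global interhemispheric fractional-
anisotropy difference (ΔFA), its cross-sectional and longitudinal
statistics, and whole-brain voxelwise comparison — driven by a synthetic
phantom generator with exact ground truth, so every stage is verifiable
without any imaging download.

## What it does

* **`hemidti.synthetic`** — mirror-symmetric white-matter phantoms on a
  configurable grid (default 48×48×24 voxels at 2.0×2.0×2.8 mm), with an
  isotropic tumor sphere (ground-truth FA < 0.2), a local peritumoral
  anisotropy depression, and a hemispheric anisotropy reduction whose blend
  factor is *calibrated by root-finding* so each session's noiseless true
  ΔFA hits a target drawn from configurable group distributions. Simulates
  the monoexponential tensor signal (48 directions at b = 800 s/mm² plus 4
  b0 volumes by default, golden-spiral direction set) under Rician noise.
* **`hemidti.dti`** — brain masking, weighted log-linear least-squares
  tensor fit, eigensystem, and FA/MD/AD/RD scalar maps.
* **`hemidti.align`** — rigid registration (masked MSE, Nelder–Mead with
  coarse-to-fine multi-start), symmetric halfway splitting of transforms,
  per-subject b0 template construction that minimizes baseline bias, and
  AC-PC landmark standardization.
* **`hemidti.roi`** — hemisphere splitting at the midsagittal plane,
  FA-thresholded means (threshold 0.2 excludes gray matter and tumor, with
  a programmatic zero-tumor-overlap quality check), mirrored-sphere local
  differences, and the global ΔFA/ΔMD/ΔAD/ΔRD statistic
  (healthy-hemisphere mean − tumor-hemisphere mean).
* **`hemidti.stats`** — own Wilcoxon–Mann–Whitney (exact by full labeling
  enumeration for ≤ 21 tie-free observations) and Spearman rank correlation
  (exact permutation p for n < 10), control noise-level summaries, the
  one-scan-per-patient-per-group cross-sectional comparison, and the
  ΔFA-versus-time-since-radiation correlation (pre-radiation scans at
  Δt = 0).
* **`hemidti.wbss`** — voxelwise group statistics on smoothed FA maps:
  Gaussian smoothing (8 mm FWHM default) with a Sinkhorn-balanced masked
  kernel that preserves both constants and the in-mask mean,
  Benjamini–Hochberg FDR at α = 0.05, and cluster-size filtering
  (512 voxels at the full 128×128×64 grid, scaled proportionally on
  smaller grids).
* **`hemidti.pipeline` / `hemidti.cli`** — manifest handling, YAML config
  with provenance hashes, and the end-to-end orchestration with
  per-subject failure isolation.

## CLI

Each stage is independently invokable:

```bash
hemidti simulate --out cohort/ --n-controls 13 --n-pre 10 --n-post 11 --seed 1
hemidti fit cohort/P001_ses-01_dwi.nii cohort/P001_ses-01.bval \
        cohort/P001_ses-01.bvec --out maps/P001
hemidti align moving_b0.nii fixed_b0.nii --out transform.json
hemidti roi maps/P001_FA.nii --hemisphere left --tumor-mask cohort/P001_ses-01_tumor.nii
hemidti run-all cohort/manifest.tsv --out results/
hemidti stats results/delta_results.tsv cohort/manifest.tsv
```

Formats: NIfTI-1 volumes, FSL-dialect bvec/bval text files, TSV manifests
(`subject_id, session_id, group, rt_status, delta_t_months,
tumor_hemisphere, dwi, bval, bvec, tumor_mask`), JSON transforms and
reports. Voxel indices are 0-based; world coordinates follow the NIfTI
affine; the midsagittal plane of even-sized grids is the half-integer
plane between the two central voxel columns (an integer plane index
excludes that column from both hemispheres).

## Notes

* The halfway registration is symmetric (both images travel half the
  estimated transform); `--halfway=moving-only` is available in the
  pipeline config.
* The voxelwise test is Mann–Whitney by default with Student's t as a
  config option; both are first-class.
* Control sessions use the fixed signed left-minus-right ΔFA convention,
  so the control noise level captures both decreases and increases.
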