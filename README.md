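# voxnmf

Decomposition of masked brain-image volumes (grey-matter volume maps,
FDG-PET SUVR maps) into nonnegative spatial components via minimum-volume
NMF, with cross-validated rank selection, elastic-net prediction of clinical
features from component loads, and back-projection of model coefficients
into interpretable voxel maps.

## What it does

1. **imaging_io** — NIfTI I/O, SUVR normalization by a reference-region
   median, grey-matter mask application, and deterministic conversion
   between 3D volumes and flat voxel vectors (first grid axis fastest).
2. **minvol_nmf** — fits `X ≈ L·D` with `L, D ≥ 0`, load rows on the capped
   simplex (`sum ≤ 1`), minimizing
   `‖X − L·D‖²_F + λ·logdet(D·Dᵀ + δI)`. The logdet volume penalty gives
   identifiability for rank-deficient dictionaries. Dictionary updates use a
   monotone majorize-minimize HALS scheme; loads are solved by accelerated
   projected gradient on the capped simplex. `project_loads` projects new
   subjects onto a fixed dictionary.
3. **rank_selection** — repeated k-fold CV scan of candidate ranks
   (5 folds × 5 repeats → 25 paired discovery/hold-out MAE values per rank)
   with a one-standard-error selection rule toward smaller ranks.
4. **clinical** — elastic-net (glmnet-style penalty) linear/logistic models
   predicting each clinical outcome from age + component loads
   (mixing α = 0.2 single-modality, 0.8 combined; strength by 5-fold CV);
   MCC/accuracy for binary outcomes, R²/median-or-mean absolute error for
   continuous ones; paired sign-flip permutation tests between modalities
   with Benjamini–Hochberg FDR adjustment.
5. **coefficient_maps** — back-projects a model's component slopes through
   the dictionary into a single signed voxel map.
6. **synthetic** — phantom cohorts (Gaussian-blob components, capped-simplex
   loads, load-linked outcomes) so every stage is testable without data.
7. **pipeline / cli** — YAML-configured orchestration of all stages.

## CLI

```sh
voxnmf run config.yaml                           # all stages
voxnmf run config.yaml --stages simulate,fit     # a subset
voxnmf rank-scan config.yaml                     # a single stage
```

Minimal config:

```yaml
output_dir: out/study
seed: 3
simulate: {n: 60, rank: 4, grid_size: 16, noise_sd: 0.02}
test_size: 15
modalities: {MRI: {}, FDG: {}}
rank_scan: {ranks: [3, 4, 5, 6], k: 5, repeats: 5}
prediction: {alpha_single: 0.2, alpha_combined: 0.8, cv_folds: 5}
```

With real data, replace `simulate` with explicit inputs:

```yaml
mask: data/mask.nii
clinical_csv: data/clinical.csv
binary_outcomes: [vsgp_psis]
continuous_outcomes: [moca]
modalities:
  MRI: {images: [data/mri/sub01.nii, ...], rank: 9}
  FDG: {images: [data/fdg/sub01.nii, ...], rank: 14}
```

Stages write their artifacts (loads CSVs, component/coefficient NIfTIs,
model JSONs, evaluation CSVs, a JSON log) into `output_dir`; re-running with
the same seed reproduces them.

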