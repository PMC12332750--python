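# anxvbm

Voxel-based morphometry (VBM), seed-based structural covariance, and
severity prediction for case-control studies of anxious depression —
with a fully synthetic data generator so the entire analysis chain can
be exercised, calibrated, and validated without access to restricted
neuroimaging data.

The package implements the statistical core of a three-group
morphometry study design:

- **Cohorts**: anxious depression (AD: HAMD-17 ≥ 17 and HAMA-14 ≥ 14),
  non-anxious depression (NAD: HAMD-17 ≥ 17, HAMA-14 < 14), and healthy
  controls (HC), recruited across multiple sites.
- **VBM** (`anxvbm.vbm`): mass-univariate ANCOVA of gray matter volume
  (GMV) with age, sex, education and site covariates; partial-F group
  maps, pairwise post-hoc t maps, and dual-threshold cluster correction
  (voxel p < 0.001, permutation null of cluster sizes, BH-FDR over
  clusters at q = 0.05); cluster GMV extraction, partial correlation
  with clinical scores, and age-stratified reruns.
- **Structural covariance** (`anxvbm.structcov`): per-voxel
  seed-by-group interaction model (seed mean GMV as response) testing
  whether seed-to-voxel coupling differs between patient groups;
  voxel-wise BH-FDR and signed clustering.
- **Severity prediction** (`anxvbm.svr`): leave-one-out ε-SVR (linear
  kernel, C = 10, ε = 0.1) predicting HAMA-14 from regional GMV, with
  fold-internal feature screening and scaling, consensus-feature weight
  maps, whole-pipeline permutation inference, and frozen-model external
  validation.
- **Synthetic data** (`anxvbm.synthetic`): cohorts drawn from published
  summary distributions under the exact diagnostic rules, and smoothed
  3D GMV images with planted group, clinical-score, and seed-coupling
  effects of known location and magnitude.
- **Plumbing** (`anxvbm.io`, `anxvbm.cli`): NIfTI/CSV/JSON/YAML formats,
  run manifests with input/output hashes, and a stage-chained CLI.

## Worked example

Simulate a three-group cohort (n = 30/group), plant a 1.5-SD GMV
reduction in the AD group inside a known region, and recover it with the
covariate-adjusted ANCOVA plus dual-threshold cluster correction:

```python
import numpy as np
from anxvbm import synthetic as syn, vbm
from anxvbm.stats import demographics_table

ispec = syn.default_image_spec(grid_shape=(14, 16, 14))
sd = syn.realized_noise_sd(ispec, rng_seed=0)          # 0.0219
cohort = syn.generate_cohort(syn.CohortSpec(n_per_group=30, rng_seed=1))
print(demographics_table(cohort, group_order=["AD", "NAD", "HC"]))

roi = syn.box_roi(ispec.grid_shape, (4, 6, 5), (4, 4, 4)) & ispec.mask
stack = syn.generate_images(
    cohort, ispec,
    [syn.PlantedEffect(roi, "group_mean_shift", 1.5 * sd, "AD")],
    rng_seed=2,
)
design = vbm.build_design(cohort)
fmap = vbm.voxelwise_ancova(stack, design, ispec.mask)
clusters = vbm.dual_threshold_clusters(
    fmap, stack, design, affine=ispec.affine, rng=np.random.default_rng(0)
)
for c in clusters:
    print(f"{c.size} voxels, peak F={c.peak_value:.2f} at MNI {c.peak_mni}, "
          f"corrected p={c.p_adjusted:.4f}")
```

Output:

```text
characteristic          AD         NAD          HC  statistic      p_value        method
     sex (M/F)       13/17       13/17       13/17   0.000000 1.000000e+00    chi-square
           age 40.46±13.87 31.73±11.10 33.27±10.51   4.586293 1.277487e-02 one-way ANOVA
     education  10.60±2.74  10.64±3.07  14.56±3.09  17.592325 3.835865e-07 one-way ANOVA
        hamd17  21.80±2.62  21.53±2.73   2.23±1.30 708.762168 1.419782e-54 one-way ANOVA
        hama14  24.27±4.70   8.33±2.62   1.80±1.19 396.400758 1.942463e-44 one-way ANOVA

64 voxels, peak F=47.52 at MNI (-9.0, 3.0, 3.0), corrected p=0.0133
```

The surviving cluster sits inside the planted region (the 4×4×4 box
centered near MNI (−9, 3, 3) on this 6 mm grid).

The same chain is available from the command line:

```bash
anxvbm simulate --out dataset --seed 0 --n-per-group 30
anxvbm demographics --dataset dataset --out output
anxvbm vbm --dataset dataset --out output --seed 0
anxvbm sc  --dataset dataset --out output      # seed = leading VBM cluster
anxvbm svr --dataset dataset --out output --seed 0
anxvbm report --out output
```

## Reproduction

All results below regenerate deterministically from a single seed:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

This recomputes the demographic test statistics from published-style
group summaries (e.g. cohort anxiety-severity t = 19.654, age ANOVA
F = 16.864, sex χ² = 4.478), then runs the calibration and recovery
experiments end to end (~2–3 minutes on one CPU). Values obtained at
seed 1:

| quantity | value |
|---|---|
| BH-FDR global-null any-discovery rate (q = 0.05) | 0.049 |
| cluster-correction family-wise null rate | 0.020 |
| planted d = 0.8 VBM effect, detection rate (50 reps, n = 89/group) | 1.00 |
| SC planted slope pair {AD 0.2, NAD 0.8}: recovered slopes | 0.194 / 0.721 |
| SC peak interaction t (lower coupling in AD) | −4.97 |
| SVR LOOCV r (planted severity signal, n = 178) | 0.773 |
| SVR permutation p (199 permutations) | 0.005 |
| SVR external-cohort r (frozen model, n = 40) | 0.863 |

The test suite (unit, property, oracle, and end-to-end acceptance
tests) runs in about 5 minutes:

```bash
python -m pytest tests/
```

## Documentation

`docs/methods.md` describes the statistical models, the synthetic
generator's scope and parameter provenance, numerical choices, and
known limitations.
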