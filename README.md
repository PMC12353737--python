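# gwjtv

Gray-white matter junction tissue volume (gwJTV) mapping and statistics.

The boundary where cortical gray matter (GM) meets white matter (WM) is a
thin transitional shell whose volume changes with aging, focal cortical
dysplasia, and — the use case this package targets — vascular and metabolic
damage in type 2 diabetes with carotid atherosclerosis. `gwjtv` computes a
per-subject gwJTV map from an already-segmented, spatially normalized
T1-weighted volume, and provides the full downstream statistical toolchain
for a two-group (carotid plaque vs no plaque) morphometry study: voxelwise
GLMs with cluster-extent thresholding, and region-of-interest tests
annotated with noncentral-t statistical power.

Because studies of this design rarely deposit subject-level MRI, the
package ships a concentric-sphere phantom generator with closed-form
partial volumes, so every stage of the chain can be validated end to end
against analytic ground truth.

## The junction map

For each subject, with T1 signal intensity SI and GM/WM/CSF partial-volume
maps:

1. **Thresholds.** Over voxels with >50% GM (resp. WM) partial volume,
   compute the mean SI and twice its sample SD. The junction band is

   ```
   BT_lower = SI_GM50_mean + (1/2)·SI_GM50_2SD
   BT_upper = SI_WM50_mean − (1/2)·SI_WM50_2SD
   ```

2. **Binary map.** Voxel = 1 iff BT_lower ≤ SI ≤ BT_upper and
   GM + WM partial volume ≥ 0.5 (intensity in-band *and* located in brain
   tissue).
3. **Box blur.** Normalized 5×5×5 convolution (weight 1/125) spreads the
   thin junction line into a local junction density.
4. **Volume and normalization.** Summing the blurred map × voxel volume
   gives gwJTV in mL; the map is divided by total intracranial volume
   (TIV = GMV + WMV + CSF) to remove head-size differences.
5. **Smoothing.** An 8 mm FWHM Gaussian prepares the map (and the
   TIV-normalized GM/WM maps) for voxel-based statistics.

Group inference is a voxelwise two-sample t-test with age as covariate
(α = 0.0005 uncorrected, ≥100 contiguous voxels, 18-connectivity); ROI
inference uses pooled-variance t-tests and age-controlled partial
correlations, each annotated with observed power from the noncentral t
distribution at the Bonferroni level α = 0.016 (= 0.05/3 for the three
tissue measures GMV, WMV, gwJTV).

## Worked example

Generate a synthetic 69-subject cohort (33 without, 36 with "plaque"; the
plaque group's junction width is reduced 15% in a target region), run the
junction pipeline, and test the ROI difference:

```python
import numpy as np
from gwjtv import (PhantomSpec, CohortSpec, make_cohort, process_subject,
                   junction_roi_mask, RoiMask, extract_roi_value,
                   group_ttest_with_power)

pspec = PhantomSpec(grid_shape=(48, 48, 48), csf_radius_mm=20.0,
                    gm_radius_mm=16.0, wm_radius_mm=10.0)
cspec = CohortSpec(seed=42)          # 33 + 36 subjects, junction_effect 0.15
subjects, table = make_cohort(cspec, pspec)

res0 = process_subject(subjects[0])
print(f"TIV = {res0.tiv:.2f} mL, gwJTV = {res0.gwjtv_total:.2f} mL")

roi = RoiMask(junction_roi_mask(pspec), "target_octant")
vals = np.array([extract_roi_value(process_subject(s).gwjtv_map, roi)
                 for s in subjects])
g = table["group"].to_numpy()
t = group_ttest_with_power(vals[g == "no_plaque"], vals[g == "plaque"],
                           alpha=0.016)
print(f"t({t.df}) = {t.t:.2f}, p = {t.p:.2e}, power = {t.power:.3f}")
```

Output:

```
subject 0: TIV = 33.54 mL, gwJTV = 1.50 mL, band = [107.1, 148.2]
ROI gwJTV: no-plaque 0.109 +/- 0.006 (n=33), plaque 0.100 +/- 0.008 (n=36)
t(67) = 5.69, p = 3.04e-07, observed power at alpha=0.016: 0.999
```

The subject's junction band [107.1, 148.2] sits between the GM (≈100) and
WM (≈160) mean intensities; the planted group reduction is recovered as a
lower mean ROI gwJTV in the plaque group with a strongly significant
pooled-variance t-test.

The same stages are scriptable from the shell:

```bash
gwjtv phantom --spec spec.json --out cohort/
gwjtv junction --t1 t1.nii.gz --gm gm.nii.gz --wm wm.nii.gz \
               --csf csf.nii.gz --out subj/
gwjtv run --out run/ --seed 1        # full phantom→junction→VBA→ROI pipeline
```

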