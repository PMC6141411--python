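# gatedpet

Biventricular volume and function analysis for **first-pass gated cardiac
PET**. During the first transit of a tracer bolus through the cardiac
cavities, an ECG-gated reconstruction of the blood pool allows left- and
right-ventricular end-diastolic volume (EDV), end-systolic volume (ESV),
stroke volume (SV = EDV − ESV) and ejection fraction (EF = SV/EDV) to be
measured from the same acquisition as, say, a perfusion study — no extra
tracer, no extra scan. The package is aimed at nuclear-medicine and
medical-image-analysis researchers who want a tested, scriptable
implementation of this processing chain, including a synthetic phantom
with known ground truth for validation.

## What it does

1. **TAC / first-pass window** (`gatedpet.tac`): extracts the cardiac-ROI
   time-activity curve from the dynamic reconstruction and locates the
   transition between the bolus peak and the tissue plateau, which bounds
   the gated reconstruction window. Manual override supported.
2. **4D immersion segmentation** (`gatedpet.segmentation`): a
   watershed-by-immersion run directly on the (gate, x, y, z) landscape
   partitions the gated images into regions centred on local intensity
   maxima; regions are assigned to LV / RV / extra-ventricular activity
   from their barycentre position relative to three operator-set planes
   (septal, valve, infundibular), with manual reassignment.
3. **Volumetry** (`gatedpet.volumetry`): count-based LV volumes
   (intensity-weighted voxels at a fixed 30% threshold of the 4D maximal
   LV intensity) and geometric RV volumes at an adjustable threshold tuned
   so RV and LV stroke volumes match; plus the 20–40% threshold sweep.
4. **Ejection-curve fitting** (`gatedpet.curvefit`): the gated samples
   {t_n, v_n} are fitted with the deformable model
   `v_n = η[R(t_n + τ(t_n))]` — R a 512-point reference ejection curve,
   η a second-order polynomial, τ a bounded sum of cosines — giving a
   continuous time-volume curve.
5. **Agreement statistics** (`gatedpet.stats`): Pearson r, Lin's
   concordance correlation coefficient, Bland–Altman bias and 95% limits
   of agreement, paired t test, Lilliefors-corrected KS normality.
6. **Phantom** (`gatedpet.phantom`): gamma-variate bolus kinetics with
   delayed/dispersed LV transit and a myocardial plateau, beating
   ellipsoidal chambers, PSF blur and Poisson counting noise — with exact
   ground-truth volumes, function and first-pass timing.

See `docs/methods.md` for the models, defaults and limitations.

## Worked example

Simulate a phantom study and run the full pipeline:

```sh
gatedpet simulate --out study/ --seed 3
cat > run.yaml <<EOF
dynamic_path: study/dynamic.nii.gz
gated_path: study/gated.nii.gz
planes_path: study/planes.json
output_dir: study/out
EOF
gatedpet run --config run.yaml
```

which prints (ground truth here: LV EDV 100.8 mL, EF 0.60, equal LV/RV
stroke volumes by construction):

```
LV EDV 80 mL EF 0.62 | RV EDV 96 mL EF 0.57
```

(along with a warning that the tuned RV stroke volume still misses the LV
one by 5.1 mL — the residual mismatch is always surfaced). The noisy
count-based EDV reads low because the 4D reference maximum is inflated by
counting noise; EF — the ratio readout — is recovered to within a few
hundredths of the 0.60 ground truth (the noiseless phantom recovers EDV
to ~5%).
`study/out/` contains the TAC (`tac.csv`), the detected first-pass window,
the 4D partition and chamber masks (NIfTI), per-gate volume curves
(`volumes.csv`), fitted curve models (`fits.json`) and a full
`report.json`. The same analysis is available in Python via
`gatedpet.phantom.render`, `gatedpet.analyze_gated` and
`gatedpet.run_pipeline`.

Two result tables can be compared (e.g. rest vs. stress) with
`gatedpet compare --a rest.csv --b stress.csv --params edv_ml,esv_ml,sv_ml,ef`,
which writes an agreement report (r, ccc, Bland–Altman, paired t) per
parameter and optional plots.

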