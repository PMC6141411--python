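# Methods

`gatedpet` implements the post-processing chain of a first-pass gated
blood-pool cardiac PET study: a single tracer bolus is imaged during its
transit through the cardiac cavities, the acquisition is reconstructed
twice (an ungated dynamic sequence to locate the bolus, then an ECG-gated
series restricted to the first-pass window), and biventricular volumes and
function are extracted from the gated images. This note records the models,
the numerical choices, and what the synthetic phantom does and does not
establish.

## First-pass window detection (`tac`)

The dynamic sequence (default schedule 14×5 s, 3×10 s, 3×20 s, 4×30 s)
yields a time-activity curve (TAC) in a cardiac ROI — by default the
central box covering 40% of each axis, which encloses the heart without
requiring segmentation. A first-pass TAC shows a sharp bolus peak followed
by a sustained tissue plateau; the gated reconstruction window must end at
the peak-to-plateau transition.

The detector fits a linear plateau to the last 25% of the frames and
declares the first pass over at the start of the earliest post-peak frame
whose measured value is within `max(one plateau-residual SD, 5% of the
peak height above the plateau)` of the plateau fit. We deliberately test
measured frame values rather than extrapolating a mono-exponential fitted
to the first post-peak frames: when the plateau is an appreciable fraction
of the peak (freely diffusible tracers accumulate in myocardium quickly),
the early post-peak frames are plateau-contaminated, the fitted decay rate
is biased low, and an extrapolation-based rule places the transition
several frames late; the junction test is also exact on the canonical
piecewise-linear fall-then-flat curve. The rule is scale-invariant and
time-shift equivariant. The window start is fixed at scan start (the bolus
arrival is part of the window); a manual override replaces the detected
window and is flagged in provenance.

## 4D immersion segmentation (`segmentation`)

The gated series is treated as a single 4D intensity landscape and
partitioned by watershed immersion: voxels at or above the flood floor
(default 10% of the global maximum, excluding air) are processed by
decreasing intensity; a voxel with no already-flooded neighbour becomes
the seed of a new region (it is a local maximum), otherwise it joins the
region of its steepest-ascent flooded neighbour. Connectivity is
6-neighbour in space plus ±1 in gate with cyclic wrap, because the cardiac
cycle is periodic. All ties (equal intensities, equal neighbours) resolve
in raster order, so the labelling is fully deterministic and reproducible.
A pure-Python level-by-level flooding implementation
(`flood_level_by_level`) with the same semantics is kept in the package as
an independent validation path; the production path is a Numba kernel over
a pre-sorted voxel order.

A small spatial Gaussian pre-smoothing (default 1 voxel FWHM) is applied
before flooding to suppress noise-induced over-segmentation; every region
statistic and all volumes are computed on the unsmoothed intensities.
Over-segmentation is harmless downstream because chambers are unions of
regions.

Regions are assigned to LV, RV or extra-ventricular activity from the
position of their intensity-weighted *spatial* barycentre (pooled over
gates — the planes are static) relative to three operator-set planes:
septal (normal toward the LV), valve (normal toward the ventricles) and
infundibular (upper RV limit, normal toward the RV body). A barycentre
within 1e-9 voxels of a plane counts as the LV/ventricular side. Manual
region reassignment is supported and logged. Chamber masks are obtained by
thresholding at a fraction of the 4D maximal intensity inside the
chamber's regions; masks are nested in the threshold by construction.

## Volumetry (`volumetry`)

LV volumes are count-based: per gate, `V = v_vox * Σ I / I_max` over the
mask, with `I_max` the 4D maximum inside the LV regions. Under uniform
intracavitary concentration this compensates partial-volume blur (the
blurred counts integrate to the chamber total). The default LV threshold
is 30%, exposed in config. RV volumes are geometric (voxel count ×
voxel volume): right-heart dilution is incomplete and a right-atrial
filling "hot spot" near the RV base at end-systole breaks the uniformity
assumption. The RV threshold is tuned by grid search (0.15–0.60, step
0.01) to minimize `|SV_RV − SV_LV|` using raw-sample stroke volumes
(decoupled from the curve model), ties toward the smaller threshold; the
residual mismatch is always reported and a manual threshold is accepted.

EDV/ESV/SV/EF are reported from the raw gate samples by default; extrema
of the fitted continuous curve (512-point evaluation) are available behind
a flag. With 8 gates the raw extrema are the reproducible baseline; both
are written to the report. The identities SV = EDV − ESV and EF = SV/EDV
hold exactly because SV and EF are derived, never re-measured.

With Poisson noise the count-based volumes are biased low (the 4D maximum
over thousands of noisy voxels overestimates the true ceiling by a few
percent), but the bias cancels in EF because EDV and ESV share the same
reference maximum — which is why noisy acceptance checks are stated on EF.

## Deformable ejection-curve model (`curvefit`)

Gated volume samples `{t_n, v_n}` are fitted with
`v = η[R(t + τ(t))]`, where `R` is a reference ejection curve sampled at
512 points of the normalized cycle, `η(r) = a0 + a1 r + a2 r²`, and
`τ(t) = Σ_k b_k cos(2π f_k (t − φ_k))` with integer frequencies fixed at 1
and 2. The population reference curve is unavailable, so `R` is an
analytic physiologic stand-in: cosine ejection from 1 to `1 − EF_ref`
(default 0.60) over the systolic fraction (default 0.35, snapped to the
sample grid), a rapid-filling cosine limb recovering 70% of the ejected
fraction over a quarter cycle, a linear diastasis recovering 10%, and an
atrial-kick cosine limb restoring end-diastole. Mis-specification of `R`
is largely absorbed by `η` and `τ`, which is the point of the deformable
formulation.

Amplitude bounds `|b1| ≤ 0.08`, `|b2| ≤ 0.035` cycles guarantee an
invertible time warp a priori (`Σ 2π f_k |b_k| < 1` implies
`d/dt (t + τ) > 0`); a runtime monotonicity check covers custom bounds,
falling back to `τ = 0` with a warning. Eight samples support at most the
model's 7 free parameters, so the parameterization is intentionally this
small. Optimization is bounded trust-region least squares
(`scipy.optimize.least_squares`) started from the closed-form affine map
of `R` onto the samples with zero warp, plus a deterministic 4-point
multi-start over the cosine phases; the τ = 0 quadratic baseline is always
a candidate, so the returned residual never exceeds it. LV and RV are
fitted independently.

## Agreement statistics (`stats`)

Pearson r (scipy), Lin's concordance coefficient with population (1/n)
moments per the original definition (1/(n−1) variants differ at small n;
two equal constant series concord perfectly), Bland–Altman bias with
t-based 95% CI and 1.96·SD limits of agreement (differences are second
argument minus first), a two-sided paired t test (NaN-flagged on
zero-variance differences), and a Lilliefors-corrected KS normality test
(statsmodels, table p-values) since the normal parameters are estimated
from the data. No multiple-testing adjustment is applied.

## Synthetic phantom (`phantom`)

The phantom renders what the pipeline consumes. Kinetics: a unit-peak
gamma-variate right-heart input (default shape 3, scale 1.5 s, arrival
5 s), the LV curve its delayed (4 s) convolution with a causal
mono-exponential dispersion kernel (2.5 s), and a myocardial concentration
rising mono-exponentially (time constant 20 s) to a plateau of 10% of the
LV peak. All pointwise values and time integrals are closed forms in the
regularized incomplete gamma function, so rendered frame totals equal the
configured kinetics to machine precision (validated against adaptive
quadrature). The ground-truth first-pass end is the post-peak time at
which the LV concentration reaches 5% of its peak — the bolus has
effectively cleared the cavities; at default kinetics this is ~28 s,
within the 18–35 s range typical of rest acquisitions.

Geometry: chambers are axis-aligned ellipsoids with a fixed 70 mm long
axis; the two equal short semi-axes are computed from the target volume
(`a = sqrt(3V / 4πc)`), so the analytic volume tracks the per-gate
physiologic curve exactly. Per-gate target volumes sample the same cycle
shape as the reference curve, with the end-systolic phase snapped to the
gate grid so the sampled minimum is exactly `EDV(1 − EF)`. The *reported*
ground truth is the voxelized occupancy volume actually rendered (count ×
voxel volume, within ~1% of the analytic target at the default grid), so
ground-truth identities hold exactly against the images. A fixed
ellipsoidal myocardial shell (3 mm gap, 8 mm thick) surrounds the LV, and
an optional hot spot (9 mm radius, 1.2× RV intensity, Gaussian-weighted
around the end-systolic gate) sits above the valve plane near the RV
base. The default grid is 64×64×47 with 3.27 mm cubic voxels, 8 gates,
870 ms cycle; defaults LV EDV 100 mL / EF 0.60 and RV EDV 113 mL / EF
0.531 give equal stroke volumes (~60 mL), representative round values for
a rest study, and 2×10⁷ first-pass prompt events with a 6 mm PSF are
representative count and resolution levels for this kind of acquisition.

The gated series splits the first-pass kinetic integral evenly across
gates (valid when the window spans many cycles); the dynamic sequence
freezes the chambers at their cycle-average volume (ungated motion
blur). Expected counts are scaled so the first-pass window totals the
configured prompts, then Poisson-sampled with a seeded generator
(bit-reproducible).

Not emulated: anatomical shape variability, respiratory motion,
attenuation/scatter artefacts, reconstruction correlations between
voxels, arrhythmic gate mixing. Passing tests therefore establish the
correctness and internal consistency of the algorithms under known
geometry and kinetics — not clinical accuracy, which requires validation
against an independent modality on real studies.

## Problem sizes used in validation

Unit tests run mostly on a coarse phantom (32×32×24, 6.54 mm) with the
same field of view; end-to-end recovery checks use the full 64×64×47 grid,
10 noise seeds for the EF error distribution, 200 random 4D images for the
watershed/oracle equivalence, 50 noise replicates for curve-fit EF
recovery, 20 kinetic settings spanning ~18–35 s transit for first-pass
detection, and 2000 replicates at n = 19 for the normality-test
calibration. The full suite and the acceptance script each complete in
well under a minute apiece on one CPU.

## Known limitations

* Count-based absolute volumes are noise-level dependent through the
  reference maximum (see above); EF is the robust noisy-data readout.
* The RV tuning objective can saturate at a search-range endpoint on very
  coarse or very noisy data; the residual mismatch is reported and should
  be inspected.
* The analytic reference curve is a stated convention, not a population
  measurement; `η`/`τ` absorb most, not all, of the discrepancy.
* Plane-based assignment uses pooled 3D barycentres; strongly through-plane
  motion could in principle move a region's barycentre across a plane.
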