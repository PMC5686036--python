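# fivedpet

Left-ventricular volumes and ejection fraction from cardiac-gated dynamic
¹⁵O-water PET — plus the parametric myocardial-blood-flow imaging that makes
it possible.

¹⁵O-water is the reference tracer for quantifying myocardial blood flow
(MBF), but because water diffuses freely it produces no myocardium-to-blood
contrast in static uptake images, so gated LV volumetrics have traditionally
required a separate MRI or echo exam. This package implements the alternative:
fit the kinetic model voxelwise *per cardiac gate*, build synthetic
blood-volume images from the fitted blood fractions, and segment the LV
cavity on those — so MBF, EDV, ESV, SV and LVEF all come from one 6-minute
dynamic scan. It is intended for PET methodologists and medical physicists
working with dynamic cardiac acquisitions.

## The model

Each voxel's time-activity curve C_T(t) follows the single-tissue-compartment
model with arterial and right-ventricular spill-over terms:

    C_T(t) = PTF · MBF · C_A(t) ⊗ e^{−(MBF/V_T)·t} + V_A · C_A(t) + V_RV · C_RV(t)

where PTF is the perfusable tissue fraction (g·mL⁻¹), MBF the myocardial
blood flow (mL·g⁻¹·min⁻¹), V_T = 0.91 mL·g⁻¹ the water partition
coefficient, and V_A, V_RV the arterial and right-ventricular blood-volume /
spill-over fractions. Fitting uses the basis-function method: 50 kernels

    B_i(t) = MBF_i · C_A(t) ⊗ e^{−(MBF_i/V_T)·t}

are precomputed on a log-spaced flow grid from 0.1 to 2.2 mL·g⁻¹·min⁻¹; for
each MBF_i the model is linear in (PTF, V_A, V_RV), so a 3-coefficient
weighted least-squares solve per grid value plus an argmin over the grid gives
the voxel's parameters. Derived images are the blood volume V_B = V_A + V_RV
(≈1 inside the ventricular cavities), the transmural flow MBFt = MBF·PTF, and
the model-free first-pass (FP) image, the duration-weighted sum of frames
10–50 s after injection. Per gate the LV cavity is segmented on V_B or FP by
half-maximum thresholding with kinetic LV/RV disambiguation; EDV/ESV are the
max/min of the gated volume curve, SV = EDV − ESV and LVEF = 100·SV/EDV.

Gated rebinning can drop cardiac cycles that straddle frame boundaries,
depressing the short early frames and hence the fitted V_B. The pipeline
therefore checks the cavity-centre V_B of every gate against a 0.9 cutoff and
excludes failing gates from the V_B path; the FP path, which involves no
modelling, is immune and is always reported.

A digital beating-heart phantom (ellipsoidal LV cavity beating between ~148
and ~63 mL, perfused myocardial shell, static RV pool, gamma-variate bolus,
5-mm Gaussian PSF, post-blur Poisson noise) provides analytic ground truth for
every stage, including the cycle-loss artifact.

## Worked example

```python
import numpy as np
from fivedpet import PhantomConfig, generate_phantom, run_pipeline

series, truth = generate_phantom(PhantomConfig(seed=1))
print("true volumes (mL):", np.round(truth.true_volumes_ml, 1))
print(f"true LVEF: {truth.metrics.lvef:.1f} %")

report = run_pipeline(series, truth.inputs)
vb = report["vb"]["volume_based"]
print(f"V_B path: EDV {vb['EDV_mL']:.1f} mL, ESV {vb['ESV_mL']:.1f} mL, "
      f"SV {vb['SV_mL']:.1f} mL, LVEF {vb['LVEF_percent']:.1f} %")
```

prints

```
true volumes (mL): [147.8 132.2  99.3  72.4  62.8  72.4  99.3 132.2]
true LVEF: 57.5 %
V_B path: EDV 147.0 mL, ESV 61.4 mL, SV 85.6 mL, LVEF 58.2 %
```

i.e. on a default noisy phantom the blood-volume pipeline recovers EDV and ESV
to within ~2 % and LVEF to within ~1 percentage point of the ground truth.
The per-gate centre V_B values in `report["validity"]` all sit near 1.0, so
every gate passes the 0.9 validity cutoff; scaling the first-pass frames down
by 20 % (``apply_cycle_loss``) drops them to ≈0.81 and the V_B path is
aborted as an outlier while the FP path is unaffected.

The lower-level modelling interface follows the familiar model/results idiom:

```python
from fivedpet import SingleTissueModel
model = SingleTissueModel(series.gate(0), truth.inputs, series.schedule, series.grid)
res = model.fit()
print(res.summary())          # fit diagnostics and map statistics
vb_image = res.blood_volume() # DerivedImage, V_A + V_RV
```

A `fivedpet` CLI wraps the same steps
(`simulate | fit | derive | segment | metrics | run`).

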