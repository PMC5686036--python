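# Methods

## Kinetic model and its assumptions

Voxel dynamics follow the single-tissue-compartment model for a freely
diffusible, metabolically inert tracer, with two blood terms that double as
spill-over corrections:

    C_T(t) = PTF · MBF · C_A(t) ⊗ e^{−(MBF/V_T)·t} + V_A · C_A(t) + V_RV · C_RV(t)

Assumptions: the input functions C_A and C_RV are known (measured from
non-gated data or supplied by the phantom), identical for all gates, and
noise-free relative to the image data; all series are decay-corrected; tissue
is kinetically homogeneous within a voxel apart from the partial-volume
mixing that PTF absorbs. The partition coefficient V_T is fixed at
0.91 mL·g⁻¹ — it is not identifiable jointly with MBF from a single-tissue
fit at this noise level.

Units: MBF is kept in the conventional mL·g⁻¹·min⁻¹ while all time axes are
in seconds, so every exponent and flow factor uses MBF/60. With
MBF = V_T = 0.91 the washout rate is exactly 1 min⁻¹ (= 1/60 s⁻¹), which the
test suite asserts against the closed-form step response.

## Numerical scheme

The convolution C_A ⊗ e^{−kt} is evaluated on the input functions' uniform
fine grid (default 0.1 s) by an exact piecewise-linear recursion: over one
step the integral of a linear segment against the exponential kernel has a
closed form, so the whole curve is a first-order IIR filter
(`scipy.signal.lfilter`) with analytically derived taps, with the spurious
initial condition removed exactly. This is O(n), free of quadrature error
beyond the piecewise-linear input representation, and passes the
grid-refinement check (halving the step changes frame averages by < 0.1 %).
Frame averages are trapezoidal integrals of the fine curve interpolated at
the exact frame boundaries, divided by frame duration.

The basis grid is `numpy.geomspace(0.1, 2.2, 50)` with both endpoints
inclusive. For each grid value the weighted 3-coefficient least-squares
problem is solved through a precomputed pseudo-inverse, vectorised over all
voxels at once; ties in the residual scan resolve to the smaller MBF so the
fit is bitwise deterministic. Frames are equally weighted by default;
duration-proportional weights are available (`weights="duration"`), since the
acquisition's 5–30 s frames have very different count content.

Constraint handling: the least-squares solves are unconstrained (keeping the
estimator linear and the residual scan exact); afterwards V_A and V_RV are
clamped to [0, 1] and PTF to ≥ 0, and clamped voxels are flagged. Under
Poisson noise most near-empty voxels clamp at zero — the flag is a
diagnostic, not an error. A TAC that is identically zero returns an all-zero
fit rather than the smallest grid flow; a rank-deficient design flags the
voxel as failed. An alternative would be non-negative least squares per grid
value; it was rejected because it breaks the closed-form per-index solution
and the clamp changes no decision in any tested scenario.

## Derived images and volumetrics

V_B = V_A + V_RV and MBFt = MBF·PTF are voxelwise algebra on the fitted maps.
First-pass images select frames by midpoint within the window (default
10–50 s; 20–70 s provided for low cardiac output — with the standard
schedule the default window is exactly the eight 5-s frames) and sum them
duration-weighted by default, so unequal frame lengths contribute in
proportion to acquired counts; a plain sum is available by flag. Midpoint
inclusion and duration weighting are package choices where only the second
ranges are standard.

Segmentation thresholds at 0.5 × the cavity plateau, the plateau estimated as
the 99th percentile of positive voxels (robust to isolated noise spikes).
Half-maximum is the principled choice here: under a symmetric PSF the
half-maximum isocontour of a homogeneous object recovers the true boundary,
which is why the ellipsoid oracle lands within 2 % at 4-mm voxels and
converges under refinement. Among above-threshold connected components the LV
is the largest one whose mean V_A exceeds its mean V_RV when fitted maps are
available; without maps (pure FP usage) the largest component is taken. The
end-to-end pipeline passes the fitted maps when segmenting FP images too —
they serve only to disambiguate LV from RV; the FP volumes themselves remain
model-free. On real data the basal boundary (atrioventricular plane) has no
image support in a blood-pool image; the CLI exposes a basal-plane clip for
that, while the phantom has no atria so none is needed.

ED and ES are identified as the max/min of the gated volume (or count) curve
rather than fixed gate indices; with eight gates the sampling of the cycle is
coarse, which biases ESV slightly upward. The count-based ejection fraction
uses summed V_B inside the mask; on the blurred phantom it is systematically
≥ the volume-based value, matching clinical experience, and it yields no
EDV/ESV in mL. A surface-fitting volumetric method is deliberately out of
scope.

## Validity check for gated count loss

Gated rebinning discards cycles straddling frame boundaries; the resulting
deficit concentrates in the short first-pass frames and biases the fitted
blood fractions low while the input functions (from non-gated data) stay
correct. The check computes the mean V_B over the 7-voxel neighbourhood of
the cavity centre (an operational definition of "at the centre of the
cavity"; the one-voxel radius damps single-voxel noise) and flags gates below
0.9. A fraction exactly at the cutoff counts as valid. If fewer than two
gates survive, the V_B volumetric path is aborted with an "outlier" verdict
but the FP path is still computed and reported, since it is structurally
immune to this artifact.

## The phantom: what it emulates and what it does not

The generator emulates an eight-gate, 20-frame (1×10, 8×5, 4×10, 2×15, 3×20,
2×30 s) gated dynamic acquisition of a beating LV on a 64×64×32 grid of 4-mm
voxels. Geometry: an ellipsoidal cavity interpolating with a cosine weight
from 28×28×45 mm semi-axes at end-diastole (≈148 mL) to 21×21×34 mm at
end-systole (≈63 mL, true LVEF 57.5 %), a myocardial shell thickening from 10
to 14 mm over systole, and a static ellipsoidal RV pool (≈111 mL) — sized so
the RV pool is comparable to, and in systole larger than, the LV cavity, as
in real hearts. Cavity voxels have V_A = 1 (RV: V_RV = 1); shell voxels carry
MBF = 1.0 mL·g⁻¹·min⁻¹ and PTF = 0.6 g·mL⁻¹, representative resting values
inside the basis grid. The arterial input is a peak-normalised gamma-variate
(amplitude 80 kBq·mL⁻¹, delay 8 s, shape 4, decay 3 s — peak at 20 s, inside
the first-pass window) plus a small recirculation tail; the RV curve is the
same shape advanced by 4 s and scaled by 1.05.

Degradation: frames are blurred with a 5-mm-FWHM 3-D Gaussian (the
reconstruction post-filter; this is the sole source of partial-volume
effects) and then Poisson noise is applied to frame-mean values converted to
expected counts — `noise_scale` (default 50) counts per voxel at the AIF peak
in a reference 5-s frame, scaling linearly with frame duration. The
cycle-loss artifact is modelled as a uniform (1 − loss) scaling of chosen
frames (default: the first-pass frames) in every gate.

Not emulated: anatomy beyond ellipsoids (no atria, outflow tract or papillary
muscles), respiratory or rigid motion, attenuation/scatter, reconstruction
correlations (noise is independent per voxel post-blur), flow heterogeneity,
and input-function estimation error. Consequently, passing tests demonstrate
the correctness of the modelling, segmentation and bookkeeping chain and its
response to count loss — not robustness to segmentation ambiguity at the
atrioventricular plane or to correlated reconstruction noise, which on real
data are the dominant difficulties.

## Problem sizes and defaults used in the checks

End-to-end checks run the full 8-gate, 64×64×32 phantom (131 072 voxels per
gate, ~10 000 fitted above the 1 %-of-peak activity mask); unit and pipeline
tests use a 40×40×24 variant of the same phantom. Noisy recovery is assessed
at the default `noise_scale` over five seeds. All stochastic steps draw from
`numpy.random.default_rng` seeded explicitly; the acceptance script derives
all sub-seeds from its `--seed` argument.

## Known limitations

* MBF is quantised to the 50-value grid (≈6.5 % spacing); no parabolic
  refinement between grid points is attempted.
* Eight gates under-sample the volume curve, so ESV (hence LVEF) carries a
  small systematic bias even noise-free (~1–2 % here).
* The validity check needs a cavity-centre estimate; the automatic locator
  (argmax of the smoothed V_B of the first gate) assumes the LV is the
  dominant blood pool in the field of view.
* The cycle-loss model scales whole frames uniformly; real rebinning loss
  varies with heart-rate variability and frame phase.
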