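# Methods

## Coflow viscometry model

The viscosity-sensing channel carries the test blood stream (flow
`Q_b − Q_ac`) and the reference stream (`Q_r`, viscosity `μ_r`, default
1.0 cP for 1× PBS at 25 °C — the standard handbook value, configurable in
the `fluids` section) side by side. Under the virtual-wall approximation the
two streams are parallel resistive conduits with equal pressure drop, which
yields

μ_b = μ_r · α_b/(1 − α_b) · Q_r/(Q_b − Q_ac) · C_f(α_b).

`C_f` is a calibrated quartic in the normalized interface position; it is a
fit, so evaluation outside its validity domain [0.05, 0.95] is an error,
never a clamp-and-continue. The gain g(α) = α/(1 − α)·C_f(α) is strictly
increasing on that domain (asserted by dense sampling at 10⁻³ steps), so the
forward interface model — the α_b produced by a given viscosity ratio and
flow pair — is the unique root of g and is found by bisection (robustness
over speed; relative residual tolerance 10⁻¹⁰, interval refined to ~10⁻¹⁶,
giving a viscosity↔interface round trip tight to 10⁻⁹ relative).

Channel resistances use the single-term aspect-corrected form
R = 12 μ L / (w h³ (1 − 0.63 h/w)); at the chip's aspect h/w ≤ 0.05 the
truncation error versus the full series is below 1 %, and the network is
only used to set synthetic flow splits. The default ac/vc junction split is
the measured blood value, Q_ac/Q_b = 5 %; the chip drawing does not fully
determine which segments form each branch, so the split is calibrated rather
than computed ab initio (a 7.3 % preset covers the pure-fluid case). Shear
rates use the low-aspect formula γ̇ = 6Q/(wh²), with the blood stream's
width reduced to α_b·w in the sensing channel. Internal canonical units are
mm, s and cP; mL/h is converted at the API boundary (1 mL/h = 1000/3600
mm³/s).

## Synthetic chip renderer

The generator emulates, per one-second trigger: (1) the delivered hematocrit
Hct(t) = Hct₀(1 + a·A·(1 − e^(−s(t)/τ))), where the sedimentation clock s(t)
advances at rate 1 while the pump delivers and κ ≥ 1 while it is off —
syringe settling continues (faster, undisturbed) during no-delivery waiting
periods; (2) a phantom viscosity μ = μ_medium(C_dex)·(1 − Hct/0.98)^(−2.5)
(Krieger–Dougherty-type divergence; medium viscosity linear in dextran at
0.075 cP per mg/mL, so 20 mg/mL gives 2.5 cP), overridable by a fixed value
for Newtonian surrogates; (3) the equilibrium interface from the inverted
coflow model; (4) plug velocities U = Q/(wh) — rendering is depth-averaged
by construction, matching what correlation velocimetry measures in a 50 µm
deep channel, so the ground-truth velocity is a scalar; (5) an aggregation
intensity deficit δ = 0.6·a·f_dex(C_dex)·(1 − Hct)·g(γ̇_ac), with f_dex
unimodal peaking at 15 mg/mL and g halving at 100 s⁻¹, clipped to [0, 0.5].

Frames are 8-bit, 760 × 400 px at 5 µm/px (the 1 mm channel spans 200 px;
the 1.8 mm² ROIs are 360 × 200 px; the pixel scale is an assumption recorded
in config, chosen for sub-minute rendering). Chambers are drawn at
I₀ − β·Hct (defaults I₀ = 220, β = 120) with dark Gaussian tracer speckle
(1000 mm⁻², σ = 1.2 px, amplitude 40 — about four tracers per 13 px window)
advected by u·Δt between the two frames of each burst; the whole aggregation
band, tracers included, is scaled by (1 − δ), so the ground-truth AI equals
δ exactly; the coflow band switches from blood to reference intensity at row
round(α_b·200). Gaussian camera noise is added last and intensities are
clipped to [0, 255]. During off phases particles do not move, the interface
stays frozen at its last delivering position, and a slow stasis darkening of
the main chamber (time constant 30 s toward the zero-shear deficit) emulates
aggregation at rest. Two frames per burst at Δt = 1 ms is the minimal PIV
pair and the storage-cheapest faithful rendering of a 1000 fps burst.

What the phantom does **not** model: optical PSFs, individual cells or
aggregate morphology, in-chip settling, gravity or 3-D interface shape, or
non-Newtonian rheology — synthetic blood is Newtonian at each instant, so
closed-loop tests validate the measurement chain, not constitutive blood
behaviour. The sedimentation amplitude A (default 0.2) is set for
qualitative realism (a monotone viscosity rise over tens of minutes), not to
reproduce any particular specimen.

## Velocimetry

Interrogation windows are derived from the physical 67 µm window (13 px at
5 µm/px, rounded odd), tiled with 50 % overlap. Each window pair is compared
at every lag up to half a window by the zero-mean normalized
cross-correlation computed over the actual overlap region (template-matching
normalization, evaluated with FFT cross-correlation plus integral-image
sums). This normalization matters twice: an exact integer shift scores
exactly 1 and is therefore always the global peak, and the loss-of-pairs
taper — which biases an unnormalized peak toward zero by
σ²_peak/(N − d) ≈ 0.2 px, i.e. a ~20 % speed underestimate at these
displacements — cancels. A perfect integer match (coefficient ≥ 1 − 10⁻⁹)
short-circuits the subpixel stage, making integer displacements exact;
otherwise a three-point Gaussian fit (parabolic fallback for non-positive
triplets) refines each axis independently, giving ≲0.03 px accuracy on
noiseless speckle.

Validation flags a vector when it deviates from its 3×3 neighbourhood median
by more than 2 × (median neighbour residual + 0.1 px) (applied only when at
least three valid neighbours exist) or lies outside the global mean ± 3 SD
of speeds. Invalid vectors are excluded from ROI averages, never
interpolated — averaging is the only consumer. The ROI mean uses the
magnitude of the mean displacement vector: for the uniform ROI flows
measured here this is the unbiased estimator, whereas averaging per-vector
magnitudes rectifies zero-mean noise into a spurious positive speed at the
aggregation channel's near-zero displacement (~0.06 px/frame). A
mean-of-magnitudes mode remains available (`method="magnitude"`). Single
pass, no window deformation: the flows are uniform inside the ROIs.

## Photometry and interface

Intensities are ROI means on raw frames. Background subtraction (first
trigger frame by default, explicit file overridable — whether the reference
background should be cell-free or the first flowing frame is genuinely
ambiguous, so both are supported) keeps the signed difference. The
aggregation index is computed on raw intensities by default: AI =
(I_mc − I_ac)/I_mc is scale-sensitive, and background subtraction can push
the denominator toward zero; the subtracted mode exists behind a flag with a
|I_mc| > 10 guard. Otsu thresholding is computed over the 256-bin histogram
of the vc ROI only (chamber content cannot shift it), maximizing
between-class variance with ties broken toward the lower threshold; the
blood class is the lower-mean class, not a spatial side, so the chip may be
mounted either way. The blood-filled width is the column-wise count of blood
pixels along the cross-channel axis, averaged over columns — accurate to the
1 px quantization of the rendered interface (0.005 mm).

## Time-series rheology

The plateau velocity ⟨U_mc⟩ is the mean over the longest contiguous run
(earliest on ties, ≥ 10 % of samples) where the centred rolling CV (window
10 % of the series) stays below 5 %; the earliest qualifying run is
preferred because in sedimenting blood later epochs drift. Flow-rate
calibration Q = U/⟨U_mc⟩·Q_b cancels any multiplicative PIV bias by
construction, so no bias correction is applied in the velocimetry itself.
The viscosity series applies the coflow formula per trigger with the
calibrated Q_mc − Q_ac; triggers with invalid interface, failed PIV or
non-positive blood stream yield NaN, never interpolation. AI_max, the
representative aggregation value, is the maximum of an 11-trigger
edge-truncated moving average (window 1 recovers the plain maximum). The
conventional stopped-flow AI is an endpoint ratio,
(I(t_stop) − I(t_stop+120 s))/I(t_stop) with I(t_stop) the mean of the first
five samples after the stop — the classical syllectometric definitions vary
between instruments, so this variant is documented rather than claimed
canonical. ND = |measured − expected|/|expected| × 100 with the theoretical
value in the denominator; COV is the sample SD over the mean; R² of a
constant-response fit is reported as 0 with a warning.

## Problem sizes and verification

Closed-loop tests run 24-trigger datasets over a grid of viscosity ratios
{1.5, 3, 6} × noise σ {0, 3, 5}; the acceptance script runs 60-trigger
datasets (one noiseless at 2.569 cP, four at 1.76–6.00 cP with σ = 3)
through full TIFF round trips. Observed recovery on these conditions:
viscosity within ~0.3 % (noiseless) and ~3 % (σ = 5) of ground truth per
trigger, AI within 0.01 absolute, interface within 1 px. These sizes are the
package's validation conditions; larger runs scale linearly.

## Known limitations

- The correction factor is calibrated on Newtonian fluids; applying it to
  shear-thinning blood introduces a systematic error the method cannot see.
- The phantom's sedimentation amplitude and hematocrit–viscosity curve are
  plausible, not donor-calibrated; passing closed-loop tests demonstrates
  the measurement chain, not biological fidelity.
- No depth-of-correlation modelling: velocities are treated as
  depth-averaged, consistent with the shallow-channel optics but untested
  against 3-D flow profiles.
- The reduced 0.9 mm² aggregation ROI used when cells crowd the upper
  channel region is exposed as configuration, never triggered automatically.
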