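# hemoflow

Image-based microfluidic viscometry and red-blood-cell (RBC) aggregation
analysis for coflow chips, with a physics-based synthetic-chip renderer for
ground-truthed validation.

## The problem

Hemorheology — blood viscosity and RBC aggregation — shifts with disease,
transfusion storage and thermal damage, but the two properties are usually
measured separately, and most microfluidic aggregometers require stopping the
flow. A three-channel chip solves both at once under continuous syringe
delivery: blood passes a high-shear **main chamber** (mc), a small fraction
branches into a low-shear **aggregation-sensing chamber** (ac) where rouleaux
form and darken the image, and the rest coflows against a reference fluid
(1× PBS) in a **viscosity-sensing channel** (vc). Timelapse frame bursts
(1000 fps pairs, triggered every second) then yield, per trigger:

- depth-averaged velocities `U_mc`, `U_ac` by micro-PIV (windowed
  cross-correlation, 67 µm interrogation windows, 50 % overlap, Gaussian
  subpixel peak fit, median/SD vector validation);
- chamber intensities `I_mc`, `I_ac` and the continuous aggregation index
  `AI = (I_mc − I_ac) / I_mc`;
- the Otsu-binarized blood-filled width `w_b` and normalized interface
  `α_b = w_b / w`.

## The model

Treating the coflow interface as a rigid "virtual wall" splits the sensing
channel into two parallel resistive conduits with a common pressure drop
(ΔP_r = ΔP_b), giving the test-fluid viscosity

```
μ_b = μ_r · α_b/(1 − α_b) · Q_r/(Q_b − Q_ac) · C_f(α_b)
```

where `C_f(α_b) = −12.038 α_b⁴ + 26.171 α_b³ − 20.770 α_b² + 7.156 α_b +
0.014` is an empirically calibrated correction factor (valid on
α_b ∈ [0.05, 0.95]) for a 1 mm × 0.05 mm channel. Flow rates are calibrated
from PIV through the plateau velocity, `Q_mc = U_mc/⟨U_mc⟩·Q_b`, which
cancels any multiplicative velocimetry bias. The blood-stream shear rate is
`γ̇ = 6(Q_b − Q_ac)/(α_b w h²)`.

The synthetic-data module renders the whole chip forward — syringe
sedimentation raising the delivered hematocrit, a hematocrit/dextran phantom
viscosity, the equilibrium interface from the inverted coflow model, tracer
speckle advected between burst frames, aggregation-induced intensity
deficits, and camera noise — and writes a ground-truth manifest, so every
analysis stage is verifiable in closed loop without laboratory data.

## Worked example

```python
from hemoflow.cli_pipeline import newtonian_config, simulate_and_analyze
import numpy as np

# a Newtonian test fluid of 2.569 cP against 1.0 cP PBS,
# Qt = 1.0 mL/h vs Qr = 2.5 mL/h, 24 one-second triggers, noiseless
cfg = newtonian_config(2.569, seed=42, n_triggers=24)
manifest, timeseries, rheology, summary = simulate_and_analyze(cfg)
print(round(timeseries["alpha_b"].iloc[0], 3))      # 0.515
print(round(summary["plateau_Umc_mm_s"], 2))        # 5.56
print(round(summary["median_mu_b_cP"], 2))          # 2.57
print(round(float(np.nanmedian(rheology["shear_s1"])), 0))  # 1229.0
```

The interface settles at α_b ≈ 0.515 (the unique root of the coflow model
for this viscosity ratio and flow split), the plateau velocity matches the
plug-flow value Q/(wh) = 5.56 mm/s, and the recovered median viscosity is
within 1 % of the 2.569 cP ground truth.

The same pipeline runs from the shell on files:

```bash
hemoflow simulate  --config run.yaml --out sim/
hemoflow analyze   --config run.yaml --tiff sim/stack.tif --out results/
hemoflow roundtrip --config run.yaml --out rt/
```

outputs: a channel time-series CSV (`t, Umc, Uac, n_valid_mc, n_valid_ac,
Imc, Iac, wb, alpha_b`), a rheology CSV (`t, Qmc_mLh, Qac_mLh, Qvc_mLh,
mu_b_cP, shear_s1, AI`), a summary JSON (plateau, AI_max, COV, counts) and,
for roundtrips, a machine-readable recovery report.

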