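# xpiv — X-ray particle image velocimetry of opaque flows

`xpiv` measures blood-flow velocity fields in vessels that cannot be imaged
optically. Microbubble tracers in X-ray projection images form a speckle
pattern; two-frame cross-correlation of that speckle yields displacement
fields, and a line-of-sight (*amassed*) velocity-profile model inverts them
into the true centreline velocity, the profile bluntness, and the volumetric
flow rate. The package is aimed at experimentalists working with
synchrotron/phase-contrast projection imaging of deep vessels (rodent aorta,
vena cava) where surrounding tissue attenuates contrast so strongly that raw
images are unusable for PIV.

## The method

**Restoration.** Raw frames carry a large static transmission pedestal,
illumination nonuniformity, and detector/intensifier noise. `restore()` runs
flat-field correction, background elimination (subtracting the pixelwise mean
of a window of consecutive frames, 100 by default), and a Gaussian-edged
spatial-frequency band-pass.

**Quality metrics.** Speckle contrast `C = σ(I)/⟨I⟩`; speckle size = FWHM of
the central lobe of the ensemble-averaged normalized autocovariance
(Wiener–Khinchin); and the accuracy surrogate `SR = P_c · C`, where `P_c` is
the peak of the zero-normalized cross-correlation map. Measurements are
considered reliable when `P_c ≥ 0.5`.

**PIV.** Tiled interrogation windows (default 32 × 64 px, long axis along
flow, 50% overlap), ZNCC with loss-of-pairs normalization, three-point
Gaussian sub-pixel localization with overlap-envelope bias correction, the
normalized-median outlier test, and ensemble averaging over (by default) 200
instantaneous fields.

**Profile inversion.** A projection image averages an axisymmetric profile
`u(r) = V_max (1 − (r/R)^K)` along each chord, giving the amassed profile
`v(x) = V_max · α(|x−x0|/R, K)` with
`α(ξ,K) = 1 − (1/√(1−ξ²)) ∫₀^√(1−ξ²) (ξ²+η²)^{K/2} dη`
(`α(0,K) = K/(K+1)`; `α(ξ,2) = ⅔(1−ξ²)`). `AmassedProfileModel(x, v).fit()`
performs bounded nonlinear least squares for `(V_max, K, x0[, R])` and reports
the flow rate `Q = V_max π R² K/(K+2)`. Bubble buoyancy is removed by
subtracting the Stokes terminal velocity `v_t = Δρ g d²/(18 μ)`
(≈ 0.043 mm/s for 13.3 μm CO₂ bubbles in blood).

**Synthetic scenes.** `generate_sequence(SceneConfig(...), n)` renders seeded,
ground-truth-known image stacks — bubbles advected through a cylindrical
vessel behind static tissue-like texture, with illumination gradients and
sensor noise — so the whole chain is testable without beamline data.

## Worked example

```python
import numpy as np
from xpiv import (SceneConfig, RunConfig, PivConfig, run_pipeline)

scene = SceneConfig(frame_shape=(256, 256), vessel_radius=200.0,
                    vessel_center_row=128, v_max=5.0, bluntness_k=3.31,
                    bubble_count=2000, seed=7)
run = RunConfig(scene=scene, n_frames=400, ensemble_size=200, seed=7,
                piv=PivConfig(window_size=(16, 32), max_displacement=(6, 10)))
result = run_pipeline(run)
print(f"raw C = {result.speckle_raw.contrast:.3f}, "
      f"restored C = {result.speckle_restored.contrast:.3f}")
fit = result.profile_fit
print(f"K = {fit.k:.2f}  V_max = {fit.v_max:.2f} mm/s  "
      f"Q = {fit.q_ml_min:.4f} mL/min")
```

prints

```
raw C = 0.112, restored C = 0.187
K = 3.02  V_max = 5.10 mm/s  Q = 0.0232 mL/min
```

The ground truth here is `K = 3.31`, `V_max = 5 mm/s`: restoration raises the
speckle contrast of the deep-vessel stack by ~70%, and the inversion recovers
the bluntness index within ~9% and the centreline velocity within 2% for this
seed. The flow rate corresponds to `Q = V_max π R² K/(K+2)` for the
200 μm-radius vessel.

The same steps are available from the shell:

```bash
xpiv simulate --config run.yaml --frames 400 -o stack.tif
xpiv preprocess stack.tif --config run.yaml -o restored.tif
xpiv metrics restored.tif -o metrics.json
xpiv piv restored.tif --config run.yaml -o field.csv
xpiv profile field.csv --radius-um 200 -o fit.json
xpiv sweep --config run.yaml -o sweep.json     # P_c vs displacement ladder
```

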