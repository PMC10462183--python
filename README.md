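# glycoscope

Quantitative analysis of how cells build and remodel their glycocalyx — the
carbohydrate-rich coat on the cell surface — and of the metabolic state that
feeds it. The package implements three computations used together in
glycobiology / mechanobiology studies:

1. **SAIM height reconstruction.** Scanning-angle interference microscopy
   localizes fluorophores axially above a silicon/oxide mirror with nanometre
   precision. Pixel intensity versus incidence angle follows
   `I_j = A·f(θ_j, H) + B` with
   `f = |1 + r_TE e^{iφ}|²`, `φ = (4π/λ) n_b H cos θ_b`, and `r_TE` the TE
   reflection coefficient of the buffer/oxide/silicon stack from its
   characteristic matrix. `glycoscope` fits `(H, A, B)` per pixel by
   separable nonlinear least squares and reports glycocalyx thickness as the
   mean dye-layer height minus the mean fibronectin-layer height over a
   100×100-pixel subregion per cell.
2. **Phasor-FLIM bound-NADH fraction.** Fluorescence decays map to phasor
   coordinates `G = ΣI cos(ωt)/ΣI`, `S = ΣI sin(ωt)/ΣI`; after calibration
   against a mono-exponential standard (Coumarin 6, τ = 2.5 ns), the bound
   fraction `FB` of NADH is each pixel's position along the chord between
   the free- and bound-NADH reference phasors, summarized per mitochondrial
   and cytosolic compartment.
3. **¹³C isotopologue arithmetic.** From LC-MS isotopologue ladders
   `M₀..Mₙ`: relative amount `= ΣMᵢ` and fractional contribution
   `FC = Σ i·Mᵢ / (n ΣMᵢ)`, with per-sample normalization to protein and
   cell number.

A seeded synthetic-data module generates angle stacks, decay cubes, and
isotopologue tables with known ground truth, so every stage is testable end
to end without instrument data. See `docs/methods.md` for models,
assumptions, and limitations.

## Worked example

Simulate a dye layer at 65 nm and a fibronectin reference at 5 nm over a
standard chip (~1900 nm oxide, 32 angles from 5° to 43.75°, Poisson shot
noise at ~10⁴ counts/pixel), reconstruct both, and quantify thickness:

```python
import numpy as np
from glycoscope import (OpticalStackConfig, default_angle_grid,
                        fit_stack, quantify_thickness)
from glycoscope.simulate import simulate_saim_stack

cfg = OpticalStackConfig(wavelength_nm=560, n_buffer=1.335, n_oxide=1.460,
                         n_silicon=4.042 + 0.032j, d_oxide_nm=1900)
grid = default_angle_grid()          # 32 angles, 5 to 43.75 degrees
dye = simulate_saim_stack(np.full((100, 100), 65.0), 8000, 500, cfg, grid,
                          noise="poisson", seed=1)
ref = simulate_saim_stack(np.full((100, 100), 5.0), 8000, 500, cfg, grid,
                          noise="poisson", seed=2)
res = quantify_thickness(fit_stack(dye, cfg), fit_stack(ref, cfg),
                         [("cell1", 0, 0)], size=100)[0]
print(res)
```

```
ThicknessResult(roi_id='cell1', mean_height_dye_nm=65.00000167243299,
                mean_height_reference_nm=4.9999687463467914,
                thickness_nm=60.00003292608619, n_pixels_used=10000)
```

The dye and reference layers are recovered at 65.000 and 5.000 nm and their
difference — the glycocalyx thickness — at 60.000 nm from the true 60 nm;
all 10 000 subregion pixels passed the fit-quality mask.

The same workflows run from the shell:

```bash
glycoscope sim saim --pattern flat --base-height-nm 65 --out sim_dye/
glycoscope saim-fit --stack sim_dye/stack.tif --angles sim_dye/angles.txt \
                    --config optics.toml --out fit_dye/
glycoscope saim-thickness --dye fit_dye/height_nm.tif --ref fit_ref/height_nm.tif \
                          --rois rois.csv --size 100 --out thickness.csv
glycoscope flim-phasor --decay decay.tif --binwidth-ns 0.195 --rep-mhz 80 \
                       --calib tau=2.5:g=0.21:s=0.55 --out phasor/
glycoscope metab-fc --in areas.csv --out fc.csv
```

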