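# cellflim

Cell-encircled fluorescence-lifetime analysis for adaptive-optics
ophthalmoscopy of the retinal pigment epithelium (RPE).

Adaptive-optics FLIM resolves single RPE cells in vivo and records a TCSPC
photon-arrival histogram per pixel. Per-pixel decay fits are starved for
photons; this package implements the alternative of summing every photon
inside a segmented cell into one histogram per cell before analysis, and
everything needed around that idea:

* **flim_core** — data model and I/O: TCSPC cubes (HDF5 or multi-frame
  TIFF + JSON calibration sidecar), 16-bit label masks (TIFF/PNG),
  per-cell CSV result tables.
* **cellwise** — outline→label conversion, per-cell aggregation with
  border and edge-cell exclusion, mask perturbations (shift, 90°
  rotation), the kernel-pooling pixel-wise baseline, and pixel→µm² area
  conversion via axial length.
* **decayfit** — bi-exponential decay model (periodic wrap at 80 MHz,
  Gaussian IRF) fitted by Poisson maximum likelihood with deterministic
  multi-start; reduced χ², 300-photon threshold.
* **phasor** — phasor transform `g = Σk cos(ωt)/Σk`, `s = Σk sin(ωt)/Σk`
  at the laser repetition frequency, mixtures and summaries.
* **statkit** — two-way mixed-effects ICC (consistency and agreement),
  absolute/percent differences, one-way and repeated-measures/mixed
  ANOVA, Holm–Bonferroni-corrected t-tests, two-group sample size,
  linear trends.
* **synth_retina** — photon-level synthetic AOFLIO generator (Voronoi RPE
  mosaics, per-cell lifetime truths, Poisson rendering, visit pairs) used
  to validate the pipeline end-to-end.
* **cellkit** — a CLI tying it together.

The model at the core: per-cell expected counts
`m_i = N·[a1·w(t_i;τ1) + a2·w(t_i;τ2)] + b` with `a1 + a2 = 1`, fitted by
maximizing `Σ k_i ln m_i − m_i`; the weighted mean lifetime is
`τm = a1τ1 + a2τ2`, and the phasor is the first Fourier harmonic of the
raw histogram. See `docs/methods.md` for the full account.

## Worked example

Simulate a small acquisition, aggregate, fit and compare the two analysis
styles:

```bash
cellkit simulate --seed 7 --size 200 --photons bright \
        --out sim.h5 --mask-out mask.tif --truth-out truth.csv
cellkit aggregate --cube sim.h5 --mask mask.tif --out cells.csv
cellkit fit --cells cells.csv --out fits.csv
cellkit phasor --cells cells.csv --out phasor.csv --summary-out summary.csv
```

The same pipeline from Python:

```python
import numpy as np
from cellflim import (TimingCalibration, MosaicSpec, PALETTES,
                      generate_mosaic, assign_cell_truth, render_cube,
                      aggregate_cells, fit_biexponential,
                      phasor_from_histogram)

calib = TimingCalibration()                  # 80 MHz, 256 bins, 12.5 ns
spec = MosaicSpec.native_crop(200, seed=7)   # 200 px crop, ~0.81 um/px
mask, geometry = generate_mosaic(spec)
truths = assign_cell_truth(mask, PALETTES["532LSC"], seed=8,
                           photons_per_cell=1e4)
cube = render_cube(mask, truths, calib, seed=9)

cells = aggregate_cells(cube, mask)          # drops frame-cut cells
fit = fit_biexponential(cells[0].histogram, calib)
ph = phasor_from_histogram(cells[0].histogram, calib)
print(f"cells analyzed: {len(cells)}")
print(f"cell {cells[0].label}: tau1 {fit.tau1_ps:.0f} ps, "
      f"tau2 {fit.tau2_ps:.0f} ps, a1 {fit.a1:.2f}, "
      f"tau_m {fit.tau_m_ps:.0f} ps, chi2r {fit.chi2_reduced:.2f}")
print(f"phasor: g {ph.g:.3f}, s {ph.s:.3f}")
```

Output:

```
cells analyzed: 101
cell 14: tau1 153 ps, tau2 856 ps, a1 0.79, tau_m 304 ps, chi2r 1.03
phasor: g 0.903, s 0.248
```

That cell's simulated truth is τ1 143 ps, τ2 852 ps, a1 0.78: the fit
recovers it to within a few percent at 10⁴ photons. χ²r ≈ 1 says the
Poisson model accounts for the residuals, and (g, s) sits inside the
universal semicircle, as any multi-exponential decay must. Here a1 is the
*amplitude* weight of the short component, so τm = a1τ1 + a2τ2 is the
amplitude-weighted mean lifetime.

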