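# Methods

## The measurement this package models

Adaptive-optics fluorescence-lifetime ophthalmoscopy (AOFLIO) resolves
individual retinal pigment epithelium (RPE) cells in vivo and records, for
every pixel of a ~1.4° field, a time-correlated single-photon counting
(TCSPC) histogram of photon arrival delays relative to the excitation pulse
(80 MHz repetition rate, so one period is 12.5 ns). Autofluorescence decays
of RPE granules are well described by a sum of two exponentials; per-pixel
photon counts, however, are low, which makes per-pixel (or small-kernel)
fits noisy.

The *cell-encircled* analysis implemented here sums all photons inside one
segmented cell into a single decay histogram before any fitting. Cells are
delineated by single-pixel hand-drawn (or synthetic) borders encoded as
label 0 in a label image; border pixels belong to no cell, so no photon is
counted twice, and cells touching the outermost pixel ring are excluded as
partially outside the field. The traditional baseline, retained for
comparison, pools a k×k (default 7) kernel around every pixel.

## Decay model and fitting

The decay is `a1·e^(−t/τ1) + a2·e^(−t/τ2)` with *amplitude* weights
`a1 + a2 = 1` — the convention under which the printed mean lifetime
`τm = a1·τ1 + a2·τ2` is the amplitude-weighted mean. Component *i* then
contributes the photon fraction `φ_i = a_i·τ_i / (a1·τ1 + a2·τ2)`, and the
expected counts in bin *i* (bin centers `t_i = (i + 0.5)·Δt`) are

    m_i = N · [ φ1·w(t_i; τ1) + φ2·w(t_i; τ2) ] + b

where `w(t; τ)` is the mono-exponential profile periodically wrapped at the
laser period, circularly convolved with a Gaussian instrument response
function (IRF), and normalized to unit sum; `N` is the total signal photon
count and `b` a constant background per bin, so `Σ m_i = N + n_bins·b`
exactly. Because the wrap multiplies the exponential by a constant on one
period, the normalized no-IRF profile is simply `e^(−t/τ)/Σ e^(−t/τ)`.
The amplitude-vs-photon distinction matters: for τ1 = 150 ps, τ2 = 900 ps,
a1 = 0.75, the amplitude-weighted τm is 338 ps while the photon-weighted
mean would be 650 ps.

Counts are Poisson, so parameters maximize the Poisson log-likelihood
`Σ k_i ln m_i − m_i`. The optimizer is L-BFGS-B on
`(ln τ1, ln τ2, φ1, ln N, b)` — the photon-fraction parameterization is
better conditioned — with analytic gradients; multi-start is
deterministic: the negative log-likelihood is screened on a 4×4 log-spaced
(τ1, τ2) grid and the best `n_starts` (default 4) candidates are refined.
Results are canonicalized to `τ1 ≤ τ2` with the fitted `φ` converted
exactly back to the amplitude weight `a1`; `τm = a1·τ1 + a2·τ2` is
attached. Goodness of fit is the Pearson reduced χ² over bins with model
expectation ≥ 1 photon (the statistic is unstable at near-zero
expectation).

Key settings (`FitConfig`):

| parameter | default | meaning |
|---|---|---|
| `min_photons` | 300 | histograms below this are rejected, not fitted |
| `tau_bounds_ps` | (10, 12000) | optimizer bounds on both lifetimes |
| `irf_fwhm_ps` | 120 | Gaussian IRF FWHM; `None` disables convolution |
| `fit_background` | True | fit a constant offset (dark counts) |
| `fit_from_peak` | False | with no IRF, fit only bins after the peak (tail fit) |
| `n_bins` (calibration) | 256 | one 12.5 ns period, 48.83 ps bins |

The 256-bin default is a common TCSPC configuration (≥ 5 bins per 300 ps
lifetime); the bin count of the original acquisitions is not fixed by the
data model, and all code takes it from the calibration. `a1` is an
amplitude fraction (not a photon fraction), matching the τm formula above.

## Phasor analysis

The phasor of a histogram is computed on the *raw* counts, no fitting and
no IRF correction: with `ω = 2π·f_rep` (first harmonic by default) and bin
centers `t_i`,

    g = Σ k_i cos(ω t_i) / Σ k_i ,   s = Σ k_i sin(ω t_i) / Σ k_i .

Mono-exponential decays lie on the universal semicircle `g² + s² = g`
(closed form `g = 1/(1+(ωτ)²)`, `s = ωτ/(1+(ωτ)²)`), and photon-weighted
mixtures combine linearly — both relations serve as analytic oracles in the
tests. No reference-dye calibration is applied by default, matching the
raw-transform definition. Bin centers (not edges) are used as the time
coordinate; with symmetric binning this leaves the first-harmonic phase
unbiased, and the discretization error at 256 bins is below 1e-3 in g and s
for lifetimes in the 0.1–3 ns range.

## Statistics

* **ICC** — single-measure two-way mixed-effects intraclass correlation,
  computed from the mean squares of the complete two-way decomposition:
  consistency `(MSR−MSE)/(MSR+(k−1)MSE)` and absolute agreement
  `(MSR−MSE)/(MSR+(k−1)MSE+k(MSC−MSE)/n)`. Interpretation bands: < 0.5
  poor, 0.5–0.75 moderate, 0.75–0.9 good, ≥ 0.9 excellent; an ICC whose
  F-test (`F = MSR/MSE`) has p > 0.05 is reported as "ns".
* **Paired differences** — per unit `|x1−x2|` and `100·|x1−x2|/pair mean`
  (the symmetric denominator), with sample SDs; zero-mean pairs are
  excluded from the percent statistic with a warning.
* **ANOVA** — fixed-factor one-way F from the between/within mean squares;
  repeated-measures and mixed designs (channel within subject,
  eccentricity between) delegate to pingouin after complete-case filtering.
* **Multiple comparisons** — unpaired pooled-variance t-tests with
  step-down Holm–Bonferroni: the i-th smallest p is tested against
  `α/(m−i+1)`; adjusted p-values are the running maximum of
  `(m−i+1)·p_(i)`, capped at 1. For 6 pairwise tests at α = 0.05 the
  smallest threshold is 0.05/6 ≈ 0.008.
* **Sample size** — normal approximation
  `n = ⌈2·(z_(1−α/side) + z_power)²·(σ/δ)²⌉`, both sidedness variants. The
  published per-group counts for the decade-apart phasor difference
  (δ = 0.013) are not all reproducible from any single standard two-group
  formula: the one-sided form reproduces the pixel-wise g value (27 at
  σ = 0.019) but not its companions. Both variants are exposed and the
  discrepancy is left as documented rather than matched.
* **Area conversion** — pixel areas scale to retinal µm² via
  `µm/px = (FOV/px)·291·(AL/24.46)` with axial length AL in mm; 291 µm/deg
  at the 24.46 mm reference eye is the standard emmetropic convention, and
  the constant is configurable.

## Synthetic AOFLIO generator

No AOFLIO datasets are publicly deposited, so validation is end-to-end
against a photon-level simulator with full ground truth:

* **Mosaic** — Voronoi tessellation of a jittered hexagonal lattice
  (jitter fraction 0.35 of the spacing), single-pixel borders set to
  label 0. The default field is 500 px per 1.4° (0.815 µm/px at the
  reference eye) with a 220 µm² mean-cell-area target, the scale observed
  in vivo. Small test images are *native-resolution crops*
  (`MosaicSpec.native_crop`): the field of view shrinks with the pixel
  count so cells stay ~330 px. Downscaling the whole field instead would
  make cells smaller than the 7-px comparison kernel and invert the
  kernel-versus-cell geometry of the real acquisition.
* **Per-cell truth** — τ1, τ2 and the amplitude weight a1 drawn per cell
  from a channel palette (normal, clipped to physical ranges), optionally
  shifted linearly with eccentricity and age. Default palettes:
  765 nm-excitation-like (τ1 150 ± 6 ps, τ2 1000 ± 40 ps, a1 0.80 ± 0.015)
  and 532 nm-like (τ1 150 ± 6 ps, τ2 900 ± 40 ps, a1 0.75 ± 0.015). The
  means are plausibility values, not fitted to any dataset. The
  cell-to-cell SDs are sized to the per-image phasor spread reported for
  cell-encircled analysis in vivo (between-cell SD of g ≈ 0.01): this
  single choice
  reproduces the observed repeatability structure — phasor ICC in the
  excellent tier at realistic cell photon counts (~10⁴), phasor ahead of
  the component lifetimes at ~10³ photons — and the variance-reduction
  contrast against kernel pooling. A much larger spread would make phasor
  ICC excellent even at 10³ photons per cell, but then the 7-px kernel's
  spatial smoothing of the between-cell field would rival kernel shot
  noise and the cell-versus-pixel SD contrast would become unstable;
  these two regimes cannot be combined in one palette.
* **Rendering** — each interior pixel receives its cell's normalized decay
  (Gaussian IRF FWHM 120 ps, periodic wrap) scaled by the cell brightness
  (photons-per-cell budget / interior pixels, log-normal cell-to-cell
  variation CV 0.1). A central disk of radius 0.3× the equivalent cell
  radius is dimmed to 0.3× brightness, reproducing the bright-border /
  dark-interior appearance of RPE cells; border pixels carry background
  only. Counts are independent Poisson draws per pixel and bin,
  reproducible from a seed. Photon presets: "bright" (10⁴/cell) and
  "threshold" (350/cell, straddling the 300-photon rule).
* **Visit pairs** — two independent Poisson realizations of the same truth
  emulate forward/backward resonant-scanner sweeps; test–retest mode adds
  an optional mask shift and per-visit brightness factor. No scanner
  distortion is modeled, so paired sweeps differ only in shot noise.

**What the simulator does not emulate** — optical blur and residual
aberrations, eye motion and registration error, within-cell fluorophore
gradients, IRF drift or mismatch between acquisition and fit, detector
afterpulsing, and autofluorescence from layers other than the RPE. Passing
tests therefore demonstrate correctness of the analysis pipeline under the
stated photon and mosaic statistics, not robustness to those instrumental
effects; in particular real exponential-fit repeatability is likely worse
than the simulated one at matched photons.

## Problem sizes used in validation

The validation suite runs the full pipeline at desk scale: 200–300 px
native-resolution crops (≈100–230 analyzable cells), 100-fit recovery
batches, and 30–50 replicate power runs with 2×100 cells. The
eccentricity-power check uses a τ1 shift of one cell SD between 0° and 12°
at the bright photon preset. These sizes give Monte-Carlo error comfortably
inside the asserted margins.

## Design choices on points the data model leaves open

* The vendor's proprietary acquisition format is not parsed; cubes travel
  in an open HDF5 layout (`/counts`, `/calibration/*`, `/meta/*`) or as
  multi-frame TIFF plus a JSON calibration sidecar.
* "Partially outside the field of view" is operationalized as any member
  pixel on the outermost pixel ring — the only frame-truncation detectable
  from the mask alone.
* Mask shifts zero-fill the vacated area (no wraparound); rotation is 90°
  counter-clockwise about the image center.
* The kernel-pooling baseline truncates at image borders (in-bounds sums).
* The segmentation-aid low-pass filter is a Gaussian (default σ 1.5 px,
  reflective boundaries) and accepts 2-D intensity images only, so it can
  never touch histogram data.
* The `compare-pixelwise` command fits kernel-pooled histograms sampled at
  cell centroids (one pooled fit per cell) rather than at every pixel,
  keeping the method contrast cell-matched and fast; image-wide pixel-wise
  SD summaries use the full in-cell pixel set.
* Triple-exponential fits, global linked-τ fitting, measured-IRF traces,
  registration between visits and phasor reference calibration are out of
  scope.
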