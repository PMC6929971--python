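# Methods

This note documents the model behind `lipoct`, the choices made where the
procedure is genuinely open, what the synthetic phantoms do and do not
emulate, and the package's known limitations.  Nothing here states a number
that the test suite or `scripts/acceptance.py` does not itself compute.

## Problem setting

An excised tumor containing an iodinated-contrast-loaded nanocarrier is
imaged by µCT at isotropic resolution (the generator's default voxel size
is 16.6144 µm, a typical preclinical scanner pitch).  Attenuation is in
scanner-native units; it becomes quantitative only through a calibration
slope, so the analysis is *semi*-quantitative: it compares relative
accumulation within and between tumors rather than absolute iohexol
concentrations.

## Pipeline

1. **Segmentation.**  The ex vivo tumor is high-contrast against its
   surroundings (tube/air), so the mask is the largest 26-connected
   component above an automatic bimodal (Otsu) threshold, closed with a
   2-voxel ball and hole-filled.  The original processing used unpublished
   in-house macros; any reasonable global method suffices at this
   contrast, and an explicit threshold override keeps results auditable.
   The boundary is not eroded (whether the original excluded capsule
   voxels is unknown).  Non-tumor voxels are set to a sentinel far below
   tissue values, which makes re-segmentation of a masked volume
   idempotent.

2. **Calibration.**  Standards spanning 0.55–27.5 mg I/mL are scanned;
   the attenuation rate is the slope of an *unweighted* ordinary
   least-squares line of mean ROI attenuation on concentration.  The
   intercept is fitted, not forced through a background value: the slope
   alone ("change in attenuation per change in concentration") carries
   meaning.  A voxel-count-weighted fit is available but off by default.

3. **Background fit.**  The within-tumor histogram uses 1024 equal-width
   bins spanning [min, max] of the masked values — fine enough that bin
   quantization is far below the recovery tolerances, coarse enough for
   stable counts at ~10⁶ voxels.  A Gaussian A·exp(−(a−µ₀)²/2σ₀²) is
   least-squares fitted (unweighted, on counts) to the bins whose centers
   lie within a percentile window of the raw voxel values: (5, 95) for IV,
   (10, 50) for ITu.  The published IV window carries an internally
   inconsistent "(median)" annotation; the printed endpoints are
   implemented and both endpoints are configuration-overridable.
   Initialization: A = max windowed count, µ = center of the max bin,
   σ = windowed interquartile range / 1.349 (the Normal IQR factor, robust
   for the one-sided ITu window).  Percentiles are always taken on raw
   voxel values, never on binned counts.  The fit requires at least 8
   occupied window bins and rejects σ below one bin width as degenerate.

4. **Differential histogram and limits.**  Excess = max(counts − fit, 0)
   per bin; negative excess is clamped because excess counts represent
   voxel populations.  The upper limit is always the within-tumor maximum.
   The lower limit a_lo is route-dependent:
   * IV — scan upward from the bin containing the voxel-value 99th
     percentile; a_lo is the center of the first bin with positive excess
     (lowest qualifying center wins).  If none qualifies, the limit is
     undefined and all integrals are zero.  The percentile is taken on
     voxel values (whether the original referred to the fitted
     distribution is unstated).
   * ITu — a_lo = µ₀.

5. **Dose.**  Vd = Σ excess × voxel volume (mm³).  Iodine mass treats each
   bin's excess population as sitting at concentration
   (bin center − µ₀)/rate, times the voxel volume in mL
   (= (voxel µm × 10⁻⁴ cm)³).  %ID = 100 · mass / injected mass, and
   %ID/cm³ divides by tumor volume in cm³.  Liposome voxels for rendering
   and shell analysis are the within-mask voxels ≥ a_lo; note this
   thresholding is only ~consistent with the histogram-excess volume (the
   excess subtracts the expected background population, a threshold does
   not) — they agree within ~10% on unblurred phantoms.

6. **Depth shells.**  Depth is the exact Euclidean distance transform to
   the nearest non-tumor voxel center, in mm, *not* a largest-inscribed-
   sphere ("local thickness") measure: shells are defined from the tumor
   periphery, which is a distance-from-surface concept.  The original
   analysis cited a local-thickness tool while describing periphery-based
   shells; the discrepancy is flagged here rather than silently resolved.
   Shell k covers depths ((k−1)·t, k·t] for k = 1..3 (t = 1 mm default)
   and shell 4 is everything deeper — half-open left, closed right, at
   voxel centers, so counts are exactly reproducible.  Per-shell output is
   the fraction of total liposome signal (mass-weighted through
   max(0, a−µ₀)/rate by default, voxel-count weighting available, since
   the original weighting is unstated) and the occupancy = liposome volume
   / shell volume, which normalizes for the peripheral shell being the
   largest in convex tumors.

7. **Projections and report.**  Maximum intensity projections along each
   axis (rays missing the mask take a background value), a depth-coded
   label volume (0 non-tumor, k shell, 10+k liposome voxel in shell k),
   and a deterministic JSON/CSV bundle echoing every applied default.
   Identical configuration and seed reproduce the bundle byte for byte.

## The phantom generator

Phantoms emulate exactly the statistical assumptions the analysis makes:
an ellipsoidal tumor (optional low-order lobulation) whose liposome-free
voxels draw from Normal(µ, σ_bg); spherical "hotspots" raised by
concentration × attenuation rate (voxel membership by center inclusion;
overlaps sum); Gaussian PSF blur of the whole field emulating partial
volume (applied *before* additive in-tumor measurement noise, because blur
is a deterministic optical/geometric effect and noise is not); a constant
outside value well separated from tissue.  Ground truth (total mass,
occupied volume, per-shell masses) is computed on the pre-blur hotspot
mask, with the per-shell rules shared verbatim with the shell module so
conventions cannot drift.  Identical seeds give bit-identical volumes.

Defaults are one choice of realistic conditions, made once: background
mean 100, background and noise SD 6 (6 % of background — high-resolution
µCT soft-tissue noise is substantial), attenuation rate 20 units per
mg I/mL (so the calibration range spans ~11–550 units), PSF σ of one
voxel, ~46 mm³ tumor.  What the phantoms do **not** emulate: beam
hardening, ring artifacts, scatter, non-Gaussian noise, spatially varying
background, vascular-network hotspot geometry, or scanner-accurate
attenuation magnitudes.  Passing the battery therefore shows the
estimators are correct *under the model's own assumptions*; it does not
certify accuracy on scanner data whose background deviates from a single
Gaussian.

### Validation batteries (problem sizes are the package's choice)

* **Null calibration** — 200 agent-free ~128³ phantoms at 16.6 µm.  Any
  detected dose is a false positive.  The IV lower-limit rule caps the
  false-positive volume near 1 % of the tumor by construction (it starts
  at the sample's own 99th percentile).  A strictly zero %ID has
  probability ~0 — some bin above the 99th percentile carries positive
  clipped excess in essentially every realization — so "no detected dose"
  is asserted as a median %ID below 0.01 percentage points (measured
  ~10⁻⁵ %).
* **Recovery battery** — one spherical deposit per phantom over
  concentrations {2, 5, 10} mg/mL × radii {0.3, 0.6, 1.0} mm, 1-voxel PSF,
  noise = σ₀, analyzed with IV limits.  The design is scale-invariant:
  voxel size = radius/25 (the PSF is always 4 % of the radius) and the
  tumor scales so the deposit occupies ~0.3 % of it — the sparse regime
  the IV rule presumes.  Two structural facts, established by simulation
  before the battery was frozen, motivate this: the IV rule truncates once
  the deposit exceeds ~1 % of the tumor (the percentile scan lands inside
  the deposit's own value cluster), and the ITu rule carries a large
  clipped-noise bias for sparse deposits (it integrates every positive
  fluctuation above µ₀).  Residual biases under the battery: partial-
  volume halo above threshold inflates Vd by up to ~+15 % at the highest
  contrast, and threshold truncation trims mass by up to ~−6 % at the
  lowest; the tests assert mass within 15 % and Vd within 25 % of truth
  plus monotonicity in concentration and radius.
* **Oracle equivalence** — with background SD, noise and PSF all zero the
  within-tumor histogram is two spikes and the percentile-window fit is
  degenerate by design (its preconditions reject it), so the test
  constructs the background model from the phantom's known parameters and
  checks the integration machinery: Vd voxel-exact against truth and the
  histogram mass within one bin's quantization of the voxel-wise direct
  sum Σ(a_v − µ₀)/rate · v.
* **Shell geometry** — digitized 5 mm sphere at 50 µm: shell volumes
  against the analytic concentric-sphere values (within 2 %; measured
  within ~0.5 %), exact partition, monotone shell volumes.
* **Shell attribution** — equal 0.5-mm-radius, 20 mg/mL deposits at
  depths 0.5 and 2.5 mm in a 3.5 mm sphere recover per-shell signal
  fractions within 5 points of the truth ledger's (≈50, 0, ≈50, 0).

## Numerical choices and degenerate inputs

* Fit convergence via `scipy.optimize.curve_fit` (xtol 1e-10, generous
  eval budget); non-convergence raises carrying the last iterate.
* σ is reported as an absolute value; σ < one bin width raises a
  degenerate-fit error.
* Constant-valued regions histogram into a single bin (and fail the
  occupied-bin precondition downstream, by design); constant volumes are
  rejected at segmentation (no bimodal split).
* Undefined IV lower limit → Vd = 0, mass = 0, empty classification, each
  with a logged note.
* Empty shells report fraction 0 and occupancy 0; zero total signal
  reports all-zero fractions with a logged note.
* Hotspot containment uses a conservative shrunken-ellipsoid test;
  overlapping hotspots are allowed and sum.
* The anisotropy check tolerates 1e-4 relative spacing differences;
  anything larger is rejected rather than resampled — every physical
  quantity derives from the single isotropic voxel size.

## Known limitations

* The route-dependent limits are heuristics with route-specific operating
  regimes (see the recovery battery notes): ITu limits on sparse signal
  over-integrate noise; IV limits on dense signal truncate.
* Detection is contrast-limited: agent below roughly the background-tail
  threshold (~2–3 σ₀ for IV) is invisible, so low-abundance, diffuse
  accumulation is under-reported — results are relative measures, not
  absolute concentrations.
* No Hounsfield/spectral calibration, no beam-hardening correction, no
  multi-tumor scenes, no DICOM ingestion (convert scanner exports to
  NIfTI/TIFF/MetaImage first).
* Depth is surface distance; geodesic (within-tissue) depth variants are
  out of scope.
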