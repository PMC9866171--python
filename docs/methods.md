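# Methods

`gfuse` implements a per-capture processing chain for paired thermal and
multispectral plant images acquired in a glasshouse: one RGB frame, four
narrow-band frames (green 550 nm, red 660 nm, red-edge 735 nm, NIR 790 nm)
on a common grid, and one 8-bit thermal screen render on its own, smaller
grid. The output is an eight-band co-registered stack in which every
non-canopy pixel is NaN, plus per-pixel vegetation indices. This note
records the models, the defaults and why they were chosen, what the
synthetic scene generator does and does not emulate, and the numerical
choices that a user reproducing or extending the pipeline should know.

## Lens model and calibration

Each multispectral band is treated as a pinhole camera with focal lengths
`fx, fy` (px), principal point `(cx, cy)` (px), zero skew, and Brown radial
distortion

    x_d = x (1 + k1 r^2 + k2 r^4 + k3 r^6),  r^2 = x^2 + y^2,

acting on normalised image coordinates. Calibration is the standard planar
bootstrap: a normalised-DLT homography per checkerboard view, a closed-form
intrinsic estimate from the homography constraints, extrinsics factored per
view, then a joint Levenberg–Marquardt minimisation of the reprojection
error over intrinsics, distortion, and all poses
(`scipy.optimize.least_squares`).

Defaults that matter:

* **Two radial coefficients** are estimated by default (`n_radial_coeffs=2`,
  `k3` pinned at 0). A checkerboard never covers enough off-axis radius for
  the `r^6` term to be identifiable; freeing it lets `k1/k2/k3` drift along
  a flat valley (fits with `k2 ≈ -2.2, k3 ≈ 19` and identical reprojection
  error were observed) while the recovered polynomial is unchanged inside
  the data's radius range. Users with fisheye-grade optics can set
  `n_radial_coeffs=3`.
* The board is counted in **squares** (default 5 × 8 of 50 mm), so the
  detectable inner-corner grid is 4 × 7 = 28 points.
* Corner detection is Harris + Förstner sub-pixel refinement
  (scikit-image), with corners ordered row-major by a principal-axis
  row-splitting scheme. The labelling is forced right-handed so a mirror
  ordering can never masquerade as a pose; the remaining 180° ambiguity of
  a checkerboard is harmless to calibration (it is a valid pose).
* Undistortion inverse-maps each output pixel through the forward radial
  model and samples bilinearly. The radial polynomial is inverted where
  needed (synthetic rendering) by Newton iteration on the radius
  (tolerance 1e-8, ≤ 20 iterations); distortion preserves direction, so
  only the scalar radius needs inversion.

## Cross-modality registration

The thermal frame is aligned to the common multispectral/RGB grid in two
stages.

**Coarse (per session).** A corflute sheet with polygonal cut-outs in front
of a warm wall gives corner features visible in both modalities (intensity
contrast in RGB, temperature contrast in thermal). Corners are detected
with Harris + sub-pixel refinement, paired across the two frames by mutual
nearest neighbours after normalising each point set to zero mean and unit
RMS radius (translation- and scale-invariant; adequate for the rig's
near-similarity geometry), and a similarity transform is estimated by MSAC:
minimal two-point samples solved with the Umeyama closed form, hypotheses
scored by the truncated squared residual `sum(min(r_i^2, T^2))` with
`T = 2 px`, the winner refit on its inliers. The sample order is drawn from
a seeded generator, so runs are reproducible. The coarse transform depends
only on camera geometry and imaging distance, so it is estimated once per
imaging session and cached in a YAML sidecar.

**Fine (per capture).** Canopy movement between the two exposures leaves a
small residual, absorbed by an affine refinement driven by mutual
information. The metric is a joint-histogram MI estimator in bits over the
jointly defined pixels, 64 equal-width bins per image spanning each image's
own range. (This is the plain-histogram form of the Mattes metric; the
B-spline Parzen smoothing of the original is unnecessary at these image
sizes.) The optimiser is an elitist (1+1) evolution strategy over
`(tx, ty, θ, shx, shy, log sx, log sy)`: Gaussian steps of radius
6.25e-3 (growth 1.05 on success, contraction 0.5^0.25 on failure, 200
iterations, seed 42 by default). Parameter scales are `(w, h, 0.3, 0.1,
0.1, 0.1, 0.1)` — the initial radius then corresponds to ~1–2 px of
translation and sub-degree rotation, and all parameters converge at
comparable rates; with unit scales on the angular/shear terms the search
stalls short of the optimum (verified on known-shift recovery). Because the
search is elitist, the returned transform never scores below the
initialisation, and a fixed seed makes it bit-reproducible.

Warping is inverse-mapped bilinear resampling (`scipy.ndimage`), with
out-of-frame and NaN-adjacent samples becoming NaN.

## Thermal radiometric rescaling

The thermal export is an 8-bit render: DN 0–255 plus a colour-scale legend
whose min/max temperatures are printed as text. The pipeline reads the two
labels with a bundled template-matching digit reader: glyph components are
split by connected components, '.'/'-' resolved geometrically (size and
vertical position), and digits matched against a 7×5 dot-matrix atlas on
each candidate's tight bounding box after average pooling — exact for
integer-scaled renders, tolerant of mild blur. The reader is pluggable
(`read_scale(..., reader=...)`) for users with a different legend font.
Label boxes and the legend-free `image_area` come from configuration,
since legend layout varies by camera software; min/max DN are scanned from
`image_area` only (legend pixels would corrupt the range). Conversion is
the linear map

    T = minT + (maxT − minT) · (DN − minDN) / (maxDN − minDN),

so `DN = minDN` maps to `minT` and `DN = maxDN` to `maxT`; out-of-range DNs
are clamped with a warning. No emissivity or ambient-reflection correction
is applied — the method targets controlled glasshouse scenes with the
canopy filling the field of view.

## Illumination correction

Two effects are removed per band, using the white 80%-reflectance backdrop
behind every plant as an in-scene reference:

1. **Directional gradient.** The mean of a 4 × 4 px ROI in each corner
   (NaN-aware) anchors a bilinear surface `Gref`; the corrected image is
   `Gcor = Iorg − (Gref − min Gref)`. The surface is anchored at the ROI
   *centres* and extrapolated to the frame edges — anchoring at the corner
   pixels would over-steepen the surface and leave a residual at the
   corners; with centre anchoring a planar gradient is removed exactly.
   Bilinear is the minimal model for a planar gradient; higher-order
   surfaces would fit canopy structure, not illumination.
2. **Level normalisation.** With a lens-capped dark capture `Idark` and a
   white reference `Iwhite` rebuilt from the corners of `Gcor` itself,
   `Icor = (Gcor − Idark) / (Iwhite − Idark) · ref` with `ref = 0.80`, the
   backdrop reflectance. Output is clamped to [0, 1]; pixels where white
   and dark references coincide become NaN with a warning. Backdrop pixels
   land exactly at 0.80, and the result is invariant to a common positive
   gain on image and white reference.

The corner ROIs are assumed to see bare backdrop. When a corner ROI's
coefficient of variation exceeds 5% a warning is logged (canopy probably
intrudes); no automatic fix is attempted, because any guess would silently
bias the white reference.

## Canopy segmentation and stacking

The canopy/background decision is made on the RGB frame (best resolution)
and propagated everywhere. The thresholded scalar is excess-green
chromaticity `ExG = 2G − R − B`: the white backdrop and its shadows are
achromatic (`ExG ≈ 0`, and a shadow scales all channels equally, leaving
ExG at zero), while leaves are strongly green — this is what makes the
mask shadow-robust. ExG is contrast-stretched to its own 1st–99th
percentile range, then a pixel is foreground when it exceeds its local
window mean by `offset`:

* `window_px = 75`, `offset = 0.02`, `min_area = 64`, 3 × 3 opening.
* The stretch makes `offset` a fraction of the scene's actual
  plant/backdrop contrast. Without it the fixed offset exceeds the
  available ExG contrast unless >20% of every window is background, which
  hollows out any canopy region wider than the window.
* Local-mean thresholding inherently requires the plant to present thin,
  striated structure relative to the window: a solid region much wider
  than 75 px will lose its interior. That is the correct regime for
  frontal images of cereal canopies; for rosette plants with solid discs
  of leaf area a global ExG threshold (the white backdrop makes one
  trivial) would be the better tool.

Background pixels are set to NaN in all bands and the stack is assembled in
the order **R, G, B, green, red-edge, NIR, red, thermal** (bands 4–7 in
reflectance, band 8 in °C). Pixels the warped thermal frame cannot see are
removed from the mask, so "defined pixel set == mask" holds for every band
by construction. The mask is computed on the RGB grid; for export to the
thermal grid it would be warped nearest-neighbour (booleans are never
interpolated). Stacks are written as 32-bit float multiband TIFFs with NaN
background and band names in the metadata.

Segmentation quality is scored without ground truth as in routine use: RMSE
between the original and the background-zeroed segmented image on a [0, 1]
greyscale (note this bound is scale-dependent: on 0–255 it would read 255×
larger), and a structural-similarity map (11 × 11 Gaussian window, standard
constants, via scikit-image).

## Vegetation indices

Built-ins: NDVI, NDRE, CIre, TVI, RDVI, CVI, CIg (formulas in the module
docstring and README). RDVI uses the √(NIR+RED) denominator and TVI the
form 0.5·(120·(NIR−G) − 200·(RED−G)) — the canonical definitions from the
indices' defining sources. Arbitrary user expressions over the band names
are evaluated by a small AST walker (`+ − × ÷ ** sqrt`, constants); no
general Python evaluation, unknown names raise with a position. Zero
denominators and any undefined input produce NaN. Thermal may appear in
custom expressions (flagged with a units warning): mixed-modality indices
are the point of the stack.

## The synthetic scene generator

All tests and the acceptance measurements run on generated captures with
known truth; every generator is a pure function of its seed (identical
seed ⇒ bit-identical output). Default geometry is the real rig scaled down
4×: common grid 320 × 240, thermal 160 × 120 (+30 px legend margin).

What is emulated, and the reasoning:

* **Canopy**: fans of thin, curved, parallel-sided blades with blunt tips
  rising from five crowns along the pot line — the striated structure of a
  frontal cereal capture, with binary (non-antialiased) edges so the truth
  mask is exact. Coverage lands at 25–35% of the frame. Blade reach is
  capped so the corner white-reference ROIs always see backdrop.
* **Reflectance**: leaf reflectances per band (green 0.25, red 0.08,
  red-edge 0.45, NIR 0.55; RGB 0.10/0.30/0.12), modulated by a smooth
  within-canopy shading field in [0.7, 1.3]; backdrop flat 0.80.
* **Temperature**: backdrop 28 °C; leaves 19–24 °C, driven by the same
  shading field (transpiring, well-lit leaf area runs cooler) — which also
  supplies the cross-modality statistical dependence that mutual
  information measures.
* **Optics**: DN = dark (5 DN) + reflectance/0.80 · illumination (190 DN)
  + additive directional gradient (default amplitude 20% of the
  illumination level, zero at its darkest corner) + Gaussian noise
  (default 1% of full scale), quantised to 8 bits. The gradient is
  *additive* because the gradient-correction equations subtract an offset:
  an additive gradient is the model the chain can invert exactly, and the
  generator defines the conditions under which the chain is claimed to
  work. Multiplicative vignetting is deliberately not emulated; under a
  multiplicative gradient the correction is exact only where reflectance
  equals the backdrop's, and the residual grows with the
  reflectance-to-backdrop contrast.
* **Thermal frame**: the true temperature field sampled through the
  inverse rig transform, mapped to DN through the inverse radiometric
  model, quantised (quantisation is its only noise), with a legend bar and
  dot-matrix labels rendered from the same digit atlas the OCR matches —
  closing the OCR loop without an external engine.
* **Checkerboards**: ray-traced through the full pinhole + distortion
  model (supersampled 3×), at close range (board fills 55–85% of the
  frame) with lateral offsets reaching the frame corners. The pose spread
  matters: with small centred boards, 0.2 px corner noise makes `k1`
  unidentifiable to a few percent no matter the estimator — frame-filling,
  corner-reaching views are what real calibration sets provide.
* **Registration target**: the same cut-out polygons rendered dark-on-light
  for RGB and hot-on-cool for thermal, anti-aliased by 4× supersampling so
  polygon vertices sit at sub-pixel-true positions.

What passing on these fixtures does **not** show: performance under
specular leaf highlights, soil or pot pixels inside the frame, saturated
thermal scenes, legend fonts other than the bundled atlas, multiplicative
vignetting, or canopies that present solid leaf area wider than the
threshold window. Those need real captures or a richer scene model.

## Problem sizes and numerical conventions

Coordinates are row-major, 0-based, pixel centres at integer positions,
`x` = column, `y` = row; transforms act on column vectors `(x, y, 1)`.
Reflectance is clamped to [0, 1] after flat-fielding so index domains stay
valid. All acceptance measurements run at the 4×-scaled-down geometry with
10 calibration views, 5 segmentation captures, and single captures for
registration — sizes at which every measurement completes in seconds while
leaving the estimators' conditioning realistic. MSAC uses 500 trials, ties
broken by lowest cost with a seeded sample order. MI bins: 64 (8-bit
images quantise cleanly into 64 levels; entropy saturates well below the
bin count at these pixel counts).

## Known limitations

* Individual radial coefficients are meaningful only as a pair with the
  radius range they were fitted on; comparisons across rigs should compare
  the distortion *curve*, not `k1` alone.
* The fine registration seed is part of the configuration: different seeds
  give different (all valid, metric-non-decreasing) refinements.
* The OCR default backend assumes the legend digits come from a
  dot-matrix-like font rendered at an integer scale; other fonts need a
  custom reader or the configured scale override.
* RMSE-based segmentation scoring depends on canopy fraction and backdrop
  brightness; it is a regression guard, not an absolute quality measure.
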