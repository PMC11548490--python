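# Methods

## Scope and design

The package re-implements, as a tested pipeline, a winter-canola
aboveground-biomass (AGB) estimation workflow over UAV hyperspectral imagery:
narrowband spectral features, GLCM texture features, two-stage feature
screening into three schemes, and a six-algorithm regression comparison, plus
two experiments on spectral bandwidth and pixel size.  Because no raw flight
imagery is publicly deposited for this kind of trial, the first-class
`scene` module generates synthetic campaigns whose spectral and textural
statistics reproduce the field study design; every downstream stage runs
identically on real rasters (ENVI/TIFF cubes + GeoJSON plot polygons + truth
CSV) through the same interfaces.

## Synthetic campaign generator

**Design.**  A campaign is `n_treatments × n_replicates` plots observed at a
list of growth stages; defaults are 15 treatments × 3 replicates = 45 plots
at overwintering, bolting, flowering and podding (180 samples), on
64 × 64-pixel plots with 1 cm pixels.  Per-stage AGB anchors are
overwintering (400, 1200), bolting (2605, 3100), flowering (8831, 10241),
podding (9000, 15000) kg/ha; bolting and flowering are measured
winter-canola ranges, podding spans the dense-canopy regime, and
overwintering is set small, consistent with sub-tonne early-season biomass.
Within a stage, treatment rank `t` of `T` draws AGB uniformly from the
`t`-th of `T` equal sub-intervals of the anchor, giving a stochastically
monotone water-nitrogen gradient while guaranteeing draws stay inside the
anchors.  The within-interval distribution is a free choice; uniform is used.

**Radiometry.**  Each plot is a binary soil/vegetation mixture.  The
vegetation endmember is piecewise smooth: absorption wells near 450/670 nm, a
green peak at 550 nm, a logistic red edge whose inflection shifts
700 → 730 nm with AGB, and a NIR plateau saturating via
`f = 1 − exp(−AGB / saturation_agb)` with `saturation_agb = 6000 kg/ha`.
All AGB dependence enters through `f`, so spectral sensitivity at
2 × saturation is e^−1.75 ≈ 17 % of that at 0.25 × saturation before any
mixture or ratio nonlinearity; the measured plot-mean NDVI slope ratio is
≈ 0.027 (asserted in the tests).  Canopy cover rises as
`0.98 · (1 − exp(−AGB / 2500))` — strictly increasing, saturating below 1 —
and the cover pattern is a thresholded Gaussian random field with exponential
covariance (circulant embedding on a doubled grid, thresholded at the
empirical quantile so the achieved cover matches the target to pixel
resolution).  The field's correlation length grows linearly with AGB from
1.5 to 5 px up to 12 000 kg/ha, so texture carries an AGB signal that does
not saturate where the spectra do.

**Noise.**  Three multiplicative lognormal components with unit mean: a
per-pixel illumination field shared across bands (cv 0.05, shadow-like), a
per-sample gain (cv 0.03), and a per-sample spectral tilt (cv 0.05) that
varies linearly in wavelength — the smooth band-to-band signature of
illumination/BRDF variation.  The tilt is nearly identical for neighbouring
bands, which is why averaging member narrowbands into a broadband cannot
average it away, while it cancels neither in raw band features nor fully in
two-band indices.  Biological plot-to-plot variability is modelled as jitter
of the endmember parameters: red-edge position ± 3 nm, NIR amplitude cv 8 %,
clump-size cv 10 % — all independent of AGB.  This jitter is what bounds the
accuracy attainable from spectra alone: in the saturated regime the AGB
signal in edge position (≈ 0.0007 nm per kg/ha at 12 000 kg/ha) is small
against the 3 nm jitter, whereas texture, being invariant to per-plot
multiplicative factors (min–max quantization removes them), degrades far
less.  All randomness descends from one campaign seed through per-(plot,
stage) seed sequences; identical seeds give bit-identical campaigns.

**What the generator does not emulate.**  No radiative transfer (PROSAIL),
BRDF geometry, real shadows, mixed soil moisture, orthomosaicking artefacts,
or atmospheric effects; these are represented only as the noise components
above.  Passing tests therefore demonstrate the pipeline's correctness and
its qualitative behaviours (saturation, texture robustness, broadband
dilution, scale effect) on data engineered to have them — not real-world
accuracy levels.

## Feature extraction

**Bands and indices.**  The default grid is 138 centers at 4 nm from 450 to
998 nm (the only uniform grid consistent with that band count and range).
Cited index wavelengths are resolved by nearest band center within 6 nm (ties
toward the shorter wavelength); no interpolation, since narrowband semantics
would be lost by inventing reflectances.  The 21-entry index registry is
evaluated on plot-mean reflectances; zero denominators yield NaN with a
logged flag, and NaN rows are excluded pairwise at screening.  Four registry
formulas circulate in a non-canonical printed form (MSR, NDI, DCNI with an
asymmetric or duplicated term; MSAVI's printed form is algebraically the
canonical one); the `paper` dialect implements them exactly as printed and a
`canonical` dialect is selectable.  The published variable spellings DNCI and
MTCAI are treated as aliases of DCNI and MTCI, logged rather than silently
resolved.

**Broadbands.**  Simulated multispectral bands are uniform (configurable
weights) averages of member narrowbands over DJI Phantom 4-style intervals:
blue 434–466, green 544–576, red 634–666, red-edge 714–746, NIR 814–866 nm.

**Texture.**  One symmetric co-occurrence matrix per whole plot per source
image — the features are per-plot scalars, so no sliding window — with
L = 32 gray levels, distance 1, four angles {0°, 45°, 90°, 135°} summed
before normalization; all parameters configurable since no community-standard
exists for them here.  Quantization is min–max per plot; VI images are first
clipped to their 1st–99th percentile so single-pixel extremes cannot shatter
the gray range (switchable).  Entropy uses the natural logarithm; 0·ln 0 = 0;
correlation is defined as 1 for zero-variance marginals (prevailing library
convention).  Band-sourced columns are named `<STAT>_<nm>` (`CON_686`) and
VI-sourced columns `<VI>_<STAT>` (`NDVI_COR`).  The implementation is
mask-aware (nodata pixels excluded pair-wise) and is verified against both a
brute-force pair-enumeration oracle and scikit-image's `graycomatrix`.

## Feature screening

Pearson correlation with AGB is computed pairwise-complete on pooled
all-stage samples; features with under 3 complete pairs or zero variance are
flagged, not scored.  The screen keeps |r| ≥ 0.6, ordered by descending |r|
(alphabetical tie-break).  The published workflow's subsequent
"after comparison" pruning step has no published procedure, so the package
defines an explicit, deterministic stand-in: a greedy pass accepting a
feature iff its |correlation| with every already-accepted feature is below
0.9.  The 0.9 cut is a configurable default chosen inside the reported range
of problematic inter-correlations (0.39–0.96); the original study's exact
8- and 23-variable outcomes are data-dependent and are therefore shipped as
fixed reference schemes, not re-derived.  The greedy rule provably equals
exhaustive search for the max-|r|-first maximal admissible subset (asserted
against a brute-force oracle up to 12 features).

## Estimation

Stratified (by stage) 7:3 modeling/validation split with
`|train| = round(0.7 n)` by largest-remainder allocation; deterministic per
seed.  Six algorithms with documented frozen defaults: RF and GBRT with 500
trees, Adaboost over depth-6 trees (300 rounds, learning rate 0.5), Xgboost
(500 rounds, depth 4, η 0.05, 90 % subsampling), SVR (RBF, C = 10, ε = 0.1)
behind feature and target standardization, and GPR (constant × RBF + white
kernel, normalized targets) behind feature standardization.  An optional
`tune=True` path selects hyperparameters by 5-fold cross-validation over
small grids inside the training partition; held-out metrics always come from
the untouched 30 %.  Stage-wise cells are fit on that stage's samples only;
pooled cells on all samples; per-cell failures (for instance stages too small
to split) are recorded in the tidy result table rather than raised.

## Experiments and problem sizes

The broadband comparison and the pixel-size ladder {1, 2, 4, 8} (the native
resolution is a stated assumption of 1 cm; the ladder brackets the 2–4 cm
operating range of interest) re-use one rendering of the campaign per seed,
resampling and re-extracting per factor; plots falling below the 8 × 8-pixel
texture minimum at a coarse factor are dropped from that factor with a logged
warning.  Multi-seed summaries use 10 seeded campaign replicates in the test
suite and 3 in the acceptance script (`--sweep-seeds` to change), sizes
chosen to keep a full verification run on one CPU comfortable while leaving
Monte-Carlo error well below the margins of the qualitative orderings
checked.  Block means are computed in float64 and conserve the global mean
exactly over fully covered blocks.

## Reproducibility

One global seed hash-derives every stage seed; `run-all` twice under one seed
produces byte-identical CSVs and manifest (content hashes of every output are
recorded).  All stochastic model fits receive explicit seeds.

## Known limitations

* Synthetic-only validation: accuracy numbers characterize the generator's
  difficulty settings, not field performance.
* The estimation protocol reports single-split held-out metrics by default;
  fold-averaged metrics require the `tune` path.
* ENVI support is limited to BSQ float32 with wavelength lists; TIFF
  wavelength metadata uses a JSON image description rather than GeoTIFF tags.
* Plot-mean spectral features are invariant to block resampling when blocks
  tile plots exactly, so the scale-effect experiment isolates the texture
  channel; rasters whose plots are not block-aligned will also show spectral
  scale sensitivity.
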