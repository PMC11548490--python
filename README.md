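# canagb — winter-canola biomass from hyperspectral spectra-texture features

`canagb` is an analysis pipeline for estimating winter-canola aboveground
biomass (AGB, kg/ha) from ultra-high-resolution UAV hyperspectral imagery by
combining **narrowband spectral features** with **gray-level co-occurrence
(GLCM) texture features**.  It is aimed at crop-phenotyping researchers who
want a tested, fully reproducible implementation of this workflow — including
a synthetic scene generator that emulates a complete water-nitrogen field
trial, so every stage runs and is verifiable without any proprietary flight
data.

## The method

For each field plot at each growth stage the pipeline derives, from a
reflectance cube of 138 narrowbands (450–998 nm at 4 nm):

* **159 spectral features** — the 138 plot-mean band reflectances
  `Band_450 … Band_998` plus 21 narrowband vegetation indices (NDVI, SAVI,
  OSAVI, EVI, PRI, TCARI, MTCI, NDRE, WDRVI, MSR, MSAVI, red-edge indices,
  …), each a pure function of reflectances R_λ resolved by a nearest-band
  rule, e.g. NDVI = (R797 − R669)/(R797 + R669);
* **954 texture features** — six GLCM statistics per source image
  (159 × 6), computed on each band and each VI image after min–max
  quantization to 32 gray levels:

      CON = Σ P(i,j)(i−j)²        DIS = Σ P(i,j)|i−j|     HOM = Σ P(i,j)/(1+(i−j)²)
      ENT = −Σ P(i,j) ln P(i,j)   ASM = Σ P(i,j)²         COR = Σ(i−μᵢ)(j−μⱼ)P(i,j)/(σᵢσⱼ)

Features are screened in two stages — keep |Pearson r| ≥ 0.6 against AGB,
then greedily drop features inter-correlated above 0.9 — and assembled into
three schemes (*spectra*, *texture*, *spectra-texture*).  Six regressors
(Adaboost, Xgboost, RF, GBRT, SVR, GPR) are fit on a stratified 7:3
modeling/validation split, pooled and per growth stage, and scored with

    R² = 1 − Σ(o−p)²/Σ(o−ō)²,  RMSE = √(Σ(o−p)²/n),  NRMSE = 100·RMSE/ō [%]

Two companion experiments probe why narrowband texture helps: simulating
multispectral broadbands as weighted averages of member narrowbands, and
block-resampling the imagery to coarser pixel sizes before re-extracting
features.

## A worked run

The numbered drivers under `analysis/` execute the study on the default
synthetic campaign (15 treatments × 3 replicates × 4 stages = 180 samples,
64×64-pixel plots at 1 cm):

    python analysis/01_simulate_campaign.py
    python analysis/02_extract_features.py
    ...
    python analysis/06_pixel_size_scale_effect.py

`02` reports the feature–AGB correlation structure,

    180 samples; 159 spectral + 954 texture features
    |r| with AGB by feature group:
                  n_features   mean    min    max
    VI                    21  0.915  0.657  0.987
    VI-texture           126  0.764  0.118  0.947
    band-texture         828  0.802  0.006  0.990
    narrowband           138  0.930  0.117  0.967

`04` prints the pooled validation accuracy matrix and its best cell,

    best: GPR on spectra — R2 0.998, RMSE 230 kg/ha, NRMSE 3.6%

and `05`/`06` quantify the two scale experiments: the simulated red-edge
broadband correlates less with AGB than its best member narrowband
(|r| 0.847 vs 0.938), and mean texture |r| falls from 0.797 at 1 cm pixels
to 0.729 at 8 cm — texture information lives at the few-centimetre canopy
scale.  (Numbers above are for driver seed 1; the generator is exactly
reproducible per seed.)

The same stages are scriptable on real or simulated rasters through the CLI
(`canagb simulate | extract-spectra | extract-texture | select-features |
train-eval | broadband-compare | scale-analysis | run-all`), which reads
ENVI/TIFF cubes, GeoJSON plot polygons, and truth CSVs.

## Layout

    src/canagb/        scene.py (synthetic campaigns)  imagery.py (raster I/O,
                       plot extraction, block resampling)  spectral.py (bands,
                       VIs, broadbands)  texture.py (GLCM)  selection.py
                       (screening, schemes)  estimation.py (models, metrics)
                       pipeline.py + cli.py (orchestration)  experiments.py
    analysis/          numbered narrative drivers writing results/
    docs/methods.md    model assumptions, parameter defaults, limitations
    tests/             pytest suite (unit, property, and acceptance checks)
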