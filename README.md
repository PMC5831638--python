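# sedmap

Multiscale seabed-sediment mapping from multibeam echosounder (MBES) data:
derive terrain and acoustic predictors at multiple spatial scales, model
grab-sample grain-size compositions with boosted regression trees (BRTs),
and produce classified mud/sand/gravel substrate maps with cross-validated
uncertainty surfaces.

It is written for benthic habitat mappers and marine geoscientists who have
co-registered bathymetry and backscatter rasters plus a table of grab
samples, and who want the *scale* of each predictor chosen by the data
rather than fixed at the raster resolution.

## The method

Sixteen attributes are derived from bathymetry and backscatter at the
native resolution - slope, eastness/northness, RDMV, focal SD, fine and
broad benthic position index (BPI), three curvatures, surface area,
rugosity, vector ruggedness, backscatter and its local range - then
focal-mean averaged over windows of 3, 5, 9, 13, 21, 35 and 55 cells (the
Fibonacci sequence rounded up when even).  With distance from the coast
this yields 129 candidate layers spanning analysis scales of 5-275 m at
5-m cells.

Grain-size fractions (mud, sand, gravel), which close to 1, are modelled on
the additive log-ratio scale with sand as reference:

    ALR_ms = log10(mud / sand),    ALR_gs = log10(gravel / sand)

with observed zeros replaced at 1e-4 before the transform.  For each
response the package screens every attribute across its eight scales with a
BRT, keeps scales contributing >= 10% of the model's influence, prunes
layers with Spearman |rho| >= 0.7 within and then across attributes
(preferring higher contributions and better-ranked models), and fits the
final BRT on the survivors.  Cellwise predictions are back-transformed

    mud    = 10^ALR_ms / (10^ALR_ms + 10^ALR_gs + 1)
    gravel = 10^ALR_gs / (10^ALR_ms + 10^ALR_gs + 1)
    sand   = 1 - mud - gravel

and classified with Long's four-class simplification of the Folk triangle
(mud & sandy mud, sand & muddy sand, mixed, coarse).  A manual 10-fold
cross-validation reports fold-averaged Spearman correlations per fraction
and per-cell standard-deviation (model-consensus) maps.

A fully synthetic scene generator (bathymetry with multi-band spatial
structure, speckle-noisy backscatter tied to a latent coarse-sediment
field, grab samples with detection-limit zeros) provides known study
conditions for testing and experimentation; see `docs/methods.md`.

## Worked example

`examples/04_full_pipeline.py` runs the whole workflow on a 200x200-cell
synthetic scene with 300 grab samples:

```
model calibration (internal CV deviance explained):
  alr_ms 81.0%   alr_gs 77.0%
discrimination (manual 10-fold CV, Spearman rho at withheld sites):
  mud     0.916
  sand    0.912
  gravel  0.909
substrate map composition:
  mud_sandy_mud        2.5%
  sand_muddy_sand     29.1%
  mixed               26.9%
  coarse              41.5%
```

The deviance figures say how much of the ALR variation the selected
multiscale predictors explain on held-out folds; the Spearman rows say how
well back-transformed fraction predictions rank withheld grab samples; the
class shares summarise the final substrate map.  The other examples show
the attribute derivations (`01`), the compositional transforms (`02`), and
the scale-selection audit trail (`03`).

A thin CLI mirrors the library for shell use:

```bash
sedmap simulate --out scene --seed 4
sedmap stack --bathy scene/bathymetry.tif --backscatter scene/backscatter.tif \
             --coast scene/coast.wkt --out stackdir
sedmap extract --stack-dir stackdir --samples scene/samples.csv --out table.csv
sedmap select --table table.csv --response alr_gs --out gs
sedmap predict --model-ms ms_model.pkl --model-gs gs_model.pkl \
               --stack-dir stackdir --out maps
sedmap classify --mud maps/mud.tif --sand maps/sand.tif --gravel maps/gravel.tif \
                --out classified.tif
sedmap evaluate --table table.csv --selection-ms ms_selection.csv \
                --selection-gs gs_selection.csv --out eval.json
```

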