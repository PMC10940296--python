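# cropsuit

Mechanistic crop-suitability modelling over gridded monthly climate and
soil pH, in the EcoCrop tradition: trapezoidal niche responses, a search
over all twelve candidate growing windows, kill-temperature screening,
iterative rainfall/temperature calibration against a yield-derived
reference, sensitivity–specificity-equalized binary thresholding,
multi-model scenario ensembling, and a six-metric validation framework.
A seeded synthetic-world generator makes the whole pipeline exercisable
end-to-end without any external dataset.

## Layout

| module | role |
| --- | --- |
| `cropsuit.registry`  | crop parameter table (23 crops: 8 cereals, 6 pulses, 6 roots & tubers, 3 banana-related), validation, CSV round-trip |
| `cropsuit.engine`    | [0, 1] suitability index per grid cell: best growing window over temperature, seasonal rainfall total and soil pH |
| `cropsuit.geo`       | grid geometry, GeoTIFF/NetCDF I/O, monthly aggregation and climatologies, bilinear resampling, spherical cell areas, archive naming |
| `cropsuit.classify`  | yield-percentile reference grids, Se=Sp threshold selection, binarization, match scoring, two-stage calibration |
| `cropsuit.validate`  | occurrence thinning/detection, country detection accuracy, area correlation/exceedance, threshold-exceedance profiles |
| `cropsuit.synth`     | seeded synthetic worlds (climate, pH, country mosaic), truth maps, occurrence/harvest/yield emulation |
| `cropsuit.pipeline`  | crop × scenario × GCM run plans, layer production, ensemble means, percent-suitable-area summaries, run manifest |
| `cropsuit.cli`       | `cropsuit` command-line interface |

The packaged crop parameter CSV (`cropsuit/data/crops.csv`) carries
*representative* niche values so the pipeline runs out of the box; they
are placeholders that users should replace with their own calibrated
parameter sets (same CSV schema).

## CLI

```sh
cropsuit --seed 7 --outdir world synth --resolution 0.5
cropsuit --outdir out run --world world --crop maize --threshold 0.4
cropsuit --seed 7 --outdir out ensemble --world world --crop maize --scenario s370
cropsuit --outdir out calibrate --world world --crop maize --yield-grid yield.tif
cropsuit --seed 7 --outdir out validate --world world --crop maize
cropsuit manifest --manifest-csv out/manifest.csv
cropsuit plan
```

Archive filenames follow `<class>_<crop>_<datatype>_<period>[_<model>]`,
e.g. `Cereals_maize_suit_s370_gfdl.tif`, with periods
`curr/s126/s370/s585` and model tokens for the ten GCMs plus `mn` for
the ensemble mean.

## Notes

- Grids are WGS84, cell-center registered, rows north to south; missing
  data is NaN throughout.
- Raster I/O is deliberately light-weight: single-band float32 GeoTIFF
  (written via tifffile with standard geo tags) and NetCDF3 12-month
  stacks (xarray/scipy); no GDAL dependency.
- Temperature × rainfall and climate × soil combination rules default to
  the product and can be switched to `min` via `EngineConfig`.
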