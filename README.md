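# frapkit

Quantitative two-colour FRAP (fluorescence recovery after photobleaching)
image analysis for centrosome-style scenes, together with a synthetic
microscopy generator so every stage can be validated against known ground
truth without real microscope data.

## Pipeline stages

| Module | What it does |
| --- | --- |
| `frapkit.synthetic_data` | Renders two-channel bead fields and centrosome FRAP time series (integrated-Gaussian PSF, Poisson + read noise, one top-level seed) with serialisable ground truth. |
| `frapkit.image_io` | Calibrated `(t, c, z, y, x)` image stacks; multi-page TIFF + JSON-sidecar round-trip, maximum-intensity projection, most-central-slice selection. |
| `frapkit.registration` | Detects sub-resolution fiducial beads, matches them mutually-nearest across channels and estimates the systematic red-minus-green shift (mean displacement vector, pooled over images) used to correct red-channel coordinates. |
| `frapkit.localization_offset` | Fivefold bilinear upscaling, threshold centre-of-mass centroiding on the most central z-slice, registration-corrected green-red displacement per centrosome, aggregation. |
| `frapkit.profiling_recovery` | Radial intensity profiles (0.028 um rings spanning 3.02 um; background-subtracted, peak-normalised, mirrored) and recovery-over-time curves from the reference-channel ROI (mean + 2 SD rule). |
| `frapkit.foci_stats` | Mother/daughter focus assignment by distance to a toroid reference centre, box-plot summaries, pairwise Mann-Whitney / Welch / permutation tests. |

## CLI

The `frapkit` entry point exposes one subcommand per stage:

```sh
frapkit simulate scene.yaml -o out/          # synthetic bead fields or FRAP series
frapkit register out/ -o model.json --csv displacements.csv
frapkit offset out/frap.tif --model model.json --window 33,59,33,59 --time 60 -o offsets.csv
frapkit profile out/frap.tif --window 33,59,33,59 -o profile.csv
frapkit recovery out/frap.tif -o recovery.csv
frapkit foci coords.csv -o foci_out
```

A `simulate` config is a YAML file with `kind` (`bead_field` or `frap`),
a `scene` mapping (image shape, pixel size 0.105 um by default, z geometry,
frame times, bleach frame, PSF and noise parameters, seed) and a `truth`
mapping; see `tests/test_cli.py` for complete examples. Generated TIFFs
carry a JSON sidecar with the calibration and a `*.truth.json` ground-truth
record.

## Conventions

Positions are continuous `(x, y)` pairs in micrometres with the origin at
the centre of pixel `(0, 0)`; `x` maps to columns, `y` to rows. On disk,
pixel data are 16-bit unsigned multi-page TIFFs, page order channel-fastest,
then z, then time.
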