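# glavenstats

Tools for analyzing what determines the color of curved transparent
objects in rendered scenes: calibrated color-space conversions,
region-ratio statistics (RMC / RSD / robust ratio), affine
convergence-model fitting scored by RRPE, color vector-field and
streamline analysis, per-object color summaries, and a deterministic
synthetic scene generator that stands in for physically rendered stimuli.

## Layout

| Module | What it does |
| --- | --- |
| `glavenstats.colorspace` | linear RGB / XYZ / CIELAB / LMS / MB-DKL conversions from a monitor calibration, CIEDE2000, spectral integration |
| `glavenstats.cone_ratios` | RMC, RSD, robust-ratio color code, dark-pixel exclusion, flat-filter gamut search |
| `glavenstats.summary_statistics` | mean LAB color, White Point, most saturated / most frequent color, CIEDE2000 threshold maps |
| `glavenstats.convergence` | 12- and 4-parameter affine fits, constrained "over" fit, RRPE, full factorial reports |
| `glavenstats.vectorfield` | unfiltered-to-filtered color vector fields, grid box-averaging, RK4 streamlines, convergence points |
| `glavenstats.synthetic_scene` | Voronoi backgrounds, spectral transmissions/illuminants, affine and glass scene simulators with ground-truth masks |
| `glavenstats.cli_io` | file I/O, observer-match aggregation, the pipeline runner, and the `glavenstats` CLI |

Bundled sensor curves (CIE 1931 color matching functions and L/M/S
sensitivities) live in `src/glavenstats/data/` as plain CSV and can be
regenerated with `python scripts/make_sensor_tables.py` or replaced by
user-supplied tables.

## CLI

```sh
# synthesize a glass scene with ground truth
glavenstats simulate --seed 7 --out scene_out/

# region-ratio statistics for an image + object mask
glavenstats ratios --image scene.npy --mask obj.png --stat rmc

# fit the convergence model (single cell or the full factorial table)
glavenstats converge --unfiltered a.npy --filtered b.npy --mask obj.png \
    --space MBDKL --family 12
glavenstats converge --unfiltered a.npy --filtered b.npy --mask obj.png --full-table

# color vector field + streamlines
glavenstats field --unfiltered a.npy --filtered b.npy --mask obj.png --grid 100

# per-object summary colors and CIEDE2000 maps
glavenstats stats --image scene.npy --mask obj.png
glavenstats diffmap --image scene.npy --mask obj.png --reference 50,10,-5

# observer-match aggregation and the full demo pipeline
glavenstats aggregate --matches matches.csv
glavenstats run --seed 17 --out pipeline_out/
```

Images are accepted as float `.npy` (linear) or 8/16-bit PNG
(gamma-decoded with the calibration's decoding gamma); masks are
single-channel PNGs with nonzero = selected.

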