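# smlm-pipeline

Analysis chain for stochastic optical reconstruction microscopy (STORM)
of membrane-labeled neural processes: single-molecule localization in 2D
and astigmatic 3D, drift correction, multicolor activator/reporter color
coding with statistical crosstalk subtraction, focal-plane and
field-of-view mosaic stitching, Gaussian rendering, and the label-density
based resolution calculus. A forward simulator of blinking,
membrane-labeled tubular structures generates every input the chain
consumes, so the whole pipeline is testable without microscope data.

It is written for microscopists and image-analysis developers who want a
tested, scriptable reference implementation of this analysis style — each
stage is a plain library function over a molecule-list table, with a thin
`smlm` CLI on top.

## The model in brief

A switching event is an elliptical Gaussian spot whose x/y widths encode
the axial position z through an astigmatism calibration
w(z) = w0·sqrt(1 + u² + Au³ + Bu⁴), u = (z−c)/d. Spots are fit by least
squares (pixel-integrated model, constant background); z is the point on
the calibration curve nearest to (√wx, √wy).

The image resolution combines two independent terms. The localization
precision is the FWHM scatter of repeated localizations of one emitter.
The label density a (labels per µm^d, d the dimension) sets a Nyquist
sampling limit equal to twice the mean label spacing,

    α_Nyquist = 2 / a^(1/d)        (a in labels/µm^d, result in µm)

and the final resolution adds the two in quadrature:

    resolution = sqrt(α_Nyquist² + precision²).

Label density itself is the localization density divided by the mean
number of switching events per label (n = 4). At a membrane-labeling
density of 2500 labels/µm² this gives α = 40 nm and, with 18 nm lateral
precision, a combined 2D resolution of ≈ 44 nm.

## Worked example

The bundled demo simulates an X-junction — two 75 nm-radius membrane
tubes crossing 300 nm apart in z, labeled at 150 labels/µm² — renders a
16 000-frame astigmatic movie with linear stage drift, then runs
localization, drift correction, color coding, crosstalk subtraction,
rendering and the resolution report:

```sh
smlm run --config examples/demo.yaml --out out/demo
```

The manifest (`out/demo/manifest.yaml`) traces every stage. With the
bundled seed (7) it reports:

```
simulate:   n_emitters: 338   n_events: 1422   n_frames: 16000
localize:   n_localizations: 1138
            rejections: {overlap: 160, border: 126, off_curve_z: 29, ...}
drift:      n_bins: 4   max_offset_nm: 48.4
colors:     per_channel: {ch405: 1085, nonspecific: 53}
crosstalk:  removed: {ch405: 26}   post_counts: {ch405: 1059}
```

and `out/demo/resolution.yaml`:

```
label_density: 122.3        # labels/µm² recovered from localization counts
nyquist_nm: 180.9           # 2000 / sqrt(a)
precision_xy_nm: 18.0
resolution_xy_nm: 181.7     # quadrature combination
```

Reading the numbers: 338 labels produced 1422 switching events (n ≈ 4.2
per label); 80 % were localized — the rest fell to overlapping spots,
window-at-border, or widths off the z-calibration curve, all counted in
the manifest. The estimated drift (48 nm at the last time bin) matches
the injected 60 nm-over-the-movie linear drift evaluated at that bin. The
recovered density (122 vs. 150 labels/µm² simulated) reflects those
rejected events; at this density the resolution is label-density limited
(181 nm of 182 nm total), which is exactly the regime the density
calculus is for.

Individual stages are also standalone commands (`smlm simulate`,
`calibrate`, `localize`, `drift`, `colors`, `crosstalk`, `mosaic`,
`render`, `resolution`) reading and writing molecule-list CSV, TIFF and
YAML.

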