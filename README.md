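# rosettearea

Rosette leaf-area quantification of *Arabidopsis thaliana* seedlings from
photographs of closed agar culture plates.

Agar-plate culture is the workhorse of *Arabidopsis* root phenotyping, but
the same photographs usually go unused for shoot traits because the rosettes
sit askew against a cluttered background. `rosettearea` measures projected
rosette area directly from those plate images, enabling simultaneous root
and shoot phenotyping from one image set — including image sets that carry
no dedicated size reference, by using the plate itself as the scale.

## What it does

For each photograph the pipeline

1. **locates the plate** by binary thresholding or canny edge detection,
   takes its minimum-area rectangle, and derives the tilt angle;
2. **segments leaf tissue** on a single contrast-rich color channel — the C
   channel of CMYK or the b\* channel of CIELAB — with a fixed or
   Otsu-selected threshold, optionally after histogram equalization;
3. restricts objects to the **top-of-plate region of interest** where
   rosettes sit (seedlings fallen below the midline are deliberately
   excluded and tallied), groups them into up to six per-plate shoots by
   deterministic 1-D clustering of centroid *x* positions, and counts each
   shoot's pixels via the zeroth image moment;
4. **calibrates** pixels to mm² from a red square reference marker of known
   area when present, falling back to the plate's known physical dimensions
   (`mm²/px = known area / measured pixel count`).

A statistics layer supplies the validation regression (ordinary
least squares, `y = βx + α`, `R² = 1 − SS_res/SS_tot`) and a sequential
fixed-effects ANOVA of area on genotype, nitrogen source and nitrogen
treatment, from which broad-sense heritability is taken as the genotype
share of the total sum of squares, `H² = SS_G / SS_total`.

A seeded synthetic-image generator (`rosettearea.synthetic`) renders
ground-truthed plate scenes — tilt, sensor noise, lighting gradients,
missing seedlings, fallen rosettes — and backs every test in the suite.

## Worked example

```bash
rosettearea-sim --n 2 --seed 3 --out demo      # synthetic plates + truth.csv
rosettearea process demo/plate_0001.png
```

prints, for a fully germinated plate:

```
slot 1: 10.733882 mm^2 (313 px)
slot 2: 36.591221 mm^2 (1067 px)
slot 3: 39.471879 mm^2 (1151 px)
slot 4: 30.624143 mm^2 (893 px)
slot 5: 19.615912 mm^2 (572 px)
slot 6: 10.836763 mm^2 (316 px)
```

Each line is one seedling position (left to right), its measured rosette
area in mm² and the underlying pixel count. Batch mode writes one CSV row
per (plate, slot) — absent seedlings appear as `present=False` rows so
germination failures remain visible to downstream statistics:

```bash
rosettearea batch demo --out results.csv
rosettearea stats results.csv --design design.csv   # ANOVA + H²
```

Per-image-set parameters (color channel, threshold, ROI extent, plate and
marker physical sizes) live in a YAML config passed via `--config`; they are
properties of an image set's background and lighting, not of single images.

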