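# fibermorph

Myofiber morphometry from instance-segmentation label images.

Skeletal-muscle histology is quantified fiber by fiber: each myofiber's
cross-sectional area (CSA, μm²), Feret diameter and per-channel staining
intensity, over thousands of fibers per section. Modern instance
segmenters (Cellpose and friends) emit *label images* — integer rasters
where 0 is background and each positive value is one fiber — but the
muscle community works with ImageJ/FIJI ROIs, calibrated measurement
tables and per-animal CSA distributions. `fibermorph` bridges that gap
for biologists and image analysts:

- **ROI conversion** — every label becomes a polygon ROI traced along the
  crack boundary between object and background pixels, so the polygon's
  shoelace area equals the pixel count exactly; ROIs are written in the
  ImageJ binary `.roi`/`.zip` format readable by the FIJI ROI Manager.
- **Label erosion** — segmenters trained on membrane stains (Laminin,
  WGA) tend to include the bright membrane in each fiber, inflating CSA.
  Each label is shrunk independently by a fixed radius *r* via the exact
  Euclidean distance transform (keep pixels with EDT > r); objects never
  merge, and vanished objects are reported, never silently dropped.
- **Morphometry** — calibrated CSA (`area_px · pixel_size_um²`), maximum
  Feret diameter (rotating-caliper distance over the traced outline),
  channel means over the (eroded) mask, fiber typing by
  myosin-heavy-chain channel thresholds, CSA histograms and color-coded
  CSA maps, all exported as tidy CSV.
- **Segmentation evaluation** — object-matched Dice: the intersection
  table between two label images is matched greedily one-to-one, each
  pair scoring 2·|A∩B|/(|A|+|B|); plus a downscale benchmark (how much
  segmentation quality survives shrinking the image) and a vessel
  false-positive check against a vasculature mask.
- **Synthetic sections** — a generator of muscle-like tessellations with
  lognormal fiber areas, a bright membrane, and uniform (snap-frozen-like)
  or heterogeneous (PFA-fixed-like) staining regimes, with exact ground
  truth, so the entire pipeline is testable without microscopy data.

## Worked example

```python
import numpy as np
from fibermorph import (
    SyntheticMuscleSpec, generate_muscle_section, absorb_membrane,
    ErosionSpec, erode_labels, relabel_connected, measure_objects,
    csa_summary, mean_dice,
)

# a 150-fiber section, lognormal(7.2, 0.35) areas in um^2, 1 um/px
spec = SyntheticMuscleSpec(n_fibers=150, seed=3)
stack, truth = generate_muscle_section(spec)

# emulate a segmenter that absorbs the membrane, then correct it
segmented = absorb_membrane(truth, 3.0)
eroded, report = erode_labels(segmented, ErosionSpec(radius_px=4))
eroded = relabel_connected(eroded)

for img, name in [(segmented, "segmented"), (eroded, "eroded   ")]:
    ms = measure_objects(img)
    s = csa_summary(ms, bin_width_um2=500.0)
    print(name, f"n={s.n_objects}  mean CSA = {s.mean_csa_um2:7.1f} um^2")
print("dice(truth, segmented) =", round(mean_dice(truth, segmented).mean_dice, 3))
print("dice(truth, eroded)    =", round(mean_dice(truth, eroded).mean_dice, 3))
```

prints

```
segmented n=150  mean CSA =  1626.9 um^2
eroded    n=150  mean CSA =  1091.9 um^2
dice(truth, segmented) = 0.953
dice(truth, eroded)    = 0.836
```

The membrane-absorbing segmentation overestimates mean CSA by ~33%; the
4-px erosion removes the membrane band (here overshooting the true
boundary, since the synthetic membrane contributes less than 4 px per
side — the radius is a per-stain choice made by visual inspection).

The same pipeline is available from the shell:

```bash
fibermorph simulate --n-fibers 150 --seed 3 --out-dir data/
fibermorph batch --input-dir data/ --output-dir results/ --erosion-radius-px 4
fibermorph dice results/section_eroded_labels.tif data/section_labels.tif
```

`fibermorph batch` pairs label files with intensity images by filename
stem (`<stem>_labels.tif` next to `<stem>.tif`; the suffix is
configurable to match e.g. Cellpose's `_cp_masks`), erodes, converts to
ROI zips, and appends everything to one tidy `measurements.csv`.

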