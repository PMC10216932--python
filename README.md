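# octafaz

Quantitative OCT-angiography (OCTA) biomarkers for anti-VEGF treatment
response in diabetic macular oedema (DME).

Roughly a third of DME patients respond poorly to intravitreal anti-VEGF
injections, and baseline OCTA biomarkers — foveal avascular zone (FAZ)
geometry, capillary density, vessel calibre — are candidate predictors of
who will respond. `octafaz` implements the full analysis chain for
researchers working with en-face OCTA images of the superficial and deep
capillary plexus:

- **FAZ segmentation** — deterministic morphological pipeline: Prewitt
  edge detection, line-element closing at 0°/45°/90°, disk closure,
  largest-region false-positive removal, infill + outline output.
- **Shape metrics** — 12 geometric FAZ parameters in physical units:
  area *A*, equivalent diameter 2√(*A*/π), moment-ellipse axes with
  orientation and eccentricity √(1 − (b/a)²), traced perimeter *P*,
  min/max Feret extents, inscribed- and circumscribed-circle radii, and
  circularity 4π*A*/*P*².
- **Vessel metrics** — tortuosity (length-weighted arc/chord ×
  (1 + inflection count) over skeleton branches), vessel diameter index
  (binarised area / skeleton length), and areal vessel density.
- **ETDRS densities** — perfusion density (%) and skeleton-length vessel
  density (mm⁻¹) per ETDRS subfield, aggregated to central / inner /
  outer / full rings.
- **Cohort statistics** — signal-strength inclusion filter, fractional
  CST change (x − y)/x, quartile-based responder / non-responder
  stratification, pooled t / χ² group comparisons with Bonferroni
  correction, and the per-factor contribution table.
- **Synthetic data** — phantom angiograms with exactly known FAZ and
  vessel ground truth, and cohorts with planted group effects, so every
  stage is validated end to end without patient data.

See `docs/methods.md` for the models, conventions and parameter defaults.

## Worked example

```python
from octafaz import (PhantomSpec, make_faz_phantom, segment_faz,
                     compute_shape_params)

spec = PhantomSpec(faz_shape="blob", radius_mm=0.35, acircularity=0.15,
                   noise_sd=10.0, seed=7)
image, truth = make_faz_phantom(spec)     # 420x420 px, 6x6 mm phantom
mask = segment_faz(image)                 # deterministic FAZ pipeline
params = compute_shape_params(mask.infill, image.scale)

print(f"true FAZ area      : {truth.true_area:.3f} mm^2")
print(f"segmented FAZ area : {params.area:.3f} mm^2")
print(f"equivalent diameter: {params.equiv_diameter * 1000:.0f} um")
print(f"eccentricity       : {params.eccentricity:.2f}")
print(f"circularity        : {params.circularity:.2f}")
```

prints

```
true FAZ area      : 0.386 mm^2
segmented FAZ area : 0.392 mm^2
equivalent diameter: 706 um
eccentricity       : 0.37
circularity        : 0.98
```

The phantom plants an irregular avascular blob of known area inside a
capillary mesh; the pipeline recovers it to within ~1.5% here. The
equivalent diameter is the diameter of the circle with the segmented
area; eccentricity 0.37 reflects the mild elongation of the perturbed
boundary, and circularity 0.98 says the region is still nearly circular
in the isoperimetric sense.

The same stages are available from the shell:

```bash
octafaz simulate --seed 1 --n-eyes 12 --out sim/
octafaz segment  --input sim/E001.png --out-mask mask.png --out-outline outline.csv
octafaz metrics  --input sim/E001.png --out metrics.csv
octafaz density  --input sim/E001.png --out density.csv
octafaz cohort   --input sim/cohort.csv --out stats/
octafaz run      --seed 1 --n-eyes 12 --out results/
```

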