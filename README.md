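# pamvasc

Layer-resolved vascular density quantification for volumetric
optical-resolution photoacoustic microscopy (OR-PAM) of skin — the analysis
chain used to monitor corticosteroid-induced vasoconstriction — together
with a synthetic skin-vasculature phantom that provides exact ground truth
for every stage.

Corticosteroids act on skin partly by constricting dermal capillaries (the
basis of the clinical "blanching" assay). OR-PAM images hemoglobin directly
in 3-D, so vasoconstriction can be measured rather than inferred from skin
colour. This package implements that measurement for longitudinal series
(seven volumes, 0–60 min at 10-min intervals, grouped into treatment arms):

1. **Surface flattening** — detect the skin profile per A-line (first
   crossing of half the A-line maximum, with one-sided rejection of
   deep-vessel lock-ons) and resample so depth is measured below the skin.
2. **Layer segmentation** — the depth histogram of suprathreshold voxels
   has two local maxima, the papillary-dermis (PD) and hypodermal (HD)
   vascular plexuses; slab boundaries between PD, reticular dermis (RD)
   and HD derive from those peaks.
3. **Layer-wise MAPs and averaged-Otsu density** — per layer and timepoint,
   a maximum-amplitude projection is binarized at the mean of the seven
   per-timepoint Otsu thresholds; vascular density is the count of pixels
   above it, normalized to t = 0:

   `relative(t) = N(t) / N(0)`, `constriction% = 100·(1 − relative(60))`.

4. **Centroid tracking** — depth of the suprathreshold voxel centroid;
   superficial constriction pushes it deeper.
5. **Group statistics** — mean ± SEM per group × layer and two-tailed
   paired t-tests on the final constriction percentages.

In vivo datasets for this protocol are scarce, so the package ships a phantom generator (`pamvasc.phantom`) that emulates the
layered dermal vasculature — a dense shallow capillary plexus, sparse
near-vertical reticular connectors, paired large hypodermal vessels —
under the system's anisotropic PSF (5 µm lateral / 30 µm axial) and noise,
with per-layer constriction schedules matching the four experimental arms
(subcutaneous injection, topical corticosteroid, topical nonsteroid,
control). Every scene carries an analytic projected-area oracle, so the
pipeline's densities are validated against geometry, not against itself.
See `docs/methods.md` for the models and design decisions.

## Worked example

```python
import pamvasc as pv

# a 4-arm study: 2 subjects per arm, 7 timepoints each, reduced field
result, bundle = pv.run_phantom_study(pv.PhantomSpec.small(seed=0), n_subjects=2)

for group in ("injection", "topical", "control"):
    row = [round(result.mean_constriction(group, layer), 1)
           for layer in ("PD", "RD", "HD", "WHOLE")]
    print(group, row)
```

prints (seed 0):

```
injection [2.6, 50.8, 2.5, 1.9]
topical [58.4, 38.0, 26.1, 35.5]
control [-0.1, 0.3, 0.1, 0.2]
```

i.e. the injected corticosteroid constricts only the mid-dermis (RD ≈ 51%),
the topical corticosteroid constricts superficial layers most
(PD ≈ 58% > RD ≈ 38% > HD ≈ 26%), and the control arm drifts by well under
1% — the layer-selectivity pattern the measurement is designed to resolve.
`result.traces`, `result.summaries`, `result.tests` and `result.centroids`
are pandas DataFrames; `result.save(out_dir)` writes CSVs, a JSON manifest
and figures.

The same pipeline runs on volumes from disk (multi-page TIFF or HDF5 with
spacing metadata):

```sh
pamvasc simulate --out data/ --seed 1 --n-subjects 6
pamvasc analyze --data data/ --out results/
pamvasc summarize --results results/
```

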