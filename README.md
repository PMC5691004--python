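# cbctshade

Prior-free, image-domain shading correction for cone-beam CT (CBCT) volumes.

CBCT reconstructions carry smooth multiplicative shading (cupping and ring
patterns, mostly scatter-induced). `cbctshade` estimates that low-frequency
bias field from the reconstructed volume itself — no planning CT, no
projection data — divides it out, and recalibrates to Hounsfield units:

1. **Preprocess** each transverse slice: locate the body center, mask bone
   (HU > 100) and gas (−750 … −500 HU) by thresholds plus morphological
   opening/dilation, fill the masks with water (0 HU).
2. **Resample to polar coordinates** (default 600 radial x 360 angular bins)
   about the body center with cubic spline interpolation, and flag the air
   outside the patient per angle at the maximum radial gradient.
3. **Estimate the bias** in polar space: a wide circular median along the
   angular direction (80° for pelvis-like, 40° for head-like sites) followed
   by a per-angle polynomial fit (order 8), then a radial pass (median width
   1, order 3).
4. **Map back to Cartesian**, stack the slices, and apply a 3D median filter.
5. **Divide** the volume (in relative attenuation, water = 1) by the bias
   field and convert back to HU.

An optional **precorrection round** removes globally radial ring shading
(half-fan/bowtie acquisitions): all angles share a single full-circle radial
median profile, which is split at its sharpest drop into inner ring /
transition / outer ring region means.

The package also ships a digital phantom generator (elliptical soft-tissue
body, bone / gas / low-contrast inserts, three shading-field families with
retained ground truth) and the standard quality metrics: ROI mean/std, mean
CT-number error with propagated standard deviation, and spatial
nonuniformity (SNU) error.

## Test

```sh
python -m pytest -q tests/
```

The suite includes `tests/test_acceptance.py`, which runs the full pipeline
on 256² x 32 phantoms for each shading family and checks bias recovery
(≤ 3 % RMS), soft-tissue accuracy (≤ 25 HU where the engineered shading error
is ≈ 250 HU), structure preservation, and determinism.

## Command line

```sh
# generate a shaded phantom with ground truth
cbct-shade simulate --spec phantom.yaml --out-dir sim/ --seed 1

# correct a volume (NIfTI, MetaImage, or raw + JSON sidecar)
cbct-shade correct --in sim/shaded.mha --out corrected.mha \
    --bias-out bias.mha --precorrection --angular-width 80

# quality metrics against a reference volume
cbct-shade evaluate --test corrected.mha --ref sim/truth.mha \
    --rois rois.txt --report report.txt
```

`phantom.yaml` holds a `phantom:` section (grid, spacing, body semi-axes,
inserts) and a `shading:` section (`GLOBAL_RING`, `LOCAL_RADIAL`, or
`SMOOTH_POLY` plus parameters). The ROI file lists one axis-aligned box per
line: `label lo_slice lo_row lo_col hi_slice hi_row hi_col` (0-based,
half-open). Every correction tunable lives in a YAML config mirrored by
`CorrectionConfig` (unknown keys are rejected); CLI flags override it.

## Python API

```python
import cbctshade as cs

vol = cs.read_volume("shaded.mha")                  # HU volume
res = cs.correct_volume(vol, cs.CorrectionConfig(precorrection=True))
cs.write_volume(res.corrected, "corrected.mha")     # corrected HU volume
res.bias                                            # combined bias field
```

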