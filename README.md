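# octseg

Automatic segmentation of the eight intraretinal layer boundaries in macular
SD-OCT volume scans, built for near-real-time use: a whole 496 × 644 × 51
voxel volume segments in seconds on one CPU.

Quantitative retinal analysis — diagnosing and monitoring glaucoma, macular
degeneration, diabetic retinopathy — needs per-layer thickness maps, which in
turn need the boundaries between the cellular layers of the retina delineated
on every B-scan of a volume.  `octseg` detects, top to bottom: ILM, RNFL_o,
IPL-INL, INL-OPL, OPL_o, IS-OS, OS-RPE and RPE-CH.  It is aimed at
researchers processing exported OCT image stacks who need full
eight-boundary segmentation plus the evaluation metrics to validate it.

## Method

Each boundary in a B-scan is found as a minimum-weight path in a sparse
graph.  A directional matched filter (an 11 × 5 kernel for an axial step
edge, in dark-to-bright and bright-to-dark variants) turns the flattened
B-scan into a normalized gradient image g ∈ [0, 1]; two virtual columns with
g = 1 are appended so the endpoints are automatic.  Each pixel is a vertex,
connected to its eight neighbours with arc weights

    w(a, b) = 2 − (g_a + g_b) + w_min,

so bright edges are cheap to traverse, and Dijkstra's algorithm extracts the
boundary as the shortest path between the virtual columns.

One graph yields one boundary, so the volume is processed by a schedule that
reuses everything already known: per-column *flattening* against a reference
boundary (the previous frame's boundary at the fovea, where intra-frame
references fail), *search-region refinement* from boundaries of the same or
the previous frame (adjacent B-scans differ by less than 10 px), a depth
*bias* map B(z) = z/(M−1) and *masking* to separate multiple edges sharing a
region, and lateral down-sampling by 2 inside each region.  Retinal vessels
cast shadows that erase the outer RNFL boundary; shadowed A-scans are found
by thresholding an enface projection — mean intensity of the IS-OS→RPE-CH
band minus the mean of the 30 px below the ILM — at −0.1, and their gradient
columns are set to 1 so the path bridges them at minimal cost.

Agreement between surface sets is reported as mean signed error ± its
standard deviation (MSE ± SSE), mean unsigned error (MUE) and the
95th-percentile unsigned error (E95), in pixels and microns.

A synthetic phantom generator produces OCT-like volumes — nine reflectivity
bands, smooth curvature, a foveal pit, multiplicative gamma speckle, vessel
shadows — with exactly known ground truth, so the entire pipeline is
testable without clinical data.

## Worked example

```python
from dataclasses import replace
from octseg import (PipelineConfig, compare_surfaces, default_specs,
                    generate_phantom, segment_volume)

spec = replace(default_specs()["vessels_speckle"], seed=1)   # 10 frames,
volume, truth, planted_vessels = generate_phantom(spec)      # speckle, 4 vessels
surfaces, enface = segment_volume(volume, PipelineConfig())
stats = compare_surfaces(surfaces, truth)
print(stats.to_dataframe().to_string(index=False,
      float_format=lambda v: f"{v:.2f}"))
```

```
boundary  mse_px  sse_px  mue_px  e95_px     n  mse_um  sse_um  mue_um  e95_um
     ILM    0.03    0.49    0.38    1.00  5170    0.13    1.92    1.47    3.91
  RNFL_o   -0.03    0.92    0.72    1.82  5170   -0.11    3.60    2.81    7.09
 IPL-INL   -0.02    0.56    0.44    1.11  5170   -0.09    2.18    1.71    4.33
 INL-OPL    0.03    0.54    0.42    1.08  5170    0.10    2.10    1.62    4.22
   OPL_o    0.12    0.52    0.42    1.08  5170    0.48    2.04    1.62    4.22
   IS-OS   -0.03    0.44    0.34    0.90  5170   -0.12    1.73    1.34    3.50
  OS-RPE    0.05    0.55    0.43    1.10  5170    0.18    2.15    1.68    4.28
  RPE-CH    0.31    0.70    0.59    1.51  5170    1.19    2.72    2.31    5.89
 overall    0.06    0.62    0.47    1.26 41360    0.22    2.41    1.82    4.90
```

Every boundary is recovered to sub-pixel mean accuracy (MUE < 1 px ≈ 4 µm,
the bias |MSE| < 0.4 px) against the planted ground truth, with E95 ≈ 1–2 px
even through the speckle and the vessel shadows; `enface.vessel_mask` marks
the shadowed columns.

The same workflow is available from the shell:

```
octseg synth vessels_speckle --seed 1 --out phantom/
octseg segment phantom/ --out detected.csv
octseg evaluate detected.csv phantom/truth_surfaces.csv
```

`segment` accepts any directory of JPEG/PNG/TIFF B-scans with an XML or JSON
sidecar giving the axial/lateral resolutions and frame spacing.

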