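# Methods

## Model

A retinal boundary in a B-scan is modelled as an axial step edge between two
tissue bands of different reflectivity.  An 11 × 5 matched filter — five
identical columns of `[1,1,1,1,1,0,−1,−1,−1,−1,−1]ᵀ`, negated for
bright-to-dark transitions — converts the image into an edge-likelihood map:
the 5-column lateral extent averages speckle, the zero centre tap makes the
response symmetric about the transition.  Negative responses are clamped and
the frame is min–max normalized to [0, 1].

Boundary extraction is a shortest-path problem: one vertex per pixel of the
search region, 8-neighbour arcs weighted `2 − (g_a + g_b) + w_min`, two
virtual columns of gradient 1 appended so any row is a free entry/exit point,
Dijkstra between the top cells of the virtual columns.  Because speckle
produces bright but disconnected pixels, no denoising beyond the kernel's own
averaging is needed: an isolated bright pixel cannot form a cheap path.

The volume schedule assumes (a) healthy macular anatomy — eight ordered
boundaries, the IS-OS the most prominent and flattest, vitreous dark,
IS-OS→RPE band bright; and (b) spatial coherence between adjacent B-scans —
boundary positions change by less than `interframe_margin` (10 px) from frame
to frame.  Under (b), the previous frame supplies both the flattening
reference and a tight search band, which is what makes the method fast and
robust at the fovea, where the same-frame IS-OS reference leaves the ILM
strongly curved and the geometrically-straight-preferring path cuts across
the pit.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `w_min` | 1e-5 | arc-weight stabilization; must be ≪ gradient contrast and > 0 to keep all weights positive |
| `interframe_margin` | 10 px | assumed bound on adjacent-frame boundary motion; sets the inter-frame search band |
| `rpe_band_height` | 40 px | search band below the flattened IS-OS containing OS-RPE and RPE-CH |
| `downsample_factor` | 2 | lateral down-sampling inside each region (layers are smooth between neighbouring columns) |
| `smooth_window` | 5 columns | centred moving average applied after linear re-interpolation; smooths interpolation scallops without erasing foveal curvature |
| `enface_threshold` | −0.1 | columns with enface value below this are vessel shadows |
| `crop_extent_mm` | 6 × 6 | macular region kept around the fovea |
| `fovea_frame_range` | 21–40 (1-based) | frames scanned for the pit; clipped, or replaced by the whole volume when it lies outside a short scan |

Geometry defaults (3.9 µm axial, ~11.6 µm lateral, ~125 µm frame spacing)
mirror a common Spectralis macular export of 61 × 768 × 496 voxels.

## Schedule details and numerical choices

* **Convolution border:** edge replication, so borders produce no spurious
  maxima and the gradient map keeps the frame's shape.
* **Normalization scope:** whole-frame after convolution; per-column min–max
  only inside regions where biasing/masking has reduced the dynamic range
  (RPE pair, inner triplet).  A constant column normalizes to 0, not 0.5, so
  featureless columns do not attract the path.
* **Flattening:** integer per-column shifts to the rounded maximum of the
  reference (downward-or-zero, nothing cropped off the top), edge-replication
  fill; exact inverse recorded and applied to every detected boundary.
  Smoothing runs in flattened region coordinates, before un-flattening.
* **Tie-breaking:** Dijkstra orders by (total weight, cumulative |row
  change|, row).  Exact ties essentially only occur where the gradient is
  constant — vessel columns forced to 1, where every arc costs `w_min` — and
  the secondary key makes the path bridge such regions with the minimal
  staircase instead of an arbitrary equal-weight detour.  The tertiary
  smaller-row preference fixes the remaining ties deterministically, so runs
  are bit-reproducible.
* **IS-OS inter-frame reference:** the previous frame's IS-OS.  A reference
  must run parallel to its target; the previous ILM (detected earlier in the
  per-frame order) would imprint an inverted foveal pit onto the IS-OS, and
  since the RPE-CH edge lies roughly one pit amplitude below, the path then
  cuts across the inverted pit along the RPE-CH.
* **Guard band:** searches bounded by an already-detected edge stay
  `8 px` (kernel half-extent + blur allowance) clear of it — the ILM region
  above the IS-OS, the RNFL_o region above the IPL-INL, and the mask above
  the OPL_o when re-searching for the IPL-INL — because an edge's response
  peaks on, and bleeds beyond, its own row.
* **RPE-CH within the 40-px band:** the band starts at the flattened IS-OS
  row, so the IS-OS's own dark-to-bright response occupies its top; the
  depth-bias map (zero at the band top) suppresses it, the same mechanism
  that suppresses the ILM in the first-frame IS-OS search.
* **Vessel flag direction:** a shadow attenuates the RPE-band term of the
  enface map and the vessel lumen brightens the sub-ILM term, so shadowed
  A-scans have *lower* enface values; vessels are flagged where E < −0.1.
* **E95:** the order statistic at ⌈0.95 n⌉ — the largest unsigned error
  after discarding the top 5% — with no interpolation.  SSE uses the
  population (n) denominator.
* **Ordering:** the eight assembled surfaces must satisfy ILM ≤ RNFL_o ≤ …
  ≤ RPE-CH everywhere; violations raise an error naming the boundary and
  frame rather than being clamped, so algorithmic failures surface in tests.
* **Degenerate inputs:** single-frame volumes run intra-frame modes only; a
  fovea range outside a short volume falls back to all frames; regions
  narrower than twice the down-sampling factor search at full resolution;
  an all-vessel frame degenerates to a straight path at `w_min` cost.

## The phantom

The generator emulates the features the pipeline actually relies on: nine
piecewise-constant reflectivity bands with the transition directions the
kernel schedule expects (the RPE band is rendered darker than the IS-OS band
above and the choroid below); shared smooth curvature (lateral and
inter-frame sinusoids); a Gaussian foveal pit, deepest at the ILM and fading
for deeper boundaries, absent in the outer retina; multiplicative gamma
speckle (shape 16, i.e. σ ≈ 25% of intensity, emulating a device that
averages several sweeps per B-scan); and vessels — bright lumen filling the
RNFL, everything below attenuated to 20% — placed outside the foveal
avascular zone.  Boundaries are rendered with a pixel-coverage convention
(the transition pixel is the 50/50 mix) plus a 1-px axial Gaussian blur, so
the matched filter of a noiseless phantom peaks at exactly the true row.

Two fixtures are built for *exact* recovery: their geometry components are
quantized to integer pixels separately (rounding whole surfaces would leave
single-column notches in flattened coordinates that no 5-column-wide kernel
can resolve), the pit is azimuthally uniform so inter-frame flattening leaves
the ILM exactly flat, its slope stays below 1 px/column, and the boundary
selected through the depth-bias map (OPL_o) is kept flat after flattening
because the bias weighting shifts near-tied step responses by one row.  The
speckled fixtures instead use a realistic steep 2-D pit (28 px ≈ 110 µm deep,
σ ≈ 12 columns), which is what makes the same-frame-flattened ILM search
fail at the pit and demonstrates the value of the inter-frame reference.

What the phantom does **not** model: real speckle correlation, depth-
dependent signal roll-off, motion artefacts, curvature of vessel tracks in
the enface plane (vessels are straight column bands), converging inner
layers that actually touch at the pit, or any pathology (edema, drusen).
Passing phantom tests therefore demonstrates the mechanics of the schedule —
region reuse, bias/mask separation, vessel bridging, exact formula
implementations — not clinical-grade accuracy on diseased eyes.

## Problem sizes used in the tests

The test and acceptance fixtures use 10-frame volumes at full frame size
(496 × 644) and one whole-volume run at 496 × 644 × 51, the size of a
cropped macular acquisition; the graph-search oracle comparison enumerates
all simple paths on grids up to 6 × 6.

## Known limitations

* Boundaries are detected per frame; there is no 3-D surface regularization,
  so the output traces frame-local detail (and frame-local errors) that a
  volumetric method would smooth away.
* The schedule assumes the healthy ordering and reflectivity pattern;
  disrupted anatomy (drusen, edema) violates the flattening and region
  assumptions and is out of scope.
* The ILM detector of the very first frame uses the same-frame IS-OS
  reference; a volume whose first frame contains the foveal pit loses the
  inter-frame advantage there (the standard fovea-centred acquisition does
  not place the pit at the volume edge).
* Exported image intensities are treated as linear; gamma-compressed exports
  are not corrected.
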