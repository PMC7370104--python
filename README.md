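# condylometry

Surface-to-surface accuracy analysis of 3D mandibular-condyle models.

When a CBCT scan is segmented into a surface model of the mandible, the
condylar region is the hardest part to get right: bone there is thin and
poorly contrasted, so threshold-based tools tend to place the boundary
*outside* the true surface (overestimation) while conservative
region-growing tools leave hypodense boundary voxels out
(underestimation).  `condylometry` implements the standard protocol for
quantifying such errors against a manually segmented reference model:

1. **Registration** — a closed-form Kabsch alignment on four operator
   landmarks (mental foramina, lingulae), refined by trimmed
   point-to-surface ICP until the RMS surface distance plateaus below a
   0.01 mm precision.
2. **Condylar ROI** — one cut plane through the sigmoid-notch point Sg,
   perpendicular to the Sg–Li direction (Li = external lingula
   projection), applied in the reference frame to every model so ROI
   definition cannot confound surface error; the cut is capped so
   volumes stay well defined.
3. **Deviation analysis** — for each test-surface vertex the exact
   point-to-triangle distance to the reference, signed by generalized
   winding number (+ outside / − inside), truncated at a 1.00 mm clamp.
   The *matching percentage* is the fraction of samples with
   |d| ≤ tolerance for the ±0.3 and ±0.6 mm bands, and colour-coded PLY
   maps show green within the band, warm colours for overestimation,
   cool for underestimation.
4. **Volumes and statistics** — watertight mesh volumes by the
   divergence theorem; Shapiro–Wilk/Levene gate, Kruskal–Wallis with
   Mann–Whitney post-hocs (exact by enumeration for small samples),
   Wilcoxon signed-rank for paired readings, and intraclass correlation
   coefficients (ICC(3,1) consistency for test-retest, ICC(2,1) absolute
   agreement between operators).

Because clinical CBCT data cannot ship with the package, a
synthetic-phantom module generates condyle-like solids with a
closed-form boundary (so volumes have an analytic oracle), voxelizes
them at the 0.3 mm scan spacing, and simulates threshold segmentation
whose boundary bias is controlled exactly through the partial-volume
blur profile.  The whole protocol therefore runs, and is tested,
end-to-end with known ground truth.

## Worked example

Simulate a permissively thresholded segmentation whose boundary sits
0.15 mm outside the truth, and measure it
(`examples/03_deviation_map.py`):

```text
mean signed deviation : +0.144 mm (positive = overestimation)
volume difference     : +112.1 mm^3
matching at ±0.3 mm   :  94.17 % (950 above, 0 below)
matching at ±0.6 mm   :  99.31 % (113 above, 0 below)
colour map written to deviation_map.ply (green = within ±0.3 mm)
```

The imposed +0.15 mm bias is recovered by the mean signed deviation, the
volume grows by the bias times the surface area, every out-of-band
sample lies on the positive (overestimation) side, and widening the
tolerance band from 0.3 to 0.6 mm raises the matching percentage — the
qualitative signature of threshold overestimation.

The other scripts in `examples/` each demonstrate one capability:
phantom generation against the analytic volume (`01`), recovery of a
known misalignment to sub-0.01 mm RMS (`02`), reliability statistics
with a deliberate between-operator bias (`04`), and the full multi-method
study with its summary tables (`05`).  A thin CLI mirrors the stages
(`condylometry synth|register|roi|deviate|stats|run`).

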