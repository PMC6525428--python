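# Methods

## The measurement problem

A widefield scanning laser ophthalmoscope images the curved posterior
surface of the eye onto a flat raster through an ellipsoid-mirror optical
path. The mapping from visual angle to pixels is therefore neither uniform
nor isotropic: a 5-degree interval near the posterior pole and one at 80
degrees eccentricity occupy different numbers of pixels, and the vertical
and horizontal directions differ. The accepted way to quantify this is a
model eye whose posterior surface carries two perpendicular tapes marked
every 5 degrees; images of the tapes are then read like a ruler.

`fundusqc` automates that reading and, since such calibration images are
rarely public, replaces the physical apparatus with a parameterised
synthetic renderer whose geometry is known exactly. Everything downstream
(measurement, metrics, statistics) operates on images alone and applies
equally to real calibration photographs.

## The projection model

Each image half-axis d (superior, inferior, left, right) carries its own
monotone radial mapping from eccentricity theta (degrees) to pixel distance
from the image center,

    r_d(theta) = f_d * theta + k3_d * theta^3 ,

with f_d > 0 (px/deg) and a cubic term k3_d that magnifies (k3 > 0) or
compresses (k3 < 0) the periphery, plus a transverse scale t_d(theta)
(px/deg perpendicular to the meridian), linearly interpolated between
samples at 0/40/80 degrees and held constant beyond the last sample.
Validation rejects any parameter set with r'_d <= 0 somewhere on the
rendered range. This family is deliberately *not* a physical model of the
ellipsoid-mirror optics: it is the minimal parameterisation that can
express both near-symmetric and strongly anisotropic behaviour (square
ratios from ~1.1 to ~3.3 at 80 degrees) while keeping every derived
quantity analytic.

### Cell geometry

Tape cells are centered on multiples of 5 degrees; the cell "at z" spans
[z - 2.5, z + 2.5] along its meridian, with rendered boundaries at
r_d(5k ± 2.5). For a cell at z > 0:

- radial extent  = r_d(z + 2.5) - r_d(z - 2.5)
- transverse extent = 2 * tape_halfwidth_deg * t_d(z)
  (= 5 * t_d(z) at the default 2.5-degree tape half-width, i.e. a
  5-degree-wide tape, so the transverse extent of the tape *is* the
  5-degree transverse scale)

Height h is the image-vertical extent (radial for superior/inferior,
transverse for left/right) and width w the image-horizontal one. The
center cell spans the pole: h_0 = r_sup(2.5) + r_inf(2.5),
w_0 = r_left(2.5) + r_right(2.5).

### Rendering

Cells alternate white (even index, the center cell counts as 0) and black
(odd), at per-cell configurable gray levels. Rendering happens in a
continuous coordinate frame with 4x supersampling and box downsampling, so
cell edges are anti-aliased and sub-pixel accurate. Degradations apply in
a fixed order — quantisation to 0-255, additive Gaussian noise (clipped),
Gaussian blur, JPEG re-encoding — and the render is a pure function of the
scene spec; the seed governs the noise and nothing else.

Two geometric details matter:

- **Tape crossing.** Under anisotropy the 5-degree-wide horizontal tape
  can be transversely wider than the radial position of the vertical
  tape's first cell boundary, which a naive overlay would occlude (as a
  physically stacked pair of tapes would). The renderer treats the
  junction as a butt joint — the horizontal tape never paints over a
  peripheral cell of the vertical tape — and repaints the vertical tape at
  sub-pixel resolution inside its own bounding box so fringe pixels stay
  exact.
- **Tape end.** A partial outer cell shorter than half a cell is not
  rendered (the tape is cut at the last 5-degree boundary). A shorter
  stub would merge with the tape-end transition and corrupt the outermost
  readable boundary; with this rule the measured field of view equals
  5 * floor(max_angle / 5) exactly whenever contrast permits.

Coordinates are (row, col), row increasing downward; superior is
decreasing row, left is decreasing column. This convention is carried
through all file outputs (0-based indexing).

## Measurement

1. **Axis location.** The tapes are the only bands whose intensity
   alternates along their length, so the mean absolute first difference
   along rows, per column, peaks on the vertical tape (and conversely for
   rows). The center is the half-maximum-weighted centroid of each band,
   after light smoothing. (Plain per-column variance is bimodal — columns
   at the tape edge mix tape and background and have the *highest*
   variance — and mislocates the center; total variation does not.) With
   a center hint the search is confined to ±2% of the image size. On
   clean renders the center is recovered to ~0.1 px; the pipeline only
   assumes it to ~2 px.
2. **Edge detection.** Along each half-axis a 1-D profile is extracted
   (bilinear interpolation, averaged over a 5-px transverse band).
   Candidate boundaries are gradient peaks of the lightly smoothed
   profile; each candidate's plateau levels are estimated as medians on
   both sides, and the edge is refined to the half-maximum crossing,
   linearly interpolated between samples. Half-maximum placement is
   invariant under symmetric blur, robust to global brightness scaling,
   and mimics where a human would set calipers on a bar target.
   A candidate is kept only if its local Michelson contrast reaches the
   readability threshold (default 0.02, chosen below the smallest
   physically reported stripe contrast of 0.03 but above the noise floor)
   *and* 25% of the 75th-percentile candidate contrast — the latter
   rejects compression artifacts (JPEG block steps have ~10-20x less
   contrast than true boundaries) while keeping genuinely faint peripheral
   boundaries (at most ~3-4x fainter than central ones). A trailing edge
   closer than half the previous spacing is discarded as the tape-end
   stub. Edge k (counting from the center) is the boundary at
   2.5 + 5k degrees; cell j lies between edges j-1 and j.
3. **Cells and stripes.** Cell extents come from the detected radial
   boundaries and from the half-maximum tape-to-background crossings of a
   transverse profile at the cell's radial center. Stripe intensities are
   the means of the 2x2 pixel block nearest each stripe's geometric
   center ("central four pixels"); the pair at z is the cell at z and its
   inner neighbour, the darker reported as B. The stripe pair at the
   center is read along the superior meridian and reported as "center".
4. **Field of view.** A marker at 5j degrees is readable when both
   boundaries of its cell are detected at or above the readability
   threshold; with E detected boundaries the field of view is 5(E - 1).
   It is non-increasing in the threshold by construction.

## Metrics and statistics

Aspect ratio h/w, square ratio (h*w)/(h0*w0), contrast |B - W|/(B + W)
(absolute value, so the statistic does not depend on which stripe is
brighter — physically reported contrasts are always positive), directional
amplitude max - min, and replicate summaries mean ± sample SD (n - 1).
Amplitudes are computed per replicate and summarised, and additionally as
the amplitude of the directional means; the two coincide when replicate
noise is direction-independent.

Devices are compared with a two-sided Mann-Whitney U test. For pooled
sizes up to 20 (the typical 10 + 10 replicate design) the p-value is exact:
all C(n1+n2, n1) group assignments of the observed pooled values are
enumerated, with midranks for ties, and the two-sided p is
min(1, 2 * min(P(U <= U_obs), P(U >= U_obs))). Larger samples use the
normal approximation with tie-corrected variance and 0.5 continuity
correction. U always refers to the first sample, so U1 + U2 = n1*n2.
No multiple-testing correction is applied (one comparison per
metric/direction/position is reported, mirroring the original protocol).

## Device-like profiles

The published model-eye measurements of two commercial devices serve as
*parameters* of built-in synthetic profiles: per direction, (f, k3, t40,
t80) are least-squares fitted (log residuals) so the scene's analytic
aspect and square ratios at 40/80 degrees, center aspect ratio and overall
scale match the published directional means; stripe levels are set as
B = m(1 - c), W = m(1 + c) around mean level m = 117 so the configured
contrasts are exact, and each direction's max_angle is the published field
of view. Two caveats:

- The cubic family ties the center cell size to the peripheral extents,
  so all seventeen targets cannot be met simultaneously. The directional
  aspect residuals are weighted 3x — the symmetry pattern is the headline
  quantity — leaving the residual misfit (up to ~4%) in the center aspect
  and square ratios.
- Peripheral contrast is published only for the superior and right
  directions; the left/inferior values in the profile tables are plausible
  fill-ins of the same order, flagged as such in
  `fundusqc.profiles.CONTRAST_FILLED`.

These scenes are ground-truthed stand-ins, not reproductions of physical
hardware; the pipeline's task on them is to recover the *configured*
values.

## What the synthetic data does and does not show

The renderer emulates the geometry and radiometry that the measurement
procedure depends on: direction-dependent monotone projection, alternating
bar cells on a 256-level scale, sensor-like degradations (noise, blur,
JPEG). It does not emulate retinal texture, vessels, reflexes, vignetting,
tape misalignment or rotation of the target relative to the raster axes
(the axes are assumed aligned with image rows/columns, as in a centered
acquisition). Passing the recovery tests therefore demonstrates the
correctness and sub-pixel accuracy of the measurement chain under
controlled conditions, not robustness to arbitrary clinical images.

## Numerical choices and problem sizes

- Inverse of the radial cubic: monotone linear interpolation on a
  4096-point grid (error ~1e-3 px at the scales used).
- Supersampling factor 4: edge positions quantised to 1/4 sub-pixel before
  box averaging, i.e. worst-case ~0.13 px rendering error — consistent
  with the observed < 0.4 px recovery error.
- Scenes render at ~6-7 px/deg (a 5-degree cell is ~30-45 px), frames
  ~1300-1700 px square: large enough that a 1-px error is < 4% of any
  extent, small enough that a full render-measure cycle takes well under a
  second.
- Validation studies use 20 randomised scenes (noiseless and noise SD 5 +
  JPEG quality 90) and 500 null repetitions of the exact test at
  n = 10 vs 10; all sizes chosen so the complete suite runs in seconds
  while keeping the binomial uncertainty of the null rejection rate
  (~±0.02) well inside the accepted band.

## Known limitations

- The measurement assumes the tape axes are pixel-axis aligned; rotated
  targets would need a rectification step first.
- Readable-marker counting assumes contrast stays readable from the center
  outward; an unreadable boundary followed by readable ones truncates the
  reported field of view (a conservative failure).
- The 5-degree-wide tape convention means the measured transverse extent
  *is* the 5-degree transverse scale; for tapes of other widths the
  transverse extent measures the tape, not 5 degrees.
- Field of view is quantised to the 5-degree marker grid; published
  device values averaged over repeated acquisitions fall between markers
  and so sit up to ~4 degrees above the grid floor the pipeline reports.
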