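# fundusqc

Model-eye based quality control of ultra-widefield fundus imaging.

Ultra-widefield scanning laser ophthalmoscopes image ~200 degrees of the
ocular fundus through an ellipsoid mirror, which inevitably distorts the
periphery: equal angular intervals on the retina map to unequal pixel
extents depending on direction and eccentricity. The standard way to
quantify this is to image a physical model eye whose posterior surface
carries two perpendicular tapes marked every 5 degrees of visual angle, and
to measure how each 5-degree cell is rendered. `fundusqc` implements that
whole analysis as a reusable pipeline — and, because model-eye images are
rarely shared, it ships a synthetic scene renderer with exact analytic
ground truth that stands in for the physical hardware.

It is written for imaging scientists and reading-center engineers who need
to characterise or compare widefield devices.

## What is measured

For a calibration image with sub-pixel located center, the pipeline reads,
per direction (superior, inferior, left, right):

- **Maximal angular field of view** — the most peripheral readable
  5-degree marker, judged by local Michelson contrast of its cell
  boundaries.
- **Aspect ratio** `h_z / w_z` — vertical over horizontal pixel extent of
  the 5-degree cell at eccentricity z (protocol positions 0, 40, 80
  degrees). 1.0 means locally symmetric imaging.
- **Square ratio** `S_z / S_0` with `S_z = h_z * w_z` — pixel area of a
  5x5-degree cell relative to the center cell; quantifies peripheral
  enlargement.
- **Stripe contrast** `|B_z - W_z| / (B_z + W_z)` — Michelson contrast of
  the mean intensities of the central four pixels of the adjacent black and
  white stripes (0-255 scale).
- **Amplitude** `max - min` of a metric across the four directions at
  fixed z — the symmetry statistic; smaller is more symmetric.

Replicate acquisitions are summarised as mean and sample SD, and devices
are compared with an exact (enumeration-based, midrank-tied) Mann-Whitney U
test at alpha = 0.05.

Cell extents are measured to sub-pixel precision via half-maximum crossings
of band-averaged intensity profiles; on noiseless synthetic renders every
cell extent is recovered to well under 1 px, and within a few percent under
Gaussian noise plus JPEG re-encoding.

## Worked example

```python
from fundusqc import device_scene, measure_image, render_scene

spec = device_scene("200Tx")        # synthetic profile of a real device
image, truth = render_scene(spec)   # 8-bit image + analytic ground truth
m = measure_image(image)            # measurement uses the image only

print(m.fov.degrees)
for c in m.cells:
    print(c.direction, c.z, round(c.h / c.w, 2))
```

prints

```
{'superior': 85.0, 'inferior': 80.0, 'left': 105.0, 'right': 105.0}
center 0.0 0.91
superior 40.0 0.79
inferior 40.0 0.82
left 40.0 1.01
right 40.0 0.97
superior 80.0 0.42
inferior 80.0 0.6
left 80.0 1.11
right 80.0 1.07
```

The field of view spans 80-105 degrees depending on direction, and the
aspect ratios show the vertically compressed imaging this profile encodes:
0.79-1.01 across directions at 40 degrees (amplitude 0.22) and 0.42-1.11 at
80 degrees — the periphery is strongly anisotropic. The `examples/`
directory has one short script per capability: rendering, measuring,
metric/amplitude tables, and device comparison. A thin CLI wraps the same
stages (`fundusqc simulate | measure | metrics | compare | run`).

## Device-like profiles

`device_scene("200Tx")` and `device_scene("California")` are synthetic
scenes whose projections were least-squares fitted so that their analytic
cell geometry reproduces the published model-eye measurements of the
corresponding commercial devices (directional aspect and square ratios at
40/80 degrees, center aspect ratio, per-direction field of view, stripe
contrasts). They are stand-ins for the physical devices: useful as
realistic, fully ground-truthed test scenes, not as replacements for
measuring real hardware.

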