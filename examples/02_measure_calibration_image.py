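"""Measure a calibration image: field of view, cell geometry, stripes.

Renders the built-in "200Tx-like" device profile (parameterised by that
device's published model-eye measurements) and runs the automated
measurement protocol on the image alone — no ground truth is consulted.
"""

from fundusqc import contrast, device_scene, measure_image, render_scene

spec = device_scene("200Tx")
image, truth = render_scene(spec)

m = measure_image(image)
print(f"located image center at ({m.frame.center[0]:.1f}, "
      f"{m.frame.center[1]:.1f}) px")
print("maximal readable marker per direction (degrees):")
for d, deg in sorted(m.fov.degrees.items()):
    print(f"  {d:9s} {deg:5.0f}")
print("5-degree cell extents (px) and stripe contrast:")
for c in m.cells:
    print(f"  {c.direction:9s} z={c.z:4.0f}  h={c.h:6.2f}  w={c.w:6.2f}  "
          f"aspect={c.h / c.w:.2f}")
for s in m.stripes:
    print(f"  {s.direction:9s} z={s.z:4.0f}  B={s.B:6.1f}  W={s.W:6.1f}  "
          f"contrast={contrast(s.B, s.W):.3f}")
print("The aspect ratios below 1 in the vertical directions reproduce the "
      "vertically compressed imaging this device profile encodes.")
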