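"""Render a degraded synthetic bull's-eye pattern and measure it.

Builds a pattern from the study lens's spec sheet (total diameter 10.89 mm,
BOZD 6.79 mm) with a 4.2 mm central bearing, degrades it with blur, sensor
noise and JPEG compression, runs the full measurement pipeline, and prints
the recovered zone widths next to the generating ground truth.
"""

from okfluor import SEEFREE, measure_raster, pattern_from_lens, render_pattern

MM_PER_PX = 0.012

spec = pattern_from_lens(
    SEEFREE, central_bearing_mm=4.2, mm_per_px=MM_PER_PX,
    width_px=1000, height_px=640,
    blur_sigma=2.0, noise_sd=0.01, jpeg_quality=85, seed=7,
)
image, truth = render_pattern(spec)
result = measure_raster(image, lens=SEEFREE, image_id="synthetic")

d1, d2, d3, d4 = truth.diameters_px
truth_mm = {
    "total_diameter": d1 * MM_PER_PX,
    "edge_lift": (d1 - d2) / 2 * MM_PER_PX,
    "mid_peripheral": (d2 - d3) / 2 * MM_PER_PX,
    "tear_reservoir": (d3 - d4) / 2 * MM_PER_PX,
    "central_bearing": d4 * MM_PER_PX,
}
w = result.widths
measured_mm = {
    "total_diameter": w.total_diameter_mm,
    "edge_lift": w.edge_lift_mm,
    "mid_peripheral": w.mid_peripheral_mm,
    "tear_reservoir": w.tear_reservoir_mm,
    "central_bearing": w.central_bearing_mm,
}

print(f"detected {len(result.peaks)} derivative peaks; "
      f"edge assignment: {result.edge_set.provenance}")
print(f"calibration: {w.mm_per_px:.4f} mm/px "
      f"(nominal diameter {SEEFREE.total_diameter_mm} mm)")
print(f"{'zone':<16}{'truth (mm)':>12}{'measured (mm)':>15}{'error (mm)':>12}")
for zone in truth_mm:
    t, m = truth_mm[zone], measured_mm[zone]
    print(f"{zone:<16}{t:>12.3f}{m:>15.3f}{m - t:>12.3f}")
print("\nEach row is one fluorescein zone width along the horizontal "
      "meridian; errors within ~0.03 mm are at the single-pixel level.")
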