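"""Synthetic fluorescein bull's-eye patterns with known zone geometry.

An ideal ortho-k fluorescein pattern alternates dark and bright concentric
zones: a dark central bearing (near lens-cornea contact), a bright tear
reservoir annulus, a dark mid-peripheral alignment annulus, and a bright
edge-lift ring, all on a dark background.  The generator renders these as
piecewise-constant annuli in the green channel (red/blue a fixed fraction
of green, emulating a blue-light / yellow-filter photograph), then applies
optional Gaussian blur, additive sensor noise and JPEG re-encoding.  The
generating boundary diameters give an exact ground-truth EdgeSet, so every
pipeline stage is testable without the study's photographs.

This is a geometric fixture, not a physical tear-film fluorescence model:
intensity does not encode tear-layer thickness, the lens is perfectly
centered and circular, and illumination is uniform.
"""

from __future__ import annotations

import io
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
from PIL import Image
from scipy.ndimage import gaussian_filter

from .edges import EdgeSet, LensSpec
from .imaging import RasterImage

__all__ = ["PatternSpec", "render_pattern", "pattern_from_lens", "write_pattern"]

#: Red and blue channel level relative to green.
RB_FRACTION = 0.25


@dataclass(frozen=True)
class PatternSpec:
    """Geometry, photometry and degradation parameters of one pattern.

    Boundary diameters ``d1 > d2 > d3 > d4`` (px) are, outside-in: lens
    outer edge, edge-lift/alignment, alignment/reservoir and
    reservoir/central-bearing.  Intensity levels are in [0, 1]; the bright
    rings (reservoir, edge lift) must exceed every dark level by >= 0.2 so
    edges stay detectable.  ``blur_sigma`` is the Gaussian blur in px,
    ``noise_sd`` the additive Gaussian noise SD (clipped to [0, 1]), and
    ``jpeg_quality`` an optional 1-95 JPEG re-encode quality.
    """

    width_px: int = 1000
    height_px: int = 600
    cx: float = 500.0
    cy: float = 300.0
    d1: float = 900.0
    d2: float = 820.0
    d3: float = 700.0
    d4: float = 400.0
    background: float = 0.05
    edge_lift_ring: float = 0.75
    alignment_ring: float = 0.15
    reservoir_ring: float = 0.9
    central_zone: float = 0.1
    blur_sigma: float = 0.0
    noise_sd: float = 0.0
    jpeg_quality: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.d1 > self.d2 > self.d3 > self.d4 > 0):
            raise ValueError(
                f"diameters must satisfy d1 > d2 > d3 > d4 > 0, got "
                f"{(self.d1, self.d2, self.d3, self.d4)}"
            )
        # the outer ring may be clipped top/bottom (as in real cropped photos)
        # but must fit horizontally so both meridian crossings are in frame
        if self.d1 > self.width_px:
            raise ValueError(
                f"outer diameter d1={self.d1} exceeds image width {self.width_px}"
            )
        for name in ("background", "edge_lift_ring", "alignment_ring", "reservoir_ring", "central_zone"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        dark_max = max(self.central_zone, self.alignment_ring, self.background)
        for name in ("reservoir_ring", "edge_lift_ring"):
            if getattr(self, name) - dark_max < 0.2:
                raise ValueError(
                    f"bright level {name}={getattr(self, name)} must exceed every "
                    f"dark level (max {dark_max}) by at least 0.2"
                )
        if self.blur_sigma < 0 or self.noise_sd < 0:
            raise ValueError("blur_sigma and noise_sd must be >= 0")
        if self.jpeg_quality is not None and not 1 <= self.jpeg_quality <= 95:
            raise ValueError(f"jpeg_quality must be in [1, 95], got {self.jpeg_quality}")

    def ground_truth_edges(self) -> EdgeSet:
        """Horizontal-meridian crossings implied by the diameters: cx +/- d(k)/2."""
        x = np.array(
            [
                self.cx - self.d1 / 2,
                self.cx - self.d2 / 2,
                self.cx - self.d3 / 2,
                self.cx - self.d4 / 2,
                self.cx + self.d4 / 2,
                self.cx + self.d3 / 2,
                self.cx + self.d2 / 2,
                self.cx + self.d1 / 2,
            ]
        )
        return EdgeSet(x, provenance="manual")


def render_pattern(spec: PatternSpec) -> tuple[RasterImage, EdgeSet]:
    """Render the pattern; returns the RGB image and the ground-truth edges.

    The green channel is piecewise constant over the concentric annuli
    (a pixel belongs to the innermost zone whose boundary circle contains
    its center), blurred, noise-corrupted with a seeded generator, and
    optionally JPEG round-tripped.  Same spec + seed gives identical bytes
    before JPEG and encoder-stable bytes after.
    """
    yy, xx = np.mgrid[0 : spec.height_px, 0 : spec.width_px]
    r = np.hypot(xx - spec.cx, yy - spec.cy)
    green = np.full((spec.height_px, spec.width_px), spec.background, dtype=np.float64)
    green[r <= spec.d1 / 2] = spec.edge_lift_ring
    green[r <= spec.d2 / 2] = spec.alignment_ring
    green[r <= spec.d3 / 2] = spec.reservoir_ring
    green[r <= spec.d4 / 2] = spec.central_zone
    rgb = np.stack([RB_FRACTION * green, green, RB_FRACTION * green], axis=-1)
    if spec.blur_sigma > 0:
        rgb = gaussian_filter(rgb, sigma=(spec.blur_sigma, spec.blur_sigma, 0))
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        rgb = rgb + rng.normal(0.0, spec.noise_sd, size=rgb.shape)
    rgb = np.clip(rgb, 0.0, 1.0)
    if spec.jpeg_quality is not None:
        buf = io.BytesIO()
        Image.fromarray((rgb * 255).round().astype(np.uint8)).save(
            buf, format="JPEG", quality=spec.jpeg_quality
        )
        buf.seek(0)
        rgb = np.asarray(Image.open(buf), dtype=np.float64) / 255.0
    return RasterImage(rgb), spec.ground_truth_edges()


def pattern_from_lens(
    lens: LensSpec,
    central_bearing_mm: float,
    mm_per_px: float,
    width_px: int = 1000,
    height_px: int = 1000,
    cx: float | None = None,
    cy: float | None = None,
    **kwargs,
) -> PatternSpec:
    """Derive a PatternSpec from a lens spec sheet and a target bearing width.

    The fluorescein boundaries map onto the lens geometry: the outer
    boundary at the total diameter, the edge-lift/alignment boundary at
    D0 + 2*D1 + 2*D2, the alignment/reservoir boundary at D0 + 2*D1, and
    the bearing boundary at the chosen central-bearing diameter — which
    must be smaller than the back optic zone diameter, since fluorescein
    clearance starts inside the BOZD edge.  ``mm_per_px`` scales mm to px.
    """
    if mm_per_px <= 0:
        raise ValueError(f"mm_per_px must be > 0, got {mm_per_px}")
    for name in ("bozd_mm", "reverse_width_mm", "alignment_width_mm"):
        if getattr(lens, name) is None:
            raise ValueError(f"lens spec is missing {name}")
    if central_bearing_mm >= lens.bozd_mm:
        raise ValueError(
            f"central bearing {central_bearing_mm} mm must be smaller than the "
            f"back optic zone diameter {lens.bozd_mm} mm"
        )
    d1 = lens.total_diameter_mm / mm_per_px
    d3 = (lens.bozd_mm + 2 * lens.reverse_width_mm) / mm_per_px
    d2 = (lens.bozd_mm + 2 * lens.reverse_width_mm + 2 * lens.alignment_width_mm) / mm_per_px
    d4 = central_bearing_mm / mm_per_px
    # keep nesting if the spec sheet's zones do not quite tile the diameter
    d2 = min(d2, d1 - 1e-9)
    if not d1 > d2 > d3 > d4 > 0:
        raise ValueError(
            f"lens geometry yields non-nested diameters {(d1, d2, d3, d4)} px"
        )
    return PatternSpec(
        width_px=width_px,
        height_px=height_px,
        cx=width_px / 2.0 if cx is None else cx,
        cy=height_px / 2.0 if cy is None else cy,
        d1=d1,
        d2=d2,
        d3=d3,
        d4=d4,
        **kwargs,
    )


def write_pattern(
    spec: PatternSpec, image_path: str | Path, sidecar_path: str | Path | None = None
) -> tuple[Path, Path]:
    """Write the rendered image (PNG or JPEG by suffix) plus a JSON sidecar.

    The sidecar records the full PatternSpec and the ground-truth edge
    positions, so a measurement run can be scored against the truth.
    """
    image_path = Path(image_path)
    if sidecar_path is None:
        sidecar_path = image_path.with_suffix(image_path.suffix + ".json")
    sidecar_path = Path(sidecar_path)
    img, truth = render_pattern(spec)
    arr = (img.pixels * 255).round().astype(np.uint8)
    pil = Image.fromarray(arr)
    if image_path.suffix.lower() in (".jpg", ".jpeg"):
        pil.save(image_path, quality=spec.jpeg_quality or 95)
    else:
        pil.save(image_path)
    sidecar = {
        "pattern_spec": asdict(spec),
        "ground_truth_edges_px": truth.x.tolist(),
        "ground_truth_diameters_px": truth.diameters_px.tolist(),
    }
    sidecar_path.write_text(json.dumps(sidecar, indent=2) + "\n")
    return image_path, sidecar_path
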