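"""End-to-end measurement of one photograph or a batch of files."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import edges as ed
from . import imaging as im

__all__ = ["MeasureConfig", "MeasureResult", "measure_image", "measure_raster", "measure_batch"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MeasureConfig:
    """Pipeline parameters; defaults are the standard processing constants
    (1,000 px working width, 60 px meridian band)."""

    target_width: int = 1000
    band_height: int = 60
    reducer: str = "mean"
    smoothing_sigma: float = 2.0
    min_prominence_frac: float = 0.1
    min_separation_px: int = 10
    mode: str = "auto"  # "auto" | "manual"

    def __post_init__(self) -> None:
        if self.mode not in ("auto", "manual"):
            raise ValueError(f"mode must be 'auto' or 'manual', got {self.mode!r}")


@dataclass(frozen=True)
class MeasureResult:
    """Everything a diagnostic review needs for one image."""

    image_id: str
    profile: im.IntensityProfile
    derivative: im.DerivativeProfile
    peaks: im.PeakSet
    edge_set: ed.EdgeSet
    widths: ed.ZoneWidths

    def rows(self, observer: str = "auto") -> list[dict]:
        """Long-format measurement rows (one per zone) for CSV export."""
        w = self.widths
        zones = {
            "total_diameter": (w.total_diameter_px, w.total_diameter_mm if w.calibrated else None),
            "edge_lift": (w.edge_lift_px, w.edge_lift_mm if w.calibrated else None),
            "mid_peripheral": (w.mid_peripheral_px, w.mid_peripheral_mm if w.calibrated else None),
            "tear_reservoir": (w.tear_reservoir_px, w.tear_reservoir_mm if w.calibrated else None),
            "central_bearing": (w.central_bearing_px, w.central_bearing_mm if w.calibrated else None),
        }
        return [
            {
                "image_id": self.image_id,
                "observer": observer,
                "method": "algorithm",
                "zone": zone,
                "width_px": px,
                "width_mm": mm,
                "mm_per_px": w.mm_per_px,
                "edge_provenance": self.edge_set.provenance,
            }
            for zone, (px, mm) in zones.items()
        ]


def measure_raster(
    img: im.RasterImage,
    lens: ed.LensSpec | None = None,
    config: MeasureConfig = MeasureConfig(),
    manual_indices=None,
    image_id: str = "<array>",
) -> MeasureResult:
    """Measure an in-memory image; see :func:`measure_image`."""
    _, profile, deriv, peaks = im.preprocess(
        img,
        target_width=config.target_width,
        band_height=config.band_height,
        reducer=config.reducer,
        smoothing_sigma=config.smoothing_sigma,
        min_prominence_frac=config.min_prominence_frac,
        min_separation_px=config.min_separation_px,
    )
    if config.mode == "manual":
        if manual_indices is None:
            raise ValueError("manual mode requires the eight chosen peak indices")
        edge_set = ed.assign_edges_manual(peaks, manual_indices)
    else:
        edge_set = ed.assign_edges_auto(peaks, config.target_width)
    widths = ed.widths_from_edges(edge_set)
    if lens is not None:
        widths = ed.calibrate(widths, lens)
    return MeasureResult(image_id, profile, deriv, peaks, edge_set, widths)


def measure_image(
    path: str | Path,
    lens: ed.LensSpec | None = None,
    config: MeasureConfig = MeasureConfig(),
    manual_indices=None,
) -> MeasureResult:
    """Measure one photograph: preprocess, assign edges, compute widths.

    With a ``lens`` the widths are calibrated to mm (anchored to the
    nominal total diameter); without one only pixel widths are filled.
    ``manual_indices`` selects the eight edge peaks when
    ``config.mode == "manual"``.
    """
    img = im.load_image(path)
    return measure_raster(
        img, lens=lens, config=config, manual_indices=manual_indices, image_id=Path(path).name
    )


def measure_batch(
    paths,
    lens: ed.LensSpec | None = None,
    config: MeasureConfig = MeasureConfig(),
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Measure many files, continuing past per-image failures.

    Returns (long-format measurement frame, {image_id: failure reason}).
    """
    rows: list[dict] = []
    failures: dict[str, str] = {}
    for path in paths:
        path = Path(path)
        try:
            result = measure_image(path, lens=lens, config=config)
        except Exception as exc:  # per-image isolation is the point
            logger.error("failed to measure %s: %s", path, exc)
            failures[path.name] = str(exc)
            continue
        rows.extend(result.rows())
    columns = [
        "image_id", "observer", "method", "zone",
        "width_px", "width_mm", "mm_per_px", "edge_provenance",
    ]
    return pd.DataFrame(rows, columns=columns), failures
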