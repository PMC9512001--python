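"""Zone-boundary assignment, width formulas and pixel-to-mm calibration.

The derivative-peak detector typically finds the eight true zone-boundary
crossings plus a few spurious peaks.  The "semiautomatic" step selects the
eight peaks that form four nested, midline-symmetric pairs — automatically
(exact minimization of the total symmetry residual) or manually (observer
supplies the eight indices).  From the four boundary diameters d(1) > d(2)
> d(3) > d(4) the zone widths follow:

    total diameter   = d(1)
    edge lift        = (d(1) - d(2)) / 2
    mid-peripheral   = (d(2) - d(3)) / 2
    tear reservoir   = (d(3) - d(4)) / 2
    central bearing  = d(4)

Pixels convert to millimeters by anchoring the measured total diameter to
the manufacturer's nominal total lens diameter.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from itertools import combinations
from pathlib import Path

import numpy as np

from .imaging import PeakSet

__all__ = [
    "LensSpec",
    "EdgeSet",
    "ZoneWidths",
    "InsufficientEdgesError",
    "AssignmentFailureError",
    "assign_edges_auto",
    "assign_edges_manual",
    "widths_from_edges",
    "calibrate",
    "check_lens_geometry",
    "read_lens_spec",
    "SEEFREE",
]

logger = logging.getLogger(__name__)

ZONES = ("central_bearing", "tear_reservoir", "mid_peripheral", "edge_lift")

#: Fraction of image width beyond which the inferred lens center is flagged
#: as decentered (the study discarded photographs with decentered lenses).
DECENTER_FRAC = 0.05


class InsufficientEdgesError(ValueError):
    """Fewer than eight candidate peaks; cannot form four boundary pairs."""


class AssignmentFailureError(ValueError):
    """No nesting-consistent selection of four symmetric pairs exists."""


@dataclass(frozen=True)
class LensSpec:
    """Reverse-geometry lens description used for calibration.

    ``bozd_mm`` (D0) is the back optic zone diameter; D1–D3 are the annular
    widths of the reverse, alignment and edge-lift zones.  Back-surface
    radii (R0–R3) are carried for completeness but unused by measurement.
    """

    total_diameter_mm: float
    bozd_mm: float | None = None
    reverse_width_mm: float | None = None
    alignment_width_mm: float | None = None
    edge_lift_width_mm: float | None = None
    bozr_mm: float | None = None
    reverse_radius_mm: float | None = None
    alignment_radius_mm: float | None = None
    peripheral_radius_mm: float | None = None

    def __post_init__(self) -> None:
        for name in (
            "total_diameter_mm",
            "bozd_mm",
            "reverse_width_mm",
            "alignment_width_mm",
            "edge_lift_width_mm",
            "bozr_mm",
            "reverse_radius_mm",
            "alignment_radius_mm",
            "peripheral_radius_mm",
        ):
            val = getattr(self, name)
            if val is not None and val <= 0:
                raise ValueError(f"{name} must be > 0, got {val}")


#: Mean geometry of the study lens (Seefree, Conoptica-Hecht Contactlinsen).
SEEFREE = LensSpec(
    total_diameter_mm=10.89,
    bozd_mm=6.79,
    reverse_width_mm=0.60,
    alignment_width_mm=0.85,
    edge_lift_width_mm=0.60,
    bozr_mm=8.40,
    reverse_radius_mm=7.19,
    alignment_radius_mm=8.08,
    peripheral_radius_mm=12.19,
)


@dataclass(frozen=True)
class EdgeSet:
    """Eight ordered horizontal-meridian crossings of the four boundaries.

    ``x`` is strictly increasing, indexed L1 < L2 < L3 < L4 < R4 < R3 < R2
    < R1 where (Lk, Rk) are the crossings of boundary circle k (1 = lens
    outer edge, 4 = reservoir/central-bearing boundary).  ``provenance``
    is ``"automatic"`` or ``"manual"``; ``decentered`` flags a lens-center
    offset above :data:`DECENTER_FRAC` of the image width.
    """

    x: np.ndarray
    provenance: str = "automatic"
    decentered: bool = False

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=np.float64)
        if x.shape != (8,):
            raise ValueError(f"an EdgeSet needs exactly 8 positions, got {x.shape}")
        if not np.all(np.diff(x) > 0):
            raise ValueError(f"edge positions must be strictly increasing: {x.tolist()}")
        d = self.__class__.diameters_of(x)
        if not (d[0] > d[1] > d[2] > d[3] > 0):
            raise ValueError(
                f"boundary diameters must be strictly nested and positive, got {d.tolist()}"
            )
        object.__setattr__(self, "x", x)

    @staticmethod
    def diameters_of(x: np.ndarray) -> np.ndarray:
        """d(k) = Rk - Lk for k = 1..4 given sorted crossings."""
        x = np.asarray(x, dtype=np.float64)
        return np.array([x[7] - x[0], x[6] - x[1], x[5] - x[2], x[4] - x[3]])

    @property
    def diameters_px(self) -> np.ndarray:
        return self.diameters_of(self.x)

    @property
    def center_px(self) -> float:
        """Lens center: mean midpoint of the four boundary pairs."""
        x = self.x
        return float(np.mean([(x[i] + x[7 - i]) / 2 for i in range(4)]))


@dataclass(frozen=True)
class ZoneWidths:
    """The five measurements in px and, after calibration, in mm.

    Closure holds exactly in px arithmetic:
    central_bearing + 2*(tear_reservoir + mid_peripheral + edge_lift)
    = total_diameter.
    """

    total_diameter_px: float
    edge_lift_px: float
    mid_peripheral_px: float
    tear_reservoir_px: float
    central_bearing_px: float
    mm_per_px: float | None = None
    lens: LensSpec | None = None

    @property
    def calibrated(self) -> bool:
        return self.mm_per_px is not None

    def _mm(self, px: float) -> float:
        if self.mm_per_px is None:
            raise ValueError("widths are not calibrated; call calibrate() first")
        return px * self.mm_per_px

    @property
    def total_diameter_mm(self) -> float:
        return self._mm(self.total_diameter_px)

    @property
    def edge_lift_mm(self) -> float:
        return self._mm(self.edge_lift_px)

    @property
    def mid_peripheral_mm(self) -> float:
        return self._mm(self.mid_peripheral_px)

    @property
    def tear_reservoir_mm(self) -> float:
        return self._mm(self.tear_reservoir_px)

    @property
    def central_bearing_mm(self) -> float:
        return self._mm(self.central_bearing_px)

    def as_dict(self) -> dict[str, float]:
        out = {
            "total_diameter_px": self.total_diameter_px,
            "edge_lift_px": self.edge_lift_px,
            "mid_peripheral_px": self.mid_peripheral_px,
            "tear_reservoir_px": self.tear_reservoir_px,
            "central_bearing_px": self.central_bearing_px,
        }
        if self.calibrated:
            out.update(
                mm_per_px=self.mm_per_px,
                total_diameter_mm=self.total_diameter_mm,
                edge_lift_mm=self.edge_lift_mm,
                mid_peripheral_mm=self.mid_peripheral_mm,
                tear_reservoir_mm=self.tear_reservoir_mm,
                central_bearing_mm=self.central_bearing_mm,
            )
        return out


def _pair_selections(positions: np.ndarray, image_width: int):
    """Yield (total_residual, x8) over all nesting-consistent 4-pair subsets.

    A nesting-consistent selection is 4 left peaks and 4 right peaks with
    every left < every right; sorting then forces the pairing (outermost
    left with outermost right, etc.), which automatically satisfies the
    strict diameter nesting d(1) > d(2) > d(3) > d(4).  Every pair must
    straddle the vertical midline.
    """
    mid = image_width / 2.0
    pos = np.asarray(positions, dtype=np.float64)
    left = pos[pos < mid]
    right = pos[pos >= mid]
    for lsel in combinations(sorted(left), 4):
        for rsel in combinations(sorted(right), 4):
            x8 = np.array(lsel + rsel, dtype=np.float64)
            d = EdgeSet.diameters_of(x8)
            if not (d[0] > d[1] > d[2] > d[3] > 0):
                continue
            resid = sum(
                abs((x8[i] + x8[7 - i]) / 2 - mid) for i in range(4)
            )
            yield resid, x8


def assign_edges_auto(peaks: PeakSet, image_width: int) -> EdgeSet:
    """Select the eight zone-boundary edges among the candidate peaks.

    Chooses the four nested pairs straddling the image midline that
    minimize the total symmetry residual sum_k |(Lk + Rk)/2 - W/2| — the
    cropped lens is centered by construction, so the true boundary pairs
    are the most midline-symmetric ones.  The search is exact (enumeration
    over 4-left/4-right peak subsets); ties break toward the
    lexicographically smallest position vector.
    """
    if len(peaks) < 8:
        raise InsufficientEdgesError(
            f"only {len(peaks)} candidate peaks; 8 are required. "
            "Use manual assignment or relax prominence/separation thresholds."
        )
    best: tuple[float, tuple[float, ...]] | None = None
    for resid, x8 in _pair_selections(peaks.positions, image_width):
        key = (resid, tuple(x8))
        if best is None or key < best:
            best = key
    if best is None:
        raise AssignmentFailureError(
            "no nesting-consistent selection of 4 midline-straddling pairs exists"
        )
    x8 = np.array(best[1])
    center = float(np.mean([(x8[i] + x8[7 - i]) / 2 for i in range(4)]))
    decentered = abs(center - image_width / 2.0) > DECENTER_FRAC * image_width
    if decentered:
        logger.warning(
            "inferred lens center %.1f px is offset more than %.0f%% of the "
            "image width from the midline; the lens may be decentered",
            center,
            100 * DECENTER_FRAC,
        )
    return EdgeSet(x8, provenance="automatic", decentered=decentered)


def assign_edges_manual(peaks: PeakSet, chosen_indices) -> EdgeSet:
    """Build an EdgeSet from eight observer-chosen peak indices.

    Mirrors the study's observer-driven protocol: the observer inspects
    the derivative plot and picks the eight peaks that correspond to real
    zone boundaries.  Indices may be given in any order; duplicates,
    out-of-range indices or a nesting violation raise ``ValueError``.
    """
    idx = list(chosen_indices)
    if len(idx) != 8:
        raise ValueError(f"exactly 8 peak indices are required, got {len(idx)}")
    if len(set(idx)) != 8:
        raise ValueError(f"duplicate peak indices in {idx}")
    for i in idx:
        if not 0 <= i < len(peaks):
            raise ValueError(f"peak index {i} out of range [0, {len(peaks)})")
    x8 = np.sort(peaks.positions[np.asarray(idx, dtype=np.int64)]).astype(np.float64)
    d = EdgeSet.diameters_of(x8)
    for k in range(3):
        if d[k] <= d[k + 1]:
            raise ValueError(
                f"nesting violation: boundary {k + 1} diameter {d[k]:.1f} px is not "
                f"greater than boundary {k + 2} diameter {d[k + 1]:.1f} px"
            )
    return EdgeSet(x8, provenance="manual")


def widths_from_edges(edges: EdgeSet) -> ZoneWidths:
    """Apply the zone-width formulas to the four boundary diameters.

    Half-width divisions use exact (possibly fractional) px values.
    """
    d1, d2, d3, d4 = edges.diameters_px
    return ZoneWidths(
        total_diameter_px=d1,
        edge_lift_px=(d1 - d2) / 2.0,
        mid_peripheral_px=(d2 - d3) / 2.0,
        tear_reservoir_px=(d3 - d4) / 2.0,
        central_bearing_px=d4,
    )


def calibrate(widths: ZoneWidths, lens: LensSpec) -> ZoneWidths:
    """Anchor pixel widths to the nominal lens diameter.

    mm_per_px = nominal total diameter / measured total diameter (px), so
    the calibrated total diameter equals the nominal diameter by
    construction.  Full precision is retained; round only at presentation.
    """
    if widths.total_diameter_px <= 0:
        raise ValueError("cannot calibrate: measured total diameter is not positive")
    mm_per_px = lens.total_diameter_mm / widths.total_diameter_px
    return replace(widths, mm_per_px=mm_per_px, lens=lens)


def check_lens_geometry(lens: LensSpec) -> float:
    """Closure residual total - (D0 + 2*(D1 + D2 + D3)) in mm.

    |residual| <= 0.01 mm passes silently; larger residuals log a warning
    (the spec sheet's zone widths should tile the lens diameter).
    """
    missing = [
        name
        for name in ("bozd_mm", "reverse_width_mm", "alignment_width_mm", "edge_lift_width_mm")
        if getattr(lens, name) is None
    ]
    if missing:
        raise ValueError(f"lens spec is missing zone fields: {', '.join(missing)}")
    residual = lens.total_diameter_mm - (
        lens.bozd_mm
        + 2.0 * (lens.reverse_width_mm + lens.alignment_width_mm + lens.edge_lift_width_mm)
    )
    if abs(residual) > 0.01:
        logger.warning(
            "lens geometry closure residual %.3f mm exceeds 0.01 mm: total "
            "diameter disagrees with D0 + 2*(D1 + D2 + D3)",
            residual,
        )
    return residual


_LENS_FIELD_ALIASES = {
    "total_diameter_mm": "total_diameter_mm",
    "d0": "bozd_mm",
    "bozd_mm": "bozd_mm",
    "d1": "reverse_width_mm",
    "reverse_width_mm": "reverse_width_mm",
    "d2": "alignment_width_mm",
    "alignment_width_mm": "alignment_width_mm",
    "d3": "edge_lift_width_mm",
    "edge_lift_width_mm": "edge_lift_width_mm",
    "r0": "bozr_mm",
    "bozr_mm": "bozr_mm",
    "r1": "reverse_radius_mm",
    "reverse_radius_mm": "reverse_radius_mm",
    "r2": "alignment_radius_mm",
    "alignment_radius_mm": "alignment_radius_mm",
    "r3": "peripheral_radius_mm",
    "peripheral_radius_mm": "peripheral_radius_mm",
}


def read_lens_spec(path: str | Path) -> LensSpec:
    """Read a LensSpec from a small key-value file.

    One ``key = value`` (or ``key: value``) pair per line; ``#`` starts a
    comment.  Keys are the spec-sheet names (total_diameter_mm, D0–D3,
    R0–R3) or the full field names, case-insensitive.
    """
    fields: dict[str, float] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        for sep in ("=", ":"):
            if sep in line:
                key, _, value = line.partition(sep)
                break
        else:
            raise ValueError(f"{path}:{lineno}: expected 'key = value', got {raw!r}")
        key = key.strip().lower()
        if key not in _LENS_FIELD_ALIASES:
            raise ValueError(f"{path}:{lineno}: unknown lens field {key!r}")
        try:
            fields[_LENS_FIELD_ALIASES[key]] = float(value.strip())
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: non-numeric value {value.strip()!r}") from exc
    if "total_diameter_mm" not in fields:
        raise ValueError(f"{path}: lens spec must define total_diameter_mm")
    return LensSpec(**fields)
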