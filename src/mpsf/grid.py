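"""Microperimetry stimulus grid, coordinate conversion and ETDRS sectors.

Stimulus locations are expressed in degrees relative to the foveal centre,
``x`` positive toward the nasal retina of a right eye (mirrored for left
eyes) and ``y`` positive superior.  The default pattern is a high-density
concentric-ring layout of 45 points within 4 deg of the fovea: one central
point plus rings of 4, 8, 8, 12 and 12 points at 0.5, 1, 2, 3 and 4 deg.

ETDRS sectors follow the standard macular grid: a central disc of 1 mm
diameter (sector 1), an inner annulus 1-3 mm and an outer annulus 3-6 mm,
each split into superior / nasal / inferior / temporal quadrants on the
+-45 deg diagonals (sectors 2-5 inner, 6-9 outer, in S, N, I, T order).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import ScanGeometry

#: Sector code for points beyond the 6 mm ETDRS circle.
SECTOR_OUTSIDE = -1

_RING_ECC_DEG = (0.5, 1.0, 2.0, 3.0, 4.0)
_RING_COUNTS = (4, 8, 8, 12, 12)
_RING_PHASE_DEG = (45.0, 0.0, 22.5, 0.0, 15.0)


@dataclass(frozen=True)
class StimulusGrid:
    """An ordered stimulus pattern in foveal degree coordinates."""

    spot_ids: tuple[int, ...]
    x_deg: tuple[float, ...]
    y_deg: tuple[float, ...]

    def __post_init__(self) -> None:
        n = len(self.spot_ids)
        if not (len(self.x_deg) == len(self.y_deg) == n):
            raise ValueError("spot_ids, x_deg, y_deg must have equal length")
        pts = set(zip(self.x_deg, self.y_deg))
        if len(pts) != n:
            raise ValueError("duplicate stimulus positions")

    def __len__(self) -> int:
        return len(self.spot_ids)

    @property
    def coords_deg(self) -> np.ndarray:
        """(n, 2) array of (x_deg, y_deg)."""
        return np.column_stack([self.x_deg, self.y_deg])

    @property
    def eccentricities_deg(self) -> np.ndarray:
        return np.hypot(np.asarray(self.x_deg), np.asarray(self.y_deg))

    @property
    def max_eccentricity_deg(self) -> float:
        return float(self.eccentricities_deg.max(initial=0.0))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"spot_id": self.spot_ids, "x_deg": self.x_deg, "y_deg": self.y_deg}
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "StimulusGrid":
        return cls(
            spot_ids=tuple(int(s) for s in df["spot_id"]),
            x_deg=tuple(float(v) for v in df["x_deg"]),
            y_deg=tuple(float(v) for v in df["y_deg"]),
        )

    @classmethod
    def from_csv(cls, path) -> "StimulusGrid":
        return cls.from_frame(pd.read_csv(path))


def generate_default_grid() -> StimulusGrid:
    """Build the default 45-point high-density pattern.

    One central stimulus plus concentric rings of 4, 8, 8, 12 and 12
    points at 0.5, 1, 2, 3 and 4 deg eccentricity, i.e. an 8 deg diameter
    field with density increasing toward the fovea.  Spot ids are 1-based,
    ordered centre outward, counter-clockwise from each ring's phase
    offset.
    """
    ids = [1]
    xs = [0.0]
    ys = [0.0]
    next_id = 2
    for ecc, count, phase in zip(_RING_ECC_DEG, _RING_COUNTS, _RING_PHASE_DEG):
        for k in range(count):
            theta = math.radians(phase + 360.0 * k / count)
            ids.append(next_id)
            xs.append(round(ecc * math.cos(theta), 12))
            ys.append(round(ecc * math.sin(theta), 12))
            next_id += 1
    return StimulusGrid(tuple(ids), tuple(xs), tuple(ys))


def eccentricity(x_deg: float, y_deg: float) -> float:
    """Angular distance from the foveal centre, degrees."""
    return math.hypot(x_deg, y_deg)


def deg_to_px(
    x_deg,
    y_deg,
    fovea_px: tuple[float, float],
    geometry: ScanGeometry,
):
    """Convert foveal degree offsets to continuous raster coordinates.

    Returns ``(x_px, y_px, in_raster)``; accepts scalars or arrays.
    Coordinates are not rounded; ``in_raster`` flags points whose
    continuous position lies within the pixel-centre bounding box.
    """
    x_deg = np.asarray(x_deg, dtype=float)
    y_deg = np.asarray(y_deg, dtype=float)
    x_px = fovea_px[0] + x_deg * geometry.mm_per_degree / geometry.ascan_spacing_mm
    y_px = fovea_px[1] + y_deg * geometry.mm_per_degree / geometry.bscan_spacing_mm
    in_raster = (
        (x_px >= 0) & (x_px <= geometry.n_ascan - 1)
        & (y_px >= 0) & (y_px <= geometry.n_bscan - 1)
    )
    if x_px.ndim == 0:
        return float(x_px), float(y_px), bool(in_raster)
    return x_px, y_px, in_raster


def px_to_deg(x_px, y_px, fovea_px: tuple[float, float], geometry: ScanGeometry):
    """Inverse of :func:`deg_to_px` (raster px -> foveal degrees)."""
    x_px = np.asarray(x_px, dtype=float)
    y_px = np.asarray(y_px, dtype=float)
    x_deg = (x_px - fovea_px[0]) * geometry.ascan_spacing_mm / geometry.mm_per_degree
    y_deg = (y_px - fovea_px[1]) * geometry.bscan_spacing_mm / geometry.mm_per_degree
    if x_deg.ndim == 0:
        return float(x_deg), float(y_deg)
    return x_deg, y_deg


def assign_etdrs_sector(
    x_deg: float,
    y_deg: float,
    laterality: str,
    mm_per_degree: float = 0.30,
) -> int:
    """Assign a stimulus to its ETDRS sector.

    Radial bands at 0.5 / 1.5 / 3.0 mm from the fovea; quadrants split on
    the +-45 deg diagonals with ties going to the vertical (superior or
    inferior) quadrant.  For left eyes the horizontal axis is mirrored so
    that "nasal" and "temporal" keep their anatomical meaning.

    Returns 1 for the central subfield, 2-5 (inner S, N, I, T), 6-9
    (outer S, N, I, T), or :data:`SECTOR_OUTSIDE` beyond 3.0 mm.
    """
    if laterality not in ("OD", "OS"):
        raise ValueError("laterality must be 'OD' or 'OS'")
    x_mm = x_deg * mm_per_degree
    y_mm = y_deg * mm_per_degree
    r_mm = math.hypot(x_mm, y_mm)
    if r_mm < 0.5:
        return 1
    if r_mm > 3.0:
        return SECTOR_OUTSIDE
    # nasal is +x for right eyes by package convention
    x_nasal = x_mm if laterality == "OD" else -x_mm
    if y_mm >= abs(x_nasal):
        quadrant = 0  # superior
    elif y_mm <= -abs(x_nasal):
        quadrant = 2  # inferior
    elif x_nasal > 0:
        quadrant = 1  # nasal
    else:
        quadrant = 3  # temporal
    base = 2 if r_mm <= 1.5 else 6
    return base + quadrant


def sector_table(grid: StimulusGrid, laterality: str,
                 mm_per_degree: float = 0.30) -> pd.DataFrame:
    """Per-spot sector assignments as a two-column table."""
    sectors = [
        assign_etdrs_sector(x, y, laterality, mm_per_degree)
        for x, y in zip(grid.x_deg, grid.y_deg)
    ]
    return pd.DataFrame({"spot_id": grid.spot_ids, "sector": sectors})
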