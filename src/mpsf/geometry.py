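"""OCT raster geometry.

The scan raster is a grid of A-scans (fast axis, ``x``) by B-scans (slow
axis, ``y``) covering a square angular field.  All physical quantities are
derived from the angular extent and an eye-model conversion factor
(mm per degree of visual angle).  With the default 20 deg x 20 deg field
sampled at 1024 x 97 and 0.30 mm/deg, the unit en-face pixel area is
(6.0/1024) x (6.0/97) mm^2 ~= 0.000362 mm^2.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field


@dataclass(frozen=True)
class ScanGeometry:
    """Dimensions and physical scaling of an en-face OCT raster.

    Parameters
    ----------
    n_ascan : int
        Number of A-scans per B-scan (raster width, ``x``).
    n_bscan : int
        Number of B-scans (raster height, ``y``).
    n_axial : int
        Axial samples per A-scan (carried for provenance; en-face maps do
        not use it).
    extent_deg : float
        Angular width (= height) of the scanned field, degrees.
    mm_per_degree : float
        Retinal mm per degree of visual angle (emmetropic schematic-eye
        default 0.30).
    """

    n_ascan: int = 1024
    n_bscan: int = 97
    n_axial: int = 496
    extent_deg: float = 20.0
    mm_per_degree: float = 0.30

    def __post_init__(self) -> None:
        if self.n_ascan <= 0 or self.n_bscan <= 0 or self.n_axial <= 0:
            raise ValueError("raster dimensions must be positive")
        if self.extent_deg <= 0 or self.mm_per_degree <= 0:
            raise ValueError("extent_deg and mm_per_degree must be positive")

    @property
    def extent_mm(self) -> float:
        return self.extent_deg * self.mm_per_degree

    @property
    def ascan_spacing_mm(self) -> float:
        """Centre-to-centre A-scan spacing along x, mm."""
        return self.extent_mm / self.n_ascan

    @property
    def bscan_spacing_mm(self) -> float:
        """Centre-to-centre B-scan spacing along y, mm."""
        return self.extent_mm / self.n_bscan

    @property
    def pixel_area_mm2(self) -> float:
        """Unit en-face pixel area (A-scan spacing x B-scan spacing), mm^2."""
        return self.ascan_spacing_mm * self.bscan_spacing_mm

    @property
    def shape(self) -> tuple[int, int]:
        """En-face array shape ``(n_bscan, n_ascan)`` (row = B-scan)."""
        return (self.n_bscan, self.n_ascan)

    @property
    def centre_px(self) -> tuple[float, float]:
        """Raster centre in continuous pixel coordinates ``(x, y)``."""
        return ((self.n_ascan - 1) / 2.0, (self.n_bscan - 1) / 2.0)

    def to_dict(self) -> dict:
        return {
            "n_ascan": self.n_ascan,
            "n_bscan": self.n_bscan,
            "n_axial": self.n_axial,
            "extent_deg": self.extent_deg,
            "mm_per_degree": self.mm_per_degree,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ScanGeometry":
        return cls(**{k: d[k] for k in
                      ("n_ascan", "n_bscan", "n_axial", "extent_deg", "mm_per_degree")
                      if k in d})

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "ScanGeometry":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


DEFAULT_GEOMETRY = ScanGeometry()
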