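"""Landmark-based affine registration of fundus photographs to the OCT frame.

The microperimeter reports stimulus locations on its colour fundus
photograph (CFP); lesion maps live on the OCT/SLO en-face raster.  Given
corresponding keypoints marked in both frames, a full 6-parameter 2D
affine CFP->SLO transform is estimated by linear least squares, and the
stimulus pattern (degrees around the CFP fovea) is projected into raster
coordinates through it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import ScanGeometry
from .grid import StimulusGrid


class RegistrationError(ValueError):
    """Raised for degenerate keypoint configurations or frame mismatches."""


@dataclass(frozen=True)
class AffineTransform:
    """2D affine map ``y = A x + b`` between labelled frames.

    ``matrix`` is the 2x2 linear part, ``offset`` the translation.
    """

    matrix: np.ndarray
    offset: np.ndarray
    frame_from: str = "CFP"
    frame_to: str = "SLO"

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float).reshape(2, 2)
        b = np.asarray(self.offset, dtype=float).reshape(2)
        if abs(np.linalg.det(m)) < 1e-12:
            raise RegistrationError("affine linear part is singular")
        object.__setattr__(self, "matrix", m)
        object.__setattr__(self, "offset", b)

    def apply(self, points) -> np.ndarray:
        """Map (n, 2) or (2,) points from the source to the target frame."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        out = pts @ self.matrix.T + self.offset
        return out[0] if np.asarray(points).ndim == 1 else out

    def inverse(self) -> "AffineTransform":
        inv = np.linalg.inv(self.matrix)
        return AffineTransform(inv, -inv @ self.offset,
                               frame_from=self.frame_to, frame_to=self.frame_from)

    def compose(self, inner: "AffineTransform") -> "AffineTransform":
        """Return ``self o inner`` (apply ``inner`` first)."""
        if inner.frame_to != self.frame_from:
            raise RegistrationError(
                f"frame mismatch: cannot compose {self.frame_from}->{self.frame_to} "
                f"after {inner.frame_from}->{inner.frame_to}")
        return AffineTransform(
            self.matrix @ inner.matrix,
            self.matrix @ inner.offset + self.offset,
            frame_from=inner.frame_from, frame_to=self.frame_to)

    @property
    def params(self) -> np.ndarray:
        """Six parameters ``(a11, a12, a21, a22, b1, b2)``."""
        return np.concatenate([self.matrix.ravel(), self.offset])

    def to_dict(self) -> dict:
        return {"matrix": self.matrix.tolist(), "offset": self.offset.tolist(),
                "frame_from": self.frame_from, "frame_to": self.frame_to}

    @classmethod
    def from_dict(cls, d: dict) -> "AffineTransform":
        return cls(np.asarray(d["matrix"]), np.asarray(d["offset"]),
                   d.get("frame_from", "CFP"), d.get("frame_to", "SLO"))

    @classmethod
    def identity(cls, frame_from: str = "CFP", frame_to: str = "SLO") -> "AffineTransform":
        return cls(np.eye(2), np.zeros(2), frame_from, frame_to)


@dataclass
class AffineFit:
    """Estimated transform plus least-squares diagnostics."""

    transform: AffineTransform
    residuals_px: np.ndarray  # per-point residual vectors in the target frame
    rms_px: float
    n_points: int

    @property
    def residual_norms_px(self) -> np.ndarray:
        return np.linalg.norm(self.residuals_px, axis=1)


def estimate_affine(
    src_points,
    dst_points,
    frame_from: str = "CFP",
    frame_to: str = "SLO",
) -> AffineFit:
    """Least-squares affine from ``src`` to ``dst`` keypoints.

    Solves ``min sum ||A x_i + b - y_i||^2`` via a QR-based ``lstsq`` on
    the homogeneous design matrix.  Requires at least 3 non-collinear
    source points.
    """
    src = np.atleast_2d(np.asarray(src_points, dtype=float))
    dst = np.atleast_2d(np.asarray(dst_points, dtype=float))
    if src.shape != dst.shape or src.shape[1] != 2:
        raise RegistrationError("keypoint arrays must both be (n, 2)")
    n = src.shape[0]
    if n < 3:
        raise RegistrationError("at least 3 keypoint pairs are required")
    design = np.column_stack([src, np.ones(n)])
    if np.linalg.matrix_rank(design) < 3:
        raise RegistrationError("keypoints are collinear; affine is unidentifiable")
    coef, *_ = np.linalg.lstsq(design, dst, rcond=None)
    matrix = coef[:2].T
    offset = coef[2]
    t = AffineTransform(matrix, offset, frame_from, frame_to)
    resid = t.apply(src) - dst
    rms = float(np.sqrt(np.mean(np.sum(resid**2, axis=1))))
    return AffineFit(transform=t, residuals_px=resid, rms_px=rms, n_points=n)


def estimate_affine_from_table(df: pd.DataFrame) -> AffineFit:
    """Estimate from a keypoint table with x_cfp, y_cfp, x_slo, y_slo columns."""
    return estimate_affine(df[["x_cfp", "y_cfp"]].to_numpy(),
                           df[["x_slo", "y_slo"]].to_numpy())


def map_grid_to_oct(
    grid: StimulusGrid,
    fovea_cfp: tuple[float, float],
    cfp_scale_px_per_deg: float,
    transform: AffineTransform,
    geometry: ScanGeometry,
) -> pd.DataFrame:
    """Project stimulus locations into OCT raster coordinates.

    Each spot's degree offset is placed on the CFP as
    ``fovea_cfp + scale * (x_deg, y_deg)`` and mapped through the CFP->SLO
    transform.  Returns a frame with spot_id, x_px, y_px and an in_raster
    flag; raises :class:`RegistrationError` if no spot lands on the raster.
    """
    if cfp_scale_px_per_deg <= 0:
        raise ValueError("cfp_scale_px_per_deg must be positive")
    cfp_pts = np.asarray(fovea_cfp, dtype=float) + cfp_scale_px_per_deg * grid.coords_deg
    slo_pts = transform.apply(cfp_pts)
    x_px, y_px = slo_pts[:, 0], slo_pts[:, 1]
    in_raster = (
        (x_px >= 0) & (x_px <= geometry.n_ascan - 1)
        & (y_px >= 0) & (y_px <= geometry.n_bscan - 1)
    )
    if not in_raster.any():
        raise RegistrationError("alignment failure: no stimulus maps into the raster")
    return pd.DataFrame({
        "spot_id": grid.spot_ids,
        "x_px": x_px,
        "y_px": y_px,
        "in_raster": in_raster,
    })
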