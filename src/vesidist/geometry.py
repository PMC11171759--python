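"""Intensity-weighted geometry of a thresholded cell.

Every pixel with intensity strictly above the threshold theta contributes a
weight proportional to its excess intensity, omega_i ∝ (y_i - theta); pixels
at or below theta carry zero weight and are excluded. From the weighted
point cloud the centre of mass

    c = sum_i omega_i x_i / sum_i omega_i

and the radius of gyration

    R_g = sqrt( sum_i omega_i ||x_i - c||^2 / sum_i omega_i )

are computed. R_g serves as the per-cell size normaliser: distances divided
by R_g are dimensionless and comparable across differently sized cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import ImageStack

__all__ = [
    "QCError",
    "CellGeometry",
    "compute_weights",
    "center_of_mass",
    "distances",
    "radius_of_gyration",
    "cell_geometry",
]


class QCError(ValueError):
    """A cell failing quality control (e.g. no suprathreshold pixels).

    Raised instead of producing degenerate output so pipelines can record
    the cell in an exclusion list rather than crash or silently drop it.
    """


def compute_weights(
    stack: ImageStack | np.ndarray, theta: float
) -> tuple[np.ndarray, np.ndarray]:
    """Suprathreshold pixel centres and normalized excess-intensity weights.

    Returns ``(coords, weights)`` where ``coords`` is an (n, 3) float array
    of voxel indices (z, y, x) of pixels with intensity strictly above
    ``theta``, and ``weights`` are the excesses (y_i - theta) normalized to
    sum to 1.

    Raises
    ------
    QCError
        If no pixel exceeds theta (the cell is rejected, not analysed).
    """
    data = stack.data if isinstance(stack, ImageStack) else np.asarray(stack)
    mask = data > theta
    if not mask.any():
        raise QCError("no suprathreshold pixels")
    coords = np.argwhere(mask).astype(np.float64)
    raw = data[mask].astype(np.float64) - theta
    return coords, raw / raw.sum()


def _check_weights(coords: np.ndarray, weights: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    coords = np.atleast_2d(np.asarray(coords, dtype=np.float64))
    weights = np.asarray(weights, dtype=np.float64).reshape(-1)
    if coords.shape[0] == 0:
        raise QCError("empty point cloud")
    if coords.shape[0] != weights.shape[0]:
        raise ValueError("coords and weights length mismatch")
    if np.any(weights <= 0):
        raise ValueError("weights must all be > 0")
    if abs(weights.sum() - 1.0) > 1e-9:
        raise ValueError("weights must sum to 1")
    return coords, weights


def center_of_mass(coords: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Weighted centre of mass c = sum_i omega_i x_i."""
    coords, weights = _check_weights(coords, weights)
    return weights @ coords


def distances(
    coords: np.ndarray,
    center: np.ndarray,
    spacing: tuple[float, float, float] | None = None,
) -> np.ndarray:
    """Euclidean distances d_i = ||x_i - c||, optionally in physical units.

    When ``spacing`` is given, the index-space offsets are scaled
    componentwise by (dz, dy, dx) before the norm, honouring anisotropic
    voxels. With the default spacing of None distances are in pixel units.
    """
    center = np.asarray(center, dtype=np.float64)
    if not np.all(np.isfinite(center)):
        raise ValueError("center must be finite")
    diff = np.atleast_2d(np.asarray(coords, dtype=np.float64)) - center
    if spacing is not None:
        diff = diff * np.asarray(spacing, dtype=np.float64)
    return np.linalg.norm(diff, axis=1)


def radius_of_gyration(
    coords: np.ndarray,
    weights: np.ndarray,
    center: np.ndarray,
    spacing: tuple[float, float, float] | None = None,
) -> float:
    """R_g = sqrt( sum_i omega_i d_i^2 ) for normalized weights."""
    coords, weights = _check_weights(coords, weights)
    d = distances(coords, center, spacing=spacing)
    return float(np.sqrt(np.sum(weights * d * d)))


@dataclass
class CellGeometry:
    """Weighted suprathreshold point cloud of one cell.

    ``coords`` are in the physical coordinate space (voxel index scaled by
    spacing); ``center`` and ``rg`` share those units. With the default
    isotropic unit spacing everything is in pixel units.
    """

    coords: np.ndarray
    weights: np.ndarray
    center: np.ndarray
    rg: float
    theta: float
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    cell_id: str = ""
    group: str = ""
    _distances: np.ndarray | None = field(default=None, repr=False)

    @property
    def n_pixels(self) -> int:
        return int(self.coords.shape[0])

    @property
    def distances(self) -> np.ndarray:
        """Per-pixel distance from the centre of mass (cached)."""
        if self._distances is None:
            self._distances = distances(self.coords, self.center)
        return self._distances


def cell_geometry(stack: ImageStack, theta: float) -> CellGeometry:
    """Threshold a stack and compute its weighted geometry.

    Voxel indices are scaled by the stack spacing before any distance is
    computed, so anisotropic voxels are handled once, up front.
    """
    idx, weights = compute_weights(stack, theta)
    coords = idx * np.asarray(stack.spacing, dtype=np.float64)
    c = center_of_mass(coords, weights)
    rg = radius_of_gyration(coords, weights, c)
    return CellGeometry(
        coords=coords,
        weights=weights,
        center=c,
        rg=rg,
        theta=float(theta),
        spacing=stack.spacing,
        cell_id=stack.cell_id,
        group=stack.group,
    )
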