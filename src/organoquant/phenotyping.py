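"""Per-organoid measurement and viability classification.

Each segmented instance is reduced to a small record: area, centroid, mean
raw pixel intensity, and eccentricity.  Dark organoids in bright-field
imaging indicate an unhealthy state, so an organoid whose mean intensity
falls strictly below a fixed 8-bit cutoff (default 50) is classified
``unhealthy``, otherwise ``healthy``.

Eccentricity measures the deviation of the region shape from a perfect
circle: with lam1 >= lam2 the eigenvalues of the region's second central
moment (covariance) matrix,

    eccentricity = sqrt(1 - lam2 / lam1)

which is 0 for a circle and approaches 1 for an elongated region.  Regions
too small to carry shape information (< 5 px, or with a degenerate moment
matrix) are assigned eccentricity 0 by convention; in practice the debris
filter removes them before they are measured.

Intensities are always taken from the RAW frame, never from the
illumination-flattened image used for segmentation: the cutoff is defined on
acquired image intensity, and flattening would silently move the boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
from skimage.measure import regionprops

from .segmentation import Frame

__all__ = [
    "OrganoidRecord",
    "HealthThreshold",
    "region_features",
    "measure_frame",
    "classify_health",
]

#: pixel-count floor below which shape moments are meaningless
_DEGENERATE_AREA_PX = 5


@dataclass(frozen=True)
class OrganoidRecord:
    """Measurements of one organoid instance at one time point."""

    well_id: str
    condition_id: str
    time_h: float
    label: int
    area_px: int
    centroid_rc: tuple[float, float]
    mean_intensity: float
    eccentricity: float
    area_um2: Optional[float] = None
    health: Optional[str] = None  # {healthy, unhealthy}
    size_bin: Optional[str] = None  # {Tiny, Small, Medium, Large, Huge}


@dataclass(frozen=True)
class HealthThreshold:
    """Mean-intensity cutoff separating healthy from unhealthy organoids."""

    cutoff: float = 50.0

    def __post_init__(self) -> None:
        if not 0 <= self.cutoff <= 255:
            raise ValueError(f"cutoff must be within [0, 255], got {self.cutoff}")


def _eccentricity(prop) -> float:
    """Moment eccentricity of one region with the degenerate conventions."""
    if prop.area < _DEGENERATE_AREA_PX:
        return 0.0
    lam1, lam2 = prop.inertia_tensor_eigvals  # lam1 >= lam2
    if lam1 <= 0:
        return 0.0
    ecc = float(np.sqrt(1.0 - lam2 / lam1))
    # A collinear region is mathematically eccentricity 1; keep the value
    # strictly inside [0, 1).
    return min(ecc, 1.0 - 1e-9)


def _record_from_prop(
    prop, frame: Frame, pixel_size_um: Optional[float]
) -> OrganoidRecord:
    area_px = int(prop.area)
    return OrganoidRecord(
        well_id=frame.well_id,
        condition_id=frame.condition_id,
        time_h=frame.time_h,
        label=int(prop.label),
        area_px=area_px,
        centroid_rc=(float(prop.centroid[0]), float(prop.centroid[1])),
        mean_intensity=float(prop.intensity_mean),
        eccentricity=_eccentricity(prop),
        area_um2=(area_px * pixel_size_um**2) if pixel_size_um else None,
    )


def region_features(
    frame: Frame,
    mask: np.ndarray,
    label: int,
    pixel_size_um: Optional[float] = None,
) -> OrganoidRecord:
    """Measure one labeled region of ``frame``; health/size bin left unset."""
    mask = np.asarray(mask)
    if mask.shape != frame.shape:
        raise ValueError(
            f"mask shape {mask.shape} does not match frame shape {frame.shape}"
        )
    for prop in regionprops(mask.astype(np.int64), intensity_image=frame.pixels):
        if prop.label == label:
            return _record_from_prop(prop, frame, pixel_size_um)
    raise KeyError(f"label {label} not present in mask")


def measure_frame(
    frame: Frame,
    mask: np.ndarray,
    pixel_size_um: Optional[float] = None,
) -> list[OrganoidRecord]:
    """Measure every instance of a mask, ordered by label."""
    mask = np.asarray(mask)
    if mask.shape != frame.shape:
        raise ValueError(
            f"mask shape {mask.shape} does not match frame shape {frame.shape}"
        )
    props = regionprops(mask.astype(np.int64), intensity_image=frame.pixels)
    props.sort(key=lambda p: p.label)
    return [_record_from_prop(p, frame, pixel_size_um) for p in props]


def classify_health(
    record: OrganoidRecord, threshold: HealthThreshold = HealthThreshold()
) -> OrganoidRecord:
    """Set the health class: unhealthy iff mean intensity < cutoff (strict)."""
    health = "unhealthy" if record.mean_intensity < threshold.cutoff else "healthy"
    return replace(record, health=health)
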