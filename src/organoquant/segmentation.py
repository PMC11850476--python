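"""Instance segmentation of bright-field organoid frames.

Organoids in transmitted-light (bright-field) imaging appear as dark-rimmed,
roughly elliptical objects on a bright, noisy background.  This module turns
a single frame into an integer instance label mask, either with a classical
pipeline --

    illumination flattening -> global threshold -> hole filling ->
    distance-transform watershed -> minimum-area (debris) filter

-- or by ingesting an externally produced mask (e.g. the output of a learned
star-convex segmenter), which is passed through the same debris filter and
relabeling so that downstream measurements are identical for both routes.

Masks follow one convention throughout the package: ``0`` is background,
instances are contiguous positive integers ``1..n`` ordered by region
centroid (row-major), and every instance is a single 8-connected component.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import tifffile
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu
from skimage.measure import regionprops
from skimage.segmentation import watershed

from .errors import AlignmentError, DimensionalityError, FormatError

__all__ = [
    "Frame",
    "SegmentationConfig",
    "flatten_illumination",
    "segment_frame",
    "load_labels",
    "relabel_mask",
    "star_convexity_score",
]

#: 8-connectivity structuring element used for all connected-component labeling.
_STRUCT8 = np.ones((3, 3), dtype=bool)

# Minimum Otsu inter-class mean separation (8-bit levels) below which an
# auto-thresholded frame is treated as empty.  Pure-noise frames otherwise
# split their noise distribution in half and percolate into one huge region.
_MIN_OTSU_CONTRAST = 16.0


@dataclass(frozen=True)
class Frame:
    """One time-stamped grayscale image of one well.

    Parameters
    ----------
    pixels
        2-D ``uint8`` raster (intensities 0-255 after loading).
    time_h
        Acquisition time in hours from the start of the series.
    well_id, condition_id
        Plate metadata carried through to every measurement.
    """

    pixels: np.ndarray
    time_h: float
    well_id: str = ""
    condition_id: str = ""

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise DimensionalityError(
                f"frame pixels must be 2-D, got {px.ndim}-D for well "
                f"{self.well_id!r} at t={self.time_h}"
            )
        if px.size == 0:
            raise DimensionalityError("frame pixels are empty")
        if self.time_h < 0:
            raise ValueError(f"time_h must be >= 0, got {self.time_h}")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class SegmentationConfig:
    """Parameters of the classical segmentation backend.

    ``min_area_px`` implements the debris floor: fragments smaller than this
    are not detectable organoids and are removed from every mask, whether
    produced internally or ingested.  ``watershed_min_distance_px <= 0``
    disables touching-object splitting (plain connected components).
    """

    method: str = "classical"  # {classical, external}
    intensity_polarity: str = "dark_objects"  # {dark_objects, bright_objects}
    background_sigma_px: float = 25.0
    threshold_mode: str = "auto"  # {auto, fixed}
    fixed_threshold: float = 128.0
    min_area_px: int = 200
    watershed_min_distance_px: float = 15.0
    fill_holes: bool = True

    def __post_init__(self) -> None:
        if self.min_area_px < 1:
            raise ValueError(f"min_area_px must be >= 1, got {self.min_area_px}")
        if self.background_sigma_px <= 0:
            raise ValueError(
                f"background_sigma_px must be > 0, got {self.background_sigma_px}"
            )
        if self.method not in ("classical", "external"):
            raise ValueError(f"unknown method {self.method!r}")
        if self.intensity_polarity not in ("dark_objects", "bright_objects"):
            raise ValueError(f"unknown polarity {self.intensity_polarity!r}")
        if self.threshold_mode not in ("auto", "fixed"):
            raise ValueError(f"unknown threshold_mode {self.threshold_mode!r}")


def _estimate_background(img: np.ndarray, sigma: float) -> np.ndarray:
    """Gaussian-weighted local plane fit of the illumination field.

    A plain Gaussian blur is biased near the image border (the window is
    one-sided there), which leaves a residual gradient after flattening.
    Fitting a local *plane* under the same Gaussian weights (normalized
    convolution) is exact for constant and linearly shaded fields
    everywhere, borders included.
    """
    rows, cols = img.shape
    # centered coordinates keep the normal equations well conditioned
    r = (np.arange(rows, dtype=np.float64) - rows / 2.0)[:, None] * np.ones(
        (1, cols)
    )
    c = np.ones((rows, 1)) * (np.arange(cols, dtype=np.float64) - cols / 2.0)[None, :]

    def smooth(a):
        return ndi.gaussian_filter(a, sigma=sigma, mode="constant", cval=0.0)

    ones = np.ones_like(img)
    n, sr, sc = smooth(ones), smooth(r), smooth(c)
    srr, scc, src = smooth(r * r), smooth(c * c), smooth(r * c)
    si, sir, sic = smooth(img), smooth(img * r), smooth(img * c)

    normal = np.stack(
        [
            np.stack([n, sr, sc], axis=-1),
            np.stack([sr, srr, src], axis=-1),
            np.stack([sc, src, scc], axis=-1),
        ],
        axis=-2,
    )
    rhs = np.stack([si, sir, sic], axis=-1)
    coef = np.linalg.solve(normal, rhs[..., None])[..., 0]
    return coef[..., 0] + coef[..., 1] * r + coef[..., 2] * c


def flatten_illumination(frame: Frame, background_sigma_px: float) -> Frame:
    """Divide out the large-scale illumination trend of a frame.

    The background is estimated by a Gaussian-weighted local plane fit at
    scale ``background_sigma_px``; the image is divided by it and rescaled
    back to the 8-bit range around the global background level, so a flat
    field is left (up to rounding) unchanged and object/background contrast
    ratios are preserved.  The result is used for segmentation only; health
    classification always reads raw intensities.
    """
    if background_sigma_px <= 0:
        raise ValueError("background_sigma_px must be > 0")
    img = np.asarray(frame.pixels, dtype=np.float64)
    if img.ndim != 2:
        raise DimensionalityError(f"expected 2-D image, got {img.ndim}-D")
    background = _estimate_background(img, background_sigma_px)
    background = np.maximum(background, 1e-9)
    flat = img / background * background.mean()
    flat = np.clip(np.rint(flat), 0, 255).astype(np.uint8)
    return replace(frame, pixels=flat)


def _watershed_split(foreground: np.ndarray, min_distance_px: float) -> np.ndarray:
    """Split touching objects with a distance-transform watershed.

    Seeds are local maxima of the (lightly smoothed) Euclidean distance map
    separated by at least ``min_distance_px``; components that receive no
    seed (small or flat) are seeded at their distance maximum so no region
    is lost.
    """
    distance = ndi.distance_transform_edt(foreground)
    # Smoothing removes rasterization plateaus that would seed one object twice.
    smooth = ndi.gaussian_filter(distance, sigma=max(1.0, min_distance_px / 4.0))
    coords = peak_local_max(
        smooth,
        min_distance=max(1, int(round(min_distance_px))),
        labels=foreground,
        exclude_border=False,
    )
    markers = np.zeros(foreground.shape, dtype=np.int32)
    for i, (r, c) in enumerate(coords, start=1):
        markers[r, c] = i
    components, n_comp = ndi.label(foreground, structure=_STRUCT8)
    seeded = set(np.unique(components[markers > 0])) - {0}
    next_marker = len(coords) + 1
    for comp_id in range(1, n_comp + 1):
        if comp_id in seeded:
            continue
        inside = components == comp_id
        flat_idx = np.argmax(np.where(inside, distance, -1.0))
        markers[np.unravel_index(flat_idx, foreground.shape)] = next_marker
        next_marker += 1
    return watershed(-smooth, markers, mask=foreground, connectivity=2)


def _filter_small(labels: np.ndarray, min_area_px: int) -> np.ndarray:
    """Zero out instances smaller than the debris floor."""
    if labels.max() == 0:
        return labels
    ids, counts = np.unique(labels[labels > 0], return_counts=True)
    keep = set(ids[counts >= min_area_px].tolist())
    out = np.where(np.isin(labels, list(keep)), labels, 0)
    return out


def relabel_mask(labels: np.ndarray) -> np.ndarray:
    """Relabel instances as contiguous 1..n ordered by centroid (row-major)."""
    labels = np.asarray(labels)
    out = np.zeros(labels.shape, dtype=np.int32)
    props = regionprops(labels.astype(np.int64))
    props.sort(key=lambda p: (p.centroid[0], p.centroid[1]))
    for new_id, p in enumerate(props, start=1):
        out[labels == p.label] = new_id
    return out


def segment_frame(frame: Frame, config: SegmentationConfig) -> np.ndarray:
    """Segment one bright-field frame into an instance label mask.

    Returns an ``int32`` mask of ``frame.shape``; 0 is background and
    instances are contiguous positive integers.  An image with no detectable
    objects yields a valid all-zero mask, never an error.
    """
    if config.method != "classical":
        raise ValueError(
            "segment_frame implements the classical backend; use load_labels "
            "for externally produced masks"
        )
    flat = flatten_illumination(frame, config.background_sigma_px).pixels
    flat_f = flat.astype(np.float64)

    if config.threshold_mode == "fixed":
        threshold = float(config.fixed_threshold)
    else:
        if flat.min() == flat.max():
            return np.zeros(frame.shape, dtype=np.int32)
        threshold = float(threshold_otsu(flat))

    if config.intensity_polarity == "dark_objects":
        foreground = flat_f < threshold
    else:
        foreground = flat_f > threshold

    if config.threshold_mode == "auto" and foreground.any() and (~foreground).any():
        # Reject splits of pure noise: class means must be clearly separated.
        contrast = abs(flat_f[~foreground].mean() - flat_f[foreground].mean())
        if contrast < _MIN_OTSU_CONTRAST:
            return np.zeros(frame.shape, dtype=np.int32)

    if config.fill_holes:
        foreground = ndi.binary_fill_holes(foreground)

    if config.watershed_min_distance_px and config.watershed_min_distance_px > 0:
        labels = _watershed_split(foreground, config.watershed_min_distance_px)
    else:
        labels, _ = ndi.label(foreground, structure=_STRUCT8)

    labels = _filter_small(labels, config.min_area_px)
    return relabel_mask(labels)


def load_labels(path: str | Path, frame: Frame, min_area_px: int = 200) -> np.ndarray:
    """Ingest an externally produced instance mask for ``frame``.

    The mask is validated against the frame shape, split so that every
    instance is one connected component, passed through the same
    ``min_area_px`` debris filter as internally produced masks, and relabeled
    contiguously.  Downstream measurements are therefore identical whichever
    segmenter produced the mask.
    """
    raw = tifffile.imread(str(path))
    raw = np.asarray(raw)
    if raw.ndim != 2:
        raise FormatError(f"mask {path} is not a single-page 2-D raster")
    if raw.shape != frame.shape:
        raise AlignmentError(
            f"mask {path} shape {raw.shape} does not match frame shape {frame.shape}"
        )
    if not np.issubdtype(raw.dtype, np.integer):
        if not np.all(np.equal(np.mod(raw, 1), 0)):
            raise FormatError(f"mask {path} holds non-integer pixel values")
        raw = raw.astype(np.int64)
    if raw.min() < 0:
        raise FormatError(f"mask {path} holds negative labels")
    # One instance per connected component, even if a label was spread over
    # several disjoint blobs in the source file.
    components, _ = ndi.label(raw > 0, structure=_STRUCT8)
    # Components bridging two source labels are split back along label lines.
    pair = components.astype(np.int64) * (np.int64(raw.max()) + 1) + raw
    pair[raw == 0] = 0
    _, split = np.unique(pair, return_inverse=True)
    split = split.reshape(raw.shape)
    split = _filter_small(split, min_area_px)
    return relabel_mask(split)


def star_convexity_score(mask: np.ndarray, label: int, n_rays: int = 32) -> float:
    """Fraction of centroid rays along which the region is star-convex.

    Casts ``n_rays`` equally spaced rays from the region centroid and samples
    region membership every half pixel.  A ray passes when its in-region
    samples form a single contiguous run starting at the ray origin, i.e. the
    boundary is visible from the centroid.  Convex regions (disks, ellipses)
    score 1.0; regions whose centroid falls outside the region (annuli,
    crescents) score 0 on the affected rays and never raise.
    """
    if n_rays < 8:
        raise ValueError(f"n_rays must be >= 8, got {n_rays}")
    mask = np.asarray(mask)
    rows, cols = np.nonzero(mask == label)
    if rows.size == 0:
        raise KeyError(f"label {label} not present in mask")
    cr, cc = rows.mean(), cols.mean()
    reach = np.hypot(rows - cr, cols - cc).max() + 2.0
    ts = np.arange(0.0, reach, 0.5)
    n_pass = 0
    for k in range(n_rays):
        angle = 2.0 * np.pi * k / n_rays
        rr = np.rint(cr + ts * np.sin(angle)).astype(int)
        cc_ = np.rint(cc + ts * np.cos(angle)).astype(int)
        ok = (rr >= 0) & (rr < mask.shape[0]) & (cc_ >= 0) & (cc_ < mask.shape[1])
        inside = np.zeros(ts.shape, dtype=bool)
        inside[ok] = mask[rr[ok], cc_[ok]] == label
        if not inside.any():
            continue
        runs = np.diff(inside.astype(np.int8))
        single_run = (runs == 1).sum() + int(inside[0]) == 1
        if single_run and inside[0]:
            n_pass += 1
    return n_pass / n_rays
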