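"""Shared fixtures and independent oracles for the test suite.

Oracles here are deliberately naive (pixel loops, flood fill, manual
interpolation) so they stay independent of the library code they check.
"""

import numpy as np
import pytest
from skimage.draw import disk as draw_disk
from skimage.draw import ellipse as draw_ellipse

from organoquant.segmentation import Frame


def make_frame(pixels, time_h=0.0, well_id="A1", condition_id="ctrl"):
    return Frame(
        pixels=np.asarray(pixels, dtype=np.uint8),
        time_h=time_h,
        well_id=well_id,
        condition_id=condition_id,
    )


@pytest.fixture
def disk_mask():
    """Rasterized disk of radius 20 in a 64x64 mask, labeled 1."""
    mask = np.zeros((64, 64), dtype=np.int32)
    rr, cc = draw_disk((32, 32), 20, shape=mask.shape)
    mask[rr, cc] = 1
    return mask


@pytest.fixture
def ellipse_mask():
    """Axis-aligned ellipse with semi-axes a=40 (cols), b=20 (rows)."""
    mask = np.zeros((96, 128), dtype=np.int32)
    rr, cc = draw_ellipse(48, 64, 20, 40, shape=mask.shape)
    mask[rr, cc] = 1
    return mask


@pytest.fixture
def annulus_mask():
    """Disk of radius 24 with a concentric hole of radius 12."""
    mask = np.zeros((72, 72), dtype=np.int32)
    rr, cc = draw_disk((36, 36), 24, shape=mask.shape)
    mask[rr, cc] = 1
    rr, cc = draw_disk((36, 36), 12, shape=mask.shape)
    mask[rr, cc] = 0
    return mask


# ---------------------------------------------------------------- oracles


def brute_force_moment_eccentricity(mask, label):
    """Eccentricity from explicit second central moments of pixel coords."""
    rows, cols = np.nonzero(mask == label)
    r = rows - rows.mean()
    c = cols - cols.mean()
    cov = np.array([[np.mean(r * r), np.mean(r * c)],
                    [np.mean(r * c), np.mean(c * c)]])
    lam1, lam2 = sorted(np.linalg.eigvalsh(cov), reverse=True)
    if lam1 <= 0:
        return 0.0
    return float(np.sqrt(1.0 - lam2 / lam1))


def brute_force_percentile(values, rank):
    """Linear-interpolation percentile on the sorted list, from scratch."""
    xs = sorted(values)
    if len(xs) == 1:
        return float(xs[0])
    pos = rank / 100.0 * (len(xs) - 1)
    lo = int(np.floor(pos))
    hi = int(np.ceil(pos))
    frac = pos - lo
    return float(xs[lo] + (xs[hi] - xs[lo]) * frac)


def brute_force_components(binary):
    """8-connected component labeling by BFS flood fill (no library calls)."""
    binary = np.asarray(binary, dtype=bool)
    labels = np.zeros(binary.shape, dtype=np.int32)
    current = 0
    for start in zip(*np.nonzero(binary)):
        if labels[start]:
            continue
        current += 1
        stack = [start]
        labels[start] = current
        while stack:
            r, c = stack.pop()
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    rr, cc = r + dr, c + dc
                    if (0 <= rr < binary.shape[0] and 0 <= cc < binary.shape[1]
                            and binary[rr, cc] and not labels[rr, cc]):
                        labels[rr, cc] = current
                        stack.append((rr, cc))
    return labels, current
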