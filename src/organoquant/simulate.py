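"""Seeded synthetic bright-field organoid movies with ground truth.

The generator emulates the phenomenology a quantification pipeline must
survive, without any optics simulation:

* organoids are rasterized ellipses with a dark rim and a brighter interior
  sitting on a bright Gaussian-noise background;
* alive organoids grow exponentially, ``area(t) = area0 * exp(g * t)``;
* under drug (abstract ``dose``), each organoid dies with per-frame hazard
  ``1 - exp(-h(dose) * dt)``; a dying organoid stops growing and darkens at
  a constant rate until its mean intensity crosses the viability cutoff
  (50), stays visibly dark for one more frame, then disintegrates into
  debris fragments, each below the debris size floor (undetectable);
* with merging enabled, two overlapping alive organoids fuse into one truth
  instance (the larger absorbs the smaller), producing the region-level
  merge signature: one fewer count, combined area retained.

Every frame comes with a ground-truth instance mask and a truth table of
per-organoid geometry, intensity and life state, plus an event log of dying
onsets, disintegrations and merges, so every downstream module can be tested
against exact truth.  Identical configuration (including the seed) yields
byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
import pandas as pd

from .errors import CapacityError
from .segmentation import Frame

__all__ = [
    "SimConfig",
    "TruthTable",
    "generate_series",
    "size_targeting_scenario",
    "linear_dose_hazard",
]

#: fraction of the ellipse radius occupied by the dark rim (area fraction
#: 1 - 0.85^2 ~ 0.28); also used in the analytic mean-intensity model.
_RIM_RADIUS_FRACTION = 0.85
_RIM_AREA_FRACTION = 1.0 - _RIM_RADIUS_FRACTION**2

#: viability cutoff the darkening schedule is driven by (mean 8-bit intensity)
_VIABILITY_CUTOFF = 50.0


def linear_dose_hazard(dose: float) -> float:
    """Default dose-to-hazard map: 0.0025 per hour per dose unit."""
    return 0.0025 * dose


@dataclass
class SimConfig:
    """Study conditions of one synthetic movie.

    Defaults mirror a typical bright-field acquisition: a 512x512 field
    imaged every 4 h for 25 frames (0-96 h) holding ~30 organoids of 10-22 px
    initial semi-major axis on a background of 200 +/- 5 intensity levels,
    healthy interiors near 120 with a rim 60 levels darker, and ~0.8%/h
    relative area growth.
    """

    image_size_px: tuple[int, int] = (512, 512)
    n_frames: int = 25
    frame_interval_h: float = 4.0
    n_organoids: int = 30
    radius_range_px: tuple[float, float] = (10.0, 22.0)
    axis_ratio_range: tuple[float, float] = (0.6, 1.0)
    background_mean: float = 200.0
    background_sd: float = 5.0
    interior_intensity_healthy: float = 120.0
    rim_darkening: float = 60.0
    growth_rate_per_h: float = 0.008
    dose: float = 0.0
    death_hazard_per_h: Callable[[float], float] = linear_dose_hazard
    darkening_rate_per_h: float = 2.0
    debris_fragments_on_death: int = 4
    allow_merging: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.radius_range_px[0] > self.radius_range_px[1]:
            raise ValueError("radius_range_px must be ordered (min, max)")
        if self.axis_ratio_range[0] > self.axis_ratio_range[1]:
            raise ValueError("axis_ratio_range must be ordered (min, max)")
        if not (0 <= self.background_mean <= 255):
            raise ValueError("background_mean must be an 8-bit intensity")
        if not (0 <= self.interior_intensity_healthy <= 255):
            raise ValueError("interior_intensity_healthy must be an 8-bit intensity")
        if self.dose < 0:
            raise ValueError("dose must be >= 0")


@dataclass
class TruthTable:
    """Ground truth of one simulated series.

    ``organoids`` holds one row per organoid per frame (geometry, interior
    intensity, life state, mask label and rasterized area); ``events`` logs
    dying onsets, disintegrations and merges.
    """

    organoids: pd.DataFrame
    events: pd.DataFrame

    def detectable_counts(self) -> pd.Series:
        """Per-frame number of truth instances present in the mask."""
        df = self.organoids
        roots = df[(df["oid"] == df["mask_label"]) & (df["state"] != "dead")]
        counts = roots.groupby("frame").size()
        frames = sorted(df["frame"].unique())
        return counts.reindex(frames, fill_value=0)

    def merge_events(self) -> pd.DataFrame:
        return self.events[self.events["kind"] == "merge"].reset_index(drop=True)

    def death_events(self) -> pd.DataFrame:
        return self.events[self.events["kind"] == "death"].reset_index(drop=True)


class _Organoid:
    """Mutable per-organoid simulation state (internal)."""

    __slots__ = (
        "oid", "row", "col", "a0", "b0", "theta", "interior",
        "state", "frozen_scale", "below_cutoff_frame", "absorbed_into",
        "debris",
    )

    def __init__(self, oid, row, col, a0, b0, theta, interior):
        self.oid = oid
        self.row = row
        self.col = col
        self.a0 = a0
        self.b0 = b0
        self.theta = theta
        self.interior = interior
        self.state = "alive"  # alive -> dying -> dead
        self.frozen_scale: Optional[float] = None
        self.below_cutoff_frame: Optional[int] = None
        self.absorbed_into: Optional[int] = None
        self.debris: list[tuple[float, float, float]] = []

    def scale(self, growth_rate: float, t: float) -> float:
        if self.frozen_scale is not None:
            return self.frozen_scale
        return float(np.exp(growth_rate * t / 2.0))

    def axes(self, growth_rate: float, t: float) -> tuple[float, float]:
        s = self.scale(growth_rate, t)
        return self.a0 * s, self.b0 * s

    def ellipse_area(self, growth_rate: float, t: float) -> float:
        a, b = self.axes(growth_rate, t)
        return float(np.pi * a * b)


def _approx_mean_intensity(interior: float, rim_darkening: float) -> float:
    """Analytic region mean of the rendered two-zone ellipse."""
    rim = max(interior - rim_darkening, 0.0)
    return (1.0 - _RIM_AREA_FRACTION) * interior + _RIM_AREA_FRACTION * rim


def _ellipse_patch(shape, row, col, a, b, theta):
    """Bounding-box grid of normalized ellipse distance f (f <= 1 inside)."""
    extent = max(a, b) + 2.0
    r0 = max(int(np.floor(row - extent)), 0)
    r1 = min(int(np.ceil(row + extent)) + 1, shape[0])
    c0 = max(int(np.floor(col - extent)), 0)
    c1 = min(int(np.ceil(col + extent)) + 1, shape[1])
    rr, cc = np.meshgrid(np.arange(r0, r1), np.arange(c0, c1), indexing="ij")
    dr = rr - row
    dc = cc - col
    cos_t, sin_t = np.cos(theta), np.sin(theta)
    u = dc * cos_t + dr * sin_t
    v = -dc * sin_t + dr * cos_t
    f = (u / a) ** 2 + (v / b) ** 2
    return (slice(r0, r1), slice(c0, c1)), f


def _place_organoids(config: SimConfig, rng: np.random.Generator) -> list[_Organoid]:
    """Random non-overlapping initial placement with growth headroom."""
    rows_px, cols_px = config.image_size_px
    horizon = (config.n_frames - 1) * config.frame_interval_h
    growth_end = float(np.exp(config.growth_rate_per_h * horizon / 2.0))
    # Without merging, organoids must never touch; with merging they may
    # grow into contact.
    sep_factor = 1.0 if config.allow_merging else growth_end
    placed: list[_Organoid] = []
    for oid in range(1, config.n_organoids + 1):
        for _ in range(500):
            a0 = rng.uniform(*config.radius_range_px)
            b0 = a0 * rng.uniform(*config.axis_ratio_range)
            theta = rng.uniform(0.0, np.pi)
            pad = a0 * growth_end + 3.0
            if 2 * pad >= min(rows_px, cols_px):
                raise CapacityError(
                    "image_size_px too small for radius_range_px x growth: "
                    f"an organoid of final extent {pad:.0f} px does not fit in "
                    f"{config.image_size_px}"
                )
            row = rng.uniform(pad, rows_px - pad)
            col = rng.uniform(pad, cols_px - pad)
            clear = all(
                np.hypot(row - o.row, col - o.col)
                > (a0 + o.a0) * sep_factor + 4.0
                for o in placed
            )
            if clear:
                interior = float(
                    np.clip(rng.normal(config.interior_intensity_healthy, 4.0), 85, 255)
                )
                placed.append(_Organoid(oid, row, col, a0, b0, theta, interior))
                break
        else:
            raise CapacityError(
                f"could not place organoid {oid}/{config.n_organoids}: scene is "
                "overcrowded (reduce n_organoids or radius_range_px, or enlarge "
                "image_size_px)"
            )
    return placed


def _root(organoids: dict[int, _Organoid], oid: int) -> int:
    """Follow merge absorption pointers to the surviving truth label."""
    while organoids[oid].absorbed_into is not None:
        oid = organoids[oid].absorbed_into
    return oid


def generate_series(
    config: SimConfig, size_hazard_slope: float = 0.0
) -> tuple[list[Frame], list[np.ndarray], TruthTable]:
    """Simulate one well: frames, truth masks, and the truth table.

    ``size_hazard_slope`` adds ``slope * current_area_px2`` to each
    organoid's hazard (see :func:`size_targeting_scenario`).  Deterministic
    given the config (seed included), byte for byte.
    """
    if size_hazard_slope < 0:
        raise ValueError("size_hazard_slope must be >= 0")
    rng = np.random.default_rng(config.seed)
    shape = tuple(config.image_size_px)
    dt = config.frame_interval_h
    base_hazard = float(config.death_hazard_per_h(config.dose))
    organoids = {o.oid: o for o in _place_organoids(config, rng)}
    order = sorted(organoids)

    frames: list[Frame] = []
    masks: list[np.ndarray] = []
    truth_rows: list[dict] = []
    event_rows: list[dict] = []
    condition = f"dose_{config.dose:g}"

    for k in range(config.n_frames):
        t = k * dt
        if k > 0:
            # Hazard uniforms are drawn for EVERY organoid every frame so
            # that, for a fixed seed, death times are pathwise monotone in
            # dose (higher dose can only move a death earlier).
            us = rng.random(len(order))
            for u, oid in zip(us, order):
                o = organoids[oid]
                if o.state != "alive" or o.absorbed_into is not None:
                    continue
                hazard = base_hazard + size_hazard_slope * o.ellipse_area(
                    config.growth_rate_per_h, t
                )
                if hazard > 0 and u < 1.0 - np.exp(-hazard * dt):
                    o.state = "dying"
                    o.frozen_scale = o.scale(config.growth_rate_per_h, t)
                    event_rows.append(
                        {"frame": k, "time_h": t, "kind": "dying_onset",
                         "oid": oid, "survivor": pd.NA}
                    )
            for oid in order:
                o = organoids[oid]
                if o.state != "dying" or o.absorbed_into is not None:
                    continue
                if o.below_cutoff_frame is not None:
                    # One full frame spent visibly dark; now disintegrate.
                    o.state = "dead"
                    n_frag = config.debris_fragments_on_death
                    o.debris = [
                        (
                            o.row + rng.uniform(-o.a0, o.a0),
                            o.col + rng.uniform(-o.a0, o.a0),
                            rng.uniform(2.0, 4.0),
                        )
                        for _ in range(n_frag)
                    ]
                    event_rows.append(
                        {"frame": k, "time_h": t, "kind": "death",
                         "oid": oid, "survivor": pd.NA}
                    )
                    continue
                o.interior = max(o.interior - config.darkening_rate_per_h * dt, 0.0)
                if _approx_mean_intensity(o.interior, config.rim_darkening) < (
                    _VIABILITY_CUTOFF
                ):
                    o.below_cutoff_frame = k

        # --- rasterize members and resolve merges -----------------------
        patches: dict[int, tuple] = {}
        for oid in order:
            o = organoids[oid]
            if o.state == "dead":
                continue
            a, b = o.axes(config.growth_rate_per_h, t)
            sl, f = _ellipse_patch(shape, o.row, o.col, a, b, o.theta)
            patches[oid] = (sl, f)

        if config.allow_merging and k >= 0:
            alive_ids = [
                oid for oid in order
                if organoids[oid].state == "alive"
            ]
            # pairwise pixel-overlap test between root instances
            for i, oid_a in enumerate(alive_ids):
                for oid_b in alive_ids[i + 1:]:
                    ra, rb = _root(organoids, oid_a), _root(organoids, oid_b)
                    if ra == rb:
                        continue
                    if organoids[ra].state != "alive" or organoids[rb].state != "alive":
                        continue
                    if _members_overlap(organoids, patches, shape, ra, rb,
                                        config.growth_rate_per_h, t):
                        big, small = sorted(
                            (ra, rb),
                            key=lambda x: -sum(
                                organoids[m].ellipse_area(config.growth_rate_per_h, t)
                                for m in _members(organoids, x)
                            ),
                        )
                        organoids[small].absorbed_into = big
                        event_rows.append(
                            {"frame": k, "time_h": t, "kind": "merge",
                             "oid": small, "survivor": big}
                        )

        # --- final truth mask (pixel goes to the nearest instance) ------
        best_f = np.full(shape, np.inf)
        mask = np.zeros(shape, dtype=np.int32)
        for oid in order:
            o = organoids[oid]
            if o.state == "dead" or oid not in patches:
                continue
            sl, f = patches[oid]
            root = _root(organoids, oid)
            inside = f <= 1.0
            better = inside & (f < best_f[sl])
            best_f[sl] = np.where(better, f, best_f[sl])
            region = mask[sl]
            region[better] = root
            mask[sl] = region

        # --- truth rows --------------------------------------------------
        labels_in_mask, areas_in_mask = np.unique(mask[mask > 0], return_counts=True)
        mask_area = dict(zip(labels_in_mask.tolist(), areas_in_mask.tolist()))
        members_of: dict[int, int] = {}
        for oid in order:
            if organoids[oid].state != "dead":
                members_of.setdefault(_root(organoids, oid), 0)
                members_of[_root(organoids, oid)] += 1
        for oid in order:
            o = organoids[oid]
            root = _root(organoids, oid)
            a, b = o.axes(config.growth_rate_per_h, t)
            state = o.state if o.absorbed_into is None else organoids[root].state
            truth_rows.append(
                {
                    "frame": k,
                    "time_h": t,
                    "oid": oid,
                    "mask_label": 0 if o.state == "dead" else root,
                    "state": state,
                    "row": o.row,
                    "col": o.col,
                    "semi_a": a,
                    "semi_b": b,
                    "orientation": o.theta,
                    "interior_intensity": (
                        organoids[root].interior if o.absorbed_into is not None
                        else o.interior
                    ),
                    "ellipse_area": o.ellipse_area(config.growth_rate_per_h, t),
                    "mask_area": mask_area.get(root, 0) if o.state != "dead" else 0,
                    "n_members": members_of.get(oid, 0),
                }
            )

        # --- render the bright-field image -------------------------------
        img = rng.normal(config.background_mean, config.background_sd, shape)
        for oid in order:
            o = organoids[oid]
            if o.state == "dead" or oid not in patches:
                continue
            sl, f = patches[oid]
            root_interior = (
                organoids[_root(organoids, oid)].interior
                if o.absorbed_into is not None
                else o.interior
            )
            rim_value = max(root_interior - config.rim_darkening, 0.0)
            interior_zone = f <= _RIM_RADIUS_FRACTION**2
            rim_zone = (f > _RIM_RADIUS_FRACTION**2) & (f <= 1.0)
            region = img[sl]
            region[interior_zone] = root_interior + rng.normal(
                0.0, 2.0, int(interior_zone.sum())
            )
            region[rim_zone] = rim_value + rng.normal(0.0, 2.0, int(rim_zone.sum()))
            img[sl] = region
        # debris: small dark fragments, rendered but never in the truth mask
        for oid in order:
            o = organoids[oid]
            if o.state != "dead":
                continue
            for dr, dc, radius in o.debris:
                sl, f = _ellipse_patch(shape, dr, dc, radius, radius, 0.0)
                region = img[sl]
                region[f <= 1.0] = max(o.interior - 10.0, 0.0)
                img[sl] = region

        pixels = np.clip(np.rint(img), 0, 255).astype(np.uint8)
        frames.append(
            Frame(pixels=pixels, time_h=t, well_id="sim", condition_id=condition)
        )
        masks.append(mask)

    truth = TruthTable(
        organoids=pd.DataFrame(truth_rows),
        events=pd.DataFrame(
            event_rows, columns=["frame", "time_h", "kind", "oid", "survivor"]
        ),
    )
    return frames, masks, truth


def _members(organoids: dict[int, _Organoid], root: int) -> list[int]:
    return [oid for oid in organoids if _root(organoids, oid) == root
            and organoids[oid].state != "dead"]


def _members_overlap(organoids, patches, shape, root_a, root_b, growth_rate, t):
    """Do any member ellipses of two truth instances share a pixel?"""
    for ma in _members(organoids, root_a):
        if ma not in patches:
            continue
        sl_a, f_a = patches[ma]
        for mb in _members(organoids, root_b):
            if mb not in patches:
                continue
            sl_b, f_b = patches[mb]
            r0 = max(sl_a[0].start, sl_b[0].start)
            r1 = min(sl_a[0].stop, sl_b[0].stop)
            c0 = max(sl_a[1].start, sl_b[1].start)
            c1 = min(sl_a[1].stop, sl_b[1].stop)
            if r0 >= r1 or c0 >= c1:
                continue
            in_a = f_a[r0 - sl_a[0].start:r1 - sl_a[0].start,
                       c0 - sl_a[1].start:c1 - sl_a[1].start] <= 1.0
            in_b = f_b[r0 - sl_b[0].start:r1 - sl_b[0].start,
                       c0 - sl_b[1].start:c1 - sl_b[1].start] <= 1.0
            if np.any(in_a & in_b):
                return True
    return False


def size_targeting_scenario(
    config: SimConfig, size_hazard_slope: float
) -> tuple[list[Frame], list[np.ndarray], TruthTable]:
    """Simulation in which the drug preferentially kills large organoids.

    The per-organoid death hazard is ``h(dose) + slope * current_area``,
    so with a positive slope the largest (Huge-bin) organoids die first:
    their normalized count falls while the Tiny-bin share rises.
    """
    if size_hazard_slope < 0:
        raise ValueError("size_hazard_slope must be >= 0")
    return generate_series(config, size_hazard_slope=size_hazard_slope)
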