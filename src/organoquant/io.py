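"""Image-series ingestion, pipeline orchestration and table export.

Frames are single-channel TIFF or PNG files, one per well per time point;
16-bit inputs are rescaled to 8 bit at load (full-range mapping 65535->255)
so the intensity-50 health semantics are scale-stable.  Acquisition times
are parsed from filenames by regex (default ``<well>_t<hours>h``) or taken
from a metadata CSV.  A plate-layout CSV maps wells to conditions.

``run_pipeline`` orchestrates segmentation (or mask ingestion),
phenotyping, binning and kinetics for every well, isolating failures to the
affected well, and writes four CSV tables plus a JSON run manifest.  Given
identical inputs, configuration and seed, outputs are byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile
import yaml

from . import __version__
from .errors import ConsistencyError, NormalizationError, TimeParseError
from .kinetics import (
    NORMALIZED_METRICS,
    BinThresholds,
    FrameSummary,
    WellSeries,
    assign_size_bin,
    compute_bin_thresholds,
    detect_merge_candidates,
    dose_response_table,
    normalize_series,
    summarize_frame,
)
from .phenotyping import HealthThreshold, OrganoidRecord, classify_health, measure_frame
from .segmentation import Frame, SegmentationConfig, load_labels, segment_frame

__all__ = [
    "PlateLayout",
    "RunConfig",
    "WellInput",
    "load_frame_image",
    "read_image_series",
    "run_pipeline",
    "records_to_table",
    "write_mask",
]

logger = logging.getLogger("organoquant")

DEFAULT_FILENAME_REGEX = r"(?P<well>[A-Za-z]+\d+)_t(?P<time>\d+(?:\.\d+)?)h"

_IMAGE_SUFFIXES = (".tif", ".tiff", ".png")

ORGANOID_COLUMNS = [
    "well_id", "condition_id", "time_h", "label", "area_px", "area_um2",
    "centroid_row", "centroid_col", "mean_intensity", "eccentricity",
    "health", "size_bin",
]


@dataclass
class PlateLayout:
    """well_id -> {condition_id, replicate, ...} mapping."""

    wells: dict[str, dict]

    def __post_init__(self) -> None:
        for well_id, meta in self.wells.items():
            if "condition_id" not in meta:
                raise ValueError(f"layout entry {well_id!r} lacks condition_id")

    @classmethod
    def from_csv(cls, path: str | Path) -> "PlateLayout":
        df = pd.read_csv(path, dtype=str)
        if "well_id" not in df.columns or "condition_id" not in df.columns:
            raise ValueError(f"layout {path} needs well_id and condition_id columns")
        if df["well_id"].duplicated().any():
            dupes = df.loc[df["well_id"].duplicated(), "well_id"].tolist()
            raise ConsistencyError(f"layout {path} duplicates wells {dupes}")
        wells = {
            row["well_id"]: {k: v for k, v in row.items() if k != "well_id"}
            for row in df.to_dict("records")
        }
        return cls(wells)

    def condition_of(self, well_id: str) -> str:
        return self.wells[well_id]["condition_id"]


@dataclass
class RunConfig:
    """Everything a pipeline run needs beyond the images themselves."""

    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    health_cutoff: float = 50.0
    bin_percentiles: tuple[float, float, float, float] = (20.0, 40.0, 60.0, 80.0)
    bin_scope: str = "condition_pooled"  # {condition_pooled, baseline_only, per_frame}
    baseline_scope: str = "well"  # {well, condition}
    pixel_size_um: Optional[float] = None
    time_source: str = "filename_pattern"  # {filename_pattern, metadata_csv}
    filename_time_regex: str = DEFAULT_FILENAME_REGEX
    metadata_csv: Optional[str] = None
    merge_area_tolerance: float = 0.1
    output_dir: str = "organoquant_out"
    seed: int = 0
    log_level: str = "info"

    def __post_init__(self) -> None:
        if self.bin_scope not in ("condition_pooled", "baseline_only", "per_frame"):
            raise ValueError(f"unknown bin_scope {self.bin_scope!r}")
        if self.baseline_scope not in ("well", "condition"):
            raise ValueError(f"unknown baseline_scope {self.baseline_scope!r}")
        if self.time_source not in ("filename_pattern", "metadata_csv"):
            raise ValueError(f"unknown time_source {self.time_source!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        seg = SegmentationConfig(**data.pop("segmentation", {}))
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys {sorted(unknown)}")
        if "bin_percentiles" in data:
            data["bin_percentiles"] = tuple(data["bin_percentiles"])
        return cls(segmentation=seg, **data)

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        out["bin_percentiles"] = list(self.bin_percentiles)
        return out


@dataclass
class WellInput:
    """Time-ordered frames (and optional mask files) of one well."""

    well_id: str
    condition_id: str
    frames: list[Frame]
    mask_paths: Optional[list[Path]] = None


def _to_uint8(arr: np.ndarray, path: str | Path) -> np.ndarray:
    """Normalize frame bit depth: 16-bit full-range mapped to 8-bit."""
    if arr.ndim == 3 and arr.shape[-1] in (3, 4):
        # grayscale stored as RGB(A): channels must agree
        if not np.all(arr[..., :3].max(axis=-1) == arr[..., :3].min(axis=-1)):
            raise ConsistencyError(f"{path} is not single-channel")
        arr = arr[..., 0]
    if arr.ndim != 2:
        raise ConsistencyError(f"{path} is not a 2-D single-channel image")
    if arr.dtype == np.uint8:
        return arr
    if arr.dtype == np.uint16:
        return np.rint(arr.astype(np.float64) / 65535.0 * 255.0).astype(np.uint8)
    if np.issubdtype(arr.dtype, np.integer):
        return np.clip(arr, 0, 255).astype(np.uint8)
    raise ConsistencyError(f"{path}: unsupported pixel dtype {arr.dtype}")


def load_frame_image(path: str | Path) -> np.ndarray:
    """Read a frame file as an 8-bit 2-D array."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(str(path))
    else:
        arr = iio.imread(str(path))
    return _to_uint8(np.asarray(arr), path)


def _parse_filename(path: Path, pattern: re.Pattern) -> tuple[str, float]:
    m = pattern.search(path.stem)
    if not m:
        raise TimeParseError(
            f"cannot parse well/time from {path.name!r} with pattern "
            f"{pattern.pattern!r}"
        )
    groups = m.groupdict()
    time_token = groups.get("time") or m.group(m.lastindex or 1)
    try:
        time_h = float(time_token)
    except (TypeError, ValueError) as exc:
        raise TimeParseError(f"non-numeric time token in {path.name!r}") from exc
    well = groups.get("well") or ""
    return well, time_h


def read_image_series(
    root: str | Path, layout: PlateLayout, config: RunConfig
) -> list[WellInput]:
    """Group and time-order the frame files under ``root`` by well.

    Wells absent from the layout are skipped with a warning; duplicate
    (well, time) pairs and unparseable filenames are errors.
    """
    root = Path(root)
    files = sorted(
        p for p in root.iterdir()
        if p.suffix.lower() in _IMAGE_SUFFIXES and not p.name.startswith("mask_")
    )
    if not files:
        raise FileNotFoundError(f"no frame images under {root}")

    if config.time_source == "metadata_csv":
        if not config.metadata_csv:
            raise ValueError("time_source=metadata_csv requires metadata_csv path")
        meta = pd.read_csv(config.metadata_csv)
        lookup = {
            Path(r["file"]).name: (str(r["well_id"]), float(r["time_h"]))
            for r in meta.to_dict("records")
        }
        def parse(path: Path) -> tuple[str, float]:
            if path.name not in lookup:
                raise TimeParseError(f"{path.name} missing from metadata CSV")
            return lookup[path.name]
    else:
        pattern = re.compile(config.filename_time_regex)
        def parse(path: Path) -> tuple[str, float]:
            return _parse_filename(path, pattern)

    grouped: dict[str, list[tuple[float, Path]]] = {}
    for path in files:
        well, time_h = parse(path)
        if well not in layout.wells:
            logger.warning("skipping %s: well %r not in layout", path.name, well)
            continue
        grouped.setdefault(well, []).append((time_h, path))

    out = []
    for well in sorted(grouped):
        entries = sorted(grouped[well])
        times = [t for t, _ in entries]
        if len(set(times)) != len(times):
            dupes = sorted({t for t in times if times.count(t) > 1})
            raise ConsistencyError(
                f"well {well!r}: duplicate time points {dupes}"
            )
        condition = layout.condition_of(well)
        frames = [
            Frame(
                pixels=load_frame_image(p), time_h=t,
                well_id=well, condition_id=condition,
            )
            for t, p in entries
        ]
        out.append(WellInput(well_id=well, condition_id=condition, frames=frames))
    return out


def write_mask(path: str | Path, mask: np.ndarray) -> None:
    """Write an instance mask as 16-bit single-page TIFF (background 0)."""
    if mask.max() > np.iinfo(np.uint16).max:
        raise ValueError("mask holds more than 65535 instances")
    tifffile.imwrite(str(path), mask.astype(np.uint16))


def records_to_table(records: Sequence[OrganoidRecord]) -> pd.DataFrame:
    """Per-organoid records as a DataFrame with the export column order."""
    rows = [
        {
            "well_id": r.well_id,
            "condition_id": r.condition_id,
            "time_h": r.time_h,
            "label": r.label,
            "area_px": r.area_px,
            "area_um2": r.area_um2 if r.area_um2 is not None else float("nan"),
            "centroid_row": r.centroid_rc[0],
            "centroid_col": r.centroid_rc[1],
            "mean_intensity": r.mean_intensity,
            "eccentricity": r.eccentricity,
            "health": r.health,
            "size_bin": r.size_bin,
        }
        for r in records
    ]
    return pd.DataFrame(rows, columns=ORGANOID_COLUMNS)


def _measure_well(
    well: WellInput, config: RunConfig
) -> dict[float, list[OrganoidRecord]]:
    """Segment (or ingest masks) and measure every frame of one well."""
    threshold = HealthThreshold(config.health_cutoff)
    per_time: dict[float, list[OrganoidRecord]] = {}
    for i, frame in enumerate(well.frames):
        if well.mask_paths is not None:
            mask = load_labels(
                well.mask_paths[i], frame,
                min_area_px=config.segmentation.min_area_px,
            )
        else:
            mask = segment_frame(frame, config.segmentation)
        records = [
            classify_health(r, threshold)
            for r in measure_frame(frame, mask, config.pixel_size_um)
        ]
        per_time[frame.time_h] = records
    return per_time


def _bin_records(
    measured: dict[str, dict[float, list[OrganoidRecord]]],
    conditions: dict[str, str],
    config: RunConfig,
) -> tuple[dict[str, dict[float, list[OrganoidRecord]]], dict[str, BinThresholds]]:
    """Assign size bins under the configured threshold scope."""
    binned: dict[str, dict[float, list[OrganoidRecord]]] = {}
    thresholds_by_condition: dict[str, BinThresholds] = {}

    if config.bin_scope == "per_frame":
        for well, per_time in measured.items():
            binned[well] = {}
            for t, records in per_time.items():
                if records:
                    th = compute_bin_thresholds(
                        [r.area_px for r in records], config.bin_percentiles,
                        source_scope=f"well {well} frame t={t}",
                    )
                    binned[well][t] = [assign_size_bin(r, th) for r in records]
                else:
                    binned[well][t] = []
        return binned, thresholds_by_condition

    for condition in sorted(set(conditions.values())):
        wells = [w for w, c in conditions.items() if c == condition]
        if config.bin_scope == "baseline_only":
            pool = [
                r.area_px
                for w in wells
                for r in measured[w][min(measured[w])]
            ]
            scope = f"condition {condition}, first time point"
        else:  # condition_pooled
            pool = [
                r.area_px
                for w in wells
                for records in measured[w].values()
                for r in records
            ]
            scope = f"condition {condition}, all time points"
        if pool:
            th = compute_bin_thresholds(
                pool, config.bin_percentiles, source_scope=scope
            )
            thresholds_by_condition[condition] = th
        for w in wells:
            binned[w] = {}
            for t, records in measured[w].items():
                if records and condition in thresholds_by_condition:
                    th = thresholds_by_condition[condition]
                    binned[w][t] = [assign_size_bin(r, th) for r in records]
                else:
                    binned[w][t] = list(records)
    return binned, thresholds_by_condition


def build_well_series(
    well_id: str,
    condition_id: str,
    per_time: dict[float, list[OrganoidRecord]],
) -> WellSeries:
    """Frame summaries (time-ordered) for one well's binned records."""
    summaries = []
    for t in sorted(per_time):
        summary = summarize_frame(per_time[t])
        summaries.append(dataclasses.replace(summary, time_h=t))
    return WellSeries(well_id=well_id, condition_id=condition_id, summaries=summaries)


def run_pipeline(
    inputs: Sequence[WellInput],
    config: RunConfig,
    output_dir: Optional[str | Path] = None,
) -> dict:
    """Run segmentation -> phenotyping -> kinetics for every well.

    Writes ``organoids.csv``, ``frame_summaries.csv``, ``normalized.csv``,
    ``merge_events.csv`` and ``manifest.json`` under ``output_dir``.  A
    failure in one well is logged and recorded in the manifest; other wells
    continue.  Returns the manifest dict (with in-memory ``well_series``
    attached under ``_series``).
    """
    out_dir = Path(output_dir if output_dir is not None else config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    inputs = sorted(inputs, key=lambda w: (w.condition_id, w.well_id))
    errors: dict[str, str] = {}
    normalization_errors: dict[str, dict[str, str]] = {}
    measured: dict[str, dict[float, list[OrganoidRecord]]] = {}
    conditions: dict[str, str] = {}
    for well in inputs:
        try:
            measured[well.well_id] = _measure_well(well, config)
            conditions[well.well_id] = well.condition_id
        except Exception as exc:  # noqa: BLE001 - well isolation is the contract
            logger.error("well %s failed: %s", well.well_id, exc)
            errors[well.well_id] = str(exc)

    binned, thresholds = _bin_records(measured, conditions, config)

    all_series: list[WellSeries] = []
    merge_rows = []
    for well_id in sorted(binned, key=lambda w: (conditions[w], w)):
        series = build_well_series(well_id, conditions[well_id], binned[well_id])
        if config.baseline_scope == "condition":
            _normalize_condition_baseline(series, all_series, binned, conditions)
        for metric in NORMALIZED_METRICS:
            try:
                series.normalized[metric] = normalize_series(series, metric)
            except NormalizationError as exc:
                normalization_errors.setdefault(well_id, {})[metric] = str(exc)
        if len(series.summaries) >= 2:
            for t_prev, t_next, drop in detect_merge_candidates(
                series, config.merge_area_tolerance
            ):
                merge_rows.append(
                    {
                        "condition_id": series.condition_id,
                        "well_id": well_id,
                        "t_prev_h": t_prev,
                        "t_next_h": t_next,
                        "count_drop": drop,
                    }
                )
        all_series.append(series)

    # ---- exports --------------------------------------------------------
    records_flat = [
        r
        for well_id in sorted(binned, key=lambda w: (conditions[w], w))
        for t in sorted(binned[well_id])
        for r in binned[well_id][t]
    ]
    records_to_table(records_flat).to_csv(out_dir / "organoids.csv", index=False)

    summary_rows = []
    for series in all_series:
        for s in series.summaries:
            row = {
                "condition_id": series.condition_id,
                "well_id": series.well_id,
                "time_h": s.time_h,
                "count": s.count,
                "total_area": s.total_area,
                "mean_area": s.mean_area,
                "mean_eccentricity": s.mean_eccentricity,
                "healthy_count": s.healthy_count,
                "unhealthy_count": s.unhealthy_count,
            }
            row.update({f"bin_{k}": v for k, v in s.bin_counts.items()})
            summary_rows.append(row)
    pd.DataFrame(summary_rows).to_csv(out_dir / "frame_summaries.csv", index=False)

    if all_series:
        dose_response_table(all_series).to_csv(out_dir / "normalized.csv", index=False)
    else:
        pd.DataFrame(
            columns=["condition_id", "well_id", "time_h", "metric", "value",
                     "normalized"]
        ).to_csv(out_dir / "normalized.csv", index=False)
    pd.DataFrame(
        merge_rows,
        columns=["condition_id", "well_id", "t_prev_h", "t_next_h", "count_drop"],
    ).to_csv(out_dir / "merge_events.csv", index=False)

    manifest = {
        "software": "organoquant",
        "version": __version__,
        "config": config.to_dict(),
        "wells": sorted(measured),
        "conditions": conditions,
        "bin_thresholds": {
            c: list(th.values) for c, th in thresholds.items()
        },
        "errors": errors,
        "normalization_errors": normalization_errors,
        "outputs": [
            "organoids.csv", "frame_summaries.csv", "normalized.csv",
            "merge_events.csv",
        ],
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    manifest["_series"] = all_series
    return manifest


def _normalize_condition_baseline(series, done_series, binned, conditions):
    """Condition-level baselines: divide by the condition-mean first value."""
    peers = [w for w, c in conditions.items() if c == series.condition_id]
    for metric in NORMALIZED_METRICS:
        baselines = []
        for w in peers:
            peer = build_well_series(w, conditions[w], binned[w])
            try:
                value = normalize_series(peer, metric)  # validates baseline
            except NormalizationError:
                continue
            from .kinetics import _metric_value
            baselines.append(_metric_value(peer.summaries[0], metric))
        if not baselines:
            continue
        base = float(np.mean(baselines))
        if base == 0:
            continue
        from .kinetics import _metric_value
        series.normalized[f"{metric}_condition_baseline"] = [
            float("nan") if _metric_value(s, metric) is None
            else _metric_value(s, metric) / base
            for s in series.summaries
        ]


def join_viability(summary_table: pd.DataFrame, viability_csv: str | Path) -> pd.DataFrame:
    """Left-join an endpoint viability CSV (well_id, viability) onto a table."""
    viability = pd.read_csv(viability_csv)
    if "well_id" not in viability.columns:
        raise ValueError("viability CSV needs a well_id column")
    return summary_table.merge(viability, on="well_id", how="left")
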