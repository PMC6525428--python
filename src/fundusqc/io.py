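"""File I/O, study configuration and the end-to-end pipeline.

A *study* compares one or more devices, each represented by a list of
replicate calibration images.  :func:`run_study` measures every image,
assembles per-device metric tables and summaries, computes directional
amplitudes, compares devices pairwise with the Mann-Whitney U test and
writes CSV/JSON/plain-text reports.

All measurement is deterministic; images are never rescaled (every metric is
a ratio within one image, so differing raster sizes between devices need no
resampling).  File outputs use 0-based ``(row, col)`` pixel indexing, UTF-8
CSV with '.' decimals and a fixed column order, and re-running on identical
inputs reproduces byte-identical tables.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from PIL import Image

from .errors import ValidationError
from .measurement import (
    CellMeasure,
    FieldOfView,
    ImageMeasurements,
    StripePair,
    measure_image,
)
from .metrics import (
    MetricTable,
    amplitude_summary,
    build_metric_table,
    summarize_table,
)
from .stats import compare_devices, comparisons_to_frame
from .synthetic_eye import (
    DIRECTIONS,
    SceneSpec,
    build_projection,
    stripe_levels_from_samples,
)

logger = logging.getLogger("fundusqc")

_FLOAT_FORMAT = "%.6f"

MEASUREMENT_COLUMNS = (
    "image_id", "direction", "z_deg", "h_px", "w_px", "B", "W", "fov_deg",
)


# ---------------------------------------------------------------------------
# Images


def load_image(path, channel: str = "red") -> np.ndarray:
    """Load an image as an 8-bit grayscale array.

    RGB inputs are reduced to the requested plane: ``red`` (the laser
    channel with the best tape contrast), ``green``, or ``luminance``
    (Rec.601 weights).  Grayscale inputs pass through unchanged; requesting
    a color plane from one logs a warning.
    """
    if channel not in ("red", "green", "luminance"):
        raise ValidationError(f"unknown channel {channel!r}")
    try:
        with Image.open(path) as pil:
            pil.load()
            if pil.mode in ("L", "I;16", "I"):
                arr = np.asarray(pil.convert("L"))
                if channel != "luminance":
                    logger.warning(
                        "%s: single-channel image, %s plane request ignored",
                        path, channel)
                return arr.astype(np.uint8)
            rgb = np.asarray(pil.convert("RGB"), dtype=float)
    except FileNotFoundError:
        raise
    except OSError as exc:
        raise OSError(f"cannot read image {path}: {exc}") from exc
    if channel == "red":
        plane = rgb[..., 0]
    elif channel == "green":
        plane = rgb[..., 1]
    else:
        plane = 0.299 * rgb[..., 0] + 0.587 * rgb[..., 1] + 0.114 * rgb[..., 2]
    return np.clip(np.round(plane), 0, 255).astype(np.uint8)


# ---------------------------------------------------------------------------
# Scene specs as config documents


def scene_from_dict(doc: Mapping) -> SceneSpec:
    """Build a :class:`SceneSpec` from a YAML/JSON-style mapping."""
    try:
        projections = {}
        for d in DIRECTIONS:
            p = doc["projections"][d]
            projections[d] = build_projection(
                f=float(p["f"]), k3=float(p.get("k3", 0.0)),
                transverse_samples=[(float(a), float(v))
                                    for a, v in p["transverse"]],
                max_angle=float(p["max_angle"]), direction=d,
            )
        stripe_levels = {}
        for d in DIRECTIONS:
            samples = {float(a): (float(bw[0]), float(bw[1]))
                       for a, bw in doc["stripe_levels"][d].items()}
            stripe_levels[d] = stripe_levels_from_samples(
                samples, projections[d].max_angle)
        jpeg = doc.get("jpeg_quality")
        return SceneSpec(
            image_shape=tuple(int(v) for v in doc["image_shape"]),
            center=tuple(float(v) for v in doc["center"]),
            projections=projections,
            stripe_levels=stripe_levels,
            tape_halfwidth_deg=float(doc.get("tape_halfwidth_deg", 2.5)),
            background_level=float(doc.get("background_level", 20.0)),
            noise_sd=float(doc.get("noise_sd", 0.0)),
            blur_sigma=float(doc.get("blur_sigma", 0.0)),
            jpeg_quality=None if jpeg is None else int(jpeg),
            seed=int(doc.get("seed", 0)),
        )
    except KeyError as exc:
        raise ValidationError(f"scene config missing key: {exc}") from exc


def load_scene_config(path) -> SceneSpec:
    with open(path, encoding="utf-8") as fh:
        return scene_from_dict(yaml.safe_load(fh))


# ---------------------------------------------------------------------------
# Study configuration


@dataclass
class DeviceConfig:
    name: str
    images: list
    center_hint: tuple[float, float] | None = None


@dataclass
class StudyConfig:
    """Configuration of a device-comparison study.

    ``devices`` preserves the order given; positions are in degrees of
    eccentricity and must lie within [0, 110].
    """

    devices: list
    channel: str = "red"
    geometry_positions: tuple = (0.0, 40.0, 80.0)
    contrast_positions: tuple = (0.0, 80.0)
    readability_threshold: float = 0.02
    alpha: float = 0.05
    output_dir: str | None = None
    seed: int = 0

    def validate(self) -> None:
        if not self.devices:
            raise ValidationError("study config needs at least one device")
        names = [d.name for d in self.devices]
        if len(set(names)) != len(names):
            raise ValidationError("device names must be unique")
        for dev in self.devices:
            if not dev.images:
                raise ValidationError(
                    f"device {dev.name!r} has an empty image list")
        for z in tuple(self.geometry_positions) + tuple(self.contrast_positions):
            if not (0 <= z <= 110):
                raise ValidationError(f"position {z} outside [0, 110] degrees")
        if self.channel not in ("red", "green", "luminance"):
            raise ValidationError(f"unknown channel {self.channel!r}")
        if not (0 < self.alpha < 1):
            raise ValidationError("alpha must lie in (0, 1)")

    @classmethod
    def from_dict(cls, doc: Mapping) -> "StudyConfig":
        devices = []
        for name, spec in doc["devices"].items():
            hint = spec.get("center_hint")
            devices.append(DeviceConfig(
                name=name, images=list(spec["images"]),
                center_hint=None if hint is None else tuple(float(v) for v in hint),
            ))
        cfg = cls(
            devices=devices,
            channel=doc.get("channel", "red"),
            geometry_positions=tuple(
                float(z) for z in doc.get("geometry_positions", (0, 40, 80))),
            contrast_positions=tuple(
                float(z) for z in doc.get("contrast_positions", (0, 80))),
            readability_threshold=float(doc.get("readability_threshold", 0.02)),
            alpha=float(doc.get("alpha", 0.05)),
            output_dir=doc.get("output_dir"),
            seed=int(doc.get("seed", 0)),
        )
        cfg.validate()
        return cfg

    @classmethod
    def from_file(cls, path) -> "StudyConfig":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))


# ---------------------------------------------------------------------------
# Measurement tables on disk


def measurements_to_frame(measured: Sequence[ImageMeasurements],
                          image_ids: Sequence) -> pd.DataFrame:
    """Per-image measurement rows in the documented CSV schema."""
    rows = []
    for image_id, m in zip(image_ids, measured):
        stripe_by_key = {(s.direction, s.z): s for s in m.stripes}
        seen = set()
        for c in m.cells:
            s = stripe_by_key.get((c.direction, c.z))
            seen.add((c.direction, c.z))
            rows.append({
                "image_id": image_id, "direction": c.direction,
                "z_deg": c.z, "h_px": c.h, "w_px": c.w,
                "B": s.B if s else np.nan, "W": s.W if s else np.nan,
                "fov_deg": m.fov.degrees.get(c.direction, np.nan),
            })
        for (direction, z), s in stripe_by_key.items():
            if (direction, z) in seen:
                continue
            rows.append({
                "image_id": image_id, "direction": direction, "z_deg": z,
                "h_px": np.nan, "w_px": np.nan, "B": s.B, "W": s.W,
                "fov_deg": m.fov.degrees.get(direction, np.nan),
            })
        for direction in DIRECTIONS:
            if not any(r["image_id"] == image_id and r["direction"] == direction
                       for r in rows):
                rows.append({
                    "image_id": image_id, "direction": direction,
                    "z_deg": np.nan, "h_px": np.nan, "w_px": np.nan,
                    "B": np.nan, "W": np.nan,
                    "fov_deg": m.fov.degrees.get(direction, np.nan),
                })
    df = pd.DataFrame(rows, columns=list(MEASUREMENT_COLUMNS))
    return df.sort_values(["image_id", "z_deg", "direction"],
                          kind="mergesort", na_position="last"
                          ).reset_index(drop=True)


def frame_to_measurements(df: pd.DataFrame) -> tuple[list, list]:
    """Rebuild per-image (cells, stripes, fov) lists from a measurement table.

    Returns ``(image_ids, measurements)`` where each measurement is an
    :class:`ImageMeasurements` without a frame (read back from CSV).
    """
    image_ids, measured = [], []
    for image_id, grp in df.groupby("image_id", sort=False):
        cells, stripes = [], []
        fov = {}
        for row in grp.itertuples(index=False):
            if not (isinstance(row.z_deg, float) and math.isnan(row.z_deg)):
                if not math.isnan(row.h_px):
                    cells.append(CellMeasure(row.direction, float(row.z_deg),
                                             float(row.h_px), float(row.w_px)))
                if not math.isnan(row.B):
                    stripes.append(StripePair(row.direction, float(row.z_deg),
                                              float(row.B), float(row.W)))
            if row.direction in DIRECTIONS and not math.isnan(row.fov_deg):
                fov[row.direction] = float(row.fov_deg)
        measured.append(ImageMeasurements(
            frame=None, fov=FieldOfView(degrees=fov),
            cells=cells, stripes=stripes))
        image_ids.append(image_id)
    return image_ids, measured


def write_csv(df: pd.DataFrame, path) -> None:
    """Write a CSV with the package's fixed, reproducible formatting."""
    df.to_csv(path, index=False, float_format=_FLOAT_FORMAT,
              lineterminator="\n")


# ---------------------------------------------------------------------------
# The end-to-end study


@dataclass
class DeviceResult:
    name: str
    image_ids: list
    measurements: list
    measurement_frame: pd.DataFrame
    metric_table: MetricTable
    summary: pd.DataFrame
    amplitudes: list
    skipped: list = field(default_factory=list)


@dataclass
class StudyReport:
    devices: dict
    comparisons: pd.DataFrame | None


def run_study(config: StudyConfig) -> StudyReport:
    """Measure every image of every device and compare the devices.

    Per-image failures are logged and skipped; a device that ends with zero
    usable replicates aborts the run.  When an output directory is
    configured, CSV tables, a JSON report and a plain-text summary are
    written there.
    """
    config.validate()
    device_results = {}
    for dev in config.devices:
        measured, ids, skipped = [], [], []
        for path in dev.images:
            try:
                image = load_image(path, config.channel)
                m = measure_image(
                    image,
                    center_hint=dev.center_hint,
                    geometry_positions=config.geometry_positions,
                    contrast_positions=config.contrast_positions,
                    readability_threshold=config.readability_threshold,
                )
            except Exception as exc:  # per-image failure: record and skip
                logger.warning("device %s: skipping %s (%s)",
                               dev.name, path, exc)
                skipped.append((str(path), str(exc)))
                continue
            measured.append(m)
            ids.append(Path(str(path)).name)
        if not measured:
            raise ValidationError(
                f"device {dev.name!r}: no usable replicate images")
        table = build_metric_table(
            measured,
            geometry_positions=config.geometry_positions,
            contrast_positions=config.contrast_positions,
            replicate_ids=ids,
        )
        device_results[dev.name] = DeviceResult(
            name=dev.name, image_ids=ids, measurements=measured,
            measurement_frame=measurements_to_frame(measured, ids),
            metric_table=table, summary=summarize_table(table),
            amplitudes=amplitude_summary(table), skipped=skipped,
        )

    comparisons = None
    names = [d.name for d in config.devices]
    if len(names) >= 2:
        frames = []
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                res = compare_devices(device_results[a].metric_table,
                                      device_results[b].metric_table,
                                      alpha=config.alpha)
                frame = comparisons_to_frame(res)
                frame.insert(0, "device_b", b)
                frame.insert(0, "device_a", a)
                frames.append(frame)
        comparisons = pd.concat(frames, ignore_index=True)

    report = StudyReport(devices=device_results, comparisons=comparisons)
    if config.output_dir is not None:
        write_report(report, config)
    return report


def _denan(obj):
    """Replace NaN floats with None so reports stay strict JSON."""
    if isinstance(obj, dict):
        return {k: _denan(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_denan(v) for v in obj]
    if isinstance(obj, float) and math.isnan(obj):
        return None
    if isinstance(obj, (np.floating, np.integer)):
        return _denan(float(obj))
    return obj


def write_report(report: StudyReport, config: StudyConfig) -> None:
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    json_doc = {"pixel_indexing": "0-based (row, col)", "devices": {}}
    lines = [
        "fundusqc study report",
        "=====================",
        "Pixel indexing: 0-based (row, col), row increases downward;",
        "superior = decreasing row, left = decreasing column.",
        "",
    ]
    for name, dev in report.devices.items():
        write_csv(dev.measurement_frame, out / f"measurements_{name}.csv")
        write_csv(dev.metric_table.data, out / f"metrics_{name}.csv")
        write_csv(dev.summary, out / f"summary_{name}.csv")
        amp = pd.DataFrame([{
            "metric": a.metric, "z_deg": a.z, "amplitude_mean": a.mean,
            "amplitude_sd": a.sd, "amplitude_of_means": a.of_means,
        } for a in dev.amplitudes])
        write_csv(amp, out / f"amplitudes_{name}.csv")

        lines.append(f"Device: {name} (n = {dev.metric_table.n} replicates)")
        fov = pd.DataFrame([m.fov.degrees for m in dev.measurements])
        for d in DIRECTIONS:
            if d in fov:
                sd = float(fov[d].std(ddof=1)) if len(fov) > 1 else 0.0
                lines.append(
                    f"  field of view {d:9s}: "
                    f"{fov[d].mean():6.1f} +/- {sd:4.1f} deg")
        for row in dev.summary.itertuples(index=False):
            parts = []
            if not math.isnan(row.aspect_ratio_mean):
                parts.append(f"aspect {row.aspect_ratio_mean:.2f} +/- {row.aspect_ratio_sd:.2f}")
            if not math.isnan(row.square_ratio_mean):
                parts.append(f"square {row.square_ratio_mean:.2f} +/- {row.square_ratio_sd:.2f}")
            if not math.isnan(row.contrast_mean):
                parts.append(f"contrast {row.contrast_mean:.2f} +/- {row.contrast_sd:.2f}")
            lines.append(f"  {row.direction:9s} z={row.z_deg:5.1f}: " + ", ".join(parts))
        for a in dev.amplitudes:
            lines.append(
                f"  amplitude {a.metric} z={a.z:.0f}: "
                f"{a.mean:.2f} +/- {a.sd:.2f}")
        if dev.skipped:
            lines.append(f"  skipped images: {len(dev.skipped)}")
        lines.append("")
        json_doc["devices"][name] = {
            "n": dev.metric_table.n,
            "image_ids": list(dev.image_ids),
            "fov_mean": {d: float(fov[d].mean()) for d in DIRECTIONS if d in fov},
            "summary": dev.summary.to_dict(orient="records"),
            "amplitudes": [{
                "metric": a.metric, "z_deg": a.z, "mean": a.mean, "sd": a.sd,
                "of_means": a.of_means,
            } for a in dev.amplitudes],
            "skipped": dev.skipped,
        }
    if report.comparisons is not None:
        write_csv(report.comparisons, out / "comparisons.csv")
        json_doc["comparisons"] = report.comparisons.to_dict(orient="records")
        lines.append(f"Comparisons (alpha = {config.alpha}):")
        for row in report.comparisons.itertuples(index=False):
            flag = "SIGNIFICANT" if row.significant else "n.s."
            lines.append(
                f"  {row.device_a} vs {row.device_b}: {row.metric} "
                f"{row.direction} z={row.z_deg:.0f}: U={row.U:.1f} "
                f"p={row.p:.4f} [{flag}]")
        lines.append("")
    (out / "report.json").write_text(
        json.dumps(_denan(json_doc), indent=1, sort_keys=True) + "\n",
        encoding="utf-8")
    (out / "report.txt").write_text("\n".join(lines) + "\n", encoding="utf-8")
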