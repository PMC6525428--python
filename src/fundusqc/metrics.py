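"""Distortion and contrast metrics for widefield calibration images.

The quantities defined here summarise how an imaging device maps equal
angular intervals on the model-eye surface to pixels:

* ``aspect_ratio``  h_z / w_z — vertical-to-horizontal pixel extent of a
  5-degree cell; 1.0 means locally symmetric imaging.
* ``square_ratio``  S_z / S_0 with S_z = h_z * w_z — pixel area of a
  5x5-degree cell relative to the center cell; measures peripheral
  enlargement.
* ``contrast``      |B_z - W_z| / (B_z + W_z) — Michelson stripe contrast
  from the mean black/white stripe intensities on the 0-255 scale.
* ``amplitude``     max - min of a metric across the four directions at one
  eccentricity; smaller amplitude means a more symmetric image.

Replicate acquisitions are summarised as mean and sample (n-1) standard
deviation, matching the convention of averaging repeated captures.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .measurement import ImageMeasurements
from .synthetic_eye import DIRECTIONS

#: Column schema of the tidy per-replicate metric table.
METRIC_COLUMNS = (
    "replicate", "direction", "z_deg", "h_px", "w_px",
    "aspect_ratio", "square_ratio", "B", "W", "contrast",
)


@dataclass(frozen=True)
class MetricTable:
    """Tidy per-(replicate, direction, eccentricity) metric table.

    ``data`` is a DataFrame with the :data:`METRIC_COLUMNS` schema; geometry
    metrics are NaN where only contrast was measured and vice versa.  ``n``
    is the replicate count.
    """

    data: pd.DataFrame
    n: int


@dataclass(frozen=True)
class AmplitudeSummary:
    """Directional amplitude of one metric at one eccentricity.

    ``per_replicate`` holds the max-min spread across the four directions
    within each replicate; ``mean``/``sd`` summarise those spreads.
    ``of_means`` is the amplitude of the directional means (the value a
    summary table of directional means yields).
    """

    metric: str
    z: float
    per_replicate: tuple[float, ...]
    mean: float
    sd: float
    of_means: float


def aspect_ratio(h: float, w: float) -> float:
    """h / w for a 5-degree cell; both extents must be positive."""
    if h <= 0 or w <= 0:
        raise ValidationError(f"cell extents must be positive, got h={h}, w={w}")
    return h / w


def square_ratio(h_z: float, w_z: float, h_0: float, w_0: float) -> float:
    """(h_z * w_z) / (h_0 * w_0): cell area relative to the center cell."""
    if min(h_z, w_z, h_0, w_0) <= 0:
        raise ValidationError("cell extents must be positive")
    return (h_z * w_z) / (h_0 * w_0)


def contrast(B: float, W: float) -> float:
    """Michelson stripe contrast |B - W| / (B + W).

    The absolute value makes the statistic independent of which stripe is
    brighter; the result lies in [0, 1].
    """
    if not (0 <= B <= 255 and 0 <= W <= 255):
        raise ValidationError("stripe intensities must lie in [0, 255]")
    if B + W == 0:
        raise ValidationError("contrast undefined for B + W = 0")
    return abs(B - W) / (B + W)


def amplitude(values: Mapping[str, float]) -> float:
    """max - min of a metric over the four directions.

    ``values`` must contain exactly superior, inferior, left and right.
    """
    if set(values) != set(DIRECTIONS):
        raise ValidationError(
            f"amplitude needs exactly the directions {DIRECTIONS}, "
            f"got {sorted(values)}"
        )
    vals = [float(values[d]) for d in DIRECTIONS]
    if not all(math.isfinite(v) for v in vals):
        raise ValidationError("amplitude requires finite values")
    return max(vals) - min(vals)


def summarize_replicates(values: Sequence[float]) -> tuple[float, float]:
    """Arithmetic mean and sample (n-1) standard deviation.

    The SD is 0.0 for a single replicate.
    """
    vals = np.asarray(list(values), dtype=float)
    if vals.size == 0:
        raise ValidationError("summarize_replicates requires at least one value")
    mean = float(vals.mean())
    sd = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
    return mean, sd


# ---------------------------------------------------------------------------
# Table assembly


def build_metric_table(
    measurements: Iterable[ImageMeasurements] | Iterable[tuple],
    geometry_positions: Sequence[float] = (0.0, 40.0, 80.0),
    contrast_positions: Sequence[float] = (0.0, 80.0),
    replicate_ids: Sequence | None = None,
) -> MetricTable:
    """Assemble the tidy metric table from per-replicate measurements.

    ``measurements`` is a sequence of :class:`ImageMeasurements` (or of
    ``(cells, stripes)`` pairs).  Each replicate must include the center
    cell — the square ratio is undefined without S_0.  Geometry rows are
    produced for ``geometry_positions`` (z=0 appears as direction
    ``"center"``), contrast for ``contrast_positions``.
    """
    rows = []
    measurements = list(measurements)
    if not measurements:
        raise ValidationError("no measurements given")
    if replicate_ids is None:
        replicate_ids = list(range(len(measurements)))
    for rep_id, m in zip(replicate_ids, measurements):
        if isinstance(m, ImageMeasurements):
            cells, stripes = m.cells, m.stripes
        else:
            cells, stripes = m
        cell_by_key = {(c.direction, c.z): c for c in cells}
        stripe_by_key = {(s.direction, s.z): s for s in stripes}
        if ("center", 0.0) not in cell_by_key:
            raise ValidationError(
                f"replicate {rep_id!r} lacks the center cell; "
                "square ratio undefined without S_0"
            )
        c0 = cell_by_key[("center", 0.0)]
        for z in geometry_positions:
            keys = [("center", 0.0)] if z == 0 else [(d, float(z)) for d in DIRECTIONS]
            for key in keys:
                cell = cell_by_key.get(key)
                if cell is None:
                    continue
                stripe = stripe_by_key.get(key)
                rows.append({
                    "replicate": rep_id,
                    "direction": key[0],
                    "z_deg": key[1],
                    "h_px": cell.h,
                    "w_px": cell.w,
                    "aspect_ratio": aspect_ratio(cell.h, cell.w),
                    "square_ratio": square_ratio(cell.h, cell.w, c0.h, c0.w),
                    "B": stripe.B if stripe else np.nan,
                    "W": stripe.W if stripe else np.nan,
                    "contrast": contrast(stripe.B, stripe.W) if stripe else np.nan,
                })
        for z in contrast_positions:
            keys = [("center", 0.0)] if z == 0 else [(d, float(z)) for d in DIRECTIONS]
            for key in keys:
                stripe = stripe_by_key.get(key)
                if stripe is None or any(
                    r["replicate"] == rep_id and r["direction"] == key[0]
                    and r["z_deg"] == key[1] and not np.isnan(r["contrast"])
                    for r in rows
                ):
                    continue
                rows.append({
                    "replicate": rep_id,
                    "direction": key[0],
                    "z_deg": key[1],
                    "h_px": np.nan, "w_px": np.nan,
                    "aspect_ratio": np.nan, "square_ratio": np.nan,
                    "B": stripe.B, "W": stripe.W,
                    "contrast": contrast(stripe.B, stripe.W),
                })
    data = pd.DataFrame(rows, columns=list(METRIC_COLUMNS))
    data = data.sort_values(["replicate", "z_deg", "direction"],
                            kind="mergesort").reset_index(drop=True)
    return MetricTable(data=data, n=len(measurements))


def summarize_table(table: MetricTable) -> pd.DataFrame:
    """Mean and sample SD of each metric per (direction, z) over replicates."""
    out = []
    for (direction, z), grp in table.data.groupby(["direction", "z_deg"],
                                                  sort=True):
        row = {"direction": direction, "z_deg": z, "n": len(grp)}
        for metric in ("aspect_ratio", "square_ratio", "contrast"):
            vals = grp[metric].dropna()
            if len(vals):
                mean, sd = summarize_replicates(vals)
                row[f"{metric}_mean"] = mean
                row[f"{metric}_sd"] = sd
            else:
                row[f"{metric}_mean"] = np.nan
                row[f"{metric}_sd"] = np.nan
        out.append(row)
    return pd.DataFrame(out)


def amplitude_summary(table: MetricTable,
                      metrics: Sequence[str] = ("aspect_ratio", "square_ratio"),
                      ) -> list[AmplitudeSummary]:
    """Directional amplitudes per replicate, with mean/SD over replicates.

    Computed for every eccentricity (above 0) at which all four directions
    carry the metric.  Also reports the amplitude of the directional means.
    """
    summaries = []
    df = table.data
    for metric in metrics:
        for z in sorted(df.loc[df["z_deg"] > 0, "z_deg"].unique()):
            sub = df[(df["z_deg"] == z) & df["direction"].isin(DIRECTIONS)]
            wide = sub.pivot_table(index="replicate", columns="direction",
                                   values=metric)
            if wide.shape[1] < 4 or wide.isna().any().any():
                continue
            per_rep = tuple(
                amplitude(row.to_dict()) for _, row in wide.iterrows())
            mean, sd = summarize_replicates(per_rep)
            of_means = amplitude(wide.mean(axis=0).to_dict())
            summaries.append(AmplitudeSummary(
                metric=metric, z=float(z), per_replicate=per_rep,
                mean=mean, sd=sd, of_means=of_means))
    return summaries
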