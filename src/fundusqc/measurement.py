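"""Automated measurement of scale-tape calibration images.

Given an image of the model-eye posterior surface with two perpendicular
angular-scale tapes, this module locates the tape axes, reads the 5-degree
cell geometry with sub-pixel precision, samples stripe intensities, and
determines the most peripheral readable marker per direction.  It replaces
manual on-screen pixel counting with a reproducible procedure:

1.  The image center is found from row/column intensity-variance profiles
    (the tapes are the only high-variance bands).
2.  Along each half-axis a 1-D intensity profile (averaged over a 5-pixel
    band) is extracted and cell boundaries are located as half-maximum
    crossings between adjacent plateau levels, linearly interpolated between
    samples.
3.  Cell extents, stripe means ("central four pixels") and the field of view
    are derived from those edges.

Edge positions are expressed as pixel distances from the center along the
meridian; cell k (centered at 5*k degrees) lies between edges k-1 and k.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, signal

from .errors import DetectionError, MeasurementError, RangeError, ValidationError
from .synthetic_eye import CELL_DEG, DIRECTIONS

#: Unit direction vectors in (row, col) image coordinates.
DIRECTION_VECTORS = {
    "superior": (-1.0, 0.0),
    "inferior": (1.0, 0.0),
    "left": (0.0, -1.0),
    "right": (0.0, 1.0),
}

#: Default local Michelson contrast below which a boundary is unreadable.
DEFAULT_READABILITY = 0.02

_BAND_HALFWIDTH = 2  # 5-pixel averaging band for meridian profiles


@dataclass(frozen=True)
class AxisFrame:
    """Located tape axes: sub-pixel center plus axis orientations.

    The axes are the image row/column directions; ``superior`` is decreasing
    row, ``left`` decreasing column.
    """

    center: tuple[float, float]
    vertical_axis: tuple[float, float] = (-1.0, 0.0)
    horizontal_axis: tuple[float, float] = (0.0, 1.0)

    def direction_vector(self, direction: str) -> tuple[float, float]:
        return DIRECTION_VECTORS[direction]


@dataclass(frozen=True)
class CellMeasure:
    """Measured 5-degree cell: image-frame vertical (h) and horizontal (w)
    pixel extents at eccentricity z along a direction."""

    direction: str
    z: float
    h: float
    w: float
    subpixel: bool = True


@dataclass(frozen=True)
class StripePair:
    """Mean gray levels (0-255) of the central 2x2 pixels of the black (B)
    and white (W) stripes adjacent at eccentricity z."""

    direction: str
    z: float
    B: float
    W: float


@dataclass(frozen=True)
class FieldOfView:
    """Most peripheral readable 5-degree marker per direction, degrees."""

    degrees: dict
    readability_threshold: float = DEFAULT_READABILITY


@dataclass(frozen=True)
class Edge:
    """A detected cell boundary along a meridian profile."""

    position: float      # pixels from center, sub-pixel
    left_level: float    # plateau level on the center side
    right_level: float   # plateau level on the peripheral side
    contrast: float      # local Michelson contrast of the two plateaus


@dataclass
class ImageMeasurements:
    """Everything measured from one image."""

    frame: AxisFrame
    fov: FieldOfView
    cells: list = field(default_factory=list)
    stripes: list = field(default_factory=list)
    errors: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# Axis location


def _profile_centroid(profile: np.ndarray, lo: int, hi: int,
                      min_peak: float) -> float:
    """Sub-pixel peak position of a band profile within [lo, hi)."""
    profile = ndimage.gaussian_filter1d(np.asarray(profile, float), 2.0)
    window = profile[lo:hi]
    floor = float(np.median(profile))
    peak_idx = int(np.argmax(window)) + lo
    peak = profile[peak_idx]
    if peak - floor < min_peak:
        raise DetectionError(
            "no tape-like structure found: variation contrast "
            f"{peak - floor:.2f} below floor {min_peak:.2f}"
        )
    half = floor + 0.5 * (peak - floor)
    # contiguous run above half-maximum containing the peak
    i0 = peak_idx
    while i0 - 1 >= lo and profile[i0 - 1] >= half:
        i0 -= 1
    i1 = peak_idx
    while i1 + 1 < hi and profile[i1 + 1] >= half:
        i1 += 1
    idx = np.arange(i0, i1 + 1)
    weights = profile[i0:i1 + 1] - half
    return float(np.sum(idx * weights) / np.sum(weights))


def locate_axes(image: np.ndarray,
                center_hint: tuple[float, float] | None = None,
                min_peak: float = 0.3) -> AxisFrame:
    """Find the tape axes from row/column intensity-variation profiles.

    Tape pixels alternate between cell levels along the meridian, so the
    mean absolute intensity difference along rows, per column, forms a band
    peaked on the vertical tape (and vice versa for the horizontal tape);
    the center is the half-maximum-weighted centroid of each band.  With
    ``center_hint`` the search is confined to +/- 2% of the image size
    around the hint.  Deterministic for fixed input; raises
    :class:`DetectionError` when the variation contrast is below
    ``min_peak`` gray levels per pixel step.
    """
    im = np.asarray(image, dtype=float)
    if im.ndim != 2:
        raise ValidationError("locate_axes expects a 2-D grayscale image")
    h_img, w_img = im.shape
    std_cols = np.abs(np.diff(im, axis=0)).mean(axis=0)
    std_rows = np.abs(np.diff(im, axis=1)).mean(axis=1)
    if center_hint is None:
        r_lo, r_hi, c_lo, c_hi = 0, h_img, 0, w_img
    else:
        hr, hc = center_hint
        dr, dc = 0.02 * h_img, 0.02 * w_img
        r_lo, r_hi = max(0, int(hr - dr)), min(h_img, int(math.ceil(hr + dr)) + 1)
        c_lo, c_hi = max(0, int(hc - dc)), min(w_img, int(math.ceil(hc + dc)) + 1)
        if r_lo >= r_hi or c_lo >= c_hi:
            raise ValidationError("center_hint lies outside the image")
    col = _profile_centroid(std_cols, c_lo, c_hi, min_peak)
    row = _profile_centroid(std_rows, r_lo, r_hi, min_peak)
    return AxisFrame(center=(row, col))


# ---------------------------------------------------------------------------
# Profiles and edge detection


def _meridian_profile(image: np.ndarray, frame: AxisFrame,
                      direction: str) -> np.ndarray:
    """Band-averaged intensity profile from the center outward.

    ``profile[i]`` is the mean intensity at distance i pixels from the
    center along ``direction``, averaged over a 5-pixel-wide transverse
    band, bilinearly interpolated (the center is sub-pixel).
    """
    im = np.asarray(image, dtype=float)
    h_img, w_img = im.shape
    row_c, col_c = frame.center
    vr, vc = DIRECTION_VECTORS[direction]
    if vr != 0:
        length = row_c if vr < 0 else (h_img - 1 - row_c)
    else:
        length = col_c if vc < 0 else (w_img - 1 - col_c)
    n = int(math.floor(length))
    dist = np.arange(n + 1, dtype=float)
    offsets = np.arange(-_BAND_HALFWIDTH, _BAND_HALFWIDTH + 1, dtype=float)
    # transverse band offsets are perpendicular to the direction vector
    rows = row_c + dist[None, :] * vr + offsets[:, None] * abs(vc)
    cols = col_c + dist[None, :] * vc + offsets[:, None] * abs(vr)
    samples = ndimage.map_coordinates(im, [rows, cols], order=1, mode="nearest")
    return samples.mean(axis=0)


def detect_edges(profile: np.ndarray,
                 min_contrast: float = DEFAULT_READABILITY,
                 min_gradient: float = 0.8,
                 min_separation: int = 4) -> list[Edge]:
    """Locate cell boundaries along a meridian profile.

    Candidate boundaries are gradient-magnitude peaks of the lightly smoothed
    profile; each is accepted if the plateau levels on its two sides have
    local Michelson contrast at or above ``min_contrast``, and refined to the
    half-maximum crossing between the plateaus (linear interpolation between
    samples).  A trailing edge closer than half the previous cell spacing is
    discarded as the tape-end transition.
    """
    p = np.asarray(profile, dtype=float)
    if p.size < 2 * min_separation + 1:
        return []
    smooth = ndimage.gaussian_filter1d(p, 1.0)
    grad = np.gradient(smooth)
    peaks, _ = signal.find_peaks(np.abs(grad), height=min_gradient,
                                 distance=min_separation)
    if peaks.size == 0:
        return []
    bounds = np.concatenate([[0], peaks, [p.size - 1]])
    edges: list[Edge] = []
    for idx, i in enumerate(peaks):
        prev_b, next_b = bounds[idx], bounds[idx + 2]
        left = _plateau_level(p, prev_b, i, side="left")
        right = _plateau_level(p, i, next_b, side="right")
        if left is None or right is None:
            continue
        denom = left + right
        contrast = abs(left - right) / denom if denom > 0 else 0.0
        if contrast < min_contrast:
            continue
        pos = _half_max_crossing(p, i, left, right, prev_b, next_b)
        if pos is None:
            continue
        edges.append(Edge(pos, left, right, contrast))
    edges.sort(key=lambda e: e.position)
    if edges:
        # scale-aware rejection of compression/noise artifacts: a genuine
        # cell boundary has a step comparable to the tape's alternation
        # amplitude, while e.g. JPEG block steps are an order of magnitude
        # smaller.  The 4x headroom keeps genuinely faint peripheral
        # boundaries alongside strong central ones.
        c75 = float(np.percentile([e.contrast for e in edges], 75))
        edges = [e for e in edges if e.contrast >= 0.25 * c75]
    return _drop_trailing_stub(edges)


def _plateau_level(p: np.ndarray, lo: int, hi: int, side: str) -> float | None:
    """Median plateau level between an edge and its neighbour."""
    gap = hi - lo
    if gap < 2:
        return None
    if side == "left":
        w0 = lo + max(1, gap // 4)
        w1 = max(w0 + 1, hi - max(2, gap // 4))
    else:
        w0 = min(hi - 1, lo + max(2, gap // 4))
        w1 = max(w0 + 1, hi - max(1, gap // 4))
    return float(np.median(p[w0:w1]))


def _half_max_crossing(p, i, left, right, lo, hi) -> float | None:
    """Sub-pixel crossing of the half level nearest the candidate index."""
    half = 0.5 * (left + right)
    j0 = max(lo, i - 5)
    j1 = min(hi, i + 5)
    seg = p[j0:j1 + 1] - half
    crossings = []
    for j in range(seg.size - 1):
        a, b = seg[j], seg[j + 1]
        if a == 0.0:
            crossings.append(j0 + j)
        elif a * b < 0:
            crossings.append(j0 + j + a / (a - b))
    if not crossings:
        return None
    return float(min(crossings, key=lambda c: abs(c - i)))


def _drop_trailing_stub(edges: list[Edge]) -> list[Edge]:
    """Drop edges closer than half the previous spacing (tape-end stubs)."""
    kept: list[Edge] = []
    prev_gap = None
    for e in edges:
        if kept:
            gap = e.position - kept[-1].position
            if prev_gap is not None and gap < 0.5 * prev_gap:
                continue
            prev_gap = gap
        kept.append(e)
    return kept


def _direction_edges(image, frame, direction,
                     min_contrast=DEFAULT_READABILITY) -> list[Edge]:
    return detect_edges(_meridian_profile(image, frame, direction),
                        min_contrast=min_contrast)


# ---------------------------------------------------------------------------
# Cell measurement


def trace_cell_edges(image, frame: AxisFrame, direction: str, z: float,
                     min_contrast: float = DEFAULT_READABILITY,
                     _edges: list[Edge] | None = None):
    """Radial and transverse boundaries of the 5-degree cell at z.

    Returns ``((inner, outer), (t_lo, t_hi))``: the two radial boundary
    positions (pixels from center along the meridian) and the two transverse
    tape boundaries (signed pixel offsets across the meridian at the cell's
    radial center).  Raises :class:`MeasurementError` when the cell's
    boundaries cannot be read.
    """
    if direction not in DIRECTIONS:
        raise ValidationError(f"unknown direction {direction!r}")
    j = int(round(z / CELL_DEG))
    if j < 1:
        raise ValidationError("trace_cell_edges requires z >= 5 degrees; "
                              "the center cell is handled by measure_cell")
    edges = _edges if _edges is not None else _direction_edges(
        image, frame, direction, min_contrast)
    if len(edges) <= j:
        raise MeasurementError(
            f"cell at z={z} deg ({direction}): only {len(edges)} readable "
            f"boundaries, need {j + 1}"
        )
    inner, outer = edges[j - 1], edges[j]
    mid = 0.5 * (inner.position + outer.position)
    t_lo, t_hi = _transverse_edges(image, frame, direction, mid)
    return (inner.position, outer.position), (t_lo, t_hi)


def _transverse_edges(image, frame, direction, radial_distance):
    """Half-maximum tape boundaries across the meridian at a radial position."""
    im = np.asarray(image, dtype=float)
    h_img, w_img = im.shape
    row_c, col_c = frame.center
    vr, vc = DIRECTION_VECTORS[direction]
    point_r = row_c + radial_distance * vr
    point_c = col_c + radial_distance * vc
    # transverse extent limited by the frame
    if vr != 0:
        limit = int(min(point_c, w_img - 1 - point_c)) - 1
    else:
        limit = int(min(point_r, h_img - 1 - point_r)) - 1
    if limit < 4:
        raise MeasurementError("no room for a transverse profile")
    t = np.arange(-limit, limit + 1, dtype=float)
    offsets = np.arange(-_BAND_HALFWIDTH, _BAND_HALFWIDTH + 1, dtype=float)
    rows = point_r + offsets[:, None] * vr + t[None, :] * abs(vc)
    cols = point_c + offsets[:, None] * vc + t[None, :] * abs(vr)
    q = ndimage.map_coordinates(im, [rows, cols], order=1,
                                mode="nearest").mean(axis=0)
    mid = limit  # index of t = 0
    tape = float(np.median(q[mid - 2:mid + 3]))
    outer = max(4, q.size // 8)
    bg = float(np.median(np.concatenate([q[:outer], q[-outer:]])))
    if abs(tape - bg) < 1.0:
        raise MeasurementError("tape indistinguishable from background "
                               "in transverse profile")
    half = 0.5 * (tape + bg)
    qs = ndimage.gaussian_filter1d(q, 1.0)
    sign_tape = qs[mid] - half

    def scan(step):
        prev = mid
        k = mid + step
        while 0 <= k < qs.size:
            if (qs[k] - half) * sign_tape <= 0:
                a = qs[prev] - half
                b = qs[k] - half
                frac = a / (a - b) if a != b else 0.5
                return float(t[prev] + frac * (t[k] - t[prev]))
            prev = k
            k += step
        return None

    t_hi = scan(+1)
    t_lo = scan(-1)
    if t_lo is None or t_hi is None:
        raise MeasurementError("transverse tape boundaries not found")
    return t_lo, t_hi


def measure_cell(image, frame: AxisFrame, direction: str, z: float,
                 min_contrast: float = DEFAULT_READABILITY,
                 _edges: dict | None = None) -> CellMeasure:
    """Measure the 5-degree cell at eccentricity z.

    For superior/inferior the cell height is the radial extent and the width
    the transverse tape extent; for left/right the roles swap.  At z = 0 the
    center cell combines all four half-axes: its height is the distance
    between the first superior and inferior boundaries, its width the
    distance between the first left and right boundaries, and the result is
    reported with direction ``"center"``.
    """
    if z == 0:
        first = {}
        for d in DIRECTIONS:
            edges = (_edges or {}).get(d) or _direction_edges(
                image, frame, d, min_contrast)
            if not edges:
                raise MeasurementError(f"no readable boundary along {d}")
            first[d] = edges[0].position
        return CellMeasure("center", 0.0,
                           h=first["superior"] + first["inferior"],
                           w=first["left"] + first["right"])
    edges = (_edges or {}).get(direction)
    (e_in, e_out), (t_lo, t_hi) = trace_cell_edges(
        image, frame, direction, z, min_contrast, _edges=edges)
    radial = e_out - e_in
    transverse = t_hi - t_lo
    if direction in ("superior", "inferior"):
        h, w = radial, transverse
    else:
        h, w = transverse, radial
    return CellMeasure(direction, float(z), h=h, w=w)


def sample_stripes(image, frame: AxisFrame, direction: str, z: float,
                   min_contrast: float = DEFAULT_READABILITY,
                   _edges: list[Edge] | None = None) -> StripePair:
    """Mean gray level of the central 2x2 pixels of the black and white
    stripes adjacent at eccentricity z.

    The pair consists of the cell at z and its inner neighbour (for z = 0,
    the center cell and the first peripheral cell along ``direction``); the
    darker member is reported as B.  Raises :class:`RangeError` when a
    stripe center falls outside the image.
    """
    im = np.asarray(image, dtype=float)
    edges = _edges if _edges is not None else _direction_edges(
        image, frame, direction, min_contrast)
    j = int(round(z / CELL_DEG))
    ja, jb = (0, 1) if j == 0 else (j - 1, j)

    def cell_center_distance(k):
        if k == 0:
            return 0.0
        if len(edges) <= k:
            raise RangeError(
                f"stripe cell {k} along {direction} not rendered/readable")
        return 0.5 * (edges[k - 1].position + edges[k].position)

    means = []
    for k in (ja, jb):
        dist = cell_center_distance(k)
        vr, vc = DIRECTION_VECTORS[direction]
        r = frame.center[0] + dist * vr
        c = frame.center[1] + dist * vc
        r0, c0 = int(math.floor(r)), int(math.floor(c))
        if r0 < 0 or c0 < 0 or r0 + 1 >= im.shape[0] or c0 + 1 >= im.shape[1]:
            raise RangeError("stripe center outside the image")
        means.append(float(im[r0:r0 + 2, c0:c0 + 2].mean()))
    b, w = sorted(means)
    return StripePair(direction if j > 0 else "center", float(z), B=b, W=w)


def max_field_of_view(image, frame: AxisFrame,
                      readability_threshold: float = DEFAULT_READABILITY,
                      _edges: dict | None = None) -> FieldOfView:
    """Most peripheral readable 5-degree marker per direction.

    A marker at 5*j degrees is readable when both boundaries of its cell are
    detected with local Michelson contrast at or above the threshold; with E
    detected boundaries the field of view is ``5 * (E - 1)`` degrees (0 when
    nothing is readable).  Non-increasing in the threshold.
    """
    degrees = {}
    for d in DIRECTIONS:
        edges = (_edges or {}).get(d)
        if edges is None:
            edges = _direction_edges(image, frame, d, readability_threshold)
        else:
            edges = _drop_trailing_stub(
                [e for e in edges if e.contrast >= readability_threshold])
        degrees[d] = CELL_DEG * max(0, len(edges) - 1)
    return FieldOfView(degrees=degrees,
                       readability_threshold=readability_threshold)


# ---------------------------------------------------------------------------
# Whole-image protocol


def measure_image(image, frame: AxisFrame | None = None,
                  center_hint: tuple[float, float] | None = None,
                  geometry_positions=(0.0, 40.0, 80.0),
                  contrast_positions=(0.0, 80.0),
                  readability_threshold: float = DEFAULT_READABILITY,
                  ) -> ImageMeasurements:
    """Run the full measurement protocol on one image.

    Locates the axes (unless a frame is given), measures the field of view,
    the cells at the geometry positions and the stripe pairs at the contrast
    positions.  Per-cell failures are recorded in ``errors`` and skipped
    rather than aborting the image.
    """
    if frame is None:
        frame = locate_axes(image, center_hint)
    edge_cache = {d: _direction_edges(image, frame, d, readability_threshold)
                  for d in DIRECTIONS}
    result = ImageMeasurements(
        frame=frame,
        fov=max_field_of_view(image, frame, readability_threshold,
                              _edges=edge_cache),
    )
    for z in geometry_positions:
        if z == 0:
            try:
                result.cells.append(
                    measure_cell(image, frame, "center", 0.0, _edges=edge_cache))
            except (MeasurementError, RangeError) as exc:
                result.errors.append(f"center cell: {exc}")
            continue
        for d in DIRECTIONS:
            try:
                result.cells.append(
                    measure_cell(image, frame, d, z, _edges=edge_cache))
            except (MeasurementError, RangeError) as exc:
                result.errors.append(f"cell {d} z={z}: {exc}")
    for z in contrast_positions:
        if z == 0:
            try:
                result.stripes.append(
                    sample_stripes(image, frame, "superior", 0.0,
                                   _edges=edge_cache["superior"]))
            except (MeasurementError, RangeError) as exc:
                result.errors.append(f"center stripes: {exc}")
            continue
        for d in DIRECTIONS:
            try:
                result.stripes.append(
                    sample_stripes(image, frame, d, z, _edges=edge_cache[d]))
            except (MeasurementError, RangeError) as exc:
                result.errors.append(f"stripes {d} z={z}: {exc}")
    return result
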