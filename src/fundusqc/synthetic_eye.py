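"""Synthetic model-eye scale-tape images with exact analytic ground truth.

A physical calibration model eye carries two perpendicular tapes on its
posterior surface, marked every 5 degrees of visual angle.  An ultra-widefield
scanning laser ophthalmoscope images that surface through its own (anisotropic,
direction-dependent) projection, so a 5-degree cell of tape maps to different
pixel extents in different directions and eccentricities.  This module renders
such images directly from a parameterised angle-to-pixel projection instead of
simulating the device optics: each image half-axis (superior, inferior, left,
right) gets a monotone radial mapping

    r(theta) = f * theta + k3 * theta**3        [pixels]

together with a transverse scale t(theta) (pixels per degree perpendicular to
the meridian, linearly interpolated between samples).  The renderer draws the
two tapes as alternating black/white 5-degree cells, optionally degrades the
image (Gaussian noise, Gaussian blur, JPEG re-encoding), and returns the exact
cell geometry and stripe intensities as ground truth, so measurement code can
be validated to sub-pixel accuracy.

Conventions
-----------
* Pixel coordinates are ``(row, col)`` with row increasing downward; pixel
  centers sit on integer coordinates.
* ``superior`` is decreasing row, ``inferior`` increasing row, ``left``
  decreasing column, ``right`` increasing column.
* Tape cells are centered on multiples of 5 degrees: the cell "at z" spans
  ``[z - 2.5, z + 2.5]`` along its meridian.  The center cell spans the pole,
  from 2.5 degrees inferior to 2.5 degrees superior (and likewise on the
  horizontal tape), and is rendered at a single shared level.
* Cells alternate white (even index, counting the center cell as 0) and black
  (odd index).
"""

from __future__ import annotations

import dataclasses
import io as _io
import json
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from PIL import Image
from scipy import ndimage

from .errors import RangeError, ValidationError

DIRECTIONS = ("superior", "inferior", "left", "right")
VERTICAL_DIRECTIONS = ("superior", "inferior")
HORIZONTAL_DIRECTIONS = ("left", "right")

#: Tape cell pitch in degrees (scale markings every 5 degrees).
CELL_DEG = 5.0
#: Half-extent of a cell along the meridian, degrees.
HALF_CELL_DEG = CELL_DEG / 2.0

_INVERSE_GRID_N = 4096


@dataclass(frozen=True)
class MeridianProjection:
    """Monotone angle-to-pixel mapping along one image half-axis.

    Parameters
    ----------
    direction
        One of ``superior``, ``inferior``, ``left``, ``right``.
    f
        Linear radial coefficient, pixels per degree; must be positive.
    k3
        Cubic radial coefficient, pixels per degree cubed.  Positive values
        magnify the periphery, negative values compress it.
    transverse_angles, transverse_values
        Samples of the transverse scale (pixels per degree perpendicular to
        the meridian); linearly interpolated, held constant beyond the last
        sample.
    max_angle
        Largest eccentricity rendered, degrees; at most 110.
    """

    direction: str
    f: float
    k3: float
    transverse_angles: tuple[float, ...]
    transverse_values: tuple[float, ...]
    max_angle: float

    def radial(self, theta):
        """Radial pixel distance from the image center at eccentricity theta."""
        theta = np.asarray(theta, dtype=float)
        return self.f * theta + self.k3 * theta**3

    def radial_derivative(self, theta):
        theta = np.asarray(theta, dtype=float)
        return self.f + 3.0 * self.k3 * theta**2

    def radial_inverse(self, r):
        """Eccentricity (degrees) at radial pixel distance ``r`` (clamped)."""
        grid_theta = np.linspace(0.0, self.max_angle, _INVERSE_GRID_N)
        grid_r = self.radial(grid_theta)
        return np.interp(np.asarray(r, dtype=float), grid_r, grid_theta)

    def transverse_scale(self, theta):
        """Transverse scale (pixels/degree) at eccentricity theta."""
        return np.interp(
            np.asarray(theta, dtype=float),
            np.asarray(self.transverse_angles),
            np.asarray(self.transverse_values),
        )

    @property
    def rendered_max_angle(self) -> float:
        """Angle at which the rendered tape actually ends.

        A partial cell beyond the last 5-degree boundary is only rendered
        when it extends at least half a cell; a shorter stub would merge
        with the tape-end transition and corrupt the outermost boundary, so
        the tape is cut at the boundary instead.
        """
        if self.max_angle < HALF_CELL_DEG:
            return self.max_angle
        last_boundary = HALF_CELL_DEG + CELL_DEG * math.floor(
            (self.max_angle - HALF_CELL_DEG) / CELL_DEG)
        if self.max_angle - last_boundary >= HALF_CELL_DEG - 1e-9:
            return self.max_angle
        return last_boundary


def build_projection(
    f: float,
    k3: float,
    transverse_samples: Sequence[tuple[float, float]],
    max_angle: float,
    direction: str = "superior",
) -> MeridianProjection:
    """Validate and build a :class:`MeridianProjection`.

    Rejects parameter sets whose radial mapping is not strictly increasing on
    ``[0, max_angle]`` (the derivative ``f + 3*k3*theta**2`` must stay
    positive), empty transverse sample lists, and non-positive transverse
    scales.
    """
    if direction not in DIRECTIONS:
        raise ValidationError(f"unknown direction {direction!r}")
    if not (f > 0):
        raise ValidationError(f"radial linear coefficient must be positive, got {f}")
    if not (0 < max_angle <= 110):
        raise ValidationError(f"max_angle must lie in (0, 110], got {max_angle}")
    samples = sorted((float(a), float(v)) for a, v in transverse_samples)
    if not samples:
        raise ValidationError("transverse_samples must not be empty")
    if samples[0][0] > 0:
        raise ValidationError("transverse samples must start at 0 degrees")
    if any(v <= 0 for _, v in samples):
        raise ValidationError("transverse scale must be positive everywhere")
    if k3 < 0:
        # derivative f + 3*k3*theta^2 first reaches zero at theta_crit
        theta_crit = math.sqrt(-f / (3.0 * k3))
        if theta_crit <= max_angle:
            raise ValidationError(
                "radial mapping is non-monotone: r'(theta) <= 0 at "
                f"theta = {theta_crit:.3f} deg (within max_angle {max_angle})"
            )
    angles, values = zip(*samples)
    return MeridianProjection(
        direction=direction,
        f=float(f),
        k3=float(k3),
        transverse_angles=tuple(angles),
        transverse_values=tuple(values),
        max_angle=float(max_angle),
    )


# ---------------------------------------------------------------------------
# Ground truth


@dataclass
class GroundTruth:
    """Analytic geometry and intensities of a rendered scene.

    ``cells`` maps ``(direction, z)`` to a dict with keys ``h``, ``w``
    (image-frame vertical/horizontal pixel extents of the 5-degree cell),
    ``radial`` and ``transverse`` (extents along/across the meridian).  The
    center cell is stored under ``("center", 0.0)``.  ``stripes`` maps
    ``(direction, z)`` to the rendered ``(black, white)`` levels of the
    adjacent stripe pair at z.  ``fov`` maps direction to the most peripheral
    readable 5-degree marker, degrees.
    """

    cells: dict = field(default_factory=dict)
    stripes: dict = field(default_factory=dict)
    fov: dict = field(default_factory=dict)

    @property
    def center(self) -> tuple[float, float]:
        """(h0, w0) of the center cell, pixels."""
        c = self.cells[("center", 0.0)]
        return c["h"], c["w"]

    def to_dict(self) -> dict:
        return {
            "cells": {f"{d}:{z:g}": v for (d, z), v in self.cells.items()},
            "stripes": {
                f"{d}:{z:g}": list(v) for (d, z), v in self.stripes.items()
            },
            "fov": dict(self.fov),
        }

    @classmethod
    def from_dict(cls, data: dict) -> "GroundTruth":
        def parse(key):
            d, z = key.rsplit(":", 1)
            return d, float(z)

        return cls(
            cells={parse(k): v for k, v in data.get("cells", {}).items()},
            stripes={parse(k): tuple(v) for k, v in data.get("stripes", {}).items()},
            fov=dict(data.get("fov", {})),
        )


def ground_truth_cells(
    projections: Mapping[str, MeridianProjection],
    eccentricities: Sequence[float],
    tape_halfwidth_deg: float = HALF_CELL_DEG,
    skip_out_of_range: bool = False,
) -> GroundTruth:
    """Analytic 5-degree cell extents for the given eccentricities.

    For a cell at eccentricity z along direction d the radial extent is
    ``r_d(z + 2.5) - r_d(z - 2.5)`` and the transverse extent is the rendered
    tape width ``2 * tape_halfwidth_deg * t_d(z)`` (equal to the 5-degree
    extent ``5 * t_d(z)`` at the default tape half-width of 2.5 degrees).
    For superior/inferior the cell height is radial and width transverse; for
    left/right the roles swap.  The center cell (z = 0) combines the four
    half-axes: height ``r_sup(2.5) + r_inf(2.5)``, width
    ``r_left(2.5) + r_right(2.5)``.

    Raises :class:`RangeError` for eccentricities whose cell does not fit in
    a direction's rendered range, unless ``skip_out_of_range`` is set.
    """
    missing = [d for d in DIRECTIONS if d not in projections]
    if missing:
        raise ValidationError(f"projections missing directions: {missing}")
    truth = GroundTruth()
    for z in eccentricities:
        z = float(z)
        if z == 0.0:
            h0 = float(
                projections["superior"].radial(HALF_CELL_DEG)
                + projections["inferior"].radial(HALF_CELL_DEG)
            )
            w0 = float(
                projections["left"].radial(HALF_CELL_DEG)
                + projections["right"].radial(HALF_CELL_DEG)
            )
            truth.cells[("center", 0.0)] = {
                "h": h0, "w": w0, "radial": h0, "transverse": w0,
            }
            continue
        for d in DIRECTIONS:
            proj = projections[d]
            if z + HALF_CELL_DEG > proj.max_angle or z - HALF_CELL_DEG < 0:
                if skip_out_of_range:
                    continue
                raise RangeError(
                    f"cell at z={z} deg ({d}) exceeds rendered range "
                    f"[0, {proj.max_angle}]"
                )
            radial = float(
                proj.radial(z + HALF_CELL_DEG) - proj.radial(z - HALF_CELL_DEG)
            )
            transverse = float(2.0 * tape_halfwidth_deg * proj.transverse_scale(z))
            if d in VERTICAL_DIRECTIONS:
                h, w = radial, transverse
            else:
                h, w = transverse, radial
            truth.cells[(d, z)] = {
                "h": h, "w": w, "radial": radial, "transverse": transverse,
            }
    return truth


# ---------------------------------------------------------------------------
# Scene specification


def stripe_levels_from_samples(
    samples: Mapping[float, tuple[float, float]], max_angle: float
) -> np.ndarray:
    """Per-cell (black, white) levels from (eccentricity -> pair) samples.

    Levels are linearly interpolated at the cell centers (multiples of 5
    degrees) and held constant beyond the outermost sample.  Returns an array
    of shape ``(n_cells, 2)``.
    """
    if not samples:
        raise ValidationError("stripe level samples must not be empty")
    # the outermost, possibly partial cell (index floor((max+2.5)/5)) still
    # renders, so its level must be defined too
    n_cells = int(math.floor((max_angle + HALF_CELL_DEG) / CELL_DEG)) + 1
    angles = np.array(sorted(samples), dtype=float)
    blacks = np.array([samples[a][0] for a in sorted(samples)], dtype=float)
    whites = np.array([samples[a][1] for a in sorted(samples)], dtype=float)
    centers = np.arange(n_cells) * CELL_DEG
    return np.stack(
        [np.interp(centers, angles, blacks), np.interp(centers, angles, whites)],
        axis=1,
    )


@dataclass
class SceneSpec:
    """Complete description of a synthetic calibration image.

    ``stripe_levels`` maps each direction to an ``(n_cells, 2)`` array of
    (black, white) gray levels per 5-degree cell (cell j centered at 5*j
    degrees).  Even cells render at their white level, odd cells at their
    black level; the shared center cell renders at the superior tape's cell-0
    white level.  Degradations are applied in the order: quantize to 0-255,
    additive Gaussian noise (SD ``noise_sd`` gray levels), Gaussian blur
    (``blur_sigma`` pixels), JPEG re-encoding at ``jpeg_quality``.  ``seed``
    governs the noise and nothing else.
    """

    image_shape: tuple[int, int]
    center: tuple[float, float]
    projections: dict
    stripe_levels: dict
    tape_halfwidth_deg: float = HALF_CELL_DEG
    background_level: float = 20.0
    noise_sd: float = 0.0
    blur_sigma: float = 0.0
    jpeg_quality: int | None = None
    seed: int = 0
    supersample: int = 4

    def replace(self, **kwargs) -> "SceneSpec":
        return dataclasses.replace(self, **kwargs)

    def validate(self) -> None:
        if self.noise_sd < 0 or self.blur_sigma < 0:
            raise ValidationError("noise_sd and blur_sigma must be non-negative")
        if not (0 <= self.background_level <= 255):
            raise ValidationError("background_level must lie in [0, 255]")
        if self.jpeg_quality is not None and not (1 <= self.jpeg_quality <= 100):
            raise ValidationError("jpeg_quality must lie in [1, 100]")
        if self.tape_halfwidth_deg <= 0:
            raise ValidationError("tape_halfwidth_deg must be positive")
        if self.supersample < 1:
            raise ValidationError("supersample must be >= 1")
        for d in DIRECTIONS:
            if d not in self.projections:
                raise ValidationError(f"projections missing direction {d!r}")
            if d not in self.stripe_levels:
                raise ValidationError(f"stripe_levels missing direction {d!r}")
            levels = np.asarray(self.stripe_levels[d], dtype=float)
            if levels.ndim != 2 or levels.shape[1] != 2:
                raise ValidationError("stripe_levels arrays must have shape (n, 2)")
            if np.any(levels < 0) or np.any(levels > 255):
                raise ValidationError("stripe levels must lie in [0, 255]")
            needed = int(math.floor(
                (self.projections[d].max_angle + HALF_CELL_DEG) / CELL_DEG)) + 1
            if levels.shape[0] < needed:
                raise ValidationError(
                    f"direction {d!r}: {needed} cell levels needed, "
                    f"got {levels.shape[0]}"
                )
        self._check_extents()

    def _check_extents(self) -> None:
        h_img, w_img = self.image_shape
        row_c, col_c = self.center
        margin = 2.0
        for d in DIRECTIONS:
            proj = self.projections[d]
            reach = float(proj.radial(proj.max_angle))
            thetas = np.linspace(0, proj.max_angle, 256)
            hw = float(
                self.tape_halfwidth_deg * np.max(proj.transverse_scale(thetas))
            )
            if d == "superior":
                ok = row_c - reach - margin >= 0 and hw + margin <= min(col_c, w_img - 1 - col_c)
            elif d == "inferior":
                ok = row_c + reach + margin <= h_img - 1 and hw + margin <= min(col_c, w_img - 1 - col_c)
            elif d == "left":
                ok = col_c - reach - margin >= 0 and hw + margin <= min(row_c, h_img - 1 - row_c)
            else:
                ok = col_c + reach + margin <= w_img - 1 and hw + margin <= min(row_c, h_img - 1 - row_c)
            if not ok:
                raise ValidationError(
                    f"tape for direction {d!r} (reach {reach:.1f} px, half-width "
                    f"{hw:.1f} px) does not fit inside the {h_img}x{w_img} frame"
                )

    # -- level bookkeeping -------------------------------------------------

    @property
    def center_level(self) -> float:
        """Gray level of the shared center cell."""
        return float(np.asarray(self.stripe_levels["superior"])[0, 1])

    def cell_fill_level(self, direction: str, j: int) -> float:
        """Rendered gray level of cell ``j`` along ``direction``."""
        if j == 0:
            return self.center_level
        levels = np.asarray(self.stripe_levels[direction], dtype=float)
        return float(levels[j, 1] if j % 2 == 0 else levels[j, 0])

    def stripe_pair(self, direction: str, z: float) -> tuple[float, float]:
        """Rendered (black, white) levels of the adjacent stripe pair at z.

        The pair consists of the cell at z and its inner neighbour (for the
        center, the first peripheral cell); the odd-indexed member is black.
        """
        j = int(round(z / CELL_DEG))
        ja, jb = (0, 1) if j == 0 else (j - 1, j)
        j_black = ja if ja % 2 == 1 else jb
        j_white = jb if j_black == ja else ja
        return (
            self.cell_fill_level(direction, j_black),
            self.cell_fill_level(direction, j_white),
        )


# ---------------------------------------------------------------------------
# Rendering

#: Default readability threshold used for the ground-truth field of view
#: (local Michelson contrast between adjacent cell levels).
DEFAULT_READABILITY = 0.02


def _truth_fov(spec: SceneSpec, direction: str,
               readability: float = DEFAULT_READABILITY) -> float:
    """Most peripheral readable 5-degree marker implied by the configuration.

    A marker is readable while every inter-cell boundary inside it has level
    contrast at or above ``readability``; the tape must also extend to the
    marker itself, which bounds the result by ``5 * floor(max_angle / 5)``.
    """
    proj = spec.projections[direction]
    geom_limit = CELL_DEG * math.floor(proj.max_angle / CELL_DEG)
    n_boundaries = int(math.floor((proj.max_angle - HALF_CELL_DEG) / CELL_DEG)) + 1
    readable = 0
    for m in range(n_boundaries):
        a = spec.cell_fill_level(direction, m)
        b = spec.cell_fill_level(direction, m + 1)
        denom = a + b
        contrast = abs(a - b) / denom if denom > 0 else 0.0
        if contrast < readability:
            break
        readable = m + 1
    return float(min(geom_limit, CELL_DEG * readable))


def _fill_levels_for_thetas(spec: SceneSpec, direction: str,
                            thetas: np.ndarray) -> np.ndarray:
    """Vectorised cell fill level lookup for meridian angles."""
    j = np.floor((thetas + HALF_CELL_DEG) / CELL_DEG).astype(int)
    levels = np.asarray(spec.stripe_levels[direction], dtype=float)
    j = np.clip(j, 0, levels.shape[0] - 1)
    fill = np.where(j % 2 == 0, levels[j, 1], levels[j, 0])
    return np.where(j == 0, spec.center_level, fill)


def _render_strip(canvas: np.ndarray, spec: SceneSpec, axis: str) -> None:
    """Composite one tape (vertical or horizontal) onto the canvas in place.

    The strip's bounding box is re-rendered on a ``supersample``-times finer
    grid seeded from the current canvas, masked sub-pixels are filled with
    the tape level, and the block is box-downsampled back — yielding
    anti-aliased, sub-pixel-accurate cell edges.
    """
    h_img, w_img = spec.image_shape
    row_c, col_c = spec.center
    S = spec.supersample
    if axis == "vertical":
        dirs = ("superior", "inferior")
        along_c, across_c, across_len = row_c, col_c, w_img
    else:
        dirs = ("left", "right")
        along_c, across_c, across_len = col_c, row_c, h_img

    reach = {d: float(spec.projections[d].radial(
        spec.projections[d].rendered_max_angle)) for d in dirs}
    hw_max = 0.0
    for d in dirs:
        proj = spec.projections[d]
        th = np.linspace(0, proj.max_angle, 256)
        hw_max = max(hw_max, float(
            spec.tape_halfwidth_deg * np.max(proj.transverse_scale(th))))

    along_len = h_img if axis == "vertical" else w_img
    a0 = max(0, int(math.floor(along_c - reach[dirs[0]] - 2)))
    a1 = min(along_len, int(math.ceil(along_c + reach[dirs[1]] + 2)) + 1)
    b0 = max(0, int(math.floor(across_c - hw_max - 2)))
    b1 = min(across_len, int(math.ceil(across_c + hw_max + 2)) + 1)

    # sub-pixel sample coordinates (pixel i covers [i-0.5, i+0.5))
    sub_along = a0 - 0.5 + (np.arange((a1 - a0) * S) + 0.5) / S
    sub_across = b0 - 0.5 + (np.arange((b1 - b0) * S) + 0.5) / S

    signed = sub_along - along_c            # negative toward superior/left
    level = np.zeros_like(signed)
    hw = np.full_like(signed, -1.0)         # negative: off tape
    for d, sign in zip(dirs, (-1.0, 1.0)):
        proj = spec.projections[d]
        dist = signed * sign
        sel = (dist >= 0) & (dist <= reach[d])
        theta = proj.radial_inverse(dist[sel])
        level[sel] = _fill_levels_for_thetas(spec, d, theta)
        hw[sel] = spec.tape_halfwidth_deg * proj.transverse_scale(theta)

    region = canvas[a0:a1, b0:b1] if axis == "vertical" else canvas[b0:b1, a0:a1].T
    block = np.repeat(np.repeat(region, S, axis=0), S, axis=1)
    mask = np.abs(sub_across - across_c)[None, :] <= hw[:, None]
    if axis == "horizontal":
        # The tapes butt-joint at the center square: the horizontal tape
        # must not occlude a peripheral (non-center) cell of the vertical
        # tape, whose transverse width near the pole can exceed the radial
        # position of the first vertical cell boundary.  The vertical tape
        # is first re-painted at sub-pixel resolution (the canvas only
        # stores box-averaged values), then the horizontal tape is drawn
        # where it does not cover a peripheral vertical cell.
        signed_v = sub_across - across_c     # row offsets from center
        theta_v = np.zeros_like(signed_v)
        hw_v = np.full_like(signed_v, -1.0)
        level_v = np.zeros_like(signed_v)
        for d, sign in zip(("superior", "inferior"), (-1.0, 1.0)):
            proj = spec.projections[d]
            dist = signed_v * sign
            sel = (dist >= 0) & (dist <= proj.radial(proj.rendered_max_angle))
            th = proj.radial_inverse(dist[sel])
            theta_v[sel] = th
            hw_v[sel] = spec.tape_halfwidth_deg * proj.transverse_scale(th)
            level_v[sel] = _fill_levels_for_thetas(spec, d, th)
        on_vertical = np.abs(sub_along - along_c)[:, None] <= hw_v[None, :]
        block = np.where(on_vertical, level_v[None, :], block)
        occluded = on_vertical & (theta_v >= HALF_CELL_DEG)[None, :]
        mask &= ~occluded
    block = np.where(mask, level[:, None], block)
    down = block.reshape(len(sub_along) // S, S, len(sub_across) // S, S)
    down = down.mean(axis=(1, 3))
    if axis == "vertical":
        canvas[a0:a1, b0:b1] = down
    else:
        canvas[b0:b1, a0:a1] = down.T


def render_scene(spec: SceneSpec) -> tuple[np.ndarray, GroundTruth]:
    """Render a scene to an 8-bit image together with its ground truth.

    The render is a pure function of the spec (including its seed): identical
    specs produce bit-identical images.
    """
    spec.validate()
    canvas = np.full(spec.image_shape, float(spec.background_level))
    _render_strip(canvas, spec, "vertical")
    _render_strip(canvas, spec, "horizontal")

    img = np.clip(np.round(canvas), 0, 255)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        img = img + rng.normal(0.0, spec.noise_sd, size=img.shape)
        img = np.clip(img, 0, 255)
    if spec.blur_sigma > 0:
        img = ndimage.gaussian_filter(img, spec.blur_sigma)
    img = np.clip(np.round(img), 0, 255).astype(np.uint8)
    if spec.jpeg_quality is not None:
        buf = _io.BytesIO()
        Image.fromarray(img, mode="L").save(
            buf, format="JPEG", quality=int(spec.jpeg_quality))
        buf.seek(0)
        img = np.asarray(Image.open(buf).convert("L"))

    # ground truth: every complete cell, per direction, plus the center
    eccs = set()
    feasible = {}
    for d in DIRECTIONS:
        max_angle = spec.projections[d].max_angle
        n = int(math.floor((max_angle - HALF_CELL_DEG) / CELL_DEG))
        feasible[d] = [CELL_DEG * j for j in range(1, n + 1)]
        eccs.update(feasible[d])
    truth = ground_truth_cells(
        spec.projections, sorted(eccs), spec.tape_halfwidth_deg,
        skip_out_of_range=True,
    )
    if all(spec.projections[d].max_angle >= HALF_CELL_DEG for d in DIRECTIONS):
        center = ground_truth_cells(spec.projections, [0.0],
                                    spec.tape_halfwidth_deg)
        truth.cells.update(center.cells)
    for d in DIRECTIONS:
        for z in [0.0] + feasible[d]:
            if z == 0.0 and not feasible[d]:
                continue
            truth.stripes[(d, z)] = spec.stripe_pair(d, z)
        truth.fov[d] = _truth_fov(spec, d)
    return img, truth


# ---------------------------------------------------------------------------
# Randomised scenes


def random_scene(seed: int, noise_sd: float = 0.0,
                 jpeg_quality: int | None = None,
                 max_angle: float = 85.0) -> SceneSpec:
    """Draw a random monotone-projection scene for validation studies.

    Per direction the radial coefficients are drawn with f between 5 and
    6.8 px/deg and k3 within the monotonicity bound (and small enough that
    the tape stays within a compact frame); the transverse scale is sampled
    independently at 0/40/80 degrees between 4.5 and 8.5 px/deg.  Stripe
    levels are drawn with strong contrast (black 30-70, white 150-220).
    The seed determines the geometry; the spec's own seed (set equal)
    governs any rendering noise.
    """
    rng = np.random.default_rng(seed)
    projections, stripe_levels = {}, {}
    reach, hw_max = 0.0, 0.0
    black = float(rng.uniform(30.0, 70.0))
    white = float(rng.uniform(150.0, 220.0))
    for d in DIRECTIONS:
        f = float(rng.uniform(5.0, 6.8))
        k3_lo = -0.5 * f / (3.0 * max_angle**2)
        k3_hi = min(2.2e-4, (620.0 - max_angle * f) / max_angle**3)
        k3 = float(rng.uniform(k3_lo, k3_hi))
        samples = [(a, float(rng.uniform(4.5, 8.5)))
                   for a in (0.0, 40.0, 80.0)]
        proj = build_projection(f, k3, samples, max_angle, direction=d)
        projections[d] = proj
        stripe_levels[d] = stripe_levels_from_samples(
            {0.0: (black, white)}, max_angle)
        reach = max(reach, float(proj.radial(max_angle)))
        hw_max = max(hw_max, HALF_CELL_DEG * max(v for _, v in samples))
    half = int(math.ceil(reach + hw_max)) + 10
    return SceneSpec(
        image_shape=(2 * half + 1, 2 * half + 1),
        center=(float(half), float(half)),
        projections=projections,
        stripe_levels=stripe_levels,
        background_level=10.0,
        noise_sd=noise_sd,
        jpeg_quality=jpeg_quality,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# File output


def save_scene(image: np.ndarray, truth: GroundTruth, path,
               jpeg_quality: int = 95) -> None:
    """Write the image (PNG or JPEG by extension) plus a ground-truth sidecar.

    The sidecar shares the image basename with suffix ``.truth.json``.  Note
    that JPEG degradation meant to be *measured* should be applied in
    :func:`render_scene` (via ``jpeg_quality`` in the spec), not here.
    """
    path = str(path)
    pil = Image.fromarray(np.asarray(image, dtype=np.uint8), mode="L")
    if path.lower().endswith((".jpg", ".jpeg")):
        pil.save(path, format="JPEG", quality=jpeg_quality)
    else:
        pil.save(path)
    sidecar = path.rsplit(".", 1)[0] + ".truth.json"
    with open(sidecar, "w", encoding="utf-8") as fh:
        json.dump(truth.to_dict(), fh, indent=1, sort_keys=True)


def load_truth(path) -> GroundTruth:
    """Read a ground-truth sidecar written by :func:`save_scene`."""
    with open(path, encoding="utf-8") as fh:
        return GroundTruth.from_dict(json.load(fh))
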