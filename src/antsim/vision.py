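"""First-person vision: a software renderer for each organism's camera.

Each organism perceives the world through a low-resolution colour frame
(30x30 by default, matching the spatial resolution of real ant compound
eyes) rendered from its head position, looking along its heading.  The
world is planar, so the renderer is a "2.5D" ray-caster: one ray per pixel
column is cast across the horizontal field of view; the nearest object hit
within the view range colours that column, and the number of vertical
pixels it covers shrinks with distance (a flat-shaded billboard).  Food is
pure green, other organisms carry their lineage colour, and everything
else is mid-grey background.

The frame is handed to the nervous system as a channel-major flat vector:
all red intensities row-major, then all green, then all blue — 2700 values
for a 30x30 frame.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numba import njit

__all__ = [
    "BACKGROUND",
    "FOOD_COLOR",
    "Frame",
    "render_frame",
    "flatten",
    "unflatten",
    "dump_frame",
    "read_ppm",
]

BACKGROUND = (0.5, 0.5, 0.5)
FOOD_COLOR = (0.0, 1.0, 0.0)

_MIN_DIST = 1e-9       # distance floor when the camera sits inside an object
_MIN_HALF_ROWS = 0.5   # any visible object covers at least the central row(s)


@dataclass
class Frame:
    """An H x W grid of (R, G, B) intensities in [0, 1]."""

    pixels: np.ndarray  # shape (height, width, 3), float64

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError("frame pixels must have shape (height, width, 3)")

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


def column_angles(width: int, fov: float) -> np.ndarray:
    """Ray angle offsets from the heading, one per column.

    Column 0 is the left edge of the image and looks counterclockwise of the
    heading; offsets are symmetric about 0, so mirroring the scene about the
    heading axis mirrors the columns.
    """
    j = np.arange(width)
    return fov / 2 - (j + 0.5) * fov / width


@njit(cache=True)
def _cast_and_paint(ox, oy, heading, centers, radii, heights, colors, active,
                    exclude, width, height, fov, view_range, frame):
    """Ray-cast one column per pixel column and paint billboards.

    ``frame`` (height, width, 3) is filled in place.  ``active`` masks out
    objects (eaten food); ``exclude`` skips the observer's own index (-1
    for none).  For each ray the nearest intersected disc within
    view_range wins (first index on exact ties); its billboard covers the
    rows within its angular half-height of the frame centre, with a floor
    of half a row so any visible object covers the central row(s).
    """
    n = centers.shape[0]
    vfov = fov * height / width
    row_center = (height - 1) / 2.0
    for jy in range(height):
        for jx in range(width):
            frame[jy, jx, 0] = BACKGROUND[0]
            frame[jy, jx, 1] = BACKGROUND[1]
            frame[jy, jx, 2] = BACKGROUND[2]
    for j in range(width):
        ang = heading + fov / 2 - (j + 0.5) * fov / width
        ux = math.cos(ang)
        uy = math.sin(ang)
        best = math.inf
        best_k = -1
        for k in range(n):
            if k == exclude or not active[k]:
                continue
            dx = centers[k, 0] - ox
            dy = centers[k, 1] - oy
            r2 = radii[k] * radii[k]
            proj = ux * dx + uy * dy
            perp = ux * dy - uy * dx
            disc = r2 - perp * perp
            if disc < 0:
                continue
            if proj <= 0 and dx * dx + dy * dy > r2:
                continue                        # behind, camera not inside
            t = proj - math.sqrt(disc)
            if t < 0.0:
                t = 0.0                         # camera inside the object
            if t > view_range or t >= best:
                continue
            best = t
            best_k = k
        if best_k < 0:
            continue
        d = best if best > _MIN_DIST else _MIN_DIST
        alpha = math.atan2(heights[best_k] / 2.0, d)
        half_rows = alpha * height / vfov
        if half_rows < _MIN_HALF_ROWS:
            half_rows = _MIN_HALF_ROWS
        for jy in range(height):
            if abs(jy - row_center) <= half_rows:
                frame[jy, j, 0] = colors[best_k, 0]
                frame[jy, j, 1] = colors[best_k, 1]
                frame[jy, j, 2] = colors[best_k, 2]


def render_scene(ox: float, oy: float, heading: float,
                 centers: np.ndarray, radii: np.ndarray, heights: np.ndarray,
                 colors: np.ndarray, width: int, height: int,
                 fov: float, view_range: float,
                 active: np.ndarray | None = None,
                 exclude: int = -1,
                 out: np.ndarray | None = None) -> np.ndarray:
    """Render arbitrary billboard discs; the core shared by all callers."""
    centers = np.ascontiguousarray(np.asarray(centers, dtype=float).reshape(-1, 2))
    radii = np.ascontiguousarray(np.asarray(radii, dtype=float))
    heights = np.ascontiguousarray(np.asarray(heights, dtype=float))
    colors = np.ascontiguousarray(np.asarray(colors, dtype=float).reshape(-1, 3))
    if active is None:
        active = np.ones(len(centers), dtype=bool)
    frame = out if out is not None else np.empty((height, width, 3))
    _cast_and_paint(ox, oy, heading, centers, radii, heights, colors, active,
                    exclude, width, height, fov, view_range, frame)
    return frame


def render_frame(state, observer, config) -> Frame:
    """Render the frame seen by ``observer`` in ``state``.

    Active food particles and all other organisms are visible; the observer's
    own body is not.  A pure, deterministic function of the state.
    """
    centers, radii, heights, colors = [], [], [], []
    for p in state.food:
        if p.active:
            centers.append((p.x, p.y))
            radii.append(config.food_radius)
            heights.append(config.food_height)
            colors.append(FOOD_COLOR)
    for org in state.iter_organisms():
        if org.id == observer.id:
            continue
        centers.append((org.pose.x, org.pose.y))
        radii.append(config.organism_radius)
        heights.append(config.organism_height)
        colors.append(org.color)
    pixels = render_scene(
        observer.pose.x, observer.pose.y, observer.pose.heading,
        np.array(centers, dtype=float).reshape(-1, 2),
        np.array(radii, dtype=float), np.array(heights, dtype=float),
        np.array(colors, dtype=float).reshape(-1, 3),
        config.vision_width, config.vision_height,
        config.fov, config.resolved_view_range,
    )
    return Frame(pixels)


# ---------------------------------------------------------------------------
# flattening (channel-major input vector)

def flatten(frame: Frame | np.ndarray) -> np.ndarray:
    """Channel-major flattening: R block row-major, then G, then B."""
    pixels = frame.pixels if isinstance(frame, Frame) else np.asarray(frame)
    return pixels.transpose(2, 0, 1).reshape(-1).copy()


def unflatten(values: np.ndarray, width: int, height: int) -> Frame:
    """Inverse of :func:`flatten`."""
    values = np.asarray(values, dtype=float)
    if values.size != 3 * width * height:
        raise ValueError(
            f"input vector length {values.size} != 3*{width}*{height}")
    return Frame(values.reshape(3, height, width).transpose(1, 2, 0).copy())


# ---------------------------------------------------------------------------
# plain PPM (P3) frame dumps

def dump_frame(frame: Frame, path, scale: int = 5) -> None:
    """Write the frame as a plain PPM (P3, 8-bit), integer-upscaled.

    The default 5x upscaling turns each receptor pixel into a 5x5 block so
    the tiny frames are legible to a human.
    """
    if scale < 1:
        raise ValueError("scale must be >= 1")
    img = np.rint(np.clip(frame.pixels, 0.0, 1.0) * 255).astype(int)
    img = np.repeat(np.repeat(img, scale, axis=0), scale, axis=1)
    h, w = img.shape[:2]
    rows = [" ".join(str(v) for v in row.reshape(-1)) for row in img]
    with open(path, "w") as fh:
        fh.write(f"P3\n{w} {h}\n255\n")
        fh.write("\n".join(rows) + "\n")


def read_ppm(path) -> Frame:
    """Read a plain PPM (P3) file back to intensities in [0, 1]."""
    with open(path) as fh:
        tokens = []
        for line in fh:
            tokens.extend(line.split("#", 1)[0].split())
    if not tokens or tokens[0] != "P3":
        raise ValueError("not a plain PPM (P3) file")
    w, h, maxval = int(tokens[1]), int(tokens[2]), int(tokens[3])
    data = np.array(tokens[4:4 + 3 * w * h], dtype=float) / maxval
    return Frame(data.reshape(h, w, 3))
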