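"""Circular field-of-view detection and the inscribed square grid.

A microphotograph taken through an eyepiece shows a bright circular field on
a dark surround.  The largest square inscribable in a circle of diameter d
has side a = d / sqrt(2) (its diagonal is a diameter); dividing that square
into an n x n lattice (n = 10 by default) gives equal cells, each 1/n^2 of
the square's area, whose four outer corners lie exactly on the circle.

Coordinate convention: pixel coordinates with the origin at the top-left,
x to the right, y down.  Cells are half-open axis-aligned rectangles
[x0, x1) x [y0, y1), indexed 0-based (row, col) row-major from the top-left,
so shared edges are never double-counted.  A pixel (i, j) belongs to a
rectangle iff its center (j + 0.5, i + 0.5) does.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
from PIL import Image, ImageDraw
from skimage import measure
from skimage.color import rgb2gray
from skimage.filters import threshold_otsu

from .errors import DetectionError, InvalidParameterError, ShapeMismatchError

SQRT2 = math.sqrt(2.0)


@dataclass(frozen=True)
class CircularFOV:
    """Fitted circle of the bright field of view, in pixel coordinates."""

    center_x: float
    center_y: float
    diameter_d: float

    def __post_init__(self) -> None:
        if self.diameter_d <= 0:
            raise InvalidParameterError(f"diameter must be positive, got {self.diameter_d}")

    @property
    def radius(self) -> float:
        return self.diameter_d / 2.0


@dataclass(frozen=True)
class GridGeometry:
    """The n x n equal-cell square grid inscribed in a circular FOV."""

    fov: CircularFOV
    n_per_side: int

    @property
    def side_a(self) -> float:
        """Side length of the inscribed square: a = d / sqrt(2)."""
        return self.fov.diameter_d / SQRT2

    @property
    def cell_side(self) -> float:
        return self.side_a / self.n_per_side

    @property
    def origin(self) -> tuple:
        """Top-left corner (x, y) of the inscribed square."""
        half = self.side_a / 2.0
        return (self.fov.center_x - half, self.fov.center_y - half)

    @property
    def corners(self) -> list:
        """The square's four corners (each at distance d/2 from the center)."""
        x0, y0 = self.origin
        a = self.side_a
        return [(x0, y0), (x0 + a, y0), (x0 + a, y0 + a), (x0, y0 + a)]

    def cell_rect(self, row: int, col: int) -> tuple:
        """Half-open rectangle (x0, y0, x1, y1) of cell (row, col)."""
        n = self.n_per_side
        if not (0 <= row < n and 0 <= col < n):
            raise IndexError(f"cell ({row}, {col}) outside {n}x{n} grid")
        ox, oy = self.origin
        s = self.cell_side
        return (ox + col * s, oy + row * s, ox + (col + 1) * s, oy + (row + 1) * s)

    @property
    def cell_rects(self) -> list:
        """All n^2 cell rectangles, row-major from the top-left."""
        n = self.n_per_side
        return [self.cell_rect(r, c) for r in range(n) for c in range(n)]

    def cell_slices(self, row: int, col: int) -> tuple:
        """(row_slice, col_slice) of the pixels whose centers fall in the cell."""
        x0, y0, x1, y1 = self.cell_rect(row, col)
        return (
            slice(math.ceil(y0 - 0.5), math.ceil(y1 - 0.5)),
            slice(math.ceil(x0 - 0.5), math.ceil(x1 - 0.5)),
        )

    def to_json(self) -> str:
        return json.dumps(
            {
                "center_x": self.fov.center_x,
                "center_y": self.fov.center_y,
                "diameter_d": self.fov.diameter_d,
                "side_a": self.side_a,
                "n_per_side": self.n_per_side,
                "cell_rects": self.cell_rects,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "GridGeometry":
        d = json.loads(text)
        return cls(
            fov=CircularFOV(d["center_x"], d["center_y"], d["diameter_d"]),
            n_per_side=d["n_per_side"],
        )


def inscribe_square_grid(fov: CircularFOV, n_per_side: int = 10) -> GridGeometry:
    """Inscribe the n x n equal-cell square grid in the FOV circle.

    The square's side is a = d / sqrt(2) and its corners touch the circle;
    the grid is axis-aligned and centered on the FOV center.
    """
    if n_per_side < 1:
        raise InvalidParameterError(f"n_per_side must be >= 1, got {n_per_side}")
    if fov.diameter_d <= 0:
        raise InvalidParameterError(f"diameter must be positive, got {fov.diameter_d}")
    return GridGeometry(fov=fov, n_per_side=n_per_side)


@dataclass(frozen=True)
class FOVDetectionConfig:
    """Parameters for circular-FOV detection.

    ``circle_override`` short-circuits detection with a known
    (center_x, center_y, diameter).  ``no_vignette`` treats the largest
    centered circle inscribed in the image as the FOV (for full-frame
    digital scans with no eyepiece vignette).  ``min_fraction`` is the
    minimum fraction of image pixels the bright region must cover for a
    detection to be accepted.
    """

    circle_override: tuple | None = None
    no_vignette: bool = False
    min_fraction: float = 0.05
    margin_tolerance: float = 5.0  # px the circle may extend past the image edge


def _lstsq_circle(points: np.ndarray) -> tuple:
    """Algebraic (Kasa) least-squares circle fit to (x, y) boundary points."""
    x, y = points[:, 0], points[:, 1]
    A = np.column_stack([2 * x, 2 * y, np.ones_like(x)])
    b = x * x + y * y
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    cx, cy, c = sol
    r = math.sqrt(max(c + cx * cx + cy * cy, 0.0))
    return float(cx), float(cy), float(r)


def fit_fov_circle(image: np.ndarray, config: FOVDetectionConfig | None = None) -> CircularFOV:
    """Fit the bright circular field of view of a microphotograph.

    Pipeline: Otsu luminance threshold -> largest connected bright
    component -> least-squares circle fit to its boundary contour.  Eyepiece
    vignettes are close to binary, so this is both fast and accurate; a
    Hough transform is unnecessary.
    """
    config = config or FOVDetectionConfig()
    if config.circle_override is not None:
        cx, cy, d = config.circle_override
        return CircularFOV(float(cx), float(cy), float(d))

    if image.ndim != 3 or image.shape[2] != 3:
        raise ShapeMismatchError(f"expected an RGB (H, W, 3) image, got shape {image.shape}")
    h, w = image.shape[:2]

    if config.no_vignette:
        return CircularFOV(w / 2.0, h / 2.0, float(min(h, w)))

    lum = rgb2gray(image)
    if float(lum.max() - lum.min()) < 1e-6:
        raise DetectionError("image has no contrast; no circular field of view found")
    mask = lum > threshold_otsu(lum)
    if mask.sum() < config.min_fraction * mask.size:
        raise DetectionError(
            f"bright region covers {mask.sum() / mask.size:.1%} of the image, "
            f"below the minimum {config.min_fraction:.1%}"
        )
    labels = measure.label(mask)
    props = max(measure.regionprops(labels), key=lambda p: p.area)
    component = labels == props.label
    if component.sum() < config.min_fraction * mask.size:
        raise DetectionError("largest bright component is too small to be the field of view")

    contours = measure.find_contours(component.astype(float), 0.5)
    boundary = max(contours, key=len)  # (row, col) points in pixel-index space
    # +0.5 converts pixel-index coordinates to the pixel-center convention
    pts = np.column_stack([boundary[:, 1] + 0.5, boundary[:, 0] + 0.5])  # -> (x, y)
    cx, cy, r = _lstsq_circle(pts)

    if (cx - r < -config.margin_tolerance or cy - r < -config.margin_tolerance
            or cx + r > w + config.margin_tolerance or cy + r > h + config.margin_tolerance):
        raise DetectionError(
            f"fitted circle (center=({cx:.1f}, {cy:.1f}), d={2 * r:.1f}) "
            "extends past the image bounds beyond the margin tolerance"
        )
    return CircularFOV(cx, cy, 2.0 * r)


def render_overlay(
    image: np.ndarray,
    grid: GridGeometry,
    labels: np.ndarray | None = None,
    line_color: tuple = (255, 220, 0),
    text_color: tuple = (255, 40, 40),
) -> np.ndarray:
    """Superimpose the grid (and optional per-cell T/S/L/NA letters) on a
    copy of the image; the input is never modified."""
    h, w = image.shape[:2]
    n = grid.n_per_side
    for cx, cy in grid.corners:
        if not (0 <= cx <= w and 0 <= cy <= h):
            raise InvalidParameterError("grid does not fit inside the image")
    if labels is not None:
        labels = np.asarray(labels, dtype=object)
        if labels.shape != (n, n):
            raise ShapeMismatchError(f"labels shape {labels.shape} != grid shape {(n, n)}")

    out = Image.fromarray(np.ascontiguousarray(image))
    draw = ImageDraw.Draw(out)
    ox, oy = grid.origin
    a = grid.side_a
    s = grid.cell_side
    for i in range(n + 1):
        draw.line([(ox + i * s, oy), (ox + i * s, oy + a)], fill=line_color, width=1)
        draw.line([(ox, oy + i * s), (ox + a, oy + i * s)], fill=line_color, width=1)
    if labels is not None:
        for r in range(n):
            for c in range(n):
                x0, y0, x1, y1 = grid.cell_rect(r, c)
                draw.text(
                    ((x0 + x1) / 2, (y0 + y1) / 2),
                    str(labels[r, c]),
                    fill=text_color,
                    anchor="mm",
                )
    return np.asarray(out)
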