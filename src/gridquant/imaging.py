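"""Per-cell tissue composition and T/S/L/NA labeling from pixels.

The grid method asks, for every small square, which tissue class occupies
more than half of it.  This module automates that reading:

1. color-deconvolve the RGB image into hematoxylin (nuclei) and eosin
   (cytoplasm/stroma) optical densities, and flag near-white pixels as
   background;
2. inside each grid cell, segment the nuclear (hematoxylin-dense) mask into
   connected blobs: small round blobs in a configurable diameter band are
   lymphocyte nuclei, larger blobs are tumor nuclear clusters;
3. convert pixel counts into class fractions and apply the predominance
   rules: a cell is T if tumor pixels exceed 50%, NA if background exceeds
   50% (or nothing is predominant), and otherwise S — promoted to L in sTIL
   mode when the cell holds >= 5 lymphocytes or is majority-lymphocyte.

Lymphocyte pixels count toward the stromal fraction (sTIL lives in the
stroma); the lymphocyte fraction is reported separately as a sub-fraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage import measure
from skimage.color import hed_from_rgb, rgb2gray, separate_stains

from .errors import InvalidParameterError, ShapeMismatchError
from .geometry import GridGeometry
from .quantify import MODE_STIL, MODE_TSR, MODES, FieldCounts

LABEL_T = "T"
LABEL_S = "S"
LABEL_L = "L"
LABEL_NA = "NA"


@dataclass(frozen=True)
class ImagingConfig:
    """Thresholds for pixel classification.

    The predominance threshold (0.5) is the method's own rule; the rest are
    engineering defaults for synthetic/eyepiece imagery and are expected to
    be tuned per dataset (mobile-camera white balance varies).

    ``lymph_diameter_band`` is in pixels and brackets small round dense
    nuclei; blobs above the band are treated as tumor nuclear clusters.
    ``l_rule`` selects how the two lymphocyte criteria combine ("or" is the
    sensitive reading of ">50% and/or >=5 per square").
    """

    stain_matrix: np.ndarray | None = None  # rows: stain OD vectors; None = standard H&E
    white_threshold: float = 0.85  # luminance above which a pixel is background
    nuclear_density: float = 0.25  # hematoxylin OD above which a pixel is nuclear
    lymph_diameter_band: tuple = (3.0, 14.0)  # px, equivalent blob diameter
    circularity_min: float = 0.4  # 4*pi*A/P^2 floor for lymphocyte blobs
    predominance: float = 0.5
    lymph_count_threshold: int = 5
    l_rule: str = "or"  # "or" | "and"

    def __post_init__(self) -> None:
        if not 0 < self.predominance < 1:
            raise InvalidParameterError("predominance must be in (0, 1)")
        if self.lymph_diameter_band[0] >= self.lymph_diameter_band[1]:
            raise InvalidParameterError("lymphocyte diameter band must be (low, high) with low < high")
        if self.l_rule not in ("or", "and"):
            raise InvalidParameterError(f"l_rule must be 'or' or 'and', got {self.l_rule!r}")

    def to_dict(self) -> dict:
        return {
            "white_threshold": self.white_threshold,
            "nuclear_density": self.nuclear_density,
            "lymph_diameter_band": list(self.lymph_diameter_band),
            "circularity_min": self.circularity_min,
            "predominance": self.predominance,
            "lymph_count_threshold": self.lymph_count_threshold,
            "l_rule": self.l_rule,
            "stain_matrix": None if self.stain_matrix is None else np.asarray(self.stain_matrix).tolist(),
        }


@dataclass(frozen=True)
class StainMaps:
    """Per-pixel stain optical densities and the background mask."""

    hematoxylin_density: np.ndarray
    eosin_density: np.ndarray
    background_mask: np.ndarray


@dataclass(frozen=True)
class CellComposition:
    """Class fractions and lymphocyte count of one grid cell."""

    tumor_fraction: float
    stroma_fraction: float
    lymphocyte_fraction: float
    background_fraction: float
    lymphocyte_count: int

    def __post_init__(self) -> None:
        total = self.tumor_fraction + self.stroma_fraction + self.background_fraction
        if total > 1.0 + 1e-6:
            raise InvalidParameterError(f"class fractions sum to {total} > 1")
        if self.lymphocyte_count < 0:
            raise InvalidParameterError("lymphocyte_count must be >= 0")


def _as_rgb_float(image: np.ndarray) -> np.ndarray:
    if image.ndim != 3 or image.shape[2] != 3:
        raise ShapeMismatchError(f"expected an RGB (H, W, 3) image, got shape {image.shape}")
    img = np.asarray(image)
    if img.dtype == np.uint8:
        return img.astype(np.float64) / 255.0
    return np.clip(img.astype(np.float64), 0.0, 1.0)


def separate_stains_hed(image: np.ndarray, config: ImagingConfig | None = None) -> StainMaps:
    """Color-deconvolve an H&E image into stain optical densities.

    Uses the standard published hematoxylin/eosin(/DAB) unmixing matrix
    unless ``config.stain_matrix`` overrides it.  Densities are clipped at
    zero; the background mask flags near-white (unstained) pixels by
    luminance.
    """
    config = config or ImagingConfig()
    rgb = _as_rgb_float(image)
    if config.stain_matrix is None:
        conv = hed_from_rgb
    else:
        m = np.asarray(config.stain_matrix, dtype=float)
        if m.shape != (3, 3):
            raise ShapeMismatchError(f"stain matrix must be 3x3, got {m.shape}")
        conv = np.linalg.inv(m)
    stains = separate_stains(rgb, conv)
    return StainMaps(
        hematoxylin_density=np.clip(stains[..., 0], 0.0, None),
        eosin_density=np.clip(stains[..., 1], 0.0, None),
        background_mask=rgb2gray(rgb) > config.white_threshold,
    )


def _nuclear_blobs(nuclear: np.ndarray, config: ImagingConfig):
    """Split a boolean nuclear mask into lymphocyte-band blobs and larger
    tumor-cluster blobs; returns (lymph_mask, tumor_mask, centroids)."""
    lo, hi = config.lymph_diameter_band
    lymph = np.zeros_like(nuclear)
    tumor = np.zeros_like(nuclear)
    centroids = []
    labels = measure.label(nuclear)
    for p in measure.regionprops(labels):
        d = p.equivalent_diameter_area
        if d < lo:
            continue  # specks: stray stroma nuclei fragments, neither class
        if d <= hi:
            perim = p.perimeter
            circ = 4.0 * np.pi * p.area / perim**2 if perim > 0 else 1.0
            if circ >= config.circularity_min:
                lymph[labels == p.label] = True
                centroids.append((float(p.centroid[0]), float(p.centroid[1])))
        else:
            tumor[labels == p.label] = True
    return lymph, tumor, centroids


def detect_lymphocytes(
    stains: StainMaps,
    config: ImagingConfig | None = None,
    region: tuple | None = None,
):
    """Count lymphocyte nuclei in a region of the stain maps.

    Lymphocytes are detected as connected hematoxylin-dense blobs whose
    equivalent diameter falls in ``config.lymph_diameter_band`` and whose
    circularity (4*pi*A/P^2) clears the floor; larger nuclear clusters
    (tumor) are ignored.  ``region`` is an optional (row_slice, col_slice)
    restriction; an empty region yields count 0.

    Returns ``(count, centroids)`` with centroids as (row, col) in the
    coordinates of the full map.
    """
    config = config or ImagingConfig()
    h = stains.hematoxylin_density
    bg = stains.background_mask
    r0 = c0 = 0
    if region is not None:
        rs, cs = region
        r0 = rs.start or 0
        c0 = cs.start or 0
        h = h[rs, cs]
        bg = bg[rs, cs]
    if h.size == 0:
        return 0, []
    nuclear = (h > config.nuclear_density) & ~bg
    lymph, _, centroids = _nuclear_blobs(nuclear, config)
    return len(centroids), [(r + r0, c + c0) for r, c in centroids]


def compose_cell(
    image: np.ndarray,
    stains: StainMaps,
    grid: GridGeometry,
    row: int,
    col: int,
    config: ImagingConfig | None = None,
) -> CellComposition:
    """Tissue composition of grid cell (row, col).

    Pixels are assigned to tumor (large hematoxylin-dense nuclear clusters),
    background (near-white), or stroma (everything else, lymphocytes
    included); fractions are pixel proportions of the cell.  The lymphocyte
    fraction and count come from the blob detector.
    """
    config = config or ImagingConfig()
    rs, cs = grid.cell_slices(row, col)  # raises IndexError for bad (row, col)
    h = stains.hematoxylin_density[rs, cs]
    bg = stains.background_mask[rs, cs]
    n_pix = h.size
    if n_pix == 0:
        return CellComposition(0.0, 0.0, 0.0, 1.0, 0)
    nuclear = (h > config.nuclear_density) & ~bg
    lymph, tumor, centroids = _nuclear_blobs(nuclear, config)
    background = bg & ~tumor
    stroma = ~tumor & ~background
    return CellComposition(
        tumor_fraction=float(tumor.sum()) / n_pix,
        stroma_fraction=float(stroma.sum()) / n_pix,
        lymphocyte_fraction=float(lymph.sum()) / n_pix,
        background_fraction=float(background.sum()) / n_pix,
        lymphocyte_count=len(centroids),
    )


def classify_cell(comp: CellComposition, mode: str, config: ImagingConfig | None = None) -> str:
    """Apply the predominance rules to a cell composition.

    Order: NA when background-predominant (or nothing is predominant);
    T when tumor occupies more than the predominance threshold; in sTIL
    mode, a stroma-predominant cell is L when it is majority-lymphocyte
    or holds >= 5 lymphocytes; otherwise S.  In TSR mode L is never
    emitted.  Exact 50/50 ties satisfy no strict majority and fall to NA.
    """
    if mode not in MODES:
        raise InvalidParameterError(f"mode must be one of {MODES}, got {mode!r}")
    config = config or ImagingConfig()
    thr = config.predominance
    if comp.background_fraction > thr:
        return LABEL_NA
    if comp.tumor_fraction > thr:
        return LABEL_T
    if comp.stroma_fraction > thr:
        if mode == MODE_STIL:
            by_fraction = comp.lymphocyte_fraction > thr
            by_count = comp.lymphocyte_count >= config.lymph_count_threshold
            hit = (by_fraction or by_count) if config.l_rule == "or" else (by_fraction and by_count)
            if hit:
                return LABEL_L
        return LABEL_S
    return LABEL_NA


def label_field(
    image: np.ndarray,
    grid: GridGeometry,
    mode: str,
    config: ImagingConfig | None = None,
    exclusion: set | None = None,
):
    """Label every grid cell of one field.

    ``exclusion`` is an optional set of (row, col) pairs forced to NA,
    mirroring the manual exclusion of necrosis/DCIS/mucin/artifact areas.
    Returns ``(labels, compositions)``: an (n, n) object array of labels and
    the matching dict of CellComposition keyed by (row, col).
    """
    config = config or ImagingConfig()
    stains = separate_stains_hed(image, config)
    n = grid.n_per_side
    labels = np.empty((n, n), dtype=object)
    comps = {}
    exclusion = exclusion or set()
    for r in range(n):
        for c in range(n):
            comp = compose_cell(image, stains, grid, r, c, config)
            comps[(r, c)] = comp
            labels[r, c] = LABEL_NA if (r, c) in exclusion else classify_cell(comp, mode, config)
    return labels, comps


def counts_from_labels(labels: np.ndarray) -> FieldCounts:
    """Tally a label matrix into FieldCounts.

    L cells are stroma-predominant by definition, so they count toward n_S
    as well as n_L.
    """
    labels = np.asarray(labels, dtype=object)
    flat = [str(v) for v in labels.ravel()]
    bad = sorted(set(flat) - {LABEL_T, LABEL_S, LABEL_L, LABEL_NA})
    if bad:
        raise InvalidParameterError(f"unknown cell labels: {bad}")
    n_t = flat.count(LABEL_T)
    n_l = flat.count(LABEL_L)
    n_s = flat.count(LABEL_S) + n_l
    n_na = flat.count(LABEL_NA)
    return FieldCounts(n_T=n_t, n_S=n_s, n_L=n_l, n_NA=n_na)
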