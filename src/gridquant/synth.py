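"""Seeded synthetic H&E-like circular-field images with full ground truth.

The generator emulates a mobile-camera-through-eyepiece microphotograph: a
bright circular field of view on a dark surround, with the inscribed grid's
cells painted according to a ground-truth label matrix —

* T cells: one dense basophilic (hematoxylin) nuclear cluster covering the
  dominant fraction of the cell;
* S cells: eosinophilic fibrous texture with a few sparse small nuclei;
* L cells: stroma plus k small round dark lymphocyte nuclei (k >= 5 by
  default, so the count rule fires);
* NA cells: left near-white (empty space).

Cells are painted in stain optical-density space and converted to RGB with
the same standard H&E unmixing matrix the imaging module inverts, so the
imaging defaults are exercised honestly.  Lymphocyte disks are drawn at
diameters inside the detector's default band and tumor clusters well above
it; changing the detector band will make the round-trip tests fail loudly.

All sampling goes through one numpy Generator seeded from the field spec's
``seed``; equal
seeds give byte-identical images.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from skimage.color import hed2rgb

from . import quantify
from .errors import InvalidParameterError
from .geometry import CircularFOV, GridGeometry, inscribe_square_grid
from .imaging import LABEL_L, LABEL_NA, LABEL_S, LABEL_T, counts_from_labels
from .quantify import FieldCounts

#: painted stain optical densities
_TUMOR_H = 0.85
_STROMA_E = 0.55
_NUCLEUS_H = 0.9
_LYMPH_RADIUS = 2.6  # px -> blob diameter ~5.2, inside the detector band (3, 14)


@dataclass(frozen=True)
class SyntheticFieldSpec:
    """Recipe for one synthetic field.

    Provide either a full (n x n) ``labels`` matrix or target ``counts``
    (placed at seeded random positions).  ``dominant_fraction`` is the area
    share of a cell its dominant class is painted over (the rest stays
    background), ``lymph_per_l_cell`` the number of lymphocyte nuclei drawn
    in each L cell, ``noise_sd`` the Gaussian pixel noise on the 0-1 RGB
    scale.
    """

    image_size: int = 384
    vignette_diameter: float = 352.0
    n_per_side: int = 10
    labels: tuple | None = None
    counts: FieldCounts | None = None
    lymph_per_l_cell: int = 8
    stroma_nuclei_per_cell: int = 2
    dominant_fraction: float = 0.9
    noise_sd: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.vignette_diameter > self.image_size:
            raise InvalidParameterError("vignette diameter exceeds the image size")
        if self.labels is None and self.counts is None:
            raise InvalidParameterError("provide labels or counts")
        if not 0 < self.dominant_fraction <= 1:
            raise InvalidParameterError("dominant_fraction must be in (0, 1]")
        if self.lymph_per_l_cell < 1:
            raise InvalidParameterError("lymph_per_l_cell must be >= 1")
        if self.labels is not None:
            arr = np.asarray(self.labels, dtype=object)
            n = self.n_per_side
            if arr.shape != (n, n):
                raise InvalidParameterError(f"labels shape {arr.shape} != ({n}, {n})")
        if self.counts is not None and self.counts.n_total != self.n_per_side**2:
            raise InvalidParameterError(
                f"counts sum to {self.counts.n_total}, grid has {self.n_per_side ** 2} cells"
            )


def labels_from_counts(counts: FieldCounts, n_per_side: int, rng: np.random.Generator) -> np.ndarray:
    """Place target counts at shuffled grid positions (n_S includes n_L)."""
    if counts.n_total != n_per_side**2:
        raise InvalidParameterError("counts do not sum to the number of grid cells")
    flat = (
        [LABEL_T] * counts.n_T
        + [LABEL_L] * counts.n_L
        + [LABEL_S] * (counts.n_S - counts.n_L)
        + [LABEL_NA] * counts.n_NA
    )
    flat = np.asarray(flat, dtype=object)
    rng.shuffle(flat)
    return flat.reshape(n_per_side, n_per_side)


def _disk(hch: np.ndarray, cy: float, cx: float, radius: float, density: float) -> None:
    r0 = max(int(cy - radius - 1), 0)
    r1 = min(int(cy + radius + 2), hch.shape[0])
    c0 = max(int(cx - radius - 1), 0)
    c1 = min(int(cx + radius + 2), hch.shape[1])
    yy, xx = np.mgrid[r0:r1, c0:c1]
    inside = (yy + 0.5 - cy) ** 2 + (xx + 0.5 - cx) ** 2 <= radius**2
    patch = hch[r0:r1, c0:c1]
    patch[inside] = np.maximum(patch[inside], density)


def _paint_cell(
    hch: np.ndarray,
    ech: np.ndarray,
    grid: GridGeometry,
    row: int,
    col: int,
    label: str,
    spec: SyntheticFieldSpec,
    rng: np.random.Generator,
) -> None:
    rs, cs = grid.cell_slices(row, col)
    height = rs.stop - rs.start
    width = cs.stop - cs.start
    if label == LABEL_NA:
        return  # near-white empty space
    # dominant-class subregion: centered, covering dominant_fraction of area
    side = np.sqrt(spec.dominant_fraction)
    mh = int(round(height * (1 - side) / 2))
    mw = int(round(width * (1 - side) / 2))
    sub_r = slice(rs.start + mh, rs.stop - mh)
    sub_c = slice(cs.start + mw, cs.stop - mw)
    sub_h = sub_r.stop - sub_r.start
    sub_w = sub_c.stop - sub_c.start
    if label == LABEL_T:
        # one solid nuclear cluster with mild chromatin texture
        tex = rng.normal(0.0, 0.04, size=(sub_h, sub_w))
        hch[sub_r, sub_c] = np.maximum(hch[sub_r, sub_c], _TUMOR_H + tex)
        ech[sub_r, sub_c] = np.maximum(ech[sub_r, sub_c], 0.08)
        return
    # S and L: eosinophilic fibrous background
    fiber = rng.normal(0.0, 0.05, size=(sub_h, sub_w))
    ech[sub_r, sub_c] = np.maximum(ech[sub_r, sub_c], _STROMA_E + fiber)
    n_nuclei = spec.lymph_per_l_cell if label == LABEL_L else spec.stroma_nuclei_per_cell
    if n_nuclei == 0:
        return
    # jittered lattice keeps nuclei separated so blobs never merge
    k = int(np.ceil(np.sqrt(n_nuclei)))
    pitch_r = sub_h / k
    pitch_c = sub_w / k
    slots = [(i, j) for i in range(k) for j in range(k)]
    rng.shuffle(slots)
    for i, j in slots[:n_nuclei]:
        cy = sub_r.start + (i + 0.5) * pitch_r + rng.uniform(-0.5, 0.5)
        cx = sub_c.start + (j + 0.5) * pitch_c + rng.uniform(-0.5, 0.5)
        _disk(hch, cy, cx, _LYMPH_RADIUS, _NUCLEUS_H)


def generate_field(spec: SyntheticFieldSpec):
    """Render one synthetic field.

    Returns ``(image, labels, grid)``: an (size, size, 3) uint8 RGB image,
    the (n, n) ground-truth label matrix, and the grid geometry used.
    """
    rng = np.random.default_rng(spec.seed)
    size = spec.image_size
    fov = CircularFOV(size / 2.0, size / 2.0, float(spec.vignette_diameter))
    grid = inscribe_square_grid(fov, spec.n_per_side)
    if spec.labels is not None:
        labels = np.asarray(spec.labels, dtype=object)
    else:
        labels = labels_from_counts(spec.counts, spec.n_per_side, rng)

    hch = np.zeros((size, size))
    ech = np.zeros((size, size))
    for r in range(spec.n_per_side):
        for c in range(spec.n_per_side):
            _paint_cell(hch, ech, grid, r, c, str(labels[r, c]), spec, rng)

    hed = np.stack([np.clip(hch, 0, None), np.clip(ech, 0, None), np.zeros_like(hch)], axis=-1)
    rgb = hed2rgb(hed)

    yy, xx = np.mgrid[0:size, 0:size]
    outside = (yy + 0.5 - fov.center_y) ** 2 + (xx + 0.5 - fov.center_x) ** 2 > fov.radius**2
    rgb[outside] = 0.06  # dark surround

    rgb = rgb + rng.normal(0.0, spec.noise_sd, size=rgb.shape)
    image = (np.clip(rgb, 0.0, 1.0) * 255).round().astype(np.uint8)
    return image, labels, grid


@dataclass(frozen=True)
class SyntheticCaseBundle:
    """A case's fields plus ground truth and expected quantification."""

    parameter: str
    images: tuple
    labels: tuple
    grid: GridGeometry
    counts: tuple  # FieldCounts per field
    expected: quantify.CaseReport  # from ground-truth counts via the formulas


def generate_case(
    parameter: str,
    target_percent: float | None = None,
    field_counts: list | None = None,
    n_fields: int = 10,
    seed: int = 0,
    **field_kwargs,
) -> SyntheticCaseBundle:
    """Generate a case of ``n_fields`` fields with known expected score.

    Either pass explicit per-field ``field_counts`` or a case-level
    ``target_percent``; with a target, every field gets the same counts:
    for TSR, n_S = round(target) of 100; for sTIL, an all-stroma field with
    n_L = round(target) of 100.  Expected percentages and score are computed
    from the ground-truth counts by the quantification formulas, never
    assumed.
    """
    if parameter not in quantify.MODES:
        raise InvalidParameterError(f"parameter must be one of {quantify.MODES}")
    if n_fields < 1:
        raise InvalidParameterError("n_fields must be >= 1")
    if (target_percent is None) == (field_counts is None):
        raise InvalidParameterError("provide exactly one of target_percent or field_counts")
    n = int(field_kwargs.get("n_per_side", 10))
    total = n * n
    if field_counts is None:
        t = int(round(target_percent / 100.0 * total))
        if parameter == quantify.MODE_TSR:
            counts = FieldCounts(n_T=total - t, n_S=t, n_L=0, n_NA=0)
        else:
            counts = FieldCounts(n_T=0, n_S=total, n_L=t, n_NA=0)
        field_counts = [counts] * n_fields
    elif len(field_counts) != n_fields:
        raise InvalidParameterError("field_counts length must equal n_fields")

    images, labels_list = [], []
    grid = None
    for i, counts in enumerate(field_counts):
        spec = SyntheticFieldSpec(counts=counts, seed=seed * 10_000 + i, **field_kwargs)
        image, labels, grid = generate_field(spec)
        images.append(image)
        labels_list.append(labels)
    for lab, counts in zip(labels_list, field_counts):
        assert counts_from_labels(lab) == counts  # ground truth consistent
    expected = quantify.aggregate_case(list(field_counts), parameter)
    return SyntheticCaseBundle(
        parameter=parameter,
        images=tuple(images),
        labels=tuple(labels_list),
        grid=grid,
        counts=tuple(field_counts),
        expected=expected,
    )


def generate_observer_scores(
    n_cases: int,
    category_dist: dict,
    agreement_prob: float,
    seed: int = 0,
):
    """Simulate two raters for the agreement module.

    Rater A draws each case's score from ``category_dist`` (category ->
    probability); rater B copies A with probability ``agreement_prob`` and
    otherwise re-draws uniformly from the other categories.  Returns a
    :class:`gridquant.agreement.RatingPair`.
    """
    from .agreement import RatingPair

    if not 0.0 <= agreement_prob <= 1.0:
        raise InvalidParameterError("agreement_prob must be in [0, 1]")
    if n_cases < 2:
        raise InvalidParameterError("need at least 2 cases")
    cats = tuple(category_dist)
    probs = np.asarray([category_dist[c] for c in cats], dtype=float)
    if probs.min() < 0 or not np.isclose(probs.sum(), 1.0):
        raise InvalidParameterError("category_dist probabilities must be >= 0 and sum to 1")
    if len(cats) < 2:
        raise InvalidParameterError("need at least 2 categories")
    rng = np.random.default_rng(seed)
    a_idx = rng.choice(len(cats), size=n_cases, p=probs)
    b_idx = a_idx.copy()
    resample = rng.random(n_cases) >= agreement_prob
    for i in np.nonzero(resample)[0]:
        others = [j for j in range(len(cats)) if j != a_idx[i]]
        b_idx[i] = rng.choice(others)
    return RatingPair(
        ratings_a=tuple(cats[i] for i in a_idx),
        ratings_b=tuple(cats[i] for i in b_idx),
        categories=cats,
    )


def expected_observer_kappa(category_dist: dict, agreement_prob: float) -> float:
    """Closed-form kappa of the observer-score sampling scheme.

    p_o = agreement_prob (a re-draw never matches A);
    marginal_b(k) = p*q_k + (1-p)(1-q_k)/(K-1);  p_e = sum_k q_k m_b(k).
    """
    cats = tuple(category_dist)
    q = np.asarray([category_dist[c] for c in cats], dtype=float)
    p = agreement_prob
    k = len(cats)
    m_b = p * q + (1 - p) * (1 - q) / (k - 1)
    p_e = float(q @ m_b)
    if p_e == 1.0:
        return 1.0
    return (p - p_e) / (1 - p_e)
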