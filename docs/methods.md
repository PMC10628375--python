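# Methods

## Grid geometry

A microphotograph taken through an eyepiece shows a bright circular field of
view (FOV) on a dark surround. The inscribed square has side *a = d/√2*,
where *d* is the FOV diameter; its four corners lie exactly on the circle.
The square is divided into an *n × n* lattice (default *n* = 10) of
congruent cells, each 1/*n*² of the square's area — for *n* = 10, each small
square is exactly 1 % of the grid. Full precision is carried internally;
rounding happens only at display (the quantity 16.6/√2 = 11.738 may be shown
as 11.74, 11.73 or 11.7 depending on the precision requested).

Coordinates are pixels, origin top-left, x right, y down. Cells are
half-open rectangles [x0, x1) × [y0, y1), indexed (row, col) 0-based
row-major; a pixel belongs to a cell iff its center does. This makes the
cells an exact partition of the inscribed square's pixel set — no pixel is
counted twice across a shared edge, which matters because the per-cell
fractions feed a strict > 50 % rule.

FOV detection thresholds the luminance with Otsu's method, keeps the largest
connected bright component, and fits a circle to its boundary contour by the
algebraic (Kasa) least-squares fit. Eyepiece vignettes are near-binary, so
this is accurate to fractions of a pixel on clean images; a Hough transform
would add cost without benefit here. A manual override (center, diameter)
bypasses detection, and a no-vignette flag treats the largest centered
inscribed circle of a full-frame scan as the FOV, extending the method to
digital slides without changing the math. Detection fails loudly when the
bright region covers less than `min_fraction` (default 5 %) of the image.
The grid is axis-aligned; rotation and perspective correction are out of
scope.

## Pixel classification

Stain separation uses optical-density color deconvolution with the standard
published hematoxylin/eosin(/DAB) unmixing matrix (config-overridable,
because mobile-camera white balance varies). Pixels with luminance above
`white_threshold` (default 0.85) are background. Within each cell, the
hematoxylin-dense mask (`nuclear_density` > 0.25 OD) is split into connected
blobs: blobs whose equivalent diameter falls in `lymph_diameter_band`
(default 3–14 px) with circularity 4πA/P² ≥ 0.4 are lymphocyte nuclei;
larger blobs are tumor nuclear clusters; sub-band specks (stray stromal
nuclei fragments) are neither. Everything that is neither background nor
tumor counts as stroma, so lymphocyte pixels contribute to the stromal
fraction and the lymphocyte fraction is reported as a sub-fraction —
sTIL is a property of the stromal compartment.

Labeling rules, applied in order with predominance threshold strictly
> 0.5 (exact 50/50 ties satisfy nothing and fall to NA):

1. NA if background-predominant, or if no class is predominant;
2. T if tumor-predominant;
3. in sTIL mode, a stroma-predominant cell is L when it is
   majority-lymphocyte **or** holds ≥ 5 lymphocytes (the "and/or" in the
   counting rule is implemented as OR — the sensitive reading; a strict AND
   is available via `l_rule`);
4. otherwise S. In TSR mode, L is never emitted.

A lymphocyte-rich but tumor-predominant cell is T: sTIL is evaluated only in
the tumor stroma, not within tumor islands. Plasma cells are not
distinguished from lymphocytes (mononuclear cells are counted together).
Exclusion regions (necrosis, DCIS, mucin, crush artifact, tertiary lymphoid
structures) are **not** auto-detected; a per-cell exclusion mask (CSV of
row, col) forces NA, mirroring the manual exclusions of the protocol. There
is no ground-truth pixel definition of "predominantly displaying"; the
thresholds above are engineering defaults and are echoed into every report
for auditability.

## Quantification and scoring

Per field, TSR = 100·n_S/(n_T+n_S) and sTIL = 100·n_L/n_S, with n_S counting
all stroma-predominant squares including the L ones (forced by the method's
no-tumor worked example: 50 lymphocytic of 100 stromal squares gives 50 %,
so the denominator includes them). A zero denominator makes the field's
value undefined; undefined fields are skipped (with a warning), not treated
as zero. The case value is the mean of the defined per-field percentages —
percentages are averaged first and the case is scored once, not per-field
scores averaged. Rounding is half-up (67.76 → 68; 49.5 → 50), not banker's.
The rounded percent is clamped into [1, 99] before scoring because 0 % and
100 % are never reported (some of the other compartment, or empty space
between lymphocytes, always exists); raw unclamped values are retained in
reports. Score tiers on the rounded integer percent are [0, 25] → 1,
[26, 50] → 2, [51, 75] → 3, [76, 100] → 4; the boundary between the upper
tiers is resolved lower-inclusive ([51, 75] / [76, 100]), and scores are
emitted 1–4.

## Agreement statistics

Unweighted Cohen's kappa on the two observers' case scores, with percent
agreement (100 × matches/n) alongside. The degenerate 0/0 case (both raters
constant and identical, p_e = 1) returns κ = 1 with a warning — constant
identical raters agree perfectly. Verbal bands: κ ≤ 0 no agreement,
(0, 0.20] none to slight (the printed scale's gap below 0.01 is folded into
this band), (0.20, 0.40] fair, (0.40, 0.60] moderate, (0.60, 0.80]
substantial, (0.80, 1.0] almost perfect. Linear- and quadratic-weighted
kappa and a large-sample normal-approximation standard error are available
as optional extras; no significance test is offered.

## Synthetic data generator

The generator emulates the study material — bright circular FOV on a dark
surround, cells painted per a ground-truth label matrix: T cells as one
dense basophilic nuclear cluster covering `dominant_fraction` (default 0.9)
of the cell, S cells as eosinophilic texture with 2 sparse small nuclei,
L cells as stroma plus `lymph_per_l_cell` (default 8) round lymphocyte
nuclei on a jittered lattice, NA cells near-white. Painting happens in stain
optical-density space and is converted to RGB through the same H&E matrix
the imaging module inverts, so the defaults are exercised honestly rather
than tuned per test; lymphocyte disks are drawn at diameter ≈ 5 px (inside
the detector band) and tumor clusters far above it, so changing the band
breaks the round-trip tests loudly. Gaussian pixel noise (default SD 0.01 on
the 0–1 scale) is added last. All randomness flows through one seeded numpy
Generator; equal seeds give byte-identical images.

Default study conditions: 384 px images with a 352 px vignette, 10 × 10
grid, 10 fields per case — a desk-scale stand-in for the 13 MP phone
photographs of the protocol that keeps a full 20-case end-to-end check
under a minute while leaving ~25 px per grid cell, enough for several
well-separated nuclei. What the generator does **not** emulate: real
chromatin texture, stain variability and white-balance drift, overlapping
or touching nuclei, necrosis/mucin/DCIS appearance, focus and illumination
gradients. Passing the synthetic round-trip therefore shows the geometry,
counting and scoring arithmetic are correct and the pixel classifiers are
self-consistent at realistic scales — not that the default thresholds are
clinically tuned; on real material the thresholds (and ideally the stain
matrix) should be calibrated per dataset, or counts entered manually.

Observer-score simulation: rater A draws from a category distribution,
rater B copies A with probability p and otherwise re-draws uniformly from
the other categories, giving closed-form p_o = p and
p_e = Σ_k q_k (p q_k + (1 − p)(1 − q_k)/(K − 1)) against which kappa
recovery is tested.

## Numerical notes and limitations

* The quantification formulas are exact rational arithmetic in floating
  point; only display rounding is lossy.
* Circle fitting is the algebraic least-squares fit; on synthetic disks it
  recovers centers to < 0.1 px and diameters to < 0.1 %. Strongly
  non-circular vignettes violate its assumptions and should use the manual
  override.
* Per-cell blob analysis runs independently per cell: a nuclear cluster
  clipped by a cell edge is judged by its within-cell size. At the default
  cell size (~25 px) a clipped tumor cluster still exceeds the lymphocyte
  band; at much smaller cell sizes it might not.
* Field order in image mode is the lexicographic filename sort; a case is a
  directory of field images.
* Whole-slide pyramidal formats, stitching, mitosis counting and IHC
  quantification are out of scope; the four-tier score plus raw percentages
  are reported, with no prognostic two-tier cutoff analysis.
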