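# gridquant

Square-grid point-counting morphometry for **tumor-stroma ratio (TSR)** and
**stromal tumor-infiltrating lymphocyte (sTIL)** scoring on circular-field
H&E microphotographs of invasive breast carcinoma, with inter-observer
agreement statistics and a fully seeded synthetic-image generator.

Pathologists increasingly report TSR and sTIL as prognostic parameters, but
eyeball estimation is subjective. A cheap, reproducible alternative is to
photograph each microscopic field (for example with a phone through the
eyepiece), inscribe a 10 × 10 square grid in the circular field of view, and
count squares. This package automates that workflow end to end: it detects
the circular field, constructs the grid, classifies every small square from
the pixels, applies the counting formulas, and scores the case — or accepts
manually counted tables and does only the arithmetic.

## The method

The largest square inscribable in a circle of diameter *d* has side

&nbsp;&nbsp;&nbsp;&nbsp;*a = d / √2*

(the square's diagonal is a diameter — Pythagoras). That square is divided
into 10 × 10 equal cells, so each small square is exactly 1 % of the grid.
Each cell is labeled by predominance (> 50 % of its area):

* **T** — tumor-predominant,
* **S** — stroma-predominant (includes **L**),
* **L** — lymphocyte-predominant stroma: > 50 % lymphocyte occupancy
  and/or ≥ 5 lymphocytes in the square (sTIL mode only),
* **NA** — inconclusive, empty, necrotic, or excluded.

Per field:

&nbsp;&nbsp;&nbsp;&nbsp;TSR (%) = 100 · n_S / (n_T + n_S) &nbsp;&nbsp;&nbsp;
sTIL (%) = 100 · n_L / n_S

NA squares never enter a denominator; for sTIL, tumor squares are excluded
entirely. A case is the average over its (typically ten) fields, rounded
half-up to a whole percent, clamped into [1, 99] (0 % and 100 % are never
reported), and binned into a four-tier score: [0, 25] → 1, [26, 50] → 2,
[51, 75] → 3, [76, 100] → 4. Agreement between two observers' case scores
is summarised by percent agreement and unweighted Cohen's kappa,
κ = (p_o − p_e)/(1 − p_e), with Cohen's verbal bands.

## Worked example

Generate a synthetic 10-field case with a known ground-truth TSR of 72 %,
then quantify it from the images alone:

```sh
$ gridquant synth --case --target-tsr 72 --seed 7 -o demo/fields
wrote 10 field(s) to demo/fields; expected tsr score 3 (72.00%)

$ gridquant quantify --mode tsr --images demo/fields -o demo/report.json
fields: tsr mean=72.00% reportable=72% score=3
```

For each of the ten PNGs the pipeline detected the circular field of view,
inscribed the *a = d/√2* grid, color-deconvolved the image into hematoxylin
and eosin densities, labeled all 100 squares, and tallied the counts. The
case mean of 72.00 % rounds to a reportable TSR of 72 % — a stroma-rich
tumor — in tier score 3 (51–75 %), matching the generator's ground truth
exactly. `demo/report.json` holds the per-field percentages, the counts and
the effective configuration.

The same arithmetic runs on manual count tables
(`gridquant quantify --mode stil --counts counts.csv -o report.json`), and
`gridquant agreement scores.csv` reports kappa, e.g.

```
kappa=0.3333 (fair), agreement=66.67% over 30 cases
```

## Library use

```python
from gridquant import FieldCounts, compute_stil, aggregate_case

field = FieldCounts(n_T=25, n_S=75, n_L=50)   # 50 of 75 stromal squares lymphocytic
compute_stil(field)                            # 66.666...
aggregate_case([field] * 10, "stil").score     # 3
```

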