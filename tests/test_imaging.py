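"""Stain separation, lymphocyte detection, cell composition, and the
predominance labeling rules."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from gridquant import (
    CellComposition,
    FieldCounts,
    ImagingConfig,
    classify_cell,
    compose_cell,
    counts_from_labels,
    detect_lymphocytes,
    label_field,
    separate_stains_hed,
)
from gridquant.errors import InvalidParameterError, ShapeMismatchError
from gridquant.synth import _LYMPH_RADIUS, SyntheticFieldSpec, _disk, generate_field

from conftest import hed_image


class TestSeparateStains:
    def test_pure_white_is_all_background_no_stain(self):
        img = np.full((32, 32, 3), 255, dtype=np.uint8)
        stains = separate_stains_hed(img)
        assert stains.background_mask.all()
        assert stains.hematoxylin_density.max() < 0.02
        assert stains.eosin_density.max() < 0.02

    def test_hematoxylin_disk_dominates_eosin(self):
        h = np.zeros((64, 64))
        e = np.zeros((64, 64))
        _disk(h, 32, 32, 10, 0.8)
        stains = separate_stains_hed(hed_image(h, e))
        inside = h > 0
        assert stains.hematoxylin_density[inside].mean() > 5 * max(
            stains.eosin_density[inside].mean(), 1e-6
        )
        assert not stains.background_mask[inside].any()

    def test_deterministic(self):
        rng = np.random.default_rng(0)
        img = rng.integers(0, 256, size=(48, 48, 3), dtype=np.uint8)
        a = separate_stains_hed(img)
        b = separate_stains_hed(img.copy())
        assert np.array_equal(a.hematoxylin_density, b.hematoxylin_density)
        assert np.array_equal(a.background_mask, b.background_mask)

    def test_non_rgb_rejected(self):
        with pytest.raises(ShapeMismatchError):
            separate_stains_hed(np.zeros((32, 32), dtype=np.uint8))


class TestDetectLymphocytes:
    def paint(self, centers, radius=_LYMPH_RADIUS, big_blob=None):
        h = np.zeros((64, 64))
        e = np.full((64, 64), 0.5)
        for cy, cx in centers:
            _disk(h, cy, cx, radius, 0.9)
        if big_blob is not None:
            cy, cx, r = big_blob
            _disk(h, cy, cx, r, 0.9)
        return separate_stains_hed(hed_image(h, e))

    def test_five_disks_counted_exactly(self):
        stains = self.paint([(10, 10), (10, 30), (30, 10), (30, 30), (50, 50)])
        count, centroids = detect_lymphocytes(stains)
        assert count == 5
        assert len(centroids) == 5

    def test_blank_background_cell_counts_zero(self):
        img = np.full((64, 64, 3), 255, dtype=np.uint8)
        count, centroids = detect_lymphocytes(separate_stains_hed(img))
        assert count == 0 and centroids == []

    def test_large_tumor_blob_excluded_by_size(self):
        stains = self.paint([(10, 10), (10, 52), (52, 10)], big_blob=(40, 40, 12))
        count, _ = detect_lymphocytes(stains)
        assert count == 3

    def test_region_restriction_and_offsets(self):
        stains = self.paint([(10, 10), (50, 50)])
        count, centroids = detect_lymphocytes(stains, region=(slice(0, 32), slice(0, 32)))
        assert count == 1
        (r, c), = centroids
        assert abs(r - 10) < 2 and abs(c - 10) < 2

    def test_empty_region_counts_zero(self):
        stains = self.paint([(10, 10)])
        count, centroids = detect_lymphocytes(stains, region=(slice(5, 5), slice(0, 10)))
        assert count == 0 and centroids == []


class TestComposeCell:
    def test_tumor_nest_cell(self, single_cell_grid):
        h = np.full((64, 64), 0.85)  # nest extends past the cell on all sides
        img = hed_image(h, np.zeros_like(h))
        comp = compose_cell(img, separate_stains_hed(img), single_cell_grid, 0, 0)
        assert comp.tumor_fraction >= 0.9

    def test_background_cell(self, single_cell_grid):
        img = np.full((64, 64, 3), 255, dtype=np.uint8)
        comp = compose_cell(img, separate_stains_hed(img), single_cell_grid, 0, 0)
        assert comp.background_fraction == pytest.approx(1.0, abs=1e-6)
        assert comp.lymphocyte_count == 0

    def test_half_tumor_half_stroma(self, single_cell_grid):
        h = np.zeros((64, 64))
        e = np.zeros((64, 64))
        h[:, :32] = 0.85
        e[:, 32:] = 0.55
        img = hed_image(h, e)
        comp = compose_cell(img, separate_stains_hed(img), single_cell_grid, 0, 0)
        assert abs(comp.tumor_fraction - 0.5) <= 0.1
        assert abs(comp.stroma_fraction - 0.5) <= 0.1

    def test_invalid_cell_index_raises(self, single_cell_grid):
        img = np.full((64, 64, 3), 255, dtype=np.uint8)
        with pytest.raises(IndexError):
            compose_cell(img, separate_stains_hed(img), single_cell_grid, 1, 0)

    def test_fractions_sum_to_at_most_one(self, clear_cut_field):
        image, _, grid = clear_cut_field
        stains = separate_stains_hed(image)
        for r in range(0, 10, 3):
            for c in range(0, 10, 3):
                comp = compose_cell(image, stains, grid, r, c)
                total = comp.tumor_fraction + comp.stroma_fraction + comp.background_fraction
                assert total <= 1.0 + 1e-6
                assert comp.lymphocyte_fraction <= comp.stroma_fraction + 1e-6


class TestClassifyCell:
    @pytest.mark.parametrize(
        "comp, mode, expected",
        [
            (CellComposition(0.8, 0.15, 0.0, 0.05, 0), "tsr", "T"),
            (CellComposition(0.1, 0.7, 0.1, 0.2, 5), "stil", "L"),
            (CellComposition(0.1, 0.3, 0.0, 0.6, 0), "tsr", "NA"),
            (CellComposition(0.1, 0.7, 0.1, 0.2, 4), "stil", "S"),
            (CellComposition(0.1, 0.6, 0.55, 0.3, 3), "stil", "L"),  # majority-lymphocyte
            (CellComposition(0.6, 0.2, 0.1, 0.2, 9), "stil", "T"),  # sTIL lives in stroma
            (CellComposition(0.5, 0.5, 0.0, 0.0, 0), "tsr", "NA"),  # exact tie
            (CellComposition(0.2, 0.75, 0.0, 0.05, 0), "tsr", "S"),
        ],
    )
    def test_decision_rules(self, comp, mode, expected):
        assert classify_cell(comp, mode) == expected

    def test_l_never_emitted_in_tsr_mode(self):
        comp = CellComposition(0.05, 0.9, 0.8, 0.05, 20)
        assert classify_cell(comp, "tsr") == "S"

    def test_and_rule_configurable(self):
        comp = CellComposition(0.1, 0.7, 0.1, 0.2, 8)  # count hits, fraction misses
        assert classify_cell(comp, "stil", ImagingConfig(l_rule="and")) == "S"
        assert classify_cell(comp, "stil", ImagingConfig(l_rule="or")) == "L"

    def test_invalid_mode_rejected(self):
        with pytest.raises(InvalidParameterError):
            classify_cell(CellComposition(1.0, 0.0, 0.0, 0.0, 0), "both")

    @given(
        st.floats(0.51, 1.0),
        st.floats(0.0, 1.0),
        st.floats(0.0, 1.0),
    )
    def test_tumor_predominance_monotone(self, t0, split, bump):
        """Once tumor-predominant, increasing the tumor share (others
        rescaled down) never flips T to S."""
        rest = 1.0 - t0
        comp0 = CellComposition(t0, rest * split, 0.0, rest * (1 - split), 0)
        assert classify_cell(comp0, "tsr") == "T"
        t1 = t0 + (1.0 - t0) * bump
        scale = (1.0 - t1) / rest if rest > 0 else 0.0
        comp1 = CellComposition(t1, rest * split * scale, 0.0, rest * (1 - split) * scale, 0)
        assert classify_cell(comp1, "tsr") == "T"


class TestFieldLabeling:
    def test_label_accuracy_on_clear_cut_cells(self):
        """>= 95% per-cell agreement with ground truth over >= 500 clear-cut
        cells (dominant fraction 0.9, lymphocyte counts away from the
        threshold) at fixed seeds."""
        total = correct = 0
        for seed in range(5):  # 5 fields x 100 cells
            spec = SyntheticFieldSpec(
                counts=FieldCounts(n_T=30, n_S=55, n_L=25, n_NA=15), seed=seed
            )
            image, truth, grid = generate_field(spec)
            pred, _ = label_field(image, grid, "stil")
            total += truth.size
            correct += int((pred == truth).sum())
        assert total >= 500
        assert correct / total >= 0.95

    def test_determinism(self, clear_cut_field):
        image, _, grid = clear_cut_field
        a, _ = label_field(image, grid, "stil")
        b, _ = label_field(image.copy(), grid, "stil")
        assert np.array_equal(a, b)

    def test_tsr_mode_never_labels_l(self, clear_cut_field):
        image, _, grid = clear_cut_field
        labels, _ = label_field(image, grid, "tsr")
        assert "L" not in set(labels.ravel())

    def test_exclusion_mask_forces_na(self, clear_cut_field):
        image, _, grid = clear_cut_field
        excl = {(0, 0), (5, 5), (9, 9)}
        labels, _ = label_field(image, grid, "stil", exclusion=excl)
        assert all(labels[r, c] == "NA" for r, c in excl)


class TestCountsFromLabels:
    def test_l_cells_count_as_stroma(self):
        labels = np.array(
            [["T", "S"], ["L", "NA"]], dtype=object
        )
        counts = counts_from_labels(labels)
        assert (counts.n_T, counts.n_S, counts.n_L, counts.n_NA) == (1, 2, 1, 1)
        assert counts.n_total == 4

    def test_unknown_label_rejected(self):
        with pytest.raises(InvalidParameterError):
            counts_from_labels(np.array([["T", "X"]], dtype=object))
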