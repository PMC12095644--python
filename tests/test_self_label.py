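"""Local entropy, threshold self-tuning, and pixel labeling."""

import numpy as np
import pytest

from flowseg.exceptions import ContractError, LabelingError, SelfTuningError
from flowseg.io import IntensityImage
from flowseg.self_label import (
    BACKGROUND,
    CELL,
    UNLABELED,
    aggregate_magnitude,
    label_pixels,
    local_entropy,
    self_label,
    tune_thresholds,
)


class TestLocalEntropy:
    def test_constant_image_has_zero_entropy(self):
        img = IntensityImage(np.full((64, 64), 0.5))
        assert local_entropy(img, 4).max() == 0.0

    def test_checkerboard_approaches_one_bit(self):
        rows, cols = np.indices((64, 64))
        board = ((rows + cols) % 2).astype(float)
        ent = local_entropy(IntensityImage(board), 4)
        interior = ent[10:-10, 10:-10]
        # two symbols in near-equal proportion inside every window
        assert abs(interior.mean() - 1.0) < 0.01
        assert interior.max() <= 1.0 + 1e-9

    def test_cells_more_entropic_than_background(self, fixture_default):
        ent = local_entropy(fixture_default.image, 4)
        mask = fixture_default.truth_mask
        assert ent[mask].mean() > ent[~mask].mean() + 0.5

    def test_invalid_window_rejected(self):
        with pytest.raises(ContractError):
            local_entropy(IntensityImage(np.zeros((64, 64))), 0)


class TestTuneThresholds:
    def test_selected_pair_is_grid_argmax(self, rng):
        # independent re-evaluation of every candidate: percentile cuts,
        # provisional labels, class-mean entropy difference
        mag = rng.gamma(2.0, 1.0, (80, 80))
        ent = 2.0 * (mag / mag.max()) + rng.normal(0, 0.05, mag.shape)
        upper, lower = (80.0, 85.0, 90.0, 95.0), (20.0, 30.0, 40.0, 50.0)
        t_cell, t_bg, report = tune_thresholds(mag, ent, upper, lower)

        best_obj, best_pair = -np.inf, None
        for up in upper:
            for lo in lower:
                tc, tb = np.percentile(mag, up), np.percentile(mag, lo)
                cell, bg = mag >= tc, mag <= tb
                if not cell.any() or not bg.any():
                    continue
                obj = ent[cell].mean() - ent[bg].mean()
                if obj > best_obj:
                    best_obj, best_pair = obj, (up, lo)

        sel = report.selected
        assert (sel.upper_percentile, sel.lower_percentile) == best_pair
        assert sel.objective == pytest.approx(best_obj, rel=1e-12)
        assert sel.objective == max(
            c.objective for c in report.candidates if not np.isnan(c.objective)
        )
        assert (t_cell, t_bg) == (sel.t_cell, sel.t_bg)
        # the report covers the full upper x lower grid
        assert len(report.candidates) == len(upper) * len(lower)

    def test_constant_magnitude_fails(self):
        with pytest.raises(SelfTuningError):
            tune_thresholds(np.ones((32, 32)), np.ones((32, 32)))

    def test_tie_break_prefers_inclusive_labels(self):
        # entropy identical everywhere -> all objectives equal (zero);
        # the smallest upper / largest lower percentile pair must win
        mag = np.linspace(0, 1, 900).reshape(30, 30)
        ent = np.ones((30, 30))
        _, _, report = tune_thresholds(mag, ent, (80.0, 90.0), (10.0, 20.0))
        assert report.selected.upper_percentile == 80.0
        assert report.selected.lower_percentile == 20.0

    def test_median_statistic_supported(self, rng):
        mag = rng.gamma(2.0, 1.0, (60, 60))
        ent = mag / mag.max()
        _, _, report = tune_thresholds(mag, ent, statistic="median")
        assert report.statistic == "median"

    def test_report_serializes_with_selection_mark(self, rng):
        mag = rng.gamma(2.0, 1.0, (60, 60))
        ent = mag / mag.max()
        _, _, report = tune_thresholds(mag, ent)
        text = report.to_text()
        assert text.count("*") == 1
        assert str(report.selected.upper_percentile.__trunc__()) in text


class TestLabelPixels:
    def test_toy_thresholds(self):
        mag = np.array([[0.0, 1.0], [2.0, 3.0]])
        out = label_pixels(mag, t_cell=2.5, t_bg=0.5)
        np.testing.assert_array_equal(
            out.labels, [[BACKGROUND, UNLABELED], [UNLABELED, CELL]]
        )
        assert out.n_cell == 1 and out.n_background == 1
        assert out.thresholds_used == (2.5, 0.5)

    def test_zero_width_band_labels_every_pixel(self, rng):
        mag = rng.random((40, 40))
        t = float(np.median(mag))
        out = label_pixels(mag, t, t)
        assert (out.labels != UNLABELED).all()

    def test_empty_class_raises(self):
        mag = np.linspace(0, 1, 100).reshape(10, 10)
        with pytest.raises(LabelingError):
            label_pixels(mag, 2.0, -1.0)  # nothing reaches t_cell

    def test_inverted_thresholds_rejected(self):
        with pytest.raises(ContractError):
            label_pixels(np.zeros((4, 4)), t_cell=0.1, t_bg=0.5)

    def test_monotonicity_in_thresholds(self, rng):
        mag = rng.random((50, 50))
        n_cell_prev, n_bg_prev = None, None
        for t_cell in (0.5, 0.6, 0.7, 0.8):
            out = label_pixels(mag, t_cell, 0.3)
            if n_cell_prev is not None:
                assert out.n_cell <= n_cell_prev  # raising t_cell shrinks CELL
            n_cell_prev = out.n_cell
        for t_bg in (0.4, 0.3, 0.2, 0.1):
            out = label_pixels(mag, 0.7, t_bg)
            if n_bg_prev is not None:
                assert out.n_background <= n_bg_prev  # lowering t_bg shrinks BG
            n_bg_prev = out.n_background


class TestSelfLabelStage:
    def test_labels_are_sparse_and_high_precision(self, fixture_default, default_config, fitted_default):
        labels = fitted_default.label_set
        total = fixture_default.image.pixels.size
        assert 0 < labels.n_cell + labels.n_background < total
        # self-labels are high-precision, low-recall by design
        truth = fixture_default.truth_mask
        assert truth[labels.cell_mask].mean() >= 0.9

    def test_cell_labels_more_entropic(self, fitted_default):
        ent = fitted_default.entropy_field
        labels = fitted_default.label_set
        assert ent[labels.cell_mask].mean() > ent[labels.background_mask].mean()

    def test_aggregation_preserves_zero_field(self):
        assert (aggregate_magnitude(np.zeros((32, 32)), 15) == 0).all()
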