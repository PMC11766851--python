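"""Overlap and distance metrics against brute-force set-arithmetic oracles."""

import numpy as np
import pytest
from scipy.spatial.distance import cdist

from ecatbrats.metrics import (DICE_EPS, MetricReport, aggregate, dice_loss,
                               dsc, hausdorff, iou)
from ecatbrats.nn import Parameter, Tensor

from helpers import gradcheck


@pytest.fixture
def rng():
    return np.random.default_rng(17)


def _random_pair(rng, p=0.3, shape=(8, 8, 8)):
    return rng.random(shape) < p, rng.random(shape) < p


class TestOverlapMetrics:
    def test_identical_nonempty_masks_score_one(self, rng):
        g, _ = _random_pair(rng)
        assert dsc(g, g) == 1.0
        assert iou(g, g) == 1.0

    def test_disjoint_nonempty_masks_score_zero(self):
        g = np.zeros((4, 4, 4), bool)
        p = np.zeros((4, 4, 4), bool)
        g[0, 0, 0] = True
        p[3, 3, 3] = True
        assert dsc(g, p) == 0.0
        assert iou(g, p) == 0.0

    def test_worked_examples(self):
        g = np.zeros((10,), bool)
        p = np.zeros((10,), bool)
        g[:4] = True          # |G| = 4
        p[1:7] = True         # |P| = 6, |G ∩ P| = 3
        assert dsc(g, p) == pytest.approx(2 * 3 / (4 + 6))  # 0.6
        assert iou(g, p) == pytest.approx(3 / 7)

    def test_both_empty_convention(self):
        e = np.zeros((3, 3, 3), bool)
        assert dsc(e, e) == 1.0
        assert iou(e, e) == 1.0

    def test_brute_force_oracle_on_random_volumes(self, rng):
        for _ in range(100):
            g, p = _random_pair(rng)
            gs = {tuple(v) for v in np.argwhere(g)}
            ps = {tuple(v) for v in np.argwhere(p)}
            inter, union = len(gs & ps), len(gs | ps)
            expected_dsc = 2 * inter / (len(gs) + len(ps)) if gs or ps else 1.0
            expected_iou = inter / union if union else 1.0
            assert dsc(g, p) == pytest.approx(expected_dsc, abs=1e-12)
            assert iou(g, p) == pytest.approx(expected_iou, abs=1e-12)

    def test_iou_dsc_identity(self, rng):
        for _ in range(50):
            g, p = _random_pair(rng)
            d = dsc(g, p)
            assert iou(g, p) == pytest.approx(d / (2 - d), abs=1e-12)

    def test_symmetry(self, rng):
        g, p = _random_pair(rng)
        assert dsc(g, p) == dsc(p, g)
        assert iou(g, p) == iou(p, g)

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            dsc(np.zeros((2, 2, 2), bool), np.zeros((3, 3, 3), bool))


class TestHausdorff:
    def test_identical_sets_distance_zero(self, rng):
        g, _ = _random_pair(rng, p=0.4)
        if not g.any():
            g[0, 0, 0] = True
        d, flagged = hausdorff(g, g)
        assert d == 0.0 and not flagged

    def test_three_four_five_triangle(self):
        g = np.zeros((5, 6, 2), bool)
        p = np.zeros((5, 6, 2), bool)
        g[0, 0, 0] = True
        p[3, 4, 0] = True
        d, _ = hausdorff(g, p)
        assert d == pytest.approx(5.0)

    def test_spacing_scales_distances(self):
        g = np.zeros((4, 4, 4), bool)
        p = np.zeros((4, 4, 4), bool)
        g[0, 0, 0] = True
        p[0, 0, 2] = True
        d, _ = hausdorff(g, p, spacing=(1.0, 1.0, 2.5))
        assert d == pytest.approx(5.0)

    def test_all_pairs_brute_force_oracle(self, rng):
        for _ in range(10):
            g, p = _random_pair(rng, p=0.15, shape=(6, 6, 6))
            if not (g.any() and p.any()):
                continue
            gp = np.argwhere(g).astype(float)
            pp = np.argwhere(p).astype(float)
            dmat = cdist(gp, pp)
            expected_dir = dmat.min(axis=1).max()
            expected_sym = max(expected_dir, dmat.min(axis=0).max())
            assert hausdorff(g, p, mode="directed")[0] == pytest.approx(expected_dir)
            assert hausdorff(g, p)[0] == pytest.approx(expected_sym)

    def test_directed_form_can_be_asymmetric(self):
        g = np.zeros((8, 1, 1), bool)
        p = np.zeros((8, 1, 1), bool)
        g[0] = True               # single point
        p[[0, 7]] = True          # contains g plus a far point
        assert hausdorff(g, p, mode="directed")[0] == 0.0
        assert hausdorff(p, g, mode="directed")[0] == pytest.approx(7.0)

    def test_percentile_95_bounds_the_maximum(self, rng):
        g, p = _random_pair(rng, p=0.2)
        if g.any() and p.any():
            assert (hausdorff(g, p, percentile=95)[0]
                    <= hausdorff(g, p, percentile=100)[0] + 1e-12)

    def test_empty_region_penalty_and_flag(self):
        g = np.zeros((4, 4, 4), bool)
        p = np.zeros((4, 4, 4), bool)
        p[0, 0, 0] = True
        d, flagged = hausdorff(g, p)
        assert flagged
        assert d == pytest.approx(np.sqrt(3 * 16))  # grid diagonal
        d2, _ = hausdorff(g, p, empty_penalty=42.0)
        assert d2 == 42.0


class TestDiceLoss:
    def test_perfect_prediction_near_zero(self, rng):
        t = (rng.random((3, 4, 4, 4)) < 0.4).astype(np.float64)
        loss = dice_loss(Tensor(t), t)
        assert float(loss.data) < 1e-5

    def test_inverted_prediction_near_one(self, rng):
        t = (rng.random((3, 4, 4, 4)) < 0.4).astype(np.float64)
        loss = dice_loss(Tensor(1.0 - t), t)
        assert float(loss.data) > 1.0 - 1e-3

    def test_worked_soft_dice_value(self):
        """2x2x1 grid, one channel: p = (0.5, 1, 0, 0), t = (1, 1, 0, 0)."""
        p = np.zeros((1, 2, 2, 1))
        t = np.zeros((1, 2, 2, 1))
        p[0, 0, 0, 0], p[0, 0, 1, 0] = 0.5, 1.0
        t[0, 0, :, 0] = 1.0
        soft = (2 * 1.5 + DICE_EPS) / (1.5 + 2.0 + DICE_EPS)
        # a 1-channel call exercises the same soft-dice core per channel
        loss = dice_loss(Tensor(np.repeat(p, 3, axis=0)),
                         np.repeat(t, 3, axis=0))
        assert float(loss.data) == pytest.approx(1.0 - soft, abs=1e-9)

    def test_gradient_matches_finite_differences(self, rng):
        t = (rng.random((3, 3, 3, 3)) < 0.5).astype(np.float64)
        p = rng.random((3, 3, 3, 3)) * 0.8 + 0.1
        gradcheck(lambda p: dice_loss(p, t), p, tol=1e-6)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            dice_loss(Tensor(np.zeros((3, 2, 2, 2))), np.zeros((3, 4, 4, 4)))


class TestAggregate:
    @staticmethod
    def _rows(values):
        rows = []
        for case, (wt, tc, et) in enumerate(values):
            for region, v in zip(("WT", "TC", "ET"), (wt, tc, et)):
                rows.append({"case_id": f"c{case}", "region": region,
                             "dsc": v, "iou": v / 2, "hd": 1 - v,
                             "hd_flagged": False})
        return rows

    def test_single_case_std_zero(self):
        report = aggregate(self._rows([(0.8, 0.7, 0.6)]))
        assert report.summary.loc[("dsc", "WT"), "std"] == 0.0

    def test_two_case_mean(self):
        report = aggregate(self._rows([(0.6, 0.6, 0.6), (0.8, 0.8, 0.8)]))
        assert report.summary.loc[("dsc", "WT"), "mean"] == pytest.approx(0.7)
        # sample standard deviation (ddof = 1)
        assert report.summary.loc[("dsc", "WT"), "std"] == pytest.approx(
            np.std([0.6, 0.8], ddof=1))

    def test_mean_row_is_mean_of_region_means(self, rng):
        values = rng.random((5, 3))
        report = aggregate(self._rows(values))
        region_means = [report.summary.loc[("dsc", r), "mean"]
                        for r in ("WT", "TC", "ET")]
        assert report.summary.loc[("dsc", "Mean"), "mean"] == pytest.approx(
            np.mean(region_means))

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            aggregate([])

    def test_text_table_mentions_all_regions(self):
        report = aggregate(self._rows([(0.9, 0.8, 0.7)]))
        text = report.to_text()
        for token in ("Mean", "TC", "WT", "ET", "DSC", "IOU", "HD"):
            assert token in text
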