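"""Temporal summaries, zonal splits, kymographs, correlation trajectories."""

import numpy as np
import pytest

from monomech.fields import MaskSequence
from monomech.spatiotemporal import (centre_fraction, correlation_trajectory,
                                     kymograph, temporal_summary, zonal_split,
                                     zonal_summary)


def rect_masks(nt=3, ny=20, nx=40):
    return MaskSequence(np.ones((nt, ny, nx), bool), np.arange(nt) / 6.0)


class TestTemporalSummary:
    def test_single_position_medians(self):
        masks = rect_masks()
        fields = [np.full((20, 40), v) for v in (1.0, 2.0, 3.0)]
        df = temporal_summary({"p": fields}, {"p": masks})
        np.testing.assert_allclose(df["mean"], [1, 2, 3])
        np.testing.assert_allclose(df["sem"], 0.0)
        assert (df["n"] == 1).all()

    def test_two_positions_hand_values(self):
        masks = rect_masks(nt=1)
        df = temporal_summary(
            {"a": [np.full((20, 40), 2.0)], "b": [np.full((20, 40), 4.0)]},
            {"a": masks, "b": masks})
        assert df.loc[0, "mean"] == 3.0
        assert df.loc[0, "sem"] == pytest.approx(1.0)

    def test_copies_of_one_position_do_not_move_mean(self):
        masks = rect_masks(nt=2)
        f = [np.full((20, 40), 5.0), np.full((20, 40), 7.0)]
        one = temporal_summary({"a": f}, {"a": masks})
        three = temporal_summary({c: f for c in "abc"},
                                 {c: masks for c in "abc"})
        np.testing.assert_allclose(one["mean"], three["mean"])

    def test_nan_pixels_ignored(self):
        masks = rect_masks(nt=1)
        f = np.full((20, 40), 2.0)
        f[0, 0] = np.nan
        df = temporal_summary({"a": [f]}, {"a": masks})
        assert df.loc[0, "mean"] == 2.0


class TestZonalSplit:
    def test_solid_rectangle_structure(self):
        """Directional erosion peels whole columns; the centre is the
        middle band and matches an explicit simulation of the loop."""
        mask = np.ones((80, 100), bool)
        labels = zonal_split(mask)
        centre = labels == 1
        # explicit simulation: drop one column from each side per round
        n, total = 0, 8000
        while (100 - 2 * n) * 80 >= total / 2:
            n += 1
        assert centre.sum() == (100 - 2 * n) * 80
        cols = centre.any(axis=0)
        assert cols[50] and not cols[n - 1] and not cols[100 - n]

    def test_paper_average_mask_centre_share(self):
        """On the printed-average 8322-px rectangle the centre zone holds
        just under half of the pixels (strict stopping rule)."""
        mask = np.ones((73, 114), bool)
        assert mask.sum() == 8322
        frac = centre_fraction(mask)
        assert frac < 0.5
        assert frac == pytest.approx(0.4913, abs=2e-4)

    def test_centre_always_minority(self, rng):
        for _ in range(5):
            ny = rng.integers(10, 40)
            nx = rng.integers(10, 60)
            frac = centre_fraction(np.ones((ny, nx), bool))
            assert frac < 0.5

    def test_partition_exact(self):
        mask = np.ones((30, 50), bool)
        labels = zonal_split(mask)
        assert ((labels > 0) == mask).all()
        assert ((labels == 1) & (labels == 2)).sum() == 0

    def test_isotropic_mode_differs(self):
        mask = np.ones((40, 40), bool)
        a = zonal_split(mask, direction="x")
        b = zonal_split(mask, direction="iso")
        assert (a == 1).sum() != (b == 1).sum() or \
            not np.array_equal(a, b)

    def test_thin_mask_rejected(self):
        mask = np.zeros((10, 10), bool)
        mask[:, 4] = True
        with pytest.raises(ValueError):
            zonal_split(mask)


class TestKymograph:
    def test_constant_field_uniform(self):
        masks = rect_masks(nt=2, ny=10, nx=30)
        fields = [np.full((10, 30), 7.0)] * 2
        k = kymograph(fields, masks, side="averaged")
        vals = k.matrix[np.isfinite(k.matrix)]
        np.testing.assert_allclose(vals, 7.0)
        assert k.matrix.shape[0] == 2

    def test_x_coordinate_field_linear_in_distance(self):
        ny, nx = 8, 40
        masks = rect_masks(nt=1, ny=ny, nx=nx)
        xx = np.tile(np.arange(nx, dtype=float), (ny, 1))
        k = kymograph([xx], masks, side="left")
        d = np.arange(k.matrix.shape[1])
        np.testing.assert_allclose(k.matrix[0], d.astype(float))
        kr = kymograph([xx], masks, side="right")
        np.testing.assert_allclose(kr.matrix[0], nx - 1.0 - d)

    def test_expanding_mask_grows_columns(self):
        ny, nx = 10, 60
        m = np.zeros((2, ny, nx), bool)
        m[0, :, 25:35] = True
        m[1, :, 20:40] = True
        masks = MaskSequence(m, np.array([0.0, 1.0]))
        k = kymograph([np.ones((ny, nx))] * 2, masks, side="left")
        assert np.isfinite(k.matrix[0]).sum() == 5
        assert np.isfinite(k.matrix[1]).sum() == 10

    def test_column_zero_is_edge_median(self):
        rng = np.random.default_rng(1)
        ny, nx = 12, 30
        f = rng.normal(size=(ny, nx))
        masks = rect_masks(nt=1, ny=ny, nx=nx)
        k = kymograph([f], masks, side="left")
        assert k.matrix[0, 0] == pytest.approx(np.median(f[:, 0]))


class TestZonalSummary:
    def test_early_late_windows(self):
        nt = 6
        masks = MaskSequence(np.ones((nt, 10, 30), bool),
                             np.array([0, 2, 3, 5, 6, 7], float))
        fields = [np.full((10, 30), float(i)) for i in range(nt)]
        df = zonal_summary({"p": fields}, {"p": masks}, split_time=4.0)
        early = df[(df.zone == "whole") & (df.window == "early")]
        late = df[(df.zone == "whole") & (df.window == "late")]
        assert early["mean"].iloc[0] == pytest.approx(1.0)   # t=0,2,3
        assert late["mean"].iloc[0] == pytest.approx(4.0)    # t=5,6,7

    def test_zones_cover_whole(self):
        masks = rect_masks(nt=2)
        fields = [np.ones((20, 40))] * 2
        df = zonal_summary({"p": fields}, {"p": masks})
        assert set(df.zone) == {"centre", "edge", "whole"}


class TestCorrelationTrajectory:
    def test_identity_line(self):
        a = np.linspace(1, 2, 10)
        pts = correlation_trajectory(a, a)
        np.testing.assert_allclose(pts[:, 0], pts[:, 1])

    def test_point_set_invariant_to_permutation(self, rng):
        a = rng.normal(size=12)
        b = 2 * a + 1
        perm = rng.permutation(12)
        p1 = correlation_trajectory(a, b)
        p2 = correlation_trajectory(a[perm], b[perm])
        assert {tuple(r) for r in np.round(p1, 12)} == \
            {tuple(r) for r in np.round(p2, 12)}

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            correlation_trajectory(np.ones(3), np.ones(4))
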