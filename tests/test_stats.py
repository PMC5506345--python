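"""Point-wise statistics: difference, t, regression, z-score, orderings."""

import numpy as np
import pytest

from retfshape.preprocess import Laterality
from retfshape.sectors import SectorLabels, SectorScheme
from retfshape.stats import (
    ThicknessMatrix,
    benjamini_hochberg,
    column_unravel,
    group_difference_map,
    largest_component_fraction,
    order_eyes,
    regression_map,
    ttest_map,
    zscore_map,
)
from retfshape.synthetic import EyeRecord, Group


def rec(i, group, age=57.0, vfmd=-0.5):
    return EyeRecord(f"E{i:02d}", f"s{i:02d}", Laterality.OD, group, age, vfmd)


def matrix(values, groups, ages=None, vfmds=None):
    values = np.asarray(values, dtype=float)
    records = [
        rec(
            i,
            g,
            age=(ages[i] if ages is not None else 57.0),
            vfmd=(vfmds[i] if vfmds is not None else -0.5),
        )
        for i, g in enumerate(groups)
    ]
    return ThicknessMatrix(values, records)


B, C = Group.B_older_normal, Group.C_older_glaucoma


class TestDifferenceMap:
    def test_identical_groups_zero(self, rng):
        x = rng.normal(size=(5, 3))
        m = matrix(np.hstack([x, x]), [B] * 3 + [C] * 3)
        assert np.allclose(group_difference_map(m, B, C).values, 0.0)

    def test_constant_offset(self, rng):
        x = rng.normal(size=(5, 3))
        m = matrix(np.hstack([x, x + 0.07]), [B] * 3 + [C] * 3)
        assert np.allclose(group_difference_map(m, B, C).values, 0.07)

    def test_hand_worked_3v3(self):
        vals = np.array([[1.0, 2.0, 3.0, 5.0, 7.0, 9.0]])
        m = matrix(vals, [B] * 3 + [C] * 3)
        # mean(C) - mean(B) = 7 - 2 (second minus first)
        assert group_difference_map(m, B, C).values[0] == pytest.approx(5.0)

    def test_empty_group_rejected(self, rng):
        m = matrix(rng.normal(size=(3, 2)), [B, B])
        with pytest.raises(ValueError, match="empty"):
            group_difference_map(m, B, C)


class TestTtestMap:
    def test_identical_groups(self, rng):
        x = rng.normal(size=(6, 4))
        m = matrix(np.hstack([x, x]), [B] * 4 + [C] * 4)
        t, p = ttest_map(m, B, C)
        assert np.allclose(t.values, 0.0)
        assert np.allclose(p.values, 1.0)

    def test_closed_form_toy_row(self):
        """g1 = {1,2,3}, g2 = {4,5,6}: pooled-variance two-sample t by hand:
        diff = -3, s_p^2 = 1, se = sqrt(2/3), t = -3.674, df = 4."""
        from scipy.stats import t as tdist

        m = matrix(np.array([[1.0, 2, 3, 4, 5, 6]]), [B] * 3 + [C] * 3)
        t, p = ttest_map(m, B, C, variant="pooled")
        expected_t = -3.0 / np.sqrt(2.0 / 3.0)
        expected_p = 2 * tdist.sf(abs(expected_t), 4)
        assert t.values[0] == pytest.approx(expected_t, rel=1e-12)
        assert p.values[0] == pytest.approx(expected_p, rel=1e-12)
        # Welch on equal-variance groups coincides here
        tw, _ = ttest_map(m, B, C, variant="welch")
        assert tw.values[0] == pytest.approx(expected_t, rel=1e-12)

    def test_swap_antisymmetry(self, rng):
        m = matrix(rng.normal(size=(8, 7)), [B] * 4 + [C] * 3)
        t1, p1 = ttest_map(m, B, C)
        t2, p2 = ttest_map(m, C, B)
        assert np.allclose(t1.values, -t2.values)
        assert np.allclose(p1.values, p2.values)

    def test_zero_variance_flags(self):
        vals = np.array([[1.0, 1.0, 1.0, 1.0], [1.0, 1.0, 2.0, 2.0]])
        m = matrix(vals, [B, B, C, C])
        t, p = ttest_map(m, B, C)
        assert t.values[0] == 0.0 and p.values[0] == 1.0
        assert np.isinf(t.values[1]) and p.values[1] == 0.0
        assert not t.valid[1]

    def test_column_order_invariance(self, rng):
        vals = rng.normal(size=(5, 8))
        groups = [B] * 4 + [C] * 4
        m = matrix(vals, groups)
        perm = rng.permutation(8)
        m2 = ThicknessMatrix(vals[:, perm], [m.records[i] for i in perm])
        t1, _ = ttest_map(m, B, C)
        t2, _ = ttest_map(m2, B, C)
        assert np.allclose(t1.values, t2.values)


class TestRegressionMap:
    def test_exact_line(self):
        ages = np.array([30.0, 40, 50, 60, 70])
        vals = (-0.003 * ages + 0.2)[None, :].repeat(4, axis=0)
        m = matrix(vals, [B] * 5, ages=ages)
        maps = regression_map(m, "age")
        assert np.allclose(maps["slope"].values, -0.003)
        assert np.allclose(maps["intercept"].values, 0.2)
        assert np.allclose(maps["r2"].values, 1.0)

    def test_hand_worked_4_points(self):
        x = np.array([0.0, 1, 2, 3])
        y = np.array([[1.0, 3, 2, 5]])
        m = matrix(y, [B] * 4, ages=x)
        maps = regression_map(m, "age")
        # normal equations by hand: slope = cov/var = 5.5/... -> 1.1, b = 1.1
        assert maps["slope"].values[0] == pytest.approx(1.1)
        assert maps["intercept"].values[0] == pytest.approx(1.1)

    def test_permutation_null_slope(self, rng):
        """Permuting the covariate kills the slope on average."""
        ages = np.linspace(30, 70, 12)
        vals = -0.002 * ages + rng.normal(0, 0.002, (6, 12))
        slopes = []
        for _ in range(100):
            perm = rng.permutation(12)
            m = matrix(vals, [B] * 12, ages=ages[perm])
            slopes.append(regression_map(m, "age")["slope"].values)
        mean_abs = np.abs(np.mean(slopes, axis=0)).max()
        assert mean_abs < 2e-4  # an order of magnitude under the imposed slope

    def test_constant_covariate_rejected(self, rng):
        m = matrix(rng.normal(size=(3, 5)), [B] * 5, ages=np.full(5, 50.0))
        with pytest.raises(ValueError, match="constant"):
            regression_map(m, "age")


class TestZscoreMap:
    def test_reference_normalization_identities(self, rng):
        vals = rng.normal(0.1, 0.03, (7, 9))
        m = matrix(vals, [B] * 5 + [C] * 4)
        z = zscore_map(m, B)
        ref = z.values[:, :5]
        assert np.allclose(ref.mean(axis=1), 0.0, atol=1e-12)
        assert np.allclose(ref.std(axis=1, ddof=1), 1.0, atol=1e-12)

    def test_unit_offsets(self, rng):
        vals = rng.normal(size=(4, 4))
        m = matrix(vals, [B] * 4)
        z = zscore_map(m, B)
        mu = vals.mean(axis=1)
        sd = vals.std(axis=1, ddof=1)
        probe = matrix(np.c_[vals, mu + sd, mu], [B] * 4 + [C, C])
        zp = zscore_map(probe, B)
        assert np.allclose(zp.values[:, 4], 1.0)
        assert np.allclose(zp.values[:, 5], 0.0)

    def test_zero_sd_rows_flagged(self):
        vals = np.array([[1.0, 1.0, 1.0, 2.0], [1.0, 2.0, 3.0, 4.0]])
        m = matrix(vals, [B] * 3 + [C])
        z = zscore_map(m, B)
        assert np.isnan(z.values[0]).all()
        assert np.isfinite(z.values[1]).all()


class TestOrderings:
    def test_column_unravel_hand_fixture(self):
        scheme = SectorScheme(annulus_bounds=[0.0, 1.0])
        ann = np.array([0, 0, 0, 0, -1, 0])
        ang = np.array(["S", "N", "S", "N", "outside", "I"], dtype=object)
        labels = SectorLabels(ann, ang, scheme)
        dist = np.array([0.9, 0.5, 0.2, 0.8, 0.1, 0.3])
        perm = column_unravel(labels, dist)
        # N before S before I; within sector by ascending distance
        assert list(perm) == [1, 3, 2, 0, 5]

    def test_unravel_is_bijection_on_band(self):
        scheme = SectorScheme(annulus_bounds=[0.0, 1.0])
        ann = np.array([0, -1, 0, 0])
        ang = np.array(["N", "outside", "I", "T"], dtype=object)
        perm = column_unravel(SectorLabels(ann, ang, scheme), np.arange(4.0))
        assert sorted(perm) == [0, 2, 3]

    def test_order_eyes(self):
        records = [
            rec(0, B, age=50, vfmd=-3.0),
            rec(1, B, age=40, vfmd=-1.0),
            rec(2, B, age=60, vfmd=-2.0),
        ]
        assert list(order_eyes(records, "age")) == [1, 0, 2]
        assert list(order_eyes(records, "vfmd")) == [0, 2, 1]
        # already sorted -> identity; reversed -> reversing
        srt = [records[i] for i in order_eyes(records, "age")]
        assert list(order_eyes(srt, "age")) == [0, 1, 2]
        assert list(order_eyes(srt[::-1], "age")) == [2, 1, 0]

    def test_missing_key_rejected(self):
        records = [rec(0, B), rec(1, B, age=np.nan)]
        with pytest.raises(ValueError, match="missing age"):
            order_eyes(records, "age")


class TestHelpers:
    def test_largest_component_fraction(self):
        # 6-vertex strip: two faces sharing an edge + one isolated face
        faces = np.array([[0, 1, 2], [1, 3, 2], [4, 5, 0]])
        mask = np.array([True, True, True, False, True, True])
        # component {0,1,2,4,5} all connected through vertex 0
        assert largest_component_fraction(faces, mask) == pytest.approx(5 / 6)
        mask2 = np.array([True, True, False, False, True, True])
        # {0,1} via face edge 0-1; {4,5}+0 -> {0,1,4,5} connected via vertex 0
        assert largest_component_fraction(faces, mask2) == pytest.approx(4 / 6)
        assert largest_component_fraction(faces, np.zeros(6, bool)) == 0.0

    def test_benjamini_hochberg_monotone(self, rng):
        p = rng.uniform(size=50)
        q = benjamini_hochberg(p)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)
        assert np.all((q >= p - 1e-12) & (q <= 1.0))
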