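"""BMO-referenced sectorization and sector averaging."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from retfshape.preprocess import BMOEllipse, bmo_distance
from retfshape.sectors import (
    SECTOR_ORDER,
    SectorLabels,
    SectorScheme,
    angular_sector,
    assign_sectors,
    sector_average,
)
from retfshape.template import canonical_annulus_template


@pytest.fixture
def flat_ellipse():
    return BMOEllipse(np.zeros(3), [0, 0, 1], [1, 0, 0], 0.9, 0.7)


class TestAngularSector:
    @pytest.mark.parametrize(
        "theta,expected",
        [
            (0.0, "N"),
            (90.0, "S"),
            (180.0, "T"),
            (270.0, "I"),
            (45.0, "SN"),
            (135.0, "ST"),
            (225.0, "IT"),
            (315.0, "IN"),
            (30.0, "SN"),  # half-open boundary goes to the next sector
            (330.0, "N"),
            (359.9, "N"),
        ],
    )
    def test_layout(self, theta, expected):
        assert angular_sector(theta) == expected

    def test_widths(self):
        scheme = SectorScheme()
        widths = {name: w for name, _, w in scheme.angular_layout}
        for name in ("N", "S", "I", "T"):
            assert widths[name] == 60.0
        for name in ("SN", "ST", "IT", "IN"):
            assert widths[name] == 30.0

    @given(st.floats(min_value=0.0, max_value=359.999))
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_every_angle_labeled(self, theta):
        assert angular_sector(theta) in SECTOR_ORDER

    def test_invalid_layout_rejected(self):
        with pytest.raises(ValueError, match="360"):
            SectorScheme(angular_layout=[("N", 0.0, 120.0)])


class TestAssignSectors:
    def test_known_positions(self, flat_ellipse):
        from retfshape.mesh import TriSurface

        # nasal vertex in the 0.25-0.75 mm band, one inside the inner crop
        pts = np.array([[0.9 + 0.5, 0.0, 0.0], [0.9 + 0.1, 0.0, 0.0], [0.0, 2.0, 0.0]])
        surf = TriSurface(pts, np.array([[0, 1, 2]]))
        labels = assign_sectors(surf, flat_ellipse)
        assert labels.annulus[0] == 0 and labels.angular[0] == "N"
        assert labels.angular[1] == "outside" and labels.annulus[1] == -1

    def test_annulus_bands(self, flat_ellipse):
        from retfshape.mesh import TriSurface

        d_targets = [0.3, 0.5, 0.8, 1.3, 2.5]
        pts = np.array([[0.9 + d, 0.0, 0.0] for d in d_targets])
        surf = TriSurface(pts, np.array([[0, 1, 2]]))
        labels = assign_sectors(surf, flat_ellipse)
        assert list(labels.annulus) == [0, 0, 1, 2, -1]

    def test_matches_brute_force_loop(self, flat_ellipse, rng):
        tmpl = canonical_annulus_template(n_rings=8, n_theta=30)
        scheme = SectorScheme()
        labels = assign_sectors(tmpl.surface, flat_ellipse, scheme)
        bounds = scheme.annulus_bounds
        for i, v in enumerate(tmpl.surface.vertices):
            d = float(bmo_distance(v, flat_ellipse))
            ann = -1
            for k in range(len(bounds) - 1):
                if bounds[k] <= d < bounds[k + 1]:
                    ann = k
            assert labels.annulus[i] == ann
            if ann >= 0:
                theta = np.rad2deg(np.arctan2(v[1], v[0])) % 360
                assert labels.angular[i] == angular_sector(theta, scheme)
            else:
                assert labels.angular[i] == "outside"

    def test_partition_and_reindex_invariance(self, flat_ellipse, rng):
        tmpl = canonical_annulus_template(n_rings=8, n_theta=30)
        labels = assign_sectors(tmpl.surface, flat_ellipse)
        in_band = labels.in_band
        tab = sector_average(np.ones(tmpl.surface.n_vertices), labels)
        assert tab["n_vertices"].sum() == in_band.sum()
        # permuting vertices permutes labels identically
        perm = rng.permutation(tmpl.surface.n_vertices)
        inv = np.argsort(perm)
        from retfshape.mesh import TriSurface

        permuted = TriSurface(tmpl.surface.vertices[perm], inv[tmpl.surface.faces])
        labels_p = assign_sectors(permuted, flat_ellipse)
        assert np.array_equal(labels_p.annulus, labels.annulus[perm])
        assert np.array_equal(labels_p.angular, labels.angular[perm])


class TestSectorAverage:
    def _toy_labels(self):
        scheme = SectorScheme(annulus_bounds=[0.0, 1.0])
        ann = np.array([0, 0, 0, 0, 0, 0, -1, -1, 0, 0, 0, 0])
        ang = np.array(
            ["N", "N", "N", "S", "S", "I", "outside", "outside", "I", "I", "T", "T"],
            dtype=object,
        )
        return SectorLabels(ann, ang, scheme)

    def test_hand_worked_means(self):
        labels = self._toy_labels()
        values = np.array([1, 2, 3, 10, 20, 5, 99, 99, 7, 9, 4, 6], dtype=float)
        tab = sector_average(values, labels)
        means = dict(zip(tab["sector"], tab["mean"]))
        assert means["N"] == pytest.approx(2.0)  # (1+2+3)/3
        assert means["S"] == pytest.approx(15.0)  # (10+20)/2
        assert means["I"] == pytest.approx(7.0)  # (5+7+9)/3
        assert means["T"] == pytest.approx(5.0)  # (4+6)/2
        assert np.isnan(means["SN"])
        assert tab.loc[tab["sector"] == "SN", "n_vertices"].iloc[0] == 0

    def test_uniform_field(self):
        labels = self._toy_labels()
        tab = sector_average(np.full(12, 3.7), labels)
        filled = tab[tab["n_vertices"] > 0]
        assert np.allclose(filled["mean"], 3.7)

    def test_vertex_vs_area_weighting(self):
        labels = self._toy_labels()
        values = np.array([1, 2, 3, 10, 20, 5, 0, 0, 7, 9, 4, 6], dtype=float)
        areas = np.ones(12)
        equal = sector_average(values, labels, "area", areas)
        assert np.allclose(
            equal["mean"].dropna(), sector_average(values, labels)["mean"].dropna()
        )
        areas[0] = 10.0  # nasal vertex dominates its sector
        skew = sector_average(values, labels, "area", areas)
        n_mean = skew.loc[skew["sector"] == "N", "mean"].iloc[0]
        assert n_mean == pytest.approx((10 * 1 + 2 + 3) / 12)

    def test_band_mean_equals_weighted_sector_mean(self, rng):
        labels = self._toy_labels()
        values = rng.normal(size=12)
        tab = sector_average(values, labels)
        tab = tab[tab["n_vertices"] > 0]
        weighted = np.sum(tab["mean"] * tab["n_vertices"]) / tab["n_vertices"].sum()
        assert weighted == pytest.approx(values[labels.in_band].mean(), abs=1e-12)
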