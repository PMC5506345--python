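"""Synthetic cohort generator: truth fields, meshes, determinism, mirroring."""

import numpy as np
import pytest

from retfshape.preprocess import Laterality, Layer, compute_thickness
from retfshape.synthetic import (
    CohortDesign,
    EyeRecord,
    GroundTruthField,
    Group,
    MeshResolution,
    NoiseConfig,
    cohort_table,
    make_bmo_points,
    make_cohort,
    make_eye,
    true_thickness,
)


def record(group=Group.B_older_normal, age=57.0, vfmd=0.0, lat=Laterality.OD):
    return EyeRecord("X01", "s01", lat, group, age, vfmd)


class TestBmoPoints:
    def test_zero_noise_points_satisfy_ellipse(self, tilted_ellipse):
        pts = make_bmo_points(tilted_ellipse, 80, 0.0, seed=4)
        rel = pts - tilted_ellipse.center
        x = rel @ tilted_ellipse.major_axis_dir
        y = rel @ tilted_ellipse.minor_axis_dir
        z = rel @ tilted_ellipse.plane_normal
        assert np.abs(z).max() < 1e-12
        assert np.allclose((x / 0.9) ** 2 + (y / 0.7) ** 2, 1.0, atol=1e-12)

    def test_default_count_is_80(self, tilted_ellipse):
        assert make_bmo_points(tilted_ellipse, noise_sd=0.0).shape == (80, 3)

    def test_same_seed_bitwise_identical(self, tilted_ellipse):
        a = make_bmo_points(tilted_ellipse, 80, 0.02, seed=9)
        b = make_bmo_points(tilted_ellipse, 80, 0.02, seed=9)
        assert np.array_equal(a, b)

    def test_too_few_points_rejected(self, tilted_ellipse):
        with pytest.raises(ValueError, match="at least 6"):
            make_bmo_points(tilted_ellipse, 5, 0.0, seed=0)


class TestTruthFields:
    def test_rnfl_hourglass_ordering(self):
        fld = GroundTruthField.default_rnfl()
        rec = record(vfmd=0.0)
        inferior = true_thickness(Layer.RNFL, 0.5, 270.0, rec, fld)
        nasal = true_thickness(Layer.RNFL, 0.5, 0.0, rec, fld)
        superior = true_thickness(Layer.RNFL, 0.5, 90.0, rec, fld)
        assert inferior > nasal
        assert superior > nasal

    def test_glaucoma_loss_in_window_and_near_bmo(self):
        fld = GroundTruthField.default_rnfl()
        healthy, sick = record(vfmd=0.0), record(vfmd=-10.0)
        th = np.arange(0.0, 360.0, 5.0)
        d_near = true_thickness(Layer.RNFL, 0.3, th, healthy, fld) - true_thickness(
            Layer.RNFL, 0.3, th, sick, fld
        )
        lo, hi = fld.affected_angular_window
        inside = (th >= lo) & (th < hi)
        assert np.all(d_near[~inside] == 0)
        assert np.all(d_near[inside & (np.abs(th - 270) < 50)] > 0)
        assert d_near.argmax() == np.argmin(np.abs(th - 270))
        d_far = true_thickness(Layer.RNFL, 1.5, th, healthy, fld) - true_thickness(
            Layer.RNFL, 1.5, th, sick, fld
        )
        assert d_far[inside].max() < d_near[inside].max()

    def test_choroid_age_effect_is_linear(self):
        fld = GroundTruthField.default_choroid()
        t30 = true_thickness(Layer.CHOROID, 0.8, 120.0, record(age=30.0), fld)
        t57 = true_thickness(Layer.CHOROID, 0.8, 120.0, record(age=57.0), fld)
        assert t30 - t57 == pytest.approx(fld.age_slope * 27.0, abs=1e-12)

    def test_choroid_thicker_nasally_superiorly(self):
        fld = GroundTruthField.default_choroid()
        rec = record()
        upper = np.mean(
            [true_thickness(Layer.CHOROID, 1.0, t, rec, fld) for t in (0.0, 45.0, 90.0)]
        )
        lower = np.mean(
            [true_thickness(Layer.CHOROID, 1.0, t, rec, fld) for t in (180.0, 225.0, 270.0)]
        )
        assert upper > lower

    def test_floor_clamp_warns(self):
        fld = GroundTruthField.default_rnfl()
        with pytest.warns(UserWarning, match="clamped"):
            t = true_thickness(Layer.RNFL, 0.0, 270.0, record(vfmd=-40.0), fld)
        assert t >= fld.floor


class TestMakeEye:
    def test_noiseless_thickness_matches_truth_in_band(self):
        eye = make_eye(
            record(),
            warp_amplitude=0.0,
            noise=NoiseConfig(field_sd=0.0),
            seed=2,
            bmo_noise_sd=0.0,
        )
        measured = compute_thickness(eye.rnfl)
        truth = eye.truth["RNFL"]
        band = (eye.param_grid["bmo_dist"] >= 0.25) & (eye.param_grid["bmo_dist"] <= 2.0)
        signal_range = truth.max() - truth.min()
        assert np.abs(measured - truth)[band].max() < 0.01 * signal_range

    def test_os_is_mirror_of_od(self):
        od = make_eye(record(lat=Laterality.OD), seed=7)
        os_ = make_eye(record(lat=Laterality.OS), seed=7)
        assert np.allclose(
            os_.rnfl.anterior.vertices,
            od.rnfl.anterior.vertices * np.array([-1.0, 1.0, 1.0]),
        )
        assert np.allclose(os_.bmo_points, od.bmo_points * np.array([-1.0, 1.0, 1.0]))
        # winding flipped so orientation stays consistent after mirroring
        assert os_.rnfl.anterior.is_consistently_oriented()

    def test_meshes_valid_and_fields_positive(self):
        eye = make_eye(record(group=Group.C_older_glaucoma, vfmd=-12.0), seed=3)
        for pair in (eye.rnfl, eye.choroid):
            pair.anterior.validate()
            pair.posterior.validate()
            assert pair.anterior.is_consistently_oriented()
        for truth in eye.truth.values():
            assert np.all(truth > 0)

    def test_degenerate_resolution_rejected(self):
        with pytest.raises(ValueError, match="3 rings"):
            MeshResolution(n_rings=2)


class TestCohort:
    def test_default_design_matches_study(self):
        design = CohortDesign()
        assert design.group_sizes[Group.A_young_normal] == 10
        assert design.group_sizes[Group.B_older_normal] == 10
        assert design.group_sizes[Group.C_older_glaucoma] == 18
        assert design.age_mean_sd[Group.A_young_normal][0] == pytest.approx(29.8)
        assert design.age_mean_sd[Group.B_older_normal][0] == pytest.approx(57.0)
        assert design.age_mean_sd[Group.C_older_glaucoma][0] == pytest.approx(61.7)

    def test_group_covariate_structure(self):
        design = CohortDesign(
            group_sizes={
                Group.A_young_normal: 6,
                Group.B_older_normal: 6,
                Group.C_older_glaucoma: 6,
            }
        )
        eyes = make_cohort(design, seed=5)
        tab = cohort_table(eyes)
        a = tab[tab.group == "A_young_normal"]
        b = tab[tab.group == "B_older_normal"]
        c = tab[tab.group == "C_older_glaucoma"]
        assert a.age.max() < b.age.min()  # A strictly younger
        assert c.vfmd.max() < b.vfmd.min()  # glaucoma below all normals
        assert (tab.vfmd <= 0).all()

    def test_zero_variance_covariates(self):
        design = CohortDesign(
            group_sizes={Group.B_older_normal: 4},
            age_mean_sd={Group.B_older_normal: (57.0, 0.0)},
            normal_vfmd_mean_sd=(-0.5, 0.0),
        )
        eyes = make_cohort(design, seed=1)
        ages = {e.record.age for e in eyes}
        vfmds = {e.record.vfmd for e in eyes}
        assert ages == {57.0}
        assert vfmds == {-0.5}

    def test_full_cohort_reproducible_from_seed(self):
        design = CohortDesign(group_sizes={Group.B_older_normal: 3})
        a = make_cohort(design, seed=17)
        b = make_cohort(design, seed=17)
        for ea, eb in zip(a, b):
            assert np.array_equal(ea.rnfl.anterior.vertices, eb.rnfl.anterior.vertices)
            assert np.array_equal(ea.bmo_points, eb.bmo_points)
            assert ea.record == eb.record
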