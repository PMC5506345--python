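"""Seeded synthetic peri-papillary eyes and cohorts.

Emulates the anatomy and statistical structure the analysis assumes: an
elliptical Bruch's membrane opening (BMO) with per-eye size and tilt
variation, annular anterior/posterior boundary surfaces for RNFL and
choroid, an hourglass RNFL thickness profile with superior and inferior
lobes decaying away from BMO, a choroid profile thicker nasally/superiorly,
glaucomatous RNFL loss proportional to visual-field mean deviation (VFMD)
concentrated in an inferior angular window and near BMO, age-related
choroidal thinning, smooth per-eye geometric warps, and spatially
correlated thickness noise.  Left (OS) eyes are generated mirrored.

Cohort defaults follow the study design this pipeline targets: groups of
10 young-normal (A), 10 older-normal (B) and 18 older-glaucoma (C) eyes
with mean ages 29.8, 57.0 and 61.7 years.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from .mesh import TriSurface, save_surface
from .preprocess import BMOEllipse, Laterality, Layer, LayerSurfacePair


class Group(str, Enum):
    A_young_normal = "A_young_normal"
    B_older_normal = "B_older_normal"
    C_older_glaucoma = "C_older_glaucoma"


@dataclass
class EyeRecord:
    eye_id: str
    subject_id: str
    laterality: Laterality
    group: Group
    age: float  # years
    vfmd: float  # dB; <= 0, near 0 for normals


@dataclass
class GroundTruthField:
    """Closed-form noiseless thickness profile t(r, theta | age, vfmd).

    r is the planar distance (mm) from the BMO ellipse boundary, theta the
    enface polar angle in the canonical right-eye frame (nasal = 0 deg,
    superior = 90 deg).  All thicknesses in mm.
    """

    layer: Layer
    base: float  # uniform floor of the healthy profile
    lobe_amp: float = 0.0  # peak height of the superior/inferior lobes
    lobe_width_deg: float = 40.0  # angular Gaussian width of each lobe
    lobe_decay_mm: float = 1.0  # radial e-folding of the lobes
    orient_amp: float = 0.0  # cosine nasal/superior bias (choroid)
    orient_peak_deg: float = 45.0  # angle of maximal orient bias
    glaucoma_loss_scale: float = 0.0  # mm per dB of |VFMD|
    age_slope: float = 0.0  # mm per year (positive = thinning with age)
    reference_age: float = 40.0  # years; age at which the age term vanishes
    affected_angular_window: tuple[float, float] = (210.0, 330.0)  # deg
    bmo_proximity_gradient: float = 1.0  # 1/mm radial decay of glaucoma loss
    floor: float = 0.005  # clamp, mm

    @classmethod
    def default_rnfl(cls) -> "GroundTruthField":
        return cls(
            layer=Layer.RNFL,
            base=0.08,
            lobe_amp=0.10,
            glaucoma_loss_scale=0.006,
        )

    @classmethod
    def default_choroid(cls) -> "GroundTruthField":
        return cls(
            layer=Layer.CHOROID,
            base=0.15,
            orient_amp=0.03,
            age_slope=0.0015,
        )


def _wrap_deg(d: np.ndarray) -> np.ndarray:
    return (np.asarray(d, dtype=float) + 180.0) % 360.0 - 180.0


def glaucoma_window_weight(theta_deg, window: tuple[float, float]) -> np.ndarray:
    """Raised-cosine angular weight: 1 at the window center, 0 outside."""
    lo, hi = window
    center = (lo + hi) / 2.0 if lo <= hi else ((lo + hi + 360.0) / 2.0) % 360.0
    half = (hi - lo) / 2.0 if lo <= hi else (hi - lo + 360.0) / 2.0
    d = np.abs(_wrap_deg(np.asarray(theta_deg, dtype=float) - center))
    w = np.where(d <= half, np.cos(np.pi * d / (2.0 * half)) ** 2, 0.0)
    return w


def true_thickness(
    layer: Layer | str,
    r,
    theta_deg,
    record: EyeRecord,
    fld: GroundTruthField,
    clamp_warn: bool = True,
) -> np.ndarray:
    """Noiseless thickness (mm) of one layer at BMO distance r and angle theta."""
    layer = Layer(layer)
    if layer is not fld.layer:
        raise ValueError(f"field is for {fld.layer}, asked for {layer}")
    r = np.asarray(r, dtype=float)
    th = np.asarray(theta_deg, dtype=float)
    t = np.full(np.broadcast(r, th).shape, fld.base, dtype=float)
    if fld.lobe_amp:
        lobes = np.zeros_like(t)
        for center in (90.0, 270.0):  # superior / inferior
            d = _wrap_deg(th - center)
            lobes += np.exp(-0.5 * (d / fld.lobe_width_deg) ** 2)
        t = t + fld.lobe_amp * lobes * np.exp(-r / fld.lobe_decay_mm)
    if fld.orient_amp:
        t = t + fld.orient_amp * np.cos(np.deg2rad(th - fld.orient_peak_deg))
    if fld.glaucoma_loss_scale:
        severity = np.abs(min(record.vfmd, 0.0))
        w = glaucoma_window_weight(th, fld.affected_angular_window)
        t = t - fld.glaucoma_loss_scale * severity * w * np.exp(
            -fld.bmo_proximity_gradient * r
        )
    if fld.age_slope:
        t = t - fld.age_slope * (record.age - fld.reference_age)
    if np.any(t < fld.floor):
        if clamp_warn:
            warnings.warn(
                f"{layer.value} truth clamped at {fld.floor} mm floor", stacklevel=2
            )
        t = np.maximum(t, fld.floor)
    return t


# -- BMO points --------------------------------------------------------------


def make_bmo_points(
    ellipse_truth: BMOEllipse,
    n_points: int = 80,
    noise_sd: float = 0.01,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Points at uniform parameter angles on the true BMO ellipse, displaced
    by isotropic Gaussian noise.  The default 80 points mirrors manual BMO
    delineation on 80 radial slices."""
    if n_points < 6:
        raise ValueError("need at least 6 BMO points for a determined ellipse fit")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    t = np.linspace(0.0, 2.0 * np.pi, n_points, endpoint=False)
    pts = ellipse_truth.boundary_points(t)
    if noise_sd > 0:
        pts = pts + rng.normal(0.0, noise_sd, size=pts.shape)
    return pts


# -- eye geometry ------------------------------------------------------------


@dataclass
class MeshResolution:
    n_rings: int = 14
    n_theta: int = 72
    inner_margin: float = 0.05  # mm outside the BMO boundary where the annulus starts
    outer_extent: float = 2.4  # mm

    def __post_init__(self) -> None:
        if self.n_rings < 3:
            raise ValueError("need at least 3 rings for an annular mesh")


@dataclass
class NoiseConfig:
    field_sd: float = 0.008  # mm, sd of the correlated boundary-position noise
    correlation_length: float = 0.4  # mm


@dataclass
class SyntheticEye:
    record: EyeRecord
    rnfl: LayerSurfacePair
    choroid: LayerSurfacePair
    bmo_points: np.ndarray
    ellipse_truth: BMOEllipse
    truth: dict[str, np.ndarray]  # layer -> noiseless thickness at anterior vertices
    param_grid: dict[str, np.ndarray]  # "bmo_dist", "theta_deg" at anterior vertices

    @property
    def pairs(self) -> dict[Layer, LayerSurfacePair]:
        return {Layer.RNFL: self.rnfl, Layer.CHOROID: self.choroid}


def _annulus_grid(res: MeshResolution, a: float, b: float):
    """Vertex enface coordinates offset along the ellipse outward normal so
    the BMO distance of ring k is exactly s_k; returns (x, y, s, faces)."""
    t = np.linspace(0.0, 2.0 * np.pi, res.n_theta, endpoint=False)
    s = np.linspace(res.inner_margin, res.outer_extent, res.n_rings)
    ct, st = np.cos(t), np.sin(t)
    nu = np.c_[b * ct, a * st]
    nu /= np.linalg.norm(nu, axis=1)[:, None]
    base = np.c_[a * ct, b * st]
    x = base[None, :, 0] + s[:, None] * nu[None, :, 0]  # (n_rings, n_theta)
    y = base[None, :, 1] + s[:, None] * nu[None, :, 1]
    faces = []
    nt = res.n_theta
    for k in range(res.n_rings - 1):
        for l in range(nt):
            l2 = (l + 1) % nt
            i00 = k * nt + l
            i01 = k * nt + l2
            i10 = (k + 1) * nt + l
            i11 = (k + 1) * nt + l2
            faces.append([i00, i01, i11])
            faces.append([i00, i11, i10])
    sv = np.repeat(s, nt)
    return x.ravel(), y.ravel(), sv, np.asarray(faces, dtype=np.int64)


def _smooth_noise_grid(rng, res: MeshResolution, noise: NoiseConfig) -> np.ndarray:
    """Correlated Gaussian field on the (ring, theta) grid, unit variance."""
    white = rng.standard_normal((res.n_rings, res.n_theta))
    ds = (res.outer_extent - res.inner_margin) / max(res.n_rings - 1, 1)
    dtheta_mm = 2.0 * np.pi * 1.5 / res.n_theta  # arc step at a 1.5 mm ring
    f = gaussian_filter1d(white, noise.correlation_length / ds, axis=0, mode="nearest")
    f = gaussian_filter1d(f, noise.correlation_length / dtheta_mm, axis=1, mode="wrap")
    sd = f.std()
    return f / (sd if sd > 0 else 1.0)


def _random_warp(rng, amplitude: float, scale_mm: float = 1.2, n_bumps: int = 4):
    """Smooth random displacement field: sum of Gaussian bumps in 3D."""
    centers = rng.uniform(-2.0, 2.0, size=(n_bumps, 2))
    centers = np.c_[centers, rng.uniform(-0.2, 0.2, n_bumps)]
    amps = rng.normal(0.0, 1.0, size=(n_bumps, 3))
    peak = np.abs(amps).sum(axis=0).max()
    if peak > 0:
        amps *= amplitude / peak

    def warp(p: np.ndarray) -> np.ndarray:
        out = p.copy()
        for c, a_vec in zip(centers, amps):
            w = np.exp(-np.sum((p - c) ** 2, axis=1) / scale_mm**2)
            out = out + w[:, None] * a_vec
        return out

    return warp


def random_ellipse_truth(rng: np.random.Generator) -> BMOEllipse:
    """Per-eye BMO ellipse with realistic size and a mild random tilt.

    The major axis stays near the temporal-nasal (x) axis with a small
    angular jitter: BMO ellipse orientation is anatomically consistent
    across eyes, and the canonical frame aligns eyes by this axis, so the
    jitter is exactly the residual rotational misalignment the pipeline
    sees after alignment."""
    a = rng.normal(0.90, 0.05)
    b = a * rng.normal(0.78, 0.04)
    a, b = max(a, b), max(min(a, b), 0.4)
    tilt = rng.normal(0.0, np.deg2rad(4.0), size=2)
    normal = np.array([np.sin(tilt[0]), np.sin(tilt[1]), 1.0])
    normal /= np.linalg.norm(normal)
    psi = rng.normal(0.0, np.deg2rad(8.0))
    in_plane = np.array([np.cos(psi), np.sin(psi), 0.0])
    major = in_plane - (in_plane @ normal) * normal
    major /= np.linalg.norm(major)
    center = np.r_[rng.normal(0.0, 0.1, 2), rng.normal(0.0, 0.05)]
    return BMOEllipse(center, normal, major, float(a), float(b))


def make_eye(
    record: EyeRecord,
    fields: dict[Layer, GroundTruthField] | None = None,
    resolution: MeshResolution | None = None,
    warp_amplitude: float = 0.08,
    noise: NoiseConfig | None = None,
    seed: int | np.random.Generator = 0,
    ellipse_truth: BMOEllipse | None = None,
    bmo_noise_sd: float = 0.01,
    n_bmo_points: int = 80,
) -> SyntheticEye:
    """Generate one synthetic eye: annular anterior surfaces around the BMO
    ellipse, posterior surfaces offset along local normals by the noiseless
    truth plus correlated noise, a smooth random warp, and noisy BMO points.

    OS eyes are the mirror image (x -> -x) of the same-seed OD eye.
    """
    fields = fields or {
        Layer.RNFL: GroundTruthField.default_rnfl(),
        Layer.CHOROID: GroundTruthField.default_choroid(),
    }
    resolution = resolution or MeshResolution()
    noise = noise or NoiseConfig()
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    if ellipse_truth is None:
        ellipse_truth = random_ellipse_truth(rng)

    a, b = ellipse_truth.semi_major, ellipse_truth.semi_minor
    x, y, s, faces = _annulus_grid(resolution, a, b)
    dome = rng.normal(0.07, 0.015)
    z = dome * s**2 + rng.normal(0.0, 0.01) * x + rng.normal(0.0, 0.01) * y

    # embed the grid in the tilted ellipse frame
    u = ellipse_truth.major_axis_dir
    n = ellipse_truth.plane_normal
    w = np.cross(n, u)
    embed = ellipse_truth.center + np.outer(x, u) + np.outer(y, w) + np.outer(z, n)

    theta_deg = np.rad2deg(np.arctan2(embed[:, 1] - ellipse_truth.center[1],
                                      embed[:, 0] - ellipse_truth.center[0])) % 360.0
    warp = _random_warp(rng, warp_amplitude)

    pairs: dict[Layer, LayerSurfacePair] = {}
    truth: dict[str, np.ndarray] = {}
    layer_z_shift = {Layer.RNFL: 0.0, Layer.CHOROID: -0.35}
    for layer in (Layer.RNFL, Layer.CHOROID):
        fld = fields[layer]
        verts = embed + layer_z_shift[layer] * n
        ant = TriSurface(verts, faces)
        t_true = true_thickness(layer, s, theta_deg, record, fld)
        noise_field = (
            noise.field_sd * _smooth_noise_grid(rng, resolution, noise).ravel()
            if noise.field_sd > 0
            else 0.0
        )
        t_noisy = np.maximum(t_true + noise_field, fld.floor)
        normals = ant.vertex_normals()
        # anterior normals point along +n by construction; posterior sits below
        post = TriSurface(verts - normals * t_noisy[:, None], faces.copy())
        ant_w = TriSurface(warp(ant.vertices), faces.copy())
        post_w = TriSurface(warp(post.vertices), faces.copy())
        pairs[layer] = LayerSurfacePair(ant_w, post_w, layer)
        truth[layer.value] = t_true

    bmo = make_bmo_points(ellipse_truth, n_bmo_points, bmo_noise_sd, rng)

    if Laterality(record.laterality) is Laterality.OS:
        for pair in pairs.values():
            for surf in (pair.anterior, pair.posterior):
                surf.vertices[:, 0] *= -1.0
                surf.faces = surf.faces[:, ::-1].copy()
        bmo = bmo * np.array([-1.0, 1.0, 1.0])
        mirrored = BMOEllipse(
            ellipse_truth.center * np.array([-1.0, 1.0, 1.0]),
            ellipse_truth.plane_normal * np.array([-1.0, 1.0, 1.0]),
            ellipse_truth.major_axis_dir * np.array([-1.0, 1.0, 1.0]),
            ellipse_truth.semi_major,
            ellipse_truth.semi_minor,
        )
        ellipse_truth = mirrored
        theta_deg = (180.0 - theta_deg) % 360.0

    return SyntheticEye(
        record=record,
        rnfl=pairs[Layer.RNFL],
        choroid=pairs[Layer.CHOROID],
        bmo_points=bmo,
        ellipse_truth=ellipse_truth,
        truth=truth,
        param_grid={"bmo_dist": s, "theta_deg": theta_deg},
    )


# -- cohorts -----------------------------------------------------------------


@dataclass
class CohortDesign:
    group_sizes: dict[Group, int] = field(
        default_factory=lambda: {
            Group.A_young_normal: 10,
            Group.B_older_normal: 10,
            Group.C_older_glaucoma: 18,
        }
    )
    age_mean_sd: dict[Group, tuple[float, float]] = field(
        default_factory=lambda: {
            Group.A_young_normal: (29.8, 3.6),
            Group.B_older_normal: (57.0, 4.4),
            Group.C_older_glaucoma: (61.7, 7.9),
        }
    )
    normal_vfmd_mean_sd: tuple[float, float] = (-0.5, 0.5)  # clipped to [-2, 0]
    glaucoma_vfmd_range: tuple[float, float] = (-15.0, -2.5)
    fields: dict[Layer, GroundTruthField] | None = None
    resolution: MeshResolution = field(default_factory=MeshResolution)
    warp_amplitude: float = 0.08
    noise: NoiseConfig = field(default_factory=NoiseConfig)
    bmo_noise_sd: float = 0.01
    eyes_per_subject: int = 2  # fellow eyes share a subject (and an age)


def make_records(design: CohortDesign, rng: np.random.Generator) -> list[EyeRecord]:
    records = []
    subject_no = 0
    for group, size in design.group_sizes.items():
        if size < 1:
            raise ValueError("group sizes must be >= 1")
        mean, sd = design.age_mean_sd[group]
        eye_in_subject = 0
        for i in range(size):
            if eye_in_subject == 0:
                subject_no += 1
                subject_age = float(np.clip(rng.normal(mean, sd), 18.0, 95.0))
            lat = Laterality.OD if eye_in_subject == 0 else Laterality.OS
            eye_in_subject = (eye_in_subject + 1) % max(design.eyes_per_subject, 1)
            if group is Group.C_older_glaucoma:
                lo, hi = design.glaucoma_vfmd_range
                vfmd = float(rng.uniform(lo, hi))
            else:
                m, s = design.normal_vfmd_mean_sd
                vfmd = float(np.clip(rng.normal(m, s), -2.0, 0.0))
            gtag = group.value.split("_")[0]
            records.append(
                EyeRecord(
                    eye_id=f"{gtag}{i + 1:02d}",
                    subject_id=f"subj{subject_no:03d}",
                    laterality=lat,
                    group=group,
                    age=subject_age,
                    vfmd=vfmd,
                )
            )
    return records


def make_cohort(design: CohortDesign | None = None, seed: int = 0) -> list[SyntheticEye]:
    """Generate a full cohort; one master seed splits into per-eye streams."""
    design = design or CohortDesign()
    ss = np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss.spawn(1)[0])
    records = make_records(design, rng)
    eye_seeds = ss.spawn(len(records))
    eyes = []
    for record, child in zip(records, eye_seeds):
        eyes.append(
            make_eye(
                record,
                fields=design.fields,
                resolution=design.resolution,
                warp_amplitude=design.warp_amplitude,
                noise=design.noise,
                seed=np.random.default_rng(child),
                bmo_noise_sd=design.bmo_noise_sd,
            )
        )
    return eyes


def cohort_table(eyes: list[SyntheticEye]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "eye_id": [e.record.eye_id for e in eyes],
            "subject_id": [e.record.subject_id for e in eyes],
            "laterality": [Laterality(e.record.laterality).value for e in eyes],
            "group": [Group(e.record.group).value for e in eyes],
            "age": [e.record.age for e in eyes],
            "vfmd": [e.record.vfmd for e in eyes],
        }
    )


def write_cohort(eyes: list[SyntheticEye], out_dir, mesh_format: str = "vtk") -> None:
    """Write meshes (anterior/posterior per layer), BMO CSVs, the cohort table
    and a JSON ground-truth sidecar.  Units mm, right-handed coordinates."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sidecar = {}
    for eye in eyes:
        eid = eye.record.eye_id
        for layer, pair in eye.pairs.items():
            lname = layer.value
            save_surface(pair.anterior, out / f"{eid}_{lname}_anterior.{mesh_format}")
            save_surface(pair.posterior, out / f"{eid}_{lname}_posterior.{mesh_format}")
        pd.DataFrame(eye.bmo_points, columns=["x", "y", "z"]).to_csv(
            out / f"{eid}_bmo.csv", index=False
        )
        sidecar[eid] = {
            "ellipse_semi_major": eye.ellipse_truth.semi_major,
            "ellipse_semi_minor": eye.ellipse_truth.semi_minor,
            "truth": {k: v.tolist() for k, v in eye.truth.items()},
            "bmo_dist": eye.param_grid["bmo_dist"].tolist(),
            "theta_deg": eye.param_grid["theta_deg"].tolist(),
        }
    cohort_table(eyes).to_csv(out / "cohort.csv", index=False)
    with open(out / "ground_truth.json", "w") as fh:
        json.dump(sidecar, fh)


__all__ = [
    "Group",
    "EyeRecord",
    "GroundTruthField",
    "MeshResolution",
    "NoiseConfig",
    "SyntheticEye",
    "CohortDesign",
    "true_thickness",
    "glaucoma_window_weight",
    "make_bmo_points",
    "make_eye",
    "make_records",
    "make_cohort",
    "cohort_table",
    "write_cohort",
    "random_ellipse_truth",
]
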