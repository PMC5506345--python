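"""Synthetic recovery experiments.

The cohort whose images this pipeline was designed for is not shareable, so
the package's claims are validated by recovery: generate cohorts whose
ground truth is known by construction, run the full analysis, and measure
how well the imposed effects (glaucomatous inferior-window RNFL deficit,
age-related choroidal thinning) and the geometric primitives (BMO ellipse
fit) are recovered.  Both the test suite and the acceptance script call
these drivers.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import least_squares

from .matching import EnergyWeights, MatchOptions, _MatchProblem
from .preprocess import (
    BMOEllipse,
    Layer,
    bmo_distance,
    compute_thickness,
    fit_bmo_ellipse,
    preprocess_eye,
)
from .sectors import SectorScheme, assign_sectors, sector_average
from .stats import (
    ThicknessMatrix,
    largest_component_fraction,
    regression_map,
    ttest_map,
    zscore_map,
)
from .synthetic import (
    CohortDesign,
    GroundTruthField,
    Group,
    make_bmo_points,
    make_cohort,
    true_thickness,
)
from .template import TemplateSchedule, canonical_annulus_template, estimate_mean_template
from .varifold import Fshape, KernelConfig, cache_target
from .workflow import (
    RegistrationSettings,
    build_template,
    preprocess_cohort,
    thickness_matrix,
)

#: angular window (deg) of the imposed glaucomatous deficit (generator default)
DEFICIT_WINDOW = GroundTruthField.default_rnfl().affected_angular_window


# ---------------------------------------------------------------------------
# end-to-end group study (imposed glaucoma deficit)
# ---------------------------------------------------------------------------


def run_group_study(
    seed: int,
    n_per_group: int = 10,
    settings: RegistrationSettings | None = None,
    n_lowest: int = 50,
) -> dict:
    """Three-group RNFL study: 10 young-normal (A), 10 older-normal (B) and
    10 glaucoma (C) eyes by default.  Registers all eyes into a mean
    template, then measures

    - where the B-vs-C t-map attains its smallest p values (fraction of the
      ``n_lowest`` lowest-p template vertices inside the imposed inferior
      angular window),
    - how well conventional sector averaging recovers the imposed sectoral
      deficit (relative error in the sector with the largest true deficit),
    - the largest contiguous p < 0.01 region of the null A-vs-B map
      (no RNFL age effect is imposed, so this map should show noise only).
    """
    settings = settings or RegistrationSettings()
    design = CohortDesign(
        group_sizes={
            Group.A_young_normal: n_per_group,
            Group.B_older_normal: n_per_group,
            Group.C_older_glaucoma: n_per_group,
        }
    )
    eyes = make_cohort(design, seed)
    pre = preprocess_cohort(eyes, Layer.RNFL)
    mean = build_template(pre, settings)
    matrix = thickness_matrix(pre, mean)

    # --- point-wise localization of the glaucoma deficit
    _, pmap = ttest_map(matrix, Group.B_older_normal, Group.C_older_glaucoma)
    v = mean.template.surface.vertices
    theta = np.rad2deg(np.arctan2(v[:, 1], v[:, 0])) % 360.0
    lo, hi = DEFICIT_WINDOW
    in_window = (theta >= lo) & (theta < hi)
    lowest = np.argsort(pmap.values)[:n_lowest]
    frac_lowest_in_window = float(in_window[lowest].mean())
    min_p_in_window = bool(in_window[int(np.argmin(pmap.values))])

    # --- null contrast: A vs B with no imposed RNFL effect
    _, null_p = ttest_map(matrix, Group.A_young_normal, Group.B_older_normal)
    null_region = largest_component_fraction(
        mean.template.surface.faces, null_p.values < 0.01
    )

    # --- conventional sector-average recovery of the imposed deficit
    sector_err = sector_deficit_error(eyes)

    return {
        "n_eyes": len(eyes),
        "n_template_vertices": int(mean.template.surface.n_vertices),
        "frac_lowest_p_in_window": frac_lowest_in_window,
        "min_p_vertex_in_window": min_p_in_window,
        "min_p": float(np.min(pmap.values)),
        "null_largest_region_frac": float(null_region),
        "sector_deficit_rel_err": sector_err["rel_err"],
        "sector_deficit_measured_mm": sector_err["measured"],
        "sector_deficit_true_mm": sector_err["true"],
        "template_energy_log": mean.convergence_log,
    }


def sector_deficit_error(eyes, scheme: SectorScheme | None = None) -> dict:
    """Recovery of the imposed B-C sectoral deficit by the conventional
    (per-eye, unregistered) sector-average route, evaluated in the sector
    with the largest ground-truth deficit."""
    scheme = scheme or SectorScheme()
    field = GroundTruthField.default_rnfl()
    meas: dict[Group, list[np.ndarray]] = {}
    true: dict[Group, list[np.ndarray]] = {}
    for eye in eyes:
        if Group(eye.record.group) is Group.A_young_normal:
            continue
        cropped, ell = preprocess_eye(eye.rnfl, eye.bmo_points, eye.record.laterality)
        labels = assign_sectors(cropped, ell, scheme)
        m = sector_average(cropped.channels["thickness_mm"], labels)["mean"].to_numpy()
        s = bmo_distance(cropped.vertices, ell)
        th = (
            np.rad2deg(
                np.arctan2(
                    cropped.vertices[:, 1] - ell.center[1],
                    cropped.vertices[:, 0] - ell.center[0],
                )
            )
            % 360.0
        )
        tt = true_thickness(Layer.RNFL, s, th, eye.record, field, clamp_warn=False)
        t = sector_average(tt, labels)["mean"].to_numpy()
        meas.setdefault(Group(eye.record.group), []).append(m)
        true.setdefault(Group(eye.record.group), []).append(t)
    dm = np.mean(meas[Group.B_older_normal], axis=0) - np.mean(
        meas[Group.C_older_glaucoma], axis=0
    )
    dt = np.mean(true[Group.B_older_normal], axis=0) - np.mean(
        true[Group.C_older_glaucoma], axis=0
    )
    peak = int(np.argmax(dt))
    return {
        "measured": float(dm[peak]),
        "true": float(dt[peak]),
        "rel_err": float(abs(dm[peak] - dt[peak]) / abs(dt[peak])),
        "peak_sector_index": peak,
    }


# ---------------------------------------------------------------------------
# age-slope recovery (imposed choroidal thinning)
# ---------------------------------------------------------------------------


def run_age_slope_study(seed: int, n_per_group: int = 10) -> dict:
    """Per-vertex OLS of measured choroidal thickness on age over the two
    normal groups.  The synthetic meshes share one parameterization, so the
    same vertex index corresponds across eyes; thickness is measured (not
    read from the truth) with the point-to-surface metric.  Reports the
    fraction of analysis-band vertices whose estimated slope lies within
    2 standard errors of the imposed slope.

    One eye per subject: fellow eyes share an age, which makes the iid OLS
    standard error optimistic; the independent design isolates the
    estimator this experiment validates (the fellow-eye caveat of the main
    cohort is documented separately)."""
    design = CohortDesign(
        group_sizes={
            Group.A_young_normal: n_per_group,
            Group.B_older_normal: n_per_group,
        },
        eyes_per_subject=1,
    )
    eyes = make_cohort(design, seed)
    field = GroundTruthField.default_choroid()
    cols = []
    for eye in eyes:
        cols.append(compute_thickness(eye.choroid))
    values = np.column_stack(cols)
    s = eyes[0].param_grid["bmo_dist"]
    band = (s >= 0.25) & (s <= 2.0)
    matrix = ThicknessMatrix(values[band], [e.record for e in eyes])
    maps = regression_map(matrix, "age")
    true_slope = -field.age_slope  # thinning: thickness falls with age
    covered = (
        np.abs(maps["slope"].values - true_slope) <= 2.0 * maps["slope_se"].values
    )
    return {
        "n_eyes": len(eyes),
        "n_vertices": int(band.sum()),
        "true_slope_mm_per_year": float(true_slope),
        "mean_slope_mm_per_year": float(maps["slope"].values.mean()),
        "coverage_2se": float(covered.mean()),
        "mean_r2": float(maps["r2"].values.mean()),
    }


# ---------------------------------------------------------------------------
# BMO ellipse fit vs geometric oracle
# ---------------------------------------------------------------------------


def geometric_ellipse_fit(points2d: np.ndarray, init: np.ndarray) -> np.ndarray:
    """Nonlinear geometric-distance (orthogonal) ellipse fit in the plane,
    run from several starting orientations; returns (xc, yc, a, b, theta)
    with a >= b.  Slower but statistically efficient; serves as the
    reference the fast algebraic fit is compared against."""
    pts = np.asarray(points2d, dtype=float)

    def resid(p):
        xc, yc, a, b, th = p
        a, b = abs(a), abs(b)
        c, s_ = np.cos(th), np.sin(th)
        x = (pts[:, 0] - xc) * c + (pts[:, 1] - yc) * s_
        y = -(pts[:, 0] - xc) * s_ + (pts[:, 1] - yc) * c
        ax, ay = np.abs(x), np.abs(y)
        t = np.arctan2(a * ay, b * ax)
        for _ in range(30):
            ct, st = np.cos(t), np.sin(t)
            g = (a * ct - ax) * (-a * st) + (b * st - ay) * (b * ct)
            gp = (
                (a * ct - ax) * (-a * ct)
                + (b * st - ay) * (-b * st)
                + a * a * st * st
                + b * b * ct * ct
            )
            t = t - np.clip(g / np.where(np.abs(gp) > 1e-300, gp, 1.0), -0.5, 0.5)
        return np.hypot(ax - a * np.cos(t), ay - b * np.sin(t))

    best = None
    for th0 in (init[4], init[4] + 0.4, init[4] - 0.4):
        start = np.r_[init[:4], th0]
        sol = least_squares(resid, start, method="lm", max_nfev=400)
        if best is None or sol.cost < best.cost:
            best = sol
    xc, yc, a, b, th = best.x
    a, b = abs(a), abs(b)
    if b > a:
        a, b = b, a
        th += np.pi / 2
    return np.array([xc, yc, a, b, th])


def run_ellipse_study(seed: int, n_draws: int = 40, noise_sd: float = 0.01) -> dict:
    """Monte-Carlo comparison of the algebraic BMO ellipse fit against the
    geometric-distance oracle on 80-point noisy BMO sets."""
    rng = np.random.default_rng(seed)
    truth = BMOEllipse(
        np.array([0.1, -0.2, 0.05]),
        np.array([0.1, 0.05, 1.0]),
        np.array([1.0, 0.0, -0.1]),
        0.9,
        0.7,
    )
    errs_alg, errs_geo = [], []
    for _ in range(n_draws):
        pts = make_bmo_points(truth, 80, noise_sd, rng)
        fit = fit_bmo_ellipse(pts)
        errs_alg.append(
            0.5 * (abs(fit.semi_major - 0.9) + abs(fit.semi_minor - 0.7))
        )
        centered = pts - pts.mean(axis=0)
        _, _, vt = np.linalg.svd(centered, full_matrices=False)
        uv = np.c_[centered @ vt[0], centered @ vt[1]]
        sol = geometric_ellipse_fit(uv, np.array([0.0, 0.0, 0.9, 0.7, 0.0]))
        errs_geo.append(0.5 * (abs(sol[2] - 0.9) + abs(sol[3] - 0.7)))
    return {
        "n_draws": n_draws,
        "noise_sd_mm": noise_sd,
        "algebraic_mean_err_mm": float(np.mean(errs_alg)),
        "oracle_mean_err_mm": float(np.mean(errs_geo)),
        "err_ratio": float(np.mean(errs_alg) / np.mean(errs_geo)),
    }


# ---------------------------------------------------------------------------
# gradient correctness (central differences)
# ---------------------------------------------------------------------------


def _small_problem(seed: int = 0):
    rng = np.random.default_rng(seed)
    tmpl = canonical_annulus_template(n_rings=4, n_theta=10, outer_extent=2.0)
    sig = 0.1 + 0.02 * np.sin(tmpl.surface.vertices[:, 0] * 3.0)
    template = Fshape(tmpl.surface, sig)
    tgt_verts = template.surface.vertices + rng.normal(0, 0.03, (template.surface.n_vertices, 3))
    from .mesh import TriSurface

    target = Fshape(
        TriSurface(tgt_verts, template.surface.faces.copy()),
        sig + rng.normal(0, 0.01, sig.shape),
    )
    k = KernelConfig(n_timesteps=4)
    w = EnergyWeights()
    problem = _MatchProblem(template, cache_target(target, k), k, w)
    p0 = rng.normal(0, 0.02, (template.surface.n_vertices, 3))
    zeta = rng.normal(0, 0.01, template.surface.n_vertices)
    return template, problem, p0, zeta, k, w


def gradient_check(seed: int = 0, n_coords: int = 12, eps: float = 1e-6) -> dict:
    """Central-difference check of the full matching-energy gradient with
    respect to momenta, residual, template vertices and template signal on a
    40-vertex fixture.  Returns the maximum relative error."""
    template, problem, p0, zeta, k, w = _small_problem(seed)
    rng = np.random.default_rng(seed + 1)
    _, g_p, g_z, g_v, g_s = problem.energy_grad(p0, zeta)
    errors = []

    def rel(fd, an):
        return abs(fd - an) / max(abs(fd), abs(an), 1e-10)

    for _ in range(n_coords):
        i, j = rng.integers(p0.shape[0]), rng.integers(3)
        pp, pm = p0.copy(), p0.copy()
        pp[i, j] += eps
        pm[i, j] -= eps
        fd = (problem.energy(pp, zeta)["total"] - problem.energy(pm, zeta)["total"]) / (2 * eps)
        errors.append(rel(fd, g_p[i, j]))
    for _ in range(n_coords):
        i = rng.integers(zeta.size)
        zp, zm = zeta.copy(), zeta.copy()
        zp[i] += eps
        zm[i] -= eps
        fd = (problem.energy(p0, zp)["total"] - problem.energy(p0, zm)["total"]) / (2 * eps)
        errors.append(rel(fd, g_z[i]))

    # template-block gradients (vertices and signal)
    from .mesh import TriSurface

    def template_energy(verts, sig):
        # residual-penalty areas are frozen at the undeformed template (the
        # objective the template block actually optimizes)
        prob = _MatchProblem(
            Fshape(TriSurface(verts, template.surface.faces.copy()), sig),
            problem.target,
            k,
            w,
            vertex_areas=problem.areas,
        )
        return prob.energy(p0, zeta)["total"]

    verts = template.surface.vertices
    sig = template.signal
    for _ in range(n_coords):
        i, j = rng.integers(verts.shape[0]), rng.integers(3)
        vp, vm = verts.copy(), verts.copy()
        vp[i, j] += eps
        vm[i, j] -= eps
        fd = (template_energy(vp, sig) - template_energy(vm, sig)) / (2 * eps)
        errors.append(rel(fd, g_v[i, j]))
    for _ in range(n_coords):
        i = rng.integers(sig.size)
        sp, sm = sig.copy(), sig.copy()
        sp[i] += eps
        sm[i] -= eps
        fd = (template_energy(verts, sp) - template_energy(verts, sm)) / (2 * eps)
        errors.append(rel(fd, g_s[i]))
    return {"max_rel_err": float(np.max(errors)), "n_checks": len(errors)}


# ---------------------------------------------------------------------------
# fixed points and shift recovery
# ---------------------------------------------------------------------------


def selfmatch_study() -> dict:
    """Matching an fshape to itself must stay at the zero fixed point; the
    reference scale is the dissimilarity to a slightly perturbed copy."""
    from .matching import match
    from .mesh import TriSurface
    from .varifold import varifold_dissimilarity

    tmpl = canonical_annulus_template(n_rings=6, n_theta=24)
    sig = 0.1 + 0.03 * np.sin(tmpl.surface.vertices[:, 1] * 2.0)
    fs = Fshape(tmpl.surface, sig)
    k = KernelConfig(n_timesteps=5)
    res = match(fs, fs, k, EnergyWeights(), MatchOptions(max_iters=20))
    rng = np.random.default_rng(0)
    pert = Fshape(
        TriSurface(
            fs.surface.vertices + rng.normal(0, 0.02, fs.surface.vertices.shape),
            fs.surface.faces.copy(),
        ),
        fs.signal,
    )
    ref = varifold_dissimilarity(fs, pert, k)
    return {
        "total_energy": res.energy_terms["total"],
        "reference_d2": ref,
        "energy_ratio": res.energy_terms["total"] / ref,
        "max_abs_momentum": float(np.abs(res.deformation.initial_momenta).max()),
        "max_abs_zeta": float(np.abs(res.zeta).max()),
    }


def identical_cohort_study(n_copies: int = 4) -> dict:
    """The mean template of identical fshapes must reproduce the input."""
    tmpl = canonical_annulus_template(n_rings=6, n_theta=24)
    sig = 0.1 + 0.03 * np.cos(tmpl.surface.vertices[:, 0] * 2.0)
    fs = Fshape(tmpl.surface, sig)
    k = KernelConfig(n_timesteps=5)
    mt = estimate_mean_template(
        [fs.copy() for _ in range(n_copies)],
        fs,
        k,
        EnergyWeights(),
        TemplateSchedule(max_outer_iters=2),
        MatchOptions(max_iters=10),
    )
    return {
        "max_geom_dev_mm": float(
            np.abs(mt.template.surface.vertices - fs.surface.vertices).max()
        ),
        "max_signal_dev_mm": float(np.abs(mt.template.signal - fs.signal).max()),
        "log_monotone": bool(np.all(np.diff(mt.convergence_log) <= 1e-9)),
    }


def shift_recovery_study(shift: float = 0.02) -> dict:
    """Matching to a constant-signal-shifted copy must recover zeta ~ shift."""
    from .matching import match

    tmpl = canonical_annulus_template(n_rings=8, n_theta=36)
    sig = 0.1 + 0.05 * np.exp(
        -(((np.rad2deg(np.arctan2(tmpl.surface.vertices[:, 1], tmpl.surface.vertices[:, 0])) - 90.0) / 40.0) ** 2)
    )
    fs = Fshape(tmpl.surface, sig)
    target = Fshape(fs.surface.copy(), fs.signal + shift)
    k = KernelConfig(n_timesteps=5)
    res = match(
        fs,
        target,
        k,
        EnergyWeights(gamma_V=0.1, gamma_f=0.001, gamma_W=1.0),
        MatchOptions(max_iters=100, optimizer="lbfgs"),
    )
    rel_err = abs(res.zeta.mean() - shift) / shift
    return {
        "imposed_shift_mm": shift,
        "mean_zeta_mm": float(res.zeta.mean()),
        "rel_err": float(rel_err),
        "max_pointwise_rel_err": float(np.abs(res.zeta - shift).max() / shift),
    }


# ---------------------------------------------------------------------------
# exact statistics identities
# ---------------------------------------------------------------------------


def stats_identity_study(seed: int = 0) -> dict:
    """z-map of the reference group has mean 0 / sd 1 per row; whole-band
    mean equals the n-weighted sector-mean average; t on identical groups is
    (0, 1)."""
    from .preprocess import Laterality
    from .synthetic import EyeRecord

    rng = np.random.default_rng(seed)
    n_rows, n_ref, n_other = 40, 8, 6
    records = [
        EyeRecord(f"R{i}", f"s{i}", Laterality.OD, Group.B_older_normal, 55.0, -0.5)
        for i in range(n_ref)
    ] + [
        EyeRecord(f"G{i}", f"t{i}", Laterality.OD, Group.C_older_glaucoma, 60.0, -8.0)
        for i in range(n_other)
    ]
    values = rng.normal(0.12, 0.02, (n_rows, n_ref + n_other))
    m = ThicknessMatrix(values, records)
    z = zscore_map(m, Group.B_older_normal)
    ref_cols = m.group_columns(Group.B_older_normal)
    zr = z.values[:, ref_cols]
    z_mean_dev = float(np.abs(zr.mean(axis=1)).max())
    z_sd_dev = float(np.abs(zr.std(axis=1, ddof=1) - 1.0).max())

    # whole-band mean vs n-weighted sector-mean average on a labeled annulus
    from .sectors import SectorScheme

    tmpl = canonical_annulus_template(n_rings=6, n_theta=24)
    ell = BMOEllipse(
        np.zeros(3), np.array([0.0, 0.0, 1.0]), np.array([1.0, 0.0, 0.0]), 0.9, 0.7
    )
    labels = assign_sectors(tmpl.surface, ell, SectorScheme())
    vals = rng.normal(0.1, 0.02, tmpl.surface.n_vertices)
    tab = sector_average(vals, labels)
    tab = tab[tab["n_vertices"] > 0]
    weighted = float(np.sum(tab["mean"] * tab["n_vertices"]) / tab["n_vertices"].sum())
    band_mean = float(vals[labels.in_band].mean())
    band_identity_dev = abs(weighted - band_mean)

    # t-test on identical groups
    dup = np.concatenate([values[:, :n_ref], values[:, :n_ref]], axis=1)
    dup_records = records[:n_ref] + [
        replace(r, group=Group.C_older_glaucoma) for r in records[:n_ref]
    ]
    md = ThicknessMatrix(dup, dup_records)
    tmap, pmap = ttest_map(md, Group.B_older_normal, Group.C_older_glaucoma)
    return {
        "zscore_ref_mean_max_abs": z_mean_dev,
        "zscore_ref_sd_max_dev": z_sd_dev,
        "band_mean_identity_dev_mm": float(band_identity_dev),
        "ttest_identical_max_abs_t": float(np.abs(tmap.values).max()),
        "ttest_identical_min_p": float(pmap.values.min()),
    }
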