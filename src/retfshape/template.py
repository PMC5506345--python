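"""Mean fshape template estimation.

The cohort template (X*, f*) is estimated by alternating block descent on

    J(X*, f*, {p0_i, zeta_i}) = sum_i E_i

over (a) the per-subject momenta and residuals (a warm-started match per
subject) and (b) the template vertex positions and signal (gradient steps
with backtracking on the summed energy).  The accepted-step energy log is
non-increasing by construction: rematching can only lower each subject
term, and template steps are accepted only when they lower the total.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .mesh import TriSurface
from .matching import (
    EnergyWeights,
    MatchOptions,
    MatchResult,
    _control_index,
    _MatchProblem,
    match,
)
from .varifold import Fshape, KernelConfig, cache_target


@dataclass
class TemplateSchedule:
    max_outer_iters: int = 10
    tolerance: float = 1e-5  # relative change of total energy between outer iters
    template_steps: int = 5  # gradient steps on (X*, f*) per outer iteration
    template_step0: float = 1.0
    max_halvings: int = 25
    update_geometry: bool = True
    update_signal: bool = True
    precondition: bool = True  # scale template gradients by 1/vertex-area
    center_signal: bool = True  # move the mean residual into f* each outer iter


@dataclass
class MeanTemplate:
    template: Fshape
    per_subject: list[MatchResult]
    convergence_log: list[float] = field(default_factory=list)
    converged: bool = False

    def transported_thickness(self, subject_index: int) -> np.ndarray:
        """Subject thickness on template coordinates: t_i = f* + zeta_i."""
        return self.template.signal + self.per_subject[subject_index].zeta

    def thickness_matrix_values(self) -> np.ndarray:
        """(n_template_vertices, n_subjects) transported thickness values."""
        return np.column_stack(
            [self.transported_thickness(i) for i in range(len(self.per_subject))]
        )


def transported_thickness(mean_template: MeanTemplate, subject_index: int) -> np.ndarray:
    return mean_template.transported_thickness(subject_index)


def canonical_annulus_template(
    semi_major: float = 0.9,
    semi_minor: float = 0.7,
    n_rings: int = 14,
    n_theta: int = 72,
    inner_margin: float = 0.05,
    outer_extent: float = 2.4,
    dome: float = 0.07,
    signal: float | np.ndarray = 0.1,
) -> Fshape:
    """Cohort-independent template initialization: a regular annular mesh
    around a canonical BMO ellipse with a gentle parabolic dome."""
    from .synthetic import MeshResolution, _annulus_grid

    res = MeshResolution(n_rings, n_theta, inner_margin, outer_extent)
    x, y, s, faces = _annulus_grid(res, semi_major, semi_minor)
    z = dome * s**2
    surf = TriSurface(np.c_[x, y, z], faces)
    sig = np.broadcast_to(np.asarray(signal, dtype=float), (surf.n_vertices,)).copy()
    return Fshape(surf, sig)


def project_mean_signal(template_surface: TriSurface, cohort: list[Fshape]) -> np.ndarray:
    """Nearest-vertex projection of each cohort signal onto the template,
    averaged across the cohort — used to seed f*."""
    out = np.zeros(template_surface.n_vertices)
    for fs in cohort:
        tree = cKDTree(fs.surface.vertices)
        _, idx = tree.query(template_surface.vertices)
        out += fs.signal[idx]
    return out / len(cohort)


def estimate_mean_template(
    cohort: list[Fshape],
    init: Fshape,
    k: KernelConfig,
    weights: EnergyWeights | None = None,
    schedule: TemplateSchedule | None = None,
    match_opts: MatchOptions | None = None,
) -> MeanTemplate:
    """Joint minimization of the summed matching energy over the template and
    all per-subject deformations/residuals (alternating block descent)."""
    if len(cohort) < 1:
        raise ValueError("cohort must contain at least one fshape")
    weights = weights or EnergyWeights()
    schedule = schedule or TemplateSchedule()
    match_opts = match_opts or MatchOptions()

    template = init.copy()
    targets = [cache_target(fs, k) for fs in cohort]
    # residual-penalty vertex areas frozen at the initial template: keeps the
    # summed energy exactly differentiable in (X*, f*, momenta, residuals)
    areas0 = init.surface.vertex_areas()
    n_vert = template.surface.n_vertices
    control_idx = _control_index(n_vert, match_opts.control_stride)
    n_ctrl = n_vert if control_idx is None else control_idx.size
    momenta = [np.zeros((n_ctrl, 3)) for _ in cohort]
    zetas = [np.zeros(n_vert) for _ in cohort]
    results: list[MatchResult] = [None] * len(cohort)  # type: ignore[list-item]

    log: list[float] = []
    step = schedule.template_step0
    converged = False

    def total_energy(tmpl: Fshape) -> float:
        tot = 0.0
        for tc, p0, z in zip(targets, momenta, zetas):
            prob = _MatchProblem(tmpl, tc, k, weights, control_idx, areas0)
            tot += prob.energy(p0, z)["total"]
        return tot

    for outer in range(schedule.max_outer_iters):
        # -- block 1: per-subject matches (warm-started)
        subject_total = 0.0
        for i, tc in enumerate(targets):
            res = match(
                template, tc, k, weights, match_opts,
                p0=momenta[i], zeta=zetas[i], vertex_areas=areas0,
            )
            momenta[i] = res.deformation.initial_momenta
            zetas[i] = res.zeta
            results[i] = res
            subject_total += res.energy_terms["total"]
        log.append(subject_total)

        # -- centering: f* <- f* + mean(zeta), zeta_i <- zeta_i - mean(zeta).
        # Every D^2 is unchanged (only f* + zeta_i enters); the residual
        # penalty can only decrease, so this is an exact descent step and
        # removes the template/residual translation degeneracy.
        if schedule.center_signal and schedule.update_signal:
            delta = np.mean(zetas, axis=0)
            if np.any(delta != 0.0):
                old_pen = sum(float(np.sum(areas0 * z**2)) for z in zetas)
                template = Fshape(template.surface, template.signal + delta)
                zetas = [z - delta for z in zetas]
                new_pen = sum(float(np.sum(areas0 * z**2)) for z in zetas)
                subject_total += weights.gamma_f * (new_pen - old_pen)
                log.append(subject_total)

        # -- block 2: template update by gradient descent with backtracking
        if schedule.update_geometry or schedule.update_signal:
            current = subject_total
            for _ in range(schedule.template_steps):
                g_verts = np.zeros((n_vert, 3))
                g_sig = np.zeros(n_vert)
                for tc, p0, z in zip(targets, momenta, zetas):
                    prob = _MatchProblem(template, tc, k, weights, control_idx, areas0)
                    _, _, _, gv, gs = prob.energy_grad(p0, z)
                    g_verts += gv
                    g_sig += gs
                if not schedule.update_geometry:
                    g_verts[:] = 0.0
                if not schedule.update_signal:
                    g_sig[:] = 0.0
                if schedule.precondition:
                    # descend in the area-weighted metric: rescaling by the
                    # local vertex area equalizes step sizes across the mesh
                    areas = np.maximum(template.surface.vertex_areas(), 1e-12)
                    g_verts = g_verts / areas[:, None]
                    g_sig = g_sig / areas
                gnorm = np.sqrt(np.sum(g_verts**2) + np.sum(g_sig**2))
                if gnorm == 0.0:
                    break
                accepted = False
                for _ in range(schedule.max_halvings):
                    trial = Fshape(
                        TriSurface(
                            template.surface.vertices - step * g_verts,
                            template.surface.faces.copy(),
                        ),
                        template.signal - step * g_sig,
                    )
                    e_try = total_energy(trial)
                    if e_try < current:
                        template = trial
                        current = e_try
                        step *= 1.5
                        accepted = True
                        break
                    step *= 0.5
                if not accepted:
                    break
            log.append(current)

        rel = (
            abs(log[-1] - log[0 if outer == 0 else -3]) / max(abs(log[-1]), 1e-300)
            if len(log) >= 2
            else np.inf
        )
        if outer > 0 and rel < schedule.tolerance:
            converged = True
            break

    # final rematch so the stored per-subject results refer to the final template
    final_total = 0.0
    for i, tc in enumerate(targets):
        res = match(
            template, tc, k, weights, match_opts,
            p0=momenta[i], zeta=zetas[i], vertex_areas=areas0,
        )
        results[i] = res
        final_total += res.energy_terms["total"]
    log.append(final_total)

    return MeanTemplate(template, list(results), log, converged)
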