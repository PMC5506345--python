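"""In-memory cohort workflow: synthetic eyes -> preprocessing -> mean
template -> thickness matrix -> statistics.

These are the same stages `pipeline.run_pipeline` drives from files; the
in-memory form is what the analysis scripts, tests and acceptance checks
use (no I/O round trip).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .matching import EnergyWeights, MatchOptions
from .preprocess import BMOEllipse, Layer, preprocess_eye
from .sectors import SectorScheme, assign_sectors
from .stats import ThicknessMatrix
from .synthetic import SyntheticEye
from .template import (
    MeanTemplate,
    TemplateSchedule,
    canonical_annulus_template,
    estimate_mean_template,
    project_mean_signal,
)
from .varifold import Fshape, KernelConfig


@dataclass
class RegistrationSettings:
    """Kernel, weights and schedule used by the cohort analyses.

    Problem sizes here are desk-scale: ~1,000-vertex meshes, a handful of
    outer iterations, 5 integration timesteps and momenta on every other
    vertex ring; they trade some registration sharpness for tractable
    single-CPU runtimes.
    """

    kernel: KernelConfig = field(
        default_factory=lambda: KernelConfig(n_timesteps=5)
    )
    weights: EnergyWeights = field(default_factory=EnergyWeights)
    match_opts: MatchOptions = field(
        default_factory=lambda: MatchOptions(
            max_iters=25, optimizer="lbfgs", control_stride=4
        )
    )
    schedule: TemplateSchedule = field(
        default_factory=lambda: TemplateSchedule(max_outer_iters=2, template_steps=2)
    )


@dataclass
class PreprocessedCohort:
    fshapes: list[Fshape]
    ellipses: list[BMOEllipse]
    eyes: list[SyntheticEye]
    layer: Layer


def preprocess_cohort(
    eyes: list[SyntheticEye],
    layer: Layer | str = Layer.RNFL,
    inner: float = 0.25,
    outer: float = 2.0,
) -> PreprocessedCohort:
    layer = Layer(layer)
    fshapes = []
    ellipses = []
    for eye in eyes:
        pair = eye.pairs[layer]
        cropped, ellipse = preprocess_eye(
            pair, eye.bmo_points, eye.record.laterality, inner, outer
        )
        fshapes.append(Fshape.from_channel(cropped))
        ellipses.append(ellipse)
    return PreprocessedCohort(fshapes, ellipses, eyes, layer)


def build_template(
    pre: PreprocessedCohort,
    settings: RegistrationSettings | None = None,
    inner: float = 0.25,
    outer: float = 2.0,
) -> MeanTemplate:
    """Mean-template estimation initialized from a canonical annulus sized by
    the cohort's median BMO ellipse, with the cohort-mean signal projected."""
    settings = settings or RegistrationSettings()
    med_a = float(np.median([e.semi_major for e in pre.ellipses]))
    med_b = float(np.median([e.semi_minor for e in pre.ellipses]))
    init = canonical_annulus_template(
        med_a, med_b, inner_margin=inner, outer_extent=outer + 0.2
    )
    init = Fshape(init.surface, project_mean_signal(init.surface, pre.fshapes))
    return estimate_mean_template(
        pre.fshapes,
        init,
        settings.kernel,
        settings.weights,
        settings.schedule,
        settings.match_opts,
    )


def template_ellipse(pre: PreprocessedCohort) -> BMOEllipse:
    med_a = float(np.median([e.semi_major for e in pre.ellipses]))
    med_b = float(np.median([e.semi_minor for e in pre.ellipses]))
    return BMOEllipse(
        np.zeros(3), np.array([0.0, 0.0, 1.0]), np.array([1.0, 0.0, 0.0]), med_a, med_b
    )


def thickness_matrix(pre: PreprocessedCohort, mean: MeanTemplate) -> ThicknessMatrix:
    return ThicknessMatrix(
        mean.thickness_matrix_values(), [e.record for e in pre.eyes]
    )


def template_sectors(
    pre: PreprocessedCohort, mean: MeanTemplate, scheme: SectorScheme | None = None
):
    return assign_sectors(mean.template.surface, template_ellipse(pre), scheme)
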