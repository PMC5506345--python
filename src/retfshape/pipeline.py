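"""End-to-end analysis pipeline: preprocess -> per-layer mean template ->
sectorization -> statistics -> exports, driven by a validated JSON config.

Each stage writes its outputs under the run directory and a manifest records
a content hash for every file, so identical inputs and config reproduce
identical runs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict

from .matching import EnergyWeights, MatchOptions
from .mesh import TriSurface, load_surface, save_surface
from .preprocess import Laterality, Layer, LayerSurfacePair, preprocess_eye
from .sectors import SectorScheme, assign_sectors, sector_average, sector_key
from .stats import (
    ThicknessMatrix,
    column_unravel,
    group_difference_map,
    order_eyes,
    regression_map,
    ttest_map,
    zscore_map,
)
from .synthetic import EyeRecord, Group
from .template import (
    TemplateSchedule,
    canonical_annulus_template,
    estimate_mean_template,
    project_mean_signal,
)
from .varifold import Fshape, KernelConfig

log = logging.getLogger("retfshape.pipeline")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[stage: {stage}] {message}")
        self.stage = stage


class KernelSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    geom_scale: float = 0.4
    signal_scale: float = 0.05
    normal_kernel: str = "unoriented_binet"
    deformation_scale: float = 0.6
    n_timesteps: int = 10


class WeightsSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    gamma_V: float = 0.1
    gamma_f: float = 20.0
    gamma_W: float = 1.0


class MatchSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    max_iters: int = 30
    tolerance: float = 1e-5
    optimizer: str = "gd"
    control_stride: int = 1
    multiscale: bool = False


class ScheduleSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    max_outer_iters: int = 3
    tolerance: float = 1e-5
    template_steps: int = 3


class SectorSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    annulus_bounds: list[float] = [0.25, 0.75, 1.25, 2.0]


class StatsSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    contrasts: list[list[str]] = [
        ["A_young_normal", "B_older_normal"],
        ["B_older_normal", "C_older_glaucoma"],
    ]
    covariates: list[str] = ["age", "vfmd"]
    zscore_reference: str = "B_older_normal"


class PipelineConfig(BaseModel):
    """Validated against this schema before any stage runs; unknown keys
    are rejected."""

    model_config = ConfigDict(extra="forbid")

    cohort_dir: str
    out_dir: str
    layers: list[str] = ["RNFL", "choroid"]
    inner_crop: float = 0.25
    outer_crop: float = 2.0
    mesh_format: str = "vtk"
    kernel: KernelSection = KernelSection()
    weights: WeightsSection = WeightsSection()
    match: MatchSection = MatchSection()
    schedule: ScheduleSection = ScheduleSection()
    sectors: SectorSection = SectorSection()
    stats: StatsSection = StatsSection()
    seed: int = 0
    write_figures: bool = True


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def load_cohort_inputs(cfg: PipelineConfig):
    cohort_dir = Path(cfg.cohort_dir)
    table_path = cohort_dir / "cohort.csv"
    if not table_path.exists():
        raise PipelineError("preprocess", f"missing cohort table {table_path}")
    table = pd.read_csv(table_path)
    eyes = []
    for _, row in table.iterrows():
        record = EyeRecord(
            eye_id=str(row["eye_id"]),
            subject_id=str(row["subject_id"]),
            laterality=Laterality(row["laterality"]),
            group=Group(row["group"]),
            age=float(row["age"]),
            vfmd=float(row["vfmd"]),
        )
        files = {}
        for layer in cfg.layers:
            for side in ("anterior", "posterior"):
                p = cohort_dir / f"{record.eye_id}_{layer}_{side}.{cfg.mesh_format}"
                if not p.exists():
                    raise PipelineError("preprocess", f"missing mesh file {p}")
                files[(layer, side)] = p
        bmo = cohort_dir / f"{record.eye_id}_bmo.csv"
        if not bmo.exists():
            raise PipelineError("preprocess", f"missing BMO file {bmo}")
        eyes.append((record, files, bmo))
    return eyes


def run_pipeline(config: PipelineConfig | dict) -> Path:
    """Execute all stages; returns the run directory."""
    cfg = config if isinstance(config, PipelineConfig) else PipelineConfig(**config)
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: list[Path] = []

    kernel = KernelConfig(**cfg.kernel.model_dump())
    weights = EnergyWeights(**cfg.weights.model_dump())
    match_opts = MatchOptions(**cfg.match.model_dump())
    schedule = TemplateSchedule(**cfg.schedule.model_dump())
    scheme = SectorScheme(annulus_bounds=list(cfg.sectors.annulus_bounds))

    # ------------------------------------------------------------------ load
    eyes = load_cohort_inputs(cfg)
    records = [e[0] for e in eyes]
    log.info("loaded %d eyes from %s", len(eyes), cfg.cohort_dir)

    results_by_layer = {}
    for layer_name in cfg.layers:
        layer = Layer(layer_name)
        # -------------------------------------------------------- preprocess
        fshapes = []
        ellipses = []
        sector_tables = []
        try:
            for record, files, bmo_path in eyes:
                pair = LayerSurfacePair(
                    load_surface(files[(layer_name, "anterior")]),
                    load_surface(files[(layer_name, "posterior")]),
                    layer,
                )
                bmo = pd.read_csv(bmo_path)[["x", "y", "z"]].to_numpy()
                cropped, ellipse = preprocess_eye(
                    pair, bmo, record.laterality, cfg.inner_crop, cfg.outer_crop
                )
                fshapes.append(Fshape.from_channel(cropped))
                ellipses.append(ellipse)
                labels = assign_sectors(cropped, ellipse, scheme)
                tab = sector_average(cropped.channels["thickness_mm"], labels)
                tab.insert(0, "eye_id", record.eye_id)
                tab.insert(1, "layer", layer_name)
                sector_tables.append(tab)
        except PipelineError:
            raise
        except Exception as exc:  # noqa: BLE001
            raise PipelineError("preprocess", f"{layer_name}: {exc}") from exc

        # ---------------------------------------------------- mean template
        try:
            med_a = float(np.median([e.semi_major for e in ellipses]))
            med_b = float(np.median([e.semi_minor for e in ellipses]))
            init = canonical_annulus_template(
                med_a,
                med_b,
                outer_extent=cfg.outer_crop + 0.2,
                inner_margin=cfg.inner_crop,
                signal=0.1,
            )
            init = Fshape(init.surface, project_mean_signal(init.surface, fshapes))
            mean = estimate_mean_template(
                fshapes, init, kernel, weights, schedule, match_opts
            )
        except Exception as exc:  # noqa: BLE001
            raise PipelineError("template", f"{layer_name}: {exc}") from exc

        # ---------------------------------------------------- sectorization
        t_ell = _template_ellipse(med_a, med_b)
        t_labels = assign_sectors(mean.template.surface, t_ell, scheme)
        center_dist = np.linalg.norm(mean.template.surface.vertices[:, :2], axis=1)

        # -------------------------------------------------------- statistics
        matrix = ThicknessMatrix(mean.thickness_matrix_values(), records)
        stats_out = _run_stats(cfg, matrix, t_labels, center_dist)

        results_by_layer[layer_name] = {
            "mean": mean,
            "matrix": matrix,
            "labels": t_labels,
            "sector_tables": pd.concat(sector_tables, ignore_index=True),
            "stats": stats_out,
            "ellipse": t_ell,
        }

    # ----------------------------------------------------------- export all
    for layer_name, resl in results_by_layer.items():
        outputs += _export_layer(cfg, out, layer_name, resl, records)

    manifest = {
        "config": json.loads(cfg.model_dump_json()),
        "config_hash": hashlib.sha256(cfg.model_dump_json().encode()).hexdigest(),
        "outputs": {str(p.relative_to(out)): _sha256(p) for p in outputs},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return out


def _template_ellipse(a: float, b: float):
    from .preprocess import BMOEllipse

    return BMOEllipse(np.zeros(3), np.array([0.0, 0.0, 1.0]), np.array([1.0, 0.0, 0.0]), a, b)


def _run_stats(cfg, matrix, labels, center_dist):
    out = {"maps": {}, "regressions": {}, "orders": {}}
    for g1, g2 in cfg.stats.contrasts:
        diff = group_difference_map(matrix, g1, g2)
        tmap, pmap = ttest_map(matrix, g1, g2)
        out["maps"][f"{g1}_vs_{g2}"] = {"diff": diff, "t": tmap, "p": pmap}
    for cov in cfg.stats.covariates:
        out["regressions"][cov] = regression_map(matrix, cov)
    out["z"] = zscore_map(matrix, cfg.stats.zscore_reference)
    out["orders"]["rows"] = column_unravel(labels, center_dist)
    for key in ("age", "vfmd"):
        out["orders"][key] = order_eyes(matrix.records, key)
    return out


def _export_layer(cfg, out: Path, layer_name: str, resl, records) -> list[Path]:
    written: list[Path] = []
    mean = resl["mean"]
    matrix = resl["matrix"]
    stats_out = resl["stats"]

    tdir = out / layer_name
    tdir.mkdir(exist_ok=True)

    surf = mean.template.surface.copy()
    surf.channels["f_star"] = mean.template.signal
    for i, rec in enumerate(records):
        surf.channels[f"thickness_{rec.eye_id}"] = mean.transported_thickness(i)
    p = tdir / "template.vtk"
    save_surface(surf, p)
    written.append(p)

    p = tdir / "energy_log.csv"
    pd.DataFrame({"total_energy": mean.convergence_log}).to_csv(p, index=False)
    written.append(p)

    p = tdir / "sector_means.csv"
    resl["sector_tables"].to_csv(p, index=False)
    written.append(p)

    p = tdir / "thickness_matrix.csv"
    df = pd.DataFrame(matrix.values, columns=[r.eye_id for r in records])
    df.to_csv(p, index=False)
    written.append(p)

    p = tdir / "orders.json"
    with open(p, "w") as fh:
        json.dump({k: v.tolist() for k, v in stats_out["orders"].items()}, fh)
    written.append(p)

    for contrast, maps in stats_out["maps"].items():
        for mname, smap in maps.items():
            p = tdir / f"{contrast}_{mname}.csv"
            pd.DataFrame(
                {"vertex_id": np.arange(smap.values.size), "value": smap.values}
            ).to_csv(p, index=False)
            written.append(p)
    for cov, maps in stats_out["regressions"].items():
        p = tdir / f"regression_{cov}.csv"
        pd.DataFrame({k: m.values for k, m in maps.items()}).to_csv(p, index=False)
        written.append(p)

    if cfg.write_figures:
        from .viz import plot_columns, plot_enface_map

        p = tdir / "template_mean.png"
        plot_enface_map(
            mean.template.surface,
            mean.template.signal,
            p,
            title=f"{layer_name} mean template thickness",
        )
        written.append(p)
        rows = stats_out["orders"]["rows"]
        key = "vfmd" if layer_name == "RNFL" else "age"
        cols = stats_out["orders"][key]
        p = tdir / "columns.png"
        plot_columns(
            matrix.values,
            rows,
            cols,
            matrix.covariate(key),
            p,
            title=f"{layer_name} transported thickness",
            key_label=key,
        )
        written.append(p)
    return written
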