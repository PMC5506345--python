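#!/usr/bin/env python
"""Point-wise group statistics on the registered thickness matrices.

Reads the per-layer thickness matrices produced by 03 (one column per eye,
rows = template vertices), computes difference/t/p maps for the age
contrast (A vs B) and the glaucoma contrast (B vs C), and per-vertex OLS
slopes of RNFL thickness on VFMD (B+C eyes) and choroidal thickness on age
(A+B eyes).  Writes map CSVs and enface figures under results/stats/.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

from retfshape.mesh import load_surface
from retfshape.preprocess import Laterality
from retfshape.stats import (
    ThicknessMatrix,
    group_difference_map,
    regression_map,
    ttest_map,
)
from retfshape.synthetic import EyeRecord, Group
from retfshape.viz import plot_enface_map

RUN = Path("results/run")
OUT = Path("results/stats")

A, B, C = Group.A_young_normal, Group.B_older_normal, Group.C_older_glaucoma


def load_matrix(layer: str) -> tuple[ThicknessMatrix, object]:
    mat = pd.read_csv(RUN / layer / "thickness_matrix.csv")
    cohort = pd.read_csv("results/data/cohort/cohort.csv").set_index("eye_id")
    records = [
        EyeRecord(
            c,
            str(cohort.loc[c, "subject_id"]),
            Laterality(cohort.loc[c, "laterality"]),
            Group(cohort.loc[c, "group"]),
            float(cohort.loc[c, "age"]),
            float(cohort.loc[c, "vfmd"]),
        )
        for c in mat.columns
    ]
    template = load_surface(RUN / layer / "template.vtk")
    return ThicknessMatrix(mat.to_numpy(), records), template


def subset(m: ThicknessMatrix, groups) -> ThicknessMatrix:
    cols = np.concatenate([m.group_columns(g) for g in groups])
    cols.sort()
    return ThicknessMatrix(m.values[:, cols], [m.records[i] for i in cols])


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    for layer in ("RNFL", "choroid"):
        m, template = load_matrix(layer)
        out_rows = {}
        for g1, g2, tag in ((A, B, "age_AvsB"), (B, C, "glaucoma_BvsC")):
            diff = group_difference_map(m, g1, g2)
            tmap, pmap = ttest_map(m, g1, g2)
            out_rows[f"{tag}_diff_mm"] = diff.values
            out_rows[f"{tag}_t"] = tmap.values
            out_rows[f"{tag}_p"] = pmap.values
            plot_enface_map(
                template, pmap.values, OUT / f"{layer}_{tag}_p.png",
                title=f"{layer} {tag} p-map", cmap="magma", vmin=0.0, vmax=0.2,
                units="p",
            )
        reg_v = regression_map(subset(m, [B, C]), "vfmd")
        reg_a = regression_map(subset(m, [A, B]), "age")
        out_rows["slope_vfmd_mm_per_db"] = reg_v["slope"].values
        out_rows["r2_vfmd"] = reg_v["r2"].values
        out_rows["slope_age_mm_per_year"] = reg_a["slope"].values
        out_rows["r2_age"] = reg_a["r2"].values
        pd.DataFrame(out_rows).to_csv(OUT / f"{layer}_maps.csv", index=False)
        plot_enface_map(
            template, reg_a["slope"].values * 1000.0,
            OUT / f"{layer}_age_slope.png",
            title=f"{layer} thickness vs age", units="um/year", cmap="coolwarm",
        )
        sig = (out_rows["glaucoma_BvsC_p"] < 0.01).mean()
        print(
            f"{layer}: {100 * sig:.1f}% of vertices p<0.01 for B-vs-C; "
            f"median age slope {1000 * np.median(out_rows['slope_age_mm_per_year']):+.2f} um/yr; "
            f"median VFMD slope {1000 * np.median(out_rows['slope_vfmd_mm_per_db']):+.2f} um/dB"
        )
    print(f"maps under {OUT}")


if __name__ == "__main__":
    sys.exit(main())
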