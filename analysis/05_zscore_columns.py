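#!/usr/bin/env python
"""Z-score normalization and multi-subject column plots.

Standardizes every eye's template-indexed thickness against a reference
group (young normals for the age comparison, older normals for glaucoma),
unravels template vertices into the N -> IN counter-clockwise sector order
(inner to outer within each sector), orders eyes by VFMD (RNFL) or age
(choroid), and writes the column plots plus the z-matrices.
"""

import importlib.util
import json
import sys
from pathlib import Path

import numpy as np
import pandas as pd

from retfshape.stats import zscore_map
from retfshape.synthetic import Group
from retfshape.viz import plot_columns

RUN = Path("results/run")
OUT = Path("results/zscores")

spec = importlib.util.spec_from_file_location(
    "pointwise", Path(__file__).parent / "04_pointwise_statistics.py"
)
pointwise = importlib.util.module_from_spec(spec)
spec.loader.exec_module(pointwise)


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    plan = {
        "RNFL": ("vfmd", Group.B_older_normal),
        "choroid": ("age", Group.A_young_normal),
    }
    for layer, (key, ref) in plan.items():
        m, _ = pointwise.load_matrix(layer)
        z = zscore_map(m, ref)
        orders = json.loads((RUN / layer / "orders.json").read_text())
        rows = np.asarray(orders["rows"], dtype=int)
        cols = np.asarray(orders[key], dtype=int)
        ids = [r.eye_id for r in m.records]
        pd.DataFrame(z.values, columns=ids).to_csv(OUT / f"{layer}_z.csv", index=False)
        plot_columns(
            m.values, rows, cols, m.covariate(key),
            OUT / f"{layer}_thickness_columns.png",
            title=f"{layer} transported thickness (mm)", key_label=key,
        )
        plot_columns(
            z.values, rows, cols, m.covariate(key),
            OUT / f"{layer}_z_columns.png",
            title=f"{layer} z vs {ref.value}", key_label=key, cmap="coolwarm",
        )
        within = z.values[:, m.group_columns(ref)]
        print(
            f"{layer}: z ref={ref.value}, eyes ordered by {key}; "
            f"reference-group z mean {within.mean():+.3f}, sd {within.std(ddof=1):.3f}"
        )
    print(f"outputs under {OUT}")


if __name__ == "__main__":
    sys.exit(main())
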