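#!/usr/bin/env python
"""Ground-truth recovery experiments (light set).

Runs the cheap recovery checks on fresh seeded cohorts: BMO ellipse fit
vs the geometric-distance oracle, choroidal age-slope recovery by
per-vertex OLS, and sector-average recovery of the imposed glaucomatous
deficit.  The heavy end-to-end registration study is what
scripts/acceptance.py runs; this script summarizes the rest into
results/recovery.json.
"""

import json
import sys
from pathlib import Path

from retfshape.experiments import (
    run_age_slope_study,
    run_ellipse_study,
    sector_deficit_error,
    shift_recovery_study,
)
from retfshape.synthetic import CohortDesign, Group, make_cohort

SEED = 1
OUT = Path("results/recovery.json")


def main() -> None:
    out = {}
    out["ellipse"] = run_ellipse_study(SEED)
    print(
        "ellipse fit: mean semi-axis error "
        f"{1000 * out['ellipse']['algebraic_mean_err_mm']:.2f} um "
        f"({out['ellipse']['err_ratio']:.2f}x the geometric oracle)"
    )
    out["age_slope"] = run_age_slope_study(SEED)
    print(
        "choroid age slope: true "
        f"{1000 * out['age_slope']['true_slope_mm_per_year']:.2f} um/yr, "
        f"estimated {1000 * out['age_slope']['mean_slope_mm_per_year']:.2f} um/yr, "
        f"2SE coverage {100 * out['age_slope']['coverage_2se']:.1f}%"
    )
    design = CohortDesign(
        group_sizes={Group.B_older_normal: 10, Group.C_older_glaucoma: 10}
    )
    out["sector_deficit"] = sector_deficit_error(make_cohort(design, SEED))
    print(
        "sector deficit: true "
        f"{1000 * out['sector_deficit']['true']:.1f} um, measured "
        f"{1000 * out['sector_deficit']['measured']:.1f} um "
        f"({100 * out['sector_deficit']['rel_err']:.1f}% error)"
    )
    out["constant_shift"] = shift_recovery_study()
    print(
        "constant-shift residual recovery error "
        f"{100 * out['constant_shift']['rel_err']:.2f}%"
    )
    OUT.parent.mkdir(parents=True, exist_ok=True)
    OUT.write_text(json.dumps(out, indent=2))
    print(f"summary in {OUT}")


if __name__ == "__main__":
    sys.exit(main())
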