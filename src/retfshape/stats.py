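"""Point-wise and sector-wise statistics on template-indexed thickness.

After registration every eye's thickness lives on the template vertices
(t_i = f* + zeta_i), forming a vertices x eyes matrix.  Rows can equally be
sector averages; the same operations apply at both granularities:
group mean-difference maps, two-sample t-test maps (Welch by default),
per-row OLS against age or visual-field mean deviation, z-score maps
against a reference group, and the row/column orderings used for
multi-subject "column" visualizations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .sectors import SECTOR_ORDER, SectorLabels
from .synthetic import EyeRecord, Group


@dataclass
class ThicknessMatrix:
    """rows = template vertices (or sectors), columns = eyes."""

    values: np.ndarray  # (n_rows, n_eyes) mm
    records: list[EyeRecord]
    row_ids: np.ndarray | None = None  # optional row labels (e.g. sector keys)
    allow_non_finite: bool = False  # z-matrices may carry flagged NaN rows

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != len(self.records):
            raise ValueError("values must be (n_rows, n_eyes) matching records")
        if not self.allow_non_finite and not np.all(np.isfinite(self.values)):
            raise ValueError("thickness matrix contains non-finite values")

    def group_columns(self, group: Group | str) -> np.ndarray:
        group = Group(group)
        cols = [i for i, r in enumerate(self.records) if Group(r.group) is group]
        return np.asarray(cols, dtype=int)

    def covariate(self, name: str) -> np.ndarray:
        if name not in ("age", "vfmd"):
            raise ValueError("covariate must be 'age' or 'vfmd'")
        return np.array([getattr(r, name) for r in self.records], dtype=float)


@dataclass
class StatMap:
    """One per-row statistic field with its metadata."""

    name: str
    values: np.ndarray
    valid: np.ndarray | None = None  # False where the statistic is undefined
    extra: dict = field(default_factory=dict)


def _group_values(m: ThicknessMatrix, g) -> np.ndarray:
    cols = m.group_columns(g)
    if cols.size == 0:
        raise ValueError(f"group {g} is empty")
    return m.values[:, cols]


def group_difference_map(m: ThicknessMatrix, g1, g2) -> StatMap:
    """Per-row mean(g2) - mean(g1) (second minus first)."""
    x1 = _group_values(m, g1)
    x2 = _group_values(m, g2)
    return StatMap("mean_diff", x2.mean(axis=1) - x1.mean(axis=1))


def ttest_map(
    m: ThicknessMatrix, g1, g2, variant: str = "welch"
) -> tuple[StatMap, StatMap]:
    """Per-row two-sample t and two-sided p between groups g1 and g2.

    t is signed as mean(g1) - mean(g2) over the usual two-sample scaling.
    Zero variance in both groups: equal means -> (t=0, p=1); unequal means
    -> (inf, 0), flagged.
    """
    if variant not in ("welch", "pooled"):
        raise ValueError("variant must be 'welch' or 'pooled'")
    x1 = _group_values(m, g1)
    x2 = _group_values(m, g2)
    if x1.shape[1] < 2 or x2.shape[1] < 2:
        raise ValueError("each group needs at least 2 eyes")
    t, p = sps.ttest_ind(x1, x2, axis=1, equal_var=(variant == "pooled"))
    t = np.asarray(t, dtype=float)
    p = np.asarray(p, dtype=float)
    diff = x1.mean(axis=1) - x2.mean(axis=1)
    degenerate = (x1.std(axis=1) == 0) & (x2.std(axis=1) == 0)
    same = degenerate & (np.abs(diff) == 0)
    differ = degenerate & (np.abs(diff) > 0)
    t[same] = 0.0
    p[same] = 1.0
    t[differ] = np.sign(diff[differ]) * np.inf
    p[differ] = 0.0
    valid = ~differ
    return StatMap("t", t, valid), StatMap("p", p, valid)


def regression_map(m: ThicknessMatrix, covariate: str) -> dict[str, StatMap]:
    """Per-row OLS thickness = a*covariate + b; returns slope (mm per
    covariate unit), intercept (mm) and r^2 maps."""
    if len(m.records) < 3:
        raise ValueError("regression needs at least 3 eyes")
    x = m.covariate(covariate)
    if np.ptp(x) == 0:
        raise ValueError(f"covariate {covariate!r} is constant")
    xm = x - x.mean()
    sxx = float(np.sum(xm**2))
    y = m.values
    ym = y - y.mean(axis=1, keepdims=True)
    slope = (ym @ xm) / sxx
    intercept = y.mean(axis=1) - slope * x.mean()
    ss_tot = np.sum(ym**2, axis=1)
    ss_reg = slope**2 * sxx
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = np.where(ss_tot > 0, ss_reg / ss_tot, 0.0)
    # standard error of the slope, for recovery/coverage checks
    dof = len(x) - 2
    resid = ym - slope[:, None] * xm[None, :]
    with np.errstate(invalid="ignore", divide="ignore"):
        se = np.sqrt(np.sum(resid**2, axis=1) / dof / sxx)
    return {
        "slope": StatMap(f"slope_{covariate}", slope),
        "intercept": StatMap("intercept", intercept),
        "r2": StatMap("r2", np.clip(r2, 0.0, 1.0)),
        "slope_se": StatMap("slope_se", se),
    }


def zscore_map(m: ThicknessMatrix, reference) -> ThicknessMatrix:
    """Per-row standardization of every eye against the reference group:
    z_k = (x_k - mean_ref_k) / sd_ref_k (sample sd, n-1).  Rows with zero
    reference sd are NaN-flagged."""
    ref = _group_values(m, reference)
    if ref.shape[1] < 2:
        raise ValueError("reference group needs at least 2 eyes")
    mu = ref.mean(axis=1)
    sd = ref.std(axis=1, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (m.values - mu[:, None]) / sd[:, None]
    z[sd == 0, :] = np.nan
    return ThicknessMatrix(z, m.records, m.row_ids, allow_non_finite=True)


def column_unravel(labels: SectorLabels, center_distances: np.ndarray) -> np.ndarray:
    """Row permutation for column plots: vertices ordered by sector sequence
    N, SN, S, ST, T, IT, I, IN (counter-clockwise from nasal), then by
    distance from the BMO center within each sector; ties by vertex index.
    Only in-band vertices appear."""
    center_distances = np.asarray(center_distances, dtype=float).ravel()
    order = []
    rank = {name: i for i, name in enumerate(SECTOR_ORDER)}
    idx = np.arange(labels.annulus.shape[0])
    in_band = labels.in_band
    keys = [
        (rank[labels.angular[i]], center_distances[i], i) for i in idx[in_band]
    ]
    order = [k[2] for k in sorted(keys)]
    return np.asarray(order, dtype=int)


def order_eyes(records: list[EyeRecord], key: str) -> np.ndarray:
    """Column permutation ordering eyes by ascending age or vfmd; ties by
    eye_id."""
    if key not in ("age", "vfmd"):
        raise ValueError("key must be 'age' or 'vfmd'")
    vals = []
    for r in records:
        v = getattr(r, key)
        if v is None or not np.isfinite(v):
            raise ValueError(f"missing {key} for eye {r.eye_id}")
        vals.append((v, r.eye_id))
    return np.asarray(sorted(range(len(vals)), key=lambda i: vals[i]), dtype=int)


def benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    """Optional FDR q-values for p-maps (off by default in the pipeline)."""
    p = np.asarray(p, dtype=float).ravel()
    n = p.size
    order = np.argsort(p)
    ranked = p[order] * n / (np.arange(n) + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.clip(q, 0.0, 1.0)
    return out


def largest_component_fraction(faces: np.ndarray, mask: np.ndarray) -> float:
    """Fraction of all vertices covered by the largest edge-connected
    component of the masked vertex set (e.g. the biggest contiguous
    p < 0.01 region of a significance map)."""
    from scipy.sparse import coo_matrix
    from scipy.sparse.csgraph import connected_components

    mask = np.asarray(mask, dtype=bool)
    n = mask.size
    if not mask.any():
        return 0.0
    edges = np.concatenate([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]])
    keep = mask[edges[:, 0]] & mask[edges[:, 1]]
    edges = edges[keep]
    adj = coo_matrix(
        (np.ones(len(edges)), (edges[:, 0], edges[:, 1])), shape=(n, n)
    )
    n_comp, labels = connected_components(adj + adj.T, directed=False)
    counts = np.bincount(labels[mask], minlength=n_comp)
    return float(counts.max()) / n


def stat_table(stat: StatMap) -> pd.DataFrame:
    return pd.DataFrame(
        {"vertex_id": np.arange(stat.values.size), "value": stat.values}
    )
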