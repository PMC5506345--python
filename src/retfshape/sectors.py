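"""BMO-referenced sectorization of peri-papillary surfaces.

Sectors are the conventional comparator to point-wise analysis: elliptical
annuli at constant planar distances from the BMO ellipse (0.25, 0.75,
1.25 mm by default), crossed with an angular layout in the canonical
right-eye frame (nasal = 0 deg, superior = 90 deg, counter-clockwise).
The four principal sectors (N, S, I, T) are 60 deg wide, centered on the
cardinal axes; the four intermediate sectors (SN, ST, IT, IN) fill the
30 deg gaps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .mesh import TriSurface
from .preprocess import BMOEllipse, bmo_distance

#: counter-clockwise column order used in multi-subject plots, starting nasal
SECTOR_ORDER = ["N", "SN", "S", "ST", "T", "IT", "I", "IN"]

_DEFAULT_ANGULAR = [
    ("N", -30.0, 60.0),
    ("SN", 30.0, 30.0),
    ("S", 60.0, 60.0),
    ("ST", 120.0, 30.0),
    ("T", 150.0, 60.0),
    ("IT", 210.0, 30.0),
    ("I", 240.0, 60.0),
    ("IN", 300.0, 30.0),
]


@dataclass
class SectorScheme:
    annulus_bounds: list[float] = field(default_factory=lambda: [0.25, 0.75, 1.25, 2.0])
    angular_layout: list[tuple[str, float, float]] = field(
        default_factory=lambda: list(_DEFAULT_ANGULAR)
    )

    def __post_init__(self) -> None:
        b = np.asarray(self.annulus_bounds, dtype=float)
        if not np.all(np.diff(b) > 0):
            raise ValueError("annulus bounds must be strictly increasing")
        widths = sum(w for _, _, w in self.angular_layout)
        if abs(widths - 360.0) > 1e-9:
            raise ValueError("angular widths must sum to 360 degrees")

    @property
    def n_annuli(self) -> int:
        return len(self.annulus_bounds) - 1

    @property
    def sector_names(self) -> list[str]:
        return [name for name, _, _ in self.angular_layout]


@dataclass
class SectorLabels:
    """Per-vertex (annulus index, angular sector name); -1/"outside" off-band."""

    annulus: np.ndarray  # int, -1 outside
    angular: np.ndarray  # object dtype of names, "outside" off-band
    scheme: SectorScheme

    @property
    def in_band(self) -> np.ndarray:
        return self.annulus >= 0


def angular_sector(theta_deg, scheme: SectorScheme | None = None):
    """Angular sector containing theta (deg, canonical frame); half-open
    [start, start+width) intervals."""
    scheme = scheme or SectorScheme()
    th = np.atleast_1d(np.asarray(theta_deg, dtype=float)) % 360.0
    out = np.full(th.shape, None, dtype=object)
    for name, start, width in scheme.angular_layout:
        lo = start % 360.0
        hi = (start + width) % 360.0
        if lo < hi:
            m = (th >= lo) & (th < hi)
        else:  # interval wraps through 0
            m = (th >= lo) | (th < hi)
        out[m] = name
    if any(v is None for v in out.ravel()):
        raise ValueError("angular layout does not cover all angles")
    return out if np.ndim(theta_deg) else str(out[0])


def assign_sectors(
    surface: TriSurface,
    ellipse: BMOEllipse,
    scheme: SectorScheme | None = None,
) -> SectorLabels:
    """Label each vertex by (annulus from BMO-boundary distance, angular
    sector about the BMO center); vertices outside all annuli -> "outside"."""
    scheme = scheme or SectorScheme()
    d = bmo_distance(surface.vertices, ellipse)
    bounds = np.asarray(scheme.annulus_bounds, dtype=float)
    ann = np.searchsorted(bounds, d, side="right") - 1
    ann = np.where((ann >= 0) & (ann < scheme.n_annuli) & (d >= bounds[0]), ann, -1)
    rel = surface.vertices - ellipse.center
    theta = np.rad2deg(np.arctan2(rel[:, 1], rel[:, 0])) % 360.0
    names = angular_sector(theta, scheme)
    names = np.where(ann >= 0, names, "outside").astype(object)
    return SectorLabels(ann.astype(int), names, scheme)


def sector_average(
    values: np.ndarray,
    labels: SectorLabels,
    weighting: str = "vertex",
    areas: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-(annulus, sector) mean of a per-vertex field.

    Default weighting is the unweighted vertex mean ("all points in the
    sector ... averaged"); "area" weights by barycentric vertex area.
    Empty sectors are reported with n=0 and NaN mean.
    """
    values = np.asarray(values, dtype=float).ravel()
    if values.shape[0] != labels.annulus.shape[0]:
        raise ValueError("values not aligned with labels")
    if weighting not in ("vertex", "area"):
        raise ValueError("weighting must be 'vertex' or 'area'")
    if weighting == "area":
        if areas is None:
            raise ValueError("area weighting requires per-vertex areas")
        wts = np.asarray(areas, dtype=float).ravel()
    else:
        wts = np.ones_like(values)
    rows = []
    for ai in range(labels.scheme.n_annuli):
        for name in labels.scheme.sector_names:
            m = (labels.annulus == ai) & (labels.angular == name)
            n = int(m.sum())
            if n:
                mean = float(np.average(values[m], weights=wts[m]))
            else:
                mean = np.nan
            rows.append(
                {"annulus": ai, "sector": name, "n_vertices": n, "mean": mean}
            )
    return pd.DataFrame(rows)


def sector_key(df: pd.DataFrame) -> pd.Series:
    """Stable (annulus, sector) key column for joining sector tables."""
    return df["annulus"].astype(str) + ":" + df["sector"].astype(str)
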