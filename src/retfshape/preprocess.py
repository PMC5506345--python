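"""BMO-referenced preprocessing of peri-papillary layer surfaces.

The Bruch's membrane opening (BMO) is the anatomical reference for every
spatial construct in this package: its best-fit 3D ellipse anchors the
canonical right-eye frame, the inner crop of the layer surfaces, and the
sector layout.  Layer thickness is the closest 3D Euclidean distance from
each anterior-surface vertex to the posterior boundary surface.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import Enum

import numpy as np
from scipy.spatial import cKDTree
from skimage.measure import EllipseModel

from .mesh import TriSurface


class Laterality(str, Enum):
    OD = "OD"
    OS = "OS"


class Layer(str, Enum):
    RNFL = "RNFL"
    CHOROID = "choroid"


@dataclass
class LayerSurfacePair:
    """Anterior and posterior boundary surfaces of one retinal layer."""

    anterior: TriSurface
    posterior: TriSurface
    layer: Layer = Layer.RNFL


@dataclass
class BMOEllipse:
    """Best-fit 3D ellipse of the Bruch's membrane opening."""

    center: np.ndarray  # (3,) mm
    plane_normal: np.ndarray  # unit
    major_axis_dir: np.ndarray  # unit, in plane
    semi_major: float  # mm
    semi_minor: float  # mm
    fit_rms: float = 0.0  # in-plane residual RMS of the fit, mm

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float).reshape(3)
        self.plane_normal = _unit(np.asarray(self.plane_normal, dtype=float))
        self.major_axis_dir = _unit(np.asarray(self.major_axis_dir, dtype=float))
        if not (self.semi_major >= self.semi_minor > 0):
            raise ValueError("require semi_major >= semi_minor > 0")
        if abs(self.plane_normal @ self.major_axis_dir) > 1e-8:
            raise ValueError("major_axis_dir must lie in the ellipse plane")

    @property
    def minor_axis_dir(self) -> np.ndarray:
        return np.cross(self.plane_normal, self.major_axis_dir)

    def boundary_points(self, t: np.ndarray) -> np.ndarray:
        """3D boundary points at parameter angles ``t`` (radians)."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        return (
            self.center
            + np.cos(t)[:, None] * self.semi_major * self.major_axis_dir
            + np.sin(t)[:, None] * self.semi_minor * self.minor_axis_dir
        )


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("zero-length direction vector")
    return v / n


def fit_bmo_ellipse(points: np.ndarray) -> BMOEllipse:
    """Fit a 3D ellipse to BMO points: PCA plane, then direct in-plane conic fit.

    The plane is spanned by the two leading principal directions of the
    centered points; the in-plane fit is the direct (ellipse-specific)
    least-squares conic fit.  Raises on < 6 points or degenerate geometry.
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 3)
    if pts.shape[0] < 6:
        raise ValueError("ellipse fit needs at least 6 points")
    centroid = pts.mean(axis=0)
    centered = pts - centroid
    # principal directions of the point cloud
    _, svals, vt = np.linalg.svd(centered, full_matrices=False)
    if svals[1] < 1e-10 * max(svals[0], 1e-300):
        raise ValueError("points are collinear; plane undefined")
    e1, e2, normal = vt[0], vt[1], vt[2]
    if normal[2] < 0:  # orient the plane normal toward anterior (+z)
        normal, e2 = -normal, -e2
    uv = np.c_[centered @ e1, centered @ e2]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FutureWarning)
        model = EllipseModel()
        ok = model.estimate(uv)
        if not ok:
            raise ValueError("direct conic fit did not produce an ellipse")
        xc, yc, a, b, theta = model.params
    if not (np.isfinite([xc, yc, a, b, theta]).all() and a > 0 and b > 0):
        raise ValueError("direct conic fit did not produce an ellipse")
    if b > a:
        a, b = b, a
        theta += np.pi / 2.0
    major2d = np.array([np.cos(theta), np.sin(theta)])
    center3d = centroid + xc * e1 + yc * e2
    major3d = major2d[0] * e1 + major2d[1] * e2
    ell = BMOEllipse(center3d, normal, major3d, float(a), float(b))
    resid = bmo_distance(pts, ell)
    ell.fit_rms = float(np.sqrt(np.mean(resid**2)))
    return ell


# -- canonical right-eye frame ---------------------------------------------


def canonical_transform(ellipse: BMOEllipse, laterality: Laterality | str) -> np.ndarray:
    """4x4 transform into the canonical frame: BMO centroid at the origin,
    BMO plane normal along +z, major axis in the +x half-plane; left (OS)
    eyes are additionally mirrored across the y-z plane so nasal is +x.
    """
    laterality = Laterality(laterality)
    n = ellipse.plane_normal
    u = ellipse.major_axis_dir
    if u[0] < 0 or (u[0] == 0 and u[1] < 0):  # fix the 180-deg ambiguity
        u = -u
    w = np.cross(n, u)
    rot = np.vstack([u, w, n])  # maps u->x, w->y, n->z; det +1
    mat = np.eye(4)
    mat[:3, :3] = rot
    mat[:3, 3] = -rot @ ellipse.center
    if laterality is Laterality.OS:
        mirror = np.diag([-1.0, 1.0, 1.0, 1.0])
        mat = mirror @ mat
    return mat


def apply_transform(points: np.ndarray, matrix: np.ndarray) -> np.ndarray:
    pts = np.asarray(points, dtype=float)
    return pts @ matrix[:3, :3].T + matrix[:3, 3]


def transform_ellipse(ellipse: BMOEllipse, matrix: np.ndarray) -> BMOEllipse:
    lin = matrix[:3, :3]
    if abs(abs(np.linalg.det(lin)) - 1.0) > 1e-9:
        raise ValueError("transform must be orthogonal (rigid or mirrored rigid)")
    normal = lin @ ellipse.plane_normal
    return BMOEllipse(
        apply_transform(ellipse.center, matrix),
        normal,
        lin @ ellipse.major_axis_dir,
        ellipse.semi_major,
        ellipse.semi_minor,
        ellipse.fit_rms,
    )


# -- BMO distance -----------------------------------------------------------


def _nearest_ellipse_distance(x: np.ndarray, y: np.ndarray, a: float, b: float) -> np.ndarray:
    """Unsigned distance from first-quadrant points (x, y >= 0) to the ellipse
    boundary x^2/a^2 + y^2/b^2 = 1.

    Newton iteration on d/dt half-squared-distance to (a cos t, b sin t),
    run from several starting parameters; interior points near an axis have a
    spurious critical point there, which the multistart avoids."""
    starts = [np.arctan2(a * y, b * x)]
    starts += [np.full_like(x, s) for s in (0.05, 0.5, 1.0, 1.52)]
    best = np.full_like(x, np.inf)
    for t in starts:
        t = t.copy()
        for _ in range(40):
            ct, st = np.cos(t), np.sin(t)
            ex, ey = a * ct, b * st
            g = (ex - x) * (-a * st) + (ey - y) * (b * ct)
            gp = (
                (ex - x) * (-a * ct)
                + (ey - y) * (-b * st)
                + a * a * st * st
                + b * b * ct * ct
            )
            step = g / np.where(np.abs(gp) > 1e-300, gp, 1.0)
            step = np.clip(step, -0.5, 0.5)
            t = np.clip(t - step, 0.0, np.pi / 2)
            if np.max(np.abs(step)) < 1e-14:
                break
        best = np.minimum(best, np.hypot(x - a * np.cos(t), y - b * np.sin(t)))
    return best


def bmo_distance(points: np.ndarray, ellipse: BMOEllipse) -> np.ndarray:
    """Signed planar distance (mm) from each point to the BMO ellipse boundary.

    Points are projected into the BMO plane; the distance is measured there to
    the nearest boundary point, positive outside and negative inside.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    rel = pts - ellipse.center
    u = ellipse.major_axis_dir
    w = ellipse.minor_axis_dir
    x = rel @ u
    y = rel @ w
    a, b = ellipse.semi_major, ellipse.semi_minor
    d = _nearest_ellipse_distance(np.abs(x), np.abs(y), a, b)
    inside = (x / a) ** 2 + (y / b) ** 2 < 1.0
    d = np.where(inside, -d, d)
    return d if np.asarray(points).ndim == 2 else d[0]


# -- thickness ---------------------------------------------------------------


def _closest_point_on_triangles(p: np.ndarray, a, b, c) -> np.ndarray:
    """Vectorized closest point on each triangle (a,b,c) to each point p.

    Region-classification algorithm (Ericson, Real-Time Collision Detection);
    all inputs (n,3), returns (n,3).
    """
    ab = b - a
    ac = c - a
    ap = p - a
    d1 = np.einsum("ij,ij->i", ab, ap)
    d2 = np.einsum("ij,ij->i", ac, ap)
    bp = p - b
    d3 = np.einsum("ij,ij->i", ab, bp)
    d4 = np.einsum("ij,ij->i", ac, bp)
    cp = p - c
    d5 = np.einsum("ij,ij->i", ab, cp)
    d6 = np.einsum("ij,ij->i", ac, cp)

    result = np.empty_like(p)
    done = np.zeros(p.shape[0], dtype=bool)

    def assign(mask, value):
        m = mask & ~done
        result[m] = value[m]
        done[m] = True

    assign((d1 <= 0) & (d2 <= 0), a)  # vertex A
    assign((d3 >= 0) & (d4 <= d3), b)  # vertex B
    assign((d6 >= 0) & (d5 <= d6), c)  # vertex C
    vc = d1 * d4 - d3 * d2
    vsafe = np.where(np.abs(d1 - d3) > 0, d1 - d3, 1.0)
    assign((vc <= 0) & (d1 >= 0) & (d3 <= 0), a + (d1 / vsafe)[:, None] * ab)  # edge AB
    vb = d5 * d2 - d1 * d6
    wsafe = np.where(np.abs(d2 - d6) > 0, d2 - d6, 1.0)
    assign((vb <= 0) & (d2 >= 0) & (d6 <= 0), a + (d2 / wsafe)[:, None] * ac)  # edge AC
    va = d3 * d6 - d5 * d4
    denom_bc = (d4 - d3) + (d5 - d6)
    dsafe = np.where(np.abs(denom_bc) > 0, denom_bc, 1.0)
    assign(
        (va <= 0) & ((d4 - d3) >= 0) & ((d5 - d6) >= 0),
        b + ((d4 - d3) / dsafe)[:, None] * (c - b),
    )  # edge BC
    # interior
    denom = va + vb + vc
    dsafe = np.where(np.abs(denom) > 0, denom, 1.0)
    v = vb / dsafe
    w = vc / dsafe
    assign(np.ones_like(done), a + v[:, None] * ab + w[:, None] * ac)
    return result


def point_to_surface_distance(
    points: np.ndarray, surface: TriSurface, n_candidates: int = 12
) -> np.ndarray:
    """Minimum Euclidean distance from each point to the triangulated surface.

    A KD-tree over face centroids proposes candidate faces; candidates within
    the proven bound (best centroid distance + largest candidate circumradius)
    are checked exactly, so the result equals the exhaustive minimum.
    """
    if surface.n_faces == 0:
        raise ValueError("posterior surface has no faces")
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    va, vb, vc = surface.face_corners()
    centers = surface.face_centers()
    # radius of the smallest centroid-centered ball containing each face
    radii = np.maximum(
        np.linalg.norm(va - centers, axis=1),
        np.maximum(
            np.linalg.norm(vb - centers, axis=1), np.linalg.norm(vc - centers, axis=1)
        ),
    )
    rmax = radii.max()
    tree = cKDTree(centers)
    k = min(n_candidates, surface.n_faces)
    dcent, idx = tree.query(pts, k=k)
    dcent = np.atleast_2d(dcent)
    idx = np.atleast_2d(idx)
    best = np.full(pts.shape[0], np.inf)
    for j in range(k):
        fi = idx[:, j]
        cand = _closest_point_on_triangles(pts, va[fi], vb[fi], vc[fi])
        best = np.minimum(best, np.linalg.norm(pts - cand, axis=1))
    # exactness guard: any face whose centroid ball could beat the bound
    need = dcent[:, -1] < best + rmax if k < surface.n_faces else np.zeros(len(pts), bool)
    for i in np.nonzero(need)[0]:
        extra = tree.query_ball_point(pts[i], best[i] + rmax)
        fi = np.asarray(extra, dtype=int)
        if fi.size:
            p = np.broadcast_to(pts[i], (fi.size, 3))
            cand = _closest_point_on_triangles(p, va[fi], vb[fi], vc[fi])
            best[i] = min(best[i], np.linalg.norm(p - cand, axis=1).min())
    return best


def compute_thickness(pair: LayerSurfacePair) -> np.ndarray:
    """Per-anterior-vertex layer thickness: closest 3D distance to the
    posterior surface (point-to-triangle).  Stored on the anterior surface
    as channel ``thickness_mm`` and returned."""
    if pair.posterior.n_faces == 0 or pair.anterior.n_vertices == 0:
        raise ValueError("both surfaces must be non-empty")
    t = point_to_surface_distance(pair.anterior.vertices, pair.posterior)
    pair.anterior.channels["thickness_mm"] = t
    return t


# -- cropping ----------------------------------------------------------------


def crop_surface(
    surface: TriSurface,
    ellipse: BMOEllipse,
    inner: float = 0.25,
    outer: float = 2.0,
) -> TriSurface:
    """Keep faces whose three vertices all lie in the BMO-distance band
    [inner, outer]; vertices are reindexed and channels carried."""
    if not inner < outer:
        raise ValueError("require inner < outer")
    d = bmo_distance(surface.vertices, ellipse)
    vert_ok = (d >= inner) & (d <= outer)
    face_ok = vert_ok[surface.faces].all(axis=1)
    if not face_ok.any():
        raise ValueError("crop removed every face")
    keep_faces = surface.faces[face_ok]
    used = np.unique(keep_faces)
    remap = np.full(surface.n_vertices, -1, dtype=np.int64)
    remap[used] = np.arange(used.size)
    return TriSurface(
        surface.vertices[used],
        remap[keep_faces],
        {k: v[used] for k, v in surface.channels.items()},
    )


def preprocess_eye(
    pair: LayerSurfacePair,
    bmo_points: np.ndarray,
    laterality: Laterality | str,
    inner: float = 0.25,
    outer: float = 2.0,
) -> tuple[TriSurface, BMOEllipse]:
    """Full per-eye preprocessing: fit the BMO ellipse, move everything into
    the canonical right-eye frame, measure thickness, crop the anterior
    surface to the analysis band.  Returns (cropped anterior with
    ``thickness_mm``, canonical-frame ellipse)."""
    ellipse = fit_bmo_ellipse(bmo_points)
    mat = canonical_transform(ellipse, laterality)
    anterior = pair.anterior.transform(mat)
    posterior = pair.posterior.transform(mat)
    ell_c = transform_ellipse(ellipse, mat)
    canon = LayerSurfacePair(anterior, posterior, pair.layer)
    compute_thickness(canon)
    cropped = crop_surface(anterior, ell_c, inner, outer)
    return cropped, ell_c
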