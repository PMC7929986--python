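"""Meshes, head models, source spaces and the atrophy (shrinkage) transform.

This module provides the geometric substrate for the EEG forward solvers:

* :class:`TriSurface` — a closed, consistently oriented triangle mesh
  representing one tissue boundary (skin, outer skull, inner skull/CSF,
  pial).
* :class:`HeadModel` — four strictly nested boundaries with per-compartment
  conductivities.
* :class:`SphericalModel` — the four-layer concentric-sphere conductor.
* :class:`SourceSpace` — cortical current dipoles (positions + unit
  orientations normal to the source surface).
* :class:`ElectrodeMontage` — scalp electrodes with a neighbour structure.
* :func:`make_synthetic_head` — a seeded generator of smoothly perturbed
  nested surfaces standing in for an MRI-derived segmentation.
* :func:`shrink` — the radial contraction toward the median centroid that
  emulates cortical atrophy (brain shrinkage with CSF expansion).

Length units are millimetres for synthetic heads and dimensionless relative
units for spherical models; all solvers only ever use ratios of lengths, so
the distinction never affects dB results.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Literal, Sequence

import numpy as np
from scipy.spatial import ConvexHull
from scipy.special import sph_harm_y

__all__ = [
    "TriSurface",
    "HeadModel",
    "SphericalModel",
    "SourceSpace",
    "ElectrodeMontage",
    "SyntheticHeadConfig",
    "make_icosphere",
    "make_synthetic_head",
    "median_centroid",
    "shrink",
    "shrink_surface",
    "shrink_source_space",
    "csf_thickness",
    "points_inside",
    "min_distance_to_surface",
    "load_surface",
    "save_surface",
]

# Memory guard for recursive icosphere subdivision (level 7 = 163842 verts).
MAX_ICOSPHERE_LEVEL = 7


# ---------------------------------------------------------------------------
# TriSurface
# ---------------------------------------------------------------------------

@dataclass
class TriSurface:
    """A closed, oriented 2-manifold triangle mesh for one tissue boundary.

    Parameters
    ----------
    vertices : (n_vertices, 3) float array
        Vertex coordinates.
    triangles : (n_triangles, 3) int array
        Vertex index triplets, counter-clockwise seen from outside
        (outward orientation, positive enclosed signed volume).
    """

    vertices: np.ndarray
    triangles: np.ndarray

    def __post_init__(self) -> None:
        self.vertices = np.ascontiguousarray(self.vertices, dtype=np.float64)
        self.triangles = np.ascontiguousarray(self.triangles, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise ValueError("vertices must be an (n, 3) array")
        if self.triangles.ndim != 2 or self.triangles.shape[1] != 3:
            raise ValueError("triangles must be an (m, 3) array")
        if self.triangles.size and (
            self.triangles.min() < 0 or self.triangles.max() >= len(self.vertices)
        ):
            raise ValueError("triangle indices out of range")

    # -- basic derived quantities -------------------------------------------

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_triangles(self) -> int:
        return len(self.triangles)

    def triangle_corners(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        v = self.vertices
        t = self.triangles
        return v[t[:, 0]], v[t[:, 1]], v[t[:, 2]]

    def triangle_normals(self, normalized: bool = True) -> np.ndarray:
        """Outward triangle normals; unnormalized = 2 * area-weighted."""
        p0, p1, p2 = self.triangle_corners()
        n = np.cross(p1 - p0, p2 - p0)
        if normalized:
            n = n / np.linalg.norm(n, axis=1, keepdims=True)
        return n

    def triangle_areas(self) -> np.ndarray:
        return 0.5 * np.linalg.norm(self.triangle_normals(normalized=False), axis=1)

    @property
    def vertex_normals(self) -> np.ndarray:
        """Unit outward vertex normals (area-weighted triangle average)."""
        n = self.triangle_normals(normalized=False)
        vn = np.zeros_like(self.vertices)
        for k in range(3):
            np.add.at(vn, self.triangles[:, k], n)
        return vn / np.linalg.norm(vn, axis=1, keepdims=True)

    def signed_volume(self) -> float:
        """Enclosed volume; positive iff the orientation is outward."""
        p0, p1, p2 = self.triangle_corners()
        return float(np.einsum("ij,ij->i", p0, np.cross(p1, p2)).sum() / 6.0)

    def mean_edge_length(self) -> float:
        p0, p1, p2 = self.triangle_corners()
        e = np.concatenate([p1 - p0, p2 - p1, p0 - p2])
        return float(np.linalg.norm(e, axis=1).mean())

    # -- validation ----------------------------------------------------------

    def validate(self, name: str = "surface") -> None:
        """Raise ``ValueError`` unless closed, 2-manifold, consistently
        outward-oriented and free of degenerate triangles."""
        areas = self.triangle_areas()
        scale = self.mean_edge_length()
        if np.any(areas <= 1e-12 * scale**2):
            raise ValueError(f"{name}: degenerate (zero-area) triangles present")
        # Every directed edge must occur exactly once and its reverse exactly
        # once: closed 2-manifold with consistent orientation.
        t = self.triangles
        edges = np.concatenate([t[:, [0, 1]], t[:, [1, 2]], t[:, [2, 0]]])
        directed = {}
        for a, b in edges:
            key = (int(a), int(b))
            directed[key] = directed.get(key, 0) + 1
        for (a, b), cnt in directed.items():
            if cnt != 1 or directed.get((b, a), 0) != 1:
                raise ValueError(
                    f"{name}: not a closed consistently-oriented 2-manifold "
                    f"(edge {(a, b)} count {cnt})"
                )
        if self.signed_volume() <= 0:
            raise ValueError(f"{name}: orientation is inward (signed volume <= 0)")

    def copy(self) -> "TriSurface":
        return TriSurface(self.vertices.copy(), self.triangles.copy())


# ---------------------------------------------------------------------------
# Winding numbers and point-to-surface distances
# ---------------------------------------------------------------------------

def _solid_angles(points: np.ndarray, surface: TriSurface) -> np.ndarray:
    """Total solid angle subtended by the surface at each point.

    4*pi for points inside a closed outward-oriented surface, 0 outside
    (van Oosterom & Strackee per-triangle formula, summed).
    """
    pts = np.atleast_2d(np.asarray(points, dtype=np.float64))
    p0, p1, p2 = surface.triangle_corners()
    out = np.empty(len(pts))
    chunk = max(1, int(2e6 / max(1, surface.n_triangles)))
    for lo in range(0, len(pts), chunk):
        x = pts[lo : lo + chunk][:, None, :]
        a, b, c = p0 - x, p1 - x, p2 - x
        la = np.linalg.norm(a, axis=-1)
        lb = np.linalg.norm(b, axis=-1)
        lc = np.linalg.norm(c, axis=-1)
        triple = np.einsum("ijk,ijk->ij", a, np.cross(b, c))
        denom = (
            la * lb * lc
            + np.einsum("ijk,ijk->ij", a, b) * lc
            + np.einsum("ijk,ijk->ij", b, c) * la
            + np.einsum("ijk,ijk->ij", a, c) * lb
        )
        out[lo : lo + chunk] = 2.0 * np.arctan2(triple, denom).sum(axis=1)
    return out


def points_inside(surface: TriSurface, points: np.ndarray) -> np.ndarray:
    """Boolean mask of points strictly inside a closed surface
    (generalized winding number > 1/2)."""
    return _solid_angles(points, surface) > 2.0 * np.pi


def min_distance_to_surface(points: np.ndarray, surface: TriSurface) -> np.ndarray:
    """Exact minimum Euclidean distance from each point to the surface.

    True point-to-triangle distances (face, edge and vertex regions), not a
    vertex-to-vertex shortcut.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=np.float64))
    p0, p1, p2 = surface.triangle_corners()
    e1 = p1 - p0
    e2 = p2 - p0
    best = np.full(len(pts), np.inf)
    chunk = max(1, int(2e6 / max(1, surface.n_triangles)))
    for lo in range(0, len(pts), chunk):
        x = pts[lo : lo + chunk]
        d = _point_triangle_dist(x, p0, e1, e2)
        best[lo : lo + chunk] = d.min(axis=1)
    return best


def _point_triangle_dist(x, p0, e1, e2):
    """Distances from points x (n,3) to triangles (m,3 corners p0,p0+e1,p0+e2).

    Projects onto the triangle plane, clamps the barycentric solution to the
    triangle via the three edge segments when outside.
    """
    # Solve min |p0 + u e1 + v e2 - x|^2 over the triangle u,v>=0, u+v<=1.
    a = np.einsum("ij,ij->j", e1.T, e1.T)  # (m,)
    b = np.einsum("ij,ij->j", e1.T, e2.T)
    c = np.einsum("ij,ij->j", e2.T, e2.T)
    w = x[:, None, :] - p0[None, :, :]  # (n, m, 3)
    d = np.einsum("nmk,mk->nm", w, e1)
    e = np.einsum("nmk,mk->nm", w, e2)
    det = a * c - b * b
    u = (c * d - b * e) / det
    v = (a * e - b * d) / det
    # Clamp outside-region solutions to each edge segment and take the best.
    inside = (u >= 0) & (v >= 0) & (u + v <= 1)
    u_in = np.where(inside, u, 0.0)
    v_in = np.where(inside, v, 0.0)
    cand = _seg_dist2(w, d, e, a, b, c, u_in, v_in, inside)
    return np.sqrt(cand)


def _seg_dist2(w, d, e, a, b, c, u_in, v_in, inside):
    # squared distance for the clamped interior solution
    def dist2(u, v):
        # |w - u e1 - v e2|^2 = |w|^2 - 2u d - 2v e + u^2 a + 2uv b + v^2 c
        w2 = np.einsum("nmk,nmk->nm", w, w)
        return w2 - 2 * u * d - 2 * v * e + u * u * a + 2 * u * v * b + v * v * c

    best = np.where(inside, dist2(u_in, v_in), np.inf)
    # edge v=0: u = clamp(d/a)
    u0 = np.clip(d / a, 0.0, 1.0)
    best = np.minimum(best, dist2(u0, np.zeros_like(u0)))
    # edge u=0: v = clamp(e/c)
    v0 = np.clip(e / c, 0.0, 1.0)
    best = np.minimum(best, dist2(np.zeros_like(v0), v0))
    # edge u+v=1: param t along it
    t = np.clip((c - b + d - e) / (a - 2 * b + c), 0.0, 1.0)
    best = np.minimum(best, dist2(t, 1.0 - t))
    return np.maximum(best, 0.0)


# ---------------------------------------------------------------------------
# Head and sphere models
# ---------------------------------------------------------------------------

#: Conductivities (S/m) at the midpoint of published ranges:
#: scalp, skull, CSF, brain.
DEFAULT_CONDUCTIVITIES = (0.3, 0.006, 1.5, 0.3)

#: Relative shell radii, outermost first: skin, outer skull, inner skull
#: (CSF boundary), brain.
DEFAULT_RELATIVE_RADII = (1.0, 0.90, 0.83, 0.78)


@dataclass
class HeadModel:
    """Four strictly nested tissue boundaries with compartment conductivities.

    ``surfaces`` are ordered outermost to innermost: skin, outer skull,
    inner skull (outer CSF boundary), pial.  ``conductivities`` follow the
    same order and name the compartment *inside* each boundary down to the
    next one: scalp, skull, CSF, and brain inside the pial surface
    (cerebellum, if present, is merged into the brain compartment).
    """

    surfaces: Sequence[TriSurface]
    conductivities: Sequence[float]
    units: Literal["relative", "mm"] = "mm"

    SURFACE_NAMES = ("skin", "outer_skull", "inner_skull", "pial")

    def __post_init__(self) -> None:
        self.surfaces = list(self.surfaces)
        self.conductivities = tuple(float(s) for s in self.conductivities)
        if len(self.surfaces) != 4 or len(self.conductivities) != 4:
            raise ValueError("exactly 4 surfaces and 4 conductivities required")
        if any(s <= 0 for s in self.conductivities):
            raise ValueError("all conductivities must be positive")

    @property
    def skin(self) -> TriSurface:
        return self.surfaces[0]

    @property
    def pial(self) -> TriSurface:
        return self.surfaces[3]

    def validate(self, min_gap: float = 0.0) -> None:
        """Check each surface and the strict nesting of the sequence."""
        for surf, name in zip(self.surfaces, self.SURFACE_NAMES):
            surf.validate(name)
        for outer, inner, oname, iname in zip(
            self.surfaces[:-1],
            self.surfaces[1:],
            self.SURFACE_NAMES[:-1],
            self.SURFACE_NAMES[1:],
        ):
            if not points_inside(outer, inner.vertices).all():
                raise ValueError(f"surface {iname!r} is not strictly inside {oname!r}")
            if min_gap > 0:
                gap = min_distance_to_surface(inner.vertices, outer).min()
                if gap < min_gap:
                    raise ValueError(
                        f"gap between {iname!r} and {oname!r} is {gap:.3g}, "
                        f"below the required minimum {min_gap:.3g}"
                    )


@dataclass
class SphericalModel:
    """Four-layer concentric-sphere volume conductor.

    ``radii`` are outer shell radii, outermost first (scalp = 1 in relative
    units); ``conductivities`` in the same order (scalp, skull, CSF, brain).
    Source dipoles sit on a sphere at ``source_radius_fraction`` times the
    brain radius.
    """

    radii: Sequence[float] = DEFAULT_RELATIVE_RADII
    conductivities: Sequence[float] = DEFAULT_CONDUCTIVITIES
    source_radius_fraction: float = 0.99

    def __post_init__(self) -> None:
        self.radii = tuple(float(r) for r in self.radii)
        self.conductivities = tuple(float(s) for s in self.conductivities)
        if len(self.radii) != len(self.conductivities):
            raise ValueError("radii and conductivities must have equal length")
        if any(np.diff(self.radii) >= 0):
            raise ValueError("radii must be strictly decreasing (outermost first)")
        if any(s <= 0 for s in self.conductivities):
            raise ValueError("all conductivities must be positive")
        if not 0.0 < self.source_radius_fraction < 1.0:
            raise ValueError("source_radius_fraction must lie in (0, 1)")

    @property
    def brain_radius(self) -> float:
        return self.radii[-1]

    @property
    def scalp_radius(self) -> float:
        return self.radii[0]

    @property
    def source_radius(self) -> float:
        return self.source_radius_fraction * self.brain_radius

    def scaled(self, factor: float) -> "SphericalModel":
        return replace(self, radii=tuple(r * factor for r in self.radii))

    def with_brain_shrunk(self, s: float) -> "SphericalModel":
        """Shrink the brain shell radius by fraction ``s`` (CSF expands
        inward to fill the vacated space); outer shells unchanged."""
        if not 0.0 <= s < 1.0:
            raise ValueError("shrink fraction must lie in [0, 1)")
        radii = self.radii[:-1] + ((1.0 - s) * self.radii[-1],)
        return replace(self, radii=radii)


@dataclass
class SourceSpace:
    """Current dipoles: positions, unit orientations, common amplitude.

    ``amplitude`` is the dipole moment magnitude q (A*m) shared by all
    simultaneously active dipoles; dB power ratios are independent of it.
    """

    positions: np.ndarray
    orientations: np.ndarray
    amplitude: float = 1e-8

    def __post_init__(self) -> None:
        self.positions = np.ascontiguousarray(self.positions, dtype=np.float64)
        self.orientations = np.ascontiguousarray(self.orientations, dtype=np.float64)
        if self.positions.shape != self.orientations.shape:
            raise ValueError("positions and orientations must have the same shape")
        if self.amplitude <= 0:
            raise ValueError("amplitude must be positive")
        norms = np.linalg.norm(self.orientations, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-8):
            raise ValueError("orientations must be unit vectors")

    def __len__(self) -> int:
        return len(self.positions)


@dataclass
class ElectrodeMontage:
    """Scalp electrodes with symmetric neighbour sets (adjacency)."""

    positions: np.ndarray
    adjacency: list[tuple[int, ...]]

    def __post_init__(self) -> None:
        self.positions = np.ascontiguousarray(self.positions, dtype=np.float64)
        if len(self.adjacency) != len(self.positions):
            raise ValueError("adjacency length must match electrode count")
        for i, nbrs in enumerate(self.adjacency):
            for j in nbrs:
                if i not in self.adjacency[j]:
                    raise ValueError(f"adjacency not symmetric at electrodes {i},{j}")

    def __len__(self) -> int:
        return len(self.positions)

    def neighborhood(self, i: int) -> tuple[int, ...]:
        """The electrode itself plus its neighbours (the local channel set
        used for power averaging)."""
        return (i,) + tuple(self.adjacency[i])


# ---------------------------------------------------------------------------
# Icosphere
# ---------------------------------------------------------------------------

def make_icosphere(subdivision_level: int, radius: float = 1.0) -> TriSurface:
    """Recursively subdivided icosahedron projected onto a sphere.

    Vertex count is ``10 * 4**L + 2`` (level 4 gives the 2562 vertices used
    for the spherical source space).
    """
    if subdivision_level < 0:
        raise ValueError("subdivision_level must be >= 0")
    if subdivision_level > MAX_ICOSPHERE_LEVEL:
        raise ValueError(
            f"subdivision_level {subdivision_level} exceeds cap {MAX_ICOSPHERE_LEVEL}"
        )
    phi = (1.0 + np.sqrt(5.0)) / 2.0
    verts = np.array(
        [
            [-1, phi, 0], [1, phi, 0], [-1, -phi, 0], [1, -phi, 0],
            [0, -1, phi], [0, 1, phi], [0, -1, -phi], [0, 1, -phi],
            [phi, 0, -1], [phi, 0, 1], [-phi, 0, -1], [-phi, 0, 1],
        ],
        dtype=np.float64,
    )
    verts /= np.linalg.norm(verts, axis=1, keepdims=True)
    tris = np.array(
        [
            [0, 11, 5], [0, 5, 1], [0, 1, 7], [0, 7, 10], [0, 10, 11],
            [1, 5, 9], [5, 11, 4], [11, 10, 2], [10, 7, 6], [7, 1, 8],
            [3, 9, 4], [3, 4, 2], [3, 2, 6], [3, 6, 8], [3, 8, 9],
            [4, 9, 5], [2, 4, 11], [6, 2, 10], [8, 6, 7], [9, 8, 1],
        ],
        dtype=np.int64,
    )
    verts_list = [v for v in verts]
    for _ in range(subdivision_level):
        cache: dict[tuple[int, int], int] = {}

        def midpoint(i: int, j: int) -> int:
            key = (i, j) if i < j else (j, i)
            if key in cache:
                return cache[key]
            m = verts_list[i] + verts_list[j]
            m /= np.linalg.norm(m)
            verts_list.append(m)
            cache[key] = len(verts_list) - 1
            return cache[key]

        new_tris = np.empty((4 * len(tris), 3), dtype=np.int64)
        for k, (a, b, c) in enumerate(tris):
            ab = midpoint(a, b)
            bc = midpoint(b, c)
            ca = midpoint(c, a)
            new_tris[4 * k : 4 * k + 4] = [
                [a, ab, ca], [b, bc, ab], [c, ca, bc], [ab, bc, ca],
            ]
        tris = new_tris
    vertices = np.asarray(verts_list) * radius
    return TriSurface(vertices, tris)


# ---------------------------------------------------------------------------
# Median centroid and shrinkage
# ---------------------------------------------------------------------------

def median_centroid(
    positions: np.ndarray,
    method: Literal["coordinate", "mean", "geometric"] = "coordinate",
) -> np.ndarray:
    """Robust centre of a dipole cloud, the fixed point of the shrinkage map.

    ``coordinate`` (default) is the coordinate-wise median; ``mean`` the
    arithmetic mean; ``geometric`` the geometric median (Weiszfeld
    iteration).  For the symmetric spherical source spaces all three
    coincide with the sphere centre.
    """
    pts = np.atleast_2d(np.asarray(positions, dtype=np.float64))
    if pts.size == 0:
        raise ValueError("median_centroid of an empty point set")
    if method == "coordinate":
        return np.median(pts, axis=0)
    if method == "mean":
        return pts.mean(axis=0)
    if method == "geometric":
        c = pts.mean(axis=0)
        for _ in range(200):
            d = np.linalg.norm(pts - c, axis=1)
            if np.any(d < 1e-12):
                return c
            w = 1.0 / d
            c_new = (pts * w[:, None]).sum(axis=0) / w.sum()
            if np.linalg.norm(c_new - c) < 1e-12 * (1.0 + np.linalg.norm(c)):
                return c_new
            c = c_new
        return c
    raise ValueError(f"unknown centroid method {method!r}")


def shrink(points: np.ndarray, center: np.ndarray, s: float) -> np.ndarray:
    """Contract points toward ``center`` by fraction ``s``:
    ``p -> center + (1 - s) * (p - center)``.

    Models whole-brain atrophy; point count is preserved and (for a source
    space) orientations are left untouched.
    """
    if not 0.0 <= s < 1.0:
        raise ValueError("shrink fraction must lie in [0, 1)")
    pts = np.asarray(points, dtype=np.float64)
    center = np.asarray(center, dtype=np.float64)
    return center + (1.0 - s) * (pts - center)


def shrink_surface(surface: TriSurface, center: np.ndarray, s: float) -> TriSurface:
    """Shrink all surface vertices toward ``center``; connectivity kept."""
    return TriSurface(shrink(surface.vertices, center, s), surface.triangles.copy())


def shrink_source_space(
    sources: SourceSpace, center: np.ndarray, s: float
) -> SourceSpace:
    """Shrink dipole positions; orientations are kept unchanged."""
    return SourceSpace(
        shrink(sources.positions, center, s),
        sources.orientations.copy(),
        sources.amplitude,
    )


# ---------------------------------------------------------------------------
# CSF thickness
# ---------------------------------------------------------------------------

def csf_thickness(
    csf_surface: TriSurface, inner_surfaces: TriSurface | Iterable[TriSurface]
) -> float:
    """Mean nodal projection distance from the CSF boundary to the brain.

    Averages, over the vertices of the inner-skull (outer CSF) surface, the
    exact distance to the nearest point on the union of the inner surfaces
    (pial, and cerebellum where modelled separately).
    """
    if isinstance(inner_surfaces, TriSurface):
        inner_surfaces = [inner_surfaces]
    inner_surfaces = list(inner_surfaces)
    if not inner_surfaces:
        raise ValueError("at least one inner surface required")
    for surf in inner_surfaces:
        if not points_inside(csf_surface, surf.vertices).all():
            raise ValueError("inner surface pokes through the CSF boundary")
    d = np.min(
        [min_distance_to_surface(csf_surface.vertices, s) for s in inner_surfaces],
        axis=0,
    )
    return float(d.mean())


# ---------------------------------------------------------------------------
# Synthetic head generator
# ---------------------------------------------------------------------------

@dataclass
class SyntheticHeadConfig:
    """Parameters of the synthetic (MRI-free) head generator.

    The four base radii (mm, outermost first) default to a 100 mm scalp
    sphere with the same relative proportions as the spherical conductor
    (0.90 / 0.83 / 0.78), giving a baseline CSF layer of 5 mm.  A single
    smooth radial perturbation field — real spherical harmonics up to
    ``harmonic_degree_max`` with seeded Gaussian coefficients, scaled so its
    maximum equals 1 — is shared by all four surfaces so that they stay
    near-parallel, and is applied as a per-surface radial factor
    ``1 + perturb_amplitude * f(direction)``.
    """

    base_radii: tuple[float, float, float, float] = (100.0, 90.0, 83.0, 78.0)
    perturb_amplitude: float = 0.03
    harmonic_degree_max: int = 4
    #: icosphere subdivision level, one int for all four boundaries or a
    #: tuple (skin, outer_skull, inner_skull, pial)
    subdivision: int | tuple[int, int, int, int] = 3
    source_subdivision: int = 4
    source_radius_fraction: float = 0.93
    n_electrodes: int = 128
    min_gap: float = 1.0
    dipole_amplitude: float = 1e-8
    seed: int = 0

    def __post_init__(self) -> None:
        if any(np.diff(self.base_radii) >= 0):
            raise ValueError("base radii must be strictly decreasing")
        if self.perturb_amplitude < 0:
            raise ValueError("perturbation amplitude must be >= 0")
        if not 0.0 < self.source_radius_fraction < 1.0:
            raise ValueError("source_radius_fraction must lie in (0, 1)")


def _draw_harmonic_coeffs(
    degree_max: int, rng: np.random.Generator
) -> list[tuple[int, int, float]]:
    """Seeded N(0,1) coefficients for real spherical harmonics of degrees
    1..degree_max; (ell, m, coeff) with m<0 denoting the sine branch."""
    coeffs = []
    for ell in range(1, degree_max + 1):
        for m in range(0, ell + 1):
            coeffs.append((ell, m, float(rng.standard_normal())))
            if m > 0:
                coeffs.append((ell, -m, float(rng.standard_normal())))
    return coeffs


def _eval_harmonic_field(
    directions: np.ndarray, coeffs: list[tuple[int, int, float]]
) -> np.ndarray:
    """Evaluate the real-spherical-harmonic sum at unit directions."""
    x, y, z = directions.T
    theta = np.arccos(np.clip(z, -1.0, 1.0))
    phi = np.arctan2(y, x)
    f = np.zeros(len(directions))
    for ell, m, c in coeffs:
        ylm = sph_harm_y(ell, abs(m), theta, phi)
        if m == 0:
            f += c * ylm.real
        elif m > 0:
            f += c * np.sqrt(2.0) * (-1.0) ** m * ylm.real
        else:
            f += c * np.sqrt(2.0) * (-1.0) ** (-m) * ylm.imag
    return f


def _ray_mesh_radial_hit(surface: TriSurface, directions: np.ndarray):
    """Intersect rays from the origin along ``directions`` with a star-shaped
    mesh (Moller-Trumbore, vectorized).  Returns (points, tri_idx, bary)."""
    p0, p1, p2 = surface.triangle_corners()
    e1 = p1 - p0
    e2 = p2 - p0
    n_pts = len(directions)
    pts = np.empty((n_pts, 3))
    tri_idx = np.empty(n_pts, dtype=np.int64)
    bary = np.empty((n_pts, 3))
    for i, d in enumerate(directions):
        h = np.cross(np.broadcast_to(d, e2.shape), e2)
        a = np.einsum("ij,ij->i", e1, h)
        ok = np.abs(a) > 1e-14
        f = np.where(ok, 1.0 / np.where(ok, a, 1.0), 0.0)
        s = -p0
        u = f * np.einsum("ij,ij->i", s, h)
        q = np.cross(s, e1)
        v = f * (q @ d)
        t = f * np.einsum("ij,ij->i", q, e2)
        eps = 1e-10
        hit = ok & (u >= -eps) & (v >= -eps) & (u + v <= 1 + eps) & (t > 0)
        if not hit.any():
            raise ValueError("radial ray misses the surface (mesh not star-shaped?)")
        cand = np.where(hit, t, np.inf)
        k = int(np.argmin(cand))
        tri_idx[i] = k
        pts[i] = cand[k] * d
        bary[i] = (1.0 - u[k] - v[k], u[k], v[k])
    return pts, tri_idx, bary


def _fibonacci_directions(n: int) -> np.ndarray:
    """Near-uniform unit directions (golden-spiral lattice)."""
    i = np.arange(n) + 0.5
    z = 1.0 - 2.0 * i / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    golden = np.pi * (3.0 - np.sqrt(5.0))
    phi = golden * np.arange(n)
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def _montage_adjacency(
    directions: np.ndarray, positions: np.ndarray, n_min: int = 4, n_max: int = 7
) -> list[tuple[int, ...]]:
    """Neighbour sets from the convex-hull triangulation of the electrode
    directions, clamped to [n_min, n_max] neighbours by distance rank."""
    hull = ConvexHull(directions)
    nbrs: list[set[int]] = [set() for _ in range(len(directions))]
    for a, b, c in hull.simplices:
        nbrs[a].update((b, c))
        nbrs[b].update((a, c))
        nbrs[c].update((a, b))
    dist = np.linalg.norm(positions[:, None, :] - positions[None, :, :], axis=-1)

    # Trim over-connected electrodes (drop farthest first, symmetrically,
    # never pushing the other end below n_min).
    changed = True
    while changed:
        changed = False
        for i in range(len(nbrs)):
            while len(nbrs[i]) > n_max:
                order = sorted(nbrs[i], key=lambda j: (-dist[i, j], j))
                for j in order:
                    if len(nbrs[j]) > n_min:
                        nbrs[i].discard(j)
                        nbrs[j].discard(i)
                        changed = True
                        break
                else:  # all neighbours at the floor; drop farthest anyway
                    j = order[0]
                    nbrs[i].discard(j)
                    nbrs[j].discard(i)
                    changed = True
    # Top up under-connected electrodes with nearest non-neighbours.
    for i in range(len(nbrs)):
        if len(nbrs[i]) < n_min:
            order = np.argsort(dist[i])
            for j in order:
                j = int(j)
                if j == i or j in nbrs[i] or len(nbrs[j]) >= n_max:
                    continue
                nbrs[i].add(j)
                nbrs[j].add(i)
                if len(nbrs[i]) >= n_min:
                    break
    return [tuple(sorted(s)) for s in nbrs]


def make_synthetic_head(
    config: SyntheticHeadConfig,
) -> tuple[HeadModel, SourceSpace, ElectrodeMontage]:
    """Generate a perturbed four-layer head, cortical source space and
    128-channel scalp montage; fully deterministic given ``config.seed``.

    Raises ``ValueError`` if the perturbation breaks nesting or the minimum
    inter-surface gap.
    """
    rng = np.random.default_rng(config.seed)
    coeffs = _draw_harmonic_coeffs(config.harmonic_degree_max, rng)
    # normalization reference: peak |f| over a fine fixed direction set, so
    # per-surface meshes of different resolution share one shape field
    ref_dirs = make_icosphere(4, 1.0).vertices
    peak = np.abs(_eval_harmonic_field(ref_dirs, coeffs)).max()
    peak = peak if peak > 0 else 1.0

    subs = config.subdivision
    if isinstance(subs, int):
        subs = (subs,) * 4
    surfaces = []
    for level, r in zip(subs, config.base_radii):
        base = make_icosphere(level, 1.0)
        f = _eval_harmonic_field(base.vertices, coeffs) / peak
        factor = 1.0 + config.perturb_amplitude * f
        surfaces.append(
            TriSurface(base.vertices * (r * factor)[:, None], base.triangles.copy())
        )
    head = HeadModel(surfaces, DEFAULT_CONDUCTIVITIES, units="mm")
    try:
        head.validate(min_gap=config.min_gap)
    except ValueError as err:
        raise ValueError(f"synthetic head generation failed: {err}") from err

    # Source surface: pial radius field sampled on a (finer) direction set,
    # scaled radially inward; orientations normal to that surface.
    src_base = make_icosphere(config.source_subdivision, 1.0)
    src_dirs = src_base.vertices
    f_src = _eval_harmonic_field(src_dirs, coeffs) / peak
    r_pial = config.base_radii[3] * (1.0 + config.perturb_amplitude * f_src)
    src_surface = TriSurface(
        src_dirs * (config.source_radius_fraction * r_pial)[:, None],
        src_base.triangles.copy(),
    )
    sources = SourceSpace(
        src_surface.vertices,
        src_surface.vertex_normals,
        amplitude=config.dipole_amplitude,
    )

    elec_dirs = _fibonacci_directions(config.n_electrodes)
    elec_pos, _, _ = _ray_mesh_radial_hit(surfaces[0], elec_dirs)
    adjacency = _montage_adjacency(elec_dirs, elec_pos)
    montage = ElectrodeMontage(elec_pos, adjacency)
    return head, sources, montage


# ---------------------------------------------------------------------------
# Mesh I/O (OFF and STL)
# ---------------------------------------------------------------------------

def save_surface(surface: TriSurface, path: str, file_format: str | None = None) -> None:
    """Write a surface to OFF (preserves vertex order round-trip) or STL
    (binary by default, ``file_format='stl_ascii'`` for text; STL stores a
    triangle soup, so only geometry — not vertex indexing — round-trips)."""
    fmt = file_format or _guess_format(path)
    if fmt == "off":
        with open(path, "w") as fh:
            fh.write("OFF\n")
            fh.write(f"{surface.n_vertices} {surface.n_triangles} 0\n")
            for v in surface.vertices:
                fh.write(f"{v[0]:.17g} {v[1]:.17g} {v[2]:.17g}\n")
            for t in surface.triangles:
                fh.write(f"3 {t[0]} {t[1]} {t[2]}\n")
        return
    if fmt in ("stl", "stl_ascii"):
        import trimesh

        mesh = trimesh.Trimesh(
            vertices=surface.vertices, faces=surface.triangles, process=False
        )
        data = trimesh.exchange.stl.export_stl_ascii(mesh) if fmt == "stl_ascii" \
            else trimesh.exchange.stl.export_stl(mesh)
        mode = "w" if isinstance(data, str) else "wb"
        with open(path, mode) as fh:
            fh.write(data)
        return
    raise ValueError(f"unsupported mesh format {fmt!r}")


def load_surface(path: str, file_format: str | None = None) -> TriSurface:
    """Read a surface from OFF or STL (both ASCII and binary)."""
    fmt = file_format or _guess_format(path)
    if fmt == "off":
        with open(path) as fh:
            tokens = fh.read().split()
        if tokens[0] != "OFF":
            raise ValueError(f"{path}: not an OFF file")
        nv, nt = int(tokens[1]), int(tokens[2])
        head = 4
        verts = np.array(tokens[head : head + 3 * nv], dtype=np.float64).reshape(nv, 3)
        pos = head + 3 * nv
        tris = np.empty((nt, 3), dtype=np.int64)
        for i in range(nt):
            cnt = int(tokens[pos])
            if cnt != 3:
                raise ValueError(f"{path}: non-triangular face in OFF file")
            tris[i] = [int(tokens[pos + 1]), int(tokens[pos + 2]), int(tokens[pos + 3])]
            pos += 4
        return TriSurface(verts, tris)
    if fmt in ("stl", "stl_ascii"):
        import trimesh

        mesh = trimesh.load(path, file_type="stl", process=False)
        # STL is a triangle soup: merge exactly coincident vertices, keeping
        # first-occurrence order so repeated save/load cycles are stable.
        mesh.merge_vertices(merge_tex=True, merge_norm=True, digits_vertex=10)
        return TriSurface(np.asarray(mesh.vertices), np.asarray(mesh.faces))
    raise ValueError(f"unsupported mesh format {fmt!r}")


def _guess_format(path: str) -> str:
    lower = str(path).lower()
    if lower.endswith(".off"):
        return "off"
    if lower.endswith(".stl"):
        return "stl"
    raise ValueError(f"cannot infer mesh format from {path!r}")
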