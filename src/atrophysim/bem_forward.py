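"""Four-compartment EEG forward solver: linear-collocation BEM with
deflation and the isolated source approach (ISA).

The potential on the tissue boundaries of a piecewise homogeneous conductor
satisfies the Geselowitz surface integral equation

    (sigma_i^- + sigma_i^+)/2 V(x) =
        sigma_src V_inf(x) - sum_j (sigma_j^- - sigma_j^+) (B_j V)(x)

with the double-layer operator
``(B_j v)(x) = 1/(4 pi) int_{S_j} v(y) (x - y).n(y) / |x - y|^3 dS(y)``.
It is discretized with potentials linear over triangles and collocation at
vertices; the element integrals (solid angle of a linear shape function over
a plane triangle) are evaluated with the standard analytic formulas (signed
solid angle plus edge line integrals), not quadrature.  The arbitrary
additive constant is fixed by deflation (a rank-one shift acting on the
outermost surface), and the low-conductivity skull is handled with the
isolated source approach using the inner-skull surface as isolation
boundary: the sub-problem consisting of the pial and inner-skull surfaces
with zero outside conductivity is solved first, and its solution replaces
the primary source term of the full problem, which removes the numerical
cancellation otherwise caused by the ~1:250 skull conductivity step.

The solver is validated against the analytic multilayer-sphere series on
meshed concentric spheres (RDM / MAG criteria; see ``rdm``, ``mag`` and
``validate_against_sphere``).
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .geometry import (
    ElectrodeMontage,
    HeadModel,
    SourceSpace,
    TriSurface,
    _ray_mesh_radial_hit,
    min_distance_to_surface,
    points_inside,
)
from .sphere_forward import GainMatrix

__all__ = [
    "BemOptions",
    "BemOperator",
    "assemble_bem",
    "bem_gain",
    "rdm",
    "mag",
    "validate_against_sphere",
    "double_layer_matrix",
]


@dataclass
class BemOptions:
    """Numerical options of the BEM solver.

    ``near_warn_factor`` / ``near_refuse_factor`` define the near-surface
    source guard in units of the pial mesh's mean edge length: closer than
    the first triggers a warning (collocation accuracy degrades), closer
    than the second is refused outright.
    """

    use_isa: bool = True
    max_vertices: int = 12000
    near_warn_factor: float = 0.5
    near_refuse_factor: float = 0.15


# ---------------------------------------------------------------------------
# Analytic linear-collocation element integrals
# ---------------------------------------------------------------------------

def double_layer_matrix(
    obs_points: np.ndarray,
    surface: TriSurface,
    self_vertex_indices: np.ndarray | None = None,
    chunk: int = 256,
) -> np.ndarray:
    """Collocation matrix W of the double-layer operator of one surface:
    ``(B v)(x_i) = (W @ v)_i`` for vertex potentials ``v``.

    For each plane triangle with outward unit normal ``n`` and linear shape
    function ``zeta_l(y) = a_l + b_l . y`` (origin at the observation
    point), the element integral is

        int_T zeta_l (x-y).n/|x-y|^3 dS = -(a_l * Omega + d * b_l . J)

    with ``d`` the signed plane distance, ``Omega`` the signed solid angle
    (van Oosterom & Strackee) and ``J = n Omega - sum_e m_e I_e`` built from
    analytic edge line integrals ``I_e = int_e dl/|y|``.

    ``self_vertex_indices[i]`` (optional) is the index of observation point
    ``i`` within the surface's own vertex array (or -1 for points not on
    this surface); triangles containing that vertex contribute a vanishing
    principal value on the flat elements and are skipped, and the curvature
    deficit is restored on the diagonal by the row-sum ("auto element")
    correction: on a smooth closed surface ``B(1) = -1/2`` exactly, so the
    missing near-vertex contribution is ``-1/2 - sum(row)``.
    """
    obs = np.atleast_2d(np.asarray(obs_points, dtype=np.float64))
    p = [c.copy() for c in surface.triangle_corners()]  # 3 x (T, 3)
    tris = surface.triangles
    n_hat = surface.triangle_normals()
    # Shape-function data (origin-independent parts).  For local vertex l,
    # the opposite edge runs from p_m to p_k ((l, m, k) cyclic).
    h = []
    denom = []
    for l in range(3):
        m, k = (l + 1) % 3, (l + 2) % 3
        h_l = np.cross(n_hat, p[k] - p[m])
        denom_l = np.einsum("ij,ij->i", p[l] - p[m], h_l)
        h.append(h_l)
        denom.append(denom_l)
    # In-plane outward edge normals, edges (0->1, 1->2, 2->0).
    edge_pairs = [(0, 1), (1, 2), (2, 0)]
    e_hat = []
    m_out = []
    for a_i, b_i in edge_pairs:
        ev = p[b_i] - p[a_i]
        ev = ev / np.linalg.norm(ev, axis=1, keepdims=True)
        e_hat.append(ev)
        m_out.append(np.cross(ev, n_hat))

    W = np.zeros((len(obs), surface.n_vertices))
    tiny = 1e-300
    for lo in range(0, len(obs), chunk):
        x = obs[lo : lo + chunk]  # (c, 3)
        c = len(x)
        y = [pp[None, :, :] - x[:, None, :] for pp in p]  # corner coords rel. x
        ly = [np.linalg.norm(yy, axis=-1) for yy in y]
        # signed solid angle
        triple = np.einsum("ctk,ctk->ct", y[0], np.cross(y[1], y[2]))
        den = (
            ly[0] * ly[1] * ly[2]
            + np.einsum("ctk,ctk->ct", y[0], y[1]) * ly[2]
            + np.einsum("ctk,ctk->ct", y[1], y[2]) * ly[0]
            + np.einsum("ctk,ctk->ct", y[0], y[2]) * ly[1]
        )
        omega = 2.0 * np.arctan2(triple, den)  # (c, T)
        d = np.einsum("ctk,tk->ct", y[0], n_hat)  # plane distance
        # edge line integrals and J
        J = n_hat[None, :, :] * omega[..., None]
        for (a_i, b_i), ev, mv in zip(edge_pairs, e_hat, m_out):
            u, w_ = y[a_i], y[b_i]
            num = np.einsum("ctk,tk->ct", w_, ev) + ly[b_i]
            dnm = np.einsum("ctk,tk->ct", u, ev) + ly[a_i]
            I_e = np.log(np.maximum(num, tiny) / np.maximum(dnm, tiny))
            J = J - mv[None, :, :] * I_e[..., None]
        # mask self-triangles (observation point is one of the corners)
        if self_vertex_indices is not None:
            idx = self_vertex_indices[lo : lo + chunk]
            self_mask = (tris[None, :, :] == idx[:, None, None]).any(axis=2)
        else:
            self_mask = None
        for l in range(3):
            a_l = (
                np.einsum("ctk,tk->ct", -y[(l + 1) % 3], h[l]) / denom[l][None, :]
            )
            # -y[m] = x - p_m  relative shift for the affine coefficient
            bJ = np.einsum("ctk,tk->ct", J, h[l]) / denom[l][None, :]
            val = -(a_l * omega + d * bJ)
            if self_mask is not None:
                val = np.where(self_mask, 0.0, val)
            np.add.at(
                W[lo : lo + chunk],
                (np.arange(c)[:, None], tris[None, :, l]),
                val,
            )
    W /= 4.0 * np.pi
    if self_vertex_indices is not None:
        rows = np.flatnonzero(self_vertex_indices >= 0)
        cols = self_vertex_indices[rows]
        W[rows, cols] += -0.5 - W[rows].sum(axis=1)
    return W


# ---------------------------------------------------------------------------
# Operator assembly
# ---------------------------------------------------------------------------

@dataclass
class BemOperator:
    """Assembled, deflated and inverted boundary system for one head."""

    head: HeadModel
    options: BemOptions
    offsets: np.ndarray  # vertex-block offsets per surface (len 5)
    a_inv: np.ndarray  # inverse of the deflated full system
    iso_inv: np.ndarray | None  # inverse of the deflated isolated system
    w_isolation: np.ndarray | None  # raw double-layer of the inner-skull
    provenance: dict = field(default_factory=dict)

    @property
    def n_vertices(self) -> int:
        return int(self.offsets[-1])

    def block(self, i: int) -> slice:
        return slice(int(self.offsets[i]), int(self.offsets[i + 1]))


def _sigma_in_out(head: HeadModel) -> tuple[np.ndarray, np.ndarray]:
    """Conductivity just inside / outside each boundary, outermost first."""
    cond = np.asarray(head.conductivities)
    sig_in = cond
    sig_out = np.concatenate([[0.0], cond[:-1]])
    return sig_in, sig_out


def _mesh_hash(head: HeadModel) -> str:
    hsh = hashlib.sha256()
    for surf in head.surfaces:
        hsh.update(np.ascontiguousarray(surf.vertices).tobytes())
        hsh.update(np.ascontiguousarray(surf.triangles).tobytes())
    hsh.update(np.asarray(head.conductivities).tobytes())
    return hsh.hexdigest()


def assemble_bem(head: HeadModel, options: BemOptions | None = None) -> BemOperator:
    """Assemble, deflate and factorize the linear-collocation BEM system.

    Validates the head model (closed, outward-oriented, strictly nested
    meshes), builds the blocked double-layer matrix, applies deflation on
    the skin surface and, when ``options.use_isa`` (default), prepares the
    isolated-source sub-system (pial + inner skull with zero outside
    conductivity) whose solution supplies the modified source term.
    """
    options = options or BemOptions()
    head.validate()
    counts = [s.n_vertices for s in head.surfaces]
    n_total = int(np.sum(counts))
    if n_total > options.max_vertices:
        raise ValueError(
            f"total vertex count {n_total} exceeds the dense-solver cap "
            f"{options.max_vertices}"
        )
    offsets = np.concatenate([[0], np.cumsum(counts)])
    sig_in, sig_out = _sigma_in_out(head)
    sig_sum = sig_in + sig_out

    all_obs = np.concatenate([s.vertices for s in head.surfaces])
    # Raw double-layer blocks of each surface evaluated at all vertices.
    W_cols = []
    for j, surf in enumerate(head.surfaces):
        self_idx = np.full(n_total, -1, dtype=np.int64)
        self_idx[offsets[j] : offsets[j + 1]] = np.arange(counts[j])
        W_cols.append(double_layer_matrix(all_obs, surf, self_idx))

    # Full system (I + C) with C_ij = 2 (sig_j^- - sig_j^+)/(sig_i^- + sig_i^+) W_ij
    A = np.eye(n_total)
    for j in range(4):
        contrast = sig_in[j] - sig_out[j]
        for i in range(4):
            gi = 2.0 * contrast / sig_sum[i]
            A[offsets[i] : offsets[i + 1], offsets[j] : offsets[j + 1]] += (
                gi * W_cols[j][offsets[i] : offsets[i + 1]]
            )
    # Deflation on the outermost (skin) surface.
    n_skin = counts[0]
    A[:, offsets[0] : offsets[1]] += 1.0 / n_skin
    a_inv = np.linalg.inv(A)

    iso_inv = None
    w_isolation = None
    if options.use_isa:
        # Isolated sub-model: surfaces [inner_skull, pial] with CSF inside
        # the inner skull, brain inside the pial, vacuum outside.
        sigma_csf, sigma_brain = head.conductivities[2], head.conductivities[3]
        iso_counts = [counts[2], counts[3]]
        iso_off = np.concatenate([[0], np.cumsum(iso_counts)])
        iso_sum = np.array([sigma_csf + 0.0, sigma_brain + sigma_csf])
        iso_contrast = np.array([sigma_csf - 0.0, sigma_brain - sigma_csf])
        iso_obs = np.concatenate([head.surfaces[2].vertices, head.surfaces[3].vertices])
        A_iso = np.eye(int(iso_off[-1]))
        for j, surf_j in enumerate((head.surfaces[2], head.surfaces[3])):
            self_idx = np.full(int(iso_off[-1]), -1, dtype=np.int64)
            self_idx[iso_off[j] : iso_off[j + 1]] = np.arange(iso_counts[j])
            Wj = double_layer_matrix(iso_obs, surf_j, self_idx)
            for i in range(2):
                gi = 2.0 * iso_contrast[j] / iso_sum[i]
                A_iso[iso_off[i] : iso_off[i + 1], iso_off[j] : iso_off[j + 1]] += (
                    gi * Wj[iso_off[i] : iso_off[i + 1]]
                )
        # Deflate on the isolated model's outermost surface (inner skull).
        A_iso[:, iso_off[0] : iso_off[1]] += 1.0 / iso_counts[0]
        iso_inv = np.linalg.inv(A_iso)
        w_isolation = W_cols[2]  # raw double layer of the isolation surface

    return BemOperator(
        head=head,
        options=options,
        offsets=offsets,
        a_inv=a_inv,
        iso_inv=iso_inv,
        w_isolation=w_isolation,
        provenance={"mesh_sha256": _mesh_hash(head), "use_isa": options.use_isa},
    )


# ---------------------------------------------------------------------------
# Gains
# ---------------------------------------------------------------------------

def _dipole_potential_inf(
    points: np.ndarray, positions: np.ndarray, orientations: np.ndarray, sigma: float
) -> np.ndarray:
    """Infinite-medium potentials (n_points, n_dipoles) per unit moment."""
    d = points[:, None, :] - positions[None, :, :]
    r3 = np.linalg.norm(d, axis=-1) ** 3
    return np.einsum("pdk,dk->pd", d, orientations) / (4.0 * np.pi * sigma * r3)


def bem_gain(
    op: BemOperator,
    sources: SourceSpace,
    montage: ElectrodeMontage | np.ndarray,
    reference: Literal["infinite", "average"] = "average",
) -> GainMatrix:
    """Lead-field matrix on a BEM head model (V per A*m).

    Infinite-medium dipole potentials at the collocation vertices form the
    right-hand side (replaced by the isolated-source term when ISA is on);
    solved skin potentials are interpolated to the electrodes
    barycentrically within the containing skin triangle, and the rows are
    deflated to the average reference by default.
    """
    head = op.head
    sig_in, sig_out = _sigma_in_out(head)
    sig_sum = sig_in + sig_out
    sigma_brain = head.conductivities[3]
    sigma_skull = head.conductivities[1]
    pial = head.surfaces[3]

    if not points_inside(pial, sources.positions).all():
        raise ValueError("source dipole(s) outside the pial surface")
    dist = min_distance_to_surface(sources.positions, pial)
    edge = pial.mean_edge_length()
    if np.any(dist < op.options.near_refuse_factor * edge):
        raise ValueError(
            "source dipole(s) closer than "
            f"{op.options.near_refuse_factor} mean edge lengths to the pial "
            "surface; collocation accuracy would collapse"
        )
    if np.any(dist < op.options.near_warn_factor * edge):
        warnings.warn(
            "source dipole(s) within half a mean edge length of the pial "
            "surface: near-singular integrals, accuracy degraded",
            RuntimeWarning,
            stacklevel=2,
        )

    offsets = op.offsets
    if op.options.use_isa:
        # Isolated sub-problem on [inner_skull, pial].
        iso_obs = np.concatenate(
            [head.surfaces[2].vertices, head.surfaces[3].vertices]
        )
        sigma_csf = head.conductivities[2]
        iso_sum = np.array([sigma_csf, sigma_brain + sigma_csf])
        v0_iso = _dipole_potential_inf(
            iso_obs, sources.positions, sources.orientations, sigma_brain
        )
        n_isk = head.surfaces[2].n_vertices
        b_iso = np.empty_like(v0_iso)
        b_iso[:n_isk] = (2.0 * sigma_brain / iso_sum[0]) * v0_iso[:n_isk]
        b_iso[n_isk:] = (2.0 * sigma_brain / iso_sum[1]) * v0_iso[n_isk:]
        v_iso = op.iso_inv @ b_iso
        v_iso_isk = v_iso[:n_isk]  # isolated potential on the inner skull
        # Modified source term of the full problem:
        # rhs_i = 2 sigma_skull/(sig_i^- + sig_i^+) *
        #         [ (B_isk v_iso)(x) - 1/2 v_iso(x) delta_{i,isk} ]
        rhs = op.w_isolation @ v_iso_isk
        rhs[offsets[2] : offsets[3]] -= 0.5 * v_iso_isk
        rhs *= (2.0 * sigma_skull / sig_sum)[
            np.searchsorted(offsets[1:], np.arange(op.n_vertices), side="right")
        ][:, None]
        sol = op.a_inv @ rhs
    else:
        all_obs = np.concatenate([s.vertices for s in head.surfaces])
        v0 = _dipole_potential_inf(
            all_obs, sources.positions, sources.orientations, sigma_brain
        )
        scale = (2.0 * sigma_brain / sig_sum)[
            np.searchsorted(offsets[1:], np.arange(op.n_vertices), side="right")
        ]
        sol = op.a_inv @ (scale[:, None] * v0)

    v_skin = sol[offsets[0] : offsets[1]]

    elec = montage.positions if isinstance(montage, ElectrodeMontage) else np.atleast_2d(montage)
    M = _electrode_interpolator(head.surfaces[0], elec)
    vals = M @ v_skin
    gain = GainMatrix(vals, "infinite")
    if reference == "average":
        gain = gain.average_referenced()
    return gain


def _electrode_interpolator(skin: TriSurface, electrodes: np.ndarray) -> np.ndarray:
    """Barycentric interpolation matrix (n_electrodes, n_skin_vertices).

    Electrodes are projected radially (from the surface centroid) onto the
    skin mesh; the projection distance is available via
    ``min_distance_to_surface`` for diagnostics.
    """
    center = skin.vertices.mean(axis=0)
    rel = electrodes - center
    dirs = rel / np.linalg.norm(rel, axis=1, keepdims=True)
    shifted = TriSurface(skin.vertices - center, skin.triangles)
    _, tri_idx, bary = _ray_mesh_radial_hit(shifted, dirs)
    M = np.zeros((len(electrodes), skin.n_vertices))
    for i, (t, w) in enumerate(zip(tri_idx, bary)):
        M[i, skin.triangles[t]] = w
    return M


# ---------------------------------------------------------------------------
# Forward-solution error metrics and sphere-oracle validation
# ---------------------------------------------------------------------------

def rdm(test: np.ndarray, ref: np.ndarray) -> float:
    """Relative difference measure between two potential vectors
    (norm of the difference of the unit-normalized vectors; 0 = identical
    topography, 2 = opposite)."""
    a = np.asarray(test).ravel()
    b = np.asarray(ref).ravel()
    return float(np.linalg.norm(a / np.linalg.norm(a) - b / np.linalg.norm(b)))


def mag(test: np.ndarray, ref: np.ndarray) -> float:
    """Magnitude ratio ||test|| / ||ref|| (1 = equal overall strength)."""
    return float(np.linalg.norm(test) / np.linalg.norm(ref))


def validate_against_sphere(
    subdivision: int | tuple[int, int, int, int] = 3,
    eccentricities: tuple[float, ...] = (0.3, 0.5, 0.7, 0.8),
    radii: tuple[float, ...] = (1.0, 0.90, 0.83, 0.78),
    conductivities: tuple[float, ...] = (0.3, 0.006, 1.5, 0.3),
    n_electrodes: int = 64,
    use_isa: bool = True,
) -> dict:
    """BEM-vs-analytic validation on meshed concentric spheres.

    Builds a four-layer icosphere head (``subdivision``: one level for all
    surfaces, or per surface outermost first), computes BEM and
    exact-series gains for radial and tangential dipoles at several
    eccentricities (fractions of the brain radius) and reports the
    worst-case RDM and MAG over dipoles, both solutions average-referenced
    over a scalp electrode set.
    """
    from .geometry import make_icosphere
    from .sphere_forward import SphericalModel, sphere_gain

    subs = (subdivision,) * 4 if isinstance(subdivision, int) else tuple(subdivision)
    surfaces = []
    for level, r in zip(subs, radii):
        ico = make_icosphere(level, 1.0)
        surfaces.append(TriSurface(ico.vertices * r, ico.triangles.copy()))
    head = HeadModel(surfaces, conductivities, units="relative")
    model = SphericalModel(radii=radii, conductivities=conductivities)

    elecs = _fibonacci_electrodes(n_electrodes, radii[0])
    montage_pos = elecs

    positions = []
    orientations = []
    z = np.array([0.0, 0.0, 1.0])
    t = np.array([1.0, 0.0, 0.0])
    for ecc in eccentricities:
        pos = z * (ecc * radii[-1])
        positions += [pos, pos]
        orientations += [z, t]
    sources = SourceSpace(np.array(positions), np.array(orientations))

    op = assemble_bem(head, BemOptions(use_isa=use_isa))
    g_bem = bem_gain(op, sources, montage_pos, reference="average")
    g_ana = sphere_gain(model, sources, montage_pos, reference="average")

    rdms = []
    mags = []
    for d in range(len(sources)):
        rdms.append(rdm(g_bem.values[:, d], g_ana.values[:, d]))
        mags.append(mag(g_bem.values[:, d], g_ana.values[:, d]))
    return {
        "rdm": rdms,
        "mag": mags,
        "rdm_max": float(np.max(rdms)),
        "mag_min": float(np.min(mags)),
        "mag_max": float(np.max(mags)),
        "eccentricities": [e for e in eccentricities for _ in (0, 1)],
    }


def _fibonacci_electrodes(n: int, radius: float) -> np.ndarray:
    from .geometry import _fibonacci_directions

    return _fibonacci_directions(n) * radius
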