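"""Geometry: meshes, synthetic head, shrinkage transform, CSF thickness."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from atrophysim.geometry import (
    HeadModel,
    SourceSpace,
    SyntheticHeadConfig,
    TriSurface,
    csf_thickness,
    load_surface,
    make_icosphere,
    make_synthetic_head,
    median_centroid,
    min_distance_to_surface,
    points_inside,
    save_surface,
    shrink,
    shrink_source_space,
)


# ---------------------------------------------------------------------------
# icosphere
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "level, n_vertices, n_triangles",
    [(0, 12, 20), (1, 42, 80), (3, 642, 1280), (4, 2562, 5120)],
)
def test_icosphere_counts(level, n_vertices, n_triangles):
    surf = make_icosphere(level, 1.0)
    assert surf.n_vertices == 10 * 4**level + 2 == n_vertices
    assert surf.n_triangles == n_triangles
    surf.validate()


def test_icosphere_projection_radius():
    surf = make_icosphere(3, 2.0)
    radii = np.linalg.norm(surf.vertices, axis=1)
    assert np.abs(radii - 2.0).max() < 1e-12


def test_icosphere_level_guards():
    with pytest.raises(ValueError):
        make_icosphere(-1)
    with pytest.raises(ValueError):
        make_icosphere(99)


# ---------------------------------------------------------------------------
# TriSurface validation
# ---------------------------------------------------------------------------

def test_reversed_triangle_rejected():
    surf = make_icosphere(1, 1.0)
    tris = surf.triangles.copy()
    tris[0] = tris[0][::-1]
    with pytest.raises(ValueError):
        TriSurface(surf.vertices, tris).validate()


def test_open_mesh_rejected():
    surf = make_icosphere(1, 1.0)
    with pytest.raises(ValueError):
        TriSurface(surf.vertices, surf.triangles[:-1]).validate()


def test_inward_orientation_rejected():
    surf = make_icosphere(1, 1.0)
    flipped = surf.triangles[:, [0, 2, 1]]
    with pytest.raises(ValueError, match="orientation"):
        TriSurface(surf.vertices, flipped).validate()


def test_signed_volume_approximates_sphere():
    surf = make_icosphere(4, 1.0)
    assert surf.signed_volume() == pytest.approx(4.0 / 3.0 * np.pi, rel=3e-3)


# ---------------------------------------------------------------------------
# median centroid
# ---------------------------------------------------------------------------

def test_median_centroid_coordinatewise_odd_count():
    pts = np.array([[0, 0, 0], [2, 0, 0], [4, 10, -6]], dtype=float)
    assert np.array_equal(median_centroid(pts), [2, 0, 0])


def test_median_centroid_symmetric_set():
    rng = np.random.default_rng(0)
    half = rng.normal(size=(50, 3))
    pts = np.vstack([half, -half])
    for method in ("coordinate", "mean", "geometric"):
        assert np.abs(median_centroid(pts, method)).max() < 1e-9


def test_median_centroid_icosphere_is_origin():
    pts = make_icosphere(4, 1.0).vertices
    assert np.abs(median_centroid(pts)).max() < 1e-9


def test_geometric_median_against_scipy():
    from scipy.optimize import minimize

    rng = np.random.default_rng(3)
    pts = rng.normal(size=(15, 3)) * [2.0, 1.0, 0.5]
    ours = median_centroid(pts, "geometric")
    obj = lambda c: np.linalg.norm(pts - c, axis=1).sum()
    ref = minimize(obj, pts.mean(axis=0), method="Nelder-Mead",
                   options={"xatol": 1e-10, "fatol": 1e-12}).x
    assert np.linalg.norm(ours - ref) < 1e-5


def test_median_centroid_empty_errors():
    with pytest.raises(ValueError):
        median_centroid(np.empty((0, 3)))


# ---------------------------------------------------------------------------
# shrink
# ---------------------------------------------------------------------------

def test_shrink_examples():
    pts = np.array([[10.0, 0.0, 0.0]])
    assert np.array_equal(shrink(pts, np.zeros(3), 0.0), pts)
    assert np.allclose(shrink(pts, np.zeros(3), 0.30), [[7.0, 0.0, 0.0]])
    with pytest.raises(ValueError):
        shrink(pts, np.zeros(3), 1.0)
    with pytest.raises(ValueError):
        shrink(pts, np.zeros(3), -0.1)


def test_shrink_sphere_radii():
    pts = make_icosphere(2, 3.0).vertices
    out = shrink(pts, np.zeros(3), 0.05)
    assert np.allclose(np.linalg.norm(out, axis=1), 0.95 * 3.0)


@settings(deadline=None, max_examples=30)
@given(
    s1=st.floats(0.0, 0.5),
    s2=st.floats(0.0, 0.5),
    seed=st.integers(0, 2**16),
)
def test_shrink_composition_law(s1, s2, seed):
    """shrink(s1) then shrink(s2) about one centre equals a single shrink by
    1 - (1-s1)(1-s2)."""
    rng = np.random.default_rng(seed)
    pts = rng.normal(size=(8, 3))
    center = rng.normal(size=3)
    combined = 1.0 - (1.0 - s1) * (1.0 - s2)
    twice = shrink(shrink(pts, center, s1), center, s2)
    once = shrink(pts, center, combined)
    assert np.abs(twice - once).max() < 1e-12


def test_shrink_source_space_keeps_orientations():
    dirs = make_icosphere(1, 1.0).vertices
    src = SourceSpace(dirs * 0.7, dirs)
    shrunk = shrink_source_space(src, np.zeros(3), 0.2)
    assert np.array_equal(shrunk.orientations, src.orientations)
    assert np.allclose(np.linalg.norm(shrunk.positions, axis=1), 0.8 * 0.7)
    assert len(shrunk) == len(src)


# ---------------------------------------------------------------------------
# CSF thickness
# ---------------------------------------------------------------------------

def test_csf_thickness_concentric_spheres():
    csf = make_icosphere(3, 83.0)
    pial = make_icosphere(3, 78.0)
    # vertex-to-surface distance between concentric icospheres: the nearest
    # inner point sits slightly inside the inner vertex radius (flat facets),
    # so the mean is 5 mm to facet-sag accuracy
    assert csf_thickness(csf, pial) == pytest.approx(5.0, abs=0.05)


def test_csf_thickness_grows_with_shrinkage():
    csf = make_icosphere(2, 83.0)
    vals = []
    for s in (0.0, 0.1, 0.2):
        pial = make_icosphere(2, (1 - s) * 78.0)
        vals.append(csf_thickness(csf, pial))
    assert vals[0] < vals[1] < vals[2]
    # closed form for concentric spheres: r_csf - (1-s) r_pial
    assert vals[2] == pytest.approx(83.0 - 0.8 * 78.0, abs=0.2)


def test_point_to_surface_distance_constrained_optimizer_oracle(small_synthetic_head):
    """The exact point-to-triangle scan agrees with an independent oracle:
    per-triangle constrained quadratic minimization (SLSQP) over the nearest
    candidate triangles, on the perturbed head."""
    from scipy.optimize import minimize

    head, _, _ = small_synthetic_head
    csf, pial = head.surfaces[2], head.surfaces[3]
    ours = min_distance_to_surface(csf.vertices, pial)
    p0, p1, p2 = pial.triangle_corners()
    centroids = (p0 + p1 + p2) / 3.0
    rng = np.random.default_rng(0)
    for i in rng.choice(len(csf.vertices), size=15, replace=False):
        x = csf.vertices[i]
        cand = np.argsort(np.linalg.norm(centroids - x, axis=1))[:12]
        best = np.inf
        for t in cand:
            e1, e2 = p1[t] - p0[t], p2[t] - p0[t]
            obj = lambda uv: np.sum((p0[t] + uv[0] * e1 + uv[1] * e2 - x) ** 2)
            res = minimize(obj, [1 / 3, 1 / 3], method="SLSQP",
                           bounds=[(0, 1), (0, 1)],
                           constraints=[{"type": "ineq", "fun": lambda uv: 1 - uv[0] - uv[1]}],
                           options={"ftol": 1e-14, "maxiter": 200})
            best = min(best, np.sqrt(res.fun))
        assert abs(ours[i] - best) < 5e-7


def test_csf_thickness_rejects_poking_surface():
    outer = make_icosphere(2, 78.0)
    inner = make_icosphere(2, 83.0)  # swapped: "inner" surface is outside
    with pytest.raises(ValueError, match="pokes"):
        csf_thickness(outer, inner)


# ---------------------------------------------------------------------------
# synthetic head generator
# ---------------------------------------------------------------------------

def test_zero_perturbation_gives_concentric_spheres():
    cfg = SyntheticHeadConfig(seed=7, perturb_amplitude=0.0, subdivision=2,
                              source_subdivision=2)
    head, src, mon = make_synthetic_head(cfg)
    r = np.linalg.norm(head.surfaces[0].vertices, axis=1)
    assert np.abs(r - 100.0).max() < 1e-9
    assert np.allclose(np.linalg.norm(src.positions, axis=1), 0.93 * 78.0)


def test_synthetic_head_deterministic(small_synthetic_head):
    head, src, mon = small_synthetic_head
    head2, src2, mon2 = make_synthetic_head(
        SyntheticHeadConfig(seed=1, subdivision=2, source_subdivision=3)
    )
    for a, b in zip(head.surfaces, head2.surfaces):
        assert np.array_equal(a.vertices, b.vertices)
    assert np.array_equal(src.positions, src2.positions)
    assert np.array_equal(mon.positions, mon2.positions)
    assert mon.adjacency == mon2.adjacency


def test_synthetic_montage_on_skin_with_bounded_adjacency(small_synthetic_head):
    head, _, mon = small_synthetic_head
    assert len(mon) == 128
    dist = min_distance_to_surface(mon.positions, head.surfaces[0])
    assert dist.max() < 1e-6 * 100.0
    sizes = {len(a) for a in mon.adjacency}
    assert sizes <= {4, 5, 6, 7}
    for i, nbrs in enumerate(mon.adjacency):  # symmetry
        for j in nbrs:
            assert i in mon.adjacency[j]


def test_synthetic_head_nested_and_sources_inside(small_synthetic_head):
    head, src, _ = small_synthetic_head
    head.validate(min_gap=1.0)
    assert points_inside(head.surfaces[3], src.positions).all()
    norms = np.linalg.norm(src.orientations, axis=1)
    assert np.abs(norms - 1.0).max() < 1e-12


def test_excessive_perturbation_raises():
    cfg = SyntheticHeadConfig(seed=0, perturb_amplitude=0.95, subdivision=2,
                              source_subdivision=2)
    with pytest.raises(ValueError, match="synthetic head"):
        make_synthetic_head(cfg)


# ---------------------------------------------------------------------------
# HeadModel invariants
# ---------------------------------------------------------------------------

def test_head_model_requires_positive_sigma_and_four_surfaces():
    ico = make_icosphere(1, 1.0)
    surfs = [TriSurface(ico.vertices * r, ico.triangles.copy())
             for r in (1.0, 0.9, 0.83, 0.78)]
    with pytest.raises(ValueError):
        HeadModel(surfs, (0.3, -1.0, 1.5, 0.3))
    with pytest.raises(ValueError):
        HeadModel(surfs[:3], (0.3, 0.006, 1.5))


def test_head_model_detects_non_nesting():
    ico = make_icosphere(1, 1.0)
    surfs = [TriSurface(ico.vertices * r, ico.triangles.copy())
             for r in (1.0, 0.9, 0.95, 0.78)]  # third surface outside second
    with pytest.raises(ValueError, match="not strictly inside"):
        HeadModel(surfs, (0.3, 0.006, 1.5, 0.3)).validate()


def test_points_inside_winding_number():
    surf = make_icosphere(2, 1.0)
    pts = np.array([[0.0, 0.0, 0.0], [0.5, 0.2, -0.3], [1.5, 0.0, 0.0], [0.0, 2.0, 0.0]])
    assert list(points_inside(surf, pts)) == [True, True, False, False]


# ---------------------------------------------------------------------------
# mesh I/O
# ---------------------------------------------------------------------------

def test_off_roundtrip_preserves_vertex_order(tmp_path):
    surf = make_icosphere(2, 83.0)
    path = tmp_path / "s.off"
    save_surface(surf, str(path))
    back = load_surface(str(path))
    assert np.array_equal(surf.vertices, back.vertices)
    assert np.array_equal(surf.triangles, back.triangles)


@pytest.mark.parametrize("fmt", ["stl", "stl_ascii"])
def test_stl_roundtrip_preserves_geometry(tmp_path, fmt):
    surf = make_icosphere(1, 1.0)
    path = tmp_path / "s.stl"
    save_surface(surf, str(path), file_format=fmt)
    back = load_surface(str(path))
    assert back.n_vertices == surf.n_vertices
    assert back.n_triangles == surf.n_triangles
    # same vertex set (STL is a triangle soup; indexing may be permuted)
    a = np.sort(np.round(surf.vertices, 6).view([("x", float), ("y", float), ("z", float)]), axis=0)
    b = np.sort(np.round(back.vertices, 6).view([("x", float), ("y", float), ("z", float)]), axis=0)
    assert np.array_equal(a, b)
    # STL stores float32 coordinates
    assert abs(back.signed_volume() - surf.signed_volume()) < 1e-5
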